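"""Shared test utilities: tiny randomized scenes and brute-force oracles."""

from __future__ import annotations

import numpy as np

from bifor.segmentation import LocusROI, NucleusMask


def region_objects(nucleus_mask: np.ndarray, locus_mask: np.ndarray, red: np.ndarray | None = None):
    """Wrap raw boolean masks into the region dataclasses the statistic takes."""
    nucleus = NucleusMask(
        mask=nucleus_mask,
        area=int(nucleus_mask.sum()),
        centroid=tuple(np.argwhere(nucleus_mask).mean(axis=0)),
        touches_border=False,
    )
    if red is None:
        red = np.zeros(nucleus_mask.shape)
    locus = LocusROI(
        mask=locus_mask,
        core_mask=locus_mask,
        centroid=tuple(np.argwhere(locus_mask).mean(axis=0)),
        peak_red_intensity=float(np.max(red[locus_mask])) if locus_mask.any() else 0.0,
        n_candidate_foci=1,
    )
    return nucleus, locus


def make_toy_scene(rng: np.random.Generator, force_max_in_locus: bool | None = None):
    """Random toy scene (<= 32x32): green image, nucleus mask, locus subset.

    When ``force_max_in_locus`` is True the nucleus-global maximum voxel is
    moved inside the locus, when False it is moved outside; None leaves it
    wherever it fell.
    """
    shape = (int(rng.integers(6, 33)), int(rng.integers(6, 33)))
    green = rng.uniform(0.0, 1000.0, size=shape)
    nucleus = np.zeros(shape, bool)
    # random rectangle covering at least a 3x3 area
    y0 = int(rng.integers(0, shape[0] - 3))
    x0 = int(rng.integers(0, shape[1] - 3))
    y1 = int(rng.integers(y0 + 3, shape[0] + 1))
    x1 = int(rng.integers(x0 + 3, shape[1] + 1))
    nucleus[y0:y1, x0:x1] = True
    coords = np.argwhere(nucleus)
    n_locus = int(rng.integers(1, max(2, len(coords) // 3)))
    chosen = coords[rng.choice(len(coords), size=n_locus, replace=False)]
    locus = np.zeros(shape, bool)
    locus[tuple(chosen.T)] = True

    masked = np.where(nucleus, green, -np.inf)
    gmax = np.unravel_index(np.argmax(masked), shape)
    if force_max_in_locus is True and not locus[gmax]:
        target = tuple(chosen[0])
        green[target] = green[gmax] + 1.0
    elif force_max_in_locus is False and locus[gmax]:
        outside = coords[~locus[tuple(coords.T)]]
        if len(outside) == 0:  # locus covers the nucleus; cannot move max out
            return make_toy_scene(rng, force_max_in_locus)
        target = tuple(outside[0])
        green[target] = green[gmax] + 1.0
    return green, nucleus, locus


def brute_force_ratio(green: np.ndarray, nucleus: np.ndarray, locus: np.ndarray) -> float:
    """Independent oracle: explicit voxel scan for both maxima."""
    locus_max = -np.inf
    nucleus_max = -np.inf
    for idx in np.ndindex(green.shape):
        if nucleus[idx]:
            nucleus_max = max(nucleus_max, float(green[idx]))
        if locus[idx]:
            locus_max = max(locus_max, float(green[idx]))
    return locus_max / nucleus_max


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 1.0
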