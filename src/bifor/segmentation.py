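"""Nucleus segmentation (DAPI) and locus-focus detection (red channel).

These two stages delimit the two regions the enrichment statistic is computed
over: the whole nucleus, and the ParB-labelled locus focus inside it. The
locus ROI is always re-intersected with the nucleus mask, so ``LocusROI ⊆
NucleusMask`` holds on every return.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .errors import NoLocusFound, NoNucleusFound

DEFAULT_SMOOTHING_SIGMA = 2.0
DEFAULT_MIN_NUCLEUS_SIZE = 500
DEFAULT_THRESHOLD_QUANTILE = 0.995
DEFAULT_DILATION_RADIUS = 2


@dataclass
class NucleusMask:
    """The whole-nucleus region, from DAPI."""

    mask: np.ndarray
    area: int
    centroid: tuple[float, ...]
    touches_border: bool

    def validate(self) -> None:
        if not self.mask.any():
            raise NoNucleusFound("empty nucleus mask")


@dataclass
class LocusROI:
    """The locus-focus region, from the red (ParB-mCherry) channel.

    ``core_mask`` is the thresholded focus before dilation; ``mask`` is the
    dilated ROI re-intersected with the nucleus. ``n_candidate_foci`` counts
    all above-threshold components (a healthy scene has exactly one).
    """

    mask: np.ndarray
    core_mask: np.ndarray
    centroid: tuple[float, ...]
    peak_red_intensity: float
    n_candidate_foci: int


def _ball_footprint(radius: int, ndim: int) -> np.ndarray:
    r = int(radius)
    grids = np.meshgrid(*([np.arange(-r, r + 1)] * ndim), indexing="ij")
    return sum(g**2 for g in grids) <= r**2


def segment_nucleus(
    dapi: np.ndarray,
    min_size: int = DEFAULT_MIN_NUCLEUS_SIZE,
    smoothing_sigma: float = DEFAULT_SMOOTHING_SIGMA,
) -> NucleusMask:
    """Segment the (single) nucleus from the DAPI channel.

    The channel is Gaussian-smoothed, thresholded with Otsu's method, holes
    are filled, components smaller than ``min_size`` voxels are dropped, and
    the largest remaining connected component is returned.

    Raises :class:`NoNucleusFound` for constant/zero input or when nothing
    survives the size filter.
    """
    dapi = np.asarray(dapi)
    if dapi.ndim not in (2, 3):
        raise ValueError(f"expected 2D or 3D channel, got {dapi.ndim}D")
    if not dapi.size or float(dapi.max()) == float(dapi.min()):
        raise NoNucleusFound("DAPI channel is constant; nothing to segment")
    smoothed = ndi.gaussian_filter(dapi.astype(np.float32), smoothing_sigma)
    threshold = threshold_otsu(smoothed)
    foreground = smoothed > threshold
    if not foreground.any():
        raise NoNucleusFound("no voxel above the Otsu threshold")
    labels, n = ndi.label(foreground)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    sizes[sizes < min_size] = 0
    if not sizes.any():
        raise NoNucleusFound(f"no connected component of at least {min_size} voxels")
    best = int(np.argmax(sizes))
    bbox = ndi.find_objects(labels, max_label=best)[best - 1]
    mask = np.zeros(labels.shape, bool)
    mask[bbox] = ndi.binary_fill_holes(labels[bbox] == best)
    centroid_local = ndi.center_of_mass(mask[bbox])
    centroid = tuple(float(c + sl.start) for c, sl in zip(centroid_local, bbox))
    border = np.zeros(mask.shape, bool)
    for ax in range(mask.ndim):
        sl = [slice(None)] * mask.ndim
        for edge in (0, -1):
            sl[ax] = edge
            border[tuple(sl)] = True
    touches = bool((mask & border).any())
    return NucleusMask(mask=mask, area=int(mask.sum()), centroid=centroid, touches_border=touches)


def detect_locus(
    red: np.ndarray,
    nucleus: NucleusMask,
    threshold_quantile: float = DEFAULT_THRESHOLD_QUANTILE,
    dilation_radius: int = DEFAULT_DILATION_RADIUS,
) -> LocusROI:
    """Detect the brightest red focus inside the nucleus.

    In-nucleus voxels above the ``threshold_quantile`` of in-nucleus red
    intensities form candidate foci; the candidate with the highest peak
    intensity is kept (extra candidates are only counted — single-locus
    preparations should have one), dilated by ``dilation_radius`` voxels to
    absorb small chromatic/registration offsets, and re-intersected with the
    nucleus.

    Raises :class:`NoLocusFound` when no voxel exceeds the threshold; such
    nuclei are excluded from analysis upstream.
    """
    red = np.asarray(red)
    nucleus.validate()
    if red.shape != nucleus.mask.shape:
        raise ValueError("red channel and nucleus mask shapes differ")
    if not (0.0 < threshold_quantile < 1.0):
        raise ValueError(f"threshold_quantile must lie in (0,1), got {threshold_quantile}")
    inside = red[nucleus.mask]
    threshold = float(np.quantile(inside, threshold_quantile))
    candidates = (red > threshold) & nucleus.mask
    if not candidates.any():
        raise NoLocusFound(f"no in-nucleus voxel above quantile {threshold_quantile} (= {threshold:.3g})")
    labels, n = ndi.label(candidates)
    cand_labels = labels[candidates]
    cand_values = np.asarray(red[candidates], dtype=float)
    peaks = np.zeros(n)
    np.maximum.at(peaks, cand_labels - 1, cand_values)
    selected = int(np.argmax(peaks)) + 1
    core = labels == selected
    mask = core
    if dilation_radius > 0:
        r = int(dilation_radius)
        bbox = ndi.find_objects(labels, max_label=selected)[selected - 1]
        grown = tuple(
            slice(max(sl.start - r, 0), min(sl.stop + r, dim))
            for sl, dim in zip(bbox, red.shape)
        )
        mask = np.zeros(core.shape, bool)
        mask[grown] = ndi.binary_dilation(core[grown], structure=_ball_footprint(r, red.ndim))
    mask = mask & nucleus.mask
    assert mask.any() and not (mask & ~nucleus.mask).any()
    coords = np.argwhere(mask)
    weights = np.asarray(red[mask], dtype=float)
    total = float(weights.sum())
    if total > 0:
        centroid = tuple(float(c) for c in (coords * weights[:, None]).sum(axis=0) / total)
    else:  # uniform zero ROI cannot happen after thresholding, but stay safe
        centroid = tuple(float(c) for c in coords.mean(axis=0))
    return LocusROI(
        mask=mask,
        core_mask=core,
        centroid=centroid,
        peak_red_intensity=float(red[core].max()),
        n_candidate_foci=int(n),
    )
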