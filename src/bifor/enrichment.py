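"""The per-nucleus locus-enrichment statistic.

For each nucleus the statistic is

    E = max(green | locus ROI) / max(green | whole nucleus)

i.e. the maximum signal intensity measured on the labelled enhancer divided by
the maximum signal intensity measured in the whole nucleus. Because the locus
ROI is contained in the nucleus, E is bounded in (0, 1], and E = 1 exactly
when the locus contains a nucleus-global maximum voxel.

``strict_max`` is the default estimator. A literal maximum is sensitive to
Poisson shot noise, so a robust variant replacing both maxima by the
q-quantile (default q = 0.999) of the respective voxel sets is also provided;
the robust variant is not guaranteed to stay <= 1.

The statistic is computed on the raw noisy channel: no background subtraction
by default (an optional in-nucleus median subtraction, clipped at zero, can be
switched on), and no deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSignal,
    NoLocusFound,
    NoNucleusFound,
    NucleusTouchesBorder,
    PipelineError,
)
from .io import ImageStack, read_stack, validate_manifest
from .segmentation import (
    DEFAULT_DILATION_RADIUS,
    DEFAULT_MIN_NUCLEUS_SIZE,
    DEFAULT_SMOOTHING_SIGMA,
    DEFAULT_THRESHOLD_QUANTILE,
    LocusROI,
    NucleusMask,
    detect_locus,
    segment_nucleus,
)

SCORE_COLUMNS = ("scene_id", "condition", "replicate", "value",
                 "locus_max", "nucleus_max", "estimator", "qc")


@dataclass
class EnrichmentScore:
    """One nucleus's enrichment ratio with provenance."""

    value: float
    locus_max: float
    nucleus_max: float
    estimator: str
    scene_id: str = ""
    condition: str = ""
    replicate: int = 0
    qc: str = "ok"


@dataclass(frozen=True)
class QuantifyParams:
    """All tunables of the quantification stage (segmentation through scoring)."""

    smoothing_sigma: float = DEFAULT_SMOOTHING_SIGMA
    min_nucleus_size: int = DEFAULT_MIN_NUCLEUS_SIZE
    threshold_quantile: float = DEFAULT_THRESHOLD_QUANTILE
    dilation_radius: int = DEFAULT_DILATION_RADIUS
    estimator: str = "strict_max"  # or "quantile"
    quantile: float = 0.999
    exclude_border: bool = True
    background_subtract: bool = False


def enrichment_ratio(
    green: np.ndarray,
    locus: LocusROI,
    nucleus: NucleusMask,
    estimator: str = "strict_max",
    quantile: float = 0.999,
) -> EnrichmentScore:
    """Compute the enrichment ratio of one nucleus.

    Raises :class:`DegenerateSignal` when the whole-nucleus statistic is zero
    (no ratio is defined), and ``ValueError`` on an empty locus ROI (which
    should have surfaced upstream as :class:`NoLocusFound`).
    """
    green = np.asarray(green)
    nucleus.validate()
    if green.shape != nucleus.mask.shape:
        raise ValueError("green channel and nucleus mask shapes differ")
    if (locus.mask & ~nucleus.mask).any():
        raise ValueError("locus ROI extends outside the nucleus mask")
    locus_voxels = green[locus.mask]
    if locus_voxels.size == 0:
        raise ValueError("empty locus ROI (should have been NoLocusFound upstream)")
    nucleus_voxels = green[nucleus.mask]
    if estimator == "strict_max":
        locus_stat = float(locus_voxels.max())
        nucleus_stat = float(nucleus_voxels.max())
        label = "strict_max"
    elif estimator == "quantile":
        locus_stat = float(np.quantile(locus_voxels, quantile))
        nucleus_stat = float(np.quantile(nucleus_voxels, quantile))
        label = f"quantile({quantile})"
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if nucleus_stat <= 0:
        raise DegenerateSignal("whole-nucleus signal statistic is zero")
    return EnrichmentScore(
        value=locus_stat / nucleus_stat,
        locus_max=locus_stat,
        nucleus_max=nucleus_stat,
        estimator=label,
    )


def score_stack(stack: ImageStack, params: QuantifyParams = QuantifyParams()) -> EnrichmentScore:
    """Run segmentation, locus detection and scoring on one stack.

    Raises the stage-specific exclusion errors (:class:`NoNucleusFound`,
    :class:`NoLocusFound`, :class:`NucleusTouchesBorder`,
    :class:`DegenerateSignal`); callers treat these as per-nucleus exclusions.
    """
    for role in ("dapi", "red", "green"):
        if role not in stack.channels:
            raise PipelineError(f"stack lacks required channel {role!r}")
    nucleus = segment_nucleus(
        stack.channels["dapi"],
        min_size=params.min_nucleus_size,
        smoothing_sigma=params.smoothing_sigma,
    )
    if params.exclude_border and nucleus.touches_border:
        raise NucleusTouchesBorder("nucleus touches the image border; maxima may be truncated")
    locus = detect_locus(
        stack.channels["red"],
        nucleus,
        threshold_quantile=params.threshold_quantile,
        dilation_radius=params.dilation_radius,
    )
    green = np.asarray(stack.channels["green"], dtype=np.float64)
    if params.background_subtract:
        green = np.clip(green - float(np.median(green[nucleus.mask])), 0.0, None)
    score = enrichment_ratio(green, locus, nucleus,
                             estimator=params.estimator, quantile=params.quantile)
    if locus.n_candidate_foci > 1:
        score.qc = f"multi_foci:{locus.n_candidate_foci}"
    return score


def score_dataset(
    manifest: pd.DataFrame,
    params: QuantifyParams = QuantifyParams(),
    root: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every scene listed in a manifest.

    Returns ``(scores, exclusions)``: one score row per analyzable nucleus,
    and one exclusion row (scene_id, condition, replicate, reason) per scene
    that could not be scored. Row-level read errors are recorded and the run
    continues; if every scene fails, a :class:`PipelineError` is raised.
    """
    manifest = validate_manifest(manifest)
    rows, excluded = [], []
    for rec in manifest.itertuples(index=False):
        path = Path(rec.path)
        if root is not None and not path.is_absolute():
            path = Path(root) / path
        try:
            stack = read_stack(path)
            score = score_stack(stack, params)
        except (NoNucleusFound, NoLocusFound, NucleusTouchesBorder, DegenerateSignal,
                FileNotFoundError, OSError) as exc:
            excluded.append(
                {"scene_id": rec.scene_id, "condition": rec.condition,
                 "replicate": rec.replicate, "reason": f"{type(exc).__name__}: {exc}"}
            )
            continue
        rows.append(
            {"scene_id": rec.scene_id, "condition": rec.condition, "replicate": rec.replicate,
             "value": score.value, "locus_max": score.locus_max, "nucleus_max": score.nucleus_max,
             "estimator": score.estimator, "qc": score.qc}
        )
    if len(manifest) and not rows:
        raise PipelineError("every scene in the manifest failed to score")
    scores = pd.DataFrame(rows, columns=list(SCORE_COLUMNS))
    exclusions = pd.DataFrame(excluded, columns=["scene_id", "condition", "replicate", "reason"])
    return scores, exclusions
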