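"""End-to-end orchestration: simulate -> quantify -> compare.

A run is driven by a :class:`RunConfig` (serializable to YAML); a run
directory holds everything needed to audit and replay it: the resolved
config, the manifest, the score table, the comparison and replicate-summary
tables, a JSON log of parameters / exclusions / versions, and an advisory
summary figure. Outputs are deterministic under a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .enrichment import QuantifyParams, score_dataset, score_stack
from .errors import ConfigError, PipelineError
from .io import CHANNEL_ROLES, validate_manifest, write_manifest
from .stats import compare_replicate_means, run_condition_matrix, summarize_by_replicate
from .synthetic import PRESETS, SceneSpec, generate_condition_dataset, generate_scene, sample_scene_specs

#: Pairwise contrasts of the seven-condition experiment: each enriched
#: condition against its matched unenriched controls.
DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("SCR_EXD_WT", "SCR_ALONE_WT"),
    ("SCR_EXD_WT", "UBX_EXD_WT"),
    ("SCR_EXD_WT", "SCR_EXD_MUT"),
    ("UBX_EXD_WT", "UBX_ALONE_WT"),
    ("SCR_EXD_MUT", "SCR_ALONE_WT"),
    ("SCR_EXD_CONS", "SCR_EXD_MUT"),
    ("UBX_EXD_CONS", "UBX_EXD_WT"),
)


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    outdir: str = "bifor_run"
    seed: int = 0
    ndim: int = 2
    presets: tuple[str, ...] = tuple(PRESETS)
    n_nuclei_per_replicate: int = 10
    n_replicates: int = 3
    channel_order: tuple[str, ...] = CHANNEL_ROLES
    smoothing_sigma: float = 2.0
    min_nucleus_size: int = 500
    threshold_quantile: float = 0.995
    dilation_radius: int = 2
    estimator: str = "strict_max"
    quantile: float = 0.999
    exclude_border: bool = True
    background_subtract: bool = False
    test: str = "mannwhitney"
    n_permutations: int = 10_000
    holm: bool = False
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS
    write_masks: bool = False

    def quantify_params(self) -> QuantifyParams:
        return QuantifyParams(
            smoothing_sigma=self.smoothing_sigma,
            min_nucleus_size=self.min_nucleus_size,
            threshold_quantile=self.threshold_quantile,
            dilation_radius=self.dilation_radius,
            estimator=self.estimator,
            quantile=self.quantile,
            exclude_border=self.exclude_border,
            background_subtract=self.background_subtract,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["presets"] = list(self.presets)
        d["channel_order"] = list(self.channel_order)
        d["comparisons"] = [list(pair) for pair in self.comparisons]
        return d


def validate_config(config: dict | RunConfig | None = None) -> RunConfig:
    """Fill defaults, check ranges, reject unknown keys.

    Accepts a plain mapping (e.g. loaded from YAML), an existing
    :class:`RunConfig`, or ``None`` for the all-defaults configuration.
    """
    if config is None:
        config = {}
    if isinstance(config, RunConfig):
        config = config.to_dict()
    if not isinstance(config, dict):
        raise ConfigError(f"config must be a mapping, got {type(config).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(config) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**{k: v for k, v in config.items()})

    if cfg.channel_order is None or tuple(cfg.channel_order) != CHANNEL_ROLES:
        raise ConfigError(
            f"channel_order must name the channels {list(CHANNEL_ROLES)} in order, got {cfg.channel_order!r}"
        )
    if cfg.ndim not in (2, 3):
        raise ConfigError(f"ndim must be 2 or 3, got {cfg.ndim}")
    if not (0.0 < cfg.threshold_quantile < 1.0):
        raise ConfigError(f"threshold_quantile must lie in (0,1), got {cfg.threshold_quantile}")
    if not (0.0 < cfg.quantile <= 1.0):
        raise ConfigError(f"quantile must lie in (0,1], got {cfg.quantile}")
    if cfg.dilation_radius < 0:
        raise ConfigError(f"dilation_radius must be >= 0, got {cfg.dilation_radius}")
    if cfg.smoothing_sigma < 0:
        raise ConfigError(f"smoothing_sigma must be >= 0, got {cfg.smoothing_sigma}")
    if cfg.min_nucleus_size < 0:
        raise ConfigError(f"min_nucleus_size must be >= 0, got {cfg.min_nucleus_size}")
    if cfg.n_nuclei_per_replicate < 0 or cfg.n_replicates < 0:
        raise ConfigError("n_nuclei_per_replicate and n_replicates must be >= 0")
    if cfg.estimator not in ("strict_max", "quantile"):
        raise ConfigError(f"estimator must be 'strict_max' or 'quantile', got {cfg.estimator!r}")
    if cfg.test not in ("mannwhitney", "permutation"):
        raise ConfigError(f"test must be 'mannwhitney' or 'permutation', got {cfg.test!r}")
    if cfg.n_permutations < 100:
        raise ConfigError("n_permutations must be >= 100")
    for name in cfg.presets:
        if name not in PRESETS:
            raise ConfigError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    cfg.presets = tuple(cfg.presets)
    cfg.channel_order = tuple(cfg.channel_order)
    cfg.comparisons = tuple((str(a), str(b)) for a, b in cfg.comparisons)
    for a, b in cfg.comparisons:
        for name in (a, b):
            if name not in cfg.presets:
                raise ConfigError(f"comparison names condition {name!r} not in presets")
    return cfg


def base_spec_for(config: RunConfig) -> SceneSpec:
    if config.ndim == 2:
        return SceneSpec()
    return SceneSpec(
        shape=(32, 256, 256),
        voxel_size=(0.2, 0.06, 0.06),
        nucleus_axes=(10.0, 85.0, 105.0),
        locus_center=(15.5, 128.0, 150.0),
        locus_sigma=(1.5, 3.0, 3.0),
        psf_sigma=(1.2, 0.85, 0.85),
    )


def simulate_condition_scores(
    preset_name: str,
    n_nuclei_per_replicate: int,
    n_replicates: int,
    seed: int,
    params: QuantifyParams = QuantifyParams(),
    base: SceneSpec | None = None,
) -> pd.DataFrame:
    """Simulate one condition and score every nucleus in memory.

    This is the disk-free path through the identical generation and
    quantification code; it backs the power and calibration studies where
    writing tens of thousands of TIFFs would be pointless.
    """
    from .errors import BiforError

    preset = PRESETS[preset_name]
    rows = []
    for scene_id, rep, spec in sample_scene_specs(preset, n_nuclei_per_replicate, n_replicates, seed, base):
        stack, _ = generate_scene(spec)
        try:
            score = score_stack(stack, params)
        except BiforError:
            continue
        rows.append({"scene_id": scene_id, "condition": preset_name, "replicate": rep,
                     "value": score.value, "locus_max": score.locus_max,
                     "nucleus_max": score.nucleus_max, "estimator": score.estimator,
                     "qc": score.qc})
    return pd.DataFrame(rows, columns=["scene_id", "condition", "replicate", "value",
                                       "locus_max", "nucleus_max", "estimator", "qc"])


def simulate_experiment_scores(
    presets: Sequence[str],
    n_nuclei_per_replicate: int,
    n_replicates: int,
    seed: int,
    params: QuantifyParams = QuantifyParams(),
    base: SceneSpec | None = None,
) -> pd.DataFrame:
    """In-memory multi-condition experiment (concatenated score tables)."""
    tables = [
        simulate_condition_scores(name, n_nuclei_per_replicate, n_replicates, seed, params, base)
        for name in presets
    ]
    return pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()


def _plot_scores(scores: pd.DataFrame, comparisons: pd.DataFrame, path: Path) -> None:
    """Advisory summary figure: per-condition score distributions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conditions = list(dict.fromkeys(scores["condition"]))
    fig, ax = plt.subplots(figsize=(1.2 * max(len(conditions), 4) + 2, 4.5))
    rng = np.random.default_rng(0)  # jitter only; cosmetic
    for i, cond in enumerate(conditions):
        vals = scores.loc[scores["condition"] == cond, "value"].to_numpy()
        x = i + rng.uniform(-0.18, 0.18, size=vals.size)
        ax.plot(x, vals, "o", ms=3, alpha=0.5)
        if vals.size:
            ax.hlines(np.median(vals), i - 0.28, i + 0.28, color="k", lw=2)
    ax.set_xticks(range(len(conditions)))
    ax.set_xticklabels(conditions, rotation=45, ha="right")
    ax.set_ylabel("enrichment ratio (locus max / nucleus max)")
    ax.set_ylim(0, 1.08)
    lines = [
        f"{r.condition_a} vs {r.condition_b}: p={r.p_value:.2e} {r.label}"
        if r.p_value is not None and not np.isnan(r.p_value)
        else f"{r.condition_a} vs {r.condition_b}: insufficient"
        for r in comparisons.itertuples(index=False)
    ]
    ax.set_title("\n".join(lines), fontsize=7, loc="left")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: dict | RunConfig | None, outdir: str | Path | None = None) -> Path:
    """Run simulate -> quantify -> compare and write the run directory.

    Any stage's fatal error is re-raised as :class:`PipelineError` naming the
    stage. Returns the run directory path.
    """
    cfg = validate_config(config)
    rundir = Path(outdir) if outdir is not None else Path(cfg.outdir)
    rundir.mkdir(parents=True, exist_ok=True)
    with open(rundir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)

    base = base_spec_for(cfg)

    try:
        manifests = []
        for name in cfg.presets:
            _, manifest = generate_condition_dataset(
                PRESETS[name], cfg.n_nuclei_per_replicate, cfg.n_replicates, cfg.seed,
                rundir / "scenes" / name, base=base, write_masks=cfg.write_masks,
            )
            manifests.append(manifest)
        manifest = (
            validate_manifest(pd.concat(manifests, ignore_index=True))
            if manifests else pd.DataFrame()
        )
        write_manifest(manifest, rundir / "manifest.csv")
    except Exception as exc:
        raise PipelineError(f"simulate stage failed: {exc}") from exc

    try:
        scores, exclusions = score_dataset(manifest, cfg.quantify_params())
        scores.to_csv(rundir / "scores.csv", index=False)
        exclusions.to_csv(rundir / "exclusions.csv", index=False)
    except Exception as exc:
        raise PipelineError(f"quantify stage failed: {exc}") from exc

    try:
        comparisons = run_condition_matrix(
            scores, cfg.comparisons, test=cfg.test, holm=cfg.holm,
            n_permutations=cfg.n_permutations, seed=cfg.seed,
        )
        comparisons.to_csv(rundir / "comparisons.csv", index=False)
        replicate_summary = summarize_by_replicate(scores)
        replicate_summary.to_csv(rundir / "replicate_summary.csv", index=False)
        rep_rows = []
        for a, b in cfg.comparisons:
            r = compare_replicate_means(scores, a, b)
            rep_rows.append({"condition_a": a, "condition_b": b, "n_a": r.n_a, "n_b": r.n_b,
                             "test": r.test_name, "statistic": r.statistic,
                             "p_value": r.p_value, "label": r.label})
        pd.DataFrame(rep_rows).to_csv(rundir / "replicate_comparisons.csv", index=False)
    except Exception as exc:
        raise PipelineError(f"compare stage failed: {exc}") from exc

    try:
        figdir = rundir / "figures"
        figdir.mkdir(exist_ok=True)
        if len(scores):
            _plot_scores(scores, comparisons, figdir / "scores.png")
    except Exception as exc:
        raise PipelineError(f"report stage failed: {exc}") from exc

    import bifor

    log = {
        "package_version": bifor.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "parameters": cfg.to_dict(),
        "n_scenes": int(len(manifest)),
        "n_scored": int(len(scores)),
        "exclusions": exclusions.to_dict(orient="records"),
    }
    with open(rundir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return rundir
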