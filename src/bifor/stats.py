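"""Between-condition comparison of per-nucleus enrichment scores.

The default test is the two-sided Mann-Whitney U on per-nucleus scores, a
robust choice for a bounded ratio with ties at 1. A seeded permutation test
on the difference of group means serves as the reference implementation; on
small groups it enumerates every label assignment exactly.

Significance labels follow the convention
``"***"`` for p <= 1e-4, ``"*"`` for 1e-4 < p <= 0.01, ``"ns"`` otherwise
(no intermediate tier is defined).

Per-nucleus scores pooled across replicates are the primary experimental
unit; a replicate-mean-level comparison (Welch's t on the per-replicate mean
scores) is always available alongside, since with few biological replicates
the two analyses can disagree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ManifestError

ALPHA_STAR = 0.01
ALPHA_TRIPLE_STAR = 1e-4

DEFAULT_N_PERMUTATIONS = 10_000

_TIE_EPS = 1e-12


def significance_label(p: float) -> str:
    """Map a p-value to the study's star convention."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value out of range: {p}")
    if p <= ALPHA_TRIPLE_STAR:
        return "***"
    if p <= ALPHA_STAR:
        return "*"
    return "ns"


@dataclass
class ComparisonResult:
    """Outcome of one two-condition comparison."""

    condition_a: str
    condition_b: str
    n_a: int
    n_b: int
    n_replicates: int
    statistic: float | None
    p_value: float | None
    label: str | None
    test_name: str
    insufficient: bool = False


def _perm_pvalue(a: np.ndarray, b: np.ndarray, n_permutations: int, seed: int) -> tuple[float, float, str]:
    """Two-sided permutation p for the difference of means.

    Enumerates all label assignments when their number does not exceed
    ``n_permutations``; otherwise draws that many random shuffles and applies
    the add-one estimator (the observed split counts as one permutation).
    """
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size
    observed = abs(a.mean() - b.mean())
    total = pooled.sum()
    n_b = n - n_a
    n_comb = math.comb(n, n_a)
    if n_comb <= n_permutations:
        hits = 0
        for idx in combinations(range(n), n_a):
            sa = pooled[list(idx)].sum()
            diff = abs(sa / n_a - (total - sa) / n_b)
            if diff >= observed - _TIE_EPS:
                hits += 1
        return observed, hits / n_comb, "permutation_exact"
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        diff = abs(perm[:n_a].mean() - perm[n_a:].mean())
        if diff >= observed - _TIE_EPS:
            hits += 1
    return observed, (hits + 1) / (n_permutations + 1), "permutation_mc"


def compare_conditions(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    test: str = "mannwhitney",
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    condition_a: str = "a",
    condition_b: str = "b",
    n_replicates: int = 0,
) -> ComparisonResult:
    """Two-sided comparison of two groups of per-nucleus scores.

    With fewer than two scores in either group no p-value is computed and the
    result is flagged insufficient.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score lists must be nonempty")
    if a.size < 2 or b.size < 2:
        return ComparisonResult(condition_a, condition_b, a.size, b.size, n_replicates,
                                None, None, None, test, insufficient=True)
    if test == "mannwhitney":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        statistic, p, name = float(res.statistic), float(res.pvalue), "mannwhitney_u"
    elif test == "permutation":
        statistic, p, name = _perm_pvalue(a, b, n_permutations, seed)
    else:
        raise ConfigError(f"unknown test {test!r}; expected 'mannwhitney' or 'permutation'")
    p = min(p, 1.0)
    return ComparisonResult(condition_a, condition_b, int(a.size), int(b.size), n_replicates,
                            statistic, p, significance_label(p), name)


def summarize_by_replicate(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-condition, per-replicate mean/median/n of the score table."""
    for col in ("condition", "replicate", "value"):
        if col not in scores.columns:
            raise ManifestError(f"score table lacks required column {col!r}")
    if scores["replicate"].isna().any():
        raise ManifestError("score table has missing replicate ids")
    out = (
        scores.groupby(["condition", "replicate"], sort=True)["value"]
        .agg(mean="mean", median="median", n="size")
        .reset_index()
    )
    return out


def compare_replicate_means(
    scores: pd.DataFrame,
    condition_a: str,
    condition_b: str,
) -> ComparisonResult:
    """Welch's t-test on per-replicate mean scores (n = replicate count).

    This treats the biological replicate as the experimental unit; with the
    usual three replicates per condition it is low-powered by construction and
    is reported alongside, not instead of, the pooled per-nucleus comparison.
    """
    summary = summarize_by_replicate(scores)
    means_a = summary.loc[summary["condition"] == condition_a, "mean"].to_numpy()
    means_b = summary.loc[summary["condition"] == condition_b, "mean"].to_numpy()
    if means_a.size == 0 or means_b.size == 0:
        raise ConfigError(f"condition missing from score table: {condition_a!r} or {condition_b!r}")
    if means_a.size < 2 or means_b.size < 2:
        return ComparisonResult(condition_a, condition_b, means_a.size, means_b.size,
                                int(min(means_a.size, means_b.size)),
                                None, None, None, "welch_t_replicate_means", insufficient=True)
    res = sps.ttest_ind(means_a, means_b, equal_var=False)
    p = float(res.pvalue)
    return ComparisonResult(condition_a, condition_b, int(means_a.size), int(means_b.size),
                            int(min(means_a.size, means_b.size)),
                            float(res.statistic), p, significance_label(p), "welch_t_replicate_means")


def run_condition_matrix(
    scores: pd.DataFrame,
    comparisons: Sequence[tuple[str, str]],
    test: str = "mannwhitney",
    holm: bool = False,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Run a list of pairwise comparisons over a score table.

    Labels are derived from raw p-values (the study's convention applies no
    multiplicity adjustment); with ``holm=True`` Holm-adjusted p-values are
    reported in an additional column.
    """
    if not len(comparisons):
        return pd.DataFrame(columns=["condition_a", "condition_b", "n_a", "n_b",
                                     "test", "statistic", "p_value", "label"])
    present = set(scores["condition"].unique()) if len(scores) else set()
    for a, b in comparisons:
        for name in (a, b):
            if name not in present:
                raise ConfigError(f"condition {name!r} not present in score table")
    n_reps = int(scores["replicate"].nunique()) if "replicate" in scores.columns else 0
    results = []
    for i, (a, b) in enumerate(comparisons):
        va = scores.loc[scores["condition"] == a, "value"].to_numpy()
        vb = scores.loc[scores["condition"] == b, "value"].to_numpy()
        res = compare_conditions(va, vb, test=test, n_permutations=n_permutations,
                                 seed=seed + i, condition_a=a, condition_b=b,
                                 n_replicates=n_reps)
        results.append(
            {"condition_a": res.condition_a, "condition_b": res.condition_b,
             "n_a": res.n_a, "n_b": res.n_b, "test": res.test_name,
             "statistic": res.statistic, "p_value": res.p_value, "label": res.label}
        )
    table = pd.DataFrame(results)
    if holm:
        computed = table["p_value"].notna()
        adjusted = np.full(len(table), np.nan)
        if computed.any():
            adjusted[computed.to_numpy()] = multipletests(
                table.loc[computed, "p_value"].to_numpy(), method="holm"
            )[1]
        table["adjusted_p"] = adjusted
    return table
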