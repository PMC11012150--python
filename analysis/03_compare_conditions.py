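#!/usr/bin/env python
"""Compare conditions and print the significance pattern.

Runs the study's pairwise contrasts on the demo score table with the default
Mann-Whitney test, reports the star labels, and writes the comparison table,
the per-replicate summary, and the replicate-mean-level comparison alongside.
"""

from pathlib import Path

import pandas as pd

from bifor.pipeline import DEFAULT_COMPARISONS
from bifor.stats import compare_replicate_means, run_condition_matrix, summarize_by_replicate

RUN = Path(__file__).resolve().parents[1] / "results" / "demo_run"


def main() -> None:
    scores = pd.read_csv(RUN / "scores.csv")
    table = run_condition_matrix(scores, DEFAULT_COMPARISONS, holm=True)
    table.to_csv(RUN / "comparisons.csv", index=False)
    summarize_by_replicate(scores).to_csv(RUN / "replicate_summary.csv", index=False)

    print("pooled per-nucleus comparisons (Mann-Whitney, two-sided):")
    for row in table.itertuples(index=False):
        print(f"  {row.condition_a:14s} vs {row.condition_b:14s} "
              f"p={row.p_value:9.3g}  {row.label}")

    print("\nreplicate-mean-level comparisons (Welch t, n = 3 replicates):")
    rep_rows = []
    for a, b in DEFAULT_COMPARISONS:
        r = compare_replicate_means(scores, a, b)
        rep_rows.append({"condition_a": a, "condition_b": b, "p_value": r.p_value, "label": r.label})
        print(f"  {a:14s} vs {b:14s} p={r.p_value:9.3g}  {r.label}")
    pd.DataFrame(rep_rows).to_csv(RUN / "replicate_comparisons.csv", index=False)


if __name__ == "__main__":
    main()
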