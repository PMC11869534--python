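"""Voiced vs. unvoiced classification with the repeated balanced harness.

Runs MLP, SVM, and RFC on shared balanced subsamples and 70/30 splits of
the 2-class synthetic dataset, then compares the families with paired
t-tests on the per-run test CCRs.  Sizes are scaled to desk hardware
(500 per class, 20 runs, a coarsened SVM grid); the library defaults
carry the full study design (3000 per class, 100 runs, full grid).
"""

from pathlib import Path

import pandas as pd

from facegest import HarnessConfig, aggregate, compare_algorithms, run_harness
from facegest.features import prune_correlated
from facegest.pipeline import build_feature_table
from facegest.synthetic import generate, two_class_scenario

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20240904


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    dataset = generate(two_class_scenario(clips_per_class=200, seed=SEED))
    table, _ = build_feature_table(dataset.predictions, dataset.clip_labels)
    reduced, _ = prune_correlated(table)

    config = HarnessConfig(
        task="voicing", n_per_class=500, n_runs=20, seed=SEED,
        svm_gamma=(0.005, 0.02, 0.05), svm_cost=(1e-4, 1e-2, 1.0),
        svm_coef0=(1.0,),
    )
    results = run_harness(reduced, config)
    summary = aggregate(results)
    summary["summary"].to_csv(RESULTS / "voicing_summary.csv")
    print("mean +/- SD test CCR per algorithm:")
    for algo in ("mlp", "svm", "rfc"):
        m = summary["summary"].loc["accuracy", (algo, "test", "mean")]
        s = summary["summary"].loc["accuracy", (algo, "test", "sd")]
        print(f"  {algo}: {100 * m:.2f} +/- {100 * s:.2f}%")

    comparison = compare_algorithms(results)
    rows = []
    for c in comparison.comparisons:
        rows.append(
            {"pair": "-".join(c.pair), "t": c.t_statistic, "df": c.df,
             "p": c.p_value, "shapiro_p": c.shapiro_p}
        )
        print(f"  {'-'.join(c.pair)}: t = {c.t_statistic:.2f}, df = {c.df}, "
              f"p = {c.p_value:.3g}")
    pd.DataFrame(rows).to_csv(RESULTS / "voicing_comparison.csv", index=False)


if __name__ == "__main__":
    main()
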