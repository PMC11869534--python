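"""Eight-context classification and the RFC confusion structure.

Repeats the balanced-subsample design over the 8 behavioral contexts
(200 per class, matching the rarest category) and writes the
row-normalized mean confusion matrix of the random forest, whose
structure shows which gestures are mutually confusable (yawning vs.
vocalization, vocalization vs. feeding).
"""

from pathlib import Path

from facegest import HarnessConfig, aggregate, run_harness
from facegest.features import prune_correlated
from facegest.pipeline import build_feature_table
from facegest.synthetic import eight_class_scenario, generate

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20240905


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    dataset = generate(eight_class_scenario(clips_per_class=100, seed=SEED))
    table, _ = build_feature_table(dataset.predictions, dataset.clip_labels)
    reduced, _ = prune_correlated(table)

    config = HarnessConfig(
        task="context", n_per_class=200, n_runs=20, seed=SEED,
        algorithms=("rfc",),
    )
    results = run_harness(reduced, config)
    summary = aggregate(results)
    summary["summary"].to_csv(RESULTS / "context_summary.csv")
    confusion = summary["confusion"]["rfc"]
    confusion.to_csv(RESULTS / "context_confusion_rfc.csv")

    m = summary["summary"].loc["accuracy", ("rfc", "test", "mean")]
    s = summary["summary"].loc["accuracy", ("rfc", "test", "sd")]
    print(f"RFC mean test CCR over {config.n_runs} runs: "
          f"{100 * m:.2f} +/- {100 * s:.2f}% (chance 12.5%)")
    print("per-class correct-classification percentages (diagonal):")
    for cls in confusion.index:
        print(f"  {cls}: {confusion.loc[cls, cls]:.1f}%")
    print("largest off-diagonal confusions:")
    off = confusion.copy()
    for cls in off.index:
        off.loc[cls, cls] = 0.0
    top = off.stack().sort_values(ascending=False).head(3)
    for (true, pred), pct in top.items():
        print(f"  true {true} -> predicted {pred}: {pct:.1f}%")


if __name__ == "__main__":
    main()
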