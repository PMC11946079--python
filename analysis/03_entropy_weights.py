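"""Indicator weights and composite scores by the entropy methods.

Computes classical and exponential-form entropy weights within each
evaluation dimension (yield / quality / efficiency) and the composite
score of every treatment per dimension.
"""

import pandas as pd
from pathlib import Path

from fertigation_mcda import run_evaluation

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = pd.read_csv(OUT / "trial_records.csv", keep_default_na=False)  # "NA" is the nitrate indicator, not a missing value
    report = run_evaluation(records)
    rows = []
    for cat, res in report.category_results.items():
        for ind in res.entropies.index:
            rows.append(
                {
                    "category": cat,
                    "indicator": ind,
                    "entropy": res.entropies[ind],
                    "weight_classical": res.weights_classical[ind],
                    "weight_improved": res.weights_improved[ind],
                }
            )
    weights = pd.DataFrame(rows)
    weights.to_csv(OUT / "entropy_weights.csv", index=False)
    report.category_scores.rename_axis("treatment").to_csv(OUT / "category_scores.csv")
    print(weights.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    best = {c: report.category_scores[c].idxmax() for c in report.category_scores}
    print(f"\nbest treatment per dimension: {best}")
    print(f"weights in {OUT/'entropy_weights.csv'}, scores in {OUT/'category_scores.csv'}")


if __name__ == "__main__":
    main()
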