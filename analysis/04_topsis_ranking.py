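"""Virtual-ideal TOPSIS ranking of the nine treatments.

Runs the full evaluation (screening, entropy weights over all twelve
indicators, virtual-ideal TOPSIS at alpha=0.9 / beta=0.1) and writes the
distance table, closeness coefficients and ranking.
"""

import json
import pandas as pd
from pathlib import Path

from fertigation_mcda import run_evaluation

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = pd.read_csv(OUT / "trial_records.csv", keep_default_na=False)  # "NA" is the nitrate indicator, not a missing value
    report = run_evaluation(records)
    report.topsis.table.rename_axis("treatment").to_csv(OUT / "topsis.csv")
    (OUT / "evaluation_summary.json").write_text(report.to_json())
    print(report.topsis.table.round(4).to_string())
    print(f"\nbest treatment: {report.best_treatment}  (ranking: {', '.join(report.ranking)})")
    print(f"tables in {OUT/'topsis.csv'}, summary in {OUT/'evaluation_summary.json'}")


if __name__ == "__main__":
    main()
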