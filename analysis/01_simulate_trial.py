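"""Generate the baseline synthetic fertigation trial and write it to disk.

Simulates the study conditions — 2 seasons, 9 treatments on the L9(3^4)
array, 3 replicate plots, 12 indicators, 5% plot CV — and writes the
tidy records plus the generator's ground truth under results/.
"""

import json
from pathlib import Path

from fertigation_mcda import default_config, generate_trial
from fertigation_mcda.synthetic import save_scenario

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20230803  # transplanting date of season one


def main() -> None:
    OUT.mkdir(exist_ok=True)
    config = default_config(seed=SEED)
    trial = generate_trial(config)
    trial.records.to_csv(OUT / "trial_records.csv", index=False)
    (OUT / "trial_truth.json").write_text(json.dumps(trial.truth, indent=2))
    save_scenario(config, OUT / "trial_scenario.yaml")
    n_plots = trial.plots_per_year
    print(f"wrote {len(trial.records)} records ({n_plots} plots per year) to {OUT/'trial_records.csv'}")
    print(f"ground truth (optimal levels per indicator) in {OUT/'trial_truth.json'}")


if __name__ == "__main__":
    main()
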