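"""Sex-stratified logistic models for SYNTAX >= 22, selected by AIC.

Runs forward selection, backward elimination, and bidirectional stepwise
search over the signed + absolute difference candidates in each sex stratum,
keeps the lowest-AIC winner, and writes the per-stratum model JSONs (with the
Coefficient/SE/tStat/P-Value table) plus the events-per-variable advisory.
Validation of the winners is done in the next script.
"""

from pathlib import Path

from pulseharm.io import read_feature_table, write_model_json
from pulseharm.pipeline import StudyConfig, fit_stratum, format_coefficient_table

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    config = StudyConfig.from_yaml(RESULTS / "study_config.yaml")
    # skip the expensive bootstrap here; script 04 validates the winners
    config.n_resamples = 0
    features = read_feature_table(SCRATCH / "features.csv")
    for sex in ("male", "female"):
        stratum = fit_stratum(features, config, sex)
        write_model_json(stratum.to_dict(), RESULTS / f"model_{sex}.json")
        print(f"== {sex} (n={stratum.n_subjects}, events={stratum.n_events}) ==")
        for method, result in stratum.searches.items():
            note = f" [{result.warnings[0]}]" if result.warnings else ""
            print(f"  {method:<9} AIC {result.model.aic:8.2f} "
                  f"({len(result.selected)} variables){note}")
        print(f"  winner: {stratum.best.method}")
        print(format_coefficient_table(stratum.model))
        if not stratum.epv.ok:
            print(f"  EPV WARNING: {stratum.epv.message}")
        print()


if __name__ == "__main__":
    main()
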