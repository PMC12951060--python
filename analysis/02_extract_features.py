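"""Extract inter-hand harmonic difference features from the simulated records.

For each subject: segment both hands into beats, resample each beat to 256
points, decompose into harmonic orders 0-11, summarize to record-level
Cn/Pn/Dn indices with CVs, and take signed and absolute left-minus-right
differences.  The full feature table (348 x 144 features) goes to
scratch/features.csv; a compact per-label summary goes to results/.
"""

from pathlib import Path

import pandas as pd

from pulseharm.io import read_cohort, read_waveform, write_feature_table
from pulseharm.pipeline import StudyConfig, extract_subject_features

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    config = StudyConfig.from_yaml(RESULTS / "study_config.yaml")
    records = read_cohort(RESULTS / "cohort.csv")
    for record in records:
        left = read_waveform(SCRATCH / "waveforms" / f"{record.subject_id}_left.csv")
        right = read_waveform(SCRATCH / "waveforms" / f"{record.subject_id}_right.csv")
        record.features = extract_subject_features(
            left, right, beat_length=config.beat_length, min_beats=config.min_beats
        )
    write_feature_table(records, SCRATCH / "features.csv")

    table = pd.DataFrame([{"sex": r.sex, "label": int(r.label), **r.features}
                          for r in records])
    picks = ["absdC6", "absdC10", "dD6", "absdD9", "absdP8", "dP1CV", "dC9CV"]
    summary = table.groupby(["sex", "label"])[picks].agg(["mean", "std"]).round(5)
    summary.to_csv(RESULTS / "feature_summary.csv")
    print(f"features extracted for {len(records)} subjects "
          f"({table.shape[1] - 2} columns) -> {SCRATCH / 'features.csv'}")
    print("\nper-stratum spread of representative difference features "
          "(events show wider |Δ| tails):")
    print(summary.to_string())


if __name__ == "__main__":
    main()
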