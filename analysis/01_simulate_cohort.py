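"""Simulate the study cohort: 249 male / 99 female subjects with two-hand PPG.

Writes the study configuration and cohort metadata under results/, and the
(bulky) per-subject waveform CSVs under scratch/waveforms/.
"""

from pathlib import Path

from pulseharm.io import write_cohort, write_waveform
from pulseharm.pipeline import StudyConfig
from pulseharm.synthetic import generate_cohort, generate_subject_waveforms

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    config = StudyConfig(seed=1)
    RESULTS.mkdir(exist_ok=True)
    (SCRATCH / "waveforms").mkdir(parents=True, exist_ok=True)
    config.to_yaml(RESULTS / "study_config.yaml")

    subjects = generate_cohort(config.cohort)
    write_cohort([s.as_subject_record() for s in subjects], RESULTS / "cohort.csv")
    for subject in subjects:
        left, right = generate_subject_waveforms(subject, config.acquisition)
        write_waveform(left, SCRATCH / "waveforms" / f"{subject.subject_id}_left.csv")
        write_waveform(right, SCRATCH / "waveforms" / f"{subject.subject_id}_right.csv")

    males = [s for s in subjects if s.sex == "male"]
    females = [s for s in subjects if s.sex == "female"]
    print(f"cohort: {len(subjects)} subjects "
          f"({len(males)} male, {len(females)} female)")
    print(f"  male events (SYNTAX >= 22): {sum(s.is_event for s in males)}")
    print(f"  female events (SYNTAX >= 22): {sum(s.is_event for s in females)}")
    print(f"  mean age: male {sum(s.age for s in males) / len(males):.1f}, "
          f"female {sum(s.age for s in females) / len(females):.1f}")
    print(f"waveforms: {2 * len(subjects)} records at "
          f"{config.acquisition.sampling_rate:.0f} Hz x "
          f"{config.acquisition.duration:.0f} s -> {SCRATCH / 'waveforms'}")


if __name__ == "__main__":
    main()
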