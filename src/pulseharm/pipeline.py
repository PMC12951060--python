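"""End-to-end study orchestration: simulate -> extract -> fit -> validate.

One :class:`StudyConfig` (YAML-serializable, one global seed) drives the whole
run; the resulting :class:`StudyReport` carries, per sex stratum, the selected
model with its Coefficient/SE/tStat/P table, AIC, apparent AUC, calibration
(Hosmer-Lemeshow) and bootstrap internal validation, plus an events-per-variable
advisory.  Every reported number is recomputable from the serialized feature
table and model.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pulseharm import __version__
from pulseharm.harmonics import (
    feature_column_names,
    inter_hand_differences,
    summarize_record,
)
from pulseharm.io import (
    SubjectRecord,
    write_cohort,
    write_feature_table,
    write_model_json,
    write_waveform,
)
from pulseharm.segmentation import beats_to_matrix, segment_beats
from pulseharm.selection import (
    SEARCH_METHODS,
    EPVAdvisory,
    FittedModel,
    SelectionResult,
    drop_degenerate,
    epv_check,
    select_best,
)
from pulseharm.synthetic import (
    AcquisitionConfig,
    CohortConfig,
    SubjectTruth,
    generate_cohort,
    generate_subject_waveforms,
)
from pulseharm.validation import ValidationReport, validate_model

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Everything one study run needs; ``seed`` governs all randomness."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    beat_length: int = 256
    min_beats: int = 5
    candidate_policy: str = "both"  # "signed" | "absolute" | "both"
    include_dncv: bool = True
    search_methods: tuple[str, ...] = ("forward", "backward", "stepwise")
    n_resamples: int = 2000
    hl_groups: int = 10
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.candidate_policy not in ("signed", "absolute", "both"):
            raise ValueError(f"unknown candidate_policy {self.candidate_policy!r}")
        unknown = set(self.search_methods) - set(SEARCH_METHODS)
        if unknown:
            raise ValueError(f"unknown search methods: {sorted(unknown)}")
        # one global seed: re-derive the cohort seed from it
        self.cohort = CohortConfig(**{**asdict(self.cohort), "seed": self.seed})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(asdict(self)), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "StudyConfig":
        payload = dict(payload)
        if "cohort" in payload:
            cohort = dict(payload["cohort"])
            for key in ("syntax_low_range", "syntax_high_range", "effect_orders"):
                if key in cohort and cohort[key] is not None:
                    cohort[key] = tuple(cohort[key])
            payload["cohort"] = CohortConfig(**cohort)
        if "acquisition" in payload:
            payload["acquisition"] = AcquisitionConfig(**payload["acquisition"])
        if "search_methods" in payload:
            payload["search_methods"] = tuple(payload["search_methods"])
        return cls(**payload)

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(_plain(asdict(self)), sort_keys=True).encode()
        ).hexdigest()[:16]


def _plain(obj):
    """Recursively convert tuples to lists for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def extract_subject_features(
    left, right, beat_length: int = 256, min_beats: int = 5
) -> dict[str, float]:
    """Waveform pair -> flat feature dict (signed + absolute differences)."""
    summaries = {}
    for rec in (left, right):
        series = segment_beats(rec, min_beats=min_beats)
        matrix = beats_to_matrix(series, beat_length=beat_length)
        summaries[rec.hand] = summarize_record(matrix, min_beats=min_beats)
    fv = inter_hand_differences(summaries["left"], summaries["right"])
    return fv.as_dict(include_absolute=True)


def simulate_and_extract(
    subjects: list[SubjectTruth],
    acq: AcquisitionConfig,
    beat_length: int = 256,
    min_beats: int = 5,
    waveform_dir: str | Path | None = None,
) -> list[SubjectRecord]:
    """Generate both hands per subject and extract the feature vector."""
    records = []
    for subject in subjects:
        left, right = generate_subject_waveforms(subject, acq)
        if waveform_dir is not None:
            d = Path(waveform_dir)
            d.mkdir(parents=True, exist_ok=True)
            write_waveform(left, d / f"{subject.subject_id}_left.csv")
            write_waveform(right, d / f"{subject.subject_id}_right.csv")
        rec = subject.as_subject_record()
        rec.features = extract_subject_features(
            left, right, beat_length=beat_length, min_beats=min_beats
        )
        records.append(rec)
    return records


def feature_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Feature table (one row per subject) with sex/label columns."""
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "sex": r.sex, "label": int(r.label)}
        row.update(r.features)
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def candidate_columns(policy: str = "both", include_dncv: bool = True) -> list[str]:
    """Candidate predictor names under the signed/absolute policy."""
    signed = feature_column_names(include_absolute=False)
    if not include_dncv:
        signed = [c for c in signed if not (c.startswith("dD") and c.endswith("CV"))]
    if policy == "signed":
        return signed
    if policy == "absolute":
        return ["abs" + c for c in signed]
    return signed + ["abs" + c for c in signed]


@dataclass
class StratumReport:
    """Per-sex results block."""

    sex: str
    n_subjects: int
    n_events: int
    searches: dict[str, SelectionResult]
    best: SelectionResult
    validation: ValidationReport
    epv: EPVAdvisory
    dropped_candidates: int

    @property
    def model(self) -> FittedModel:
        return self.best.model

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "n_subjects": self.n_subjects,
            "n_events": self.n_events,
            "search_aics": {m: r.model.aic for m, r in self.searches.items()},
            "search_warnings": {m: r.warnings for m, r in self.searches.items()},
            "best_method": self.best.method,
            "selected_variables": self.best.selected,
            "model": self.best.model.to_dict(),
            "aic": self.best.model.aic,
            "validation": self.validation.to_dict(),
            "epv": {
                "n_events": self.epv.n_events, "n_params": self.epv.n_params,
                "ok": self.epv.ok, "message": self.epv.message,
            },
            "dropped_candidates": self.dropped_candidates,
        }


@dataclass
class StudyReport:
    strata: dict[str, StratumReport]
    seed: int
    config_hash: str
    version: str
    timings: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "strata": {s: r.to_dict() for s, r in self.strata.items()},
            "provenance": {
                "seed": self.seed, "config_hash": self.config_hash,
                "version": self.version,
            },
            "timings_s": {k: round(v, 3) for k, v in self.timings.items()},
        }


def fit_stratum(
    features: pd.DataFrame,
    config: StudyConfig,
    sex: str,
) -> StratumReport:
    """Run the three searches, pick the winner, and validate it, for one sex."""
    sub = features[features["sex"] == sex]
    y = sub["label"].to_numpy(dtype=float)
    candidates = [c for c in candidate_columns(config.candidate_policy, config.include_dncv)
                  if c in sub.columns]
    kept = drop_degenerate(sub, candidates)
    results = {}
    for method in config.search_methods:
        results[method] = SEARCH_METHODS[method](sub, y, kept)
        logger.info("%s/%s: AIC %.2f with %d variables", sex, method,
                    results[method].model.aic, len(results[method].selected))
    best = select_best(list(results.values()))
    epv = epv_check(int(y.sum()), best.model.k - 1)
    validation = validate_model(
        best.model, sub, y, n_resamples=config.n_resamples,
        n_groups=config.hl_groups, seed=config.seed + (0 if sex == "male" else 1),
    )
    return StratumReport(
        sex=sex, n_subjects=len(sub), n_events=int(y.sum()),
        searches=results, best=best, validation=validation, epv=epv,
        dropped_candidates=len(candidates) - len(kept),
    )


def run_pipeline(config: StudyConfig) -> StudyReport:
    """Simulate the cohort, extract features, and fit/validate both strata."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    subjects = generate_cohort(config.cohort)
    timings["simulate_cohort"] = time.perf_counter() - t0

    out_dir = Path(config.out_dir) if config.out_dir else None
    waveform_dir = out_dir / "waveforms" if out_dir else None
    t0 = time.perf_counter()
    records = simulate_and_extract(
        subjects, config.acquisition,
        beat_length=config.beat_length, min_beats=config.min_beats,
        waveform_dir=waveform_dir,
    )
    timings["extract_features"] = time.perf_counter() - t0
    features = feature_frame(records)

    strata = {}
    for sex in ("male", "female"):
        t0 = time.perf_counter()
        strata[sex] = fit_stratum(features, config, sex)
        timings[f"fit_{sex}"] = time.perf_counter() - t0

    report = StudyReport(
        strata=strata, seed=config.seed, config_hash=config.config_hash(),
        version=__version__,
    )
    report.timings = timings
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort([s.as_subject_record() for s in subjects], out_dir / "cohort.csv")
        write_feature_table(records, out_dir / "features.csv")
        for sex, stratum in strata.items():
            write_model_json(stratum.to_dict(), out_dir / f"model_{sex}.json")
        write_model_json(report.to_dict(), out_dir / "study_report.json")
    return report


def refit_from_features(
    features: pd.DataFrame, config: StudyConfig
) -> StudyReport:
    """Re-run selection + validation from a saved feature table (no simulation)."""
    strata = {
        sex: fit_stratum(features, config, sex) for sex in ("male", "female")
    }
    return StudyReport(
        strata=strata, seed=config.seed, config_hash=config.config_hash(),
        version=__version__,
    )


def format_coefficient_table(model: FittedModel) -> str:
    """Plain-text per-variable table: Coefficient / SE / tStat / P Value.

    The intercept row is listed separately below the predictors; P < 0.05 is
    starred.
    """
    table = model.coefficient_table()
    lines = [f"{'-':<12}{'Coefficient':>14}{'SE':>10}{'tStat':>8}  P Value"]
    order = model.variables + ["(intercept)"]
    for name in order:
        p = table.loc[name, "P Value"]
        star = "*" if p < 0.05 else ""
        lines.append(
            f"{name:<12}{table.loc[name, 'Coefficient']:>14.2f}"
            f"{table.loc[name, 'SE']:>10.2f}{table.loc[name, 'tStat']:>8.2f}"
            f"  {p:.2f}{star}"
        )
    return "\n".join(lines)


def report_tables(report: StudyReport) -> str:
    """Human-readable study summary with per-stratum coefficient tables."""
    blocks = []
    for sex, stratum in report.strata.items():
        v = stratum.validation
        lines = [
            f"== {sex} stratum (n={stratum.n_subjects}, events={stratum.n_events}) ==",
            f"best search: {stratum.best.method}; AIC = {stratum.model.aic:.2f}",
            format_coefficient_table(stratum.model),
            f"apparent AUC = {v.auc:.2f}",
            f"Hosmer-Lemeshow = {v.hl.statistic:.2f} (df={v.hl.df}, P={v.hl.p_value:.2f})",
        ]
        if v.bootstrap is not None:
            lines.append(
                f"bootstrap mean AUC = {v.bootstrap.mean_auc:.2f} "
                f"[{v.bootstrap.ci[0]:.2f}, {v.bootstrap.ci[1]:.2f}] "
                f"({v.bootstrap.n_resamples} resamples)"
            )
        if not stratum.epv.ok:
            lines.append(f"WARNING {stratum.epv.message}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks)


def plot_validation(report: StudyReport, out_dir: str | Path) -> list[Path]:
    """ROC and calibration plots per stratum (PNG files)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sex, stratum in report.strata.items():
        v = stratum.validation
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.plot(v.roc_points[:, 0], v.roc_points[:, 1], label=f"AUC={v.auc:.2f}")
        ax1.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax1.set_xlabel("1 - specificity")
        ax1.set_ylabel("sensitivity")
        ax1.set_title(f"ROC, {sex}")
        ax1.legend()
        ax2.plot(v.calibration_points[:, 0], v.calibration_points[:, 1], "o-")
        ax2.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax2.set_xlabel("predicted probability")
        ax2.set_ylabel("observed event rate")
        ax2.set_title(f"Calibration, {sex}")
        fig.tight_layout()
        path = out_dir / f"validation_{sex}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
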