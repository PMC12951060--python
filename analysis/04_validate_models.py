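"""Validate the selected models: ROC/AUC, Hosmer-Lemeshow, 2000-resample bootstrap.

Reads the per-stratum model JSONs from script 03, recomputes apparent
discrimination and calibration on the development sample, runs the bootstrap
internal validation (refit coefficients on each resample, score the original
sample), and writes validation JSONs plus ROC/calibration plots.
"""

import json
from pathlib import Path

import numpy as np

from pulseharm.io import read_feature_table, read_model_json
from pulseharm.pipeline import StudyConfig
from pulseharm.selection import FittedModel
from pulseharm.validation import validate_model

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    config = StudyConfig.from_yaml(RESULTS / "study_config.yaml")
    features = read_feature_table(SCRATCH / "features.csv")
    summaries = {}
    for sex in ("male", "female"):
        payload = read_model_json(RESULTS / f"model_{sex}.json")
        model = FittedModel.from_dict(payload["model"])
        sub = features[features["sex"] == sex]
        y = sub["label"].to_numpy(dtype=float)
        report = validate_model(
            model, sub, y, n_resamples=config.n_resamples,
            n_groups=config.hl_groups,
            seed=config.seed + (0 if sex == "male" else 1),
        )
        (RESULTS / f"validation_{sex}.json").write_text(
            json.dumps(report.to_dict(), indent=2) + "\n"
        )
        summaries[sex] = report
        boot = report.bootstrap
        print(f"== {sex} ==")
        print(f"  apparent AUC        {report.auc:.3f}")
        print(f"  Hosmer-Lemeshow     {report.hl.statistic:.2f} "
              f"(df={report.hl.df}, P={report.hl.p_value:.2f})")
        print(f"  bootstrap mean AUC  {boot.mean_auc:.3f} "
              f"[{boot.ci[0]:.3f}, {boot.ci[1]:.3f}] over {boot.n_resamples} resamples")
        if boot.degenerate_warning:
            print(f"  WARNING: {boot.n_degenerate} degenerate resamples")

    try:
        from pulseharm.pipeline import StudyReport, StratumReport  # noqa: F401
        _plot(summaries)
    except Exception as exc:  # plotting is best-effort
        print(f"plots skipped: {exc}")


def _plot(summaries) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plots = RESULTS / "plots"
    plots.mkdir(exist_ok=True)
    for sex, report in summaries.items():
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.plot(report.roc_points[:, 0], report.roc_points[:, 1],
                 label=f"AUC={report.auc:.2f}")
        ax1.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax1.set(xlabel="1 - specificity", ylabel="sensitivity", title=f"ROC, {sex}")
        ax1.legend()
        pts = np.asarray(report.calibration_points)
        ax2.plot(pts[:, 0], pts[:, 1], "o-")
        ax2.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax2.set(xlabel="predicted probability", ylabel="observed rate",
                title=f"Calibration, {sex}")
        fig.tight_layout()
        fig.savefig(plots / f"validation_{sex}.png", dpi=120)
        plt.close(fig)
    print(f"plots -> {plots}")


if __name__ == "__main__":
    main()
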