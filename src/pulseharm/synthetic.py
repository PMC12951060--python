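"""Synthetic two-hand PPG cohort generator.

The generator is the study's data source: no public recordings exist for the
two-hand finger-PPG protocol, so every downstream stage is exercised on
simulated cohorts whose statistical structure matches the analysis
assumptions:

* each subject has ground-truth per-order (0-11) beat harmonics for the left
  hand, drawn around a fixed physiologically-shaped template (dominant first
  harmonic, monotonically decaying high orders, a dicrotic-notch-like
  inflection from orders 2-4);
* the right hand equals the left plus per-order additive asymmetry offsets;
  subjects with severe coronary lesions (SYNTAX score >= 22, the "events")
  receive Gaussian offsets on a configurable set of orders, non-events
  near-zero offsets — this is the disease link the logistic models recover;
* records are built beat-by-beat with lognormal period and amplitude jitter
  and wrapped-normal phase jitter, then additive Gaussian noise and a slow
  sinusoidal baseline drift are applied.

Default acquisition: 200 Hz sampling for 60 s per hand (the device protocol
reports roughly one minute of recording; the sampling rate is an assumption
of this package, documented in the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from pulseharm.errors import ConfigError
from pulseharm.harmonics import (
    N_ORDERS,
    HarmonicSummary,
    wrap_phase,
)
from pulseharm.io import SYNTAX_THRESHOLD, SubjectRecord, WaveformRecord

#: Default beat template: per-order amplitudes (arbitrary PPG units; order 0 is
#: the beat mean) and phase delays (radians).  Dominant order 1, monotone decay
#: from order 1 upward, mid-order phases shaped to produce a sharp systolic
#: upstroke followed by a dicrotic-notch-like inflection.
TEMPLATE_AMPLITUDES = np.array(
    [1.0, 0.42, 0.24, 0.135, 0.075, 0.046, 0.028, 0.018, 0.011, 0.007, 0.0045, 0.003]
)
TEMPLATE_PHASES = np.array(
    [0.0, 1.25, 2.25, 3.05, -2.55, -1.75, -0.95, -0.25, 0.45, 1.10, 1.70, 2.30]
)

#: Orders that receive disease-linked asymmetry by default: the union of the
#: harmonic orders appearing in the final male and female models.
DEFAULT_EFFECT_ORDERS = (1, 2, 3, 4, 5, 6, 8, 9, 10)


@dataclass
class AcquisitionConfig:
    """Recording protocol: sampling rate (Hz), duration (s), heart rate (bpm)."""

    sampling_rate: float = 200.0
    duration: float = 60.0
    heart_rate: float = 70.0

    def __post_init__(self) -> None:
        if self.sampling_rate < 50:
            raise ConfigError(f"sampling_rate must be >= 50 Hz, got {self.sampling_rate}")
        if self.duration <= 0:
            raise ConfigError(f"duration must be positive, got {self.duration}")
        if not 30 < self.heart_rate < 200:
            raise ConfigError(f"heart_rate must be in (30, 200) bpm, got {self.heart_rate}")


@dataclass
class CohortConfig:
    """Cohort composition and effect-size distribution.

    Event counts follow the source cohort by default: 249 male subjects with
    32 events (SYNTAX >= 22) and 99 female subjects with 13 events.  Either
    exact counts (``n_events_*``) or Bernoulli prevalences (``prevalence_*``)
    may be given; exact counts take precedence.
    """

    n_male: int = 249
    n_female: int = 99
    n_events_male: int | None = 32
    n_events_female: int | None = 13
    prevalence_male: float | None = None
    prevalence_female: float | None = None
    syntax_low_range: tuple[float, float] = (1.0, 21.0)
    syntax_high_range: tuple[float, float] = (22.0, 45.0)
    seed: int = 0
    # disease-linked asymmetry: everyone carries some physiological
    # inter-hand asymmetry; severe lesions amplify it ~2x in SD on the
    # affected orders
    effect_orders: tuple[int, ...] = DEFAULT_EFFECT_ORDERS
    amp_effect_scale: float = 0.10  # SD of event amplitude offsets, relative to template
    phase_effect_scale: float = 0.12  # SD of event phase offsets, radians
    null_effect_fraction: float = 0.5  # non-event offsets as fraction of the above
    # between-subject baseline variability
    subject_amp_sigma: float = 0.10  # lognormal sigma on template amplitudes
    subject_phase_sigma: float = 0.10  # wrapped-normal sigma on template phases
    # within-record beat-to-beat jitter and noise defaults
    amp_jitter_cv: float = 0.08
    phase_jitter_sd: float = 0.06
    period_cv: float = 0.04
    noise_sd: float = 0.02
    drift_amplitude: float = 0.05

    def __post_init__(self) -> None:
        for name in ("n_male", "n_female"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name, total in (("n_events_male", self.n_male), ("n_events_female", self.n_female)):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= total:
                raise ConfigError(f"{name}={v} must be in [0, {total}]")
        for name in ("prevalence_male", "prevalence_female"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} must be a probability in [0, 1]")
        if not self.syntax_low_range[0] <= self.syntax_low_range[1] < SYNTAX_THRESHOLD:
            raise ConfigError(f"syntax_low_range {self.syntax_low_range} must lie entirely below 22")
        if not SYNTAX_THRESHOLD <= self.syntax_high_range[0] <= self.syntax_high_range[1]:
            raise ConfigError(f"syntax_high_range {self.syntax_high_range} must lie at or above 22")
        if any(not 0 <= n < N_ORDERS for n in self.effect_orders):
            raise ConfigError(f"effect_orders must be within 0..11, got {self.effect_orders}")
        for name in ("amp_effect_scale", "phase_effect_scale", "null_effect_fraction",
                     "subject_amp_sigma", "subject_phase_sigma", "amp_jitter_cv",
                     "phase_jitter_sd", "period_cv", "noise_sd", "drift_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass
class SubjectTruth:
    """Ground-truth generative parameters for one subject."""

    subject_id: str
    sex: str
    age: float
    syntax_score: float
    base_amplitudes: np.ndarray  # left-hand per-order amplitudes, order 0..11
    base_phases: np.ndarray  # left-hand per-order phase delays, radians
    asym_amplitudes: np.ndarray  # additive right-hand amplitude offsets
    asym_phases: np.ndarray  # additive right-hand phase offsets
    amp_jitter_cv: float = 0.08
    phase_jitter_sd: float = 0.06
    period_cv: float = 0.04
    noise_sd: float = 0.02
    drift_amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_amplitudes", "base_phases", "asym_amplitudes", "asym_phases"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_ORDERS,):
                raise ConfigError(f"{name} must have shape (12,), got {arr.shape}")
            setattr(self, name, arr)
        if np.any(self.base_amplitudes < 0):
            raise ConfigError("base_amplitudes must be non-negative")
        for name in ("amp_jitter_cv", "phase_jitter_sd", "period_cv", "noise_sd", "drift_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    @property
    def is_event(self) -> bool:
        return self.syntax_score >= SYNTAX_THRESHOLD

    def hand_harmonics(self, hand: str) -> tuple[np.ndarray, np.ndarray]:
        """Ground-truth (amplitudes, phases) for one hand."""
        if hand == "left":
            return self.base_amplitudes.copy(), self.base_phases.copy()
        if hand == "right":
            amps = np.clip(self.base_amplitudes + self.asym_amplitudes, 0.0, None)
            return amps, wrap_phase(self.base_phases + self.asym_phases)
        raise ValueError(f"hand must be 'left' or 'right', got {hand!r}")

    def as_subject_record(self) -> SubjectRecord:
        return SubjectRecord(
            subject_id=self.subject_id, sex=self.sex, age=self.age,
            syntax_score=self.syntax_score,
        )


def synthesize_beat(
    amplitudes: np.ndarray, phases: np.ndarray, n_points: int
) -> np.ndarray:
    """Evaluate f(x) = A0 + sum_{n=1..11} A_n cos(2 pi n x / L - theta_n).

    Exactly inverts :func:`pulseharm.harmonics.beat_harmonics` for
    band-limited beats.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    phases = np.asarray(phases, dtype=float)
    if amplitudes.shape != (N_ORDERS,) or phases.shape != (N_ORDERS,):
        raise ValueError(
            f"need exactly {N_ORDERS} amplitude/phase pairs, got "
            f"{amplitudes.shape} and {phases.shape}"
        )
    if n_points < 24:
        raise ValueError(f"n_points must be >= 24, got {n_points}")
    u = np.arange(n_points) / n_points
    return _eval_series(amplitudes, phases, u)


def _eval_series(amplitudes: np.ndarray, phases: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Evaluate the cosine series at cycle fractions ``u`` (0..1 per period)."""
    orders = np.arange(1, N_ORDERS)
    ang = 2.0 * np.pi * np.outer(u, orders) - phases[1:]
    return amplitudes[0] + np.cos(ang) @ amplitudes[1:]


def _generate_sex_stratum(
    cfg: CohortConfig, sex: str, n: int, n_events: int | None,
    prevalence: float | None, rng: np.random.Generator,
) -> list[SubjectTruth]:
    if n_events is not None:
        event = np.zeros(n, dtype=bool)
        event[:n_events] = True
        rng.shuffle(event)
    elif prevalence is not None:
        event = rng.random(n) < prevalence
    else:
        raise ConfigError(f"neither n_events_{sex} nor prevalence_{sex} given")
    age_mean = 59.80 if sex == "male" else 67.52
    prefix = "M" if sex == "male" else "F"
    subjects = []
    for i in range(n):
        age = float(np.clip(rng.normal(age_mean, 9.0), 30.0, 92.0))
        if event[i]:
            syntax = float(rng.uniform(*cfg.syntax_high_range))
            scale = 1.0
        else:
            syntax = float(rng.uniform(*cfg.syntax_low_range))
            scale = cfg.null_effect_fraction
        base_amps = TEMPLATE_AMPLITUDES * np.exp(rng.normal(0.0, cfg.subject_amp_sigma, N_ORDERS))
        base_phases = wrap_phase(TEMPLATE_PHASES + rng.normal(0.0, cfg.subject_phase_sigma, N_ORDERS))
        base_phases[0] = 0.0
        asym_amps = np.zeros(N_ORDERS)
        asym_phases = np.zeros(N_ORDERS)
        for order in cfg.effect_orders:
            asym_amps[order] = rng.normal(0.0, scale * cfg.amp_effect_scale * TEMPLATE_AMPLITUDES[order])
            asym_phases[order] = rng.normal(0.0, scale * cfg.phase_effect_scale)
        subjects.append(
            SubjectTruth(
                subject_id=f"{prefix}{i + 1:03d}", sex=sex, age=age, syntax_score=syntax,
                base_amplitudes=base_amps, base_phases=base_phases,
                asym_amplitudes=asym_amps, asym_phases=asym_phases,
                amp_jitter_cv=cfg.amp_jitter_cv, phase_jitter_sd=cfg.phase_jitter_sd,
                period_cv=cfg.period_cv, noise_sd=cfg.noise_sd,
                drift_amplitude=cfg.drift_amplitude,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return subjects


def generate_cohort(config: CohortConfig) -> list[SubjectTruth]:
    """Draw a full two-sex cohort of subject ground truths.

    Deterministic given ``config.seed``.  In exact-count mode the number of
    subjects with ``syntax_score >= 22`` equals ``n_events_*`` per sex.
    """
    rng = np.random.default_rng(config.seed)
    males = _generate_sex_stratum(
        config, "male", config.n_male, config.n_events_male, config.prevalence_male, rng
    )
    females = _generate_sex_stratum(
        config, "female", config.n_female, config.n_events_female, config.prevalence_female, rng
    )
    return males + females


def _jittered_beats(
    amps: np.ndarray, phases: np.ndarray, subject: SubjectTruth,
    n_beats: int, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-beat (n_beats, 12) amplitude and phase draws for one hand."""
    amp_sigma = np.sqrt(np.log1p(subject.amp_jitter_cv**2))  # lognormal with given CV
    beat_amps = amps * np.exp(
        rng.normal(0.0, 1.0, (n_beats, N_ORDERS)) * amp_sigma - amp_sigma**2 / 2.0
    )
    beat_phases = wrap_phase(
        phases + rng.normal(0.0, 1.0, (n_beats, N_ORDERS)) * subject.phase_jitter_sd
    )
    beat_phases[:, 0] = 0.0
    return beat_amps, beat_phases


def generate_subject_waveforms(
    subject: SubjectTruth,
    acq: AcquisitionConfig,
    seed: int | None = None,
) -> tuple[WaveformRecord, WaveformRecord]:
    """Simulate both hands' records for one subject.

    Beats are concatenated with per-beat lognormal period jitter; both hands
    share the per-beat period sequence (they are driven by the same heart) but
    draw independent amplitude/phase jitter, measurement noise, and baseline
    drift.  Partial beats at the record edges are left in place for the
    segmenter to discard.  Deterministic given the seed (defaults to the
    subject's own seed).
    """
    rng = np.random.default_rng(subject.seed if seed is None else seed)
    fs, duration = acq.sampling_rate, acq.duration
    base_period = 60.0 / acq.heart_rate
    n_beats = int(np.ceil(duration / base_period * 1.3)) + 3
    period_sigma = np.sqrt(np.log1p(subject.period_cv**2))
    periods = base_period * np.exp(
        rng.normal(0.0, 1.0, n_beats) * period_sigma - period_sigma**2 / 2.0
    )
    boundaries = np.cumsum(periods)
    starts = boundaries - periods

    n_samples = int(round(duration * fs))
    t = np.arange(n_samples) / fs
    idx = np.searchsorted(boundaries, t, side="right")
    idx = np.clip(idx, 0, n_beats - 1)
    u = (t - starts[idx]) / periods[idx]

    records = []
    for hand in ("left", "right"):
        amps, phases = subject.hand_harmonics(hand)
        beat_amps, beat_phases = _jittered_beats(amps, phases, subject, n_beats, rng)
        orders = np.arange(1, N_ORDERS)
        ang = 2.0 * np.pi * u[:, None] * orders - beat_phases[idx, 1:]
        samples = beat_amps[idx, 0] + np.sum(beat_amps[idx, 1:] * np.cos(ang), axis=1)
        samples = samples + rng.normal(0.0, 1.0, n_samples) * subject.noise_sd
        drift_freq = rng.uniform(0.05, 0.2)
        drift_phase = rng.uniform(0.0, 2.0 * np.pi)
        samples = samples + subject.drift_amplitude * np.sin(
            2.0 * np.pi * drift_freq * t + drift_phase
        )
        records.append(
            WaveformRecord(
                subject_id=subject.subject_id, hand=hand,
                sampling_rate=fs, samples=samples,
            )
        )
    return records[0], records[1]


def ground_truth_summary(subject: SubjectTruth, hand: str) -> HarmonicSummary:
    """Noiseless record-level indices implied by a subject's ground truth.

    With zero jitter every beat is identical, so all CVs are exactly zero and
    Cn/Pn/Dn reduce to closed forms of the hand's harmonic parameters.
    """
    amps, phases = subject.hand_harmonics(hand)
    if amps[0] <= 0:
        raise ValueError("ground-truth A0 must be positive")
    power = amps[0] ** 2 + np.sum(amps[1:] ** 2) / 2.0
    E = np.empty(N_ORDERS)
    E[0] = amps[0] ** 2 / power
    E[1:] = amps[1:] ** 2 / 2.0 / power
    return HarmonicSummary(
        C=amps / amps[0], P=np.where(amps > 0, phases, 0.0), D=E,
        C_cv=np.zeros(N_ORDERS), P_cv=np.zeros(N_ORDERS), D_cv=np.zeros(N_ORDERS),
        n_beats=0,
    )


def zero_jitter(subject: SubjectTruth) -> SubjectTruth:
    """Copy of a subject with all stochastic record-level effects disabled."""
    return replace(
        subject, amp_jitter_cv=0.0, phase_jitter_sd=0.0, period_cv=0.0,
        noise_sd=0.0, drift_amplitude=0.0,
    )
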