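"""Beat segmentation: split a continuous PPG record into pulse periods.

Feet (beat onsets) are located as the local minima immediately preceding the
steepest systolic upstrokes of a zero-phase low-pass (10 Hz) smoothed copy of
the record; beats run foot-to-foot on the raw samples.  Partial beats at the
record edges are discarded, and beats with implausible periods or grossly
outlying amplitudes are flagged rejected rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, find_peaks

from pulseharm.errors import InsufficientBeatsError
from pulseharm.io import WaveformRecord

#: physiological pulse period window in seconds (30-200 bpm)
PERIOD_BOUNDS_S = (0.3, 2.0)
#: amplitude rejection threshold: |ptp - median| > 4 * MAD
AMPLITUDE_MAD_FACTOR = 4.0
#: low-pass cutoff used only for foot localization, Hz
SMOOTHING_CUTOFF_HZ = 10.0
DEFAULT_BEAT_LENGTH = 256
MIN_ACCEPTED_BEATS = 5


@dataclass
class BeatSeries:
    """Foot-to-foot beats of one record with per-beat quality flags."""

    beats: list[np.ndarray]
    periods: np.ndarray  # seconds
    quality_flags: np.ndarray  # bool, True = accepted
    sampling_rate: float

    @property
    def accepted(self) -> list[np.ndarray]:
        return [b for b, ok in zip(self.beats, self.quality_flags) if ok]

    @property
    def n_accepted(self) -> int:
        return int(np.sum(self.quality_flags))


def _smooth(samples: np.ndarray, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    cutoff = min(SMOOTHING_CUTOFF_HZ, 0.8 * nyq)
    b, a = butter(4, cutoff / nyq)
    return filtfilt(b, a, samples)


def _detect_feet(samples: np.ndarray, fs: float) -> np.ndarray:
    """Indices of beat onsets (waveform feet)."""
    smoothed = _smooth(samples, fs)
    slope = np.gradient(smoothed)
    max_slope = float(np.max(slope)) if slope.size else 0.0
    if max_slope <= 0 or np.ptp(smoothed) < 1e-12 * max(1.0, np.max(np.abs(smoothed))):
        return np.array([], dtype=int)
    # dominant pulse period from the autocorrelation of the smoothed record:
    # using ~0.7 of it as the minimum upstroke spacing stops dicrotic waves
    # from being counted as extra beats
    centered = smoothed - smoothed.mean()
    acf = np.correlate(centered, centered, mode="full")[centered.size - 1 :]
    lo_lag = int(round(PERIOD_BOUNDS_S[0] * fs))
    hi_lag = min(int(round(PERIOD_BOUNDS_S[1] * fs)), acf.size - 1)
    if hi_lag <= lo_lag:
        return np.array([], dtype=int)
    period_est = lo_lag + int(np.argmax(acf[lo_lag : hi_lag + 1]))
    min_dist = max(1, int(round(0.7 * period_est)))
    # two-pass threshold: the median candidate upstroke slope is robust to a
    # single grossly rescaled beat, unlike the global maximum
    candidates, props = find_peaks(slope, height=1e-3 * max_slope, distance=min_dist)
    if candidates.size == 0:
        return np.array([], dtype=int)
    threshold = 0.3 * float(np.median(props["peak_heights"]))
    upstrokes = candidates[props["peak_heights"] >= threshold]
    # the foot is the waveform minimum between consecutive upstrokes; the
    # stretch before the first detected upstroke is a partial beat and skipped
    feet = []
    for lo, up in zip(upstrokes[:-1], upstrokes[1:]):
        f = lo + int(np.argmin(smoothed[lo : up + 1]))
        # a true foot is a local minimum; record-edge minima are partial beats
        if 0 < f < smoothed.size - 1 and smoothed[f] <= smoothed[f - 1] and smoothed[f] <= smoothed[f + 1]:
            feet.append(f)
    return np.unique(np.asarray(feet, dtype=int))


def segment_beats(
    record: WaveformRecord, min_beats: int = MIN_ACCEPTED_BEATS
) -> BeatSeries:
    """Split a record into foot-to-foot beats with quality flags.

    Beats with a period outside 0.3-2.0 s, or whose peak-to-peak amplitude
    deviates from the record median by more than 4 median absolute deviations,
    are flagged rejected.  Raises :class:`InsufficientBeatsError` when fewer
    than ``min_beats`` beats survive.
    """
    samples = np.asarray(record.samples, dtype=float)
    fs = record.sampling_rate
    if samples.size < 5 * fs:
        raise ValueError("record shorter than 5 s cannot be segmented reliably")
    feet = _detect_feet(samples, fs)
    if feet.size < 2:
        raise InsufficientBeatsError(
            f"found {max(feet.size - 1, 0)} beats, need >= {min_beats}"
        )
    beats = [samples[a:b] for a, b in zip(feet[:-1], feet[1:])]
    periods = np.diff(feet) / fs

    flags = (periods >= PERIOD_BOUNDS_S[0]) & (periods <= PERIOD_BOUNDS_S[1])
    ptp = np.array([np.ptp(b) for b in beats])
    med = np.median(ptp)
    mad = np.median(np.abs(ptp - med))
    scale = max(mad, 1e-9 * max(med, 1.0))
    flags &= np.abs(ptp - med) <= AMPLITUDE_MAD_FACTOR * scale
    series = BeatSeries(
        beats=beats, periods=periods, quality_flags=flags, sampling_rate=fs
    )
    if series.n_accepted < min_beats:
        raise InsufficientBeatsError(
            f"only {series.n_accepted} accepted beats, need >= {min_beats}"
        )
    return series


def resample_beat(beat: np.ndarray, n_points: int = DEFAULT_BEAT_LENGTH) -> np.ndarray:
    """Resample one beat onto exactly ``n_points`` uniform points per period.

    Uses a periodic cubic spline (the beat is one period foot-to-foot, so the
    next sample after the last is the first of the next period); a beat whose
    length already equals ``n_points`` is returned unchanged up to
    interpolation round-off at the grid points.
    """
    beat = np.asarray(beat, dtype=float)
    if beat.size < 24:
        raise ValueError(f"beat too short to resample: {beat.size} < 24 samples")
    if n_points < 24:
        raise ValueError(f"n_points must be >= 24, got {n_points}")
    L = beat.size
    x = np.arange(L + 1)
    y = np.concatenate([beat, beat[:1]])
    spline = CubicSpline(x, y, bc_type="periodic")
    return spline(np.arange(n_points) * (L / n_points))


def beats_to_matrix(series: BeatSeries, beat_length: int = DEFAULT_BEAT_LENGTH):
    """Resample all accepted beats and analyze them into a HarmonicBeatMatrix."""
    from pulseharm.harmonics import HarmonicBeatMatrix

    resampled = [resample_beat(b, beat_length) for b in series.accepted]
    return HarmonicBeatMatrix.from_beats(resampled)
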