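"""Per-beat harmonic decomposition and record-level pulse-harmonic indices.

A single pulse beat resampled to ``L`` points is written as a truncated
Fourier series in cosine-phase (delay) convention

    f(x) = A(0) + sum_{n=1..11} A(n) * cos(2*pi*n*x/L - theta(n)),

where ``A(0)`` is the beat mean, ``A(n) >= 0`` the harmonic amplitude and
``theta(n)`` the phase delay in ``(-pi, pi]``.  Orders 0-11 are used because
they carry essentially all (>98%) of the spectral energy of an arterial
pressure wave.

Record-level indices over the M accepted beats of one hand:

* ``Cn``  — mean over beats of the A(0)-normalized amplitude ``A(n,m)/A(0,m)``
  (dimensionless, sensor-gain invariant),
* ``Pn``  — circular mean over beats of ``theta(n,m)``,
* ``Dn``  — mean over beats of the Parseval energy fraction of order n,
* ``CnCV``, ``PnCV``, ``DnCV`` — beat-to-beat coefficients of variation
  (sample SD / mean; phases are re-branched to within pi of the circular
  mean before the linear CV is taken).

Inter-hand difference features are signed left-minus-right differences
(phases wrapped back to ``(-pi, pi]``) plus their absolute values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pulseharm.errors import PulseharmError

#: Harmonic orders 0..11 inclusive.
N_ORDERS = 12

#: Index families summarized per record.
INDEX_FAMILIES = ("C", "P", "D", "CCV", "PCV", "DCV")

_NEAR_ZERO_PHASE_MEAN = 1e-6


def beat_harmonics(beat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decompose one fixed-length beat into harmonic orders 0-11.

    Parameters
    ----------
    beat
        Samples of a single beat, length ``L >= 24`` (so that order 11 sits
        below the Nyquist order ``L/2``).

    Returns
    -------
    (A, theta, E)
        ``A[n]`` amplitudes (``A[0]`` is the beat mean), ``theta[n]`` phase
        delays in ``(-pi, pi]`` (``theta[0] = 0``; 0 for degenerate orders
        with zero amplitude), ``E[n]`` Parseval energy fractions:
        ``E[0] = A0**2 / P`` and ``E[n] = A_n**2 / 2 / P`` with
        ``P = mean(f**2)`` the total beat power.  ``sum_n E[n] <= 1`` with
        equality when the beat is band-limited to order 11.
    """
    beat = np.asarray(beat, dtype=float)
    if beat.ndim != 1 or beat.size < 24:
        raise ValueError(f"beat must be 1-D with >=24 samples, got shape {beat.shape}")
    L = beat.size
    spec = np.fft.rfft(beat)
    A = np.empty(N_ORDERS)
    theta = np.zeros(N_ORDERS)
    A[0] = spec[0].real / L
    A[1:] = 2.0 * np.abs(spec[1:N_ORDERS]) / L
    # amplitude below machine-noise of the beat scale -> phase undefined, report 0
    tol = 1e-12 * max(1.0, float(np.max(np.abs(beat))))
    nz = A[1:] > tol
    theta[1:][nz] = wrap_phase(-np.angle(spec[1:N_ORDERS][nz]))
    power = float(np.mean(beat**2))
    if power <= 0.0:
        E = np.zeros(N_ORDERS)
    else:
        E = np.empty(N_ORDERS)
        E[0] = A[0] ** 2 / power
        E[1:] = A[1:] ** 2 / 2.0 / power
    return A, theta, E


def spectral_energy_fraction(beat: np.ndarray, max_order: int = N_ORDERS - 1) -> float:
    """Fraction of total spectral energy carried by orders ``0..max_order``.

    Uses the full discrete spectrum (Parseval: ``mean(f**2)`` equals the sum
    of per-order energies including the Nyquist bin), so the result is exact
    for any beat, band-limited or not.
    """
    beat = np.asarray(beat, dtype=float)
    power = float(np.mean(beat**2))
    if power <= 0.0:
        raise ValueError("zero-power beat has no defined energy fraction")
    L = beat.size
    spec = np.fft.rfft(beat)
    energies = 2.0 * np.abs(spec) ** 2 / L**2
    energies[0] = np.abs(spec[0]) ** 2 / L**2
    if L % 2 == 0:
        energies[-1] = np.abs(spec[-1]) ** 2 / L**2
    # the ratio is <= 1 by construction; clip floating-point excess
    return float(min(1.0, np.sum(energies[: max_order + 1]) / np.sum(energies)))


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to the principal branch ``(-pi, pi]``."""
    wrapped = -np.mod(-np.asarray(phi) + np.pi, 2.0 * np.pi) + np.pi
    if np.ndim(phi) == 0:
        return float(wrapped)
    return wrapped


def circular_mean(phases: np.ndarray) -> float:
    """Mean direction of angles on the unit circle, in ``(-pi, pi]``."""
    phases = np.asarray(phases, dtype=float)
    return float(wrap_phase(np.angle(np.mean(np.exp(1j * phases)))))


@dataclass
class HarmonicBeatMatrix:
    """Per-beat harmonic coefficients of one hand's record.

    ``A``, ``theta`` and ``E`` are ``(12, M)`` arrays over harmonic order n
    (rows) and accepted beat m (columns).
    """

    A: np.ndarray
    theta: np.ndarray
    E: np.ndarray

    @property
    def n_beats(self) -> int:
        return self.A.shape[1]

    def __post_init__(self) -> None:
        for name in ("A", "theta", "E"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[0] != N_ORDERS:
                raise ValueError(f"{name} must have shape (12, M), got {arr.shape}")
            setattr(self, name, arr)
        if np.any(self.A < 0):
            raise ValueError("amplitudes must be non-negative")

    @classmethod
    def from_beats(cls, beats: list[np.ndarray]) -> "HarmonicBeatMatrix":
        """Analyze a list of fixed-length beats into the (order, beat) matrices."""
        cols = [beat_harmonics(b) for b in beats]
        A = np.stack([c[0] for c in cols], axis=1)
        theta = np.stack([c[1] for c in cols], axis=1)
        E = np.stack([c[2] for c in cols], axis=1)
        return cls(A=A, theta=theta, E=E)


@dataclass
class HarmonicSummary:
    """Record-level indices per order: Cn, Pn, Dn and their CVs.

    ``C[0] == 1`` and ``P[0] == 0`` by construction (A0-normalization); they
    carry no information and are dropped from candidate predictors downstream.
    """

    C: np.ndarray
    P: np.ndarray
    D: np.ndarray
    C_cv: np.ndarray
    P_cv: np.ndarray
    D_cv: np.ndarray
    n_beats: int = 0
    #: orders whose PnCV denominator |mean phase| fell below 1e-6 and was floored
    near_zero_phase_mean: tuple[int, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for fam, arr in (("C", self.C), ("P", self.P), ("D", self.D),
                         ("CCV", self.C_cv), ("PCV", self.P_cv), ("DCV", self.D_cv)):
            if fam.endswith("CV"):
                names = [f"{fam[0]}{n}CV" for n in range(N_ORDERS)]
            else:
                names = [f"{fam}{n}" for n in range(N_ORDERS)]
            out.update(zip(names, arr.tolist()))
        return out


def _linear_cv(values: np.ndarray) -> np.ndarray:
    """Row-wise sample SD / mean, 0 where the rows are constant-zero."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    denom = np.where(np.abs(mean) > 0, np.abs(mean), 1.0)
    return np.where(np.abs(mean) > 0, sd / denom, 0.0)


def summarize_record(matrix: HarmonicBeatMatrix, min_beats: int = 5) -> HarmonicSummary:
    """Collapse per-beat harmonics into record-level Cn/Pn/Dn indices and CVs.

    Per beat m the normalized amplitude is ``a(n,m) = A(n,m) / A(0,m)``;
    ``Cn`` is its mean over beats and ``CnCV`` its sample-SD/mean.  ``Pn`` is
    the circular mean of ``theta(n, .)``; ``PnCV`` is the linear SD/|mean| of
    the phases after re-branching each one to within pi of the circular mean
    (a plain linear CV is ill-defined for circular data).  ``Dn``/``DnCV``
    summarize the energy fractions.

    Raises
    ------
    InsufficientBeatsError
        Fewer than ``min_beats`` beats.
    PulseharmError
        Any beat with non-positive mean A(0,m) (non-physiological record).
    """
    from pulseharm.errors import InsufficientBeatsError

    M = matrix.n_beats
    if M < min_beats:
        raise InsufficientBeatsError(f"need >= {min_beats} beats, got {M}")
    A0 = matrix.A[0]
    if np.any(A0 <= 0):
        bad = int(np.argmax(A0 <= 0))
        raise PulseharmError(f"non-positive beat mean A(0,m) at beat {bad}")
    a = matrix.A / A0  # a[0] == 1 for every beat

    C = a.mean(axis=1)
    C_cv = _linear_cv(a)
    D = matrix.E.mean(axis=1)
    D_cv = _linear_cv(matrix.E)

    P = np.zeros(N_ORDERS)
    P_cv = np.zeros(N_ORDERS)
    flagged: list[int] = []
    for n in range(1, N_ORDERS):
        mu = circular_mean(matrix.theta[n])
        P[n] = mu
        # re-branch each phase to the branch nearest the circular mean
        rebranched = mu + wrap_phase(matrix.theta[n] - mu)
        m = rebranched.mean()
        sd = rebranched.std(ddof=1)
        if abs(m) < _NEAR_ZERO_PHASE_MEAN:
            flagged.append(n)
            m = _NEAR_ZERO_PHASE_MEAN
        P_cv[n] = sd / abs(m)
    return HarmonicSummary(C=C, P=P, D=D, C_cv=C_cv, P_cv=P_cv, D_cv=D_cv,
                           n_beats=M, near_zero_phase_mean=tuple(flagged))


@dataclass
class FeatureVector:
    """Signed (left minus right) and absolute inter-hand difference features."""

    dC: np.ndarray
    dP: np.ndarray
    dD: np.ndarray
    dC_cv: np.ndarray
    dP_cv: np.ndarray
    dD_cv: np.ndarray

    def as_dict(self, include_absolute: bool = True) -> dict[str, float]:
        """Flatten to the CSV column naming: dC9CV for |delta|-free indices,
        prefix ``absd`` for absolute values (e.g. absdC10 for |ΔC10|)."""
        out: dict[str, float] = {}
        for fam, arr in self.signed_items():
            for n in range(N_ORDERS):
                name = _column_name(fam, n)
                out[name] = float(arr[n])
                if include_absolute:
                    out["abs" + name] = abs(float(arr[n]))
        return out

    def signed_items(self):
        return (("C", self.dC), ("P", self.dP), ("D", self.dD),
                ("CCV", self.dC_cv), ("PCV", self.dP_cv), ("DCV", self.dD_cv))


def _column_name(family: str, order: int) -> str:
    if family.endswith("CV"):
        return f"d{family[0]}{order}CV"
    return f"d{family}{order}"


def feature_column_names(include_absolute: bool = True) -> list[str]:
    """All feature column names in canonical order (signed, then absolute)."""
    signed = [_column_name(fam, n) for fam in INDEX_FAMILIES for n in range(N_ORDERS)]
    if not include_absolute:
        return signed
    return signed + ["abs" + c for c in signed]


def inter_hand_differences(left: HarmonicSummary, right: HarmonicSummary) -> FeatureVector:
    """Signed left-minus-right differences of every record-level index.

    Phase differences are wrapped to ``(-pi, pi]`` before any absolute value
    is taken, so e.g. phases +3.0 and -3.0 differ by ``-(2*pi - 6.0)``, not 6.
    CVs and energies subtract linearly.  Antisymmetric: swapping hands negates
    every signed entry.
    """
    return FeatureVector(
        dC=left.C - right.C,
        dP=wrap_phase(left.P - right.P),
        dD=left.D - right.D,
        dC_cv=left.C_cv - right.C_cv,
        dP_cv=left.P_cv - right.P_cv,
        dD_cv=left.D_cv - right.D_cv,
    )
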