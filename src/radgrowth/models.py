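"""Tumour growth laws, linear-quadratic cell kill, and the continuous
radiation death-rate term.

Three growth laws are supported (exponential, logistic, exponential-linear).
Radiotherapy enters either impulsively (see :mod:`radgrowth.solver`) or as a
continuous death rate: each fraction removes the LQ-predicted kill spread
uniformly over a short treatment window, switched on and off by a smooth
tanh approximation of the Heaviside step so the right-hand side stays
continuous — a requirement for Caputo fractional dynamics.

Time is measured in days (non-dimensionalized by a 1-day characteristic
scale); volumes in cm^3.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError, ProtocolError, ValidationError

__all__ = [
    "GrowthLaw",
    "GrowthParameters",
    "RadiationParameters",
    "TreatmentProtocol",
    "TumourTimeSeries",
    "ModelSpec",
    "growth_rate",
    "lq_survival_fraction",
    "smooth_heaviside",
    "death_rate",
    "treated_rhs",
    "standard_fractionation",
    "DEFAULT_TW",
    "DEFAULT_EPSILON",
    "DEFAULT_PSI",
]

#: Default treatment-window length: 15 minutes expressed in days.
DEFAULT_TW = 1.0 / 96.0
#: Default smoothing width of the tanh Heaviside approximation (days).
DEFAULT_EPSILON = 1e-5
#: Default sharpness of the exponential-to-linear transition.
DEFAULT_PSI = 20.0


class GrowthLaw(str, enum.Enum):
    EXPONENTIAL = "exponential"
    LOGISTIC = "logistic"
    EXPONENTIAL_LINEAR = "exponential_linear"


def _as_law(law: "GrowthLaw | str") -> GrowthLaw:
    if isinstance(law, GrowthLaw):
        return law
    try:
        return GrowthLaw(law)
    except ValueError as exc:
        raise ConfigurationError(f"unknown growth law: {law!r}") from exc


@dataclass(frozen=True)
class GrowthParameters:
    """Parameters of one growth law; fields irrelevant to ``law`` stay None.

    ``a`` is the exponential / intrinsic rate (per day), ``K`` the logistic
    carrying capacity (cm^3), ``lambda0`` the early exponential rate (per
    day), ``lambda1`` the late linear rate (cm^3 per day) and ``psi`` the
    transition sharpness of the exponential-linear law.
    """

    law: GrowthLaw
    a: float | None = None
    K: float | None = None
    lambda0: float | None = None
    lambda1: float | None = None
    psi: float = DEFAULT_PSI

    def __post_init__(self) -> None:
        object.__setattr__(self, "law", _as_law(self.law))
        if self.psi < 1:
            raise ConfigurationError(f"psi must be >= 1, got {self.psi}")
        if self.law is GrowthLaw.EXPONENTIAL:
            self._require_positive(a=self.a)
        elif self.law is GrowthLaw.LOGISTIC:
            self._require_positive(a=self.a, K=self.K)
        else:
            self._require_positive(lambda0=self.lambda0, lambda1=self.lambda1)

    def _require_positive(self, **fields: float | None) -> None:
        for name, value in fields.items():
            if value is None:
                raise ConfigurationError(
                    f"{self.law.value} law requires parameter {name!r}"
                )
            if not (value > 0) or not math.isfinite(value):
                raise ConfigurationError(
                    f"parameter {name!r} must be finite and > 0, got {value}"
                )


@dataclass(frozen=True)
class RadiationParameters:
    """LQ radio-sensitivities ``alpha`` (1/Gy), ``beta`` (1/Gy^2) and the
    Heaviside smoothing width ``epsilon`` (days)."""

    alpha: float
    beta: float
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ConfigurationError(
                f"alpha and beta must be >= 0, got alpha={self.alpha}, beta={self.beta}"
            )
        if not (0 < self.epsilon < 1e-2):
            raise ConfigurationError(
                f"epsilon must lie in (0, 1e-2), got {self.epsilon}"
            )

    @classmethod
    def from_alpha(
        cls, alpha: float, ratio: float = 10.0, epsilon: float = DEFAULT_EPSILON
    ) -> "RadiationParameters":
        """Build from ``alpha`` alone under the fixed alpha/beta ratio
        (default 10 Gy, the head-and-neck convention)."""
        return cls(alpha=alpha, beta=alpha / ratio, epsilon=epsilon)


@dataclass(frozen=True)
class TreatmentProtocol:
    """A fractionation schedule: constant dose per fraction, strictly
    increasing treatment times (days) and the window length ``tw`` (days)
    over which each fraction's kill is spread."""

    dose_per_fraction: float
    treatment_times: tuple[float, ...]
    tw: float = DEFAULT_TW

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.treatment_times)
        object.__setattr__(self, "treatment_times", times)
        if self.dose_per_fraction < 0:
            raise ProtocolError("dose_per_fraction must be >= 0")
        if not (self.tw > 0):
            raise ProtocolError(f"tw must be > 0, got {self.tw}")
        arr = np.asarray(times, dtype=float)
        if arr.size and not np.all(np.diff(arr) > 0):
            raise ProtocolError("treatment_times must be strictly increasing")
        if arr.size and np.any(np.diff(arr) <= self.tw):
            raise ProtocolError(
                f"treatment windows overlap: spacing must exceed tw={self.tw}"
            )

    @property
    def times_array(self) -> np.ndarray:
        return np.asarray(self.treatment_times, dtype=float)

    @property
    def n_fractions(self) -> int:
        return len(self.treatment_times)

    @property
    def total_dose(self) -> float:
        return self.dose_per_fraction * self.n_fractions

    @property
    def last_time(self) -> float:
        return self.treatment_times[-1] if self.treatment_times else 0.0

    def with_tw(self, tw: float) -> "TreatmentProtocol":
        return TreatmentProtocol(self.dose_per_fraction, self.treatment_times, tw)


@dataclass
class TumourTimeSeries:
    """Measured (day, volume) pairs for one patient.  The model clock
    starts at the first measurement, so ``times[0]`` must be 0."""

    times: np.ndarray
    volumes: np.ndarray
    patient_id: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.volumes.shape:
            raise ValidationError("times and volumes must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise ValidationError("time series is empty")
        if abs(self.times[0]) > 1e-12:
            raise ValidationError(
                f"times[0] must be 0 (clock starts at first measurement), got {self.times[0]}"
            )
        bad = np.nonzero(np.diff(self.times) <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"times must be strictly increasing; violation at row {bad[0] + 1}"
            )
        bad = np.nonzero(~(self.volumes > 0))[0]
        if bad.size:
            raise ValidationError(
                f"volumes must be strictly positive; violation at row {bad[0]}"
            )

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def v0(self) -> float:
        return float(self.volumes[0])


@dataclass(frozen=True)
class ModelSpec:
    """A fully specified treated model: growth law + radiation response +
    fractional order (``mu = 1`` is the ordinary case)."""

    growth: GrowthParameters
    radiation: RadiationParameters
    mu: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.mu <= 1):
            raise DomainError(f"fractional order mu must lie in (0, 1], got {self.mu}")

    @property
    def fractional(self) -> bool:
        return self.mu < 1.0


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def growth_rate(p: GrowthParameters, v):
    """Untreated growth rate dv/dt (cm^3/day) at volume ``v``.

    Accepts scalars or arrays.  The exponential-linear law is evaluated in
    log space so it stays finite far beyond the transition volume.
    """
    v_arr = np.asarray(v, dtype=float)
    if np.any(v_arr < 0):
        raise DomainError("volume must be >= 0")
    if p.law is GrowthLaw.EXPONENTIAL:
        out = p.a * v_arr
    elif p.law is GrowthLaw.LOGISTIC:
        out = p.a * v_arr * (1.0 - v_arr / p.K)
    else:
        # lam0*v * (1 + (lam0*v/lam1)^psi)^(-1/psi); the bracket is
        # exp(-log1p(exp(psi*log(lam0*v/lam1)))/psi), with the large-x branch
        # log1p(e^x) = x + log1p(e^-x) to avoid overflow.
        with np.errstate(divide="ignore"):
            x = p.psi * (np.log(p.lambda0 * v_arr) - math.log(p.lambda1))
        x = np.where(v_arr > 0, x, -np.inf)
        log_bracket = np.where(
            x > 0,
            x + np.log1p(np.exp(-np.abs(x))),
            np.log1p(np.exp(np.minimum(x, 0.0))),
        )
        out = p.lambda0 * v_arr * np.exp(-log_bracket / p.psi)
    return out if isinstance(out, np.ndarray) and np.ndim(v) else float(out)


def lq_survival_fraction(r: RadiationParameters, d: float) -> float:
    """Linear-quadratic surviving fraction exp(-alpha*d - beta*d^2)."""
    if d < 0:
        raise DomainError(f"dose must be >= 0, got {d}")
    return math.exp(-r.alpha * d - r.beta * d * d)


def smooth_heaviside(t, epsilon: float = DEFAULT_EPSILON):
    """Smooth step (1 + tanh(t/epsilon))/2; accepts scalars or arrays."""
    if not (epsilon > 0):
        raise ConfigurationError(f"epsilon must be > 0, got {epsilon}")
    out = 0.5 * (1.0 + np.tanh(np.asarray(t, dtype=float) / epsilon))
    return out if np.ndim(t) else float(out)


def window_train(proto: TreatmentProtocol, t, epsilon: float, cutoff: float | None = None):
    """Sum over fractions of [H(t-tau_i) - H(t-tau_i-tw)] / tw.

    Each term integrates to exactly 1 over time, so the train carries unit
    kill per fraction.  Terms whose window lies further than ``cutoff``
    (default 50*epsilon) from ``t`` are dropped; the tanh tail bounds the
    resulting error below ~1e-40.
    """
    if cutoff is None:
        cutoff = 50.0 * epsilon
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    taus = proto.times_array
    if taus.size == 0:
        total = np.zeros_like(t_arr)
    else:
        dt = t_arr[:, None] - taus[None, :]  # (nt, n_fractions)
        active = (dt >= -cutoff) & (dt <= proto.tw + cutoff)
        term = np.where(
            active,
            smooth_heaviside(dt, epsilon) - smooth_heaviside(dt - proto.tw, epsilon),
            0.0,
        )
        total = term.sum(axis=1)
    total /= proto.tw
    return total if np.ndim(t) else float(total[0])


def death_rate(
    r: RadiationParameters,
    proto: TreatmentProtocol,
    t,
    v,
    cutoff: float | None = None,
):
    """Continuous radiation-induced death rate (cm^3/day).

    v * (1 - SF) * sum_i [H(t-tau_i) - H(t-tau_i-tw)] / tw, where SF is the
    per-fraction LQ surviving fraction.
    """
    if np.any(np.asarray(v) < 0):
        raise DomainError("volume must be >= 0")
    sf = lq_survival_fraction(r, proto.dose_per_fraction)
    out = np.asarray(v, dtype=float) * (1.0 - sf) * window_train(proto, t, r.epsilon, cutoff)
    return out if (np.ndim(v) or np.ndim(t)) else float(out)


def treated_rhs(
    p: GrowthParameters,
    r: RadiationParameters,
    proto: TreatmentProtocol,
    t,
    v,
):
    """Full right-hand side: growth minus continuous death rate.

    Continuous in ``t`` by construction, which is what makes the Caputo
    fractional variants well posed.
    """
    return growth_rate(p, v) - death_rate(r, proto, t, v)


def standard_fractionation(
    total_dose: float,
    dose_per_fraction: float = 2.0,
    start_day: float = 0.0,
    tw: float = DEFAULT_TW,
    start_weekday: int = 0,
) -> TreatmentProtocol:
    """Weekday-only fractionation: 5 fractions on / 2 off, one per day.

    ``start_weekday`` is 0 for Monday through 4 for Friday; ``start_day`` is
    the model-clock day of the first fraction.
    """
    n_frac = total_dose / dose_per_fraction
    if abs(n_frac - round(n_frac)) > 1e-9:
        raise ConfigurationError(
            f"total_dose {total_dose} is not divisible by dose_per_fraction {dose_per_fraction}"
        )
    n_frac = int(round(n_frac))
    if not 0 <= start_weekday <= 4:
        raise ConfigurationError("start_weekday must be a weekday index 0..4")
    times = []
    for k in range(n_frac):
        w = start_weekday + k
        day = start_day + (w // 5) * 7 + (w % 5) - start_weekday
        times.append(float(day))
    return TreatmentProtocol(dose_per_fraction, tuple(times), tw)
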