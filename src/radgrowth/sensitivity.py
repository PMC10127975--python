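"""Dynamic local relative-sensitivity analysis.

For a parameter p with nominal value p0 and nominal trajectory v0(t), the
relative sensitivity curve is the one-sided finite difference

    S(t) = [v(t; p0 + dp) - v(t; p0)] / v0(t) * p0 / dp,

with dp = direction * rel_step * p0 (1% by default).  Two solver runs per
curve, both with the solver settings used for the fit so numerical error
does not masquerade as parameter effect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DirectionError, DomainError
from .models import ModelSpec, RadiationParameters, TreatmentProtocol
from .solver import DEFAULT_STEP, solve_treated

__all__ = ["SensitivityCurve", "relative_sensitivity", "perturb_spec"]

_GROWTH_FIELDS = {"a", "K", "lambda0", "lambda1", "psi"}
_RADIATION_FIELDS = {"alpha", "beta"}


@dataclass
class SensitivityCurve:
    parameter: str
    direction: int
    rel_step: float
    t: np.ndarray
    values: np.ndarray

    @property
    def final(self) -> float:
        return float(self.values[-1])


def _applicable(spec: ModelSpec, parameter: str) -> bool:
    if parameter == "mu" or parameter in _RADIATION_FIELDS:
        return True
    if parameter not in _GROWTH_FIELDS:
        raise ConfigurationError(f"unknown parameter {parameter!r}")
    return getattr(spec.growth, parameter) is not None


def perturb_spec(
    spec: ModelSpec,
    parameter: str,
    direction: int,
    rel_step: float,
    honour_alpha_beta_ratio: bool = True,
) -> ModelSpec:
    """Return a copy of ``spec`` with one parameter nudged by
    ``direction * rel_step`` relative.  Perturbing alpha drags beta along
    when the alpha/beta constraint is honoured (the fitting assumption)."""
    if direction not in (-1, 1):
        raise ConfigurationError(f"direction must be +1 or -1, got {direction}")
    factor = 1.0 + direction * rel_step
    if parameter == "mu":
        new_mu = spec.mu * factor
        if new_mu > 1.0:
            raise DirectionError(
                f"mu + {rel_step:.0%} = {new_mu:.6f} exceeds the admissible bound 1; "
                "perturb with direction=-1 instead"
            )
        return dataclasses.replace(spec, mu=new_mu)
    if parameter in _RADIATION_FIELDS:
        r = spec.radiation
        if parameter == "alpha":
            new_alpha = r.alpha * factor
            new_beta = new_alpha / (r.alpha / r.beta) if (honour_alpha_beta_ratio and r.beta > 0) else r.beta
            radiation = RadiationParameters(alpha=new_alpha, beta=new_beta, epsilon=r.epsilon)
        else:
            radiation = RadiationParameters(alpha=r.alpha, beta=r.beta * factor, epsilon=r.epsilon)
        return dataclasses.replace(spec, radiation=radiation)
    if parameter in _GROWTH_FIELDS:
        value = getattr(spec.growth, parameter)
        if value is None:
            raise ConfigurationError(
                f"parameter {parameter!r} does not apply to the {spec.growth.law.value} law"
            )
        growth = dataclasses.replace(spec.growth, **{parameter: value * factor})
        return dataclasses.replace(spec, growth=growth)
    raise ConfigurationError(f"unknown parameter {parameter!r}")


def relative_sensitivity(
    spec: ModelSpec,
    proto: TreatmentProtocol,
    v0: float,
    parameter: str,
    direction: int = 1,
    rel_step: float = 0.01,
    t_end: float = 50.0,
    h: float = DEFAULT_STEP,
    corrector_iterations: int = 1,
    honour_alpha_beta_ratio: bool = True,
) -> SensitivityCurve:
    """Relative sensitivity curve of the predicted volume to one parameter.

    A parameter that does not enter the model (e.g. alpha with no
    treatment) yields an identically-zero curve.
    """
    nominal = solve_treated(spec, proto, v0, t_end, h=h, corrector_iterations=corrector_iterations)
    if np.any(nominal.v <= 0):
        raise DomainError("nominal trajectory must stay strictly positive")
    if not _applicable(spec, parameter):
        return SensitivityCurve(parameter, direction, rel_step, nominal.t, np.zeros_like(nominal.v))
    perturbed_spec = perturb_spec(spec, parameter, direction, rel_step, honour_alpha_beta_ratio)
    perturbed = solve_treated(
        perturbed_spec, proto, v0, t_end, h=h, corrector_iterations=corrector_iterations
    )
    values = (perturbed.v - nominal.v) / (nominal.v * direction * rel_step)
    return SensitivityCurve(parameter, direction, rel_step, nominal.t, values)
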