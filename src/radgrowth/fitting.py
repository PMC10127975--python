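"""SSR objective and bounded multistart fitting of the treated models.

Six model variants are fitted: the three growth laws in ordinary form and
their Caputo-fractional counterparts.  Fixed modelling assumptions (kept
as flags on :class:`FitConfig`): alpha/beta = 10 Gy so beta is derived
from alpha, the logistic carrying capacity K = 2 * v0, psi = 20, and the
treatment window length.  Fitted parameter counts are therefore

=====================  ==========  =========
variant                parameters  count (K)
=====================  ==========  =========
exponential            a, alpha           2
logistic               a, alpha           2
exponential-linear     l0, l1, alpha      3
fractional variants    ... + mu          +1
=====================  ==========  =========
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
import numpy as np
from scipy.optimize import minimize

from .errors import ConfigurationError, DomainError, IntegrationError, ValidationError
from .models import (
    DEFAULT_PSI,
    GrowthLaw,
    GrowthParameters,
    ModelSpec,
    RadiationParameters,
    TreatmentProtocol,
    TumourTimeSeries,
)
from .solver import DEFAULT_STEP, Trajectory, solve_treated

__all__ = ["FitConfig", "FitResult", "ssr", "fit_model", "n_fitted_parameters"]

_PENALTY = 1e12  # objective value for failed integrations


@dataclass(frozen=True)
class FitConfig:
    """Optimizer configuration and fixed modelling assumptions."""

    n_starts: int = 20
    seed: int = 0
    h: float = DEFAULT_STEP
    corrector_iterations: int = 1
    # bounds
    rate_bounds: tuple[float, float] = (0.001, 1.0)  # a, lambda0, lambda1, mu
    alpha_bounds: tuple[float, float] = (1e-9, 10.0)  # finite cap on an open-ended range
    # initial-guess sampling ranges (clipped into bounds)
    rate_guess_range: tuple[float, float] = (0.0, 0.1)  # a, alpha, lambda0
    lambda1_guess_range: tuple[float, float] = (0.0, 1.0)
    mu_initial: float = 0.5
    # fixed assumptions
    alpha_beta_ratio: float = 10.0
    k_capacity_factor: float = 2.0  # K = factor * v0
    psi: float = DEFAULT_PSI
    epsilon: float = 1e-5
    # optimizer
    maxiter: int = 200
    fd_rel_step: float = 1e-6


@dataclass
class FitResult:
    """Outcome of one multistart fit."""

    law: str
    fractional: bool
    parameters: dict[str, float]
    ssr: float
    n: int
    n_params: int
    v0: float
    success: bool
    message: str
    best_start: int
    n_starts: int
    seed: int
    h: float
    corrector_iterations: int

    @property
    def mu(self) -> float:
        return self.parameters.get("mu", 1.0)

    def model_spec(self) -> ModelSpec:
        """Rebuild the fitted :class:`ModelSpec` (including derived beta/K)."""
        p = self.parameters
        law = GrowthLaw(self.law)
        if law is GrowthLaw.EXPONENTIAL:
            growth = GrowthParameters(law=law, a=p["a"])
        elif law is GrowthLaw.LOGISTIC:
            growth = GrowthParameters(law=law, a=p["a"], K=p["K"])
        else:
            growth = GrowthParameters(
                law=law, lambda0=p["lambda0"], lambda1=p["lambda1"], psi=p.get("psi", DEFAULT_PSI)
            )
        radiation = RadiationParameters(
            alpha=p["alpha"], beta=p["beta"], epsilon=p.get("epsilon", 1e-5)
        )
        return ModelSpec(growth=growth, radiation=radiation, mu=self.mu)

    def to_dict(self) -> dict:
        return asdict(self)


def n_fitted_parameters(law: GrowthLaw | str, fractional: bool) -> int:
    law = GrowthLaw(law)
    k = 3 if law is GrowthLaw.EXPONENTIAL_LINEAR else 2
    return k + (1 if fractional else 0)


def ssr(observed: TumourTimeSeries, trajectory: Trajectory) -> float:
    """Sum of squared residuals between data and the model trajectory,
    linearly interpolated at the measurement times."""
    if observed.times[-1] > trajectory.t[-1] + 1e-9:
        raise ValidationError(
            f"trajectory ends at t={trajectory.t[-1]} but data extend to "
            f"t={observed.times[-1]}"
        )
    pred = trajectory.at(observed.times)
    resid = pred - observed.volumes
    return float(np.dot(resid, resid))


def _build_spec(
    theta: np.ndarray,
    law: GrowthLaw,
    fractional: bool,
    v0: float,
    config: FitConfig,
) -> ModelSpec:
    mu = float(theta[-1]) if fractional else 1.0
    alpha = float(theta[-2]) if fractional else float(theta[-1])
    if law is GrowthLaw.EXPONENTIAL:
        growth = GrowthParameters(law=law, a=float(theta[0]))
    elif law is GrowthLaw.LOGISTIC:
        growth = GrowthParameters(law=law, a=float(theta[0]), K=config.k_capacity_factor * v0)
    else:
        growth = GrowthParameters(
            law=law, lambda0=float(theta[0]), lambda1=float(theta[1]), psi=config.psi
        )
    radiation = RadiationParameters(
        alpha=alpha, beta=alpha / config.alpha_beta_ratio, epsilon=config.epsilon
    )
    return ModelSpec(growth=growth, radiation=radiation, mu=min(mu, 1.0))


def _bounds_and_starts(
    law: GrowthLaw, fractional: bool, config: FitConfig, rng: np.random.Generator
) -> tuple[list[tuple[float, float]], np.ndarray]:
    lo_r, hi_r = config.rate_bounds
    bounds: list[tuple[float, float]] = []
    cols: list[np.ndarray] = []

    def sample(rng_range: tuple[float, float], bound: tuple[float, float]) -> np.ndarray:
        raw = rng.uniform(rng_range[0], rng_range[1], size=config.n_starts)
        return np.clip(raw, bound[0], bound[1])

    if law is GrowthLaw.EXPONENTIAL_LINEAR:
        bounds.append((lo_r, hi_r))  # lambda0
        cols.append(sample(config.rate_guess_range, (lo_r, hi_r)))
        bounds.append((lo_r, hi_r))  # lambda1
        cols.append(sample(config.lambda1_guess_range, (lo_r, hi_r)))
    else:
        bounds.append((lo_r, hi_r))  # a
        cols.append(sample(config.rate_guess_range, (lo_r, hi_r)))
    bounds.append(config.alpha_bounds)  # alpha
    cols.append(sample(config.rate_guess_range, config.alpha_bounds))
    if fractional:
        bounds.append((lo_r, 1.0))  # mu
        cols.append(np.full(config.n_starts, config.mu_initial))
    return bounds, np.column_stack(cols)


def fit_model(
    data: TumourTimeSeries,
    law: GrowthLaw | str,
    fractional: bool,
    proto: TreatmentProtocol,
    config: FitConfig | None = None,
) -> FitResult:
    """Bounded multistart SSR minimization for one model variant.

    The initial volume is taken as the first measurement (not fitted);
    beta and K are derived from the fixed assumptions.  Deterministic for
    a given ``config.seed``.
    """
    config = config or FitConfig()
    law = GrowthLaw(law)
    v0 = data.v0
    t_end = float(data.times[-1])
    rng = np.random.default_rng(config.seed)
    bounds, starts = _bounds_and_starts(law, fractional, config, rng)

    def objective(theta: np.ndarray) -> float:
        try:
            spec = _build_spec(theta, law, fractional, v0, config)
            traj = solve_treated(
                spec, proto, v0, t_end, h=config.h,
                corrector_iterations=config.corrector_iterations,
            )
            return ssr(data, traj)
        except (DomainError, ConfigurationError, IntegrationError, OverflowError, FloatingPointError):
            return _PENALTY

    best = None
    best_start = -1
    any_success = False
    message = ""
    for i in range(starts.shape[0]):
        res = minimize(
            objective,
            starts[i],
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.maxiter, "finite_diff_rel_step": config.fd_rel_step},
        )
        if res.fun >= _PENALTY:
            continue
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
            best_start = i
            message = str(res.message)

    n = len(data)
    k = n_fitted_parameters(law, fractional)
    if best is None:
        return FitResult(
            law=law.value, fractional=fractional, parameters={}, ssr=float("inf"),
            n=n, n_params=k, v0=v0, success=False,
            message="all multistarts failed to produce a finite objective",
            best_start=-1, n_starts=config.n_starts, seed=config.seed,
            h=config.h, corrector_iterations=config.corrector_iterations,
        )

    theta = best.x
    params: dict[str, float] = {}
    if law is GrowthLaw.EXPONENTIAL_LINEAR:
        params["lambda0"], params["lambda1"] = float(theta[0]), float(theta[1])
        params["psi"] = config.psi
    else:
        params["a"] = float(theta[0])
        if law is GrowthLaw.LOGISTIC:
            params["K"] = config.k_capacity_factor * v0
    alpha = float(theta[-2]) if fractional else float(theta[-1])
    params["alpha"] = alpha
    params["beta"] = alpha / config.alpha_beta_ratio
    params["epsilon"] = config.epsilon
    if fractional:
        params["mu"] = float(theta[-1])

    return FitResult(
        law=law.value, fractional=fractional, parameters=params, ssr=float(best.fun),
        n=n, n_params=k, v0=v0, success=any_success, message=message,
        best_start=best_start, n_starts=config.n_starts, seed=config.seed,
        h=config.h, corrector_iterations=config.corrector_iterations,
    )
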