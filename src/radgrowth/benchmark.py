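"""Repeated-fit benchmark harness.

Compares three representations of radiation cell kill on one dataset:

* ``death_rate_smooth`` — the continuous tanh-windowed death rate (the
  package default, solved by the fixed-step scheme);
* ``death_rate_hard``  — the same death rate with a sharp (discontinuous)
  indicator window, solved with an adaptive integrator.  Kept only for
  comparison; it is incredibly slow and not recommended;
* ``impulsive``        — stop/restart integration with a multiplicative
  surviving-fraction kick at each fraction.

Each repetition is a single-start seeded fit, so the harness also reports
a "consensus" fraction: the share of repetitions landing within a stated
SSR tolerance of the best SSR found.  Timings are reported, never
asserted — they are hardware facts, not model facts.
"""

from __future__ import annotations

import time

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from .errors import ConfigurationError, IntegrationError
from .fitting import FitConfig, ssr as ssr_of
from .models import (
    GrowthLaw,
    GrowthParameters,
    ModelSpec,
    RadiationParameters,
    TreatmentProtocol,
    TumourTimeSeries,
    growth_rate,
    lq_survival_fraction,
)
from .solver import Trajectory, solve_impulsive, solve_treated

__all__ = ["benchmark_fit", "BENCHMARK_VARIANTS"]

BENCHMARK_VARIANTS = ("death_rate_smooth", "death_rate_hard", "impulsive")


def _solve_hard(
    spec: ModelSpec,
    proto: TreatmentProtocol,
    v0: float,
    t_end: float,
    max_step: float,
) -> Trajectory:
    """Adaptive integration of the death-rate model with a sharp window
    indicator (no tanh smoothing)."""
    taus = proto.times_array
    kill = 1.0 - lq_survival_fraction(spec.radiation, proto.dose_per_fraction)
    tw = proto.tw

    def rhs(t, y):
        v = max(y[0], 0.0)
        active = np.sum((t >= taus) & (t < taus + tw))
        return [growth_rate(spec.growth, v) - v * kill * active / tw]

    sol = solve_ivp(
        rhs, (0.0, t_end), [v0], method="RK45",
        max_step=max_step, rtol=1e-6, atol=1e-9, dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(f"hard-window integration failed: {sol.message}")
    t = np.arange(int(np.ceil(t_end / max_step)) + 1) * max_step
    t = np.clip(t, 0.0, sol.t[-1])
    return Trajectory(t, sol.sol(t)[0], mu=1.0, h=max_step, solver="hard_window_rk45")


def _single_fit(
    variant: str,
    data: TumourTimeSeries,
    proto: TreatmentProtocol,
    start: np.ndarray,
    config: FitConfig,
):
    v0 = data.v0
    t_end = float(data.times[-1])

    def objective(theta):
        a, alpha = float(theta[0]), float(theta[1])
        try:
            growth = GrowthParameters(law=GrowthLaw.EXPONENTIAL, a=a)
            radiation = RadiationParameters(
                alpha=alpha, beta=alpha / config.alpha_beta_ratio, epsilon=config.epsilon
            )
            spec = ModelSpec(growth=growth, radiation=radiation, mu=1.0)
            if variant == "death_rate_smooth":
                traj = solve_treated(spec, proto, v0, t_end, h=config.h,
                                     corrector_iterations=config.corrector_iterations)
            elif variant == "death_rate_hard":
                traj = _solve_hard(spec, proto, v0, t_end, max_step=config.h)
            else:
                traj = solve_impulsive(growth, radiation, proto, v0, t_end,
                                       rtol=1e-8, atol=1e-10)
            return ssr_of(data, traj)
        except (ConfigurationError, IntegrationError, OverflowError):
            return 1e12

    bounds = [config.rate_bounds, config.alpha_bounds]
    res = minimize(objective, start, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": config.maxiter,
                            "finite_diff_rel_step": config.fd_rel_step})
    return res


def benchmark_fit(
    variant: str,
    data: TumourTimeSeries,
    proto: TreatmentProtocol,
    repetitions: int = 1,
    seed: int = 0,
    config: FitConfig | None = None,
    ssr_rel_tol: float = 0.05,
) -> dict:
    """Run ``repetitions`` seeded single-start exponential-model fits with
    the chosen kill representation and time them.

    Returns wall/CPU time per fit, the best SSR and parameters, the
    per-repetition SSRs, and the consensus count (repetitions with SSR
    within ``ssr_rel_tol`` of the best, failures excluded).
    """
    if variant not in BENCHMARK_VARIANTS:
        raise ConfigurationError(
            f"unknown variant {variant!r}; choose one of {BENCHMARK_VARIANTS}"
        )
    if repetitions < 1:
        raise ConfigurationError("repetitions must be >= 1")
    config = config or FitConfig()
    rng = np.random.default_rng(seed)
    starts = np.column_stack([
        rng.uniform(0.0, 0.2, size=repetitions).clip(*config.rate_bounds),
        rng.uniform(0.0, 0.1, size=repetitions).clip(*config.alpha_bounds),
    ])
    ssrs, params, failed = [], [], 0
    wall0 = time.perf_counter()
    cpu0 = time.process_time()
    for i in range(repetitions):
        res = _single_fit(variant, data, proto, starts[i], config)
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            failed += 1
            ssrs.append(float("inf"))
            params.append(None)
        else:
            ssrs.append(float(res.fun))
            params.append({"a": float(res.x[0]), "alpha": float(res.x[1])})
    wall = time.perf_counter() - wall0
    cpu = time.process_time() - cpu0
    finite = [s for s in ssrs if np.isfinite(s)]
    best_ssr = min(finite) if finite else float("inf")
    consensus = sum(1 for s in finite if s <= best_ssr * (1.0 + ssr_rel_tol))
    best_idx = int(np.argmin(ssrs)) if finite else -1
    return {
        "variant": variant,
        "repetitions": repetitions,
        "seed": seed,
        "wall_time_per_fit": wall / repetitions,
        "cpu_time_per_fit": cpu / repetitions,
        "best_ssr": best_ssr,
        "best_parameters": params[best_idx] if best_idx >= 0 else None,
        "ssr_values": ssrs,
        "consensus": consensus,
        "failed_repetitions": failed,
        "ssr_rel_tol": ssr_rel_tol,
    }
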