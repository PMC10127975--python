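"""Synthetic patient-cohort generator.

Emulates the structure of a radiotherapy head-and-neck cohort: 66-70 Gy
delivered in 2 Gy weekday fractions, volumes measured at planning (model
day 0), immediately before the first fraction, weekly during treatment,
and on the last treatment day.  No clinical data ship with the package;
this module is the test bed for fitting, selection and convergence
studies.

Noise is multiplicative lognormal (volumes are positive and measurement
error plausibly scales with size); parameter priors are independent
uniforms over configurable ranges.  Everything is reproducible from a
single seed via spawned substreams.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigurationError, IntegrationError, RadGrowthError
from .models import (
    DEFAULT_TW,
    GrowthLaw,
    GrowthParameters,
    ModelSpec,
    RadiationParameters,
    TreatmentProtocol,
    TumourTimeSeries,
    standard_fractionation,
)
from .solver import DEFAULT_STEP, solve_treated

__all__ = ["CohortConfig", "SyntheticPatient", "generate_patient", "generate_cohort"]


@dataclass(frozen=True)
class CohortConfig:
    """Sampling distributions and schedule structure for a virtual cohort.

    Default parameter ranges are the observed min-max spread of fitted
    exponential-model values in a published 19-patient head-and-neck
    cohort; they are priors of convenience, not estimates.
    """

    n_patients: int = 19
    law: GrowthLaw | str = GrowthLaw.EXPONENTIAL
    mu: float = 1.0  # generating fractional order; 1 = ordinary dynamics
    a_range: tuple[float, float] = (0.0010, 0.0404)
    alpha_range: tuple[float, float] = (0.0048, 0.0450)
    lambda0_range: tuple[float, float] = (0.0018, 0.0653)
    lambda1_range: tuple[float, float] = (0.1, 1.0)
    v0_range: tuple[float, float] = (5.0, 50.0)
    k_capacity_factor: float = 2.0
    alpha_beta_ratio: float = 10.0
    psi: float = 20.0
    planning_gap_days: float = 7.0
    total_doses: tuple[float, ...] = (66.0, 68.0, 70.0)
    dose_per_fraction: float = 2.0
    tw: float = DEFAULT_TW
    epsilon: float = 1e-5
    sigma: float = 0.05  # lognormal noise scale; 0 disables noise
    seed: int = 0
    h: float = DEFAULT_STEP
    corrector_iterations: int = 1
    max_resamples: int = 20

    def __post_init__(self) -> None:
        object.__setattr__(self, "law", GrowthLaw(self.law))
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        if not (0 < self.mu <= 1):
            raise ConfigurationError("mu must lie in (0, 1]")
        if self.planning_gap_days < 0:
            raise ConfigurationError("planning_gap_days must be >= 0")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["law"] = GrowthLaw(self.law).value
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=float).encode()
        ).hexdigest()[:16]


@dataclass
class SyntheticPatient:
    patient_id: str
    series: TumourTimeSeries
    protocol: TreatmentProtocol
    truth: dict
    seed_entropy: int


def _measurement_days(config: CohortConfig, proto: TreatmentProtocol) -> np.ndarray:
    first = proto.treatment_times[0]
    last = proto.last_time
    days = [0.0, first]
    wk = first + 7.0
    while wk < last - 1e-9:
        days.append(wk)
        wk += 7.0
    days.append(last)
    return np.unique(np.asarray(days))


def _sample_parameters(config: CohortConfig, rng: np.random.Generator, v0: float) -> tuple[ModelSpec, dict]:
    law = GrowthLaw(config.law)
    alpha = float(rng.uniform(*config.alpha_range))
    truth: dict = {"alpha": alpha, "beta": alpha / config.alpha_beta_ratio, "mu": config.mu, "v0": v0}
    if law is GrowthLaw.EXPONENTIAL:
        a = float(rng.uniform(*config.a_range))
        growth = GrowthParameters(law=law, a=a)
        truth["a"] = a
    elif law is GrowthLaw.LOGISTIC:
        a = float(rng.uniform(*config.a_range))
        growth = GrowthParameters(law=law, a=a, K=config.k_capacity_factor * v0)
        truth.update(a=a, K=config.k_capacity_factor * v0)
    else:
        lam0 = float(rng.uniform(*config.lambda0_range))
        lam1 = float(rng.uniform(*config.lambda1_range))
        growth = GrowthParameters(law=law, lambda0=lam0, lambda1=lam1, psi=config.psi)
        truth.update(lambda0=lam0, lambda1=lam1, psi=config.psi)
    radiation = RadiationParameters(alpha=alpha, beta=truth["beta"], epsilon=config.epsilon)
    return ModelSpec(growth=growth, radiation=radiation, mu=config.mu), truth


def generate_patient(
    config: CohortConfig,
    rng: np.random.Generator,
    patient_id: str = "patient_01",
    seed_entropy: int = 0,
) -> SyntheticPatient:
    """Simulate one virtual patient: sample parameters, build the weekday
    protocol, integrate the generating model, sample measurement days and
    apply noise.  Non-positive simulated volumes trigger a logged resample
    (up to ``config.max_resamples``)."""
    total_dose = float(rng.choice(np.asarray(config.total_doses)))
    proto = standard_fractionation(
        total_dose,
        config.dose_per_fraction,
        start_day=config.planning_gap_days,
        tw=config.tw,
    )
    days = _measurement_days(config, proto)
    for _ in range(config.max_resamples):
        v0 = float(rng.uniform(*config.v0_range))
        spec, truth = _sample_parameters(config, rng, v0)
        try:
            traj = solve_treated(
                spec, proto, v0, float(days[-1]),
                h=config.h, corrector_iterations=config.corrector_iterations,
            )
        except IntegrationError:
            continue
        clean = traj.at(days)
        if np.all(clean > 0):
            break
    else:
        raise RadGrowthError(
            f"could not generate a positive trajectory for {patient_id} "
            f"after {config.max_resamples} resamples"
        )
    if config.sigma > 0:
        noise = np.exp(config.sigma * rng.standard_normal(days.size))
        volumes = clean * noise
    else:
        volumes = clean.copy()
    truth.update(total_dose=total_dose, clean_volumes=clean.tolist())
    series = TumourTimeSeries(times=days, volumes=volumes, patient_id=patient_id)
    return SyntheticPatient(patient_id, series, proto, truth, seed_entropy)


def generate_cohort(config: CohortConfig) -> tuple[list[SyntheticPatient], dict]:
    """Generate ``config.n_patients`` patients on independent substreams of
    the seed, plus a manifest recording truth and provenance."""
    streams = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    patients = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pid = f"patient_{i + 1:02d}"
        patients.append(generate_patient(config, rng, pid, seed_entropy=int(ss.entropy)))
    manifest = {
        "config": {**asdict(config), "law": GrowthLaw(config.law).value},
        "config_hash": config.config_hash(),
        "patients": [
            {
                "patient_id": p.patient_id,
                "truth": p.truth,
                "n_measurements": len(p.series),
                "total_dose": p.protocol.total_dose,
            }
            for p in patients
        ],
    }
    return patients, manifest
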