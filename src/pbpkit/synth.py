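"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the statistical structure the analysis assumes so
that every stage is testable without laboratory data:

* 1- and 2-compartment plasma profiles with multiplicative log-normal
  residual error and LLOQ censoring (default LLOQ 1.01 ng/mL, matching the
  bioanalytical assay range),
* mono-exponential microsomal depletion time courses (triplicates at
  0/15/30/60 min),
* equilibrium-dialysis plasma/buffer pairs at a fixed unbound fraction and
  two plasma concentration levels (0.1 and 1 ug/mL),
* heteroscedastic quadratic calibration responses with constant-CV noise
  (the error model that motivates 1/x^2 weighting).

Every generator is a pure function of its :class:`GeneratorConfig`; the
same seed reproduces the same dataset byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError
from .invitro import DepletionAssay, DialysisPair
from .nca import ConcentrationProfile

__all__ = [
    "GeneratorConfig",
    "gen_pk_profiles",
    "gen_depletion",
    "gen_dialysis",
    "gen_calibration_responses",
    "one_compartment_curve",
    "two_compartment_curve",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared generator settings.

    noise_cv is the fractional coefficient of variation of the
    multiplicative log-normal error (0 disables noise); lloq censors
    concentrations below the assay quantification limit.
    """

    seed: int = 0
    noise_cv: float = 0.0
    lloq: float = 1.01  # ng/mL

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise DomainError("noise_cv must be >= 0")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))

    def lognormal_factors(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.noise_cv == 0:
            return np.ones(n)
        sigma = math.sqrt(math.log(1.0 + self.noise_cv**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def one_compartment_curve(
    t: np.ndarray,
    dose: float,
    v: float,
    k: float,
    route: str = "iv_bolus",
    ka: float = 0.0,
    f: float = 1.0,
) -> np.ndarray:
    """Analytic 1-compartment concentration (ng/mL).

    dose in ng/kg, v in mL/kg, k and ka in 1/min, f the bioavailable
    fraction for oral dosing.
    """
    t = np.asarray(t, dtype=float)
    if route == "iv_bolus":
        return dose / v * np.exp(-k * t)
    if route == "oral":
        if ka <= 0 or ka == k:
            raise DomainError("oral curve requires ka > 0 and ka != k")
        return f * dose * ka / (v * (ka - k)) * (np.exp(-k * t) - np.exp(-ka * t))
    raise DomainError(f"unknown route {route!r}")


def two_compartment_curve(
    t: np.ndarray, dose: float, v1: float, v2: float, q_ic: float, k: float
) -> np.ndarray:
    """Analytic 2-compartment IV-bolus concentration (ng/mL).

    v1/v2 central/peripheral volumes (mL/kg), q_ic intercompartmental
    clearance (mL/min/kg), k the central elimination rate constant (1/min).
    """
    t = np.asarray(t, dtype=float)
    if min(v1, v2, q_ic) <= 0 or k <= 0:
        raise DomainError("2-compartment parameters must be positive")
    k12 = q_ic / v1
    k21 = q_ic / v2
    k10 = k
    s = k10 + k12 + k21
    disc = math.sqrt(s * s - 4.0 * k10 * k21)
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    a = dose / v1 * (alpha - k21) / (alpha - beta)
    b = dose / v1 * (k21 - beta) / (alpha - beta)
    return a * np.exp(-alpha * t) + b * np.exp(-beta * t)


def gen_pk_profiles(
    model: str,
    params: dict,
    dose: float,
    route: str,
    sampling_times: Sequence[float],
    n_subjects: int,
    config: GeneratorConfig,
    species: str = "rat",
) -> list[ConcentrationProfile]:
    """Generate noisy subject-level plasma profiles.

    Parameters
    ----------
    model : {"1c", "2c"}
        Analytic disposition model.
    params : dict
        ``{"v", "k"}`` for 1-compartment (plus ``"ka"``, ``"f"`` for oral)
        or ``{"v1", "v2", "q", "k"}`` for 2-compartment IV.  Volumes mL/kg,
        rates 1/min.
    dose : float
        ng per kg body weight.
    sampling_times : sequence
        Minutes post-dose.
    n_subjects : int
        Number of independent noisy replicates.

    Values falling below ``config.lloq`` are censored to zero with the
    profile's ``blq`` mask set.
    """
    t = np.asarray(sampling_times, dtype=float)
    if model == "1c":
        curve = one_compartment_curve(
            t,
            dose,
            params["v"],
            params["k"],
            route=route,
            ka=params.get("ka", 0.0),
            f=params.get("f", 1.0),
        )
    elif model == "2c":
        if route != "iv_bolus":
            raise DomainError("2-compartment generator supports IV bolus only")
        curve = two_compartment_curve(
            t, dose, params["v1"], params["v2"], params["q"], params["k"]
        )
    else:
        raise DomainError(f"unknown model {model!r}")

    rng = config.rng(stream=1)
    profiles = []
    for _ in range(n_subjects):
        noisy = curve * config.lognormal_factors(rng, t.size)
        blq = noisy < config.lloq
        censored = np.where(blq, 0.0, noisy)
        profiles.append(
            ConcentrationProfile(
                times=tuple(t),
                conc=tuple(censored),
                dose=dose,
                route=route,
                species=species,
                blq=tuple(bool(b) for b in blq),
            )
        )
    return profiles


def gen_depletion(
    t_half: float,
    protein_conc: float,
    config: GeneratorConfig,
    times: Sequence[float] = (0.0, 15.0, 30.0, 60.0),
    replicates: int = 3,
) -> DepletionAssay:
    """Generate a microsomal depletion assay (percent remaining vs time).

    ``t_half`` in minutes; ``math.inf`` yields a stable compound (flat
    100%).  Noise is multiplicative log-normal per observation.
    """
    if not (t_half > 0):
        raise DomainError("t_half must be positive (use math.inf for stable)")
    t = np.asarray(times, dtype=float)
    if math.isinf(t_half):
        clean = np.full(t.size, 100.0)
    else:
        clean = 100.0 * np.exp(-0.693 * t / t_half)

    rng = config.rng(stream=2)
    all_t: list[float] = []
    all_rem: list[float] = []
    for _ in range(replicates):
        noisy = clean * config.lognormal_factors(rng, t.size)
        all_t.extend(t.tolist())
        all_rem.extend(noisy.tolist())
    return DepletionAssay(
        times=tuple(all_t), remaining=tuple(all_rem), protein_conc=protein_conc
    )


def gen_dialysis(
    fup: float,
    config: GeneratorConfig,
    plasma_concs: Sequence[float] = (100.0, 1000.0),
) -> list[DialysisPair]:
    """Generate equilibrium-dialysis pairs at the given true unbound fraction.

    ``plasma_concs`` in ng/mL (defaults: the 0.1 and 1 ug/mL assay levels).
    """
    if not 0 < fup <= 1:
        raise DomainError("fup must lie in (0, 1]")
    rng = config.rng(stream=3)
    factors = config.lognormal_factors(rng, len(plasma_concs))
    return [
        DialysisPair(plasma_conc=float(cp), buffer_conc=float(fup * cp * f))
        for cp, f in zip(plasma_concs, factors)
    ]


def gen_calibration_responses(
    coefficients: tuple[float, float, float],
    concentrations: Sequence[float],
    config: GeneratorConfig,
) -> np.ndarray:
    """Quadratic instrument responses with constant-CV (heteroscedastic) noise.

    ``coefficients`` = (a, b, c) of y = a x^2 + b x + c.  Constant-CV
    multiplicative noise is exactly the error structure that 1/x^2
    weighting corrects for in the calibration fit.
    """
    a, b, c = coefficients
    x = np.asarray(concentrations, dtype=float)
    clean = a * x**2 + b * x + c
    rng = config.rng(stream=4)
    return clean * config.lognormal_factors(rng, x.size)
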