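"""Reduction of in vitro ADME assays: microsomal stability and protein binding.

Substrate-depletion time courses (percent analyte remaining vs incubation
time in liver microsomes) are reduced to an in vitro intrinsic clearance

    Clint,in vitro = (0.693 / T1/2) * (1 / C_protein)      [mL/min/mg]

with T1/2 = 0.693/k and k the negative slope of the log-linear regression of
remaining amount on time.  The constant 0.693 is used as printed in the
source equation rather than ln 2; the difference (2e-4 relative) is far
below assay noise.

Equilibrium-dialysis pairs give the unbound fraction in plasma,
Fup = 100 * C_buffer / C_plasma (percent).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError, InsufficientPointsError, LogDomainError

__all__ = [
    "DepletionAssay",
    "DialysisPair",
    "ClintResult",
    "clint_from_depletion",
    "mean_clint",
    "fup_from_dialysis",
]

#: half-life constant as printed in the defining equation
LN2_PRINTED = 0.693


@dataclass(frozen=True)
class DepletionAssay:
    """Pooled substrate-depletion observations at one protein concentration.

    ``times`` and ``remaining`` are paired long-form arrays, so triplicate
    incubations appear as repeated time values.  ``remaining`` is percent of
    the t=0 response (peak-area ratio normalized to 100 at time zero).
    """

    times: tuple[float, ...]  # min
    remaining: tuple[float, ...]  # percent
    protein_conc: float  # mg microsomal protein / mL

    def __post_init__(self) -> None:
        if len(self.times) != len(self.remaining):
            raise DomainError("times and remaining must be paired")
        if not self.protein_conc > 0:
            raise DomainError("protein_conc must be > 0")
        uniq = sorted(set(self.times))
        if uniq[0] != 0:
            raise DomainError("depletion time course must start at t = 0")


@dataclass(frozen=True)
class DialysisPair:
    """Matched plasma/buffer concentrations from one equilibrium dialysis."""

    plasma_conc: float  # ng/mL
    buffer_conc: float  # ng/mL

    def __post_init__(self) -> None:
        if not self.plasma_conc > 0:
            raise DomainError("plasma_conc must be > 0")
        if self.buffer_conc < 0:
            raise DomainError("buffer_conc must be >= 0")
        if self.buffer_conc > self.plasma_conc:
            warnings.warn(
                "buffer concentration exceeds plasma concentration; "
                "apparent Fup > 100%",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ClintResult:
    """Depletion-assay reduction: rate constant, half-life, intrinsic clearance."""

    clint: float  # mL/min/mg
    t_half: float  # min (inf for a stable compound)
    k: float  # 1/min
    stable: bool
    intercept_pct: float  # fitted remaining-% at t = 0


def clint_from_depletion(assay: DepletionAssay) -> ClintResult:
    """Reduce a depletion time course to in vitro intrinsic clearance.

    All replicate points are pooled into a single ordinary least-squares
    regression of ln(remaining) on time; k is the negative slope.  A
    non-positive k (no measurable depletion) returns Clint = 0 with the
    ``stable`` flag set.

    Raises
    ------
    LogDomainError
        If any remaining value is <= 0.
    InsufficientPointsError
        If fewer than 3 usable points are available.
    """
    t = np.asarray(assay.times, dtype=float)
    rem = np.asarray(assay.remaining, dtype=float)
    if np.any(rem <= 0):
        raise LogDomainError("remaining-% values must be positive for log regression")
    if t.size < 3 or len(set(assay.times)) < 3:
        raise InsufficientPointsError("need >= 3 time points for the depletion fit")

    slope, intercept = np.polyfit(t, np.log(rem), 1)
    k = -float(slope)
    intercept_pct = float(np.exp(intercept))
    # a fitted rate at floating-point noise level is no depletion at all
    if k <= 1e-12:
        return ClintResult(
            clint=0.0, t_half=math.inf, k=k, stable=True, intercept_pct=intercept_pct
        )
    t_half = LN2_PRINTED / k
    clint = (LN2_PRINTED / t_half) / assay.protein_conc  # == k / protein_conc
    return ClintResult(
        clint=clint, t_half=t_half, k=k, stable=False, intercept_pct=intercept_pct
    )


def mean_clint(assays: Iterable[DepletionAssay]) -> tuple[float, list[ClintResult]]:
    """Per-protein-level Clint values and their arithmetic mean.

    Mirrors the pooling rule for assays run at several microsomal protein
    concentrations (0.5-2 mg/mL): each level is reduced separately and the
    mean of the level estimates is reported.
    """
    results = [clint_from_depletion(a) for a in assays]
    if not results:
        raise InsufficientPointsError("mean_clint requires at least one assay")
    return float(np.mean([r.clint for r in results])), results


def fup_from_dialysis(
    pairs: DialysisPair | Sequence[DialysisPair],
) -> tuple[float, list[float]]:
    """Unbound fraction in plasma (percent) from equilibrium dialysis.

    A single pair returns its own estimate; a sequence returns the
    arithmetic mean across pairs (the concentration-independence pooling
    rule) together with the per-pair values.

    Returns
    -------
    (mean_fup_pct, per_pair_pct)
    """
    if isinstance(pairs, DialysisPair):
        pairs = [pairs]
    if not pairs:
        raise DomainError("fup_from_dialysis requires at least one pair")
    per_pair = [100.0 * p.buffer_conc / p.plasma_conc for p in pairs]
    return float(np.mean(per_pair)), per_pair
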