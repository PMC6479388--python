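"""Whole-body perfusion-limited PBPK simulator.

The model is a linear ODE system over 14 compartments: arterial and venous
blood, lung (in series between them), and eleven perfused tissues in
parallel.  Gut and spleen drain through the portal vein into the liver.
Drug states are *amounts* (ng) per compartment, which makes mass balance
exact by construction; concentrations are derived by dividing by anatomical
volume.  A perfusion-limited tissue leaves in venous equilibrium with the
tissue at its partition coefficient:

    V_i dC_i/dt = Q_i (C_ab - C_i Rbp / Kp_i)

where C_ab is arterial blood concentration and C_i Rbp / Kp_i the emergent
venous *blood* concentration (Kp is tissue:plasma, Rbp blood:plasma).

Elimination:

* hepatic — well-stirred intrinsic clearance acting on the liver outflow
  blood concentration, rate = Clint_hep * BW * C_liver Rbp / Kp_liver.
  Setting ``unbound_hepatic=True`` multiplies by fup (the unbound-driven
  variant).
* renal — a clearance applied to the kidney inflow blood concentration
  (``renal_site="blood"``) or the corresponding plasma concentration
  (``renal_site="plasma"``).

Oral dosing uses a first-order gut-lumen depot: a fraction ``fa`` of the
transferred amount enters the portal stream at rate ``ka``, the remainder
is never absorbed.

Plasma concentration is reported as venous blood concentration / Rbp.

Tissue:plasma partition coefficients are predicted from tissue composition
by the Poulin-Theil method (octanol-water partitioning for lean tissues,
vegetable-oil-water for adipose), or supplied directly by the user.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, DomainError, SolverFailureError
from .physiology import PERFUSED_TISSUES, PORTAL_TISSUES, SpeciesPhysiology

__all__ = [
    "CompoundProperties",
    "PBPKParameters",
    "DoseRegimen",
    "SimulationResult",
    "predict_kp",
    "simulate",
    "mass_balance",
    "mass_balance_series",
    "KP_METHODS",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundProperties:
    """Physicochemical and in vitro ADME inputs for one compound.

    ``fup`` and ``clint_in_vitro`` may be a single float or a per-species
    mapping.  ``pka_types`` labels each pKa as ``"acid"`` or ``"base"``;
    when omitted, pKa values below 7 are treated as basic and above 7 as
    acidic (yielding mostly-neutral behaviour at physiological pH for
    compounds whose ionizable groups sit far from 7.4).
    """

    name: str
    mw: float  # g/mol
    pka: tuple[float, ...]
    logp: float
    rbp: float  # blood/plasma concentration ratio
    fup: float | Mapping[str, float]  # fraction unbound (0-1]
    solubility: float  # mg/mL
    permeability: float  # effective permeability (as reported)
    clint_in_vitro: float | Mapping[str, float]  # mL/min/mg
    pka_types: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise DomainError("mw must be > 0")
        if not self.rbp > 0:
            raise DomainError("rbp must be > 0")
        values = self.fup.values() if isinstance(self.fup, Mapping) else (self.fup,)
        for f in values:
            if not 0 < f <= 1:
                raise DomainError("fup must lie in (0, 1]")

    def _per_species(self, value, species: str | None) -> float:
        if isinstance(value, Mapping):
            if species is None:
                raise ConfigurationError("species required for per-species property")
            try:
                return float(value[species])
            except KeyError as exc:
                raise ConfigurationError(f"no value for species {species!r}") from exc
        return float(value)

    def fup_for(self, species: str | None = None) -> float:
        return self._per_species(self.fup, species)

    def clint_for(self, species: str | None = None) -> float:
        return self._per_species(self.clint_in_vitro, species)

    def logd(self, ph: float = 7.4) -> float:
        """Octanol-water log D at the given pH via Henderson-Hasselbalch."""
        types = self.pka_types
        if types is None:
            types = tuple("base" if p < 7 else "acid" for p in self.pka)
        f_neutral = 1.0
        for pka, kind in zip(self.pka, types):
            if kind == "base":
                f_neutral *= 1.0 / (1.0 + 10.0 ** (pka - ph))
            elif kind == "acid":
                f_neutral *= 1.0 / (1.0 + 10.0 ** (ph - pka))
            else:
                raise ConfigurationError(f"unknown pKa type {kind!r}")
        return self.logp + math.log10(max(f_neutral, 1e-30))


@dataclass(frozen=True)
class PBPKParameters:
    """Disposition parameters of the PBPK model (all clearances per kg)."""

    kp: Mapping[str, float]  # tissue:plasma partition coefficients
    clint_hepatic: float  # mL/min/kg, in vivo scale
    cl_renal: float  # mL/min/kg
    ka: float = 0.0  # 1/min, first-order absorption (oral)
    fa: float = 1.0  # fraction absorbed (0-1]
    unbound_hepatic: bool = False  # multiply hepatic term by fup
    renal_site: str = "blood"  # "blood" or "plasma" inflow concentration

    def __post_init__(self) -> None:
        for name, value in self.kp.items():
            if not value > 0:
                raise DomainError(f"Kp[{name!r}] must be > 0")
        if self.clint_hepatic < 0 or self.cl_renal < 0 or self.ka < 0:
            raise DomainError("clearances and ka must be >= 0")
        if not 0 < self.fa <= 1:
            raise DomainError("fa must lie in (0, 1]")
        if self.renal_site not in ("blood", "plasma"):
            raise DomainError("renal_site must be 'blood' or 'plasma'")

    def with_updates(self, **kwargs) -> "PBPKParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DoseRegimen:
    """A single administration: IV bolus or first-order oral dose."""

    route: str  # "iv_bolus" or "oral"
    dose: float  # in `dose_unit`
    dose_unit: str = "mg_per_kg"  # or "mg" (total)
    start: float = 0.0  # min

    def __post_init__(self) -> None:
        if self.route not in ("iv_bolus", "oral"):
            raise DomainError(f"unknown route {self.route!r}")
        if self.dose < 0:
            raise DomainError("dose must be >= 0")
        if self.dose_unit not in ("mg_per_kg", "mg"):
            raise DomainError("dose_unit must be 'mg_per_kg' or 'mg'")
        if self.start < 0:
            raise DomainError("start must be >= 0")

    def dose_ng(self, body_weight: float) -> float:
        mg = self.dose * body_weight if self.dose_unit == "mg_per_kg" else self.dose
        return mg * 1e6


@dataclass
class SimulationResult:
    """Output of :func:`simulate` on a fixed time grid."""

    times: np.ndarray  # min
    plasma_conc: np.ndarray  # ng/mL (venous blood / Rbp)
    tissue_amounts: dict[str, np.ndarray]  # ng per compartment
    eliminated: dict[str, np.ndarray]  # ng cumulative: hepatic, renal, unabsorbed
    dose_ng: float
    body_weight: float
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Kp prediction (tissue-composition method)
# ---------------------------------------------------------------------------

# Fractional tissue composition (water, neutral lipid, phospholipid) from the
# published compendium used by tissue-composition Kp methods.  The synthetic
# "rest" compartment reuses muscle composition.
_COMPOSITION = {
    "rat": {
        "adipose": (0.120, 0.8530, 0.0020),
        "bone": (0.446, 0.0273, 0.0027),
        "brain": (0.788, 0.0392, 0.0533),
        "gut": (0.749, 0.0292, 0.0138),
        "heart": (0.779, 0.0140, 0.0118),
        "kidney": (0.771, 0.0123, 0.0284),
        "liver": (0.705, 0.0138, 0.0303),
        "lung": (0.790, 0.0219, 0.0140),
        "muscle": (0.756, 0.0100, 0.0090),
        "skin": (0.651, 0.0239, 0.0180),
        "spleen": (0.771, 0.0077, 0.0136),
        "plasma": (0.960, 0.00147, 0.00083),
    },
    "human": {
        "adipose": (0.180, 0.7900, 0.0020),
        "bone": (0.439, 0.0740, 0.0011),
        "brain": (0.770, 0.0510, 0.0565),
        "gut": (0.718, 0.0487, 0.0163),
        "heart": (0.758, 0.0115, 0.0166),
        "kidney": (0.783, 0.0207, 0.0162),
        "liver": (0.751, 0.0348, 0.0252),
        "lung": (0.811, 0.0030, 0.0090),
        "muscle": (0.760, 0.0238, 0.0072),
        "skin": (0.718, 0.0284, 0.0111),
        "spleen": (0.788, 0.0201, 0.0198),
        "plasma": (0.945, 0.0035, 0.00225),
    },
}

#: compartments that receive a Kp value
KP_TISSUES = ("lung",) + PERFUSED_TISSUES


def _poulin_theil_kp(
    compound: CompoundProperties, physiology: SpeciesPhysiology
) -> dict[str, float]:
    comp = _COMPOSITION.get(physiology.species)
    if comp is None:
        raise ConfigurationError(
            f"no tissue-composition table for species {physiology.species!r}"
        )
    fup = compound.fup_for(physiology.species)
    # tissue binding from plasma binding: interstitial/tissue protein at
    # half plasma strength
    fut = 1.0 / (1.0 + 0.5 * (1.0 - fup) / fup)
    logd = compound.logd(7.4)
    p_ow = 10.0**logd
    # vegetable-oil/water coefficient for adipose (Leo regression)
    d_vow = 10.0 ** (1.115 * logd - 1.35)

    vw_p, vnl_p, vph_p = comp["plasma"]
    kp: dict[str, float] = {}
    for name in KP_TISSUES:
        vw, vnl, vph = comp.get(name, comp["muscle"])
        if name == "adipose":
            num = d_vow * (vnl + 0.3 * vph) + (vw + 0.7 * vph)
            den = d_vow * (vnl_p + 0.3 * vph_p) + (vw_p + 0.7 * vph_p)
            kp[name] = (num / den) * fup  # adipose assumed non-binding (fut = 1)
        else:
            num = p_ow * (vnl + 0.3 * vph) + (vw + 0.7 * vph)
            den = p_ow * (vnl_p + 0.3 * vph_p) + (vw_p + 0.7 * vph_p)
            kp[name] = (num / den) * fup / fut
    return kp


def _unity_kp(
    compound: CompoundProperties, physiology: SpeciesPhysiology
) -> dict[str, float]:
    return {name: 1.0 for name in KP_TISSUES}


KP_METHODS: dict[str, Callable[[CompoundProperties, SpeciesPhysiology], dict[str, float]]] = {
    "poulin_theil": _poulin_theil_kp,
    "unity": _unity_kp,
}


def predict_kp(
    compound: CompoundProperties,
    physiology: SpeciesPhysiology,
    method: str = "poulin_theil",
) -> dict[str, float]:
    """Predict tissue:plasma partition coefficients for every compartment.

    ``method`` selects among :data:`KP_METHODS` (default the Poulin-Theil
    tissue-composition method; ``"unity"`` sets every Kp to 1 for limit
    checks).  Deterministic for fixed inputs.
    """
    try:
        fn = KP_METHODS[method]
    except KeyError:
        raise ConfigurationError(
            f"unknown Kp method {method!r}; available: {sorted(KP_METHODS)}"
        ) from None
    return fn(compound, physiology)


# ---------------------------------------------------------------------------
# ODE system
# ---------------------------------------------------------------------------

_EXTRA_STATES = ("gut_lumen", "unabsorbed", "eliminated_hepatic", "eliminated_renal")


def _build_matrix(
    physiology: SpeciesPhysiology,
    compound: CompoundProperties,
    params: PBPKParameters,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the constant coefficient matrix M with states in ng.

    Every transport term appears with opposite signs in its source and
    destination rows, so the column sums of M vanish and total mass
    (including the bookkeeping states) is conserved exactly.
    """
    bw = physiology.body_weight
    rbp = compound.rbp
    fup = compound.fup_for(physiology.species)

    names = ["venous_blood", "arterial_blood", "lung"] + list(PERFUSED_TISSUES)
    names += list(_EXTRA_STATES)
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    m = np.zeros((n, n))

    vol = {t.name: t.volume * bw * 1000.0 for t in physiology.tissues}  # mL
    flow = {t.name: t.blood_flow * bw for t in physiology.tissues}  # mL/min
    co = physiology.cardiac_output * bw
    q_ha = physiology.hepatic_artery_flow() * bw

    missing = [t for t in KP_TISSUES if t not in params.kp]
    if missing:
        raise ConfigurationError(f"missing Kp values for tissues: {missing}")

    def out_coeff(tissue: str) -> float:
        """d(C_blood,out)/d(A_tissue) = Rbp / (Kp * V)."""
        return rbp / (params.kp[tissue] * vol[tissue])

    i_ven, i_art, i_lung = idx["venous_blood"], idx["arterial_blood"], idx["lung"]

    # venous -> lung -> arterial (lung in series at cardiac output)
    m[i_ven, i_ven] -= co / vol["venous_blood"]
    m[i_lung, i_ven] += co / vol["venous_blood"]
    m[i_lung, i_lung] -= co * out_coeff("lung")
    m[i_art, i_lung] += co * out_coeff("lung")

    # arterial supply to parallel tissues (liver gets the hepatic artery)
    for name in PERFUSED_TISSUES:
        q_in = q_ha if name == "liver" else flow[name]
        m[i_art, i_art] -= q_in / vol["arterial_blood"]
        m[idx[name], i_art] += q_in / vol["arterial_blood"]

    # venous outflow of non-portal tissues; portal tissues drain to liver
    i_liv = idx["liver"]
    for name in PERFUSED_TISSUES:
        if name == "liver":
            continue
        dest = i_liv if name in PORTAL_TISSUES else i_ven
        m[idx[name], idx[name]] -= flow[name] * out_coeff(name)
        m[dest, idx[name]] += flow[name] * out_coeff(name)

    # liver outflow at total hepatic flow, plus hepatic elimination on the
    # outflow blood concentration
    m[i_liv, i_liv] -= flow["liver"] * out_coeff("liver")
    m[i_ven, i_liv] += flow["liver"] * out_coeff("liver")
    cl_h = params.clint_hepatic * bw * (fup if params.unbound_hepatic else 1.0)
    m[i_liv, i_liv] -= cl_h * out_coeff("liver")
    m[idx["eliminated_hepatic"], i_liv] += cl_h * out_coeff("liver")

    # renal elimination on kidney inflow (arterial) concentration
    cl_r = params.cl_renal * bw
    if params.renal_site == "plasma":
        cl_r /= rbp
    i_kid = idx["kidney"]
    m[i_kid, i_art] -= cl_r / vol["arterial_blood"]
    m[idx["eliminated_renal"], i_art] += cl_r / vol["arterial_blood"]
    # note: the clearance removes mass from the kidney inflow, so it is
    # debited against the kidney compartment's arterial supply

    # oral absorption from the gut-lumen depot into the portal stream
    i_dep = idx["gut_lumen"]
    m[i_dep, i_dep] -= params.ka
    m[i_liv, i_dep] += params.ka * params.fa
    m[idx["unabsorbed"], i_dep] += params.ka * (1.0 - params.fa)

    return m, names


def simulate(
    physiology: SpeciesPhysiology,
    compound: CompoundProperties,
    params: PBPKParameters,
    regimen: DoseRegimen,
    t_end: float,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-3,
) -> SimulationResult:
    """Integrate the PBPK system and return the concentration-time result.

    Parameters
    ----------
    t_end : float
        End of simulation, minutes (> regimen.start).
    t_eval : array, optional
        Output grid in minutes; default is a 1-minute grid (capped at ~4000
        points) which keeps trapezoidal NCA discretization error well below
        1% for the profiles of interest.
    rtol, atol : float
        Integrator tolerances (LSODA); atol is in ng.

    Raises
    ------
    SolverFailureError
        If the integrator fails or produces non-finite state.
    DomainError
        If ``t_end`` is not positive or does not exceed the dose start.
    """
    if not t_end > 0 or t_end <= regimen.start:
        raise DomainError("t_end must be positive and after the dose start")
    if params.ka == 0.0 and regimen.route == "oral":
        raise ConfigurationError("oral dosing requires ka > 0")

    m, names = _build_matrix(physiology, compound, params)
    nstate = len(names)
    dose = regimen.dose_ng(physiology.body_weight)

    y0 = np.zeros(nstate)
    if regimen.route == "iv_bolus":
        y0[names.index("venous_blood")] = dose
    else:
        y0[names.index("gut_lumen")] = dose

    if t_eval is None:
        span = t_end - regimen.start
        npts = min(int(round(span)) + 1, 4001)
        npts = max(npts, 201)
        t_eval = np.linspace(regimen.start, t_end, npts)
    else:
        t_eval = np.asarray(t_eval, dtype=float)

    grid = t_eval[t_eval >= regimen.start]
    pre = t_eval[t_eval < regimen.start]

    if dose == 0.0:
        sol_y = np.zeros((nstate, grid.size))
    else:
        sol = solve_ivp(
            lambda t, y: m @ y,
            (regimen.start, t_end),
            y0,
            method="LSODA",
            t_eval=grid,
            jac=lambda t, y: m,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SolverFailureError(f"ODE integration failed: {sol.message}")
        if not np.all(np.isfinite(sol.y)):
            raise SolverFailureError("non-finite state encountered during integration")
        sol_y = sol.y

    if pre.size:
        sol_y = np.hstack([np.zeros((nstate, pre.size)), sol_y])
    times = np.concatenate([pre, grid])

    bw = physiology.body_weight
    v_ven = physiology.tissue("venous_blood").volume * bw * 1000.0
    # integrator noise below atol can leave tiny negative tails; the
    # reported concentration is clipped at zero (amount states are kept
    # raw so mass-balance checks see the solver's true error)
    plasma = np.maximum(sol_y[names.index("venous_blood")], 0.0) / v_ven / compound.rbp

    amounts = {name: sol_y[i] for i, name in enumerate(names)}
    eliminated = {
        "hepatic": amounts.pop("eliminated_hepatic"),
        "renal": amounts.pop("eliminated_renal"),
        "unabsorbed": amounts.pop("unabsorbed"),
    }
    return SimulationResult(
        times=times,
        plasma_conc=plasma,
        tissue_amounts=amounts,
        eliminated=eliminated,
        dose_ng=dose,
        body_weight=bw,
        metadata={
            "species": physiology.species,
            "route": regimen.route,
            "dose": regimen.dose,
            "dose_unit": regimen.dose_unit,
            "rtol": rtol,
            "atol": atol,
            "unbound_hepatic": params.unbound_hepatic,
            "renal_site": params.renal_site,
        },
    )


def mass_balance_series(result: SimulationResult) -> np.ndarray:
    """Recovered mass fraction (system + eliminated)/dose at every time."""
    total = np.zeros_like(result.times, dtype=float)
    for arr in result.tissue_amounts.values():
        total = total + arr
    for arr in result.eliminated.values():
        total = total + arr
    if result.dose_ng == 0.0:
        return np.ones_like(total)
    return total / result.dose_ng


def mass_balance(result: SimulationResult) -> float:
    """Recovered mass fraction at the final time (1.0 for a zero dose)."""
    return float(mass_balance_series(result)[-1])
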