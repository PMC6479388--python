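"""Whole-body PBPK simulator: Kp prediction, conservation, limiting cases."""

import dataclasses

import numpy as np
import pytest

from pbpkit.errors import ConfigurationError, DomainError
from pbpkit.pbpk import (
    _COMPOSITION,
    CompoundProperties,
    DoseRegimen,
    PBPKParameters,
    mass_balance,
    mass_balance_series,
    predict_kp,
    simulate,
)
from pbpkit.physiology import PERFUSED_TISSUES, get_physiology
from pbpkit.workflow import build_model, simulate_and_nca

ALL_KP_TISSUES = ("lung",) + PERFUSED_TISSUES


def _neutral_compound(rbp=1.0, fup=1.0):
    return CompoundProperties(
        name="probe",
        mw=400.0,
        pka=(),
        logp=1.0,
        rbp=rbp,
        fup=fup,
        solubility=1.0,
        permeability=1.0,
        clint_in_vitro=0.001,
    )


def _unit_params(clint=0.0, cl_renal=0.0, ka=0.0, fa=1.0):
    return PBPKParameters(
        kp={t: 1.0 for t in ALL_KP_TISSUES},
        clint_hepatic=clint,
        cl_renal=cl_renal,
        ka=ka,
        fa=fa,
    )


def _fast_flow_physiology(factor=1e6):
    """Physiology with all flows scaled up: the whole body becomes one
    well-mixed compartment (the perfusion-limited -> one-compartment limit)."""
    phys = get_physiology("rat")
    return dataclasses.replace(
        phys,
        tissues=tuple(
            dataclasses.replace(t, blood_flow=t.blood_flow * factor)
            for t in phys.tissues
        ),
        cardiac_output=phys.cardiac_output * factor,
        hepatic_blood_flow=phys.hepatic_blood_flow * factor,
    )


# ---------------------------------------------------------------------------
# Kp prediction
# ---------------------------------------------------------------------------


def _reference_kp(compound, species):
    """Independent re-evaluation of the tissue-composition partition formula
    (plain arithmetic, no shared code path with the implementation)."""
    comp = _COMPOSITION[species]
    fup = compound.fup_for(species)
    fut = 1.0 / (1.0 + 0.5 * (1.0 - fup) / fup)
    logd = compound.logd(7.4)
    p = 10.0**logd
    dvo = 10.0 ** (1.115 * logd - 1.35)
    vw_p, vnl_p, vph_p = comp["plasma"]
    out = {}
    for name in ALL_KP_TISSUES:
        vw, vnl, vph = comp.get(name, comp["muscle"])
        if name == "adipose":
            num = dvo * (vnl + 0.3 * vph) + vw + 0.7 * vph
            den = dvo * (vnl_p + 0.3 * vph_p) + vw_p + 0.7 * vph_p
            out[name] = num / den * fup
        else:
            num = p * (vnl + 0.3 * vph) + vw + 0.7 * vph
            den = p * (vnl_p + 0.3 * vph_p) + vw_p + 0.7 * vph_p
            out[name] = num / den * fup / fut
    return out


@pytest.mark.parametrize("species", ["rat", "human"])
def test_kp_matches_reference_formula(species, tozadenant):
    kp = predict_kp(tozadenant, get_physiology(species))
    ref = _reference_kp(tozadenant, species)
    for name in ALL_KP_TISSUES:
        assert kp[name] == pytest.approx(ref[name], rel=1e-6)
        assert kp[name] > 0


def test_kp_neutral_compound_in_aqueous_tissue_near_unity():
    """A non-binding, non-lipophilic compound partitions ~1:1 between a
    watery tissue and plasma (water-water partitioning)."""
    compound = dataclasses.replace(_neutral_compound(), logp=-3.0)
    kp = predict_kp(compound, get_physiology("rat"))
    assert kp["muscle"] == pytest.approx(1.0, abs=0.25)


def test_kp_unknown_method_lists_available():
    with pytest.raises(ConfigurationError, match="poulin_theil"):
        predict_kp(_neutral_compound(), get_physiology("rat"), method="nope")


def test_unity_method():
    kp = predict_kp(_neutral_compound(), get_physiology("rat"), method="unity")
    assert all(v == 1.0 for v in kp.values())


def test_logd_of_mostly_neutral_compound(tozadenant):
    """With ionizable groups far from pH 7.4, log D ~= log P."""
    assert tozadenant.logd(7.4) == pytest.approx(tozadenant.logp, abs=0.01)


def test_vss_with_unit_partitioning():
    """With every Kp = 1 (and Rbp = fup = 1) the NCA steady-state volume of
    a slowly cleared IV dose approaches total anatomical volume per kg."""
    phys = get_physiology("rat")
    bundle = build_model("rat")
    bundle = dataclasses.replace(bundle)
    bundle.compound = _neutral_compound()
    bundle.params = _unit_params(clint=1.0)  # low extraction
    _, nca = simulate_and_nca(bundle, DoseRegimen(route="iv_bolus", dose=1.0), 20000.0)
    v_total = sum(t.volume for t in phys.tissues)  # L/kg
    assert nca.vss == pytest.approx(v_total, rel=0.03)


# ---------------------------------------------------------------------------
# conservation and linearity
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "route, dose, ka",
    [
        ("iv_bolus", 1.0, 0.0),
        ("iv_bolus", 5.0, 0.0),
        ("oral", 1.0, 0.13),
        ("oral", 5.0, 0.02),
    ],
)
def test_mass_balance_over_regimen_grid(route, dose, ka, tozadenant):
    """Recovered mass (system + eliminated) stays within 1e-4 of the dose at
    every reported time for IV and oral regimens at both dose levels."""
    phys = get_physiology("rat")
    params = PBPKParameters(
        kp=predict_kp(tozadenant, phys),
        clint_hepatic=3.76,
        cl_renal=13.0,
        ka=ka,
        fa=0.74 if route == "oral" else 1.0,
    )
    res = simulate(phys, tozadenant, params, DoseRegimen(route=route, dose=dose), 480.0)
    series = mass_balance_series(res)
    assert np.max(np.abs(series - 1.0)) <= 1e-4
    assert mass_balance(res) == pytest.approx(1.0, abs=1e-4)


def test_conservation_without_elimination():
    """With zero clearance, nothing is eliminated and total mass equals the
    dose at every output time."""
    phys = get_physiology("rat")
    res = simulate(
        phys, _neutral_compound(), _unit_params(), DoseRegimen(route="iv_bolus", dose=1.0), 480.0
    )
    for arr in res.eliminated.values():
        assert np.allclose(arr, 0.0, atol=1e-6)
    total = sum(res.tissue_amounts.values())
    assert np.allclose(total, res.dose_ng, rtol=1e-6)


def test_zero_dose_is_identically_zero():
    phys = get_physiology("rat")
    res = simulate(
        phys, _neutral_compound(), _unit_params(), DoseRegimen(route="iv_bolus", dose=0.0), 100.0
    )
    assert np.all(res.plasma_conc == 0.0)
    assert mass_balance(res) == 1.0  # zero-dose convention


def test_dose_linearity(tozadenant):
    """Doubling the dose doubles the concentration pointwise (linear system)."""
    phys = get_physiology("rat")
    params = PBPKParameters(
        kp=predict_kp(tozadenant, phys), clint_hepatic=3.76, cl_renal=13.0
    )
    r1 = simulate(phys, tozadenant, params, DoseRegimen(route="iv_bolus", dose=1.0), 480.0)
    r2 = simulate(phys, tozadenant, params, DoseRegimen(route="iv_bolus", dose=2.0), 480.0)
    mask = r1.plasma_conc > r1.plasma_conc.max() * 1e-9
    ratio = r2.plasma_conc[mask] / r1.plasma_conc[mask]
    assert np.max(np.abs(ratio - 2.0)) / 2.0 <= 1e-6


# ---------------------------------------------------------------------------
# limiting behaviour
# ---------------------------------------------------------------------------


def test_one_compartment_limit():
    """With all flows x1e6 and unit partitioning the simulator collapses to
    the analytic one-compartment solution C(t) = (D/V) exp(-Cl t / V)."""
    fast = _fast_flow_physiology()
    compound = _neutral_compound()
    params = _unit_params(clint=10.0)
    res = simulate(fast, compound, params, DoseRegimen(route="iv_bolus", dose=1.0), 480.0)
    v = sum(t.volume for t in fast.tissues) * 1000.0  # mL/kg
    d = 1e6  # ng/kg
    cl = 10.0  # Q >> Clint: hepatic clearance -> Clint
    mixed = res.times >= 5.0  # skip the sub-minute venous mixing transient
    analytic = d / v * np.exp(-cl * res.times[mixed] / v)
    assert np.max(np.abs(res.plasma_conc[mixed] - analytic) / analytic) < 0.01


def test_oral_availability_matches_first_pass_theory():
    """In the one-compartment limit, oral AUC = fa (1 - E) x IV AUC with
    E = Clint/(Q_h + Clint) the well-stirred hepatic extraction."""
    fast = _fast_flow_physiology(1e4)
    compound = _neutral_compound()
    clint, fa = 10.0, 0.8
    bundle = build_model("rat")
    bundle.physiology = fast
    bundle.compound = compound
    bundle.params = _unit_params(clint=clint)
    _, nca_iv = simulate_and_nca(bundle, DoseRegimen(route="iv_bolus", dose=1.0), 4800.0)
    bundle.params = _unit_params(clint=clint, ka=0.05, fa=fa)
    _, nca_po = simulate_and_nca(bundle, DoseRegimen(route="oral", dose=1.0), 4800.0)
    q_h = 55.2 * 1e4
    expected_f = fa * (1.0 - clint / (q_h + clint))
    assert nca_po.auc_inf / nca_iv.auc_inf == pytest.approx(expected_f, rel=0.01)


def test_cmax_monotone_in_ka(tozadenant):
    """Oral Cmax strictly increases with the absorption rate constant."""
    phys = get_physiology("rat")
    kp = predict_kp(tozadenant, phys)
    cmaxes = []
    for ka in (0.02, 0.05, 0.13, 0.4):
        params = PBPKParameters(
            kp=kp, clint_hepatic=3.76, cl_renal=13.0, ka=ka, fa=0.74
        )
        res = simulate(phys, tozadenant, params, DoseRegimen(route="oral", dose=1.0), 480.0)
        cmaxes.append(res.plasma_conc.max())
    assert all(a < b for a, b in zip(cmaxes, cmaxes[1:]))


def test_high_clint_plasma_clearance_ceiling(tozadenant):
    """Total plasma clearance saturates at the hepatic-flow ceiling (scaled
    by the blood/plasma ratio) and never exceeds it."""
    phys = get_physiology("rat")
    bundle = build_model("rat")
    bundle.params = PBPKParameters(
        kp=predict_kp(tozadenant, phys), clint_hepatic=1e6, cl_renal=0.0
    )
    _, nca = simulate_and_nca(bundle, DoseRegimen(route="iv_bolus", dose=1.0), 480.0)
    # plasma is sampled venous, i.e. downstream of hepatic extraction: at
    # complete extraction AUC_venous = (1 - Q_h/CO) AUC_arterial, so the
    # apparent venous-plasma clearance ceiling is Q_h/(1 - Q_h/CO) x Rbp
    q_h, co = phys.hepatic_blood_flow, phys.cardiac_output
    ceiling = q_h / (1.0 - q_h / co) * tozadenant.rbp
    assert nca.cl <= ceiling * 1.02
    assert nca.cl >= ceiling * 0.9


# ---------------------------------------------------------------------------
# bookkeeping and validation
# ---------------------------------------------------------------------------


def test_dose_start_shifts_profile(tozadenant):
    phys = get_physiology("rat")
    params = PBPKParameters(
        kp=predict_kp(tozadenant, phys), clint_hepatic=3.76, cl_renal=13.0,
        ka=0.13, fa=0.74,
    )
    res = simulate(
        phys, tozadenant, params,
        DoseRegimen(route="oral", dose=1.0, start=60.0), 480.0,
        t_eval=np.arange(0.0, 481.0, 1.0),
    )
    before = res.times < 60.0
    assert np.all(res.plasma_conc[before] == 0.0)
    assert res.plasma_conc[~before].max() > 0.0


def test_invalid_inputs_rejected(tozadenant):
    phys = get_physiology("rat")
    params = PBPKParameters(kp=predict_kp(tozadenant, phys), clint_hepatic=1.0, cl_renal=0.0)
    with pytest.raises(DomainError):
        simulate(phys, tozadenant, params, DoseRegimen(route="iv_bolus", dose=1.0), -5.0)
    with pytest.raises(ConfigurationError):
        simulate(phys, tozadenant, params, DoseRegimen(route="oral", dose=1.0), 480.0)
    with pytest.raises(DomainError):
        PBPKParameters(kp={"liver": -1.0}, clint_hepatic=1.0, cl_renal=0.0)
    with pytest.raises(DomainError):
        DoseRegimen(route="intramuscular", dose=1.0)


def test_loose_tolerance_degrades_mass_balance(tozadenant):
    """A deliberately loosened solver tolerance shows a larger conservation
    error than the tight default (which is the tolerance-violation signal)."""
    phys = get_physiology("rat")
    params = PBPKParameters(
        kp=predict_kp(tozadenant, phys), clint_hepatic=3.76, cl_renal=13.0
    )
    reg = DoseRegimen(route="iv_bolus", dose=1.0)
    tight = simulate(phys, tozadenant, params, reg, 480.0)
    loose = simulate(phys, tozadenant, params, reg, 480.0, rtol=1e-2, atol=1e3)
    err_tight = abs(mass_balance(tight) - 1.0)
    err_loose = abs(mass_balance(loose) - 1.0)
    assert err_tight <= 1e-4
    assert err_loose > err_tight
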