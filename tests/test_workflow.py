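"""Model building, calibration, validation and human scale-up."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbpkit import datasets
from pbpkit.errors import ConfigurationError, DomainError
from pbpkit.pbpk import DoseRegimen
from pbpkit.workflow import (
    CalibrationTarget,
    calibrate_rat_model,
    build_model,
    compare_metrics,
    fold_error,
    humanize_and_simulate,
    parameter_recovery_experiment,
    run_workflow,
    simulate_and_nca,
    validate_fold_errors,
)


# ---------------------------------------------------------------------------
# fold-error bookkeeping
# ---------------------------------------------------------------------------


def test_fold_error_reference_row():
    """The reported human prediction row: predicted/observed fold errors
    round to (1.4, 1.0, 0.7, 1.2) for AUC_last, Cmax, Tmax, T1/2."""
    report = compare_metrics(
        "human",
        datasets.HUMAN_REPORTED_PREDICTION_240MG,
        datasets.HUMAN_OBSERVED_240MG,
    )
    folds = {m: round(e.fold, 1) for m, e in report.entries.items()}
    assert folds == {"auc_last": 1.4, "cmax": 1.0, "tmax": 0.7, "t_half": 1.2}
    assert report.all_within_twofold


def test_fold_error_trivial_and_missing():
    report = compare_metrics("x", {"auc_last": 5.0}, {"auc_last": 5.0, "cmax": 2.0})
    assert report.entries["auc_last"].fold == 1.0
    assert "cmax" not in report.entries and report.notes
    with pytest.raises(DomainError):
        fold_error(0.0, 1.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    pred=st.floats(min_value=1e-6, max_value=1e6),
    obs=st.floats(min_value=1e-6, max_value=1e6),
)
def test_fold_error_reciprocal_identity(pred, obs):
    """fold(pred, obs) * fold(obs, pred) = 1."""
    assert fold_error(pred, obs) * fold_error(obs, pred) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def test_calibration_reproduces_rat_targets(calibrated_rat):
    """The calibrated rat model's simulated IV 1 mg/kg NCA reproduces the
    observed Cl (14.36 mL/min/kg) and Vd (1.63 L/kg) within 10%."""
    _, outcome = calibrated_rat
    assert outcome.converged
    assert outcome.achieved_cl == pytest.approx(14.36, rel=0.10)
    assert outcome.achieved_vss == pytest.approx(1.63, rel=0.10)
    assert 0.0 <= outcome.cl_renal <= 50.0
    assert 0.1 <= outcome.kp_liver_mult <= 50.0
    assert 0.1 <= outcome.kp_kidney_mult <= 50.0


def test_calibration_already_satisfied_returns_initial():
    """If the starting model already meets the target, no optimization
    happens: the initial parameters come back after a single evaluation."""
    bundle = build_model("rat")
    _, nca0 = simulate_and_nca(bundle, DoseRegimen(route="iv_bolus", dose=1.0), 480.0)
    target = CalibrationTarget(observed_cl=nca0.cl, observed_vd=nca0.vss)
    outcome = calibrate_rat_model(bundle, target)
    assert outcome.n_fev == 1
    assert outcome.kp_liver_mult == 1.0 and outcome.kp_kidney_mult == 1.0
    assert outcome.params == bundle.params


def test_calibration_target_validation():
    with pytest.raises(ConfigurationError):
        CalibrationTarget()
    with pytest.raises(ConfigurationError):
        CalibrationTarget(observed_cl=14.36)  # vd missing, no profile


def test_synthetic_parameter_recovery_single():
    """The calibrator recovers known generating parameters from a noiseless
    synthetic study well within 5% per parameter."""
    rep = parameter_recovery_experiment(n_problems=2, seed=99)
    for problem in rep["problems"]:
        for err in problem["relative_errors"].values():
            assert err < 0.05


# ---------------------------------------------------------------------------
# validation and human prediction
# ---------------------------------------------------------------------------


def test_validation_fold_errors_shape(calibrated_rat):
    bundle, outcome = calibrated_rat
    calibrated = build_model("rat")
    calibrated.params = outcome.params
    regimens = [
        DoseRegimen(route="iv_bolus", dose=5.0),
        DoseRegimen(route="oral", dose=1.0),
        DoseRegimen(route="oral", dose=5.0),
    ]
    observed = [
        datasets.RAT_OBSERVED_NCA[("iv_bolus", 5.0)],
        datasets.RAT_OBSERVED_NCA[("oral", 1.0)],
        datasets.RAT_OBSERVED_NCA[("oral", 5.0)],
    ]
    reports = validate_fold_errors(calibrated, regimens, observed)
    assert len(reports) == 3
    for rep in reports:
        for entry in rep.entries.values():
            assert entry.fold > 0
        # the oral groups (the dosing-route extrapolation) stay within
        # two-fold on every reported metric
    for rep in reports[1:]:
        assert rep.all_within_twofold


def test_human_prediction_structure(calibrated_rat):
    _, outcome = calibrated_rat
    human = humanize_and_simulate(outcome)
    assert human.bundle.physiology.species == "human"
    assert human.bundle.params.clint_hepatic == pytest.approx(1.003328, rel=1e-9)
    # default renal model: fup x GFR
    assert human.bundle.params.cl_renal == pytest.approx(0.2672 * 1.8, rel=1e-9)
    assert human.summary["auc_last"] > 0 and human.summary["cmax"] > 0
    assert human.fold_report.entries["auc_last"].fold > 0


def test_human_low_extraction_matches_ivive(calibrated_rat):
    """The human hepatic elimination is consistent with the IVIVE
    well-stirred clearance (~0.95 mL/min/kg): the cumulative
    hepatic:renal elimination split matches the closed-form integral
    accounting for an orally absorbed dose with first-pass extraction."""
    _, outcome = calibrated_rat
    human = humanize_and_simulate(outcome, t_end=20000.0)
    f_hep = human.result.eliminated["hepatic"][-1]
    f_ren = human.result.eliminated["renal"][-1]
    clint = human.bundle.params.clint_hepatic  # 1.0033 mL/min/kg (human IVIVE)
    cl_r = human.bundle.params.cl_renal  # fup x GFR
    q = 20.7
    # per unit absorbed mass: cl_r*x + clint*(q*x + 1)/(q + clint) = 1
    x = (1.0 - clint / (q + clint)) / (cl_r + clint * q / (q + clint))
    hep = clint * (q * x + 1.0) / (q + clint)
    assert f_hep / f_ren == pytest.approx(hep / (cl_r * x), rel=0.02)
    # and the low-extraction regime itself: E = Cl_H/Q well below 10%
    assert clint / (q + clint) < 0.1


def test_human_dose_linearity(calibrated_rat):
    """Doubling the human dose doubles AUC_last (linear model)."""
    _, outcome = calibrated_rat
    h1 = humanize_and_simulate(outcome, dose_mg=240.0)
    h2 = humanize_and_simulate(outcome, dose_mg=480.0)
    assert h2.summary["auc_last"] == pytest.approx(2 * h1.summary["auc_last"], rel=1e-5)


def test_renal_scaling_options(calibrated_rat):
    _, outcome = calibrated_rat
    carry = humanize_and_simulate(outcome, renal_scaling="carry")
    flow = humanize_and_simulate(outcome, renal_scaling="kidney_flow")
    allo = humanize_and_simulate(outcome, renal_scaling="allometric")
    assert carry.bundle.params.cl_renal == pytest.approx(outcome.cl_renal)
    assert flow.bundle.params.cl_renal == pytest.approx(
        outcome.cl_renal * 15.2 / 41.7
    )
    assert allo.bundle.params.cl_renal == pytest.approx(
        outcome.cl_renal * (70.0 / 0.3) ** -0.25
    )
    with pytest.raises(ConfigurationError):
        humanize_and_simulate(outcome, renal_scaling="nope")


def test_kp_carryover_multiplicative(calibrated_rat):
    _, outcome = calibrated_rat
    none = humanize_and_simulate(outcome, kp_carryover="none")
    mult = humanize_and_simulate(outcome, kp_carryover="multiplicative")
    ratio = (
        mult.bundle.params.kp["liver"] / none.bundle.params.kp["liver"]
    )
    assert ratio == pytest.approx(outcome.kp_liver_mult, rel=1e-9)
    with pytest.raises(ConfigurationError):
        humanize_and_simulate(outcome, kp_carryover="additive")


def test_missing_human_inputs_rejected(calibrated_rat):
    import dataclasses

    _, outcome = calibrated_rat
    rat_only = dataclasses.replace(
        datasets.TOZADENANT, fup={"rat": 0.2663}, clint_in_vitro={"rat": 0.0021}
    )
    with pytest.raises(ConfigurationError):
        humanize_and_simulate(outcome, compound=rat_only)


def test_workflow_end_to_end_deterministic():
    """Two full pipeline runs produce byte-identical JSON reports."""
    rep1 = run_workflow()
    rep2 = run_workflow()
    assert json.dumps(rep1, sort_keys=True) == json.dumps(rep2, sort_keys=True)
    assert rep1["rat_calibration"]["converged"]
    assert "human_prediction" in rep1
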