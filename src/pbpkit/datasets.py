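"""Published input values for the tozadenant case study.

Tozadenant is an orally administered selective adenosine A2a receptor
antagonist investigated for Parkinson's disease.  The dictionaries below
collect the published compound properties, the measured in vitro ADME
inputs, the observed rat NCA parameter means (n = 4 per group), and the
observed human PK of a 240 mg oral dose, which together drive the
rat-to-human prediction workflow.  They are model *inputs*, not outputs:
everything else in the package is computed from them.
"""

from __future__ import annotations

from .pbpk import CompoundProperties

__all__ = [
    "TOZADENANT",
    "STANDARD_LEVELS_NG_ML",
    "QC_LEVELS_NG_ML",
    "RAT_OBSERVED_NCA",
    "RAT_IV1_CALIBRATION_TARGET",
    "HUMAN_OBSERVED_240MG",
    "HUMAN_REPORTED_PREDICTION_240MG",
    "HUMAN_DOSE_MG",
]

#: compound-property inputs (structure-predicted physicochemistry plus the
#: measured unbound fraction and microsomal intrinsic clearance)
TOZADENANT = CompoundProperties(
    name="tozadenant",
    mw=406.5,  # g/mol
    pka=(3.28, 4.7, 10.81),
    logp=1.96,
    rbp=0.82,  # blood/plasma concentration ratio
    fup={"rat": 0.2663, "human": 0.2672},  # fraction unbound
    solubility=0.28,  # mg/mL at pH 7
    permeability=1.62,  # effective permeability (reported predicted value)
    clint_in_vitro={"rat": 0.0021, "human": 0.0008},  # mL/min/mg
)

#: calibration standard concentrations, ng/mL
STANDARD_LEVELS_NG_ML = (1.01, 3.02, 9.05, 27.2, 81.5, 244, 733, 2200)

#: quality-control levels, ng/mL (low / medium / high, plus the 5x dilution QC)
QC_LEVELS_NG_ML = {"low": 15.04, "medium": 165.46, "high": 1820.0, "dilution": 6600.0}

#: observed rat NCA parameter means per dose group.
#: Units: t_half min, tmax min, cmax ng/mL, auc_last and auc_inf min*ng/mL,
#: cl mL/min/kg, vd L/kg.  Dose in mg/kg; route iv_bolus or oral.
RAT_OBSERVED_NCA = {
    ("iv_bolus", 1.0): {
        "t_half": 139.26,
        "tmax": 2.0,
        "cmax": 1118.92,
        "auc_last": 67142.34,
        "auc_inf": 70342.35,
        "cl": 14.36,
        "vd": 1.63,
    },
    ("iv_bolus", 5.0): {
        "t_half": 99.69,
        "tmax": 2.0,
        "cmax": 7820.27,
        "auc_last": 431241.43,
        "auc_inf": 445005.24,
        "cl": 11.31,
        "vd": 1.28,
    },
    ("oral", 1.0): {
        "t_half": 147.91,
        "tmax": 22.5,
        "cmax": 368.97,
        "auc_last": 48958.98,
        "auc_inf": 54665.08,
    },
    ("oral", 5.0): {
        "t_half": 144.84,
        "tmax": 27.5,
        "cmax": 1666.3,
        "auc_last": 279450.32,
        "auc_inf": 313549.48,
    },
}

#: the rat IV 1 mg/kg summary parameters the PBPK model is calibrated to
RAT_IV1_CALIBRATION_TARGET = {"cl": 14.36, "vd": 1.63}  # mL/min/kg, L/kg

#: observed clinical PK of a single 240 mg oral dose
#: (auc_last ug*h/mL, cmax ug/mL, tmax h, t_half h)
HUMAN_OBSERVED_240MG = {"auc_last": 35.0, "cmax": 1.74, "tmax": 4.0, "t_half": 15.0}

#: the previously reported model prediction for the same dose (same units);
#: used only for fold-error bookkeeping checks, never as a model input
HUMAN_REPORTED_PREDICTION_240MG = {
    "auc_last": 49.6,
    "cmax": 1.8,
    "tmax": 2.8,
    "t_half": 17.4,
}

HUMAN_DOSE_MG = 240.0

#: rat PK study sampling grid, minutes post-dose
RAT_SAMPLING_GRID_MIN = (0, 2, 5, 10, 20, 40, 60, 90, 120, 240, 360, 480)
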