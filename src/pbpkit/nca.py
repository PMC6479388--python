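"""Non-compartmental analysis of concentration-time profiles.

Model-free PK parameter estimation: Cmax/Tmax from the observed points,
AUC by the trapezoidal rule (lin-up/log-down by default, which is exact
for mono-exponential decay between samples; plain linear available),
terminal rate constant lambda_z by log-linear regression over an
automatically selected terminal window, and the derived parameters

    t1/2    = ln 2 / lambda_z
    AUC_inf = AUC_last + C_last / lambda_z
    Cl      = dose / AUC_inf                      (IV)
    Vss     = dose * AUMC_inf / AUC_inf^2         (IV bolus)
    Vz      = Cl / lambda_z

Terminal-window rule: all windows of >= 3 consecutive points ending at the
last positive concentration and starting strictly after Tmax are fitted;
the window with the highest adjusted R^2 wins, ties (within 1e-4) going to
the window with more points.  This mirrors the best-fit convention of
commercial NCA software.  On dense simulated grids the candidate starts are
thinned to at most 40 evenly spaced positions to bound cost.

Absolute oral bioavailability:

    F = (Dose_iv / Dose_po) * (AUC_po / AUC_iv) * 100  (%)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError

__all__ = [
    "ConcentrationProfile",
    "NCAResult",
    "run_nca",
    "bioavailability",
    "mean_bioavailability",
]


@dataclass(frozen=True)
class ConcentrationProfile:
    """A plasma concentration-time series with dosing metadata.

    times in min (strictly increasing), conc in ng/mL (>= 0, at least 3
    points), dose in ng per kg body weight.
    """

    times: tuple[float, ...]
    conc: tuple[float, ...]
    dose: float  # ng/kg
    route: str  # "iv_bolus" or "oral"
    species: str = ""
    blq: tuple[bool, ...] | None = None  # censored-below-LLOQ mask

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if t.size != c.size or t.size < 3:
            raise DomainError("profile needs >= 3 paired points")
        if np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(c < 0):
            raise DomainError("concentrations must be >= 0")
        if self.route not in ("iv_bolus", "oral"):
            raise DomainError(f"unknown route {self.route!r}")


@dataclass
class NCAResult:
    """Non-compartmental parameters; lambda_z-dependent fields are NaN when
    the terminal phase is not estimable (``lambda_z_estimable`` False)."""

    cmax: float  # ng/mL
    tmax: float  # min
    lambda_z: float  # 1/min
    t_half: float  # min
    auc_last: float  # min*ng/mL
    auc_inf: float  # min*ng/mL
    cl: float  # mL/min/kg (dose/AUC_inf; CL/F for oral)
    vss: float  # L/kg (IV bolus only, else NaN)
    vz: float  # L/kg
    n_lambda_points: int
    lambda_z_estimable: bool
    c0_extrapolated: float = float("nan")  # back-extrapolated C(0), IV only

    def as_dict(self) -> dict:
        return {
            "cmax_ng_ml": self.cmax,
            "tmax_min": self.tmax,
            "lambda_z_per_min": self.lambda_z,
            "t_half_min": self.t_half,
            "auc_last_min_ng_ml": self.auc_last,
            "auc_inf_min_ng_ml": self.auc_inf,
            "cl_ml_min_kg": self.cl,
            "vss_l_kg": self.vss,
            "vz_l_kg": self.vz,
            "n_lambda_points": self.n_lambda_points,
            "lambda_z_estimable": self.lambda_z_estimable,
        }


def _trapz(t: np.ndarray, c: np.ndarray, method: str) -> float:
    if method == "linear":
        return float(np.trapezoid(c, t))
    if method == "linear_log":
        # linear up, logarithmic down between positive points
        auc = 0.0
        for i in range(len(t) - 1):
            dt = t[i + 1] - t[i]
            c1, c2 = c[i], c[i + 1]
            if c2 < c1 and c2 > 0 and c1 > 0:
                auc += dt * (c1 - c2) / math.log(c1 / c2)
            else:
                auc += dt * 0.5 * (c1 + c2)
        return auc
    raise DomainError(f"unknown AUC method {method!r}")


def _select_lambda_window(
    t: np.ndarray, c: np.ndarray, i_tmax: int, max_candidates: int = 40
) -> tuple[float, float, int, float] | None:
    """Best terminal log-linear window.

    Returns (lambda_z, intercept, n_points, adj_r2) or None if not
    estimable.  Only points strictly after Tmax with positive concentration
    are eligible; trailing non-positive points are dropped first.
    """
    last = len(c) - 1
    while last >= 0 and c[last] <= 0:
        last -= 1
    eligible = [i for i in range(i_tmax + 1, last + 1) if c[i] > 0]
    if len(eligible) < 3:
        return None

    starts = list(range(len(eligible) - 2))
    if len(starts) > max_candidates:
        pick = np.unique(np.linspace(0, len(starts) - 1, max_candidates).astype(int))
        starts = [starts[i] for i in pick]

    best: tuple[float, float, int, float] | None = None
    best_key: tuple[float, int] | None = None
    for s in starts:
        ids = eligible[s:]
        tt = t[ids]
        yy = np.log(c[ids])
        n = len(ids)
        slope, intercept = np.polyfit(tt, yy, 1)
        if slope >= 0:
            continue
        fit = slope * tt + intercept
        ss_res = float(np.sum((yy - fit) ** 2))
        ss_tot = float(np.sum((yy - yy.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        key = (round(adj, 4), n)
        if best_key is None or key > best_key:
            best_key = key
            best = (-float(slope), float(intercept), n, float(adj))
    return best


def run_nca(
    profile: ConcentrationProfile,
    auc_method: str = "linear_log",
) -> NCAResult:
    """Run non-compartmental analysis on one profile.

    For an IV bolus whose first sample is at t > 0 (or is zero at t = 0,
    i.e. a pre-dose sample), C(0) is back-extrapolated from the log-linear
    fit of the first two positive points, the standard convention.
    """
    t = np.asarray(profile.times, dtype=float)
    c = np.asarray(profile.conc, dtype=float)

    c0_extrap = float("nan")
    if profile.route == "iv_bolus":
        pos = np.flatnonzero(c > 0)
        if pos.size >= 2:
            i1, i2 = pos[0], pos[1]
            need_c0 = t[0] > 0 or (t[0] == 0 and c[0] == 0)
            if need_c0 and c[i1] != c[i2]:
                slope = (math.log(c[i2]) - math.log(c[i1])) / (t[i2] - t[i1])
                c0_extrap = float(math.exp(math.log(c[i1]) - slope * t[i1]))
                if t[0] == 0:
                    c = c.copy()
                    c[0] = c0_extrap
                else:
                    t = np.concatenate([[0.0], t])
                    c = np.concatenate([[c0_extrap], c])

    i_cmax = int(np.argmax(c))
    cmax = float(c[i_cmax])
    tmax = float(t[i_cmax])
    # for Cmax/Tmax report the *observed* maximum (not the extrapolated C0)
    obs_c = np.asarray(profile.conc, dtype=float)
    obs_t = np.asarray(profile.times, dtype=float)
    i_obs = int(np.argmax(obs_c))
    cmax_obs, tmax_obs = float(obs_c[i_obs]), float(obs_t[i_obs])

    auc_last = _trapz(t, c, auc_method)
    aumc_last = _trapz(t, t * c, auc_method)

    window = _select_lambda_window(t, c, i_cmax)
    if window is None:
        return NCAResult(
            cmax=cmax_obs,
            tmax=tmax_obs,
            lambda_z=float("nan"),
            t_half=float("nan"),
            auc_last=auc_last,
            auc_inf=float("nan"),
            cl=float("nan"),
            vss=float("nan"),
            vz=float("nan"),
            n_lambda_points=0,
            lambda_z_estimable=False,
            c0_extrapolated=c0_extrap,
        )

    lam, _, n_pts, _ = window
    # last positive concentration closes the extrapolation
    pos = np.flatnonzero(c > 0)
    c_last, t_last = float(c[pos[-1]]), float(t[pos[-1]])

    auc_inf = auc_last + c_last / lam
    aumc_inf = aumc_last + c_last * t_last / lam + c_last / lam**2
    t_half = math.log(2.0) / lam

    cl = profile.dose / auc_inf  # mL/min/kg (ng/kg / (min*ng/mL))
    vz = cl / lam / 1000.0  # L/kg
    if profile.route == "iv_bolus":
        vss = cl * (aumc_inf / auc_inf) / 1000.0  # = D*AUMC/AUC^2, L/kg
    else:
        vss = float("nan")

    return NCAResult(
        cmax=cmax_obs,
        tmax=tmax_obs,
        lambda_z=lam,
        t_half=t_half,
        auc_last=auc_last,
        auc_inf=auc_inf,
        cl=cl,
        vss=vss,
        vz=vz,
        n_lambda_points=n_pts,
        lambda_z_estimable=True,
        c0_extrapolated=c0_extrap,
    )


def bioavailability(
    auc_po: float, dose_po: float, auc_iv: float, dose_iv: float
) -> float:
    """Absolute oral bioavailability F (%) from dose-normalized AUC ratio."""
    for v, label in [
        (auc_po, "auc_po"),
        (dose_po, "dose_po"),
        (auc_iv, "auc_iv"),
        (dose_iv, "dose_iv"),
    ]:
        if not v > 0:
            raise DomainError(f"{label} must be > 0")
    return (dose_iv / dose_po) * (auc_po / auc_iv) * 100.0


def mean_bioavailability(
    groups: Sequence[tuple[float, float, float, float]],
) -> float:
    """Arithmetic mean of per-dose-group F values.

    Each group is (auc_po, dose_po, auc_iv, dose_iv); used to average F
    across dose levels computed from group-mean AUCs.
    """
    if not groups:
        raise DomainError("mean_bioavailability requires at least one group")
    return float(np.mean([bioavailability(*g) for g in groups]))
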