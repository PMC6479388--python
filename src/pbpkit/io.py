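"""CSV and plain-text configuration I/O.

Column dialect: snake_case with units embedded (time_min, conc_ng_ml,
plasma_ng_ml, buffer_ng_ml, remaining_pct, response_ratio), one header row,
UTF-8, '.' decimal separator.  Readers raise :class:`SchemaError` naming
the offending column rather than failing deep inside pandas.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import SchemaError
from .invitro import DepletionAssay, DialysisPair
from .nca import ConcentrationProfile

__all__ = [
    "read_profile_csv",
    "write_profile_csv",
    "read_depletion_csv",
    "read_dialysis_csv",
    "read_responses_csv",
    "read_keyvalue_config",
]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


def read_profile_csv(
    path, dose: float, route: str, species: str = ""
) -> ConcentrationProfile:
    """Read a concentration-time table (columns time_min, conc_ng_ml).

    ``dose`` in ng per kg body weight.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["time_min", "conc_ng_ml"], path)
    df = df.sort_values("time_min")
    return ConcentrationProfile(
        times=tuple(float(v) for v in df["time_min"]),
        conc=tuple(float(v) for v in df["conc_ng_ml"]),
        dose=dose,
        route=route,
        species=species,
    )


def write_profile_csv(path, times, conc) -> None:
    pd.DataFrame({"time_min": times, "conc_ng_ml": conc}).to_csv(path, index=False)


def read_depletion_csv(path) -> list[DepletionAssay]:
    """Read depletion data (time_min, replicate, remaining_pct, protein_mg_ml).

    Rows are grouped by protein concentration; one assay per level with all
    replicates pooled.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["time_min", "remaining_pct", "protein_mg_ml"], path)
    assays = []
    for protein, grp in df.groupby("protein_mg_ml"):
        assays.append(
            DepletionAssay(
                times=tuple(float(v) for v in grp["time_min"]),
                remaining=tuple(float(v) for v in grp["remaining_pct"]),
                protein_conc=float(protein),
            )
        )
    return assays


def read_dialysis_csv(path) -> list[DialysisPair]:
    """Read dialysis pairs (plasma_ng_ml, buffer_ng_ml)."""
    df = pd.read_csv(path)
    _require_columns(df, ["plasma_ng_ml", "buffer_ng_ml"], path)
    return [
        DialysisPair(plasma_conc=float(r.plasma_ng_ml), buffer_conc=float(r.buffer_ng_ml))
        for r in df.itertuples()
    ]


def read_responses_csv(path) -> pd.DataFrame:
    """Read calibration/QC responses (sample_id, [nominal_ng_ml], response_ratio)."""
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "response_ratio"], path)
    return df


def read_keyvalue_config(path) -> dict[str, str]:
    """Parse a plain-text ``key = value`` configuration file.

    Lines starting with '#' (or inline '#' comments) are ignored.
    """
    config: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError(f"{path}: malformed config line {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        config[key] = value
    return config
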