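"""Species anatomy and physiology for whole-body PBPK simulation.

The body is represented by 14 compartments — arterial blood, venous blood,
lung, and eleven perfused tissues (adipose, muscle, liver, spleen, gut,
heart, brain, kidney, skin, bone+marrow, rest-of-body) — linked by the
arterial/venous circulation with the lung in series.  Gut and spleen drain
into the portal vein, so their venous outflow passes through the liver
together with the hepatic-artery supply.

Tissue volumes and regional blood flows are standard reference-compendium
values for the rat (0.3 kg) and human (70 kg), lightly adjusted so that the
two circulatory identities hold exactly:

* the sum of venous returns equals cardiac output, and
* hepatic artery + gut + spleen flows equal total hepatic blood flow.

Four constants are fixed to the values used by the clearance-scaling
equations: hepatic blood flow (rat 55.2, human 20.7 mL/min/kg), microsomal
protein content (44.8 / 48.8 mg per g liver) and liver mass (40 / 25.7 g per
kg body weight).  Glomerular filtration rate (rat 5.2, human 1.8 mL/min/kg)
is carried along because the default renal clearance model is fup x GFR.

All volumes are L per kg body weight, all flows mL/min per kg body weight.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ConfigurationError, UnsupportedSpeciesError

__all__ = [
    "TissueSpec",
    "SpeciesPhysiology",
    "get_physiology",
    "PORTAL_TISSUES",
    "BLOOD_COMPARTMENTS",
    "PERFUSED_TISSUES",
]

#: tissues whose venous outflow drains into the portal vein (through the liver)
PORTAL_TISSUES = ("gut", "spleen")

#: the two blood pools
BLOOD_COMPARTMENTS = ("venous_blood", "arterial_blood")

#: perfused parallel tissues (lung is in series and handled separately)
PERFUSED_TISSUES = (
    "adipose",
    "muscle",
    "liver",
    "spleen",
    "gut",
    "heart",
    "brain",
    "kidney",
    "skin",
    "bone",
    "rest",
)


@dataclass(frozen=True)
class TissueSpec:
    """One compartment of the whole-body model.

    Parameters
    ----------
    name : str
        Tissue identifier (see :data:`PERFUSED_TISSUES`).
    volume : float
        Anatomical volume, L per kg body weight.
    blood_flow : float
        Perfusing blood flow, mL/min per kg body weight.  For the liver this
        is the *total* hepatic flow (hepatic artery + portal vein); for the
        blood pools and lung it equals cardiac output.
    is_eliminating : bool
        True for organs that clear drug (liver, kidney).
    """

    name: str
    volume: float
    blood_flow: float
    is_eliminating: bool = False

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise ConfigurationError(f"tissue {self.name!r}: volume must be > 0")
        if self.blood_flow < 0:
            raise ConfigurationError(f"tissue {self.name!r}: blood_flow must be >= 0")


@dataclass(frozen=True)
class SpeciesPhysiology:
    """Complete anatomical/physiological parameter set for one species."""

    species: str
    body_weight: float  # kg
    tissues: tuple[TissueSpec, ...]
    cardiac_output: float  # mL/min/kg
    hepatic_blood_flow: float  # mL/min/kg, = hepatic artery + portal
    mppgl: float  # mg microsomal protein per g liver
    liver_mass: float  # g liver per kg body weight
    gfr: float  # mL/min/kg glomerular filtration rate

    def __post_init__(self) -> None:
        names = [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            raise ConfigurationError("tissue names must be unique")
        for value, label in [
            (self.body_weight, "body_weight"),
            (self.cardiac_output, "cardiac_output"),
            (self.hepatic_blood_flow, "hepatic_blood_flow"),
            (self.mppgl, "mppgl"),
            (self.liver_mass, "liver_mass"),
            (self.gfr, "gfr"),
        ]:
            if not value > 0:
                raise ConfigurationError(f"{label} must be strictly positive")
        self.validate_flows()

    # -- lookups ---------------------------------------------------------
    def tissue(self, name: str) -> TissueSpec:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def tissue_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.tissues)

    def hepatic_artery_flow(self) -> float:
        """Hepatic-artery flow = total hepatic flow minus portal inflow."""
        portal = sum(self.tissue(n).blood_flow for n in PORTAL_TISSUES)
        return self.tissue("liver").blood_flow - portal

    def venous_return(self) -> float:
        """Sum of venous outflows reaching the vena cava (mL/min/kg).

        Portal tissues are excluded: their outflow reaches the venous pool
        via the liver, whose total outflow is counted once.
        """
        return sum(
            t.blood_flow
            for t in self.tissues
            if t.name in PERFUSED_TISSUES and t.name not in PORTAL_TISSUES
        )

    # -- invariants ------------------------------------------------------
    def validate_flows(self, tol: float = 0.01) -> None:
        """Check the two circulatory identities to relative tolerance `tol`."""
        ret = self.venous_return()
        if abs(ret - self.cardiac_output) > tol * self.cardiac_output:
            raise ConfigurationError(
                f"venous return {ret:.2f} differs from cardiac output "
                f"{self.cardiac_output:.2f} by more than {tol:.0%}"
            )
        q_liver = self.tissue("liver").blood_flow
        if abs(q_liver - self.hepatic_blood_flow) > tol * self.hepatic_blood_flow:
            raise ConfigurationError(
                f"liver flow {q_liver:.2f} differs from hepatic_blood_flow "
                f"{self.hepatic_blood_flow:.2f} by more than {tol:.0%}"
            )
        if self.hepatic_artery_flow() <= 0:
            raise ConfigurationError("hepatic artery flow must be positive")

    # -- plain-text round trip -------------------------------------------
    def to_text(self) -> str:
        """Serialize as a plain-text key-value document (one tissue per block)."""
        lines = [
            f"species = {self.species}",
            f"body_weight_kg = {self.body_weight!r}",
            f"cardiac_output_ml_min_kg = {self.cardiac_output!r}",
            f"hepatic_blood_flow_ml_min_kg = {self.hepatic_blood_flow!r}",
            f"mppgl_mg_g = {self.mppgl!r}",
            f"liver_mass_g_kg = {self.liver_mass!r}",
            f"gfr_ml_min_kg = {self.gfr!r}",
        ]
        for t in self.tissues:
            lines += [
                "",
                f"[tissue {t.name}]",
                f"volume_l_kg = {t.volume!r}",
                f"blood_flow_ml_min_kg = {t.blood_flow!r}",
                f"is_eliminating = {str(t.is_eliminating).lower()}",
            ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SpeciesPhysiology":
        """Parse the document produced by :meth:`to_text` (overrides allowed)."""
        header: dict[str, str] = {}
        tissues: list[TissueSpec] = []
        current: dict[str, str] | None = None
        current_name = ""

        def flush() -> None:
            if current is None:
                return
            try:
                tissues.append(
                    TissueSpec(
                        name=current_name,
                        volume=float(current["volume_l_kg"]),
                        blood_flow=float(current["blood_flow_ml_min_kg"]),
                        is_eliminating=current.get("is_eliminating", "false") == "true",
                    )
                )
            except KeyError as exc:  # pragma: no cover - defensive
                raise ConfigurationError(
                    f"tissue block {current_name!r} missing key {exc}"
                ) from exc

        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[tissue ") and line.endswith("]"):
                flush()
                current_name = line[len("[tissue ") : -1].strip()
                current = {}
                continue
            if "=" not in line:
                raise ConfigurationError(f"malformed physiology line: {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            (header if current is None else current)[key] = value
        flush()

        try:
            return cls(
                species=header["species"],
                body_weight=float(header["body_weight_kg"]),
                tissues=tuple(tissues),
                cardiac_output=float(header["cardiac_output_ml_min_kg"]),
                hepatic_blood_flow=float(header["hepatic_blood_flow_ml_min_kg"]),
                mppgl=float(header["mppgl_mg_g"]),
                liver_mass=float(header["liver_mass_g_kg"]),
                gfr=float(header["gfr_ml_min_kg"]),
            )
        except KeyError as exc:
            raise ConfigurationError(f"physiology document missing key {exc}") from exc

    def with_body_weight(self, body_weight: float) -> "SpeciesPhysiology":
        return replace(self, body_weight=body_weight)


def _make(
    species: str,
    body_weight: float,
    cardiac_output: float,
    hepatic_blood_flow: float,
    mppgl: float,
    liver_mass: float,
    gfr: float,
    volumes: dict[str, float],
    flows: dict[str, float],
) -> SpeciesPhysiology:
    tissues = []
    order = BLOOD_COMPARTMENTS + ("lung",) + PERFUSED_TISSUES
    for name in order:
        tissues.append(
            TissueSpec(
                name=name,
                volume=volumes[name],
                blood_flow=flows.get(name, cardiac_output),
                is_eliminating=name in ("liver", "kidney"),
            )
        )
    return SpeciesPhysiology(
        species=species,
        body_weight=body_weight,
        tissues=tuple(tissues),
        cardiac_output=cardiac_output,
        hepatic_blood_flow=hepatic_blood_flow,
        mppgl=mppgl,
        liver_mass=liver_mass,
        gfr=gfr,
    )


# Reference-compendium tissue volumes (L/kg body weight).  Liver volume set
# equal to liver mass at unit density so the two bookkeeping routes agree.
_RAT_VOLUMES = {
    "venous_blood": 0.0359,
    "arterial_blood": 0.0181,
    "lung": 0.0050,
    "adipose": 0.0761,
    "muscle": 0.4040,
    "liver": 0.0400,
    "spleen": 0.0020,
    "gut": 0.0270,
    "heart": 0.0033,
    "brain": 0.0057,
    "kidney": 0.0073,
    "skin": 0.1900,
    "bone": 0.0745,
    "rest": 0.0500,
}

# Regional flows (mL/min/kg).  Venous returns sum exactly to cardiac output:
# 20.7+82.3+14.5+5.9+41.7+17.2+36.1+22.4+55.2 = 296.0; hepatic artery
# = 55.2 - 40.0 - 9.0 = 6.2.
_RAT_FLOWS = {
    "adipose": 20.7,
    "muscle": 82.3,
    "liver": 55.2,
    "spleen": 9.0,
    "gut": 40.0,
    "heart": 14.5,
    "brain": 5.9,
    "kidney": 41.7,
    "skin": 17.2,
    "bone": 36.1,
    "rest": 22.4,
}

_HUMAN_VOLUMES = {
    "venous_blood": 0.0490,
    "arterial_blood": 0.0250,
    "lung": 0.0076,
    "adipose": 0.2100,
    "muscle": 0.4000,
    "liver": 0.0257,
    "spleen": 0.0026,
    "gut": 0.0171,
    "heart": 0.0047,
    "brain": 0.0200,
    "kidney": 0.0044,
    "skin": 0.0371,
    "bone": 0.1143,
    "rest": 0.0500,
}

# 4.0+13.6+14.5...: venous returns 4.0+13.6+4.0+9.6+15.2+4.0+4.0+4.9+20.7 = 80.0;
# hepatic artery = 20.7 - 13.0 - 3.4 = 4.3.
_HUMAN_FLOWS = {
    "adipose": 4.0,
    "muscle": 13.6,
    "liver": 20.7,
    "spleen": 3.4,
    "gut": 13.0,
    "heart": 4.0,
    "brain": 9.6,
    "kidney": 15.2,
    "skin": 4.0,
    "bone": 4.0,
    "rest": 4.9,
}


def get_physiology(species: str) -> SpeciesPhysiology:
    """Return the built-in physiology for ``"rat"`` or ``"human"``.

    Raises
    ------
    UnsupportedSpeciesError
        For any other species identifier.
    """
    key = species.strip().lower()
    if key == "rat":
        return _make(
            "rat",
            body_weight=0.3,
            cardiac_output=296.0,
            hepatic_blood_flow=55.2,
            mppgl=44.8,
            liver_mass=40.0,
            gfr=5.2,
            volumes=_RAT_VOLUMES,
            flows=_RAT_FLOWS,
        )
    if key == "human":
        return _make(
            "human",
            body_weight=70.0,
            cardiac_output=80.0,
            hepatic_blood_flow=20.7,
            mppgl=48.8,
            liver_mass=25.7,
            gfr=1.8,
            volumes=_HUMAN_VOLUMES,
            flows=_HUMAN_FLOWS,
        )
    raise UnsupportedSpeciesError(
        f"no built-in physiology for species {species!r}; supported: rat, human"
    )
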