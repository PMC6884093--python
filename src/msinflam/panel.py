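"""Biomarker panel definitions.

The default panel mirrors a standard clinical inflammation work-up in two
compartments: eight blood acute phase reactants (APRs) and eight
cerebrospinal-fluid (CSF) immune-activation analytes.  Negative APRs
(serum albumin, iron, transferrin) *fall* during systemic inflammation, so
their standardized scores are multiplied by -1 before cluster derivation
and scoring; that polarity is recorded here, not hard-coded downstream.
"""
from __future__ import annotations

from dataclasses import dataclass


BLOOD = "blood"
CSF = "csf"

#: analytes whose concentration decreases during an acute phase response
NEGATIVE_APRS = ("serum_albumin", "iron", "transferrin")


@dataclass(frozen=True)
class BiomarkerSpec:
    """Metadata for one analyte: compartment, polarity and units."""

    name: str
    compartment: str
    polarity: str = "positive"
    units: str = ""
    display: str = ""

    def __post_init__(self):
        if self.compartment not in (BLOOD, CSF):
            raise ValueError(f"unknown compartment {self.compartment!r} for {self.name}")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r} for {self.name}")
        if not self.display:
            object.__setattr__(self, "display", self.name)


def default_panel() -> list[BiomarkerSpec]:
    """The 8 blood APRs + 8 CSF analytes used throughout the pipeline."""
    b, c = BLOOD, CSF
    return [
        BiomarkerSpec("serum_albumin", b, "negative", "g/dL", "Serum albumin"),
        BiomarkerSpec("ceruloplasmin", b, "positive", "mg/dL", "Ceruloplasmin"),
        BiomarkerSpec("wbc", b, "positive", "cells/uL", "WBC"),
        BiomarkerSpec("crp", b, "positive", "mg/L", "CRP"),
        BiomarkerSpec("esr", b, "positive", "mm/h", "ESR"),
        BiomarkerSpec("iron", b, "negative", "mcg/dL", "Iron"),
        BiomarkerSpec("ferritin", b, "positive", "mcg/L", "Ferritin"),
        BiomarkerSpec("transferrin", b, "negative", "mg/dL", "Transferrin"),
        BiomarkerSpec("csf_scd14", c, "positive", "ng/mL", "CSF sCD14"),
        BiomarkerSpec("csf_scd163", c, "positive", "ng/mL", "CSF sCD163"),
        BiomarkerSpec("csf_chi3l1", c, "positive", "ng/mL", "CSF CHI3L1"),
        BiomarkerSpec("csf_sbcma", c, "positive", "pg/mL", "CSF sBCMA"),
        BiomarkerSpec("csf_scd27", c, "positive", "U/mL", "CSF sCD27"),
        BiomarkerSpec("csf_albumin", c, "positive", "mg/dL", "CSF albumin"),
        BiomarkerSpec("csf_igg", c, "positive", "mg/dL", "CSF IgG"),
        BiomarkerSpec("igg_index", c, "positive", "", "IgG index"),
    ]


def panel_map(panel: list[BiomarkerSpec] | None = None) -> dict[str, BiomarkerSpec]:
    specs = panel if panel is not None else default_panel()
    out: dict[str, BiomarkerSpec] = {}
    for s in specs:
        if s.name in out:
            raise ValueError(f"duplicate analyte name {s.name!r} in panel")
        out[s.name] = s
    return out


def compartment_names(compartment: str, panel: list[BiomarkerSpec] | None = None) -> list[str]:
    specs = panel if panel is not None else default_panel()
    return [s.name for s in specs if s.compartment == compartment]


def blood_names(panel=None) -> list[str]:
    return compartment_names(BLOOD, panel)


def csf_names(panel=None) -> list[str]:
    return compartment_names(CSF, panel)


#: published composite layout: three blood clusters, an innate (myeloid) and
#: a humoral CSF cluster, with sCD27 (T-cell marker) and CSF albumin
#: (blood-brain-barrier marker) kept as standalone scores.
FROZEN_CLUSTER_LAYOUT: list[tuple[str, str, tuple[str, ...]]] = [
    ("Blood cluster 1", BLOOD, ("ceruloplasmin", "crp", "esr", "iron")),
    ("Blood cluster 2", BLOOD, ("wbc", "serum_albumin")),
    ("Blood cluster 3", BLOOD, ("ferritin", "transferrin")),
    ("CSF cluster 1", CSF, ("csf_scd14", "csf_scd163", "csf_chi3l1")),
    ("CSF cluster 2", CSF, ("csf_igg", "igg_index", "csf_sbcma")),
    ("sCD27", CSF, ("csf_scd27",)),
    ("CSF albumin", CSF, ("csf_albumin",)),
]
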