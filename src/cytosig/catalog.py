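"""Default assay catalogue.

The study design this package analyses: PBMC cultures from healthy donors
treated with ten model innate immune response modulating impurities (IIRMIs)
at four concentrations each, with or without co-exposure to the drug product
teriparatide (TP), alongside vehicle negative controls (NC) and an
LPS/PHA-M/ODN positive control (PC).  Supernatants are read on a 16-plex
cytokine immunoassay.

Everything here is plain data: the cytokine panel and its fixed ordering
(used for deterministic tie-breaking), the stimulus catalogue with tested
concentrations, per-stimulus signature cytokines used as synthetic-study
defaults, and the reference top-3 induction matrix used for panel-reduction
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

# 16-plex panel in assay order; the index of a cytokine in this tuple is its
# `panel_order`, the deterministic tie-break rank used throughout.
CYTOKINES_16: tuple[str, ...] = (
    "IFNα", "IFNγ", "IFNλ",
    "IL-1α", "IL-1β", "IL-2", "IL-6", "IL-8", "IL-10", "IL-12", "IL-17",
    "IP-10", "TNFα", "PGE-2", "MIP-1α", "MCP-1",
)

# Reduced 7-plex panel: the six IIRMI signature cytokines plus the
# drug-product marker PGE-2.
CYTOKINES_7: tuple[str, ...] = (
    "IL-1α", "MIP-1α", "IP-10", "MCP-1", "IL-6", "IL-8", "PGE-2",
)

NC = "NC"
PC = "PC"
DRUG = "TP"

ROLE_NEGATIVE = "negative_control"
ROLE_POSITIVE = "positive_control"
ROLE_TREATMENT = "treatment"
ROLES = (ROLE_NEGATIVE, ROLE_POSITIVE, ROLE_TREATMENT)

CENSOR_NONE = "none"
CENSOR_BDL = "BDL"   # below detection limit -> substituted with 0
CENSOR_ADL = "ADL"   # above detection limit -> substituted with the ULOQ
CENSOR_VALUES = (CENSOR_NONE, CENSOR_BDL, CENSOR_ADL)

# Stimulus dose units, as multiples of pg/mL (internal canonical unit).
UNIT_TO_PG = {
    "pg/mL": 1.0,
    "ng/mL": 1e3,
    "ug/mL": 1e6,
    "µg/mL": 1e6,
    "μg/mL": 1e6,
    "mg/mL": 1e9,
}


@dataclass(frozen=True)
class StimulusEntry:
    """One catalogued stimulus: receptor annotation and tested doses."""

    name: str
    receptor: str
    location: str                 # membrane | endosome | cytosol | drug
    doses: tuple[float, ...]      # tested concentrations, pg/mL, descending
    unit: str                     # display unit for reports

    @property
    def doses_ascending(self) -> tuple[float, ...]:
        return tuple(sorted(self.doses))


def _entry(name: str, receptor: str, location: str,
           doses_in_unit: tuple[float, ...], unit: str) -> StimulusEntry:
    factor = UNIT_TO_PG[unit]
    return StimulusEntry(name, receptor, location,
                         tuple(d * factor for d in doses_in_unit), unit)


# Ten model IIRMIs with their cognate pattern-recognition receptors and the
# four tested final concentrations, plus the drug product tested alone.
# Membrane-tethered PRRs first, then endosomal, then cytosolic.
DEFAULT_DESIGN: dict[str, StimulusEntry] = {
    e.name: e
    for e in (
        _entry("flagellin", "TLR5", "membrane", (10, 1, 0.1, 0.01), "ug/mL"),
        _entry("FSL-1", "TLR2/TLR6", "membrane", (10, 1, 0.1, 0.01), "ng/mL"),
        _entry("zymosan", "TLR2/Dectin 1", "membrane", (10, 1, 0.1, 0.01), "ug/mL"),
        _entry("LPS", "TLR4", "membrane", (1, 0.1, 0.01, 0.001), "ng/mL"),
        _entry("ODN2006", "TLR9", "endosome", (10, 1, 0.1, 0.01), "ug/mL"),
        _entry("poly(I:C) HMW", "TLR3", "endosome", (10, 1, 0.1, 0.01), "ug/mL"),
        _entry("poly(I:C) LMW", "TLR3", "endosome", (10, 1, 0.1, 0.01), "ug/mL"),
        _entry("CLO75", "TLR8", "endosome", (10, 1, 0.1, 0.01), "ug/mL"),
        _entry("ODN2216", "TLR9", "endosome", (5, 0.5, 0.05, 0.005), "ug/mL"),
        _entry("MDP", "NOD2", "cytosol", (10, 1, 0.1, 0.01), "ug/mL"),
        _entry("TP", "none", "drug", (25, 2.5, 0.25, 0.025), "ug/mL"),
    )
}

IIRMI_STIMULI: tuple[str, ...] = tuple(
    name for name, e in DEFAULT_DESIGN.items() if e.location != "drug"
)

MEMBRANE_STIMULI: tuple[str, ...] = tuple(
    name for name, e in DEFAULT_DESIGN.items() if e.location == "membrane"
)

# Per-stimulus signature cytokine (the single most sensitive readout of the
# 16-plex screen), used as the planted responsive cytokine in default
# synthetic studies.
DEFAULT_SIGNATURES: dict[str, str] = {
    "flagellin": "IL-1β",
    "FSL-1": "IL-1α",
    "zymosan": "MIP-1α",
    "LPS": "IL-1α",
    "ODN2006": "IFNα",
    "poly(I:C) HMW": "IP-10",
    "poly(I:C) LMW": "MCP-1",
    "CLO75": "IL-10",
    "ODN2216": "IL-6",
    "MDP": "IL-8",
    "TP": "PGE-2",
}

# Reference induction matrix: top-3 signature-cytokine calls per IIRMI from
# the 16-plex screening study (rows grouped by PRR location: membrane,
# endosome, cytosol).  This fixed matrix drives the reduced-panel set-cover
# analyses and serves as a deterministic test fixture.
REFERENCE_ROW_ORDER: tuple[str, ...] = (
    "flagellin", "FSL-1", "zymosan", "LPS",
    "ODN2006", "poly(I:C) HMW", "poly(I:C) LMW", "CLO75", "ODN2216",
    "MDP",
)

REFERENCE_TOP3: dict[str, frozenset[str]] = {
    "flagellin": frozenset({"IL-1α", "IL-1β", "MIP-1α"}),
    "FSL-1": frozenset({"IL-1α", "IL-1β", "MIP-1α"}),
    "zymosan": frozenset({"IL-1α", "MCP-1", "MIP-1α"}),
    "LPS": frozenset({"IL-1α", "IL-1β", "MIP-1α"}),
    "ODN2006": frozenset({"IFNα", "IL-8", "MCP-1"}),
    "poly(I:C) HMW": frozenset({"IL-6", "IP-10", "MCP-1"}),
    "poly(I:C) LMW": frozenset({"IFNγ", "IP-10", "MCP-1"}),
    "CLO75": frozenset({"IL-10", "IL-6", "IL-8"}),
    "ODN2216": frozenset({"IFNα", "IP-10", "MCP-1"}),
    "MDP": frozenset({"IL-6", "IL-8", "IP-10"}),
}

# Typical unstimulated (NC) secretion levels, natural-log pg/mL.  Chemokines
# sit well above the assay floor, interferons near it.
DEFAULT_BASELINE_LOG_MEAN: dict[str, float] = {
    "IFNα": 2.3, "IFNγ": 2.3, "IFNλ": 2.3,
    "IL-1α": 3.4, "IL-1β": 3.7, "IL-2": 2.7, "IL-6": 4.4, "IL-8": 6.4,
    "IL-10": 3.0, "IL-12": 3.0, "IL-17": 2.3,
    "IP-10": 5.0, "TNFα": 4.1, "PGE-2": 4.6, "MIP-1α": 5.3, "MCP-1": 6.0,
}

DEFAULT_BASELINE_LOG_SD = 0.5
DEFAULT_LIMITS: dict[str, tuple[float, float]] = {
    c: (5.0, 1e5) for c in CYTOKINES_16
}


def dose_to_pg(value: float, unit: str) -> float:
    """Convert a stimulus dose from `unit` per mL to pg/mL."""
    try:
        return value * UNIT_TO_PG[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit: {unit!r}") from None


def format_concentration(pg: float, unit: str) -> str:
    """Render a pg/mL dose in its display unit, e.g. 1e4 -> '0.01 µg/mL'."""
    return f"{pg / UNIT_TO_PG[unit]:g} {unit}"
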