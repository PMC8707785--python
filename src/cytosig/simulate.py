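"""Synthetic immunostimulation studies with planted ground truth.

The generator emulates the statistical structure the analysis assumes: for
donor *i*, cytokine *c* and condition (stimulus *s* at dose *d*) the
log-concentration of a well is

    log v = baseline(c) + donor(i) + donor(i, c)
            + emax(s, c) * d^h / (d^h + ec50^h)        (Hill induction)
            + co-exposure log-effect(s, c)              (if the drug is present)
            + replicate noise

with log-normal replicate noise of a given coefficient of variation, a
shared per-donor responder offset, and per-(donor, cytokine) baseline
offsets.  The positive control induces every cytokine by a fixed strong
log-effect.  Values outside the assay's quantification range are emitted as
censored (BDL/ADL) records, exactly as a plate export would flag them.

The planted truth — which cytokines respond to which stimulus, and the
direction of any drug co-exposure effect — is returned alongside the table
so recovery of the analysis pipeline can be measured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog
from .catalog import (
    CENSOR_ADL,
    CENSOR_BDL,
    CENSOR_NONE,
    CYTOKINES_16,
    DRUG,
    NC,
    PC,
    ROLE_NEGATIVE,
    ROLE_POSITIVE,
    ROLE_TREATMENT,
    StimulusEntry,
)
from .errors import ConfigurationError
from .panels import InductionMatrix
from .study import AssayLimits, CytokinePanel, StudyTable


@dataclass(frozen=True)
class DoseResponseSpec:
    """Hill/Emax dose-response of one (stimulus, cytokine) pair.

    ``emax_log`` is the maximal log-fold induction at saturating dose
    (natural-log units); ``ec50`` is in pg/mL, the same scale as catalogued
    doses; ``hill`` is the Hill coefficient.
    """

    stimulus: str
    cytokine: str
    emax_log: float
    ec50: float
    hill: float = 1.0

    def effect_at(self, dose_pg: float) -> float:
        if dose_pg <= 0:
            return 0.0
        dh = dose_pg ** self.hill
        return self.emax_log * dh / (dh + self.ec50 ** self.hill)


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic study."""

    n_donors: int = 10
    n_replicates: int = 2
    panel: tuple[str, ...] = CYTOKINES_16
    baseline_log_mean: dict[str, float] = field(
        default_factory=lambda: dict(catalog.DEFAULT_BASELINE_LOG_MEAN))
    baseline_log_sd: dict[str, float] = field(
        default_factory=lambda: {c: catalog.DEFAULT_BASELINE_LOG_SD
                                 for c in CYTOKINES_16})
    donor_sd: float = 0.5
    replicate_cv: float = 0.15
    limits: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(catalog.DEFAULT_LIMITS))
    design: dict[str, StimulusEntry] = field(
        default_factory=lambda: dict(catalog.DEFAULT_DESIGN))
    responses: tuple[DoseResponseSpec, ...] = ()
    co_exposure_effects: dict[tuple[str, str], float] = field(
        default_factory=dict)
    include_co_exposure: bool = True
    co_exposure_label: str = DRUG
    pc_effect: float = 3.0
    # log-units subtracted from the induction term at a stimulus's top dose
    # (emulates exhaustion/toxicity at saturating exposure); keyed like
    # co_exposure_effects
    top_dose_attenuation: dict[tuple[str, str], float] = field(
        default_factory=dict)
    cohort: str = "fresh"
    seed: int = 0

    def validate(self) -> None:
        if self.n_donors < 2:
            raise ConfigurationError("need at least 2 donors")
        if self.n_replicates < 1:
            raise ConfigurationError("need at least 1 replicate")
        if self.replicate_cv <= 0:
            raise ConfigurationError("replicate_cv must be positive")
        missing = [c for c in self.panel
                   if c not in self.baseline_log_mean
                   or c not in self.baseline_log_sd or c not in self.limits]
        if missing:
            raise ConfigurationError(
                f"panel cytokines without baseline/limits: {missing}")
        for r in self.responses:
            if r.stimulus not in self.design:
                raise ConfigurationError(
                    f"response for uncatalogued stimulus {r.stimulus!r}")
            if r.cytokine not in self.panel:
                raise ConfigurationError(
                    f"response for unknown cytokine {r.cytokine!r}")
            if r.emax_log < 0 or r.ec50 <= 0 or r.hill <= 0:
                raise ConfigurationError(
                    f"invalid dose-response for ({r.stimulus}, {r.cytokine})")
        for (stim, cyt) in self.co_exposure_effects:
            if stim not in self.design or cyt not in self.panel:
                raise ConfigurationError(
                    f"co-exposure effect for unknown pair ({stim}, {cyt})")


@dataclass
class PlantedTruth:
    """Ground truth of a generated study."""

    responses: dict[str, dict[str, DoseResponseSpec]]
    modulation: dict[str, dict[str, str]]   # stimulus -> cytokine -> direction
    pc_effect: float

    def responsive(self, stimulus: str) -> frozenset[str]:
        return frozenset(self.responses.get(stimulus, {}))

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "pc_effect": self.pc_effect,
            "responses": [
                {"stimulus": r.stimulus, "cytokine": r.cytokine,
                 "emax_log": r.emax_log, "ec50_pg": r.ec50, "hill": r.hill}
                for per in self.responses.values() for r in per.values()
            ],
            "modulation": self.modulation,
        }
        text = json.dumps(doc, indent=2, ensure_ascii=False, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def default_config(seed: int = 0,
                   emax_log: float = 3.0,
                   signatures: dict[str, str] | None = None,
                   **overrides) -> GeneratorConfig:
    """The standard synthetic study: the default design with one planted
    responsive cytokine per stimulus (its signature cytokine), saturating
    from the lowest tested dose."""
    design = overrides.pop("design", dict(catalog.DEFAULT_DESIGN))
    signatures = signatures if signatures is not None else {
        s: catalog.DEFAULT_SIGNATURES[s] for s in design
        if s in catalog.DEFAULT_SIGNATURES}
    responses = tuple(
        DoseResponseSpec(stimulus=s, cytokine=c, emax_log=emax_log,
                         ec50=min(design[s].doses), hill=1.0)
        for s, c in signatures.items()
    )
    return GeneratorConfig(design=design, responses=responses, seed=seed,
                           **overrides)


def _conditions(config: GeneratorConfig) -> list[tuple[str, float, str, str]]:
    """(stimulus, dose_pg, co_exposure, role) in deterministic order."""
    conds: list[tuple[str, float, str, str]] = [
        (NC, 0.0, "", ROLE_NEGATIVE),
        (PC, 0.0, "", ROLE_POSITIVE),
    ]
    for entry in config.design.values():
        for dose in entry.doses_ascending:
            conds.append((entry.name, dose, "", ROLE_TREATMENT))
        if config.include_co_exposure and entry.location != "drug":
            for dose in entry.doses_ascending:
                conds.append((entry.name, dose, config.co_exposure_label,
                              ROLE_TREATMENT))
    return conds


def generate_study(config: GeneratorConfig) -> tuple[StudyTable, PlantedTruth]:
    """Sample a study table and its planted truth.

    Identical configs (including the seed) yield bit-identical tables.
    """
    config.validate()

    panel = list(config.panel)
    cyt_index = {c: i for i, c in enumerate(panel)}
    conds = _conditions(config)
    n_c, n_k = len(panel), len(conds)
    n_d, n_r = config.n_donors, config.n_replicates

    # fixed-shape effect matrix [condition, cytokine]
    effect = np.zeros((n_k, n_c))
    resp_by_stim: dict[str, dict[str, DoseResponseSpec]] = {}
    for r in config.responses:
        resp_by_stim.setdefault(r.stimulus, {})[r.cytokine] = r
    top_dose = {name: max(e.doses) for name, e in config.design.items()}
    for k, (stim, dose, co, role) in enumerate(conds):
        if role == ROLE_POSITIVE:
            effect[k, :] = config.pc_effect
            continue
        if role != ROLE_TREATMENT:
            continue
        for cyt, spec in resp_by_stim.get(stim, {}).items():
            e = spec.effect_at(dose)
            if dose == top_dose[stim]:
                e -= config.top_dose_attenuation.get((stim, cyt), 0.0)
            effect[k, cyt_index[cyt]] += e
        if co:
            for (s, cyt), shift in config.co_exposure_effects.items():
                if s == stim:
                    effect[k, cyt_index[cyt]] += shift

    ss = np.random.SeedSequence(config.seed)
    rng_donor, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    base = np.array([config.baseline_log_mean[c] for c in panel])
    base_sd = np.array([config.baseline_log_sd[c] for c in panel])
    donor_shared = rng_donor.normal(0.0, config.donor_sd, size=n_d)
    donor_cyt = rng_donor.normal(0.0, 1.0, size=(n_d, n_c)) * base_sd

    sd_log = float(np.sqrt(np.log1p(config.replicate_cv ** 2)))
    noise = rng_noise.normal(0.0, sd_log, size=(n_k, n_d, n_c, n_r))
    noise -= sd_log ** 2 / 2.0   # mean-one multiplicative noise

    log_v = (base[None, None, :, None]
             + donor_shared[None, :, None, None]
             + donor_cyt[None, :, :, None]
             + effect[:, None, :, None]
             + noise)
    values = np.exp(log_v)

    lloq = np.array([config.limits[c][0] for c in panel])
    uloq = np.array([config.limits[c][1] for c in panel])
    bdl = values < lloq[None, None, :, None]
    adl = values > uloq[None, None, :, None]

    donors = [f"D{i + 1:02d}" for i in range(n_d)]
    stim_arr = np.array([c[0] for c in conds])
    dose_arr = np.array([c[1] for c in conds])
    co_arr = np.array([c[2] for c in conds])
    role_arr = np.array([c[3] for c in conds])
    unit_arr = np.array([
        config.design[c[0]].unit if c[0] in config.design else "pg/mL"
        for c in conds])

    size = n_k * n_d * n_c * n_r
    censor = np.full(size, CENSOR_NONE, dtype=object)
    flat_bdl, flat_adl = bdl.ravel(), adl.ravel()
    censor[flat_bdl] = CENSOR_BDL
    censor[flat_adl] = CENSOR_ADL
    flat_values = values.ravel()
    flat_values = np.where(flat_bdl | flat_adl, np.nan, flat_values)

    df = pd.DataFrame({
        "donor": np.tile(np.repeat(donors, n_c * n_r), n_k),
        "cohort": config.cohort,
        "stimulus": np.repeat(stim_arr, n_d * n_c * n_r),
        "concentration": np.repeat(dose_arr, n_d * n_c * n_r),
        "unit": np.repeat(unit_arr, n_d * n_c * n_r),
        "co_exposure": np.repeat(co_arr, n_d * n_c * n_r),
        "role": np.repeat(role_arr, n_d * n_c * n_r),
        "cytokine": np.tile(np.repeat(panel, n_r), n_k * n_d),
        "replicate": np.tile(np.arange(n_r), n_k * n_d * n_c),
        "value": flat_values,
        "censor": censor,
    })

    table = StudyTable(df, dict(config.design), AssayLimits(dict(config.limits)),
                       CytokinePanel(tuple(panel)))
    modulation = {}
    for (stim, cyt), shift in config.co_exposure_effects.items():
        if shift != 0:
            modulation.setdefault(stim, {})[cyt] = (
                "enhanced" if shift > 0 else "inhibited")
    truth = PlantedTruth(responses=resp_by_stim, modulation=modulation,
                         pc_effect=config.pc_effect)
    return table, truth


def reference_induction_matrix() -> InductionMatrix:
    """The fixed reference matrix of top-3 induction calls for the ten model
    IIRMIs on the 16-plex panel (rows grouped membrane / endosome / cytosol).

    Every row carries exactly three TRUE cells; this matrix is the input of
    the reduced-panel set-cover analyses and a deterministic test fixture.
    """
    stimuli = list(catalog.REFERENCE_ROW_ORDER)
    cytokines = list(CYTOKINES_16)
    values = np.array(
        [[cyt in catalog.REFERENCE_TOP3[s] for cyt in cytokines]
         for s in stimuli], dtype=bool)
    return InductionMatrix(stimuli=stimuli, cytokines=cytokines,
                           values=values, provenance="reference")
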