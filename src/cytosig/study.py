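"""Study data model and plate-table IO.

The canonical interchange format is a long ("tidy") CSV with one row per
well-level cytokine reading:

    donor,cohort,stimulus,concentration,unit,co_exposure,role,cytokine,
    replicate,value,censor

`concentration` is the stimulus dose in the stated `unit` (per mL); readings
(`value`) are always pg/mL.  Censoring is explicit: `censor` is one of
``none``, ``BDL`` (below detection limit) or ``ADL`` (above detection
limit), and censored rows carry no value until :func:`apply_censoring`
substitutes 0 (BDL) or the cytokine's ULOQ (ADL).

Two auxiliary CSVs accompany the measurements: a design catalogue
(stimulus, receptor, location, conc1..conc4, unit) listing the tested
concentrations per stimulus, and an assay-limits table
(cytokine, lloq, uloq).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog
from .catalog import (
    CENSOR_ADL,
    CENSOR_BDL,
    CENSOR_NONE,
    CENSOR_VALUES,
    CYTOKINES_16,
    ROLE_NEGATIVE,
    ROLE_TREATMENT,
    ROLES,
    StimulusEntry,
    dose_to_pg,
)
from .errors import ConfigurationError, FormatError, ValidationError

MEASUREMENT_COLUMNS = (
    "donor", "cohort", "stimulus", "concentration", "unit", "co_exposure",
    "role", "cytokine", "replicate", "value", "censor",
)

KEY_COLUMNS = (
    "donor", "cohort", "stimulus", "concentration", "co_exposure",
    "cytokine", "replicate",
)

DEFAULT_COHORT = "fresh"

_REPLICATE_LETTERS = {"a": 0, "b": 1, "c": 2, "d": 3}


@dataclass(frozen=True)
class CytokinePanel:
    """An ordered cytokine panel; list position is the tie-break rank."""

    names: tuple[str, ...] = CYTOKINES_16

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValidationError("cytokine names must be unique within a panel")

    @property
    def order(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.names)}

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class AssayLimits:
    """Per-cytokine quantification limits (LLOQ, ULOQ) in pg/mL."""

    limits: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(catalog.DEFAULT_LIMITS))

    def __post_init__(self) -> None:
        for cyt, (lloq, uloq) in self.limits.items():
            if not (0 < lloq < uloq):
                raise ConfigurationError(
                    f"invalid limits for {cyt}: need 0 < LLOQ < ULOQ, "
                    f"got ({lloq}, {uloq})")

    def lloq(self, cytokine: str) -> float:
        return self._get(cytokine)[0]

    def uloq(self, cytokine: str) -> float:
        return self._get(cytokine)[1]

    def _get(self, cytokine: str) -> tuple[float, float]:
        try:
            return self.limits[cytokine]
        except KeyError:
            raise ConfigurationError(
                f"no assay limits configured for cytokine {cytokine!r}"
            ) from None

    def __contains__(self, cytokine: str) -> bool:
        return cytokine in self.limits


@dataclass
class StudyTable:
    """A validated study: well-level records plus design, limits and panel.

    ``data`` holds one row per well-level reading with the columns in
    :data:`MEASUREMENT_COLUMNS`; ``concentration`` is internally normalized
    to pg/mL while ``unit`` keeps the display unit.
    """

    data: pd.DataFrame
    design: dict[str, StimulusEntry]
    limits: AssayLimits
    panel: CytokinePanel

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"measurement table missing columns: {missing}")

        bad_roles = sorted(set(df["role"]) - set(ROLES))
        if bad_roles:
            raise ValidationError(f"unknown roles: {bad_roles}")
        bad_censor = sorted(set(df["censor"]) - set(CENSOR_VALUES))
        if bad_censor:
            raise ValidationError(f"unknown censor flags: {bad_censor}")

        unknown_cyt = sorted(set(df["cytokine"]) - set(self.panel.names))
        if unknown_cyt:
            raise ValidationError(
                f"cytokines not in the configured panel: {unknown_cyt}")

        treated = df[df["role"] == ROLE_TREATMENT]
        unknown_stim = sorted(set(treated["stimulus"]) - set(self.design))
        if unknown_stim:
            raise ValidationError(
                f"stimuli not in the design catalogue: {unknown_stim}")

        # every treatment dose must be a catalogued concentration
        offenders = []
        for (stim, conc), _ in treated.groupby(["stimulus", "concentration"]):
            doses = np.asarray(self.design[stim].doses, dtype=float)
            if not np.any(np.isclose(conc, doses, rtol=1e-9, atol=0.0)):
                offenders.append((stim, conc))
        if offenders:
            raise ValidationError(
                "treatment concentrations absent from the design catalogue "
                f"(pg/mL): {offenders}")

        nc = df[df["role"] == ROLE_NEGATIVE]
        if nc.empty:
            raise ValidationError("study has no negative-control condition")
        if (nc["concentration"] != 0).any():
            raise ValidationError(
                "negative-control rows must have zero concentration")

        dup = df.duplicated(subset=list(KEY_COLUMNS))
        if dup.any():
            keys = df.loc[dup, list(KEY_COLUMNS)].head(5).to_dict("records")
            raise ValidationError(f"duplicate well keys, e.g. {keys}")

        uncensored = df["censor"] == CENSOR_NONE
        if df.loc[uncensored, "value"].isna().any():
            raise ValidationError("uncensored records must carry a value")
        if (df.loc[uncensored, "value"] < 0).any():
            raise ValidationError("cytokine readings must be non-negative")

    @property
    def n_records(self) -> int:
        return len(self.data)

    def copy(self) -> "StudyTable":
        return replace(self, data=self.data.copy())


def _require_columns(df: pd.DataFrame, required: tuple[str, ...],
                     what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing required column(s): {missing}")


def read_design(path: str | Path) -> dict[str, StimulusEntry]:
    """Read a design catalogue CSV (stimulus, receptor, location,
    conc1..conc4, unit); concentrations are converted to pg/mL."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("stimulus", "unit"), "design table")
    conc_cols = [c for c in df.columns if c.startswith("conc")]
    if not conc_cols:
        raise FormatError("design table has no conc1..concN columns")
    design: dict[str, StimulusEntry] = {}
    for row in df.itertuples(index=False):
        doses = tuple(
            dose_to_pg(float(getattr(row, c)), row.unit)
            for c in conc_cols if pd.notna(getattr(row, c))
        )
        if not doses:
            raise ValidationError(f"stimulus {row.stimulus!r} lists no doses")
        design[row.stimulus] = StimulusEntry(
            name=row.stimulus,
            receptor=getattr(row, "receptor", ""),
            location=getattr(row, "location", ""),
            doses=tuple(sorted(doses, reverse=True)),
            unit=row.unit,
        )
    return design


def read_limits(path: str | Path) -> AssayLimits:
    """Read an assay-limits CSV (cytokine, lloq, uloq)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("cytokine", "lloq", "uloq"), "limits table")
    return AssayLimits({
        row.cytokine: (float(row.lloq), float(row.uloq))
        for row in df.itertuples(index=False)
    })


def _normalize_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce a raw measurements frame to canonical dtypes and pg/mL doses."""
    df = df.copy()
    if "cohort" not in df.columns:
        df["cohort"] = DEFAULT_COHORT
    _require_columns(df, MEASUREMENT_COLUMNS, "measurements table")

    df["cohort"] = df["cohort"].fillna(DEFAULT_COHORT)
    df["co_exposure"] = df["co_exposure"].fillna("").astype(str)
    df.loc[df["co_exposure"].isin(("nan", "None")), "co_exposure"] = ""
    df["unit"] = df["unit"].fillna("pg/mL")
    df["censor"] = df["censor"].fillna(CENSOR_NONE)

    def _rep(r):
        if isinstance(r, str) and r.strip().lower() in _REPLICATE_LETTERS:
            return _REPLICATE_LETTERS[r.strip().lower()]
        return int(r)

    df["replicate"] = df["replicate"].map(_rep)

    factors = df["unit"].map(catalog.UNIT_TO_PG)
    if factors.isna().any():
        bad = sorted(set(df.loc[factors.isna(), "unit"]))
        raise FormatError(f"unknown concentration unit(s): {bad}")
    df["concentration"] = df["concentration"].astype(float) * factors
    df["value"] = pd.to_numeric(df["value"], errors="coerce")

    censored = df["censor"] != CENSOR_NONE
    if df.loc[censored, "value"].notna().any():
        raise ValidationError(
            "censored records must not carry a value; the substitution "
            "policy fills them in")
    return df[list(MEASUREMENT_COLUMNS)]


def read_study(measurements_path: str | Path,
               design_path: str | Path,
               limits_path: str | Path,
               panel: CytokinePanel | None = None) -> StudyTable:
    """Read and validate a full study from its three CSV files.

    Row order in the file never affects downstream results: records are
    sorted into a canonical key order on ingestion.
    """
    design = read_design(design_path)
    limits = read_limits(limits_path)
    raw = pd.read_csv(measurements_path, float_precision="round_trip")
    df = _normalize_measurements(raw)
    df = df.sort_values(list(KEY_COLUMNS), kind="mergesort",
                        ignore_index=True)
    return StudyTable(df, design, limits, panel or CytokinePanel())


def write_study(table: StudyTable, out_dir: str | Path) -> dict[str, Path]:
    """Write a study's three CSVs; reading them back round-trips exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": out / "measurements.csv",
        "design": out / "design.csv",
        "limits": out / "limits.csv",
    }

    df = table.data.copy()
    factors = df["unit"].map(catalog.UNIT_TO_PG)
    # doses are re-displayed in their original unit; 12 significant digits
    # round-trips exactly through the pg/mL conversion for catalogued doses
    df["concentration"] = (df["concentration"] / factors).map(
        lambda v: f"{v:.12g}")
    _write_csv(df, paths["measurements"])

    n_doses = max(len(e.doses) for e in table.design.values())
    rows = []
    for e in table.design.values():
        doses = [float(f"{d / catalog.UNIT_TO_PG[e.unit]:.12g}")
                 for d in e.doses]
        doses += [np.nan] * (n_doses - len(doses))
        rows.append({"stimulus": e.name, "receptor": e.receptor,
                     "location": e.location,
                     **{f"conc{i + 1}": d for i, d in enumerate(doses)},
                     "unit": e.unit})
    _write_csv(pd.DataFrame(rows), paths["design"])

    lim = pd.DataFrame(
        [{"cytokine": c, "lloq": lo, "uloq": hi}
         for c, (lo, hi) in table.limits.limits.items()])
    _write_csv(lim, paths["limits"])
    return paths


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # %.17g preserves doubles exactly across a write/read cycle
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.17g")
    path.write_text(buf.getvalue(), encoding="utf-8")


def apply_censoring(table: StudyTable) -> StudyTable:
    """Substitute censored readings: BDL -> 0, ADL -> the cytokine's ULOQ.

    Idempotent; rows with ``censor == none`` are untouched.  A censored
    record for a cytokine without configured limits is a configuration
    error.
    """
    df = table.data.copy()
    censored = df["censor"] != CENSOR_NONE
    no_limits = sorted(
        set(df.loc[censored, "cytokine"]) - set(table.limits.limits))
    if no_limits:
        raise ConfigurationError(
            f"censored records but no assay limits for: {no_limits}")

    bdl = df["censor"] == CENSOR_BDL
    adl = df["censor"] == CENSOR_ADL
    df.loc[bdl, "value"] = 0.0
    if adl.any():
        df.loc[adl, "value"] = df.loc[adl, "cytokine"].map(
            lambda c: float(table.limits.uloq(c)))
    if df["value"].isna().any():
        raise ValidationError("table still has absent values after censoring")
    return replace(table, data=df)


AVERAGED_KEYS = (
    "donor", "cohort", "stimulus", "concentration", "unit", "co_exposure",
    "role", "cytokine",
)


def average_replicates(df_or_table: StudyTable | pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean over replicates per (donor, condition, cytokine).

    Censoring must already have been applied (no absent values).  Returns a
    frame keyed by :data:`AVERAGED_KEYS` with columns ``value`` (mean) and
    ``n_replicates``.
    """
    df = df_or_table.data if isinstance(df_or_table, StudyTable) else df_or_table
    if df["value"].isna().any():
        raise ValidationError(
            "cannot average replicates before censoring substitution")
    out = (
        df.groupby(list(AVERAGED_KEYS), sort=True, as_index=False)
        .agg(value=("value", "mean"), n_replicates=("value", "size"))
    )
    return out
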