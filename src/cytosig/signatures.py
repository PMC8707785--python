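"""Signature-cytokine, top-k and drug-modulation calls.

A stimulus's *signature cytokine* is found by scanning its tested doses in
ascending order: at the first dose where at least one cytokine is
significantly elevated over the pooled negative control, the cytokine with
the smallest p-value wins (ties broken by fixed panel order).  The top-k
variant keeps scanning until a dose yields at least k significant
cytokines and returns the k smallest p-values there.  Both operate on a
precomputed significance grid, so paired/unpaired mode and threshold
strictness are properties of the grid and of the call.

Drug-modulation calls compare each (stimulus, cytokine) with and without
drug co-exposure across matched donor × dose arms; significant shifts are
called ``inhibited`` or ``enhanced`` by the direction of the medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import ROLE_TREATMENT
from .errors import ValidationError
from .ranktests import DEFAULT_EXACT_CUTOFF, MODE_PAIRED, wilcoxon
from .study import CytokinePanel


@dataclass(frozen=True)
class SignatureCall:
    """The signature cytokine selected for one stimulus."""

    stimulus: str
    signature_cytokine: str
    concentration: float            # pg/mL; lowest dose with a significant hit
    concentration_label: str
    p_value: float
    co_induced: tuple[str, ...] = ()   # other significant cytokines, same dose


@dataclass(frozen=True)
class TopKCall:
    """The k most significant cytokines for one stimulus."""

    stimulus: str
    selected: tuple[str, ...]       # ascending p, ties by panel order
    concentration: float | None
    concentration_label: str = ""
    p_values: tuple[float, ...] = ()
    short: bool = False             # fewer than k found anywhere


@dataclass(frozen=True)
class ModulationCall:
    """A drug co-exposure effect on one stimulus-induced cytokine."""

    stimulus: str
    cytokine: str
    direction: str                  # "inhibited" | "enhanced"
    p_value: float


def _stimulus_cells(grid: pd.DataFrame, stimulus: str,
                    co_exposure: str = "") -> pd.DataFrame:
    cells = grid[(grid["stimulus"] == stimulus)
                 & (grid["co_exposure"] == co_exposure)]
    if cells.empty:
        raise ValidationError(f"stimulus {stimulus!r} absent from the grid")
    return cells


def _significant(cells: pd.DataFrame, alpha: float,
                 strict: bool) -> pd.Series:
    below = cells["p"] < alpha if strict else cells["p"] <= alpha
    return below & cells["elevated"] & ~cells["missing"]


def _rank_key(cells: pd.DataFrame, order: dict[str, int]) -> pd.DataFrame:
    cells = cells.copy()
    cells["_order"] = cells["cytokine"].map(order)
    return cells.sort_values(["p", "_order"], kind="mergesort")


def select_signature(grid: pd.DataFrame, stimulus: str,
                     alpha: float = 0.05, strict: bool = True,
                     panel: CytokinePanel | None = None
                     ) -> SignatureCall | None:
    """Signature cytokine for ``stimulus``, or None when no dose qualifies.

    Doses are scanned ascending; at the first dose with >= 1 significantly
    elevated cytokine the minimum-p cytokine is selected (panel-order
    tie-break) and the remaining significant cytokines at that dose are
    reported as co-induced.
    """
    order = (panel or CytokinePanel()).order
    cells = _stimulus_cells(grid, stimulus)
    for conc in sorted(cells["concentration"].unique()):
        at_dose = cells[cells["concentration"] == conc]
        hits = at_dose[_significant(at_dose, alpha, strict)]
        if hits.empty:
            continue
        ranked = _rank_key(hits, order)
        winner = ranked.iloc[0]
        co = tuple(ranked["cytokine"].iloc[1:])
        from .catalog import format_concentration
        return SignatureCall(
            stimulus=stimulus,
            signature_cytokine=winner["cytokine"],
            concentration=float(conc),
            concentration_label=format_concentration(
                float(conc), winner["unit"]),
            p_value=float(winner["p"]),
            co_induced=co,
        )
    return None


def select_top_k(grid: pd.DataFrame, stimulus: str, k: int = 3,
                 alpha: float = 0.05, strict: bool = False,
                 panel: CytokinePanel | None = None) -> TopKCall:
    """Top-k cytokines for ``stimulus``.

    Scans doses ascending for the first dose with >= k significant
    cytokines.  When no dose yields k, all significant cytokines at the top
    dose are returned with ``short=True`` (possibly none).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    order = (panel or CytokinePanel()).order
    cells = _stimulus_cells(grid, stimulus)
    from .catalog import format_concentration

    doses = sorted(cells["concentration"].unique())
    fallback: pd.DataFrame | None = None
    fallback_conc: float | None = None
    for conc in doses:
        at_dose = cells[cells["concentration"] == conc]
        hits = at_dose[_significant(at_dose, alpha, strict)]
        fallback, fallback_conc = hits, conc   # ends at the top dose
        if len(hits) >= k:
            ranked = _rank_key(hits, order).head(k)
            return TopKCall(
                stimulus=stimulus,
                selected=tuple(ranked["cytokine"]),
                concentration=float(conc),
                concentration_label=format_concentration(
                    float(conc), ranked.iloc[0]["unit"]),
                p_values=tuple(ranked["p"]),
                short=False,
            )
    ranked = _rank_key(fallback, order) if fallback is not None else None
    if ranked is None or ranked.empty:
        return TopKCall(stimulus=stimulus, selected=(), concentration=None,
                        short=True)
    return TopKCall(
        stimulus=stimulus,
        selected=tuple(ranked["cytokine"]),
        concentration=float(fallback_conc),
        concentration_label=format_concentration(
            float(fallback_conc), ranked.iloc[0]["unit"]),
        p_values=tuple(ranked["p"]),
        short=True,
    )


def signature_table(grid: pd.DataFrame, stimuli,
                    alpha: float = 0.05, strict: bool = True,
                    panel: CytokinePanel | None = None) -> pd.DataFrame:
    """One row per stimulus: signature cytokine, dose, p, co-induced set."""
    rows = []
    for stim in stimuli:
        call = select_signature(grid, stim, alpha=alpha, strict=strict,
                                panel=panel)
        if call is None:
            rows.append({"stimulus": stim, "signature_cytokine": "",
                         "concentration": np.nan, "p_value": np.nan,
                         "co_induced": ""})
        else:
            rows.append({"stimulus": stim,
                         "signature_cytokine": call.signature_cytokine,
                         "concentration": call.concentration_label,
                         "p_value": call.p_value,
                         "co_induced": ", ".join(call.co_induced)})
    return pd.DataFrame(rows)


def modulation_table(averaged: pd.DataFrame,
                     co_exposure_label: str,
                     alpha: float = 0.05,
                     per_dose: bool = False,
                     mode: str = MODE_PAIRED,
                     exact_cutoff: int = DEFAULT_EXACT_CUTOFF,
                     panel: CytokinePanel | None = None) -> pd.DataFrame:
    """Test, per (stimulus, cytokine), whether drug co-exposure shifts the
    stimulus-induced response.

    Arms with and without co-exposure are matched on (donor, dose) and
    compared with a two-sided Wilcoxon test, pooled over the stimulus's
    doses by default (``per_dose=True`` tests each dose separately).
    """
    treated = averaged[averaged["role"] == ROLE_TREATMENT]
    with_co = treated[treated["co_exposure"] == co_exposure_label]
    without = treated[treated["co_exposure"] == ""]
    if with_co.empty:
        raise ValidationError(
            f"no arms with co-exposure {co_exposure_label!r}")

    keys = ["donor", "stimulus", "concentration", "cytokine"]
    merged = pd.merge(
        with_co[keys + ["value"]], without[keys + ["value"]],
        on=keys, suffixes=("_co", "_alone"))
    if merged.empty:
        raise ValidationError("no matched (stimulus, dose) arms with and "
                              "without co-exposure")

    group_keys = ["stimulus", "concentration", "cytokine"] if per_dose \
        else ["stimulus", "cytokine"]
    rows = []
    for key, sub in merged.groupby(group_keys, sort=True):
        x = sub["value_co"].to_numpy()
        y = sub["value_alone"].to_numpy()
        res = wilcoxon(x, y, mode=mode, exact_cutoff=exact_cutoff)
        med_co, med_alone = float(np.median(x)), float(np.median(y))
        record = dict(zip(group_keys, key if isinstance(key, tuple) else (key,)))
        record.update({
            "n_pairs": len(sub),
            "p": res.p_two_sided,
            "direction": "enhanced" if med_co > med_alone else "inhibited",
            "median_co": med_co,
            "median_alone": med_alone,
            "significant": res.p_two_sided < alpha,
        })
        rows.append(record)
    out = pd.DataFrame(rows)
    out.attrs.update(alpha=alpha, mode=mode, per_dose=per_dose,
                     co_exposure_label=co_exposure_label)
    return out


def modulation_calls(averaged: pd.DataFrame, co_exposure_label: str,
                     alpha: float = 0.05, **kwargs) -> list[ModulationCall]:
    """Significant drug-modulation calls (see :func:`modulation_table`)."""
    table = modulation_table(averaged, co_exposure_label, alpha=alpha,
                             **kwargs)
    return [
        ModulationCall(stimulus=row.stimulus, cytokine=row.cytokine,
                       direction=row.direction, p_value=row.p)
        for row in table[table["significant"]].itertuples(index=False)
    ]
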