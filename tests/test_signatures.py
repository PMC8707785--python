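"""Signature selection, top-k selection and drug-modulation calls."""

import numpy as np
import pandas as pd
import pytest

from cytosig.catalog import DEFAULT_SIGNATURES, IIRMI_STIMULI
from cytosig.errors import ValidationError
from cytosig.ranktests import GRID_COLUMNS, significance_grid
from cytosig.signatures import (
    modulation_calls,
    modulation_table,
    select_signature,
    select_top_k,
)
from cytosig.simulate import default_config, generate_study
from cytosig.study import CytokinePanel

from conftest import averaged_normalized


def make_grid(cells):
    """Grid fixture from (stimulus, conc, cytokine, p, elevated) tuples."""
    rows = [
        (stim, conc, "ug/mL", "", cyt, 10, 10, 0.0, p, "exact", elevated,
         False, False)
        for stim, conc, cyt, p, elevated in cells
    ]
    grid = pd.DataFrame(rows, columns=GRID_COLUMNS)
    below = grid["p"] < 0.05
    grid["significant"] = below & grid["elevated"]
    return grid


def test_signature_is_min_p_at_first_qualifying_dose():
    grid = make_grid([
        ("zymosan", 0.01, "IL-6", 0.50, True),
        ("zymosan", 0.01, "IL-8", 0.20, True),
        ("zymosan", 0.1, "MIP-1α", 0.001, True),
        ("zymosan", 0.1, "IL-1α", 0.010, True),
        ("zymosan", 0.1, "IL-6", 0.002, False),   # not elevated: ignored
        ("zymosan", 1.0, "IFNα", 1e-9, True),     # later dose: ignored
    ])
    call = select_signature(grid, "zymosan")
    assert call.signature_cytokine == "MIP-1α"
    assert call.concentration == 0.1
    assert call.p_value == 0.001
    assert call.co_induced == ("IL-1α",)


def test_signature_tie_broken_by_panel_order():
    grid = make_grid([
        ("zymosan", 0.01, "MIP-1α", 0.01, True),
        ("zymosan", 0.01, "IL-1β", 0.01, True),
    ])
    call = select_signature(grid, "zymosan")
    assert call.signature_cytokine == "IL-1β"     # earlier panel position


def test_no_significant_cell_yields_none():
    grid = make_grid([("zymosan", 0.01, "IL-6", 0.9, True)])
    assert select_signature(grid, "zymosan") is None


def test_unknown_stimulus_rejected():
    grid = make_grid([("zymosan", 0.01, "IL-6", 0.9, True)])
    with pytest.raises(ValidationError):
        select_signature(grid, "LPS")


def test_lower_dose_without_hits_never_changes_the_call():
    base = [("MDP", 0.1, "IL-8", 0.003, True),
            ("MDP", 0.1, "IL-6", 0.020, True)]
    extra = [("MDP", 0.01, "IL-8", 0.60, True),
             ("MDP", 0.01, "IL-6", 0.08, False)]
    a = select_signature(make_grid(base), "MDP")
    b = select_signature(make_grid(extra + base), "MDP")
    assert (a.signature_cytokine, a.concentration, a.p_value) == \
           (b.signature_cytokine, b.concentration, b.p_value)


def test_top_k_scans_until_k_significant():
    grid = make_grid([
        ("CLO75", 0.01, "IL-10", 0.001, True),
        ("CLO75", 0.01, "IL-6", 0.30, True),
        ("CLO75", 0.1, "IL-10", 0.001, True),
        ("CLO75", 0.1, "IL-6", 0.002, True),
        ("CLO75", 0.1, "IL-8", 0.010, True),
        ("CLO75", 0.1, "TNFα", 0.020, True),
    ])
    call = select_top_k(grid, "CLO75", k=3)
    assert call.concentration == 0.1
    assert call.selected == ("IL-10", "IL-6", "IL-8")
    assert not call.short


def test_top_k_exhausted_design_returns_short_flagged_call():
    grid = make_grid([
        ("ODN2216", 0.01, "IL-6", 0.001, True),
        ("ODN2216", 0.1, "IL-6", 0.001, True),
        ("ODN2216", 0.1, "MCP-1", 0.030, True),
    ])
    call = select_top_k(grid, "ODN2216", k=3)
    assert call.short
    assert call.concentration == 0.1              # top dose evaluated last
    assert call.selected == ("IL-6", "MCP-1")

    empty = make_grid([("ODN2216", 0.01, "IL-6", 0.9, True)])
    call = select_top_k(empty, "ODN2216", k=3)
    assert call.short and call.selected == ()


def test_top_1_agrees_with_signature_selection():
    rng = np.random.default_rng(123)
    cytokines = ["IL-6", "IL-8", "IL-10", "MIP-1α", "IFNα"]
    for _ in range(30):
        cells = []
        for conc in (0.01, 0.1, 1.0):
            for cyt in cytokines:
                cells.append(("zymosan", conc, cyt,
                              float(rng.uniform(0, 0.2)),
                              bool(rng.uniform() < 0.7)))
        grid = make_grid(cells)
        sig = select_signature(grid, "zymosan", strict=True)
        top1 = select_top_k(grid, "zymosan", k=1, strict=True)
        if sig is None:
            assert top1.selected == ()
        else:
            assert top1.selected == (sig.signature_cytokine,)
            assert top1.concentration == sig.concentration


def test_planted_stimulus_recovers_its_three_induced_cytokines():
    planted = {"zymosan": "MIP-1α", "CLO75": "IL-10", "MDP": "IL-8"}
    cfg = default_config(seed=77, signatures=planted,
                         include_co_exposure=False)
    table, truth = generate_study(cfg)
    avg, _ = averaged_normalized(table)
    grid = significance_grid(avg, table.design, table.panel,
                             mode="unpaired", strict=False)
    for stim, cyt in planted.items():
        call = select_top_k(grid, stim, k=1, strict=False, panel=table.panel)
        assert call.selected == (cyt,)


def test_modulation_directions_match_planted_effects():
    effects = {("zymosan", "IL-1β"): -2.5, ("zymosan", "PGE-2"): 2.5}
    cfg = default_config(seed=5, include_co_exposure=True,
                         co_exposure_effects=effects)
    table, truth = generate_study(cfg)
    avg, _ = averaged_normalized(table)
    calls = {(c.stimulus, c.cytokine): c.direction
             for c in modulation_calls(avg, "TP")}
    assert calls[("zymosan", "IL-1β")] == "inhibited"
    assert calls[("zymosan", "PGE-2")] == "enhanced"
    assert truth.modulation["zymosan"] == {"IL-1β": "inhibited",
                                           "PGE-2": "enhanced"}


def test_modulation_requires_matched_arms(small_study):
    table, _ = small_study                         # no co-exposure arms
    avg, _ = averaged_normalized(table)
    with pytest.raises(ValidationError):
        modulation_table(avg, "TP")
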