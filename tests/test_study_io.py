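"""Plate-table reading, validation, censoring and replicate averaging."""

import numpy as np
import pandas as pd
import pytest

from cytosig.errors import ConfigurationError, FormatError, ValidationError
from cytosig.ranktests import significance_grid
from cytosig.study import (
    apply_censoring,
    average_replicates,
    read_study,
    write_study,
)

from conftest import averaged_normalized, toy_csv_bundle


def _toy_rows(unit="ug/mL", conc="0.01"):
    return [
        f"G9L1,fresh,NC,0,pg/mL,,negative_control,IL-6,a,12.5,none",
        f"G9L1,fresh,NC,0,pg/mL,,negative_control,IL-6,b,14.5,none",
        f"G9L1,fresh,zymosan,{conc},{unit},,treatment,IL-6,a,100,none",
        f"G9L1,fresh,zymosan,{conc},{unit},,treatment,IL-6,b,120,none",
    ]


def test_minimal_wellformed_study_reads(tmp_path):
    paths = toy_csv_bundle(tmp_path, _toy_rows())
    table = read_study(*paths)
    assert table.n_records == 4
    assert set(table.data["stimulus"]) == {"NC", "zymosan"}
    # dose normalized to pg/mL internally
    treated = table.data[table.data["role"] == "treatment"]
    assert treated["concentration"].unique().tolist() == [
        pytest.approx(0.01 * 1e6)]


def test_mixed_units_normalize_to_same_internal_dose(tmp_path):
    a = read_study(*toy_csv_bundle(tmp_path / "a", _toy_rows("ug/mL", "0.01")))
    b = read_study(*toy_csv_bundle(tmp_path / "b", _toy_rows("ng/mL", "10")))
    ca = a.data.loc[a.data["role"] == "treatment", "concentration"].unique()
    cb = b.data.loc[b.data["role"] == "treatment", "concentration"].unique()
    assert ca.tolist() == pytest.approx(cb.tolist())


def test_uncatalogued_dose_rejected(tmp_path):
    paths = toy_csv_bundle(tmp_path, _toy_rows(conc="7"))
    with pytest.raises(ValidationError, match="design catalogue"):
        read_study(*paths)


def test_missing_column_named_in_error(tmp_path):
    paths = toy_csv_bundle(tmp_path, _toy_rows())
    text = paths[0].read_text(encoding="utf-8").replace("censor", "flag")
    paths[0].write_text(text, encoding="utf-8")
    with pytest.raises(FormatError, match="censor"):
        read_study(*paths)


def test_unknown_stimulus_and_cytokine_rejected(tmp_path):
    rows = _toy_rows() + [
        "G9L1,fresh,unobtainium,0.01,ug/mL,,treatment,IL-6,a,5,none"]
    with pytest.raises(ValidationError, match="unobtainium"):
        read_study(*toy_csv_bundle(tmp_path / "s", rows))
    rows = _toy_rows() + [
        "G9L1,fresh,NC,0,pg/mL,,negative_control,IL-99,a,5,none"]
    with pytest.raises(ValidationError, match="IL-99"):
        read_study(*toy_csv_bundle(tmp_path / "c", rows))


def test_duplicate_well_key_rejected(tmp_path):
    rows = _toy_rows() + [_toy_rows()[0]]
    with pytest.raises(ValidationError, match="duplicate"):
        read_study(*toy_csv_bundle(tmp_path, rows))


def test_censored_record_with_value_rejected(tmp_path):
    rows = _toy_rows()[:3] + [
        "G9L1,fresh,zymosan,0.01,ug/mL,,treatment,IL-6,b,120,BDL"]
    with pytest.raises(ValidationError, match="censored"):
        read_study(*toy_csv_bundle(tmp_path, rows))


def test_cohort_column_defaults_to_fresh(tmp_path):
    paths = toy_csv_bundle(tmp_path, _toy_rows())
    df = pd.read_csv(paths[0]).drop(columns=["cohort"])
    df.to_csv(paths[0], index=False)
    table = read_study(*paths)
    assert (table.data["cohort"] == "fresh").all()


def test_censoring_substitution_rules(tmp_path):
    rows = _toy_rows()[:2] + [
        "G9L1,fresh,zymosan,0.01,ug/mL,,treatment,IL-6,a,,ADL",
        "G9L1,fresh,zymosan,0.01,ug/mL,,treatment,IL-6,b,,BDL",
    ]
    table = read_study(*toy_csv_bundle(tmp_path, rows))
    out = apply_censoring(table)
    adl = out.data[out.data["censor"] == "ADL"]
    bdl = out.data[out.data["censor"] == "BDL"]
    assert adl["value"].tolist() == [100000.0]   # the configured IL-6 ULOQ
    assert bdl["value"].tolist() == [0.0]
    # idempotent, and identity on uncensored tables
    again = apply_censoring(out)
    pd.testing.assert_frame_equal(out.data, again.data)


def test_censored_cytokine_without_limits_is_config_error(tmp_path):
    rows = _toy_rows()[:2] + [
        "G9L1,fresh,zymosan,0.01,ug/mL,,treatment,IL-8,a,,BDL"]
    limits = ["IL-6,5,100000"]     # IL-8 has censored data but no limits
    table = read_study(*toy_csv_bundle(tmp_path, rows, limits_rows=limits))
    with pytest.raises(ConfigurationError, match="IL-8"):
        apply_censoring(table)


def test_replicate_averaging():
    df = pd.DataFrame({
        "donor": ["d1"] * 2 + ["d2"] + ["d3"] * 2,
        "cohort": "fresh", "stimulus": "NC", "concentration": 0.0,
        "unit": "pg/mL", "co_exposure": "", "role": "negative_control",
        "cytokine": "IL-6", "replicate": [0, 1, 0, 0, 1],
        "value": [100.0, 120.0, 7.0, 0.0, 0.0], "censor": "none",
    })
    out = average_replicates(df)
    by_donor = out.set_index("donor")["value"]
    assert by_donor["d1"] == 110.0        # mean of duplicates
    assert by_donor["d2"] == 7.0          # single replicate passes through
    assert by_donor["d3"] == 0.0          # both wells at the censoring floor
    assert out.set_index("donor")["n_replicates"].tolist() == [2, 1, 2]


def test_write_read_roundtrip(small_study, tmp_path):
    table, _ = small_study
    paths = write_study(table, tmp_path)
    back = read_study(paths["measurements"], paths["design"], paths["limits"])
    a = table.data.sort_values(list(table.data.columns), ignore_index=True)
    b = back.data.sort_values(list(back.data.columns), ignore_index=True)
    pd.testing.assert_frame_equal(a, b, check_dtype=False, check_exact=True)


def test_row_permutation_leaves_grid_bit_identical(small_study, tmp_path):
    table, _ = small_study
    paths = write_study(table, tmp_path)
    df = pd.read_csv(paths["measurements"])
    shuffled = df.sample(frac=1.0, random_state=5)
    shuffled.to_csv(paths["measurements"], index=False)
    permuted = read_study(paths["measurements"], paths["design"],
                          paths["limits"])

    avg_a, _ = averaged_normalized(table)
    avg_b, _ = averaged_normalized(permuted)
    grid_a = significance_grid(avg_a, table.design, table.panel)
    grid_b = significance_grid(avg_b, permuted.design, permuted.panel)
    pd.testing.assert_frame_equal(grid_a, grid_b)
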