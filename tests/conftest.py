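import numpy as np
import pandas as pd
import pytest

from cytosig.catalog import DEFAULT_DESIGN
from cytosig.normalize import normalize_by_global_sd
from cytosig.simulate import default_config, generate_study
from cytosig.study import apply_censoring, average_replicates


SMALL_STIMULI = ("zymosan", "ODN2216")


def small_config(seed: int = 42, **overrides):
    """A reduced study (4 donors, 2 stimuli) for fast unit tests."""
    design = {s: DEFAULT_DESIGN[s] for s in SMALL_STIMULI}
    overrides.setdefault("n_donors", 4)
    overrides.setdefault("include_co_exposure", False)
    return default_config(seed=seed, design=design, **overrides)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_config())


@pytest.fixture(scope="session")
def default_study():
    """One full-design study with planted signature responses."""
    return generate_study(default_config(seed=42, include_co_exposure=False))


def averaged_normalized(table):
    """Censoring -> global-SD normalization -> replicate averaging."""
    norm = normalize_by_global_sd(apply_censoring(table).data)
    return average_replicates(norm.data), norm


def toy_csv_bundle(tmp_path, measurement_rows, design_rows=None,
                   limits_rows=None):
    """Write a minimal measurements/design/limits CSV bundle."""
    tmp_path.mkdir(parents=True, exist_ok=True)
    header = ("donor,cohort,stimulus,concentration,unit,co_exposure,role,"
              "cytokine,replicate,value,censor")
    m = tmp_path / "measurements.csv"
    m.write_text("\n".join([header, *measurement_rows]) + "\n",
                 encoding="utf-8")
    d = tmp_path / "design.csv"
    design_rows = design_rows or [
        "zymosan,TLR2/Dectin 1,membrane,10,1,0.1,0.01,ug/mL"]
    d.write_text("\n".join(
        ["stimulus,receptor,location,conc1,conc2,conc3,conc4,unit",
         *design_rows]) + "\n", encoding="utf-8")
    li = tmp_path / "limits.csv"
    limits_rows = limits_rows or ["IL-6,5,100000"]
    li.write_text("\n".join(["cytokine,lloq,uloq", *limits_rows]) + "\n",
                  encoding="utf-8")
    return m, d, li
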