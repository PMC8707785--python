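"""Global SD normalization and plate quality control.

Normalization scales each cytokine reading by that cytokine's sample
standard deviation computed across *all* collected values in the study —
every donor, condition, cohort and control.  This brings cytokines spanning
very different concentration ranges onto a common scale for global
(clustering, heatmap) analyses while leaving every rank-test result
unchanged, since a positive per-cytokine rescaling preserves ranks.

QC mirrors the assay's acceptance checks: every cytokine must read
significantly higher in the positive control than in the negative control,
duplicate wells should agree within 25 %CV, and replicate runs (a vs b)
should correlate within each treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .catalog import ROLE_NEGATIVE, ROLE_POSITIVE
from .errors import ValidationError
from .ranktests import DEFAULT_EXACT_CUTOFF, MODE_PAIRED, MODE_UNPAIRED, wilcoxon

DEFAULT_CV_THRESHOLD = 25.0


@dataclass
class NormalizedTable:
    """A measurement frame with SD-scaled values.

    ``scales`` maps each cytokine to the standard deviation its values were
    divided by; ``zero_variance`` lists cytokines whose SD was zero — those
    are flagged and passed through unscaled.
    """

    data: pd.DataFrame
    scales: pd.Series
    zero_variance: tuple[str, ...] = ()


def normalize_by_global_sd(df: pd.DataFrame,
                           scale_from: pd.DataFrame | None = None
                           ) -> NormalizedTable:
    """Divide each value by its cytokine's global sample SD (ddof=1).

    ``scale_from`` optionally supplies the table the SDs are computed from
    (e.g. the well-level table when normalizing a replicate-averaged one);
    by default SDs come from ``df`` itself.  Censoring substitution must
    already have happened — absent values are an error.
    """
    if len(df) == 0:
        raise ValidationError("cannot normalize an empty table")
    source = df if scale_from is None else scale_from
    if source["value"].isna().any() or df["value"].isna().any():
        raise ValidationError("normalize after censoring substitution; "
                              "table has absent values")
    counts = source.groupby("cytokine")["value"].size()
    too_few = counts[counts < 2]
    if len(too_few):
        raise ValidationError(
            f"cytokines with fewer than 2 values: {list(too_few.index)}")

    sd = source.groupby("cytokine")["value"].std(ddof=1)
    zero_var = tuple(sd.index[sd == 0.0])
    scales = sd.mask(sd == 0.0, 1.0)

    out = df.copy()
    out["value"] = out["value"] / out["cytokine"].map(scales).astype(float)
    return NormalizedTable(out, scales, zero_var)


@dataclass
class QcReport:
    """Outcome of the control-based quality checks.

    ``overall_pass`` is true exactly when every cytokine's PC-above-NC test
    passes.  %CV failures and undefined CVs (zero-mean duplicate pairs) are
    flagged per record but do not fail the study.
    """

    cytokine_tests: pd.DataFrame     # cytokine, p_greater, medians, passed
    replicate_cv: pd.DataFrame       # per duplicate set: cv, passed, undefined
    replicate_correlation: pd.DataFrame  # per condition: pearson r, n
    overall_pass: bool
    alpha: float
    cv_threshold: float = DEFAULT_CV_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "overall_pass": bool(self.overall_pass),
            "alpha": self.alpha,
            "cv_threshold": self.cv_threshold,
            "cytokine_tests": self.cytokine_tests.to_dict("records"),
            "n_cv_failures": int((~self.replicate_cv["passed"]).sum()),
            "n_cv_undefined": int(self.replicate_cv["undefined"].sum()),
            "replicate_correlation":
                self.replicate_correlation.to_dict("records"),
        }


def qc_controls(norm: NormalizedTable,
                alpha: float = 0.05,
                cv_threshold: float = DEFAULT_CV_THRESHOLD,
                paired: bool = False,
                exact_cutoff: int = DEFAULT_EXACT_CUTOFF) -> QcReport:
    """Run the control-based QC on a normalized *well-level* table.

    Per cytokine, a one-sided Wilcoxon test of PC above NC is run on
    replicate-averaged values (unpaired across donors by default; paired
    within donor with ``paired=True``); the check passes when p < ``alpha``
    and the PC median exceeds the NC median.
    """
    df = norm.data
    nc = df[df["role"] == ROLE_NEGATIVE]
    pc = df[df["role"] == ROLE_POSITIVE]
    if nc.empty or pc.empty:
        raise ValidationError("QC requires both NC and PC conditions")

    nc_avg = nc.groupby(["donor", "cytokine"])["value"].mean()
    pc_avg = pc.groupby(["donor", "cytokine"])["value"].mean()

    rows = []
    for cyt in sorted(set(df["cytokine"])):
        nc_v = nc_avg.xs(cyt, level="cytokine")
        pc_v = pc_avg.xs(cyt, level="cytokine")
        if paired:
            donors = nc_v.index.intersection(pc_v.index)
            res = wilcoxon(pc_v.loc[donors], nc_v.loc[donors],
                           mode=MODE_PAIRED, exact_cutoff=exact_cutoff)
        else:
            res = wilcoxon(pc_v, nc_v, mode=MODE_UNPAIRED,
                           exact_cutoff=exact_cutoff)
        pc_med, nc_med = float(pc_v.median()), float(nc_v.median())
        passed = (res.p_greater < alpha) and (pc_med > nc_med)
        rows.append({"cytokine": cyt, "p_greater": res.p_greater,
                     "pc_median": pc_med, "nc_median": nc_med,
                     "method": res.method, "passed": passed})
    cytokine_tests = pd.DataFrame(rows)

    cv = _replicate_cv(df, cv_threshold)
    corr = _replicate_correlation(df)
    return QcReport(cytokine_tests, cv, corr,
                    overall_pass=bool(cytokine_tests["passed"].all()),
                    alpha=alpha, cv_threshold=cv_threshold)


_CONDITION_KEYS = ["cohort", "stimulus", "concentration", "co_exposure"]


def _replicate_cv(df: pd.DataFrame, threshold: float) -> pd.DataFrame:
    g = df.groupby(["donor", *_CONDITION_KEYS, "cytokine"])["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="size").reset_index()
    out = out[out["n"] >= 2].copy()
    undefined = (out["mean"] == 0.0).to_numpy()
    mean = out["mean"].to_numpy(dtype=float)
    sd = out["sd"].to_numpy(dtype=float)
    cv = np.full(len(out), np.nan)
    np.divide(100.0 * sd, mean, out=cv, where=~undefined)
    out["cv"] = cv
    out["undefined"] = undefined
    # undefined CVs are flagged, not failed
    out["passed"] = undefined | (out["cv"] < threshold)
    return out.drop(columns=["sd"])


def _replicate_correlation(df: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of first vs second replicate within each condition,
    across donor x cytokine wells."""
    reps = df[df["replicate"].isin((0, 1))]
    wide = reps.pivot_table(index=[*_CONDITION_KEYS, "donor", "cytokine"],
                            columns="replicate", values="value")
    rows = []
    for key, sub in wide.groupby(level=_CONDITION_KEYS):
        sub = sub.dropna()
        record = dict(zip(_CONDITION_KEYS, key))
        record["n_pairs"] = len(sub)
        if len(sub) >= 2 and sub[0].std() > 0 and sub[1].std() > 0:
            record["r"] = float(pearsonr(sub[0], sub[1]).statistic)
        else:
            record["r"] = np.nan
        rows.append(record)
    return pd.DataFrame(rows)
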