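"""Exact and asymptotic Wilcoxon tests, and the treatment significance grid.

Because plate readings censored below the detection limit are substituted
with zeros, treated-versus-control comparisons use rank tests throughout:
the unpaired test is the rank-sum (Mann–Whitney) test on pooled mid-ranks,
the paired test the signed-rank test on non-zero within-donor differences.

For small samples the null distribution is computed exactly, including
under ties, by an integer subset-sum dynamic program over doubled mid-ranks
(mid-ranks are multiples of 1/2, so doubling makes them integers).  This is
equivalent to full enumeration of all rank splits / sign patterns but runs
in polynomial time.  Larger samples fall back to the tie-corrected normal
approximation with continuity correction (via scipy).

Two-sided p-values follow the doubled-smaller-tail convention, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from .errors import ValidationError
from .study import CytokinePanel
from .catalog import ROLE_NEGATIVE, ROLE_TREATMENT, StimulusEntry

DEFAULT_EXACT_CUTOFF = 12

METHOD_EXACT = "exact"
METHOD_APPROX = "normal_approx"

MODE_PAIRED = "paired"
MODE_UNPAIRED = "unpaired"


@dataclass(frozen=True)
class TestResult:
    """Outcome of a Wilcoxon comparison of sample x against sample y."""

    statistic: float          # rank-sum U (unpaired) or signed-rank W+ (paired)
    p_two_sided: float
    p_greater: float          # evidence that x is shifted above y
    method: str               # "exact" | "normal_approx"
    n_x: int
    n_y: int
    tie_flag: bool
    n_zero_dropped: int = 0   # paired only: zero differences removed


def _midranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks of a 1-D array (ties averaged), like scipy's rankdata but
    without per-call dispatch overhead."""
    order = np.argsort(values, kind="stable")
    sorted_v = values[order]
    new_group = np.empty(len(values), dtype=bool)
    new_group[0] = True
    new_group[1:] = sorted_v[1:] != sorted_v[:-1]
    group = np.cumsum(new_group) - 1
    counts = np.bincount(group)
    ends = np.cumsum(counts)
    mid = ends - (counts - 1) / 2.0      # average of ranks start+1 .. end
    ranks = np.empty(len(values))
    ranks[order] = mid[group]
    return ranks


def _doubled_midranks(ranks: np.ndarray) -> np.ndarray:
    """Mid-ranks times two, as exact integers (mid-ranks are halves)."""
    return np.rint(2.0 * ranks).astype(np.int64)


def _ranksum_tails(ranks2: np.ndarray, n_x: int, obs2: int) -> tuple[float, float]:
    """Exact P(R >= obs) and P(R <= obs) for the sum of ``n_x`` doubled
    mid-ranks drawn without replacement from ``ranks2``.

    Subset-sum DP: f[j, s] counts j-subsets of the pooled ranks with doubled
    sum s.  Ties are handled exactly because equal mid-ranks simply repeat.
    """
    total_sum = int(ranks2.sum())
    f = np.zeros((n_x + 1, total_sum + 1), dtype=np.int64)
    f[0, 0] = 1
    for r in ranks2:
        g = f.copy()
        g[1:, r:] += f[:-1, : total_sum + 1 - r]
        f = g
    counts = f[n_x]
    total = counts.sum()
    tail_ge = counts[obs2:].sum() / total
    tail_le = counts[: obs2 + 1].sum() / total
    return float(tail_ge), float(tail_le)


def _signedrank_tails(ranks2: np.ndarray, obs2: int) -> tuple[float, float]:
    """Exact tails of W+ (doubled) under independent random sign flips."""
    total_sum = int(ranks2.sum())
    g = np.zeros(total_sum + 1, dtype=np.int64)
    g[0] = 1
    for r in ranks2:
        h = g.copy()
        h[r:] += g[: total_sum + 1 - r]
        g = h
    total = g.sum()
    tail_ge = g[obs2:].sum() / total
    tail_le = g[: obs2 + 1].sum() / total
    return float(tail_ge), float(tail_le)


def _two_sided(tail_ge: float, tail_le: float) -> float:
    return min(1.0, 2.0 * min(tail_ge, tail_le))


def wilcoxon(x, y, mode: str = MODE_UNPAIRED,
             exact_cutoff: int = DEFAULT_EXACT_CUTOFF) -> TestResult:
    """Wilcoxon comparison of ``x`` against ``y``.

    Parameters
    ----------
    x, y : array-like
        Samples.  In paired mode they must have equal length and are
        compared through their elementwise differences ``x - y``; zero
        differences are dropped (their count is reported).
    mode : "unpaired" | "paired"
    exact_cutoff : int
        Largest per-group size (unpaired) or number of non-zero pairs
        (paired) for which the exact null distribution is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or (mode == MODE_UNPAIRED and y.size == 0):
        raise ValidationError("empty sample")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("samples must be finite")

    if mode == MODE_PAIRED:
        if x.size != y.size:
            raise ValidationError(
                f"paired samples must have equal length ({x.size} != {y.size})")
        return _paired(x, y, exact_cutoff)
    if mode == MODE_UNPAIRED:
        return _unpaired(x, y, exact_cutoff)
    raise ValidationError(f"unknown mode {mode!r}")


def _unpaired(x: np.ndarray, y: np.ndarray, exact_cutoff: int) -> TestResult:
    n_x, n_y = x.size, y.size
    pooled = np.concatenate([x, y])
    tie_flag = len(np.unique(pooled)) < pooled.size
    ranks = _midranks(pooled)
    r_x = float(ranks[:n_x].sum())
    u = r_x - n_x * (n_x + 1) / 2.0

    if max(n_x, n_y) <= exact_cutoff:
        ranks2 = _doubled_midranks(ranks)
        obs2 = int(np.rint(2.0 * r_x))
        tail_ge, tail_le = _ranksum_tails(ranks2, n_x, obs2)
        return TestResult(u, _two_sided(tail_ge, tail_le), tail_ge,
                          METHOD_EXACT, n_x, n_y, tie_flag)

    two = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    greater = sps.mannwhitneyu(x, y, alternative="greater",
                               method="asymptotic", use_continuity=True)
    return TestResult(u, float(two.pvalue), float(greater.pvalue),
                      METHOD_APPROX, n_x, n_y, tie_flag)


def _paired(x: np.ndarray, y: np.ndarray, exact_cutoff: int) -> TestResult:
    d = x - y
    nonzero = d != 0
    n_zero = int((~nonzero).sum())
    d = d[nonzero]
    n = d.size
    if n == 0:
        # no evidence either way
        return TestResult(0.0, 1.0, 1.0, METHOD_EXACT, x.size, y.size,
                          tie_flag=False, n_zero_dropped=n_zero)

    abs_d = np.abs(d)
    tie_flag = len(np.unique(abs_d)) < n
    ranks = _midranks(abs_d)
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_cutoff:
        ranks2 = _doubled_midranks(ranks)
        obs2 = int(np.rint(2.0 * w_plus))
        tail_ge, tail_le = _signedrank_tails(ranks2, obs2)
        return TestResult(w_plus, _two_sided(tail_ge, tail_le), tail_ge,
                          METHOD_EXACT, x.size, y.size, tie_flag, n_zero)

    two = sps.wilcoxon(d, zero_method="wilcox", correction=True,
                       alternative="two-sided", method="approx")
    greater = sps.wilcoxon(d, zero_method="wilcox", correction=True,
                           alternative="greater", method="approx")
    return TestResult(w_plus, float(two.pvalue), float(greater.pvalue),
                      METHOD_APPROX, x.size, y.size, tie_flag, n_zero)


GRID_COLUMNS = (
    "stimulus", "concentration", "unit", "co_exposure", "cytokine",
    "n_treated", "n_nc", "statistic", "p", "method", "elevated",
    "significant", "missing",
)


def significance_grid(averaged: pd.DataFrame,
                      design: dict[str, StimulusEntry],
                      panel: CytokinePanel,
                      alpha: float = 0.05,
                      mode: str = MODE_PAIRED,
                      strict: bool = True,
                      exact_cutoff: int = DEFAULT_EXACT_CUTOFF,
                      bh: bool = False) -> pd.DataFrame:
    """Test every (stimulus, dose, co-exposure, cytokine) cell against the
    negative control.

    ``averaged`` is a replicate-averaged table with the keys of
    :data:`cytosig.study.AVERAGED_KEYS` and a ``value`` column (raw or
    normalized; rank tests cannot tell the difference).

    In paired mode each donor's treated value is paired with that donor's
    own NC mean; in unpaired mode the treated sample is tested against all
    per-donor NC values pooled as one sample.  A cell is ``significant``
    when its two-sided p is below ``alpha`` (strictly, or inclusively with
    ``strict=False``) *and* the treated median exceeds the pooled-NC median.
    ``bh=True`` applies a Benjamini–Hochberg adjustment to the non-missing
    p-values before thresholding.

    The grid is complete over the catalogued doses of every stimulus present
    in the table crossed with the full panel; cells with no treated values
    are recorded as missing, never significant.
    """
    if not 0 <= alpha <= 1:      # alpha = 0 is a valid boundary: nothing
        raise ValidationError(    # can be significant
            f"alpha must be in [0, 1], got {alpha}")
    df = averaged
    nc = df[df["role"] == ROLE_NEGATIVE]
    if nc.empty:
        raise ValidationError("no negative-control records in the table")
    # pool NC wells within donor first, one baseline value per donor
    nc_by_donor = nc.groupby(["donor", "cytokine"])["value"].mean()
    nc_donor_map: dict[str, dict[str, float]] = {}
    for (donor, cyt), v in nc_by_donor.items():
        nc_donor_map.setdefault(cyt, {})[donor] = v
    nc_pooled = {c: np.fromiter(d.values(), dtype=float)
                 for c, d in nc_donor_map.items()}
    nc_median = {c: float(np.median(v)) for c, v in nc_pooled.items()}

    treated = df[df["role"] == ROLE_TREATMENT]
    donor_arr = treated["donor"].to_numpy()
    value_arr = treated["value"].to_numpy(dtype=float)
    indices = treated.groupby(
        ["stimulus", "concentration", "co_exposure", "cytokine"],
        sort=False).indices
    co_by_stim: dict[str, set[str]] = {}
    for stim, _, co, _ in indices:
        co_by_stim.setdefault(stim, set()).add(co)

    rows = []
    for stim in design:
        if stim not in co_by_stim:
            continue
        entry = design[stim]
        for conc in entry.doses_ascending:
            for co in sorted(co_by_stim[stim]):
                for cyt in panel:
                    idx = indices.get((stim, conc, co, cyt))
                    nc_map = nc_donor_map.get(cyt)
                    if idx is None or not nc_map:
                        rows.append((stim, conc, entry.unit, co, cyt,
                                     0, 0, np.nan, np.nan, "", False, False,
                                     True))
                        continue
                    values = value_arr[idx]
                    if mode == MODE_PAIRED:
                        pairs = [(v, nc_map[d]) for v, d in
                                 zip(values, donor_arr[idx]) if d in nc_map]
                        if not pairs:
                            rows.append((stim, conc, entry.unit, co, cyt,
                                         0, 0, np.nan, np.nan, "", False,
                                         False, True))
                            continue
                        xv = np.array([p[0] for p in pairs])
                        yv = np.array([p[1] for p in pairs])
                    else:
                        xv = values
                        yv = nc_pooled[cyt]
                    res = wilcoxon(xv, yv, mode=mode,
                                   exact_cutoff=exact_cutoff)
                    elevated = float(np.median(values)) > nc_median[cyt]
                    rows.append((stim, conc, entry.unit, co, cyt,
                                 res.n_x, res.n_y, res.statistic,
                                 res.p_two_sided, res.method, elevated,
                                 False, False))

    grid = pd.DataFrame(rows, columns=GRID_COLUMNS)
    if bh and grid["p"].notna().any():
        ok = grid["p"].notna()
        grid.loc[ok, "p"] = sps.false_discovery_control(
            grid.loc[ok, "p"].to_numpy(), method="bh")
    below = grid["p"] < alpha if strict else grid["p"] <= alpha
    grid["significant"] = below.fillna(False) & grid["elevated"]
    grid.attrs.update(alpha=alpha, mode=mode, strict=strict, bh=bh)
    return grid
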