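# Methods

## Study design and data model

The unit of data is one well-level reading: (donor, cohort, stimulus, dose,
co-exposure, cytokine, replicate) → concentration in pg/mL with an explicit
censoring flag.  The canonical interchange format is a tidy CSV; censoring
is never inferred from sentinel values, so the substitution policy stays
auditable.  A design catalogue fixes the tested concentrations per stimulus
(ten model IIRMIs at four decade-spaced doses each, plus the drug product);
every treatment row must match a catalogued dose.  Doses are normalized
internally to pg/mL (1 µg/mL = 10⁶ pg/mL) while display units are kept as
metadata.  A `cohort` tag (fresh, cultured24h, cryopreserved, refrigerated
blood, whole blood) lets the same pipeline run per handling condition; it
defaults to `fresh` when absent.

Assay quantification limits are user-supplied configuration (per-cytokine
LLOQ/ULOQ), since multiplex kits differ and vendors rarely publish them.

## Censoring and normalization

Readings below the detection limit are substituted with 0 and readings
above it with the cytokine's ULOQ before any statistics.  This floor/cap
substitution is why all inference is rank-based: the substituted values are
correct in rank but not in magnitude.

Normalization divides each cytokine's readings by that cytokine's sample
SD (ddof = 1) computed across all collected wells — every donor, condition,
cohort and control, before replicate averaging.  It exists purely to put
analytes spanning four orders of magnitude on one scale for clustering and
heatmaps.  Because it is a positive per-cytokine rescaling it provably
cannot change any rank-test result; the test suite asserts bit-identical
significance grids on raw vs normalized values.  Zero-variance cytokines
are flagged and passed through unscaled.

## Quality control

Three checks mirror assay acceptance practice: (1) per cytokine, a
one-sided Wilcoxon test that the positive control reads above the negative
control on replicate-averaged normalized values (unpaired across donors by
default; donor-paired optionally — the appropriate pairing depends on how
controls were plated).  The study-level pass flag is the conjunction of
these per-cytokine checks.  (2) Duplicate-well agreement, %CV < 25;
pairs with zero mean (both wells censored to the floor) have no defined CV
and are flagged, not failed, and %CV failures flag records without
excluding them — the criterion is reported, the action left to the analyst.
(3) Pearson correlation of replicate runs (a vs b) within each treatment.

## Rank tests

Unpaired comparisons use the rank-sum (Mann–Whitney) test on pooled
mid-ranks; paired comparisons the signed-rank test on non-zero differences
(zeros dropped and counted).  For small samples (each group ≤ 12 by
default) the null distribution is computed exactly *including ties*: with
mid-ranks doubled to integers, the number of rank subsets (or sign
patterns) attaining each statistic value is counted by a subset-sum dynamic
program — equivalent to full enumeration of all C(n, n₁) splits or 2ⁿ sign
patterns, in polynomial time.  Two-sided p-values double the smaller tail
and cap at 1.  Larger samples use the tie- and continuity-corrected normal
approximation (scipy).  An independent enumeration oracle in the test suite
checks the exact path bit-for-bit.

The significance grid tests every (stimulus, dose, co-exposure, cytokine)
cell against the negative control.  Two pairings are supported, because
both are defensible for this design and the choice matters at n = 10:
*paired* (default for signature selection) pairs each donor's treated value
with that donor's own NC mean — donor effects cancel, maximum sensitivity
2/2¹⁰; *unpaired* (default for top-k selection) pools all per-donor NC
values as one reference sample.  Significance requires the elevation gate
(treated median > pooled-NC median) on top of the p threshold; suppression
is never "significant" here.  Threshold strictness (p < α vs p ≤ α) is
likewise configurable per call path: strict for signature selection,
inclusive for top-k.  No multiple-testing correction is applied by default
— the grid reports raw p-values as assay screens conventionally do — with
an optional Benjamini–Hochberg flag.

## Signature, top-k and modulation calls

Signature selection scans a stimulus's doses in ascending order and stops
at the first dose with at least one significantly elevated cytokine; the
minimum-p cytokine wins, with ties broken deterministically by fixed panel
order (the assay's plate order).  Other significant cytokines at that dose
are reported as co-induced.  Top-k scans for the first dose with ≥ k
significant cytokines and returns the k smallest p-values; a design
exhausted without k hits yields the significant set at the top dose,
flagged `short`, rather than an error — some impurities genuinely induce
almost nothing.  `select_top_k(k=1)` coincides with `select_signature`
under identical mode and strictness (property-tested).

Modulation calls compare each (stimulus, cytokine) with and without drug
co-exposure.  Arms are matched on (donor, dose) and tested with a paired
two-sided Wilcoxon, pooled over the stimulus's doses by default (per-dose
and unpaired variants are configurable); pairing is the default because
matched arms exist by design and donor effects dominate between-donor
variance.  Significant calls carry a direction from the medians:
`inhibited` or `enhanced`.

## Panel construction

Top-3 calls across stimuli form a boolean induction matrix.  Minimal
covering panels are found by exhaustive search in ascending cardinality —
with ≤ 16 cytokines this is at most a few thousand subsets, so exact search
is preferred over a greedy heuristic whose output could not be certified
minimal.  All covers of the minimum size are enumerated (alternative panels
matter in practice when one analyte is unavailable on a small-plex kit),
deterministically ordered by panel order.  A stimulus row with no TRUE cell
makes covering impossible and raises an error naming the stimulus.  The
fixed reference matrix of top-3 calls for the ten model IIRMIs ships with
the package; on it the minimum covering panel size is 3.

## Structure analyses

The response matrix averages normalized values over donors per (condition,
cytokine); never-measured cells are imputed as 0 — the post-censoring floor,
where absence behaves like non-detection — and logged.  Rows and columns
are clustered agglomeratively on Euclidean distances.  Both complete and
Ward linkage are implemented and configurable, with complete the default;
the two disagree only in how cluster heights grow, and on well-separated
data produce the same topology.  Cytokines can also be clustered on
1 − Pearson r across all treatment conditions; zero-variance items are
excluded with a flag.  Dendrograms are exported as Newick with node depths
equal to merge heights.  Clustering delegates to scipy's linkage; the test
suite checks its merge sequences against a naive O(n³) Lance–Williams
agglomeration written independently.

## Synthetic studies

The generator emulates the data-generating process the analysis assumes.
For donor i, cytokine c, condition (s, d), log concentration is

    baseline(c) + a_i + b_ic + Emax(s,c) · dʰ/(dʰ + EC50ʰ) + m(s,c) + ε

with a_i ~ N(0, donor_sd) a shared responder offset, b_ic ~ N(0, sd_c) a
per-(donor, cytokine) baseline offset, m(s, c) the co-exposure log-effect
when the drug is present, and ε log-normal replicate noise of coefficient
of variation `replicate_cv` (mean-one corrected).  The positive control
induces every cytokine by a fixed `pc_effect`.  Values outside [LLOQ,
ULOQ] are emitted as censored records.  An optional top-dose attenuation
term reproduces the exhaustion/toxicity dips sometimes seen at saturating
exposure.

Defaults (chosen once, as plausible study conditions): 10 donors,
duplicates, the full stimulus catalogue; one planted responsive cytokine
per stimulus — its known signature cytokine — with emax_log = 3 (a
20-fold maximal induction), Hill coefficient 1 and EC50 at the lowest
catalogued dose, consistent with signatures being detectable from the
lowest tested concentration for most impurities; donor_sd = 0.5 and
per-cytokine baseline log-SD 0.5 (donor-to-donor spread of a few fold);
replicate CV 0.15, comfortably inside the 25 %CV duplicate gate;
baselines from ~10 pg/mL (interferons, partly below a 5 pg/mL LLOQ, so
negative controls are realistically censored) to ~600 pg/mL (IL-8);
ULOQ 10⁵ pg/mL; pc_effect = 3.

What passing recovery tests shows — and what it does not: the generator
reproduces the *statistical* structure (skewed positive concentrations,
donor random effects, saturating dose–response, censoring, duplicate
noise), so recovery demonstrates that the selection logic identifies truly
responsive cytokines under realistic noise.  It does not model receptor
biology, cytokine cross-induction, plate/batch effects, or inter-cytokine
correlation beyond the shared donor offset, so it cannot validate
biological conclusions about any particular impurity.

## Numerical choices and edge cases

- Ties in p are broken by fixed panel order everywhere a single winner is
  needed; determinism is tested end to end (identical config ⇒
  byte-identical report bundle).
- Exact-test tails use integer counting; p-values are exact rationals
  rounded once at the final division.
- All-zero paired differences give p = 1 (no evidence), not an error.
- Equal-height cluster merges follow scipy's deterministic ordering; on
  continuous data exact height ties have probability zero.
- CSVs are written with 17 significant digits and read with round-trip
  float parsing, so write → read is bit-exact.
- Randomness flows from a single integer seed through named substreams
  (donor effects vs replicate noise), so adding donors does not perturb
  the noise stream and same-seed runs are bit-identical.

## Known limitations

- Co-exposed arms apply the stimulus response plus the co-exposure effect;
  the drug's own induced response is not added on top, so synergy between
  drug and impurity responses is not modeled.
- The NC-vs-PC QC test's pairing (donor-paired vs pooled) is configurable
  because plating practice varies; the default is unpaired.
- Whether modulation comparisons should pool doses or run per dose is
  assay-dependent; pooled is the default.
- Normalization SDs are computed over the whole table including controls;
  cohort-stratified scaling is available only by filtering to a cohort
  before normalizing.
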