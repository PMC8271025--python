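# Methods

## Scope and data model

`radstab` analyses long-format feature tables: one record per
(object, object type, sequence, scan, segmentation session, feature).
It does not read images or compute features from them; extraction is
upstream.  The feature namespace is pinned as a static catalog of the
107 "original" radiomic features (14 shape, 18 first-order, 24 GLCM,
16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM), with `shape_LeastAxisLength`
flagged excluded — segmenting only the middle portion of each object
biases the least-axis estimate systematically — leaving 106 analysis
features.  Pinning the catalog keeps the pipeline free of any
extraction dependency and makes name validation exact.

Session labels are fixed to `R1S1`, `R1S2` (reader 1, one month later)
and `R2` (reader 2).  The intra-observer pair is (R1S1, R1S2), the
inter-observer pair (R1S1, R2).  Scan–rescan robustness uses session
R1S1 by default; this is configurable because a measured dataset does
not dictate which segmentation enters the robustness arm.

## Robustness: CCC and DR

Lin's concordance correlation coefficient is computed with population
(1/n) moments — Lin's original estimator — with a sample-moment
(1/(n−1)) variant behind a switch; the choice affects only the weight
of the mean-shift term.  The dynamic range normalises the mean absolute
scan–rescan difference by the pooled range of both samples; this is the
only denominator convention consistent with both boundary cases (two
distinct constant samples → 0; identical non-constant samples → 1), and
it confines DR to [0, 1] since every within-pair difference is bounded
by the pooled range.

Degenerate rows (zero CCC denominator, or zero pooled range) are
reported as NaN, excluded from all fractions and selections, and
tallied in an `n_undefined` count rather than being treated as
failures: a constant feature carries no evidence either way.

A feature is robust at cutoff c when CCC ≥ c **and** DR ≥ c, both
inclusive, at the conventional cutoffs 0.85/0.90/0.95.  Class-level
"combined" fractions default to the unweighted mean of the five
per-sequence fractions (pooling across sequences is available); the
per-sequence fractions are always reported alongside.

The bias-corrected coefficient CCC_corr = CCC + (1 − intra-observer
ICC) is computed and reported unclipped (it can exceed 1 by
construction).  Selection gates on the raw CCC by default, with a
switch to gate on CCC_corr; published analyses are ambiguous about
which value enters their selection tables, so both are first-class.

## Reproducibility: two-way ICC

ICC is computed from the two-way complete-layout ANOVA mean squares.
The default form is absolute agreement, single measures — ICC(2,1),
(MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n) — because the design
crosses the same subjects with two fixed raters and a systematic
reader offset must count against reliability (inter-observer
deterioration is a finding, not noise to be absorbed).  The consistency
form ICC(3,1) is available as an option.  Subjects default to the 32
object–scan combinations per sequence (both scans were re-segmented);
averaging scans first (16 subjects) is behind a switch.

ICC categories (excellent ≥ 0.75, good 0.60–0.74, moderate 0.40–0.59,
poor ≤ 0.39) are two-decimal bands; values are rounded half-up to two
decimals before banding so the interval (0.745, 0.75) is not left
unassigned.

The joint robust-and-reproducible criterion is
CCC ≥ 0.90 ∧ DR ≥ 0.90 ∧ intra-ICC ≥ 0.75 ∧ inter-ICC ≥ 0.75,
all inclusive, applied per sequence; the cross-sequence set is the
intersection of the per-sequence sets.  DR is part of the criterion
even though shorthand phrasings of it sometimes omit DR.

## Discrimination: exact Mann–Whitney Gini screening

Each object contributes six replicates (3 sessions × 2 scans) per
feature and sequence.  For every unordered object pair, U counts
replicate pairs with the second group above the first, ties ½
(equivalently the midrank convention; the implementation counts pairs
directly, which is exact for these group sizes, and is cross-checked
against `scipy.stats.mannwhitneyu` in the tests).  AUC = U/(n₁n₂),
Gini = 2·AUC − 1.

"Perfect" means complete separation in either direction
(AUC ∈ {0, 1}): either orientation distinguishes the two objects.  A
tie straddling the groups caps AUC strictly inside (0, 1) and therefore
vetoes perfection automatically.  The significance of a perfect score
stays one-sided, p = n₁!n₂!/(n₁+n₂)! (1/924 for 6 vs 6), computed in
exact rational arithmetic; a two-sided option doubles it.  The
orientation-insensitive success definition with a one-sided null is a
deliberate asymmetry: the null probability refers to one fixed
orientation, which is how the 1/924 figure is conventionally quoted.
Group-level screening numbers follow exactly:
FDR = 1 − (1 − p)^m over m features, and the probability that all
pairs succeed by chance is bounded by FDR^(number of pairs) under
independence — reported explicitly as an independence bound, since
features are correlated in real data and the true joint probability is
not identifiable from the table.

A group of features "succeeds" for a pair when at least one member
attains a perfect score.  Success counts are reported per sequence, per
class within sequence, and per single feature; the per-feature report
is ranked competition-style (ties share a rank, next rank skipped,
alphabetical tie-break for determinism).

## Synthetic phantom generator

The generator emulates the study design's statistical structure, not
its physics.  Per feature f and sequence s:

    value = base_level + T(type) + B(object) + O(object, session) + E(object, scan, session)

with independent zero-mean Gaussian components: T with spread
`sigma_type` (per type), B with `sigma_obj` (per object), measurement
noise E with `sigma_scan` redrawn for every (object, scan, session)
cell, and a session effect O that is 0 for R1S1, per-object noise with
spread `sigma_obs·eps_intra` for R1S2, and `obs_shift` plus per-object
noise with spread `sigma_obs` for R2.  Shape-class features have
`sigma_scan` scaled by `shape_scan_factor` (default 0.2): geometric
descriptors of rigid objects barely respond to repositioning, which
reproduces "shape is the most robust class" as a testable property.

Defaults (`sigma_type=3, sigma_obj=1, sigma_scan=0.3, sigma_obs=0.3,
obs_shift=0.2, eps_intra=0.1, base_level=100`) describe a stable
acquisition with strong between-object contrast — scan–rescan CCC near
0.99 — chosen once as a realistic regime for a rigid-phantom study; no
published noise magnitudes exist to estimate them from, so they are
free parameters of the emulation, not estimates of any scanner.

Reproducibility contract: one root seed; one substream per feature,
keyed on a CRC-32 digest of the feature name, so subsetting the catalog
never changes other features' values; standard-normal draws are scaled
by the sigmas afterwards, so configs differing only in a sigma share
the same noise realisation (which makes noise-monotonicity testable
seed by seed).  Identical seeds give byte-identical tables.

### Closed-form targets and their finite-design caveat

Under the model, the scan–rescan CCC converges (in object count) to
σ_b²/(σ_b² + σ_scan²) with σ_b² = σ_type² + σ_obj², and the
absolute-agreement ICC to σ_b²/(σ_b² + σ_e²).  Two structural points:

- Only the comparison session carries observer noise (R1S1 is the
  reference with a zero session effect), so the comparison session's
  observer variance and the squared systematic shift enter the two-way
  error term at **half weight**:
  ICC_inter → σ_b²/(σ_b² + σ_scan² + (σ_obs² + shift²)/2), and
  analogously for the intra pair with σ_obs·eps_intra.
  `expected_stats(config)` encodes these targets.
- The closed forms are asymptotic.  At the default 16-object design the
  moment/ANOVA estimators carry an O(1/n) downward bias (shrinkage of
  sample moments plus the mean-difference term) of order 0.01–0.02 —
  larger than three standard errors of a 106-feature mean.  The
  parameter-recovery tests therefore check the default design against
  an independent Monte-Carlo oracle of the same finite design (direct
  numpy draws through the definitional formulas), and check the closed
  forms at a 200-object design where the asymptotics hold, both within
  three standard errors.

What passing these tests shows: the generator, the statistics and their
assembly are mutually consistent under a known Gaussian
variance-component truth.  What they do not show: behaviour under
heavy-tailed or heteroscedastic real acquisitions, feature–feature
correlation structure (synthetic features are independent given the
design), sequence-specific noise, or segmentation failure modes.
Published sequence-specific fractions (e.g. which sequence yields the
most robust features) depend on the measured data and are not
reproducible from synthetic inputs; the printed-table fixtures cover
the parts of the published analysis that are exactly reproducible
(selection counts: 84 for the T2 map table, the 8-feature
cross-sequence intersection with 7 shape features).

## Reporting conventions

Bland–Altman differences follow the x − y convention (scan1 − scan2,
reader1 − reader2), with limits mean ± 1.96·SD and the n−1 standard
deviation.  Box-whisker summaries report median, quartiles and 5th/95th
percentiles via linear interpolation (numpy default), listing values
outside [p5, p95] individually as outliers.  Significance markers
follow *p < 0.05, **p < 0.01, ***p < 0.001.  The pipeline writes CSV
for tables, JSON for machine-readable summaries, and logs every
decision-relevant setting (seed, cutoffs, ICC variant, moment
convention, orientation policy, percentile method).

## Numerical choices and degenerate inputs

- CCC/DR/ICC return NaN (never raise) for degenerate-but-valid inputs
  (constant samples, all-identical grids); structural errors (length
  mismatch, n < 2, incomplete grids) raise `ValueError`.
- Exact combinatorics use `fractions.Fraction`; 0.108¹²⁰ ≈ 1.7·10⁻¹¹⁶
  remains representable in double precision, so no log-space fallback
  is needed at these problem sizes.
- Feature-table CSV values are serialised at 12 significant digits,
  making write–read round trips value-stable and repeated writes
  byte-stable.
- Cutoff comparisons are inclusive (≥) everywhere.

## Known limitations

- Two raters and two scans only; no >2-session designs, no
  Krippendorff/kappa alternatives, no longitudinal repeatability
  models.
- The all-pairs significance bound assumes independence across pairs
  and features; it is an upper-bound heuristic, labelled as such.
- The generator's Gaussian components cannot emulate outlier-driven
  ICC collapse seen in real inter-observer data.
- Problem sizes in tests (default 16-object design, a 200-object
  asymptotic check, 20-seed monotonicity sweeps, 3–4k Monte-Carlo
  replicates) were chosen to make the statistical checks decisive at
  three standard errors while keeping the suite quick on a laptop.
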