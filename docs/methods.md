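# Methods

This note documents the models and procedures implemented in `placmir`, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical decisions made where the design was open.

## Screening a pooled array without replicates

The screening substrate is a long-format Cq table (assay, plate, group, Cq
or an "Undetermined" flag), one well per assay per group.  Invariants are
enforced at construction: at most one well per (assay, group), one plate per
assay, finite positive Cq unless flagged.

**Detection.** An assay is detected in a group when its Cq is present, not
flagged, and strictly below `cq_max` (default 40, the instrument's cycle
maximum; observed screen Cq values run well below it).  The threshold is
configurable because instruments and pre-amplification protocols differ.

**MA statistics.** `M = Cq(Con) − Cq(N3)` and `A = (Cq(Con)+Cq(N3))/2`.
Because expression is proportional to 2^−Cq, a *lower* Cq in the
intervention pool means *higher* expression, so this sign convention makes
positive M an up-regulation in the intervention group — the convention under
which a +1.53-fold validated up-regulation carries a positive fold change.
Fold changes are encoded the way screening tables print them: `2^M` for
M ≥ 0 and `−2^(−M)` for M < 0, so a 3.5176-cycle down-shift prints as
−11.45 rather than 0.087.

**Normalization.** Intensity-dependent bias is removed separately per plate
by fitting a smooth trend of M on A and subtracting it (the cyclic-loess
idea; with exactly two samples the cycle is a single M-on-A pass).  The
trend estimator is a least-squares fit on a low-rank natural-cubic-spline
basis with interior knots at quantiles of A (roughly `2/span` knots, span
default 0.7).  A projection smoother was chosen deliberately: subtracting a
projection is *exactly idempotent*, so re-normalizing normalized data is a
no-op to machine precision — a property classical tricube lowess does not
have (its fit-and-subtract iteration is not even convergent, because the
local-linear smoother matrix has negative eigenmodes).  Trend-removal
quality is verified in the tests against an independent lowess refit of the
residuals.  Plates with fewer than 10 defined points fall back to
median-centering with a warning.  Assays with undefined M (one or both
groups undetected) pass through untouched.

**Adaptive cutoff.** For τ = 0.05 and 0.95, a quadratic polynomial in A is
fitted to normalized M by minimizing the pinball loss (iteratively
reweighted least squares; an exact linear-programming solver for the same
loss is kept in the library and used as the test oracle).  A is centered
and scaled internally for conditioning; a rank-deficient design (constant A)
raises a diagnostic error.  Points strictly below the 0.05 curve or strictly
above the 0.95 curve are flagged; ties on a curve count as inside.  By
construction ~10% of null assays are flagged — the envelope is a selection
device for follow-up validation, not a significance test.

**Classification and summary.** Assays detected in both groups are called
up/down/unchanged from the envelope; assays detected in exactly one group
become group-unique calls (`n3_only`/`con_only`) and count as differential;
assays detected in neither are `undetected` and excluded from every
denominator except the screened total.  The per-assay signed fold change is
derived from normalized M so that call = up ⇔ fold > 1 ⇔ M above the upper
curve holds identically.  `median_cq` is the median of the assay's defined
Cq values across wells (with one well per group, the mid-point of the two).
Venn counts obey inclusion–exclusion exactly, and percentages of the
screened total are rounded half-up to one decimal, matching how such tables
are printed.

## Seed-site prediction

The seed is nucleotides 2–8 of the mature microRNA.  A site is any 7-nt
transcript window pairing antiparallel with the seed — window position j
(5'→3', 0-based) against seed position 6−j — with at most `max_mismatch`
non-pairing positions (0–2).  Pairing is Watson–Crick; a `--allow-wobble`
flag counts G:U as pairing, off by default because rendered alignments mark
*complementary* matches.  Coordinates are 1-based inclusive.  Region labels
come from the window midpoint, with a `boundary` flag when a window
straddles regions.  The 3'-supplementary score counts Watson–Crick pairs
between miRNA nucleotides 13–16 and the target bases opposite them in a
linear duplex anchored at the seed (miRNA nt 2 opposite the window's 3'
end); the loop allowance between seed and 3' pairing defaults to 0 nt and
is configurable.  The window and zero-offset defaults follow the canonical
supplementary-pairing convention of the target-prediction literature.
Alignments are deterministic fixed-width text: target 5'→3', a star line,
and the microRNA 3'→5' with the seed upper-cased.  DNA input (T) is
transcribed to RNA (U) with a warning.

## Enrichment

Per gene, sites aggregate to `Σ w(region) / (1 + mismatches)` with default
weights 3'UTR 1.0, CDS 0.5, 5'UTR 0.25 — a documented, configurable local
stand-in for server-side target scores, weighting canonical 3'UTR sites
highest and penalizing mismatched seeds.  Regulated-set versus background
scores are compared by a one-sided Wilcoxon rank-sum test (alternative:
regulated stochastically greater).  For n+m ≤ 12 the p-value is exact by
enumerating all C(n+m, n) assignments with midranks (correct under ties);
beyond that, the normal approximation with tie-corrected variance and a 0.5
continuity correction.  "Genes over threshold" counts regulated genes with
score strictly above the threshold (default 0.5); ties at the threshold are
excluded.

## Relative quantification (2^−ΔΔCq)

ΔCq = Cq(target) − mean(Cq of reference genes): the arithmetic mean of Cq
*is* the geometric mean of linear quantities on the log2 scale, so no
double exponentiation.  Relative expression is calibrated to the
female-control (Con-F) cell as `rel% = 100 · 2^(−ΔCq) / mean(2^(−ΔCq) over
calibrator samples)`.  Calibrating against the mean *linear* quantity, not
the mean ΔCq, is deliberate: by Jensen's inequality the log-scale calibrator
would make the calibrator-cell mean exceed 100% whenever its ΔCq values
vary, while the linear calibrator pins it at exactly 100% — the identity the
validation tables are built on.  Amplification efficiency is fixed at 2.0;
efficiency correction is out of scope.  Per-sample shifts applied to target
and reference Cq alike cancel exactly.

## Cohort statistics

Group-sex models are OLS with treatment and sex indicators; the additive
model supplies the Treatment and Sex p-values, the interaction model the
interaction p and four pairwise cell contrasts (Con-M−Con-F, N3-M−N3-F,
N3-F−Con-F, N3-M−Con-M) with homoscedastic t-based inference (no
robust-covariance option — plain OLS contrasts).  With no covariates the
interaction model is saturated and reproduces the four observed cell means
exactly.  Skewed analytes (amino acids) can be natural-log transformed as
outcomes; predictors are never transformed.  Baseline adjustment (e.g.
week-15 levels) enters as an ordinary covariate.

Association models: Model 1 regresses outcome on predictor alone; Model 2
adds baseline taurine, baseline tryptophan, sex and group, plus
breastfeeding status (binary: fully vs partial/formula) for postnatal
outcomes.  Missing data are handled by listwise deletion per model with the
model's n reported; fits require at least p+2 complete cases.  No
multiplicity correction is applied anywhere, by design — the analyses are
exploratory and every p-value is reported as-is.

Spearman correlations use midranks; the two-sided p-value is exact by full
permutation enumeration for n ≤ 9 (kept small so the test oracle can
enumerate too) and the t approximation otherwise.  |Rs| is banded weak
(< 0.4), moderate (0.4 to < 0.7), strong (≥ 0.7).

## Synthetic data

The generators are pure functions of (parameters, seed) — regeneration is
byte-identical — and each returns a JSON-serializable truth manifest.

* **Array** (default 667 assays, two alternating plates): base Cq uniform on
  14–36 (bracketing the Cq span such screens observe), per-well Gaussian
  noise (SD 0.25 cycles, a typical technical replicate SD), optional
  polynomial intensity bias added to the intervention pool, planted ΔCq
  effects by assay or auto-placed in a Cq window, and logistic high-Cq
  dropout centered at Cq 38 (scale 0.5) so wells fade out near the
  instrument limit rather than at a hard cliff.
* **Transcripts**: i.i.d. uniform nucleotides with a 15/55/30%
  5'UTR/CDS/3'UTR layout; planted sites insert the reverse complement of
  the seed with the requested number of substitutions at recorded
  coordinates, redraw on overlap, and are re-verified after generation so a
  plant can never be silently destroyed.
* **Cohort** (default 41 pairs split 11/9/10/11 across Con-F/Con-M/N3-F/
  N3-M): amino acids log-normal around field-realistic medians (ln-scale SD
  0.25, consistent with the right-skew that motivates log transforms);
  expression ΔCq = target baseline + planted per-cell shift + N(0, 0.6);
  outcomes = realistic intercept + planted slopes × centered predictors +
  Gaussian noise; breastfeeding Bernoulli(0.6 fully).  Validation Cq records
  add a per-sample loading shift to target and reference genes alike, so
  ΔCq recovers the cohort value exactly up to reference noise.

Scenario presets (per-cell fold patterns, planted association slopes) live
in `configs/scenarios/` as YAML, not in code.

What the generators do *not* emulate: real microRNA abundance distributions
or cross-hybridization, pre-amplification bias, transcript composition bias
(real UTRs are not uniform-random), assay-specific amplification
efficiencies, or correlated missingness in the cohort.  Passing tests
therefore demonstrate that the *procedures* are implemented correctly and
calibrated under their stated assumptions — not that those assumptions hold
in any particular real dataset.

## Problem sizes and verification

The test suite checks, among others: null flagging calibration (mean
flagged fraction within [0.08, 0.12] over 200 simulated null arrays of 667
assays), ≥ 90% flagging of planted 2-cycle effects, exhaustive-oracle
equality of the seed scanner on 1,000 random transcripts up to 1 kb at all
mismatch levels, 100% planted-site recall, exactness of the rank-sum test
against enumeration for all n+m ≤ 12, the ddCq identities, interaction-test
type-I error within [0.03, 0.07] over 500 null cohorts of 41 pairs, and
95%-CI coverage of a planted slope within [0.93, 0.97] over 2,000
replicates (the larger replicate count keeps binomial noise on the coverage
estimate well inside the band).  `scripts/acceptance.py` recomputes the
same quantities from scratch at slightly reduced replicate counts (100 null
arrays, 200 oracle transcripts, 500/2,000 inference replicates) and writes
them as JSON.

## Known limitations

* The enrichment score is a local surrogate; printed p-values from
  server-side prediction scores cannot be reproduced and are not targeted.
* One pool per group means screening calls are selection heuristics;
  statistical confirmation only happens in the validation cohort layer.
* Quantile-regression flags near the curve depend on solver tolerance at
  exact-tie boundaries; ties are defined as inside to make this stable.
* The exact Spearman path is limited to n ≤ 9 by factorial growth.
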