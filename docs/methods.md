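# Methods

This note documents the models implemented in `muscleomics`, the
defaults chosen where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Experimental design and preprocessing

The design is 2 genotypes (WT, KI) × 3 timepoints (SED, T10, EXH) × 3
replicates per cell, with each sex quantified in its own isobaric-label
plex (18 samples per sex). Because plexes are separate batches, the two
sexes are processed as independent datasets end to end; no cross-sex
normalization is attempted.

Preprocessing order: (1) complete-case filtering — a feature missing in
*any* sample of a sex is removed for that sex, matching the behaviour of
a plex where the feature was simply not quantified; (2) sample-median
subtraction (removes loading differences); (3) feature median-centering.
Intensities are assumed to arrive already log2-transformed, so medians
are computed on the log2 scale. Medians of an even number of values are
the midpoint of the two central order statistics.

Shared peptides are assigned to the candidate protein with the most
total peptide identifications. The tie-break is the lexicographically
smallest accession — deterministic and order-independent. Phosphosites
give absolute priority to proteins detected in the global proteome
before applying the same parsimony rule.

## Differential model

Per feature, a cell-means linear model (one indicator per
genotype×timepoint level, no intercept) is fit by least squares;
with uniform weights the coefficients are exactly the cell sample
means, and the residual df is `d = n − 6`.

**Sample quality weights.** Optionally (on by default only for the
global-proteomics style of analysis, where a few noisy channels are
common), per-sample weights are estimated by iterating: weighted fit →
per-sample mean squared standardized residual `m_j` (residuals scaled
by the feature residual SD and the leverage correction `1 − h_jj`) →
`w_j ← 1/m_j`, renormalized to geometric mean 1, until the maximum
relative change falls below 1e-6 (cap 50 iterations). This satisfies
the contract — noisy samples are down-weighted without losing degrees
of freedom — with a simple, deterministic fixed-point scheme rather
than a REML fit.

**Variance moderation.** Writing `z = log s²`, under the scaled-F prior
predictive `E[z] = log s0² + ψ(d/2) − log(d/2) − ψ(d0/2) + log(d0/2)`
and `Var[z] = ψ′(d/2) + ψ′(d0/2)`. The prior parameters follow in
closed form: `d0 = 2·ψ′⁻¹(Var̂[z] − ψ′(d/2))` (Newton inversion of the
trigamma function) and `s0²` from the mean equation. Posterior
variances are `s̃² = (d0 s0² + d s²)/(d0 + d)` with `d0 + d` total df.

Numerical choices:

* *Robust estimation* (default on): features whose `log s²` lies more
  than 4 MAD-standardized units from the median are excluded from the
  moment matching. Under clean data essentially nothing is excluded, so
  the estimator stays consistent; a handful of wild variances cannot
  drag the prior.
* *Degenerate prior*: when the observed spread of `log s²` does not
  exceed its sampling noise, `d0 = ∞` and the prior variance is the
  geometric mean of the observed `s²`. This makes a constant variance
  vector an exact fixed point of the shrinkage (all `s² = c` ⇒
  `s̃² = c`), which we consider the right contract for the degenerate
  case even though it differs by a factor `exp(ψ(d/2) − log(d/2))` from
  the large-`d0` limit of the finite estimator.
* *Mean–variance trend* (default off): `s0²` becomes a lowess smooth
  (frac = 0.5) of `log s²` against mean abundance.
* p-values of exactly 0 are floored at the smallest positive double
  before FDR adjustment.

**Contrasts and FDR.** The named contrasts are the four
exercise-vs-sedentary responses per genotype, the sedentary genotype
difference, and the exhaustion-response interaction. BH adjustment is
applied once to the pooled exercise-vs-SED family and once to the
pooled remaining contrasts, so the two questions carry separate FDR
budgets.

## Enrichment

Moderated t-statistics are mapped to z-scores through log-scale tail
areas (`Φ⁻¹(F_t(t; df))` computed via `logsf` + `ndtri_exp`), which
keeps |z| accurate beyond the double-precision CDF saturation point.
Features sharing an identifier are collapsed per contrast to the
feature with maximal |z| (ties: lexicographically smallest feature id);
unmapped features keep their own identifier rather than being dropped.

Annotation sets are intersected with the measured universe and filtered
by minimum overlap — defaults 10 for gene sets, 3 for kinase-substrate
sets, 10 for metabolite subclasses. Near-duplicate sets are clustered
as connected components of the graph with an edge when Jaccard ≥
cutoff. The cutoff is not externally fixed; the default is 0.85 and it
is exposed as a flag (results should be reported with the cutoff used).
Jaccard is computed on universe-intersected memberships (a flag can
switch to original memberships by skipping the filter step). One
representative per cluster survives, chosen by the cascade: largest
intersected size → highest proportion of original members retained →
shortest whitespace-normalized description → alphabetically first name.

The competitive test (parametric CAMERA-PR) compares the set's mean z
against the background with a pooled-variance two-sample t-statistic
whose set term carries `VIF = 1 + (m−1)ρ`, on `G − 2` df. The pooled
variance is the classical within-group pooled variance (computed
stably from the overall variance and the mean difference), so at
`ρ = 0` the statistic is *exactly* the ordinary equal-variance
two-sample t. The default `ρ = 0.01` is the conventional prior
inter-feature correlation for this family of tests; `ρ` only ever
attenuates significance (|T| is monotonically decreasing in ρ).

## Motif classification

Windows are 15 residues centered on the phosphosite (0-based index 7).
Tiers, all case-insensitive:

| tier    | −5 (idx 2) | −3 (idx 4) | 0 (idx 7) | +4 (idx 11) |
|---------|------------|------------|-----------|-------------|
| strict  | I/V/L/M    | R/K        | S/T       | I/F/L/M     |
| relaxed | —          | R/K        | S/T       | I/F/L/M     |
| minimal | —          | R/K        | S/T       | —           |

so strict ⊂ relaxed ⊂ minimal by construction. The minimal tier is
interpreted as *only* the basic residue at −3 plus the S/T center
(the published pattern string for the minimal tier is shorter than the
window; we apply it at the same −3/0 offsets). Windows extending past a
protein terminus are padded with `_`, and the padding character fails
every positional criterion — a site too close to the terminus cannot
satisfy a constraint at a position that does not exist. Sites with
ambiguous localization are classified once per reported site id.

The bundled 18-window reference panel (curated exercise-regulated
candidate AMPK substrates with published annotations) is the ground
truth for the scanner: re-classification reproduces all strict/relaxed
flags and the −5/−3/+4 residue columns, with tier counts 7 strict and
18 relaxed.

## Bioenergetics

ΔG\_ATP values for the CK-clamp states are fixed constants (computed
externally for 37 °C, 170 mM ionic strength, 5 mM creatine, 10 mM
phosphate, pH 7.1): −12.94 kcal/mol for maximal phosphorylating
respiration and −13.38 / −13.71 / −14.12 / −14.45 kcal/mol for the
1 / 2 / 4 / 6 mM PCr titrations. Unknown PCr levels are an error; no
interpolation. The cytochrome-c integrity check fails on a JO₂ rise
*strictly* greater than 15% (the boundary itself passes; boundary
semantics were unspecified, so the strict inequality is our choice).
Conductance is |slope| of the OLS fit of JO₂ on ΔG\_ATP over the four
titration states; including the maximal state is an explicit flag, off
by default since the titrations define the linear force–flow range.
Group comparisons of conductance use a two-sample t on per-subject
slopes, matching the study-level convention of t-tests, not a mixed
model.

## Cross-study overlap

Quadrants follow the convention q1 (+,+), q2 (−,+), q3 (−,−), q4 (+,−)
with the reference study on the x-axis; exactly-zero effects are left
unclassified rather than arbitrarily signed. Signature intersections
optionally require per-study significance flags (caller-supplied, since
external studies define significance differently) and sign concordance.
Identifier matching is by case-normalized symbol only; no ortholog
mapping.

## Synthetic data: what it emulates, and what it does not

The omics generator reproduces the *statistical* structure the
inference relies on: per-sex plexes of 18 samples, additive log2
effects planted per cell, feature variances drawn from a scaled
inverse-chi-square prior `s0²·d0/χ²(d0)` (defaults d0 = 4,
s0² = 0.09 — a typical shrinkage target for well-replicated TMT data;
baseline log2 intensity 20 ± 2), optional per-sample variance
inflation, and missingness applied at the whole-feature-within-sex
level (the filtering rule operates per sex, so cellwise missingness
would never be observed downstream). It does **not** simulate reporter
ion interference, retention-time structure, mean–variance trends
(optional flag only), non-Gaussian noise, or correlated features —
passing tests therefore demonstrate correctness of the inference
machinery under its own assumptions, not robustness to every real-data
pathology.

Window generation is constructive: the four class counts are allocated
exactly (largest-remainder rounding) and each window is verified
against the classifier at generation time, so class counts are exact
rather than stochastic. Set-family generation draws each family from a
disjoint slice of the universe; near-duplicates swap `jitter` members,
giving hub–variant Jaccard `(s − j)/(s + j)`, and the hub's shorter
description makes it the intended representative under the cascade.
Respirometry traces are linear in ΔG\_ATP with i.i.d. Gaussian noise
and JO₂ floored at zero.

## Problem sizes and determinism

The test suite and the reference analyses use 2000-feature experiments
(the scale at which the moment-matching estimator is stable to within
±25% on d0), 1000-set null calibrations, and 500-replicate Monte-Carlo
checks for the respirometry fit — sizes chosen so every statistical
property is measured with comfortable margins while the whole suite
runs in seconds. All generators are deterministic under a fixed seed
(identical seed ⇒ bit-identical output), and the pipeline manifest
records seed, parameters and package version for every run.

## Known limitations

* The sample-weight scheme is a fixed-point heuristic, not REML; it
  matches the qualitative contract (monotone down-weighting of noisy
  samples, geometric mean 1) but not any particular reference
  implementation bit for bit.
* The robust moderation excludes outliers instead of modelling them
  with a heavier-tailed prior; per-feature robust df are not produced.
* CAMERA-PR is the parametric variant only; rank-based and
  permutation/self-contained tests are out of scope.
* The Jaccard cutoff (0.85) and ρ (0.01) defaults are conventional, not
  fitted; conclusions sensitive to them should be checked across a
  grid.
* Quadrant/intersection analyses assume shared gene symbols; human–
  mouse comparisons beyond symbol matching need external ortholog maps.
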