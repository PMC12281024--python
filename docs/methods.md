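# Methods

This note documents the models and numerical choices behind `dietlink`:
what each stage assumes, which parameters matter, what the synthetic
studies do and do not emulate, and where the design was genuinely open.

## Curation model

The curation chain assumes a MOTU × PCR-replicate table of non-negative
integer read counts with a replicate→sample map, and per-MOTU metadata
(sequence length, dataset-wide read total, best reference-database
identity, family, functional group).

**Basic filter.** MOTUs with sequence length < 10 bp or ≤ 10 reads in
the whole dataset are removed before any sample-wise computation. Both
boundaries are sharp: a 10 bp sequence survives, a 10-read MOTU does
not.

**Replicate-outlier filter.** The statistic contrasts within-sample
against between-sample variation. Replicate profiles are converted to
read proportions (so replicates of different depth are comparable — the
scale the method needs, though raw-count and transformed variants are
conceivable), each sample's current replicates are averaged, and

- *dw* = Euclidean distance of each replicate's proportion vector to
  its own sample average,
- *db* = all pairwise Euclidean distances between sample averages.

A functional PCR replicate should satisfy dw ≪ db. The removal
threshold is the crossing point of the two distance densities, each
smoothed with a Gaussian kernel using **one shared Silverman bandwidth
computed on the pooled dw ∪ db values**, searched between the two
distribution means; if either set is numerically constant or no
crossing exists there, the midpoint of the means is used. The shared
bandwidth matters: when the clean replicates are nearly identical
(deep sequencing of a fixed composition), a per-set bandwidth turns the
dw density into a needle whose crossing lands on its own tail and
removes good replicates; with the pooled bandwidth the crossing behaves
like a decision boundary between the two clusters (false removals drop
from ~9% to <1% on synthetic studies at no cost in sensitivity).

Per iteration, **at most the worst flagged replicate per sample** is
removed (ties keep the earlier column). A failed replicate contaminates
its own sample average and inflates its siblings' dw; removing
everything above threshold at once would discard those siblings, while
worst-only removal lets the next iteration's recomputed average clear
them. The loop runs until no replicate is removed (hard cap: the total
replicate count; strict shrinkage guarantees termination) and is
idempotent on its own output. Only after convergence are samples with a
single surviving replicate dropped. Every removal is recorded with its
iteration and dw value. Removal uses strictly-greater-than the
threshold, so exact ties are kept (conservative).

**Averaging and RRA.** Surviving replicates are normalised to
proportions first and then averaged unweighted, so a replicate's
sequencing depth carries no weight. The result is the per-sample
relative read abundance (RRA) profile; rows sum to one.

**Abundance/identity filter.** A MOTU is kept iff its *maximum* RRA
over samples is ≥ 1% **and** its best identity is ≥ 94%. The ≥-1%-
somewhere reading resolves the inherent ambiguity of "below 1% in at
least one sample" (read literally, that would discard any MOTU ever
rare, i.e., almost everything); discard-unless-it-ever-matters is the
conventional interpretation. Rows are renormalised afterwards and the
discarded mass per sample is logged, so the un-renormalised profile is
recoverable.

**Aggregation** sums RRA within families or functional groups
(lexicographic group order); row sums are conserved to floating
tolerance.

## Diversity

Hill numbers are evaluated in the log domain
(`exp(logsumexp(q·log p)/(1−q))`), which keeps orders near q = 1 stable;
q = 1 itself uses the exponential-of-Shannon limit. Zero categories are
ignored; counts are normalised internally.

Chao1 uses `S_obs + F1²/(2 F2)` and the bias-corrected
`S_obs + F1(F1−1)/(2(F2+1))` when no doubleton exists (avoids the 0/0
and is the standard small-sample form). It requires integer counts;
common-scaled tables are therefore rounded half-to-even by default
(an unrounded variant is available via `round_counts=False` for
sensitivity checks). Whether Chao1 should see scaled-then-rounded or
raw counts is a genuinely open choice; the pipeline computes it on the
rounded common-scaled table so that all samples share one depth.

Common scaling multiplies each sample by (minimum depth / own depth);
the minimum-depth sample is returned bit-identical, and rounded depths
stay within 0.5 × (number of ASVs) of the target.

The arcsine transform is the variance-stabilising `arcsin(√p)` (the
square root is included; the transform without it has no stabilising
rationale for proportions).

## Association statistics

All permutation p-values use `(b + 1)/(m + 1)` with the observed
statistic counted — never exactly zero, standard practice.

**Bray–Curtis** is `Σ|x−y|/Σ(x+y)` on non-negative profiles; the matrix
is explicitly symmetrised against floating asymmetry and validated
(zero diagonal, entries in [0, 1] for non-negative input).

**Mantel** correlates the lower-triangle entries of two distance
matrices (Pearson, or Spearman with average-rank ties) and permutes the
rows/columns of the second matrix jointly; the test is one-sided
(upper tail). With n = 5 the Monte-Carlo p-value agrees with exhaustive
enumeration of the 120 label permutations to Monte-Carlo error.

**Sequential PERMANOVA.** Squared distances are Gower-centred,
`G = −½ J (D∘D) J`. Terms enter in the caller's stated order; each
term's sum of squares is `tr((H_k − H_{k−1}) G)` for hat matrices of the
cumulative design (intercept first; categorical terms as full dummy
codings with first-level reference, so term df = number of dummies).
Pseudo-F is `(SS_term/df_term)/(SS_resid/df_resid)`; R² is
`SS_term/SS_total`, and term + residual R² sum to one by construction.
Significance uses free permutation of sample labels (the named tool's
default; restricted/residual permutation schemes are a documented
difference risk), recomputing the full sequential table per
permutation. On Euclidean distances of a one-dimensional embedding the
pseudo-F equals the classical one-way ANOVA F exactly, and the full
sequential table matches an independent vegan `adonis2(by = "terms")`
run frozen into the test suite. Rank-deficient cumulative designs are
rejected with the offending term named.

**Standardised OLS and paths.** Continuous variables are z-scored
(n−1 denominator); dummies stay 0/1. The fit itself is ordinary least
squares (statsmodels); partial correlations come from the
t-statistics, `r = t/√(t² + df_resid)`, sign-matched. The path
decomposition fits `diversity ~ Salix [+ adjusters]` (coefficient *a*)
and `mass ~ Salix + diversity [+ adjusters]` (*c′* and *b*); the
indirect effect is the product `a·b` and the total `c′ + a·b`, both
exact identities of the result object. This is a two-equation piecewise
formulation on z-scored variables; it deliberately omits random
intercepts (a year-level random effect belongs to the body-mass model
family that is out of scope here) and fits no Salix × lactation
interaction.

## Synthetic studies

The generator emulates the sampled design of the survey the package is
built around: 97 females across 4 valleys × 7 years (13 cells of 4 and
15 cells of 3 animals), triplicate PCR, 39 diet MOTUs in 14 families
and 8 functional groups, ~60k reads per diet replicate, a 300-ASV
microbiome at ~45k reads, half the animals lactating, ages 2–13.

- **Diet.** Valley mean *Salix* fractions are 0.245/0.468/0.745/0.915
  (Eskerdalen/Sassendalen/Colesdalen/Semmeldalen); the annual NDVI
  series (mean 0.226, sd 0.044, rising, with the warm first summer
  second-lowest) shifts the *Salix* mean on the logit scale
  (slope 0.5), and the July-temperature series (mean 6.93 °C, sd 0.8,
  trendless) shifts the grass mean (base 0.045, slope 0.4).
  Compositions are hierarchical: family fractions are Dirichlet draws
  around the cell mean with concentration 8 (strong individual
  variation), within-family MOTU ratios are Dirichlet draws around a
  0.75-decay profile with concentration 60 (stable ratios). The
  hierarchy is what lets every genuine MOTU clear the 1%-RRA rule
  somewhere in a ~97-animal study — as the survey's MOTU set, which is
  by construction the post-filter survivor set, did.
- **Replicates.** Multinomial reads of the animal's true composition at
  a depth ~ Normal(60k, 20%). With probability 0.10 a replicate is a
  planted failed PCR: multinomial reads of an unrelated sparse
  symmetric Dirichlet (concentration 0.15) composition. Sparse matters:
  near-uniform junk compositions resemble *each other*, so two failures
  in one sample would mimic a consistent sample and be undetectable in
  principle; spiky junk (closer to real failed reactions) keeps the
  planted truth unambiguous.
- **Artefact MOTUs** (6 by default) cycle through four defect types —
  8 bp but abundant; ≤ 10 reads dataset-wide; 0.90 identity but
  abundant; well-sequenced but never reaching 1% RRA — each registered
  with the pipeline rule that should catch it (in pipeline order: a
  ≤ 10-read MOTU is necessarily also sub-1%, but the basic filter sees
  it first).
- **Microbiome.** A latent diversity `div = a·z(Salix) + √(1−a²)·ε`
  sets the mixing weight `w = 0.5 + 0.17·div` (clipped to [0.02, 0.98])
  between an even and an uneven community archetype; per-sample
  compositions are Dirichlet draws (concentration 2000) around the
  mixture, additionally tilted by fixed per-ASV log-fold responses to
  z(Salix) (scale 0.3) — taxa that wax and wane with *Salix* intake.
  The tilt is essential for realism: coupling through the single
  diversity scalar alone yields Mantel r ≈ 0.1 (distance correlations
  roughly square the variable-level correlation), i.e., no detectable
  diet–microbiome association; with it, default studies give Mantel
  r ≈ 0.2–0.4 and clearly significant sequential-PERMANOVA *Salix*
  terms, matching the kind of signal the emulated survey reported.
- **Body mass (kg).** `49 + valley offset + 1.6·(age−2) − 0.13·(age−2)²
  + 5·(c′·z(Salix) + 0.1·z(Salix)·lactating + b·div + 0.9·ε)` with
  defaults a = 0.3, b = −0.25, c′ = 0.4. The quadratic age curve
  (peaking near 8 years) stands in for a spline; the lactation
  interaction reflects that reproductive females benefit more from
  *Salix*.
- **Randomness.** One seed per study, split into fixed named
  sub-streams (design, diet, replicates, outliers, artefacts,
  microbiome, host), so adding a stage never perturbs earlier draws and
  identical configs are byte-identical.

**Recovery configuration.** Structural-coefficient recovery simulations
use n = 96 (4 valleys × 6 years × 4), no planted defects, no
compositional Salix tilt, and a stripped mass model: zero valley
offsets, zero age effect, zero lactation interaction, mass scale 1 and
residual sd solved so that var(mass) = 1. Standardised coefficients are
only recoverable as stated when the mass variance is dominated by the
structural equation; the full-study defaults deliberately violate that
(valley and age structure), in which case naive standardised estimates
shrink — exactly as they would in a real observational analysis. The
recovery setup therefore validates the estimator under the path model's
own assumptions, not the full observational confounding problem.

**What passing tests do and do not show.** The generator produces
multinomial/Dirichlet count noise, planted defects with clean labels,
and a microbiome coupled to diet through two known channels. It does
not simulate reads (no chimeras, tag jumps, index hopping or
contamination gradients), PCR amplification bias, taxonomic
mis-assignment, phylogenetic structure among ASVs, or temporal
autocorrelation beyond the NDVI/temperature series. Recovery results
therefore certify the algorithms against their own generative
assumptions, not the full messiness of wet-lab data.

## Problem sizes and tolerances

Simulation-based checks use: 50 studies for replicate-filter recovery
(sensitivity ≥ 0.9, false removal ≤ 0.05, scored on the filter's kept
table — a replicate counts as removed whether the dw rule or the
single-replicate sample drop eliminated it); 200 studies of n = 96 for
path recovery (mean estimates within ±0.05 of truth); 500 null runs of
999 permutations at n = 30 for type-I calibration (rejection at
α = 0.05 inside [0.03, 0.07]). Row-sum and symmetry checks use 1e-9 to
1e-12; oracle equivalences (ANOVA-F, vegan sequential table, scipy
distances, normal equations) hold to 1e-4 or better. Iteration caps,
tie handling and degenerate-input behaviour (constant distance sets,
zero-read replicates, all-zero samples, rank-deficient designs) are
described above and exercised in the unit tests.

## Known limitations

- The density-intersection threshold depends on kernel smoothing; very
  small studies (few samples) fall back to the midpoint rule, which is
  cruder.
- Free permutation in PERMANOVA ignores any restriction structure
  (e.g., permuting only within valleys); with strong spatial blocking
  the *Salix* p-values can be liberal.
- The path decomposition is two OLS equations; no random effects,
  no interaction terms, no measurement-error correction for diversity
  (measured Shannon attenuates |b| by a percent or two relative to the
  latent diversity in the generator's own terms).
- `spike_artefacts` perturbs replicate depths slightly (spiked reads
  are added on top) — negligible at the defaults but not exactly
  depth-preserving.
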