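# Methods

This note documents the models, parameter defaults and design choices behind
`atroprot`, and what the synthetic-data tests do and do not demonstrate about
real data.

## Study design being modelled

A unilateral denervation experiment in mouse: each animal supplies a control
and a denervated gastrocnemius. Protein expression is measured at days 1, 4,
7 and 14 post-denervation in biological triplicate against a common, fully
¹³C₆-lysine-labelled spike-in standard mixed 1:1 into every light sample.
Protein synthesis is measured by switching animals to the heavy-lysine diet
at denervation and sampling after 4, 7 or 11 days of labelling.
Ubiquitination is read out as diglycine-remnant (K-ε-GG) sites quantified as
den/ctrl log2 ratios per time point and replicate.

## Spike-in quantification

Because the heavy standard is identical in all samples, per-sample
log2(L/H) values are directly comparable and the den/ctrl fold change is
their difference; any protein-specific property of the standard cancels
exactly (tested as an invariance property). Sample loading differences are
removed by subtracting each sample's median log2(L/H) over its quantified
proteins; the offsets are reported in the run manifest. H/L ratios supported
by fewer than two peptide ratio measurements are treated as missing
(idempotent masking, applied on read). Replicates are paired by index for
the ratio of ratios, matching the within-animal control/denervated design.

## Moderated statistic and permutation FDR

The test statistic is `d = effect / (se + S0)` with the pooled two-sample
standard error (or `sd/sqrt(n)` for one-sample tests against zero) and fudge
factor `S0 = 0.1` (default). S0 bounds the influence of tiny variance
estimates; `|d| <= |t|` always, and `|d|` is non-increasing in S0.

FDR estimation: for a candidate cutoff θ,
`FDR(θ) = median_perms #{|d_perm| >= θ} / max(1, #{|d_obs| >= θ})`,
with group-label permutations for two-sample tests and sign flips for
one-sample tests, π₀ fixed at 1 (conservative Tusher-style estimate). The
significant set is the largest set whose estimated FDR is at or below the
target (0.05 default); ties in |d| at the cutoff are included. When the
permutation space has at most `n_perm` (default 250) elements it is
enumerated exhaustively, identity included — for 3 vs 3 this is all
C(6,3) = 20 label splits — and the implementation is tested for exact
agreement with an independent plain-loop brute force. With π₀ = 1 and the
median false count, the procedure is conservative; the widely used desktop
implementation it mirrors does not publish its exact internals, so exactness
is claimed only against the brute force, not against that tool.

Features are tested only with ≥2 valid replicate values per group; there is
no imputation. The Storey q-value companion estimates π₀ from
`#{p > λ}/(m(1−λ))` on λ = 0.05…0.95 with a cubic smoother evaluated at
λ = 0.95, falling back to π₀ = 1 below 100 p-values, and applies the usual
step-up `q_(i) = min_{j≥i} π₀ m p_(j)/j`.

## Label incorporation

The labelled fraction is `f = (H/L)/(H/L+1)`. Synthesis over the pulse is
summarized by the trapezoidal AUC of `f(t)` in fraction·days; the origin
(0, 0) is prepended by default (`anchor_zero`) since no label is present
before the diet switch — exposed as a flag because either convention is
defensible. Differential synthesis is tested per time point on
`log2[(H/L)_den/(H/L)_ctrl]` (one-sample moderated test), not on fractions:
the log ratio is approximately normal and condition-symmetric. Storey
q-values are computed from the plain-t p-values per time point. Proteins
observed at fewer than two pulse time points get no AUC but remain in
per-time tests. With triplicates throughout, the generator is slightly more
powered than a day-4 duplicate design; per-time results at n = 2 should be
read as low-powered.

`fit_one_pool_rate` fits `f(t) = 1 − e^(−kt)` on the linearized form
`−ln(1−f) = kt` through the origin. This is a validation utility for the
generator's kinetics — the analysis itself derives no absolute turnover
rates, because converting incorporation into absolute rates would require
correcting for the precursor-pool relative isotope abundance, which is out
of scope.

## Synthetic data generator

The generator is the test bed: it produces expression, pulse and site tables
with the statistical structure the analysis assumes, plus the ground truth
to score against.

* **Expression.** Heavy intensity per protein constant across samples
  (spike-in); light `L = A_p · 2^(δ_p(t)·[denervated] + ε)`,
  `ε ~ N(0, σ)` on the log2 scale (multiplicative lognormal on intensity,
  hence additive on log-ratio). δ_p(t) is zero for unregulated proteins and
  an archetype template scaled by `effect_log2` otherwise.
* **Archetypes.** Six piecewise-linear templates anchored at days 1/4/7/14:
  step, ramp and peak-and-return shapes in both directions. Because the
  clustering pipeline z-scores each profile, only profile *shape* is
  identifiable: a constant-offset-down template is congruent after z-scoring
  to the step-down template, so the sixth default archetype is
  transient-down rather than constant-down; custom templates (including
  constant profiles) can be supplied.
* **Defaults as study conditions.** 1000 proteins, triplicates, 20%
  regulated, `effect_log2 = 1` (typical significant fold changes in this
  tissue run ~1.5–6-fold), `σ = 0.33`. The noise default was calibrated so
  that roughly 10–40% of regulated proteins reach significance at n = 3
  (measured ≈32% on average across seeds, any-time-point call) — a
  deliberately marginal-power regime mimicking the real experiment, where a
  single day's volcano yields a minority of the truly changing proteome.
* **Pulse.** One-pool exponential incorporation; per-protein control rate
  `k ~ 0.05/day × lognormal(0, 0.4)` (median half-life ≈ 2 weeks, a
  realistic bulk-muscle figure); denervated rate `γ·k` with `γ =
  rate_shift_factor` (default 2) for a `frac_rate_shifted` subset (default
  5%, chosen independently of the expression-regulated set so that
  "stabilized" proteins — expression up, synthesis unchanged — exist).
* **Sites.** Sites-per-protein `1 + Poisson(mean−1)` with mean 3.5 (matching
  the observed ~2300 sites on ~670 proteins); site log2 ratio =
  protein δ_p(t) + occupancy shift u_j + noise, with `u_j = ±1.5` log2 units
  for a 15% regulated-site fraction.
* **Annotations.** Null terms with random membership plus planted terms
  drawn from truly up-/down-regulated proteins at configurable purity.

One seed fully determines all outputs; in noise-free mode (σ = 0 and no
ratio-count dropout) downstream point estimates recover the ground truth to
machine precision, which the acceptance suite asserts at 1e−12.

What the generator does **not** model: peptide-level missingness mechanisms
beyond ratio-count masking, fibre-type mixtures, shared-precursor recycling,
batch effects, and intensity-dependent variance. Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
robustness to every real-data pathology.

## Clustering

Profiles are z-scored per protein (population SD; rows with missing time
points or zero variance are dropped, not imputed). Fuzzy c-means uses
Euclidean distance, random data-row initialization with 10 seeded restarts
(best final objective kept), `tol = 1e-6`, `max_iter = 1000`. The fuzzifier
default is the Schwämmle–Jensen estimate
`m = 1 + (1418/n + 22.05)d⁻² + (12.33/n + 0.243)d^(−0.0406 ln n − 0.1134)`;
at the scale of the full real data set (thousands of proteins, four time
points) it evaluates to ≈2.54, the reference configuration value, while on
smaller synthetic sets it is larger (≈2.85 at n = 300) — the estimate is
recorded in the manifest rather than forced. Hard labels are argmax
membership above `min_membership` (ties to the lowest cluster index). The
archetype-recovery test runs at replicate-averaged profile noise ≈0.12 log2
units (σ = 0.2, triplicates), chosen as clearly-clustered input typical of
averaged triplicates of strongly regulated proteins: the test validates the
clustering algorithm, not power at the detection margin.

## Annotation enrichment

Per term, members vs non-members by two-sided Mann–Whitney U on the
per-protein values (the per-time mean profile value when run over a time
course); score `s = 2U/(n_in·n_out) − 1` is the rank-biserial correlation,
bounded in [−1, 1], invariant under monotone transforms and antisymmetric
under value negation. Benjamini–Hochberg across terms; `min_size = 10`.

## Atrogene-likeness scoring

"Shuffling the complete data set" is implemented as column-wise independent
resampling: each negative example draws its value at every time point from
that column's empirical distribution, preserving per-time marginals while
destroying exactly the temporal correlation the classifier must learn (a
row-permutation variant is available behind a flag). Per repeat and class,
fresh negatives are drawn (as many as positives), mtry is tuned over
1…n_features by stratified k-fold Cohen's kappa at the 0.5 vote threshold,
and a 500-tree forest is trained one-vs-negatives; probabilities are
averaged over 50 repeats (defaults). Features are the log2(den/ctrl) values
at the four expression days; proteins with ≥3 observed days are scored after
nearest-value filling of the gap. Candidates require an averaged probability
strictly above 0.7. Both the in-sample training-exemplar average (the
conventional summary) and an out-of-fold estimate
(`oof_training_scores`) are available, since in-sample averages are
optimistic. Tests and the acceptance script run reduced ensembles
(5–10 repeats, 60–100 trees, 3 folds) as their chosen problem sizes; the
recovery margins are large (recall/precision ≈0.95 against the 0.8/0.6
assertions), so the reduction does not change conclusions.

## Ubiquitination sites

Site ratios are normalized by subtracting the protein's replicate-mean log2
ratio at the matched time point — not replicate-paired, because site and
protein measurements come from different digestion workflows. The regulated
flag requires permutation-FDR significance AND |fold change| > 1.5; the fold
criterion applies to the raw site ratio, with the normalized value reported
alongside (both raw and normalized testing modes are provided, since either
could underlie a reported volcano). The positional statistic is a one-sided
Mann–Whitney on relative positions (regulated sites closer to the
C-terminus) with a signed rank-biserial effect size — rank-based because the
qualitative claim being quantified (proteolysis progressing from the M-band
C-terminus) implies no particular functional form.

## Integration and QC

Sectors cross expression state (down/unchanged/up, by the permutation-FDR
call and effect sign) with incorporation state (per-time q < 0.05 call);
"unchanged" is a significance call, not an effect-size band, because both
axes are the same log2 ratios tested upstream. The sector index is row-major
(expression slowest), so expression-up/incorporation-unchanged — the
stabilization signature — is sector 8. QC computes pairwise Pearson
correlations on complete pairs, average-linkage clustering of the Euclidean
distances between correlation rows, and PCA of samples on mean-centred
complete protein rows (no variance scaling, complete-case only).

## Determinism and numerics

All randomness flows from one master seed through named `SeedSequence`
spawns (stage seeds, per-repeat forest seeds, restart seeds). Result TSVs
have deterministic column order, and the JSON manifest (parameters, seed,
package versions) contains no timestamp, so identical configurations produce
byte-identical output directories — asserted in the test suite. Degenerate
cases are defined explicitly: a point coinciding with a centroid takes full
membership; features with <2 valid replicates are "not testable" (NaN, never
an exception); an empty significant set yields an infinite cutoff; zero-rate
kinetics fit to k = 0.

## Known limitations

* The FDR procedure approximates the desktop tool's
  permutation FDR; internals may differ (π₀ handling, tie conventions).
* The one-pool incorporation model ignores precursor-pool recycling; rate
  constants are relative validation quantities, not absolute half-lives.
* Archetype templates are stylized; real cluster shapes are data-driven.
* The feature vector for the forest (four log2 ratios) is the minimal choice
  consistent with time-profile scoring; richer features (significance,
  AUCs) were not explored.
* Headline counts from any real experiment (numbers of quantified
  proteins, sites, candidates) depend on that MS data set and are not
  reproduced here; the package validates the methods on synthetic
  ground truth instead.
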