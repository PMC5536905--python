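# atroprot

Integrated quantitative proteomics of denervation-induced skeletal-muscle
atrophy: spike-in SILAC protein quantification, pulsed-SILAC protein-synthesis
analysis, permutation-FDR differential statistics, fuzzy time-profile
clustering, 1D annotation enrichment, diglycine-remnant (ubiquitination) site
analysis, expression-vs-synthesis integration, and random-forest
"atrogene-likeness" scoring — exercised end-to-end on synthetic studies with
known ground truth.

## Who this is for

Proteomics analysts working with MaxQuant-style SILAC output who want a
tested, scriptable re-implementation of the denervation-atrophy analysis
workflow: unilateral sciatic nerve section in mouse, gastrocnemius sampled at
days 1/4/7/14 (expression) against a fully ¹³C₆-lysine-labelled spike-in
standard, a Lys6 diet pulse of 4/7/11 days (synthesis), and K-ε-GG
immunoaffinity enrichment (ubiquitination sites).

## The core quantities

* **Spike-in ratio of ratios.** Every light sample is mixed 1:1 with the same
  heavy standard, so for protein *p* the den/ctrl fold change is
  `log2(L_den/H) − log2(L_ctrl/H)` — the standard cancels. H/L ratios with
  fewer than 2 peptide ratio counts are discarded; per-sample log2(L/H) is
  median-centred.
* **Moderated test with permutation FDR.** SAM-style statistic
  `d = Δ / (se + S0)` with fudge factor `S0 = 0.1`; the FDR of a cutoff θ is
  the median over label permutations (sign flips for one-sample tests) of
  `#{|d_perm| ≥ θ} / #{|d_obs| ≥ θ}`, π₀ fixed at 1; target FDR 0.05.
* **Label incorporation.** Labelled fraction `f = (H/L)/(H/L + 1)`; synthesis
  summarized by the trapezoidal AUC of `f(t)` (anchored at the origin); the
  synthetic generator uses one-pool kinetics `f(t) = 1 − e^(−kt)`.
* **Soft clustering.** z-scored profiles, fuzzy c-means with `c = 6` and the
  data-estimated fuzzifier `m` (Schwämmle–Jensen rule; ≈2.54 at the scale of
  a full muscle proteome with four time points).
* **1D enrichment.** Per term, rank-biserial score
  `s = 2U/(n_in·n_out) − 1 ∈ [−1, 1]` from a two-sided Mann–Whitney U,
  BH-adjusted across terms.
* **Atrogene scoring.** Two curated classes (up / down upon denervation) are
  each discriminated from shuffled negatives (column-wise resampling of the
  profile matrix) by 50 random forests with mtry tuned on Cohen's kappa;
  averaged probabilities give the Delta Score `Δ = P(Class1) − P(Class2)`,
  candidates require `P > 0.7`.
* **Ubiquitination sites.** Site log2 ratios normalized by subtracting the
  protein-level ratio at the matched time; regulated sites need FDR
  significance *and* fold change > 1.5; a rank test quantifies C-terminal
  (N→C) positional gradients of regulated sites.
* **Integration.** 3×3 sectors of expression state × incorporation state;
  expression-up with unchanged incorporation (sector 8) marks protein
  *stabilization*.

## Worked example

```sh
atroprot demo --seed 1 --out demo_out
```

runs the full pipeline on a small synthetic study (300 proteins, triplicates)
and writes TSVs plus `manifest.json` to `demo_out/`. In Python:

```python
from atroprot import quant, stats
from atroprot.synthetic import GeneratorConfig, generate_expression_study

cfg = GeneratorConfig(n_proteins=1000, seed=3)
table, design, truth = generate_expression_study(cfg)
norm = quant.normalize_sample_ratios(table)
day7 = design.subset(time_day=7.0)
res = stats.permutation_fdr(norm.log2_lh[day7.sample_ids],
                            labels=day7.frame["condition"].to_numpy(),
                            groups=("denervated", "control"),
                            s0=0.1, target_fdr=0.05, seed=3)
sig = res.table["significant"]
print(f"significant: {int(sig.sum())} of {len(sig)}")
print(f"|d| cutoff:  {res.fdr_threshold_stat:.2f}")
print(f"true positives: {int((sig & truth.proteins['regulated']).sum())}")
```

prints

```
significant: 27 of 1000
|d| cutoff:  3.59
true positives: 27
```

i.e. at the day-7 time point 27 proteins exceed the moderated-statistic
cutoff that the permutation procedure estimates for a 5% false-discovery
rate, and all 27 are truly regulated in the generator's ground truth. The
defaults deliberately encode a marginal-power regime — ~20% of proteins on
regulated time-profiles at |log2 FC| = 1 under replicate noise calibrated so
that only a minority of them are detectable at n = 3 — so the discovery
count varies noticeably between seeds (some give none at a single day).

## Command-line interface

`atroprot` exposes `demo`, `generate`, `run-all` and per-stage subcommands
(`quantify`, `test`, `cluster`, `enrich`, `rf-score`, `sites`, `integrate`);
`--config` takes a YAML file mirroring `atroprot.pipeline.PipelineConfig`,
and CLI flags override config keys. See `docs/methods.md` for the models,
parameter defaults and design choices.
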