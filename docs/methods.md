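# Methods

This note records the models, conventions and numerical choices behind
the package, and what the synthetic generator does and does not emulate.

## Trial design and reference data

The reference input (`table1.py`) is the published table of group means
and standard errors from a two-year, four-treatment, three-replicate
field trial: a pure chemical fertilizer control (NPK) against 50 %
substitution of fertilizer N by composted cow (CM), pig (PM) or sheep
(SM) manure at equal total N-P₂O₅-K₂O rates (225/135/112.5 kg ha⁻¹).
Sixteen measured variables are carried: ten physicochemical indicators
(pH, total porosity SP, totals TC/TN/TP/TK, available NH₄⁺/NO₃⁻/AP/AK)
and six enzyme activities (CAT, INV, NAG, URE, ALP, GLS). Units follow
the published conventions (g kg⁻¹, mg kg⁻¹, U g⁻¹); whether enzyme
activity is per dry or fresh soil is not recorded upstream, so units
are carried opaquely.

## Soil quality index

The total-dataset method: each indicator is linearly scored over a pool
of samples, `S = (x − L)/(H − L)` for more-is-better indicators (the
mirror image for less-is-better), and combined as

    SQI = 0.5 · Σ Sᵢ² · sin(2π/n).

This is the area of the radar polygon with the scores as spokes. Two
consequences are enforced rather than papered over: the formula is
degenerate for n ≤ 2 (`sin(2π/n) ≤ 0`), which raises an error, and its
maximum is `0.5·n·sin(2π/n)` (2.9389 at n = 10).

Choices:

- **Pool = per year** by default. The published per-year EMF treatment
  means sum to zero in both years, which pins the per-year
  standardization convention; SQI follows the same pooling for
  coherence. Both are configurable (`pool="global"`).
- **All ten indicators default to more-is-better, including pH.** On
  this alkaline soil the control has the highest pH and near-minimum
  everything else; only a positive pH contribution reproduces the
  published control SQI (≈ 0.3–0.36). Directions are configurable per
  indicator.
- **Constant indicator (H = L)**: scored 0.5 with a warning by default,
  or an error (`constant_policy="error"`).
- With only group means available, the four treatment means of a year
  act as the scoring pool. Absolute SQI then reproduces the published
  control value approximately (0.30 vs 0.36 printed) — whether the
  published values were computed on replicates or means is not stated —
  but fold changes between treatments are reproduced exactly from the
  printed SQI means.

## Ecological multifunctionality

EMF is the averaged z-score of the six enzyme activities: per function,
`z = (value − pool mean)/pool SD` with sample SD (ddof 1, appropriate
for n = 3 replicate groups), averaged per sample. Within each pool the
EMF values average to zero by construction. Zero-variance functions are
dropped with a warning. On the treatment-mean pool this reproduces the
published 2022 values (CM +0.318 → printed 0.32; NPK −1.180 → printed
−1.2 ± 0.15).

## Nitrogen use efficiency

`PFP_N = Y_T/F_N`, `AE_N = (Y_T − Y₀)/F_N`, F_N = 225 kg N ha⁻¹. The
trial has no unfertilized plot, so Y₀ is an explicit assumption
surfaced in the generator config (default 60 % of the control yield);
AE_N may be negative and satisfies `AE_N = PFP_N − Y₀/F_N`.

## Synthetic generator

What it emulates:

- **Soil variables**: independent truncated normals per (treatment,
  year) group, mean = published mean, SD = SE·√3 (the published
  dispersions are standard errors with n = 3), truncated at 0 for
  strictly positive quantities.
- **Yields**: NPK baseline 4200 kg ha⁻¹ (a typical foxtail-millet yield
  at 13 % moisture), CV 3 %, per-year treatment multipliers defaulting
  to the published pig-manure gains (+4.81 % in 2022, +7.87 % in 2023)
  with cow/sheep interpolated at 1/3 and 2/3 of that gain, preserving
  the reported PM > SM > CM > NPK order.
- **Communities**: Dirichlet-multinomial per sample. Treatments act at
  phylum rank via multiplicative concentration shifts (Proteobacteria
  up under CM; Bacteroidetes/Ascomycota up under PM; Acidobacteria,
  Chloroflexi, Basidiomycota, Thaumarchaeota up under the control);
  the species-within-phylum split is drawn once and shared by all
  treatments. A per-sample lognormal random effect at phylum rank
  (`phylum_sigma`, default SD 0.3) models environmental filtering and
  is what makes species of a phylum co-occur: without it, Dirichlet
  components are only weakly negatively correlated and co-occurrence
  networks are structurally empty. The network stage therefore uses a
  strongly-coupled profile (`network_community_config`: concentration
  500, phylum_sigma 1.0) and ten replicates per treatment rather than
  the field trial's three, since pairwise correlations are otherwise
  not estimable.

What it does not emulate: sequencing reads or their error structure,
functional-gene (KEGG/CAZy) profiles, taxa-soil feedbacks, spatial or
temporal autocorrelation between plots and years, and realistic
rank-abundance tails. Passing tests therefore demonstrate that the
analysis machinery is correct and calibrated under the configured
statistical structure — not that the biological conclusions would
replicate on the deposited sequence data.

Everything is deterministic under (config, seed); all randomness flows
through `numpy.random.default_rng`.

## Diversity, ordination, PERMANOVA

- Shannon in natural log by default (base configurable); Chao1
  bias-corrected `S + F₁(F₁−1)/(2(F₂+1))` by default, classic
  `S + F₁²/(2F₂)` selectable (falling back to bias-corrected when
  F₂ = 0).
- PCoA is classical scaling: Gower double-centering of squared
  distances, `eigh`, axes sorted by descending eigenvalue. Negative
  eigenvalues (expected for Bray-Curtis) are reported with a flag; no
  Lingoes/Cailliet correction. Proportions explained are relative to
  the positive-eigenvalue sum.
- PERMANOVA uses the standard partitioning of squared distances into
  among/within-group sums with pseudo-F, permutation p-value
  `(1 + #{F* ≥ F})/(1 + n_perm)`, a required seed, and an exhaustive
  mode that enumerates all label permutations for small designs. Note
  that permutations recreating the observed partition legitimately tie
  the observed F, so the attainable p floor depends on group sizes,
  not only on n_perm.

## Networks

Defaults follow the field-standard convention behind the common web
tools, which publish the abundance filters but not the edge rule:
Spearman |ρ| ≥ 0.6 with BH-FDR < 0.05, computed per treatment over
that treatment's samples. All thresholds are arguments. Constant taxa
are excluded (detected by exact value equality — a floating-point SD
test misses them). Module detection is seeded Louvain on absolute edge
weights (modularity is defined for non-negative weights; the sign is
kept as edge metadata). Zi uses the population SD (ddof 0) of
within-module degree, 0 when the spread is zero; Pi is
`1 − Σ (k_is/k_i)²`; thresholds 2.5/0.62 (the Guimerà-Amaral
convention). Average path length is computed over connected pairs only
and flagged when the graph is disconnected.

## Treatment statistics

- **Duncan's multiple range test**: critical ranges
  `R_p = q((1−α)^(p−1); p, df)·√(MSE/n)` from
  `scipy.stats.studentized_range` rather than digitized tables
  (validated against published table excerpts); harmonic mean n for
  unequal groups; letters by the standard insert-and-absorb sweep over
  descending means, with enclosing non-significant ranges protecting
  inner pairs. Zero within-group variance everywhere falls back to
  letters by exact equality.
- **Orthogonal contrasts** use the pooled ANOVA MSE with
  `t = Σc·mean / √(MSE·Σc²/n)` on N − g df.
- **Spearman grids** are BH-adjusted across the entire grid (not per
  row) — conservative, configurable; stars at 0.05/0.01/0.001/0.0001.
- **Variance partitioning**: Hellinger transform of the composition
  (standard for compositional responses), redundancy-analysis R² per
  predictor-group subset, Ezekiel adjustment, unique/shared fractions
  by Möbius inversion over subsets. Small negative fractions are
  reported as-is; with the adjustment, even exactly orthogonal groups
  yield a shared fraction of −1/(n−2), so exact zeros appear only with
  `adjust=False`.
- **Fold-change report**: organic/control mean ratios (differences for
  pH) per treatment and year, min-max ranges, rounded half away from
  zero to 2 decimals to match the printed style.

## Problem sizes

The calibration checks run 200 null simulations each (PERMANOVA on
12-sample communities with 99 permutations; edge-FDR on 20 × 30
independent lognormal tables), parameter recovery uses 200 generator
seeds and 100 community datasets, and the exhaustive PERMANOVA oracle
enumerates all 720 permutations of a 6-sample design — sizes chosen so
the full suite completes in a couple of minutes while the binomial 95 %
acceptance bands around the nominal rates remain tight.

## Known limitations

- The edge rule (correlation threshold, adjustment, pooling) used by
  the original web tools is unrecoverable; results depend on it.
- VPA fractions can be slightly negative by construction; they are not
  truncated.
- PCoA axes are sign- and rotation-ambiguous (compared via Procrustes
  in tests).
- Missing values are rejected rather than imputed (complete-case
  design).
- The pipeline regenerates all stages on each run; stage artifacts are
  inspectable on disk but no incremental-build graph is maintained.
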