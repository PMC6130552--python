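# Methods

## The analysis model

The package compares two groups of subjects, each carrying a functional and
a structural brain network on the same ordered set of N regions. All
inference is built for very small cohorts (the reference design is 4
subjects per group), which dictates the statistical machinery: permutation
tests with the `+1/(n+1)` finite-sample correction (exhaustive enumeration
of all C(8,4) = 70 label assignments when feasible), and ordinary linear
models only where a continuous covariate (network density) must be held
fixed.

Assumptions worth stating explicitly:

* **Edge semantics.** Functional edges are Fisher-z transformed Pearson
  correlations with negative values set to zero — the analysis treats
  positive-correlation networks only, because negative-correlation networks
  have qualitatively different topology. A zero therefore means "absent or
  anticorrelated", and functional networks are zero-inflated by
  construction. Structural edges are mean streamline FA where at least 3
  streamlines connect a pair (an inclusive "at least three" reading of the
  false-positive streamline threshold), max-scaled per subject so the
  strongest edge is 1 and zero still means "no edge" (an affine min-max
  scaling would assign weight 0 to the weakest *present* edge, conflating
  absence with weakness).
* **Exchangeability.** Group labels are exchangeable under the null; the
  permutation tests shuffle subject labels, never values within a subject,
  so the within-subject dependence of metric curves across densities is
  preserved.
* **Weight-to-length mapping.** Path-based metrics convert weights to
  lengths as 1/w. Weighted clustering uses the Onnela geometric-mean
  triangle formula on max-normalized weights. Both are conventional choices
  of the standard connectome toolboxes.

## Pipeline parameters

| parameter | default | meaning / rationale |
|---|---|---|
| density grid step | 0.01 | fraction of possible edges; reproduces conventional reporting densities (0.24, 0.34, 0.40, 0.50) as grid points |
| maximum density | 0.5 | above ~50% density binarized graph metrics saturate and false positives dominate |
| n_random | 20 | rewired nulls per network for λ, γ, σ normalization |
| n_perm | 2,000 | permutation iterations (two-tailed); exact enumeration used at 4v4 where only 70 assignments exist |
| min_streamlines | 3 | streamline count below which a structural edge is discarded |
| Fisher-z cap | \|r\| ≤ 1 − 1e−7 | keeps atanh finite for (near-)duplicated signals |
| Louvain restarts | 100 | best-of-restarts partition; greedy Louvain is order-dependent |
| NBS primary threshold | t = 3.0 | required, logged parameter; component inference is conditional on it |
| asymmetry tolerance | 1e−8 | matrices asymmetric beyond this are rejected, not silently repaired (catches transposed/truncated files); below it, averaged |

The minimum connection density is the smallest grid density at which every
subject's thresholded network forms a single connected component — computed
jointly over the cohort so all subjects are analysed on a common range.
The small-world range extends from there to the last density whose
group-mean σ exceeds 1 (a `--sw-rule all` variant requires every subject
to exceed 1), capped at 0.5. The AUC windows split this range at the first
density where the two group-mean σ curves cross; if they never cross, only
the full-range AUC is tested.

Proportional thresholding keeps the ⌊d·N(N−1)/2⌋ strongest edges with a
deterministic tie-break (weight descending, then lexicographic (i, j)), so
thresholded networks are nested across densities and identical across runs
and platforms.

## Small-world exclusion

Subjects whose network has σ ≤ 1 (strictly) are excluded before
single-density and weighted functional contrasts, mirroring standard
practice: comparing "small-world metrics" of a network that is not
small-world is not interpretable. The exclusion is applied to functional
analyses only; weighted structural networks are analysed in full. An
exclusion that empties a group is an error, not a silent degradation.

## Power-law machinery

Tail fitting follows the maximum-likelihood recipe: discrete (Hurwitz-zeta
normalization) for integer degrees of thresholded networks, continuous for
node strengths of weighted networks (the binary degree of a near-complete
weighted graph is degenerate at N−1). x_min is chosen among observed values
to minimize the KS distance, requiring ≥ 10 tail points. For tied discrete
data the KS distance compares step CDFs at unique values; the continuous
two-sided empirical envelope would be inflated by ties. Goodness of fit is
a semi-parametric bootstrap (resample below x_min from the data, above from
the fitted model, refit, compare KS; 1,000 resamples by default). The
exponentially truncated variant p(x) ∝ x^(−α) e^(−rate·x) is fitted by
direct likelihood optimization. The between-group comparison the package
offers is a label-permutation test on subject-level KS statistics — a
documented, reproducible surrogate for "comparing power-law fit", not a
claim about what any particular prior analysis did.

## The synthetic cohort generator

The generator exists so that every pipeline stage can be exercised, and its
statistical behaviour calibrated, without scan data.

**Structural.** Watts–Strogatz ring lattice, N = 32, k = 18 ring neighbors,
rewiring probability β per group (control default 0.1). k = 18 puts the
structural density near 0.52–0.55 so proportional thresholding across the
full 0.24–0.5 analysis range is meaningful. Present edges receive integer
streamline counts 3 + Poisson(7); 6% of true edges lose their streamlines
(tractography false negatives — this is what makes density vary across
subjects, so the density covariate in the weighted GLM has variance), and
5% of absent pairs receive 1–2 spurious streamlines that the 3-streamline
threshold must remove. FA-like weights are Beta(6, 4) (mean 0.6).

**Disease-like preset.** Two mechanisms, both exposed as per-group knobs:

1. *Higher rewiring* (β = 0.85 in the "large" preset vs 0.1): the
   proportionally thresholded binarized networks of the disease group are
   more random — lower normalized clustering γ, small-worldness σ and
   modularity Q across the upper density window.
2. *Weakened long-range weights* (×0.35 on edges whose ring distance
   exceeds k/2): weighted shortest paths must pay for shortcuts that the
   degree-preserving nulls, which shuffle the weight multiset onto rewired
   topology, get cheaply — so weighted λ is *higher* in the disease group.
   A weight manipulation whose placement is exchangeable under the null's
   weight shuffle (e.g. any i.i.d. rescaling, or one uncorrelated with
   topological position) cancels exactly in the λ normalization; weight–
   position correlation is the only lever that moves weighted λ. A
   within-module rescaling variant is also provided
   (`within_module_scale`), but it lowers rather than raises weighted λ
   (the rewiring shortcuts dominate), so the preset uses the long-range
   mechanism.

Edge density stays matched between groups by construction (rewiring
preserves edge count), isolating topology effects — which is precisely
what a density-covaried group model is meant to see.

**Functional.** A stable first-order diffusion recursion on the structural
graph, x_t = c·P x_(t−1) + ε_t with P the row-normalized structural
weights, c ∈ [0, 1) the per-group coupling (disease preset: 0.85 vs 0.45),
ε unit Gaussian, T = 450 volumes after a 50-step burn-in. Two
post-processing steps emulate what resting-state pipelines do and are
essential to the generator's statistical behaviour: a moving-average filter
(window 5 samples — the slow-fluctuation band at a 2 s sampling interval)
that converts lagged network covariance into zero-lag correlation, and
removal of the across-region mean at each timepoint (the analogue of
global/physiological component removal). Without the filter, sampling noise
at T = 450 swamps the planted structure–function signal; without the
demeaning, the recursion's shared global mode drives nearly every pairwise
correlation positive and functional networks become near-complete. With
both, functional connectome density is ≈ 0.36 and mean coupling r rises
monotonically (≈ 0.06 → 0.42) across c ∈ {0, 0.3, 0.6, 0.9}.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: hemodynamics (the diffusion recursion is not
a BOLD model), spatial embedding and geometric constraints on wiring,
scanner/physiological noise structure, subject-level covariates (age, sex),
and any disease biology beyond the three planted network effects. Tests
against this generator validate the *statistical machinery* (calibration,
power, determinism), not neuroscientific conclusions.

## Numerical choices and degenerate inputs

* Disconnected pairs are excluded (with a logged warning) from
  characteristic path length and contribute zero to efficiency; analyses at
  or above the minimum connection density avoid the branch, but rewired
  nulls of sparse graphs can be disconnected.
* Near-complete graphs cannot be rewired; nulls fall back to copies of the
  original with a warning (λ = γ = σ = 1, correctly signalling "no
  normalization information").
* Column-wise z-scoring of a single-entry column (N = 2) is defined as 0.
* Collinear predictors in the coupling regression are dropped with a
  warning, in fixed order; a constant density covariate in the GLM is
  dropped (its coefficient reported as 0) rather than fitted singularly.
* Coupling correlations are Fisher-z transformed before the group t test
  (raw-r comparison available). The t test is pooled-variance by default;
  Welch by flag.
* Search information and path transitivity on binary graphs depend on
  which of several tied shortest paths is followed; values are
  deterministic (fixed predecessor choice) but tie-dependent. On weighted
  graphs with continuous weights, ties have measure zero and the measures
  are oracle-exact.

## Known limitations

* **Edge-wise FDR at n = 4v4 is not calibrated.** On null synthetic
  cohorts the Benjamini–Hochberg procedure over parametric edge p-values
  rejects at ≈ 0.10 family-wise under the global null — the edge p's are
  marginally near-uniform (slightly conservative), but connectome edges are
  strongly positively dependent and two-sided, which breaks the BH
  global-null guarantee; a permutation-based edge-p variant is degenerate
  at 4v4 (the attainable p floor of 2/70 can never cross the BH threshold
  0.05/496, so it never rejects). This is a property of edge-wise FDR at
  this sample size, not of the implementation, and it is the reason
  component-level NBS — which calibrates correctly here — is the primary
  regional method. Findings from `fdr_edges` on cohorts this small should
  be treated as exploratory.
* The 4v4 permutation floor is p = 2/70 ≈ 0.029 two-tailed: no effect,
  however large, can reach p < 0.029, and "power" means the probability of
  complete group separation.
* Louvain is a heuristic; with 100 restarts on 32-node networks it
  recovers exhaustive-search partitions in testing, but optimality is not
  guaranteed.

## Problem sizes used by the test suite

The suite's simulation sizes are chosen to keep the default run fast while
retaining statistical resolution: oracle equivalence over 100 random graphs
of ≤ 8 nodes; type-I calibration over 200 null cohorts at n_perm = 200;
effect-recovery power over 60 cohorts at the large preset with the upper
window sampled at a 0.04 step and 3 Louvain restarts (power at these
settings: γ 0.90, σ 0.92, Q 0.92, weighted λ 0.97, coupling 1.00);
exponent recovery at n = 5,000 samples for α ∈ {2, 2.5, 3}. The end-to-end
pipeline test runs at full study settings (0.01 grid, 20 nulls, 2,000
permutations, 100 restarts).
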