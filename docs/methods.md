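# Methods

This note records the models implemented in `clinekit`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Geographic cline model

A cline describes a trait frequency along a one-dimensional transect. The
central segment is the logistic sigmoid `f(x) = 1/(1+exp(−4(x−c)/w))`, so
`w` (km) is the inverse of the maximum slope and `c` (km) is the position
of the 0.5 crossing. Beyond optional attachment points at `c − δ_L` and
`c + δ_R` the curve follows exponential introgression tails in the
Szymura–Barton parameterization used by hybrid-zone cline software:
for `x < c − δ_L`,

```
f(x) = g · exp( 4 τ_L (x − c + δ_L) / (w (1 + exp(−4 δ_L / w))) ),
g = 1 / (1 + exp(4 δ_L / w)),
```

mirrored on the right. The tail attaches continuously; its initial slope
is the fraction `τ ∈ (0, 1]` of the sigmoid slope at the attachment point,
so `τ = 1` is the C¹ limit of the family (the tail then matches the
sigmoid's value and derivative at the attachment, though it is not
pointwise identical to the sigmoid away from it — an inherent property of
the exponential form). With free scaling the observed frequency is
`p(x) = p_min + (p_max − p_min) f(x)`.

**Likelihood.** Per-deme counts `k_i` of `N_i` are binomial with
probability `p(x_i)` clamped to `[1e-9, 1 − 1e-9]`. Mean admixture
proportions are converted to effective allele counts
(`k = round(mean Q · 2n)`, round-half-even, out of `N = 2n`), mirroring
frequency-based cline machinery; a beta-precision likelihood was
considered and rejected as a default because the binomial version keeps
the AIC ladder comparable across nuclear and mtDNA series.

**Fitting.** Bounded multi-start maximum likelihood: stratified random
starts (centre uniform over the sampled range, width log-uniform, tails up
to half the span), L-BFGS-B followed by a Nelder–Mead polish, best final
log-likelihood wins. Default 50 starts; the experiments below use 6–10
starts, which reach the same optima on 25-deme series (doubling starts
changes the best log-likelihood by < 1e-6 in tests). Bounds: `c` within
the sampled range ± one span, `w ∈ (0, 4·span]`, `δ ∈ [0, span]`,
`τ ∈ (0, 1]`. Intervals are profile-likelihood at a log-likelihood drop of
1.92 (≈95%); no MCMC is used.

**Model ladder.** {fixed, free} scaling × {none, left, right, mirror,
both} tails = 10 candidate models with 2/4/4/4/6 and 4/6/6/6/8 parameters
(mirror shares δ, τ across sides), ranked by AIC = 2k − 2ℓ; ties break
toward fewer parameters, then lexical name. AIC rather than AICc is the
default (AICc would subtract little at 17–25 demes and is trivially
derivable from the reported k and ℓ).

**Selection against hybrids.** Under a tension-zone model with
heterozygote disadvantage, `w ≈ 2σ/√s*`, so `s* = (2σ/w)²` with σ the
parent–offspring dispersal per generation (km, diffusion scale). σ is a
user input; `calibrate_sigma(w, s*)` recovers the σ implied by an anchor
pair — e.g. anchoring a 30-km cline at s* = 0.05 gives σ ≈ 3.354 and a
98-km cline then implies s* ≈ 0.005, a ten-fold difference that is
independent of σ (σ cancels in the ratio).

## Admixture estimation

The clustering model treats each gene copy of individual *i* at locus *l*
as drawn from cluster *k* with probability `Q_ik`, then allele *a* with
probability `F_kla` — the same mixture model that underlies Bayesian
clustering of unlinked markers, here fit by maximum-likelihood EM instead
of MCMC: deterministic given a seed, desk-scale, with closed-form Q/F
updates and a provably non-decreasing log-likelihood (asserted to 1e-8 in
tests). Defaults: 10 random restarts (best final log-likelihood wins),
convergence at relative log-likelihood change 1e-6, missing gene copies
dropped from the likelihood (MCAR). No correlated-frequencies prior, no
LOCPRIOR, no linkage model.

The supervised hybrid index maximizes
`∏ [h f_B + (1 − h) f_A]` over gene copies for `h ∈ [0, 1]` given two
parental allele-frequency profiles; the log-likelihood is concave in `h`,
solved by bounded scalar optimization with the interval endpoints checked
(boundary MLEs are common with diagnostic loci). Reference frequencies are
floored at 1e-6 so private alleles in hybrids cannot zero the likelihood.
Profile-likelihood CIs use the same 1.92 drop.

Replicate label-switching is resolved by the assignment problem maximizing
summed Pearson correlation between Q columns (solved exactly with the
Hungarian algorithm; verified against exhaustive permutation search at
K=3). The number of clusters is chosen by the Evanno second-difference
statistic `ΔK = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K))`
(sample sd; infinite with a warning when replicates are identical).

F_ST is the multiallelic Weir & Cockerham (1984) θ: per-allele variance
components a (among populations), b (among individuals within), c (within
individuals), summed over loci and alleles; pairs must have n ≥ 5 per
population (the conventional cutoff for microsatellite F_ST), missing
genotypes are dropped per locus, slightly negative estimates are reported
as-is, and a pair with no allele-frequency variance is NaN, never 0.

A population is classified *mixed* for mapping if both mtDNA haplotypes
are present and/or the mean ancestry of its majority cluster falls
strictly below 0.9.

## Comparative statistics

The proportional-odds model `P(Y ≤ j | x) = logistic(α_j − βx)` is fit by
Newton iterations (analytic gradient, finite-difference Hessian,
step-halving, cutpoint ordering enforced); the slope is clipped at
|β| ≤ 50 with a separation warning. The likelihood-ratio statistic is
`2(ℓ_full − ℓ_null)` against the intercepts-only model whose MLE is the
closed-form category proportions; p-values are χ² with df = 1 (one slope).
The solver's MLE matches statsmodels' `OrderedModel` to 1e-4 in tests.

The 2×2 test of independence uses the Yates continuity correction by
default, `χ² = N(max(0, |ad − bc| − N/2))² / (r₁r₂c₁c₂)`; the uncorrected
statistic is available.

The Mann–Whitney test uses midranks; the reported `W` is the U statistic
of the first group (rank sum minus `n_A(n_A+1)/2`), with the opposite
orientation in the notes. P-values are exact by enumeration of all
`C(n, n_A)` assignments when the pooled sample is tie-free and n ≤ 12,
else a normal approximation with tie-corrected variance and a ±0.5
continuity correction. The approximation is accurate to ≤ 0.02 of the
exact p at the balanced pooled size of 10; in very small or unbalanced
groups its error at mid-range p-values can reach ~0.03–0.09 (largest for
2 vs 2), which the test suite documents — exact enumeration is always
preferred where feasible.

Coding choices for the packaged contact-zone table: transition categories
are ordered by amount of admixture (`no_gene_flow < steep < wide`; the LR
is invariant to reversing the order); contact epochs are coded
Holocene/Anthropocene (Antiquity, 1950s, post-glacial) versus Pleistocene
(≥ LGM); the 2×2 and Mann–Whitney comparisons exclude the single
sympatry-without-gene-flow contact (n = 9), with the steep group first in
the Mann–Whitney call.

## Synthetic data: what it emulates, and what it does not

The generator draws, per locus, an ancestral allele-frequency vector from
a flat Dirichlet and two parental profiles from
`Dirichlet(p_ancestral (1 − F)/F)` — a single Balding–Nichols-style drift
knob. The default `F = 0.35` was calibrated once by simulation sweep so
that the realized multilocus θ between two pure demes of 50 is ≈ 0.35 at
the default panel (26 loci, 8 alleles per locus; the per-locus diversity
of real microsatellite panels varies and 8 is a stated guess). Individuals
at transect position x have ancestry `q = cline(x)`; every gene copy is an
independent draw from `q P_B + (1 − q) P_A` (Hardy–Weinberg within demes,
no linkage, no inbreeding — the implicit model behind admixture clustering
of unlinked microsatellites). The mtDNA haplotype is one Bernoulli draw
per individual from a coincident mt cline. Missingness is completely at
random, masking both allele slots of a cell (microsatellite dropout hits
the whole PCR). Pure reference populations (`refA`/`refB`, 16 diploids per
side by default) emulate samples collected outside the hybrid zone; an
optional deeply diverged outgroup population supports K = 3 exercises.

The default transect (`atlantic_transect_config`) has 25 demes every
25 km over 0–600 km, n = 10 diploids per deme, a nuclear cline at
c = 405 km, w = 100 km with a right exponential tail (δ = 30 km, τ = 0.5)
and an mtDNA cline at c = 405 km, w = 45 km — chosen to resemble the
geometry of a wide Atlantic-coast amphibian hybrid zone, not to match any
empirical dataset numerically.

Not emulated: spatially explicit forward-time dynamics, linkage, hybrid
zone movement, locality-specific sampling density, genotyping error, or
non-random missingness. Passing recovery tests therefore shows the
estimators work when the model that generated the data is the model being
fit; they say nothing about robustness to linkage or to scoring artefacts
in real microsatellite data.

**A measured information limit.** With the default geometry, the nuclear
width (spanning ~5 demes) is recovered by the full pipeline with ~6%
median error and the selected model carries a right-side tail in a
majority of replicates, but the 45-km mtDNA cline sampled every 25 km at
binomial n = 10 is under-determined: in a substantial fraction of
replicates a degenerate near-step model (w → 0 absorbed by a tail) is the
genuine maximum-likelihood/AIC optimum, and the best-model width has
~35–40% median error. Deeper per-deme sampling (n = 20) restores ±20%
recovery. This is a property of the sampling design, not of the
optimizer, and is left visible in the acceptance suite rather than hidden
by changing the generator's conditions.

## Problem sizes used by the test suite

Recovery experiments run at 25 demes with binomial N = 100 per deme over
50 seeds (width bias, ladder consistency), 20 seeds at n = 50 per deme for
tail-detection power, 5 seeds of the full synthetic pipeline at the
default n = 10, and 8 seeds for ΔK recovery — sizes chosen to give stable
medians and majorities while the whole suite stays desk-scale.

## Known limitations

- The transect origin convention (distance from the northernmost transect
  locality, great-circle with mean Earth radius 6371.0088 km) makes cline
  centres origin-relative; only widths and centre differences are
  origin-free.
- Exact bit-parity with the R cline-fitting package's tail algebra is not
  guaranteed; the parameterization here follows the published
  Szymura–Barton form with the continuity convention stated above.
- Ordinal-regression p-values are LR-based; Wald-based p-values would
  differ slightly in small samples.
- No phylogenetic correction is applied for contacts sharing species in
  the comparative suite.
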