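# clinekit

Hybrid-zone analysis in Python: admixture estimation from multiallelic
genotypes, geographic cline fitting with AIC model selection, conversion of
cline width into a selection coefficient against hybrids, and the
comparative statistics that relate contact-zone history to the amount of
introgression.

## The scientific problem

When two diverged lineages meet, the sharpness of the genetic transition
across their contact zone reflects the balance between dispersal and
selection against hybrids — so cline width is routinely read as a proxy for
reproductive isolation. But contact zones have histories: a transition
sitting inside a glacial refugium may be hundreds of thousands of years
old, while one formed by post-glacial expansion (or a human introduction)
is only a few thousand years old and may not have reached equilibrium.
`clinekit` packages the full analysis chain needed to study this question
in a group such as the Western-Palearctic tree frogs (*Hyla*): a speciation
continuum with ten documented secondary contacts spanning Miocene to
Plio-Pleistocene divergences, including a wide *H. arborea* / *H. molleri*
hybrid zone along the Atlantic coast of France.

The package is aimed at population geneticists who want a desk-scale,
fully reproducible re-implementation of this workflow — every stage is
testable against a synthetic-data generator with known truth, with no
external downloads.

## What is inside

| module | contents |
| --- | --- |
| `clinekit.synthgen` | transect simulator: two parental gene pools with a Balding–Nichols drift parameter, Hardy–Weinberg genotypes drawn from the mixture q·P_B + (1−q)·P_A along a true ancestry cline, coincident mtDNA cline, MCAR missingness |
| `clinekit.geno_io` | STRUCTURE-style and long-format genotype I/O, locality tables, great-circle transect distances, the packaged ten-contact table |
| `clinekit.ancestry` | EM admixture (maximum-likelihood analogue of Bayesian clustering), supervised hybrid index with profile-likelihood CIs, replicate label alignment, Evanno ΔK, multiallelic Weir–Cockerham θ, pure/mixed classification |
| `clinekit.cline` | the 2–8-parameter geographic cline (sigmoid centre, exponential introgression tails), binomial likelihood, multi-start ML fitting, the 10-model AIC ladder, profile-likelihood intervals, `s* = (2σ/w)²` |
| `clinekit.comparative` | proportional-odds ordinal regression with LR tests, Yates-corrected 2×2 χ², tie-aware Mann–Whitney (exact by enumeration when feasible) |
| `clinekit.cli` | thin `clinekit` command: `simulate`, `admixture`, `hybrid-index`, `fst`, `cline`, `comparative`, `replay` |

The core cline model is

```
f(x) = 1 / (1 + exp(−4 (x − c) / w))
```

with width `w` the inverse of the maximum frequency slope, centre `c` the
position of the 0.5 crossing, optional exponential tails of attachment
distance δ and slope ratio τ on either side, and optional free parental
frequencies `p_min`, `p_max`. Model selection crosses {fixed, free} scaling
with {none, left, right, mirror, both} tails (2 to 8 parameters) and ranks
by AIC. Under a tension-zone model, `w ≈ 2σ/√s*` links width, dispersal σ
and the selection coefficient s* against hybrids.

## Worked example

```bash
python examples/contact_zone_statistics.py
```

```
10 contacts loaded
transition ~ divergence:   LR chi2 = 7.73, df = 1, P = 0.005
transition ~ contact age:  LR chi2 = 3.85, df = 1, P = 0.050
wide/steep x post/pre-LGM: chi2 = 5.41 (Yates), n = 9, P = 0.020
divergence, steep vs wide: W = 13.5, P = 0.45
```

The first line says that across the ten contacts, older species pairs show
less admixture (an ordinal regression of the transition category —
no gene flow < steep < wide — on divergence time in Ma). The second says
the age of the contact itself also predicts the category: transitions
formed after the Last Glacial Maximum (including one 1950s introduction)
are the wide ones. The χ² makes the same point on the 2×2 table of
wide/steep × post-/pre-LGM contacts, and the Mann–Whitney shows the steep
and wide groups do *not* differ in divergence time — history, not just
divergence, shapes the transition.

`examples/simulate_and_fit_clines.py` runs the simulation → hybrid index →
cline-ladder chain and converts the fitted nuclear width into s*;
`examples/admixture_and_fst.py` demonstrates EM admixture, ΔK, replicate
alignment and Weir–Cockerham θ. The same chain is available from the shell:

```bash
clinekit simulate --seed 1 --out run/
clinekit cline run/mtdna_counts.tsv --sigma 3.354 --out run/cline.tsv
clinekit comparative
```

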