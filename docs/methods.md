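# Methods notes

This note records the models implemented in `hetri`, the defaults and the
reasoning behind the numerical and design choices, and what the synthetic
data can and cannot establish about real data.

## Invasion simulator (`hetri.simulate`)

### State and interactions

The population is N haploid individuals with genotypes over *het-r*
(`R`/`r`) and *het-v* (`V`/`V1`).  `RV` is lethal at germination, so the
state is the count vector over (`rV`, `RV1`, `rV1`).  Incompatibility is
evaluated pairwise: the allelic system fires when *het-v* alleles differ;
the non-allelic system when one partner carries `R` and the other `V`.
`rV` vs `RV1` triggers both; `rV1` vs `RV1` triggers neither (different
*het-r* alleles alone are inert).

### Fitness

NFDS from vegetative encounters is modelled as

    w(g) = 1 + b_nonallelic * x_RV(g) + b_allelic * x_VV1(g)

with x_sys(g) the frequency of individuals incompatible with g under that
system.  The linear frequency dependence is the simplest NFDS form
consistent with a rare-partner advantage; the function is deliberately
small and local (`nfds_fitness`) so an alternative form can be swapped in.

### Reproduction and the lethal-zygote cost

Per offspring slot: mother ~ fitness; selfing with probability σ
reproduces the parental haploid genotype; otherwise father ~ fitness and
the attempt succeeds with probability ∏(1 − ι_sys) over triggered systems,
then the two loci segregate independently (unlinked, free recombination).
A lethal `RV` zygote aborts the attempt.  Any failed attempt is redrawn in
full (soft selection: N is exact every generation), so failure costs the
participating genotypes mating opportunities but costs the population
nothing globally.

Treating the `RV` zygote as a failed attempt is load-bearing.  If the
lethal class were instead renormalised away inside each cross, mixed
matings would be costless at ι = 0 and a rare genotype under NFDS would
invade even with σ = 0, which is the opposite of the system's observed
logic: without selfing, a rare `rV` invader does almost all of its mating
against `RV1`, transmits a viable copy of itself through only 1/4 of raw
zygotes, and is eliminated.  With the abort-and-redraw semantics the
simulator reproduces all three regimes: deterministic loss at σ = 0,
invasion to intermediate frequency under selfing + NFDS, and exclusion of
the recombinant under strong prezygotic isolation.

Because redrawing is equivalent to conditioning the per-slot offspring law
on eventual success, the per-generation update is an exact multinomial
draw from a closed-form categorical distribution — no per-individual loop
and no approximation.  The unit suite checks this law against a literal
enumeration over all mating events.

A note on neutrality: with b = 0 and ι = 0 the dynamics are neutral only
for genotype contrasts that differ at a single locus (e.g. `rV1` invading
`RV1`), where no lethal class can arise; the invader frequency is then a
martingale and its fixation probability equals its initial frequency.  The
two-locus contrast `rV` vs `RV1` is *never* neutral — the lethal class
penalises mixed matings by construction — and the neutral calibration uses
the single-locus pair accordingly.

### Defaults

N = 1000, G = 500 generations, f0 = 0.05, 100 replicates per condition,
non-allelic intensity 0.5; all exposed on `SimParams`.  Mating types are
omitted (every individual can act as mother or father): mating-type
bookkeeping does not change two-locus genotype dynamics under random
mating in this life cycle.  Sterility is applied symmetrically per
triggered system; the documented biological asymmetry (the `R` female
organ is damaged by `V` products, not vice versa) only redistributes which
parent pays and does not alter the genotype dynamics at this level of
description.  A single master seed spawns one stream per replicate;
replicates stop early once monomorphic (an absorbing state), which is
exact.

## Synthetic data (`hetri.synthetic`)

* **Neutral alignments** — standard Kingman coalescent with infinite-sites
  mutations (msprime backend; haploid samples, unit population size,
  per-site rate θ/2), giving the closed-form expectations E[π] = θ and
  E[S] = θ·L·a_n used by the calibration tests.  The default
  θ = 5×10⁻⁴/site matches the diversity level of a highly selfing dung
  fungus population.  Continuous mutation positions are floored to
  integer coordinates; the rare collision is dropped (negligible at this
  θ).
* **Two-group SNP matrices** — background sites are drawn from the
  neutral frequency spectrum independently of group labels; the primary
  island is fixed-different between groups (complete lineage sorting, so
  any window inside it has Hudson F_st = 1); a secondary island draws
  group frequencies 0.5 ± δ with δ = sqrt(t/(8−4t)) so the expected
  Hudson F_st equals the target t.  Background polymorphism is excluded
  from the island spans to keep within-island variation purely
  between-group.
* **Coverage** — negative-binomial depth with variance m + dispersion·m²
  (dispersion 0 → constant depth); artifact regions scale the mean,
  emulating collapsed repeats or dropouts.  Defaults (mean 80×) mirror
  deep short-read sequencing of haploids.
* **Mating matrices** — within-group crosses code 1, between-group 4–6,
  optional uniform renoising; non-symmetric by construction.

What passing tests show: the estimators, the clustering and the scan
recover planted truth under idealised sampling.  What they do not show:
robustness to mapping error, index hopping, uneven sampling through time,
partial selfing pedigree structure or multi-allelic het systems — none of
which the generators emulate.

## Windowed scan (`hetri.popgen`)

* Windows are 10 kb with 1 kb steps (defaults), 1-based inclusive, tiled
  from position 1; the final partial windows are kept and fall to the
  minimum-effective-length filter (5 kb) if short.  Statistics in windows
  with L_eff below the minimum are missing (`NA` in TSV output, never 0).
* Masking: per sample, sites with depth strictly below its 25% quantile
  or strictly above its 98.5% quantile (type-7 empirical quantiles) are
  bad; the mask is the intersection of bad-in-all-samples with the repeat
  annotation.  Strict inequalities mean constant coverage masks nothing.
  Masked bp are excluded from L_eff — the denominator of π, θ_W and D_xy —
  so adding fully masked sites never moves an estimate.
* π uses the unbiased per-site pairwise difference 2j(n−j)/(n(n−1));
  θ_W applies the harmonic correction per segregating site (equal to
  S/(a_n·L_eff) for complete calls); Tajima's D uses the 1989 normalising
  constants with the median per-site call count and is missing (not zero)
  at S = 0.
* F_st is Hudson-type, window-level ratio of averages
  1 − ΣH_w/ΣH_b, with H_w the mean of the two within-group per-site π
  values and H_b the per-site D_xy; sites need ≥ 2 calls per group.
  Ratio-of-averages is the standard choice for windowed scans and is
  robust to low-frequency sites.  The permutation null rearranges samples
  into groups of the observed sizes, shares each permutation across all
  windows, and reports p = (1 + #{perm ≥ obs})/(n_perm + 1); no
  multiple-testing correction is applied.
* PCA: complete-call sites, MAF ≥ 1%, column-centred 0/1 matrix (no
  unit-variance scaling by default; a `scale` flag is provided since
  common toolkits differ), SVD.  RI assignment thresholds PC1 at zero
  after orienting the sign by labelled anchors; a sample exactly at zero
  stays unassigned.

## LD (`hetri.ld`)

r² is the squared allele-frequency correlation on pairwise-complete
haploid calls (phase known).  Decay pairs come from 30 random 50-kb
windows per chromosome (overlaps allowed, duplicate pairs deduplicated)
with singletons removed.  The decay expectation is the one-parameter
recombination–drift equilibrium curve in C = ρ·d with the finite-sample
correction in n; it is 10/22 at C = 0 (large n) and tends to 1/n as
C → ∞.  ρ is fitted by bounded least squares on log ρ with multi-start
over 10⁻⁵…10⁻¹/bp (the SS surface can be flat for noisy data);
non-convergence is flagged on the result rather than raised.  The
distance where the fitted curve crosses r² = 0.2 is found by bracketed
root-finding.  Thinning is greedy left-to-right at 1 kb minimum spacing
with MAF > 0.02; a region filter reproduces arm-restricted analyses
without hard-coded coordinates.

## Mating clustering (`hetri.mating`)

Cross outcomes are coded 1–6 (1 mature fruiting bodies on both partners …
6 none on either).  Each strain's row of codes is one observation; Gower
dissimilarity treats the codes as interval-scaled (range-normalised
absolute difference — the numeric-column default of the classical
implementation), with an ordinal-rank option and pairwise deletion of
missing cells; strains missing > 50% of cells are dropped with a warning.
PAM is the classical BUILD + best-improvement SWAP with lowest-index tie
breaks, so results are deterministic and row-order invariant up to
relabelling.  The cluster count is chosen by maximum average silhouette
width over k = 2..k_max (authoritative), with the Tibshirani Gap statistic
(uniform reference sets over per-variable ranges, B = 100, one-SE rule,
PAM on Euclidean distances of the coded matrix) reported alongside —
the Gap can return k = 1 where silhouette cannot.  PCoA is classical
scaling (double-centred −½JD²J, eigendecomposition); negative eigenvalues
from non-Euclidean input are dropped and counted.  Concordance between
cluster and genotype labels reports the best-permuted confusion matrix and
the adjusted Rand index.

## Genotype utilities (`hetri.genotypes`)

WD40 repeat count is the nearest integer to amplicon_bp/126 (half-integers
round down with a warning — gel sizing is coarse).  `R` requires exactly
11 repeats in the reference order; 11 repeats with unknown order is a
provisional call flagged for sequencing; anything else is `r`.  The
substrate contingency test is a Pearson χ² on the 2×2 group × substrate
table with the continuity correction off by default (a `yates` flag is
provided; published 2×2 statistics are ambiguous about the correction).
Allele trajectories suppress years with fewer than six genotyped strains.
Map-distance arithmetic keeps full precision internally and rounds to one
decimal only in the report fields.

## Problem sizes

The test suite and the acceptance script run the simulator at N = 1000
for 100 replicates × 500 generations (the per-generation update is a
single multinomial draw, so this is seconds), the neutral calibration at
200 replicates of 1 Mb, the permutation null at 1000 permutations over an
800-window two-chromosome genome, and the LD recovery at 400–500 pairs ×
50 seeds.  These sizes give Monte-Carlo standard errors comfortably inside
every asserted tolerance.

## Known limitations

No recombination map, demography or sequencing-error model in the
generators; no linkage between *het-v* and the nearby spore-killer
element; no multi-allelic het systems; no phasing or indel handling; the
simulator tracks genotype counts, not genome sequences.
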