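# Methods

## Per-site rate estimation on a fixed chronogram

The rate estimator treats the supplied tree as known and time-calibrated:
branch lengths are in Ma, so a site evolving at rate λ (substitutions per
site per Ma) accumulates an expected distance d = λ·t along a branch of
duration t. Each column's likelihood is the Felsenstein pruning
likelihood under JC69 with uniform root frequencies; λ is the only free
parameter per site, and its MLE is found on [0, λ_max].

JC69 was chosen deliberately: the substitution model behind published
per-site rate tables is rarely reported, and a parameter-free model keeps
the per-site optimisation nuisance-free and deterministic. The synthetic
generator simulates under HKY with unequal frequencies precisely so the
tests quantify how the JC estimator behaves under model violation (rate
*ordering* across partitions is preserved; absolute rates of heavily
saturated HKY partitions are mildly biased). A TSV reader
(`SiteRateTable.read_tsv`) accepts externally produced per-site rate
tables in the same layout, so rates from another estimator — including
relative-rate conventions — can be injected into the downstream stages
unchanged.

Numerics: the likelihood is evaluated vectorised across columns (duplicate
column patterns are collapsed first); per column the optimiser is a
65-point grid scan over [0, λ_max] followed by golden-section refinement
of the bracketing interval to an absolute tolerance of 1e-8. The grid
scan guards against the occasional multi-modality of single-site
likelihood surfaces; a test checks that the returned optimum is never
beaten by a 2000-point reference grid. Defaults: λ_max = 20/T where T is
the root age (≈20 expected root-to-tip substitutions, far beyond
saturation). Degenerate columns — constant, all-missing, or with fewer
than two non-missing taxa — get λ̂ = 0 with a boundary flag rather than
NA so that informativeness sums over sites stay defined; the flag also
marks sites whose MLE sits at λ_max (within 1e-4·λ_max of either end).
Partial likelihoods are rescaled per node with accumulated log factors,
so deep trees cannot underflow. Non-ultrametric input warns but does not
fail: the rates remain per-unit-branch-length, only the time axis of the
profiles becomes suspect.

## Informativeness profiles

Per site, `rho_original(t; λ) = 16 λ² t e^(−4λt)` and
`rho_modified(t; λ) = λ t e^(−4λt)`. "Removing the normalisation" is
interpreted as dropping the 16λ factor that gives each site unit area
under its curve — the only reading consistent with all three qualitative
behaviours the three profile variants are expected to show (lower, more
extended peaks; fast sites higher at shallow times; slow sites
surpassing fast ones only at deep times). Dropping 16λ² instead would
make slow sites dominate at *all* times. The `rho` function takes the
variant as an argument, so an alternative algebraic form can be swapped
in without touching the profile machinery.

Partition profiles sum `rho` over the partition's sites on a time grid
(default: 512 evenly spaced points on (0, T]); the average-modified
variant divides by the partition length L. Analytic conveniences:
`peak_time(λ) = 1/(4λ)` and the closed-form crossing time of two
modified curves, both property-tested against numeric oracles.

## Saturation tables

Uncorrected p-distances use pairwise deletion: only positions where both
sequences carry an unambiguous base are compared, and pairs with zero
comparable positions are dropped with a warning. This matches the
realities of concatenated matrices with fragment-level missing data,
where complete-case deletion would discard most pairs. Reference
distances are patristic distances on whatever tree is supplied — the
operation takes the tree explicitly rather than guessing between a
combined-analysis tree and single-gene trees. Summaries are limited to
OLS slope/intercept and Pearson r per partition; saturation is a visual
judgement and no bespoke index is invented.

## Site classification

Ignoring missing symbols, a column is conserved with ≤1 distinct state,
parsimony-informative with ≥2 states each in ≥2 taxa, otherwise variable
but uninformative. Ambiguity codes count as missing, not partial states
(the simplest defensible rule). Reported "variable" counts *include*
informative sites, so conserved + variable = total; this is the stacked
convention used when such proportions are plotted per gene and codon
position, and the output header says so. All-missing columns are counted
as conserved and also tallied separately.

## Calibration priors

Offset exponential (offset o, mean m): quantile q maps to
o + m·(−ln(1−q)). Offset lognormal: "mean" and "sd" are the real-space
mean and standard deviation of the non-offset component, converted by
moment matching (σ² = ln(1+sd²/m²), μ = ln m − σ²/2). This
parameterisation is the one under which the canonical example — offset
34 Ma, mean 7, sd 5 — yields a prior median of 39.70 Ma (≈40) and a 2.5%
quantile of 35.62 Ma (≈36). Its 97.5% quantile is 54.05 Ma; an
often-quoted upper bound of 50 Ma is not consistent with the same median
under any of the standard parameterisations, so no code or test forces
that endpoint. Quantile/CDF round-trips and Monte-Carlo medians are
property-tested.

## Synthetic data generator

Trees are pure-birth (Yule): the simplest ultrametric generator, since
topology realism is irrelevant to the maths being tested. The sampler
stops at the n-th birth event, which would leave a zero-length cherry;
leaf edges are therefore extended by the exponential waiting time to the
(n+1)-th event before the whole tree is rescaled to the exact target
root age. Sequences evolve root-to-tips with per-branch transition
matrices from a spectral decomposition of the (reversible) HKY rate
matrix, vectorised over per-site distances; JC is the κ=1, equal-
frequency special case. All randomness flows from a single integer seed
through named numpy generators; identical seeds give byte-identical
output files.

The benchmark dataset (`aciliini_fixture`) emulates the *structure* of an
eight-fragment concatenated beetle matrix: fragment lengths 2008, 821,
684, 671, 670, 466, 447, 328 bp (total 6095), codon-position
sub-partitions for the six protein-coding fragments (20 partitions in
all), 40 tips, 110 Ma root, and 11% *fragment-level* missingness (whole
taxon-by-fragment cells wiped, matching how failed amplifications behave).
Rate regimes (substitutions/site/Ma) are eight well-separated classes:

| class | λ | rationale |
|---|---|---|
| mitochondrial pos3 | 0.050 | λ·T = 5.5 root-to-tip: saturated |
| H3 pos3 | 0.010 | fast nuclear third positions, slightly saturated |
| CAD pos3 | 0.007 | PI peak at 1/(4λ) ≈ 36 Ma |
| Wnt pos3 | 0.0045 | peak ≈ 56 Ma, overtakes CAD at depth |
| 16S | 0.0024 | mitochondrial ribosomal, intermediate |
| mitochondrial pos1+2 | 0.0012 | λ·T = 0.13: unsaturated |
| nuclear pos1+2 | 0.0006 | slowest coding class |
| 28S | 0.0004 | most conserved fragment |

Among-site variation is Γ(shape 4) within each partition; mitochondrial
fragments use HKY κ=4 with AT-rich frequencies (0.30, 0.20, 0.20, 0.30 —
stationary mismatch ceiling 0.74), nuclear coding fragments HKY κ=2, 28S
JC. All constants live in `simulate.RATE_CLASSES`/module config and are
recorded in the bundle's `config.txt`.

What the generator does *not* emulate: indels (real CAD fragments carry a
short indel region), base-composition heterogeneity across lineages,
within-fragment rate gradients (e.g. a hypervariable 5′ stretch), and
realistic per-gene variability percentages — with 40 taxa and ~1500 Ma of
total tree length, even the 16S class leaves most sites variable, unlike
a typical empirical matrix. Passing tests therefore demonstrate the
correctness of the estimators and the recoverability of rate *structure*,
not that real data of this shape would give identical proportions.

## Known limitations and deliberate scope cuts

- Rank recovery is asserted at the rate-class level (8 classes), not per
  partition: partitions sharing a class are exchangeable by construction
  and their estimated means differ only by noise.
- Profile orderings between curves that are both near zero — a saturated
  mitochondrial class vs an ultra-slow ribosomal class at deep times —
  are not stable under estimation error plus JC/HKY mismatch, and the
  tests deliberately pin down only the informative top of the ranking at
  each evaluation time.
- NEXUS dialects, amino-acid alphabets, network trees, codon/selection
  models, model-corrected distances and any tree or date *inference* are
  out of scope; the package evaluates markers on trees supplied to it.
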