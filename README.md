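# phyloinform

Utilities for asking a practical question in molecular systematics: **which
markers, and which codon positions, carry phylogenetic signal at which
timescales?** Given a multiple sequence alignment, a time-calibrated
(ultrametric) tree, and a partition scheme, the package

- estimates a **per-site substitution rate** λ (substitutions/site/Ma) for
  every alignment column by maximum likelihood on the fixed tree
  (Felsenstein pruning under JC69, 1-D optimisation per site);
- turns rates into **phylogenetic informativeness (PI) profiles** over time
  in three variants — *original* (per-site curves normalised to unit area),
  *modified* (normalisation removed), and *average-modified* (modified,
  divided by partition length for per-base comparison across markers);
- classifies sites as **conserved / variable / parsimony-informative** per
  partition;
- builds **substitution-saturation tables** (pairwise uncorrected
  p-distances against patristic distances on a reference tree, with OLS
  slope and Pearson r per partition);
- summarises **fossil-calibration priors** (offset lognormal and offset
  exponential node-age priors) by quantiles;
- and ships a **synthetic-data generator** that produces partitioned
  alignments with known per-site rates on Yule chronograms, including a
  benchmark dataset shaped like an eight-fragment diving-beetle matrix
  (6095 bp, 40 taxa, 110 Ma root, codon substructure, saturating
  mitochondrial third positions, 11% fragment-level missing data).

It is aimed at systematists designing or post-hoc evaluating multi-marker
datasets, and at method developers who need ground-truth fixtures for
signal/saturation analyses.

## The core quantities

For a site with rate λ, the informativeness of the site for resolving a
divergence at age *t* has the closed form

```
rho_original(t; λ) = 16 λ² t e^(−4λt)        (∫₀^∞ rho dt = 1)
rho_modified(t; λ) =     λ  t e^(−4λt)
```

Both peak at `t* = 1/(4λ)`. The modified variant's peak height is the
rate-free constant `e⁻¹/4 ≈ 0.0920`, so fast and slow sites are no longer
forced to contribute equal area; a slow and a fast site cross exactly once,
at `t_x = ln(λ_fast/λ_slow) / (4(λ_fast − λ_slow))`, with the slow site more
informative beyond `t_x`. Partition profiles are sums over sites; the
average-modified profile divides by the partition length L.

Saturation is read from the uncorrected p-distance: under JC its
expectation at tree distance *d* is `(3/4)(1 − e^(−4λd/3))`, plateauing at
the stationary ceiling `1 − Σπ²` (3/4 for equal base frequencies).

Offset priors: the exponential prior has quantiles
`offset + mean·(−ln(1−q))`; the lognormal prior is parameterised by the
real-space mean and standard deviation of the non-offset part
(`σ² = ln(1 + sd²/mean²)`, `μ = ln mean − σ²/2`).

## Worked example

Simulate the benchmark dataset and run the whole pipeline:

```
$ phyloinform simulate --out data --seed 1
$ phyloinform run --alignment data/alignment.fasta --tree data/tree.nwk \
      --partitions data/partitions.txt --out results --seed 1
site_classes      results/site_classes.tsv
site_rates        results/site_rates.tsv
pi_profiles       results/pi_profiles.tsv
saturation_pairs  results/saturation_pairs.tsv
saturation_summary  results/saturation_summary.tsv
```

`site_classes.tsv` (excerpt) shows the expected contrast between slow and
fast partitions — third codon positions of the fast mitochondrial fragment
are informative at almost every site, the conserved nuclear ribosomal
fragment at a quarter of them:

```
partition    n_sites  n_conserved  n_variable  n_parsimony_informative
28S          670      373          297         164
CAD_pos1     670      301          369         213
CAD_pos3     669      1            668         654
COI_3p_pos3  273      0            273         273
```

The average-modified PI profile at 15 Ma ranks nuclear and mitochondrial
third positions on top, per aligned base:

```
t_ma     partition    pi
15.04    H3_pos3      0.070601
15.04    CAD_pos3     0.060764
15.04    COI_5p_pos3  0.053029
```

and the saturation summary separates the saturated mitochondrial third
positions (flat slope beyond a high intercept, low r) from clean, linear
slow partitions:

```
partition    slope        intercept   pearson_r
CAD_pos3     0.00169524   0.223521    0.933099
COI_3p_pos3  0.000424057  0.652250    0.526027
28S          0.000326742  0.00788726  0.911113
```

Fossil-calibration priors from the command line:

```
$ phyloinform priors --kind lognormal --offset 34 --mean 7 --sd 5
quantile  age_ma
0.025     35.6183
0.05      35.9812
0.5       39.6961
0.95      50.3772
0.975     54.0496
```

i.e. a prior with its median at ~40 Ma and 2.5% bound at ~36 Ma above a
34 Ma fossil floor. Every number above is produced by the commands shown.

The same functionality is available as a library (`import phyloinform`):
`estimate_all_rates`, `profile`, `saturation_table`, `summarize`,
`offset_lognormal` / `offset_exponential`, `aciliini_fixture`, etc.

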