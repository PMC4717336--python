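# barcodesim

How many individuals per species do you need to sequence before a DNA
barcode library says something reliable about that species' genetic
polymorphism? `barcodesim` answers this by simulation: it generates
populations of barcode-like sequences under a neutral coalescent model
and measures how four standard polymorphism estimators behave when only a
subsample of the population is available.

The package is aimed at barcoding practitioners and population
geneticists who want to reproduce, extend, or stress-test
sampling-depth recommendations on synthetic data with known truth.

## The model in brief

* **Genealogies**: Kingman coalescent for a constant-size panmictic
  population; with *j* lineages the next coalescence happens at rate
  *j(j−1)/2* in units of 2N generations, so E[TMRCA] = 2(1 − 1/n).
* **Sequences**: 1,500-bp (CO1-length) alignments evolved under the
  Jukes–Cantor model, with branch lengths rescaled case by case so the
  maximum pairwise JC distance *d = −(3/4)·ln(1 − 4p/3)* stays below 3%,
  as in intraspecific barcode data. An infinite-sites overlay with
  θ = 4Nμ = 3 validates the simulator (E[pairwise differences] = θ).
* **Distances**: all-pairs JC distances, min-max normalized onto
  [0.00, 0.03] so datasets are comparable.
* **Estimators under subsampling**: the mismatch distribution
  (histogram + kernel density), nucleotide diversity
  π = (X₁ + … + X_k)/k (the mean of the k pairwise distances, compared
  to the full-dataset value β via the percentage of replicates within
  β ± 0.001), the number of haplotypes (whose median–size curve is fit
  by the Michaelis–Menten form F(x) = ax/(1+bx)), and the maximum
  pairwise distance.

See `docs/methods.md` for assumptions, parameter defaults, and design
choices.

## Worked example

Simulate one 60-sequence population, compute distances, and subsample
nucleotide diversity:

```sh
$ barcodesim simulate --n 60 --seed 4 --outdir demo
wrote 60 sequences of 1500 bp (max JC distance 0.0272) to demo

$ barcodesim distances demo/alignment.fasta --outdir demo
60 sequences, 1770 pairwise distances

$ barcodesim resample demo/alignment.fasta --estimator diversity \
    --sizes 2,10,20,40 --replicates 2000 --seed 4 --out demo/diversity.csv
wrote 8000 values to demo/diversity.csv
  size    2: mean=0.0150 pct_in_band=0.40%
  size   10: mean=0.0152 pct_in_band=42.65%
  size   20: mean=0.0151 pct_in_band=68.95%
  size   40: mean=0.0152 pct_in_band=98.35%
```

Reading the output: the subsample mean diversity is essentially unbiased
at every size (≈0.015 throughout, the full-dataset β), but the *spread*
collapses only as samples grow — with 2 individuals almost no replicate
lands within β ± 0.001, with 20 about two-thirds do, with 40 nearly all.
That concentration with sample size is the study's central effect.

The full protocol — ten 500-sequence datasets plus one of 300 and one of
1000, with the per-estimator subsampling schedules — runs with
`barcodesim study --seed 0 --outdir study_output` (tens of minutes) and
writes per-dataset FASTA/Newick/CSV outputs, a diversity summary table,
and a JSON manifest from which the run can be reproduced byte for byte.
`barcodesim study --smoke` exercises every stage in seconds.

The same functionality is available as a library
(`barcodesim.simulate_genealogy`, `evolve_jc`, `pairwise_matrix`,
`run_schedule`, `fit_michaelis_menten`, …).

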