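# Methods

## Model and pipeline

`barcodesim` studies how intraspecific sample size affects four estimators
of genetic polymorphism used in DNA barcoding — the mismatch distribution,
nucleotide diversity (π), the number of haplotypes, and the maximum
pairwise distance — on data simulated under the simplest neutral model: a
single panmictic population of constant size, no recombination, no
selection, a constant mutation rate.

The pipeline has four stages.

1. **Genealogy** (`genealogy`). Kingman coalescent: with `j` active
   lineages the waiting time to the next merger is exponential with rate
   `j(j-1)/2`, and the merging pair is uniform over unordered pairs. Time
   is measured in units of 2N generations, so `E[TMRCA] = 2(1 − 1/n)` and
   the mean pairwise coalescence time is 1. Tree shape is summarised by
   the Colless imbalance index and by Aldous-style split profiles (the
   larger-daughter clade size along a greedy descent from the root).

2. **Sequences** (`seqsim`). Branch lengths are rescaled to expected
   substitutions per site and 1,500-bp sequences (the approximate length
   of the mitochondrial CO1 barcode) are evolved under Jukes–Cantor.
   Rather than simulating substitution events one by one, each site flips
   along a branch of length `t` with the closed-form probability
   `p_change(t) = (3/4)(1 − e^(−4t/3))` to a uniformly chosen different
   base; for JC this is distributionally exact and much faster. A second,
   infinite-sites machinery overlays `Poisson(θ/2 · branch length)`
   mutations on coalescent-scale branches. It plays no role in sequence
   generation — its purpose is validation, since under neutrality the
   expected pairwise difference count equals θ = 4Nμ (default 3.0).

3. **Distances** (`distances`). All-pairs JC-corrected distances,
   `d = −(3/4) ln(1 − 4p/3)`, followed by min-max normalization of the
   off-diagonal values onto [0.00, 0.03]. The zero diagonal is excluded
   from the source range so the smallest *pairwise* distance maps to the
   new minimum. Normalization is strictly monotone, so subsample distance
   pools are taken from the normalized full-dataset matrix as-is.

4. **Subsampling** (`estimators`, `resampling`, `study`). Subsamples are
   drawn uniformly **without replacement** (a sample of specimens cannot
   contain the same individual twice); distinct replicates may repeat a
   subset by chance and are not deduplicated. Each estimator runs on a
   grid of sizes × replicates, with summaries described below.

## The divergence cap

Real barcoding datasets keep intraspecific divergence small; the study
protocol requires the maximum pairwise JC distance within each dataset to
stay below 3%. Because the realized maximum is stochastic, the cap is
enforced by construction: the tree is first rescaled to a tip-to-tip
diameter of `0.85 × cap` (so the *expected* maximum divergence sits
comfortably below the cap), sequences are evolved, and while the realized
maximum JC distance is at or above the cap the tree is shrunk by a factor
0.9 and re-evolved with the same seed. The loop almost always accepts on
the first or second pass; twenty failed iterations raise an error (never
observed). The realized bound — not merely the expected one — therefore
holds in every accepted dataset. Note that at L = 1500 the largest
mismatch count below the cap is 44 (45/1500 JC-corrects to 3.07%), so the
realized per-dataset maximum is quantized and typically sits at
`jc(44/1500) ≈ 2.99%`.

## Estimator summaries

* **Mismatch distribution**: histogram of the normalized pairwise
  distances over [0, 0.03] with half-open bins of width 0.001 (the last
  bin closed), plus a Gaussian KDE with Silverman's rule-of-thumb
  bandwidth on a 512-point grid extended four bandwidths past the data so
  the density integrates to ≈1. Gap reports list maximal runs of empty
  *interior* bins; leading/trailing empty bins are outside the realized
  range, not gaps. Modality is counted on the KDE after suppressing local
  maxima below 1% of the global peak (an anti-noise guard). The bin width
  and KDE details are package choices; they resolve the multimodal
  structure that constant-size coalescent data produce.

* **Nucleotide diversity**: π is the mean of the `s(s−1)/2` pairwise
  distances in the subsample — computed on distances, not per-site
  mismatch counts. Because every pair of individuals appears in the same
  number of size-`s` subsets, the subset-average of π is *exactly* the
  full-dataset value β (verified by exhaustive enumeration in tests). Per
  size we report the mean and the percentage of replicates within the
  closed band β ± 0.001, on unrounded values (three-decimal display is
  formatting only). CLT diagnostics (variance and skewness per size)
  check the qualitative bell-shape claim; the `σ²/k` variance of the
  i.i.d. central limit theorem is *not* asserted, since pairwise
  distances within a subsample are dependent.

* **Haplotypes**: exact distinct-sequence counting (simulated data have
  no gaps or ambiguity codes). Per-size five-number summaries use linear
  interpolation for quartiles and the midpoint convention for even-count
  medians. The median–size relationship is fit by the Michaelis–Menten
  saturation curve `F(x) = ax/(1 + bx)` (asymptote `a/b`, slope
  `a/(1+bx)²`): starting values come from ordinary least squares on the
  linearization `1/F = (1/a)(1/x) + b/a`, then `scipy.optimize.curve_fit`
  minimizes the untransformed residual sum of squares.
  `residual_variance` is RSS/(n−2), two constants having been fitted.

* **Maximum pairwise distance**: subsample maxima are compared to the
  full-dataset maximum; the probability of capturing the full maximum is
  nondecreasing in sample size and reaches 1 at the full size.

## Study protocol and randomness

The default configuration mirrors the study design: ten independent
datasets of 500 sequences plus one of 300 (seq_K) and one of 1000
(seq_L); mismatch subsamples of {5, 10, 20, 30, 50, 100} × 10 replicates;
diversity and maximum-distance subsamples of {2, 5, 10, 20, …, 100} ×
10,000 replicates (sizes truncated at 60 for both additional datasets);
haplotype subsamples over 16 sizes {2, 10, 20, …, 150} × 100 replicates
({2, 20, …, 140} for the additional datasets); θ = 3.0, L = 1500 bp,
divergence cap 3%.

One root seed drives everything. Per-dataset streams are derived through
`numpy.random.SeedSequence([root_seed, stream, dataset_index])` with fixed
stream constants (1 = genealogy, 2 = sequences, 3 = schedules), and each
schedule further splits by (estimator, size), so any stage can be re-run
in isolation and a study re-run from its JSON manifest reproduces every
CSV byte for byte. A failing dataset is logged, recorded in the manifest,
and skipped without aborting the rest of the run.

## What the generator does and does not emulate

The synthetic data reproduce the neutral single-deme conditions of the
study: clock-like evolution, equal base frequencies, no rate
heterogeneity, no indels, no migration or population-size change. Passing
tests therefore demonstrate the estimators' sampling behaviour under
those conditions only. Real barcode data add alignment error, ambiguity
codes, rate variation among sites and lineages, and population structure
— none of which are modelled, and all of which can widen the spread of
subsample estimates relative to what is shown here.

## Numerical and design choices

* **Colless normalization**: the caterpillar maximum `(n−1)(n−2)/2`. The
  alternative `n(n−1)/2` denominator differs by <0.5% at n = 500 and both
  are compatible with the observed range 0.0173–0.0247; tests assert
  the mean over ≥50 trees falls inside (0.0173, 0.0247).
* **Split-profile descent**: ties between equal daughters go to the first
  child; the balanced reference profile is iterated ceiling-halving.
* **JC saturation**: mismatch proportions ≥ 0.75 raise an error with the
  offending pair identified; unreachable under the 3% cap.
* **Degenerate normalization** (all pairwise distances equal) is refused
  rather than mapped to a constant.
* **Bell-shape acceptance diagnostic**: at the acceptance scale (one
  500-sequence dataset, 1,000 replicates per size) a distribution is
  called unimodal when no secondary KDE maximum exceeds 10% of the main
  peak — Monte-Carlo ripples a few percent high are not modes — and its
  mode must lie within one per-size sampling standard deviation of β.
* **Problem sizes in tests**: closed-form Monte-Carlo checks use
  1,500–10,000 replicates (three standard errors); the enumeration
  equivalence check uses 50,000 draws against all C(7,3) subsets; the
  study smoke tests run two 30-sequence datasets. These sizes make the
  suite quick while keeping Monte-Carlo error well below the asserted
  tolerances.

## Known limitations

* Sequence evolution is plain JC; no other substitution models are
  offered.
* The mismatch-distribution comparison across sample sizes is reported as
  tables (range, gaps, modality); no automatic shape-distance statistic
  is computed between subsample and full-dataset distributions.
* Extrapolating the Michaelis–Menten asymptote `a/b` to a population
  haplotype richness is deliberately not exposed as an estimate; for real
  species it is not a practical quantity.
* The coalescent simulator is O(n²) per tree; fine for n ≤ a few
  thousand, not intended for much larger samples.
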