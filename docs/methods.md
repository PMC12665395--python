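# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the bundled synthetic data can and cannot demonstrate.

## Resampling model

Let the superalignment have `L` sites over `n` taxa.  A *subsample* is a
uniform without-replacement draw of `l` site indices; an *upsampled
replicate* draws `L` sites with replacement from the subsample, represented
internally as a multinomial weight vector over the `l` sites (replicates
are never materialized unless an external tree program needs a FASTA
file).  Consequences used throughout:

* every subsample site appears `L/l` times in expectation in a replicate;
* a replicate's distinct-site fraction is at most `l/L` (≈1.6% at
  `L = 10⁶`, versus `1 − (1 − 1/L)^L → 63.2%` for the standard bootstrap
  and ≈46.9% for the double bootstrap, by Poisson thinning — the popular
  0.63² ≈ 39% heuristic is an approximation, so the package reports the
  measured fraction rather than asserting either constant);
* conditional on a subsample, a replicate's effective information content
  is that of `L` draws, so replicate trees within a subsample are nearly
  deterministic reruns of the subsample's signal, while *between*
  subsamples the signal varies with the genomic mixture — this separation
  is what makes bcl distributions informative about heterogeneity.

**Subsample size.**  `l = ⌊L^g⌋`, default `g = 0.7`, clamped to
`[4, L − 1]`, evaluated in 50-digit decimal arithmetic so exact integer
powers are not lost to floating-point rounding (1024^0.7 must be exactly
128, and L = 1,207,638 must give exactly 18,086).  The exponent is a
user-facing parameter: published analyses exist whose automatic
subsample-size protocol implies `g ≈ 0.79`, so no single constant is
privileged; 0.7 is the default because it reproduces the canonical
18,086-site example.

**Seeding.**  A master seed spawns one independent PCG64 stream per
(subsample index, replicate index) through `numpy.random.SeedSequence`
spawn keys.  Results are bit-identical across reruns and independent of
execution order; all run metadata lands in the JSON manifest.

## Support estimators

Within one subsample, `bcl(clade) = 100 · (replicate trees containing the
clade) / R`, on a `100/R` grid (`R = 20` by default, giving 5-point
resolution).  A clade absent from every replicate tree of a subsample
scores `bcl = 0` there: support is a frequency and absence is evidence of
absence under resampling.  Across `S` subsamples:

* `NBS = mean{bcl}` — equal, when `R` is constant, to the clade's frequency
  among all pooled `S × R` replicate trees (asserted by an oracle test);
* `FBS_est = median{bcl}` — an estimate of the classic full-superalignment
  bootstrap support;
* `OC = FBS_ref − NBS`, with `FBS_ref` defaulting to `FBS_est` so both
  estimates come from the same bcl distribution; an externally computed
  full-data FBS may be supplied instead.

## Adaptive stopping

The run starts with `s0 = 5` subsamples × `R = 20` replicates and adds one
subsample per iteration.  After each addition the per-clade NBS vector
(union clade set, absentees = 0) is compared with the previous iteration's
by root mean squared deviation **on the [0, 1] proportion scale**; the
printed threshold 0.05 therefore means 5 support points.  (On the percent
scale an 0.05-point threshold would be unattainable at the 5-point bcl
resolution; the manifest records this scale choice prominently.)  The loop
stops when RMSD < 0.05 on two consecutive iterations — a deliberately
conservative reading of "stabilized", since single additions with a
two-hit rule cannot stop on one lucky draw — or flags `converged = false`
at `s_max = 100`.  A subsample in which some taxon has no unambiguous
residue is skipped with a warning and redrawn.  An optional validation
mode repeats the analysis at doubled `l` and reports per-clade NBS deltas.

## Tree engine

The built-in engine computes weighted p-distances (or Jukes–Cantor
corrected distances: `−(3/4)ln(1 − 4p/3)` for DNA, `−(19/20)ln(1 − 20p/19)`
for protein) under pairwise deletion, consuming replicate weight vectors
directly, followed by neighbor joining with lowest-index tie-breaking
(deterministic across platforms) and negative branch lengths clamped to 0.
Saturated pairs (`p` beyond the correction's domain) are capped at a
configurable distance (default 5.0) with a warning rather than erroring,
because upsampled replicates of tiny subsamples can saturate by chance.
A taxon pair sharing no weighted comparable sites is a hard error naming
the pair.

The NBS statistics are engine-agnostic; any ML program can be plugged in
through a command template (`{aln}`, `{out}`, `{seed}`) that receives a
materialized FASTA replicate and must write one Newick tree.  Replicates
whose external command fails are logged and dropped from the numerator
(the 5-point grid is preserved by keeping `R` in the denominator); a
subsample with more than 50% failures aborts the run.  The distance/NJ
engine exists to make the statistics testable and usable at desk scale —
its trees are not a substitute for ML trees in a publication analysis.

## Modality tests

bcl values are rescaled to [0, 1].  Because they live on the `100/R` grid,
tied values are jittered by a fixed-seed uniform `±(100/R)/20` — far below
the grid spacing — before the dip test, which is ill-behaved on heavily
tied samples.  Distributions whose entire range fits within one grid step
are declared unimodal outright (modes cannot be resolved below the support
resolution), and fewer than 4 subsamples yields an "untested" verdict.

*Dip.*  Hartigan's statistic — the sup-distance between the ECDF and the
nearest unimodal CDF — is computed by the greatest-convex-minorant /
least-concave-majorant modal-interval-shrinking algorithm on sorted data.
The implementation is validated against an independent brute-force oracle
(linear programs over piecewise-linear unimodal CDFs with an optional atom
at the mode, minimized over all mode positions) and against closed forms
(equal two-point mass → 0.25; the minimal dip `1/(2n)` on uniform grids).
The p-value is Monte Carlo: the proportion of `n_mc = 2000` uniform(0,1)
samples of equal size whose dip is at least the observed one, with an
add-one correction `(b + 1)/(n_mc + 1)` so p is never exactly 0.

*Silverman.*  For k = 1, 2, …: the critical bandwidth `h_k` is the
smallest Gaussian-KDE bandwidth giving ≤ k modes (bisection, using the
monotone decrease of the Gaussian-KDE mode count in bandwidth; the KDE
grid refines automatically when `h` is small relative to the data span so
narrow modes are never lost between grid points).  The p-value for "≤ k
modes" is a smoothed bootstrap with variance rescaling (`n_boot = 500`);
the reported mode count is the smallest k not rejected at α = 0.05.  A
clade is *multimodal* iff the dip rejects unimodality **and** Silverman
finds ≥ 2 modes.

*Wilcoxon.*  The signed-rank test (used to compare OC between groups of
clades) is exact for n ≤ 25 — a dynamic-programming enumeration of all 2ⁿ
sign assignments with mid-ranked ties, ranks doubled to stay integral —
and a tie/continuity-corrected normal approximation beyond.  Because
correct and incorrect clades form unpaired groups, an unpaired rank-sum
companion (`rank_sum_test`) is provided as well; outputs state which test
was used.

## Synthetic data

The simulator emulates the data regimes the method targets, not their
generative mechanisms:

* **Heterogeneity** is a finite mixture of gene-tree topologies (e.g. a
  50/50 nearest-neighbor-interchange pair), not coalescent sampling.  This
  reproduces the operative property — a controlled discordance frequency —
  with exactness: mixture weights are realized by largest-remainder
  allocation so a nominal 50/50 is not blurred by allocation noise.
  Passing tests therefore demonstrate that NBS recovers the *frequency* of
  a conflicting signal; they say nothing about coalescent branch-length
  signatures, which the method does not use.
* **GTEE regimes** scale all branch lengths uniformly (0.1 / 0.07 / 0.05
  for low / medium / high error), starving per-gene trees of substitutions
  while keeping the concatenated signal consistent.
* **Sequence evolution** is Jukes–Cantor only (uniform root, per-branch
  change probability `(3/4)(1 − e^{−4t/3})`, independent sites).  No rate
  heterogeneity, indels, or compositional bias; richer models belong to
  external simulators and would stress the distance engine rather than
  the support statistics.
* **Gene lengths** can be lognormal with the shape solved numerically for
  a target population skewness (matching the long right tail of empirical
  gene-length distributions, e.g. skewness ≈ 3.2 at mean ≈ 970 bp); note
  the *sample* skewness of a lognormal is noisy and right-heavy, so tests
  check the median over repeated draws.
* **Missing data** replaces a per-taxon fraction of residues with '?'.
  The coverage profile (`mf`, the missing/ambiguous/gap fraction per
  taxon) drives the published policy: warn above 50%, optionally drop at
  ≥ 95%, never below 4 remaining taxa.  IUPAC partial ambiguities count as
  missing for `mf` but pass through to engines untouched.

Gene boundaries are recorded in the partition map but deliberately ignored
by the NBS pipeline (sites are subsampled without regard to biological
annotation); they exist for diagnostics and evaluation only.

## Problem sizes in the test suite

Tests and the acceptance script run on reduced designs chosen to leave the
statistical phenomena intact: homogeneous recovery uses 20 taxa × 50,000
sites; heterogeneity detection uses a 16-taxon 50/50 mixture of 100 genes
× 1,600 sites analyzed with 30 initial subsamples (the larger `s0` gives
the modality tests a usable sample size, mirroring exploratory analyses
that use on the order of 100 subsamples); the dip calibration check uses
500 uniform samples of size 100 against fresh 2,000-sample Monte Carlo
calibrations.  These sizes are the package's own trade-off between
statistical resolution and a test suite that runs in well under a minute
per property.

## Known limitations

* The built-in engine is distance-based; model misspecification effects on
  NBS under ML engines are untested here.
* A 50/50 mixture leaves the contested clade's NBS a near-fair coin
  average over subsamples; with moderate `S` its NBS has a sampling
  standard deviation of ≈ `100/(2√S)` points, which the adaptive rule
  bounds but does not eliminate.
* The dip test's Monte Carlo null (uniform) is the conventional
  calibration; it is conservative for peaked unimodal alternatives.
* Greedy consensus beyond the majority-rule set is order-dependent in
  principle; ties are broken by descending NBS then canonical clade mask,
  so output is deterministic.
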