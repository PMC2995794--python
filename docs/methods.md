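# Methods

## Signal model and smoothing

Input is an `n_probes × n_samples` matrix of normalised log2 ratios with
1-based bp probe positions on an ordered set of chromosomes. All scores
are evaluated on a regular per-chromosome grid of sampling points at
spacing/2, 3·spacing/2, … (default spacing 50 kb); the grid never spans a
chromosome boundary. We parameterize grid resolution by spacing in bp
rather than by a point count because spacing is directly interpretable
against kernel width and aberration size; every run reports the
resulting point count.

The KC score at grid point x is the Nadaraya–Watson (local-constant
weighted regression) estimate with a truncated Gaussian kernel:

    KC(x) = Σᵢ k(posᵢ − x) sᵢ / Σᵢ k(posᵢ − x),
    k(δ)  = exp(−δ²/2σ²) for |δ| ≤ width, else 0,  σ = width/4.

Choices and their reasons:

* **σ = width/4, truncation at ±width.** The user-facing "kernel width"
  then spans ≈4σ (95% of the kernel mass), so a 200 kb kernel is matched
  to ~200 kb aberrations. Weights are exactly zero beyond the width, so
  perturbing one probe can only affect grid points within one width of
  it on the same chromosome (a tested locality property).
* **Local-constant (not higher-order) weighting.** Dividing by the
  kernel-weighted probe mass is the simplest locally weighted regression
  that corrects unequal probe spacing exactly: a constant signal maps to
  that constant at every covered point regardless of probe density
  (tested for uniform and log-normal-gap spacings). It also makes the
  smoother linear in the signal with a shared denominator across
  samples, so the sum of per-sample profiles equals the profile of the
  summed signal — an identity the tests exploit.
* **Coverage floor.** Where the weight mass falls below 1e−8 (kernel
  peak weight is 1) the point sits in a probe desert (e.g. a
  centromere); its score is defined as 0 and flagged uncovered rather
  than risking 0/0. A warning is emitted when the largest inter-probe
  gap on a chromosome exceeds the kernel support.
* **Cost.** The weight matrix is built per chromosome by sorted-window
  search and stored sparse, so one geometry serves any number of signal
  vectors; total cost is O(n_probes + n_points · probes-in-support),
  linear in probes and samples. The empirical doubling ratio is measured
  by the acceptance script.

## Recurrent (one-class) analysis

Per-probe ratios are summed across samples; the summed signal is split
into gain = max(s, 0) and loss = max(−s, 0), and each channel is
smoothed separately. The null model shuffles the summed values across
all genome-wide probe positions (positions fixed, values permuted),
re-splits and re-smooths, and records the genome-wide maximum KC score
per channel; the significance threshold is the empirical (1−α) quantile
(type-7 linear interpolation) of those maxima. This preserves the
marginal intensity distribution while destroying positional clustering —
exactly the structure the KC score detects — and its cost is independent
of sample count because only the summed vector is permuted. A single
genome-wide threshold per channel gives family-wise control: on null
data the probability that any point exceeds the threshold ≈ α (verified
by a 200-replicate calibration in the acceptance suite). Gains and
losses are thresholded independently, since their null maxima differ
when the data are asymmetric. Requesting α < 1/n_perms is rejected
rather than extrapolated.

Maximal runs of grid points above the threshold become regions, extended
by spacing/2 on each side and clipped to the chromosome; the exceedance
is strict (KC > threshold), so an all-zero cohort with a zero threshold
calls nothing. The scale-space analysis repeats the full pipeline for a
strictly increasing list of widths, each width standalone with the same
master seed; the per-point significance level inside significant regions
is −log10(max(1, #{null maxima ≥ KC(x)})/n_perms), bounded by
log10(n_perms), and 0 elsewhere. The colour scale of the scale-space
heatmap is this quantity directly.

## Comparative (two-class) analysis

Each sample's signed profile is smoothed individually (no gain/loss
split — direction is meaningful here). At every grid point,

    SNR(i) = (μ¹(i) − μ²(i)) / (σ_pooled(i) + f),

with σ_pooled the square root of the standard two-sample pooled variance
(≥1 df per class required, hence ≥2 samples per class) and f the 95th
percentile (type-7) of σ_pooled over all grid points. The denominator is
on the SD scale — f is defined on that scale and must be addable to the
noise term; SD is also the conventional SNR denominator. A zero
denominator with f = 0 is an error at points with a nonzero class
difference (the statistic is undefined there), while fully degenerate
inputs (no variation and no difference) are handled gracefully.

Class labels are permuted preserving group sizes, with f recomputed per
permutation so the permuted statistic is exchangeable with the observed
one. The plug-in FDR estimate at candidate threshold t is

    FDR̂(t) = mean over permutations of #{i: |SNR_perm(i)| ≥ t}
              / #{i: |SNR_obs(i)| ≥ t},   clipped to [0, 1],

with no π₀ correction (a conservative simplification; π₀ estimation is a
possible refinement). The working threshold is the smallest observed
|SNR| with FDR̂ ≤ target, or +∞ (no calls) when none qualifies. Calls use
|SNR| ≥ threshold: because the threshold is itself an observed value,
a strict inequality would silently drop the very point that defines it.
FDR is controlled per sampling point, not per region. Points with
SNR ≥ thr form diff_up regions (class 1 higher), points with
SNR ≤ −thr form diff_down, with the same run/boundary rules as the
recurrent caller; a single symmetric threshold on |SNR| covers both
directions. Label exchange exactly negates SNR, swaps the two channels
and leaves the threshold unchanged; adding a constant to every profile,
or scaling all profiles by c > 0, leaves SNR unchanged (f scales with
the data). These invariances are asserted in the tests.

## Synthetic cohorts

The generator writes interval-shaped aberrations (log2 effect, carrier
fraction, whole-cohort or one class) on top of i.i.d. Gaussian probe
noise, with uniform or log-normal inter-probe gaps. Default conditions:
probe noise SD 0.3 log2 units (typical array noise), effects quoted in
log2 units (+0.58 ≈ one extra copy in a diploid background, −1.0 a
heterozygous-scale loss), genomes of two 20–50 Mb chromosomes with
500–800 probes each (25–100 kb spacing, from oligo-array-dense to
BAC-like), cohorts of 10–20 samples. Identical seeds give bit-identical
cohorts.

What the generator does *not* emulate: wave/GC artefacts, segmental
autocorrelation of noise, tumour-cell-fraction dilution, platform
dye bias. Passing calibration and recovery tests therefore demonstrate
correctness of the statistics under clean assumptions, not robustness to
real-array artefacts; autocorrelated noise is the obvious extension
hook.

Recovery is scored on bp intervals: per-truth-region Jaccard against the
best same-channel call, plus genome-wide bp sensitivity (truth covered
by same-channel calls) and specificity (non-truth bp left uncalled).

## Numerical and reproducibility details

* Quantiles everywhere are empirical type-7 (numpy default).
* One master seed per analysis; per-permutation RNG streams are spawned
  from it (`SeedSequence.spawn`), so results are reproducible and can be
  extended in n_perms without replaying earlier permutations.
* Probe tables are loaded with round-trip float parsing, so write→read
  is bitwise exact; duplicate (chrom, pos) rows are averaged (replicate
  spots are common on BAC arrays), unsorted input is re-sorted with a
  warning, and rows with missing ratios are dropped by default (the
  summation and pooled-variance steps need complete rows) or
  zero-imputed on request; only explicit NA markers qualify — any other
  non-numeric ratio is a data error.
* Coordinates are 1-based bp internally; BED export is 0-based
  half-open with scores rescaled to [0, 1000] by the file maximum.
* Plot files are not bit-stable across matplotlib versions; determinism
  guarantees apply to the TSV/BED/JSON outputs.

## Known limitations

* The permutation null assumes exchangeable probe values genome-wide;
  strong ploidy shifts or wave artefacts violate this and inflate the
  null (conservative for focal events, anticonservative for broad ones).
* With probe spacing at or above the kernel width the smoother
  degenerates to nearest-probe interpolation and the permutation null
  maxima concentrate on the (permutation-invariant) maximum probe value;
  significance decisions at such scales rest on tiny adjacency effects
  and should not be trusted. Choose kernel widths of at least a few
  median probe spacings.
* Cohort-level recurrent signal strength grows as √n_samples after
  summation, so even "low-amplitude" per-sample events become
  individually prominent probes in large cohorts and can surface at
  small kernel widths as isolated specks; the scale-space view shows a
  broad event as a contiguous block only at matching widths.
* FDR control in the comparative mode is per sampling point; adjacent
  points are strongly dependent through the kernel, so the count of
  significant *regions* is not FDR-controlled.
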