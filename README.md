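# kcscan

Kernel-convolution detection of recurrent and class-specific DNA
copy-number aberrations in multi-sample aCGH data.

## The problem

Array CGH measures DNA copy number as log2 ratios of tumour versus
diploid-control hybridization intensity at probes scattered along the
genome. Tumour samples are heterogeneous cell mixtures, so the measured
ratios are continuous dosage averages; discretizing them into
gain/no-change/loss states before looking for recurrent events throws
that information away. `kcscan` works on the continuous signal directly:

* **Recurrent aberrations** (which regions are gained or lost again and
  again across a cohort?) — the per-probe log2 ratios are summed over all
  samples, split into a non-negative gain part and loss part, and each
  part is smoothed onto a regular genomic grid with a truncated Gaussian
  kernel using Nadaraya–Watson (local-constant) weighting,

      KC(x) = Σᵢ k(posᵢ − x)·sᵢ / Σᵢ k(posᵢ − x),

  the *KC score*. Normalising by the kernel-weighted probe mass corrects
  for unevenly spaced probes. Significance is assessed by shuffling the
  summed probe values across genome-wide probe positions: each
  permutation is re-split and re-smoothed and its genome-wide maximum KC
  score recorded; the threshold is the empirical (1−α) quantile of those
  maxima, a family-wise (genome-wide) criterion. Repeating the analysis
  over a ladder of kernel widths — the *scale space* — separates focal
  events from broad, low-amplitude ones.

* **Class-specific aberrations** (which regions differ between, say,
  HER2-positive and HER2-negative tumours, or B- and T-cell lymphomas?)
  — each sample's signed profile is smoothed individually and at every
  grid point *i* a regularized signal-to-noise ratio is computed,

      SNR(i) = (μ¹(i) − μ²(i)) / (σ_pooled(i) + f),

  where μ¹, μ² are the class means of the per-sample KC scores,
  σ_pooled the two-class pooled standard deviation, and *f* — the 95th
  percentile of σ_pooled across all grid points — keeps near-zero
  variances from dominating. The |SNR| threshold at a target FDR comes
  from class-label permutations (f recomputed per shuffle).

A synthetic-cohort generator with known ground truth (spiked recurrent
gains, class-exclusive deletions mimicking VDJ-recombination losses,
uniform or log-normal probe spacing) makes every stage testable without
external data.

## Worked example

`examples/recurrent_scan.py` simulates 20 profiles with a 1 Mb gain
(+0.58 log2, i.e. roughly one extra copy, carried by 80% of samples,
probe noise SD 0.3) and runs the recurrent analysis at a 1 Mb kernel:

```
cohort: 20 samples x 1000 probes, 17 carriers of the spiked gain
permutation thresholds: gain 2.843, loss 1.327 (alpha=0.05, FWER)
called gain regions (peak KC = summed log2-ratio scale):
chrom  start_bp   end_bp channel    score  n_points
 chr1   9850000 11150000    gain 9.557095        26
recovery vs truth: Jaccard 0.77, sensitivity 1.00, specificity 0.994
```

The peak KC score of 9.56 is on the summed-ratio scale (17 carriers ×
0.58 ≈ 9.9, shrunk slightly by smoothing across the region edges); it
clears the permutation threshold of 2.84, and the called interval
overlaps the true 10–11 Mb gain with Jaccard 0.77.
`examples/two_group_comparison.py` and `examples/scale_space_overview.py`
walk through the comparative and multi-scale analyses the same way.

## Command line

The same pipelines are available as a thin CLI:

```sh
kcscan simulate  --layout layout.tsv --n-probes 500 --n1 10 --n2 10 \
                 --spec chr1:8000000:9000000:-1.0:1.0:class1 --out-prefix sim_
kcscan recurrent --input sim_probes.tsv --layout layout.tsv --out-prefix rec_
kcscan compare   --input sim_probes.tsv --layout layout.tsv \
                 --labels sim_labels.tsv --kernel-width 200000 --out-prefix cmp_
kcscan scalespace --input sim_probes.tsv --layout layout.tsv \
                 --kernel-width 200000 --kernel-width 1000000 --out-prefix ss_
```

Each run writes TSV profiles, BED regions, a genome-wide plot and a JSON
run log (all resolved parameters, including the seed) sufficient to
reproduce the outputs byte for byte.

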