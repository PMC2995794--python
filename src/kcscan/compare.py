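"""Two-class differential copy-number analysis.

Each sample's signed log2-ratio profile is kernel-smoothed individually,
and at every sampling point i a regularized signal-to-noise ratio is
computed:

    SNR(i) = (mu1(i) - mu2(i)) / (sd_pooled(i) + f)

where mu1, mu2 are the group means of the per-sample KC scores,
sd_pooled is the two-group pooled standard deviation, and the
regularization factor f is the 95th percentile of the pooled standard
deviation across all sampling points — it stops near-zero variances from
dominating the statistic. Significance is assessed by shuffling the class
labels (group sizes preserved, f and SNR recomputed per shuffle) and
choosing the smallest observed |SNR| whose plug-in false-discovery-rate
estimate

    FDR_hat(t) = mean_perm #{i : |SNR_perm(i)| >= t} / #{i : |SNR_obs(i)| >= t}

is at or below the user's target; points with |SNR| >= that threshold are
called, split by sign into diff_up (group 1 higher) and diff_down runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (ProbeMatrix, RegionSet, SamplePointGrid,
                         regions_from_mask)
from .kernel import KernelSpec, per_sample_kc


@dataclass(frozen=True)
class ClassLabels:
    """Per-sample two-class assignment (labels 1 and 2, each group >= 2
    samples so the pooled variance has at least one df per group)."""

    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        bad = sorted({l for l in self.labels} - {1, 2})
        if bad:
            raise ValueError(f"labels must be 1 or 2, got {bad}")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each class needs at least 2 samples "
                             f"(got n1={self.n1}, n2={self.n2})")

    @property
    def n1(self) -> int:
        return sum(1 for l in self.labels if l == 1)

    @property
    def n2(self) -> int:
        return sum(1 for l in self.labels if l == 2)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=np.int64)

    @classmethod
    def from_file(cls, path: str | Path, sample_ids: "tuple[str, ...]") -> "ClassLabels":
        """Read a two-column (sample_id, label) TSV, header optional, and
        align it to ``sample_ids``; unmatched ids on either side raise."""
        df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                         names=["sample_id", "label"])
        if df.iloc[0, 0] == "sample_id":
            df = df.iloc[1:].reset_index(drop=True)
        mapping = dict(zip(df["sample_id"], df["label"]))
        missing = [s for s in sample_ids if s not in mapping]
        extra = [s for s in mapping if s not in sample_ids]
        if missing or extra:
            raise ValueError(
                "label file does not match the sample columns; "
                f"missing labels for {missing}, labels without samples {extra}")
        try:
            labels = tuple(int(mapping[s]) for s in sample_ids)
        except ValueError:
            raise ValueError("class labels must be the integers 1 and 2") from None
        return cls(labels)


@dataclass
class ComparativeResult:
    """Everything the SNR analysis produced at each sampling point."""

    grid: SamplePointGrid | None
    labels: ClassLabels
    mu1: np.ndarray
    mu2: np.ndarray
    pooled_sd: np.ndarray
    f: float
    snr: np.ndarray
    fdr: float
    thr: float
    regions: RegionSet | None
    null_exceedance: np.ndarray  #: per-permutation count of |SNR_perm| >= thr


def _group_masks(labels: ClassLabels) -> tuple[np.ndarray, np.ndarray]:
    arr = labels.as_array()
    return arr == 1, arr == 2


def pooled_sd(profiles: np.ndarray, labels: ClassLabels) -> np.ndarray:
    """Two-group pooled standard deviation per sampling point:
    sqrt(((n1-1) var1 + (n2-1) var2) / (n1 + n2 - 2)) with unbiased
    within-group variances."""
    profiles = np.asarray(profiles, dtype=np.float64)
    if profiles.shape[0] != len(labels.labels):
        raise ValueError("profiles rows must match number of labels")
    m1, m2 = _group_masks(labels)
    n1, n2 = labels.n1, labels.n2
    v1 = profiles[m1].var(axis=0, ddof=1)
    v2 = profiles[m2].var(axis=0, ddof=1)
    return np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))


def regularization_factor(profiles: np.ndarray, labels: ClassLabels) -> float:
    """95th percentile (type-7) of the pooled SD across sampling points."""
    return float(np.quantile(pooled_sd(profiles, labels), 0.95))


def snr_statistic(profiles: np.ndarray, labels: ClassLabels,
                  f: float) -> np.ndarray:
    """Regularized signal-to-noise ratio per sampling point."""
    if f < 0:
        raise ValueError("regularization factor f must be non-negative")
    profiles = np.asarray(profiles, dtype=np.float64)
    m1, m2 = _group_masks(labels)
    denom = pooled_sd(profiles, labels) + f
    if np.any(denom == 0):
        raise ValueError(
            "zero pooled SD with f = 0 at some points; use a nonzero "
            "regularization factor to keep the statistic defined")
    return (profiles[m1].mean(axis=0) - profiles[m2].mean(axis=0)) / denom


def _snr_for_labels(profiles: np.ndarray, label_arr: np.ndarray) -> np.ndarray:
    """SNR for an arbitrary permuted label vector; points where the permuted
    denominator is zero (both permuted groups internally constant) get 0."""
    m1 = label_arr == 1
    m2 = ~m1
    n1, n2 = int(m1.sum()), int(m2.sum())
    v1 = profiles[m1].var(axis=0, ddof=1)
    v2 = profiles[m2].var(axis=0, ddof=1)
    sd = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    f = float(np.quantile(sd, 0.95))
    denom = sd + f
    diff = profiles[m1].mean(axis=0) - profiles[m2].mean(axis=0)
    out = np.zeros_like(diff)
    ok = denom > 0
    out[ok] = diff[ok] / denom[ok]
    return out


def snr_fdr_threshold(profiles: np.ndarray, labels: ClassLabels,
                      fdr_target: float = 0.05, n_perms: int = 500,
                      seed: int = 0, grid: SamplePointGrid | None = None,
                      ) -> tuple[float, ComparativeResult]:
    """Class-label permutation threshold on |SNR| at a target FDR.

    The threshold is the smallest observed |SNR| value whose plug-in FDR
    estimate (clipped to [0, 1]) is at or below ``fdr_target``; if no value
    qualifies the threshold is +inf and nothing is called. f is recomputed
    for every permutation so the permuted statistic is exchangeable with
    the observed one. Deterministic given ``seed``.
    """
    if not 0 < fdr_target < 1:
        raise ValueError("fdr_target must lie in (0, 1)")
    if n_perms < 20:
        raise ValueError("need at least 20 permutations for a stable FDR")
    profiles = np.asarray(profiles, dtype=np.float64)

    psd = pooled_sd(profiles, labels)
    f = float(np.quantile(psd, 0.95))
    denom = psd + f
    if np.any(denom == 0):
        # degenerate points: no within-group variation anywhere relevant;
        # a zero mean difference there carries no evidence (SNR 0), but a
        # nonzero one is genuinely undefined
        m1_, m2_ = _group_masks(labels)
        diff = profiles[m1_].mean(axis=0) - profiles[m2_].mean(axis=0)
        if np.any(diff[denom == 0] != 0):
            raise ValueError(
                "zero pooled SD with f = 0 at points with a nonzero group "
                "difference; the SNR statistic is undefined there")
        snr = np.zeros_like(diff)
        ok = denom > 0
        snr[ok] = diff[ok] / denom[ok]
    else:
        snr = snr_statistic(profiles, labels, f)
    abs_obs_sorted = np.sort(np.abs(snr))
    n_points = len(snr)

    lab = labels.as_array()
    null_abs = np.empty((n_perms, n_points))
    children = np.random.SeedSequence(seed).spawn(n_perms)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        null_abs[i] = np.abs(_snr_for_labels(profiles, rng.permutation(lab)))
    null_sorted = np.sort(null_abs.ravel())

    candidates = np.unique(abs_obs_sorted)
    obs_ge = n_points - np.searchsorted(abs_obs_sorted, candidates, side="left")
    null_ge = (len(null_sorted)
               - np.searchsorted(null_sorted, candidates, side="left")) / n_perms
    fdr_hat = np.clip(null_ge / obs_ge, 0.0, 1.0)
    qualifying = np.flatnonzero(fdr_hat <= fdr_target)
    thr = float(candidates[qualifying[0]]) if len(qualifying) else np.inf

    if np.isinf(thr):
        null_exceedance = np.zeros(n_perms)
    else:
        null_exceedance = (null_abs >= thr).sum(axis=1).astype(np.float64)

    m1, m2 = _group_masks(labels)
    result = ComparativeResult(
        grid=grid, labels=labels,
        mu1=profiles[m1].mean(axis=0), mu2=profiles[m2].mean(axis=0),
        pooled_sd=psd, f=f, snr=snr, fdr=fdr_target, thr=thr,
        regions=None, null_exceedance=null_exceedance)
    if grid is not None:
        result.regions = call_differential_regions(result, grid)
    return thr, result


def call_differential_regions(result: ComparativeResult,
                              grid: SamplePointGrid) -> RegionSet:
    """Runs of SNR >= thr become diff_up regions, runs of SNR <= -thr
    diff_down; boundary/merge rules match the unsupervised region caller."""
    if np.isinf(result.thr):
        return RegionSet([], layout=grid.layout)
    up = regions_from_mask(result.snr >= result.thr, result.snr, grid, "diff_up")
    down = regions_from_mask(result.snr <= -result.thr, result.snr, grid, "diff_down")
    return RegionSet(list(up) + list(down), layout=grid.layout)


def compare_classes(pm: ProbeMatrix, labels: ClassLabels,
                    grid: SamplePointGrid, kernel: KernelSpec,
                    fdr_target: float = 0.05, n_perms: int = 500,
                    seed: int = 0) -> ComparativeResult:
    """Full supervised run on a probe matrix: per-sample smoothing of the
    signed ratios (no gain/loss split), then the SNR/FDR analysis."""
    if len(labels.labels) != pm.n_samples:
        raise ValueError("labels must cover every sample")
    profiles = per_sample_kc(pm, grid, kernel)
    _, result = snr_fdr_threshold(profiles, labels, fdr_target=fdr_target,
                                  n_perms=n_perms, seed=seed, grid=grid)
    return result
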