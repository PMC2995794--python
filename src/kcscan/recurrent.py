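"""Recurrent copy-number aberration detection across a sample set.

Pipeline: sum per-probe log2 ratios across samples, split the summed
signal into non-negative gain and loss channels, smooth each channel onto
the grid (KC scores), and compare against a permutation null. The null
shuffles the summed per-probe values across genome-wide probe positions
(positions fixed, values permuted), re-splits the channels, re-smooths,
and records the genome-wide maximum KC score per channel; the significance
threshold is the empirical (1 - alpha) quantile of those maxima, i.e. a
family-wise (genome-wide) error criterion. Repeating the analysis over a
strictly increasing list of kernel widths — the scale space — reveals
aberrations at different genomic scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_model import ProbeMatrix, RegionSet, SamplePointGrid, regions_from_mask
from .kernel import KCProfile, KernelSmoother, KernelSpec, split_gain_loss


@dataclass
class PermutationNull:
    """Genome-wide maximum KC score for each permutation of one channel."""

    n_perms: int
    seed: int
    per_perm_max: np.ndarray
    channel: str

    def __post_init__(self) -> None:
        self.per_perm_max = np.asarray(self.per_perm_max, dtype=np.float64)
        if len(self.per_perm_max) != self.n_perms:
            raise ValueError("need one maximum per permutation")
        if np.any(self.per_perm_max < 0):
            raise ValueError("channel maxima must be non-negative")


@dataclass
class SignificanceResult:
    """One channel's profile, its permutation threshold and the regions
    whose KC scores exceed it."""

    profile: KCProfile
    threshold: float
    alpha: float
    regions: RegionSet
    null: PermutationNull


@dataclass
class ScaleSpaceResult:
    """Per-width unsupervised results plus the width x grid-point
    significance-level matrices (-log10 empirical p, 0 where not
    significant) for each channel."""

    kernel_widths: tuple[float, ...]
    gain: list[SignificanceResult]
    loss: list[SignificanceResult]
    levels_gain: np.ndarray
    levels_loss: np.ndarray
    grid: SamplePointGrid

    def combined_levels(self) -> np.ndarray:
        return np.maximum(self.levels_gain, self.levels_loss)


def summed_kc(pm: ProbeMatrix, grid: SamplePointGrid,
              kernel: KernelSpec) -> tuple[KCProfile, KCProfile]:
    """KC profiles of the across-sample summed signal, per channel."""
    sm = KernelSmoother(pm.chrom, pm.pos, grid, kernel)
    g, l = split_gain_loss(pm.ratios.sum(axis=1))
    vals = sm.smooth_columns(np.column_stack([g, l]))
    gain = KCProfile(grid, vals[:, 0], "gain", kernel, sm.weight_mass)
    loss = KCProfile(grid, vals[:, 1], "loss", kernel, sm.weight_mass)
    return gain, loss


def permutation_maxima(smoother: KernelSmoother, summed_signal: np.ndarray,
                       n_perms: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-permutation genome-wide max KC per channel.

    Each permutation shuffles the summed per-probe values across all probe
    positions genome-wide, re-splits gains/losses and re-smooths. Streams
    are spawned from one master seed so runs are reproducible and
    extendable in n_perms.
    """
    max_g = np.empty(n_perms)
    max_l = np.empty(n_perms)
    children = np.random.SeedSequence(seed).spawn(n_perms)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        perm = rng.permutation(summed_signal)
        g, l = split_gain_loss(perm)
        vals = smoother.smooth_columns(np.column_stack([g, l]))
        max_g[i] = vals[:, 0].max(initial=0.0)
        max_l[i] = vals[:, 1].max(initial=0.0)
    return max_g, max_l


def _check_alpha(alpha: float, n_perms: int) -> None:
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_perms < 1:
        raise ValueError("n_perms must be at least 1")
    if alpha < 1.0 / n_perms:
        raise ValueError(
            f"alpha={alpha} is below the permutation resolution; use at "
            f"least n_perms={math.ceil(1.0 / alpha)}")


def permutation_threshold(pm: ProbeMatrix, grid: SamplePointGrid,
                          kernel: KernelSpec, n_perms: int = 1000,
                          alpha: float = 0.05, seed: int = 0,
                          ) -> tuple[float, float, PermutationNull, PermutationNull]:
    """Permutation significance thresholds for the gain and loss channels.

    Thresholds are the empirical (1 - alpha) quantile (type-7 linear
    interpolation) of the per-permutation genome-wide channel maxima.
    """
    _check_alpha(alpha, n_perms)
    sm = KernelSmoother(pm.chrom, pm.pos, grid, kernel)
    s = pm.ratios.sum(axis=1)
    max_g, max_l = permutation_maxima(sm, s, n_perms, seed)
    thr_g = float(np.quantile(max_g, 1.0 - alpha))
    thr_l = float(np.quantile(max_l, 1.0 - alpha))
    return (thr_g, thr_l,
            PermutationNull(n_perms, seed, max_g, "gain"),
            PermutationNull(n_perms, seed, max_l, "loss"))


def call_regions(profile: KCProfile, threshold: float) -> RegionSet:
    """Maximal runs of grid points with KC strictly above the threshold,
    extended by spacing/2 per side and clipped to the chromosome."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    mask = profile.values > threshold
    return regions_from_mask(mask, profile.values, profile.grid, profile.channel)


def analyze_recurrent(pm: ProbeMatrix, grid: SamplePointGrid, kernel: KernelSpec,
                      n_perms: int = 1000, alpha: float = 0.05, seed: int = 0,
                      ) -> tuple[SignificanceResult, SignificanceResult]:
    """Full unsupervised run: summed KC, permutation thresholds, regions.

    Returns (gain, loss) results; the smoother is built once and shared by
    the observed profiles and the permutations.
    """
    _check_alpha(alpha, n_perms)
    sm = KernelSmoother(pm.chrom, pm.pos, grid, kernel)
    s = pm.ratios.sum(axis=1)
    g, l = split_gain_loss(s)
    vals = sm.smooth_columns(np.column_stack([g, l]))
    gain = KCProfile(grid, vals[:, 0], "gain", kernel, sm.weight_mass)
    loss = KCProfile(grid, vals[:, 1], "loss", kernel, sm.weight_mass)
    max_g, max_l = permutation_maxima(sm, s, n_perms, seed)
    thr_g = float(np.quantile(max_g, 1.0 - alpha))
    thr_l = float(np.quantile(max_l, 1.0 - alpha))
    res_g = SignificanceResult(gain, thr_g, alpha, call_regions(gain, thr_g),
                               PermutationNull(n_perms, seed, max_g, "gain"))
    res_l = SignificanceResult(loss, thr_l, alpha, call_regions(loss, thr_l),
                               PermutationNull(n_perms, seed, max_l, "loss"))
    return res_g, res_l


def _significance_levels(result: SignificanceResult) -> np.ndarray:
    """-log10 empirical p of each significant point's KC score under the
    null-max distribution; 0 outside significant regions."""
    values = result.profile.values
    maxima = np.sort(result.null.per_perm_max)
    n = result.null.n_perms
    mask = values > result.threshold
    counts = n - np.searchsorted(maxima, values, side="left")
    p = np.maximum(1, counts) / n
    levels = np.where(mask, -np.log10(p), 0.0)
    return levels


def scale_space(pm: ProbeMatrix, grid: SamplePointGrid,
                kernel_widths: "list[float] | tuple[float, ...]",
                n_perms: int = 1000, alpha: float = 0.05,
                seed: int = 0) -> ScaleSpaceResult:
    """Repeat the unsupervised analysis across a strictly increasing list
    of kernel widths; each width runs standalone with the same seed."""
    widths = tuple(float(w) for w in kernel_widths)
    if len(widths) == 0:
        raise ValueError("need at least one kernel width")
    if any(b <= a for a, b in zip(widths, widths[1:])):
        raise ValueError("kernel widths must be strictly increasing")
    gains, losses = [], []
    lv_g = np.zeros((len(widths), grid.n_points))
    lv_l = np.zeros((len(widths), grid.n_points))
    for k, w in enumerate(widths):
        res_g, res_l = analyze_recurrent(pm, grid, KernelSpec(w),
                                         n_perms=n_perms, alpha=alpha, seed=seed)
        gains.append(res_g)
        losses.append(res_l)
        lv_g[k] = _significance_levels(res_g)
        lv_l[k] = _significance_levels(res_l)
    return ScaleSpaceResult(widths, gains, losses, lv_g, lv_l, grid)
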