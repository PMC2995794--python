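"""Kernel-convolution smoothing of probe log2 ratios onto a sampling grid.

The KC score at a grid point x is the Nadaraya–Watson (local-constant
weighted regression) estimate

    KC(x) = sum_i k(pos_i - x) * s_i / sum_i k(pos_i - x)

with a truncated Gaussian kernel k. Normalising by the kernel-weighted
probe mass corrects for unequally spaced probes: a constant signal maps to
a constant profile regardless of probe density. Smoothing never crosses a
chromosome boundary, and points whose probe mass falls below a floor
(probe deserts such as centromeres) are reported as 0 and flagged
uncovered.

The sparse weight matrix depends only on probe and grid positions, so one
:class:`KernelSmoother` serves every signal vector on the same geometry —
this is what makes the permutation tests cheap, and it keeps the cost
O(n_probes + n_points * probes-in-support).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .data_model import ProbeMatrix, SamplePointGrid

#: Kernel weights peak at 1; below this total mass a point counts as uncovered.
MASS_FLOOR = 1e-8


@dataclass(frozen=True)
class KernelSpec:
    """Truncated Gaussian smoothing kernel.

    ``width`` is the user-facing kernel size in bp and sets the genomic
    scale of detectable aberrations: sigma = width/4 (so the width spans
    about 4 sigma, ~95% of the kernel mass) and weights are exactly zero
    beyond |delta| > width.
    """

    width: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("kernel width must be positive")
        if self.shape != "gaussian":
            raise ValueError("only the gaussian kernel is implemented")

    @property
    def sigma(self) -> float:
        return self.width / 4.0

    @property
    def support(self) -> float:
        return self.width

    def weight(self, delta: np.ndarray) -> np.ndarray:
        delta = np.asarray(delta, dtype=np.float64)
        w = np.exp(-(delta ** 2) / (2.0 * self.sigma ** 2))
        w[np.abs(delta) > self.support] = 0.0
        return w


@dataclass
class KCProfile:
    """Smoothed scores on a grid for one channel, with the geometry that
    produced them and the per-point kernel weight mass (probe density)."""

    grid: SamplePointGrid
    values: np.ndarray
    channel: str
    kernel: KernelSpec
    weight_mass: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.weight_mass = np.asarray(self.weight_mass, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("KC profile contains non-finite values")
        if self.channel in ("gain", "loss") and np.any(self.values < 0):
            raise ValueError(f"{self.channel} profile must be non-negative")

    @property
    def covered(self) -> np.ndarray:
        return self.weight_mass >= MASS_FLOOR


def split_gain_loss(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a signed signal into its non-negative gain and loss parts,
    with gain - loss == signal and gain * loss == 0 elementwise."""
    signal = np.asarray(signal, dtype=np.float64)
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite entries")
    return np.maximum(signal, 0.0), np.maximum(-signal, 0.0)


class KernelSmoother:
    """Precomputed sparse kernel-weight operator for one probe/grid geometry.

    Builds the (n_points x n_probes) truncated-Gaussian weight matrix per
    chromosome via sorted-position windowing, records the per-point weight
    mass, and smooths any number of signal vectors against it.
    """

    def __init__(self, chrom: np.ndarray, pos: np.ndarray,
                 grid: SamplePointGrid, kernel: KernelSpec):
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.float64)
        if len(chrom) != len(pos):
            raise ValueError("chrom and pos must have equal length")
        self.grid = grid
        self.kernel = kernel
        self.n_probes = len(pos)

        layout = grid.layout
        probe_slices: dict[str, slice] = {}
        start = 0
        for name in layout.names:
            n = int(np.sum(chrom == name))
            probe_slices[name] = slice(start, start + n)
            start += n
        if start != len(pos):
            raise ValueError("probes reference chromosomes outside the layout")

        rows_all, cols_all, w_all = [], [], []
        support = kernel.support
        for name, _length in layout:
            psl = probe_slices[name]
            gsl = grid.chrom_slice(name)
            p = pos[psl]
            x = grid.x[gsl]
            if len(x) == 0:
                continue
            if len(p) == 0:
                warnings.warn(f"chromosome {name} has grid points but no probes; "
                              "its profile will be zero", stacklevel=2)
                continue
            if len(p) > 1 and np.max(np.diff(p)) > support:
                warnings.warn(
                    f"largest inter-probe gap on {name} exceeds the kernel "
                    f"support ({support:g} bp); some points will be uncovered",
                    stacklevel=2)
            lo = np.searchsorted(p, x - support, side="left")
            hi = np.searchsorted(p, x + support, side="right")
            counts = hi - lo
            total = int(counts.sum())
            if total == 0:
                continue
            local_rows = np.repeat(np.arange(len(x)), counts)
            offsets = np.repeat(np.concatenate(([0], np.cumsum(counts)[:-1])), counts)
            local_cols = (np.arange(total) - offsets) + np.repeat(lo, counts)
            delta = p[local_cols] - x[local_rows]
            w = np.exp(-(delta ** 2) / (2.0 * kernel.sigma ** 2))
            rows_all.append(local_rows + gsl.start)
            cols_all.append(local_cols + psl.start)
            w_all.append(w)

        if rows_all:
            rows = np.concatenate(rows_all)
            cols = np.concatenate(cols_all)
            ws = np.concatenate(w_all)
        else:
            rows = cols = np.empty(0, dtype=np.int64)
            ws = np.empty(0, dtype=np.float64)
        self.weights = sparse.csr_matrix(
            (ws, (rows, cols)), shape=(grid.n_points, self.n_probes))
        self.weight_mass = np.asarray(self.weights.sum(axis=1)).ravel()
        self.covered = self.weight_mass >= MASS_FLOOR

    def smooth(self, signal: np.ndarray) -> np.ndarray:
        """Nadaraya–Watson smooth one signal vector; uncovered points -> 0."""
        signal = np.asarray(signal, dtype=np.float64)
        if len(signal) != self.n_probes:
            raise ValueError("signal length does not match probe count")
        num = self.weights @ signal
        out = np.zeros(self.grid.n_points)
        out[self.covered] = num[self.covered] / self.weight_mass[self.covered]
        return out

    def smooth_columns(self, signals: np.ndarray) -> np.ndarray:
        """Smooth several signals at once: (n_probes, k) -> (n_points, k)."""
        signals = np.asarray(signals, dtype=np.float64)
        if signals.shape[0] != self.n_probes:
            raise ValueError("signals must have n_probes rows")
        num = self.weights @ signals
        out = np.zeros_like(num)
        out[self.covered] = num[self.covered] / self.weight_mass[self.covered, None]
        return out


def kc_convolve(chrom: np.ndarray, pos: np.ndarray, signal: np.ndarray,
                grid: SamplePointGrid, kernel: KernelSpec,
                channel: str = "signed") -> KCProfile:
    """Smooth one per-probe signal onto the grid (see module docstring).

    Probes must be sorted in layout order; the convolution never crosses a
    chromosome boundary and points with weight mass below the floor get 0.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if len(signal) != len(pos):
        raise ValueError("signal length must equal number of probes")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite entries")
    sm = KernelSmoother(chrom, pos, grid, kernel)
    return KCProfile(grid=grid, values=sm.smooth(signal), channel=channel,
                     kernel=kernel, weight_mass=sm.weight_mass)


def per_sample_kc(pm: ProbeMatrix, grid: SamplePointGrid,
                  kernel: KernelSpec) -> np.ndarray:
    """Smooth each sample's signed log2 ratios individually.

    Returns an (n_samples x n_points) matrix; every row shares the same
    weight-mass vector since the probe geometry is common to all samples.
    """
    sm = KernelSmoother(pm.chrom, pm.pos, grid, kernel)
    return sm.smooth_columns(pm.ratios).T
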