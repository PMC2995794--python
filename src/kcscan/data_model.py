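"""Core domain types and I/O for multi-sample aCGH copy-number analysis.

The analysis operates on three coordinate-bearing objects:

* :class:`GenomeLayout` — the ordered chromosomes and their lengths in bp.
  The layout order defines the concatenation order used for genome-wide
  plots and for sorting probes.
* :class:`ProbeMatrix` — per-probe genomic annotation plus an
  ``n_probes x n_samples`` matrix of normalised log2 ratios.
* :class:`SamplePointGrid` — the regular grid of genomic positions at
  which smoothed KC scores are evaluated (distinct from probe positions).

Coordinate conventions: input probe positions and all internal computation
are 1-based bp; BED export is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Region channels: recurrent gains/losses and two-class differences
#: (diff_up = group 1 above group 2, diff_down = group 1 below group 2).
CHANNELS = ("gain", "loss", "diff_up", "diff_down")


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp).

    The ordering is stable for a run and defines probe sort order and the
    left-to-right concatenation used in genome-wide plots.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths must have equal length")
        if len(self.names) == 0:
            raise ValueError("layout must contain at least one chromosome")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(str(k) for k in d), tuple(int(v) for v in d.values()))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column (chrom, length) tab-delimited file, no header."""
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                         dtype={"chrom": str})
        return cls(tuple(df["chrom"]), tuple(int(x) for x in df["length"]))

    def index(self, chrom: str) -> int:
        try:
            return self.names.index(chrom)
        except ValueError:
            raise KeyError(f"chromosome {chrom!r} not in layout") from None

    def length(self, chrom: str) -> int:
        return self.lengths[self.index(chrom)]

    @property
    def total_bp(self) -> int:
        return int(sum(self.lengths))

    def offsets(self) -> dict[str, int]:
        """Cumulative bp offset of each chromosome start (for genome-wide x)."""
        out, acc = {}, 0
        for name, length in zip(self.names, self.lengths):
            out[name] = acc
            acc += length
        return out

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(zip(self.names, self.lengths))


@dataclass
class ProbeMatrix:
    """Sorted probe annotations plus the log2-ratio matrix.

    Probes are sorted by (layout chromosome order, position); duplicate
    positions have been collapsed by the loader. ``ratios`` is
    ``n_probes x n_samples`` with no missing values.
    """

    layout: GenomeLayout
    probe_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    sample_ids: tuple[str, ...]
    ratios: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ratios = np.asarray(self.ratios, dtype=np.float64)
        if self.ratios.ndim != 2:
            raise ValueError("ratios must be 2-D (n_probes x n_samples)")
        n = len(self.pos)
        if not (len(self.chrom) == len(self.probe_ids) == self.ratios.shape[0] == n):
            raise ValueError("probe annotation arrays and ratios rows disagree")
        if n < 1 or self.ratios.shape[1] < 1:
            raise ValueError("need at least one probe and one sample")
        if len(self.sample_ids) != self.ratios.shape[1]:
            raise ValueError("sample_ids length must match ratio columns")
        if not np.all(np.isfinite(self.ratios)):
            raise ValueError("ratios contain missing or non-finite values")
        order_idx = np.array([self.layout.index(c) for c in self.chrom])
        for c, p in zip(self.chrom, self.pos):
            if p < 1 or p > self.layout.length(c):
                raise ValueError(f"probe position {p} outside chromosome {c}")
        key = order_idx * (max(self.layout.lengths) + 1) + self.pos
        if not np.all(np.diff(key) > 0):
            raise ValueError("probes must be sorted by layout order then position, "
                             "without duplicate positions")

    @property
    def n_probes(self) -> int:
        return self.ratios.shape[0]

    @property
    def n_samples(self) -> int:
        return self.ratios.shape[1]


@dataclass
class SamplePointGrid:
    """Regular per-chromosome grid of sampling points for KC scores.

    Points sit at spacing/2, 3*spacing/2, ... within each chromosome and
    never span a chromosome boundary.
    """

    layout: GenomeLayout
    chrom: np.ndarray
    x: np.ndarray
    spacing: float
    _slices: dict[str, slice] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.x = np.asarray(self.x, dtype=np.float64)
        if not self._slices:
            start = 0
            for name in self.layout.names:
                n = int(np.sum(self.chrom == name))
                self._slices[name] = slice(start, start + n)
                start += n

    @property
    def n_points(self) -> int:
        return len(self.x)

    def chrom_slice(self, chrom: str) -> slice:
        return self._slices[chrom]


def build_sample_points(layout: GenomeLayout, spacing: float) -> SamplePointGrid:
    """Lay a regular sampling grid over every chromosome.

    Per chromosome of length L the points are spacing/2, 3*spacing/2, ... <= L,
    i.e. floor((L - spacing/2)/spacing) + 1 points.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    too_short = [name for name, length in layout if length <= spacing]
    if too_short:
        raise ValueError(
            "spacing must be smaller than every chromosome; these would get "
            f"no usable grid: {', '.join(too_short)}")
    chroms, xs = [], []
    for name, length in layout:
        pts = np.arange(spacing / 2.0, length + 0.5, spacing)
        pts = pts[pts <= length]
        chroms.extend([name] * len(pts))
        xs.append(pts)
    return SamplePointGrid(layout, np.array(chroms, dtype=object),
                           np.concatenate(xs), float(spacing))


@dataclass(frozen=True)
class Region:
    """One called interval: 1-based inclusive bp bounds, a channel, the peak
    statistic inside the interval, and the number of grid points it covers."""

    chrom: str
    start_bp: int
    end_bp: int
    channel: str
    score: float
    n_points: int

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError("region start must precede end")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


class RegionSet:
    """A sorted, per-(chromosome, channel) non-overlapping set of regions."""

    def __init__(self, regions: Iterable[Region], layout: GenomeLayout | None = None):
        regions = list(regions)
        if layout is not None:
            key = lambda r: (layout.index(r.chrom), r.start_bp, r.channel)
        else:
            key = lambda r: (r.chrom, r.start_bp, r.channel)
        self.regions = sorted(regions, key=key)
        self.layout = layout
        seen: dict[tuple[str, str], int] = {}
        for r in sorted(regions, key=lambda r: (r.chrom, r.channel, r.start_bp)):
            k = (r.chrom, r.channel)
            if k in seen and r.start_bp < seen[k]:
                raise ValueError(f"overlapping regions on {k}")
            seen[k] = r.end_bp

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> Region:
        return self.regions[i]

    def by_channel(self, channel: str) -> list[Region]:
        return [r for r in self.regions if r.channel == channel]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.chrom, r.start_bp, r.end_bp, r.channel, r.score, r.n_points)
             for r in self.regions],
            columns=["chrom", "start_bp", "end_bp", "channel", "score", "n_points"])


def load_probe_table(path: str | Path, layout: GenomeLayout,
                     na_policy: str = "drop") -> ProbeMatrix:
    """Load a tab-delimited probe table into a :class:`ProbeMatrix`.

    Expected header: ``probe_id  chrom  pos  <sample> ...`` with positions as
    1-based bp. Rows are re-sorted to layout order if needed (warning),
    duplicate (chrom, pos) rows are averaged (warning), and rows with missing
    ratios are dropped or zero-imputed per ``na_policy``. Only explicit NA
    markers are treated as missing; other non-numeric ratio entries raise.
    """
    if na_policy not in ("drop", "impute_zero"):
        raise ValueError("na_policy must be 'drop' or 'impute_zero'")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns[:3]) != ["probe_id", "chrom", "pos"]:
        raise ValueError("probe table must start with columns probe_id, chrom, pos")
    df["probe_id"] = df["probe_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    sample_ids = tuple(str(c) for c in df.columns[3:])
    if not sample_ids:
        raise ValueError("probe table has no sample columns")

    pos = pd.to_numeric(df["pos"], errors="raise")
    if (pos <= 0).any() or (pos != pos.round()).any():
        raise ValueError("probe positions must be positive integers (1-based bp)")
    df["pos"] = pos.astype(np.int64)

    for c in df["chrom"].unique():
        if c not in layout.names:
            row = df.index[df["chrom"] == c][0]
            raise ValueError(
                f"unknown chromosome {c!r} at row {row} (probe "
                f"{df.loc[row, 'probe_id']!r}) — not present in the layout")
    for _, r in df.iterrows():
        if r["pos"] > layout.length(r["chrom"]):
            raise ValueError(
                f"probe {r['probe_id']!r} position {r['pos']} exceeds length "
                f"of chromosome {r['chrom']}")

    # Ratio columns: explicit NA markers become NaN at parse time; anything
    # else non-numeric is a data error regardless of na_policy.
    ratios = df[list(sample_ids)].apply(lambda col: pd.to_numeric(col, errors="raise"))

    na_rows = ratios.isna().any(axis=1)
    if na_policy == "drop":
        if na_rows.any():
            logger.warning("dropping %d probe row(s) with missing ratios",
                           int(na_rows.sum()))
            df = df.loc[~na_rows].reset_index(drop=True)
            ratios = ratios.loc[~na_rows].reset_index(drop=True)
    else:
        if na_rows.any():
            logger.warning("imputing 0 for %d missing ratio value(s)",
                           int(ratios.isna().to_numpy().sum()))
            ratios = ratios.fillna(0.0)
    if len(df) == 0:
        raise ValueError("no usable probe rows after missing-value handling")

    df = pd.concat([df[["probe_id", "chrom", "pos"]], ratios], axis=1)

    dup = df.duplicated(subset=["chrom", "pos"], keep=False)
    if dup.any():
        logger.warning("averaging %d duplicate (chrom, pos) probe row(s)",
                       int(dup.sum()))
        agg = {c: "mean" for c in sample_ids}
        agg["probe_id"] = "first"
        df = (df.groupby(["chrom", "pos"], as_index=False, sort=False)
                .agg(agg)[["probe_id", "chrom", "pos", *sample_ids]])

    order_idx = df["chrom"].map(lambda c: layout.index(c))
    sort_key = np.lexsort((df["pos"].to_numpy(), order_idx.to_numpy()))
    if not np.array_equal(sort_key, np.arange(len(df))):
        logger.warning("probe table was not sorted by layout order; re-sorting")
        df = df.iloc[sort_key].reset_index(drop=True)

    return ProbeMatrix(
        layout=layout,
        probe_ids=df["probe_id"].to_numpy(dtype=object),
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        sample_ids=sample_ids,
        ratios=df[list(sample_ids)].to_numpy(dtype=np.float64),
    )


def write_probe_table(pm: ProbeMatrix, path: str | Path) -> None:
    """Write a ProbeMatrix back to the tab-delimited probe-table dialect."""
    df = pd.DataFrame({"probe_id": pm.probe_ids, "chrom": pm.chrom, "pos": pm.pos})
    for j, s in enumerate(pm.sample_ids):
        df[s] = pm.ratios[:, j]
    df.to_csv(path, sep="\t", index=False)


def write_regions_bed(regions: RegionSet, path: str | Path) -> None:
    """Export regions as BED (0-based half-open); score scaled to [0, 1000]
    by the maximum |peak statistic| in the file; an empty set yields an
    empty (valid) file."""
    lines = []
    max_score = max((abs(r.score) for r in regions), default=0.0)
    if regions.layout is not None:
        ordered = sorted(regions, key=lambda r: (regions.layout.index(r.chrom),
                                                 r.start_bp, r.channel))
    else:
        ordered = sorted(regions, key=lambda r: (r.chrom, r.start_bp, r.channel))
    for r in ordered:
        bed_score = 0 if max_score == 0 else int(round(1000 * abs(r.score) / max_score))
        lines.append(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.channel}\t{bed_score}")
    Path(path).write_text("".join(line + "\n" for line in lines))


def regions_from_mask(mask: np.ndarray, values: np.ndarray,
                      grid: SamplePointGrid, channel: str) -> RegionSet:
    """Turn maximal runs of flagged grid points into regions.

    Run bounds are extended by spacing/2 on each side and clipped to the
    chromosome. The peak statistic is the extreme value inside the run
    (maximum, or minimum for diff_down where scores are negative).
    """
    regions = []
    half = grid.spacing / 2.0
    for name, length in grid.layout:
        sl = grid.chrom_slice(name)
        m = mask[sl]
        if not m.any():
            continue
        v = values[sl]
        xs = grid.x[sl]
        idx = np.flatnonzero(m)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(idx) - 1]))
        for s, e in zip(starts, ends):
            i0, i1 = idx[s], idx[e]
            run = v[i0:i1 + 1]
            peak = float(run.min() if channel == "diff_down" else run.max())
            regions.append(Region(
                chrom=name,
                start_bp=int(max(1, round(xs[i0] - half))),
                end_bp=int(min(length, round(xs[i1] + half))),
                channel=channel,
                score=peak,
                n_points=int(i1 - i0 + 1),
            ))
    return RegionSet(regions, layout=grid.layout)
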