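"""Synthetic aCGH data with known truth.

Generates probe tables whose log2 ratios are a sum of interval-shaped
aberration effects (shared across the cohort or confined to one sample
class, each carried by a configurable fraction of its target samples)
plus i.i.d. Gaussian probe noise. Probe positions can be uniform or drawn
with log-normal inter-probe gaps to exercise the density correction of
the smoother. The generator emulates the structures the method is built
to find — focal class-specific losses such as the VDJ-recombination
deletions of lymphocyte-derived tumours, and class-specific amplicons
such as the 17q/HER2 gain of HER2-positive breast cancer — without any
external dataset.

Effects are in log2 units: +0.58 is roughly a single-copy gain in a
diploid genome, -1.0 a heterozygous-scale loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compare import ClassLabels
from .data_model import (GenomeLayout, ProbeMatrix, Region, RegionSet)

_TARGETS = ("all", "class1", "class2")


@dataclass(frozen=True)
class AberrationSpec:
    """One ground-truth aberration interval.

    ``recurrence`` is the fraction of targeted samples that carry it;
    ``target`` selects the whole cohort or one class.
    """

    chrom: str
    start_bp: int
    end_bp: int
    effect: float
    recurrence: float = 1.0
    target: str = "all"

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError("aberration start must precede end")
        if not 0 < self.recurrence <= 1:
            raise ValueError("recurrence must lie in (0, 1]")
        if self.target not in _TARGETS:
            raise ValueError(f"target must be one of {_TARGETS}")

    @property
    def channel(self) -> str:
        """Truth channel implied by effect sign and target class."""
        if self.target == "all":
            return "gain" if self.effect > 0 else "loss"
        group1_higher = (self.effect > 0) == (self.target == "class1")
        return "diff_up" if group1_higher else "diff_down"


@dataclass
class SyntheticDataset:
    """Generated probe matrix plus its ground truth."""

    probes: ProbeMatrix
    truth: RegionSet
    carriers: np.ndarray  #: (n_specs x n_samples) bool carrier matrix
    labels: ClassLabels | None

    def __iter__(self):  # allow tuple-style unpacking
        return iter((self.probes, self.truth, self.carriers))


def _probe_positions(length: int, n: int, mode: str,
                     rng: np.random.Generator) -> np.ndarray:
    if mode == "uniform":
        pos = np.round((np.arange(n) + 0.5) * length / n)
    elif mode == "lognormal_gaps":
        gaps = rng.lognormal(mean=0.0, sigma=1.0, size=n)
        cum = np.cumsum(gaps)
        pos = np.round(cum * (length - 1) / cum[-1])
    else:
        raise ValueError("spacing_mode must be 'uniform' or 'lognormal_gaps'")
    pos = np.unique(np.clip(pos, 1, length)).astype(np.int64)
    return pos


def _merge_truth(specs: "list[AberrationSpec]",
                 layout: GenomeLayout) -> RegionSet:
    """Merge overlapping same-channel truth intervals into a RegionSet."""
    by_key: dict[tuple[str, str], list[AberrationSpec]] = {}
    for s in specs:
        by_key.setdefault((s.chrom, s.channel), []).append(s)
    regions = []
    for (chrom, channel), group in by_key.items():
        group = sorted(group, key=lambda s: s.start_bp)
        cur_start, cur_end, cur_eff = group[0].start_bp, group[0].end_bp, group[0].effect
        for s in group[1:]:
            if s.start_bp <= cur_end:
                cur_end = max(cur_end, s.end_bp)
                cur_eff = max(cur_eff, s.effect, key=abs)
            else:
                regions.append(Region(chrom, cur_start, cur_end, channel,
                                      cur_eff, 1))
                cur_start, cur_end, cur_eff = s.start_bp, s.end_bp, s.effect
        regions.append(Region(chrom, cur_start, cur_end, channel, cur_eff, 1))
    return RegionSet(regions, layout=layout)


def generate_dataset(layout: GenomeLayout, n1: int, n2: int = 0, *,
                     n_probes_per_chrom: int | None = None,
                     probe_positions: "dict[str, np.ndarray] | None" = None,
                     specs: "list[AberrationSpec] | tuple[AberrationSpec, ...]" = (),
                     noise_sd: float = 0.3,
                     spacing_mode: str = "uniform",
                     seed: int = 0) -> SyntheticDataset:
    """Simulate an aCGH cohort with known aberrations.

    ``n1`` samples belong to class 1 and ``n2`` to class 2 (labels are only
    attached when both groups have >= 2 samples). Probe positions are
    either generated (``n_probes_per_chrom`` with ``spacing_mode``) or
    given explicitly per chromosome via ``probe_positions``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if (n_probes_per_chrom is None) == (probe_positions is None):
        raise ValueError("give exactly one of n_probes_per_chrom or probe_positions")
    specs = list(specs)
    for s in specs:
        if s.chrom not in layout.names:
            raise ValueError(f"aberration on unknown chromosome {s.chrom!r}")
        if s.end_bp > layout.length(s.chrom):
            raise ValueError(f"aberration {s.chrom}:{s.start_bp}-{s.end_bp} "
                             "extends beyond the chromosome")
    if any(s.target != "all" for s in specs) and (n1 < 1 or n2 < 1):
        raise ValueError("class-targeted aberrations need samples in both classes")

    rng = np.random.default_rng(seed)
    n_samples = n1 + n2
    chroms, poss = [], []
    for name, length in layout:
        if probe_positions is not None:
            p = np.asarray(probe_positions.get(name, []), dtype=np.int64)
            p = np.unique(p)
        else:
            p = _probe_positions(length, n_probes_per_chrom, spacing_mode, rng)
        chroms.extend([name] * len(p))
        poss.append(p)
    chrom = np.array(chroms, dtype=object)
    pos = np.concatenate(poss)
    n_probes = len(pos)
    if n_probes == 0:
        raise ValueError("no probes generated")

    carriers = np.zeros((len(specs), n_samples), dtype=bool)
    ratios = np.zeros((n_probes, n_samples))
    is_class1 = np.arange(n_samples) < n1
    for k, s in enumerate(specs):
        if s.target == "all":
            eligible = np.ones(n_samples, dtype=bool)
        elif s.target == "class1":
            eligible = is_class1
        else:
            eligible = ~is_class1
        carry = eligible & (rng.random(n_samples) < s.recurrence)
        carriers[k] = carry
        in_iv = (chrom == s.chrom) & (pos >= s.start_bp) & (pos <= s.end_bp)
        ratios[np.ix_(in_iv, carry)] += s.effect
    if noise_sd > 0:
        ratios += rng.normal(0.0, noise_sd, size=ratios.shape)

    sample_ids = tuple(f"S{j + 1:03d}" for j in range(n_samples))
    pm = ProbeMatrix(layout=layout,
                     probe_ids=np.array([f"P{i + 1:06d}" for i in range(n_probes)],
                                        dtype=object),
                     chrom=chrom, pos=pos, sample_ids=sample_ids, ratios=ratios)
    labels = (ClassLabels(tuple([1] * n1 + [2] * n2))
              if n1 >= 2 and n2 >= 2 else None)
    return SyntheticDataset(pm, _merge_truth(specs, layout), carriers, labels)


@dataclass
class RecoveryScore:
    """Per-truth-region Jaccard (best same-channel call) plus global
    bp-level sensitivity and specificity."""

    jaccards: "list[float]"
    sensitivity: float
    specificity: float


def _merged_intervals(regions, chrom: str, channel: str | None):
    ivs = sorted((r.start_bp, r.end_bp) for r in regions
                 if r.chrom == chrom and (channel is None or r.channel == channel))
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return merged


def _covered_bp(intervals) -> float:
    return float(sum(e - s for s, e in intervals))


def _overlap_bp(a, b) -> float:
    total, j = 0.0, 0
    for s, e in a:
        for s2, e2 in b:
            total += max(0.0, min(e, e2) - max(s, s2))
    return total


def score_recovery(called: RegionSet, truth: RegionSet,
                   layout: GenomeLayout) -> RecoveryScore:
    """Measure how well called regions recover the ground truth.

    Jaccard is bp intersection over union against the best-overlapping
    same-channel called region; sensitivity is truth bp covered by
    same-channel calls; specificity is non-truth bp left uncalled.
    """
    jaccards = []
    for t in truth:
        best = 0.0
        for c in called.by_channel(t.channel):
            if c.chrom != t.chrom:
                continue
            inter = max(0.0, min(t.end_bp, c.end_bp) - max(t.start_bp, c.start_bp))
            union = ((t.end_bp - t.start_bp) + (c.end_bp - c.start_bp) - inter)
            if union > 0:
                best = max(best, inter / union)
        jaccards.append(best)

    truth_bp = covered_truth = 0.0
    called_outside = 0.0
    total_bp = float(layout.total_bp)
    all_called_bp = 0.0
    for name, _length in layout:
        call_iv = _merged_intervals(called, name, None)
        all_called_bp += _covered_bp(call_iv)
        truth_iv = _merged_intervals(truth, name, None)
        truth_bp += _covered_bp(truth_iv)
        called_outside += _covered_bp(call_iv) - _overlap_bp(call_iv, truth_iv)
        for t in truth:
            if t.chrom != name:
                continue
            same = _merged_intervals(called, name, t.channel)
            covered_truth += _overlap_bp([(t.start_bp, t.end_bp)], same)
    sens = covered_truth / truth_bp if truth_bp > 0 else 0.0
    non_truth = total_bp - truth_bp
    spec = (non_truth - called_outside) / non_truth if non_truth > 0 else 1.0
    return RecoveryScore(jaccards, sens, spec)
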