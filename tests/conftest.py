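import numpy as np
import pytest

from kcscan import GenomeLayout, ProbeMatrix, build_sample_points


@pytest.fixture
def layout():
    return GenomeLayout(("chrA", "chrB"), (1_000_000, 500_000))


@pytest.fixture
def grid(layout):
    return build_sample_points(layout, 50_000)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def make_probe_matrix(layout, positions_by_chrom, ratios, sample_ids=None):
    """Assemble a ProbeMatrix from explicit per-chromosome positions."""
    chroms, poss = [], []
    for name in layout.names:
        p = np.asarray(positions_by_chrom.get(name, []), dtype=np.int64)
        chroms.extend([name] * len(p))
        poss.append(p)
    pos = np.concatenate(poss)
    ratios = np.atleast_2d(np.asarray(ratios, dtype=float))
    if ratios.shape[0] != len(pos):
        ratios = ratios.T
    if sample_ids is None:
        sample_ids = tuple(f"S{j}" for j in range(ratios.shape[1]))
    return ProbeMatrix(
        layout=layout,
        probe_ids=np.array([f"P{i}" for i in range(len(pos))], dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=pos,
        sample_ids=sample_ids,
        ratios=ratios,
    )


def write_probe_tsv(path, rows, sample_names=("s1", "s2")):
    """Write a probe-table TSV from (probe_id, chrom, pos, *ratios) rows."""
    header = "probe_id\tchrom\tpos\t" + "\t".join(sample_names)
    lines = [header] + ["\t".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path
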