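import numpy as np
import pytest

from svhic.contact_core import BinGrid, ContactMap

BIN = 5000


def make_grid(n_bins: int, chrom: str = "chr5") -> BinGrid:
    return BinGrid(chrom, n_bins * BIN, BIN)


def random_map(n_bins: int, seed: int, density: float = 1.0, **kwargs) -> ContactMap:
    """Random symmetric non-negative integer contact map."""
    rng = np.random.default_rng(seed)
    v = rng.poisson(20.0, size=(n_bins, n_bins)).astype(float)
    if density < 1.0:
        v[rng.random((n_bins, n_bins)) > density] = 0.0
    v = np.triu(v)
    v = v + np.triu(v, 1).T
    return ContactMap(make_grid(n_bins), v, **kwargs)


def distance_only_map(n_bins: int, fn, **kwargs) -> ContactMap:
    i = np.arange(n_bins)
    v = fn(np.abs(i[:, None] - i[None, :]).astype(float))
    return ContactMap(make_grid(n_bins), v, **kwargs)


@pytest.fixture
def grid8():
    return make_grid(8)


@pytest.fixture
def toy2():
    """The 2-bin map [[4, 2], [2, 1]]."""
    return ContactMap(make_grid(2), np.array([[4.0, 2.0], [2.0, 1.0]]))


def random_synteny_case(rng, n_src):
    """Random 2-3 block bin-aligned synteny map plus target grid size (bins)."""
    from svhic.liftover import SyntenyBlock, SyntenyMap

    n_blocks = rng.integers(2, 4)
    cuts = np.sort(rng.choice(np.arange(1, n_src), size=2 * n_blocks, replace=False))
    spans = [(cuts[2 * i], cuts[2 * i + 1]) for i in range(n_blocks)]
    spans = [(a, b) for a, b in spans if b > a]
    blocks, tgt_pos = [], 0
    for a, b in spans:
        orient = "+" if rng.random() < 0.7 else "-"
        gap = int(rng.integers(0, 2))
        tgt_pos += gap
        blocks.append(SyntenyBlock(
            "chr5", int(a) * BIN, int(b) * BIN,
            "chr5", tgt_pos * BIN, (tgt_pos + b - a) * BIN, orient))
        tgt_pos += b - a
    return SyntenyMap(blocks), tgt_pos
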