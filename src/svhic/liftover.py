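"""Synteny maps and contact liftover across genome rearrangements.

A deletion induces a two-block synteny map between the reference and the
deleted genome.  Contacts are remapped through such maps under two models:

* **easy** — coordinate-only remapping: each contact keeps its value and is
  reassigned to the bins its loci occupy in the target genome (bins straddling
  block edges are redistributed by overlap fraction).
* **balanced** — the distance-only null: as easy, but each remapped pair is
  additionally rescaled by P(s')/P(s), the ratio of the map's own distance
  decay evaluated at the new vs old bin separation.  This realizes the
  assumption that the rearrangement perturbs architecture only through
  genomic distance.

Composing balanced (reference -> deleted genome) with easy (deleted genome ->
reference) yields the distance-only prediction of a wild-type map under a
deletion, in reference coordinates — the null against which observed mutant
maps are scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_core import BinGrid, ContactMap, ExpectedProfile, estimate_expected

__all__ = [
    "SyntenyBlock",
    "SyntenyMap",
    "DeletionSpec",
    "deletion_to_synteny",
    "fill_codirected_gaps",
    "liftover_easy",
    "liftover_balanced",
    "simulate_wt_under_deletion",
    "read_synteny_map",
    "write_synteny_map",
]


@dataclass(frozen=True)
class SyntenyBlock:
    """One aligned interval pair; coordinates 0-based half-open, equal length."""

    src_chrom: str
    src_start: int
    src_end: int
    tgt_chrom: str
    tgt_start: int
    tgt_end: int
    orientation: str = "+"  # '+' codirected, '-' inverted

    def __post_init__(self) -> None:
        if not (0 <= self.src_start < self.src_end):
            raise ValueError(f"bad source interval [{self.src_start}, {self.src_end})")
        if not (0 <= self.tgt_start < self.tgt_end):
            raise ValueError(f"bad target interval [{self.tgt_start}, {self.tgt_end})")
        if self.src_end - self.src_start != self.tgt_end - self.tgt_start:
            raise ValueError("source and target intervals must have equal length")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")

    def invert(self) -> "SyntenyBlock":
        return SyntenyBlock(
            self.tgt_chrom,
            self.tgt_start,
            self.tgt_end,
            self.src_chrom,
            self.src_start,
            self.src_end,
            self.orientation,
        )

    def map_point(self, pos: float) -> float:
        """Map a source coordinate (may be fractional) into target coordinates."""
        off = pos - self.src_start
        if self.orientation == "+":
            return self.tgt_start + off
        return self.tgt_end - off


@dataclass
class SyntenyMap:
    blocks: list[SyntenyBlock]
    source_genome: str = "source"
    target_genome: str = "target"

    def __post_init__(self) -> None:
        for key in ("src", "tgt"):
            ivs = sorted(
                (getattr(b, f"{key}_start"), getattr(b, f"{key}_end"))
                for b in self.blocks
            )
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"{key} intervals overlap: {(s1, e1)} and {(s2, e2)}")

    def invert(self) -> "SyntenyMap":
        return SyntenyMap(
            [b.invert() for b in self.blocks],
            source_genome=self.target_genome,
            target_genome=self.source_genome,
        )


@dataclass(frozen=True)
class DeletionSpec:
    """A deletion on the reference genome; 0-based half-open; may be empty
    (start == end), which induces the identity map."""

    chrom: str
    start: int
    end: int
    label: str = "deletion"

    def __post_init__(self) -> None:
        if not 0 <= self.start <= self.end:
            raise ValueError(f"bad deletion interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def deletion_to_synteny(
    deletion: DeletionSpec,
    chrom_length: int,
    source_genome: str = "reference",
    target_genome: str | None = None,
) -> SyntenyMap:
    """Synteny map from the reference genome to the deleted genome.

    Two codirected blocks: [0, start) maps to itself and [end, L) shifts left
    by the deletion length.  A zero-length deletion yields the identity map;
    a deletion touching a chromosome end yields a single block.
    """
    if deletion.end > chrom_length:
        raise ValueError(
            f"deletion end {deletion.end} exceeds chromosome length {chrom_length}"
        )
    target_genome = target_genome or f"{source_genome}_{deletion.label}"
    c = deletion.chrom
    if deletion.length == 0:
        return SyntenyMap(
            [SyntenyBlock(c, 0, chrom_length, c, 0, chrom_length)],
            source_genome=source_genome,
            target_genome=target_genome,
        )
    blocks = []
    if deletion.start > 0:
        blocks.append(SyntenyBlock(c, 0, deletion.start, c, 0, deletion.start))
    if deletion.end < chrom_length:
        blocks.append(
            SyntenyBlock(
                c,
                deletion.end,
                chrom_length,
                c,
                deletion.start,
                chrom_length - deletion.length,
            )
        )
    if not blocks:
        raise ValueError("deletion removes the whole chromosome")
    return SyntenyMap(blocks, source_genome=source_genome, target_genome=target_genome)


def fill_codirected_gaps(smap: SyntenyMap, max_gap: int = 1_000_000) -> SyntenyMap:
    """Bridge gaps splitting codirected synteny blocks.

    Consecutive '+' blocks whose source gap and target gap are equal in
    length and both shorter than ``max_gap`` are merged into one block;
    everything else is left untouched.
    """
    blocks = sorted(smap.blocks, key=lambda b: b.src_start)
    merged: list[SyntenyBlock] = []
    for b in blocks:
        if merged:
            a = merged[-1]
            src_gap = b.src_start - a.src_end
            tgt_gap = b.tgt_start - a.tgt_end
            if (
                a.orientation == b.orientation == "+"
                and a.src_chrom == b.src_chrom
                and a.tgt_chrom == b.tgt_chrom
                and 0 <= src_gap < max_gap
                and src_gap == tgt_gap
            ):
                merged[-1] = SyntenyBlock(
                    a.src_chrom, a.src_start, b.src_end,
                    a.tgt_chrom, a.tgt_start, b.tgt_end, "+",
                )
                continue
        merged.append(b)
    return SyntenyMap(
        merged, source_genome=smap.source_genome, target_genome=smap.target_genome
    )


def read_synteny_map(path, source_genome="source", target_genome="target") -> SyntenyMap:
    """Read `src_chrom src_start src_end tgt_chrom tgt_start tgt_end strand` TSV."""
    blocks = []
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith("#"):
                continue
            t = ln.split()
            blocks.append(
                SyntenyBlock(t[0], int(t[1]), int(t[2]), t[3], int(t[4]), int(t[5]), t[6])
            )
    return SyntenyMap(blocks, source_genome=source_genome, target_genome=target_genome)


def write_synteny_map(smap: SyntenyMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# svhic synteny map {smap.source_genome} -> {smap.target_genome}\n")
        for b in smap.blocks:
            fh.write(
                f"{b.src_chrom}\t{b.src_start}\t{b.src_end}\t"
                f"{b.tgt_chrom}\t{b.tgt_start}\t{b.tgt_end}\t{b.orientation}\n"
            )


# ---------------------------------------------------------------------------
# Bin-level mapping machinery


def _bin_assignments(
    smap: SyntenyMap, src_grid: BinGrid, tgt_grid: BinGrid
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decompose the synteny map into (src_bin, tgt_bin, weight) triples.

    Weight is the fraction of the source bin carried to the target bin
    (overlap in bp / bin size), so a fully mapped source bin has total
    outgoing weight 1 and contact mass is conserved.
    """
    if src_grid.bin_size != tgt_grid.bin_size:
        raise ValueError(
            f"bin size mismatch: source {src_grid.bin_size}, target {tgt_grid.bin_size}"
        )
    bs = src_grid.bin_size
    src, tgt, wt = [], [], []
    for block in smap.blocks:
        if block.src_chrom != src_grid.chrom or block.tgt_chrom != tgt_grid.chrom:
            raise ValueError("synteny block chromosome does not match grids")
        i0 = block.src_start // bs
        i1 = (min(block.src_end, src_grid.chrom_length) - 1) // bs
        for i in range(i0, i1 + 1):
            lo = max(block.src_start, src_grid.bin_start(i))
            hi = min(block.src_end, src_grid.bin_end(i))
            if hi <= lo:
                continue
            # image of [lo, hi) in target coordinates
            a, b = block.map_point(lo), block.map_point(hi)
            tlo, thi = (a, b) if a <= b else (b, a)
            j0 = int(tlo) // bs
            j1 = (int(np.ceil(thi)) - 1) // bs
            for j in range(j0, min(j1, tgt_grid.n_bins - 1) + 1):
                olo = max(tlo, tgt_grid.bin_start(j))
                ohi = min(thi, tgt_grid.bin_end(j))
                if ohi > olo:
                    src.append(i)
                    tgt.append(j)
                    wt.append((ohi - olo) / bs)
    return np.asarray(src, int), np.asarray(tgt, int), np.asarray(wt, float)


def _check_genome(cmap: ContactMap, smap: SyntenyMap) -> None:
    if cmap.genome is not None and cmap.genome != smap.source_genome:
        raise ValueError(
            f"map genome {cmap.genome!r} does not match synteny source "
            f"{smap.source_genome!r}"
        )


def _lift(
    cmap: ContactMap,
    smap: SyntenyMap,
    tgt_grid: BinGrid,
    expected: ExpectedProfile | None,
) -> ContactMap:
    """Shared implementation of the easy (expected=None) and balanced models."""
    _check_genome(cmap, smap)
    src, tgt, wt = _bin_assignments(smap, cmap.grid, tgt_grid)
    keep = cmap.mask[src]
    src, tgt, wt = src[keep], tgt[keep], wt[keep]
    m = len(src)
    nt = tgt_grid.n_bins
    out = np.zeros((nt, nt))

    # all ordered entry pairs; V is symmetric so the output is symmetric too
    A, B = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    a, b = A.ravel(), B.ravel()
    contrib = cmap.values[src[a], src[b]] * wt[a] * wt[b]
    if expected is not None:
        s_old = np.abs(src[a] - src[b])
        s_new = np.abs(tgt[a] - tgt[b])
        p_old = expected.values[s_old]
        p_new = np.full(len(a), np.nan)
        in_range = s_new < len(expected.values)
        p_new[in_range] = expected.values[s_new[in_range]]
        ratio = np.where(
            np.isnan(p_old) | np.isnan(p_new) | (p_old <= 0), 0.0, p_new / np.where(p_old > 0, p_old, 1.0)
        )
        contrib = contrib * ratio
    np.add.at(out, (tgt[a], tgt[b]), contrib)
    out = 0.5 * (out + out.T)  # remove float-order asymmetry

    coverage = np.zeros(nt)
    np.add.at(coverage, tgt, wt)
    mask = coverage > 1e-12
    return ContactMap(
        grid=tgt_grid,
        values=out,
        mask=mask,
        normalization=cmap.normalization,
        role="liftovered" if expected is not None else cmap.role,
        genome=smap.target_genome,
    )


def liftover_easy(cmap: ContactMap, smap: SyntenyMap, tgt_grid: BinGrid) -> ContactMap:
    """Coordinate-only remapping of contacts through a synteny map.

    Values are redistributed by overlap fraction and never rescaled, so total
    contact mass over fully mapped pairs is conserved.  Target regions not
    covered by any block are masked.
    """
    return _lift(cmap, smap, tgt_grid, expected=None)


def liftover_balanced(
    cmap: ContactMap,
    smap: SyntenyMap,
    expected: ExpectedProfile,
    tgt_grid: BinGrid,
) -> ContactMap:
    """Distance-decay-rescaled remapping: each pair moving from separation s
    to s' is multiplied by P(s')/P(s).

    ``expected`` must be estimated from ``cmap`` itself (same grid); pairs
    whose source separation has undefined or zero P contribute nothing.
    """
    if expected.grid != cmap.grid:
        raise ValueError("expected profile grid does not match the contact map grid")
    out = _lift(cmap, smap, tgt_grid, expected=expected)
    return out


def simulate_wt_under_deletion(
    wt: ContactMap, deletion: DeletionSpec, expected: ExpectedProfile | None = None
) -> ContactMap:
    """Distance-only null prediction V* of a wild-type map under a deletion.

    Composition: estimate the wild-type distance decay; lift the map into
    deleted-genome coordinates under the balanced model; lift back to
    reference coordinates under the easy model.  The result lives on the
    wild-type grid, is masked over the deletion, and is tagged
    ``role='liftovered'``.
    """
    g = wt.grid
    if deletion.length == 0:
        return wt.with_values(wt.values.copy(), role="liftovered")
    if expected is None:
        expected = estimate_expected(wt)
    smap = deletion_to_synteny(
        deletion, g.chrom_length, source_genome=wt.genome or "reference"
    )
    del_grid = BinGrid(g.chrom, g.chrom_length - deletion.length, g.bin_size)
    on_mutant = liftover_balanced(wt, smap, expected, del_grid)
    back = liftover_easy(on_mutant, smap.invert(), g)
    return back.with_values(back.values, role="liftovered")
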