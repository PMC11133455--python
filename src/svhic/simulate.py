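"""Synthetic capture Hi-C and hybrid-cross SNP-coverage generators.

The contact model is a TAD block model on a power-law distance decay: the
expected contact between bins i and j is

    E[i, j]  ∝  (1 + |i - j|)^(-alpha) * prod(delta_b)  * (1 + loop bumps)

where the product runs over boundaries b lying strictly between i and j and
delta_b in (0, 1] is the boundary's insulation multiplier (delta = 1 means no
boundary).  Counts are Poisson around E scaled to a target sequencing depth.

The default locus template emulates a ~2.275 Mb capture region at 5 kb
resolution (455 bins) holding three TADs, with two nested sub-TAD boundaries
inside the middle TAD — the architecture of a tyrosine-kinase receptor gene
cluster (Pdgfra / Kit / Kdr) whose middle boundary is the target of the
deletion experiments this package analyzes.

A deletion experiment simulates the wild type on the reference grid and the
mutant on the collapsed (deleted) grid — with the deleted boundary either
retained at the fusion point or removed ("fused") — then re-expresses the
mutant in reference coordinates the way reads from a deletion allele map back
to the reference genome, masking the deleted region.

SNP coverage tables draw the musculus-allele count of each SNP from
Binomial(coverage, r/(1+r)) at true allelic ratio r.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .contact_core import BinGrid, ContactMap
from .liftover import DeletionSpec, deletion_to_synteny, liftover_easy

__all__ = [
    "Boundary",
    "Loop",
    "TadModel",
    "ExperimentSpec",
    "default_locus_model",
    "default_experiment",
    "simulate_contact_map",
    "simulate_deletion_experiment",
    "simulate_snp_counts",
]


@dataclass(frozen=True)
class Boundary:
    """Insulation boundary at the left edge of bin ``position`` (i.e. between
    bins position-1 and position); ``delta`` multiplies expected contacts of
    every pair spanning it."""

    position: int
    delta: float

    def __post_init__(self) -> None:
        if not 0.0 < self.delta <= 1.0:
            raise ValueError(f"delta must be in (0, 1], got {self.delta}")
        if self.position < 0:
            raise ValueError(f"boundary position must be >= 0, got {self.position}")


@dataclass(frozen=True)
class Loop:
    """Gaussian contact bump of the given amplitude centered at (bin_i, bin_j)."""

    bin_i: int
    bin_j: int
    amplitude: float = 1.0
    width: float = 1.0


@dataclass(frozen=True)
class TadModel:
    grid: BinGrid
    decay_exponent: float = 1.0
    boundaries: tuple[Boundary, ...] = ()
    loops: tuple[Loop, ...] = ()
    depth: float = 5e6

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0:
            raise ValueError("decay exponent must be positive")
        if self.depth <= 0:
            raise ValueError("sequencing depth must be positive")
        for b in self.boundaries:
            if b.position > self.grid.n_bins:
                raise ValueError(f"boundary at bin {b.position} outside the grid")

    def expected_matrix(self, normalize_depth: bool = True) -> np.ndarray:
        """Expected contact matrix; if ``normalize_depth``, scaled so the sum
        over unordered pairs (upper triangle incl. diagonal) equals depth."""
        n = self.grid.n_bins
        i = np.arange(n)
        sep = np.abs(i[:, None] - i[None, :])
        E = (1.0 + sep) ** (-self.decay_exponent)
        for b in self.boundaries:
            # pair (i, j), i<j spans the boundary iff i < b.position <= j
            left = i < b.position
            spans = left[:, None] != left[None, :]
            E = np.where(spans, E * b.delta, E)
        for lp in self.loops:
            for (ci, cj) in ((lp.bin_i, lp.bin_j), (lp.bin_j, lp.bin_i)):
                bump = np.exp(
                    -((i[:, None] - ci) ** 2 + (i[None, :] - cj) ** 2)
                    / (2.0 * lp.width**2)
                )
                E = E * (1.0 + lp.amplitude * bump)
        if normalize_depth:
            E = E * (self.depth / np.triu(E).sum())
        return E


@dataclass(frozen=True)
class ExperimentSpec:
    """A boundary-deletion experiment: wild-type model, deletion, and whether
    the deletion removes ("fuses") the boundary it contains."""

    wt_model: TadModel
    deletion: DeletionSpec
    fused: bool
    seed: int = 0
    depth: float | None = None  # per-sample depth; defaults to the model's

    def __post_init__(self) -> None:
        g = self.wt_model.grid
        if self.deletion.chrom != g.chrom or self.deletion.end > g.chrom_length:
            raise ValueError("deletion interval lies outside the model grid")


def default_locus_model(
    bin_size: int = 5000,
    n_bins: int = 455,
    depth: float = 5e6,
    decay_exponent: float = 1.0,
    chrom: str = "chr5",
) -> TadModel:
    """Three-TAD capture-region template (455 x 5 kb = 2.275 Mb).

    Major boundaries at bins 150 and 300 (delta 0.2) delimit three TADs; two
    milder sub-TAD boundaries (delta 0.6) at bins 200 and 250 nest inside the
    middle TAD.  For a non-default ``n_bins`` the boundary positions scale
    proportionally.
    """
    grid = BinGrid(chrom, n_bins * bin_size, bin_size)
    pos = lambda b455: int(round(n_bins * b455 / 455))
    boundaries = (
        Boundary(pos(150), 0.2),
        Boundary(pos(200), 0.6),
        Boundary(pos(250), 0.6),
        Boundary(pos(300), 0.2),
    )
    return TadModel(
        grid=grid,
        decay_exponent=decay_exponent,
        boundaries=boundaries,
        depth=depth,
    )


def default_experiment(
    fused: bool, seed: int = 0, depth: float = 5e6, model: TadModel | None = None
) -> ExperimentSpec:
    """A 30 kb deletion spanning the third-boundary bin (bins 297..302 on the
    default grid), emulating removal of the boundary region between the last
    two TADs."""
    model = model or default_locus_model(depth=depth)
    bs = model.grid.bin_size
    b3 = max((b.position for b in model.boundaries), default=model.grid.n_bins // 2)
    deletion = DeletionSpec(model.grid.chrom, (b3 - 3) * bs, (b3 + 3) * bs,
                            label="del30k")
    return ExperimentSpec(
        wt_model=model, deletion=deletion, fused=fused, seed=seed, depth=depth
    )


def simulate_contact_map(
    model: TadModel, seed: int, overdispersion: float = 0.0
) -> ContactMap:
    """Draw a raw-count contact map from the model.

    Counts are independent Poisson per unordered bin pair with mean E[i, j]
    scaled so the expected total equals the model depth; with
    ``overdispersion`` d > 0 the Poisson mean is gamma-jittered
    (shape 1/d, scale d*E), giving a negative-binomial marginal.
    """
    rng = np.random.default_rng(seed)
    E = model.expected_matrix(normalize_depth=True)
    n = model.grid.n_bins
    iu = np.triu_indices(n)
    lam = E[iu]
    if overdispersion > 0:
        lam = rng.gamma(shape=1.0 / overdispersion, scale=overdispersion * lam)
    counts = rng.poisson(lam)
    V = np.zeros((n, n))
    V[iu] = counts
    V = V + np.triu(V, k=1).T
    return ContactMap(grid=model.grid, values=V, normalization="raw", role="observed")


def _delete_from_model(model: TadModel, deletion: DeletionSpec, fused: bool) -> TadModel:
    """Model of the mutant chromosome: grid collapsed over the deletion and
    boundary positions remapped.

    A boundary strictly inside the deletion is removed when ``fused`` is
    true, otherwise retained at the fusion point.
    """
    g = model.grid
    if deletion.start % g.bin_size or deletion.end % g.bin_size:
        raise ValueError(
            "simulated deletions must be aligned to bin edges "
            f"(bin size {g.bin_size})"
        )
    ds, de = deletion.start // g.bin_size, deletion.end // g.bin_size
    shift = de - ds
    new_boundaries = []
    for b in model.boundaries:
        if b.position <= ds:
            new_boundaries.append(b)
        elif b.position >= de:
            new_boundaries.append(replace(b, position=b.position - shift))
        elif not fused:
            new_boundaries.append(replace(b, position=ds))
        # else: boundary deleted -> delta effectively 1
    new_loops = []
    for lp in model.loops:
        if all(not (ds <= p < de) for p in (lp.bin_i, lp.bin_j)):
            remap = lambda p: p if p < ds else p - shift
            new_loops.append(replace(lp, bin_i=remap(lp.bin_i), bin_j=remap(lp.bin_j)))
    new_grid = BinGrid(g.chrom, g.chrom_length - deletion.length, g.bin_size)
    return TadModel(
        grid=new_grid,
        decay_exponent=model.decay_exponent,
        boundaries=tuple(new_boundaries),
        loops=tuple(new_loops),
        depth=model.depth,
    )


def simulate_deletion_experiment(spec: ExperimentSpec) -> tuple[ContactMap, ContactMap]:
    """Simulate (wild type, mutant-in-reference-coordinates) raw maps.

    The mutant is simulated on the collapsed grid (distances recomputed after
    the deletion) and then re-expressed in reference coordinates through the
    inverse deletion coordinate map, with the deletion masked — mirroring how
    mutant reads are mapped onto the reference assembly.
    """
    model = spec.wt_model
    if spec.depth is not None:
        model = replace(model, depth=spec.depth)
    ss = np.random.SeedSequence(spec.seed)
    seed_wt, seed_mut = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))

    wt = simulate_contact_map(model, seed_wt)
    wt = replace(wt, genome="reference")

    mut_model = _delete_from_model(model, spec.deletion, spec.fused)
    mut = simulate_contact_map(mut_model, seed_mut)
    smap = deletion_to_synteny(
        spec.deletion, model.grid.chrom_length, source_genome="reference"
    )
    mut = replace(mut, genome=smap.target_genome)
    mut_ref = liftover_easy(mut, smap.invert(), model.grid)
    return wt, mut_ref


def simulate_snp_counts(
    gene: str,
    n_snps: int,
    coverage_per_snp: int,
    true_ratio: float,
    seed: int,
    genotype: str = "Wt",
    overdispersion: float = 0.0,
) -> pd.DataFrame:
    """Simulate a per-SNP allele coverage table for one gene and genotype.

    The musculus count of SNP k is Binomial(coverage, r/(1+r)); with
    ``overdispersion`` rho > 0 the per-SNP success probability is
    beta-jittered around r/(1+r) (beta-binomial sampling).
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if coverage_per_snp < 0:
        raise ValueError("coverage must be >= 0")
    if true_ratio <= 0:
        raise ValueError("true_ratio must be positive")
    rng = np.random.default_rng(seed)
    p = true_ratio / (1.0 + true_ratio)
    if overdispersion > 0:
        conc = (1.0 - overdispersion) / overdispersion
        ps = rng.beta(p * conc, (1.0 - p) * conc, size=n_snps)
    else:
        ps = np.full(n_snps, p)
    mus = rng.binomial(coverage_per_snp, ps)
    cast = coverage_per_snp - mus
    return pd.DataFrame(
        {
            "gene": gene,
            "pos": 1000 * (np.arange(n_snps) + 1),
            "mus_count": mus.astype(int),
            "cast_count": cast.astype(int),
            "genotype": genotype,
        }
    )
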