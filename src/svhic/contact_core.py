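"""Binned contact-map data model, text I/O, VC_SQRT balancing, distance decay.

The central object is :class:`ContactMap`: a symmetric matrix of contact
values over a :class:`BinGrid` (one chromosome or capture region binned at a
fixed resolution), with a per-bin validity mask.  Maps move through the
pipeline in two normalization states: ``raw`` (integer-like counts) and
``vc_sqrt`` (vanilla-coverage square-root balanced).  The ``role`` tag
distinguishes directly observed maps from maps produced by liftover through a
rearrangement, which downstream differential statistics treat as the null
prediction.

Coordinates are 0-based, half-open everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "BinGrid",
    "ContactMap",
    "ExpectedProfile",
    "SubtractionMap",
    "read_contact_map",
    "write_contact_map",
    "vc_sqrt_normalize",
    "estimate_expected",
    "subtraction_map",
    "parse_region",
]

_NORMALIZATIONS = ("raw", "vc_sqrt")
_ROLES = ("observed", "liftovered")


@dataclass(frozen=True)
class BinGrid:
    """Uniform tiling of ``[0, chrom_length)`` into half-open bins.

    Bin ``i`` covers ``[i*bin_size, min((i+1)*bin_size, chrom_length))``.
    """

    chrom: str
    chrom_length: int
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        if self.chrom_length <= 0:
            raise ValueError(
                f"chrom_length must be positive, got {self.chrom_length}"
            )

    @property
    def n_bins(self) -> int:
        return math.ceil(self.chrom_length / self.bin_size)

    def bin_index(self, pos: int) -> int:
        if not 0 <= pos < self.chrom_length:
            raise ValueError(
                f"position {pos} outside [0, {self.chrom_length}) on {self.chrom}"
            )
        return pos // self.bin_size

    def bin_start(self, i: int) -> int:
        return i * self.bin_size

    def bin_end(self, i: int) -> int:
        return min((i + 1) * self.bin_size, self.chrom_length)


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive, commas allowed) to
    0-based half-open ``(chrom, start, end)``."""
    chrom, _, span = region.partition(":")
    if not span:
        raise ValueError(f"malformed region string: {region!r}")
    lo, _, hi = span.replace(",", "").partition("-")
    start, end = int(lo) - 1, int(hi)
    if not 0 <= start < end:
        raise ValueError(f"malformed region string: {region!r}")
    return chrom, start, end


@dataclass
class ContactMap:
    """Symmetric non-negative contact matrix over a :class:`BinGrid`.

    ``mask[i]`` is True for valid bins; masked bins carry all-zero rows and
    columns (enforced at construction).  ``genome`` is an optional label used
    by liftover bookkeeping to refuse composition across mismatched genomes.
    """

    grid: BinGrid
    values: np.ndarray
    mask: np.ndarray | None = None
    normalization: str = "raw"
    role: str = "observed"
    genome: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = self.grid.n_bins
        if v.shape != (n, n):
            raise ValueError(f"values shape {v.shape} != grid ({n}, {n})")
        if not np.isfinite(v).all():
            raise ValueError("contact values must be finite")
        if (v < 0).any():
            raise ValueError("contact values must be non-negative")
        if not np.allclose(v, v.T):
            raise ValueError("contact matrix must be symmetric")
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.mask is None:
            mask = np.ones(n, dtype=bool)
        else:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != (n,):
                raise ValueError(f"mask shape {mask.shape} != ({n},)")
        v = v.copy()
        v[~mask, :] = 0.0
        v[:, ~mask] = 0.0
        self.values = v
        self.mask = mask

    @property
    def n_bins(self) -> int:
        return self.grid.n_bins

    def total(self) -> float:
        """Total matrix sum over unmasked bins (all entries, both triangles)."""
        return float(self.values.sum())

    def with_values(self, values: np.ndarray, **changes) -> "ContactMap":
        return replace(self, values=values, **changes)


@dataclass
class ExpectedProfile:
    """Distance decay P(s): mean contact value at each bin separation s.

    ``values[s]`` is NaN where no unmasked pair exists at separation ``s``.
    """

    grid: BinGrid
    values: np.ndarray
    counts: np.ndarray
    smoothed: bool = False

    def at(self, s: np.ndarray | int) -> np.ndarray | float:
        return self.values[s]

    def defined(self, s: np.ndarray | int) -> np.ndarray | bool:
        return ~np.isnan(self.values[s])


@dataclass
class SubtractionMap:
    """Signed difference (observed − liftovered) after mutual depth scaling,
    optionally aggregated to a coarser grid."""

    grid: BinGrid
    values: np.ndarray
    mask: np.ndarray
    scale_observed: float
    scale_liftovered: float


# ---------------------------------------------------------------------------
# I/O


def _parse_header(lines: list[str]) -> dict:
    meta = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        for tok in body.split():
            if "=" in tok:
                k, _, v = tok.partition("=")
                meta[k] = v
    return meta


def read_contact_map(path, grid: BinGrid, dialect: str | None = None) -> ContactMap:
    """Read a contact map from sparse-triplet or dense-matrix text.

    Triplet rows are ``chrom start1 start2 value`` (whitespace separated);
    each row is mirrored to the symmetric cell, and duplicate pairs are
    summed.  Dense files are an ``n x n`` numeric table.  ``dialect`` is
    auto-detected when None (a row of 4 fields whose first field matches the
    grid chromosome is treated as a triplet).
    """
    with open(path) as fh:
        raw_lines = fh.read().splitlines()
    header = [ln for ln in raw_lines if ln.startswith(("#", "track"))]
    lines = [ln for ln in raw_lines if ln.strip() and not ln.startswith(("#", "track"))]
    meta = _parse_header(header)

    n = grid.n_bins
    values = np.zeros((n, n))

    if dialect is None:
        if not lines:
            dialect = "triplet"
        else:
            toks = lines[0].split()
            dialect = "triplet" if len(toks) == 4 and toks[0] == grid.chrom else "dense"

    if dialect == "triplet":
        for ln in lines:
            toks = ln.split()
            if len(toks) != 4:
                raise ValueError(f"malformed triplet row: {ln!r}")
            chrom, s1, s2, val = toks[0], int(toks[1]), int(toks[2]), float(toks[3])
            if chrom != grid.chrom:
                raise ValueError(f"chromosome {chrom!r} != grid {grid.chrom!r}")
            for s in (s1, s2):
                if s % grid.bin_size != 0:
                    raise ValueError(
                        f"coordinate {s} is not a multiple of bin_size {grid.bin_size}"
                    )
            if val < 0:
                raise ValueError(f"negative contact value at ({s1}, {s2}): {val}")
            i, j = grid.bin_index(s1), grid.bin_index(s2)
            values[i, j] += val
            if i != j:
                values[j, i] += val
    elif dialect == "dense":
        arr = np.loadtxt(path, ndmin=2, comments=["#", "track"])
        if arr.shape != (n, n):
            raise ValueError(f"dense matrix shape {arr.shape} != ({n}, {n})")
        values = arr
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    mask = None
    if "mask" in meta:
        mask = np.array([c == "1" for c in meta["mask"]], dtype=bool)
    return ContactMap(
        grid=grid,
        values=values,
        mask=mask,
        normalization=meta.get("normalization", "raw"),
        role=meta.get("role", "observed"),
        genome=meta.get("genome") or None,
    )


def write_contact_map(cmap: ContactMap, path, dialect: str = "triplet") -> None:
    """Write a contact map; triplet dialect emits the upper triangle once.

    A ``#`` header records grid, normalization, role and mask so the
    round-trip through :func:`read_contact_map` is exact.
    """
    g = cmap.grid
    maskstr = "".join("1" if m else "0" for m in cmap.mask)
    header = (
        f"# svhic contact map chrom={g.chrom} chrom_length={g.chrom_length} "
        f"bin_size={g.bin_size} normalization={cmap.normalization} "
        f"role={cmap.role} genome={cmap.genome or ''} mask={maskstr}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        if dialect == "triplet":
            ii, jj = np.nonzero(np.triu(cmap.values))
            for i, j in zip(ii, jj):
                fh.write(
                    f"{g.chrom}\t{g.bin_start(i)}\t{g.bin_start(j)}\t"
                    f"{cmap.values[i, j]:.10g}\n"
                )
        elif dialect == "dense":
            np.savetxt(fh, cmap.values, fmt="%.10g", delimiter="\t")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Normalization and distance decay


def vc_sqrt_normalize(cmap: ContactMap) -> ContactMap:
    """Vanilla-coverage square-root balancing.

    W[i,j] = V[i,j] / sqrt(r_i * r_j) with r_i the marginal (row sum) of V
    over unmasked bins, rescaled by a single global constant so the total
    matrix sum equals the input's.  Bins with zero marginal are masked.
    """
    if cmap.normalization != "raw":
        raise ValueError(
            f"map is already normalized ({cmap.normalization}); refusing to "
            "normalize twice"
        )
    V = cmap.values
    r = V.sum(axis=1)
    if not (r > 0).any():
        raise ValueError("map has no positive values")
    mask = cmap.mask & (r > 0)
    denom = np.sqrt(np.outer(r, r), where=np.outer(r, r) > 0, out=np.zeros_like(V))
    W = np.divide(V, denom, where=denom > 0, out=np.zeros_like(V))
    W[~mask, :] = 0.0
    W[:, ~mask] = 0.0
    scale = V.sum() / W.sum()
    return cmap.with_values(W * scale, mask=mask, normalization="vc_sqrt")


def estimate_expected(
    cmap: ContactMap, smooth: bool = False, smooth_bins_per_octave: int = 8
) -> ExpectedProfile:
    """Estimate the distance-decay profile P(s) of a map.

    P(s) is the arithmetic mean of values over all unmasked pairs at bin
    separation ``s``; separations with no unmasked pair are NaN.  With
    ``smooth=True`` a log-spaced running geometric smoother is applied
    (useful on sparse maps); off by default so P is exact on distance-only
    maps.
    """
    mask = cmap.mask
    if not mask.any():
        raise ValueError("cannot estimate expected profile of a fully masked map")
    n = cmap.n_bins
    idx = np.nonzero(mask)[0]
    sep = np.abs(idx[:, None] - idx[None, :])
    vals = cmap.values[np.ix_(idx, idx)]
    counts = np.bincount(sep.ravel(), minlength=n).astype(float)
    sums = np.bincount(sep.ravel(), weights=vals.ravel(), minlength=n)
    # every off-diagonal pair is counted twice in both arrays, so means are
    # unaffected
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    means[counts == 0] = np.nan
    counts_pairs = np.where(np.arange(n) == 0, counts, counts / 2)

    if smooth:
        means = _log_smooth(means, smooth_bins_per_octave)
    return ExpectedProfile(
        grid=cmap.grid, values=means, counts=counts_pairs, smoothed=smooth
    )


def _log_smooth(p: np.ndarray, bins_per_octave: int) -> np.ndarray:
    """Geometric running mean in windows whose width grows with separation."""
    out = p.copy()
    n = len(p)
    for s in range(1, n):
        half = max(1, int(s * (2 ** (1 / bins_per_octave) - 1)))
        lo, hi = max(1, s - half), min(n, s + half + 1)
        win = p[lo:hi]
        win = win[~np.isnan(win) & (win > 0)]
        if win.size:
            out[s] = float(np.exp(np.mean(np.log(win))))
    return out


# ---------------------------------------------------------------------------
# Subtraction maps


def _mutual_scale(a: ContactMap, b: ContactMap, weights: np.ndarray) -> tuple[float, float]:
    """Scale factors bringing both maps to the same total over ``weights``
    (a boolean pair selection); the common target is the mean of the two
    totals, which keeps the operation symmetric in its arguments."""
    ta = float(a.values[weights].sum())
    tb = float(b.values[weights].sum())
    if ta <= 0 or tb <= 0:
        raise ValueError("cannot scale maps with non-positive joint totals")
    target = 0.5 * (ta + tb)
    return target / ta, target / tb


def subtraction_map(
    observed: ContactMap, liftovered: ContactMap, out_bin_size: int | None = None
) -> SubtractionMap:
    """Depth-matched difference map (observed − liftovered), optionally
    aggregated to a coarser resolution.

    Both inputs are scaled to a common total over bins unmasked in both, then
    summed into coarse bins of ``out_bin_size`` (default: input resolution).
    """
    if observed.grid != liftovered.grid:
        raise ValueError("subtraction requires maps on the same grid")
    if observed.normalization != liftovered.normalization:
        raise ValueError("subtraction requires maps in the same normalization state")
    g = observed.grid
    if out_bin_size is None:
        out_bin_size = g.bin_size
    if out_bin_size % g.bin_size != 0:
        raise ValueError(
            f"out_bin_size {out_bin_size} is not a multiple of bin_size {g.bin_size}"
        )
    joint = observed.mask & liftovered.mask
    pair_ok = np.outer(joint, joint)
    sa, sb = _mutual_scale(observed, liftovered, pair_ok)
    diff = sa * observed.values - sb * liftovered.values
    diff[~pair_ok] = 0.0

    factor = out_bin_size // g.bin_size
    n = g.n_bins
    nc = math.ceil(n / factor)
    pad = nc * factor - n
    if pad:
        diff = np.pad(diff, ((0, pad), (0, pad)))
    coarse = diff.reshape(nc, factor, nc, factor).sum(axis=(1, 3))
    cmask = np.zeros(nc, dtype=bool)
    cmask[np.nonzero(joint)[0] // factor] = True
    out_grid = BinGrid(g.chrom, g.chrom_length, out_bin_size)
    return SubtractionMap(
        grid=out_grid,
        values=coarse,
        mask=cmask,
        scale_observed=sa,
        scale_liftovered=sb,
    )
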