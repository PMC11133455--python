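"""Differential contact-enrichment scoring between an observed map and its
distance-only null prediction.

For each bin k the statistic D(k, f) is the mean natural-log ratio
log(V_ij / V*_ij) over pairs spanning k within a window of f bins on each
side — i in [k-f, k), j in (k, k+f] — restricted to pairs where both the
observed value V and the null prediction V* are positive.  D is then
Z-transformed across all defined positions; runs of |Z| above a threshold
are emitted as insulation-change calls (gain or loss of cross-boundary
contacts).

Before taking ratios the two maps are scaled to equal totals over their
jointly positive pairs, so sequencing-depth differences do not shift D by a
constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_core import BinGrid, ContactMap

__all__ = [
    "DifferentialInsulationTrack",
    "InsulationChangeCall",
    "d_score",
    "call_insulation_changes",
    "enrichment_track_export",
    "read_bedgraph_track",
]


@dataclass
class DifferentialInsulationTrack:
    """Per-bin D(k, f) values and their Z-scores.

    ``d`` and ``z`` are NaN where no valid pair exists in the window of k;
    over defined bins Z has mean 0 and (population) standard deviation 1,
    except in the degenerate zero-variance case where Z is all-zero.
    """

    grid: BinGrid
    f: int
    d: np.ndarray
    z: np.ndarray
    n_pairs: np.ndarray
    scale_observed: float
    scale_liftovered: float

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.d)


@dataclass(frozen=True)
class InsulationChangeCall:
    chrom: str
    start: int
    end: int
    peak_z: float
    sign: str  # 'gain' or 'loss'


def d_score(
    observed: ContactMap, liftovered: ContactMap, f: int
) -> DifferentialInsulationTrack:
    """Compute the D(k, f) track and its Z-transform.

    Windows are truncated at chromosome ends.  A position with zero valid
    pairs is undefined (NaN), not zero.
    """
    if observed.grid != liftovered.grid:
        raise ValueError("d_score requires maps on the same grid")
    if observed.normalization != liftovered.normalization:
        raise ValueError("d_score requires maps in the same normalization state")
    n = observed.grid.n_bins
    if f < 1:
        raise ValueError(f"window f must be >= 1, got {f}")
    if f >= n:
        raise ValueError(f"window f={f} must be smaller than the map ({n} bins)")

    V, W = observed.values, liftovered.values
    joint_bins = observed.mask & liftovered.mask
    valid = (V > 0) & (W > 0) & np.outer(joint_bins, joint_bins)
    if not valid.any():
        raise ValueError("no pairs are positive in both maps")

    ta, tb = float(V[valid].sum()), float(W[valid].sum())
    target = 0.5 * (ta + tb)
    sa, sb = target / ta, target / tb

    logratio = np.zeros_like(V)
    logratio[valid] = np.log((sa * V[valid]) / (sb * W[valid]))

    d = np.full(n, np.nan)
    n_pairs = np.zeros(n, dtype=int)
    for k in range(n):
        i_lo, i_hi = max(0, k - f), k        # i in [k-f, k)
        j_lo, j_hi = k + 1, min(n, k + f + 1)  # j in (k, k+f]
        if i_lo >= i_hi or j_lo >= j_hi:
            continue
        sub_valid = valid[i_lo:i_hi, j_lo:j_hi]
        cnt = int(sub_valid.sum())
        n_pairs[k] = cnt
        if cnt:
            d[k] = logratio[i_lo:i_hi, j_lo:j_hi][sub_valid].mean()

    z = np.full(n, np.nan)
    defined = ~np.isnan(d)
    if defined.any():
        mu = d[defined].mean()
        sd = d[defined].std()
        if sd > 0:
            z[defined] = (d[defined] - mu) / sd
        else:
            z[defined] = 0.0  # identical inputs must not produce NaNs
    return DifferentialInsulationTrack(
        grid=observed.grid,
        f=f,
        d=d,
        z=z,
        n_pairs=n_pairs,
        scale_observed=sa,
        scale_liftovered=sb,
    )


def call_insulation_changes(
    track: DifferentialInsulationTrack, z_threshold: float = 2.0
) -> list[InsulationChangeCall]:
    """Merge maximal runs of |Z| >= threshold with constant sign into calls.

    Undefined bins break runs.  ``sign`` is 'gain' for positive Z (more
    cross-position contacts than the distance-only null predicts) and 'loss'
    for negative Z.
    """
    g = track.grid
    calls: list[InsulationChangeCall] = []
    run_start = None
    run_sign = 0
    peak = 0.0

    def flush(end_bin: int) -> None:
        nonlocal run_start
        if run_start is not None:
            calls.append(
                InsulationChangeCall(
                    chrom=g.chrom,
                    start=g.bin_start(run_start),
                    end=g.bin_end(end_bin - 1),
                    peak_z=peak,
                    sign="gain" if run_sign > 0 else "loss",
                )
            )
            run_start = None

    for k in range(g.n_bins):
        zk = track.z[k]
        if np.isnan(zk) or abs(zk) < z_threshold or zk == 0:
            flush(k)
            continue
        sgn = 1 if zk > 0 else -1
        if run_start is None or sgn != run_sign:
            flush(k)
            run_start, run_sign, peak = k, sgn, zk
        else:
            peak = max(peak, zk) if sgn > 0 else min(peak, zk)
    flush(g.n_bins)
    return calls


def enrichment_track_export(track: DifferentialInsulationTrack, path) -> None:
    """Write the Z track as bedGraph; undefined bins are omitted."""
    g = track.grid
    with open(path, "w") as fh:
        fh.write(
            f'track type=bedGraph name="svhic_contact_enrichment" '
            f"description=\"Z of D(k,f), f={track.f}\"\n"
        )
        for k in np.nonzero(track.defined)[0]:
            fh.write(f"{g.chrom}\t{g.bin_start(k)}\t{g.bin_end(k)}\t{track.z[k]:.6f}\n")


def read_bedgraph_track(path) -> list[tuple[str, int, int, float]]:
    """Parse a bedGraph file into (chrom, start, end, value) tuples."""
    out = []
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith(("#", "track")):
                continue
            c, s, e, v = ln.split()
            out.append((c, int(s), int(e), float(v)))
    return out
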