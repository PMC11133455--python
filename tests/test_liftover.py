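import numpy as np
import pytest

from svhic.contact_core import BinGrid, ContactMap, estimate_expected
from svhic.liftover import (
    DeletionSpec,
    SyntenyBlock,
    SyntenyMap,
    deletion_to_synteny,
    fill_codirected_gaps,
    liftover_balanced,
    liftover_easy,
    read_synteny_map,
    simulate_wt_under_deletion,
    write_synteny_map,
)

from conftest import BIN, distance_only_map, make_grid, random_map, random_synteny_case
from oracles import brute_liftover


def identity_synteny(n_bins, chrom="chr5"):
    L = n_bins * BIN
    return SyntenyMap([SyntenyBlock(chrom, 0, L, chrom, 0, L)])


class TestDeletionToSynteny:
    def test_interior_deletion_two_codirected_blocks(self):
        smap = deletion_to_synteny(DeletionSpec("chr1", 30_000, 60_000), 100_000)
        assert [(b.src_start, b.src_end, b.tgt_start, b.tgt_end, b.orientation)
                for b in smap.blocks] == [
            (0, 30_000, 0, 30_000, "+"),
            (60_000, 100_000, 30_000, 70_000, "+"),
        ]

    def test_zero_length_deletion_is_identity(self):
        smap = deletion_to_synteny(DeletionSpec("chr1", 50_000, 50_000), 100_000)
        assert len(smap.blocks) == 1
        b = smap.blocks[0]
        assert (b.src_start, b.src_end) == (b.tgt_start, b.tgt_end) == (0, 100_000)

    def test_deletion_at_chromosome_start(self):
        smap = deletion_to_synteny(DeletionSpec("chr1", 0, 10_000), 100_000)
        assert len(smap.blocks) == 1
        b = smap.blocks[0]
        assert (b.src_start, b.src_end, b.tgt_start, b.tgt_end) == (
            10_000, 100_000, 0, 90_000)

    def test_invertibility(self):
        smap = deletion_to_synteny(DeletionSpec("chr1", 30_000, 60_000), 100_000)
        inv = smap.invert()
        assert inv.blocks[1].src_start == 30_000 and inv.blocks[1].tgt_start == 60_000
        assert inv.source_genome == smap.target_genome


class TestFillCodirectedGaps:
    @staticmethod
    def two_blocks(gap):
        return SyntenyMap([
            SyntenyBlock("a", 0, 100_000, "b", 0, 100_000),
            SyntenyBlock("a", 100_000 + gap, 300_000 + gap,
                         "b", 100_000 + gap, 300_000 + gap),
        ])

    def test_small_matching_gap_merged(self):
        merged = fill_codirected_gaps(self.two_blocks(500_000))
        assert len(merged.blocks) == 1
        b = merged.blocks[0]
        assert (b.src_start, b.src_end) == (0, 800_000)

    def test_large_gap_untouched(self):
        assert len(fill_codirected_gaps(self.two_blocks(2_000_000)).blocks) == 2

    def test_inverted_neighbor_untouched(self):
        smap = SyntenyMap([
            SyntenyBlock("a", 0, 100_000, "b", 0, 100_000, "+"),
            SyntenyBlock("a", 150_000, 250_000, "b", 150_000, 250_000, "-"),
        ])
        assert len(fill_codirected_gaps(smap).blocks) == 2

    def test_unequal_gaps_untouched(self):
        smap = SyntenyMap([
            SyntenyBlock("a", 0, 100_000, "b", 0, 100_000),
            SyntenyBlock("a", 200_000, 300_000, "b", 150_000, 250_000),
        ])
        assert len(fill_codirected_gaps(smap).blocks) == 2


class TestSyntenyIO:
    def test_round_trip(self, tmp_path):
        smap = SyntenyMap(
            [SyntenyBlock("a", 0, 10_000, "b", 5000, 15_000, "-")],
            source_genome="a", target_genome="b",
        )
        p = tmp_path / "syn.tsv"
        write_synteny_map(smap, p)
        back = read_synteny_map(p, "a", "b")
        assert back.blocks == smap.blocks


class TestLiftoverEasy:
    def test_identity_synteny_is_identity(self):
        m = random_map(6, seed=0)
        out = liftover_easy(m, identity_synteny(6), m.grid)
        np.testing.assert_allclose(out.values, m.values)

    def test_deletion_direction_masks_deletion_and_preserves_rest(self):
        # mutant (6 bins) -> reference (8 bins), deletion at reference bins 3-4
        mut = random_map(6, seed=1, genome="mutant")
        ref_grid = make_grid(8)
        smap = deletion_to_synteny(
            DeletionSpec("chr5", 3 * BIN, 5 * BIN), 8 * BIN,
            source_genome="reference", target_genome="mutant",
        ).invert()
        out = liftover_easy(mut, smap, ref_grid)
        assert list(out.mask) == [True] * 3 + [False] * 2 + [True] * 3
        keep = [0, 1, 2, 5, 6, 7]
        np.testing.assert_allclose(out.values[np.ix_(keep, keep)], mut.values)

    def test_inverted_block_hand_remap(self):
        # bins 0-2 keep place; bins 3-5 are inverted in place
        m = random_map(6, seed=2)
        L = 6 * BIN
        smap = SyntenyMap([
            SyntenyBlock("chr5", 0, 3 * BIN, "chr5", 0, 3 * BIN, "+"),
            SyntenyBlock("chr5", 3 * BIN, L, "chr5", 3 * BIN, L, "-"),
        ])
        out = liftover_easy(m, smap, m.grid)
        perm = [0, 1, 2, 5, 4, 3]
        np.testing.assert_allclose(out.values, m.values[np.ix_(perm, perm)])

    def test_mass_conserved_without_rescaling(self):
        m = random_map(10, seed=3)
        smap = deletion_to_synteny(DeletionSpec("chr5", 2 * BIN, 5 * BIN), 10 * BIN)
        out = liftover_easy(m, smap, make_grid(7))
        kept = [0, 1] + list(range(5, 10))
        assert out.values.sum() == pytest.approx(
            m.values[np.ix_(kept, kept)].sum(), rel=1e-9)

    def test_partial_bin_redistribution_conserves_mapped_mass(self):
        # 300 bp deletion: blocks not aligned to 5 kb bins; the deleted 300 bp
        # of the straddled bin carries away its overlap fraction of contacts
        m = random_map(6, seed=4)
        smap = deletion_to_synteny(DeletionSpec("chr5", 10_000, 10_300), 6 * BIN)
        out = liftover_easy(m, smap, BinGrid("chr5", 6 * BIN - 300, BIN))
        w = np.ones(6)
        w[2] = 4700 / 5000  # surviving fraction of the straddled bin
        assert out.values.sum() == pytest.approx(
            (m.values * np.outer(w, w)).sum(), rel=1e-9)
        np.testing.assert_allclose(out.values, out.values.T)

    def test_rejects_bin_size_mismatch_and_wrong_genome(self):
        m = random_map(6, seed=5)
        with pytest.raises(ValueError, match="bin size"):
            liftover_easy(m, identity_synteny(6), BinGrid("chr5", 6 * BIN, 2 * BIN))
        labeled = random_map(6, seed=5, genome="reference")
        smap = identity_synteny(6)
        smap.source_genome = "other"
        with pytest.raises(ValueError, match="genome"):
            liftover_easy(labeled, smap, labeled.grid)


class TestLiftoverBalanced:
    def test_identity_synteny_is_identity(self):
        m = random_map(8, seed=6, normalization="vc_sqrt")
        out = liftover_balanced(m, identity_synteny(8), estimate_expected(m), m.grid)
        np.testing.assert_allclose(out.values, m.values, atol=1e-12)
        assert out.role == "liftovered"

    def test_same_side_pairs_unchanged(self):
        m = random_map(8, seed=7, normalization="vc_sqrt")
        smap = deletion_to_synteny(DeletionSpec("chr5", 3 * BIN, 5 * BIN), 8 * BIN)
        out = liftover_balanced(m, smap, estimate_expected(m), make_grid(6))
        np.testing.assert_allclose(out.values[:3, :3], m.values[:3, :3], atol=1e-12)

    def test_eight_bin_hand_computation(self):
        # P(s) = 8/(1+s); deletion of bins 3-4 moves pair (1,6) from s=5 to
        # s'=3, scaling its value by (8/4)/(8/6) = 1.5
        m = distance_only_map(8, lambda s: 8.0 / (1.0 + s), normalization="vc_sqrt")
        smap = deletion_to_synteny(DeletionSpec("chr5", 3 * BIN, 5 * BIN), 8 * BIN)
        out = liftover_balanced(m, smap, estimate_expected(m), make_grid(6))
        assert out.values[1, 4] == pytest.approx(1.5 * m.values[1, 6])

    def test_reverse_balanced_roundtrip_identity_on_distance_only(self):
        # reverse liftover with the target-derived decay undoes the forward
        # rescaling wherever the smaller genome's P(s) supports the original
        # separation; beyond its support pairs are masked (zero), by design
        m = distance_only_map(10, lambda s: 5.0 / (1.0 + s) ** 1.2,
                              normalization="vc_sqrt")
        smap = deletion_to_synteny(DeletionSpec("chr5", 4 * BIN, 6 * BIN), 10 * BIN)
        fwd = liftover_balanced(m, smap, estimate_expected(m), make_grid(8))
        back = liftover_balanced(fwd, smap.invert(), estimate_expected(fwd), m.grid)
        kept = np.nonzero(back.mask)[0]
        for a in kept:
            for b in kept:
                if abs(a - b) <= fwd.n_bins - 1:
                    assert back.values[a, b] == pytest.approx(m.values[a, b])
                else:
                    assert back.values[a, b] == 0.0

    def test_rejects_profile_from_other_grid(self):
        m = random_map(8, seed=8, normalization="vc_sqrt")
        other = estimate_expected(random_map(9, seed=8, normalization="vc_sqrt"))
        with pytest.raises(ValueError, match="grid"):
            liftover_balanced(m, identity_synteny(8), other, m.grid)


class TestSimulateWtUnderDeletion:
    def test_zero_length_deletion_identity(self):
        m = random_map(8, seed=9, normalization="vc_sqrt")
        out = simulate_wt_under_deletion(m, DeletionSpec("chr5", 4 * BIN, 4 * BIN))
        np.testing.assert_allclose(out.values, m.values)
        assert out.role == "liftovered"

    @pytest.mark.parametrize("del_bins", [(3, 5), (0, 2), (10, 12)])
    def test_distance_only_map_closed_form(self, del_bins):
        n = 12
        p = lambda s: 7.0 / (1.0 + s) ** 1.1
        m = distance_only_map(n, p, normalization="vc_sqrt")
        lo, hi = del_bins
        vstar = simulate_wt_under_deletion(m, DeletionSpec("chr5", lo * BIN, hi * BIN))
        # every surviving pair sits at its post-deletion separation s'
        kept = np.nonzero(vstar.mask)[0]
        new_index = {b: (b if b < lo else b - (hi - lo)) for b in kept}
        for a in kept:
            for b in kept:
                s_new = abs(new_index[a] - new_index[b])
                assert vstar.values[a, b] == pytest.approx(p(s_new))
        assert not vstar.mask[lo:hi].any()

    def test_same_side_pairs_exact_on_noisy_map(self):
        m = random_map(12, seed=10, normalization="vc_sqrt")
        vstar = simulate_wt_under_deletion(m, DeletionSpec("chr5", 5 * BIN, 8 * BIN))
        np.testing.assert_allclose(vstar.values[:5, :5], m.values[:5, :5], atol=1e-12)
        np.testing.assert_allclose(vstar.values[8:, 8:], m.values[8:, 8:], atol=1e-12)


class TestBruteForceOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_easy_and_balanced_match_per_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 13))
        mask = rng.random(n) > 0.1
        m = random_map(n, seed=seed + 100, density=0.9, mask=mask,
                       normalization="vc_sqrt")
        smap, n_tgt = random_synteny_case(rng, n)
        tgt_grid = make_grid(n_tgt)

        easy = liftover_easy(m, smap, tgt_grid)
        ref, ref_mask = brute_liftover(m.values, m.mask, smap.blocks, BIN, n_tgt)
        ref[~ref_mask, :] = 0.0
        ref[:, ~ref_mask] = 0.0
        np.testing.assert_allclose(easy.values, ref, atol=1e-9)
        assert list(easy.mask) == list(ref_mask)

        prof = estimate_expected(m)
        bal = liftover_balanced(m, smap, prof, tgt_grid)
        refb, _ = brute_liftover(m.values, m.mask, smap.blocks, BIN, n_tgt,
                                 expected=prof.values)
        refb[~ref_mask, :] = 0.0
        refb[:, ~ref_mask] = 0.0
        np.testing.assert_allclose(bal.values, refb, atol=1e-9)
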