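"""Contact-map I/O, normalization and Hi-C-style observables."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from chromocycle.contact_maps import (
    ContactMap, GenomicRegion, compartment_profile,
    enhanced_contacts, expected_by_distance, insulation_profile,
    normalize_adjacent, read_contact_map, synthetic_region, tad_boundaries,
    write_contact_map,
)


def _make_map(P):
    return ContactMap(synthetic_region(P.shape[0]), np.asarray(P, dtype=float))


class TestGenomicRegion:
    def test_chr1_segment_has_510_loci(self):
        region = GenomicRegion("chr1", 20.5, 71.4, 100.0)
        assert region.locus_count == 510

    def test_inclusive_start_fencepost(self):
        # 0-0.5 Mb at 100 kb: starts at 0.0, 0.1, ..., 0.5
        assert GenomicRegion("chrS", 0.0, 0.5, 100.0).locus_count == 6

    @pytest.mark.parametrize("start,end,res", [(1.0, 1.0, 100.0), (2.0, 1.0, 100.0),
                                               (0.0, 1.0, 0.0)])
    def test_invalid_regions_rejected(self, start, end, res):
        with pytest.raises(ValueError):
            GenomicRegion("chr1", start, end, res)


class TestIO:
    def test_dense_round_trip_bit_exact(self, random_map, tmp_path):
        path = tmp_path / "map.txt"
        write_contact_map(random_map, path)
        back = read_contact_map(path, random_map.region)
        assert np.array_equal(back.P, random_map.P)

    def test_triples_dialect_equals_dense(self, random_map, tmp_path):
        dense, triples = tmp_path / "d.txt", tmp_path / "t.txt"
        write_contact_map(random_map, dense)
        write_contact_map(random_map, triples, dialect="triples")
        region = random_map.region
        assert np.array_equal(read_contact_map(dense, region).P,
                              read_contact_map(triples, region).P)

    def test_triples_are_mirrored(self, tmp_path):
        path = tmp_path / "t.txt"
        path.write_text("0 1 0.5\n")
        cmap = read_contact_map(path, synthetic_region(3))
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 0] = 0.5
        assert np.array_equal(cmap.P, expected)

    def test_wrong_sized_dense_rejected(self, tmp_path):
        region = GenomicRegion("chr1", 20.5, 71.4, 100.0)  # 510 loci
        n = 509
        path = tmp_path / "small.txt"
        np.savetxt(path, np.zeros((n, n)))
        with pytest.raises(ValueError, match="509"):
            read_contact_map(path, region)

    @pytest.mark.parametrize("content,match", [
        ("0 5 0.1\n", "out of range"),
        ("0 2 -0.5\n", "negative"),
    ])
    def test_bad_triples_name_the_record(self, tmp_path, content, match):
        path = tmp_path / "bad.txt"
        path.write_text(content)
        with pytest.raises(ValueError, match=match):
            read_contact_map(path, synthetic_region(3))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ContactMap(synthetic_region(2), np.zeros((0, 0)))

    def test_asymmetric_matrix_rejected(self):
        P = np.eye(4)
        P[0, 2] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            _make_map(P)


class TestNormalizeAdjacent:
    def test_divide_by_anchor_oracle(self):
        # first off-diagonal all 0.2, one long-range pair at 0.1 -> 0.5
        P = np.zeros((5, 5))
        idx = np.arange(4)
        P[idx, idx + 1] = P[idx + 1, idx] = 0.2
        P[0, 3] = P[3, 0] = 0.1
        out = normalize_adjacent(_make_map(P))
        assert np.allclose(np.diagonal(out.P, 1), 1.0)
        assert out.P[0, 3] == pytest.approx(0.5)

    def test_adjacent_band_exactly_one(self, random_map):
        assert np.all(np.diagonal(random_map.P, 1) == 1.0)
        assert np.all(np.diagonal(random_map.P, -1) == 1.0)

    def test_idempotent(self, random_map):
        again = normalize_adjacent(random_map)
        assert np.array_equal(again.P, random_map.P)

    def test_entries_clipped_to_unit(self, rng):
        P = rng.uniform(0, 1, (10, 10))
        P = 0.5 * (P + P.T)
        idx = np.arange(9)
        P[idx, idx + 1] = P[idx + 1, idx] = 0.1  # anchor far below the max
        out = normalize_adjacent(_make_map(P))
        assert out.P.max() <= 1.0

    def test_zero_anchor_is_an_error(self):
        with pytest.raises(ValueError, match="off-diagonal"):
            normalize_adjacent(_make_map(np.eye(4)))

    @given(st.integers(0, 2**32 - 1))
    def test_symmetry_preserved(self, seed):
        g = np.random.default_rng(seed)
        P = g.uniform(0.01, 1, (8, 8))
        P = 0.5 * (P + P.T)
        out = normalize_adjacent(_make_map(P))
        assert np.array_equal(out.P, out.P.T)


class TestExpectedByDistance:
    def test_unit_adjacent_band(self):
        P = np.eye(4)
        idx = np.arange(3)
        P[idx, idx + 1] = P[idx + 1, idx] = 1.0
        assert expected_by_distance(_make_map(P))[0] == 1.0

    def test_distance_function_is_reproduced_exactly(self):
        n = 7
        S = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        P = 1.0 / (1.0 + S)
        exp = expected_by_distance(_make_map(P))
        assert np.allclose(exp, 1.0 / (1.0 + np.arange(1, n)))

    def test_matches_brute_force(self, rng):
        n = 6
        P = rng.uniform(0, 1, (n, n))
        P = 0.5 * (P + P.T)
        exp = expected_by_distance(_make_map(P))
        for s in range(1, n):
            vals = [P[i, i + s] for i in range(n - s)]
            assert exp[s - 1] == pytest.approx(np.mean(vals))


class TestEnhancedContacts:
    def test_distance_only_map_gives_zero_log_ratio(self):
        n = 30
        S = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        P = 0.9 ** S
        emap = enhanced_contacts(_make_map(P), coarse_resolution_kb=1000.0)
        assert np.allclose(emap.matrix[emap.defined], 0.0, atol=1e-12)

    def test_enriched_block_found_by_hand_summed_oracle(self, rng):
        n = 20
        S = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        P = 0.5 ** S
        P[0:5, 10:15] *= 8.0
        P[10:15, 0:5] *= 8.0
        cmap = _make_map(P)
        emap = enhanced_contacts(cmap, coarse_resolution_kb=500.0)  # 5-locus blocks
        # brute-force block sums (fine diagonal excluded)
        Pd = P.copy()
        np.fill_diagonal(Pd, 0.0)
        obs = np.array([[Pd[5 * I:5 * I + 5, 5 * J:5 * J + 5].sum()
                         for J in range(4)] for I in range(4)])
        exp = np.array([np.diagonal(obs, offset=s).mean() for s in range(4)])
        expected_ratio = np.log2(obs[0, 2] / exp[2])
        assert emap.matrix[0, 2] == pytest.approx(expected_ratio)
        assert expected_ratio > 0
        # the enriched coarse cell is the unique strongly positive one
        off = emap.matrix.copy()
        off[0, 2] = off[2, 0] = -np.inf
        assert np.nanmax(off) < expected_ratio

    def test_invariant_under_global_scaling(self, random_map):
        emap1 = enhanced_contacts(random_map)
        doubled = ContactMap(random_map.region, random_map.P * 0.5)
        emap2 = enhanced_contacts(doubled)
        assert np.allclose(emap1.matrix[emap1.defined],
                           emap2.matrix[emap2.defined])

    def test_non_divisible_resolution_rejected(self, random_map):
        with pytest.raises(ValueError, match="multiple"):
            enhanced_contacts(random_map, coarse_resolution_kb=250.0)


class TestInsulation:
    def test_uniform_map_scores_zero(self):
        P = np.full((20, 20), 0.3)
        np.fill_diagonal(P, 1.0)
        prof = insulation_profile(_make_map(P), window_kb=500.0)
        assert np.allclose(prof.scores[prof.defined], 0.0, atol=1e-12)
        # mask width = window / resolution on each end
        assert not prof.defined[:5].any() and not prof.defined[-5:].any()

    def test_two_blocks_dip_at_the_split(self):
        # near-zero inter-block contact (exactly zero would be masked -inf)
        n, b = 30, 15
        P = np.full((n, n), 0.02)
        P[:b, :b] = 0.8
        P[b:, b:] = 0.8
        np.fill_diagonal(P, 1.0)
        idx = np.arange(n - 1)
        P[idx, idx + 1] = P[idx + 1, idx] = 1.0
        prof = insulation_profile(_make_map(P), window_kb=500.0)
        scores = np.where(prof.defined, prof.scores, np.inf)
        assert abs(int(np.argmin(scores)) - b) <= 1

    def test_matches_brute_force_sliding_window(self, rng):
        n, w = 30, 5
        P = rng.uniform(0.05, 1, (n, n))
        P = 0.5 * (P + P.T)
        prof = insulation_profile(_make_map(P), window_kb=500.0)
        raw = np.full(n, np.nan)
        for i in range(w, n - w):
            block = [P[r, c] for r in range(i - w, i) for c in range(i + 1, i + w + 1)]
            raw[i] = np.mean(block)
        ref = np.log2(raw / np.nanmean(raw))
        assert np.allclose(prof.scores[prof.defined], ref[prof.defined])

    def test_window_too_large_rejected(self):
        with pytest.raises(ValueError, match="too large"):
            insulation_profile(_make_map(np.eye(8) + 0.1), window_kb=500.0)


class TestTadBoundaries:
    @staticmethod
    def _profile(scores):
        from chromocycle.contact_maps import InsulationProfile
        scores = np.asarray(scores, dtype=float)
        return InsulationProfile(scores, 500.0, np.isfinite(scores))

    def test_monotone_profile_has_no_boundaries(self):
        assert tad_boundaries(self._profile(np.linspace(-1, 1, 9))) == []

    def test_v_shape_gives_one_boundary_at_the_vertex(self):
        prof = self._profile([0.5, 0.2, -0.4, 0.1, 0.6])
        assert tad_boundaries(prof, strength_threshold=0.1) == [2]

    def test_shallow_minimum_filtered_by_strength(self):
        prof = self._profile([0.02, 0.0, 0.02, 0.01, 0.03])
        assert tad_boundaries(prof, strength_threshold=0.1) == []


class TestCompartmentProfile:
    def test_checkerboard_recovers_class_labels(self):
        from chromocycle.contact_maps import EnhancedMap
        n = 8
        labels = np.array([1, -1, 1, -1, 1, -1, 1, -1])
        matrix = 0.7 * np.outer(labels, labels)
        emap = EnhancedMap(matrix, np.ones((n, n), bool), synthetic_region(n))
        prof = compartment_profile(emap)
        assert np.linalg.norm(prof.loadings) == pytest.approx(1.0)
        signs = np.sign(prof.loadings)
        assert np.array_equal(signs, labels) or np.array_equal(signs, -labels)

    def test_all_zero_map_is_degenerate(self):
        from chromocycle.contact_maps import EnhancedMap
        emap = EnhancedMap(np.zeros((5, 5)), np.ones((5, 5), bool),
                           synthetic_region(5))
        with pytest.raises(ValueError, match="degenerate"):
            compartment_profile(emap)

    def test_negation_resolved_identically_by_convention(self):
        from chromocycle.contact_maps import EnhancedMap
        n = 8
        labels = np.array([1, 1, -1, -1, 1, 1, -1, -1])
        matrix = 0.4 * np.outer(labels, labels)
        emap = EnhancedMap(matrix, np.ones((n, n), bool), synthetic_region(n))
        emap_neg = EnhancedMap(-matrix, np.ones((n, n), bool), synthetic_region(n))
        v1 = compartment_profile(emap).loadings
        v2 = compartment_profile(emap_neg).loadings
        # same axis, deterministically signed by the same rule
        assert np.allclose(np.abs(v1), np.abs(v2))
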