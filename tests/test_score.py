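"""GLOCON score: distance matrices, noise filter, gap normalization, invariances."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glocon import (
    ChainRecord,
    GloconParams,
    apply_noise_filter,
    ca_distance_matrix,
    difference_matrix,
    fraction_modeled,
    glocon_score,
    pair_glocon,
    pairwise_glocon,
)
from glocon.errors import (
    CorruptCoordinatesError,
    InsufficientOverlapError,
    SegmentScoreError,
)
from glocon.fixtures import apply_hinge, generate_backbone, random_rigid_motion

from conftest import make_chain, segment_of


def _chain_from_coords(coords, sid="c1", start=1):
    residues = {start + i: np.asarray(c, float) for i, c in enumerate(coords)}
    return ChainRecord(sid, "A", "SYN00001", residues)


def _drop(chain, numbers):
    kept = {n: p for n, p in chain.residues.items() if n not in set(numbers)}
    return ChainRecord(chain.structure_id, chain.chain_id, chain.accession, kept)


class TestCaDistanceMatrix:
    def test_collinear_three_residue_chain(self):
        chain = _chain_from_coords([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
        m = ca_distance_matrix(chain)
        assert m.D[0, 1] == pytest.approx(3.8)
        assert m.D[0, 2] == pytest.approx(7.6)
        assert m.D[1, 2] == pytest.approx(3.8)
        assert np.all(np.diag(m.D) == 0)

    def test_invariant_under_rigid_motion(self, rng):
        chain = make_chain("inv1", 1, 25)
        R, t = random_rigid_motion(rng)
        moved = chain.transformed(R, t)
        np.testing.assert_allclose(
            ca_distance_matrix(chain).D, ca_distance_matrix(moved).D, atol=1e-9
        )

    def test_matches_brute_force_pairwise_norms(self, rng):
        coords = rng.uniform(-20, 20, size=(10, 3))
        chain = _chain_from_coords(coords)
        m = ca_distance_matrix(chain)
        for i, j in itertools.combinations(range(10), 2):
            expected = float(np.sqrt(((coords[i] - coords[j]) ** 2).sum()))
            assert m.D[i, j] == pytest.approx(expected, abs=1e-12)

    def test_absurd_distances_rejected(self):
        chain = _chain_from_coords([[0, 0, 0], [3.8, 0, 0], [2e4, 0, 0]])
        with pytest.raises(CorruptCoordinatesError):
            ca_distance_matrix(chain)


class TestDifferenceMatrix:
    def test_identical_chains_give_zero_matrix(self):
        chain = make_chain("d1", 1, 30)
        diff, common = difference_matrix(chain, chain)
        assert common == list(range(1, 31))
        assert np.all(diff == 0)

    def test_single_displaced_residue_affects_exactly_its_row_and_column(self):
        a = make_chain("d2", 1, 20)
        moved = dict(a.residues)
        moved[7] = moved[7] + np.array([5.0, 0, 0])
        b = ChainRecord("d2b", "A", a.accession, moved)
        diff, common = difference_matrix(a, b)
        k = common.index(7)
        # oracle: recompute the expected difference entry-by-entry
        for i, ri in enumerate(common):
            for j, rj in enumerate(common):
                da = np.linalg.norm(a.residues[ri] - a.residues[rj])
                db = np.linalg.norm(b.residues[ri] - b.residues[rj])
                assert diff[i, j] == pytest.approx(abs(da - db), abs=1e-12)
        off_rowcol = np.delete(np.delete(diff, k, 0), k, 1)
        assert np.all(off_rowcol == 0)
        assert diff[k].sum() > 0

    def test_intersection_semantics_for_unequal_coverage(self):
        a = make_chain("d3", 1, 100)
        b = _drop(make_chain("d3b", 1, 100), range(91, 101))
        diff, common = difference_matrix(a, b)
        assert diff.shape == (90, 90)
        assert common == list(range(1, 91))

    def test_fewer_than_three_common_residues_is_an_error(self):
        a = _drop(make_chain("d4", 1, 10), [1, 2, 3, 4])   # keeps 5..10
        b = _drop(make_chain("d4b", 1, 10), range(6, 11))  # keeps 1..5
        with pytest.raises(InsufficientOverlapError) as exc:
            difference_matrix(a, b)
        assert exc.value.n_common == 1


class TestNoiseFilter:
    def test_entry_below_threshold_zeroed(self):
        m = np.array([[0.0, 2.9], [2.9, 0.0]])
        assert np.all(apply_noise_filter(m, 3.0) == 0)

    def test_entry_at_threshold_kept(self):
        # the filter drops strictly-below-threshold entries only
        m = np.array([[0.0, 3.0], [3.0, 0.0]])
        out = apply_noise_filter(m, 3.0)
        assert out[0, 1] == 3.0

    def test_zero_threshold_is_identity(self, rng):
        m = rng.uniform(0, 5, size=(6, 6))
        np.testing.assert_array_equal(apply_noise_filter(m, 0.0), m)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            apply_noise_filter(np.zeros((2, 2)), -1.0)


class TestGloconScore:
    def test_all_zero_matrix_scores_zero(self):
        assert glocon_score(np.zeros((5, 5)), 0.3) == 0.0

    def test_literal_product_arithmetic(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 4.0
        m[0, 2] = m[2, 0] = 5.0
        assert glocon_score(m, 0.5, "literal_product") == pytest.approx(4.5)

    def test_mean_then_fraction_arithmetic(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 4.0
        m[0, 2] = m[2, 0] = 5.0
        assert glocon_score(m, 0.5, "mean_then_fraction") == pytest.approx(9.0 / 3 * 0.5)

    def test_matches_two_loop_oracle_on_random_matrix(self, rng):
        raw = rng.uniform(0, 8, size=(20, 20))
        m = np.triu(raw, 1) + np.triu(raw, 1).T
        expected = 0.0
        for i in range(20):
            for j in range(i + 1, 20):
                expected += m[i, j]
        assert glocon_score(m, 0.7) == pytest.approx(expected * 0.7, rel=1e-12)

    @pytest.mark.parametrize("f", [0.0, -0.1, 1.5])
    def test_fraction_outside_unit_interval_rejected(self, f):
        with pytest.raises(ValueError):
            glocon_score(np.zeros((3, 3)), f)


class TestFractionModeled:
    def test_complete_chains_give_one(self):
        a, b = make_chain("f1", 1, 100), make_chain("f2", 1, 100)
        assert fraction_modeled(a, b, segment_of([a, b])) == 1.0

    def test_single_gap(self):
        a = _drop(make_chain("f1", 1, 100), range(11, 21))
        b = make_chain("f2", 1, 100)
        assert fraction_modeled(a, b, segment_of([a, b])) == pytest.approx(0.9)

    def test_overlapping_gaps_counted_once(self):
        a = _drop(make_chain("f1", 1, 100), range(1, 11))
        b = _drop(make_chain("f2", 1, 100), range(6, 16))
        seg = segment_of([a, b], )
        # union of gaps is 1..15 -> 85 common residues over a 100-long segment
        assert fraction_modeled(a, b, seg) == pytest.approx(0.85)

    def test_matches_set_arithmetic_oracle_on_random_gap_patterns(self, rng):
        full = make_chain("f0", 1, 80)
        seg_len = 80
        for _ in range(50):
            gaps_a = set(rng.choice(range(1, 81), size=rng.integers(0, 40), replace=False))
            gaps_b = set(rng.choice(range(1, 81), size=rng.integers(0, 40), replace=False))
            if 80 - len(gaps_a) < 3 or 80 - len(gaps_b) < 3:
                continue
            a = _drop(make_chain("fa", 1, 80), gaps_a)
            b = _drop(make_chain("fb", 1, 80), gaps_b)
            seg = segment_of([a, b])
            seg = type(seg)(seg.segment_id, seg.accession, 1, 80, seg.members)
            expected = len((set(range(1, 81)) - gaps_a) & (set(range(1, 81)) - gaps_b)) / seg_len
            if expected == 0:
                with pytest.raises(InsufficientOverlapError):
                    fraction_modeled(a, b, seg)
            else:
                assert fraction_modeled(a, b, seg) == pytest.approx(expected, abs=1e-12)


class TestPairwiseGlocon:
    def test_identical_chains_score_zero(self):
        a, b = make_chain("p1", 1, 40), make_chain("p2", 1, 40)
        g = pairwise_glocon(segment_of([a, b]))
        np.testing.assert_array_equal(g.G, np.zeros((2, 2)))

    def test_every_entry_equals_single_pair_computation(self, rng):
        chains = [make_chain(f"p{i:02d}", 1, 30, rng=rng) for i in range(10)]
        # displace half of them into a second conformation
        for c in chains[5:]:
            for n in list(c.residues)[15:]:
                c.residues[n] += np.array([6.0, 0, 0])
        seg = segment_of(chains)
        g = pairwise_glocon(seg)
        params = GloconParams()
        for i in range(10):
            for j in range(i + 1, 10):
                s, _ = pair_glocon(chains[i], chains[j], seg, params)
                assert g.G[i, j] == pytest.approx(s, abs=1e-12)
        np.testing.assert_array_equal(g.G, g.G.T)

    def test_unscorable_pair_fails_whole_segment_with_pair_listed(self):
        a = _drop(make_chain("q1", 1, 20), range(11, 21))  # 1..10
        b = _drop(make_chain("q2", 1, 20), range(1, 11))   # 11..20
        c = make_chain("q3", 1, 20)
        with pytest.raises(SegmentScoreError) as exc:
            pairwise_glocon(segment_of([a, b, c]))
        assert ("q1_A", "q2_A") in [(e.chain_a, e.chain_b) for e in exc.value.pair_errors]

    def test_export_formats(self, tmp_path):
        a, b = make_chain("e1", 1, 20), make_chain("e2", 1, 20)
        g = pairwise_glocon(segment_of([a, b]))
        g.to_csv(tmp_path / "g.csv")
        g.to_phylip(tmp_path / "g.phy")
        lines = (tmp_path / "g.phy").read_text().splitlines()
        assert lines[0].strip() == "2"
        assert len(lines) == 3


class TestScoreInvariances:
    def test_rigid_motion_invariance_of_glocon_matrix(self, rng, two_state_ensemble):
        """Independently moving every chain never changes the score matrix."""
        from glocon import assign_segments
        ens = two_state_ensemble
        seg = assign_segments(ens.chains, ens.mapping)[0]
        baseline = pairwise_glocon(seg).G
        for _ in range(5):
            moved = []
            for chain in seg.members:
                R, t = random_rigid_motion(rng)
                moved.append(chain.transformed(R, t))
            g = pairwise_glocon(segment_of(moved, seg.segment_id))
            np.testing.assert_allclose(g.G, baseline, atol=1e-9)

    def test_sub_threshold_displacements_are_invisible(self, rng):
        a = make_chain("s1", 1, 40)
        jitter = {n: p + rng.normal(0, 0.2, 3) for n, p in a.residues.items()}
        b = ChainRecord("s2", "A", a.accession, jitter)
        seg = segment_of([a, b])
        s, _ = pair_glocon(a, b, seg)
        assert s == 0.0

    def test_glocon_non_decreasing_with_hinge_angle(self):
        """Opening a two-domain hinge further never lowers the score."""
        base = apply_hinge(generate_backbone(60), 30, 90.0)  # bent L-shape
        ref = ChainRecord("h000", "A", base.accession, base.residues)
        scores = []
        for angle in range(0, 91, 10):
            conf = apply_hinge(base, 30, float(angle)) if angle else base
            other = ChainRecord(f"h{angle:03d}b", "A", base.accession, conf.residues)
            seg = segment_of([ref, other])
            s, _ = pair_glocon(ref, other, seg)
            scores.append(s)
        assert scores[0] == 0.0
        assert all(s2 >= s1 for s1, s2 in zip(scores, scores[1:]))
        assert scores[-1] > 0

    def test_gappier_pair_never_scores_higher_for_fixed_differences(self):
        """With literal normalization, gaps can only shrink the score."""
        base = apply_hinge(generate_backbone(60), 30, 90.0)
        conf = apply_hinge(base, 30, 30.0)
        a = ChainRecord("g1", "A", base.accession, base.residues)
        b_full = ChainRecord("g2", "A", base.accession, conf.residues)
        seg = segment_of([a, b_full])
        s_full, _ = pair_glocon(a, b_full, seg)
        for gap in [range(5, 10), range(40, 50), range(55, 61)]:
            b_gappy = _drop(b_full, gap)
            seg_g = type(seg)(seg.segment_id, seg.accession, 1, 60, (a, b_gappy))
            s_gappy, _ = pair_glocon(a, b_gappy, seg_g)
            assert s_gappy <= s_full


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1), st.floats(0.0, 6.0))
def test_score_symmetry_and_nonnegativity_property(seed, tau):
    """G(a,b) = G(b,a) >= 0 for arbitrary noisy chains and thresholds."""
    rng = np.random.default_rng(seed)
    a = make_chain("pa", 1, 15, rng=rng)
    b = make_chain("pb", 1, 15, rng=rng)
    for n in list(b.residues)[8:]:
        b.residues[n] += rng.normal(0, 2.0, 3)
    seg = segment_of([a, b])
    params = GloconParams(noise_threshold=tau)
    s_ab, _ = pair_glocon(a, b, seg, params)
    s_ba, _ = pair_glocon(b, a, seg, params)
    assert s_ab == pytest.approx(s_ba, abs=1e-12)
    assert s_ab >= 0
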