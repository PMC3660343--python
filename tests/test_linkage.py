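"""Two-point estimation, grouping, ordering and map statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carpmap.dataio import MarkerRecord, PipelineConfig
from carpmap.linkage import (
    estimate_rf,
    group_markers,
    inverse_kosambi,
    kosambi_cM,
    map_stats,
    order_group,
    segregation_test,
    two_point_matrix,
    GeneticMap,
    LinkageGroupMap,
)


def lm_pair(n_rec: int, n: int) -> tuple[MarkerRecord, MarkerRecord]:
    """Coupling-phase lmxll pair with n_rec recombinants of n meioses."""
    a = ("lm",) * (n // 2) + ("ll",) * (n - n // 2)
    b = tuple(("ll" if c == "lm" else "lm") if i < n_rec else c for i, c in enumerate(a))
    return MarkerRecord("A", "lmxll", a), MarkerRecord("B", "lmxll", b)


class TestKosambi:
    def test_known_values(self):
        assert kosambi_cM(0.0) == 0.0
        assert kosambi_cM(0.2) == pytest.approx(25 * np.log(1.4 / 0.6), abs=1e-9)
        assert kosambi_cM(0.2) == pytest.approx(21.18, abs=0.005)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            kosambi_cM(0.5)
        with pytest.raises(ValueError):
            inverse_kosambi(-1.0)

    @given(st.floats(min_value=0.0, max_value=0.49))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, r):
        assert inverse_kosambi(kosambi_cM(r)) == pytest.approx(r, abs=1e-12)


class TestSegregationTest:
    def test_mild_deviation(self):
        m = MarkerRecord("m", "lmxll", ("lm",) * 50 + ("ll",) * 57)
        chi2, df, p = segregation_test(m)
        assert chi2 == pytest.approx(2 * 3.5**2 / 53.5, abs=1e-9)
        assert df == 1
        assert p > 0.01

    def test_perfect_split_is_zero(self):
        m = MarkerRecord("m", "nnxnp", ("nn",) * 50 + ("np",) * 50)
        assert segregation_test(m)[0] == 0.0

    def test_strong_distortion_rejected(self):
        m = MarkerRecord("m", "lmxll", ("lm",) * 80 + ("ll",) * 27)
        chi2, df, p = segregation_test(m)
        assert chi2 == pytest.approx(26.25, abs=0.01)
        assert p < 0.01

    def test_one_to_two_to_one_expectation(self):
        m = MarkerRecord("m", "hkxhk", ("hh",) * 25 + ("hk",) * 50 + ("kk",) * 25)
        chi2, df, _ = segregation_test(m)
        assert chi2 == 0.0
        assert df == 2

    def test_all_missing_is_an_error(self):
        m = MarkerRecord("m", "lmxll", ("--", "--"))
        with pytest.raises(ValueError, match="missing"):
            segregation_test(m)


class TestEstimateRf:
    def test_ten_recombinants_of_hundred(self):
        a, b = lm_pair(10, 100)
        est = estimate_rf(a, b)
        assert est.rf_hat == pytest.approx(0.10, abs=1e-6)
        expected_lod = 10 * np.log10(0.1) + 90 * np.log10(0.9) + 100 * np.log10(2)
        assert est.lod == pytest.approx(expected_lod, abs=1e-6)
        assert est.n_informative == 100

    def test_phase_flip_on_apparent_repulsion(self):
        a, b = lm_pair(90, 100)
        est = estimate_rf(a, b)
        assert est.rf_hat == pytest.approx(0.10, abs=1e-6)
        assert est.phase_choice[0] == "r"

    def test_null_pair(self):
        a, b = lm_pair(50, 100)
        est = estimate_rf(a, b)
        assert est.rf_hat == 0.5
        assert est.lod == 0.0

    def test_uninformative_type_pair(self):
        a = MarkerRecord("A", "lmxll", ("lm",) * 50 + ("ll",) * 50)
        b = MarkerRecord("B", "nnxnp", ("nn",) * 50 + ("np",) * 50)
        est = estimate_rf(a, b)
        assert (est.rf_hat, est.lod, est.n_informative) == (0.5, 0.0, 0)

    def test_known_phase_restricts_search(self):
        # same data as the flip test, but phases declared as coupling:
        # the estimator must not flip and lands at rf ~ 0.9 -> clamped 0.5
        a, b = lm_pair(90, 100)
        a2 = MarkerRecord("A", "lmxll", a.genotype_codes, phase="0-")
        b2 = MarkerRecord("B", "lmxll", b.genotype_codes, phase="0-")
        est = estimate_rf(a2, b2)
        assert est.rf_hat == 0.5
        assert est.lod == 0.0

    def test_matrix_agrees_with_scalar_path(self):
        rng = np.random.default_rng(3)
        markers = []
        for t in ("lmxll", "nnxnp", "hkxhk", "efxeg", "abxcd"):
            from carpmap.dataio import genotype_alphabet

            alpha = genotype_alphabet(t)
            for j in range(2):
                codes = tuple(rng.choice(alpha, size=80))
                markers.append(MarkerRecord(f"{t}{j}", t, codes))
        rf, lod, ninf = two_point_matrix(markers)
        for i in range(len(markers)):
            for j in range(i + 1, len(markers)):
                est = estimate_rf(markers[i], markers[j])
                assert rf[i, j] == pytest.approx(est.rf_hat, abs=2e-3)
                assert lod[i, j] == pytest.approx(est.lod, abs=0.02)
                assert ninf[i, j] == est.n_informative


class TestGrouping:
    def _mats(self, n, edges):
        rf = np.full((n, n), 0.5)
        lod = np.zeros((n, n))
        np.fill_diagonal(rf, 0.0)
        for i, j in edges:
            rf[i, j] = rf[j, i] = 0.1
            lod[i, j] = lod[j, i] = 10.0
        return rf, lod

    def test_transitive_closure(self, cfg):
        rf, lod = self._mats(3, [(0, 1), (1, 2)])
        groups = group_markers(rf, lod, cfg)
        assert groups[0] == [0, 1, 2]

    def test_no_edges_gives_singletons(self, cfg):
        rf, lod = self._mats(4, [])
        groups = group_markers(rf, lod, cfg)
        assert sorted(map(len, groups)) == [1, 1, 1, 1]

    def test_high_rf_edge_not_linked(self, cfg):
        rf, lod = self._mats(2, [(0, 1)])
        rf[0, 1] = rf[1, 0] = 0.45  # above max_rf 0.4 despite high LOD
        assert sorted(map(len, group_markers(rf, lod, cfg))) == [1, 1]

    def test_invariant_under_marker_permutation(self, cfg, clean_sim):
        markers = list(clean_sim.family.markers)
        rf, lod, _ = two_point_matrix(markers)
        base = group_markers(rf, lod, cfg)
        base_sets = {frozenset(markers[i].marker_id for i in g) for g in base}
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(markers))
        shuffled = [markers[i] for i in perm]
        rf2, lod2, _ = two_point_matrix(shuffled)
        got = {
            frozenset(shuffled[i].marker_id for i in g)
            for g in group_markers(rf2, lod2, cfg)
        }
        assert got == base_sets


class TestOrdering:
    def test_two_marker_group_length_is_kosambi(self):
        rf = np.array([[0.0, 0.0935], [0.0935, 0.0]])
        lod = np.array([[0.0, 12.0], [12.0, 0.0]])
        order, pos = order_group([0, 1], rf, lod)
        assert pos[0] == 0.0
        assert pos[1] == pytest.approx(kosambi_cM(0.0935), abs=1e-9)
        assert pos[1] == pytest.approx(9.46, abs=0.01)

    def test_single_marker_group(self):
        order, pos = order_group([0], np.zeros((1, 1)), np.zeros((1, 1)))
        assert (order, pos) == ([0], [0.0])

    def test_total_length_invariant_under_reversal(self):
        # exact pairwise distances from a known order
        true_pos = np.array([0.0, 6.0, 13.0, 21.0, 30.0])
        n = len(true_pos)
        d = np.abs(true_pos[:, None] - true_pos[None, :])
        rf = 0.5 * np.tanh(d / 50.0)
        lod = np.where(np.eye(n) == 1, 0.0, 10.0)
        _, pos_fwd = order_group(list(range(n)), rf, lod)
        rev = list(range(n))[::-1]
        # reversed input indices: same rf matrix, reversed member list
        _, pos_rev = order_group(rev, rf, lod)
        assert pos_fwd[-1] == pytest.approx(pos_rev[-1], abs=1e-6)
        assert pos_fwd[-1] == pytest.approx(30.0, abs=1e-6)

    def test_recovers_exact_distances(self):
        true_pos = np.array([0.0, 5.0, 12.0, 20.0])
        d = np.abs(true_pos[:, None] - true_pos[None, :])
        rf = 0.5 * np.tanh(d / 50.0)
        lod = np.where(np.eye(4) == 1, 0.0, 8.0)
        order, pos = order_group([0, 1, 2, 3], rf, lod)
        assert order in ([0, 1, 2, 3], [3, 2, 1, 0])
        assert np.allclose(np.diff(pos), [5.0, 7.0, 8.0] if order[0] == 0 else [8.0, 7.0, 5.0], atol=1e-6)


class TestMapStats:
    def test_basic_table(self):
        gmap = GeneticMap(
            [
                LinkageGroupMap("LG1", ["a", "b"], [0.0, 10.0]),
                LinkageGroupMap("LG2", ["c"], [0.0]),
            ]
        )
        df = map_stats(gmap)
        lg1 = df[df.lg_id == "LG1"].iloc[0]
        assert lg1.avg_spacing_cM == 10.0
        assert lg1.max_spacing_cM == 10.0
        assert np.isnan(df[df.lg_id == "LG2"].iloc[0].avg_spacing_cM)
        total = df[df.lg_id == "Total"].iloc[0]
        assert total.n_markers == 3
        assert total.length_cM == 10.0
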