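"""Centroid / random-forest classifiers and the supervised admixture EM."""

import numpy as np
import pytest

from scancestry.classify import (
    AncestryCall,
    admixture_loglik,
    assign_from_proportions,
    centroid_classify,
    em_step,
    fit_supervised_admixture,
    group_frequencies,
    rf_classify,
)
from scancestry.genotype import MISSING, GenotypeMatrix, ReferencePanel
from scancestry.pca import fit_reference_pca, project
from scancestry.simulate import sample_genotypes

from conftest import make_snps, matrix_from


def _panel_from(dosages, groups, pops=None):
    m = matrix_from(dosages)
    groups = np.asarray(groups, dtype=object)
    pops = groups if pops is None else np.asarray(pops, dtype=object)
    return ReferencePanel(m, pops, groups)


class TestCentroid:
    def test_query_at_centroid(self):
        ref = np.array([[0.0, 0], [2, 0], [10, 0], [12, 0]])
        groups = ["A", "A", "B", "B"]
        calls = centroid_classify(ref, groups, np.array([[1.0, 0]]), ["q"])
        assert calls[0].assigned_group == "A"
        assert calls[0].score_type == "inverse_distance"

    def test_equidistant_tie_goes_lexicographic(self):
        ref = np.array([[0.0], [10.0]])
        calls = centroid_classify(ref, ["B", "A"], np.array([[5.0]]), ["q"])
        assert calls[0].assigned_group == "A"

    def test_zero_distance_is_certain(self):
        ref = np.array([[0.0], [10.0]])
        calls = centroid_classify(ref, ["A", "B"], np.array([[10.0]]), ["q"])
        assert calls[0].proportions == {"A": 0.0, "B": 1.0}

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            centroid_classify(np.zeros((0, 2)), [], np.zeros((1, 2)), ["q"])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(20, 3))
        groups = ["A"] * 10 + ["B"] * 10
        ref[10:] += 5
        q = rng.normal(size=(6, 3))
        calls = centroid_classify(ref, groups, q, [f"q{i}" for i in range(6)])
        perm = rng.permutation(6)
        calls_p = centroid_classify(ref, groups, q[perm],
                                    [f"q{i}" for i in perm])
        by_id = {c.sample_id: c.assigned_group for c in calls}
        assert all(by_id[c.sample_id] == c.assigned_group for c in calls_p)


class TestRandomForest:
    def test_deep_cluster_point_high_probability(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.3, size=(30, 2))
        b = rng.normal(8, 0.3, size=(30, 2))
        ref = np.vstack([a, b])
        groups = ["A"] * 30 + ["B"] * 30
        calls = rf_classify(ref, groups, a[:1], ["q"], seed=0)
        assert calls[0].assigned_group == "A"
        assert calls[0].proportions["A"] >= 0.9

    def test_same_seed_identical_probabilities(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(40, 2))
        groups = ["A"] * 20 + ["B"] * 20
        q = rng.normal(size=(5, 2))
        ids = [f"q{i}" for i in range(5)]
        c1 = rf_classify(ref, groups, q, ids, seed=7)
        c2 = rf_classify(ref, groups, q, ids, seed=7)
        assert all(a.proportions == b.proportions for a, b in zip(c1, c2))

    def test_separable_training_data_memorized(self):
        ref = np.array([[0.0], [1.0], [10.0], [11.0]])
        groups = ["A", "A", "B", "B"]
        calls = rf_classify(ref, groups, ref, list("wxyz"), seed=0)
        assert [c.assigned_group for c in calls] == ["A", "A", "B", "B"]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 ancestry groups"):
            rf_classify(np.zeros((3, 2)), ["A"] * 3, np.zeros((1, 2)), ["q"])


class TestGroupFrequencies:
    def test_direct_count(self):
        panel = _panel_from([[0], [2], [1], [1]], ["A", "A", "B", "B"])
        groups, F = group_frequencies(panel)
        assert groups == ["A", "B"]
        assert F[0, 0] == pytest.approx(0.5)
        assert F[1, 0] == pytest.approx(0.5)

    def test_clamping_at_zero(self):
        panel = _panel_from([[0], [0], [2], [2]], ["A", "A", "B", "B"])
        _, F = group_frequencies(panel)
        assert F[0, 0] == pytest.approx(1e-6)
        assert F[1, 0] == pytest.approx(1 - 1e-6)

    def test_all_missing_group_falls_back_to_panel(self):
        dosages = np.array([[MISSING], [MISSING], [2], [2]])
        panel = _panel_from(dosages, ["A", "A", "B", "B"])
        _, F = group_frequencies(panel)
        assert F[0, 0] == pytest.approx(1 - 1e-6)  # panel-wide freq = 1, clamped

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(3)
        dosages = rng.integers(0, 3, size=(30, 15)).astype(np.int8)
        dosages[rng.random(dosages.shape) < 0.1] = MISSING
        groups = rng.choice(["A", "B", "C"], size=30)
        panel = _panel_from(dosages, groups)
        names, F = group_frequencies(panel)
        for k, g in enumerate(names):
            for j in range(15):
                vals = [dosages[i, j] for i in range(30)
                        if groups[i] == g and dosages[i, j] != MISSING]
                if vals:
                    expect = np.clip(sum(vals) / (2 * len(vals)), 1e-6, 1 - 1e-6)
                    assert F[k, j] == pytest.approx(expect)


class TestLoglik:
    def test_closed_form_single_het(self):
        G = np.array([[1]], dtype=np.int8)
        ll = admixture_loglik(G, np.array([[1.0]]), np.array([[0.5]]))
        assert ll == pytest.approx(2 * np.log(0.5), abs=1e-12)

    def test_all_missing_is_zero(self):
        G = np.full((3, 4), MISSING, dtype=np.int8)
        assert admixture_loglik(G, np.full((3, 2), 0.5), np.full((2, 4), 0.3)) == 0.0

    def test_nan_rejected(self):
        G = np.array([[1]], dtype=np.int8)
        with pytest.raises(ValueError, match="NaN"):
            admixture_loglik(G, np.array([[np.nan]]), np.array([[0.5]]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        N, M, K = 8, 20, 3
        G = rng.integers(0, 3, size=(N, M)).astype(np.int8)
        G[rng.random(G.shape) < 0.1] = MISSING
        Q = rng.dirichlet(np.ones(K), size=N)
        F = rng.uniform(0.05, 0.95, size=(K, M))
        expect = 0.0
        for i in range(N):
            for j in range(M):
                if G[i, j] == MISSING:
                    continue
                pa = sum(Q[i, k] * F[k, j] for k in range(K))
                pb = sum(Q[i, k] * (1 - F[k, j]) for k in range(K))
                expect += G[i, j] * np.log(pa) + (2 - G[i, j]) * np.log(pb)
        assert admixture_loglik(G, Q, F) == pytest.approx(expect, abs=1e-9)


class TestEmStep:
    def test_het_with_opposite_fixed_frequencies(self):
        # f1 -> 1, f2 -> 0, g = 1: MLE is q = (1/2, 1/2)
        G = np.array([[1]], dtype=np.int8)
        F = np.array([[1 - 1e-6], [1e-6]])
        Q = np.array([[0.3, 0.7]])
        for _ in range(2000):
            Q, _ = em_step(G, Q, F, frozen_F=True)
        assert np.allclose(Q, [[0.5, 0.5]], atol=1e-4)

    def test_hom_alt_drives_q_to_one(self):
        G = np.array([[2]], dtype=np.int8)
        F = np.array([[1 - 1e-6], [1e-6]])
        Q = np.array([[0.5, 0.5]])
        for _ in range(5000):
            Q, _ = em_step(G, Q, F, frozen_F=True)
        assert Q[0, 0] > 1 - 1e-4

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_loglik_and_simplex(self, seed):
        rng = np.random.default_rng(seed)
        N, M, K = 10, 30, 3
        G = rng.integers(0, 3, size=(N, M)).astype(np.int8)
        G[rng.random(G.shape) < 0.1] = MISSING
        Q = rng.dirichlet(np.ones(K), size=N)
        F = rng.uniform(0.05, 0.95, size=(K, M))
        ll = admixture_loglik(G, Q, F)
        for _ in range(100):
            Q, F = em_step(G, Q, F)
            new_ll = admixture_loglik(G, Q, F)
            assert new_ll >= ll - 1e-9
            assert np.allclose(Q.sum(axis=1), 1.0, atol=1e-10)
            ll = new_ll

    def test_frozen_rows_stay_frozen(self):
        rng = np.random.default_rng(9)
        G = rng.integers(0, 3, size=(4, 10)).astype(np.int8)
        Q = rng.dirichlet([1, 1], size=4)
        F = rng.uniform(0.1, 0.9, size=(2, 10))
        Q2, _ = em_step(G, Q, F, frozen_q_rows=[0, 2])
        assert np.array_equal(Q2[[0, 2]], Q[[0, 2]])
        assert not np.allclose(Q2[[1, 3]], Q[[1, 3]])

    def test_group_frequencies_are_fixed_point_of_reference_update(self):
        """One-hot reference rows leave F invariant under the EM F-update,
        which is what licenses the fixed-F fast path of the supervised fit."""
        rng = np.random.default_rng(11)
        dosages = rng.integers(0, 3, size=(20, 12)).astype(np.int8)
        groups = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        panel = _panel_from(dosages, groups)
        names, F = group_frequencies(panel)
        Q = np.zeros((20, 2))
        for i, g in enumerate(groups):
            Q[i, names.index(g)] = 1.0
        _, F2 = em_step(dosages, Q, F, frozen_q_rows=np.arange(20))
        assert np.allclose(F2, F, atol=1e-12)


class TestSupervisedFit:
    def test_duplicated_reference_individual_recovered(self, small_panel):
        ref = small_panel
        i = 0
        query = GenotypeMatrix(
            ["copy"], ref.genotypes.snps, ref.genotypes.dosages[[i]].copy()
        )
        fit = fit_supervised_admixture(ref, query)
        k = fit.groups.index(ref.ancestry_group[i])
        assert fit.query_Q[0, k] >= 0.9

    def test_identical_ancestral_frequencies_leave_q_uniform(self):
        # when the K frequency rows coincide the likelihood is constant in q,
        # so EM from the uniform start never moves
        rng = np.random.default_rng(5)
        freqs = rng.uniform(0.2, 0.8, size=50)
        G = sample_genotypes(freqs, 5, 3).dosages
        F = np.vstack([freqs, freqs])
        Q = np.full((5, 2), 0.5)
        ll0 = admixture_loglik(G, Q, F)
        for _ in range(50):
            Q, _ = em_step(G, Q, F, frozen_F=True)
        assert np.allclose(Q, 0.5, atol=1e-12)
        assert admixture_loglik(G, Q, F) == pytest.approx(ll0)

    def test_monotone_trace_and_convergence_flag(self, small_panel):
        query = GenotypeMatrix(
            ["q1", "q2"], small_panel.genotypes.snps,
            small_panel.genotypes.dosages[:2].copy(),
        )
        fit = fit_supervised_admixture(small_panel, query)
        assert fit.converged
        assert np.all(np.diff(fit.loglik_trace) >= -1e-6)

    def test_joint_F_update_matches_fixed_F_closely(self, small_panel):
        """With few queries the joint-F variant must land near the fixed-F one."""
        query = GenotypeMatrix(
            ["q1"], small_panel.genotypes.snps,
            small_panel.genotypes.dosages[[5]].copy(),
        )
        fit_fixed = fit_supervised_admixture(small_panel, query)
        fit_joint = fit_supervised_admixture(small_panel, query,
                                             update_F_with_queries=True)
        assert np.allclose(fit_fixed.query_Q, fit_joint.query_Q, atol=0.1)
        assert np.argmax(fit_fixed.query_Q) == np.argmax(fit_joint.query_Q)

    def test_unaligned_query_rejected(self, small_panel):
        query = matrix_from(np.zeros((1, 3), dtype=np.int8),
                            snps=make_snps(3, chrom="7"))
        with pytest.raises(ValueError, match="aligned"):
            fit_supervised_admixture(small_panel, query)


class TestAssignment:
    def test_argmax_and_ties(self):
        ids = ["a", "b", "c"]
        groups = ["AFR", "EAS", "EUR"]
        mat = np.array([[0.7, 0.1, 0.2], [0.5, 0.0, 0.5], [0.0, 0.0, 1.0]])
        calls = assign_from_proportions((ids, groups, mat))
        assert [c.assigned_group for c in calls] == ["AFR", "AFR", "EUR"]

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            assign_from_proportions((["a"], ["X", "Y"], np.zeros((1, 2))))

    def test_ancestry_call_consistency_enforced(self):
        with pytest.raises(ValueError, match="argmax"):
            AncestryCall("s", {"A": 0.2, "B": 0.8}, "A")
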