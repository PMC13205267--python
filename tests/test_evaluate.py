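import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mhsgtr.evaluate import (adjusted_rand_index, clinical_enrichment,
                             logrank_test, select_k, spectral_cluster)
from mhsgtr.io import ClinicalTable, SurvivalTable
from mhsgtr.simulate import SyntheticSpec, generate_dataset


def logrank_oracle(time, event, labels):
    """Independent risk-set enumeration of the multi-group log-rank test."""
    time, event, labels = map(np.asarray, (time, event, labels))
    groups = np.unique(labels)
    k = len(groups)
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        d = ((time == t) & (event == 1)).sum()
        ng = np.array([(at_risk & (labels == g)).sum() for g in groups])
        dg = np.array([((time == t) & (event == 1) & (labels == g)).sum()
                       for g in groups])
        O += dg
        E += d * ng / n
        if n > 1:
            c = d * (n - d) / (n - 1)
            V += c * (np.diag(ng / n) - np.outer(ng, ng) / n ** 2)
    z = (O - E)[:-1]
    chi2 = float(z @ np.linalg.pinv(V[:-1, :-1]) @ z)
    p = float(stats.chi2.sf(chi2, k - 1))
    return chi2, p


class TestSpectralClustering:
    def test_block_diagonal_graph_recovered_exactly(self):
        S = np.zeros((10, 10))
        S[:5, :5] = 0.8
        S[5:, 5:] = 0.6
        np.fill_diagonal(S, 1.0)
        res = spectral_cluster(S, 2, seed=0)
        assert adjusted_rand_index(res.labels,
                                   [0] * 5 + [1] * 5) == 1.0
        assert sorted(np.unique(res.labels)) == [1, 2]

    def test_invariance_to_uniform_scaling(self, rng):
        S = rng.uniform(0, 1, size=(20, 20))
        S = (S + S.T) / 2
        a = spectral_cluster(S, 3, seed=1).labels
        b = spectral_cluster(12.5 * S, 3, seed=1).labels
        assert adjusted_rand_index(a, b) == 1.0

    def test_duplicating_samples_preserves_partition(self):
        S = np.zeros((8, 8))
        S[:4, :4] = 0.9
        S[4:, 4:] = 0.9
        np.fill_diagonal(S, 1.0)
        base = spectral_cluster(S, 2, seed=0).labels
        idx = np.concatenate([np.arange(8), np.arange(8)])
        S2 = S[np.ix_(idx, idx)]
        doubled = spectral_cluster(S2, 2, seed=0).labels
        assert adjusted_rand_index(doubled[:8], base) == 1.0
        assert adjusted_rand_index(doubled[:8], doubled[8:]) == 1.0

    def test_k_bounds_enforced(self, rng):
        S = np.abs(rng.normal(size=(5, 5)))
        with pytest.raises(ValueError):
            spectral_cluster(S, 5, seed=0)
        with pytest.raises(ValueError):
            spectral_cluster(S, 1, seed=0)

    def test_select_k_two_ideal_blocks(self):
        S = np.zeros((12, 12))
        S[:6, :6] = 1.0
        S[6:, 6:] = 1.0
        assert select_k(S) == 2

    def test_select_k_single_block_warns_kmin(self):
        S = np.ones((8, 8))
        with pytest.warns(UserWarning):
            assert select_k(S) == 2

    def test_select_k_planted_four_blocks(self, rng):
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            S = np.full((40, 40), 0.05) + r.uniform(0, 0.05, (40, 40))
            for b in range(4):
                S[b * 10:(b + 1) * 10, b * 10:(b + 1) * 10] += 0.8
            S = (S + S.T) / 2
            hits += select_k(S) == 4
        assert hits >= 4


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        surv = SurvivalTable([f"s{i}" for i in range(6)], t, e)
        chi2, p, _ = logrank_test(surv, np.array([0, 0, 0, 1, 1, 1]))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_risk_set_oracle_on_random_data(self):
        rng = np.random.default_rng(99)
        for trial in range(50):
            n = int(rng.integers(8, 30))
            k = int(rng.integers(2, 4))
            t = np.round(rng.exponential(1.0, n), 3) + 0.001
            e = rng.integers(0, 2, n)
            lab = rng.integers(0, k, n)
            if e.sum() == 0 or len(np.unique(lab)) < k:
                continue
            surv = SurvivalTable([f"s{i}" for i in range(n)], t, e)
            chi2, p, _ = logrank_test(surv, lab)
            ochi2, op = logrank_oracle(t, e, lab)
            assert chi2 == pytest.approx(ochi2, abs=1e-6)
            assert p == pytest.approx(op, abs=1e-6)

    def test_power_under_planted_hazard_separation(self):
        hits = 0
        for seed in range(10):
            spec = SyntheticSpec(n_samples=200, n_clusters=2, view_dims=(5,),
                                 hazard_rates=(1.0, 0.25), seed=seed)
            ds, labels = generate_dataset(spec)
            _, p, _ = logrank_test(ds.survival, labels)
            hits += p < 0.001
        assert hits >= 9

    def test_degenerate_inputs_rejected(self):
        surv = SurvivalTable(["a", "b"], [1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="two groups"):
            logrank_test(surv, np.array([0, 0]))
        surv0 = SurvivalTable(["a", "b"], [1.0, 2.0], [0, 0])
        with pytest.raises(ValueError, match="event"):
            logrank_test(surv0, np.array([0, 1]))


class TestEnrichment:
    def test_chi_square_perfect_association_no_correction(self):
        # 2x2 table [[10,0],[0,10]] -> chi2 = 20 without continuity correction
        col = ["x"] * 10 + ["y"] * 10
        labels = np.array([1] * 10 + [2] * 10)
        clin = ClinicalTable([f"s{i}" for i in range(20)],
                             pd.DataFrame({"c": col},
                                          index=[f"s{i}" for i in range(20)]),
                             {"c": "categorical"})
        rep = clinical_enrichment(clin, labels)
        assert rep.table["statistic"].iloc[0] == pytest.approx(20.0)

    def test_bh_adjustment_step_up_example(self):
        from statsmodels.stats.multitest import multipletests
        _, p_adj, _, _ = multipletests([0.01, 0.02, 0.03, 0.04],
                                       method="fdr_bh")
        np.testing.assert_allclose(p_adj, 0.04)

    def test_kruskal_wallis_for_numeric_and_skipped_single_level(self):
        rng = np.random.default_rng(3)
        n = 60
        labels = np.repeat([1, 2, 3], 20)
        age = rng.normal(50, 5, n) + 10 * labels
        const = ["only"] * n
        ids = [f"s{i}" for i in range(n)]
        clin = ClinicalTable(ids, pd.DataFrame({"age": age, "const": const},
                                               index=ids),
                             {"age": "numeric", "const": "categorical"})
        with pytest.warns(UserWarning, match="single level"):
            rep = clinical_enrichment(clin, labels)
        assert rep.skipped == ["const"]
        row = rep.table.iloc[0]
        assert row["test"] == "kruskal-wallis" and row["significant"]
        assert rep.n_significant == 1
        assert (rep.table["p_adjusted"] >= rep.table["p"] - 1e-15).all()

    def test_null_enrichment_calibrated_near_alpha(self):
        rng = np.random.default_rng(11)
        n, reps, hits = 150, 400, 0
        for _ in range(reps):
            labels = rng.integers(1, 4, n)
            col = rng.choice(["A", "B", "C"], n)
            ct = pd.crosstab(pd.Series(col), pd.Series(labels))
            _, p, _, _ = __import__("scipy.stats", fromlist=["chi2_contingency"]
                                    ).chi2_contingency(ct, correction=False)
            hits += p < 0.05
        rate = hits / reps
        assert 0.02 < rate < 0.09  # wide band for 400 replicates


def test_adjusted_rand_index_properties(rng):
    a = rng.integers(0, 3, 200)
    assert adjusted_rand_index(a, a) == 1.0
    perm = np.array([2, 0, 1])[a]
    assert adjusted_rand_index(a, perm) == 1.0
    b = rng.integers(0, 3, 200)
    assert abs(adjusted_rand_index(a, b)) < 0.15
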