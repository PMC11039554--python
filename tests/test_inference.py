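"""GLM group contrasts, NBS permutation inference, Yeo summaries,
and partial-correlation clinical association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from iscn.cohort import NetworkAssignment
from iscn.inference import (
    NbsComponent,
    clinical_association,
    glm_compare,
    nbs,
    summarize_networks,
)
from iscn.simulate import simulate_edge_features


def _pheno(n_pat, n_con, rng):
    n = n_pat + n_con
    return pd.DataFrame(
        {
            "group": ["patient"] * n_pat + ["control"] * n_con,
            "age": rng.uniform(20, 60, n),
            "gender": rng.choice(["male", "female"], n),
        }
    )


class TestGlmCompare:
    def test_type_i_error_rate_on_null_features(self, rng):
        pheno = _pheno(50, 50, rng)
        feats = pd.DataFrame(rng.normal(0, 1, (100, 400)))
        res = glm_compare(feats, pheno, family=5)
        fpr = (res["p"] < 0.05).mean()
        assert 0.02 < fpr < 0.08  # ~5% uncorrected
        assert res["significant"].sum() <= 2  # ~0 Bonferroni survivors at family 5

    def test_power_for_standardized_effect(self):
        """d = 0.8 at 60/60 is detected after Bonferroni (family 5) with
        power > 0.9 (noncentral-t power at alpha/5 is ~0.96)."""
        detected = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            pheno = _pheno(60, 60, rng)
            y = rng.normal(0, 1, 120)
            y[:60] += 0.8
            res = glm_compare(pd.DataFrame({"f": y}), pheno, family=5)
            detected += bool(res["significant"].iloc[0])
        assert detected / n_seeds > 0.9

    def test_estimate_sign_and_d_consistency(self, rng):
        pheno = _pheno(40, 40, rng)
        y = rng.normal(0, 1, 80)
        y[:40] += 1.0
        res = glm_compare(pd.DataFrame({"f": y}), pheno)
        row = res.iloc[0]
        assert row["estimate"] > 0 and row["t"] > 0
        assert np.sign(row["cohens_d"]) == np.sign(row["estimate"])
        # p consistent with |t| at the model dof (n - 5 regressors)
        assert row["p"] == pytest.approx(2 * stats.t.sf(abs(row["t"]), 80 - 4))

    def test_constant_feature_yields_nan_not_spurious_p(self, rng):
        pheno = _pheno(10, 10, rng)
        res = glm_compare(pd.DataFrame({"f": np.ones(20)}), pheno)
        assert np.isnan(res["t"].iloc[0]) and np.isnan(res["p"].iloc[0])
        assert not res["significant"].iloc[0]

    def test_collinear_covariates_error(self, rng):
        pheno = _pheno(10, 10, rng)
        pheno["age2"] = pheno["age"]
        with pytest.raises(ValueError, match="collinear"):
            glm_compare(pd.DataFrame({"f": rng.normal(size=20)}), pheno, covariates=("age", "age2"))

    def test_bonferroni_flag_matches_threshold_exactly(self, rng):
        pheno = _pheno(30, 30, rng)
        feats = pd.DataFrame(rng.normal(0, 1, (60, 50)))
        res = glm_compare(feats, pheno, family=50)
        assert (res["significant"] == (res["p"] < 0.05 / 50)).all()


class TestNbs:
    def test_observed_equals_identity_permutation(self, rng):
        y, pheno, _ = simulate_edge_features(15, 15, 10, seed=4)
        res = nbs(pd.DataFrame(y), pheno, n_perm=200, seed=0)
        for direction in ("increased", "decreased"):
            obs_max = max((c.size for c in res[direction].components), default=0)
            assert res[direction].null_max_sizes[0] == obs_max

    def test_subject_order_invariance(self, rng):
        y, pheno, _ = simulate_edge_features(12, 12, 8, effect_edges=[(1, 2, 2.0)], seed=9)
        res1 = nbs(pd.DataFrame(y), pheno, n_perm=150, seed=3)
        perm = rng.permutation(len(pheno))
        res2 = nbs(pd.DataFrame(y[perm]), pheno.iloc[perm].reset_index(drop=True), n_perm=150, seed=3)
        for d in ("increased", "decreased"):
            assert [c.edges for c in res1[d].components] == [c.edges for c in res2[d].components]

    def test_planted_clique_recovered_single_seed(self):
        clique = [(a, b, 1.5) for a in range(1, 9) for b in range(a + 1, 9)]
        y, pheno, mask = simulate_edge_features(30, 30, 40, effect_edges=clique, seed=2)
        res = nbs(pd.DataFrame(y), pheno, n_perm=500, seed=0)
        sig = res["increased"].significant_components
        assert sig
        found = {tuple(sorted(e)) for c in sig for e in c.edges}
        planted = {(a, b) for a, b, _ in clique}
        assert len(found & planted) >= 0.8 * len(planted)

    def test_freedman_lane_scheme_detects_planted_clique(self):
        clique = [(a, b, 1.5) for a in range(1, 7) for b in range(a + 1, 7)]
        y, pheno, _ = simulate_edge_features(25, 25, 20, effect_edges=clique, seed=8)
        res = nbs(pd.DataFrame(y), pheno, n_perm=400, seed=0, scheme="freedman-lane")
        assert res["increased"].significant_components
        with pytest.raises(ValueError, match="scheme"):
            nbs(pd.DataFrame(y), pheno, n_perm=150, seed=0, scheme="bogus")

    def test_no_suprathreshold_edges_gives_empty_result(self, rng):
        y, pheno, _ = simulate_edge_features(8, 8, 6, seed=1)
        res = nbs(pd.DataFrame(y), pheno, edge_p=1e-12, n_perm=120, seed=0)
        assert res["increased"].components == []
        assert res["decreased"].components == []

    def test_small_n_perm_warns(self, rng):
        y, pheno, _ = simulate_edge_features(8, 8, 5, seed=1)
        with pytest.warns(UserWarning, match="n_perm"):
            nbs(pd.DataFrame(y), pheno, n_perm=50, seed=0)

    def test_corrected_p_floor_is_one_over_nperm(self):
        clique = [(a, b, 3.0) for a in range(1, 7) for b in range(a + 1, 7)]
        y, pheno, _ = simulate_edge_features(25, 25, 20, effect_edges=clique, seed=5)
        res = nbs(pd.DataFrame(y), pheno, n_perm=200, seed=0)
        for c in res["increased"].components:
            assert 1 / 200 <= c.p <= 1


class TestSummarizeNetworks:
    def _assignment(self):
        # A=DMN regions 1-3, B=VN regions 4-7, rest subcortical
        m = {r: "subcortical" for r in range(1, 11)}
        m.update({1: "DMN", 2: "DMN", 3: "DMN", 4: "VN", 5: "VN", 6: "VN", 7: "VN"})
        return NetworkAssignment(m)

    def test_saturated_within_network_weight_one(self):
        comp = NbsComponent(
            nodes=[1, 2, 3],
            edges=[(1, 2), (1, 3), (2, 3)],
            size=3, p=0.01, significant=True,
        )
        w = summarize_networks(comp, self._assignment())["weights"]
        assert w.loc["DMN", "DMN"] == 1.0

    def test_between_network_arithmetic(self):
        comp = NbsComponent(nodes=[1, 2, 4, 5], edges=[(1, 4), (2, 5)], size=2, p=0.01, significant=True)
        w = summarize_networks(comp, self._assignment())["weights"]
        assert w.loc["DMN", "VN"] == pytest.approx(2 / 12)
        assert w.loc["VN", "DMN"] == pytest.approx(2 / 12)

    def test_random_component_matches_recount_oracle(self, rng):
        na = self._assignment()
        edges = [tuple(sorted(rng.choice(np.arange(1, 11), 2, replace=False))) for _ in range(12)]
        edges = list({e for e in edges})
        nodes = sorted({v for e in edges for v in e})
        comp = NbsComponent(nodes=nodes, edges=edges, size=len(edges), p=0.01, significant=True)
        w = summarize_networks(comp, na)["weights"]
        n_per = {lab: sum(1 for v in na.mapping.values() if v == lab) for lab in set(na.mapping.values())}
        for la in ("DMN", "VN", "subcortical"):
            for lb in ("DMN", "VN", "subcortical"):
                cnt = sum(
                    1 for a, b in edges
                    if {na[a], na[b]} == ({la, lb} if la != lb else {la})
                )
                denom = n_per[la] * n_per[lb] if la != lb else n_per[la] * (n_per[la] - 1) / 2
                assert w.loc[la, lb] == pytest.approx(cnt / denom)

    def test_unassigned_node_errors(self):
        comp = NbsComponent(nodes=[1, 99], edges=[(1, 99)], size=1, p=0.01, significant=True)
        with pytest.raises(ValueError, match="99"):
            summarize_networks(comp, self._assignment())


class TestClinicalAssociation:
    def test_feature_equal_to_score_gives_r_one(self, rng):
        n = 40
        pheno = _pheno(n, 0, rng)
        pheno["hamd17"] = rng.uniform(18, 52, n)
        feats = pd.DataFrame({"f": pheno["hamd17"].to_numpy()})
        res = clinical_association(feats, pheno)
        assert res["partial_r"].iloc[0] == pytest.approx(1.0)
        assert res["p"].iloc[0] == 0.0

    def test_null_false_positive_rate(self, rng):
        n = 80
        pheno = _pheno(n, 0, rng)
        pheno["hamd17"] = rng.uniform(18, 52, n)
        feats = pd.DataFrame(rng.normal(0, 1, (n, 400)))
        res = clinical_association(feats, pheno)
        assert 0.02 < (res["p"] < 0.05).mean() < 0.08

    def test_known_partial_r_recovered(self, rng):
        n = 300
        pheno = _pheno(n, 0, rng)
        x = rng.normal(0, 1, n)
        pheno["hamd17"] = np.clip(30 + 6 * (0.5 * x + np.sqrt(0.75) * rng.normal(0, 1, n)), 0, 52)
        res = clinical_association(pd.DataFrame({"f": x}), pheno)
        assert res["partial_r"].iloc[0] == pytest.approx(0.5, abs=0.1)

    def test_insufficient_n_errors(self, rng):
        pheno = _pheno(4, 0, rng)
        pheno["hamd17"] = [20, 25, 30, 35]
        with pytest.raises(ValueError, match="too small"):
            clinical_association(pd.DataFrame({"f": rng.normal(size=4)}), pheno)
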