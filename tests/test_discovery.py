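"""Supervised metagene discovery: matched DE, correlation-distance
clustering, the coherence cut with arm reunification, and the early
(Lipa) variant."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from metabrain import (
    assign_arms,
    cluster_genes,
    cut_to_metagenes,
    differential_expression,
    discover_early_metagene,
    matched_subset,
    bh_fdr,
)

from conftest import small_config
from metabrain import generate_cohort


def labeled(n_a, n_b):
    labels = ["A"] * n_a + ["B"] * n_b
    cols = [f"s{j}" for j in range(n_a + n_b)]
    return pd.Series(labels, index=cols), cols


class TestDifferentialExpression:
    def test_identical_groups_fail(self):
        labels, cols = labeled(3, 3)
        expr = pd.DataFrame([[0.5] * 6], index=["g"], columns=cols)
        de = differential_expression(expr, labels)
        assert de.loc["g", "t"] == 0
        assert de.loc["g", "p"] == 1
        assert not de.loc["g", "passed"]

    def test_planted_shift_passes_all_filters(self, rng):
        labels, cols = labeled(20, 20)
        row = np.concatenate([rng.normal(0.5, 0.01, 20), rng.normal(0.0, 0.01, 20)])
        expr = pd.DataFrame([row], index=["g"], columns=cols)
        assert differential_expression(expr, labels).loc["g", "passed"]

    def test_q_at_least_p(self, rng):
        labels, cols = labeled(5, 5)
        expr = pd.DataFrame(rng.normal(size=(50, 10)), index=[f"g{i}" for i in range(50)], columns=cols)
        de = differential_expression(expr, labels)
        assert (de["q"] >= de["p"] - 1e-15).all()

    def test_matches_brute_force_filter_oracle(self, rng):
        labels, cols = labeled(15, 15)
        x = rng.normal(scale=0.2, size=(500, 30))
        x[:30, :15] += 0.5  # planted genes
        expr = pd.DataFrame(x, index=[f"g{i}" for i in range(500)], columns=cols)
        de = differential_expression(expr, labels)
        pvals, passes = [], {}
        for g in expr.index:
            a, b = expr.loc[g, cols[:15]], expr.loc[g, cols[15:]]
            t, p = sps.ttest_ind(a, b, equal_var=True)
            pvals.append(p)
        q = bh_fdr(pvals)
        for i, g in enumerate(expr.index):
            a, b = expr.loc[g, cols[:15]], expr.loc[g, cols[15:]]
            fc = a.mean() - b.mean()
            passes[g] = (pvals[i] < 0.005) and (abs(fc) > np.log10(1.25)) and (q[i] < 0.1)
        assert de["passed"].to_dict() == passes

    def test_small_group_error(self):
        labels, cols = labeled(1, 4)
        expr = pd.DataFrame([[0.1] * 5], index=["g"], columns=cols)
        with pytest.raises(ValueError, match=">= 2 samples"):
            differential_expression(expr, labels)


class TestMatchedSubset:
    def test_closed_interval_boundaries(self):
        scores = pd.Series([-0.2, 0.0, 0.3, 0.31], index=list("abcd"))
        assert list(matched_subset(scores, (-0.1, 0.3))) == ["b", "c"]

    def test_all_inside(self):
        scores = pd.Series([0.0, 0.1], index=list("ab"))
        assert list(matched_subset(scores, (-0.1, 0.3))) == ["a", "b"]

    def test_matches_loop_oracle(self, rng):
        scores = pd.Series(rng.normal(scale=0.3, size=100), index=[f"s{j}" for j in range(100)])
        got = set(matched_subset(scores))
        expected = {s for s, v in scores.items() if -0.1 <= v <= 0.3}
        assert got == expected

    def test_empty_result_error(self):
        with pytest.raises(ValueError, match="widen"):
            matched_subset(pd.Series([5.0, 6.0], index=list("ab")), (-0.1, 0.3))


class TestClustering:
    def test_perfectly_correlated_merge_at_zero(self, rng):
        base = rng.normal(size=10)
        expr = pd.DataFrame([base, 2 * base + 1], index=["a", "b"], columns=[f"s{j}" for j in range(10)])
        dend = cluster_genes(expr)
        assert dend.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_merge_at_two(self, rng):
        base = rng.normal(size=10)
        expr = pd.DataFrame([base, -base], index=["a", "b"], columns=[f"s{j}" for j in range(10)])
        dend = cluster_genes(expr)
        assert dend.linkage[0, 2] == pytest.approx(2.0, abs=1e-12)
        dend_abs = cluster_genes(expr, distance="one_minus_abs_corr")
        assert dend_abs.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_two_planted_blocks_separate_exactly(self, rng):
        lat1, lat2 = rng.normal(size=20), rng.normal(size=20)
        rows, names = [], []
        for i in range(6):
            rows.append(lat1 + rng.normal(scale=0.1, size=20)), names.append(f"a{i}")
        for i in range(6):
            rows.append(lat2 + rng.normal(scale=0.1, size=20)), names.append(f"b{i}")
        expr = pd.DataFrame(rows, index=names, columns=[f"s{j}" for j in range(20)])
        dend = cluster_genes(expr)
        from scipy.cluster.hierarchy import fcluster

        two = fcluster(dend.linkage, 2, criterion="maxclust")
        groups = {}
        for gene, c in zip(dend.genes, two):
            groups.setdefault(c, set()).add(gene)
        assert sorted(map(sorted, groups.values())) == [sorted(f"a{i}" for i in range(6)), sorted(f"b{i}" for i in range(6))]

    def test_newick_export_contains_all_leaves(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 12)), index=list("abcde"), columns=[f"s{j}" for j in range(12)])
        nwk = cluster_genes(expr).to_newick()
        assert nwk.endswith(";")
        for g in "abcde":
            assert g in nwk


class TestAssignArms:
    def test_exact_negation_split(self, rng):
        lat = rng.normal(size=15)
        rows = {f"p{i}": lat * (1 + 0.1 * i) for i in range(3)}
        rows.update({f"n{i}": -lat * (1 + 0.1 * i) for i in range(2)})
        expr = pd.DataFrame.from_dict(rows, orient="index", columns=[f"s{j}" for j in range(15)])
        pos, neg = assign_arms(expr, list(rows))
        assert set(pos) == {"p0", "p1", "p2"}
        assert set(neg) == {"n0", "n1"}

    def test_all_positive_gives_empty_negative_arm(self, rng):
        lat = rng.normal(size=15)
        expr = pd.DataFrame([lat, lat * 2, lat + 0.1], index=list("abc"), columns=[f"s{j}" for j in range(15)])
        pos, neg = assign_arms(expr, list("abc"))
        assert set(pos) == set("abc") and neg == ()

    def test_matches_two_pass_oracle(self, rng):
        lat = rng.normal(size=25)
        rows = {f"g{i}": (1 if i % 3 else -1) * lat + rng.normal(scale=0.4, size=25) for i in range(9)}
        expr = pd.DataFrame.from_dict(rows, orient="index", columns=[f"s{j}" for j in range(25)])
        pos, neg = assign_arms(expr, list(rows))
        # independent two-pass oracle
        x = expr.to_numpy()
        xc = x - x.mean(axis=1, keepdims=True)
        m0 = x.mean(axis=0)
        s1 = np.where(xc @ (m0 - m0.mean()) >= 0, 1, -1)
        m1 = (xc * s1[:, None]).mean(axis=0)
        s2 = np.where(xc @ (m1 - m1.mean()) >= 0, 1, -1)
        oracle_pos = {g for g, s in zip(rows, s2) if s > 0}
        oracle_neg = set(rows) - oracle_pos
        if len(oracle_neg) > len(oracle_pos):
            oracle_pos, oracle_neg = oracle_neg, oracle_pos
        assert set(pos) == oracle_pos and set(neg) == oracle_neg


class TestCutToMetagenes:
    def make_block_expr(self, rng, blocks, n_noise=0, n_samples=80, noise_scale=0.3, within=0.05):
        rows, names = [], []
        for label, size, sign_frac in blocks:
            lat = rng.normal(size=n_samples)
            for i in range(size):
                sign = -1 if i < int(sign_frac * size) else 1
                rows.append(sign * lat + rng.normal(scale=within, size=n_samples))
                names.append(f"{label}{i}")
        for i in range(n_noise):
            rows.append(rng.normal(scale=noise_scale, size=n_samples))
            names.append(f"noise{i}")
        return pd.DataFrame(rows, index=names, columns=[f"s{j}" for j in range(n_samples)])

    def test_single_perfect_block(self, rng):
        expr = self.make_block_expr(rng, [("x", 250, 0.0)], within=1e-9)
        mgs = cut_to_metagenes(cluster_genes(expr), expr, min_size=200)
        assert len(mgs) == 1
        assert mgs[0].size == 250
        assert mgs[0].coherence == pytest.approx(1.0, abs=1e-6)

    def test_undersized_block_yields_empty_list(self, rng):
        expr = self.make_block_expr(rng, [("x", 150, 0.0)])
        assert cut_to_metagenes(cluster_genes(expr), expr, min_size=200) == []

    def test_two_blocks_recovered_among_noise(self, rng):
        # within-block noise scale 0.42 gives pairwise correlations near 0.85
        expr = self.make_block_expr(rng, [("a", 220, 0.0), ("b", 260, 0.0)], n_noise=500, within=0.42)
        mgs = cut_to_metagenes(cluster_genes(expr), expr, min_size=200)
        assert len(mgs) == 2
        found = [set(m.members) for m in mgs]
        for label, size in (("b", 260), ("a", 220)):
            planted = {f"{label}{i}" for i in range(size)}
            jac = max(len(planted & f) / len(planted | f) for f in found)
            assert jac >= 0.9

    def test_two_arm_block_reunited(self, rng):
        expr = self.make_block_expr(rng, [("x", 300, 0.4)], n_noise=100)
        mgs = cut_to_metagenes(cluster_genes(expr), expr, min_size=200)
        assert len(mgs) == 1
        mg = mgs[0]
        assert mg.size == 300
        assert len(mg.negative_arm) in (120, 180)  # orientation picks the larger arm positive
        assert mg.coherence >= 0.75

    def test_invariant_to_gene_input_order(self, rng):
        expr = self.make_block_expr(rng, [("a", 210, 0.0)], n_noise=60)
        mgs1 = cut_to_metagenes(cluster_genes(expr), expr, min_size=200)
        shuffled = expr.sample(frac=1, random_state=5)
        mgs2 = cut_to_metagenes(cluster_genes(shuffled), shuffled, min_size=200)
        assert [set(m.members) for m in mgs1] == [set(m.members) for m in mgs2]

    def test_returned_coherence_recomputed_independently(self, rng):
        from metabrain import coherence

        expr = self.make_block_expr(rng, [("a", 220, 0.3)], n_noise=80, within=0.4)
        for mg in cut_to_metagenes(cluster_genes(expr), expr, min_size=200):
            assert coherence(expr, mg) == pytest.approx(mg.coherence, abs=1e-12)
            assert mg.coherence >= 0.75


class TestEarlyMetagene:
    def test_planted_early_factor_recovered(self):
        from metabrain import BrainAgingModel, CohortConfig

        cohort = generate_cohort(CohortConfig(seed=0))
        res = BrainAgingModel.from_cohort(cohort).fit()
        planted = set(cohort.truth.factor_genes("lipa"))
        found = set(res.metagenes["Lipa"].members)
        assert len(planted & found) / len(planted | found) >= 0.8

    def test_no_planted_early_factor_returns_none(self, rng):
        cfg = small_config(factors=("bioage",), genes_per_factor={"bioage": 250})
        cohort = generate_cohort(cfg)
        scores = pd.Series(
            cohort.truth.latent_factors["bioage"].to_numpy() - cohort.truth.latent_factors["bioage"].mean(),
            index=cohort.expression.columns,
        )
        normals = cohort.annotation["diagnosis"] == "normal"
        result = discover_early_metagene(
            cohort.expression, scores, normals, min_size=200, exclude_genes=cohort.truth.factor_genes("bioage")
        )
        assert result is None

    def test_empty_mask_is_an_error(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 20)), index=[f"g{i}" for i in range(10)], columns=[f"s{j}" for j in range(20)])
        scores = pd.Series(rng.normal(size=20), index=expr.columns)
        with pytest.raises(ValueError, match="no samples"):
            discover_early_metagene(expr, scores, pd.Series(False, index=expr.columns))
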