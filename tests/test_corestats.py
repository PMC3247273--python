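"""Scoring and statistics primitives against independent oracles."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metabrain import Metagene, auroc, bh_fdr, biomarker_score, coherence, overlap_test, pearson_fisher


def expr_from_rows(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=[f"s{j}" for j in range(len(next(iter(rows.values()))))])


class TestBiomarkerScore:
    def test_zero_expression_scores_zero(self):
        expr = expr_from_rows({"a": [0, 0, 0], "b": [0, 0, 0]})
        score = biomarker_score(expr, Metagene("m", ("a", "b")))
        assert (score == 0).all()

    def test_positive_arm_mean(self):
        expr = expr_from_rows({"a": [0.2], "b": [0.4]})
        score = biomarker_score(expr, Metagene("m", ("a", "b")))
        assert score.iloc[0] == pytest.approx(0.3)

    def test_arm_difference(self):
        expr = expr_from_rows({"a": [0.2], "b": [0.4], "c": [-0.1]})
        score = biomarker_score(expr, Metagene("m", ("a", "b"), ("c",)))
        assert score.iloc[0] == pytest.approx(0.4)

    def test_missing_member_genes_reaveraged_per_sample(self):
        expr = expr_from_rows({"a": [0.2, np.nan], "b": [0.4, 0.6]})
        score = biomarker_score(expr, Metagene("m", ("a", "b")))
        assert score.tolist() == pytest.approx([0.3, 0.6])

    def test_absent_metagene_is_an_error(self):
        expr = expr_from_rows({"a": [0.1]})
        with pytest.raises(ValueError, match="no member genes"):
            biomarker_score(expr, Metagene("m", ("x", "y")))

    def test_linearity_in_expression_scale(self, rng):
        expr = expr_from_rows({k: rng.normal(size=8) for k in "abcd"})
        mg = Metagene("m", ("a", "b"), ("c",))
        assert np.allclose(biomarker_score(3 * expr, mg), 3 * biomarker_score(expr, mg))


class TestCoherence:
    def test_identical_rows_is_one(self):
        row = [0.1, -0.2, 0.4, 0.0]
        expr = expr_from_rows({"a": row, "b": row, "c": row})
        assert coherence(expr, Metagene("m", ("a", "b", "c"))) == pytest.approx(1.0)

    def test_exact_negations_with_correct_arms_is_one(self):
        row = np.array([0.1, -0.2, 0.4, 0.0])
        expr = expr_from_rows({"a": row, "b": -row})
        assert coherence(expr, Metagene("m", ("a",), ("b",))) == pytest.approx(1.0)

    def test_matches_gene_loop_oracle(self, rng):
        latent = rng.normal(size=30)
        rows = {f"g{i}": latent * rng.uniform(0.5, 1.5) + rng.normal(scale=0.5, size=30) for i in range(6)}
        rows.update({f"n{i}": -latent + rng.normal(scale=0.5, size=30) for i in range(3)})
        expr = expr_from_rows(rows)
        mg = Metagene("m", tuple(f"g{i}" for i in range(6)), tuple(f"n{i}" for i in range(3)))
        corrected = np.vstack([expr.loc[list(mg.positive_arm)].to_numpy(), -expr.loc[list(mg.negative_arm)].to_numpy()])
        mean = corrected.mean(axis=0)
        oracle = np.mean([np.corrcoef(g, mean)[0, 1] for g in corrected])
        assert coherence(expr, mg) == pytest.approx(oracle, abs=1e-12)

    def test_invariant_to_arm_swap_with_row_negation(self, rng):
        latent = rng.normal(size=20)
        expr = expr_from_rows({"a": latent, "b": latent * 0.8 + rng.normal(scale=0.1, size=20), "c": -latent})
        c1 = coherence(expr, Metagene("m", ("a", "b"), ("c",)))
        flipped = expr.copy()
        flipped.loc["c"] = -flipped.loc["c"]
        c2 = coherence(flipped, Metagene("m", ("a", "b", "c")))
        assert c1 == pytest.approx(c2, abs=1e-12)


class TestPearsonFisher:
    def test_zero_correlation_gives_p_one(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # exactly orthogonal to x
        res = pearson_fisher(x, y)
        assert res.rho == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_known_value_rho_half_n28(self, rng):
        # construct vectors with exact sample correlation 0.5
        x = rng.normal(size=28)
        x = (x - x.mean()) / x.std()
        e = rng.normal(size=28)
        e = e - e.mean()
        e -= x * (e @ x) / (x @ x)  # orthogonalize
        e /= e.std()
        y = 0.5 * x + np.sqrt(1 - 0.25) * e
        res = pearson_fisher(x, y)
        assert res.rho == pytest.approx(0.5, abs=1e-12)
        assert res.z == pytest.approx(np.arctanh(0.5) * 5, abs=1e-9)
        assert res.p == pytest.approx(0.0060, abs=2e-4)

    def test_p_decreases_as_rho_increases(self, rng):
        x = np.linspace(-1, 1, 30)
        noise = rng.normal(size=30)
        noise -= noise.mean() + x * (noise @ x) / (x @ x)
        last = 1.1
        for w in (0.2, 0.5, 0.8, 0.95):
            y = w * x + (1 - w) * noise
            p = pearson_fisher(x, y).p
            assert p < last
            last = p

    def test_errors(self):
        with pytest.raises(ValueError, match="n >= 4"):
            pearson_fisher([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="constant"):
            pearson_fisher([1, 1, 1, 1], [1, 2, 3, 4])


class TestBH:
    def test_single_p_is_its_own_q(self):
        assert bh_fdr([0.042]) == pytest.approx([0.042])

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_worked_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @staticmethod
    def step_up_oracle(p):
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        q = np.empty(m)
        q[order] = np.minimum(adj, 1.0)
        return q

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_step_up_oracle(self, pvals):
        assert np.allclose(bh_fdr(pvals), self.step_up_oracle(pvals), atol=1e-12)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3, 4], [0, 0, 1, 1]).auroc == 1.0

    def test_all_tied_is_half(self):
        assert auroc([2, 2, 2, 2], [0, 1, 0, 1]).auroc == 0.5

    def test_worked_example(self):
        assert auroc([3, 1, 2, 4], [0, 1, 0, 1]).auroc == pytest.approx(0.5)

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc([1, 2], [1, 1])

    @staticmethod
    def pair_counting_oracle(scores, labels):
        pos = [s for s, l in zip(scores, labels) if l == 1]
        neg = [s for s, l in zip(scores, labels) if l == 0]
        wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
        return wins / (len(pos) * len(neg))

    @given(
        st.lists(st.integers(min_value=-5, max_value=5), min_size=4, max_size=30),
        st.data(),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_pair_counting_oracle(self, scores, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores)).filter(
                lambda l: 0 < sum(l) < len(l)
            )
        )
        got = auroc(scores, labels).auroc
        assert got == pytest.approx(self.pair_counting_oracle(scores, labels), abs=1e-12)

    def test_anti_scores_complement(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        assert auroc(scores, labels).auroc + auroc(-scores, labels).auroc == pytest.approx(1.0)


class TestOverlap:
    @staticmethod
    def enumeration_oracle(n_a, n_b, k, universe):
        total = comb(universe, n_b)
        return sum(comb(n_a, i) * comb(universe - n_a, n_b - i) for i in range(k, min(n_a, n_b) + 1)) / total

    def test_worked_example_universe20(self):
        a = set(range(5))
        b = {0, 1, 2, 10, 11}
        p, _ = overlap_test(a, b, universe_size=20)
        assert p == pytest.approx(self.enumeration_oracle(5, 5, 3, 20), rel=1e-12)

    @pytest.mark.parametrize("universe,n_a,n_b,k", [(10, 3, 4, 2), (25, 8, 6, 3), (30, 10, 10, 5)])
    def test_matches_enumeration(self, universe, n_a, n_b, k):
        a = set(range(n_a))
        b = set(range(k)) | set(range(universe - (n_b - k), universe))
        p, _ = overlap_test(a, b, universe)
        assert p == pytest.approx(self.enumeration_oracle(n_a, n_b, k, universe), rel=1e-10)

    def test_identical_sets_boundary(self):
        a = set(range(5))
        p, _ = overlap_test(a, a, universe_size=20)
        assert p == pytest.approx(1 / comb(20, 5), rel=1e-9)

    def test_disjoint_cover_is_near_one(self):
        p, _ = overlap_test(set(range(10)), set(range(10, 20)), universe_size=20)
        assert p == pytest.approx(1.0)

    def test_bonferroni(self):
        p, pb = overlap_test(set(range(5)), set(range(5)), universe_size=20, n_tests=10)
        assert pb == pytest.approx(min(1.0, p * 10))

    def test_inconsistent_sizes_error(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_test(set(range(30)), set(), universe_size=20)
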