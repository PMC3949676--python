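"""Spearman correlation, permutation tests, classification, pathway ratios."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from metaweight.graph import Pathway
from metaweight.stats import (ClassificationConfig, EnzymeClass,
                              classify_enzymes, enzyme_inclusion,
                              inter_enzyme_set, intra_enzyme_set,
                              paired_inter_weights, pathway_ratios,
                              permutation_test, spearman)
from metaweight.weighting import AggregatedWeights, GenomeProfile

from oracles import exhaustive_permutation_p, spearman_oracle


def agg(values, kind="taxonomic", domain="A"):
    return AggregatedWeights(kind=kind, domain=domain, mean_values=values,
                             support={k: 1 for k in values}, n_replicates=1)


class TestSpearman:
    def test_identity_and_reversal(self):
        x = [0.1, 0.5, 0.3, 0.9, 0.7]
        assert spearman(x, x).rho == pytest.approx(1.0)
        assert spearman(x, [-v for v in x]).rho == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_matches_direct_rank_pearson(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.random(6).tolist()
            y = rng.random(6).tolist()
            assert spearman(x, y).rho == pytest.approx(spearman_oracle(x, y))

    def test_matches_scipy_large_n(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(50), rng.random(50)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic)
        assert res.p_analytic == pytest.approx(ref.pvalue)

    def test_exact_p_small_n_is_valid_probability(self):
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert 0 <= res.p_analytic <= 1

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_monotone_invariance(self, a, b):
        x = [0.1, 0.4, 0.2, 0.8, 0.6, 0.35]
        y = [a * v + b for v in x]
        assert spearman(x, y).rho == pytest.approx(1.0)


class TestPermutationTest:
    def test_exhaustive_matches_enumeration_oracle_n4(self):
        x = [0.3, 0.1, 0.9, 0.5]
        y = [0.2, 0.4, 0.8, 0.6]
        for tail in ("greater", "less"):
            got = permutation_test(x, y, exhaustive=True, tail=tail)
            assert got == pytest.approx(
                exhaustive_permutation_p(x, y, tail=tail))

    def test_monte_carlo_converges_to_exhaustive(self):
        x = [0.3, 0.1, 0.9, 0.5, 0.7]
        y = [0.2, 0.4, 0.8, 0.6, 0.9]
        exact = permutation_test(x, y, exhaustive=True)
        mc = permutation_test(x, y, m=20000, seed=1)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        x, y = rng.random(12), rng.random(12)
        assert permutation_test(x, y, m=200, seed=5) == \
            permutation_test(x, y, m=200, seed=5)

    def test_strong_positive_correlation_significant(self):
        x = np.arange(20.0)
        y = x + np.random.default_rng(0).normal(0, 0.5, 20)
        assert permutation_test(x, y, m=1000, seed=0) < 0.05

    def test_type_i_error_calibrated(self):
        # under the null, rejection rate at alpha=0.05 stays near 0.05
        rng = np.random.default_rng(7)
        n_sims, m, alpha = 600, 200, 0.05
        rejections = 0
        for s in range(n_sims):
            x = rng.random(15)
            y = rng.random(15)
            if permutation_test(x, y, m=m, seed=s) < alpha:
                rejections += 1
        rate = rejections / n_sims
        se = np.sqrt(alpha * (1 - alpha) / n_sims)
        assert abs(rate - alpha) < 3 * se


class TestInclusion:
    def make_profiles(self):
        spec = {"g1": {"e1": ("p1",), "e2": ("p2",)},
                "g2": {"e1": ("p3",)},
                "g3": {"e3": ("p4",)}}
        return {g: GenomeProfile(genome_id=g, domain="A", enzymes=e)
                for g, e in spec.items()}

    def test_intra_requires_two_genomes(self):
        got = intra_enzyme_set(["g1", "g2", "g3"], self.make_profiles(),
                               ["e1", "e2", "e3", "e4"])
        assert got == {"e1"}

    def test_inter_union_with_zero_imputation(self):
        a = agg({"e1": 0.5, "e2": 0.0})
        b = agg({"e3": 0.2}, domain="B")
        assert inter_enzyme_set(a, b) == {"e1", "e3"}
        ecs, xa, xb = paired_inter_weights(a, b)
        assert ecs == ["e1", "e3"]
        assert list(xa) == [0.5, 0.0]
        assert list(xb) == [0.0, 0.2]

    def test_empty_vectors_empty_set(self):
        assert inter_enzyme_set(agg({}), agg({}, domain="B")) == set()

    def test_dispatch(self):
        assert enzyme_inclusion("inter", agg({"e1": 1.0}),
                                agg({}, domain="B")) == {"e1"}
        with pytest.raises(ValueError):
            enzyme_inclusion("sideways", agg({}), agg({}))


class TestClassifier:
    CFG = ClassificationConfig(t_high=0.667)

    def test_paper_thresholds(self):
        a = agg({"e1": 0.9, "e2": 0.9, "e3": 0.5})
        b = agg({"e1": 0.1, "e2": 0.9, "e3": 0.5}, domain="B")
        labels = {c.ec: c.label for c in classify_enzymes(a, b, self.CFG)}
        assert labels == {"e1": "specific_to_A", "e2": "ubiquitous",
                          "e3": "neither"}

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        a = agg({f"e{i}": float(rng.random()) for i in range(30)})
        b = agg({f"e{i}": float(rng.random()) for i in range(30)}, domain="B")
        fwd = {c.ec: c.label for c in classify_enzymes(a, b, self.CFG)}
        rev = {c.ec: c.label for c in classify_enzymes(b, a, self.CFG)}
        swap = {"specific_to_A": "specific_to_B",
                "specific_to_B": "specific_to_A"}
        for ec in fwd:
            assert rev[ec] == swap.get(fwd[ec], fwd[ec])

    def test_missing_mean_treated_as_zero(self):
        a = agg({"e1": 0.9})
        b = agg({}, domain="B")
        labels = {c.ec: c.label for c in classify_enzymes(a, b, self.CFG)}
        assert labels["e1"] == "specific_to_A"

    def test_iso_thresholds_explicit(self):
        cfg = ClassificationConfig.isoenzymatic(t_high=1.0, t_low=1.0)
        a = agg({"e1": 1.5}, kind="isoenzymatic")
        b = agg({"e1": 0.5}, kind="isoenzymatic", domain="B")
        labels = {c.ec: c.label for c in classify_enzymes(a, b, cfg)}
        assert labels["e1"] == "specific_to_A"


class TestPathwayRatios:
    def make(self, n, prefix="e"):
        return [f"{prefix}{i}" for i in range(n)]

    def test_min_weighted_filter(self):
        ecs = self.make(12)
        pw = Pathway("p1", "P one", set(ecs), set())
        a = agg({ec: 0.5 for ec in ecs})
        b = agg({ec: 0.5 for ec in ecs[:9]}, domain="B")  # only 9 weighted
        classes = [EnzymeClass(ec, "neither") for ec in ecs]
        table = pathway_ratios([pw], classes, a, b, min_weighted=10)
        assert table.empty

    def test_ratios_match_counting_oracle(self):
        ecs = self.make(10)
        pw = Pathway("p1", "P one", set(ecs), set())
        a = agg({ec: 0.9 for ec in ecs})
        b = agg({ec: 0.9 for ec in ecs}, domain="B")
        labels = (["ubiquitous"] * 5 + ["specific_to_A"] * 2 +
                  ["neither"] * 3)
        classes = [EnzymeClass(ec, lab) for ec, lab in zip(ecs, labels)]
        table = pathway_ratios([pw], classes, a, b, min_weighted=10)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.n_weighted == 10
        assert row.ubiquitous_ratio == pytest.approx(0.5)
        assert row.specific_ratio == pytest.approx(0.2)
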