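import math

import numpy as np
import pandas as pd
import pytest

from spermprog.de import (
    bh_adjust,
    consistency_filter,
    define_gene_sets,
    estimate_dispersion,
    expression_correlation,
    nb_exact_test,
    run_de,
    size_factors,
)
from spermprog.simulate import SimulationConfig, generate_embryo_counts, generate_truth

from conftest import make_counts


def bh_oracle(p):
    """Brute-force step-up: q_(i) = min_{j>=i} m p_(j)/j, input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = [
        min(min(m * p[order[j]] / (j + 1) for j in range(i, m)), 1.0) for i in range(m)
    ]
    out = np.empty(m)
    out[order] = q_sorted
    return out


def binomial_two_sided_oracle(sa, total):
    """Conditional equal-probability binomial two-sided p by enumeration."""
    w = np.array([math.comb(total, s) * 0.5**total for s in range(total + 1)])
    return w[w <= w[sa] * (1 + 1e-7)].sum()


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 30], "b": [10, 30], "c": [10, 30]})
        np.testing.assert_allclose(size_factors(counts), 1.0)

    def test_doubled_column_ratio(self):
        counts = pd.DataFrame({"a": [10, 30], "b": [20, 60]})
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, size=(100, 6)) + 1)
        sf = size_factors(counts)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_no_all_positive_gene_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(counts)


class TestDispersion:
    def test_moment_formula(self):
        """s^2 = 2 m, m = 10 -> phi = (20 - 10) / 100 = 0.1."""
        # two groups of {10+d, 10-d}: pooled variance = 4 d^2 / (4 - 2)
        # = 2 d^2, so d = sqrt(10) gives s^2 = 20 on unit size factors
        a = 10 + math.sqrt(10)
        b = 10 - math.sqrt(10)
        counts = pd.DataFrame(
            {"s1": [a], "s2": [b], "s3": [a], "s4": [b]}, index=["g"]
        )
        design = pd.DataFrame(
            {
                "sample": ["s1", "s2", "s3", "s4"],
                "group": ["x", "x", "y", "y"],
                "experiment": [1, 2, 1, 2],
            }
        )
        sf = pd.Series(1.0, index=counts.columns)
        phi = estimate_dispersion(counts, design, sf)
        assert phi["g"] == pytest.approx(0.1)

    def test_constant_counts_floor_to_zero(self):
        counts = pd.DataFrame(np.full((3, 4), 7.0), columns=list("abcd"))
        design = pd.DataFrame(
            {"sample": list("abcd"), "group": list("xxyy"), "experiment": [1, 2, 1, 2]}
        )
        sf = pd.Series(1.0, index=counts.columns)
        assert (estimate_dispersion(counts, design, sf) == 0).all()

    def test_poisson_counts_give_near_zero_dispersion(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(100, size=(2000, 8)))
        design = pd.DataFrame(
            {
                "sample": list(range(8)),
                "group": ["x"] * 4 + ["y"] * 4,
                "experiment": [1, 2, 3, 4] * 2,
            }
        )
        counts.columns = design["sample"]
        sf = pd.Series(1.0, index=counts.columns)
        phi = estimate_dispersion(counts, design, sf)
        assert abs(np.median(phi)) < 0.01


class TestNbExactTest:
    def test_symmetric_split_is_modal(self):
        p = nb_exact_test(np.array([5]), np.array([5]), phi=0.0)
        assert p == pytest.approx(1.0)

    def test_extreme_split_matches_hand_value(self):
        p = nb_exact_test(np.array([0]), np.array([10]), phi=0.0)
        assert p == pytest.approx(2 * 0.5**10, abs=1e-12)

    @pytest.mark.parametrize("sa,sb", [(3, 9), (0, 7), (14, 14), (1, 25), (11, 4)])
    def test_phi_zero_equals_binomial_enumeration(self, sa, sb):
        p = nb_exact_test(np.array([sa]), np.array([sb]), phi=0.0)
        assert p == pytest.approx(binomial_two_sided_oracle(sa, sa + sb), abs=1e-12)

    def test_unequal_group_sizes_null_mean(self):
        # 2 vs 1 samples: mu_a = 2/3 of the total under H0
        p_balanced = nb_exact_test(np.array([10, 10]), np.array([10]), phi=0.0)
        p_skewed = nb_exact_test(np.array([1, 1]), np.array([28]), phi=0.0)
        assert p_balanced > 0.5
        assert p_skewed < 0.01

    def test_zero_total_p_one(self):
        assert nb_exact_test(np.array([0, 0]), np.array([0, 0]), phi=0.1) == 1.0

    def test_windowed_support_matches_full_enumeration(self):
        """Large totals switch to a truncated support; the p-value must
        agree with the full-support computation."""
        rng = np.random.default_rng(7)
        a = rng.poisson(400, 7)
        b = rng.poisson(500, 7)
        full = nb_exact_test(a, b, phi=0.05, full_support_max=10**9)
        windowed = nb_exact_test(a, b, phi=0.05, full_support_max=0)
        assert windowed == pytest.approx(full, rel=1e-9)

    def test_null_pvalues_super_uniform(self):
        """Paired E=7 null at phi = 0.05: type-I error <= 0.06 at 0.05,
        pooled over three simulated nulls (> 7000 genes)."""
        hits = total = 0
        for seed in (11, 12, 13):
            cfg = SimulationConfig(n_genes=2500, effect_logfc=0.0, seed=seed)
            cm = generate_embryo_counts(generate_truth(cfg), cfg)
            de = run_de(cm)
            assert len(de) >= 2000
            hits += int((de["p"] < 0.05).sum())
            total += len(de)
        assert hits / total <= 0.06


class TestBH:
    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_stated_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_ties_forced(self):
        np.testing.assert_allclose(bh_adjust([0.05] * 4), 0.05)

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for n in (1, 2, 5, 12):
            for _ in range(20):
                p = rng.random(n)
                np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestConsistency:
    @pytest.mark.parametrize(
        "signs,min_consistent,expected",
        [
            ([1, 1, 1, 1, 1, 1, 1], 6, True),
            ([1, 1, 1, 1, 1, -1, -1], 6, False),
            ([1, 1, 1, 1, 1, 1, -1], 6, True),
            ([-1, -1, -1, -1, -1, -1, 1], 6, True),
            ([1, 1, 1, 1, 1, 1, 0], 6, True),  # zeros count toward neither
            ([1, 1, 1, 1, 1, 0, 0], 6, False),
        ],
    )
    def test_sign_rule(self, signs, min_consistent, expected):
        arr = np.array([signs], dtype=float) * 0.7
        assert consistency_filter(arr, min_consistent)[0] == expected

    def test_min_consistent_range_validated(self):
        with pytest.raises(ValueError):
            consistency_filter(np.ones((1, 7)), 8)


class TestGeneSets:
    def test_threshold_logic(self):
        de = pd.DataFrame(
            {
                "fdr": [0.01, 0.3, 0.5, 0.01],
                "logFC": [1.0, 0.5, 2.0, 0.1],
                "consistent": [True, True, True, False],
            },
            index=["mis", "ext_only", "neither", "fdr_only"],
        )
        mis, ext = define_gene_sets(de)
        assert mis == {"mis"}
        # fdr_only fails the |logFC| >= 0.2 requirement of the extended set
        assert ext == {"mis", "ext_only"}

    def test_misregulated_requires_consistency_and_fdr(self):
        de = pd.DataFrame(
            {"fdr": [0.01], "logFC": [1.0], "consistent": [False]}, index=["g"]
        )
        mis, _ = define_gene_sets(de)
        assert mis == set()


class TestExpressionCorrelation:
    def test_linear_relation(self):
        x = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        assert expression_correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert expression_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        x = pd.Series([1.0, 2, 3, 4])
        y = pd.Series([1.0, 3, 2, 4])
        assert expression_correlation(x, y) == pytest.approx(0.8)

    def test_zero_variance_rejected(self):
        x = pd.Series([1.0, 1, 1])
        with pytest.raises(ValueError):
            expression_correlation(x, pd.Series([1.0, 2, 3]))


class TestRunDe:
    def test_label_swap_negates_logfc_keeps_p(self):
        rng = np.random.default_rng(9)
        arr = rng.poisson(60, size=(80, 6))
        cm = make_counts(arr, 3)
        de = run_de(cm, min_consistent=2)
        swapped = cm.counts.copy()
        design = cm.design.copy()
        design["group"] = design["group"].map(
            {"sperm_embryo": "spermatid_embryo", "spermatid_embryo": "sperm_embryo"}
        )
        from spermprog.io import CountMatrix

        de_sw = run_de(CountMatrix(counts=swapped, design=design), min_consistent=2)
        np.testing.assert_allclose(de_sw["logFC"], -de["logFC"], atol=1e-12)
        np.testing.assert_allclose(de_sw["p"], de["p"], atol=1e-12)

    def test_misregulated_subset_of_fdr_significant(self):
        cfg = SimulationConfig(n_genes=600, seed=3)
        cm = generate_embryo_counts(generate_truth(cfg), cfg)
        de = run_de(cm)
        assert (de.loc[de["misregulated"], "fdr"] < 0.05).all()
        assert (de.loc[de["misregulated"], "consistent"]).all()
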