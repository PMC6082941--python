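import math
from fractions import Fraction

import numpy as np
import pytest

from indelpanel.types import DegenerateInputError, GenotypeMatrix
from indelpanel import divergence as dv
from indelpanel.simulate import (
    simulate_balding_nichols,
    simulate_hwe_population,
)


def fisher_oracle(table) -> float:
    """Two-sided Fisher exact p by direct hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def tab_prob(x):
        return Fraction(
            math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1)
        )

    p_obs = tab_prob(a)
    total = sum(
        p
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if (p := tab_prob(x)) <= p_obs
    )
    return float(total)


class TestAlleleCounts:
    def test_fixed_difference_table(self):
        gm = GenotypeMatrix(
            ["a", "b", "c", "d"],
            ["x", "x", "y", "y"],
            ["L1"],
            np.array([[2], [2], [0], [0]]),
        )
        t = dv.allele_count_2x2(gm, "x", "y", "L1")
        assert t.tolist() == [[4, 0], [0, 4]]
        assert t.sum() == 2 * 4  # conservation: 2 alleles per individual

    def test_identical_populations_identical_rows(self):
        gm = GenotypeMatrix(
            ["a", "b", "c", "d"],
            ["x", "x", "y", "y"],
            ["L1"],
            np.array([[1], [2], [1], [2]]),
        )
        t = dv.allele_count_2x2(gm, "x", "y", "L1")
        assert t[0].tolist() == t[1].tolist()


class TestFisherExact:
    def test_hand_enumerated_example(self):
        assert dv.fisher_exact_2x2([[4, 0], [0, 4]]) == pytest.approx(2 / 70, abs=1e-12)

    def test_identical_rows_give_one(self):
        assert dv.fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_symmetry_under_row_and_column_swap(self, rng):
        for _ in range(30):
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum() == 0:
                continue
            p = dv.fisher_exact_2x2(t)
            assert dv.fisher_exact_2x2(t[::-1]) == pytest.approx(p, abs=1e-12)
            assert dv.fisher_exact_2x2(t[:, ::-1]) == pytest.approx(p, abs=1e-12)

    def test_matches_enumeration_oracle_small_tables(self, rng):
        for _ in range(150):
            t = rng.integers(0, 11, size=(2, 2))
            if t.sum() == 0 or t.sum() > 40:
                continue
            assert dv.fisher_exact_2x2(t) == pytest.approx(
                fisher_oracle(t.tolist()), abs=1e-9
            )

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            dv.fisher_exact_2x2([[0, 0], [0, 0]])


class TestPermutationFst:
    def test_uniform_under_null(self):
        gm = simulate_hwe_population(60, 1, seed=31)
        labels = ["a"] * 30 + ["b"] * 30
        gm.population_labels = labels
        pvals = [
            dv.permutation_fst_test(gm, "a", "b", "L1", n_perm=199, seed=s)
            for s in range(20)
        ]
        assert 0.2 < float(np.median(pvals)) < 0.8

    def test_fixed_difference_minimal_p(self):
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(40)],
            ["a"] * 20 + ["b"] * 20,
            ["L1"],
            np.array([[2]] * 20 + [[0]] * 20),
        )
        p = dv.permutation_fst_test(gm, "a", "b", "L1", n_perm=199, seed=7)
        assert p == pytest.approx(1 / 200, abs=1e-12)

    def test_invariant_to_population_order(self):
        gm = simulate_balding_nichols(30, 5, 0.1, seed=13, n_pops=2)
        p1 = dv.permutation_fst_test(gm, "pop_1", "pop_2", "L1", n_perm=199, seed=5)
        p2 = dv.permutation_fst_test(gm, "pop_2", "pop_1", "L1", n_perm=199, seed=5)
        assert p1 == pytest.approx(p2, abs=0.05)

    def test_seed_required(self):
        gm = simulate_balding_nichols(20, 2, 0.1, seed=13, n_pops=2)
        with pytest.raises(ValueError):
            dv.permutation_fst_test(gm, "pop_1", "pop_2", "L1", n_perm=199)


class TestDifferentiationProfile:
    def test_population_vs_itself_clone(self):
        gm = simulate_hwe_population(80, 10, seed=3)
        gm2 = simulate_hwe_population(80, 10, seed=3, population="pop_2")
        prof = dv.differentiation_profile(gm.concat(gm2), "pop_1", "pop_2")
        assert prof.n_significant == 0
        assert np.all(prof.p_values == 1.0)

    def test_diverged_populations_detected(self):
        gm = simulate_balding_nichols(169, 30, 0.15, seed=17, n_pops=2)
        prof = dv.differentiation_profile(gm, "pop_1", "pop_2")
        assert prof.n_significant > 0
        assert prof.threshold == pytest.approx(0.05 / 30)

    def test_monotone_in_alpha(self):
        gm = simulate_balding_nichols(100, 20, 0.1, seed=29, n_pops=2)
        counts = [
            dv.differentiation_profile(gm, "pop_1", "pop_2", alpha=a).n_significant
            for a in (0.001, 0.01, 0.05, 0.2)
        ]
        assert counts == sorted(counts)


class TestNeiDA:
    def test_identical_vectors_zero(self):
        f = np.array([0.3, 0.7, 0.5])
        assert dv.nei_da(f, f) == pytest.approx(0.0, abs=1e-15)

    def test_maximal_divergence(self):
        assert dv.nei_da([1.0], [0.0]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        assert dv.nei_da([0.8], [0.2]) == pytest.approx(1 - 2 * math.sqrt(0.16), abs=1e-12)

    def test_metric_like_properties(self, rng):
        for _ in range(50):
            x = rng.uniform(0, 1, 10)
            y = rng.uniform(0, 1, 10)
            d = dv.nei_da(x, y)
            assert 0.0 <= d <= 1.0
            assert dv.nei_da(y, x) == pytest.approx(d, abs=1e-15)
        assert dv.nei_da(x, x) == pytest.approx(0.0, abs=1e-15)

    def test_mismatched_loci_rejected(self):
        with pytest.raises(ValueError):
            dv.nei_da([0.5, 0.5], [0.5])


class TestWCFst:
    def test_null_split_near_zero(self):
        gm = simulate_hwe_population(500, 100, seed=41)
        gm.population_labels = ["a"] * 250 + ["b"] * 250
        assert abs(dv.wc_fst(gm, ["a", "b"])) < 0.01

    def test_fixed_difference_approaches_one(self):
        n = 200
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(2 * n)],
            ["a"] * n + ["b"] * n,
            ["L1", "L2"],
            np.array([[2, 2]] * n + [[0, 0]] * n),
        )
        assert dv.wc_fst(gm, ["a", "b"]) > 0.99

    def test_invariant_to_allele_label_swap_and_pop_order(self):
        gm = simulate_balding_nichols(80, 40, 0.1, seed=53, n_pops=2)
        theta = dv.wc_fst(gm, ["pop_1", "pop_2"])
        assert dv.wc_fst(gm, ["pop_2", "pop_1"]) == pytest.approx(theta, abs=1e-12)
        flipped = GenotypeMatrix(
            gm.sample_ids,
            gm.population_labels,
            gm.locus_ids,
            (2 - gm.calls).astype(np.int8),
        )
        assert dv.wc_fst(flipped, ["pop_1", "pop_2"]) == pytest.approx(theta, abs=1e-12)

    def test_too_small_population_rejected(self):
        gm = GenotypeMatrix(
            ["a", "b", "c"], ["x", "y", "y"], ["L1"], np.array([[1], [1], [2]])
        )
        with pytest.raises(DegenerateInputError):
            dv.wc_fst(gm, ["x", "y"])


class TestDistanceMatrix:
    def test_identical_populations_zero_da(self):
        gm = simulate_hwe_population(50, 10, seed=3)
        gm2 = simulate_hwe_population(50, 10, seed=3, population="pop_2")
        dm = dv.distance_matrix(gm.concat(gm2), "da")
        assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_zero_diagonal(self, two_pop_gm):
        for metric in ("da", "fst"):
            dm = dv.distance_matrix(two_pop_gm, metric)
            assert np.allclose(dm.values, dm.values.T)
            assert np.all(np.diag(dm.values) == 0)
            assert np.all(dm.values >= 0)

    def test_da_and_fst_rank_correlate(self):
        from scipy.stats import spearmanr

        # heterogeneous divergence: population pairs at several depths
        gm = simulate_balding_nichols([60, 60], 40, 0.02, seed=61)
        far = simulate_balding_nichols([60, 60], 40, 0.25, seed=62)
        far_relab = GenotypeMatrix(
            [f"f_{s}" for s in far.sample_ids],
            [p.replace("pop", "farpop") for p in far.population_labels],
            far.locus_ids,
            far.calls,
        )
        combo = gm.concat(far_relab)
        da = dv.distance_matrix(combo, "da")
        fst = dv.distance_matrix(combo, "fst")
        iu = np.triu_indices(da.size, 1)
        rho = spearmanr(da.values[iu], fst.values[iu]).statistic
        assert rho > 0

    def test_near_far_ordering_reproducible(self):
        # a close and a distant companion population are ordered correctly
        # by both distance metrics in nearly all replicates
        wins_da = wins_fst = 0
        reps = 40
        for r in range(reps):
            near = simulate_balding_nichols([50, 50], 30, 0.02, seed=7000 + r)
            far = simulate_balding_nichols([50, 50], 30, 0.3, seed=8000 + r)
            ref_near = near
            far_re = GenotypeMatrix(
                [f"f_{s}" for s in far.sample_ids],
                ["ref" if p == "pop_1" else "far" for p in far.population_labels],
                far.locus_ids,
                far.calls,
            )
            near_re = GenotypeMatrix(
                ref_near.sample_ids,
                ["ref" if p == "pop_1" else "near" for p in ref_near.population_labels],
                ref_near.locus_ids,
                ref_near.calls,
            )
            # share the same reference individuals for the far comparison
            far_only = far_re.subset_population("far")
            combo = near_re.concat(far_only)
            da = dv.distance_matrix(combo, "da")
            fst = dv.distance_matrix(combo, "fst")
            if da.get("ref", "near") < da.get("ref", "far"):
                wins_da += 1
            if fst.get("ref", "near") < fst.get("ref", "far"):
                wins_fst += 1
        assert wins_da / reps >= 0.95
        assert wins_fst / reps >= 0.95

    def test_da_accepts_freq_table_directly(self, two_pop_gm):
        from indelpanel.types import FreqTable

        ft = FreqTable.from_genotypes(two_pop_gm)
        dm = dv.distance_matrix(ft, "da")
        dm2 = dv.distance_matrix(two_pop_gm, "da")
        assert np.allclose(dm.values, dm2.values, atol=1e-12)
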