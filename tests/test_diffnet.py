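from itertools import combinations

import numpy as np
import pytest

from diffpcor import (
    GroupedDataset,
    SimulationSpec,
    build_differential_network,
    classify_change,
    permutation_null,
    permutation_pvalues,
    pcor_from_data,
    sample_dataset,
)
from conftest import make_null_dataset


class TestPermutationNull:
    def test_seeded_determinism(self, small_dataset):
        a = permutation_null(small_dataset, n_perm=1, seed=99)
        b = permutation_null(small_dataset, n_perm=1, seed=99)
        assert np.array_equal(a, b)
        assert a.shape == (1, 6)

    def test_zero_permutations_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_null(small_dataset, n_perm=0, seed=0)

    def test_exchangeable_groups_mean_d(self):
        """Both groups from one model: the permutation mean of d* matches
        the observed mean of d over pairs within Monte-Carlo error."""
        data = make_null_dataset(seed=4, n_a=100, n_b=100)
        null = permutation_null(data, n_perm=500, seed=1)
        ra = pcor_from_data(data.values_for("A")).pcor
        rb = pcor_from_data(data.values_for("B")).pcor
        iu, ju = np.triu_indices(data.n_variables, k=1)
        d_obs = np.abs(ra[iu, ju] - rb[iu, ju])
        null_means = null.mean(axis=1)  # per-permutation mean over pairs
        mcse = null_means.std(ddof=1) / np.sqrt(len(null_means))
        assert abs(null_means.mean() - d_obs.mean()) <= 3 * mcse + 1e-3

    def test_matches_exhaustive_enumeration(self):
        """N_A = N_B = 3, M = 2: every sampled d* is one of the C(6,3)=20
        enumerable values, and p-values agree with exact enumeration."""
        rng = np.random.default_rng(8)
        values = rng.standard_normal((6, 2))
        data = GroupedDataset(
            values, ["x", "y"], np.array(list("AAABBB"), dtype=object)
        )
        exact_d = []
        for rows_a in combinations(range(6), 3):
            rows_b = [r for r in range(6) if r not in rows_a]
            pa = pcor_from_data(values[list(rows_a)]).pcor[0, 1]
            pb = pcor_from_data(values[rows_b]).pcor[0, 1]
            exact_d.append(abs(pa - pb))
        exact_d = np.array(sorted(exact_d))

        n_perm = 2000
        null = permutation_null(data, n_perm=n_perm, seed=3)[:, 0]
        # every sampled statistic is an enumerated one
        for v in np.unique(null):
            assert np.min(np.abs(exact_d - v)) < 1e-10

        ra = pcor_from_data(data.values_for("A")).pcor[0, 1]
        rb = pcor_from_data(data.values_for("B")).pcor[0, 1]
        d_obs = abs(ra - rb)
        p_exact = np.mean(exact_d >= d_obs - 1e-12)
        p_sampled = permutation_pvalues(np.array([d_obs]), null[:, None])[0]
        mcse = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_sampled - p_exact) <= 3 * mcse + 1.0 / (n_perm + 1)


class TestPermutationPvalues:
    def test_zero_statistic_gives_p_one(self):
        null = np.abs(np.random.default_rng(0).normal(size=(50, 3)))
        p = permutation_pvalues(np.zeros(3), null)
        np.testing.assert_array_equal(p, 1.0)

    def test_add_one_arithmetic(self):
        null = np.linspace(0, 1, 99)[:, None]
        p = permutation_pvalues(np.array([2.0]), null)
        assert p[0] == pytest.approx(0.01)

    def test_never_zero(self, rng):
        null = np.abs(rng.normal(size=(200, 4)))
        p = permutation_pvalues(np.full(4, 1e9), null)
        assert np.all(p > 0)


class TestClassifyChange:
    @pytest.mark.parametrize(
        "r_a,r_b,sig,expected",
        [
            (0.20, -0.15, True, "sign_change"),
            (0.10, 0.30, True, "increase"),
            (0.30, 0.10, True, "decrease"),
            (0.10, 0.30, False, "none"),
            (0.03, -0.30, True, "increase"),  # |r_A| below the sign gate
            (-0.30, 0.03, True, "decrease"),
            (-0.2, -0.4, True, "increase"),  # same sign, magnitude grew
        ],
    )
    def test_rules(self, r_a, r_b, sig, expected):
        assert classify_change(r_a, r_b, sig, min_magnitude=0.05) == expected

    def test_gate_is_configurable(self):
        assert classify_change(0.2, -0.15, True, min_magnitude=0.18) == "decrease"


class TestBuildDifferentialNetwork:
    def test_zero_permutations_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="n_perm"):
            build_differential_network(small_dataset, n_perm=0, seed=0)

    def test_category_significance_coupling(self, small_dataset):
        res = build_differential_network(small_dataset, n_perm=100, seed=5)
        tab = res.table
        sig = tab["p_perm"] <= res.alpha
        assert ((tab["category"] != "none") == sig).all()
        assert (tab["d_obs"] >= 0).all()
        assert ((tab["p_perm"] > 0) & (tab["p_perm"] <= 1)).all()

    def test_label_swap_leaves_pvalues_unchanged(self):
        data = make_null_dataset(seed=2, n_a=60, n_b=40, block_sizes=(4, 4))
        res = build_differential_network(data, n_perm=300, seed=7)
        relabel = {"A": "B", "B": "A"}
        swapped = GroupedDataset(
            data.values,
            data.variable_names,
            np.array([relabel[l] for l in data.group_labels], dtype=object),
        )
        res2 = build_differential_network(swapped, n_perm=300, seed=7)
        assert np.array_equal(res.table["p_perm"].values, res2.table["p_perm"].values)

    def test_end_to_end_determinism(self):
        data = make_null_dataset(seed=3, n_a=50, n_b=50, block_sizes=(3, 3))
        r1 = build_differential_network(data, n_perm=200, seed=11)
        r2 = build_differential_network(data, n_perm=200, seed=11)
        assert r1.table.equals(r2.table)

    def test_pvalues_not_anticonservative_under_null(self):
        """Global null: the p-value distribution over pairs is stochastically
        no smaller than uniform (averaged over datasets)."""
        reps = 8
        fracs = {t: [] for t in (0.05, 0.1, 0.25, 0.5)}
        for seed in range(reps):
            data = make_null_dataset(seed=100 + seed, n_a=100, n_b=100)
            res = build_differential_network(data, n_perm=500, seed=seed)
            p = res.table["p_perm"].values
            for t in fracs:
                fracs[t].append(np.mean(p <= t))
        for t, vals in fracs.items():
            mcse = np.std(vals, ddof=1) / np.sqrt(reps)
            assert np.mean(vals) <= t + 3 * mcse + 0.01

    def test_power_monotone_in_effect_size(self):
        """Detection rate of a planted cross-block change is non-decreasing
        in |delta pcor| in {0.1, 0.2, 0.4}."""
        rates = []
        for delta in (0.1, 0.2, 0.4):
            hits = 0
            reps = 30
            for seed in range(reps):
                spec = SimulationSpec(
                    block_sizes=[3, 3], n_a=300, n_b=300, seed=1000 + seed,
                    cross_block_edges=[[0, 3, 0.0]],
                    differential_edges=[[0, 3, delta, "increase"]],
                )
                data = sample_dataset(spec)
                res = build_differential_network(data, n_perm=200, seed=seed)
                row = res.table.query(
                    "variable_i == 'B01V1' and variable_j == 'B02V1'"
                )
                hits += int(row["p_perm"].item() <= 0.05)
            rates.append(hits / reps)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]
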