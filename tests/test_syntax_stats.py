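"""Unit, oracle and property tests for the transition-dynamics statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from usvsyntax import (
    SILENCE,
    STATES,
    TRANSITIONS,
    combine_pvalues_tpm,
    compare_paired,
    compare_two_sample,
    conditional_probabilities,
    fdr_adjust,
    group_mean_probabilities,
    heatmap_table,
    local_tests_paired,
    local_tests_two_sample,
    transition_counts,
)
from usvsyntax.syntax_stats import (
    fisher_pvalue,
    permutation_test,
    tpm_pvalue_montecarlo,
    wmw_pvalue,
    wsr_pvalue,
)
from usvsyntax.synthetic import CohortSpec, sample_cohort


def brute_force_wsr(diffs):
    """Exhaustive two-sided signed-rank p over all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    w_all = [
        np.sum([r for r, s in zip(ranks, signs) if s > 0])
        for signs in itertools.product([-1, 1], repeat=d.size)
    ]
    w_all = np.array(w_all)
    le = np.mean(w_all <= w_obs + 1e-9)
    ge = np.mean(w_all >= w_obs - 1e-9)
    return min(1.0, 2 * min(le, ge))


def brute_force_wmw(x, y):
    """Exhaustive two-sided rank-sum p over all label assignments."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(x)
    r_obs = ranks[:n1].sum()
    sums = np.array(
        [ranks[list(c)].sum() for c in itertools.combinations(range(len(pooled)), n1)]
    )
    le = np.mean(sums <= r_obs + 1e-9)
    ge = np.mean(sums >= r_obs - 1e-9)
    return min(1.0, 2 * min(le, ge))


def matrices_from_corpus(corpora):
    return [conditional_probabilities(transition_counts(c)) for c in corpora]


class TestTransitionCounts:
    def test_single_sequence(self):
        tc = transition_counts(["ssdm"])
        s, d, u, m, X = (STATES.index(c) for c in "sdumX")
        assert tc.counts[X, s] == 1
        assert tc.counts[s, s] == 1
        assert tc.counts[s, d] == 1
        assert tc.counts[d, m] == 1
        assert tc.counts[m, X] == 1
        assert tc.total == 5  # L + 1

    def test_repeated_singletons(self):
        tc = transition_counts(["s", "s"])
        s, X = STATES.index("s"), STATES.index("X")
        assert tc.counts[X, s] == 2 and tc.counts[s, X] == 2

    def test_total_is_sum_of_length_plus_one(self):
        tc = transition_counts(["sd", "sdm", "sdum"])
        assert tc.total == 3 + 4 + 5

    def test_empty_corpus_all_zero(self):
        assert transition_counts([]).total == 0

    def test_bad_label_is_an_error(self):
        with pytest.raises(ValueError, match="invalid"):
            transition_counts(["sXz"])


class TestConditionalProbabilities:
    def test_worked_example(self):
        p = conditional_probabilities(transition_counts(["ssdm"]))
        s, d, u, m, X = (STATES.index(c) for c in "sdumX")
        assert p[s, s] == pytest.approx(0.5)
        assert p[s, d] == pytest.approx(0.5)
        assert p[d, m] == pytest.approx(1.0)
        assert p[X, s] == pytest.approx(1.0)
        assert p[m, X] == pytest.approx(1.0)
        assert np.all(np.isnan(p[u]))  # "u" never occurred

    def test_all_zero_counts_are_undefined(self):
        p = conditional_probabilities(transition_counts([]))
        assert np.all(np.isnan(p))

    def test_rows_sum_to_one_against_naive_recount(self):
        # Eq-style oracle: naive recount from coded strings
        rng = np.random.default_rng(1)
        letters = np.array(list("sdum"))
        for _ in range(50):
            corpus = [
                "".join(rng.choice(letters, size=rng.integers(1, 10)))
                for _ in range(rng.integers(1, 20))
            ]
            p = conditional_probabilities(transition_counts(corpus))
            naive = np.zeros((5, 5))
            for seq in corpus:
                path = ["X", *seq, "X"]
                for a, b in zip(path[:-1], path[1:]):
                    naive[STATES.index(a), STATES.index(b)] += 1
            for i in range(5):
                row_total = naive[i].sum()
                if row_total == 0:
                    assert np.all(np.isnan(p[i]))
                else:
                    assert np.nansum(p[i]) == pytest.approx(1.0, abs=1e-9)
                    for j in range(5):
                        if not np.isnan(p[i, j]):
                            assert p[i, j] == pytest.approx(naive[i, j] / row_total)


class TestGroupMean:
    def test_simple_mean(self):
        a = np.full((5, 5), 0.2)
        b = np.full((5, 5), 0.4)
        mean, n = group_mean_probabilities([a, b])
        assert np.allclose(mean, 0.3)
        assert np.all(n == 2)

    def test_missing_row_excluded_per_cell(self):
        a = np.full((5, 5), 0.2)
        b = np.full((5, 5), 0.4)
        b[2, :] = np.nan  # this animal never produced "u"
        mean, n = group_mean_probabilities([a, b])
        assert np.allclose(mean[2], 0.2)
        assert np.all(n[2] == 1)

    def test_idempotent_for_identical_animals(self):
        a = np.full((5, 5), 0.25)
        mean, _ = group_mean_probabilities([a, a, a])
        assert np.allclose(mean, a)


class TestLocalRankTests:
    def test_wsr_worked_examples(self):
        assert wsr_pvalue([0.1, 0.2, 0.3]) == pytest.approx(0.25)
        assert wsr_pvalue([0.1, -0.1]) == pytest.approx(1.0)
        assert np.isnan(wsr_pvalue([0.0, 0.0, 0.0]))

    def test_wmw_worked_examples(self):
        assert wmw_pvalue([0.1, 0.2], [0.3, 0.4]) == pytest.approx(1 / 3)
        assert wmw_pvalue([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert wmw_pvalue([0, 0, 0], [1, 1, 1]) == pytest.approx(0.1)

    def test_exact_paths_match_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            n = int(rng.integers(2, 9))
            d = np.round(rng.normal(size=n), 1)  # rounding plants ties/zeros
            if np.all(d == 0):
                continue
            assert wsr_pvalue(d) == pytest.approx(brute_force_wsr(d))
            n1 = int(rng.integers(2, 5))
            n2 = int(rng.integers(2, 5))
            x = np.round(rng.normal(size=n1), 1)
            y = np.round(rng.normal(size=n2), 1)
            assert wmw_pvalue(x, y) == pytest.approx(brute_force_wmw(x, y))

    def test_approx_path_close_to_exact_at_boundary(self):
        rng = np.random.default_rng(4)
        d = rng.normal(size=12)
        exact = wsr_pvalue(d, exact_max_n=12)
        approx = wsr_pvalue(d, exact_max_n=2)
        assert approx == pytest.approx(exact, abs=0.03)

    def test_local_test_matrices(self):
        rng = np.random.default_rng(5)
        a = [rng.dirichlet(np.ones(5), size=5) for _ in range(6)]
        b = [rng.dirichlet(np.ones(5), size=5) for _ in range(6)]
        for mats in (a, b):
            for m in mats:
                m[4, 4] = np.nan
        pm = local_tests_paired(a, b)
        tm = local_tests_two_sample(a, b)
        for p in (pm, tm):
            assert np.isnan(p[4, 4])
            vals = p[~np.isnan(p)]
            assert np.all((vals > 0) & (vals <= 1))
        with pytest.raises(ValueError, match="same animals"):
            local_tests_paired(a, b, animal_ids_a=["x"] * 6, animal_ids_b=["y"] * 6)


class TestTpm:
    def test_product_and_fisher_form(self):
        res = combine_pvalues_tpm([0.5, 0.5], tau=1.0)
        assert res.w == pytest.approx(0.25)
        # closed form for k = 2: W(1 - ln W)
        assert fisher_pvalue(res.w, 2) == pytest.approx(0.25 * (1 - np.log(0.25)))

    def test_empty_product_is_one(self):
        assert combine_pvalues_tpm([0.2, 0.9], tau=0.05).w == 1.0

    def test_single_small_p_passes_through(self):
        assert combine_pvalues_tpm([0.03], tau=0.05).w == pytest.approx(0.03)

    def test_all_missing_gives_missing(self):
        assert np.isnan(combine_pvalues_tpm([np.nan, np.nan]).w)

    def test_montecarlo_matches_fisher_at_tau_one(self):
        p = tpm_pvalue_montecarlo(0.25, 2, tau=1.0, n_draws=20_000, rng=0)
        assert p == pytest.approx(fisher_pvalue(0.25, 2), abs=0.02)


class TestFdr:
    def test_step_up_worked_example(self):
        adj = fdr_adjust([0.01, 0.02, 0.03, 0.04, 0.05])
        assert adj == pytest.approx([0.05] * 5)

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2]) == pytest.approx([0.2])

    def test_capping(self):
        assert fdr_adjust([0.5, 1.0]) == pytest.approx([1.0, 1.0])

    def test_nan_passthrough_and_monotonicity(self):
        adj = fdr_adjust([0.01, np.nan, 0.5])
        assert np.isnan(adj[1])
        assert adj[0] >= 0.01 and adj[2] >= 0.5


@pytest.fixture(scope="module")
def cohort_matrices():
    spec = CohortSpec(n_animals=(6, 6), contexts=("UF", "LF"), n_sequences=60)
    c = sample_cohort(spec, seed=11)
    out = {}
    for g in (0, 1):
        for ctx in ("UF", "LF"):
            out[(g, ctx)] = matrices_from_corpus(
                [c.corpus(g, a, ctx) for a in c.animals(g)]
            )
    return out


class TestPermutationComparisons:
    def test_observed_row_matches_local_test_functions(self, cohort_matrices):
        m1, m2 = cohort_matrices[(0, "UF")], cohort_matrices[(1, "UF")]
        res = compare_two_sample(m1, m2, n_perm=50, seed=1)
        expected = local_tests_two_sample(m1, m2)
        assert np.allclose(res.local_p, expected, equal_nan=True)
        a, b = cohort_matrices[(0, "UF")], cohort_matrices[(0, "LF")]
        resp = compare_paired(a, b, n_perm=50, seed=1)
        assert np.allclose(resp.local_p, local_tests_paired(a, b), equal_nan=True)

    def test_determinism_under_fixed_seed(self, cohort_matrices):
        m1, m2 = cohort_matrices[(0, "UF")], cohort_matrices[(1, "UF")]
        r1 = compare_two_sample(m1, m2, n_perm=200, seed=9)
        r2 = compare_two_sample(m1, m2, n_perm=200, seed=9)
        assert r1.to_json_dict() == r2.to_json_dict()

    def test_identical_groups_give_p_one(self, cohort_matrices):
        m1 = cohort_matrices[(0, "UF")]
        res = compare_two_sample(m1, list(m1), n_perm=100, seed=2)
        assert res.global_p == pytest.approx(1.0)

    def test_p_floor_is_one_over_nperm_plus_one(self, cohort_matrices):
        res = compare_two_sample(
            cohort_matrices[(0, "UF")], cohort_matrices[(1, "UF")],
            n_perm=100, seed=3,
        )
        for p in [res.global_p, *res.to_p.values(), *res.from_p.values()]:
            if not np.isnan(p):
                assert 1 / 101 <= p <= 1.0

    def test_adjusted_at_least_raw(self, cohort_matrices):
        res = compare_two_sample(
            cohort_matrices[(0, "UF")], cohort_matrices[(1, "UF")],
            n_perm=100, seed=4,
        )
        for s in STATES:
            assert res.to_p_adjusted[s] >= res.to_p[s] - 1e-12
            assert res.from_p_adjusted[s] >= res.from_p[s] - 1e-12

    def test_too_few_animals_is_an_error(self, cohort_matrices):
        m = cohort_matrices[(0, "UF")]
        with pytest.raises(ValueError, match="at least 2"):
            compare_two_sample(m[:1], m, n_perm=10, seed=0)
        with pytest.raises(ValueError, match="at least 2"):
            compare_paired(m[:1], m[:1], n_perm=10, seed=0)

    def test_all_zero_differences_give_missing(self):
        a = [np.full((5, 5), 0.2) for _ in range(4)]
        res = compare_paired(a, [m.copy() for m in a], n_perm=20, seed=0)
        assert np.all(np.isnan(res.local_p))
        assert np.isnan(res.global_p)

    def test_single_target_wrapper(self, cohort_matrices):
        m1, m2 = cohort_matrices[(0, "UF")], cohort_matrices[(1, "UF")]
        p = permutation_test(m1, m2, target="to:X", n_perm=100, seed=5)
        res = compare_two_sample(m1, m2, n_perm=100, seed=5, fdr_family="none")
        assert p == res.to_p["X"]
        with pytest.raises(ValueError, match="unknown target"):
            permutation_test(m1, m2, target="sideways", n_perm=10, seed=0)


class TestHeatmapTable:
    def test_structure_and_round_trip(self, tmp_path):
        spec = CohortSpec(n_animals=(5, 5), n_sequences=40)
        c = sample_cohort(spec, seed=21)
        mats = {
            g: matrices_from_corpus([c.corpus(g, a, "UF") for a in c.animals(g)])
            for g in (0, 1)
        }
        res = compare_two_sample(mats[0], mats[1], n_perm=100, seed=6)
        table = heatmap_table(res)
        assert list(table.index) == [*STATES, "to_combined"]
        assert list(table.columns) == [*STATES, "from_combined"]
        assert np.isnan(table.loc[SILENCE, SILENCE])
        local = table.loc[list(STATES), list(STATES)].to_numpy(dtype=float)
        assert np.sum(~np.isnan(local)) == len(TRANSITIONS)
        assert table.loc["to_combined", "from_combined"] == res.global_p
        path = tmp_path / "heat.csv"
        table.to_csv(path)
        back = pd.read_csv(path, index_col=0)
        assert np.allclose(
            back.to_numpy(dtype=float), table.to_numpy(dtype=float), equal_nan=True
        )
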