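import numpy as np
import pytest

from itemrel import (
    CumulativeTables,
    DegenerateItemError,
    InsufficientItemsError,
    ItemScoreMatrix,
    build_pplus,
    candidate_values,
    condition,
    estimate_cumulative_tables,
    ms_approximate,
    ms_reliability,
    population_item_reliability,
    simulate_dataset,
)
from itemrel.ms import source_proportions


def _constant_tables(j=3, p=0.5, c=0.5):
    """All marginals equal p, all cross-item joints equal c (dichotomous)."""
    marginal = np.column_stack([np.ones(j), np.full(j, p)])
    joint = np.full((j, j, 1, 1), float(c))
    return CumulativeTables(marginal, joint, np.full(j, p * (1 - p)))


class TestCandidateValues:
    def test_worked_example_cell_8_2_sources(self, artificial_example):
        # pi_1(1),2(1') at 1-based cell (8,2): no lower neighbor, so only the
        # proportions .32 at (8,1), .51 at (7,2), and .70 at (8,3) are drawn on
        pp = build_pplus(artificial_example)
        for scheme in ("ratio", "pp", "pp_mm"):
            assert source_proportions(pp, 7, 1, scheme) == {0.32, 0.51, 0.70}

    def test_worked_example_cell_8_2_raw_mean(self, artificial_example):
        pp = build_pplus(artificial_example)
        cands = candidate_values(pp, 7, 1, scheme="pp")
        assert sorted(c.value for c in cands) == [0.32, 0.51, 0.70]
        assert np.mean([c.value for c in cands]) == pytest.approx(0.51)

    def test_at_most_eight_candidates(self, artificial_example):
        pp = build_pplus(artificial_example)
        position = {s: k for k, s in enumerate(pp.steps)}
        for i in range(4):
            for x in (1, 2):
                for y in (1, 2):
                    n = len(candidate_values(pp, position[(i, x)], position[(i, y)]))
                    assert 1 <= n <= 8

    def test_interior_cell_has_eight_ratio_candidates(self, artificial_example):
        pp = build_pplus(artificial_example)
        # cell (4,6) 1-based: pi_2(3),1(3'); all four neighbors observable
        cands = candidate_values(pp, 3, 5, scheme="ratio")
        assert len(cands) == 8
        assert {c.matrix for c in cands} == {"pp", "mm"}

    def test_unknown_scheme_rejected(self, artificial_example):
        pp = build_pplus(artificial_example)
        with pytest.raises(ValueError):
            candidate_values(pp, 0, 0, scheme="nope")


class TestMSApproximate:
    @pytest.mark.parametrize("scheme", ["ratio", "pp", "pp_mm"])
    def test_constant_matrix_reproduces_constant(self, scheme):
        approx = ms_approximate(build_pplus(_constant_tables()), scheme=scheme)
        for i in range(3):
            assert approx.tables[i][0, 0] == pytest.approx(0.5)

    def test_cell_values_are_candidate_means(self, small_data):
        tables = estimate_cumulative_tables(small_data)
        approx = ms_approximate(build_pplus(tables))
        for (i, x, y), cands in approx.candidates.items():
            if cands:
                expected = np.clip(np.mean([c.value for c in cands]), 0, 1)
                assert approx.tables[i][x - 1, y - 1] == pytest.approx(expected)

    def test_values_in_unit_interval(self, small_data):
        tables = estimate_cumulative_tables(small_data)
        approx = ms_approximate(build_pplus(tables))
        for table in approx.tables.values():
            assert np.all(table >= 0.0) and np.all(table <= 1.0)

    def test_single_item_is_error(self):
        data = ItemScoreMatrix(np.array([[0], [1], [1]]), m=1)
        with pytest.raises(InsufficientItemsError):
            ms_approximate(build_pplus(estimate_cumulative_tables(data)))

    def test_independence_fallback_warns(self):
        # both steps of the hard item are the two smallest marginals, so its
        # diagonal cell has no observable neighbor at all
        marginal = np.array([[1.0, 0.2, 0.1], [1.0, 0.9, 0.8]])
        joint = np.full((2, 2, 2, 2), np.nan)
        for x in (1, 2):
            for y in (1, 2):
                v = min(marginal[0, x], marginal[1, y]) * 0.9
                joint[0, 1, x - 1, y - 1] = v
                joint[1, 0, y - 1, x - 1] = v
        tables = CumulativeTables(marginal, joint, np.array([0.2, 0.2]))
        with pytest.warns(UserWarning, match="independence"):
            approx = ms_approximate(build_pplus(tables))
        assert approx.tables[0][1, 1] == pytest.approx(0.1 * 0.1)

    def test_agreement_with_brute_force_oracle(self, small_data):
        """Cellwise agreement with an independent dictionary-based oracle."""
        tables = estimate_cumulative_tables(small_data)
        pp = build_pplus(tables)
        approx = ms_approximate(pp, scheme="ratio")

        # oracle: recompute everything with plain dicts and loops
        J, m, scores = small_data.n_items, small_data.m, small_data.scores
        n = len(scores)
        pi = {
            (i, x): np.mean(scores[:, i] >= x)
            for i in range(J)
            for x in range(1, m + 1)
        }
        steps = sorted(pi, key=lambda s: (pi[s], s[0], -s[1]))
        joint = {}
        for r, (i, x) in enumerate(steps):
            for c, (j, y) in enumerate(steps):
                if i != j:
                    joint[(r, c)] = np.mean(
                        (scores[:, i] >= x) & (scores[:, j] >= y)
                    )
        p = [pi[s] for s in steps]
        for i in range(J):
            for x in range(1, m + 1):
                for y in range(1, m + 1):
                    r = steps.index((i, x))
                    c = steps.index((i, y))
                    cands = []
                    for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                        if (rr, cc) not in joint:
                            continue
                        v = joint[(rr, cc)]
                        q = 1 - p[rr] - p[cc] + v
                        if rr != r:  # row neighbor: rescale the row marginal
                            cands.append(v * p[r] / p[rr])
                            cands.append(
                                q * (1 - p[r]) / (1 - p[rr]) + p[r] + p[c] - 1
                            )
                        else:
                            cands.append(v * p[c] / p[cc])
                            cands.append(
                                q * (1 - p[c]) / (1 - p[cc]) + p[r] + p[c] - 1
                            )
                    expected = np.clip(np.mean(cands), 0, 1)
                    assert approx.tables[i][x - 1, y - 1] == pytest.approx(expected)


class TestMSReliability:
    def test_comonotone_limit_gives_one(self):
        tables = _constant_tables(j=3, p=0.5, c=0.5)
        approx = ms_approximate(build_pplus(tables))
        from itemrel import reliability_from_approximation

        for i in range(3):
            rho = reliability_from_approximation(
                approx.tables[i], tables.marginal[i, 1:], tables.item_variances[i]
            )
            assert rho == pytest.approx((0.5 - 0.25) / 0.25)

    def test_independent_items_near_zero(self, rng):
        scores = rng.integers(0, 2, size=(20000, 4))
        data = ItemScoreMatrix(scores, m=1)
        report = ms_reliability(data)
        assert np.all(np.abs(report.estimates) < 0.05)

    def test_determinism(self, small_data):
        a = ms_reliability(small_data)
        b = ms_reliability(small_data)
        np.testing.assert_array_equal(a.estimates, b.estimates)

    def test_person_permutation_invariance(self, small_data, rng):
        perm = rng.permutation(small_data.n_persons)
        permuted = ItemScoreMatrix(small_data.scores[perm], small_data.m)
        np.testing.assert_allclose(
            ms_reliability(permuted).estimates, ms_reliability(small_data).estimates
        )

    def test_item_permutation_equivariance(self, rng):
        scores = simulate_dataset(condition("standard"), seed=101).scores
        # marginals must be tie-free for the ordering to be permutation-stable
        data = ItemScoreMatrix(scores, m=1)
        assert len(set(data.scores.mean(axis=0))) == data.n_items
        perm = rng.permutation(data.n_items)
        permuted = ItemScoreMatrix(scores[:, perm], 1)
        np.testing.assert_allclose(
            ms_reliability(permuted).estimates,
            ms_reliability(data).estimates[perm],
        )

    def test_degenerate_item_named(self):
        scores = np.array([[0, 0], [1, 0], [0, 0], [1, 0]])
        with pytest.raises(DegenerateItemError, match="V2"):
            ms_reliability(ItemScoreMatrix(scores, m=1))

    def test_single_item_is_error(self):
        with pytest.raises(InsufficientItemsError):
            ms_reliability(ItemScoreMatrix(np.array([[0], [1]]), m=1))

    def test_parameter_recovery_identical_items(self):
        # identical items: every population P(++) entry is equal, the regime
        # in which the approximation is exact
        cond = condition(
            "standard",
            name="identical",
            location=np.zeros((6, 1)),
            n_persons=10_000,
        )
        rho = population_item_reliability(cond, 200_000, seed=3)
        report = ms_reliability(simulate_dataset(cond, seed=4))
        assert np.median(np.abs(report.estimates - rho)) < 0.03
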