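"""Statistical primitives against independent enumeration oracles, and the
stage-screening cascade on planted cohorts."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lncarray as la
from lncarray.screen import kendall_tau_test


def mann_whitney_enumeration(x, y):
    """Exact two-sided p by enumerating all group assignments (no ties)."""
    pooled = np.concatenate([x, y])
    n = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    nm = len(x) * len(y)
    tail = min(u_obs, nm - u_obs)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        xs = pooled[list(combo)]
        ys = np.delete(pooled, list(combo))
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        if u <= tail or u >= nm - tail:
            count += 1
        total += 1
    return count / total


def kendall_pair_counting(values, stages):
    """tau-b by O(n^2) concordant/discordant pair counting with tie terms."""
    n = len(values)
    concordant = discordant = 0
    for i in range(n):
        for j in range(i + 1, n):
            prod = np.sign(values[i] - values[j]) * np.sign(stages[i] - stages[j])
            if prod > 0:
                concordant += 1
            elif prod < 0:
                discordant += 1
    n0 = n * (n - 1) / 2
    _, cv = np.unique(values, return_counts=True)
    _, cs = np.unique(stages, return_counts=True)
    n1 = sum(c * (c - 1) / 2 for c in cv)
    n2 = sum(c * (c - 1) / 2 for c in cs)
    return (concordant - discordant) / np.sqrt((n0 - n1) * (n0 - n2))


class TestMannWhitney:
    def test_extreme_separation_exact(self):
        U, p = la.mann_whitney([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 arrangements

    def test_identical_groups_p_one(self):
        _, p = la.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(la.LncArrayError):
            la.mann_whitney([], [1.0])

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_path_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        m = int(rng.integers(2, 11 - n))
        pooled = rng.permutation(np.arange(1.0, n + m + 1))  # untied ranks
        x, y = pooled[:n], pooled[n:]
        _, p = la.mann_whitney(x, y)
        assert p == pytest.approx(mann_whitney_enumeration(x, y))


class TestStudentsT:
    def test_hand_computed_statistic(self):
        t, _ = la.students_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)  # pooled sd 1, se 0.8165

    def test_zero_variance_equal_means(self):
        assert la.students_t([0, 0], [0, 0])[1] == 1.0
        assert la.students_t([1, 2], [1, 2])[1] == 1.0

    def test_zero_variance_unequal_means(self):
        assert la.students_t([1, 1], [2, 2])[1] == 0.0

    def test_matches_scipy_on_random_data(self):
        from scipy import stats
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        t, p = la.students_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestBHFDR:
    def test_step_up_by_hand(self):
        assert np.allclose(la.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])
        assert np.allclose(la.bh_fdr([0.005, 0.1]), [0.01, 0.1])

    def test_all_ones(self):
        assert np.allclose(la.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert la.bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(la.LncArrayError):
            la.bh_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_q_at_least_p_and_monotone_in_sorted_order(self, pvals):
        q = la.bh_fdr(pvals)
        p = np.asarray(pvals)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestKendallTau:
    def test_perfect_concordance(self):
        assert la.kendall_tau([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_hand_counted_example(self):
        # C=4, D=2 over 6 pairs -> tau = 1/3
        assert la.kendall_tau([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(1 / 3)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=20)
        s = rng.integers(1, 5, size=20)
        assert la.kendall_tau(v, s) == pytest.approx(-la.kendall_tau(-v, s))

    def test_all_stages_identical_rejected(self):
        with pytest.raises(la.LncArrayError):
            la.kendall_tau([1, 2, 3], [2, 2, 2])

    @pytest.mark.parametrize("seed,n", [(0, 10), (1, 25), (2, 50)])
    def test_matches_pair_counting_oracle_with_ties(self, seed, n):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 8, size=n).astype(float)  # deliberate ties
        stages = rng.integers(1, 5, size=n).astype(float)
        assert la.kendall_tau(values, stages) == pytest.approx(
            kendall_pair_counting(values, stages))


class TestScreenStageMarkers:
    def test_planted_markers_selected(self, planted_cohort):
        cohort, planted = planted_cohort
        result = la.screen_stage_markers(cohort)
        assert result.loc[planted.index, "selected"].mean() >= 0.9
        # q >= p per probe, flags consistent
        assert (result["q_mw"] >= result["p_mw"] - 1e-12).all()
        assert (result["selected"] <= result["pass_discrimination"]).all()
        assert (result["selected"] <= result["pass_tau"]).all()

    def test_planted_direction_split_matches_generator(self, planted_cohort):
        cohort, planted = planted_cohort
        result = la.screen_stage_markers(cohort)
        taus = result.loc[planted.index, "tau"]
        agree = np.sign(taus.to_numpy()) == planted["sign"].to_numpy()
        assert agree.mean() >= 0.95

    def test_null_cohort_selects_almost_nothing(self):
        cohort, _ = la.gen_cohort(la.CohortGenSpec(
            n_patients=60, n_probes=400, n_informative=0,
            effect_per_stage=0.0, seed=21))
        result = la.screen_stage_markers(cohort)
        assert result["selected"].mean() <= 0.01

    def test_non_mna_restriction_drops_samples(self, planted_cohort):
        cohort, _ = planted_cohort
        n_mna = int(cohort.metadata["mycn_amplified"].fillna(False).sum())
        assert n_mna > 0
        full = la.screen_stage_markers(cohort, restrict="all")
        non_mna = la.screen_stage_markers(cohort, restrict="non_mna")
        assert not full["p_mw"].equals(non_mna["p_mw"])

    def test_insufficient_samples_rejected(self, planted_cohort):
        cohort, _ = planted_cohort
        small = cohort.subset(samples=cohort.sample_ids[:4])
        with pytest.raises(la.LncArrayError):
            la.screen_stage_markers(small)

    def test_constant_probe_fails_tau_without_crashing(self, tiny_matrix):
        import pandas as pd
        values = tiny_matrix.values.copy()
        values.loc["p1"] = 5.0
        # add samples so each stage group has >= 3
        for i, stage in enumerate(["1", "2", "3", "4", "1", "3"]):
            values[f"x{i}"] = [5.0, float(i), float(i * 2)]
        meta = pd.DataFrame(
            {"stage": ["1", "2", "3", "4", "1", "2", "3", "4", "1", "3"]},
            index=list(values.columns))
        cohort = la.CohortMatrix(values, meta)
        result = la.screen_stage_markers(cohort)
        assert np.isnan(result.loc["p1", "tau"])
        assert not result.loc["p1", "selected"]


class TestKendallTauTest:
    def test_constant_anchor_rejected(self):
        with pytest.raises(la.LncArrayError):
            kendall_tau_test([1, 1, 1], [1, 2, 3])
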