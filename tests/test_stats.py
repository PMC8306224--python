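import itertools

import numpy as np
import pytest
from scipy import stats as sps

from resectnet.anatomy import ROILabeling
from resectnet.netmetrics import CentralityTable
from resectnet.stats import (DECREASE, INCREASE, NO_CHANGE, StatResult,
                             SurgeryCase, compare_pre_post,
                             correlate_covariates, holm, spearman,
                             wilcoxon_rank_sum, wilcoxon_signed_rank)


class TestSignedRank:
    def test_five_uniform_positive_pairs_exact(self):
        """All 5 differences positive: p = 2 / 2^5 by sign-pattern enumeration."""
        pre = np.zeros(5)
        post = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = wilcoxon_signed_rank(pre, post)
        assert res.p_value == pytest.approx(0.0625)
        assert res.direction == NO_CHANGE  # 0.0625 >= alpha
        assert res.n == 5

    def test_identical_pairs_give_p_one(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0 and res.direction == NO_CHANGE

    def test_exact_branch_matches_bruteforce_enumeration(self, rng):
        """DP null distribution equals explicit 2^n sign enumeration."""
        d = rng.standard_normal(9)
        d = d[d != 0]
        pre = np.zeros(len(d))
        res = wilcoxon_signed_rank(pre, d)
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = [ranks[np.array(signs, dtype=bool)].sum()
              for signs in itertools.product([0, 1], repeat=len(d))]
        ws = np.array(ws)
        p_brute = min(1.0, 2 * min(np.mean(ws <= w_obs), np.mean(ws >= w_obs)))
        assert res.p_value == pytest.approx(p_brute)

    def test_exact_branch_matches_scipy_without_ties(self, rng):
        pre = rng.standard_normal(12)
        post = pre + rng.standard_normal(12)
        ours = wilcoxon_signed_rank(pre, post)
        ref = sps.wilcoxon(post - pre, method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_exact_and_approximate_branches_agree(self, rng):
        """Around the exact/approximate cross-over the two nulls agree ~0.01."""
        for n in (26, 28, 30):
            pre = rng.standard_normal(n)
            post = pre + 0.3 + rng.standard_normal(n)
            approx = wilcoxon_signed_rank(pre, post)
            from resectnet.stats import _signed_rank_exact_p
            d = post - pre
            ranks = sps.rankdata(np.abs(d))
            exact_p = _signed_rank_exact_p(ranks[d > 0].sum(), ranks)
            assert approx.p_value == pytest.approx(exact_p, abs=0.01)

    def test_direction_follows_median_difference(self):
        pre = np.arange(10, dtype=float)
        res_up = wilcoxon_signed_rank(pre, pre + 1.0)
        res_dn = wilcoxon_signed_rank(pre, pre - 1.0)
        assert res_up.direction == INCREASE and res_dn.direction == DECREASE

    def test_too_few_nonzero_pairs_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0, 0, 0, 1], [0, 0, 0, 2])


class TestRankSum:
    def test_disjoint_triples_exact(self):
        """{1,2,3} vs {4,5,6}: 2/20 arrangements are as extreme -> p = 0.1."""
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)

    def test_enumeration_oracle_on_small_samples(self, rng):
        a = rng.standard_normal(4)
        b = rng.standard_normal(3) + 0.5
        res = wilcoxon_rank_sum(a, b)
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        obs = ranks[:4].sum()
        stats = [sum(combo) for combo in itertools.combinations(ranks, 4)]
        stats = np.array(stats)
        mu = stats.mean()
        p_brute = np.mean(np.abs(stats - mu) >= abs(obs - mu) - 1e-12)
        assert res.p_value == pytest.approx(p_brute)

    def test_identical_samples_not_significant(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value > 0.9 and res.direction == NO_CHANGE

    def test_symmetric_under_argument_exchange(self, rng):
        a, b = rng.standard_normal(8), rng.standard_normal(10) + 1
        assert wilcoxon_rank_sum(a, b).p_value == pytest.approx(
            wilcoxon_rank_sum(b, a).p_value)

    def test_monotone_rescaling_invariance(self, rng):
        a, b = rng.standard_normal(8), rng.standard_normal(8) + 0.5
        p1 = wilcoxon_rank_sum(a, b).p_value
        p2 = wilcoxon_rank_sum(np.exp(a), np.exp(b)).p_value
        assert p1 == pytest.approx(p2)


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        assert spearman(x, x**3).statistic == pytest.approx(1.0)
        assert spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_exact_permutation_null_at_n6(self, rng):
        x = rng.standard_normal(6)
        y = rng.standard_normal(6)
        res = spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        rho_obs = np.corrcoef(rx, ry)[0, 1]
        count = sum(
            abs(np.corrcoef(rx, perm)[0, 1]) >= abs(rho_obs) - 1e-12
            for perm in itertools.permutations(ry))
        assert res.p_value == pytest.approx(count / 720)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_large_n_uses_t_approximation(self, rng):
        x = rng.standard_normal(40)
        y = x + rng.standard_normal(40)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)


class TestHolm:
    def test_adjusted_values_dominate_raw(self):
        raw = [0.01, 0.04, 0.03, 0.20]
        adj = holm(raw)
        assert all(a >= r for a, r in zip(adj, raw))
        assert adj == pytest.approx([0.04, 0.09, 0.09, 0.20])


def _table(vals, names):
    vals = np.asarray(vals, dtype=float)
    return CentralityTable(roi_names=list(names), betweenness=vals,
                           closeness=vals, eigenvector=vals,
                           global_centrality=vals)


def _labeling(names, labels):
    return ROILabeling(roi_names=list(names), labels=list(labels),
                       fractions=np.zeros(len(names)),
                       distances_mm=np.full(len(names), 20.0),
                       resection_hemisphere="left")


def _case(case_id, pre_vals, post_vals, names, labels, group="seizure-free",
          outcome="good", metadata=None):
    return SurgeryCase(
        case_id=case_id, group=group, outcomes={1: outcome},
        centrality={"pre": {"theta": _table(pre_vals, names)},
                    "post": {"theta": _table(post_vals, names)}},
        labeling={1: _labeling(names, labels)},
        metadata=metadata or {},
    )


class TestComparePrePost:
    NAMES = [f"r{i}" for i in range(8)]
    LABELS = ["overlap-excluded"] + ["far"] * 5 + ["adjacent"] * 2

    def test_pools_only_requested_class_and_detects_increase(self, rng):
        cases = []
        for k in range(3):
            pre = rng.uniform(0.2, 0.6, 8)
            post = pre + 0.2
            cases.append(_case(f"c{k}", pre, post, self.NAMES, self.LABELS))
        res = compare_pre_post(cases, "theta", "far", "first-successful")
        assert res.n == 15  # 3 cases x 5 far ROIs
        assert res.direction == INCREASE and res.p_value < 0.05

    def test_missing_stratum_raises_named_error(self):
        cases = [_case("c0", np.ones(8), np.ones(8), self.NAMES, self.LABELS)]
        with pytest.raises(ValueError, match="second-failed"):
            compare_pre_post(cases, "theta", "far", "second-failed")

    def test_small_pool_surfaces_inner_precondition(self, rng):
        labels = ["far"] + ["overlap-excluded"] * 7
        cases = [_case("c0", rng.uniform(size=8), rng.uniform(size=8),
                       self.NAMES, labels)]
        with pytest.raises(ValueError):
            compare_pre_post(cases, "theta", "far", "first-successful")

    def test_unknown_surgery_type_rejected(self):
        with pytest.raises(ValueError):
            compare_pre_post([], "theta", "far", "third-time-lucky")


class TestCorrelateCovariates:
    NAMES = [f"r{i}" for i in range(6)]
    LABELS = ["overlap-excluded"] + ["far"] * 4 + ["adjacent"]

    def _cohort(self, rng, age_effect=0.0, n_cases=10):
        cases = []
        for k in range(n_cases):
            age = float(rng.uniform(2, 18))
            pre = rng.uniform(0.3, 0.7, 6)
            delta = -age_effect * age + 0.05 * rng.standard_normal(6)
            cases.append(_case(f"c{k}", pre, pre + delta, self.NAMES,
                               self.LABELS, metadata={"age_years": age}))
        return cases

    def test_planted_age_effect_sign_recovered(self, rng):
        cases = self._cohort(rng, age_effect=0.02)
        res = correlate_covariates(cases, "age", "mean_delta_far", "theta")
        assert res.statistic < 0 and res.p_value < 0.05

    def test_null_covariate_rarely_significant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cases = self._cohort(rng, age_effect=0.0)
            res = correlate_covariates(cases, "age", "mean_delta_far", "theta")
            hits += res.p_value < 0.05
        assert hits <= 2  # >= 90% of null runs stay non-significant

    def test_constant_covariate_flagged(self, rng):
        cases = self._cohort(rng)
        for c in cases:
            c.metadata["age_years"] = 10.0
        with pytest.raises(ValueError):
            correlate_covariates(cases, "age", "mean_delta_far", "theta")

    def test_missing_covariates_dropped(self, rng):
        cases = self._cohort(rng, age_effect=0.02)
        cases[0].metadata.pop("age_years")
        res = correlate_covariates(cases, "age", "mean_delta_far", "theta")
        assert res.n == len(cases) - 1


class TestStatResult:
    def test_p_value_range_enforced(self):
        with pytest.raises(ValueError):
            StatResult("t", 5, 0.0, 1.5, NO_CHANGE)
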