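"""Normality-gated dispatch, exact nonparametric p-values, reporting."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from nhejacc.stats_reporting import (
    InsufficientDataError,
    PairedAccuracy,
    build_report,
    choose_group_test,
    choose_paired_test,
    compare_ends,
    compare_groups,
    report_medians,
    spearman_corr,
    wilcoxon_signed_rank,
)
from nhejacc.target_model import EndLabel


def wilcoxon_brute_force_p(diffs):
    """Enumerate all 2^n sign assignments of the nonzero differences."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = sps.rankdata(np.abs(d))
    total = ranks.sum()
    w_obs = ranks[d > 0].sum()
    hits = 0
    n = d.size
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if abs(w - total / 2) >= abs(w_obs - total / 2) - 1e-9:
            hits += 1
    return hits / 2**n


def spearman_brute_force(x, y):
    """rho from the closed covariance form; p over all n! orderings."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)

    def rho_of(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))

    rho = rho_of(rx, ry)
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho_of(rx, np.asarray(perm))) >= abs(rho) - 1e-12:
            hits += 1
    return rho, hits / total


class TestDispatch:
    def test_normal_differences_choose_paired_t(self):
        d = np.random.default_rng(4).normal(0.1, 0.05, size=18)
        assert choose_paired_test(d) == "paired_t"

    def test_bimodal_differences_choose_wilcoxon(self):
        d = np.array([-1.0] * 9 + [1.0] * 9) + np.random.default_rng(1).normal(
            0, 0.01, 18
        )
        assert choose_paired_test(d) == "wilcoxon_signed_rank"

    def test_too_few_pairs_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            choose_paired_test([0.1, 0.2])

    def test_group_dispatch(self):
        r = np.random.default_rng(7)
        normal_groups = [r.normal(0, 1, 12) for _ in range(3)]
        assert choose_group_test(normal_groups) == "one_way_anova"
        skewed = [np.exp(r.normal(0, 1, 30)) for _ in range(3)]
        assert choose_group_test(skewed) == "kruskal_wallis"
        assert compare_groups(skewed).test_name == "kruskal_wallis"

    def test_dispatch_rate_under_normal_null(self):
        """The Shapiro gate passes normal differences at roughly 1 - alpha."""
        r = np.random.default_rng(11)
        chosen = [
            choose_paired_test(r.normal(0, 1, 18)) == "paired_t"
            for _ in range(400)
        ]
        assert 0.90 <= np.mean(chosen) <= 0.99


class TestWilcoxon:
    def test_all_positive_signs_six_pairs(self):
        pairs = [(0.2, 0.1), (0.3, 0.1), (0.4, 0.2), (0.5, 0.2), (0.6, 0.3),
                 (0.7, 0.3)]
        data = [PairedAccuracy(f"t{i}", d, p) for i, (d, p) in enumerate(pairs)]
        res = compare_ends(data, test="wilcoxon_signed_rank")
        assert res.test_name == "wilcoxon_signed_rank"
        # all six signs positive: only W+ = 21 and W+ = 0 are as extreme,
        # so the exact two-sided p is 2/2^6
        assert res.p_value == pytest.approx(0.03125, abs=1e-12)

    def test_degenerate_all_zero_differences(self):
        data = [PairedAccuracy(f"t{i}", 0.4, 0.4) for i in range(6)]
        res = compare_ends(data)
        assert res.degenerate and res.p_value == 1.0

    @pytest.mark.parametrize(
        "diffs",
        [
            [0.12, -0.05, 0.31, 0.22, -0.14, 0.40, 0.08, 0.27, -0.02, 0.19],
            [0.1, 0.1, -0.1, 0.2, 0.2, -0.3, 0.4, 0.05],  # ties in |d|
            [0.3, 0.0, -0.2, 0.5, 0.0, 0.1, 0.25],  # zeros dropped
            [-0.4, -0.1, -0.2, -0.35, -0.15, -0.25],
        ],
    )
    def test_exact_p_matches_sign_enumeration(self, diffs):
        res = wilcoxon_signed_rank(diffs)
        assert res.p_value == pytest.approx(wilcoxon_brute_force_p(diffs), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        d = [0.12, -0.05, 0.31, 0.22, -0.14, 0.40, 0.08, 0.27, -0.02, 0.19]
        ours = wilcoxon_signed_rank(d).p_value
        theirs = sps.wilcoxon(d, mode="exact").pvalue
        assert ours == pytest.approx(float(theirs), abs=1e-12)

    def test_large_n_normal_approximation_close_to_exact(self):
        r = np.random.default_rng(3)
        d = r.normal(0.15, 0.2, size=30)
        approx = wilcoxon_signed_rank(d, exact_max_n=25).p_value
        exact = wilcoxon_signed_rank(d, exact_max_n=40).p_value
        assert approx == pytest.approx(exact, rel=0.2, abs=0.01)


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman_corr(x, x).rho == pytest.approx(1.0)
        assert spearman_corr(x, x[::-1]).rho == pytest.approx(-1.0)

    def test_constant_vector_flagged(self):
        res = spearman_corr([1, 2, 3, 4], [5, 5, 5, 5])
        assert res.degenerate and np.isnan(res.rho)

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]),
            ([0.1, 0.9, 0.3, 0.7, 0.5, 0.2], [0.5, 0.2, 0.6, 0.1, 0.9, 0.8]),
            ([3, 1, 4, 1, 5], [9, 2, 6, 5, 3]),  # tie in x
        ],
    )
    def test_small_n_matches_permutation_oracle(self, x, y):
        res = spearman_corr(x, y)
        rho_o, p_o = spearman_brute_force(np.asarray(x, float), np.asarray(y, float))
        assert res.rho == pytest.approx(rho_o, abs=1e-12)
        assert res.p_value == pytest.approx(p_o, abs=1e-12)

    def test_large_n_uses_t_approximation(self):
        r = np.random.default_rng(8)
        x = r.normal(size=40)
        y = x + r.normal(scale=1.0, size=40)
        res = spearman_corr(x, y)
        ref = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(float(ref.statistic), abs=1e-12)
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-6)


class TestReporting:
    def test_empty_inputs_give_header_only_tables(self, tmp_path):
        paths = build_report([], [], {}, tmp_path)
        for key in ("accuracy", "profiles", "tests"):
            lines = paths[key].read_text().splitlines()
            assert len(lines) == 1 and "\t" in lines[0]

    def test_report_medians_equal_recomputation(self, toy_target, tag):
        from nhejacc.synthetic_data import SimulationConfig, simulate_pool
        from nhejacc.pipeline import run_accuracy_analysis

        summaries = []
        for seed in range(5):
            cfg = SimulationConfig(target=toy_target, tag=tag, n_reads=3000,
                                   subst_error_rate=0.0, seed=seed)
            records, _ = simulate_pool(cfg)
            _, s = run_accuracy_analysis(records, toy_target, tag)
            summaries.append(s)
        med = report_medians(summaries)
        for end in EndLabel:
            vals = [s.accuracy[end] for s in summaries if s.accuracy[end] is not None]
            assert med[end] == pytest.approx(float(np.median(vals)))

    def test_report_files_round_trip(self, tmp_path, toy_target, tag):
        from nhejacc.synthetic_data import SimulationConfig, simulate_pool
        from nhejacc.pipeline import run_accuracy_analysis, run_indel_profiling

        cfg = SimulationConfig(target=toy_target, tag=tag, n_reads=3000, seed=1)
        records, _ = simulate_pool(cfg)
        _, summary = run_accuracy_analysis(records, toy_target, tag)
        profile = run_indel_profiling(records, toy_target, tag=tag)
        tests = {"ends": compare_ends(
            [PairedAccuracy(f"t{i}", 0.6 + 0.02 * i, 0.4) for i in range(6)]
        )}
        paths = build_report([summary], [profile], tests, tmp_path)
        table = paths["accuracy"].read_text().splitlines()
        assert len(table) == 3  # header + one row per end
        assert paths["summary"].read_text().startswith("Per-end NHEJ accuracy")
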