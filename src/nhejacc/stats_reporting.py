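"""Normality-gated statistics and report generation.

The analysis layer follows a simple dispatch rule: parametric tests
(paired t, one-way ANOVA) are used only when the data pass a
Shapiro-Wilk normality check at alpha = 0.05; otherwise the Wilcoxon
signed-rank or Kruskal-Wallis test is used.  All tests are two-sided and
p-values are reported uncorrected.

The Wilcoxon signed-rank p-value is computed from the exact permutation
distribution over all 2^n sign assignments for n <= 25 (a subset-sum
convolution over tie-adjusted ranks scaled to integers, so average-rank
ties are handled exactly), and from the tie-corrected normal
approximation above.  Spearman's rho uses average ranks; its p-value is
an exact permutation p for n <= 9 and the t approximation above.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from nhejacc.target_model import EndLabel

SHAPIRO_ALPHA = 0.05


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class PairedAccuracy:
    target: str
    distal: float
    proximal: float

    def __post_init__(self) -> None:
        for v in (self.distal, self.proximal):
            if not 0.0 <= v <= 1.0:
                raise ValueError("accuracies must lie in [0, 1]")


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: int
    sidedness: str = "two_sided"
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str = "spearman"
    degenerate: bool = False


def _shapiro_normal(x: np.ndarray, alpha: float = SHAPIRO_ALPHA) -> bool:
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:  # constant sample: Shapiro-Wilk undefined, treat as non-normal
        return False
    return sps.shapiro(x).pvalue >= alpha


def choose_paired_test(
    differences: Sequence[float], alpha: float = SHAPIRO_ALPHA
) -> str:
    """'paired_t' when the paired differences look normal, else
    'wilcoxon_signed_rank'."""
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise InsufficientDataError("need at least 3 paired differences")
    return "paired_t" if _shapiro_normal(d, alpha) else "wilcoxon_signed_rank"


def choose_group_test(
    groups: Sequence[Sequence[float]], alpha: float = SHAPIRO_ALPHA
) -> str:
    """'one_way_anova' when every group looks normal, else 'kruskal_wallis'."""
    if len(groups) < 2 or any(len(g) < 3 for g in groups):
        raise InsufficientDataError("need >= 2 groups with n >= 3 each")
    ok = all(_shapiro_normal(np.asarray(g, dtype=float), alpha) for g in groups)
    return "one_way_anova" if ok else "kruskal_wallis"


def wilcoxon_signed_rank(
    differences: Sequence[float], exact_max_n: int = 25
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's original treatment); |d| is
    ranked with average ties; the statistic is W+ (sum of positive
    ranks).  For n <= ``exact_max_n`` the p-value is exact over all 2^n
    sign assignments; above, the tie-corrected normal approximation is
    used.  All-zero differences yield the degenerate result p = 1.
    """
    d = np.asarray(differences, dtype=float)
    n_pairs = d.size
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(
            "wilcoxon_signed_rank", 0.0, 1.0, n_pairs, degenerate=True
        )
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _wilcoxon_exact_p(ranks, w_plus)
    else:
        p = _wilcoxon_normal_p(ranks, w_plus)
    return TestResult("wilcoxon_signed_rank", w_plus, p, n_pairs)


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    # Subset-sum convolution over 2*ranks (integers even with .5 average ties).
    scaled = np.rint(2 * ranks).astype(int)
    total = int(scaled.sum())
    counts = [0] * (total + 1)
    counts[0] = 1
    for s in scaled:
        s = int(s)
        for k in range(total, s - 1, -1):
            if counts[k - s]:
                counts[k] += counts[k - s]
    # two-sided: sign assignments whose W+ lies at least as far from the
    # symmetry center T/2 as the observed one; all integer arithmetic
    # (scaled units, deviations doubled), so the comparison is exact
    obs = int(round(2 * w_plus))
    obs_dev = abs(2 * obs - total)
    extreme = sum(c for k, c in enumerate(counts) if abs(2 * k - total) >= obs_dev)
    return extreme / (1 << len(ranks))


def _wilcoxon_normal_p(ranks: np.ndarray, w_plus: float) -> float:
    n = ranks.size
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    z = (w_plus - mean) / np.sqrt(var)
    return float(2 * sps.norm.sf(abs(z)))


def paired_t(differences: Sequence[float]) -> TestResult:
    d = np.asarray(differences, dtype=float)
    if np.ptp(d) == 0:
        return TestResult("paired_t", 0.0, 1.0, d.size, degenerate=True)
    res = sps.ttest_1samp(d, 0.0)
    return TestResult("paired_t", float(res.statistic), float(res.pvalue), d.size)


def compare_ends(
    data: Sequence[PairedAccuracy], test: str = "auto"
) -> TestResult:
    """Two-sided paired comparison of PAM-distal vs PAM-proximal accuracy.

    With ``test="auto"`` (default) the branch is chosen by the
    Shapiro-Wilk gate on the paired differences; passing
    ``"wilcoxon_signed_rank"`` or ``"paired_t"`` forces that branch.
    """
    if len(data) < 3:
        raise InsufficientDataError("need >= 3 paired targets")
    d = np.asarray([p.distal - p.proximal for p in data], dtype=float)
    if np.all(d == 0):
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, d.size, degenerate=True)
    branch = choose_paired_test(d) if test == "auto" else test
    if branch not in ("paired_t", "wilcoxon_signed_rank"):
        raise ValueError(f"unknown test {branch!r}")
    return paired_t(d) if branch == "paired_t" else wilcoxon_signed_rank(d)


def compare_groups(groups: Sequence[Sequence[float]]) -> TestResult:
    """Two-sided multi-group comparison through the normality gate."""
    branch = choose_group_test(groups)
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if branch == "one_way_anova":
        res = sps.f_oneway(*arrays)
        return TestResult("one_way_anova", float(res.statistic), float(res.pvalue),
                          sum(a.size for a in arrays))
    res = sps.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(res.statistic), float(res.pvalue),
                      sum(a.size for a in arrays))


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def spearman_corr(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 9
) -> CorrelationResult:
    """Spearman rank correlation with average-tie ranks, signed rho.

    p-value: exact permutation over all n! orderings for n <= 9, t
    approximation with n-2 df above.  A constant input vector makes rho
    undefined; the result is flagged degenerate with rho = nan.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise InsufficientDataError("need n >= 4 for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, degenerate=True)
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = _rank_rho(rx, ry)
    if n <= exact_max_n:
        tol = 1e-12
        hits = total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rank_rho(rx, np.asarray(perm))) >= abs(rho) - tol:
                hits += 1
        p = hits / total
    else:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1 - rho**2))
        p = float(2 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(rho, float(p), n)


# ---------------------------------------------------------------------------
# reporting


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def build_report(
    summaries: Iterable,
    profiles: Iterable,
    tests: dict[str, TestResult | CorrelationResult],
    outdir: str | Path,
    plots: bool = False,
) -> dict[str, Path]:
    """Write per-target and cross-target TSVs plus a readable summary.

    ``summaries`` are AccuracySummary objects, ``profiles`` are
    MutationProfile objects; ``tests`` maps a label to a test result.
    Returns the paths written.  With ``plots=True`` a per-end accuracy
    box plot is also written (requires matplotlib).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    acc_path = outdir / "accuracy_summary.tsv"
    rows = []
    with open(acc_path, "w") as fh:
        fh.write(
            "target\tend\tn_total\tn_wt\tn_dsodn\tn_mutation\t"
            "n_assessable\tn_accurate\taccuracy\taccuracy_all_dsodn\n"
        )
        for s in summaries:
            for end in EndLabel:
                acc = s.accuracy[end]
                rows.append((s.target, end, acc))
                fh.write(
                    f"{s.target}\t{end.value}\t{s.n_total}\t{s.n_wt}\t"
                    f"{s.n_dsodn}\t{s.n_mutation}\t"
                    f"{s.n_assessable.get(end, 0)}\t{s.n_accurate.get(end, 0)}\t"
                    f"{_fmt(acc)}\t{_fmt(s.accuracy_all_dsodn[end])}\n"
                )
    paths["accuracy"] = acc_path

    prof_path = outdir / "mutation_profiles.tsv"
    from nhejacc.indel_profiling import write_profile_table

    write_profile_table(prof_path, profiles)
    paths["profiles"] = prof_path

    tests_path = outdir / "tests.tsv"
    with open(tests_path, "w") as fh:
        fh.write("label\ttest\tstatistic_or_rho\tp_value\tn\n")
        for label, res in tests.items():
            if isinstance(res, CorrelationResult):
                fh.write(
                    f"{label}\t{res.method}\t{_fmt(res.rho)}\t"
                    f"{_fmt(res.p_value)}\t{res.n}\n"
                )
            else:
                fh.write(
                    f"{label}\t{res.test_name}\t{_fmt(res.statistic)}\t"
                    f"{_fmt(res.p_value)}\t{res.n}\n"
                )
    paths["tests"] = tests_path

    summary_path = outdir / "summary.txt"
    with open(summary_path, "w") as fh:
        fh.write("Per-end NHEJ accuracy (median, 25-75% percentiles)\n")
        for end in EndLabel:
            vals = np.array([a for (_, e, a) in rows if e is end and a is not None])
            if vals.size:
                q25, med, q75 = np.percentile(vals, [25, 50, 75])
                fh.write(
                    f"  {end.value}: median {med:.4f}, IQR [{q25:.4f}, {q75:.4f}]"
                    f" (n={vals.size})\n"
                )
            else:
                fh.write(f"  {end.value}: no defined values\n")
        fh.write("\nStatistical tests\n")
        for label, res in tests.items():
            if isinstance(res, CorrelationResult):
                fh.write(
                    f"  {label}: rho={_fmt(res.rho)}, p={_fmt(res.p_value)}, "
                    f"n={res.n}\n"
                )
            else:
                fh.write(
                    f"  {label}: {res.test_name}, stat={_fmt(res.statistic)}, "
                    f"p={_fmt(res.p_value)}, n={res.n}\n"
                )
    paths["summary"] = summary_path

    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        data = [
            [a for (_, e, a) in rows if e is end and a is not None]
            for end in EndLabel
        ]
        ax.boxplot(data, tick_labels=[e.value for e in EndLabel])
        ax.set_ylabel("NHEJ accuracy")
        fig.tight_layout()
        plot_path = outdir / "accuracy_boxplot.png"
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
        paths["plot"] = plot_path

    return paths


def report_medians(summaries: Iterable) -> dict[EndLabel, float | None]:
    """Median per-end accuracy across targets (None when undefined)."""
    out: dict[EndLabel, float | None] = {}
    acc = {end: [] for end in EndLabel}
    for s in summaries:
        for end in EndLabel:
            v = s.accuracy[end]
            if v is not None:
                acc[end].append(v)
    for end in EndLabel:
        out[end] = float(np.median(acc[end])) if acc[end] else None
    return out
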