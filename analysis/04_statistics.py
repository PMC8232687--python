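"""Statistical comparisons across the 18 simulated targets.

Pairs the per-end accuracies from step 02 and the insertion fractions
from step 03, then runs the study's statistical layer: a two-sided
Wilcoxon signed-rank comparison of PAM-distal vs PAM-proximal accuracy,
and Spearman rank correlations of the insertion fraction against
accuracy at each end.  Writes results/statistics.tsv and a readable
summary under results/report/.

Run after 02 and 03:  python analysis/04_statistics.py
"""

import sys
from pathlib import Path

import pandas as pd

from nhejacc.stats_reporting import (
    PairedAccuracy,
    choose_paired_test,
    compare_ends,
    spearman_corr,
)

RESULTS = Path("results")


def main() -> int:
    acc = pd.read_csv(RESULTS / "accuracy_per_target.tsv", sep="\t")
    prof = pd.read_csv(RESULTS / "mutation_profiles.tsv", sep="\t")
    merged = acc.merge(prof[["target", "insertion_fraction"]], on="target")

    paired = [
        PairedAccuracy(r.target, r.accuracy_distal, r.accuracy_proximal)
        for r in merged.itertuples()
    ]
    branch = choose_paired_test(
        [p.distal - p.proximal for p in paired]
    )
    ends_auto = compare_ends(paired)
    ends_wilcoxon = compare_ends(paired, test="wilcoxon_signed_rank")
    rho_prox = spearman_corr(
        merged.insertion_fraction.tolist(), merged.accuracy_proximal.tolist()
    )
    rho_dist = spearman_corr(
        merged.insertion_fraction.tolist(), merged.accuracy_distal.tolist()
    )

    rows = [
        dict(comparison="distal_vs_proximal", test=ends_auto.test_name,
             statistic=ends_auto.statistic, p_value=ends_auto.p_value,
             n=ends_auto.n),
        dict(comparison="distal_vs_proximal_wilcoxon",
             test=ends_wilcoxon.test_name, statistic=ends_wilcoxon.statistic,
             p_value=ends_wilcoxon.p_value, n=ends_wilcoxon.n),
        dict(comparison="insertion_fraction_vs_proximal", test="spearman",
             statistic=rho_prox.rho, p_value=rho_prox.p_value, n=rho_prox.n),
        dict(comparison="insertion_fraction_vs_distal", test="spearman",
             statistic=rho_dist.rho, p_value=rho_dist.p_value, n=rho_dist.n),
    ]
    df = pd.DataFrame(rows)
    out = RESULTS / "statistics.tsv"
    df.to_csv(out, sep="\t", index=False)

    print(f"normality gate chose: {branch}")
    print(f"distal vs proximal (Wilcoxon signed rank): "
          f"p = {ends_wilcoxon.p_value:.3g} "
          f"(mean distal {merged.accuracy_distal.mean():.3f}, "
          f"mean proximal {merged.accuracy_proximal.mean():.3f})")
    print(f"insertion fraction vs proximal accuracy: rho = {rho_prox.rho:.3f}, "
          f"p = {rho_prox.p_value:.3g}")
    print(f"insertion fraction vs distal accuracy:   rho = {rho_dist.rho:.3f}, "
          f"p = {rho_dist.p_value:.3g}")
    print(f"wrote {out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
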