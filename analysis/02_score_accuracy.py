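"""Classify the dsODN-capture pools and score per-end NHEJ accuracy.

Reads each target's simulated accuracy pool from scratch/sim/, runs
duplicate collapsing, singleton removal, indicator selection and the
three-way classification, and writes per-target per-end accuracies to
results/accuracy_per_target.tsv.  Prints measured vs ground-truth
accuracy so recovery is visible at a glance.

Run after 01_simulate_pools.py:  python analysis/02_score_accuracy.py
"""

import sys
from pathlib import Path

import pandas as pd

from nhejacc.pipeline import run_accuracy_analysis
from nhejacc.read_processing import read_merged
from nhejacc.synthetic_data import DEFAULT_TAG
from nhejacc.target_model import EndLabel, GenomeTarget

SIM_DIR = Path("scratch/sim")
RESULTS = Path("results")


def main() -> int:
    conditions = pd.read_csv(RESULTS / "study_conditions.tsv", sep="\t")
    rows = []
    for cond in conditions.itertuples():
        target = GenomeTarget(
            name=cond.target, reference=cond.reference,
            protospacer=cond.protospacer, strand=cond.strand,
        )
        reads = read_merged(SIM_DIR / f"{cond.target}_dsodn.fastq.gz")
        _, summary = run_accuracy_analysis(reads, target, DEFAULT_TAG)
        acc_d = summary.accuracy[EndLabel.PAM_DISTAL]
        acc_p = summary.accuracy[EndLabel.PAM_PROXIMAL]
        rows.append(
            dict(
                target=cond.target,
                n_total=summary.n_total, n_wt=summary.n_wt,
                n_dsodn=summary.n_dsodn, n_mutation=summary.n_mutation,
                accuracy_distal=acc_d, accuracy_proximal=acc_p,
                true_p_distal=cond.p_acc_distal,
                true_p_proximal=cond.p_acc_proximal,
            )
        )
        print(
            f"{cond.target}: distal {acc_d:.3f} (true {cond.p_acc_distal:.3f})"
            f"  proximal {acc_p:.3f} (true {cond.p_acc_proximal:.3f})"
        )

    df = pd.DataFrame(rows)
    out = RESULTS / "accuracy_per_target.tsv"
    df.to_csv(out, sep="\t", index=False)
    err_d = (df.accuracy_distal - df.true_p_distal).abs().mean()
    err_p = (df.accuracy_proximal - df.true_p_proximal).abs().mean()
    print(f"\nmean |measured - true|: distal {err_d:.4f}, proximal {err_p:.4f}")
    print(f"wrote {out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
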