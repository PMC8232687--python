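"""Simulate every read pool the downstream analyses consume.

Draws the 18-target study conditions (per-end junction accuracies,
per-target insertion fractions), then writes, per target, a dsODN-capture
accuracy pool and a matched dsODN-free profiling pool as FASTQ plus an
allele-level truth table, and the three dual-guide deletion pools.  Raw
reads go under scratch/sim/ (they are bulky and regenerable); the drawn
ground-truth conditions — what later steps try to recover — are recorded
in results/study_conditions.tsv.

Run from the repository root:  python analysis/01_simulate_pools.py
"""

import sys
from pathlib import Path

import numpy as np

from nhejacc.study import (
    DUAL_P_PRECISE,
    accuracy_config,
    child_seed,
    draw_study_conditions,
    profiling_config,
)
from nhejacc.synthetic_data import (
    make_dual_design,
    simulate_dual_pool,
    simulate_to_files,
    write_truth_table,
)
from nhejacc.read_processing import write_fastq

SEED = 20260929
SIM_DIR = Path("scratch/sim")
RESULTS = Path("results")


def main() -> int:
    rng = np.random.default_rng(SEED)
    SIM_DIR.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    conditions = draw_study_conditions(rng)
    with open(RESULTS / "study_conditions.tsv", "w") as fh:
        fh.write(
            "target\tstrand\tp_acc_distal\tp_acc_proximal\t"
            "mut_insertion_fraction\treference\tprotospacer\n"
        )
        for cond in conditions:
            t = cond.target
            fh.write(
                f"{t.name}\t{t.strand}\t{cond.p_acc_distal:.6f}\t"
                f"{cond.p_acc_proximal:.6f}\t{cond.mut_insertion_fraction:.6f}\t"
                f"{t.reference}\t{t.protospacer}\n"
            )

    for cond in conditions:
        name = cond.target.name
        simulate_to_files(
            accuracy_config(cond, child_seed(rng)),
            SIM_DIR / f"{name}_dsodn.fastq.gz",
            SIM_DIR / f"{name}_dsodn_truth.tsv",
        )
        simulate_to_files(
            profiling_config(cond, child_seed(rng)),
            SIM_DIR / f"{name}_nodsodn.fastq.gz",
            SIM_DIR / f"{name}_nodsodn_truth.tsv",
        )
        print(f"simulated {name}: accuracy + profiling pools")

    for config, p_precise in DUAL_P_PRECISE.items():
        design = make_dual_design(np.random.default_rng(child_seed(rng)), config)
        records, truth = simulate_dual_pool(
            design, n_reads=10_000, p_precise=p_precise, seed=child_seed(rng)
        )
        write_fastq(SIM_DIR / f"dual_{config}.fastq.gz", records)
        write_truth_table(SIM_DIR / f"dual_{config}_truth.tsv", truth)
        # later steps need the design; store the two sites alongside
        with open(SIM_DIR / f"dual_{config}_design.tsv", "w") as fh:
            fh.write("site\treference\tprotospacer\tstrand\n")
            for site in (design.site_a, design.site_b):
                fh.write(
                    f"{site.name}\t{site.reference}\t{site.protospacer}\t"
                    f"{site.strand}\n"
                )
        print(f"simulated dual-guide pool: {config} (p_precise={p_precise:.3f})")

    print(f"\nwrote study conditions for {len(conditions)} targets to "
          f"{RESULTS / 'study_conditions.tsv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
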