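"""Profile indel outcomes in the dsODN-free pools.

Aligns mutation reads to each reference, calls indels near the cut,
types reads as insertion / deletion / complex, and measures how often a
1-bp insertion duplicates the N4 base (the protospacer base immediately
5' of the cut).  Writes results/mutation_profiles.tsv.

Run after 01_simulate_pools.py:  python analysis/03_profile_indels.py
"""

import sys
from pathlib import Path

import pandas as pd

from nhejacc.pipeline import run_indel_profiling
from nhejacc.read_processing import read_merged
from nhejacc.target_model import GenomeTarget

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
        reads = read_merged(SIM_DIR / f"{cond.target}_nodsodn.fastq.gz")
        p = run_indel_profiling(reads, target)
        rows.append(
            dict(
                target=cond.target,
                n_mut_reads=p.n_mut_reads,
                n_insertion=p.n_insertion_reads,
                n_deletion=p.n_deletion_reads,
                n_complex=p.n_complex_reads,
                insertion_fraction=p.insertion_fraction,
                true_insertion_fraction=cond.mut_insertion_fraction,
                n4_base=p.n4,
                one_bp_insertions=p.one_bp_insertion_count,
                n4_fraction=p.n4_fraction,
            )
        )
        print(
            f"{cond.target}: insertion fraction "
            f"{p.insertion_fraction:.3f} (true {cond.mut_insertion_fraction:.3f}),"
            f" N4 identity {p.n4_fraction if p.n4_fraction is None else round(p.n4_fraction, 3)}"
        )

    df = pd.DataFrame(rows)
    out = RESULTS / "mutation_profiles.tsv"
    df.to_csv(out, sep="\t", index=False)
    pooled_n4 = df.n4_fraction.mul(df.one_bp_insertions).sum() / df.one_bp_insertions.sum()
    print(f"\npooled 1-bp insertion N4-identity fraction: {pooled_n4:.4f}")
    print(f"wrote {out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
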