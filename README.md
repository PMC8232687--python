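# nhejacc

Quantifying the accuracy of non-homologous end joining (NHEJ) repair at
CRISPR-Cas9 double-strand breaks from dsODN-tagged amplicon sequencing.

## The problem

When SpCas9 cuts genomic DNA (a blunt cut 3 nt 5′ of the NGG PAM), the
break is usually resealed by NHEJ. Scoring how often that repair is
*perfect* is confounded by re-cutting: a perfectly repaired site is cut
again until it acquires a mutation, while a never-cut allele looks like a
perfect repair. Capturing a short end-protected double-stranded
oligodeoxynucleotide (dsODN) in the break solves both problems — the tag
marks exactly one cleavage event and destroys the protospacer so the
locus cannot be re-cut. Each genomic-DNA/dsODN junction then reports one
ligation event, and the two junctions report the two break ends
separately: the **PAM-distal** end (the side without the PAM) and the
**PAM-proximal** end (the side with it).

This package implements that analysis as a tested pipeline over merged
amplicon reads:

1. **Read preparation** — join R1/R2 by their 3′ overlap, collapse
   duplicate sequences to counts, drop singletons, and select reads
   spanning a break end by exact match to a 12-nt *indicator* placed
   70 nt from the cut.
2. **Classification** — precedence-ordered: *wild type* if the read
   contains the intact 10-nt WT marker straddling the cut (excluded from
   all accuracy denominators); else *dsODN-inserted* if it contains any
   contiguous 10-mer of the tag in either orientation; else *mutation*.
3. **Junction accuracy** — a dsODN read is *accurate* at an end iff the
   10-nt genomic flank abuts the 10-nt terminal segment of the
   (orientation-resolved) tag as one contiguous exact 20-nt substring:

   `accuracy(end) = n_accurate(end) / n_dsODN(end)`

   count-weighted over the dsODN reads assessable at that end.
4. **Indel profiling** (dsODN-free pools) — affine-gap global alignment
   to the reference, indel events called within ±5 nt of the cut, reads
   typed insertion / deletion / complex, and 1-bp insertions checked for
   identity to the N4 base (the protospacer base immediately 5′ of the
   cut, duplicated when Cas9 leaves a 1-nt 5′ overhang).
5. **Statistics** — Shapiro–Wilk-gated dispatch (paired *t* / one-way
   ANOVA only when normality passes, otherwise Wilcoxon signed-rank /
   Kruskal–Wallis), all two-sided; the Wilcoxon p-value is exact (full
   sign-assignment distribution, tie-aware) up to n = 25, and Spearman's
   ρ uses an exact permutation p up to n = 9.
6. **Dual-guide deletions** — reads joining two cut sites are scored
   precise iff the two outer 5-nt flanks meet exactly, separately for the
   PAM-in / PAM-out / PAM-in/out configurations.

A seeded simulator (`nhejacc.synthetic_data`) generates all of these read
pools with an allele-level ground-truth table, so every stage is testable
without sequencing data.

## Worked example

Simulate a pool and score it from the shell:

```bash
nhejacc simulate --out-fastq pool.fastq.gz --out-truth truth.tsv \
    --seed 4 --n-reads 3000
nhejacc run --targets targets.yaml --fastq pool.fastq.gz --merged \
    --outdir out/
```

which prints

```
cli_demo PAM_distal: accuracy 0.7822 (n_dsodn=551)
cli_demo PAM_proximal: accuracy 0.4174 (n_dsodn=551)
```

— of 3000 simulated reads, 551 (count-weighted) carried the tag and were
assessable at each end; 78.2% of distal junctions and 41.7% of proximal
junctions were indel-free, recovering the simulation's configured
per-end accuracies (0.7418 / 0.3862) within binomial noise. The same
operations are available as library calls:

```python
import numpy as np
from nhejacc import run_accuracy_analysis, EndLabel
from nhejacc.synthetic_data import (
    DEFAULT_TAG, SimulationConfig, make_synthetic_target, simulate_pool,
)

target = make_synthetic_target(np.random.default_rng(4))
cfg = SimulationConfig(target=target, n_reads=3000, seed=4)
records, truth = simulate_pool(cfg)
classified, summary = run_accuracy_analysis(records, target, DEFAULT_TAG)
print(summary.accuracy[EndLabel.PAM_DISTAL])   # 0.7822...
```

## The analysis

The numbered drivers under `analysis/` run the full synthetic study —
18 targets with per-end junction accuracies centred on 74.18%
(PAM-distal) and 38.62% (PAM-proximal), proximal accuracy declining with
each target's insertion fraction, plus dual-guide deletion pools:

```bash
python analysis/01_simulate_pools.py   # pools + truth → scratch/sim/
python analysis/02_score_accuracy.py   # → results/accuracy_per_target.tsv
python analysis/03_profile_indels.py   # → results/mutation_profiles.tsv
python analysis/04_statistics.py       # → results/statistics.tsv
python analysis/05_dual_deletion.py    # → results/dual_deletion.tsv
```

A representative run ends with

```
distal vs proximal (Wilcoxon signed rank): p = 7.63e-06 (mean distal 0.777, mean proximal 0.421)
insertion fraction vs proximal accuracy: rho = -0.868, p = 3.05e-06
insertion fraction vs distal accuracy:   rho = -0.238, p = 0.341
```

i.e. the pipeline recovers the built-in end asymmetry and the negative
insertion-fraction/proximal-accuracy correlation, while the independent
distal end shows no significant correlation.

## Layout

```
src/nhejacc/        target_model, read_processing, classification,
                    indel_profiling, stats_reporting, synthetic_data,
                    pipeline, study, cli
analysis/           numbered study drivers (thin, narrative)
tests/              pytest suite incl. end-to-end acceptance properties
scripts/acceptance.py
docs/methods.md     model, parameters, simulator scope, numerical choices
```
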