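"""End-to-end drivers tying the processing stages together.

Each driver takes merged reads (sequences, MergedRead objects, or FASTQ
records) and a target definition, and runs: duplicate collapsing →
singleton removal → per-end indicator selection → classification /
profiling.  These are the entry points the analysis scripts, the CLI and
the acceptance checks all share.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from nhejacc.classification import (
    AccuracySummary,
    ClassifiedRead,
    DualCutDesign,
    classify_pool,
    assess_dual_deletion,
)
from nhejacc.indel_profiling import MutationProfile, profile_target
from nhejacc.read_processing import (
    CountedRead,
    collapse_duplicates,
    filter_singletons,
    select_by_indicator,
)
from nhejacc.target_model import (
    DsODNTag,
    EndLabel,
    GenomeTarget,
    indicator_for_end,
    revcomp,
    wt_marker,
)


def _as_sequences(reads: Iterable) -> list[str]:
    out = []
    for r in reads:
        if isinstance(r, str):
            out.append(r)
        elif isinstance(r, tuple):  # FASTQ record (id, seq, qual)
            out.append(r[1])
        else:  # MergedRead
            out.append(r.sequence)
    return out


def prepare_pool(
    reads: Iterable, min_count: int = 2
) -> list[CountedRead]:
    """Collapse duplicates and drop singletons."""
    return filter_singletons(collapse_duplicates(_as_sequences(reads)), min_count)


def run_accuracy_analysis(
    reads: Iterable,
    target: GenomeTarget,
    tag: DsODNTag,
    min_count: int = 2,
    indicator_offset: int = 70,
    indicator_length: int = 12,
    marker_halfwidth: int = 5,
    k: int = 10,
) -> tuple[list[ClassifiedRead], AccuracySummary]:
    """Full single-cut accuracy pipeline on merged reads."""
    pool = prepare_pool(reads, min_count)
    reads_by_end = {
        end: select_by_indicator(
            pool, target, end, offset=indicator_offset, length=indicator_length
        )
        for end in EndLabel
    }
    return classify_pool(
        reads_by_end, target, tag, marker_halfwidth=marker_halfwidth, k=k
    )


def run_indel_profiling(
    reads: Iterable,
    target: GenomeTarget,
    tag: DsODNTag | None = None,
    min_count: int = 2,
    indicator_offset: int = 70,
    indicator_length: int = 12,
    marker_halfwidth: int = 5,
    window: int = 5,
) -> MutationProfile:
    """dsODN-free indel profiling: mutation reads spanning the cut.

    Reads must carry both end indicators (so the whole cut region is
    covered), lack the WT marker, and — when a tag is given — lack the
    tag, before they are aligned and typed.
    """
    pool = prepare_pool(reads, min_count)
    ind = {
        end: indicator_for_end(
            target, end, offset=indicator_offset, length=indicator_length
        )
        for end in EndLabel
    }
    marker = wt_marker(target, marker_halfwidth)
    mutation_reads = []
    for r in pool:
        seq = r.sequence
        if ind[EndLabel.PAM_DISTAL] not in seq:
            seq = revcomp(seq)
        if any(ind[end] not in seq for end in EndLabel):
            continue
        if marker in seq:
            continue
        if tag is not None:
            from nhejacc.classification import detect_dsodn

            if detect_dsodn(seq, tag) is not None:
                continue
        mutation_reads.append(CountedRead(sequence=seq, count=r.count))
    return profile_target(mutation_reads, target, window=window)


def run_dual_deletion(
    reads: Iterable,
    design: DualCutDesign,
    min_count: int = 2,
) -> tuple[int, int, float | None]:
    """Dual-guide precise-deletion pipeline on merged reads."""
    pool = prepare_pool(reads, min_count)
    return assess_dual_deletion(pool, design)


def accuracy_from_truth(truth: Sequence, surviving_only: bool = False):
    """Realised per-end accurate fractions in a simulation truth table.

    The truth-side counterpart of AccuracySummary.accuracy, weighted by
    allele multiplicity.
    """
    n = {EndLabel.PAM_DISTAL: 0, EndLabel.PAM_PROXIMAL: 0}
    acc = {EndLabel.PAM_DISTAL: 0, EndLabel.PAM_PROXIMAL: 0}
    for rec in truth:
        if rec.cls != "dsodn_inserted":
            continue
        if surviving_only and rec.multiplicity < 2:
            continue
        w = rec.multiplicity
        n[EndLabel.PAM_DISTAL] += w
        n[EndLabel.PAM_PROXIMAL] += w
        if rec.distal_accurate:
            acc[EndLabel.PAM_DISTAL] += w
        if rec.proximal_accurate:
            acc[EndLabel.PAM_PROXIMAL] += w
    return {
        end: (acc[end] / n[end] if n[end] else None) for end in EndLabel
    }
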