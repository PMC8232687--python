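"""Indel outcome profiling for dsODN-free experiments.

Without the tag, NHEJ outcomes are read directly as indels at the cut
site.  Mutation reads are globally aligned to the reference under affine
gap scoring, gap runs are called as insertion/deletion events, events
are localised to a window around the cut, and each read is typed as an
insertion, deletion or complex (both) outcome.  The insertion fraction
is taken over insertion+deletion reads only; complex reads are reported
separately.

A well-known Cas9 signature is tracked explicitly: staggered cleavage
with a 1-nt 5' overhang duplicates the protospacer base immediately 5'
of the cut (the 4th base upstream of the PAM, "N4"), so 1-bp insertions
are checked for identity to that base, strand-resolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from Bio import Align

from nhejacc.read_processing import CountedRead
from nhejacc.target_model import GenomeTarget, compute_cut_site, revcomp


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment as two equal-length gapped strings."""

    aligned_read: str
    aligned_ref: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_read) != len(self.aligned_ref):
            raise ValueError("gapped rows must have equal length")
        if any(a == b == "-" for a, b in zip(self.aligned_read, self.aligned_ref)):
            raise ValueError("column gapped in both rows")


@dataclass(frozen=True)
class IndelEvent:
    kind: Literal["insertion", "deletion"]
    ref_position: int  # inter-base position (insertions) / interval start (deletions)
    length: int
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.kind == "insertion" and len(self.inserted_seq) != self.length:
            raise ValueError("insertion length must equal inserted_seq length")


@dataclass
class MutationProfile:
    """Count-weighted indel typing for one target's mutation reads."""

    target: str
    n4: str
    n_mut_reads: int = 0
    n_insertion_reads: int = 0
    n_deletion_reads: int = 0
    n_complex_reads: int = 0
    n_none_reads: int = 0
    one_bp_insertion_count: int = 0
    n4_match_count: int = 0

    @property
    def insertion_fraction(self) -> float | None:
        denom = self.n_insertion_reads + self.n_deletion_reads
        return self.n_insertion_reads / denom if denom else None

    @property
    def n4_fraction(self) -> float | None:
        if not self.one_bp_insertion_count:
            return None
        return self.n4_match_count / self.one_bp_insertion_count


def _make_aligner(
    match: float, mismatch: float, gap_open: float, gap_extend: float
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # Biopython's open score is charged for the first gapped base
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def align_global(
    read: str,
    reference: str,
    match: float = 5,
    mismatch: float = -4,
    gap_open: float = -10,
    gap_extend: float = -1,
) -> AlignmentResult:
    """Optimal global alignment of a read to the reference (affine gaps).

    A gap of length L costs ``gap_open + L * gap_extend``.  The first
    optimal alignment in Biopython's deterministic traversal order is
    taken; gap placement is normalised downstream by left-alignment, so
    score-equivalent placements yield identical event calls.
    """
    if not read or not reference:
        raise ValueError("read and reference must be nonempty")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(reference, read)[0]
    ref_row, read_row = str(aln[0]), str(aln[1])
    return AlignmentResult(aligned_read=read_row, aligned_ref=ref_row, score=aln.score)


def _left_align_deletion(ref: str, start: int, length: int) -> int:
    # shift a deletion of ref[start:start+length] left through repeats
    while start > 0 and ref[start - 1] == ref[start + length - 1]:
        start -= 1
    return start


def _left_align_insertion(ref: str, pos: int, seq: str) -> tuple[int, str]:
    # rotate an insertion at inter-base pos left through matching context
    while pos > 0 and ref[pos - 1] == seq[-1]:
        seq = seq[-1] + seq[:-1]
        pos -= 1
    return pos, seq


def call_indels(
    aln: AlignmentResult, cut: int, window: int = 5
) -> list[IndelEvent]:
    """Gap runs as events, left-aligned, kept if they touch the cut window.

    An event is retained when its reference footprint intersects
    ``[cut - window, cut + window]`` (deletions: base interval overlap;
    insertions: inter-base position within the closed interval).
    """
    ref_row, read_row = aln.aligned_ref, aln.aligned_read
    ref = ref_row.replace("-", "")
    events: list[IndelEvent] = []
    ref_pos = 0
    i = 0
    n = len(ref_row)
    while i < n:
        if ref_row[i] == "-":  # insertion relative to reference
            j = i
            while j < n and ref_row[j] == "-":
                j += 1
            seq = read_row[i:j]
            pos, seq = _left_align_insertion(ref, ref_pos, seq)
            events.append(
                IndelEvent(kind="insertion", ref_position=pos, length=j - i,
                           inserted_seq=seq)
            )
            i = j
        elif read_row[i] == "-":  # deletion relative to reference
            j = i
            while j < n and read_row[j] == "-":
                j += 1
            length = j - i
            start = _left_align_deletion(ref, ref_pos, length)
            events.append(
                IndelEvent(kind="deletion", ref_position=start, length=length)
            )
            ref_pos += length
            i = j
        else:
            ref_pos += 1
            i += 1

    lo, hi = cut - window, cut + window
    kept = []
    for ev in events:
        if ev.kind == "insertion":
            if lo <= ev.ref_position <= hi:
                kept.append(ev)
        else:
            if ev.ref_position < hi and ev.ref_position + ev.length > lo:
                kept.append(ev)
    return kept


def type_mutation_read(
    events: Iterable[IndelEvent],
) -> Literal["insertion", "deletion", "complex", "none"]:
    """Per-read outcome type from its cut-window events."""
    has_ins = any(ev.kind == "insertion" for ev in events)
    has_del = any(ev.kind == "deletion" for ev in events)
    if has_ins and has_del:
        return "complex"
    if has_ins:
        return "insertion"
    if has_del:
        return "deletion"
    return "none"


def n4_base(target: GenomeTarget) -> str:
    """The protospacer-strand base 4 positions 5' of the PAM.

    This is protospacer position 17 (1-based) — the base immediately 5'
    of the blunt cut, and the template of the canonical 1-bp insertion.
    """
    return target.protospacer[16]


def _n4_in_reference(target: GenomeTarget) -> str:
    """N4 expressed in reference-strand orientation, for comparing
    inserted bases called from reference-orientation alignments."""
    base = n4_base(target)
    return base if target.strand == "+" else revcomp(base)


def profile_target(
    mutation_reads: Iterable[CountedRead],
    target: GenomeTarget,
    window: int = 5,
    **align_kwargs,
) -> MutationProfile:
    """Count-weighted indel typing of dsODN-free mutation reads.

    ``insertion_fraction`` is computed over insertion+deletion reads
    (complex reads excluded, reported separately); among 1-bp insertions
    the inserted base is compared to N4, strand-resolved.
    """
    geom = compute_cut_site(target)
    profile = MutationProfile(target=target.name, n4=n4_base(target))
    n4_ref = _n4_in_reference(target)
    for read in mutation_reads:
        aln = align_global(read.sequence, target.reference, **align_kwargs)
        events = call_indels(aln, geom.cut, window=window)
        kind = type_mutation_read(events)
        profile.n_mut_reads += read.count
        if kind == "insertion":
            profile.n_insertion_reads += read.count
            ins = [ev for ev in events if ev.kind == "insertion"]
            if len(ins) == 1 and ins[0].length == 1:
                profile.one_bp_insertion_count += read.count
                if ins[0].inserted_seq == n4_ref:
                    profile.n4_match_count += read.count
        elif kind == "deletion":
            profile.n_deletion_reads += read.count
        elif kind == "complex":
            profile.n_complex_reads += read.count
        else:
            profile.n_none_reads += read.count
    return profile


def write_profile_table(path, profiles: Iterable[MutationProfile]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "target\tn_mut_reads\tn_insertion\tn_deletion\tn_complex\tn_none\t"
            "insertion_fraction\tn4_base\tone_bp_insertions\tn4_fraction\n"
        )
        for p in profiles:
            insf = "NA" if p.insertion_fraction is None else f"{p.insertion_fraction:.6f}"
            n4f = "NA" if p.n4_fraction is None else f"{p.n4_fraction:.6f}"
            fh.write(
                f"{p.target}\t{p.n_mut_reads}\t{p.n_insertion_reads}\t"
                f"{p.n_deletion_reads}\t{p.n_complex_reads}\t{p.n_none_reads}\t"
                f"{insf}\t{p.n4}\t{p.one_bp_insertion_count}\t{n4f}\n"
            )
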