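"""Read preparation: pair merging, duplicate collapsing, end selection.

Amplicon libraries are sequenced paired-end; R1 and R2 overlap on the
amplicon and are joined into a single merged sequence before analysis.
Merged reads are then collapsed to distinct sequences with multiplicities
(PCR duplicates), singleton sequences are dropped as likely artefacts,
and reads are assigned to a break end by exact match to that end's 12-nt
indicator.  All downstream frequencies are count-weighted.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from nhejacc.target_model import EndLabel, GenomeTarget, indicator_for_end, revcomp


@dataclass(frozen=True)
class RawReadPair:
    """One paired-end read: R2 reverse-complements onto R1's 3' end."""

    id: str
    r1: str
    q1: str
    r2: str
    q2: str

    def __post_init__(self) -> None:
        if len(self.r1) != len(self.q1) or len(self.r2) != len(self.q2):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class MergedRead:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty merged read")


@dataclass(frozen=True)
class CountedRead:
    """A distinct merged sequence and its multiplicity in the pool."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


def merge_pair(
    pair: RawReadPair,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> MergedRead | None:
    """Join a read pair by its best ungapped 3' overlap.

    Scans all overlap lengths, keeps candidates of length >= ``min_overlap``
    whose mismatch fraction is <= ``max_mismatch_frac``, and takes the one
    with the most matching bases (ties: the longer overlap).  Disagreeing
    overlap positions are resolved by the higher-quality base (R1 wins
    ties).  Returns ``None`` when no acceptable overlap exists — a normal,
    counted outcome, not an error.
    """
    s1, q1 = pair.r1, pair.q1
    s2, q2 = revcomp(pair.r2), pair.q2[::-1]
    best = None  # (matches, overlap_len)
    max_olap = min(len(s1), len(s2))
    for olap in range(min_overlap, max_olap + 1):
        a, b = s1[len(s1) - olap :], s2[:olap]
        mism = sum(x != y for x, y in zip(a, b))
        if mism / olap > max_mismatch_frac:
            continue
        cand = (olap - mism, olap)
        if best is None or cand > best[:2]:
            best = (olap - mism, olap)
    if best is None:
        return None
    olap = best[1]
    head = s1[: len(s1) - olap]
    tail = s2[olap:]
    consensus = []
    for i in range(olap):
        c1, c2 = s1[len(s1) - olap + i], s2[i]
        if c1 == c2:
            consensus.append(c1)
        else:
            p1, p2 = q1[len(s1) - olap + i], q2[i]
            consensus.append(c1 if p1 >= p2 else c2)
    return MergedRead(id=pair.id, sequence=head + "".join(consensus) + tail)


def merge_pool(
    pairs: Iterable[RawReadPair],
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> tuple[list[MergedRead], int]:
    """Merge a pool of pairs; returns (merged reads, number unmerged)."""
    merged, unmerged = [], 0
    for pair in pairs:
        m = merge_pair(pair, min_overlap, max_mismatch_frac)
        if m is None:
            unmerged += 1
        else:
            merged.append(m)
    return merged, unmerged


def collapse_duplicates(reads: Iterable[MergedRead | str]) -> list[CountedRead]:
    """One CountedRead per distinct sequence; counts sum to the input size.

    Output order: descending count, then lexicographic (deterministic).
    """
    counts: dict[str, int] = {}
    for r in reads:
        seq = r if isinstance(r, str) else r.sequence
        counts[seq] = counts.get(seq, 0) + 1
    return [
        CountedRead(sequence=s, count=c)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def filter_singletons(
    reads: Iterable[CountedRead], min_count: int = 2
) -> list[CountedRead]:
    """Drop distinct sequences seen fewer than ``min_count`` times."""
    return [r for r in reads if r.count >= min_count]


def _hamming_contains(read: str, probe: str, max_mismatch: int) -> bool:
    if max_mismatch == 0:
        return probe in read
    n, m = len(read), len(probe)
    for i in range(n - m + 1):
        mism = 0
        for a, b in zip(read[i : i + m], probe):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return True
    return False


def select_by_indicator(
    reads: Iterable[CountedRead],
    target: GenomeTarget,
    end: EndLabel,
    offset: int = 70,
    length: int = 12,
    max_mismatch: int = 0,
) -> list[CountedRead]:
    """Reads spanning a break end: exact indicator match, either strand.

    Reverse-complement hits are canonicalised to the reference orientation
    before return, so downstream marker searches are single-stranded.
    """
    indicator = indicator_for_end(target, end, offset=offset, length=length)
    out = []
    for r in reads:
        if _hamming_contains(r.sequence, indicator, max_mismatch):
            out.append(r)
        elif _hamming_contains(revcomp(r.sequence), indicator, max_mismatch):
            out.append(CountedRead(sequence=revcomp(r.sequence), count=r.count))
    return out


# ---------------------------------------------------------------------------
# FASTQ IO (plain or gzipped)


def _open(path: str | Path, mode: str = "rt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) records from a FASTQ file."""
    with _open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            yield header.strip()[1:].split()[0], seq.upper(), qual


def read_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[RawReadPair]:
    for (i1, s1, q1), (i2, s2, q2) in zip(read_fastq(r1_path), read_fastq(r2_path)):
        yield RawReadPair(id=i1, r1=s1, q1=q1, r2=s2, q2=q2)


def read_merged(path: str | Path) -> list[MergedRead]:
    """Read pre-merged single-end FASTQ (skips the joining step)."""
    return [MergedRead(id=i, sequence=s) for i, s, _ in read_fastq(path)]


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    with _open(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_count_table(path: str | Path, reads: Iterable[CountedRead]) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for r in reads:
            fh.write(f"{r.sequence}\t{r.count}\n")
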