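"""Locus geometry for a single SpCas9 target.

Everything downstream — read selection, wild-type detection, junction
accuracy — is driven by a handful of short reference substrings derived
here from the target definition: the blunt cut site (3 nt 5' of the NGG
PAM on the protospacer strand), a 12-nt *indicator* on each side of the
cut used to select reads spanning that break end, a 10-nt *WT marker*
straddling the cut whose intact presence identifies an uncut or perfectly
restored allele, and the 10-nt genomic *junction flanks* that must abut
the integrated dsODN tag in an accurately repaired read.

Coordinates are 0-based and half-open throughout.  The cut is an
inter-base position ``cut``: the phosphodiester bond between
``reference[cut-1]`` and ``reference[cut]``.  Break ends are always
referred to by :class:`EndLabel` (PAM-distal / PAM-proximal); the mapping
to the left/right side of the reference depends on the protospacer strand
and is resolved by :class:`CutGeometry`.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

_DNA_RE = re.compile(r"^[ACGT]+$")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PROTOSPACER_LEN = 20
#: distance (nt) from the PAM-proximal protospacer boundary to the blunt cut
CUT_OFFSET_FROM_PAM = 3


class TargetError(ValueError):
    """Invalid or ambiguous target definition."""


class GeometryError(ValueError):
    """A requested window falls outside the reference."""


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


class Side(str, enum.Enum):
    """Side of the cut in reference coordinates."""

    LEFT = "left"
    RIGHT = "right"

    @property
    def other(self) -> "Side":
        return Side.RIGHT if self is Side.LEFT else Side.LEFT


class EndLabel(str, enum.Enum):
    """The two DSB ends, named relative to the PAM."""

    PAM_DISTAL = "PAM_distal"
    PAM_PROXIMAL = "PAM_proximal"


@dataclass(frozen=True)
class GenomeTarget:
    """A locus definition: amplicon reference plus protospacer placement.

    ``protospacer_start`` is the 0-based offset of the protospacer's
    footprint in the reference (its leftmost base in reference
    coordinates, for either strand).  For a ``-`` strand target the
    protospacer sequence equals the reverse complement of
    ``reference[start:start+20]`` and the PAM footprint lies immediately
    to the *left* of the protospacer footprint.
    """

    name: str
    reference: str
    protospacer: str
    strand: str
    protospacer_start: int = field(default=-1)

    def __post_init__(self) -> None:
        if not _DNA_RE.match(self.reference):
            raise TargetError(f"{self.name}: reference must be uppercase ACGT")
        if len(self.protospacer) != PROTOSPACER_LEN or not _DNA_RE.match(
            self.protospacer
        ):
            raise TargetError(
                f"{self.name}: protospacer must be {PROTOSPACER_LEN} nt of ACGT"
            )
        if self.strand not in ("+", "-"):
            raise TargetError(f"{self.name}: strand must be '+' or '-'")
        if self.protospacer_start < 0:
            object.__setattr__(self, "protospacer_start", self._locate())
        self._validate_placement()

    def _locate(self) -> int:
        footprint = (
            self.protospacer if self.strand == "+" else revcomp(self.protospacer)
        )
        hits = [
            m.start()
            for m in re.finditer(f"(?={re.escape(footprint)})", self.reference)
        ]
        if len(hits) != 1:
            raise TargetError(
                f"{self.name}: protospacer occurs {len(hits)} times in the "
                "reference on the stated strand (must be exactly once)"
            )
        return hits[0]

    def _validate_placement(self) -> None:
        s = self.protospacer_start
        footprint = (
            self.protospacer if self.strand == "+" else revcomp(self.protospacer)
        )
        if self.reference[s : s + PROTOSPACER_LEN] != footprint:
            raise TargetError(f"{self.name}: protospacer_start does not match")
        pam = self.pam
        if len(pam) != 3 or pam[1:] != "GG":
            raise TargetError(f"{self.name}: PAM {pam!r} does not match NGG")

    @property
    def pam(self) -> str:
        """The 3-nt PAM in protospacer-strand orientation."""
        s = self.protospacer_start
        if self.strand == "+":
            pam = self.reference[s + PROTOSPACER_LEN : s + PROTOSPACER_LEN + 3]
        else:
            pam = revcomp(self.reference[s - 3 : s])
        if len(pam) != 3:
            raise TargetError(f"{self.name}: PAM footprint outside reference")
        return pam


@dataclass(frozen=True)
class CutGeometry:
    """Blunt-cut position and end-to-side mapping for one target."""

    cut: int
    distal_side: Side
    proximal_side: Side

    def side_of(self, end: EndLabel) -> Side:
        return self.distal_side if end is EndLabel.PAM_DISTAL else self.proximal_side

    def end_of(self, side: Side) -> EndLabel:
        return EndLabel.PAM_DISTAL if side is self.distal_side else EndLabel.PAM_PROXIMAL


@dataclass(frozen=True)
class DsODNTag:
    """The double-stranded oligodeoxynucleotide tag captured at DSBs.

    The tag integrates in either orientation, so both ``sequence`` and its
    reverse complement are searched downstream.
    """

    sequence: str
    label: str = "dsODN"

    MIN_LENGTH = 20

    def __post_init__(self) -> None:
        if not _DNA_RE.match(self.sequence):
            raise TargetError(f"{self.label}: tag must be uppercase ACGT")
        if len(self.sequence) < self.MIN_LENGTH:
            raise TargetError(
                f"{self.label}: tag length {len(self.sequence)} < "
                f"{self.MIN_LENGTH}"
            )


def compute_cut_site(target: GenomeTarget) -> CutGeometry:
    """Blunt SpCas9 cut: 3 nt 5' of the PAM on the protospacer strand.

    Equivalently, the bond between protospacer positions 17|18 (1-based).
    The PAM-proximal side is the side of the cut carrying the PAM.
    """
    s = target.protospacer_start
    if target.strand == "+":
        cut = s + PROTOSPACER_LEN - CUT_OFFSET_FROM_PAM
        proximal = Side.RIGHT
    else:
        cut = s + CUT_OFFSET_FROM_PAM
        proximal = Side.LEFT
    return CutGeometry(cut=cut, distal_side=proximal.other, proximal_side=proximal)


def _side_window(
    reference: str, cut: int, side: Side, start_off: int, length: int
) -> str:
    """Reference window ``length`` nt whose near edge is ``start_off`` nt
    from the cut, on the given side."""
    if side is Side.LEFT:
        lo, hi = cut - start_off - length, cut - start_off
    else:
        lo, hi = cut + start_off, cut + start_off + length
    if lo < 0 or hi > len(reference):
        raise GeometryError(
            f"window [{lo}, {hi}) outside reference of length {len(reference)}"
        )
    return reference[lo:hi]


def indicator_for_end(
    target: GenomeTarget,
    end: EndLabel,
    offset: int = 70,
    length: int = 12,
) -> str:
    """12-nt reference indicator whose near edge is ``offset`` nt from the cut.

    Reads carrying this exact substring (either orientation) are taken to
    span the corresponding break end.
    """
    geom = compute_cut_site(target)
    return _side_window(target.reference, geom.cut, geom.side_of(end), offset, length)


def wt_marker(target: GenomeTarget, halfwidth: int = 5) -> str:
    """Reference window of ``halfwidth`` nt on each side of the cut.

    Present intact only in alleles whose cut-site region is unedited.
    """
    if halfwidth < 1:
        raise GeometryError("halfwidth must be >= 1")
    geom = compute_cut_site(target)
    cut, ref = geom.cut, target.reference
    if cut - halfwidth < 0 or cut + halfwidth > len(ref):
        raise GeometryError("WT marker window outside reference")
    return ref[cut - halfwidth : cut + halfwidth]


def junction_flanks(
    target: GenomeTarget, end: EndLabel, k: int = 10
) -> tuple[str, Side]:
    """The k-nt genomic flank that must abut the dsODN at this end.

    Returns the flank sequence and the side of the dsODN it abuts: the
    left-side flank (``reference[cut-k:cut]``) precedes the tag, the
    right-side flank (``reference[cut:cut+k]``) follows it.
    """
    if k < 1:
        raise GeometryError("flank length k must be >= 1")
    geom = compute_cut_site(target)
    side = geom.side_of(end)
    flank = _side_window(target.reference, geom.cut, side, 0, k)
    return flank, side


# ---------------------------------------------------------------------------
# target config IO


def load_targets(path: str | Path) -> list[GenomeTarget]:
    """Read target definitions from a YAML config.

    Each record needs ``name``, ``protospacer``, ``strand`` and either an
    inline ``reference`` sequence or a ``reference_fasta`` path (first
    record used unless ``reference_id`` names one).
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    records = doc["targets"] if isinstance(doc, dict) else doc
    targets = []
    for rec in records:
        if "reference" in rec:
            ref = rec["reference"].upper()
        else:
            fasta = path.parent / rec["reference_fasta"]
            seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta), "fasta")}
            ref = seqs[rec["reference_id"]] if "reference_id" in rec else next(
                iter(seqs.values())
            )
        targets.append(
            GenomeTarget(
                name=rec["name"],
                reference=ref,
                protospacer=rec["protospacer"].upper(),
                strand=rec.get("strand", "+"),
            )
        )
    return targets
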