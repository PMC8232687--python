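"""Read classification and junction-accuracy scoring.

Every selected read falls into exactly one of three classes, tested in
this order:

1. **wild_type** — the read contains the intact 10-nt WT marker spanning
   the cut; the locus was never cleaved (or was restored perfectly) and
   the read is excluded from all accuracy denominators.
2. **dsodn_inserted** — the read contains any contiguous 10-mer of the
   dsODN tag (either orientation); the break captured the tag, freezing
   the first repair event.
3. **mutation** — everything else: the cut-site region is altered but no
   tag integrated (NHEJ indel without capture).

For dsODN reads, repair accuracy is scored per break end: a junction is
*accurate* when the read contains, as one contiguous exact substring, the
10-nt genomic flank for that end immediately abutting the 10-nt terminal
segment of the (orientation-resolved) tag — i.e. zero inserted, deleted
or substituted bases across the 20-nt junction window.  NHEJ accuracy at
an end is the count-weighted fraction of accurate junctions among dsODN
reads assessable at that end.

Dual-guide precise deletions are scored analogously: a deletion-junction
read must join the two cut sites' outer flanks exactly (5 nt each side).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from nhejacc.read_processing import CountedRead
from nhejacc.target_model import (
    CutGeometry,
    DsODNTag,
    EndLabel,
    GenomeTarget,
    Side,
    compute_cut_site,
    indicator_for_end,
    junction_flanks,
    revcomp,
    wt_marker,
)


class ReadClass(str, enum.Enum):
    WILD_TYPE = "wild_type"
    DSODN_INSERTED = "dsodn_inserted"
    MUTATION = "mutation"


class Orientation(str, enum.Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


@dataclass(frozen=True)
class JunctionCall:
    end: EndLabel
    accurate: bool
    dsodn_orientation: Orientation


@dataclass(frozen=True)
class ClassifiedRead:
    read: CountedRead
    cls: ReadClass
    junctions: tuple[JunctionCall, ...] = ()

    def __post_init__(self) -> None:
        if self.cls is not ReadClass.DSODN_INSERTED and self.junctions:
            raise ValueError("only dsODN-inserted reads carry junction calls")

    def junction(self, end: EndLabel) -> JunctionCall | None:
        for j in self.junctions:
            if j.end is end:
                return j
        return None


@dataclass
class AccuracySummary:
    """Count-weighted per-target tallies and per-end accuracy fractions.

    ``accuracy[end]`` uses dsODN reads *assessable* at that end (those
    selected by the end's indicator) as the denominator;
    ``accuracy_all_dsodn[end]`` uses all dsODN reads.  Undefined fractions
    (zero denominator) are ``None``, never 0.
    """

    target: str
    n_total: int = 0
    n_wt: int = 0
    n_dsodn: int = 0
    n_mutation: int = 0
    n_assessable: dict[EndLabel, int] = field(default_factory=dict)
    n_accurate: dict[EndLabel, int] = field(default_factory=dict)

    @property
    def accuracy(self) -> dict[EndLabel, float | None]:
        return {
            end: (self.n_accurate.get(end, 0) / n if n else None)
            for end, n in (
                (e, self.n_assessable.get(e, 0)) for e in EndLabel
            )
        }

    @property
    def accuracy_all_dsodn(self) -> dict[EndLabel, float | None]:
        return {
            end: (self.n_accurate.get(end, 0) / self.n_dsodn if self.n_dsodn else None)
            for end in EndLabel
        }


class ContractError(RuntimeError):
    """An operation was called outside its stated precondition."""


def detect_dsodn(
    read: CountedRead | str, tag: DsODNTag, k: int = 10
) -> Orientation | None:
    """Is any contiguous k-mer of the tag (either orientation) in the read?

    Returns the matching orientation (forward preferred on ties) or
    ``None`` when absent.
    """
    if len(tag.sequence) < k:
        raise ContractError(f"tag shorter than k={k}")
    seq = read if isinstance(read, str) else read.sequence
    fwd = tag.sequence
    for probe, orient in ((fwd, Orientation.FORWARD), (revcomp(fwd), Orientation.REVERSE)):
        if any(probe[i : i + k] in seq for i in range(len(probe) - k + 1)):
            return orient
    return None


def classify_read(
    read: CountedRead,
    target: GenomeTarget,
    tag: DsODNTag,
    marker_halfwidth: int = 5,
    k: int = 10,
) -> ClassifiedRead:
    """Assign the read class with precedence WT > dsODN-inserted > mutation.

    Junction calls are attached separately (:func:`assess_junction` /
    :func:`classify_pool`); this function decides the class only.
    """
    if wt_marker(target, marker_halfwidth) in read.sequence:
        return ClassifiedRead(read=read, cls=ReadClass.WILD_TYPE)
    if detect_dsodn(read, tag, k=k) is not None:
        return ClassifiedRead(read=read, cls=ReadClass.DSODN_INSERTED)
    return ClassifiedRead(read=read, cls=ReadClass.MUTATION)


def _junction_window(
    target: GenomeTarget, tag: DsODNTag, end: EndLabel, orientation: Orientation, k: int
) -> str:
    """The 2k-nt window: genomic flank abutting the tag's terminal k-mer."""
    flank, side = junction_flanks(target, end, k=k)
    tag_seq = tag.sequence if orientation is Orientation.FORWARD else revcomp(tag.sequence)
    if side is Side.LEFT:
        return flank + tag_seq[:k]
    return tag_seq[-k:] + flank


def assess_junction(
    read: ClassifiedRead,
    target: GenomeTarget,
    tag: DsODNTag,
    end: EndLabel,
    k: int = 10,
) -> JunctionCall:
    """Score one genomic-DNA/dsODN junction of a dsODN-inserted read.

    Accurate iff the exact 2k-nt junction window for this end (resolved to
    the read's tag orientation) occurs contiguously in the read.
    """
    if read.cls is not ReadClass.DSODN_INSERTED:
        raise ContractError("junctions are defined only for dsODN-inserted reads")
    orientation = detect_dsodn(read.read, tag, k=k)
    if orientation is None:
        raise ContractError("read does not contain the tag")
    window = _junction_window(target, tag, end, orientation, k)
    return JunctionCall(
        end=end,
        accurate=window in read.read.sequence,
        dsodn_orientation=orientation,
    )


def classify_pool(
    reads_by_end: dict[EndLabel, list[CountedRead]],
    target: GenomeTarget,
    tag: DsODNTag,
    marker_halfwidth: int = 5,
    k: int = 10,
) -> tuple[list[ClassifiedRead], AccuracySummary]:
    """Classify indicator-selected reads and tally per-end accuracy.

    ``reads_by_end`` maps each break end to the reads selected by its
    indicator (one read may appear under both ends; it is counted once in
    the class tallies and assessed at every end that selected it).
    """
    summary = AccuracySummary(target=target.name)
    calls: dict[str, ClassifiedRead] = {}
    counted: set[str] = set()
    for end, reads in reads_by_end.items():
        for read in reads:
            key = read.sequence
            if key not in calls:
                base = classify_read(read, target, tag, marker_halfwidth, k)
                calls[key] = base
            cr = calls[key]
            if key not in counted:
                counted.add(key)
                summary.n_total += cr.read.count
                if cr.cls is ReadClass.WILD_TYPE:
                    summary.n_wt += cr.read.count
                elif cr.cls is ReadClass.DSODN_INSERTED:
                    summary.n_dsodn += cr.read.count
                else:
                    summary.n_mutation += cr.read.count
            if cr.cls is ReadClass.DSODN_INSERTED:
                call = assess_junction(cr, target, tag, end, k=k)
                calls[key] = ClassifiedRead(
                    read=cr.read, cls=cr.cls, junctions=cr.junctions + (call,)
                )
                summary.n_assessable[end] = (
                    summary.n_assessable.get(end, 0) + cr.read.count
                )
                if call.accurate:
                    summary.n_accurate[end] = (
                        summary.n_accurate.get(end, 0) + cr.read.count
                    )
    return list(calls.values()), summary


def summarize_accuracy(
    reads: list[ClassifiedRead], target: GenomeTarget | str
) -> AccuracySummary:
    """Tally classified reads that already carry junction calls."""
    name = target if isinstance(target, str) else target.name
    summary = AccuracySummary(target=name)
    for cr in reads:
        summary.n_total += cr.read.count
        if cr.cls is ReadClass.WILD_TYPE:
            summary.n_wt += cr.read.count
        elif cr.cls is ReadClass.MUTATION:
            summary.n_mutation += cr.read.count
        else:
            summary.n_dsodn += cr.read.count
            for call in cr.junctions:
                summary.n_assessable[call.end] = (
                    summary.n_assessable.get(call.end, 0) + cr.read.count
                )
                if call.accurate:
                    summary.n_accurate[call.end] = (
                        summary.n_accurate.get(call.end, 0) + cr.read.count
                    )
    return summary


# ---------------------------------------------------------------------------
# dual-guide precise deletion


class DualConfiguration(str, enum.Enum):
    PAM_IN = "PAM_in"
    PAM_OUT = "PAM_out"
    PAM_IN_OUT = "PAM_in_out"


@dataclass(frozen=True)
class DualCutDesign:
    """Two cuts on one shared reference; the segment between is deleted.

    The retained ends are the left side of the left cut (site_a) and the
    right side of the right cut (site_b); the configuration records
    whether those retained ends are PAM-distal (PAM-in), PAM-proximal
    (PAM-out) or mixed.
    """

    site_a: GenomeTarget
    site_b: GenomeTarget
    marker_halfwidth: int = 5

    def __post_init__(self) -> None:
        if self.site_a.reference != self.site_b.reference:
            raise ValueError("dual-cut sites must share one reference")
        if self.geometry_a.cut >= self.geometry_b.cut:
            raise ValueError("site_a's cut must lie left of site_b's cut")

    @property
    def geometry_a(self) -> CutGeometry:
        return compute_cut_site(self.site_a)

    @property
    def geometry_b(self) -> CutGeometry:
        return compute_cut_site(self.site_b)

    @property
    def configuration(self) -> DualConfiguration:
        a_distal = self.geometry_a.distal_side is Side.LEFT
        b_distal = self.geometry_b.distal_side is Side.RIGHT
        if a_distal and b_distal:
            return DualConfiguration.PAM_IN
        if not a_distal and not b_distal:
            return DualConfiguration.PAM_OUT
        return DualConfiguration.PAM_IN_OUT

    @property
    def precise_junction(self) -> str:
        """The 2*halfwidth marker present only in a precise deletion."""
        ref, h = self.site_a.reference, self.marker_halfwidth
        cut_a, cut_b = self.geometry_a.cut, self.geometry_b.cut
        return ref[cut_a - h : cut_a] + ref[cut_b : cut_b + h]


def assess_dual_deletion(
    reads: list[CountedRead],
    design: DualCutDesign,
    indicator_offset: int = 70,
    indicator_length: int = 12,
) -> tuple[int, int, float | None]:
    """Score precise excision between two cuts.

    A read is a deletion-junction read iff it contains both outer
    indicators (left of cut_a, right of cut_b) and lacks both cuts' WT
    markers; it is accurate iff it contains the two cut sites' outer
    5-nt flanks joined as one contiguous exact substring.  Returns
    ``(n_junction_reads, n_accurate, accuracy)`` count-weighted;
    accuracy is ``None`` when no junction reads exist.
    """
    ref = design.site_a.reference
    cut_a, cut_b = design.geometry_a.cut, design.geometry_b.cut
    L, h = indicator_length, design.marker_halfwidth
    off = indicator_offset
    left_ind = ref[cut_a - off - L : cut_a - off]
    right_ind = ref[cut_b + off : cut_b + off + L]
    if len(left_ind) != L or len(right_ind) != L:
        raise ValueError("indicator windows outside reference")
    wt_a = ref[cut_a - h : cut_a + h]
    wt_b = ref[cut_b - h : cut_b + h]
    joint = design.precise_junction

    n_junction = n_accurate = 0
    for read in reads:
        seq = read.sequence
        if left_ind not in seq and left_ind in revcomp(seq):
            seq = revcomp(seq)
        if left_ind not in seq or right_ind not in seq:
            continue
        if wt_a in seq or wt_b in seq:
            continue
        n_junction += read.count
        if joint in seq:
            n_accurate += read.count
    accuracy = n_accurate / n_junction if n_junction else None
    return n_junction, n_accurate, accuracy


def write_classification_table(path, reads: list[ClassifiedRead]) -> None:
    """Per-read TSV: sequence, count, class, per-end calls, orientation."""
    with open(path, "w") as fh:
        fh.write(
            "sequence\tcount\tclass\tdistal_accurate\tproximal_accurate\torientation\n"
        )
        for cr in reads:
            jd = cr.junction(EndLabel.PAM_DISTAL)
            jp = cr.junction(EndLabel.PAM_PROXIMAL)
            orient = (jd or jp).dsodn_orientation.value if (jd or jp) else "NA"
            fh.write(
                f"{cr.read.sequence}\t{cr.read.count}\t{cr.cls.value}\t"
                f"{jd.accurate if jd else 'NA'}\t{jp.accurate if jp else 'NA'}\t"
                f"{orient}\n"
            )
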