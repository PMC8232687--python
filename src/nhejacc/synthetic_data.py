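"""Seeded amplicon-read simulator with a ground-truth table.

The simulator emulates merged amplicon pools from a dsODN-capture
experiment at one Cas9 target: wild-type alleles, dsODN integrations
whose two genomic-DNA/tag junctions are independently accurate or carry
a small indel, tag-free NHEJ indel outcomes with a controllable
insertion:deletion balance and N4-templated 1-bp insertions, plus
off-target junk.  PCR-duplicate structure is modelled by replicating
each allele to a drawn multiplicity; per-base substitution sequencing
error is applied independently to every copy, so most error-bearing
copies become singletons — which is exactly what the pipeline's
duplicate-collapse + singleton-removal step is there to remove.

Everything is driven by a single integer seed; identical seeds give
byte-identical output.  A truth table records one row per generated
allele with its class, per-end junction accuracy, event description and
multiplicity (multiplicities sum to ``n_reads`` exactly; class totals
are an exact multinomial draw at ``n_reads``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from nhejacc.classification import DualCutDesign
from nhejacc.read_processing import write_fastq
from nhejacc.target_model import (
    DsODNTag,
    EndLabel,
    GenomeTarget,
    Side,
    compute_cut_site,
    revcomp,
)

BASES = "ACGT"

#: synthetic 34-nt dsODN used throughout the simulations; constructed to
#: avoid long runs so random references essentially never share a 10-mer
DEFAULT_TAG = DsODNTag(sequence="GTTGTCATAGCGTCCTAACGGACTTCAGGTCGCA", label="synthetic-dsODN")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated target pool.

    Defaults mirror a deep-sequenced dsODN-capture amplicon experiment:
    per-end junction accuracies at the reported HEK 293T means (0.7418
    PAM-distal, 0.3862 PAM-proximal), a read pool dominated by unedited
    alleles, Illumina-like 1e-3 per-base substitution error, and PCR
    multiplicities of 1-5 copies per allele.
    """

    target: GenomeTarget
    tag: DsODNTag = DEFAULT_TAG
    n_reads: int = 20_000
    f_wt: float = 0.60
    f_dsodn: float = 0.25
    f_mut: float = 0.13
    p_acc_distal: float = 0.7418
    p_acc_proximal: float = 0.3862
    p_tag_reverse: float = 0.5
    mut_insertion_fraction: float = 0.5
    p_n4_identity: float = 0.9
    insertion_length_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.90, 2: 0.07, 3: 0.03}
    )
    deletion_length_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.30, 2: 0.20, 3: 0.15, 4: 0.10, 5: 0.10,
                                 6: 0.05, 7: 0.05, 8: 0.03, 9: 0.01, 10: 0.01}
    )
    junction_error_lengths: dict[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.20, 3: 0.15, 4: 0.10, 5: 0.05,
                                 6: 0.04, 7: 0.03, 8: 0.01, 9: 0.01, 10: 0.01}
    )
    subst_error_rate: float = 1e-3
    duplicate_multiplicity_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.15, 2: 0.30, 3: 0.25, 4: 0.20, 5: 0.10}
    )
    paired_mode: bool = False
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = dict(
            f_wt=self.f_wt, f_dsodn=self.f_dsodn, f_mut=self.f_mut,
            p_acc_distal=self.p_acc_distal, p_acc_proximal=self.p_acc_proximal,
            p_tag_reverse=self.p_tag_reverse,
            mut_insertion_fraction=self.mut_insertion_fraction,
            p_n4_identity=self.p_n4_identity,
            subst_error_rate=self.subst_error_rate,
        )
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.f_wt + self.f_dsodn + self.f_mut > 1.0 + 1e-9:
            raise ValueError("f_wt + f_dsodn + f_mut must be <= 1")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        for dist in (
            self.insertion_length_distribution,
            self.deletion_length_distribution,
            self.junction_error_lengths,
            self.duplicate_multiplicity_distribution,
        ):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("categorical distributions must sum to 1")

    @property
    def f_junk(self) -> float:
        return max(0.0, 1.0 - self.f_wt - self.f_dsodn - self.f_mut)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one distinct generated allele."""

    allele_id: str
    cls: str  # wild_type | dsodn_inserted | mutation | junk | deletion_junction
    multiplicity: int
    distal_accurate: bool | None = None
    proximal_accurate: bool | None = None
    orientation: str | None = None
    event_kind: str | None = None  # insertion | deletion
    event_length: int | None = None
    event_position: int | None = None
    inserted_seq: str | None = None


def _draw_categorical(rng: np.random.Generator, dist: dict[int, float]) -> int:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=probs / probs.sum()))


def random_reference(
    rng: np.random.Generator, length: int = 200, max_homopolymer: int = 3
) -> str:
    """Random ACGT sequence with homopolymer runs capped.

    Capping runs keeps indel left-alignment shifts small, so simulated
    events near the cut stay inside the calling window.
    """
    out: list[str] = []
    while len(out) < length:
        b = BASES[rng.integers(4)]
        run = len(out) >= max_homopolymer and all(
            x == b for x in out[-max_homopolymer:]
        )
        if not run:
            out.append(b)
    return "".join(out)


def make_synthetic_target(
    rng: np.random.Generator,
    name: str = "synthetic",
    length: int = 220,
    protospacer_start: int = 90,
    strand: str = "+",
    tag: DsODNTag = DEFAULT_TAG,
) -> GenomeTarget:
    """A random amplicon target with a valid NGG PAM and unique protospacer.

    Rejection-samples until the protospacer is unique in the reference and
    the reference shares no 10-mer with the tag (either orientation), so
    tag detection can never fire on unedited sequence.
    """
    tag_kmers = {
        s[i : i + 10]
        for s in (tag.sequence, revcomp(tag.sequence))
        for i in range(len(s) - 9)
    }
    for _ in range(200):
        ref = list(random_reference(rng, length))
        if strand == "+":
            pam_at = protospacer_start + 20
            ref[pam_at + 1] = "G"
            ref[pam_at + 2] = "G"
        else:
            ref[protospacer_start - 3] = "C"
            ref[protospacer_start - 2] = "C"
        ref_s = "".join(ref)
        if any(ref_s[i : i + 10] in tag_kmers for i in range(len(ref_s) - 9)):
            continue
        footprint = ref_s[protospacer_start : protospacer_start + 20]
        proto = footprint if strand == "+" else revcomp(footprint)
        try:
            return GenomeTarget(
                name=name, reference=ref_s, protospacer=proto, strand=strand
            )
        except ValueError:
            continue
    raise RuntimeError("could not construct a synthetic target")


def _apply_subst_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(4, size=length))


def _junction_error(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    genomic: str,
    tag_seq: str,
    side: Side,
) -> tuple[str, str, str | None]:
    """Apply one small indel at a genomic/tag junction.

    ``side`` is the side of the cut the genomic segment sits on.  Returns
    (genomic, tag_seq, insert) where ``insert`` is an inserted spacer
    sequence (or None).  Tag-side deletions are capped so at least one
    intact 10-mer of the tag always survives.
    """
    length = _draw_categorical(rng, cfg.junction_error_lengths)
    mode = rng.choice(["del_genomic", "del_tag", "insert"])
    if mode == "insert":
        return genomic, tag_seq, _random_seq(rng, length)
    if mode == "del_genomic":
        if side is Side.LEFT:
            return genomic[:-length], tag_seq, None
        return genomic[length:], tag_seq, None
    cap = min(length, max(1, (len(tag_seq) - 14) // 2))
    if side is Side.LEFT:  # genomic left of cut abuts the tag's 5' end
        return genomic, tag_seq[cap:], None
    return genomic, tag_seq[:-cap], None


def _build_dsodn_allele(
    rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[str, dict]:
    target, tag = cfg.target, cfg.tag
    geom = compute_cut_site(target)
    cut = geom.cut
    ref = target.reference
    reverse = rng.random() < cfg.p_tag_reverse
    tag_seq = revcomp(tag.sequence) if reverse else tag.sequence

    acc = {
        EndLabel.PAM_DISTAL: rng.random() < cfg.p_acc_distal,
        EndLabel.PAM_PROXIMAL: rng.random() < cfg.p_acc_proximal,
    }
    left_end = geom.end_of(Side.LEFT)
    right_end = geom.end_of(Side.RIGHT)

    left, right = ref[:cut], ref[cut:]
    left_ins = right_ins = ""
    if not acc[left_end]:
        left, tag_seq, ins = _junction_error(rng, cfg, left, tag_seq, Side.LEFT)
        left_ins = ins or ""
    if not acc[right_end]:
        right, tag_seq, ins = _junction_error(rng, cfg, right, tag_seq, Side.RIGHT)
        right_ins = ins or ""
    seq = left + left_ins + tag_seq + right_ins + right
    truth = dict(
        distal_accurate=acc[EndLabel.PAM_DISTAL],
        proximal_accurate=acc[EndLabel.PAM_PROXIMAL],
        orientation="reverse" if reverse else "forward",
    )
    return seq, truth


def _build_mutation_allele(
    rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[str, dict]:
    target = cfg.target
    cut = compute_cut_site(target).cut
    ref = target.reference
    if rng.random() < cfg.mut_insertion_fraction:
        length = _draw_categorical(rng, cfg.insertion_length_distribution)
        if length == 1:
            n4_ref = ref[cut - 1] if target.strand == "+" else ref[cut]
            if rng.random() < cfg.p_n4_identity:
                ins = n4_ref
            else:
                ins = BASES.replace(n4_ref, "")[rng.integers(3)]
        else:
            ins = _random_seq(rng, length)
        seq = ref[:cut] + ins + ref[cut:]
        truth = dict(event_kind="insertion", event_length=length,
                     event_position=cut, inserted_seq=ins)
    else:
        length = _draw_categorical(rng, cfg.deletion_length_distribution)
        start = cut - int(rng.integers(0, length + 1))  # deletion covers the cut
        start = max(0, min(start, len(ref) - length))
        seq = ref[:start] + ref[start + length :]
        truth = dict(event_kind="deletion", event_length=length,
                     event_position=start)
    return seq, truth


def simulate_pool(
    cfg: SimulationConfig,
) -> tuple[list[tuple[str, str, str]], list[TruthRecord]]:
    """Simulate one merged-read pool (or R1/R2 pairs in paired mode).

    Returns FASTQ records ``(id, sequence, quality)`` — in paired mode,
    interleaved R1/R2 records with ``/1`` and ``/2`` suffixes — plus the
    allele-level truth table.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    probs = [cfg.f_wt, cfg.f_dsodn, cfg.f_mut, cfg.f_junk]
    class_totals = rng.multinomial(cfg.n_reads, probs)
    classes = ("wild_type", "dsodn_inserted", "mutation", "junk")

    records: list[tuple[str, str, str]] = []
    truth: list[TruthRecord] = []
    allele_i = 0
    for cls, total in zip(classes, class_totals):
        remaining = int(total)
        while remaining > 0:
            mult = min(
                _draw_categorical(rng, cfg.duplicate_multiplicity_distribution),
                remaining,
            )
            remaining -= mult
            extra: dict = {}
            if cls == "wild_type":
                seq = cfg.target.reference
            elif cls == "dsodn_inserted":
                seq, extra = _build_dsodn_allele(rng, cfg)
            elif cls == "mutation":
                seq, extra = _build_mutation_allele(rng, cfg)
            else:
                seq = _random_seq(rng, len(cfg.target.reference))
            allele_id = f"allele{allele_i:06d}"
            allele_i += 1
            truth.append(TruthRecord(allele_id=allele_id, cls=cls,
                                     multiplicity=mult, **extra))
            for copy in range(mult):
                read = _apply_subst_errors(rng, seq, cfg.subst_error_rate)
                rid = f"{allele_id}_copy{copy}"
                if cfg.paired_mode:
                    rl = min(cfg.read_length, len(read))
                    r1, r2 = read[:rl], revcomp(read[-rl:])
                    records.append((rid + "/1", r1, "I" * len(r1)))
                    records.append((rid + "/2", r2, "I" * len(r2)))
                else:
                    records.append((rid, read, "I" * len(read)))
    return records, truth


def simulate_dual_pool(
    design: DualCutDesign,
    n_reads: int = 10_000,
    p_precise: float = 0.7,
    f_deletion: float = 0.5,
    f_wt: float = 0.3,
    f_single_indel: float = 0.15,
    subst_error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], list[TruthRecord]]:
    """Simulate a dual-guide deletion pool on one shared reference.

    Deletion-junction reads join the two cut sites, precisely with
    probability ``p_precise`` (imprecise joints lose or gain 1-10 nt);
    the remainder are wild-type, single-cut indel contaminants, and junk.
    """
    if not 0.0 <= p_precise <= 1.0:
        raise ValueError("p_precise outside [0, 1]")
    if f_deletion + f_wt + f_single_indel > 1.0 + 1e-9:
        raise ValueError("class fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    ref = design.site_a.reference
    cut_a, cut_b = design.geometry_a.cut, design.geometry_b.cut
    f_junk = max(0.0, 1.0 - f_deletion - f_wt - f_single_indel)
    totals = rng.multinomial(n_reads, [f_deletion, f_wt, f_single_indel, f_junk])
    classes = ("deletion_junction", "wild_type", "single_cut_indel", "junk")

    records: list[tuple[str, str, str]] = []
    truth: list[TruthRecord] = []
    for i, (cls, total) in enumerate(zip(classes, totals)):
        for j in range(int(total)):
            extra: dict = {}
            if cls == "deletion_junction":
                precise = rng.random() < p_precise
                left, right = ref[:cut_a], ref[cut_b:]
                if not precise:
                    length = int(rng.integers(1, 11))
                    mode = rng.choice(["del", "ins"])
                    if mode == "del":
                        take_left = int(rng.integers(0, length + 1))
                        left = left[: len(left) - take_left]
                        right = right[length - take_left :]
                        seq = left + right
                    else:
                        seq = left + _random_seq(rng, length) + right
                else:
                    seq = left + right
                extra = dict(distal_accurate=precise)
            elif cls == "wild_type":
                seq = ref
            elif cls == "single_cut_indel":
                cut = cut_a if rng.random() < 0.5 else cut_b
                length = int(rng.integers(1, 6))
                start = max(0, cut - int(rng.integers(0, length + 1)))
                seq = ref[:start] + ref[start + length :]
            else:
                seq = _random_seq(rng, len(ref))
            seq = _apply_subst_errors(rng, seq, subst_error_rate)
            rid = f"dual_{cls}_{j:06d}"
            truth.append(TruthRecord(allele_id=rid, cls=cls, multiplicity=1, **extra))
            records.append((rid, seq, "I" * len(seq)))
    return records, truth


def make_dual_design(
    rng: np.random.Generator,
    configuration: str = "PAM_in",
    deletion_span: int = 60,
    flank: int = 95,
    tag: DsODNTag = DEFAULT_TAG,
) -> DualCutDesign:
    """A synthetic two-cut design in the requested PAM configuration."""
    strands = {
        "PAM_in": ("+", "-"),
        "PAM_out": ("-", "+"),
        "PAM_in_out": ("+", "+"),
    }[configuration]
    length = 2 * flank + deletion_span + 50
    cuts = (flank, flank + deletion_span)
    for _ in range(200):
        ref_l = list(random_reference(rng, length))
        for cut, strand in zip(cuts, strands):
            _force_pam(ref_l, cut, strand)
        ref = "".join(ref_l)
        try:
            sa = GenomeTarget(name="site_a", reference=ref,
                              protospacer=_protospacer_at(ref, cuts[0], strands[0]),
                              strand=strands[0])
            sb = GenomeTarget(name="site_b", reference=ref,
                              protospacer=_protospacer_at(ref, cuts[1], strands[1]),
                              strand=strands[1])
            design = DualCutDesign(site_a=sa, site_b=sb)
        except ValueError:
            continue
        if design.configuration.value == configuration:
            return design
    raise RuntimeError("could not construct a dual-cut design")


def _force_pam(ref_l: list[str], cut: int, strand: str) -> None:
    """Force an NGG PAM so that a protospacer cutting at ``cut`` exists."""
    if strand == "+":
        # cut = start + 17 → protospacer ref[cut-17:cut+3], PAM at cut+3
        ref_l[cut + 4] = "G"
        ref_l[cut + 5] = "G"
    else:
        # cut = start + 3 → footprint ref[cut-3:cut+17], PAM at cut-6..cut-4
        ref_l[cut - 6] = "C"
        ref_l[cut - 5] = "C"


def _protospacer_at(ref: str, cut: int, strand: str) -> str:
    if strand == "+":
        return ref[cut - 17 : cut + 3]
    return revcomp(ref[cut - 3 : cut + 17])


# ---------------------------------------------------------------------------
# file output


def write_truth_table(path: str | Path, truth: Sequence[TruthRecord]) -> None:
    cols = ("allele_id", "cls", "multiplicity", "distal_accurate",
            "proximal_accurate", "orientation", "event_kind", "event_length",
            "event_position", "inserted_seq")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in truth:
            fh.write(
                "\t".join(
                    "NA" if getattr(rec, c) is None else str(getattr(rec, c))
                    for c in cols
                )
                + "\n"
            )


def simulate_to_files(
    cfg: SimulationConfig, fastq_path: str | Path, truth_path: str | Path
) -> None:
    """Run :func:`simulate_pool` and write FASTQ (.gz honoured) + truth TSV."""
    records, truth = simulate_pool(cfg)
    write_fastq(fastq_path, records)
    write_truth_table(truth_path, truth)
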