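"""Lightweight ungapped read mapping and two-step mitochondrial extraction.

The extraction mirrors the strategy of mining off-target mtDNA reads from a
capture experiment: first align every read to the mitochondrial reference
alone (cheap, and only mtDNA-like reads survive), then competitively
realign that subset against the combined nuclear + mitochondrial reference
so that reads actually originating from NUMTs — diverged nuclear copies of
mtDNA — relocate back to the nuclear genome.  A read is retained as
mitochondrial only when its best competitive placement on the mitochondrial
contig scores strictly higher than any nuclear placement; ties go to the
nuclear genome (conservative), and tied reads are counted as ambiguous.

The aligner is seed-and-extend with exact k-mer seeds and full-length
ungapped scoring (match +1, mismatch -4, no indels).  ``mapq_proxy`` is the
score gap between the best and second-best placement — a proxy for mapping
quality, not a calibrated probability.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .reference_kb import (
    MitoReference,
    NuclearDecoy,
    TargetRegions,
    is_mito_contig,
)
from .simulate import revcomp

__all__ = [
    "ScoringScheme",
    "Alignment",
    "AlignmentTally",
    "SeedIndex",
    "TwoStepResult",
    "Read",
    "read_fastq",
    "align_read",
    "two_step_mito_extract",
    "deduplicate",
    "pair_mates",
    "import_alignments",
    "write_sam",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Ungapped scoring: match reward, mismatch penalty, minimum score."""

    match: int = 1
    mismatch: int = -4
    min_score: int = 20

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0:
            raise ValueError("mismatch penalty must be negative")


@dataclass
class Alignment:
    """A placed read.  ``seq``/``qual`` are in reference orientation."""

    read_id: str
    contig: str
    start: int  # 0-based leftmost reference position
    strand: str  # "+" or "-"
    score: int
    mismatches: int
    mapq_proxy: int
    seq: str
    qual: str
    mate: "Alignment | None" = field(default=None, repr=False, compare=False)

    @property
    def end(self) -> int:
        """0-based exclusive end (may exceed contig length on circular refs)."""
        return self.start + len(self.seq)


@dataclass
class AlignmentTally:
    """Read-level accounting for one sample.

    ``on_target + off_target == mapped`` and ``total_reads == mapped +
    unmapped``; mitochondrial reads count as off-target (mtDNA is never in
    the capture design), so ``mito_mapped <= off_target``.
    """

    total_reads: int = 0
    mapped: int = 0
    on_target: int = 0
    off_target: int = 0
    mito_mapped: int = 0
    duplicates_removed: int = 0

    @property
    def unmapped(self) -> int:
        return self.total_reads - self.mapped

    def validate(self) -> None:
        if self.on_target + self.off_target != self.mapped:
            raise ValueError("tally violates on + off == mapped")
        if self.mito_mapped > self.off_target:
            raise ValueError("tally violates mito_mapped <= off_target")


@dataclass(frozen=True)
class Read:
    name: str
    seq: str
    qual: str


def read_fastq(path) -> list[Read]:
    """Load a FASTQ file (plain text) into reads."""
    from Bio import SeqIO

    return [
        Read(rec.id, str(rec.seq).upper(), "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        ))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


# ---------------------------------------------------------------------------
# Seed index
# ---------------------------------------------------------------------------


class SeedIndex:
    """Exact k-mer index over the forward strand of each contig.

    Circular contigs are indexed across the origin junction, and candidate
    placements on them are taken modulo the contig length.  Reverse-strand
    hits are found by querying the reverse complement of the read.
    """

    def __init__(
        self,
        refs: Sequence[MitoReference | NuclearDecoy | tuple[str, str, bool]],
        k: int = 15,
    ):
        if not refs:
            raise ValueError("empty sequence set")
        if k < 11:
            raise ValueError("k must be >= 11")
        self.k = k
        self.contigs: dict[str, tuple[np.ndarray, bool]] = {}
        self.index: dict[bytes, list[tuple[str, int]]] = {}
        for ref in refs:
            if isinstance(ref, tuple):
                name, seq, circular = ref
            else:
                name, seq = ref.name, ref.sequence
                circular = bool(getattr(ref, "circular", False))
            if len(seq) < k:
                raise ValueError(
                    f"k={k} larger than contig {name!r} of length {len(seq)}"
                )
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            self.contigs[name] = (arr, circular)
            indexed = seq + (seq[: k - 1] if circular else "")
            data = indexed.encode("ascii")
            L = len(seq)
            for pos in range(len(data) - k + 1):
                self.index.setdefault(data[pos : pos + k], []).append(
                    (name, pos % L)
                )

    def lookup(self, kmer: str | bytes) -> list[tuple[str, int]]:
        if isinstance(kmer, str):
            kmer = kmer.encode("ascii")
        return self.index.get(kmer, [])


def _score_placement(
    query: np.ndarray, contig: np.ndarray, start: int, circular: bool, scoring: ScoringScheme
) -> tuple[int, int] | None:
    """Score a full-length ungapped placement; None if it falls off a linear contig."""
    m = len(query)
    L = len(contig)
    if circular:
        ref = contig[(start + np.arange(m)) % L]
    else:
        if start < 0 or start + m > L:
            return None
        ref = contig[start : start + m]
    matches = int((ref == query).sum())
    mismatches = m - matches
    return scoring.match * matches + scoring.mismatch * mismatches, mismatches


def _candidates(
    read_seq: str, index: SeedIndex, scoring: ScoringScheme, stride: int | None = None
) -> list[tuple[str, int, str, int, int]]:
    """All scored candidate placements (contig, start, strand, score, mismatches)."""
    k = index.k
    m = len(read_seq)
    if m < k:
        return []
    stride = stride or k
    out: list[tuple[str, int, str, int, int]] = []
    for strand, q in (("+", read_seq), ("-", revcomp(read_seq))):
        qarr = np.frombuffer(q.encode("ascii"), dtype=np.uint8)
        seen: set[tuple[str, int]] = set()
        offs = list(range(0, m - k + 1, stride))
        if offs[-1] != m - k:
            offs.append(m - k)
        for off in offs:
            for contig, pos in index.lookup(q[off : off + k]):
                arr, circular = index.contigs[contig]
                start = pos - off
                if circular:
                    start %= len(arr)
                if (contig, start) in seen:
                    continue
                seen.add((contig, start))
                scored = _score_placement(qarr, arr, start, circular, scoring)
                if scored is None:
                    continue
                out.append((contig, start, strand, scored[0], scored[1]))
    out.sort(key=lambda c: (-c[3], c[0], c[1], c[2]))
    return out


def align_read(
    read: Read, index: SeedIndex, scoring: ScoringScheme = ScoringScheme()
) -> Alignment | None:
    """Best-scoring placement of a read, or None if unmappable.

    Reads shorter than k are unmappable by construction (warned once per
    call site via the returned None).  ``mapq_proxy`` is best minus
    second-best score when a second placement exists, else the best score
    itself.
    """
    cands = _candidates(read.seq, index, scoring)
    if not cands:
        return None
    contig, start, strand, score, mismatches = cands[0]
    if score < scoring.min_score:
        return None
    proxy = score - cands[1][3] if len(cands) > 1 else score
    if strand == "+":
        seq, qual = read.seq, read.qual
    else:
        seq, qual = revcomp(read.seq), read.qual[::-1]
    return Alignment(
        read_id=read.name,
        contig=contig,
        start=start,
        strand=strand,
        score=score,
        mismatches=mismatches,
        mapq_proxy=max(proxy, 0),
        seq=seq,
        qual=qual,
    )


# ---------------------------------------------------------------------------
# Two-step extraction
# ---------------------------------------------------------------------------


@dataclass
class TwoStepResult:
    mito_alignments: list[Alignment]
    relocated: int  # step-1 mito hits whose best competitive placement is nuclear
    ambiguous: int  # step-1 hits tied between mito and nuclear (assigned nuclear)
    tally: AlignmentTally | None  # filled only when targets are supplied


def two_step_mito_extract(
    reads: Iterable[Read],
    mito_ref: MitoReference,
    combined_refs: Sequence[MitoReference | NuclearDecoy],
    scoring: ScoringScheme = ScoringScheme(),
    k: int = 15,
    targets: TargetRegions | None = None,
) -> TwoStepResult:
    """Two-step mitochondrial read extraction with NUMT relocation.

    Step 1 aligns every read to the mitochondrial reference alone; step 2
    competitively realigns the step-1 hits against the combined reference.
    A read is retained as mitochondrial iff its best step-2 placement on
    the mito contig is strictly better than its best nuclear placement.

    When ``targets`` is given, all reads are additionally aligned to the
    combined reference to produce a full on/off-target
    :class:`AlignmentTally` (slower); otherwise ``tally`` is None.
    """
    names = [r.name for r in combined_refs]
    if mito_ref.name not in names:
        raise ValueError(
            f"combined reference lacks the mito contig {mito_ref.name!r}"
        )
    reads = [r if isinstance(r, Read) else Read(*r) for r in reads]
    mito_index = SeedIndex([mito_ref], k=k)
    combined_index = SeedIndex(list(combined_refs), k=k)

    step1_hits: list[Read] = []
    for read in reads:
        if align_read(read, mito_index, scoring) is not None:
            step1_hits.append(read)

    retained: list[Alignment] = []
    ambiguous = 0
    for read in step1_hits:
        cands = _candidates(read.seq, combined_index, scoring)
        cands = [c for c in cands if c[3] >= scoring.min_score]
        if not cands:
            continue
        best_mito = max(
            (c for c in cands if c[0] == mito_ref.name),
            key=lambda c: c[3],
            default=None,
        )
        best_nuc = max(
            (c for c in cands if c[0] != mito_ref.name),
            key=lambda c: c[3],
            default=None,
        )
        if best_mito is None:
            continue
        if best_nuc is not None and best_nuc[3] >= best_mito[3]:
            if best_nuc[3] == best_mito[3]:
                ambiguous += 1
            continue
        contig, start, strand, score, mismatches = best_mito
        second = max(
            (c[3] for c in cands if (c[0], c[1], c[2]) != (contig, start, strand)),
            default=None,
        )
        proxy = score - second if second is not None else score
        seq = read.seq if strand == "+" else revcomp(read.seq)
        qual = read.qual if strand == "+" else read.qual[::-1]
        retained.append(
            Alignment(
                read_id=read.name,
                contig=contig,
                start=start,
                strand=strand,
                score=score,
                mismatches=mismatches,
                mapq_proxy=max(proxy, 0),
                seq=seq,
                qual=qual,
            )
        )
    relocated = len(step1_hits) - len(retained)

    tally = None
    if targets is not None:
        retained_ids = {a.read_id for a in retained}
        tally = AlignmentTally(total_reads=len(reads))
        for read in reads:
            aln = align_read(read, combined_index, scoring)
            if aln is None:
                continue
            tally.mapped += 1
            if targets.overlaps(aln.contig, aln.start, aln.end):
                tally.on_target += 1
            else:
                tally.off_target += 1
                if read.name in retained_ids:
                    tally.mito_mapped += 1
        tally.validate()
    return TwoStepResult(
        mito_alignments=retained,
        relocated=relocated,
        ambiguous=ambiguous,
        tally=tally,
    )


# ---------------------------------------------------------------------------
# Mate pairing and deduplication
# ---------------------------------------------------------------------------

_MATE_SUFFIX = re.compile(r"/[12]$")


def pair_mates(alignments: Iterable[Alignment]) -> list[Alignment]:
    """Link mates that share a read name up to a trailing ``/1`` / ``/2``.

    Returns the same alignments with ``mate`` set where both mates aligned.
    """
    alignments = list(alignments)
    by_base: dict[str, list[Alignment]] = {}
    for aln in alignments:
        base = _MATE_SUFFIX.sub("", aln.read_id)
        by_base.setdefault(base, []).append(aln)
    for group in by_base.values():
        if len(group) == 2:
            group[0].mate = group[1]
            group[1].mate = group[0]
    return alignments


def _fragment_key(aln: Alignment) -> tuple:
    if aln.mate is not None and aln.mate.contig == aln.contig:
        left, right = sorted([aln, aln.mate], key=lambda a: (a.start, a.strand))
        return (aln.contig, left.start, right.end, left.strand, right.strand)
    return (aln.contig, aln.start, aln.strand, None, None)


def deduplicate(
    alignments: Iterable[Alignment],
) -> tuple[list[Alignment], int]:
    """Coordinate-based duplicate removal; idempotent.

    Alignments sharing a fragment signature — (contig, outer start, outer
    end, strand orientation) for linked pairs, (contig, start, strand) for
    singletons — keep exactly one representative fragment (deterministic:
    lowest read id).  Returns (kept alignments, fragments removed).
    """
    alignments = list(alignments)
    by_base: dict[str, list[Alignment]] = {}
    for aln in alignments:
        by_base.setdefault(_MATE_SUFFIX.sub("", aln.read_id), []).append(aln)
    groups = sorted(by_base.items())
    seen: dict[tuple, str] = {}
    kept: list[Alignment] = []
    removed = 0
    for base, alns in groups:
        key = _fragment_key(alns[0])
        if key in seen:
            removed += 1
            continue
        seen[key] = base
        kept.extend(alns)
    return kept, removed


# ---------------------------------------------------------------------------
# SAM interoperability
# ---------------------------------------------------------------------------


def write_sam(
    alignments: Sequence[Alignment],
    refs: Sequence[MitoReference | NuclearDecoy],
    path,
    header_comments: Sequence[str] = (),
) -> None:
    """Write alignments as minimal SAM (ungapped: CIGAR is all-M)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": r.name, "LN": len(r.sequence)} for r in refs],
        "CO": list(header_comments),
    }
    lengths = {r.name: len(r.sequence) for r in refs}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            a = pysam.AlignedSegment(out.header)
            a.query_name = aln.read_id
            a.flag = 16 if aln.strand == "-" else 0
            a.reference_id = out.header.references.index(aln.contig)
            # origin-spanning placements on the circular contig are stored
            # at their start; the M run may extend past LN in this dialect
            a.reference_start = aln.start % lengths[aln.contig]
            a.mapping_quality = min(int(aln.mapq_proxy), 60)
            a.cigarstring = f"{len(aln.seq)}M"
            a.query_sequence = aln.seq
            a.query_qualities = pysam.qualitystring_to_array(aln.qual)
            a.set_tag("NM", int(aln.mismatches))
            a.set_tag("AS", int(aln.score))
            out.write(a)


def import_alignments(
    sam_source,
    targets: TargetRegions | None = None,
    mito_name: str | None = None,
    on_unknown_mito: str = "warn",
) -> tuple[list[Alignment], AlignmentTally]:
    """Import SAM/BAM alignments and tally on/off-target and mito reads.

    A mapped read is on-target when it overlaps a target interval by at
    least one base; the mitochondrial contig is matched case-insensitively
    among {MT, chrM, chrMT} or ``mito_name``.  Reads with non-M CIGAR
    operations are tallied but not returned (this dialect is ungapped).
    """

    def _is_mito(name: str) -> bool:
        if mito_name is not None and name == mito_name:
            return True
        return is_mito_contig(name)

    tally = AlignmentTally()
    alignments: list[Alignment] = []
    mode = "rb" if str(sam_source).endswith(".bam") else "r"
    saw_mito = False
    with pysam.AlignmentFile(str(sam_source), mode, check_sq=False) as f:
        for read in f:
            tally.total_reads += 1
            if read.is_unmapped:
                continue
            tally.mapped += 1
            contig = read.reference_name
            start = read.reference_start
            end = read.reference_end or (start + read.query_length)
            if _is_mito(contig):
                saw_mito = True
            on = targets.overlaps(contig, start, end) if targets else False
            if on:
                tally.on_target += 1
            else:
                tally.off_target += 1
                if _is_mito(contig):
                    tally.mito_mapped += 1
            if any(op != 0 for op, _ in (read.cigartuples or [])):
                continue
            qual = (
                "".join(chr(q + 33) for q in read.query_qualities)
                if read.query_qualities is not None
                else "I" * (read.query_length or 0)
            )
            alignments.append(
                Alignment(
                    read_id=read.query_name,
                    contig=contig,
                    start=start,
                    strand="-" if read.is_reverse else "+",
                    score=int(read.get_tag("AS")) if read.has_tag("AS") else 0,
                    mismatches=int(read.get_tag("NM")) if read.has_tag("NM") else 0,
                    mapq_proxy=read.mapping_quality,
                    seq=(read.query_sequence or "").upper(),
                    qual=qual,
                )
            )
    if not saw_mito and tally.mapped > 0:
        msg = (
            "no recognised mitochondrial contig (MT/chrM/chrMT"
            + (f"/{mito_name}" if mito_name else "")
            + ") among mapped reads"
        )
        if on_unknown_mito == "error":
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    tally.validate()
    return alignments, tally
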