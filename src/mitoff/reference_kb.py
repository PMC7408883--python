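"""References, capture targets and the *MT-RNR1* ototoxicity knowledge base.

Coordinate conventions
----------------------
External formats keep their native conventions: BED is 0-based half-open,
rCRS / VCF positions are 1-based inclusive.  All internal interval arithmetic
is 0-based half-open; conversion happens at the I/O boundary and nowhere else.

The mitochondrial reference is modelled as a circular contig in rCRS-style
coordinates (16,569 bases for the canonical sequence, but any length is
accepted so scaled-down references can be used).  Nuclear decoy contigs are
linear and may carry annotated NUMT segments — diverged copies of a
mitochondrial span embedded in nuclear sequence.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MitoReference",
    "NuclearDecoy",
    "NumtAnnotation",
    "TargetRegions",
    "KBEntry",
    "RegionDef",
    "MT_RNR1",
    "MITO_CONTIG_NAMES",
    "FastaParseError",
    "BedParseError",
    "KBValidationError",
    "load_fasta_records",
    "load_mito_reference",
    "load_decoys",
    "load_targets",
    "load_kb",
    "write_fasta",
    "write_targets",
    "write_kb",
]

VALID_BASES = frozenset("ACGTN")

#: Contig names recognised as the mitochondrial chromosome (case-insensitive).
MITO_CONTIG_NAMES = frozenset({"MT", "CHRM", "CHRMT"})


class FastaParseError(ValueError):
    """Raised for empty or non-IUPAC FASTA input."""


class BedParseError(ValueError):
    """Raised for malformed BED lines."""


class KBValidationError(ValueError):
    """Raised when a knowledge-base entry violates its invariants."""


PathLike = Union[str, Path, TextIO]


def _as_handle(source: PathLike, mode: str = "r"):
    """Return (handle, needs_close) for a path or an open text handle."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode), True


def is_mito_contig(name: str) -> bool:
    return name.upper() in MITO_CONTIG_NAMES


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MitoReference:
    """Circular mitochondrial reference in 1-based rCRS-style coordinates."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise FastaParseError(f"empty sequence for contig {self.name!r}")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FastaParseError(
                f"contig {self.name!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Reference base at 1-based position ``position``."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(
                f"position {position} outside 1..{len(self.sequence)}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class NumtAnnotation:
    """A NUMT segment: mito span copied (with divergence) into a decoy."""

    mt_start: int  # 1-based inclusive, on the mito reference
    mt_end: int  # 1-based inclusive
    divergence: float  # substitution fraction applied to the copy
    insert_pos: int  # 1-based position of the copy's first base in the decoy

    def __post_init__(self):
        if self.mt_start > self.mt_end:
            raise ValueError(
                f"NUMT span start {self.mt_start} > end {self.mt_end}"
            )
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError(f"divergence {self.divergence} outside [0, 1]")

    @property
    def length(self) -> int:
        return self.mt_end - self.mt_start + 1


@dataclass(frozen=True)
class NuclearDecoy:
    """Linear nuclear contig, optionally carrying annotated NUMT segments."""

    name: str
    sequence: str
    numt_annotations: tuple[NumtAnnotation, ...] = ()

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise FastaParseError(f"empty sequence for contig {self.name!r}")
        for numt in self.numt_annotations:
            if numt.insert_pos < 1 or numt.insert_pos + numt.length - 1 > len(
                self.sequence
            ):
                raise ValueError(
                    f"NUMT at {numt.insert_pos} (len {numt.length}) outside "
                    f"decoy {self.name!r} of length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TargetRegions:
    """Capture target intervals, stored 0-based half-open, merged per contig.

    ``mito_intervals`` keeps any intervals that fell on a mitochondrial
    contig: they are accepted but flagged, because in the capture designs
    this tool addresses the mitochondrial genome is off-target by design.
    """

    intervals: tuple[tuple[str, int, int], ...]
    mito_intervals: tuple[tuple[str, int, int], ...] = ()

    @staticmethod
    def from_intervals(
        intervals: Iterable[tuple[str, int, int]],
    ) -> "TargetRegions":
        """Normalise: validate, split off mito-contig intervals, sort, merge."""
        plain: list[tuple[str, int, int]] = []
        mito: list[tuple[str, int, int]] = []
        for contig, start, end in intervals:
            if start >= end:
                raise BedParseError(
                    f"interval {contig}:{start}-{end} has start >= end"
                )
            if start < 0:
                raise BedParseError(f"interval {contig}:{start}-{end} negative")
            (mito if is_mito_contig(contig) else plain).append(
                (contig, int(start), int(end))
            )
        if mito:
            warnings.warn(
                "capture targets include mitochondrial intervals; the "
                "mitochondrial genome is expected to be off-target",
                stacklevel=3,
            )
        return TargetRegions(
            intervals=tuple(_merge(plain)), mito_intervals=tuple(_merge(mito))
        )

    def total_size(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def for_contig(self, contig: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e in self.intervals if c == contig]

    def overlaps(self, contig: str, start: int, end: int) -> bool:
        """≥1-base overlap with any target interval (0-based half-open)."""
        for s, e in self.for_contig(contig):
            if start < e and s < end:
                return True
        return False


def _merge(
    intervals: list[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    for contig, start, end in sorted(intervals):
        if out and out[-1][0] == contig and start <= out[-1][2]:
            prev = out.pop()
            out.append((contig, prev[1], max(prev[2], end)))
        else:
            out.append((contig, start, end))
    return out


@dataclass(frozen=True)
class KBEntry:
    """One knowledge-base variant (1-based rCRS position)."""

    position: int
    ref_base: str
    alt_base: str
    evidence_tier: str  # "strong" | "needs_further_study"
    note: str = ""
    pmid_refs: str = ""

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise KBValidationError(
                f"KB entry at {self.position}: alt equals ref ({self.ref_base})"
            )
        if self.evidence_tier not in ("strong", "needs_further_study"):
            raise KBValidationError(
                f"unknown evidence tier {self.evidence_tier!r}"
            )


@dataclass(frozen=True)
class RegionDef:
    """A named 1-based inclusive span on the mitochondrial reference."""

    gene: str
    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad region span {self.start}-{self.end}")

    def positions(self) -> range:
        """1-based positions covered by the region."""
        return range(self.start, self.end + 1)

    def __len__(self) -> int:
        return self.end - self.start + 1


#: Default span of the 12S rRNA gene (standard rCRS annotation).  The span is
#: a configuration default, not a measured quantity; override where needed.
MT_RNR1 = RegionDef("MT-RNR1", 648, 1601)

#: Ototoxicity positions whose depth is always reported by name.
NAMED_POSITIONS = (1555, 1494, 1095)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def load_fasta_records(source: PathLike) -> list[tuple[str, str]]:
    """Parse FASTA into ``[(name, uppercased sequence), ...]``.

    Record order is preserved; lowercase bases are uppercased; an empty file
    or a non-IUPAC character is a :class:`FastaParseError` naming the record.
    """
    handle, close = _as_handle(source)
    try:
        records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(handle, "fasta")]
    finally:
        if close:
            handle.close()
    if not records:
        raise FastaParseError("no FASTA records found")
    for name, seq in records:
        if not seq:
            raise FastaParseError(f"record {name!r} has an empty sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            raise FastaParseError(
                f"record {name!r} contains non-IUPAC characters: {sorted(bad)}"
            )
    return records


def load_mito_reference(source: PathLike, circular: bool = True) -> MitoReference:
    """Load the (single-record) mitochondrial reference FASTA."""
    records = load_fasta_records(source)
    name, seq = records[0]
    return MitoReference(name=name, sequence=seq, circular=circular)


def load_decoys(source: PathLike) -> list[NuclearDecoy]:
    """Load nuclear decoy contigs (NUMT annotations are not FASTA-borne)."""
    return [NuclearDecoy(name=n, sequence=s) for n, s in load_fasta_records(source)]


def write_fasta(
    records: Sequence[Union[MitoReference, NuclearDecoy, tuple[str, str]]],
    dest: PathLike,
) -> None:
    seqrecords = []
    for rec in records:
        if isinstance(rec, tuple):
            name, seq = rec
        else:
            name, seq = rec.name, rec.sequence
        seqrecords.append(SeqRecord(Seq(seq), id=name, description=""))
    handle, close = _as_handle(dest, "w")
    try:
        SeqIO.write(seqrecords, handle, "fasta")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# BED targets
# ---------------------------------------------------------------------------


def load_targets(source: PathLike) -> TargetRegions:
    """Load a ≥3-column BED file of capture targets (0-based half-open)."""
    handle, close = _as_handle(source)
    intervals: list[tuple[str, int, int]] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(
                    f"line {lineno}: expected >=3 BED columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinate") from exc
            if start >= end:
                raise BedParseError(
                    f"line {lineno}: start {start} >= end {end}"
                )
            intervals.append((fields[0], start, end))
    finally:
        if close:
            handle.close()
    return TargetRegions.from_intervals(intervals)


def write_targets(targets: TargetRegions, dest: PathLike) -> None:
    handle, close = _as_handle(dest, "w")
    try:
        for contig, start, end in list(targets.intervals) + list(
            targets.mito_intervals
        ):
            handle.write(f"{contig}\t{start}\t{end}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Knowledge base
# ---------------------------------------------------------------------------

KB_COLUMNS = ("position", "ref", "alt", "tier", "note", "pmid_refs")


def load_kb(
    source: PathLike | None = None,
    mito_ref: MitoReference | None = None,
) -> list[KBEntry]:
    """Load the variant knowledge base (default: bundled 16-entry table).

    If ``mito_ref`` is given, every entry's reference base is checked against
    the loaded mitochondrial sequence; a mismatch is a
    :class:`KBValidationError`.
    """
    if source is None:
        text = (
            resources.files("mitoff.data").joinpath("mtrnr1_kb.tsv").read_text()
        )
        handle, close = io.StringIO(text), False
    else:
        handle, close = _as_handle(source)
    entries: list[KBEntry] = []
    try:
        header: list[str] | None = None
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if tuple(header) != KB_COLUMNS:
                    raise KBValidationError(
                        f"unexpected KB header {header!r}; expected {KB_COLUMNS}"
                    )
                continue
            row = dict(zip(header, fields))
            entries.append(
                KBEntry(
                    position=int(row["position"]),
                    ref_base=row["ref"].upper(),
                    alt_base=row["alt"].upper(),
                    evidence_tier=row["tier"],
                    note="" if row["note"] == "." else row["note"],
                    pmid_refs="" if row["pmid_refs"] == "." else row["pmid_refs"],
                )
            )
    finally:
        if close:
            handle.close()

    keys = [(e.position, e.ref_base, e.alt_base) for e in entries]
    if len(keys) != len(set(keys)):
        raise KBValidationError("duplicate (position, ref, alt) in KB")
    if mito_ref is not None:
        for e in entries:
            if e.position > len(mito_ref):
                raise KBValidationError(
                    f"KB position {e.position} beyond reference length "
                    f"{len(mito_ref)}"
                )
            actual = mito_ref.base(e.position)
            if actual != e.ref_base:
                raise KBValidationError(
                    f"KB ref {e.ref_base} at {e.position} does not match "
                    f"reference base {actual}"
                )
    return entries


def write_kb(entries: Sequence[KBEntry], dest: PathLike) -> None:
    handle, close = _as_handle(dest, "w")
    try:
        handle.write("\t".join(KB_COLUMNS) + "\n")
        for e in entries:
            handle.write(
                "\t".join(
                    [
                        str(e.position),
                        e.ref_base,
                        e.alt_base,
                        e.evidence_tier,
                        e.note or ".",
                        e.pmid_refs or ".",
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()


def kb_lookup(
    entries: Iterable[KBEntry],
) -> dict[tuple[int, str, str], KBEntry]:
    """Index KB entries by (position, ref, alt)."""
    return {(e.position, e.ref_base, e.alt_base): e for e in entries}
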