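"""Synthetic targeted-capture experiments with per-read ground truth.

The simulator emulates the read-provenance structure a capture experiment
produces: on-target nuclear fragments, off-target nuclear fragments, true
mitochondrial fragments (whose share of the off-target mass reflects mtDNA
copy number and DNA integrity), NUMT-derived fragments, heteroplasmic
variant mixing, per-base substitution error and PCR duplicates.

Fragment model: uniform fragment start per contig; fragment length drawn
from a truncated normal (mean 300 bp, sd 50 bp, floored at the read length).
Paired 100 bp reads are taken from the fragment ends (mate 2 is the reverse
complement of the fragment's 3' end).  Base qualities are constant
Q30-style.  Duplicates are exact copies of already-emitted fragments, so
coordinate-based deduplication can remove them exactly.

Presets correspond to the sample-type regimes a capture study sees (custom
panel vs whole-exome, blood / saliva / FFPE / frozen tissue): panel designs
(~135 kb) leave about half of the reads off-target, exomes (~60 Mb) about
15%, and of the off-target mass only a few parts in ten thousand derive
from true mtDNA — FFPE material, with degraded nuclear DNA, shows both the
highest off-target share and the highest mtDNA coverage.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference_kb import (
    MitoReference,
    NuclearDecoy,
    NumtAnnotation,
    TargetRegions,
    load_kb,
)

__all__ = [
    "SampleProfile",
    "PRESETS",
    "GenotypeSpec",
    "TruthRecord",
    "SyntheticGenome",
    "SimulatedSample",
    "build_synthetic_genome",
    "simulate_sample",
    "simulate_cohort",
    "write_fastq",
    "write_truth_table",
    "parse_read_name",
]

READ_QUALITY_CHAR = "?"  # Phred 30

_RC = bytes.maketrans(b"ACGTN", b"TGCAN")
_BASE2IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE2IDX[_b] = _i
_IDX2BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

PROVENANCE_CLASSES = ("on_target", "off_target_nuclear", "mito", "numt")


def _seq_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def revcomp(seq: str) -> str:
    return seq.encode("ascii").translate(_RC)[::-1].decode("ascii")


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleProfile:
    """Generative parameters for one capture experiment.

    ``off_target_fraction`` is the expected share of fragments not drawn
    from targets; within that off-target mass, ``mito_weight`` is the share
    of true mitochondrial fragments and ``numt_weight`` the share of
    NUMT-derived fragments (the remainder is off-target nuclear).
    """

    name: str
    total_read_pairs: int
    off_target_fraction: float
    mito_weight: float
    numt_weight: float = 1e-4
    read_length: int = 100
    error_rate: float = 1e-3
    duplicate_rate: float = 0.02
    fragment_mean: float = 300.0
    fragment_sd: float = 50.0
    preset: str | None = None

    def __post_init__(self):
        for attr in (
            "off_target_fraction",
            "mito_weight",
            "numt_weight",
            "error_rate",
            "duplicate_rate",
        ):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr}={v} outside [0, 1]")
        if self.mito_weight + self.numt_weight > 1.0:
            raise ValueError("mito_weight + numt_weight exceeds 1")
        if self.total_read_pairs < 0:
            raise ValueError("total_read_pairs must be >= 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")

    def scaled(self, factor: float) -> "SampleProfile":
        """Copy with ``total_read_pairs`` scaled (coverage scales with it)."""
        return replace(self, total_read_pairs=int(round(self.total_read_pairs * factor)))


#: Sample-type regimes.  Off-target fractions and the mito shares of the
#: panel-blood and WES-blood regimes follow the observed 50%/15% off-target
#: and 0.03%/0.02% mito-of-off-target figures; the remaining mito weights
#: are calibrated so the expected mtDNA coverage lands near the published
#: per-regime medians (5-93x panel, 5-59x WES) at the stated sequencing
#: depths (2M panel pairs, 44M research-WES pairs, 75M clinical-WES pairs).
PRESETS: Mapping[str, SampleProfile] = {
    "blood_panel": SampleProfile(
        "blood_panel", 2_000_000, 0.50, 3e-4, preset="blood_panel"
    ),
    "saliva_panel": SampleProfile(
        "saliva_panel", 2_000_000, 0.50, 9e-4, preset="saliva_panel"
    ),
    "ffpe_panel": SampleProfile(
        "ffpe_panel", 2_000_000, 0.73, 5.3e-3, preset="ffpe_panel"
    ),
    "blood_wes": SampleProfile(
        "blood_wes", 44_000_000, 0.15, 2e-4, preset="blood_wes"
    ),
    "frozen_wes": SampleProfile(
        "frozen_wes", 44_000_000, 0.05, 1.9e-4, preset="frozen_wes"
    ),
    "clinical_wes": SampleProfile(
        "clinical_wes", 75_000_000, 0.15, 4.3e-4, preset="clinical_wes"
    ),
}


# ---------------------------------------------------------------------------
# Genotype and truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeSpec:
    """Mitochondrial variants carried by a sample.

    ``variants`` lists (1-based rCRS position, alt base, heteroplasmy h).
    h is the fraction of mtDNA molecules carrying the alt allele; h=1 is a
    homoplasmic alt.
    """

    variants: tuple[tuple[int, str, float], ...] = ()

    def __post_init__(self):
        positions = [p for p, _, _ in self.variants]
        if len(positions) != len(set(positions)):
            raise ValueError("duplicate positions in genotype spec")
        for pos, alt, h in self.variants:
            if pos < 1:
                raise ValueError(f"position {pos} must be >= 1")
            if alt not in "ACGT":
                raise ValueError(f"alt base {alt!r} not in ACGT")
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"heteroplasmy {h} outside [0, 1]")

    @staticmethod
    def wild_type() -> "GenotypeSpec":
        return GenotypeSpec(())


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated sample."""

    sample: str
    genotype: GenotypeSpec
    counts: Mapping[str, int]  # provenance class -> emitted fragment count
    seed: int

    @property
    def total_fragments(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class SyntheticGenome:
    mito: MitoReference
    decoys: tuple[NuclearDecoy, ...]
    targets: TargetRegions


@dataclass
class SimulatedSample:
    """Reads plus ground truth for one sample.

    ``fragments`` records each emitted fragment (contig, 0-based start,
    length, provenance class, duplicate source index or -1); read sequences
    are kept as uint8 matrices and rendered to FASTQ text on demand.
    """

    sample_id: str
    profile: SampleProfile
    truth: TruthRecord
    fragments: pd.DataFrame
    _r1: np.ndarray  # (n_fragments, read_length) uint8
    _r2: np.ndarray

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def read_names(self) -> list[str]:
        names = []
        for i, row in enumerate(self.fragments.itertuples(index=False)):
            tag = f"d{i:07d}" if row.dup_of >= 0 else f"f{i:07d}"
            names.append(f"{self.sample_id}.{tag}.{row.provenance}")
        return names

    def read_pairs(self) -> Iterable[tuple[str, str, str, str, str]]:
        """Yield (name, seq1, qual1, seq2, qual2) per fragment."""
        qual = READ_QUALITY_CHAR * self.profile.read_length
        for name, r1, r2 in zip(self.read_names(), self._r1, self._r2):
            yield name, r1.tobytes().decode(), qual, r2.tobytes().decode(), qual

    def reads(self) -> Iterable[tuple[str, str, str]]:
        """Yield individual reads as (name/1|2, seq, qual)."""
        for name, s1, q1, s2, q2 in self.read_pairs():
            yield f"{name}/1", s1, q1
            yield f"{name}/2", s2, q2


def parse_read_name(name: str) -> tuple[str, str, str]:
    """Split a simulated read name into (sample, fragment tag, provenance)."""
    base = name.split("/")[0]
    sample, tag, prov = base.rsplit(".", 2)
    return sample, tag, prov


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

#: rCRS-matching context patched around position 961: the reference T sits
#: between cytosine runs (four upstream, five downstream), the homopolymer
#: neighbourhood that makes indel calls there unreliable.
_HOMOPOLYMER_961 = {p: "C" for p in range(957, 961)} | {
    p: "C" for p in range(962, 967)
}


def build_synthetic_genome(
    n_decoys: int = 1,
    decoy_length: int = 30_000,
    numt_specs: Sequence[tuple[int, int, float]] = ((1_000, 1_600, 0.05),),
    seed: int = 0,
    mito_length: int = 16_569,
    mito_name: str = "MT",
    target_fraction: float = 0.05,
    target_length: int = 400,
) -> SyntheticGenome:
    """Build a random mito reference, NUMT-bearing decoys and capture targets.

    The mitochondrial sequence is random except that knowledge-base
    positions (and the 961 homopolymer neighbourhood) carry their canonical
    reference bases, so the bundled variant table validates against it.
    NUMT specs give (mt_start, mt_end, divergence) and are assigned to
    decoys round-robin; each copy is the mito span with substitutions at the
    stated divergence.  Targets tile ``target_fraction`` of each decoy and
    never touch the mitochondrial contig or a NUMT span.
    """
    if mito_length < 1:
        raise ValueError("mito_length must be >= 1")
    rng = np.random.default_rng(seed)

    mito_arr = _IDX2BASE[rng.integers(0, 4, size=mito_length)]
    patches: dict[int, str] = dict(_HOMOPOLYMER_961)
    for entry in load_kb():
        patches[entry.position] = entry.ref_base
    patches.setdefault(1095, "T")
    for pos, base in patches.items():
        if pos <= mito_length:
            mito_arr[pos - 1] = ord(base)
    mito = MitoReference(mito_name, mito_arr.tobytes().decode(), circular=True)

    decoy_arrs = [
        _IDX2BASE[rng.integers(0, 4, size=decoy_length)] for _ in range(n_decoys)
    ]
    annotations: list[list[NumtAnnotation]] = [[] for _ in range(n_decoys)]
    for i, (mt_start, mt_end, divergence) in enumerate(numt_specs):
        if mt_start > mt_end:
            raise ValueError(f"NUMT span start {mt_start} > end {mt_end}")
        if mt_end > mito_length:
            raise ValueError(f"NUMT span end {mt_end} beyond mito length")
        seg = mito_arr[mt_start - 1 : mt_end].copy()
        if len(seg) > decoy_length:
            raise ValueError(
                f"NUMT of length {len(seg)} longer than decoy ({decoy_length})"
            )
        mutate = rng.random(len(seg)) < divergence
        shift = rng.integers(1, 4, size=int(mutate.sum()))
        idx = _BASE2IDX[seg[mutate]].astype(np.int64)
        seg[mutate] = _IDX2BASE[(idx + shift) % 4]
        which = i % n_decoys
        insert_pos = int(rng.integers(0, decoy_length - len(seg) + 1)) + 1
        decoy_arrs[which][insert_pos - 1 : insert_pos - 1 + len(seg)] = seg
        annotations[which].append(
            NumtAnnotation(mt_start, mt_end, divergence, insert_pos)
        )

    decoys = tuple(
        NuclearDecoy(
            name=f"decoy{j + 1}",
            sequence=decoy_arrs[j].tobytes().decode(),
            numt_annotations=tuple(annotations[j]),
        )
        for j in range(n_decoys)
    )

    intervals: list[tuple[str, int, int]] = []
    for decoy in decoys:
        n_targets = max(1, int(decoy_length * target_fraction / target_length))
        spacing = decoy_length // n_targets
        numt_spans = [
            (a.insert_pos - 1, a.insert_pos - 1 + a.length)
            for a in decoy.numt_annotations
        ]
        for t in range(n_targets):
            start = t * spacing
            end = min(start + target_length, decoy_length)
            if any(start < ne and ns < end for ns, ne in numt_spans):
                continue
            if end > start:
                intervals.append((decoy.name, start, end))
    targets = TargetRegions.from_intervals(intervals)
    return SyntheticGenome(mito=mito, decoys=decoys, targets=targets)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _fragment_lengths(rng, n: int, profile: SampleProfile, max_len: int) -> np.ndarray:
    lens = rng.normal(profile.fragment_mean, profile.fragment_sd, size=n)
    lens = np.clip(np.rint(lens), profile.read_length, max_len).astype(np.int64)
    return lens


def _reads_from_windows(
    contig: np.ndarray, starts: np.ndarray, flens: np.ndarray, rl: int, circular: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Extract mate-1 / mate-2 windows (mate 2 still in reference orientation)."""
    offsets = np.arange(rl)
    idx1 = starts[:, None] + offsets
    idx2 = (starts + flens - rl)[:, None] + offsets
    if circular:
        idx1 %= len(contig)
        idx2 %= len(contig)
    return contig[idx1], contig[idx2]


def _apply_errors(rng, reads: np.ndarray, error_rate: float) -> None:
    if error_rate <= 0 or reads.size == 0:
        return
    mask = rng.random(reads.shape) < error_rate
    n_err = int(mask.sum())
    if n_err == 0:
        return
    idx = _BASE2IDX[reads[mask]].astype(np.int64)
    reads[mask] = _IDX2BASE[(idx + rng.integers(1, 4, size=n_err)) % 4]


def _revcomp_u8(reads: np.ndarray) -> np.ndarray:
    comp = np.frombuffer(
        bytes(range(256)).translate(_RC), dtype=np.uint8
    )
    return comp[reads][:, ::-1]


def simulate_sample(
    genome: SyntheticGenome,
    profile: SampleProfile,
    genotype: GenotypeSpec | None = None,
    seed: int = 0,
    sample_id: str | None = None,
) -> SimulatedSample:
    """Simulate one sample's paired reads plus its :class:`TruthRecord`."""
    genotype = genotype or GenotypeSpec.wild_type()
    sample_id = sample_id or profile.name
    L = len(genome.mito)
    for pos, alt, _h in genotype.variants:
        if pos > L:
            raise ValueError(f"variant position {pos} beyond mito length {L}")
        if genome.mito.base(pos) == alt:
            raise ValueError(f"alt base at {pos} equals the reference base")

    rng = np.random.default_rng(seed)
    rl = profile.read_length
    ot = profile.off_target_fraction
    p = np.array(
        [
            1.0 - ot,
            ot * (1.0 - profile.mito_weight - profile.numt_weight),
            ot * profile.mito_weight,
            ot * profile.numt_weight,
        ]
    )
    n_by_class = rng.multinomial(profile.total_read_pairs, p)

    mito_arr = _seq_u8(genome.mito.sequence)
    decoy_arrs = {d.name: _seq_u8(d.sequence) for d in genome.decoys}

    frag_contig: list[np.ndarray] = []
    frag_start: list[np.ndarray] = []
    frag_len: list[np.ndarray] = []
    frag_prov: list[np.ndarray] = []
    r1_parts: list[np.ndarray] = []
    r2_parts: list[np.ndarray] = []

    def emit(contig_name, contig_arr, starts, flens, prov, circular):
        r1, r2raw = _reads_from_windows(contig_arr, starts, flens, rl, circular)
        frag_contig.append(np.full(len(starts), contig_name, dtype=object))
        frag_start.append(starts)
        frag_len.append(flens)
        frag_prov.append(np.full(len(starts), prov, dtype=object))
        r1_parts.append(r1)
        r2_parts.append(r2raw)

    # --- on-target fragments: start inside a target interval -------------
    n_on = int(n_by_class[0])
    if n_on:
        ivs = genome.targets.intervals
        if not ivs:
            raise ValueError("profile requests on-target reads but no targets")
        sizes = np.array([e - s for _, s, e in ivs], dtype=float)
        choice = rng.choice(len(ivs), size=n_on, p=sizes / sizes.sum())
        flens = _fragment_lengths(rng, n_on, profile, 10_000)
        starts = np.empty(n_on, dtype=np.int64)
        contigs = np.empty(n_on, dtype=object)
        for i, c in enumerate(choice):
            name, s, e = ivs[c]
            clen = len(decoy_arrs[name])
            flens[i] = min(flens[i], clen)
            starts[i] = min(int(rng.integers(s, e)), clen - flens[i])
            contigs[i] = name
        for name in decoy_arrs:
            sel = contigs == name
            if sel.any():
                emit(name, decoy_arrs[name], starts[sel], flens[sel], "on_target", False)

    # --- off-target nuclear: uniform over decoys, rejecting target overlap
    n_off = int(n_by_class[1])
    if n_off:
        if not genome.decoys:
            raise ValueError("profile requests nuclear reads but no decoys")
        dnames = [d.name for d in genome.decoys]
        dsizes = np.array([len(d) for d in genome.decoys], dtype=float)
        choice = rng.choice(len(dnames), size=n_off, p=dsizes / dsizes.sum())
        flens = _fragment_lengths(rng, n_off, profile, int(dsizes.min()))
        starts = np.empty(n_off, dtype=np.int64)
        contigs = np.array([dnames[c] for c in choice], dtype=object)
        # per-decoy prefix sums of the in-target mask for fast overlap tests
        csums = {}
        for d in genome.decoys:
            mask = np.zeros(len(d) + 1, dtype=np.int64)
            for s, e in genome.targets.for_contig(d.name):
                mask[s:e] = 1
            csums[d.name] = np.concatenate([[0], np.cumsum(mask[:-1])])
        for i in range(n_off):
            name = contigs[i]
            clen = len(decoy_arrs[name])
            cs = csums[name]
            for _attempt in range(200):
                s = int(rng.integers(0, clen - flens[i] + 1))
                if cs[min(s + flens[i], clen)] - cs[s] == 0:
                    break
            starts[i] = s
        for name in decoy_arrs:
            sel = contigs == name
            if sel.any():
                emit(
                    name,
                    decoy_arrs[name],
                    starts[sel],
                    flens[sel],
                    "off_target_nuclear",
                    False,
                )

    # --- true mitochondrial fragments (haplotype mixing happens here) ----
    n_mito = int(n_by_class[2])
    if n_mito:
        flens = _fragment_lengths(rng, n_mito, profile, L)
        starts = rng.integers(0, L, size=n_mito)
        r1, r2raw = _reads_from_windows(mito_arr, starts, flens, rl, True)
        offsets = np.arange(rl)
        idx1 = (starts[:, None] + offsets) % L
        idx2 = ((starts + flens - rl)[:, None] + offsets) % L
        for pos, alt, h in genotype.variants:
            carrier = rng.random(n_mito) < h
            alt_u8 = np.uint8(ord(alt))
            hit1 = carrier[:, None] & (idx1 == pos - 1)
            hit2 = carrier[:, None] & (idx2 == pos - 1)
            r1[hit1] = alt_u8
            r2raw[hit2] = alt_u8
        frag_contig.append(np.full(n_mito, genome.mito.name, dtype=object))
        frag_start.append(starts)
        frag_len.append(flens)
        frag_prov.append(np.full(n_mito, "mito", dtype=object))
        r1_parts.append(r1)
        r2_parts.append(r2raw)

    # --- NUMT-derived fragments ------------------------------------------
    n_numt = int(n_by_class[3])
    if n_numt:
        numts = [
            (d.name, a) for d in genome.decoys for a in d.numt_annotations
        ]
        if not numts:
            raise ValueError("profile requests NUMT reads but genome has no NUMTs")
        choice = rng.integers(0, len(numts), size=n_numt)
        flens = _fragment_lengths(
            rng, n_numt, profile, min(len(decoy_arrs[n]) for n, _ in numts)
        )
        starts = np.empty(n_numt, dtype=np.int64)
        contigs = np.empty(n_numt, dtype=object)
        for i, c in enumerate(choice):
            name, ann = numts[c]
            clen = len(decoy_arrs[name])
            lo = ann.insert_pos - 1
            hi = max(lo + 1, lo + ann.length - int(flens[i]) + 1)
            s = int(rng.integers(lo, hi))
            starts[i] = min(s, clen - flens[i])
            contigs[i] = name
        for name in decoy_arrs:
            sel = contigs == name
            if sel.any():
                emit(name, decoy_arrs[name], starts[sel], flens[sel], "numt", False)

    if frag_start:
        contig_all = np.concatenate(frag_contig)
        start_all = np.concatenate(frag_start)
        len_all = np.concatenate(frag_len)
        prov_all = np.concatenate(frag_prov)
        r1_all = np.vstack(r1_parts)
        r2raw_all = np.vstack(r2_parts)
    else:
        contig_all = np.empty(0, dtype=object)
        start_all = np.empty(0, dtype=np.int64)
        len_all = np.empty(0, dtype=np.int64)
        prov_all = np.empty(0, dtype=object)
        r1_all = np.empty((0, rl), dtype=np.uint8)
        r2raw_all = np.empty((0, rl), dtype=np.uint8)

    # sequencing error is applied after variant assignment
    _apply_errors(rng, r1_all, profile.error_rate)
    _apply_errors(rng, r2raw_all, profile.error_rate)
    r2_all = _revcomp_u8(r2raw_all)

    # --- PCR duplicates: exact copies of existing fragments --------------
    n_total = len(start_all)
    n_dup = int(rng.binomial(n_total, profile.duplicate_rate)) if n_total else 0
    dup_of = np.full(n_total, -1, dtype=np.int64)
    if n_dup:
        src = rng.integers(0, n_total, size=n_dup)
        contig_all = np.concatenate([contig_all, contig_all[src]])
        start_all = np.concatenate([start_all, start_all[src]])
        len_all = np.concatenate([len_all, len_all[src]])
        prov_all = np.concatenate([prov_all, prov_all[src]])
        r1_all = np.vstack([r1_all, r1_all[src]])
        r2_all = np.vstack([r2_all, r2_all[src]])
        dup_of = np.concatenate([dup_of, src])

    fragments = pd.DataFrame(
        {
            "contig": contig_all,
            "start": start_all,
            "length": len_all,
            "provenance": prov_all,
            "dup_of": dup_of,
        }
    )
    counts = {cls: int(n) for cls, n in zip(PROVENANCE_CLASSES, n_by_class)}
    counts["duplicates"] = n_dup
    truth = TruthRecord(
        sample=sample_id, genotype=genotype, counts=counts, seed=seed
    )
    return SimulatedSample(
        sample_id=sample_id,
        profile=profile,
        truth=truth,
        fragments=fragments,
        _r1=r1_all,
        _r2=r2_all,
    )


# ---------------------------------------------------------------------------
# Cohorts and I/O
# ---------------------------------------------------------------------------


def derive_sample_seed(master_seed: int, sample_id: str) -> int:
    """Stable per-sample seed; independent of cohort ordering, < 2**31."""
    return zlib.crc32(f"{master_seed}:{sample_id}".encode()) & 0x7FFFFFFF


def simulate_cohort(
    genome: SyntheticGenome,
    cohort_spec: Sequence[tuple[str, SampleProfile, GenotypeSpec]],
    seed: int = 0,
    outdir: str | Path | None = None,
) -> tuple[dict[str, SimulatedSample], pd.DataFrame]:
    """Simulate a cohort; optionally write FASTQs plus a truth TSV.

    Returns (samples keyed by id, truth table with one row per sample and
    variant — wild-type samples get a single row with pos 0).
    """
    ids = [sid for sid, _, _ in cohort_spec]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sample ids in cohort spec")
    samples: dict[str, SimulatedSample] = {}
    rows = []
    for sid, profile, genotype in cohort_spec:
        s_seed = derive_sample_seed(seed, sid)
        sim = simulate_sample(genome, profile, genotype, seed=s_seed, sample_id=sid)
        samples[sid] = sim
        variants = sim.truth.genotype.variants or ((0, ".", 0.0),)
        for pos, alt, h in variants:
            ref = genome.mito.base(pos) if pos >= 1 else "."
            rows.append(
                {
                    "sample": sid,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "h": h,
                    "n_mito": sim.truth.counts["mito"],
                    "n_numt": sim.truth.counts["numt"],
                    "n_ontarget": sim.truth.counts["on_target"],
                    "n_offtarget": sim.truth.counts["off_target_nuclear"],
                    "n_dup": sim.truth.counts["duplicates"],
                    "seed": s_seed,
                }
            )
    truth_table = pd.DataFrame(
        rows,
        columns=[
            "sample",
            "pos",
            "ref",
            "alt",
            "h",
            "n_mito",
            "n_numt",
            "n_ontarget",
            "n_offtarget",
            "n_dup",
            "seed",
        ],
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sid, sim in samples.items():
            write_fastq(sim, outdir / f"{sid}_R1.fastq", outdir / f"{sid}_R2.fastq")
        write_truth_table(truth_table, outdir / "truth.tsv")
    return samples, truth_table


def write_fastq(sample: SimulatedSample, r1_path, r2_path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for name, s1, q1, s2, q2 in sample.read_pairs():
            f1.write(f"@{name}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{q2}\n")


def write_truth_table(truth_table: pd.DataFrame, path) -> None:
    truth_table.to_csv(path, sep="\t", index=False)
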