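"""Per-position base counts over the mitochondrial genome plus coverage,
off-target and regression metrics.

The pileup counts each aligned base whose base quality and read
``mapq_proxy`` clear the configured filters (defaults min_bq=20,
min_mq=1 — explicit configuration, echoed into every output header, since
readcount tools differ in their defaults).  Overlapping mates are counted
independently, which mildly inflates depth where fragments are shorter
than twice the read length; this is documented rather than corrected.
Median coverage includes zero-depth positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align_extract import Alignment, AlignmentTally
from .reference_kb import MitoReference, RegionDef, MT_RNR1, NAMED_POSITIONS

__all__ = [
    "PileupFilters",
    "Pileup",
    "CoverageSummary",
    "RegressionResult",
    "build_pileup",
    "off_target_fraction",
    "coverage_summary",
    "cohort_coverage_table",
    "regress",
    "write_pileup_tsv",
    "read_pileup_tsv",
]

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class PileupFilters:
    min_bq: int = 20
    min_mq: int = 1


@dataclass
class Pileup:
    """Filtered base counts over the mitochondrial genome.

    ``counts`` has shape (L, 4) in A/C/G/T order, row i holding 1-based
    position i+1.  Depth at every position equals the row sum.
    """

    contig: str
    counts: np.ndarray
    filters: PileupFilters

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def base_counts(self, position: int) -> dict[str, int]:
        """Counts at a 1-based position."""
        row = self.counts[position - 1]
        return {b: int(row[i]) for i, b in enumerate(_BASES)}

    def depth_at(self, position: int) -> int:
        return int(self.counts[position - 1].sum())


def build_pileup(
    mito_alignments: Iterable[Alignment],
    mito_ref: MitoReference,
    filters: PileupFilters = PileupFilters(),
) -> Pileup:
    """Accumulate filtered base counts from mito-contig alignments.

    Alignments are expected deduplicated and on the mitochondrial contig
    only.  On the circular reference, positions wrap across the origin; in
    non-circular mode an alignment running past the end is an error.
    """
    L = len(mito_ref)
    counts = np.zeros((L, 4), dtype=np.int64)
    for aln in mito_alignments:
        if aln.contig != mito_ref.name:
            raise ValueError(
                f"alignment on {aln.contig!r}, expected {mito_ref.name!r}"
            )
        if aln.mapq_proxy < filters.min_mq:
            continue
        m = len(aln.seq)
        if aln.start + m > L and not mito_ref.circular:
            raise ValueError(
                f"alignment at {aln.start}+{m} beyond non-circular contig end {L}"
            )
        pos = (aln.start + np.arange(m)) % L
        seq = np.frombuffer(aln.seq.encode("ascii"), dtype=np.uint8)
        qual = np.frombuffer(aln.qual.encode("ascii"), dtype=np.uint8) - 33
        for i, b in enumerate(_BASES.encode("ascii")):
            sel = (seq == b) & (qual >= filters.min_bq)
            if sel.any():
                np.add.at(counts[:, i], pos[sel], 1)
    return Pileup(contig=mito_ref.name, counts=counts, filters=filters)


def off_target_fraction(tally: AlignmentTally) -> float | None:
    """Share of off-target reads that map to the mitochondrial genome.

    Defined as mito-mapped reads over all off-target reads; undefined
    (None, reported as missing) when there are no off-target reads.
    """
    if tally.off_target == 0:
        return None
    return tally.mito_mapped / tally.off_target


@dataclass(frozen=True)
class CoverageSummary:
    region: RegionDef
    median: float
    threshold_fractions: Mapping[int, float]  # depth >= t, per position
    named_depths: Mapping[int, int]  # depth at named rCRS positions


def coverage_summary(
    pileup: Pileup,
    region: RegionDef | None = None,
    thresholds: Sequence[int] = (5, 20, 30, 40),
    named_positions: Sequence[int] = NAMED_POSITIONS,
) -> CoverageSummary:
    """Median depth and threshold fractions over a region (zeros included)."""
    if region is None:
        region = RegionDef(pileup.contig, 1, pileup.length)
    if region.end > pileup.length:
        raise ValueError(
            f"region {region.gene} ends at {region.end} beyond contig length "
            f"{pileup.length}"
        )
    depth = pileup.depth[region.start - 1 : region.end]
    if depth.size == 0:
        raise ValueError("empty region")
    return CoverageSummary(
        region=region,
        median=float(np.median(depth)),
        threshold_fractions={
            t: float((depth >= t).mean()) for t in thresholds
        },
        named_depths={
            p: pileup.depth_at(p) for p in named_positions if p <= pileup.length
        },
    )


def cohort_coverage_table(
    samples: Mapping[str, tuple[AlignmentTally | None, Pileup]],
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample metrics plus the across-sample per-position median track.

    Returns a DataFrame (sample, off_target_fraction, median_mito_coverage,
    depth_m1555) and a length-L array of per-position median depth across
    samples.
    """
    if not samples:
        raise ValueError("cohort_coverage_table requires >= 1 sample")
    rows = []
    depths = []
    for sample, (tally, pileup) in samples.items():
        summary = coverage_summary(pileup)
        rows.append(
            {
                "sample": sample,
                "off_target_fraction": (
                    off_target_fraction(tally) if tally is not None else None
                ),
                "median_mito_coverage": summary.median,
                "depth_m1555": summary.named_depths.get(1555),
            }
        )
        depths.append(pileup.depth)
    lengths = {d.size for d in depths}
    if len(lengths) != 1:
        raise ValueError("samples have pileups of different lengths")
    median_track = np.median(np.vstack(depths), axis=0)
    return pd.DataFrame(rows), median_track


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float  # two-sided, t-distributed with n-2 df
    n: int


def regress(x_values: Sequence[float], y_values: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x (e.g., mito coverage on off-target).

    Pearson r and the two-sided p-value come from the t statistic with
    n-2 degrees of freedom.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"regression needs n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------


def write_pileup_tsv(
    pileup: Pileup, mito_ref: MitoReference, path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as out:
        out.write(
            f"# contig={pileup.contig} min_bq={pileup.filters.min_bq} "
            f"min_mq={pileup.filters.min_mq}\n"
        )
        for line in header_lines:
            out.write(f"# {line}\n")
        out.write("pos\tref\tA\tC\tG\tT\tdepth\n")
        depth = pileup.depth
        for i in range(pileup.length):
            a, c, g, t = pileup.counts[i]
            out.write(
                f"{i + 1}\t{mito_ref.sequence[i]}\t{a}\t{c}\t{g}\t{t}\t{depth[i]}\n"
            )


def read_pileup_tsv(path) -> Pileup:
    filters = PileupFilters()
    contig = "MT"
    rows = []
    with open(path) as f:
        for line in f:
            if line.startswith("#"):
                if "min_bq=" in line:
                    fields = dict(
                        kv.split("=") for kv in line[1:].split() if "=" in kv
                    )
                    contig = fields.get("contig", contig)
                    filters = PileupFilters(
                        min_bq=int(fields.get("min_bq", filters.min_bq)),
                        min_mq=int(fields.get("min_mq", filters.min_mq)),
                    )
                continue
            if line.startswith("pos\t"):
                continue
            fields = line.split("\t")
            rows.append([int(fields[2]), int(fields[3]), int(fields[4]), int(fields[5])])
    return Pileup(
        contig=contig, counts=np.array(rows, dtype=np.int64), filters=filters
    )
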