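"""Knowledge-base annotation, cohort prevalence and heteroplasmy evidence.

Prevalence arithmetic is exact rational until the formatting boundary:
percent values are rendered in two styles (two decimals for tables,
one decimal for prose-style summaries) but never fed back into any
computation.  Undetermined samples stay in the denominator by default,
matching how carrier frequency is quoted for a diagnostic cohort; a
switch excludes them for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genotype import (
    CARRIER_CLASSES,
    GenotypeClass,
    VariantCall,
    round_half_up,
)
from .reference_kb import KBEntry, kb_lookup

__all__ = [
    "annotate",
    "PrevalenceReport",
    "cohort_prevalence",
    "heteroplasmy_evidence",
    "write_vcf",
]


def annotate(
    variant_calls: Sequence[VariantCall], kb: Sequence[KBEntry]
) -> pd.DataFrame:
    """Left-join PASS-stage calls to the knowledge base.

    Every input call yields exactly one output row; calls absent from the
    KB get tier ``not_in_kb``.  Homopolymer-flagged KB entries carry their
    caution note through.
    """
    lut = kb_lookup(kb)
    rows = []
    for call in variant_calls:
        entry = lut.get((call.position, call.ref, call.alt))
        rows.append(
            {
                "pos": call.position,
                "ref": call.ref,
                "alt": call.alt,
                "alt_reads": call.alt_reads,
                "depth": call.depth,
                "vaf": call.vaf,
                "filter": call.filter,
                "tier": entry.evidence_tier if entry else "not_in_kb",
                "note": entry.note if entry else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pos",
            "ref",
            "alt",
            "alt_reads",
            "depth",
            "vaf",
            "filter",
            "tier",
            "note",
        ],
    )


@dataclass(frozen=True)
class PrevalenceReport:
    n_samples: int
    n_carriers: int
    fraction: Fraction  # exact n_carriers / n_samples
    per_variant: Mapping[tuple[int, str], int]  # (pos, alt) -> carrier count
    undetermined_samples: tuple[str, ...]

    @property
    def percent(self) -> float:
        """Carrier percentage, half-up to two decimals (table style)."""
        return round_half_up(100 * float(self.fraction), 2)

    @property
    def percent_1dp(self) -> float:
        """Carrier percentage, half-up to one decimal (prose style)."""
        return round_half_up(100 * float(self.fraction), 1)

    @property
    def ratio(self) -> str | None:
        """Carrier odds as '1:N' with N = round(samples / carriers)."""
        if self.n_carriers == 0:
            return None
        return f"1:{round(self.n_samples / self.n_carriers)}"


def cohort_prevalence(
    genotype_table: pd.DataFrame, include_undetermined: bool = True
) -> PrevalenceReport:
    """Carrier prevalence over a genotype table.

    A sample is a carrier when any of its site calls is a carrier class.
    Samples undetermined at every site are listed separately and, by
    default, kept in the denominator.
    """
    if genotype_table.empty:
        raise ValueError("cohort_prevalence requires a non-empty genotype table")
    carrier_values = {c.value for c in CARRIER_CLASSES}
    by_sample = genotype_table.groupby("sample")["class"]
    carriers = by_sample.apply(lambda s: s.isin(carrier_values).any())
    undetermined = by_sample.apply(
        lambda s: (s == GenotypeClass.UNDETERMINED.value).all()
    )
    n_total = int(carriers.size)
    if not include_undetermined:
        n_total -= int(undetermined.sum())
    n_carriers = int(carriers.sum())
    if n_total == 0:
        raise ValueError("prevalence denominator is zero")
    carrier_rows = genotype_table[genotype_table["class"].isin(carrier_values)]
    per_variant: dict[tuple[int, str], int] = {}
    for _, row in carrier_rows.iterrows():
        key = (int(row["pos"]), str(row["alt"]))
        per_variant[key] = per_variant.get(key, 0) + 1
    return PrevalenceReport(
        n_samples=n_total,
        n_carriers=n_carriers,
        fraction=Fraction(n_carriers, n_total),
        per_variant=per_variant,
        undetermined_samples=tuple(undetermined[undetermined].index),
    )


def heteroplasmy_evidence(
    genotype_table: pd.DataFrame,
    promoted: Iterable[tuple[str, int]] = (),
) -> pd.DataFrame:
    """Samples with heteroplasmy evidence.

    Automatic entries are carrier_heteroplasmic calls (VAF within the
    0.10-0.90 window with >5 reads on each allele).  ``promoted`` lists
    (sample, position) manual-review calls a reviewer chose to include —
    the pattern of a near-homoplasmic VAF at high depth judged real on
    inspection; these appear with provenance ``manual_review``.
    """
    promoted = set(promoted)
    rows = []
    for _, row in genotype_table.iterrows():
        key = (row["sample"], int(row["pos"]))
        if row["class"] == GenotypeClass.CARRIER_HETEROPLASMIC.value:
            rows.append({**_evidence_row(row), "provenance": "automatic"})
        elif row["class"] == GenotypeClass.MANUAL_REVIEW.value and key in promoted:
            rows.append({**_evidence_row(row), "provenance": "manual_review"})
    return pd.DataFrame(
        rows, columns=["sample", "pos", "ref", "alt", "vaf", "provenance"]
    )


def _evidence_row(row) -> dict:
    return {
        "sample": row["sample"],
        "pos": int(row["pos"]),
        "ref": row["ref"],
        "alt": row["alt"],
        "vaf": round_half_up(row["vaf"], 2) if row["vaf"] == row["vaf"] else None,
    }


def write_vcf(
    genotype_table: pd.DataFrame,
    mito_name: str,
    mito_length: int,
    path,
    mode: str = "clinical",
    vaf_min: float = 0.10,
    header_extra: Sequence[str] = (),
) -> None:
    """Write per-sample site calls as VCF v4.2 (substitutions only).

    One record per (sample, position) with a non-reference allele; the
    sample id travels in INFO/SAMPLE since records are concatenated rather
    than merged into a multi-sample matrix.  FILTER is ``below_vaf`` for
    retained-below-threshold records, PASS otherwise.
    """
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write(f"##contig=<ID={mito_name},length={mito_length}>\n")
        out.write(
            '##INFO=<ID=VAF,Number=1,Type=Float,Description='
            '"Variant allele fraction (alt / (ref + alt))">\n'
        )
        out.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Ref + alt depth">\n')
        out.write(
            '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample identifier">\n'
        )
        out.write(
            '##INFO=<ID=CLASS,Number=1,Type=String,Description="Genotype class">\n'
        )
        out.write(
            '##FILTER=<ID=below_vaf,Description='
            f'"VAF below the {vaf_min:g} retention threshold">\n'
        )
        out.write(f"##mitoff_mode={mode}\n")
        for line in header_extra:
            out.write(f"##{line}\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        table = genotype_table.sort_values(["pos", "sample"])
        for _, row in table.iterrows():
            if row["alt"] in (".", None) or row["alt_reads"] == 0:
                continue
            vaf = row["vaf"]
            filt = "PASS" if vaf is not None and vaf >= vaf_min else "below_vaf"
            depth = int(row["ref_reads"]) + int(row["alt_reads"])
            out.write(
                f"{mito_name}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}\t.\t"
                f"{filt}\tVAF={vaf:.4f};DP={depth};SAMPLE={row['sample']};"
                f"CLASS={row['class']}\n"
            )
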