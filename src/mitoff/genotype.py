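"""Variant retention and genotype / heteroplasmy classification.

Two gates operate in sequence.  Retention: at each position the most
frequent non-reference base is considered and PASSes when its variant
allele fraction (VAF = alt / (ref + alt)) is at least 10%.  Classification
then assigns a genotype class from the ref/alt read counts:

Clinical mode (adequate coverage, conservative):
  * depth < min_depth (default 5)            -> undetermined
  * alt == 0                                 -> wild_type
  * alt == 1 and depth > artifact_depth (40) -> wild_type_artifact
    (a single variant read at good depth is an artifact or very low
    heteroplasmy, not a carrier call)
  * 0.10 <= VAF <= 0.90, ref > 5, alt > 5    -> carrier_heteroplasmic
  * VAF > 0.90 and ref <= 5                  -> carrier_homoplasmic
  * VAF > 0.90 and ref > 5                   -> manual_review
  * anything else                            -> manual_review

Research low-coverage mode (sparse off-target pileups; homoplasmy is
assumed because a handful of molecules cannot quantify heteroplasmy):
  * depth == 0                  -> undetermined
  * alt >= 1 and ref == 0       -> carrier_homoplasmic (low_coverage flag)
  * alt == 0                    -> wild_type
  * alt >= 1 and ref >= 1       -> manual_review (mixtures are not
    resolvable at this depth)

VAFs are computed on raw fractions; rounding (half-up, two decimals)
happens only at the reporting boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .pileup_metrics import Pileup
from .reference_kb import MitoReference, RegionDef, MT_RNR1, load_kb

__all__ = [
    "GenotypeClass",
    "Mode",
    "ClassifyParams",
    "SiteCall",
    "VariantCall",
    "round_half_up",
    "call_variants",
    "classify_site",
    "classify_pileup_site",
    "genotype_cohort",
    "concordance",
    "ConcordanceSummary",
    "CARRIER_CLASSES",
]

_BASES = "ACGT"


class GenotypeClass(str, Enum):
    WILD_TYPE = "wild_type"
    CARRIER_HOMOPLASMIC = "carrier_homoplasmic"
    CARRIER_HETEROPLASMIC = "carrier_heteroplasmic"
    WILD_TYPE_ARTIFACT = "wild_type_artifact"
    UNDETERMINED = "undetermined"
    MANUAL_REVIEW = "manual_review"


CARRIER_CLASSES = frozenset(
    {GenotypeClass.CARRIER_HOMOPLASMIC, GenotypeClass.CARRIER_HETEROPLASMIC}
)


class Mode(str, Enum):
    CLINICAL = "clinical"
    RESEARCH_LOW_COVERAGE = "research_low_coverage"


@dataclass(frozen=True)
class ClassifyParams:
    """Classification thresholds (configuration, echoed into outputs)."""

    min_depth_clinical: int = 5
    min_depth_research: int = 1
    artifact_depth: int = 40  # single alt read at depth > this -> artifact
    het_vaf_low: float = 0.10  # heteroplasmy window, inclusive
    het_vaf_high: float = 0.90
    het_min_allele_reads: int = 5  # window requires ref > 5 and alt > 5

    def min_depth(self, mode: Mode) -> int:
        return (
            self.min_depth_clinical
            if mode is Mode.CLINICAL
            else self.min_depth_research
        )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.125 -> 0.13), used only for reporting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SiteCall:
    """Genotype call at one position from ref/alt read counts."""

    position: int
    ref_base: str
    alt_base: str | None
    ref_reads: int
    alt_reads: int
    genotype_class: GenotypeClass
    flags: frozenset[str] = frozenset()

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads

    @property
    def vaf(self) -> float | None:
        """Raw alt fraction of ref+alt reads; None at zero depth."""
        if self.depth == 0:
            return None
        return self.alt_reads / self.depth

    @property
    def vaf_2dp(self) -> float | None:
        """VAF rounded half-up to two decimals (reporting style)."""
        return None if self.vaf is None else round_half_up(self.vaf, 2)


@dataclass(frozen=True)
class VariantCall:
    """Retention-stage record for the top non-reference base at a position."""

    position: int
    ref: str
    alt: str
    alt_reads: int
    depth: int
    filter: str  # PASS | below_vaf | below_depth

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.depth if self.depth else 0.0

    @property
    def vaf_2dp(self) -> float:
        return round_half_up(self.vaf, 2)


def call_variants(
    pileup: Pileup,
    mito_ref: MitoReference,
    region: RegionDef = MT_RNR1,
    vaf_min: float = 0.10,
    min_alt_reads: int = 2,
) -> list[VariantCall]:
    """Retention gate: top non-reference base per position, VAF-filtered.

    PASS requires both ``alt_reads >= min_alt_reads`` and ``vaf >=
    vaf_min`` (raw fraction); records failing only the read-support floor
    are ``below_depth``, those failing the fraction are ``below_vaf``.
    """
    calls: list[VariantCall] = []
    for pos in region.positions():
        if pos > pileup.length:
            break
        counts = pileup.base_counts(pos)
        ref = mito_ref.base(pos)
        depth = sum(counts.values())
        if depth == 0:
            continue
        alts = {b: n for b, n in counts.items() if b != ref and n > 0}
        if not alts:
            continue
        alt = max(sorted(alts), key=lambda b: alts[b])
        alt_reads = alts[alt]
        vaf = alt_reads / depth
        if alt_reads < min_alt_reads:
            status = "below_depth"
        elif vaf >= vaf_min:
            status = "PASS"
        else:
            status = "below_vaf"
        calls.append(
            VariantCall(
                position=pos,
                ref=ref,
                alt=alt,
                alt_reads=alt_reads,
                depth=depth,
                filter=status,
            )
        )
    return calls


def classify_site(
    ref_reads: int,
    alt_reads: int,
    mode: Mode | str = Mode.CLINICAL,
    params: ClassifyParams = ClassifyParams(),
    position: int = 0,
    ref_base: str = "N",
    alt_base: str | None = None,
    extra_flags: Iterable[str] = (),
) -> SiteCall:
    """Classify one site from its reference and alternative read counts.

    Total over non-negative count pairs: every (ref, alt) maps to exactly
    one genotype class per mode, and the class is ``undetermined`` iff the
    depth is below the mode's minimum.
    """
    mode = Mode(mode)
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    depth = ref_reads + alt_reads
    flags = set(extra_flags)
    vaf = alt_reads / depth if depth else None

    if depth < params.min_depth(mode):
        cls = GenotypeClass.UNDETERMINED
        if mode is Mode.CLINICAL and depth > 0:
            flags.add("low_coverage")
    elif mode is Mode.RESEARCH_LOW_COVERAGE:
        if alt_reads >= 1 and ref_reads == 0:
            cls = GenotypeClass.CARRIER_HOMOPLASMIC
            flags.add("low_coverage")
        elif alt_reads == 0:
            cls = GenotypeClass.WILD_TYPE
        else:
            cls = GenotypeClass.MANUAL_REVIEW
            flags.add("low_coverage")
    else:  # clinical
        if alt_reads == 0:
            cls = GenotypeClass.WILD_TYPE
        elif alt_reads == 1 and depth > params.artifact_depth:
            cls = GenotypeClass.WILD_TYPE_ARTIFACT
        elif (
            params.het_vaf_low <= vaf <= params.het_vaf_high
            and ref_reads > params.het_min_allele_reads
            and alt_reads > params.het_min_allele_reads
        ):
            cls = GenotypeClass.CARRIER_HETEROPLASMIC
        elif vaf > params.het_vaf_high and ref_reads <= params.het_min_allele_reads:
            cls = GenotypeClass.CARRIER_HOMOPLASMIC
        elif vaf > params.het_vaf_high:
            cls = GenotypeClass.MANUAL_REVIEW
        else:
            cls = GenotypeClass.MANUAL_REVIEW
    return SiteCall(
        position=position,
        ref_base=ref_base,
        alt_base=alt_base,
        ref_reads=ref_reads,
        alt_reads=alt_reads,
        genotype_class=cls,
        flags=frozenset(flags),
    )


def _homopolymer_context(sequence: str, position: int, min_run: int = 4) -> bool:
    """True when a run of >= min_run identical bases touches the position.

    The run may contain the position or abut it on either side (the 961
    case: a lone T between cytosine runs still gets the flag).
    """
    L = len(sequence)
    i = position - 1
    for j in (i - 1, i, i + 1):
        if not 0 <= j < L:
            continue
        base = sequence[j]
        run = 1
        k = j - 1
        while k >= 0 and sequence[k] == base:
            run += 1
            k -= 1
        k = j + 1
        while k < L and sequence[k] == base:
            run += 1
            k += 1
        if run >= min_run:
            return True
    return False


def classify_pileup_site(
    pileup: Pileup,
    mito_ref: MitoReference,
    position: int,
    mode: Mode | str = Mode.CLINICAL,
    params: ClassifyParams = ClassifyParams(),
) -> SiteCall:
    """Classify a position from a pileup (top non-ref base is the alt)."""
    counts = pileup.base_counts(position)
    ref = mito_ref.base(position)
    ref_reads = counts.get(ref, 0)
    alts = {b: n for b, n in counts.items() if b != ref}
    alt = max(sorted(alts), key=lambda b: alts[b]) if alts else None
    alt_reads = alts[alt] if alt and alts[alt] > 0 else 0
    flags = (
        {"homopolymer_context"}
        if _homopolymer_context(mito_ref.sequence, position)
        else set()
    )
    return classify_site(
        ref_reads,
        alt_reads,
        mode=mode,
        params=params,
        position=position,
        ref_base=ref,
        alt_base=alt if alt_reads > 0 else None,
        extra_flags=flags,
    )


def genotype_cohort(
    pileups: Mapping[str, Pileup],
    mito_ref: MitoReference,
    positions: Sequence[int] | None = None,
    mode: Mode | str = Mode.CLINICAL,
    params: ClassifyParams = ClassifyParams(),
) -> pd.DataFrame:
    """One SiteCall per (sample, position), as a tidy table.

    Default positions are the knowledge-base ototoxicity positions that fit
    on the reference.
    """
    if positions is None:
        positions = sorted(
            {e.position for e in load_kb() if e.position <= len(mito_ref)}
        )
    rows = []
    for sample in sorted(pileups):
        for pos in positions:
            call = classify_pileup_site(
                pileups[sample], mito_ref, pos, mode=mode, params=params
            )
            rows.append(_call_row(sample, call))
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


_TABLE_COLUMNS = [
    "sample",
    "pos",
    "ref",
    "alt",
    "ref_reads",
    "alt_reads",
    "vaf",
    "class",
    "flags",
]


def _call_row(sample: str, call: SiteCall) -> dict:
    return {
        "sample": sample,
        "pos": call.position,
        "ref": call.ref_base,
        "alt": call.alt_base or ".",
        "ref_reads": call.ref_reads,
        "alt_reads": call.alt_reads,
        "vaf": call.vaf,
        "class": call.genotype_class.value,
        "flags": ",".join(sorted(call.flags)) or ".",
    }


def calls_to_table(calls: Mapping[str, SiteCall] | Iterable[tuple[str, SiteCall]]) -> pd.DataFrame:
    """Assemble (sample, SiteCall) pairs into the genotype-table layout."""
    items = calls.items() if isinstance(calls, Mapping) else calls
    return pd.DataFrame(
        [_call_row(sample, call) for sample, call in items], columns=_TABLE_COLUMNS
    )


_COLLAPSE = {
    GenotypeClass.WILD_TYPE.value: "wild_type",
    GenotypeClass.WILD_TYPE_ARTIFACT.value: "wild_type",
    GenotypeClass.CARRIER_HOMOPLASMIC.value: "carrier",
    GenotypeClass.CARRIER_HETEROPLASMIC.value: "carrier",
    GenotypeClass.MANUAL_REVIEW.value: "manual_review",
    GenotypeClass.UNDETERMINED.value: "undetermined",
}


@dataclass(frozen=True)
class ConcordanceSummary:
    concordant: int
    discordant: int
    unilaterally_undetermined: int
    compared: int  # pairs entering the concordance denominator

    @property
    def concordance_rate(self) -> float | None:
        return self.concordant / self.compared if self.compared else None


def concordance(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> ConcordanceSummary:
    """Compare two genotype tables on shared (sample, position) pairs.

    Classes collapse to carrier / wild_type / manual_review before
    comparison; pairs undetermined on either side leave the denominator and
    are counted separately (a sample with no reads is not a discordance).
    """
    merged = table_a.merge(
        table_b, on=["sample", "pos"], suffixes=("_a", "_b"), how="inner"
    )
    if merged.empty:
        warnings.warn("no shared (sample, position) pairs to compare", stacklevel=2)
        return ConcordanceSummary(0, 0, 0, 0)
    a = merged["class_a"].map(_COLLAPSE)
    b = merged["class_b"].map(_COLLAPSE)
    undet = (a == "undetermined") | (b == "undetermined")
    conc = int(((a == b) & ~undet).sum())
    disc = int(((a != b) & ~undet).sum())
    return ConcordanceSummary(
        concordant=conc,
        discordant=disc,
        unilaterally_undetermined=int(undet.sum()),
        compared=conc + disc,
    )
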