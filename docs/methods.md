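# Methods

This note documents the models, parameter choices and limitations behind
`mitoff`: what each stage assumes, why the defaults are what they are, and
what passing the test suite does and does not demonstrate about real data.

## Problem setting

Hybridization-capture NGS (custom gene panels, exomes) targets nuclear
regions only, but enrichment is imperfect: panels of ~135 kb leave roughly
half of all reads off-target, exomes (~60 Mb) around 15%. A few parts in
ten thousand of that off-target mass derive from true mitochondrial DNA —
enough, at exome sequencing depths, for tens-fold coverage of the
mitochondrial genome and hence for genotyping the *MT-RNR1* ototoxicity
positions. The two obstacles are (1) NUMTs, diverged nuclear copies of
mtDNA whose reads masquerade as mitochondrial and distort allele
fractions, and (2) the low and variable depth of an off-target signal,
which forces explicit rules for when a genotype may be called at all.

## Coordinates and references

External formats keep native conventions (BED 0-based half-open; rCRS and
VCF positions 1-based); all internal interval arithmetic is 0-based
half-open with conversion at the I/O boundary. The mitochondrial contig is
circular; the aligner indexes k-mers across the origin junction and
placements wrap modulo the contig length. The *MT-RNR1* span defaults to
rCRS 648–1601 — a standard annotation convention, configurable, used for
gene-level coverage summaries. The bundled knowledge base is data, not
code: a 16-row TSV of reported ototoxicity variants (m.1555A>G and
m.1494C>T tier *strong*; fourteen variants, including both m.961T>C and
m.961T>G, tier *needs further study*), validated against the loaded
reference at load time.

## Synthetic capture experiments

The simulator emulates the provenance structure of a capture experiment:
each fragment is on-target nuclear, off-target nuclear, true
mitochondrial, or NUMT-derived, drawn multinomially from the profile's
`off_target_fraction` and, within the off-target mass, `mito_weight` and
`numt_weight`. Fragment starts are uniform per contig (off-target nuclear
starts reject target overlap, so the realized off-target fraction
converges to the profile's); fragment lengths are normal (mean 300 bp, sd
50 bp) truncated at the read length; 100 bp mates are taken from the
fragment ends. Heteroplasmy is molecule-level: at each specified variant a
fragment carries the alternative allele with probability *h*,
independently per fragment; per-base substitution errors (default 10⁻³,
uniform across the three other bases) are applied after variant
assignment. PCR duplicates are exact copies of already-emitted fragments
(default rate 2%), so coordinate-based deduplication can remove them
exactly. Base qualities are constant Q30-style. Per-sample seeds derive
from the master seed and the sample id, so cohorts are reproducible and
order-independent.

Preset profiles encode the sample-type regimes such experiments show.
The panel and exome off-target fractions (0.50 / 0.15) and the blood-type
mito shares of off-target mass (3×10⁻⁴ panel, 2×10⁻⁴ exome) are the
observed figures for those regimes; the remaining weights (saliva
9×10⁻⁴; FFPE panel 0.73 off-target with 5.3×10⁻³ mito share; frozen
tissue 0.05 / 1.9×10⁻⁴; clinical exome 4.3×10⁻⁴ at 75 M pairs) are
calibrated once so expected mtDNA coverage lands near the per-regime
medians (≈5× panel blood through ≈93× FFPE, ≈59× clinical exome) at the
stated sequencing depths. These presets define regimes, not generative
truths: medians constrain them only loosely.

What the simulator does **not** model: indels, FFPE deamination
chemistry, platform error profiles, GC coverage bias, chimeric fragments,
and NUMT content beyond the explicitly inserted segments. Passing
recovery tests therefore shows the pipeline's logic is correct under the
stated generative assumptions, not that real-data artifacts (notably
homopolymer indels around m.961 and unannotated NUMTs) are handled.

## Alignment and two-step extraction

The aligner is deliberately minimal: exact 15-mer seeds (forward index;
reverse strand via the read's reverse complement), full-length ungapped
scoring at match +1 / mismatch −4, minimum reported score 20 (≈13
mismatches over 100 bp). No indels — the substitution variants at issue
do not need them, and indel calling at the m.961 homopolymer is flagged,
not solved. `mapq_proxy` is the best-minus-second-best score gap (the
best score itself when the placement is unique); it is a confidence
proxy, not a calibrated MAPQ, and the pileup's default `min_mq=1` simply
drops placement ties.

Extraction follows the two-step design: step 1 aligns everything to the
mitochondrial reference alone (cheap — reads without a mitochondrial
15-mer short-circuit); step 2 competitively realigns step-1 hits against
the combined reference. Retention as mitochondrial requires the best mito
placement to beat every nuclear placement **strictly**; ties are assigned
nuclear and counted as ambiguous. The tie rule minimizes false mito
retention at a small sensitivity cost — a true mtDNA read whose span
contains no site distinguishing it from a NUMT copy is indistinguishable
from that copy, and the ambiguous count quantifies the trade-off. On
simulated NUMT reads at 5% divergence the wrongly-retained fraction is
bounded by the probability that a read window covers zero diverged sites
(and is zero under the strict rule); the test suite checks both this
bound and exact equivalence with a brute-force all-placements oracle on
500-read instances.

Duplicates are removed by fragment signature — (contig, outer start,
outer end, strand orientation) for linked mates, (contig, start, strand)
for singletons — keeping the lexicographically first read id, which makes
the operation deterministic and idempotent. External alignments import
from SAM/BAM; the mitochondrial contig is recognized case-insensitively
among MT/chrM/chrMT, and a read is on-target when it overlaps a target
interval by at least one base.

## Pileup and metrics

Each aligned base increments its counter when base quality ≥ `min_bq`
(default 20) and the read's `mapq_proxy` ≥ `min_mq` (default 1); the
filters are explicit configuration echoed into every output header,
because readcount tools differ in their defaults. Overlapping mates are
counted independently — a documented upward bias on depth (and a variance
reduction on VAF) where fragments are shorter than twice the read length.
Median coverage includes zero-depth positions. The off-target mito
fraction is mito-mapped reads over off-target reads, undefined (missing,
not zero) when no off-target reads exist. The coverage↔off-target
association uses ordinary least squares (scipy's linregress), with
Pearson r and a two-sided p from the t statistic at n−2 df; a
normal-equations oracle pins the implementation to 10⁻⁹.

## Genotype classification

Retention and classification are two separate gates. Retention keeps the
most frequent non-reference base per position when VAF ≥ 0.10 (records
with fewer than 2 supporting reads are filtered `below_depth`, those
under the fraction `below_vaf`). Classification is a total function of
(ref, alt) counts per mode; the clinical rules are listed in the README.
Noteworthy choices:

* The heteroplasmy window [0.10, 0.90] is inclusive at both edges and
  additionally requires more than five reads supporting each allele.
* `artifact_depth` = 40: exactly one alternative read at depth > 40 is
  called wild type (artifact or sub-quantifiable heteroplasmy) rather
  than carrier.
* A VAF > 0.90 with more than five reference reads is *manual review*,
  not homoplasmic — at high depth residual reference support may be real
  low-level heteroplasmy or NUMT leakage, and deserves eyes.
* Residual configurations (e.g., VAF < 0.10 with several alt reads)
  resolve to *manual review* rather than silent wild type: clinical
  conservatism where no rule clearly applies.
* Research low-coverage mode calls a homoplasmic carrier only when **no**
  read supports the reference; any mixture at such depths goes to manual
  review. The minimum depths (clinical 5, research 1) are conventions,
  logged in outputs, not measured constants.
* VAF is rounded half-up to two decimals only at the reporting boundary;
  raw fractions drive every comparison.

Positions whose immediate neighbourhood (the position or an adjacent
base) lies in a run of ≥4 identical reference bases carry a
`homopolymer_context` flag — m.961, a lone T between cytosine runs, is
the motivating case.

## Reporting

Prevalence is exact rational arithmetic (carriers / samples, undetermined
samples kept in the denominator by default, with an exclusion switch);
formatting — two decimals for tables, one for prose, the `1:N` ratio with
N = round(samples/carriers) — never feeds back into computation.
Heteroplasmy evidence lists automatic heteroplasmic calls plus
manual-review entries explicitly promoted by a reviewer, with provenance.
VCF v4.2 output carries VAF/DP/CLASS in INFO, `below_vaf` in FILTER and
the mode and thresholds in the header.

## Problem sizes in the test suite

Tests run on a 3,000-base circular mitochondrial reference (every
knowledge-base position sits below 1,601, so all coordinate paths are
exercised) with an 8,000-base decoy carrying one 601-base NUMT at 5%
divergence. Deep-coverage recovery tests use ~1,600 read pairs with an
inflated mito weight, giving ≥50× at m.1555 in seconds; the
law-of-large-numbers check uses 100,000 pairs; the NUMT-relocation bound
uses 10,000 NUMT-origin reads; brute-force oracle comparisons use 500
reads. These sizes are the package's own scaling choice: the statistical
structure (provenance proportions, binomial heteroplasmy, divergence
geometry) is preserved while keeping exhaustive oracles affordable.

## Known limitations

* Ungapped alignment only: indels, split reads and soft-clipping are out
  of scope, and the SAM dialect is all-M.
* The NUMT model covers annotated, inserted segments; genome-wide NUMT
  catalogs are not bundled.
* VAF is not corrected for residual NUMT contamination beyond the
  alignment-stage relocation.
* `mapq_proxy` thresholds are not comparable to BWA MAPQ values.
* The simulator's quality model is constant; base-quality-sensitive
  behaviour beyond a single threshold is untested.
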