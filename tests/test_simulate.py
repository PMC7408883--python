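"""Simulator: determinism, provenance conservation, variant mixing, errors."""

import numpy as np
import pytest
from scipy import stats

from mitoff.simulate import (
    GenotypeSpec,
    PRESETS,
    SampleProfile,
    build_synthetic_genome,
    parse_read_name,
    simulate_cohort,
    simulate_sample,
)
from conftest import NUMT_SPEC, SMALL_MITO_LEN, deep_profile


class TestGenomeConstruction:
    def test_numt_divergence_matches_binomial(self, small_genome):
        """The inserted NUMT differs from its mito source at ~divergence."""
        mt_start, mt_end, div = NUMT_SPEC
        decoy = small_genome.decoys[0]
        ann = decoy.numt_annotations[0]
        src = small_genome.mito.sequence[mt_start - 1 : mt_end]
        copy = decoy.sequence[ann.insert_pos - 1 : ann.insert_pos - 1 + ann.length]
        mismatches = sum(a != b for a, b in zip(src, copy))
        n = len(src)
        lo, hi = stats.binom.interval(0.999, n, div)
        assert lo <= mismatches <= hi

    def test_no_numts_means_no_shared_kmers(self, numt_free_genome):
        k = 15
        mito_kmers = {
            numt_free_genome.mito.sequence[i : i + k]
            for i in range(SMALL_MITO_LEN - k + 1)
        }
        decoy = numt_free_genome.decoys[0].sequence
        shared = sum(decoy[i : i + k] in mito_kmers for i in range(len(decoy) - k + 1))
        assert shared == 0  # chance collision at 15-mers is ~1e-2 per genome

    def test_targets_never_on_mito_and_cover_stated_fraction(self, small_genome):
        assert all(c != "MT" for c, _, _ in small_genome.targets.intervals)
        frac = small_genome.targets.total_size() / 8000
        assert 0.025 <= frac <= 0.06  # one target dropped near the NUMT is fine

    def test_inverted_numt_span_rejected(self):
        with pytest.raises(ValueError, match="start"):
            build_synthetic_genome(numt_specs=((1600, 1000, 0.05),), mito_length=3000)

    def test_numt_longer_than_decoy_rejected(self):
        with pytest.raises(ValueError, match="longer than decoy"):
            build_synthetic_genome(
                decoy_length=300, numt_specs=((1, 500, 0.02),), mito_length=3000
            )

    def test_deterministic_for_fixed_seed(self):
        g1 = build_synthetic_genome(seed=3, mito_length=3000)
        g2 = build_synthetic_genome(seed=3, mito_length=3000)
        assert g1.mito.sequence == g2.mito.sequence
        assert g1.decoys[0].sequence == g2.decoys[0].sequence


class TestSimulateSample:
    def test_provenance_conservation(self, deep_sample):
        assert deep_sample.truth.total_fragments == deep_sample.n_fragments
        provs = deep_sample.fragments["provenance"].value_counts().to_dict()
        dups = int((deep_sample.fragments["dup_of"] >= 0).sum())
        assert dups == deep_sample.truth.counts["duplicates"]
        for cls in ("on_target", "off_target_nuclear", "mito", "numt"):
            non_dup = int(
                (
                    (deep_sample.fragments["provenance"] == cls)
                    & (deep_sample.fragments["dup_of"] < 0)
                ).sum()
            )
            assert non_dup == deep_sample.truth.counts[cls]

    def test_zero_mito_weight_yields_zero_mito_reads(self, small_genome):
        profile = SampleProfile(
            "nomito", 500, 0.5, mito_weight=0.0, numt_weight=0.0
        )
        sim = simulate_sample(small_genome, profile, seed=5)
        assert sim.truth.counts["mito"] == 0
        assert not (sim.fragments["provenance"] == "mito").any()

    def test_error_free_mito_reads_match_haplotype(self, small_genome):
        """With e=0 every mito read equals the variant-substituted reference."""
        genotype = GenotypeSpec(((1555, "G", 1.0),))
        sim = simulate_sample(
            small_genome, deep_profile(400, duplicate_rate=0.0), genotype, seed=3
        )
        hap = list(small_genome.mito.sequence)
        hap[1554] = "G"
        hap = "".join(hap)
        doubled = hap + hap  # circular reads wrap
        rc = str.maketrans("ACGT", "TGCA")
        checked = 0
        for name, s1, _q1, s2, _q2 in sim.read_pairs():
            if parse_read_name(name)[2] != "mito":
                continue
            assert s1 in doubled
            assert s2.translate(rc)[::-1] in doubled
            checked += 1
        assert checked > 100

    def test_heteroplasmy_fraction_within_binomial_ci(self, small_genome):
        """h=0.5 at m.1555, e=0: alt share of covering mito reads is binomial."""
        sim = simulate_sample(
            small_genome,
            deep_profile(2500, duplicate_rate=0.0),
            GenotypeSpec(((1555, "G", 0.5),)),
            seed=11,
        )
        ref_b = small_genome.mito.base(1555)
        alt = ref = 0
        for name, s1, _q1, s2, _q2 in sim.read_pairs():
            if parse_read_name(name)[2] != "mito":
                continue
            row = sim.fragments.iloc[int(name.split(".")[1][1:])]
            L = SMALL_MITO_LEN
            # mate-1 window covers 1555?
            off = (1554 - row.start) % L
            if off < len(s1):
                alt += s1[off] == "G"
                ref += s1[off] == ref_b
            off2 = (1554 - (row.start + row.length - len(s1))) % L
            if off2 < len(s1):
                base = s2.translate(str.maketrans("ACGT", "TGCA"))[::-1][off2]
                alt += base == "G"
                ref += base == ref_b
        n = alt + ref
        lo, hi = stats.binom.interval(0.99, n, 0.5)
        assert lo <= alt <= hi

    def test_invalid_heteroplasmy_rejected(self):
        with pytest.raises(ValueError):
            GenotypeSpec(((1555, "G", 1.5),))

    def test_alt_equal_reference_rejected(self, small_genome):
        ref_b = small_genome.mito.base(1555)
        with pytest.raises(ValueError, match="reference"):
            simulate_sample(
                small_genome,
                deep_profile(10),
                GenotypeSpec(((1555, ref_b, 1.0),)),
                seed=1,
            )

    def test_duplicates_are_exact_copies(self, deep_sample):
        frags = deep_sample.fragments
        names = deep_sample.read_names()
        pairs = {i: (s1, s2) for i, (_, s1, _, s2, _) in enumerate(deep_sample.read_pairs())}
        dup_rows = frags.index[frags["dup_of"] >= 0]
        assert len(dup_rows) > 0
        for i in dup_rows[:50]:
            src = int(frags.loc[i, "dup_of"])
            assert pairs[i] == pairs[src]

    def test_off_target_fraction_converges(self, small_genome):
        """Law of large numbers at 100,000 pairs: within 3 s.e. of the profile."""
        profile = SampleProfile(
            "lln", 100_000, 0.3, mito_weight=0.01, numt_weight=0.01,
            error_rate=0.0, duplicate_rate=0.0,
        )
        sim = simulate_sample(small_genome, profile, seed=23)
        c = sim.truth.counts
        off = c["off_target_nuclear"] + c["mito"] + c["numt"]
        n = profile.total_read_pairs
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(off / n - 0.3) <= 3 * se


class TestPresetsAndCohorts:
    def test_presets_are_valid_and_ffpe_exceeds_blood(self):
        for profile in PRESETS.values():
            assert 0 <= profile.off_target_fraction <= 1
        blood, ffpe = PRESETS["blood_panel"], PRESETS["ffpe_panel"]
        assert ffpe.off_target_fraction > blood.off_target_fraction
        assert ffpe.mito_weight > blood.mito_weight

    def test_ffpe_realizes_higher_offtarget_and_mito_than_blood(self, small_genome):
        """The degraded-DNA regime yields more off-target and mtDNA reads."""
        sims = {
            name: simulate_sample(
                small_genome, PRESETS[name].scaled(5e-3), seed=9, sample_id=name
            )
            for name in ("blood_panel", "ffpe_panel")
        }
        def off(s):
            c = s.truth.counts
            return c["off_target_nuclear"] + c["mito"] + c["numt"]
        assert off(sims["ffpe_panel"]) > off(sims["blood_panel"])
        assert (
            sims["ffpe_panel"].truth.counts["mito"]
            > sims["blood_panel"].truth.counts["mito"]
        )

    def test_cohort_truth_and_determinism(self, small_genome, tmp_path):
        spec = [
            ("W1", deep_profile(100), GenotypeSpec.wild_type()),
            ("C1", deep_profile(100), GenotypeSpec(((1555, "G", 1.0),))),
        ]
        samples1, truth1 = simulate_cohort(small_genome, spec, seed=5, outdir=tmp_path / "a")
        _samples2, _ = simulate_cohort(small_genome, spec, seed=5, outdir=tmp_path / "b")
        carriers = truth1[truth1["pos"] == 1555]
        assert len(carriers) == 1 and carriers.iloc[0]["sample"] == "C1"
        r1a = (tmp_path / "a" / "C1_R1.fastq").read_bytes()
        r1b = (tmp_path / "b" / "C1_R1.fastq").read_bytes()
        assert r1a == r1b

    def test_cohort_order_independent_per_sample_seeds(self, small_genome):
        spec = [
            ("A", deep_profile(50), GenotypeSpec.wild_type()),
            ("B", deep_profile(50), GenotypeSpec.wild_type()),
        ]
        fwd, _ = simulate_cohort(small_genome, spec, seed=5)
        rev, _ = simulate_cohort(small_genome, spec[::-1], seed=5)
        assert fwd["A"].fragments.equals(rev["A"].fragments)

    def test_duplicate_sample_ids_rejected(self, small_genome):
        spec = [("X", deep_profile(10), GenotypeSpec.wild_type())] * 2
        with pytest.raises(ValueError, match="duplicate"):
            simulate_cohort(small_genome, spec, seed=1)

    def test_empty_cohort(self, small_genome):
        samples, truth = simulate_cohort(small_genome, [], seed=1)
        assert samples == {} and truth.empty
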