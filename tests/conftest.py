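"""Shared fixtures: a scaled-down synthetic genome and deep-coverage profiles.

Tests run on a 3,000-base circular mitochondrial reference (all knowledge-
base positions fit below 1,601) with one NUMT-bearing nuclear decoy; this
keeps exhaustive oracles affordable while exercising every coordinate path
the full-length reference uses.
"""

import numpy as np
import pytest

from mitoff.simulate import (
    GenotypeSpec,
    SampleProfile,
    build_synthetic_genome,
    simulate_sample,
)

SMALL_MITO_LEN = 3000
NUMT_SPEC = (1000, 1600, 0.05)


@pytest.fixture(scope="session")
def small_genome():
    return build_synthetic_genome(
        n_decoys=1,
        decoy_length=8000,
        numt_specs=(NUMT_SPEC,),
        seed=7,
        mito_length=SMALL_MITO_LEN,
    )


@pytest.fixture(scope="session")
def numt_free_genome():
    return build_synthetic_genome(
        n_decoys=1,
        decoy_length=8000,
        numt_specs=(),
        seed=7,
        mito_length=SMALL_MITO_LEN,
    )


def deep_profile(n_pairs=2500, error_rate=0.0, duplicate_rate=0.02, numt_weight=0.05):
    """High mito share so m.1555 reaches clinical-grade depth quickly."""
    return SampleProfile(
        "deep",
        total_read_pairs=n_pairs,
        off_target_fraction=0.8,
        mito_weight=0.9,
        numt_weight=numt_weight,
        error_rate=error_rate,
        duplicate_rate=duplicate_rate,
    )


@pytest.fixture(scope="session")
def deep_sample(small_genome):
    """One heteroplasmic (h=0.5 at m.1555) deeply covered sample."""
    return simulate_sample(
        small_genome,
        deep_profile(),
        GenotypeSpec(((1555, "G", 0.5),)),
        seed=11,
        sample_id="S1",
    )
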