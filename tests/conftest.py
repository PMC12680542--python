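"""Shared fixtures: synthetic references and simulated libraries.

The heavy simulated dataset (10x coverage of a 16,660 bp circular genome at
72%-class terminal damage) is session-scoped so unit, property and acceptance
tests can share one realization.
"""

import numpy as np
import pytest

from paleomito.alignio import ReferenceSequence, build_pileup
from paleomito.damage import estimate_profile
from paleomito.simulate import SimulationConfig, simulate_dataset

#: Length of the real horse mitochondrial reference; the synthetic genome
#: mirrors it so coverage/counts live on a realistic scale.
MITO_LEN = 16660

GENOME_SEED = 7  # fixed: the synthetic reference is part of the study design


def _random_genome(length: int, seed: int = GENOME_SEED) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def mito_ref() -> ReferenceSequence:
    """16,660 bp synthetic circular mitogenome."""
    return ReferenceSequence("mt_synth", _random_genome(MITO_LEN), circular=True)


@pytest.fixture(scope="session")
def small_ref() -> ReferenceSequence:
    """2 kb circular genome for fast simulator-level tests."""
    return ReferenceSequence("mt_small", _random_genome(2000, seed=11), circular=True)


@pytest.fixture(scope="session")
def scen_dataset(mito_ref):
    """One SCEN001-like simulated library with its pileup and damage profile.

    10x coverage, 70% terminal 5' C->T, 100 true variants, seed 1.
    """
    config = SimulationConfig(seed=1, target_cov=10.0, damage_amp5=0.7, n_variants=100)
    reads, truth = simulate_dataset(mito_ref, config)
    pileup = build_pileup(reads, mito_ref)
    profile = estimate_profile(pileup)
    return {
        "config": config,
        "reads": reads,
        "truth": truth,
        "pileup": pileup,
        "profile": profile,
        "ref": mito_ref,
    }
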