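"""Shared fixtures: hand-built matrices and session-scoped synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from faroh.genotype_io import GenotypeMatrix
from faroh.roh_caller import sweep_roh
from faroh.synthetic_data import (
    CohortSpec,
    Pedigree,
    make_private_shared_cohort,
    simulate_cohort,
)

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_matrix(samples, chrom, pos, genotypes, ref="A", alt="G", qual=100.0):
    """Small GenotypeMatrix from plain lists (one chromosome by default)."""
    pos = list(pos)
    n = len(pos)
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n if np.isscalar(chrom) else list(chrom),
            "pos": pos,
            "ref": [ref] * n if isinstance(ref, str) else list(ref),
            "alt": [alt] * n if isinstance(alt, str) else list(alt),
            "qual": [qual] * n if np.isscalar(qual) else list(qual),
        }
    )
    return GenotypeMatrix(list(samples), sites, np.array(genotypes, dtype=np.int8))


@pytest.fixture(scope="session")
def founder_cohort():
    """Default study conditions: 8 samples, founder event 50 generations back."""
    return simulate_cohort(CohortSpec(seed=101))


@pytest.fixture(scope="session")
def founder_sweep(founder_cohort):
    return sweep_roh(founder_cohort.matrix)


@pytest.fixture(scope="session")
def private_shared_cohort():
    """8 samples; 800 private sites each (80% het), 2000 shared (30% het)."""
    return make_private_shared_cohort(
        n_samples=8, n_shared_sites=2000, n_private_sites=800, seed=7
    )


def replicated_pedigree(builder, n_rep: int):
    """n_rep independent copies of a two-sample pedigree in one structure.

    Returns (pedigree, pairs): the emitted samples are each family's pair of
    interest, suffixed per replicate; ``pairs`` lists those pairs.
    """
    combined = Pedigree()
    pairs = []
    for r in range(n_rep):
        unit = builder()
        sfx = f"_{r}"
        for name in unit.order:
            par = unit.parents[name]
            if par is None:
                combined.add_founder(name + sfx)
            else:
                combined.add_child(name + sfx, par[0] + sfx, par[1] + sfx)
        pairs.append((unit.samples[0] + sfx, unit.samples[1] + sfx))
    combined.samples = [s for pair in pairs for s in pair]
    return combined, pairs
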