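import numpy as np
import pandas as pd
import pytest

from cottonwood.containers import GenotypeMatrix
from cottonwood.sim import LineageSimSpec, simulate_lineages


def make_genotypes(calls, populations=None, chrom=None, pos=None):
    """Build a GenotypeMatrix from a plain 2D array of codes (NaN = missing)."""
    calls = np.asarray(calls, dtype=float)
    n, L = calls.shape
    ind = pd.Index([f"i{k}" for k in range(n)], name="individual")
    loc = pd.Index([f"L{j}" for j in range(L)], name="locus")
    individuals = pd.DataFrame(
        {"population": populations if populations is not None else ["p0"] * n},
        index=ind,
    )
    loci = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["Chr01"] * L,
            "pos": pos if pos is not None else list(range(1, L + 1)),
            "gene": ".",
        },
        index=loc,
    )
    return GenotypeMatrix(pd.DataFrame(calls, index=ind, columns=loc), individuals, loci)


@pytest.fixture(scope="session")
def structured_sim():
    """Moderately sized three-lineage dataset with planted captures."""
    cr = np.zeros((3, 3))
    cr[1, 0] = 0.08  # lineage 1 nuclei carrying lineage 0 chloroplasts
    cr[0, 1] = 0.015
    spec = LineageSimSpec(
        n_lineages=3,
        n_pops_per_lineage=4,
        n_ind_per_pop=12,
        n_loci=93,
        lineage_fst=(0.15, 0.15, 0.15),
        admix_fraction=0.1,
        capture_rates=cr,
        missing_rate=0.01,
        seed=20_260_929,
    )
    return simulate_lineages(spec)
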