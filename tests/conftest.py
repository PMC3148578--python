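import numpy as np
import pytest

from ippca import GenotypeTable, IppcaConfig, SimulationConfig, run_ippca, simulate


def make_table(sym_calls, ids=None, marker_ids=None, labels=None):
    """Build a GenotypeTable from nested allele-symbol pairs (None = missing)."""
    m = len(sym_calls)
    nm = len(sym_calls[0])
    ids = ids or [f"i{k + 1}" for k in range(m)]
    marker_ids = marker_ids or [f"m{j + 1}" for j in range(nm)]
    alleles = [[] for _ in range(nm)]
    lookup = [{} for _ in range(nm)]
    calls = np.full((m, nm, 2), -1, dtype=np.int16)
    for i, row in enumerate(sym_calls):
        for j, pair in enumerate(row):
            if pair is None:
                continue
            for s, sym in enumerate(pair):
                if sym not in lookup[j]:
                    lookup[j][sym] = len(alleles[j])
                    alleles[j].append(sym)
                calls[i, j, s] = lookup[j][sym]
    return GenotypeTable(ids, marker_ids, calls, alleles, labels)


@pytest.fixture(scope="session")
def two_pop_table():
    """Two strongly diverged subpopulations of 100, 500 SNPs."""
    return simulate(
        SimulationConfig(subpop_sizes=(100, 100), n_markers=500, divergence=0.05, seed=11)
    )


@pytest.fixture(scope="session")
def null_table():
    """One homogeneous population of 120, 500 SNPs."""
    return simulate(SimulationConfig(subpop_sizes=(120,), n_markers=500, seed=12))


@pytest.fixture(scope="session")
def two_pop_tree(two_pop_table):
    return run_ippca(two_pop_table, IppcaConfig(seed=5))
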