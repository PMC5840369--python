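"""Shared fixtures: small synthetic panels built once per session."""

import numpy as np
import pandas as pd
import pytest

from domescan.io import GenotypePanel
from domescan import simdata


def make_panel(genotypes, group_sizes, phased=True, chrom="1", spacing=1000):
    """Panel from an explicit (sites, individuals, 2) array.

    group_sizes: list of (group, role, n) consuming individuals in order.
    """
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_ind, _ = genotypes.shape
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n_sites + 1) * spacing,
            "ref": "A",
            "alt": "C",
        }
    )
    individuals, groups, roles = [], {}, {}
    i = 0
    for group, role, n in group_sizes:
        roles[group] = role
        for _ in range(n):
            name = f"{group}_{i:02d}"
            individuals.append(name)
            groups[name] = group
            i += 1
    assert i == n_ind
    return GenotypePanel(sites, genotypes, individuals, groups, roles, phased=phased)


def random_panel(rng, n_sites=60, group_sizes=(("W", "wild", 5), ("A", "domestic_A", 5),
                                               ("B", "domestic_B", 5)), p=None):
    n_ind = sum(n for _, _, n in group_sizes)
    if p is None:
        p = rng.uniform(0.2, 0.8, size=n_sites)
    g = (rng.random((n_sites, n_ind, 2)) < p[:, None, None]).astype(np.int8)
    return make_panel(g, list(group_sizes))


@pytest.fixture(scope="session")
def small_scenario():
    return simdata.demo_scenario(
        123, n_snps_per_chrom=400, n_shared_sweeps=1, n_specific_sweeps=1,
        n_relaxation=1, intensity=1.0,
    )


@pytest.fixture(scope="session")
def small_panel(small_scenario):
    panel, truth = simdata.simulate_genus(small_scenario, 1)
    return panel, truth
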