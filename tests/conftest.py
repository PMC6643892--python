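"""Shared fixtures: synthetic maps, simulated populations and IBD grids.

Heavy objects are session-scoped so the estimation pipeline runs once and is
reused across test modules.  Everything is generated programmatically from
fixed seeds; no data files are needed.
"""

import numpy as np
import pytest

from polyqtl.ibd import haplotype_probs, ibd_posterior, spline_to_grid
from polyqtl.maps import even_coverage_map, uneven_coverage_map
from polyqtl.meiosis import genotype_population, simulate_population


@pytest.fixture(scope="session")
def even_map():
    return even_coverage_map(ploidy=4, n_markers=100, length_cm=100.0, seed=1)


@pytest.fixture(scope="session")
def uneven_map():
    return uneven_coverage_map(ploidy=4, n_markers=60, length_cm=100.0, seed=7)


@pytest.fixture(scope="session")
def pop200(even_map):
    return simulate_population(even_map, 200, q=0.0, seed=2)


@pytest.fixture(scope="session")
def dosages200(pop200, even_map):
    return genotype_population(pop200, even_map, eps=0.0, seed=3)


@pytest.fixture(scope="session")
def posterior200(dosages200, even_map):
    return ibd_posterior(dosages200, even_map, model="noDR", eps=0.001)


@pytest.fixture(scope="session")
def grid200(posterior200):
    return spline_to_grid(posterior200)


@pytest.fixture(scope="session")
def hap200(grid200):
    return haplotype_probs(grid200)


@pytest.fixture(scope="session")
def informative_map():
    """A fully informative dense map: at every ~1 cM each homolog of each
    parent is uniquely tagged by a simplex marker."""
    ploidy, length = 4, 50.0
    positions, alleles = [], []
    step = 1.0
    x = 0.0
    off = 0.001
    while x <= length:
        for h in range(2 * ploidy):
            positions.append(min(x + off * h, length))
            row = np.zeros(2 * ploidy, dtype=np.int8)
            row[h] = 1
            alleles.append(row)
        x += step
    names = [f"T{i:04d}" for i in range(len(positions))]
    from polyqtl.maps import PhasedMap

    return PhasedMap(
        chromosome="dense",
        length=length,
        names=names,
        positions=np.asarray(positions),
        alleles=np.asarray(alleles),
        ploidy=ploidy,
    )
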