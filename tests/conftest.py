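import numpy as np
import pytest

import encapmap as em


@pytest.fixture(scope="session")
def fine_map():
    """Default fine-mapping fixture: 12 evenly spaced markers on 3-27 cM."""
    return em.evenly_spaced_map()


@pytest.fixture(scope="session")
def gene():
    """Toy gene (CDS, upstream) carrying the 21-bp regulatory motif."""
    return em.toy_gene()


@pytest.fixture()
def two_marker_cohort():
    """Complete-penetrance cohort: fully informative marker at 0 cM,
    10 melanized HET and 10 non-melanized HOM_S individuals."""
    gmap = em.GeneticMap("2", (("m1", 0.0), ("m2", 20.0)))
    geno = np.zeros((20, 2), dtype=np.int8)
    geno[:10, :] = em.HET
    phenotype = np.array([True] * 10 + [False] * 10)
    return em.BackcrossCohort(gmap, geno, phenotype, np.ones(20, bool))
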