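import numpy as np
import pytest

from ecoplace.refdata import parse_reference_package

TINY_NEWICK = "((A:0.1,B:0.1):0.05,C:0.2);"
TINY_FASTA = """>A
ACDEFGHIKL
>B
ACDEFGHIKM
>C
ACDEFWHIKL
"""
TINY_TAX = "A\tSAR11;Ia;Ia.1\nB\tSAR11;Ia;Ia.1\nC\tSAR11;Ia;Ia.3\n"


@pytest.fixture
def tiny_package():
    """3-leaf rooted package: A,B in Ia.1, C in Ia.3."""
    return parse_reference_package(TINY_NEWICK, TINY_FASTA, TINY_TAX,
                                   gene="rpoB")


@pytest.fixture(scope="session")
def rpob_package():
    """Clade-structured synthetic rpoB package shared across tests."""
    from ecoplace.synth import evolve_reference_set
    return evolve_reference_set(seed=11, n_clades=4, leaves_per_clade=2,
                                depth_scale=0.3, n_columns=120, gene="rpoB")


@pytest.fixture(scope="session")
def rpob_engine(rpob_package):
    from ecoplace.placement import PlacementEngine
    return PlacementEngine(rpob_package)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
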