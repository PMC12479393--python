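import numpy as np
import pytest

from gapfold import fixtures
from gapfold.structures_io import ChainRecord, Complex


@pytest.fixture
def two_chain_complex():
    """Toy 2-chain complex (60 + 55 residues) with a dense interface."""
    return fixtures.make_complex([60, 55], seed=0)


@pytest.fixture
def three_chain_complex():
    return fixtures.make_complex([30, 25, 20], seed=1)


@pytest.fixture
def renumbered(two_chain_complex):
    """Same complex with residues renumbered 1..L (prediction numbering)."""
    return renumber(two_chain_complex)


def renumber(complex: Complex) -> Complex:
    chains = [
        ChainRecord(
            chain_id=c.chain_id,
            sequence=c.sequence,
            residue_numbers=list(range(1, len(c) + 1)),
            cb_coords=c.cb_coords.copy(),
            ca_coords=c.ca_coords.copy(),
            com=c.com.copy(),
        )
        for c in complex.chains
    ]
    return Complex(chains=chains, source_format=complex.source_format)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
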