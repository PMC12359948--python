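import numpy as np
import pytest
from rdkit import Chem

from molgnn.conformers import conformer_pipeline
from molgnn.standardize import standardize_dataset
from molgnn.synth import toy_library


@pytest.fixture(scope="session")
def toy_outcomes():
    """Standardisation outcomes for the whole bundled toy library."""
    return standardize_dataset(toy_library())


@pytest.fixture(scope="session")
def accepted_toy(toy_outcomes):
    return [o for o in toy_outcomes if o.accepted]


@pytest.fixture(scope="session")
def toy_conformers(accepted_toy):
    """(name, standardised mol, ConformerResult) for every accepted toy record."""
    out = []
    for o in accepted_toy:
        mol = Chem.MolFromSmiles(o.standardized_smiles)
        out.append((o.record.name, mol, conformer_pipeline(mol, seed=11)))
    return out


def random_topology(rng: np.random.Generator, n: int):
    """A random undirected simple graph as (adjacency, src, dst) arrays."""
    adj = (rng.random((n, n)) < 0.45).astype(float)
    adj = np.triu(adj, 1)
    adj = adj + adj.T
    src, dst = np.nonzero(adj)
    return adj, src, dst
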