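import numpy as np
import pytest

from contactnet.core import ContactMap, CONTACT, IGNORED, NON_CONTACT
from contactnet.features import derive_pair_potential
from contactnet.synthetic import generate_dataset, generate_target


def random_symmetric_probs(L: int, rng: np.random.Generator) -> np.ndarray:
    """Random contact-probability map, symmetric with zero diagonal."""
    p = rng.random((L, L))
    p = (p + p.T) / 2.0
    np.fill_diagonal(p, 0.0)
    return p


def random_contact_map(L: int, rng: np.random.Generator,
                       contact_frac: float = 0.06,
                       missing_frac: float = 0.05) -> ContactMap:
    """Random ternary map with a few unresolved residues."""
    states = np.full((L, L), NON_CONTACT, dtype=np.int8)
    iu, ju = np.triu_indices(L, k=1)
    pick = rng.random(len(iu)) < contact_frac
    states[iu[pick], ju[pick]] = CONTACT
    states[ju[pick], iu[pick]] = CONTACT
    missing = rng.random(L) < missing_frac
    states[missing, :] = IGNORED
    states[:, missing] = IGNORED
    np.fill_diagonal(states, np.where(missing, IGNORED, NON_CONTACT))
    return ContactMap(states=states)


@pytest.fixture(scope="session")
def toy_target():
    return generate_target("fixture0", n_helices=2, n_strands=1, seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """Six tiny targets with a shallow MSA — fast shared fixture."""
    return generate_dataset(6, length_range=(40, 60), seed=5, msa_depth=60)


@pytest.fixture(scope="session")
def pair_potential(small_dataset):
    return derive_pair_potential(
        [(t.record.sequence, t.contact_map) for t in small_dataset.train]
    )
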