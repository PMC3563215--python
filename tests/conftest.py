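import numpy as np
import pytest

from domaincut import Contact, ContactList
from domaincut.synthetic import SimSpec, generate_helix_coordinates, generate_multidomain_contacts


@pytest.fixture(scope="session")
def helix60():
    return generate_helix_coordinates(60)


@pytest.fixture(scope="session")
def two_block_contacts():
    """Deterministic two-domain fixture: residues 1-50 and 51-100 densely
    intra-connected (separations 5-30), nothing crossing position 50/51."""
    contacts = []
    for lo, hi in [(1, 50), (51, 100)]:
        for i in range(lo, hi + 1):
            for j in range(i + 5, min(i + 30, hi) + 1):
                contacts.append(Contact(i, j, 1.0 - 1e-4 * len(contacts)))
    return ContactList(100, contacts)


@pytest.fixture(scope="session")
def sim_two_domain():
    """Seeded noise-free 60+60 fixture with known boundary at 61."""
    spec = SimSpec(domain_lengths=(60, 60), p_inter=0.0, noise_frac=0.0, seed=1)
    return generate_multidomain_contacts(spec)


def profile_oracle(pairs, L, sigma):
    """Naive reference for the contact-cut profile: explicit loops over
    contacts and the residues strictly between them, Gaussian kernels
    evaluated at every integer position, then unit-sum normalization."""
    positions = np.arange(1, L + 1, dtype=float)
    dens = np.zeros(L)
    for (i, j) in pairs:
        for r in range(i + 1, j):
            z = (positions - r) / sigma
            dens += np.exp(-0.5 * z * z) / (sigma * np.sqrt(2 * np.pi))
    total = dens.sum()
    if total == 0:
        raise ValueError("no kernel mass")
    return dens / total
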