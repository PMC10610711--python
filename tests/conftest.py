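from __future__ import annotations

import numpy as np
import pytest

from sorbtrack import SyntheticSpec, gen_walkers
from sorbtrack.trajio import ATOMIC_MASSES, Topology


@pytest.fixture(scope="session")
def small_brownian():
    """40 walkers, 60 frames, D = 5e-10 m²/s: shared smoke ensemble."""
    spec = SyntheticSpec(mode="brownian", n_molecules=40, n_frames=60, d_true=5e-10, box=25.0, seed=11)
    wrapped, continuous, topo = gen_walkers(spec)
    return spec, wrapped, continuous, topo


def random_hbond_topology(rng: np.random.Generator, n_waters: int, n_carbonyls: int, n_hydroxyls: int):
    """Random mixed scene: waters + polymer carbonyl (C=O acceptor) and
    hydroxyl (C-O-H donor) fragments scattered uniformly in the box.
    Geometry is intentionally arbitrary — only the detector vs oracle
    agreement matters."""
    elements, masses, mol_ids, species = [], [], [], []
    bonds, donor_h, acceptor = [], [], []
    mol = 0

    def add_atom(e, sp, m_id, don=False, acc=False):
        elements.append(e)
        masses.append(ATOMIC_MASSES[e])
        mol_ids.append(m_id)
        species.append(sp)
        donor_h.append(don)
        acceptor.append(acc)
        return len(elements) - 1

    for _ in range(n_waters):
        o = add_atom("O", "water", mol, acc=True)
        h1 = add_atom("H", "water", mol, don=True)
        h2 = add_atom("H", "water", mol, don=True)
        bonds += [(o, h1), (o, h2)]
        mol += 1
    for _ in range(n_carbonyls):
        c = add_atom("C", "polymer", mol)
        o = add_atom("O", "polymer", mol, acc=True)
        bonds.append((c, o))
        mol += 1
    for _ in range(n_hydroxyls):
        c = add_atom("C", "polymer", mol)
        o = add_atom("O", "polymer", mol, acc=True)
        h = add_atom("H", "polymer", mol, don=True)
        bonds += [(c, o), (o, h)]
        mol += 1
    return Topology(elements, masses, mol_ids, species, bonds, donor_h, acceptor)
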