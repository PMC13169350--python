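import numpy as np
import pytest

from nptraj.md_io import AtomRecord, Trajectory


@pytest.fixture
def tiny_topology():
    """Three-atom, two-residue protein topology plus one gold atom."""
    return [
        AtomRecord("CA", "C", "GLY", 1, "A"),
        AtomRecord("CB", "C", "ALA", 2, "A"),
        AtomRecord("N", "N", "ALA", 2, "A"),
        AtomRecord("AU", "AU", "AUN", 100, "Z", is_nanoparticle=True),
    ]


@pytest.fixture
def tiny_trajectory(tiny_topology):
    rng = np.random.default_rng(0)
    coords = rng.random((4, 4, 3))
    return Trajectory(tiny_topology, coords, np.arange(4.0))


def random_protein_trajectory(n_residues=5, atoms_per_residue=3, n_frames=6,
                              seed=0, spread=1.0):
    """Random-coordinate trajectory with a CA-led residue topology."""
    rng = np.random.default_rng(seed)
    names = ["CA", "CB", "N", "O", "C"]
    topology = []
    for r in range(n_residues):
        for a in range(atoms_per_residue):
            topology.append(AtomRecord(names[a], names[a][0], "GLY",
                                       r + 1, "A"))
    coords = rng.normal(scale=spread,
                        size=(n_frames, len(topology), 3))
    return Trajectory(topology, coords, np.arange(float(n_frames)))
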