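import numpy as np
import pytest

from endstate.core import Atom, ComplexPartition, Frame, Topology
from endstate.synthetic import GeneratorSpec, make_host_guest


def plain_atom(serial, name="X", element="C", res_name="UNK", res_seq=1,
               chain="A", charge=0.0, rmin_half=1.7, epsilon=0.1,
               gb_radius=1.7, gb_screen=0.72, mass=12.0):
    return Atom(
        serial=serial, name=name, element=element, residue_name=res_name,
        residue_seq=res_seq, chain_id=chain, charge=charge,
        lj_rmin_half=rmin_half, lj_epsilon=epsilon, gb_radius=gb_radius,
        gb_screen=gb_screen, mass=mass,
    )


@pytest.fixture
def host_guest():
    """Default toy complex: (topology, bound-pose frame, partition)."""
    return make_host_guest(GeneratorSpec(seed=0))


@pytest.fixture
def peptide_topology():
    """4-residue backbone-only peptide (N, CA, C, O per residue)."""
    atoms = []
    coords = []
    serial = 1
    for res in range(1, 5):
        for k, name in enumerate(["N", "CA", "C", "O"]):
            element = name[0]
            atoms.append(plain_atom(serial, name=name, element=element,
                                    res_name="ALA", res_seq=res))
            coords.append([3.8 * res + 0.9 * k, 0.0, 0.0])
            serial += 1
    topo = Topology(atoms=atoms)
    return topo, Frame(coordinates=np.array(coords, dtype=float))


def two_particle_system(q1=1.0, q2=-1.0, r=3.320637, eps=0.0,
                        rmin_half=1.7, gb_radius=1.5):
    """Two-atom receptor/ligand toy used across energetics tests."""
    atoms = [
        plain_atom(1, name="A1", res_name="REC", res_seq=1, charge=q1,
                   epsilon=eps, rmin_half=rmin_half, gb_radius=gb_radius),
        plain_atom(2, name="B1", res_name="LIG", res_seq=2, charge=q2,
                   epsilon=eps, rmin_half=rmin_half, gb_radius=gb_radius),
    ]
    topo = Topology(atoms=atoms)
    frame = Frame(coordinates=np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]))
    part = ComplexPartition(receptor=frozenset({0}), ligand=frozenset({1}))
    return topo, frame, part
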