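import numpy as np
import pytest

from hemescan.structure_io import Atom, Chain, Residue, Structure


def make_atom(name, element, xyz, occupancy=1.0, altloc=""):
    return Atom(name=name, element=element, coords=np.asarray(xyz, float),
                occupancy=occupancy, altloc=altloc)


def make_residue(chain_id, pos, name, atoms, hetero=False):
    return Residue(chain_id=chain_id, seq_position=str(pos), name=name,
                   atoms=atoms, is_hetero=hetero)


def bare_heme(center=(0.0, 0.0, 0.0), n_extra_carbons=4, pos="501"):
    """Minimal unrotated heme-like hetero residue with FE at ``center``.

    Atom positions are exact, which the boundary-distance tests rely on.
    """
    c = np.asarray(center, float)
    atoms = [make_atom("FE", "FE", c)]
    for i, (name, off) in enumerate(zip(
            ("NA", "NB", "NC", "ND"),
            ([2.05, 0, 0], [0, 2.05, 0], [-2.05, 0, 0], [0, -2.05, 0]))):
        atoms.append(make_atom(name, "N", c + np.asarray(off)))
    for k in range(n_extra_carbons):
        ang = 2 * np.pi * k / max(n_extra_carbons, 1)
        atoms.append(make_atom(f"C{k + 1}", "C",
                               c + 4.3 * np.array([np.cos(ang), np.sin(ang), 0])))
    return make_residue("X", pos, "HEM", atoms, hetero=True)


def assemble(residues, hetero, structure_id="TST", **kw):
    chains = {}
    for r in residues:
        chains.setdefault(r.chain_id, []).append(r)
    return Structure(structure_id=structure_id,
                     chains=[Chain(cid, rs) for cid, rs in chains.items()],
                     hetero_groups=list(hetero), **kw)


@pytest.fixture
def simple_heme_structure():
    """One heme, one His axial ligand (NE2 at 2.1 Å), one Phe contact."""
    heme = bare_heme()
    his = make_residue("A", 10, "HIS", [
        make_atom("NE2", "N", [0, 0, 2.1]),
        make_atom("CE1", "C", [1.0, 0, 2.9]),
        make_atom("CA", "C", [1.5, 0, 5.0]),
    ])
    phe = make_residue("A", 20, "PHE", [
        make_atom("CZ", "C", [4.3 + 4.0, 0, 0.1]),  # ~4 Å from a ring carbon
        make_atom("CA", "C", [4.3 + 6.5, 0, 0.1]),
    ])
    far = make_residue("A", 30, "LYS", [make_atom("NZ", "N", [30, 30, 30]),
                                        make_atom("CA", "C", [31, 30, 30])])
    return assemble([his, phe, far], [heme])
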