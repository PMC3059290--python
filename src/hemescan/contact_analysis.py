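"""Geometric rules for heme recognition in protein structures.

Three distance rules drive the whole analysis:

* a residue is an **axial ligand** when one of its N/S/O heavy atoms
  lies within 3.0 Å of the heme iron (coordination-bond range),
* a residue **interacts** with a heme when any of its heavy atoms lies
  within 4.5 Å of any heme heavy atom (van der Waals contact range),
* a chain is **heme binding** when it contributes at least one axial
  ligand or at least ten interacting residues.

All cutoffs are inclusive (``<=``).  Neighbor searches use a k-d tree
over heme heavy atoms; tests cross-check against an all-pairs scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Atom, Residue, Structure

__all__ = [
    "HemeGroup",
    "AxialLigand",
    "ContactRecord",
    "BindingVerdict",
    "IronCoordinator",
    "find_heme_groups",
    "find_axial_ligands",
    "find_interacting_residues",
    "find_nonresidue_coordinators",
    "classify_binding_chains",
    "count_hemes_per_chain",
    "AXIAL_CUTOFF",
    "CONTACT_CUTOFF",
    "MIN_CONTACTS",
]

AXIAL_CUTOFF = 3.0    # Å, N/S/O donor to Fe
CONTACT_CUTOFF = 4.5  # Å, heavy atom to heavy atom
MIN_CONTACTS = 10     # distinct interacting residues for the no-ligand route

DONOR_ELEMENTS = {"N", "S", "O"}
PROPIONATE_ATOMS = {"CAA", "CBA", "CGA", "O1A", "O2A", "CAD", "CBD", "CGD", "O1D", "O2D"}
HEME_TYPE = {"HEM": "b", "HEC": "c"}


@dataclass
class HemeGroup:
    heme_id: tuple[str, str, str]  # (structure, chain, seq_position)
    heme_type: str                 # 'b' (HEM) or 'c' (HEC)
    residue: Residue
    iron: Atom
    is_mini: bool = False          # reduced fixture heme (unit tests only)

    def __post_init__(self):
        n_heavy = len(self.residue.heavy_atoms())
        if n_heavy < 5:
            raise ValueError(f"heme {self.heme_id}: only {n_heavy} heavy atoms")
        self.is_mini = n_heavy < 20

    def ring_atoms(self) -> list[Atom]:
        return [a for a in self.residue.heavy_atoms()
                if a.name not in PROPIONATE_ATOMS and a.element.upper() != "FE"]

    def propionate_atoms(self) -> list[Atom]:
        return [a for a in self.residue.heavy_atoms() if a.name in PROPIONATE_ATOMS]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.residue.heavy_atoms()])


@dataclass(frozen=True)
class AxialLigand:
    residue: Residue
    heme_id: tuple[str, str, str]
    donor_atom: str
    donor_element: str
    distance: float

    def __post_init__(self):
        if self.donor_element not in DONOR_ELEMENTS:
            raise ValueError(f"donor element {self.donor_element} not in N/S/O")


@dataclass(frozen=True)
class ContactRecord:
    residue: Residue
    heme_id: tuple[str, str, str]
    min_distance: float
    n_atom_pairs_within_cutoff: int


@dataclass(frozen=True)
class IronCoordinator:
    """Non-residue small molecule (e.g. GSH, IMD) coordinating the iron."""
    group: Residue
    heme_id: tuple[str, str, str]
    donor_atom: str
    distance: float


@dataclass(frozen=True)
class BindingVerdict:
    chain_id: str
    is_binding: bool
    n_axial: int
    n_contacts: int  # distinct residues of the chain across all hemes
    reason: str      # "axial" | "contacts" | "none"


def find_heme_groups(s: Structure) -> list[HemeGroup]:
    """One HemeGroup per HEM/HEC hetero residue that contains an iron atom.

    Hemes lacking an FE atom are skipped with a warning (degenerate or
    truncated entries).
    """
    groups = []
    for res in s.hetero_groups:
        if res.name not in HEME_TYPE:
            continue
        irons = [a for a in res.atoms if a.element.upper() == "FE"]
        if not irons:
            warnings.warn(
                f"{s.structure_id}: {res.name} {res.chain_id}{res.seq_position} "
                "has no FE atom; skipped", stacklevel=2)
            continue
        groups.append(HemeGroup(
            heme_id=(s.structure_id, res.chain_id, res.seq_position),
            heme_type=HEME_TYPE[res.name],
            residue=res,
            iron=irons[0],
        ))
    return groups


def find_axial_ligands(h: HemeGroup, s: Structure,
                       cutoff: float = AXIAL_CUTOFF) -> list[AxialLigand]:
    """Protein residues with an N/S/O heavy atom within ``cutoff`` of the iron.

    The closest qualifying atom is the donor; distance ties are broken
    by atom-name order for determinism.  Donors may be side-chain or
    backbone atoms — the donor atom name is recorded so callers can
    filter.
    """
    fe = h.iron.coords
    out = []
    for res in s.protein_residues():
        best: tuple[float, str, str] | None = None
        for a in res.heavy_atoms():
            if a.element.upper() not in DONOR_ELEMENTS:
                continue
            d = float(np.linalg.norm(a.coords - fe))
            if d <= cutoff:
                cand = (d, a.name, a.element.upper())
                if best is None or cand < best:
                    best = cand
        if best is not None:
            out.append(AxialLigand(
                residue=res, heme_id=h.heme_id,
                donor_atom=best[1], donor_element=best[2], distance=best[0]))
    return out


def find_interacting_residues(h: HemeGroup, s: Structure,
                              cutoff: float = CONTACT_CUTOFF) -> list[ContactRecord]:
    """Protein residues with any heavy atom within ``cutoff`` of any heme heavy atom."""
    heme_xyz = h.heavy_coords()
    tree = cKDTree(heme_xyz)
    out = []
    for res in s.protein_residues():
        xyz = np.array([a.coords for a in res.heavy_atoms()])
        if xyz.size == 0:
            continue
        dists, _ = tree.query(xyz, k=1)
        n_pairs = int(sum(len(hits) for hits in tree.query_ball_point(xyz, cutoff)))
        dmin = float(np.min(dists))
        if dmin <= cutoff:
            out.append(ContactRecord(
                residue=res, heme_id=h.heme_id,
                min_distance=dmin, n_atom_pairs_within_cutoff=n_pairs))
    return out


def find_nonresidue_coordinators(h: HemeGroup, s: Structure,
                                 cutoff: float = AXIAL_CUTOFF) -> list[IronCoordinator]:
    """Hetero small molecules (not water, not heme) coordinating the iron.

    Mirrors cases like glutathione or imidazole standing in for a
    protein axial ligand; reported separately from residue contacts.
    """
    fe = h.iron.coords
    out = []
    for grp in s.hetero_groups:
        if grp is h.residue or grp.is_water or grp.name in HEME_TYPE:
            continue
        best = None
        for a in grp.heavy_atoms():
            d = float(np.linalg.norm(a.coords - fe))
            if d <= cutoff:
                cand = (d, a.name)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            out.append(IronCoordinator(group=grp, heme_id=h.heme_id,
                                       donor_atom=best[1], distance=best[0]))
    return out


def classify_binding_chains(
    s: Structure,
    axial_cutoff: float = AXIAL_CUTOFF,
    contact_cutoff: float = CONTACT_CUTOFF,
    min_contacts: int = MIN_CONTACTS,
    per_heme: bool = False,
) -> list[BindingVerdict]:
    """Per-chain heme-binding verdicts aggregated over all hemes.

    With ``per_heme=True`` the >=``min_contacts`` rule is applied to
    each heme separately (a chain binds if it passes for any single
    heme) instead of pooling distinct residues across hemes.
    """
    hemes = find_heme_groups(s)
    axial_by_chain: dict[str, set] = {}
    contacts_by_chain: dict[str, set] = {}
    contacts_by_chain_heme: dict[tuple, set] = {}
    for h in hemes:
        for lig in find_axial_ligands(h, s, axial_cutoff):
            axial_by_chain.setdefault(lig.residue.chain_id, set()).add(
                (lig.residue.key(), h.heme_id))
        for rec in find_interacting_residues(h, s, contact_cutoff):
            cid = rec.residue.chain_id
            contacts_by_chain.setdefault(cid, set()).add(rec.residue.key())
            contacts_by_chain_heme.setdefault((cid, h.heme_id), set()).add(
                rec.residue.key())

    verdicts = []
    for chain in s.chains:
        cid = chain.chain_id
        n_axial = len({k for k, _ in axial_by_chain.get(cid, set())})
        n_contacts = len(contacts_by_chain.get(cid, set()))
        if per_heme:
            contacts_ok = any(
                len(v) >= min_contacts
                for (c, _), v in contacts_by_chain_heme.items() if c == cid)
        else:
            contacts_ok = n_contacts >= min_contacts
        if n_axial >= 1:
            reason = "axial"
        elif contacts_ok:
            reason = "contacts"
        else:
            reason = "none"
        verdicts.append(BindingVerdict(
            chain_id=cid, is_binding=reason != "none",
            n_axial=n_axial, n_contacts=n_contacts, reason=reason))
    return verdicts


def count_hemes_per_chain(
    s: Structure,
    axial_cutoff: float = AXIAL_CUTOFF,
    contact_cutoff: float = CONTACT_CUTOFF,
) -> dict[str, int]:
    """Number of hemes attributed to each chain.

    A heme counts for every chain for which it contributes an axial
    ligand or at least one residue contact; a heme shared between two
    chains is counted for both.
    """
    counts: dict[str, set] = {}
    for h in find_heme_groups(s):
        chains = set()
        for lig in find_axial_ligands(h, s, axial_cutoff):
            chains.add(lig.residue.chain_id)
        for rec in find_interacting_residues(h, s, contact_cutoff):
            chains.add(rec.residue.chain_id)
        for cid in chains:
            counts.setdefault(cid, set()).add(h.heme_id)
    return {cid: len(hids) for cid, hids in sorted(counts.items())}
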