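"""Reading and canonicalizing macromolecular structures and DSSP files.

The in-memory model is deliberately small: a :class:`Structure` holds
protein chains (ordered standard residues) and a flat list of hetero
groups (cofactors, ions, waters).  Canonicalization applied on parse:

* model 1 only (multi-model entries are typically NMR or trajectories;
  the downstream geometry rules assume a single conformer),
* one alternate location per atom — the highest-occupancy altloc wins,
  ties broken by altloc label order,
* modified standard residues (MSE, ...) are mapped to their parent
  amino acid for sequence purposes and flagged.
"""

from __future__ import annotations

import io
import os
import re
import tempfile
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "DsspRecord",
    "ParseError",
    "parse_structure",
    "parse_dssp",
    "load_heme_like_ligands",
    "write_report",
    "structure_to_pdb",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: modified residues mapped to the parent standard amino acid
NONSTANDARD_PARENT = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
}

WATER_NAMES = {"HOH", "WAT", "DOD"}


class ParseError(ValueError):
    """Raised when a structure or DSSP source cannot be interpreted."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")


@dataclass
class Residue:
    chain_id: str
    seq_position: str  # author numbering + insertion code, e.g. "42" or "42A"
    name: str
    atoms: list[Atom]
    is_hetero: bool = False
    modified_parent: str | None = None  # set for MSE etc.

    @property
    def is_standard_aa(self) -> bool:
        return self.effective_name in THREE_TO_ONE

    @property
    def effective_name(self) -> str:
        return self.modified_parent or self.name

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.effective_name, "X")

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def key(self) -> tuple[str, str]:
        return (self.chain_id, self.seq_position)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def observed_sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues if r.is_standard_aa)

    def standard_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_standard_aa]


@dataclass
class Structure:
    structure_id: str
    chains: list[Chain] = field(default_factory=list)
    hetero_groups: list[Residue] = field(default_factory=list)
    resolution: float | None = None
    r_value: float | None = None
    experiment: str | None = None

    def __post_init__(self):
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain_ids")
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when present")

    def get_chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def protein_residues(self) -> Iterable[Residue]:
        for c in self.chains:
            yield from c.standard_residues()


@dataclass(frozen=True)
class DsspRecord:
    chain_id: str
    seq_position: str
    ss_code: str  # one of H,G,I,E,B,T,S,' '
    acc: float    # absolute exposed area, Å²

    def __post_init__(self):
        if self.acc < 0:
            raise ValueError("acc must be non-negative")


# ---------------------------------------------------------------------------
# PDB parsing

_RVALUE_RE = re.compile(
    r"^REMARK   3\s+R VALUE\s+\((?:WORKING SET|WORKING \+ TEST SET)[^)]*\)\s*:\s*([0-9.]+)",
    re.MULTILINE,
)
_EXPDTA_RE = re.compile(r"^EXPDTA\s+(.+?)\s*$", re.MULTILINE)


def _select_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc label order
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def parse_structure(source: str, structure_id: str | None = None) -> Structure:
    """Parse PDB-format text into a canonical :class:`Structure`.

    Only model 1 is read; one altloc is retained per atom; HETATM
    residues that are not (modified) standard amino acids are routed to
    ``hetero_groups``.  Resolution, R-value and experiment method are
    taken from REMARK 2 / REMARK 3 / EXPDTA records when present.
    """
    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    ):
        path = os.fspath(source)
        with open(path) as fh:
            source = fh.read()
        if structure_id is None:
            structure_id = os.path.splitext(os.path.basename(path))[0]

    for lineno, line in enumerate(source.splitlines(), 1):
        if line.startswith(("ATOM  ", "HETATM")):
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                raise ParseError(
                    f"malformed coordinate field on line {lineno}: {line!r}")

    try:
        st = gemmi.read_pdb_string(source)
    except (RuntimeError, ValueError) as exc:  # gemmi names the offending line
        raise ParseError(f"malformed PDB input: {exc}") from exc
    if len(st) == 0 or st[0].count_atom_sites() == 0:
        raise ParseError("no ATOM/HETATM records found")

    if structure_id is None:
        structure_id = st.name.strip() or "UNKNOWN"

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    m = _RVALUE_RE.search(source)
    r_value = float(m.group(1)) if m else None
    m = _EXPDTA_RE.search(source)
    experiment = m.group(1) if m else None

    chains: dict[str, Chain] = {}
    hetero: list[Residue] = []
    model = st[0]  # model 1 only
    for gchain in model:
        for gres in gchain:
            by_name: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                by_name.setdefault(ga.name, []).append(ga)
            atoms = []
            for aname in by_name:
                ga = _select_altloc(by_name[aname])
                atoms.append(Atom(
                    name=aname,
                    element=ga.element.name,
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    altloc=ga.altloc if ga.altloc != "\x00" else "",
                ))
            seq_position = f"{gres.seqid.num}{gres.seqid.icode}".strip()
            name = gres.name
            parent = NONSTANDARD_PARENT.get(name)
            is_het = gres.het_flag == "H"
            res = Residue(
                chain_id=gchain.name,
                seq_position=seq_position,
                name=name,
                atoms=atoms,
                is_hetero=is_het and parent is None and name not in THREE_TO_ONE,
                modified_parent=parent,
            )
            if res.is_hetero:
                hetero.append(res)
            else:
                chains.setdefault(gchain.name, Chain(gchain.name)).residues.append(res)

    return Structure(
        structure_id=structure_id,
        chains=list(chains.values()),
        hetero_groups=hetero,
        resolution=resolution,
        r_value=r_value,
        experiment=experiment,
    )


def structure_to_pdb(s: Structure) -> str:
    """Serialize a canonical Structure back to minimal PDB-format text."""
    lines = []
    if s.experiment:
        lines.append(f"EXPDTA    {s.experiment}")
    if s.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {s.resolution:8.2f} ANGSTROMS.")
    if s.r_value is not None:
        lines.append(f"REMARK   3   R VALUE            (WORKING SET) : {s.r_value:.3f}")
    serial = 1

    def fmt(record: str, a: Atom, r: Residue) -> str:
        nonlocal serial
        num = "".join(ch for ch in r.seq_position if ch.isdigit() or ch == "-")
        icode = r.seq_position[len(num):] or " "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        line = (
            f"{record:<6s}{serial:5d} {name:4s} {r.name:<3s} {r.chain_id:1s}"
            f"{int(num):4d}{icode:1s}   "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element.upper():>2s}"
        )
        serial += 1
        return line

    for chain in s.chains:
        for r in chain.residues:
            rec = "HETATM" if (r.is_hetero or r.modified_parent) else "ATOM"
            for a in r.atoms:
                lines.append(fmt(rec, a, r))
        lines.append("TER")
    for r in s.hetero_groups:
        for a in r.atoms:
            lines.append(fmt("HETATM", a, r))
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# DSSP

def parse_dssp(source: str) -> list[DsspRecord]:
    """Parse classic DSSP output into per-residue records.

    Chain-break lines ('!') are skipped.  A blank secondary-structure
    column is preserved as ' ' (treated as coil downstream).
    """
    from Bio.PDB.DSSP import make_dssp_dict

    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    ):
        with open(source) as fh:
            source = fh.read()
    if "  #  RESIDUE" not in source:
        raise ParseError("unrecognized DSSP layout (missing residue table header)")

    with tempfile.NamedTemporaryFile("w", suffix=".dssp", delete=False) as fh:
        fh.write(source)
        tmp = fh.name
    try:
        dssp_dict, keys = make_dssp_dict(tmp)
    except Exception as exc:
        raise ParseError(f"unrecognized DSSP layout: {exc}") from exc
    finally:
        os.unlink(tmp)

    records = []
    for key in keys:
        chain_id, (_het, resnum, icode) = key
        aa, ss, acc = dssp_dict[key][:3]
        ss = " " if ss == "-" else ss
        records.append(DsspRecord(
            chain_id=chain_id,
            seq_position=f"{resnum}{icode}".strip(),
            ss_code=ss,
            acc=float(acc),
        ))
    return records


# ---------------------------------------------------------------------------
# Ligand exclusion table / reports

def load_heme_like_ligands(source) -> set[str]:
    """Load a two-column TSV (ligand_code, label) of heme-like ligands.

    Codes are case-folded to upper case; HEM and HEC are always members.
    Duplicate codes elicit a warning and are deduplicated.
    """
    if (isinstance(source, (str, os.PathLike)) and "\n" not in str(source)
            and os.path.exists(str(source))):
        fh = open(source)
    else:
        fh = io.StringIO(source)
    codes: set[str] = set()
    with fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            code = line.split("\t")[0].split()[0].upper()
            if not 1 <= len(code) <= 3:
                raise ValueError(f"invalid ligand code {code!r}")
            if code in codes:
                warnings.warn(f"duplicate ligand code {code}", stacklevel=2)
            codes.add(code)
    codes |= {"HEM", "HEC"}
    return codes


def packaged_heme_like_ligands() -> set[str]:
    """Representative heme-like ligand exclusion set shipped with the package."""
    from importlib.resources import files

    return load_heme_like_ligands(
        str(files("hemescan.data").joinpath("heme_like_ligands.tsv"))
    )


def write_report(records, destination, sort_by: Sequence[str] | None = None,
                 columns: Sequence[str] | None = None) -> None:
    """Write tabular results as TSV with a header and deterministic row order.

    ``records`` may be a DataFrame or a list of dicts sharing a schema.
    When ``sort_by`` is omitted the rows are sorted by all columns.
    ``columns`` fixes the schema, so an empty record list still yields a
    header-only file.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if columns is not None:
        df = df.reindex(columns=list(columns))
    if len(df):
        keys = list(sort_by) if sort_by else list(df.columns)
        df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
    df.to_csv(destination, sep="\t", index=False, float_format="%.6g")
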