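"""Structure filtering, redundancy culling and apo–holo pair discovery.

Curation proceeds in three stages: quality filtering of crystal
structures (method, resolution, R-value), greedy redundancy culling at
a sequence-identity cutoff (PISCES-style: best-resolved chains kept
first), and pairing of heme-bound (holo) chains with heme-free (apo)
chains at high identity and coverage, rejecting candidates that carry
a heme-like ligand or any other ligand parked in the heme pocket.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align

from .structure_io import Structure

__all__ = [
    "FilterCriteria",
    "HEME_SET_CRITERIA",
    "BACKGROUND_SET_CRITERIA",
    "PairwiseAlignment",
    "ApoHoloPair",
    "CullEntry",
    "filter_structures",
    "pairwise_identity",
    "greedy_cull",
    "find_apo_candidates",
    "validate_apo_pocket",
]

logger = logging.getLogger(__name__)

PAIR_IDENTITY_CUTOFF = 0.90
PAIR_COVERAGE_CUTOFF = 0.95
CULL_CUTOFF = 0.25


@dataclass(frozen=True)
class FilterCriteria:
    method: str = "X-RAY DIFFRACTION"
    max_resolution: float = 3.0
    max_r_value: float = 0.3

    def __post_init__(self):
        if self.max_resolution <= 0:
            raise ValueError("max_resolution must be positive")
        if not 0 < self.max_r_value < 1:
            raise ValueError("max_r_value must be in (0,1)")


#: heme dataset: X-ray, ≤3 Å, R ≤ 0.3
HEME_SET_CRITERIA = FilterCriteria()
#: background dataset: X-ray, ≤2.5 Å, R ≤ 0.3
BACKGROUND_SET_CRITERIA = FilterCriteria(max_resolution=2.5)


@dataclass(frozen=True)
class PairwiseAlignment:
    identity: float   # identities / aligned (both non-gap) columns
    coverage: float   # aligned columns / shorter sequence length
    aligned_positions: tuple[tuple[int, int], ...]  # 0-based (pos_a, pos_b)

    def __post_init__(self):
        if not (0 <= self.identity <= 1 and 0 <= self.coverage <= 1):
            raise ValueError("identity and coverage must lie in [0,1]")


@dataclass
class ApoHoloPair:
    holo_id: str
    apo_id: str
    identity: float
    coverage: float
    alignment: PairwiseAlignment
    apo_pocket_clear: bool | None = None


@dataclass(frozen=True)
class CullEntry:
    """A chain presented to the culling step with its selection priority."""
    chain_id: str
    sequence: str
    resolution: float = float("inf")
    r_value: float = float("inf")

    @property
    def priority(self) -> tuple:
        return (self.resolution, self.r_value, self.chain_id)


def filter_structures(structures: list[Structure],
                      criteria: FilterCriteria) -> list[Structure]:
    """Keep structures matching the method with resolution and R-value
    at or below the cutoffs.  Structures lacking either value are
    excluded and logged."""
    kept = []
    for s in structures:
        if s.resolution is None or s.r_value is None or s.experiment is None:
            logger.info("filter: %s excluded (missing resolution, R-value, "
                        "or experiment method)", s.structure_id)
            continue
        if criteria.method.upper() not in s.experiment.upper():
            continue
        if s.resolution <= criteria.max_resolution and s.r_value <= criteria.max_r_value:
            kept.append(s)
    return kept


def _get_aligner(match: float = 1.0, mismatch: float = 0.0,
                 gap_open: float = -5.0, gap_extend: float = -0.5):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # terminal gaps are free so a fragment aligns cleanly to a full chain
    aligner.end_gap_score = 0.0
    return aligner


def pairwise_identity(a: str, b: str, **scores) -> PairwiseAlignment:
    """Global alignment of two sequences with identity and coverage.

    Identity = identical aligned columns / all aligned (both non-gap)
    columns; coverage = aligned columns / length of the shorter
    sequence.  Scoring: match 1, mismatch 0, affine gaps, free end
    gaps (overridable via keyword arguments).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _get_aligner(**scores)
    aln = aligner.align(a.upper(), b.upper())[0]
    positions = []
    n_match = 0
    for (ta0, ta1), (qa0, qa1) in zip(*aln.aligned):
        for i, j in zip(range(ta0, ta1), range(qa0, qa1)):
            positions.append((i, j))
            if aln.target[i] == aln.query[j]:
                n_match += 1
    n_cols = len(positions)
    identity = n_match / n_cols if n_cols else 0.0
    coverage = n_cols / min(len(a), len(b))
    return PairwiseAlignment(identity=identity, coverage=min(coverage, 1.0),
                             aligned_positions=tuple(positions))


def greedy_cull(entries: list[CullEntry], cutoff: float = CULL_CUTOFF) -> list[CullEntry]:
    """PISCES-style greedy redundancy removal.

    Entries are visited in priority order (better resolution, then
    lower R-value, then lexicographic id); an entry is kept iff its
    identity to every already-kept entry is below the cutoff.  The
    output therefore has all pairwise identities < cutoff.
    """
    kept: list[CullEntry] = []
    for e in sorted(entries, key=lambda e: e.priority):
        if all(pairwise_identity(e.sequence, k.sequence).identity < cutoff
               for k in kept):
            kept.append(e)
    return kept


def find_apo_candidates(
    holo_chains: list[tuple[str, str]],
    candidate_chains: list[tuple[str, str, set[str]]],
    heme_like: set[str],
    identity_cutoff: float = PAIR_IDENTITY_CUTOFF,
    coverage_cutoff: float = PAIR_COVERAGE_CUTOFF,
) -> list[ApoHoloPair]:
    """Pair holo chains with apo candidates at high identity/coverage.

    ``holo_chains``: (chain_id, sequence).  ``candidate_chains``:
    (chain_id, sequence, hetero ligand codes of the parent structure).
    Candidates whose structure carries any heme-like ligand are
    rejected outright.  Pocket clearance is validated separately by
    :func:`validate_apo_pocket`.
    """
    pairs = []
    for holo_id, holo_seq in holo_chains:
        for cand_id, cand_seq, ligands in candidate_chains:
            if {c.upper() for c in ligands} & heme_like:
                continue
            aln = pairwise_identity(holo_seq, cand_seq)
            if aln.identity >= identity_cutoff and aln.coverage >= coverage_cutoff:
                pairs.append(ApoHoloPair(
                    holo_id=holo_id, apo_id=cand_id,
                    identity=aln.identity, coverage=aln.coverage,
                    alignment=aln))
    return pairs


def validate_apo_pocket(
    apo: Structure,
    pocket_residues: list[tuple[str, str]],
    any_ligand_cutoff: float = 4.5,
) -> bool:
    """True iff no non-water hetero heavy atom sits in the apo pocket.

    ``pocket_residues`` are (chain_id, seq_position) keys of the apo
    residues mapped (through the pair alignment) from the holo heme
    contacts; a hetero heavy atom within ``any_ligand_cutoff`` Å of
    any of their heavy atoms marks the pocket as occupied.
    """
    wanted = set(pocket_residues)
    pocket_xyz = [a.coords for res in apo.protein_residues()
                  if res.key() in wanted for a in res.heavy_atoms()]
    if not pocket_xyz:
        return True
    pocket_xyz = np.array(pocket_xyz)
    for grp in apo.hetero_groups:
        if grp.is_water:
            continue
        for atom in grp.heavy_atoms():
            d = np.linalg.norm(pocket_xyz - atom.coords, axis=1)
            if float(d.min()) <= any_ligand_cutoff:
                return False
    return True
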