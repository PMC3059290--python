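"""Sequence-guided rigid superposition of apo–holo chain pairs.

The correspondence between the two chains comes from the pairing
alignment (at ≥90% identity a sequence alignment pins the residue
matching unambiguously), and the optimal proper rotation/translation
is found with the Kabsch algorithm.  Conformational change is then
reported as the Cα RMSD over aligned residues, with no outlier
trimming by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataset_curation import ApoHoloPair
from .structure_io import Chain

__all__ = [
    "SuperpositionResult",
    "DegenerateGeometryError",
    "matched_calpha",
    "kabsch_superpose",
    "compare_pair",
]

logger = logging.getLogger(__name__)


class DegenerateGeometryError(ValueError):
    """Raised for point sets that do not determine a superposition."""


@dataclass
class SuperpositionResult:
    n_aligned: int
    rotation: np.ndarray     # (3,3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float              # Å
    holo_id: str = ""
    apo_id: str = ""

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be 3x3 orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        if self.rmsd < 0 or self.n_aligned < 3:
            raise ValueError("invalid rmsd or n_aligned")


def matched_calpha(pair: ApoHoloPair, holo_chain: Chain,
                   apo_chain: Chain) -> tuple[np.ndarray, np.ndarray]:
    """Cα coordinates at aligned, non-gap positions of the pair.

    Alignment positions index the observed standard residues of each
    chain.  Positions lacking a Cα in either partner are dropped and
    logged.  Fewer than three matched pairs is an error.
    """
    holo_res = holo_chain.standard_residues()
    apo_res = apo_chain.standard_residues()
    a_coords, b_coords = [], []
    n_dropped = 0
    for i, j in pair.alignment.aligned_positions:
        ca_a = holo_res[i].get_atom("CA") if i < len(holo_res) else None
        ca_b = apo_res[j].get_atom("CA") if j < len(apo_res) else None
        if ca_a is None or ca_b is None:
            n_dropped += 1
            continue
        a_coords.append(ca_a.coords)
        b_coords.append(ca_b.coords)
    if n_dropped:
        logger.info("matched_calpha %s/%s: dropped %d positions lacking CA",
                    pair.holo_id, pair.apo_id, n_dropped)
    if len(a_coords) < 3:
        raise DegenerateGeometryError(
            f"only {len(a_coords)} matched Cα pairs (need ≥3)")
    return np.array(a_coords), np.array(b_coords)


def kabsch_superpose(coords_a: np.ndarray,
                     coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal proper rotation/translation of B onto A.

    Returns R, t minimizing Σ‖a_i − (R b_i + t)‖² and the resulting
    RMSD.  Reflections are never returned: the smallest singular
    direction is flipped when det < 0 (standard Kabsch correction).
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n,3)")
    n = A.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 points")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValueError("coordinates must be finite")

    cen_a = A.mean(axis=0)
    cen_b = B.mean(axis=0)
    Ac = A - cen_a
    Bc = B - cen_b
    H = Bc.T @ Ac
    U, S, Vt = np.linalg.svd(H)
    # collinear point sets leave the rotation about the line undetermined
    if S[1] <= 1e-10 * max(S[0], 1.0):
        raise DegenerateGeometryError("collinear points: rotation undetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cen_a - R @ cen_b
    diff = A - (B @ R.T + t)
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    return SuperpositionResult(n_aligned=n, rotation=R, translation=t, rmsd=rmsd)


def compare_pair(pair: ApoHoloPair, holo_chain: Chain,
                 apo_chain: Chain) -> SuperpositionResult:
    """Superpose an apo–holo pair and report the aligned-Cα RMSD."""
    A, B = matched_calpha(pair, holo_chain, apo_chain)
    result = kabsch_superpose(A, B)
    result.holo_id = pair.holo_id
    result.apo_id = pair.apo_id
    return result
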