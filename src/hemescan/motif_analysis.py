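"""Ligand-flanking sequence windows and heme motif statistics.

Flanking windows of four residues on each side of an axial ligand
(nine positions, '-'-padded at chain termini) are the unit used to
look for coordination motifs such as the cytochrome *c* CXXCH pattern
and the cysteine-proline (CP) heme-regulatory dipeptide.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

from scipy import stats

from .contact_analysis import AxialLigand
from .structure_io import Chain

__all__ = [
    "MotifWindow",
    "MotifMatch",
    "extract_windows",
    "find_motifs",
    "cp_positional_census",
    "cp_enrichment_test",
    "WINDOW_FLANK",
]

WINDOW_FLANK = 4  # residues on each side of the axial ligand


@dataclass(frozen=True)
class MotifWindow:
    chain_id: str
    center_position: str  # author numbering of the axial ligand
    window: str           # 9 characters, '-' padding at termini
    ligand_residue: str   # 1-letter code

    def __post_init__(self):
        if len(self.window) != 2 * WINDOW_FLANK + 1:
            raise ValueError("window must span ±4 residues")
        if self.window[WINDOW_FLANK] != self.ligand_residue:
            raise ValueError("window center must be the ligand residue")


@dataclass(frozen=True)
class MotifMatch:
    chain_id: str
    start_position: int  # 1-based
    pattern_name: str
    matched_text: str


def extract_windows(ligands: list[AxialLigand],
                    chains: dict[str, Chain] | list[Chain]) -> list[MotifWindow]:
    """One ±4-residue window per axial ligand, centered on the ligand.

    Indexing follows the observed residues of the chain (disordered
    stretches therefore do not silently shift the window); positions
    beyond the termini are padded with '-'.
    """
    if not isinstance(chains, dict):
        chains = {c.chain_id: c for c in chains}
    out = []
    for lig in ligands:
        chain = chains[lig.residue.chain_id]
        standard = chain.standard_residues()
        seq = chain.observed_sequence
        try:
            center = next(i for i, r in enumerate(standard)
                          if r.key() == lig.residue.key())
        except StopIteration:
            raise KeyError(
                f"ligand residue {lig.residue.key()} not in chain "
                f"{chain.chain_id} observed sequence") from None
        window = "".join(
            seq[i] if 0 <= i < len(seq) else "-"
            for i in range(center - WINDOW_FLANK, center + WINDOW_FLANK + 1))
        out.append(MotifWindow(
            chain_id=chain.chain_id,
            center_position=lig.residue.seq_position,
            window=window,
            ligand_residue=lig.residue.one_letter))
    return out


def _pattern_to_regex(pattern: str) -> str:
    """Translate an X-wildcard / bracketed-class motif pattern to a regex."""
    out = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "X":
            out.append("[A-Z]")
            i += 1
        elif ch == "[":
            j = pattern.index("]", i)
            out.append(pattern[i:j + 1])
            i = j + 1
        elif ch.isalpha():
            out.append(ch.upper())
            i += 1
        else:
            raise ValueError(f"invalid pattern character {ch!r} in {pattern!r}")
    return "".join(out)


def find_motifs(sequence: str, pattern: str,
                pattern_name: str | None = None,
                chain_id: str = "") -> list[MotifMatch]:
    """All (overlapping) matches of a motif pattern, 1-based starts.

    ``X`` matches any residue; ``[PLAV]`` matches a residue class;
    plain letters match themselves.
    """
    regex = _pattern_to_regex(pattern)
    name = pattern_name or pattern
    seq = sequence.upper()
    matches = []
    for m in re.finditer(f"(?=({regex}))", seq):
        matches.append(MotifMatch(
            chain_id=chain_id,
            start_position=m.start() + 1,
            pattern_name=name,
            matched_text=m.group(1)))
    return matches


def cp_positional_census(windows: list[MotifWindow]) -> Counter:
    """Residue counts at the +1 position of cysteine-ligand windows.

    Windows padded at +1 (ligand at the chain terminus) are excluded
    from the census.
    """
    pos = WINDOW_FLANK + 1
    return Counter(w.window[pos] for w in windows if w.window[pos] != "-")


def cp_enrichment_test(
    heme_seqs: list[str],
    control_seqs: list[str],
    per_residue: bool = False,
) -> dict:
    """Test whether CP dipeptides are enriched in heme-protein sequences.

    Default: a 2×2 test on sequences containing ≥1 CP versus not
    (χ² with continuity correction; Fisher's exact test when any
    expected cell is below 5).  ``per_residue=True`` instead compares
    CP occurrences per dipeptide position between the pooled sets.
    Returns per-set occurrence counts alongside the statistic and p.
    """
    if not heme_seqs or not control_seqs:
        raise ValueError("both sequence sets must be non-empty")

    def count_occurrences(seqs):
        return sum(len(find_motifs(s, "CP")) for s in seqs)

    def count_positions(seqs):
        return sum(max(len(s) - 1, 0) for s in seqs)

    result = {
        "n_heme_seqs": len(heme_seqs),
        "n_control_seqs": len(control_seqs),
        "heme_cp_occurrences": count_occurrences(heme_seqs),
        "control_cp_occurrences": count_occurrences(control_seqs),
        "heme_seqs_with_cp": sum(1 for s in heme_seqs if "CP" in s.upper()),
        "control_seqs_with_cp": sum(1 for s in control_seqs if "CP" in s.upper()),
    }
    if per_residue:
        table = [
            [result["heme_cp_occurrences"],
             count_positions(heme_seqs) - result["heme_cp_occurrences"]],
            [result["control_cp_occurrences"],
             count_positions(control_seqs) - result["control_cp_occurrences"]],
        ]
    else:
        table = [
            [result["heme_seqs_with_cp"],
             len(heme_seqs) - result["heme_seqs_with_cp"]],
            [result["control_seqs_with_cp"],
             len(control_seqs) - result["control_seqs_with_cp"]],
        ]

    import numpy as np

    tab = np.asarray(table, dtype=float)
    if tab.min() < 0:
        raise ValueError("negative cell count")
    total = tab.sum()
    expected = np.outer(tab.sum(1), tab.sum(0)) / total
    if (expected < 5).any() or (tab.sum(1) == 0).any() or (tab.sum(0) == 0).any():
        odds, p = stats.fisher_exact(tab.astype(int))
        result.update(test="fisher_exact", statistic=float(odds), p=float(p))
    else:
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=True)
        result.update(test="chi2_cc", statistic=float(chi2), p=float(p))
    result["table"] = table
    return result
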