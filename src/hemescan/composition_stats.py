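"""Residue, secondary-structure and accessibility preference statistics.

Heme-interacting residues are compared against a background set by
pooled category frequencies; enrichment is expressed as the ratio of
the site frequency to the background frequency (so a ratio of 8 for
cysteine means cysteine occurs eight times more often among interacting
residues than expected from the background composition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib.resources import files

import numpy as np
import pandas as pd
from scipy import stats

from .contact_analysis import AxialLigand, ContactRecord

__all__ = [
    "AMINO_ACIDS",
    "SS_STATES",
    "RSA_STATES",
    "FrequencyProfile",
    "RelativeProfile",
    "RsaClass",
    "residue_frequencies",
    "site_frequencies",
    "relative_profile",
    "ss_state",
    "classify_rsa",
    "profile_chi_square",
    "load_max_accessibility",
    "fold_class_summary",
    "load_fold_census",
]

logger = logging.getLogger(__name__)

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
SS_STATES = ("helix", "strand", "coil")
RSA_STATES = ("buried", "intermediate", "exposed")

RSA_BURIED_MAX = 0.07
RSA_INTERMEDIATE_MAX = 0.37


@dataclass
class FrequencyProfile:
    categories: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.categories):
            raise ValueError("counts/categories length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def freqs(self) -> np.ndarray:
        n = self.n_total
        return self.counts / n if n else np.zeros_like(self.counts, dtype=float)

    @classmethod
    def from_items(cls, items, categories) -> "FrequencyProfile":
        idx = {c: i for i, c in enumerate(categories)}
        counts = np.zeros(len(categories), dtype=np.int64)
        for it in items:
            if it in idx:
                counts[idx[it]] += 1
        return cls(tuple(categories), counts)


@dataclass
class RelativeProfile:
    categories: tuple[str, ...]
    ratios: np.ndarray                       # site freq / background freq
    undefined: tuple[str, ...] = field(default_factory=tuple)  # zero background

    def ratio(self, category: str) -> float:
        return float(self.ratios[self.categories.index(category)])


@dataclass(frozen=True)
class RsaClass:
    label: str
    rsa: float

    def __post_init__(self):
        if self.label not in RSA_STATES:
            raise ValueError(self.label)


def residue_frequencies(sequences: list[str]) -> FrequencyProfile:
    """Pooled amino-acid frequencies over a set of sequences.

    Non-standard letters (X etc.) are ignored with a log message.
    """
    if not sequences:
        raise ValueError("empty sequence set")
    valid = set(AMINO_ACIDS)
    n_skipped = 0
    counts = np.zeros(len(AMINO_ACIDS), dtype=np.int64)
    idx = {c: i for i, c in enumerate(AMINO_ACIDS)}
    for seq in sequences:
        for ch in seq.upper():
            if ch in valid:
                counts[idx[ch]] += 1
            else:
                n_skipped += 1
    if n_skipped:
        logger.info("residue_frequencies: ignored %d non-standard letters", n_skipped)
    return FrequencyProfile(AMINO_ACIDS, counts)


def site_frequencies(
    contacts: list[ContactRecord],
    exclude_axial: bool = False,
    axial: list[AxialLigand] | None = None,
    distinct: bool = True,
) -> FrequencyProfile:
    """Amino-acid frequencies of heme-interacting residues.

    Interacting residues are counted as distinct (chain, position)
    sites by default; ``distinct=False`` counts one occurrence per
    heme contact instead.  With ``exclude_axial`` the residues that
    serve as axial ligands (given in ``axial``) are removed before
    counting, which isolates porphyrin-contact preferences from
    iron-coordination preferences.
    """
    axial_keys = {lig.residue.key() for lig in (axial or [])}
    seen = set()
    letters = []
    for rec in contacts:
        key = rec.residue.key()
        if exclude_axial and key in axial_keys:
            continue
        if distinct:
            if key in seen:
                continue
            seen.add(key)
        letters.append(rec.residue.one_letter)
    return FrequencyProfile.from_items(letters, AMINO_ACIDS)


def relative_profile(site: FrequencyProfile,
                     background: FrequencyProfile) -> RelativeProfile:
    """Elementwise site/background frequency ratios.

    Categories with zero background count are flagged undefined (ratio
    NaN) rather than divided.
    """
    if site.categories != background.categories:
        raise ValueError("category mismatch between site and background profiles")
    bg = background.freqs
    ratios = np.full(len(bg), np.nan)
    ok = background.counts > 0
    ratios[ok] = site.freqs[ok] / bg[ok]
    undefined = tuple(c for c, good in zip(site.categories, ok) if not good)
    return RelativeProfile(site.categories, ratios, undefined)


def ss_state(ss_code: str) -> str:
    """Map a DSSP code to the three-state convention.

    H (α-helix), G (3₁₀-helix) and I (π-helix) are helix; E (extended
    strand) and B (isolated bridge) are strand; everything else
    (turns, bends, blank) is coil.
    """
    if ss_code in ("H", "G", "I"):
        return "helix"
    if ss_code in ("E", "B"):
        return "strand"
    return "coil"


def load_max_accessibility(source=None) -> dict[str, float]:
    """Per-residue maximum accessible areas (Å²); user-overridable table."""
    if source is None:
        source = str(files("hemescan.data").joinpath("max_accessibility.tsv"))
    df = pd.read_csv(source, sep="\t", comment="#", header=None,
                     names=["residue", "max_acc"])
    return dict(zip(df["residue"].str.upper(), df["max_acc"].astype(float)))


def classify_rsa(acc: float, residue_name: str,
                 max_acc: dict[str, float] | None = None) -> RsaClass:
    """Three-state relative solvent accessibility class.

    rsa = acc / max_acc, capped at 1.0 (crystal contacts can push the
    DSSP area above the tabulated maximum).  Classes: buried (≤7%),
    intermediate (>7% and ≤37%), exposed (>37%).
    """
    if acc < 0:
        raise ValueError("acc must be non-negative")
    table = max_acc if max_acc is not None else load_max_accessibility()
    key = residue_name.upper()
    if key not in table:
        raise KeyError(f"no maximum accessibility for residue {residue_name!r}")
    rsa = min(acc / table[key], 1.0)
    eps = 1e-9  # absorb float round-off at the class boundaries
    if rsa <= RSA_BURIED_MAX + eps:
        label = "buried"
    elif rsa <= RSA_INTERMEDIATE_MAX + eps:
        label = "intermediate"
    else:
        label = "exposed"
    return RsaClass(label, rsa)


def profile_chi_square(a: FrequencyProfile,
                       b: FrequencyProfile) -> tuple[float, int, float]:
    """Pearson χ² of profile ``a``'s counts against expectations from ``b``.

    Expected counts are ``b``'s frequencies scaled to ``a``'s total;
    zero-expectation categories are dropped (logged).  Degrees of
    freedom = remaining categories − 1.
    """
    if a.categories != b.categories:
        raise ValueError("category mismatch")
    if a.n_total == 0 or b.n_total == 0:
        raise ValueError("empty profile")
    expected = b.freqs * a.n_total
    keep = expected > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("profile_chi_square: dropped %d zero-expectation categories",
                    n_dropped)
    obs = a.counts[keep].astype(float)
    exp = expected[keep]
    # rescale so totals match after dropping categories (chisquare requires it)
    exp = exp * obs.sum() / exp.sum()
    stat = float(np.sum((obs - exp) ** 2 / exp))
    df = int(keep.sum()) - 1
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p


# ---------------------------------------------------------------------------
# Fold census arithmetic (printed-table input)

def load_fold_census(source=None) -> pd.DataFrame:
    if source is None:
        source = str(files("hemescan.data").joinpath("scop_fold_census.tsv"))
    return pd.read_csv(source, sep="\t", comment="#")


def fold_class_summary(census: pd.DataFrame | None = None) -> dict:
    """Summarize a fold census table: totals and per-class fractions.

    Returns the number of distinct folds, the number of annotated
    chains, per-structural-class chain counts (SCOP class = the letter
    prefix of the fold id) and the all-α fraction of annotated chains.
    """
    df = census if census is not None else load_fold_census()
    cls = df["fold_id"].str.split(".").str[0]
    class_counts = df.groupby(cls)["n_chains"].sum().to_dict()
    total = int(df["n_chains"].sum())
    return {
        "n_folds": int(len(df)),
        "n_annotated_chains": total,
        "class_counts": {k: int(v) for k, v in sorted(class_counts.items())},
        "all_alpha_fraction": class_counts.get("a", 0) / total if total else float("nan"),
    }
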