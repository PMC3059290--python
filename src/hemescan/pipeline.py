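"""Run-level orchestration: configuration, stages, manifest.

A run consumes a directory of PDB files (plus optional DSSP files,
background FASTA and a CASTp-style pocket table) and executes the
stages in dependency order::

    contacts ──> stats
          └────> motifs
    curate ──> pairs ──> compare
    pockets (independent)

Each stage writes TSV reports whose headers embed the cutoff values
that produced them; a JSON manifest records parameters, outputs and
content digests, so reruns with the same configuration and seed are
byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import contact_analysis as ca
from . import composition_stats as cs
from . import dataset_curation as dc
from . import motif_analysis as ma
from . import pocket_metrics as pm
from . import structure_compare as sc
from .structure_io import (Structure, load_heme_like_ligands,
                           packaged_heme_like_ligands, parse_dssp,
                           parse_structure, write_report)

logger = logging.getLogger(__name__)

CONTACT_COLUMNS = ("structure", "chain", "resnum", "resname", "heme_id",
                   "min_distance", "is_axial")


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    seed: int = 0
    axial_cutoff: float = ca.AXIAL_CUTOFF
    contact_cutoff: float = ca.CONTACT_CUTOFF
    min_contacts: int = ca.MIN_CONTACTS
    cull_cutoff: float = dc.CULL_CUTOFF
    pair_identity: float = dc.PAIR_IDENTITY_CUTOFF
    pair_coverage: float = dc.PAIR_COVERAGE_CUTOFF
    rsa_buried: float = cs.RSA_BURIED_MAX
    rsa_intermediate: float = cs.RSA_INTERMEDIATE_MAX
    pocket_window: tuple[float, float] = pm.SIZE_WINDOW
    heme_like_table: str | None = None
    background_fasta: str | None = None
    pocket_table: str | None = None

    def __post_init__(self):
        positive = [self.axial_cutoff, self.contact_cutoff, self.min_contacts,
                    self.cull_cutoff, self.pair_identity, self.pair_coverage,
                    self.rsa_buried, self.rsa_intermediate, *self.pocket_window]
        if any(v <= 0 for v in positive):
            raise ValueError("all cutoffs must be positive")
        if not self.rsa_buried < self.rsa_intermediate:
            raise ValueError("rsa thresholds must be ordered")

    @classmethod
    def from_toml(cls, path: str) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        if "pocket_window" in raw:
            raw["pocket_window"] = tuple(raw["pocket_window"])
        return cls(**raw)

    def params(self) -> dict:
        d = asdict(self)
        d["pocket_window"] = list(self.pocket_window)
        return d


def _write(df, path: Path, params: dict, sort_by=None, columns=None):
    """write_report plus '# key=value' parameter provenance lines."""
    tmp = path.with_suffix(path.suffix + ".body")
    write_report(df, tmp, sort_by=sort_by, columns=columns)
    with open(path, "w") as out:
        for k in sorted(params):
            out.write(f"# {k}={params[k]}\n")
        out.write(tmp.read_text())
    tmp.unlink()


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def load_structures(input_dir: str) -> list[Structure]:
    structures = []
    for p in sorted(Path(input_dir).glob("*.pdb")):
        structures.append(parse_structure(str(p)))
    return structures


# ---------------------------------------------------------------------------
# Stages

def stage_contacts(structures: list[Structure], outdir: Path, cfg: RunConfig) -> dict:
    params = {"axial_cutoff": cfg.axial_cutoff,
              "contact_cutoff": cfg.contact_cutoff,
              "min_contacts": cfg.min_contacts}
    contact_rows, axial_rows, verdict_rows = [], [], []
    for s in structures:
        hemes = ca.find_heme_groups(s)
        axial_keys = set()
        for h in hemes:
            for lig in ca.find_axial_ligands(h, s, cfg.axial_cutoff):
                axial_keys.add((lig.residue.key(), h.heme_id))
                axial_rows.append({
                    "structure": s.structure_id, "chain": lig.residue.chain_id,
                    "resnum": lig.residue.seq_position, "resname": lig.residue.name,
                    "heme_id": "".join(h.heme_id[1:]), "donor_atom": lig.donor_atom,
                    "donor_element": lig.donor_element,
                    "distance": round(lig.distance, 3)})
        for h in hemes:
            for rec in ca.find_interacting_residues(h, s, cfg.contact_cutoff):
                contact_rows.append({
                    "structure": s.structure_id, "chain": rec.residue.chain_id,
                    "resnum": rec.residue.seq_position, "resname": rec.residue.name,
                    "heme_id": "".join(h.heme_id[1:]),
                    "min_distance": round(rec.min_distance, 3),
                    "is_axial": (rec.residue.key(), h.heme_id) in axial_keys})
        for v in ca.classify_binding_chains(
                s, cfg.axial_cutoff, cfg.contact_cutoff, cfg.min_contacts):
            verdict_rows.append({
                "structure": s.structure_id, "chain": v.chain_id,
                "is_binding": v.is_binding, "n_axial": v.n_axial,
                "n_contacts": v.n_contacts, "reason": v.reason})
    _write(contact_rows, outdir / "contacts.tsv", params, columns=CONTACT_COLUMNS)
    _write(axial_rows, outdir / "axial_ligands.tsv", params,
           columns=("structure", "chain", "resnum", "resname", "heme_id",
                    "donor_atom", "donor_element", "distance"))
    _write(verdict_rows, outdir / "binding_chains.tsv", params,
           columns=("structure", "chain", "is_binding", "n_axial",
                    "n_contacts", "reason"))
    return {"n_structures": len(structures), "n_contacts": len(contact_rows),
            "n_axial": len(axial_rows)}


def _read_fasta(path: str) -> list[str]:
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(path, "fasta")]


def stage_stats(structures: list[Structure], outdir: Path, cfg: RunConfig) -> dict:
    params = {"axial_cutoff": cfg.axial_cutoff, "contact_cutoff": cfg.contact_cutoff,
              "rsa_buried": cfg.rsa_buried, "rsa_intermediate": cfg.rsa_intermediate}
    contacts, axial = [], []
    for s in structures:
        for h in ca.find_heme_groups(s):
            contacts += ca.find_interacting_residues(h, s, cfg.contact_cutoff)
            axial += ca.find_axial_ligands(h, s, cfg.axial_cutoff)
    if not contacts:
        raise ValueError("no heme contacts found; stats stage needs contacts")

    if cfg.background_fasta:
        background_seqs = _read_fasta(cfg.background_fasta)
    else:
        logger.warning("stats: no full-length background FASTA supplied; "
                       "falling back to observed chain sequences")
        background_seqs = [c.observed_sequence for s in structures for c in s.chains]
    background = cs.residue_frequencies(background_seqs)
    site = cs.site_frequencies(contacts)
    site_noax = cs.site_frequencies(contacts, exclude_axial=True, axial=axial)
    rel = cs.relative_profile(site, background)
    chi2, df, p = cs.profile_chi_square(site, background)

    _write(pd.DataFrame({
        "category": site.categories, "site_count": site.counts,
        "site_freq": site.freqs, "site_freq_no_axial": site_noax.freqs,
        "background_freq": background.freqs, "relative_freq": rel.ratios,
    }), outdir / "residue_profile.tsv", params, sort_by=["category"])

    # secondary structure / accessibility profiles from DSSP files, if present
    dssp_records = {}
    for p_dssp in sorted(Path(cfg.input_dir).glob("*.dssp")):
        sid = p_dssp.stem
        for rec in parse_dssp(str(p_dssp)):
            dssp_records[(sid, rec.chain_id, rec.seq_position)] = rec
    summary = {"chi2": chi2, "chi2_df": df, "chi2_p": p,
               "n_site_residues": site.n_total}
    if dssp_records:
        max_acc = cs.load_max_accessibility()
        name_of = {(s.structure_id, r.chain_id, r.seq_position): r.effective_name
                   for s in structures for r in s.protein_residues()}
        site_keys = {(rec.heme_id[0], rec.residue.chain_id,
                      rec.residue.seq_position) for rec in contacts}
        ss_site, ss_bg, rsa_site, rsa_bg = [], [], [], []
        for key, rec in dssp_records.items():
            if key not in name_of:
                continue
            state = cs.ss_state(rec.ss_code)
            rsa_cls = cs.classify_rsa(rec.acc, name_of[key], max_acc).label
            ss_bg.append(state)
            rsa_bg.append(rsa_cls)
            if key in site_keys:
                ss_site.append(state)
                rsa_site.append(rsa_cls)
        for name, cats, site_items, bg_items in (
                ("ss_profile", cs.SS_STATES, ss_site, ss_bg),
                ("rsa_profile", cs.RSA_STATES, rsa_site, rsa_bg)):
            sp = cs.FrequencyProfile.from_items(site_items, cats)
            bp = cs.FrequencyProfile.from_items(bg_items, cats)
            rr = cs.relative_profile(sp, bp)
            _write(pd.DataFrame({
                "category": cats, "site_count": sp.counts,
                "site_freq": sp.freqs, "background_freq": bp.freqs,
                "relative_freq": rr.ratios,
            }), outdir / f"{name}.tsv", params, sort_by=["category"])
        summary["n_dssp_residues"] = len(dssp_records)
    return summary


def stage_motifs(structures: list[Structure], outdir: Path, cfg: RunConfig,
                 patterns: tuple[str, ...] = ("CXXCH", "CP")) -> dict:
    params = {"axial_cutoff": cfg.axial_cutoff, "patterns": ",".join(patterns)}
    window_rows, match_rows = [], []
    n_ligands = 0
    for s in structures:
        chains = {c.chain_id: c for c in s.chains}
        ligands = []
        for h in ca.find_heme_groups(s):
            ligands += ca.find_axial_ligands(h, s, cfg.axial_cutoff)
        n_ligands += len(ligands)
        for w in ma.extract_windows(ligands, chains):
            window_rows.append({
                "structure": s.structure_id, "chain": w.chain_id,
                "center": w.center_position, "ligand": w.ligand_residue,
                "window": w.window})
        for c in s.chains:
            for pat in patterns:
                for m in ma.find_motifs(c.observed_sequence, pat,
                                        chain_id=c.chain_id):
                    match_rows.append({
                        "structure": s.structure_id, "chain": m.chain_id,
                        "start": m.start_position, "pattern": m.pattern_name,
                        "match": m.matched_text})
    _write(window_rows, outdir / "windows.tsv", params,
           columns=("structure", "chain", "center", "ligand", "window"))
    _write(match_rows, outdir / "motif_matches.tsv", params,
           columns=("structure", "chain", "start", "pattern", "match"))
    return {"n_ligand_windows": len(window_rows), "n_matches": len(match_rows)}


def stage_pairs(structures: list[Structure], outdir: Path, cfg: RunConfig) -> dict:
    params = {"pair_identity": cfg.pair_identity,
              "pair_coverage": cfg.pair_coverage,
              "contact_cutoff": cfg.contact_cutoff}
    heme_like = (load_heme_like_ligands(cfg.heme_like_table)
                 if cfg.heme_like_table else packaged_heme_like_ligands())
    by_id = {}
    holo, candidates = [], []
    for s in structures:
        ligs = {g.name.upper() for g in s.hetero_groups}
        for c in s.chains:
            cid = f"{s.structure_id}:{c.chain_id}"
            by_id[cid] = (s, c)
            if not c.observed_sequence:
                continue
            if ligs & heme_like:
                holo.append((cid, c.observed_sequence))
            else:
                candidates.append((cid, c.observed_sequence, ligs))
    pairs = dc.find_apo_candidates(holo, candidates, heme_like,
                                   cfg.pair_identity, cfg.pair_coverage)
    rows = []
    for p in pairs:
        holo_s, holo_c = by_id[p.holo_id]
        apo_s, apo_c = by_id[p.apo_id]
        pocket_keys = set()
        for h in ca.find_heme_groups(holo_s):
            for rec in ca.find_interacting_residues(h, holo_s, cfg.contact_cutoff):
                if rec.residue.chain_id != holo_c.chain_id:
                    continue
                holo_std = holo_c.standard_residues()
                apo_std = apo_c.standard_residues()
                idx = {r.key(): i for i, r in enumerate(holo_std)}
                if rec.residue.key() in idx:
                    i = idx[rec.residue.key()]
                    for (a, b) in p.alignment.aligned_positions:
                        if a == i and b < len(apo_std):
                            pocket_keys.add(apo_std[b].key())
        p.apo_pocket_clear = dc.validate_apo_pocket(
            apo_s, sorted(pocket_keys), cfg.contact_cutoff)
        rows.append({"holo": p.holo_id, "apo": p.apo_id,
                     "identity": round(p.identity, 4),
                     "coverage": round(p.coverage, 4),
                     "apo_pocket_clear": p.apo_pocket_clear})
    _write(rows, outdir / "pairs.tsv", params,
           columns=("holo", "apo", "identity", "coverage", "apo_pocket_clear"))
    return {"n_pairs": len(rows), "pairs": pairs, "by_id": by_id}


def stage_compare(pairs_info: dict, outdir: Path, cfg: RunConfig) -> dict:
    params = {"pair_identity": cfg.pair_identity}
    rows = []
    for p in pairs_info["pairs"]:
        if p.apo_pocket_clear is False:
            continue
        _, holo_c = pairs_info["by_id"][p.holo_id]
        _, apo_c = pairs_info["by_id"][p.apo_id]
        res = sc.compare_pair(p, holo_c, apo_c)
        rows.append({"holo": p.holo_id, "apo": p.apo_id,
                     "identity": round(p.identity, 4),
                     "n_aligned": res.n_aligned, "rmsd": round(res.rmsd, 3)})
    _write(rows, outdir / "rmsd.tsv", params,
           columns=("holo", "apo", "identity", "n_aligned", "rmsd"))
    return {"n_compared": len(rows)}


def stage_pockets(outdir: Path, cfg: RunConfig) -> dict:
    params = {"pocket_window": list(cfg.pocket_window)}
    df = pm.load_pocket_table(cfg.pocket_table)
    _write(df, outdir / "pockets.tsv", params)
    return {"n_pockets": int(len(df))}


# ---------------------------------------------------------------------------
# Pipeline driver

STAGE_DEPS = {
    "contacts": (),
    "stats": ("contacts",),
    "motifs": ("contacts",),
    "pairs": (),
    "compare": ("pairs",),
    "pockets": (),
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order and write manifest.json.

    A stage failure halts its dependents but independent stages still
    run; the failure (message + traceback) is recorded in the manifest.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    structures = load_structures(config.input_dir)
    if not structures:
        raise ValueError(f"no PDB files found in {config.input_dir}")

    manifest = {"config": config.params(), "stages": {}}
    status: dict[str, bool] = {}
    carry: dict[str, dict] = {}

    runners = {
        "contacts": lambda: stage_contacts(structures, outdir, config),
        "stats": lambda: stage_stats(structures, outdir, config),
        "motifs": lambda: stage_motifs(structures, outdir, config),
        "pairs": lambda: stage_pairs(structures, outdir, config),
        "compare": lambda: stage_compare(carry["pairs"], outdir, config),
        "pockets": lambda: stage_pockets(outdir, config),
    }
    for name in STAGE_DEPS:
        if not all(status.get(dep, False) for dep in STAGE_DEPS[name]):
            manifest["stages"][name] = {"status": "skipped (failed dependency)"}
            status[name] = False
            continue
        try:
            result = runners[name]()
            carry[name] = result
            manifest["stages"][name] = {
                "status": "ok",
                "summary": {k: v for k, v in result.items()
                            if isinstance(v, (int, float, str, bool))}}
            status[name] = True
        except Exception as exc:
            logger.error("stage %s failed: %s", name, exc)
            manifest["stages"][name] = {
                "status": "failed", "error": str(exc),
                "traceback": traceback.format_exc()}
            status[name] = False

    outputs = {}
    for p in sorted(outdir.glob("*.tsv")):
        outputs[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest["outputs"] = outputs
    manifest["digest"] = hashlib.sha256(
        json.dumps(outputs, sort_keys=True).encode()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
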