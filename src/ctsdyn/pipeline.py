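"""End-to-end orchestration of the sequence and structure arms.

``run_sequence_arm`` takes a CTS FASTA and/or an alignment and emits the
CTS descriptor table, the NJ tree (with optional bootstrap) and the
conservation profile.  ``run_structure_arm`` takes two endpoint ring
structures, builds the mixed two-basin ENM surface, generates the
T -> R'' transition path and writes every motion metric table.  Each run
writes a JSON-lines manifest with the resolved configuration and input
digests, and all randomness flows from one seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ctsdyn import enm, menm, metrics, phylo, seq_features, structure

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "ctsdyn_out"
    seed: int = 0
    # sequence arm
    fasta: str | None = None
    alignment: str | None = None
    anchor_window: int = 40
    gamma_shape: float = 1.0
    bootstrap: int = 0
    plurality: float = 0.5
    # structure arm
    pdb_t: str | None = None
    pdb_r: str | None = None
    cutoff: float = 12.0
    spring: str = "uniform"
    n_modes: int = 50
    beta: float | None = None
    n_frames: int = 50
    cts_range: tuple[int, int] | None = None   # residue ids, inclusive


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _write_manifest(cfg: RunConfig, inputs: list[str], out_dir: Path) -> None:
    rec = {"config": asdict(cfg),
           "inputs": {p: _digest(p) for p in inputs if p}}
    with open(out_dir / "manifest.jsonl", "a") as fh:
        fh.write(json.dumps(rec, sort_keys=True) + "\n")


def run_sequence_arm(cfg: RunConfig) -> dict:
    """CTS table (TSV), NJ tree (Newick), conservation profile (TSV)."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    inputs = []

    if cfg.fasta:
        inputs.append(cfg.fasta)
        records = seq_features.scan_fasta(cfg.fasta, cfg.anchor_window)
        if not records:
            raise RuntimeError("no CTS could be extracted from the FASTA")
        table = pd.DataFrame([
            {"parent_id": r.parent_id, "anchor_pos": r.anchor_pos,
             "tail": r.tail, "length": len(r.tail), "gravy": r.gravy,
             "pi": r.pi, "class_label": r.class_label}
            for r in records
        ])
        table.to_csv(out_dir / "cts_table.tsv", sep="\t", index=False)
        results["cts_table"] = table
        # NJ tree over the tails themselves (padded to equal length) is
        # only possible from an alignment; tails go to the tree stage
        # when an alignment is supplied.

    if cfg.alignment:
        inputs.append(cfg.alignment)
        msa = phylo.Msa.read(cfg.alignment)
        if cfg.bootstrap > 0:
            tree = phylo.bootstrap_support(
                msa, replicates=cfg.bootstrap, seed=cfg.seed,
                shape=cfg.gamma_shape, cap=10.0)
        else:
            tree = phylo.nj_from_msa(msa, shape=cfg.gamma_shape, cap=10.0)
        (out_dir / "tree.nwk").write_text(
            tree.newick(with_support=cfg.bootstrap > 0) + "\n")
        results["tree"] = tree
        ref_id = msa.ids[0]
        try:
            profile = phylo.conservation_profile(msa, ref_id)
            pd.DataFrame({
                "position": profile.positions,
                "score": profile.scores,
                "coverage": profile.coverage,
            }).to_csv(out_dir / "conservation.tsv", sep="\t", index=False)
            results["conservation"] = profile
        except phylo.FlatProfileError as exc:
            log.warning("conservation profile skipped: %s", exc)
        results["n_substitutions"] = phylo.count_substitutions(msa, tree=tree)

    if not inputs:
        raise ValueError("sequence arm needs a FASTA or an alignment")
    _write_manifest(cfg, inputs, out_dir)
    return results


def run_structure_arm(cfg: RunConfig) -> dict:
    """Transition path plus fluctuation/segment/aperture/correlation
    tables for a pair of endpoint ring structures."""
    if not (cfg.pdb_t and cfg.pdb_r):
        raise ValueError("structure arm needs both endpoint structures")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    st_t = structure.read_pdb(cfg.pdb_t)
    st_r = structure.read_pdb(cfg.pdb_r)
    cmap = metrics.ChainMap.from_structure(st_t)
    xyz_t = st_t.ca_coords()
    xyz_r = st_r.ca_coords()
    if xyz_t.shape != xyz_r.shape:
        raise ValueError("endpoint structures differ in C-alpha count")

    enm_t = enm.build_enm(xyz_t, cutoff=cfg.cutoff, spring=cfg.spring)
    enm_r = enm.build_enm(xyz_r, cutoff=cfg.cutoff, spring=cfg.spring)
    mp = menm.build_mixed_potential(enm_t, enm_r, beta=cfg.beta)
    saddle = menm.find_saddle(mp)
    path = menm.transition_path(mp, n_frames=cfg.n_frames, saddle=saddle)

    results: dict = {"path": path, "saddle": saddle}
    pd.DataFrame({
        "frame": np.arange(len(path.frames)),
        "progress": path.progress,
        "energy": path.energies,
    }).to_csv(out_dir / "path_energy.tsv", sep="\t", index=False)

    frames_structs = []
    for f in path.frames:
        s = st_t.copy()
        s.atoms.coord = np.asarray(f, dtype=np.float32)
        frames_structs.append(s)
    structure.write_pdb(frames_structs, out_dir / "path.pdb")

    # CTS node selection: residue-id range per chain, else the trailing
    # run of residues nearest the axis is unknown for real input -- the
    # caller supplies cts_range.
    if cfg.cts_range is not None:
        lo, hi = cfg.cts_range
        atoms = st_t.atoms
        ca = np.flatnonzero(atoms.atom_name == "CA")
        cts = {}
        for c in cmap.chain_ids:
            sel = [pos for pos, idx in enumerate(ca)
                   if atoms.chain_id[idx] == c
                   and lo <= atoms.res_id[idx] <= hi]
            cts[c] = np.asarray(sel)

        profile = metrics.fluctuation_profile(path.frames, cmap)
        pd.DataFrame({
            "position": np.arange(1, cmap.residues_per_chain + 1),
            "d_ca": profile.d_ca,
            "d_alpha": profile.d_alpha,
        }).to_csv(out_dir / "fluctuations.tsv", sep="\t", index=False)
        results["fluctuations"] = profile

        non_cts = np.setdiff1d(np.arange(path.frames.shape[1]),
                               np.concatenate(list(cts.values())))
        motion = metrics.segment_motion(
            path.frames[0], path.frames[-1], cmap, cts,
            pre_superpose=non_cts)
        pd.DataFrame([
            {"chain": c, "rotation_deg": r, "translation_ang": t}
            for c, (r, t) in motion.per_chain.items()
        ] + [{"chain": "mean", "rotation_deg": motion.rotation_deg,
              "translation_ang": motion.translation_ang}]
        ).to_csv(out_dir / "segment_motion.tsv", sep="\t", index=False)
        results["segment_motion"] = motion

        base_sel = np.concatenate(list(cts.values()))
        aperture = metrics.aperture_radius(path.frames, cmap, base_sel)
        pd.DataFrame({"frame": np.arange(len(aperture)),
                      "aperture": aperture}
                     ).to_csv(out_dir / "aperture.tsv", sep="\t", index=False)
        results["aperture"] = aperture

        if len(path.frames) >= 3:
            corr = metrics.cts_chain_correlation(path.frames, cmap, cts)
            pd.DataFrame(corr.values, index=corr.labels, columns=corr.labels
                         ).to_csv(out_dir / "chain_correlation.tsv", sep="\t")
            results["chain_correlation"] = corr

    _write_manifest(cfg, [cfg.pdb_t, cfg.pdb_r], out_dir)
    return results
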