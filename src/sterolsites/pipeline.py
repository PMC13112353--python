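"""End-to-end pipeline runner and YAML configuration.

Two branches mirror how sterol sites are mapped in practice:

* docking branch — a docked pose ensemble is RMSD-clustered (2 Å),
  significance-filtered (≥ 2% of poses), fingerprinted, grouped into sites
  and scanned against CRAC/CARC/CRAC-like motifs;
* grid branch — probe trajectories become FragMaps, the system is tiled
  into boxes, rigid-body annealing MC samples hotspot poses, which are
  COM-clustered and then follow the same site/motif analysis.

All tunables carry the defaults used throughout the method (2 Å RMSD, 2%
significance, 3 Å/4 Å two-stage COM radii, −3.5 kcal/mol LGFE gate, 1 Å
voxels, 300 K, +3 kcal/mol cap, OC > 0.6, 50 000 + 40 000 MC steps from
300 to 0 K).  Every run writes tab-separated reports plus a manifest
echoing the effective configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import ResidueFingerprint, contact_fingerprint
from .core_model import (
    Pose,
    PoseEnsemble,
    ResidueKey,
    Structure,
    VdwRadiiTable,
    read_pose_ensemble,
    read_structure,
)
from .fragmaps import (
    FragMapSet,
    GridSpec,
    MCSchedule,
    ProbeTrajectory,
    build_occupancy,
    default_sterol_classifier,
    mc_hotspot_sample,
    occupancy_to_gfe,
    oc_convergence,
    partition_boxes,
)
from .motifs import BUILTIN_PATTERNS, merge_matches, motif_binding_fraction, motif_cluster_assignment, scan_motif
from .pose_clustering import (
    PoseCluster,
    SiteGroup,
    cluster_by_rmsd,
    com_cluster,
    filter_significant,
    group_by_fingerprint,
    subunit_occupancy,
)
from .core_model import extract_sequence

logger = logging.getLogger("sterolsites")

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    # inputs
    structure: str | None = None
    ensemble: str | None = None  # docked poses (multi-model PDB / PDBQT)
    epi_ensemble: str | None = None  # epicholesterol control ensemble
    probe_trajectory: str | None = None  # frame/class/x/y/z table
    ligand: str | None = None  # single-model ligand PDB for MC sampling
    output_dir: str = "sterolsites_run"
    # clustering / grouping
    rmsd_tolerance: float = 2.0
    min_fraction: float = 0.02
    stage1_radius: float = 3.0
    stage2_radius: float = 4.0
    lgfe_cutoff: float = -3.5
    similarity_threshold: float = 0.5
    symmetry_order: int = 4
    # fragmaps
    voxel: float = 1.0
    temperature: float = 300.0
    cap: float = 3.0
    oc_threshold: float = 0.6
    # MC schedule
    hot_steps: int = 50_000
    cool_steps: int = 40_000
    t_start: float = 300.0
    t_end: float = 0.0
    max_translation: float = 0.5
    max_rotation: float = 15.0
    repeats: int = 1000
    box_edge: float = 14.14
    # motifs
    motif_kinds: list[str] = field(default_factory=lambda: ["CRAC", "CARC", "CRAC_LIKE"])
    seed: int = 0

    def schedule(self) -> MCSchedule:
        return MCSchedule(
            hot_steps=self.hot_steps,
            cool_steps=self.cool_steps,
            t_start=self.t_start,
            t_end=self.t_end,
            max_translation=self.max_translation,
            max_rotation=self.max_rotation,
            repeats=self.repeats,
        )


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected before any computation."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


# --- report writers ---------------------------------------------------------


def _fp_str(fp: ResidueFingerprint) -> str:
    return ",".join(str(k) for k in sorted(fp.residues))


def parse_fingerprint(text: str) -> ResidueFingerprint:
    keys = set()
    for tok in text.split(","):
        tok = tok.strip()
        if not tok:
            continue
        chain, rest = tok.split(":")
        num = int("".join(c for c in rest if c.isdigit() or c == "-"))
        icode = rest[len(str(num)):] if rest != str(num) else ""
        keys.add(ResidueKey(chain, num, icode))
    return ResidueFingerprint(residues=frozenset(keys))


def _write_clusters(path: Path, clusters: list[PoseCluster], ensemble: PoseEnsemble) -> None:
    rows = []
    for i, c in enumerate(clusters):
        rep = ensemble.poses[c.representative]
        com = rep.com()
        rows.append(
            {
                "cluster": i,
                "size": c.size,
                "fraction": round(c.fraction, 6),
                "rep_label": rep.label,
                "rep_energy": rep.energy,
                "rep_lgfe": rep.lgfe,
                "com_x": round(float(com[0]), 3),
                "com_y": round(float(com[1]), 3),
                "com_z": round(float(com[2]), 3),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_fingerprints(path: Path, fps: list[ResidueFingerprint], structure: Structure) -> None:
    name_of = {r.key: r.name3 for r in structure.residues()}
    rows = []
    for fp in fps:
        for key in sorted(fp.residues):
            rows.append(
                {
                    "pose": fp.source_pose,
                    "chain": key.chain_id,
                    "residue_number": key.number,
                    "residue_name": name_of.get(key, "UNK"),
                }
            )
    pd.DataFrame(rows, columns=["pose", "chain", "residue_number", "residue_name"]).to_csv(
        path, sep="\t", index=False
    )


def _write_groups(path: Path, groups: list[SiteGroup]) -> None:
    rows = [
        {
            "group": g.label,
            "occupancy": g.occupancy,
            "n_poses": g.total_size,
            "clusters": ",".join(map(str, g.cluster_ids)),
            "stereospecific": g.stereospecific,
            "residues": _fp_str(g.union_fingerprint),
        }
        for g in groups
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- pipeline ---------------------------------------------------------------


def _motif_analysis(structure: Structure, groups: list[SiteGroup], cfg: PipelineConfig, outdir: Path) -> None:
    regions = []
    rows = []
    for chain in structure.chains:
        seq = extract_sequence(structure, chain)
        for kind in cfg.motif_kinds:
            matches = scan_motif(seq, BUILTIN_PATTERNS[kind])
            for region in merge_matches(matches):
                regions.append(region)
                rows.append(
                    {
                        "kind": kind,
                        "chain": chain,
                        "anchors": region.label(),
                        "span_min": region.span[0],
                        "span_max": region.span[1],
                        "n_alternatives": len(region.alternatives),
                    }
                )
    pd.DataFrame(rows, columns=["kind", "chain", "anchors", "span_min", "span_max", "n_alternatives"]).to_csv(
        outdir / "motifs.tsv", sep="\t", index=False
    )

    assign_rows = []
    for g in groups:
        for region in regions:
            strict = motif_cluster_assignment(g.union_fingerprint, region, "strict")
            relaxed = motif_cluster_assignment(g.union_fingerprint, region, "relaxed")
            if strict or relaxed:
                assign_rows.append(
                    {
                        "group": g.label,
                        "kind": region.kind,
                        "chain": region.chain,
                        "anchors": region.label(),
                        "strict": strict,
                        "relaxed": relaxed,
                    }
                )
    pd.DataFrame(
        assign_rows, columns=["group", "kind", "chain", "anchors", "strict", "relaxed"]
    ).to_csv(outdir / "motif_assignment.tsv", sep="\t", index=False)

    if groups:
        summary = []
        for kind in cfg.motif_kinds:
            kind_regions = [r for r in regions if r.kind == kind]
            for mode in ("strict", "relaxed"):
                pct = motif_binding_fraction(groups, kind_regions, mode) if kind_regions else 0.0
                summary.append({"kind": kind, "mode": mode, "percent_of_groups": round(pct, 2)})
        pd.DataFrame(summary).to_csv(outdir / "motif_summary.tsv", sep="\t", index=False)


def _analyse_ensemble(
    structure: Structure,
    ensemble: PoseEnsemble,
    clusters: list[PoseCluster],
    cfg: PipelineConfig,
    outdir: Path,
    prefix: str = "",
) -> list[SiteGroup]:
    table = VdwRadiiTable()
    _write_clusters(outdir / f"{prefix}clusters.tsv", clusters, ensemble)
    fps = [
        contact_fingerprint(structure, ensemble.poses[c.representative], table) for c in clusters
    ]
    _write_fingerprints(outdir / f"{prefix}fingerprints.tsv", fps, structure)
    groups = group_by_fingerprint(clusters, fps, threshold=cfg.similarity_threshold)
    for g in groups:
        try:
            g.occupancy = subunit_occupancy(g, structure, cfg.similarity_threshold)
        except ValueError:
            g.occupancy = None
    _write_groups(outdir / f"{prefix}groups.tsv", groups)
    return groups


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured branch and write all reports to the run dir."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.structure is None:
        raise ValueError("stage input: a structure PDB is required")
    structure = read_structure(config.structure, symmetry_order=config.symmetry_order)

    groups: list[SiteGroup] = []
    if config.ensemble is not None:
        try:
            ensemble = read_pose_ensemble(config.ensemble)
            clusters = filter_significant(
                cluster_by_rmsd(ensemble, tolerance=config.rmsd_tolerance),
                len(ensemble),
                min_fraction=config.min_fraction,
            )
            groups = _analyse_ensemble(structure, ensemble, clusters, config, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage docking-ensemble ({config.ensemble}): {exc}") from exc
    elif config.probe_trajectory is not None and config.ligand is not None:
        try:
            traj = ProbeTrajectory.read(config.probe_trajectory)
            grid = GridSpec.from_bounds(traj.box[0], traj.box[1], spacing=config.voxel)
            maps = {}
            oc_rows = []
            for cls in sorted(traj.classes()):
                occ = build_occupancy(traj, cls, grid)
                maps[cls] = occupancy_to_gfe(occ, temperature=config.temperature, cap=config.cap)
                oc, ok = oc_convergence(traj, cls, grid, threshold=config.oc_threshold)
                oc_rows.append({"atom_class": cls, "oc_first_vs_second_half": round(oc, 4), "converged": ok})
            pd.DataFrame(oc_rows).to_csv(outdir / "oc_convergence.tsv", sep="\t", index=False)

            ligand = read_pose_ensemble(config.ligand).poses[0]
            classifier = {}
            fallback = sorted(maps)[0]
            for key, target in default_sterol_classifier().items():
                classifier[key] = target if target in maps else fallback
            fset = FragMapSet(maps=maps, classifier=classifier)

            all_poses = []
            for bi, box in enumerate(partition_boxes(traj.box, edge=config.box_edge)):
                blo = np.maximum(box[0], grid.origin)
                bhi = np.minimum(box[1], grid.upper)
                sampled = mc_hotspot_sample(
                    fset, ligand, (blo, bhi), schedule=config.schedule(), seed=config.seed + bi
                )
                all_poses.extend(sampled.poses)
            hotspot_ensemble = PoseEnsemble(ligand_name="LIG", poses=all_poses)
            clusters = com_cluster(
                hotspot_ensemble,
                stage1_radius=config.stage1_radius,
                lgfe_cutoff=config.lgfe_cutoff,
                stage2_radius=config.stage2_radius,
            )
            groups = _analyse_ensemble(structure, hotspot_ensemble, clusters, config, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage fragmap-hotspots ({config.probe_trajectory}): {exc}") from exc
    else:
        raise ValueError(
            "stage input: supply either 'ensemble' (docking branch) or "
            "'probe_trajectory' + 'ligand' (grid branch)"
        )

    try:
        _motif_analysis(structure, groups, config, outdir)
    except Exception as exc:
        raise RuntimeError(f"stage motifs: {exc}") from exc

    if config.epi_ensemble is not None and config.ensemble is not None:
        from .state_compare import stereospecificity_flags

        try:
            epi = read_pose_ensemble(config.epi_ensemble)
            epi_clusters = filter_significant(
                cluster_by_rmsd(epi, tolerance=config.rmsd_tolerance),
                len(epi),
                min_fraction=config.min_fraction,
            )
            epi_groups = _analyse_ensemble(structure, epi, epi_clusters, config, outdir, prefix="epi_")
            flags = stereospecificity_flags(groups, epi_groups, threshold=config.similarity_threshold)
            for g, f in zip(groups, flags):
                g.stereospecific = f
            _write_groups(outdir / "groups.tsv", groups)
        except Exception as exc:
            raise RuntimeError(f"stage stereospecificity ({config.epi_ensemble}): {exc}") from exc

    manifest = {
        "package": "sterolsites",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline finished: %d site groups → %s", len(groups), outdir)
    return outdir
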