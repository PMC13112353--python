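"""Synthetic fixtures with known ground truth.

Every stage of the site-mapping pipeline can be exercised without
downloading structures: this module builds

* ideal-geometry C4-symmetric helical tetramers with motif sequences
  planted on a poly-alanine background (α-helix: 1.5 Å rise and 100°
  twist per residue — canonical values, chosen for geometric realism);
* pose ensembles as Gaussian positional scatter of a rigid sterol-like
  dummy ligand around planted sites, with assigned energies/LGFEs;
* probe "trajectories" drawn from 3D Gaussian mixtures over a uniform
  background, so GFE minima and depths are analytically known.

All randomness flows through one seeded NumPy generator per call; outputs
are bit-reproducible from the seed.  The dummy sterol is a planar fused-ring
approximation with one hydroxyl oxygen — sufficient for the contact,
classifier and clustering logic; no chemical accuracy is claimed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .core_model import Atom, Pose, PoseEnsemble, Residue, Structure
from .fragmaps import ProbeTrajectory
from .motifs import BUILTIN_PATTERNS

__all__ = [
    "GroundTruth",
    "PlantedMotif",
    "SiteSpec",
    "make_tetramer",
    "make_two_helix_bundle",
    "make_pose_ensemble",
    "make_probe_trajectory",
    "sterol_ligand",
    "symmetric_points",
]

_RISE = 1.5  # Å per residue along the helix axis
_TWIST = 100.0  # degrees per residue
_CA_RADIUS = 2.3  # Å, CA distance from the helix axis

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


@dataclass
class GroundTruth:
    """What was planted: site centres and fingerprints, motif anchors,
    density components — everything reproducible from ``seed``."""

    seed: int
    planted_sites: list[dict] = field(default_factory=list)
    planted_motifs: list[tuple[str, tuple[int, int, int]]] = field(default_factory=list)
    density_components: list[dict] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "planted_sites": [
                {**s, "center": list(map(float, s["center"]))} for s in self.planted_sites
            ],
            "planted_motifs": [[k, list(a)] for k, a in self.planted_motifs],
            "density_components": [
                {**c, "mean": list(map(float, c["mean"]))} for c in self.density_components
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass(frozen=True)
class PlantedMotif:
    """A motif to embed: kind, author number of the start anchor, and the two
    intervening-residue gap lengths (each 1–5)."""

    kind: str
    start_number: int
    gap1: int = 2
    gap2: int = 1
    letters: tuple[str, str, str] | None = None

    def resolved_letters(self) -> tuple[str, str, str]:
        if self.letters is not None:
            return self.letters
        pat = BUILTIN_PATTERNS[self.kind]
        return (min(pat.start_set), min(pat.center_set), min(pat.end_set))

    def anchor_numbers(self) -> tuple[int, int, int]:
        return (
            self.start_number,
            self.start_number + self.gap1 + 1,
            self.start_number + self.gap1 + self.gap2 + 2,
        )


def _helix_atoms(
    n_res: int,
    axis_xy: np.ndarray,
    z0: float = 0.0,
    phase: float = 0.0,
) -> list[dict]:
    """Backbone + CB coordinates for an ideal helix with axis ∥ z at axis_xy."""
    ca = np.empty((n_res, 3))
    for i in range(n_res):
        theta = math.radians(phase + _TWIST * i)
        ca[i] = (
            axis_xy[0] + _CA_RADIUS * math.cos(theta),
            axis_xy[1] + _CA_RADIUS * math.sin(theta),
            z0 + _RISE * i,
        )
    out = []
    for i in range(n_res):
        prev_dir = ca[i] - ca[i - 1] if i > 0 else ca[min(i + 1, n_res - 1)] - ca[i]
        next_dir = ca[i + 1] - ca[i] if i < n_res - 1 else ca[i] - ca[i - 1]
        prev_dir = prev_dir / np.linalg.norm(prev_dir)
        next_dir = next_dir / np.linalg.norm(next_dir)
        outward = ca[i] - np.array([axis_xy[0], axis_xy[1], ca[i][2]])
        outward = outward / np.linalg.norm(outward)
        out.append(
            {
                "N": ca[i] - 1.45 * prev_dir,
                "CA": ca[i],
                "C": ca[i] + 1.52 * next_dir,
                "O": ca[i] + 1.52 * next_dir + 1.23 * outward,
                "CB": ca[i] + 1.53 * outward,
            }
        )
    return out


def _build_residues(
    chain_id: str,
    codes: Sequence[str],
    atom_sets: list[dict],
    first_number: int,
    serial0: int,
) -> tuple[list[Residue], int]:
    residues = []
    serial = serial0
    for i, (code, atoms) in enumerate(zip(codes, atom_sets)):
        name3 = _THREE.get(code, "UNK")
        alist = []
        for aname in ("N", "CA", "C", "O", "CB"):
            elem = aname[0]
            alist.append(Atom(serial=serial, name=aname, element=elem, position=atoms[aname]))
            serial += 1
        residues.append(
            Residue(
                chain_id=chain_id,
                number=first_number + i,
                insertion_code="",
                name3=name3,
                code1=code,
                atoms=alist,
            )
        )
    return residues, serial


def _rotate_residues(residues: list[Residue], angle_deg: float, chain_id: str, serial0: int) -> tuple[list[Residue], int]:
    rot = Rotation.from_euler("z", angle_deg, degrees=True)
    out = []
    serial = serial0
    for r in residues:
        atoms = []
        for a in r.atoms:
            atoms.append(Atom(serial=serial, name=a.name, element=a.element, position=rot.apply(a.position)))
            serial += 1
        out.append(Residue(chain_id, r.number, r.insertion_code, r.name3, r.code1, atoms))
    return out, serial


def make_tetramer(
    res_per_helix: int = 40,
    motif_spec: Sequence[PlantedMotif] = (),
    seed: int = 0,
    first_number: int = 430,
    bundle_radius: float = 12.0,
) -> tuple[Structure, GroundTruth]:
    """Four-chain helical bundle with exact C4 symmetry about z.

    Chain A is an ideal α-helix (axis ∥ z at ``bundle_radius`` from the
    symmetry axis); chains B–D are chain A rotated by 90°/180°/270°.  Motifs
    are planted at their author numbers on every chain over a poly-alanine
    background.
    """
    if res_per_helix < 12:
        raise ValueError("need at least 12 residues per helix")
    codes = ["A"] * res_per_helix
    truth = GroundTruth(seed=seed)
    for pm in motif_spec:
        if pm.kind not in BUILTIN_PATTERNS:
            raise ValueError(f"unknown motif kind {pm.kind!r}")
        if not (1 <= pm.gap1 <= 5 and 1 <= pm.gap2 <= 5):
            raise ValueError(f"motif gaps must be 1–5, got {pm.gap1}, {pm.gap2}")
        letters = pm.resolved_letters()
        pat = BUILTIN_PATTERNS[pm.kind]
        for letter, allowed in zip(letters, (pat.start_set, pat.center_set, pat.end_set)):
            if letter not in allowed:
                raise ValueError(f"{pm.kind}: letter {letter!r} not allowed for its anchor")
        anchors = pm.anchor_numbers()
        if anchors[2] - first_number >= res_per_helix or anchors[0] < first_number:
            raise ValueError(f"motif at {anchors} does not fit in the chain")
        for num, letter in zip(anchors, letters):
            codes[num - first_number] = letter
        truth.planted_motifs.append((pm.kind, anchors))

    atom_sets = _helix_atoms(res_per_helix, axis_xy=np.array([bundle_radius, 0.0]))
    chain_a, serial = _build_residues("A", codes, atom_sets, first_number, serial0=1)
    chains = {"A": chain_a}
    for cid, angle in (("B", 90.0), ("C", 180.0), ("D", 270.0)):
        rotated, serial = _rotate_residues(chain_a, angle, cid, serial)
        chains[cid] = rotated
    return Structure(chains=chains, symmetry_order=4), truth


def make_two_helix_bundle(
    n_res: int = 16,
    separation: float = 9.0,
    triad: tuple[tuple[int, str], ...] = ((2, "W"), (4, "I"), (6, "K")),
    partner: tuple[int, str] = (4, "F"),
    seed: int = 0,
    first_number: int = 1,
) -> tuple[Structure, list[tuple[str, int, int]], GroundTruth]:
    """Two parallel helices in one chain for CCM detection tests: the triad
    residues are planted (by list position) on helix 1, the partner on the
    facing helix 2, ``separation`` Å away."""
    codes1 = ["A"] * n_res
    for pos, letter in triad:
        codes1[pos] = letter
    codes2 = ["A"] * n_res
    codes2[partner[0]] = partner[1]

    sets1 = _helix_atoms(n_res, axis_xy=np.array([0.0, 0.0]))
    # facing phase: CB of helix 2 points back toward helix 1
    sets2 = _helix_atoms(n_res, axis_xy=np.array([separation, 0.0]), phase=180.0)
    res1, serial = _build_residues("A", codes1, sets1, first_number, serial0=1)
    res2, _ = _build_residues("A", codes2, sets2, first_number + n_res + 10, serial0=serial)
    structure = Structure(chains={"A": res1 + res2}, symmetry_order=1)
    helices = [
        ("A", first_number, first_number + n_res - 1),
        ("A", first_number + n_res + 10, first_number + 2 * n_res + 9),
    ]
    truth = GroundTruth(seed=seed)
    return structure, helices, truth


# --- dummy sterol ligand ----------------------------------------------------


def sterol_ligand(n_carbons: int = 17) -> Pose:
    """Rigid sterol-like dummy: planar fused-ring carbon scaffold plus one
    hydroxyl oxygen (named O3, as on a sterol A-ring).  10–30 heavy atoms."""
    if not (9 <= n_carbons <= 29):
        raise ValueError("dummy sterol supports 10–30 heavy atoms")
    atoms = []
    serial = 1
    # hexagonal-ish lattice rows approximating four fused rings
    k = 0
    for row in range(3):
        for col in range(10):
            if k >= n_carbons:
                break
            x = 1.4 * col + (0.7 if row % 2 else 0.0)
            y = 1.2 * row
            atoms.append(Atom(serial, f"C{k + 1}", "C", np.array([x, y, 0.0])))
            serial += 1
            k += 1
    # 3-hydroxyl at the A-ring end
    atoms.append(Atom(serial, "O3", "O", np.array([-1.2, 0.6, 0.0])))
    return Pose(atoms=atoms, label="sterol")


def symmetric_points(center: Sequence[float], order: int = 4) -> list[np.ndarray]:
    """Copies of a point under C_n rotation about the z axis."""
    c = np.asarray(center, float)
    return [
        Rotation.from_euler("z", 360.0 * i / order, degrees=True).apply(c) for i in range(order)
    ]


@dataclass(frozen=True)
class SiteSpec:
    """One planted binding site for pose-ensemble generation."""

    center: tuple[float, float, float]
    n_poses: int = 30
    sigma: float = 0.5
    energy_mean: float = -10.0
    energy_sd: float = 0.5
    lgfe_mean: float = -6.0
    lgfe_sd: float = 0.5


def make_pose_ensemble(
    structure: Structure | None,
    sites: Sequence[SiteSpec],
    seed: int = 0,
    ligand: Pose | None = None,
    orient: bool = True,
) -> tuple[PoseEnsemble, GroundTruth]:
    """Gaussian positional scatter of a rigid dummy sterol around each site.

    Pose COMs are drawn N(center, sigma²·I); orientations are uniform random
    rotations (or fixed when ``orient`` is False, which keeps every pose's
    atom-atom RMSD equal to its COM displacement); energies and LGFEs are
    drawn from the per-site normals.  Bit-reproducible from ``seed``.
    """
    if not sites or all(s.n_poses == 0 for s in sites):
        raise ValueError("no poses requested: every site has n_poses = 0")
    rng = np.random.default_rng(seed)
    template = ligand if ligand is not None else sterol_ligand()
    base = template.coords() - template.coords().mean(axis=0)
    truth = GroundTruth(seed=seed)
    poses = []
    if structure is not None:
        coords = structure.atom_table()[0]
        lo, hi = coords.min(axis=0) - 15.0, coords.max(axis=0) + 15.0
    for si, site in enumerate(sites):
        center = np.asarray(site.center, float)
        if structure is not None and (np.any(center < lo) or np.any(center > hi)):
            import logging

            logging.getLogger("sterolsites").warning(
                "site %d centre %s far outside the structure bounding region", si, center
            )
        for pi in range(site.n_poses):
            com = center + rng.normal(scale=site.sigma, size=3)
            rot = Rotation.random(rng=rng) if orient else Rotation.identity()
            coords_p = rot.apply(base) + com
            atoms = [
                Atom(a.serial, a.name, a.element, coords_p[j])
                for j, a in enumerate(template.atoms)
            ]
            poses.append(
                Pose(
                    atoms=atoms,
                    energy=float(rng.normal(site.energy_mean, site.energy_sd)),
                    lgfe=float(rng.normal(site.lgfe_mean, site.lgfe_sd)),
                    label=f"s{si}_p{pi}",
                )
            )
        truth.planted_sites.append(
            {"center": center, "n_poses": site.n_poses, "sigma": site.sigma, "site_index": si}
        )
    return PoseEnsemble(ligand_name="CLR", poses=poses), truth


def make_probe_trajectory(
    components: Sequence[tuple[Sequence[float], float, float, str]],
    n_frames: int = 1000,
    box: tuple[Sequence[float], Sequence[float]] = ((0, 0, 0), (20, 20, 20)),
    background_weight: float = 0.0,
    seed: int = 0,
) -> tuple[ProbeTrajectory, GroundTruth]:
    """Probe point trajectory from a Gaussian mixture over a uniform background.

    ``components`` are (mean, sigma, weight, atom_class) with ``weight`` the
    number of points drawn per frame; ``background_weight`` adds that many
    uniform points per frame *per atom class present*.  Points are clipped
    to the box.  Bit-reproducible from ``seed``.
    """
    if not components and background_weight <= 0:
        raise ValueError("need at least one density component or a background")
    if any(w < 0 for _, _, w, _ in components) or background_weight < 0:
        raise ValueError("weights must be ≥ 0")
    if components and all(w == 0 for _, _, w, _ in components) and background_weight == 0:
        raise ValueError("zero total weight")
    rng = np.random.default_rng(seed)
    lo = np.asarray(box[0], float)
    hi = np.asarray(box[1], float)
    classes = sorted({c for *_, c in components}) or ["water_oxygen"]
    truth = GroundTruth(seed=seed)
    for mean, sigma, weight, cls in components:
        truth.density_components.append(
            {"mean": np.asarray(mean, float), "sigma": sigma, "weight": weight, "atom_class": cls}
        )
    frames = []
    for _ in range(n_frames):
        frame: list[tuple[str, np.ndarray]] = []
        for mean, sigma, weight, cls in components:
            pts = rng.normal(loc=np.asarray(mean, float), scale=sigma, size=(int(round(weight)), 3))
            for p in np.clip(pts, lo, hi):
                frame.append((cls, p))
        n_bg = int(round(background_weight))
        for cls in classes:
            for p in lo + rng.random((n_bg, 3)) * (hi - lo):
                frame.append((cls, p))
        frames.append(frame)
    return ProbeTrajectory(frames=frames, box=(tuple(lo), tuple(hi))), truth
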