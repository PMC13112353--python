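"""Lite fragment free-energy maps (FragMaps), LGFE scoring and MC hotspots.

Probe-molecule occupancy on a cubic voxel grid (1 Å default spacing) is
Boltzmann-inverted into per-voxel grid free energies (GFE):

    GFE_v = −k_B·T · ln(ρ_v / ρ_bulk)

with ρ_bulk the mean voxel density, empty voxels capped at +3 kcal/mol, and
the voxel average subtracted so every map has exactly zero mean.  A ligand
pose is scored by its LGFE — the sum, over classified heavy atoms, of the
matching map's value at the atom's voxel.  Overlap coefficients
OC = Σ_v min(p_v, q_v) between normalised occupancy maps serve as a
convergence diagnostic (good when > 0.6 between trajectory halves).

Hotspot search tiles the system into 14.14 Å boxes and runs, per box,
repeated rigid-body simulated-annealing Monte Carlo on the LGFE field:
a hot phase at 300 K followed by a linear ramp to 0 K, where only
LGFE-decreasing moves are accepted.  Final poses feed the two-stage COM
clustering in :mod:`.pose_clustering`.

Maps are written and read in the OpenDX regular-grid format.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .core_model import Atom, Pose, PoseEnsemble

logger = logging.getLogger("sterolsites")

#: Boltzmann constant in kcal·mol⁻¹·K⁻¹
KB = 0.0019872

__all__ = [
    "KB",
    "GridSpec",
    "OccupancyMap",
    "GfeMap",
    "FragMapSet",
    "ProbeTrajectory",
    "MCSchedule",
    "DEFAULT_MAP_CLASSES",
    "default_fragmap_classes",
    "default_sterol_classifier",
    "build_occupancy",
    "occupancy_to_gfe",
    "overlap_coefficient",
    "score_lgfe",
    "partition_boxes",
    "mc_hotspot_sample",
    "oc_convergence",
    "write_dx",
    "read_dx",
]


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned cubic-voxel grid: origin (Å), spacing (Å), dims (voxels)."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must be ≥ 1")

    @classmethod
    def from_bounds(cls, lo: Sequence[float], hi: Sequence[float], spacing: float = 1.0) -> "GridSpec":
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        dims = tuple(int(math.ceil((h - l) / spacing - 1e-9)) for l, h in zip(lo, hi))
        return cls(origin=tuple(lo), spacing=spacing, dims=tuple(max(1, d) for d in dims))

    @property
    def upper(self) -> np.ndarray:
        return np.asarray(self.origin) + self.spacing * np.asarray(self.dims)

    def voxel_of(self, points: np.ndarray) -> np.ndarray:
        """Half-open binning [lo, hi): boundary points go to the higher voxel."""
        return np.floor((np.atleast_2d(points) - np.asarray(self.origin)) / self.spacing).astype(int)

    def inside(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(idx)
        return np.all((idx >= 0) & (idx < np.asarray(self.dims)), axis=1)

    def centers(self) -> np.ndarray:
        """Voxel-centre coordinates, shape dims + (3,)."""
        axes = [
            self.origin[k] + self.spacing * (np.arange(self.dims[k]) + 0.5) for k in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


@dataclass
class OccupancyMap:
    grid: GridSpec
    counts: np.ndarray
    n_frames: int
    atom_class: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != self.grid.dims:
            raise ValueError("counts shape must match grid dims")
        if np.any(self.counts < 0):
            raise ValueError("occupancy counts must be non-negative")


@dataclass
class GfeMap:
    grid: GridSpec
    values: np.ndarray
    temperature: float = 300.0
    cap: float = 3.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != self.grid.dims:
            raise ValueError("values shape must match grid dims")
        if abs(float(self.values.mean())) > 1e-9:
            raise ValueError("GFE map must have zero voxel mean")


@dataclass
class ProbeTrajectory:
    """Frames of (atom-class, position) point sets inside a bounding box."""

    frames: list[list[tuple[str, np.ndarray]]]
    box: tuple[tuple[float, float, float], tuple[float, float, float]]

    def classes(self) -> set[str]:
        return {cls for frame in self.frames for cls, _ in frame}

    def to_table(self) -> "np.ndarray":
        rows = []
        for fi, frame in enumerate(self.frames):
            for cls, pos in frame:
                rows.append((fi, cls, pos[0], pos[1], pos[2]))
        return rows

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# frame class x y z\n")
            for fi, frame in enumerate(self.frames):
                for cls, pos in frame:
                    fh.write(f"{fi}\t{cls}\t{pos[0]:.4f}\t{pos[1]:.4f}\t{pos[2]:.4f}\n")

    @classmethod
    def read(cls, path: str | Path, box=None) -> "ProbeTrajectory":
        frames: dict[int, list[tuple[str, np.ndarray]]] = {}
        pts = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            fi, c, x, y, z = line.split()
            p = np.array([float(x), float(y), float(z)])
            frames.setdefault(int(fi), []).append((c, p))
            pts.append(p)
        pts = np.asarray(pts)
        if box is None:
            box = (tuple(pts.min(axis=0)), tuple(pts.max(axis=0)))
        ordered = [frames[k] for k in sorted(frames)]
        return cls(frames=ordered, box=box)


@dataclass(frozen=True)
class MCSchedule:
    """Simulated-annealing schedule: a hot phase at ``t_start`` followed by a
    linear temperature ramp to ``t_end`` (0 K ⇒ strictly downhill moves)."""

    hot_steps: int = 50_000
    cool_steps: int = 40_000
    t_start: float = 300.0
    t_end: float = 0.0
    max_translation: float = 0.5
    max_rotation: float = 15.0
    repeats: int = 1000

    def __post_init__(self) -> None:
        if self.hot_steps < 0 or self.cool_steps < 0:
            raise ValueError("step counts must be ≥ 0")
        if not (self.t_start >= self.t_end >= 0):
            raise ValueError("need t_start ≥ t_end ≥ 0")


# --- atom-class registry ----------------------------------------------------

#: Map classes derived from the 8 standard probes (benzene, propane, methanol,
#: formamide, dimethyl ether, methylammonium, imidazole, acetate) plus water:
#: one class per distinguishable probe heavy-atom type and three generic
#: merged classes, 14 in total.
DEFAULT_MAP_CLASSES = (
    "benzene_carbon",
    "propane_carbon",
    "methanol_oxygen",
    "formamide_nitrogen",
    "formamide_oxygen",
    "dimethylether_oxygen",
    "methylammonium_nitrogen",
    "imidazole_donor_nitrogen",
    "imidazole_acceptor_nitrogen",
    "acetate_oxygen",
    "water_oxygen",
    "generic_apolar",
    "generic_donor",
    "generic_acceptor",
)


def default_fragmap_classes() -> tuple[str, ...]:
    return DEFAULT_MAP_CLASSES


def default_sterol_classifier() -> dict[str, str]:
    """Ligand-atom → map-class rules for a sterol: the hydroxyl oxygen maps to
    the donor/acceptor hydroxyl class, ring and aliphatic carbons to the
    apolar class, with per-element generic fallbacks."""
    return {
        "O.hydroxyl": "methanol_oxygen",
        "C": "generic_apolar",
        "N": "generic_donor",
        "O": "generic_acceptor",
        "S": "generic_apolar",
        "P": "generic_apolar",
    }


@dataclass
class FragMapSet:
    maps: dict[str, GfeMap]
    classifier: dict[str, str] = field(default_factory=default_sterol_classifier)

    def __post_init__(self) -> None:
        grids = {m.grid for m in self.maps.values()}
        if len(grids) > 1:
            raise ValueError("all maps in a set must share one GridSpec")
        missing = set(self.classifier.values()) - set(self.maps)
        if missing:
            raise ValueError(f"classifier targets without maps: {sorted(missing)}")

    @property
    def grid(self) -> GridSpec:
        return next(iter(self.maps.values())).grid

    def classify(self, atom: Atom) -> str:
        """Class for a ligand heavy atom from element + name context."""
        name = atom.name.upper()
        if atom.element == "O" and ("H" in name[1:] or name in {"O3", "OH", "O1"}):
            key = "O.hydroxyl"
            if key in self.classifier:
                return self.classifier[key]
        if atom.element in self.classifier:
            return self.classifier[atom.element]
        raise KeyError(f"atom {atom.serial} {atom.name} ({atom.element}): no map class")


# --- occupancy and GFE ------------------------------------------------------


def build_occupancy(traj: ProbeTrajectory, atom_class: str, grid: GridSpec) -> OccupancyMap:
    """Per-voxel count of ``atom_class`` points over all frames (half-open bins)."""
    counts = np.zeros(grid.dims, dtype=np.int64)
    n_pts = 0
    for frame in traj.frames:
        for cls, pos in frame:
            if cls != atom_class:
                continue
            n_pts += 1
            idx = grid.voxel_of(pos)[0]
            if grid.inside(idx)[0]:
                counts[tuple(idx)] += 1
    if n_pts == 0:
        logger.warning("atom class %r absent from trajectory: zero occupancy map", atom_class)
    return OccupancyMap(grid=grid, counts=counts, n_frames=len(traj.frames), atom_class=atom_class)


def occupancy_to_gfe(
    occ: OccupancyMap,
    temperature: float = 300.0,
    cap: float = 3.0,
    bulk_density: float | None = None,
) -> GfeMap:
    """Boltzmann-invert an occupancy map into a zero-mean GFE map.

    raw_v = −k_B·T·ln(ρ_v/ρ_bulk), ρ_bulk defaulting to the mean voxel
    density; empty voxels get raw = +cap; the voxel average of raw is then
    subtracted so the map mean is exactly zero.
    """
    if occ.n_frames <= 0:
        raise ValueError("occupancy map has no frames")
    counts = occ.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"map {occ.atom_class!r} has no density: cannot Boltzmann-invert")
    bulk = bulk_density if bulk_density is not None else total / counts.size
    raw = np.full(counts.shape, float(cap))
    nz = counts > 0
    raw[nz] = -KB * temperature * np.log(counts[nz] / bulk)
    raw -= raw.mean()
    raw -= raw.mean()  # second pass squeezes the fp remainder below 1e-9
    return GfeMap(grid=occ.grid, values=raw, temperature=temperature, cap=cap)


def overlap_coefficient(map_a: OccupancyMap, map_b: OccupancyMap) -> float:
    """OC = Σ_v min(p_v, q_v) of the two voxel probability distributions."""
    if map_a.grid != map_b.grid:
        raise ValueError("overlap coefficient requires identical grids")
    ta, tb = map_a.counts.sum(), map_b.counts.sum()
    if ta == 0 or tb == 0:
        raise ValueError("overlap coefficient undefined for an all-zero map")
    p = map_a.counts / ta
    q = map_b.counts / tb
    return float(np.minimum(p, q).sum())


def oc_convergence(
    traj: ProbeTrajectory, atom_class: str, grid: GridSpec, threshold: float = 0.6
) -> tuple[float, bool]:
    """Convergence diagnostic: OC between occupancy maps of the first and
    second half of the trajectory; converged when OC > threshold."""
    n = len(traj.frames)
    half = n // 2
    first = ProbeTrajectory(frames=traj.frames[:half], box=traj.box)
    second = ProbeTrajectory(frames=traj.frames[half:], box=traj.box)
    oc = overlap_coefficient(
        build_occupancy(first, atom_class, grid), build_occupancy(second, atom_class, grid)
    )
    return oc, oc > threshold


# --- LGFE scoring -----------------------------------------------------------


def score_lgfe(pose: Pose, maps: FragMapSet, interpolate: bool = False) -> float:
    """Ligand grid free energy: sum of per-heavy-atom map values.

    Nearest-voxel lookup by default (exactly additive over atoms); atoms
    falling outside the grid contribute zero and are reported in a warning.
    """
    grid = maps.grid
    total = 0.0
    outside = 0
    for atom in pose.atoms:
        gfe_map = maps.maps[maps.classify(atom)]
        if interpolate:
            total += _trilinear(gfe_map, atom.position)
            continue
        idx = grid.voxel_of(atom.position)[0]
        if grid.inside(idx)[0]:
            total += float(gfe_map.values[tuple(idx)])
        else:
            outside += 1
    if outside:
        logger.warning("%d/%d ligand atoms outside the grid contributed 0", outside, len(pose.atoms))
    return total


def _trilinear(gfe_map: GfeMap, point: np.ndarray) -> float:
    g = gfe_map.grid
    u = (np.asarray(point) - np.asarray(g.origin)) / g.spacing - 0.5
    i0 = np.floor(u).astype(int)
    f = u - i0
    val = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                idx = i0 + (dx, dy, dz)
                if np.all(idx >= 0) and np.all(idx < g.dims):
                    w = (
                        (f[0] if dx else 1 - f[0])
                        * (f[1] if dy else 1 - f[1])
                        * (f[2] if dz else 1 - f[2])
                    )
                    val += w * float(gfe_map.values[tuple(idx)])
    return val


def _lgfe_vectorised(coords: np.ndarray, map_index: np.ndarray, stack: np.ndarray, grid: GridSpec) -> float:
    """LGFE for one pose given precomputed per-atom map indices (MC hot path)."""
    idx = np.floor((coords - np.asarray(grid.origin)) / grid.spacing).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(grid.dims)), axis=1)
    if not np.any(ok):
        return 0.0
    sel = idx[ok]
    return float(stack[map_index[ok], sel[:, 0], sel[:, 1], sel[:, 2]].sum())


# --- box partition and MC sampling -----------------------------------------


def partition_boxes(
    bounds: tuple[Sequence[float], Sequence[float]], edge: float = 14.14
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Tile a bounding box with cubes of the given edge; the last tile on each
    axis may extend past the bounds so the union always covers them."""
    lo = np.asarray(bounds[0], float)
    hi = np.asarray(bounds[1], float)
    if np.any(hi <= lo):
        raise ValueError("degenerate bounds")
    n = np.maximum(1, np.ceil((hi - lo) / edge - 1e-9).astype(int))
    boxes = []
    for i in range(n[0]):
        for j in range(n[1]):
            for k in range(n[2]):
                blo = lo + edge * np.array([i, j, k])
                boxes.append((blo, blo + edge))
    return boxes


def mc_hotspot_sample(
    maps: FragMapSet,
    ligand: Pose,
    box: tuple[Sequence[float], Sequence[float]],
    schedule: MCSchedule = MCSchedule(),
    seed: int = 0,
) -> PoseEnsemble:
    """Repeated rigid-body simulated-annealing MC of one ligand in one box.

    Each repeat starts from a uniformly random placement (COM in box,
    uniform random orientation) and runs Metropolis MC on the LGFE with
    uniform translation/rotation moves: ``hot_steps`` at ``t_start``, then
    ``cool_steps`` with the temperature ramped linearly to ``t_end``.  At
    zero temperature only strictly LGFE-decreasing moves are accepted, so
    the final LGFE never exceeds the value at the start of the ramp.
    Sampling is *within* the box: translations that would carry the COM out
    of it are rejected, which keeps walkers from diffusing away across the
    flat far-field of the maps.  Fully reproducible from ``seed``.
    """
    grid = maps.grid
    lo = np.asarray(box[0], float)
    hi = np.asarray(box[1], float)
    if np.any(lo < np.asarray(grid.origin) - 1e-9) or np.any(hi > grid.upper + 1e-9):
        raise ValueError("sampling box must lie within the FragMap grid")

    class_names = sorted(maps.maps)
    stack = np.stack([maps.maps[c].values for c in class_names])
    map_index = np.array([class_names.index(maps.classify(a)) for a in ligand.atoms])
    base = ligand.coords()
    base_centred = base - base.mean(axis=0)

    temps = np.concatenate(
        [
            np.full(schedule.hot_steps, schedule.t_start),
            schedule.t_start
            + (schedule.t_end - schedule.t_start)
            * (np.arange(1, schedule.cool_steps + 1) / max(schedule.cool_steps, 1)),
        ]
    )

    poses = []
    for rep in range(schedule.repeats):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(rep,)))
        com = lo + rng.random(3) * (hi - lo)
        rot = Rotation.random(rng=rng)
        coords = rot.apply(base_centred) + com
        energy = _lgfe_vectorised(coords, map_index, stack, grid)
        for t in temps:
            if rng.random() < 0.5:
                shift = (rng.random(3) * 2 - 1) * schedule.max_translation
                trial = coords + shift
                if np.any(trial.mean(axis=0) < lo) or np.any(trial.mean(axis=0) > hi):
                    continue  # COM must stay inside the sampling box
            else:
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                angle = (rng.random() * 2 - 1) * math.radians(schedule.max_rotation)
                r = Rotation.from_rotvec(axis * angle)
                c = coords.mean(axis=0)
                trial = r.apply(coords - c) + c
            e_trial = _lgfe_vectorised(trial, map_index, stack, grid)
            de = e_trial - energy
            if de < 0 or (t > 0 and rng.random() < math.exp(-de / (KB * t))):
                coords, energy = trial, e_trial
        atoms = [
            Atom(a.serial, a.name, a.element, coords[i]) for i, a in enumerate(ligand.atoms)
        ]
        poses.append(Pose(atoms=atoms, lgfe=energy, label=f"rep{rep}"))
    return PoseEnsemble(ligand_name="LIG", poses=poses)


# --- OpenDX I/O -------------------------------------------------------------


def write_dx(gfe_map: GfeMap | OccupancyMap, path: str | Path) -> None:
    """Write a map on a regular grid in OpenDX format."""
    g = gfe_map.grid
    data = gfe_map.values if isinstance(gfe_map, GfeMap) else gfe_map.counts.astype(float)
    nx, ny, nz = g.dims
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {g.origin[0]:.6f} {g.origin[1]:.6f} {g.origin[2]:.6f}",
        f"delta {g.spacing:.6f} 0.000000 0.000000",
        f"delta 0.000000 {g.spacing:.6f} 0.000000",
        f"delta 0.000000 0.000000 {g.spacing:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = data.ravel(order="C")
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.6e}" for v in flat[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    Path(path).write_text("\n".join(lines) + "\n")


def read_dx(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    """Read an OpenDX regular-grid scalar map."""
    dims = origin = None
    deltas = []
    values: list[float] = []
    in_data = False
    for line in Path(path).read_text().splitlines():
        ls = line.strip()
        if ls.startswith("object 1"):
            dims = tuple(int(x) for x in ls.split()[-3:])
        elif ls.startswith("origin"):
            origin = tuple(float(x) for x in ls.split()[1:4])
        elif ls.startswith("delta"):
            deltas.append([float(x) for x in ls.split()[1:4]])
        elif "data follows" in ls:
            in_data = True
        elif ls.startswith("attribute"):
            in_data = False
        elif in_data and ls:
            values.extend(float(x) for x in ls.split())
    if dims is None or origin is None or len(deltas) < 3:
        raise ValueError(f"{path}: not a regular-grid OpenDX file")
    spacing = deltas[0][0]
    grid = GridSpec(origin=origin, spacing=spacing, dims=dims)
    return grid, np.asarray(values).reshape(dims, order="C")
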