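"""Structure and pose data model with PDB-family I/O.

Sterol-site mapping works on three kinds of coordinate data: a (usually
tetrameric) protein structure, ensembles of rigid ligand poses from docking
or Monte Carlo sampling, and per-chain numbered sequences for motif scanning.
All contact logic downstream is heavy-atom only, so hydrogens are dropped at
parse time.  Residues keep their *author* numbering (including insertion
codes): binding-site residues are reported with the labels crystallographers
and electrophysiologists use (e.g. V469, Y487), which are author numbers.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from biotite.sequence import ProteinSequence

logger = logging.getLogger("sterolsites")

__all__ = [
    "Atom",
    "Residue",
    "ResidueKey",
    "Structure",
    "NumberedSequence",
    "Pose",
    "PoseEnsemble",
    "VdwRadiiTable",
    "DEFAULT_VDW",
    "read_structure",
    "write_structure",
    "extract_sequence",
    "read_pose_ensemble",
    "write_pose_ensemble",
    "StructureParseError",
    "TopologyError",
]


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


class TopologyError(ValueError):
    """Raised when poses in one ensemble do not share atom count/order."""


class ResidueKey(NamedTuple):
    """Identity of a residue: chain id, author number, insertion code."""

    chain_id: str
    number: int
    insertion_code: str = ""

    def __str__(self) -> str:  # e.g. "A:469" or "A:469A"
        return f"{self.chain_id}:{self.number}{self.insertion_code}"


@dataclass(slots=True)
class Atom:
    """One heavy atom: serial, PDB atom name, element symbol, position in Å."""

    serial: int
    name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial} {self.name}: position must be a finite 3-vector")


@dataclass(slots=True)
class Residue:
    chain_id: str
    number: int
    insertion_code: str
    name3: str
    code1: str
    atoms: list[Atom]

    @property
    def key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.number, self.insertion_code)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def sidechain_centroid(self) -> np.ndarray:
        """Centroid of non-backbone heavy atoms; falls back to all atoms (GLY)."""
        side = [a.position for a in self.atoms if a.name not in _BACKBONE_NAMES]
        if not side:
            side = [a.position for a in self.atoms]
        return np.mean(side, axis=0)


_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


@dataclass
class Structure:
    """Chains of residues; ``symmetry_order`` is the assumed rotational symmetry
    of the oligomer (4 for a homotetrameric channel)."""

    chains: dict[str, list[Residue]]
    symmetry_order: int = 4

    def __post_init__(self) -> None:
        seen: set[ResidueKey] = set()
        for cid, residues in self.chains.items():
            last = None
            for r in residues:
                if not r.atoms:
                    raise ValueError(f"residue {r.key} has no heavy atoms")
                if r.key in seen:
                    raise ValueError(f"duplicate residue identity {r.key}")
                seen.add(r.key)
                if last is not None and r.number <= last and not r.insertion_code:
                    raise ValueError(
                        f"residue numbers not strictly increasing in chain {cid} at {r.number}"
                    )
                last = r.number
        self._atom_cache: tuple[np.ndarray, np.ndarray, list[ResidueKey]] | None = None

    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def atom_table(self) -> tuple[np.ndarray, np.ndarray, list[ResidueKey]]:
        """Flat view (coords [N,3], elements [N], residue key per atom)."""
        if self._atom_cache is None:
            coords, elements, keys = [], [], []
            for r in self.residues():
                for a in r.atoms:
                    coords.append(a.position)
                    elements.append(a.element)
                    keys.append(r.key)
            self._atom_cache = (
                np.asarray(coords, dtype=float).reshape(-1, 3),
                np.asarray(elements, dtype=object),
                keys,
            )
        return self._atom_cache


@dataclass(frozen=True)
class NumberedSequence:
    """Ordered (author residue number, one-letter code) pairs for one chain."""

    chain_id: str
    entries: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        numbers = [n for n, _ in self.entries]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError("residue numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def string(self) -> str:
        return "".join(c for _, c in self.entries)


@dataclass
class Pose:
    """One rigid ligand placement, optionally scored.

    ``energy`` is a docking score and ``lgfe`` a ligand grid free energy, both
    in kcal/mol; either may be absent depending on the pipeline branch.
    """

    atoms: list[Atom]
    energy: float | None = None
    lgfe: float | None = None
    label: str = ""

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def com(self) -> np.ndarray:
        """Unweighted heavy-atom centroid (masses are not carried by PDBQT)."""
        return self.coords().mean(axis=0)


@dataclass
class PoseEnsemble:
    ligand_name: str
    poses: list[Pose]

    def __post_init__(self) -> None:
        if not self.poses:
            raise ValueError("pose ensemble must be non-empty")
        ref = [a.name for a in self.poses[0].atoms]
        for i, p in enumerate(self.poses):
            names = [a.name for a in p.atoms]
            if names != ref:
                raise TopologyError(
                    f"pose {i} ({p.label!r}) has atom list {len(names)} differing from pose 0"
                )

    def __len__(self) -> int:
        return len(self.poses)


# --- van der Waals radii ----------------------------------------------------

#: Heavy-atom vdW radii (Å) used for the contact criterion; C/N/O are the
#: commonly accepted values, S/P are this package's defaults.
DEFAULT_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}


@dataclass(frozen=True)
class VdwRadiiTable:
    radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW))
    default_radius: float = 1.70

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii.values()) or self.default_radius <= 0:
            raise ValueError("vdW radii must be strictly positive")

    def radius(self, element: str) -> float:
        elem = element.strip().upper()
        try:
            return self.radii[elem]
        except KeyError:
            logger.warning("unknown element %r: using default radius %.2f Å", element, self.default_radius)
            return self.default_radius


# --- element inference ------------------------------------------------------

_TWO_LETTER = {"CL", "BR", "FE", "ZN", "MG", "MN", "NA", "CA", "SE", "CU", "NI", "CD"}


def _element_from_name(atom_name: str) -> str:
    """PDB atom-name heuristic: strip digits/primes, honour two-letter symbols."""
    name = atom_name.strip()
    alpha = re.sub(r"[^A-Za-z]", "", name).upper()
    if not alpha:
        return ""
    if alpha[:2] in _TWO_LETTER and len(name) >= 2 and not name[0].isdigit():
        return alpha[:2].capitalize()
    return alpha[0]


def _is_hydrogen(element: str, atom_name: str) -> bool:
    e = element.strip().upper()
    if e in {"H", "D", "T"}:
        return True
    if not e:
        return _element_from_name(atom_name) == "H"
    return False


# --- PDB reading ------------------------------------------------------------


def _atoms_from_array(arr: "struc.AtomArray") -> Iterator[tuple[int, Atom, str, int, str, str]]:
    """Yield (index, Atom, chain, resnum, icode, resname) for heavy atoms."""
    ins = arr.ins_code if "ins_code" in arr.get_annotation_categories() else [""] * arr.array_length()
    for i in range(arr.array_length()):
        elem = str(arr.element[i]).strip()
        name = str(arr.atom_name[i]).strip()
        if not elem:
            elem = _element_from_name(name)
        if _is_hydrogen(elem, name):
            continue
        elem = elem.capitalize() if len(elem) > 1 else elem.upper()
        atom = Atom(
            serial=int(arr.atom_id[i]) if "atom_id" in arr.get_annotation_categories() else i + 1,
            name=name,
            element=elem,
            position=np.asarray(arr.coord[i], dtype=float),
        )
        yield i, atom, str(arr.chain_id[i]).strip(), int(arr.res_id[i]), str(ins[i]).strip(), str(
            arr.res_name[i]
        ).strip()


def _structure_from_array(arr: "struc.AtomArray", symmetry_order: int) -> Structure:
    chains: dict[str, list[Residue]] = {}
    current: Residue | None = None
    for _, atom, cid, num, icode, name3 in _atoms_from_array(arr):
        if (
            current is None
            or current.chain_id != cid
            or current.number != num
            or current.insertion_code != icode
        ):
            try:
                code1 = ProteinSequence.convert_letter_3to1(name3)
            except Exception:
                code1 = "X"
            current = Residue(cid, num, icode, name3, code1, [])
            chains.setdefault(cid, []).append(current)
        current.atoms.append(atom)
    if not chains:
        raise StructureParseError("no heavy atoms found (empty structure)")
    return Structure(chains=chains, symmetry_order=symmetry_order)


def read_structure(path: str | Path, format: str = "pdb", symmetry_order: int = 4) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Hydrogens are dropped; for altloc groups only the highest-occupancy
    conformer is kept; author residue numbers and insertion codes are
    preserved.  Only the first MODEL of a multi-model file is used.
    """
    if format.lower() != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    path = Path(path)
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        arr = pdb_file.get_structure(model=1, altloc="occupancy", extra_fields=["atom_id"])
    except Exception as exc:  # surface the offending line where biotite reports it
        raise StructureParseError(f"cannot parse {path.name}: {exc}") from exc
    return _structure_from_array(arr, symmetry_order)


def _structure_to_array(structure: Structure) -> "struc.AtomArray":
    n = structure.n_atoms()
    arr = struc.AtomArray(n)
    arr.add_annotation("atom_id", int)
    i = 0
    for r in structure.residues():
        for a in r.atoms:
            arr.coord[i] = a.position
            arr.chain_id[i] = r.chain_id
            arr.res_id[i] = r.number
            arr.ins_code[i] = r.insertion_code
            arr.res_name[i] = r.name3
            arr.atom_name[i] = a.name
            arr.element[i] = a.element.upper()
            arr.hetero[i] = False
            arr.atom_id[i] = a.serial
            i += 1
    return arr


def write_structure(structure: Structure, path: str | Path) -> None:
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(_structure_to_array(structure))
    pdb_file.write(str(Path(path)))


def extract_sequence(structure: Structure, chain: str) -> NumberedSequence:
    """One (author number, one-letter code) entry per residue of ``chain``."""
    if chain not in structure.chains:
        raise KeyError(f"chain {chain!r} not in structure (has {sorted(structure.chains)})")
    entries = tuple((r.number, r.code1 if r.code1 else "X") for r in structure.chains[chain])
    return NumberedSequence(chain_id=chain, entries=entries)


# --- pose ensemble I/O ------------------------------------------------------

# Per-model energy remark conventions understood on input (kcal/mol):
#   AutoDock: "USER    Estimated Free Energy of Binding    =  -10.20 kcal/mol"
#   Vina:     "REMARK VINA RESULT:     -10.2  ..."
#   generic:  "REMARK ENERGY -10.2" / "REMARK LGFE -5.0" (this package's output)
_ENERGY_PATTERNS = [
    re.compile(r"Estimated Free Energy of Binding\s*=\s*(-?\d+\.?\d*)"),
    re.compile(r"VINA RESULT:\s*(-?\d+\.?\d*)"),
    re.compile(r"^(?:REMARK|USER)\s+ENERGY[:= ]\s*(-?\d+\.?\d*)", re.IGNORECASE),
]
_LGFE_PATTERN = re.compile(r"^(?:REMARK|USER)\s+LGFE[:= ]\s*(-?\d+\.?\d*)", re.IGNORECASE)

# PDBQT AutoDock atom types → element symbols (others fall back to name heuristic)
_ADTYPE_TO_ELEMENT = {
    "A": "C", "C": "C", "N": "N", "NA": "N", "NS": "N", "OA": "O", "OS": "O",
    "SA": "S", "S": "S", "P": "P", "F": "F", "CL": "Cl", "BR": "Br", "I": "I",
    "HD": "H", "HS": "H", "H": "H",
}


def _split_models(text: str) -> list[list[str]]:
    """Split file text into per-model line blocks (whole file if no MODEL)."""
    blocks: list[list[str]] = []
    current: list[str] | None = None
    saw_model = False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            current = []
            blocks.append(current)
        elif rec == "ENDMDL":
            current = None
        elif current is not None:
            current.append(line)
    if not saw_model:
        blocks = [text.splitlines()]
    return [b for b in blocks if any(l[:6].strip() in ("ATOM", "HETATM") for l in b)]


def _parse_model_block(lines: list[str], is_pdbqt: bool, model_idx: int) -> Pose:
    energy = lgfe = None
    atom_lines = []
    elements: list[str | None] = []
    for line in lines:
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            elem = None
            if is_pdbqt:
                # charge + AutoDock type trail the standard columns; tolerate
                # off-by-one alignment by taking the last token after col 66
                tail = line[66:].split()
                adtype = tail[-1].upper() if len(tail) >= 2 else ""
                elem = _ADTYPE_TO_ELEMENT.get(adtype)
                line = line[:66]  # strip charge/type columns so biotite sees plain PDB
            atom_lines.append(line)
            elements.append(elem)
        elif rec in ("REMARK", "USER"):
            for pat in _ENERGY_PATTERNS:
                m = pat.search(line)
                if m:
                    energy = float(m.group(1))
                    break
            m = _LGFE_PATTERN.search(line)
            if m:
                lgfe = float(m.group(1))
    if not atom_lines:
        raise StructureParseError(f"model {model_idx}: no coordinate records")
    pdb_file = pdbio.PDBFile.read(io.StringIO("\n".join(atom_lines) + "\n"))
    try:
        arr = pdb_file.get_structure(model=1, extra_fields=["atom_id"])
    except Exception as exc:
        raise StructureParseError(f"model {model_idx}: cannot parse coordinates: {exc}") from exc
    atoms = []
    for i in range(arr.array_length()):
        name = str(arr.atom_name[i]).strip()
        elem = elements[i] or str(arr.element[i]).strip() or _element_from_name(name)
        if _is_hydrogen(elem, name):
            continue
        elem = elem.capitalize() if len(elem) > 1 else elem.upper()
        atoms.append(Atom(int(arr.atom_id[i]), name, elem, np.asarray(arr.coord[i], dtype=float)))
    return Pose(atoms=atoms, energy=energy, lgfe=lgfe, label=f"m{model_idx}")


def read_pose_ensemble(path: str | Path, format: str | None = None, ligand_name: str = "LIG") -> PoseEnsemble:
    """Read a multi-model PDB or PDBQT pose ensemble.

    All models must share atom count and order; per-model energies are read
    from AutoDock/Vina/this package's remark lines when present.  PDBQT is
    accepted read-only; torsion-tree records are ignored.
    """
    path = Path(path)
    if format is None:
        format = "pdbqt" if path.suffix.lower() == ".pdbqt" else "pdb"
    is_pdbqt = format.lower() == "pdbqt"
    blocks = _split_models(path.read_text())
    if not blocks:
        raise StructureParseError(f"{path.name}: no models with coordinate records")
    poses = [_parse_model_block(b, is_pdbqt, i + 1) for i, b in enumerate(blocks)]
    ref = [a.name for a in poses[0].atoms]
    for i, p in enumerate(poses):
        if [a.name for a in p.atoms] != ref:
            raise TopologyError(f"{path.name}: model {i + 1} atom list differs from model 1")
    return PoseEnsemble(ligand_name=ligand_name, poses=poses)


def write_pose_ensemble(ensemble: PoseEnsemble, path: str | Path) -> None:
    """Write a multi-model PDB with per-model REMARK ENERGY / REMARK LGFE."""
    out = []
    for i, pose in enumerate(ensemble.poses, start=1):
        out.append(f"MODEL     {i:4d}")
        if pose.energy is not None:
            out.append(f"REMARK ENERGY {pose.energy:.4f}")
        if pose.lgfe is not None:
            out.append(f"REMARK LGFE {pose.lgfe:.4f}")
        arr = struc.AtomArray(len(pose.atoms))
        for j, a in enumerate(pose.atoms):
            arr.coord[j] = a.position
            arr.chain_id[j] = "L"
            arr.res_id[j] = 1
            arr.res_name[j] = ensemble.ligand_name[:3]
            arr.atom_name[j] = a.name
            arr.element[j] = a.element.upper()
            arr.hetero[j] = True
        pdb_file = pdbio.PDBFile()
        pdb_file.set_structure(arr)
        buf = io.StringIO()
        pdb_file.write(buf)
        out.extend(l for l in buf.getvalue().splitlines() if l[:6].strip() in ("ATOM", "HETATM"))
        out.append("ENDMDL")
    out.append("END")
    Path(path).write_text("\n".join(out) + "\n")
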