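"""Heavy-atom contact criterion and residue fingerprints.

A protein residue is counted as interacting with a ligand pose if *any* of
its heavy atoms lies within the sum of the van der Waals radii of the two
atoms (inclusive: distance == cutoff counts).  With the default radii this
gives contact distances of ~3.4–4.0 Å for typical C–C and C–heteroatom
pairs.  The set of contacted residues is a pose's *fingerprint*; fingerprint
overlap (Jaccard) is what the clustering stages use to decide that two pose
clusters occupy the same binding site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet

import numpy as np
from scipy.spatial import cKDTree

from .core_model import Pose, ResidueKey, Structure, VdwRadiiTable

__all__ = [
    "ResidueFingerprint",
    "contact_cutoff",
    "contact_fingerprint",
    "fingerprint_similarity",
]


@dataclass(frozen=True)
class ResidueFingerprint:
    """Set of residue identities contacted by one pose."""

    residues: FrozenSet[ResidueKey]
    source_pose: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def numbers_by_chain(self) -> dict[str, frozenset[int]]:
        out: dict[str, set[int]] = {}
        for key in self.residues:
            out.setdefault(key.chain_id, set()).add(key.number)
        return {c: frozenset(s) for c, s in out.items()}

    def stripped(self) -> frozenset[int]:
        """Residue numbers with chain ids removed (for symmetry analysis)."""
        return frozenset(key.number for key in self.residues)


def contact_cutoff(elem_a: str, elem_b: str, table: VdwRadiiTable | None = None) -> float:
    """Contact distance (Å) for an element pair: sum of the two vdW radii."""
    table = table or VdwRadiiTable()
    return table.radius(elem_a) + table.radius(elem_b)


def contact_fingerprint(
    structure: Structure,
    pose: Pose,
    table: VdwRadiiTable | None = None,
    method: str = "auto",
) -> ResidueFingerprint:
    """Residues of ``structure`` with any heavy atom within vdW-sum distance
    of any pose heavy atom.

    ``method``: "auto" uses a KD-tree prefilter with an exact per-pair check
    (identical results to "brute", the all-pairs reference path).
    """
    if not pose.atoms:
        raise ValueError("empty pose: no heavy atoms to test for contacts")
    table = table or VdwRadiiTable()
    p_coords, p_elems, p_keys = structure.atom_table()
    l_coords = pose.coords()
    l_radii = np.array([table.radius(a.element) for a in pose.atoms])
    p_radii = np.array([table.radius(e) for e in p_elems])

    hit = np.zeros(len(p_coords), dtype=bool)
    if method == "brute":
        d = np.linalg.norm(p_coords[:, None, :] - l_coords[None, :, :], axis=2)
        hit = np.any(d <= p_radii[:, None] + l_radii[None, :], axis=1)
    elif method == "auto":
        tree = cKDTree(l_coords)
        rmax = float(l_radii.max())
        # prefilter at the largest possible cutoff, then exact per-pair test
        for i in np.arange(len(p_coords)):
            idx = tree.query_ball_point(p_coords[i], p_radii[i] + rmax)
            if not idx:
                continue
            d = np.linalg.norm(l_coords[idx] - p_coords[i], axis=1)
            if np.any(d <= p_radii[i] + l_radii[idx]):
                hit[i] = True
    else:
        raise ValueError(f"unknown method {method!r}")

    residues = frozenset(p_keys[i] for i in np.nonzero(hit)[0])
    return ResidueFingerprint(residues=residues, source_pose=pose.label)


def fingerprint_similarity(fp_a: ResidueFingerprint, fp_b: ResidueFingerprint) -> float:
    """Jaccard index of two fingerprints; two empty sets give 0.0."""
    a, b = fp_a.residues, fp_b.residues
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)
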