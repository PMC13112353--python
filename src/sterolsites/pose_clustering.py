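"""Pose clustering and binding-site grouping.

Two clustering routes feed the site analysis:

* the docking route — greedy energy-seeded RMSD clustering at a 2 Å
  tolerance (the AutoDock convention), followed by a significance filter
  keeping clusters with at least 2% of all docked conformations;
* the grid-sampling route — two-stage centre-of-mass clustering of Monte
  Carlo hotspot poses (3 Å first stage over poses with LGFE below
  −3.5 kcal/mol, then 4 Å over the stage-1 representatives).

Clusters whose representative fingerprints share most of their interacting
residues (Jaccard ≥ 0.5, single linkage) are merged into *site groups*; a
group's subunit occupancy counts on how many symmetry-related chains the
equivalent site was found independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .contacts import ResidueFingerprint, fingerprint_similarity
from .core_model import Pose, PoseEnsemble, Structure

__all__ = [
    "PoseCluster",
    "SiteGroup",
    "pose_rmsd",
    "cluster_by_rmsd",
    "filter_significant",
    "group_by_fingerprint",
    "com_cluster",
    "subunit_occupancy",
]


@dataclass
class PoseCluster:
    """Indices into a pose ensemble; representative is the lowest-score member."""

    member_indices: list[int]
    representative: int
    size: int
    fraction: float

    def __post_init__(self) -> None:
        if self.representative not in self.member_indices:
            raise ValueError("representative must be a member")
        if self.size != len(self.member_indices):
            raise ValueError("size must equal number of members")


@dataclass
class SiteGroup:
    """A cluster-of-clusters: one candidate binding site."""

    cluster_ids: list[int]
    union_fingerprint: ResidueFingerprint
    cluster_fingerprints: list[ResidueFingerprint]
    label: str
    occupancy: int | None = None
    stereospecific: bool | None = None
    total_size: int = 0


def pose_rmsd(a: Pose, b: Pose) -> float:
    """Heavy-atom RMSD in the shared receptor frame.

    No superposition and no symmetry correction: docked poses already live
    in one coordinate frame, so plain per-atom deviation is the convention.
    """
    ca, cb = a.coords(), b.coords()
    if ca.shape != cb.shape:
        raise ValueError(f"topology mismatch: {ca.shape[0]} vs {cb.shape[0]} atoms")
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


def _greedy_cluster(order: list[int], join, n_total: int) -> list[PoseCluster]:
    """Greedy seeding in the given order: each item joins the first cluster
    whose seed accepts it, else seeds a new cluster."""
    seeds: list[int] = []
    members: list[list[int]] = []
    for idx in order:
        for s, mem in zip(seeds, members):
            if join(s, idx):
                mem.append(idx)
                break
        else:
            seeds.append(idx)
            members.append([idx])
    return [
        PoseCluster(member_indices=mem, representative=seed, size=len(mem), fraction=len(mem) / n_total)
        for seed, mem in zip(seeds, members)
    ]


def cluster_by_rmsd(ensemble: PoseEnsemble, tolerance: float = 2.0) -> list[PoseCluster]:
    """Energy-seeded greedy RMSD clustering.

    Poses sorted by ascending energy (ties by pose index) are assigned to the
    first existing cluster whose representative lies within ``tolerance``;
    otherwise they seed a new cluster.  Clusters come out ordered by
    ascending representative energy, and each representative is its
    cluster's lowest-energy member by construction.
    """
    if any(p.energy is None for p in ensemble.poses):
        raise ValueError(
            "cluster_by_rmsd requires per-pose energies; supply energies or use com_cluster"
        )
    order = sorted(range(len(ensemble)), key=lambda i: (ensemble.poses[i].energy, i))
    coords = [p.coords() for p in ensemble.poses]

    def join(seed: int, idx: int) -> bool:
        d = coords[seed] - coords[idx]
        return float(np.sqrt(np.mean(np.sum(d * d, axis=1)))) <= tolerance

    return _greedy_cluster(order, join, len(ensemble))


def filter_significant(
    clusters: list[PoseCluster], ensemble_size: int, min_fraction: float = 0.02
) -> list[PoseCluster]:
    """Keep clusters holding at least ``min_fraction`` of all docked poses.

    "At least 2%" means size ≥ ceil(0.02 · N): for N = 300 the minimum
    significant size is 6.  (The 1e-9 guard keeps binary rounding of
    0.02 · 300 = 6.000000000000001 from shifting the threshold to 7.)
    """
    min_size = math.ceil(min_fraction * ensemble_size - 1e-9)
    return [c for c in clusters if c.size >= min_size]


def group_by_fingerprint(
    clusters: list[PoseCluster],
    fingerprints: list[ResidueFingerprint],
    threshold: float = 0.5,
    ignore_chains: bool = True,
) -> list[SiteGroup]:
    """Single-linkage merge of clusters sharing most of their residues.

    Two clusters are linked when the Jaccard similarity of their
    representative fingerprints is ≥ ``threshold``; linkage is transitive.
    With ``ignore_chains`` (the default) similarity is computed on
    chain-stripped residue-number sets, so symmetry-equivalent clusters on
    different subunits collapse into one group — the convention of
    per-group residue lists with a separate subunit-occupancy count.
    Groups are labelled G1, G2, ... in descending total pose count.
    """
    if len(clusters) != len(fingerprints):
        raise ValueError("one fingerprint per cluster required")

    def similarity(a: ResidueFingerprint, b: ResidueFingerprint) -> float:
        if not ignore_chains:
            return fingerprint_similarity(a, b)
        sa, sb = a.stripped(), b.stripped()
        union = sa | sb
        return len(sa & sb) / len(union) if union else 0.0

    n = len(clusters)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if similarity(fingerprints[i], fingerprints[j]) >= threshold:
                parent[find(i)] = find(j)

    by_root: dict[int, list[int]] = {}
    for i in range(n):
        by_root.setdefault(find(i), []).append(i)

    raw = sorted(
        by_root.values(),
        key=lambda ids: (-sum(clusters[i].size for i in ids), min(ids)),
    )
    groups = []
    for rank, ids in enumerate(raw, start=1):
        union = frozenset().union(*(fingerprints[i].residues for i in ids))
        groups.append(
            SiteGroup(
                cluster_ids=ids,
                union_fingerprint=ResidueFingerprint(residues=union),
                cluster_fingerprints=[fingerprints[i] for i in ids],
                label=f"G{rank}",
                total_size=sum(clusters[i].size for i in ids),
            )
        )
    return groups


def com_cluster(
    ensemble: PoseEnsemble,
    stage1_radius: float = 3.0,
    lgfe_cutoff: float = -3.5,
    stage2_radius: float = 4.0,
) -> list[PoseCluster]:
    """Two-stage centre-of-mass clustering of grid-sampled poses.

    Poses with LGFE below ``lgfe_cutoff`` are clustered greedily (ascending
    LGFE) at ``stage1_radius``; the stage-1 representatives are re-clustered
    at ``stage2_radius`` and the stage-1 member sets merged.  Each final
    hotspot's representative is its lowest-LGFE member.  COMs are unweighted
    heavy-atom centroids.
    """
    if any(p.lgfe is None for p in ensemble.poses):
        raise ValueError("com_cluster requires per-pose LGFE values")
    kept = [i for i, p in enumerate(ensemble.poses) if p.lgfe < lgfe_cutoff]
    if not kept:
        return []
    coms = {i: ensemble.poses[i].com() for i in kept}
    order = sorted(kept, key=lambda i: (ensemble.poses[i].lgfe, i))

    def join1(seed: int, idx: int) -> bool:
        return float(np.linalg.norm(coms[seed] - coms[idx])) <= stage1_radius

    stage1 = _greedy_cluster(order, join1, len(ensemble))

    reps = [c.representative for c in stage1]  # already in ascending-LGFE order

    def join2(seed: int, idx: int) -> bool:
        return float(np.linalg.norm(coms[seed] - coms[idx])) <= stage2_radius

    stage2 = _greedy_cluster(reps, join2, len(ensemble))

    members_of = {c.representative: c.member_indices for c in stage1}
    final = []
    for c in stage2:
        merged: list[int] = []
        for rep in c.member_indices:
            merged.extend(members_of[rep])
        rep = min(merged, key=lambda i: (ensemble.poses[i].lgfe, i))
        final.append(
            PoseCluster(
                member_indices=merged,
                representative=rep,
                size=len(merged),
                fraction=len(merged) / len(ensemble),
            )
        )
    return final


def subunit_occupancy(
    group: SiteGroup, structure: Structure, similarity_threshold: float = 0.5
) -> int:
    """Number of symmetry-related chains on which the site occurs independently.

    Member fingerprints are stripped of chain ids to form a consensus
    residue-number set (numbers present in at least half of the member
    fingerprints); a chain counts as occupied when its chain-attributed
    residue-number set matches the consensus at Jaccard ≥ threshold.
    Bounded by the structure's symmetry order.
    """
    fps = group.cluster_fingerprints
    if not fps or all(len(fp) == 0 for fp in fps):
        raise ValueError(f"group {group.label}: no fingerprints to attribute to subunits")
    counts: dict[int, int] = {}
    for fp in fps:
        for num in fp.stripped():
            counts[num] = counts.get(num, 0) + 1
    consensus = frozenset(n for n, c in counts.items() if c >= len(fps) / 2)

    per_chain: dict[str, set[int]] = {}
    for fp in fps:
        for chain, nums in fp.numbers_by_chain().items():
            per_chain.setdefault(chain, set()).update(nums)

    occupied = 0
    for nums in per_chain.values():
        union = consensus | nums
        if union and len(consensus & nums) / len(union) >= similarity_threshold:
            occupied += 1
    return max(1, min(occupied, structure.symmetry_order))
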