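"""Cholesterol-recognition motif scanning and cluster-to-motif assignment.

Linear motifs are scanned on numbered one-chain sequences:

* CRAC       L/V-(X)1–5-Y-(X)1–5-R/K      (N→C)
* CARC       R/K-(X)1–5-Y/F-(X)1–5-L/V    (inverted CRAC, central Y or F)
* CRAC-like  L/V-(X)1–5-F-(X)1–5-R/K      (CRAC with a central phenylalanine)

The (X)1–5 gaps count *sequence positions* between anchors (1–5 intervening
residues); a match whose anchors straddle a gap in the author numbering is
flagged.  Overlapping matches of one kind merge into a region carrying all
alternative anchor triplets — regions are what binding-site tables report
(e.g. "L524/V525/V527/V528–Y530–R534/K535").

The CCM (cholesterol consensus motif) is three-dimensional: a
(W/Y)-(I/V/L)-(K/R) triad on one helix facing an aromatic/basic residue
(F/Y/R) on a spatially adjacent helix; helix annotations must be supplied.

A binding cluster is assigned to a motif either strictly (all three anchors
of some alternative contacted) or in a relaxed way (the central aromatic
anchor plus at least one terminal anchor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .contacts import ResidueFingerprint
from .core_model import NumberedSequence, Residue, Structure
from .pose_clustering import SiteGroup

__all__ = [
    "MotifPattern",
    "MotifMatch",
    "MotifRegion",
    "CcmSite",
    "BUILTIN_PATTERNS",
    "scan_motif",
    "merge_matches",
    "detect_ccm",
    "motif_cluster_assignment",
    "motif_binding_fraction",
]


@dataclass(frozen=True)
class MotifPattern:
    kind: str
    start_set: frozenset[str]
    center_set: frozenset[str]
    end_set: frozenset[str]
    gap_min: int = 1
    gap_max: int = 5

    def __post_init__(self) -> None:
        if self.gap_min > self.gap_max:
            raise ValueError("gap_min must not exceed gap_max")
        if not (self.start_set and self.center_set and self.end_set):
            raise ValueError("anchor sets must be non-empty")

    @classmethod
    def crac(cls) -> "MotifPattern":
        return cls("CRAC", frozenset("LV"), frozenset("Y"), frozenset("RK"))

    @classmethod
    def carc(cls) -> "MotifPattern":
        return cls("CARC", frozenset("RK"), frozenset("YF"), frozenset("LV"))

    @classmethod
    def crac_like(cls) -> "MotifPattern":
        return cls("CRAC_LIKE", frozenset("LV"), frozenset("F"), frozenset("RK"))


BUILTIN_PATTERNS: dict[str, MotifPattern] = {
    "CRAC": MotifPattern.crac(),
    "CARC": MotifPattern.carc(),
    "CRAC_LIKE": MotifPattern.crac_like(),
}


@dataclass(frozen=True)
class MotifMatch:
    chain: str
    anchors: tuple[int, int, int]  # author residue numbers (start, center, end)
    kind: str
    positions: tuple[int, int, int] = (0, 0, 0)  # sequence indices
    spans_numbering_gap: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return (self.anchors[0], self.anchors[2])


@dataclass(frozen=True)
class MotifRegion:
    kind: str
    chain: str
    span: tuple[int, int]
    alternatives: tuple[MotifMatch, ...]

    def label(self) -> str:
        """Table-style label, alternatives joined by '/': e.g. V482/V486–F488/F489–R491."""
        starts = sorted({m.anchors[0] for m in self.alternatives})
        centers = sorted({m.anchors[1] for m in self.alternatives})
        ends = sorted({m.anchors[2] for m in self.alternatives})
        return "–".join("/".join(str(x) for x in grp) for grp in (starts, centers, ends))


@dataclass(frozen=True)
class CcmSite:
    triad: tuple[Residue, Residue, Residue]
    partner: Residue
    triad_helix: int
    partner_helix: int


def scan_motif(seq: NumberedSequence, pattern: MotifPattern) -> list[MotifMatch]:
    """All anchor triples (i < j < k) matching the pattern with both
    sequence-position gaps in [gap_min, gap_max], ordered by anchors."""
    entries = seq.entries
    n = len(entries)
    starts = [i for i in range(n) if entries[i][1] in pattern.start_set]
    matches = []
    for i in starts:
        for j in range(i + pattern.gap_min + 1, min(i + pattern.gap_max + 2, n)):
            if entries[j][1] not in pattern.center_set:
                continue
            for k in range(j + pattern.gap_min + 1, min(j + pattern.gap_max + 2, n)):
                if entries[k][1] not in pattern.end_set:
                    continue
                nums = (entries[i][0], entries[j][0], entries[k][0])
                # author numbering jumps inside the window ⇒ flag the match
                gap = nums[2] - nums[0] != k - i
                matches.append(
                    MotifMatch(
                        chain=seq.chain_id,
                        anchors=nums,
                        kind=pattern.kind,
                        positions=(i, j, k),
                        spans_numbering_gap=gap,
                    )
                )
    matches.sort(key=lambda m: m.anchors)
    return matches


def merge_matches(matches: Sequence[MotifMatch]) -> list[MotifRegion]:
    """Transitively merge matches with overlapping residue-number spans."""
    if not matches:
        return []
    kinds = {m.kind for m in matches}
    chains = {m.chain for m in matches}
    if len(kinds) > 1 or len(chains) > 1:
        raise ValueError(f"merge_matches requires one kind and chain, got {kinds} on {chains}")
    ordered = sorted(matches, key=lambda m: m.anchors)
    regions: list[list[MotifMatch]] = []
    cur = [ordered[0]]
    lo, hi = ordered[0].span
    for m in ordered[1:]:
        a, b = m.span
        if a <= hi:  # spans overlap (sorted by start, so only the right edge matters)
            cur.append(m)
            hi = max(hi, b)
        else:
            regions.append(cur)
            cur, (lo, hi) = [m], m.span
    regions.append(cur)
    return [
        MotifRegion(
            kind=ms[0].kind,
            chain=ms[0].chain,
            span=(min(m.span[0] for m in ms), max(m.span[1] for m in ms)),
            alternatives=tuple(ms),
        )
        for ms in regions
    ]


_CCM_TRIAD = (frozenset("WY"), frozenset("IVL"), frozenset("KR"))
_CCM_PARTNER = frozenset("FYR")


def detect_ccm(
    structure: Structure,
    helices: list[tuple[str, int, int]],
    triad_window: int = 8,
    adjacency_cutoff: float = 10.0,
) -> list[CcmSite]:
    """CCM sites: a (W/Y)-(I/V/L)-(K/R) triad within ``triad_window``
    consecutive residues of one helix, facing an F/Y/R whose side-chain
    centroid lies within ``adjacency_cutoff`` Å of the triad centroid on a
    *different* helix.  Helix annotations are (chain, first, last) author
    numbers and must be supplied — they are not derived from geometry.
    """
    if not helices:
        raise ValueError("detect_ccm requires helix annotations")
    helix_residues: list[list[Residue]] = []
    for chain, start, end in helices:
        if chain not in structure.chains:
            raise KeyError(f"helix chain {chain!r} not in structure")
        helix_residues.append(
            [r for r in structure.chains[chain] if start <= r.number <= end]
        )

    sites = []
    for hi, residues in enumerate(helix_residues):
        n = len(residues)
        for a in range(n):
            if residues[a].code1 not in _CCM_TRIAD[0]:
                continue
            for b in range(a + 1, min(a + triad_window, n)):
                if residues[b].code1 not in _CCM_TRIAD[1]:
                    continue
                for c in range(b + 1, min(a + triad_window, n)):
                    if residues[c].code1 not in _CCM_TRIAD[2]:
                        continue
                    triad = (residues[a], residues[b], residues[c])
                    centroid = np.mean(
                        [np.mean(r.coords(), axis=0) for r in triad], axis=0
                    )
                    for hj, partners in enumerate(helix_residues):
                        if hj == hi:
                            continue
                        for p in partners:
                            if p.code1 not in _CCM_PARTNER:
                                continue
                            d = float(np.linalg.norm(p.sidechain_centroid() - centroid))
                            if d <= adjacency_cutoff:
                                sites.append(CcmSite(triad, p, hi, hj))
    return sites


def motif_cluster_assignment(
    fingerprint: ResidueFingerprint,
    region: MotifRegion,
    mode: Literal["strict", "relaxed"] = "strict",
) -> bool:
    """Does a binding fingerprint hit a motif region?

    strict — some alternative has all three anchors contacted on one chain;
    relaxed — some alternative has its central aromatic anchor plus at least
    one terminal anchor contacted.  Chains are evaluated independently and
    OR-ed, so intersubunit sites can satisfy a motif on either chain.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    by_chain = fingerprint.numbers_by_chain()
    for nums in by_chain.values():
        for alt in region.alternatives:
            s, c, e = alt.anchors
            if mode == "strict":
                if s in nums and c in nums and e in nums:
                    return True
            else:
                if c in nums and (s in nums or e in nums):
                    return True
    return False


def motif_binding_fraction(
    groups: Sequence[SiteGroup],
    regions: Sequence[MotifRegion],
    mode: Literal["strict", "relaxed"] = "strict",
) -> float:
    """Percentage of site groups assigned to at least one motif region."""
    if not groups:
        raise ValueError("motif_binding_fraction needs at least one site group")
    hits = sum(
        1
        for g in groups
        if any(motif_cluster_assignment(g.union_fingerprint, r, mode) for r in regions)
    )
    return 100.0 * hits / len(groups)
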