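"""Cross-conformation site matching and sterol stereospecificity.

Binding-site groups found on two conformational states of the same channel
(e.g. open vs closed) are matched one-to-one: candidate pairs are scored by
fingerprint Jaccard (shared author numbering) or by representative-COM
distance (shared frame), and matched greedily best-first.  Unmatched groups
are state-specific.

Stereospecificity contrasts cholesterol with its 3α-hydroxy diastereomer
epicholesterol: a cholesterol site is flagged stereospecific when no
epicholesterol group binds an equivalent residue set, i.e. the two sterols
show distinguishable binding behaviour there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .contacts import fingerprint_similarity
from .pose_clustering import SiteGroup

logger = logging.getLogger("sterolsites")

__all__ = ["StateMatch", "match_clusters_across_states", "stereospecificity_flags"]


@dataclass
class StateMatch:
    pairs: list[tuple[int, int]]  # (index in state A, index in state B)
    scores: list[float]
    mode: str
    threshold: float
    unmatched_a: list[int]
    unmatched_b: list[int]


def _candidate_scores(
    groups_a: Sequence[SiteGroup],
    groups_b: Sequence[SiteGroup],
    mode: str,
    threshold: float,
    coms_a: Sequence[np.ndarray] | None,
    coms_b: Sequence[np.ndarray] | None,
) -> list[tuple[float, int, int]]:
    cands = []
    for i, ga in enumerate(groups_a):
        for j, gb in enumerate(groups_b):
            if mode == "fingerprint":
                s = fingerprint_similarity(ga.union_fingerprint, gb.union_fingerprint)
                if s >= threshold:
                    cands.append((-s, i, j))  # negative: best first
            else:
                d = float(np.linalg.norm(np.asarray(coms_a[i]) - np.asarray(coms_b[j])))
                if d <= threshold:
                    cands.append((d, i, j))
    return cands


def match_clusters_across_states(
    groups_a: Sequence[SiteGroup],
    groups_b: Sequence[SiteGroup],
    mode: Literal["fingerprint", "com"] = "fingerprint",
    threshold: float = 0.5,
    com_threshold: float = 4.0,
    coms_a: Sequence[np.ndarray] | None = None,
    coms_b: Sequence[np.ndarray] | None = None,
) -> StateMatch:
    """Greedy best-first one-to-one matching of site groups across states.

    fingerprint mode requires both states to use the same author numbering;
    com mode requires representative COMs in a common frame (superpose the
    structures first).  Ties break toward smaller group indices.
    """
    if mode not in ("fingerprint", "com"):
        raise ValueError(f"unknown mode {mode!r}")
    eff_threshold = threshold if mode == "fingerprint" else com_threshold
    if mode == "com" and (coms_a is None or coms_b is None):
        raise ValueError("com mode needs representative COMs in a common frame")
    cands = _candidate_scores(groups_a, groups_b, mode, eff_threshold, coms_a, coms_b)
    cands.sort()  # by score, then (i, j) for deterministic ties
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs, scores = [], []
    for score, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
        scores.append(-score if mode == "fingerprint" else score)
    return StateMatch(
        pairs=pairs,
        scores=scores,
        mode=mode,
        threshold=eff_threshold,
        unmatched_a=[i for i in range(len(groups_a)) if i not in used_a],
        unmatched_b=[j for j in range(len(groups_b)) if j not in used_b],
    )


def stereospecificity_flags(
    chol_groups: Sequence[SiteGroup],
    epi_groups: Sequence[SiteGroup],
    threshold: float = 0.5,
) -> list[bool]:
    """Per-cholesterol-group flag: True = stereospecific (no epicholesterol
    group matches at Jaccard ≥ threshold, inclusive), False = both sterols
    bind the site in a similar manner."""
    if not epi_groups:
        logger.warning("no epicholesterol groups supplied: all sites flagged stereospecific")
        return [True] * len(chol_groups)
    flags = []
    for g in chol_groups:
        matched = any(
            fingerprint_similarity(g.union_fingerprint, e.union_fingerprint) >= threshold
            for e in epi_groups
        )
        flags.append(not matched)
    return flags
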