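"""Structural divergence within clusters of identical sequences.

Predicted structure databases contain many exact sequence duplicates whose
models nevertheless differ.  This module quantifies that divergence per
cluster (maximum pairwise superposed Cα RMSD), selects a representative
medoid structure, and derives a cluster-level consensus segmentation by
majority vote over the members' domain assignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .consensus import (
    ConsensusDomain,
    ConsensusResult,
    IOU_MIN_DEFAULT,
    match_choppings,
)
from .geometry import kabsch
from .io_formats import Chopping, ResidueChain

__all__ = [
    "RedundantCluster",
    "max_pairwise_rmsd",
    "medoid",
    "cluster_consensus_domains",
    "analyse_cluster",
]

# exact all-pairs RMSD up to this many members; beyond it, the maximum is
# approximated through the medoid (flagged in the output record)
EXACT_PAIRS_LIMIT = 50


@dataclass
class RedundantCluster:
    """Analysis record for one identical-sequence cluster."""

    cluster_id: str
    n_members: int
    max_pairwise_rmsd: float
    max_pair: tuple[int, int]
    medoid_index: int
    exact: bool  # False when the medoid-anchored approximation was used


def _check_members(members: Sequence[ResidueChain]) -> None:
    n0 = members[0].residue_numbers
    for m in members[1:]:
        if m.residue_numbers != n0:
            raise ValueError(
                "cluster members must share length and residue numbering"
            )


def _rmsd_matrix(members: Sequence[ResidueChain]) -> np.ndarray:
    k = len(members)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            _, r = kabsch(members[i].ca_coords, members[j].ca_coords)
            d[i, j] = d[j, i] = r
    return d


def max_pairwise_rmsd(
    members: Sequence[ResidueChain],
) -> tuple[float, tuple[int, int], bool]:
    """Maximum superposed Cα RMSD over all unordered member pairs.

    Exact enumeration up to :data:`EXACT_PAIRS_LIMIT` members; for larger
    clusters the member with the largest RMSD to the medoid anchors an
    approximate maximum (returned with ``exact=False``).
    """
    if len(members) < 2:
        raise ValueError("need at least 2 members")
    _check_members(members)
    if len(members) <= EXACT_PAIRS_LIMIT:
        d = _rmsd_matrix(members)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        i, j = int(min(i, j)), int(max(i, j))
        return float(d[i, j]), (i, j), True
    # medoid-anchored approximation: RMSD of every member to the medoid,
    # then one extra sweep from the farthest member
    med = medoid(members)
    to_med = np.array(
        [kabsch(m.ca_coords, members[med].ca_coords)[1] for m in members]
    )
    far = int(np.argmax(to_med))
    to_far = np.array(
        [kabsch(m.ca_coords, members[far].ca_coords)[1] for m in members]
    )
    far2 = int(np.argmax(to_far))
    i, j = min(far, far2), max(far, far2)
    return float(to_far[far2]), (i, j), False


def medoid(members: Sequence[ResidueChain]) -> int:
    """Index of the member minimising total superposed RMSD to all others.

    Deterministic tie-break: the lowest index wins.  A single member is its
    own medoid.
    """
    if not members:
        raise ValueError("empty cluster")
    if len(members) == 1:
        return 0
    _check_members(members)
    d = _rmsd_matrix(members)
    sums = d.sum(axis=1)
    return int(np.argmin(sums))  # argmin takes the first minimum


def cluster_consensus_domains(
    members: Sequence[ResidueChain],
    choppings: Sequence[Chopping],
    iou_min: float = IOU_MIN_DEFAULT,
    min_len: int = 1,
) -> ConsensusResult:
    """Majority-vote consensus segmentation across an identical-sequence cluster.

    Domains are matched across members by IoU against an anchor member (the
    member with the most domains; ties to the lowest index).  A residue joins
    a consensus domain when a strict majority of members assign it to that
    domain group; residues without a majority become NDR.
    """
    if len(members) != len(choppings):
        raise ValueError("one chopping per member required")
    _check_members(members)
    m = len(members)
    chain_residues = members[0].residue_set

    anchor = max(range(m), key=lambda i: (len(choppings[i]), -i))
    anchor_sets = choppings[anchor].residue_sets()
    # group[g][i] = residue set of member i's domain matched to anchor domain g
    groups: list[dict[int, frozenset[int]]] = [
        {anchor: s} for s in anchor_sets
    ]
    for i in range(m):
        if i == anchor:
            continue
        for g_idx, m_idx in match_choppings(
            choppings[anchor], choppings[i], iou_min=iou_min
        ):
            groups[g_idx][i] = choppings[i].residue_sets()[m_idx]

    domains: list[ConsensusDomain] = []
    need = m // 2 + 1  # strict majority of members
    for grp in groups:
        votes: dict[int, int] = {}
        for s in grp.values():
            for r in s:
                votes[r] = votes.get(r, 0) + 1
        voted = frozenset(r for r, v in votes.items() if v >= need)
        if len(voted) < min_len or not voted:
            continue
        support = frozenset(f"member{i}" for i in grp)
        domains.append(
            ConsensusDomain(
                residues=voted,
                confidence="high" if len(grp) == m else "medium",
                supporting_methods=support,
            )
        )
    domains.sort(key=lambda d: min(d.residues))
    covered: set[int] = set()
    for d in domains:
        covered |= d.residues
    return ConsensusResult(
        chain_id=members[0].chain_id,
        domains=domains,
        ndr_residues=frozenset(chain_residues - covered),
    )


def analyse_cluster(
    cluster_id: str,
    members: Sequence[ResidueChain],
) -> RedundantCluster:
    """Full divergence record for one cluster."""
    rmsd, pair, exact = max_pairwise_rmsd(members)
    return RedundantCluster(
        cluster_id=cluster_id,
        n_members=len(members),
        max_pairwise_rmsd=rmsd,
        max_pair=pair,
        medoid_index=medoid(members),
        exact=exact,
    )
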