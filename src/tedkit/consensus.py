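"""Consensus domain segmentation from three independent parsers.

Each full-length chain is chopped into domains by three methods; a consensus
is taken by matching domains across methods with a residue-set
intersection-over-union (IoU) criterion and voting per residue.  Domains on
which all three methods agree are high-confidence, two-method agreement is
medium, everything else falls back to non-domain residues (NDR).  Only high
and medium consensus domains flow into downstream analysis.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io_formats import Chopping, Segment, segments_from_residues

__all__ = [
    "ConsensusDomain",
    "ConsensusResult",
    "domain_iou",
    "match_choppings",
    "consensus_assign",
    "summarize_targets",
]

IOU_MIN_DEFAULT = 0.7
MIN_LEN_DEFAULT = 25

# exact enumeration of assignments is used up to this many domains per
# chopping; beyond it the Hungarian algorithm takes over
_EXACT_MATCH_LIMIT = 7


@dataclass
class ConsensusDomain:
    """One consensus domain with its provenance.

    ``confidence`` is "high" when all three methods support the domain and
    "medium" when exactly two do.
    """

    residues: frozenset[int]
    confidence: str
    supporting_methods: frozenset[str]
    avg_plddt: float = math.nan
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("consensus domain with empty residue set")
        if self.confidence not in ("high", "medium"):
            raise ValueError(f"unknown confidence tier {self.confidence!r}")
        if not self.segments:
            self.segments = segments_from_residues(self.residues)

    @property
    def n_methods(self) -> int:
        return len(self.supporting_methods)

    def chopping_string(self) -> str:
        return "_".join(f"{s.start}-{s.end}" for s in self.segments)


@dataclass
class ConsensusResult:
    """Consensus segmentation of one chain: domains plus NDR set."""

    chain_id: str
    domains: list[ConsensusDomain]
    ndr_residues: frozenset[int]

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    def chain_residues(self) -> frozenset[int]:
        out: set[int] = set(self.ndr_residues)
        for d in self.domains:
            out |= d.residues
        return frozenset(out)

    def ndr_fraction(self) -> float:
        total = len(self.chain_residues())
        return len(self.ndr_residues) / total if total else 0.0


def domain_iou(a: Iterable[int], b: Iterable[int]) -> float:
    """Intersection-over-union of two residue-number sets."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("domain_iou requires nonempty residue sets")
    return len(a & b) / len(a | b)


def _content_key(residues: frozenset[int]) -> tuple[int, ...]:
    return tuple(sorted(residues))


def match_choppings(
    x: Chopping,
    y: Chopping,
    iou_min: float = IOU_MIN_DEFAULT,
) -> list[tuple[int, int]]:
    """One-to-one matching of domains between two choppings of a chain.

    Maximises the total IoU over pairs with IoU >= ``iou_min``.  Ties are
    broken deterministically and symmetrically (by domain content, so the
    result is the transpose of matching the arguments in the other order).
    Returns (index-in-x, index-in-y) pairs sorted by x index.
    """
    sx, sy = x.residue_sets(), y.residue_sets()
    if not sx or not sy:
        return []
    # orient by content so the matching is symmetric in its arguments
    kx = tuple(_content_key(s) for s in sx)
    ky = tuple(_content_key(s) for s in sy)
    if kx <= ky:
        pairs = _match_sets(sx, sy, iou_min)
        return sorted(pairs)
    pairs = _match_sets(sy, sx, iou_min)
    return sorted((j, i) for i, j in pairs)


def _iou_matrix(sa: Sequence[frozenset[int]], sb: Sequence[frozenset[int]]) -> np.ndarray:
    m = np.zeros((len(sa), len(sb)))
    for i, a in enumerate(sa):
        for j, b in enumerate(sb):
            m[i, j] = len(a & b) / len(a | b)
    return m

def _match_sets(
    sa: Sequence[frozenset[int]],
    sb: Sequence[frozenset[int]],
    iou_min: float,
) -> list[tuple[int, int]]:
    iou = _iou_matrix(sa, sb)
    na, nb = iou.shape
    if max(na, nb) <= _EXACT_MATCH_LIMIT:
        return _match_exact(iou, iou_min)
    # Hungarian on the negated IoU; eligible pairs only are kept afterwards.
    row, col = linear_sum_assignment(-iou)
    return [(int(i), int(j)) for i, j in zip(row, col) if iou[i, j] >= iou_min]


def _match_exact(iou: np.ndarray, iou_min: float) -> list[tuple[int, int]]:
    """Exhaustive maximum-total-IoU assignment with lexicographic tie-break."""
    na, nb = iou.shape
    transpose = na > nb
    if transpose:
        iou = iou.T
        na, nb = nb, na
    best: list[tuple[int, int]] | None = None
    best_total = -1.0
    for cols in itertools.permutations(range(nb), na):
        pairs = [(i, j) for i, j in enumerate(cols) if iou[i, j] >= iou_min]
        total = sum(iou[i, j] for i, j in pairs)
        if total > best_total + 1e-12 or (
            abs(total - best_total) <= 1e-12 and (best is None or pairs < best)
        ):
            best_total = total
            best = pairs
    assert best is not None
    if transpose:
        return [(j, i) for i, j in best]
    return list(best)


def consensus_assign(
    m1: Chopping,
    m2: Chopping,
    m3: Chopping,
    iou_min: float = IOU_MIN_DEFAULT,
    min_len: int = MIN_LEN_DEFAULT,
    chain_id: str = "",
    chain_residues: Iterable[int] | None = None,
    plddt: Mapping[int, float] | None = None,
) -> ConsensusResult:
    """Merge three per-method choppings into a consensus segmentation.

    Domain groups are built from the three pairwise matchings: a mutually
    consistent triple forms a high-confidence group, a remaining matched pair
    forms a medium group, and unmatched domains contribute only NDR.  The
    group's residue set is a per-residue vote: a residue is kept when at
    least two of a high group's three domains contain it, or both domains of
    a medium group.  Voted groups shorter than ``min_len`` residues are
    discarded into the NDR set.

    If transitivity fails (A~B and B~C but not A~C), the pair with the best
    IoU forms a medium group and the third domain is left unmatched.

    The result is invariant to the order of the three input choppings.
    """
    chops = [m1, m2, m3]
    sets = [c.residue_sets() for c in chops]
    names = [c.source or f"method{i + 1}" for i, c in enumerate(chops)]
    if len(set(names)) != 3:
        names = [f"{n}#{i}" if names.index(n) != i else n for i, n in enumerate(names)]

    universe: set[int] = set()
    for s in sets:
        for dom in s:
            universe |= dom
    if chain_residues is not None:
        chain_residues = frozenset(int(r) for r in chain_residues)
        if not universe <= chain_residues:
            extra = sorted(universe - chain_residues)
            raise ValueError(
                f"chopping residues {extra[:5]}... not in the supplied chain residue set"
            )
    else:
        chain_residues = frozenset(universe)

    # pairwise matchings, stored both ways for convenient lookup
    match: dict[tuple[int, int], dict[int, int]] = {}
    for a, b in itertools.combinations(range(3), 2):
        pairs = match_choppings(chops[a], chops[b], iou_min=iou_min)
        match[(a, b)] = dict(pairs)
        match[(b, a)] = {j: i for i, j in pairs}

    used = [set(), set(), set()]  # domain indices consumed per method
    groups: list[tuple[str, list[tuple[int, int]]]] = []  # (tier, [(method, idx)])

    # high groups: mutually consistent triples
    triples = []
    for i, j in match[(0, 1)].items():
        k = match[(0, 2)].get(i)
        if k is not None and match[(1, 2)].get(j) == k:
            triples.append((i, j, k))
    for i, j, k in triples:
        groups.append(("high", [(0, i), (1, j), (2, k)]))
        used[0].add(i)
        used[1].add(j)
        used[2].add(k)

    # medium groups from the remaining matched pairs, best IoU first;
    # tie-break on domain content so input order does not matter
    candidates = []
    for a, b in itertools.combinations(range(3), 2):
        for i, j in match[(a, b)].items():
            iou = len(sets[a][i] & sets[b][j]) / len(sets[a][i] | sets[b][j])
            key = tuple(sorted((_content_key(sets[a][i]), _content_key(sets[b][j]))))
            candidates.append((-iou, key, a, i, b, j))
    for _, _, a, i, b, j in sorted(candidates):
        if i in used[a] or j in used[b]:
            continue
        groups.append(("medium", [(a, i), (b, j)]))
        used[a].add(i)
        used[b].add(j)

    domains: list[ConsensusDomain] = []
    for tier, members in groups:
        member_sets = [sets[m][i] for m, i in members]
        need = 2
        votes: dict[int, int] = {}
        for s in member_sets:
            for r in s:
                votes[r] = votes.get(r, 0) + 1
        voted = frozenset(r for r, v in votes.items() if v >= need)
        if len(voted) < min_len:
            continue
        avg = (
            float(np.mean([plddt[r] for r in voted])) if plddt is not None else math.nan
        )
        domains.append(
            ConsensusDomain(
                residues=voted,
                confidence=tier,
                supporting_methods=frozenset(names[m] for m, _ in members),
                avg_plddt=avg,
            )
        )

    domains.sort(key=lambda d: min(d.residues))
    covered: set[int] = set()
    for d in domains:
        covered |= d.residues
    ndr = frozenset(chain_residues - covered)
    return ConsensusResult(chain_id=chain_id, domains=domains, ndr_residues=ndr)


def summarize_targets(results: Sequence[ConsensusResult]) -> dict:
    """Aggregate segmentation statistics over a set of chains.

    Reports counts and fractions of targets with zero, one or multiple
    consensus domains, the per-target NDR fraction, and the domain-count
    histogram.
    """
    if not results:
        raise ValueError("summarize_targets requires a nonempty result list")
    n = len(results)
    counts = [r.n_domains for r in results]
    hist: dict[int, int] = {}
    for c in counts:
        hist[c] = hist.get(c, 0) + 1
    n_none = sum(1 for c in counts if c == 0)
    n_single = sum(1 for c in counts if c == 1)
    n_multi = sum(1 for c in counts if c >= 2)
    return {
        "n_targets": n,
        "n_none": n_none,
        "n_single": n_single,
        "n_multi": n_multi,
        "frac_none": n_none / n,
        "frac_single": n_single / n,
        "frac_multi": n_multi / n,
        "ndr_fraction": [r.ndr_fraction() for r in results],
        "mean_ndr_fraction": float(np.mean([r.ndr_fraction() for r in results])),
        "domain_count_histogram": dict(sorted(hist.items())),
    }
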