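"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from tedkit.io_formats import Chopping, Segment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_chopping(rng: np.random.Generator, chain_len: int = 300,
                    max_domains: int = 5, source: str = "") -> Chopping:
    """Random valid chopping: up to max_domains disjoint contiguous domains
    with random gaps, occasionally a discontinuous domain."""
    n_dom = int(rng.integers(1, max_domains + 1))
    cuts = sorted(rng.choice(np.arange(2, chain_len), size=2 * n_dom, replace=False))
    domains: list[list[Segment]] = []
    for i in range(n_dom):
        start, end = int(cuts[2 * i]), int(cuts[2 * i + 1] - 1)
        if end < start:
            end = start
        domains.append([Segment(start, end)])
    # occasionally merge two adjacent domains into one discontinuous domain
    if n_dom >= 2 and rng.random() < 0.3:
        domains[-2] = domains[-2] + domains[-1]
        domains.pop()
    return Chopping(domains, source=source)


def oracle_match(sets_x, sets_y, iou_min: float):
    """Exhaustive maximum-total-IoU one-to-one matching (independent of the
    implementation): enumerates every injection, restricted to pairs with
    IoU >= iou_min, picking the lexicographically smallest optimal pair list."""
    nx, ny = len(sets_x), len(sets_y)

    def iou(a, b):
        return len(a & b) / len(a | b)

    best_pairs, best_total = [], -1.0
    small, large, flip = (nx, ny, False) if nx <= ny else (ny, nx, True)
    for perm in itertools.permutations(range(large), small):
        pairs = []
        total = 0.0
        for i, j in enumerate(perm):
            a, b = (sets_x[i], sets_y[j]) if not flip else (sets_x[j], sets_y[i])
            v = iou(a, b)
            if v >= iou_min:
                pairs.append((i, j) if not flip else (j, i))
                total += v
        pairs.sort()
        if total > best_total + 1e-12 or (
            abs(total - best_total) <= 1e-12 and pairs < best_pairs
        ):
            best_total, best_pairs = total, pairs
    return best_pairs, best_total


def oracle_consensus(chops, iou_min: float, min_len: int):
    """Brute-force consensus: exhaustive pairwise matchings, mutually
    consistent triples as high groups, remaining pairs greedily by IoU as
    medium groups, per-residue vote, min-length filter.

    Returns a set of (confidence, frozenset-of-residues) descriptors.
    """
    sets = [c.residue_sets() for c in chops]

    def iou(a, b):
        return len(a & b) / len(a | b)

    matches = {}
    for a, b in itertools.combinations(range(3), 2):
        pairs, _ = oracle_match(sets[a], sets[b], iou_min)
        matches[(a, b)] = dict(pairs)

    groups = []
    used = [set(), set(), set()]
    for i, j in matches[(0, 1)].items():
        k = matches[(0, 2)].get(i)
        if k is not None and matches[(1, 2)].get(j) == k:
            groups.append([(0, i), (1, j), (2, k)])
            used[0].add(i), used[1].add(j), used[2].add(k)
    cands = []
    for (a, b), m in matches.items():
        for i, j in m.items():
            key = tuple(sorted((tuple(sorted(sets[a][i])), tuple(sorted(sets[b][j])))))
            cands.append((-iou(sets[a][i], sets[b][j]), key, a, i, b, j))
    for _, _, a, i, b, j in sorted(cands):
        if i in used[a] or j in used[b]:
            continue
        groups.append([(a, i), (b, j)])
        used[a].add(i), used[b].add(j)

    out = set()
    for grp in groups:
        votes = {}
        for m, i in grp:
            for r in sets[m][i]:
                votes[r] = votes.get(r, 0) + 1
        voted = frozenset(r for r, v in votes.items() if v >= 2)
        if len(voted) >= min_len:
            conf = "high" if len(grp) == 3 else "medium"
            out.add((conf, voted))
    return out
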