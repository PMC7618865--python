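"""Seeded generators for every input the toolkit consumes.

Everything here is a pure function of its arguments and the seed, producing
bit-reproducible toy data: compact random-walk "domains" with 3.8 Å Cα
spacing, Cn-symmetric rings, block-structured PAE matrices, two-domain
ensembles with controlled orientation dispersion, and identical-sequence
clusters with or without a planted hinge motion.  Ground-truth metadata
always accompanies the data so downstream tests are self-grading.

The domains are geometric stand-ins, not physical folds: every statistic the
toolkit computes (IoU, RMSD, centres of mass, PAE block means, shift
periodicity) is geometry-level, so compact random walks exercise the code on
realistic length scales without modelling energetics or secondary structure.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np

from .classification import CathCode, DomainLabel
from .consensus import ConsensusDomain, ConsensusResult
from .geometry import Transform
from .io_formats import (
    Chopping,
    PAEMatrix,
    ResidueChain,
    Segment,
    format_chopping,
    write_pae,
    write_structure,
)

__all__ = [
    "make_chain",
    "make_cn_symmetric",
    "make_pae",
    "make_isp_ensemble",
    "make_redundant_cluster",
    "make_embeddings",
    "perturb_chopping",
    "make_pipeline_suite",
]

CA_STEP = 3.8  # Å between consecutive Cα atoms
LINKER_LEN = 5  # residues between consecutive domains

# plDDT ranges emulating AFDB models: confident cores, flexible linkers
PLDDT_DOMAIN = (90.0, 98.0)
PLDDT_LINKER = (30.0, 50.0)


def _compact_walk(n: int, rng: np.random.Generator, origin: np.ndarray) -> np.ndarray:
    """Random walk with fixed step length confined to a sphere whose radius
    follows globular Rg scaling, giving compact, domain-like blobs."""
    radius = 2.5 * n**0.38
    pts = np.empty((n, 3))
    pts[0] = origin
    center = origin.copy()
    for i in range(1, n):
        for _ in range(64):
            step = rng.normal(size=3)
            step *= CA_STEP / np.linalg.norm(step)
            cand = pts[i - 1] + step
            if np.linalg.norm(cand - center) <= radius:
                break
            # pull back toward the centre when the walk strays
            step = center - pts[i - 1]
            step *= CA_STEP / np.linalg.norm(step)
            cand = pts[i - 1] + step
        pts[i] = cand
    return pts


def make_chain(
    layout: Sequence[int],
    seed: int,
    chain_id: str = "A",
    linker_len: int = LINKER_LEN,
) -> tuple[ResidueChain, Chopping]:
    """Generate a chain of compact random-walk domains joined by linkers.

    Returns the chain plus the ground-truth chopping.  Domains get high
    plDDT (90-98), linkers low (30-50).  Layout ``[80, 120]`` yields truth
    ``"1-80,86-205"`` with the default 5-residue linker.
    """
    if any(n < 10 for n in layout):
        raise ValueError("domain lengths must be >= 10")
    rng = np.random.default_rng(seed)
    coords: list[np.ndarray] = []
    plddt: list[float] = []
    segments: list[Segment] = []
    pos = 1
    origin = np.zeros(3)
    for d, n in enumerate(layout):
        dom = _compact_walk(n, rng, origin)
        coords.append(dom)
        plddt.extend(rng.uniform(*PLDDT_DOMAIN, size=n))
        segments.append(Segment(pos, pos + n - 1))
        pos += n
        if d < len(layout) - 1 and linker_len:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            link = dom[-1] + np.outer(np.arange(1, linker_len + 1), direction * CA_STEP)
            coords.append(link)
            plddt.extend(rng.uniform(*PLDDT_LINKER, size=linker_len))
            pos += linker_len
            origin = link[-1] + direction * CA_STEP
    all_coords = np.vstack(coords)
    n_total = all_coords.shape[0]
    chain = ResidueChain(
        chain_id=chain_id,
        residue_numbers=tuple(range(1, n_total + 1)),
        ca_coords=all_coords,
        plddt=np.asarray(plddt),
    )
    truth = Chopping([[s] for s in segments], source="truth")
    return chain, truth


def make_cn_symmetric(
    n_copies: int,
    unit_len: int,
    radius: float = 16.0,
    seed: int = 0,
    chain_id: str = "SYM",
) -> ResidueChain:
    """A Cn-symmetric ring: one random-walk unit replicated by rotation of
    360/n about the z axis, serially concatenated."""
    if n_copies < 2:
        raise ValueError("need at least 2 copies")
    rng = np.random.default_rng(seed)
    unit = _compact_walk(unit_len, rng, np.zeros(3))
    unit = unit - unit.mean(axis=0) + np.array([radius, 0.0, 0.0])
    blocks = []
    for k in range(n_copies):
        theta = 2.0 * math.pi * k / n_copies
        c, s = math.cos(theta), math.sin(theta)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        blocks.append(unit @ rot.T)
    coords = np.vstack(blocks)
    n = coords.shape[0]
    return ResidueChain(
        chain_id=chain_id,
        residue_numbers=tuple(range(1, n + 1)),
        ca_coords=coords,
        plddt=np.full(n, 92.0),
    )


def make_pae(
    layout: Sequence[int],
    intra_level: float = 3.0,
    inter_level: float = 15.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    linker_len: int = 0,
    symmetric: bool = True,
) -> PAEMatrix:
    """Block-structured PAE matrix matching a domain layout.

    Within-domain entries sit at ``intra_level``, everything else (including
    linker rows/columns) at ``inter_level``, plus optional truncated Gaussian
    noise.  ``linker_len`` must match the chain generator's linker length
    when the matrix is paired with :func:`make_chain` output.
    """
    if intra_level < 0 or inter_level < 0:
        raise ValueError("PAE levels must be >= 0")
    block_id: list[int] = []
    for d, n in enumerate(layout):
        block_id.extend([d] * n)
        if d < len(layout) - 1 and linker_len:
            block_id.extend([-1] * linker_len)
    bid = np.asarray(block_id)
    same = (bid[:, None] == bid[None, :]) & (bid[:, None] >= 0)
    values = np.where(same, intra_level, inter_level).astype(float)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sigma, size=values.shape)
        if symmetric:
            noise = (noise + noise.T) / 2.0
        values = np.clip(values + noise, 0.0, None)
    np.fill_diagonal(values, np.minimum(values.diagonal(), 0.5))
    return PAEMatrix(values)


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _sample_direction(
    rng: np.random.Generator, mu: np.ndarray, kappa: float
) -> np.ndarray:
    """Direction on the unit sphere: uniform for kappa=0, von Mises-Fisher
    concentration kappa about mu otherwise, exact mu for kappa=inf."""
    if kappa == 0:
        return _unit_vector(rng)
    if math.isinf(kappa):
        return mu.copy()
    from scipy.stats import vonmises_fisher

    return vonmises_fisher(mu, kappa).rvs(1, random_state=rng)[0]


def _random_transform(rng: np.random.Generator, trans_scale: float = 30.0) -> Transform:
    from scipy.stats import special_ortho_group

    R = special_ortho_group.rvs(3, random_state=rng)
    t = rng.uniform(-trans_scale, trans_scale, size=3)
    return Transform(R, t)


CODE_A = CathCode(1, 10, 10, 10)
CODE_B = CathCode(3, 40, 50, 300)


def make_isp_ensemble(
    n_instances: int,
    kappa: float,
    seed: int = 0,
    dom_len: int = 40,
    dist_max: float = 8.0,
    min_pairs: int = 3,
) -> dict:
    """Ensemble of two-domain chains whose second domain is placed along a
    direction drawn with concentration ``kappa`` about a mean direction.

    kappa=0 gives uniformly random orientations, kappa=inf exact copies.
    Every instance passes the contact and PAE filters by construction.
    Returns chains (as ``extract_isps`` input tuples), per-domain coordinate
    lookups, and the true placement directions.
    """
    if n_instances < 1:
        raise ValueError("need at least one instance")
    rng = np.random.default_rng(seed)
    dom_a = _compact_walk(dom_len, rng, np.zeros(3))
    dom_a -= dom_a.mean(axis=0)
    dom_b0 = _compact_walk(dom_len, rng, np.zeros(3))
    dom_b0 -= dom_b0.mean(axis=0)
    mu = _unit_vector(rng)

    chains = []
    domain_coords: dict[str, np.ndarray] = {}
    directions = []
    pae = make_pae([dom_len, dom_len], intra_level=3.0, inter_level=6.0)
    for i in range(n_instances):
        d = _sample_direction(rng, mu, kappa)
        # slide the second domain inward along d until contact is satisfied
        sep = 2.6 * dom_len**0.38 * 2
        placed = None
        while sep > 1.0:
            cand = dom_b0 + sep * d
            dists = np.linalg.norm(
                dom_a[:, None, :] - cand[None, :, :], axis=2
            )
            if (dists <= dist_max).sum() >= min_pairs:
                placed = cand
                break
            sep -= 0.5
        if placed is None:
            placed = dom_b0 + 1.0 * d
        coords = np.vstack([dom_a, placed])
        tr = _random_transform(rng)
        coords = tr.apply(coords)
        chain_id = f"isp{i:04d}"
        chain = ResidueChain(
            chain_id=chain_id,
            residue_numbers=tuple(range(1, 2 * dom_len + 1)),
            ca_coords=coords,
            plddt=np.full(2 * dom_len, 92.0),
        )
        res_a = frozenset(range(1, dom_len + 1))
        res_b = frozenset(range(dom_len + 1, 2 * dom_len + 1))
        cons = ConsensusResult(
            chain_id=chain_id,
            domains=[
                ConsensusDomain(res_a, "high", frozenset({"m1", "m2", "m3"})),
                ConsensusDomain(res_b, "high", frozenset({"m1", "m2", "m3"})),
            ],
            ndr_residues=frozenset(),
        )
        id_a, id_b = f"{chain_id}_01", f"{chain_id}_02"
        labels = {
            id_a: DomainLabel(id_a, "H", CODE_A, "structure_search"),
            id_b: DomainLabel(id_b, "H", CODE_B, "structure_search"),
        }
        chains.append((chain, cons, labels, pae))
        domain_coords[id_a] = chain.coords_for(res_a)
        domain_coords[id_b] = chain.coords_for(res_b)
        directions.append(d)
    return {
        "chains": chains,
        "domain_coords": domain_coords,
        "directions": np.asarray(directions),
        "mean_direction": mu,
    }


def make_redundant_cluster(
    n_members: int,
    divergent: bool,
    seed: int = 0,
    layout: Sequence[int] = (60, 60),
    jitter_sigma: float = 0.05,
    hinge_degrees: float = 30.0,
) -> list[ResidueChain]:
    """Identical-sequence cluster: jittered copies of one two-domain chain.

    When ``divergent``, the last member's second domain is rotated about a
    hinge at the start of the linker, producing a maximum pairwise RMSD well
    above 1 Å; otherwise only sub-Å coordinate jitter is applied.
    """
    if n_members < 2:
        raise ValueError("need at least 2 members")
    rng = np.random.default_rng(seed)
    base, truth = make_chain(layout, seed=int(rng.integers(2**31)), chain_id="R")
    members = []
    for i in range(n_members):
        coords = base.ca_coords + rng.normal(0.0, jitter_sigma, size=base.ca_coords.shape)
        if divergent and i == n_members - 1:
            hinge_idx = layout[0]  # first linker residue
            pivot = coords[hinge_idx]
            axis = _unit_vector(rng)
            theta = math.radians(hinge_degrees)
            K = np.array(
                [
                    [0, -axis[2], axis[1]],
                    [axis[2], 0, -axis[0]],
                    [-axis[1], axis[0], 0],
                ]
            )
            R = np.eye(3) + math.sin(theta) * K + (1 - math.cos(theta)) * (K @ K)
            coords[hinge_idx:] = (coords[hinge_idx:] - pivot) @ R.T + pivot
        members.append(
            ResidueChain(
                chain_id=f"R{i:02d}",
                residue_numbers=base.residue_numbers,
                ca_coords=coords,
                plddt=base.plddt,
            )
        )
    return members


def make_embeddings(
    n: int,
    dim: int = 16,
    seed: int = 0,
    prefix: str = "ref",
    spread: float = 1.0,
    offset: float = 0.0,
) -> list:
    """Gaussian embedding vectors, optionally displaced from the origin by
    ``offset`` along the first axis (to plant outliers)."""
    from .novelty import EmbeddingVector

    rng = np.random.default_rng(seed)
    vecs = rng.normal(0.0, spread, size=(n, dim))
    vecs[:, 0] += offset
    return [EmbeddingVector(f"{prefix}{i:04d}", vecs[i]) for i in range(n)]


def perturb_chopping(
    truth: Chopping,
    rng: np.random.Generator,
    max_jitter: int = 3,
    source: str = "",
    max_residue: int | None = None,
) -> Chopping:
    """Jitter each segment boundary by up to ``max_jitter`` residues while
    keeping domains disjoint and ordered — emulates a parser that agrees with
    the truth to within a few residues."""
    doms = []
    prev_end = 0
    flat = [(di, seg) for di, segs in enumerate(truth.domains) for seg in segs]
    new_segs: dict[int, list[Segment]] = {di: [] for di, _ in flat}
    for idx, (di, seg) in enumerate(flat):
        start = seg.start + int(rng.integers(-max_jitter, max_jitter + 1))
        end = seg.end + int(rng.integers(-max_jitter, max_jitter + 1))
        start = max(start, prev_end + 1)
        end = max(end, start)
        if max_residue is not None:
            end = min(end, max_residue)
            start = min(start, end)
        if idx + 1 < len(flat):
            nxt = flat[idx + 1][1]
            end = min(end, nxt.start - 1)
        prev_end = end
        new_segs[di].append(Segment(start, end))
    for di in sorted(new_segs):
        doms.append(new_segs[di])
    return Chopping(doms, source=source)


# CATH superfamily codes used when labelling pipeline-suite domains
_CODE_POOL = [
    "1.10.10.10",
    "1.10.510.10",
    "2.40.30.200",
    "2.60.40.10",
    "3.40.50.300",
    "3.40.50.720",
]


def make_pipeline_suite(
    out_dir: str | Path,
    n_chains: int = 20,
    seed: int = 0,
    frac_single: float = 0.45,
    frac_none: float = 0.1,
    frac_unlabelled: float = 0.3,
) -> dict:
    """Write a complete pipeline input directory of synthetic chains.

    Chains are a mix of single- and multi-domain targets (plus a fraction
    whose three parsers disagree so completely that no consensus emerges);
    a fraction of domains is left unlabelled, with embedding vectors so the
    novelty stage has work to do.  Returns the ground-truth bookkeeping.
    """
    out = Path(out_dir)
    (out / "chains").mkdir(parents=True, exist_ok=True)
    (out / "pae").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    chop_rows = []
    hit_rows = []
    cluster_rows = []
    emb_rows: dict[str, np.ndarray] = {}
    truth = {"n_single": 0, "n_multi": 0, "n_none": 0, "labelled": [], "unlabelled": []}

    for ci in range(n_chains):
        chain_id = f"T{ci:03d}"
        u = rng.random()
        if u < frac_none:
            layout = [70]
            kind = "none"
        elif u < frac_none + frac_single:
            layout = [int(rng.integers(60, 140))]
            kind = "single"
        else:
            k = int(rng.integers(2, 4))
            layout = [int(rng.integers(50, 100)) for _ in range(k)]
            kind = "multi"
        chain, truth_chop = make_chain(layout, seed=int(rng.integers(2**31)), chain_id=chain_id)
        write_structure(chain, out / "chains" / f"{chain_id}.pdb")
        pae = make_pae(
            layout,
            intra_level=3.0,
            inter_level=6.0,
            noise_sigma=0.3,
            seed=int(rng.integers(2**31)),
            linker_len=LINKER_LEN,
        )
        write_pae(pae, out / "pae" / f"{chain_id}.json")

        if kind == "none":
            # three mutually disagreeing single-domain parsers: no consensus
            n = len(chain)
            third = n // 3
            chops = [
                Chopping([[Segment(1, third)]], source="m1"),
                Chopping([[Segment(third + 1, 2 * third)]], source="m2"),
                Chopping([[Segment(2 * third + 1, n)]], source="m3"),
            ]
            truth["n_none"] += 1
        else:
            chops = [
                perturb_chopping(truth_chop, rng, source=m, max_residue=len(chain))
                for m in ("m1", "m2", "m3")
            ]
            truth["n_single" if kind == "single" else "n_multi"] += 1
        for ch in chops:
            chop_rows.append((chain_id, ch.source, format_chopping(ch)))

        if kind != "none":
            for di in range(len(layout)):
                did = f"{chain_id}_{di + 1:02d}"
                cluster_rows.append((f"cl_{did}", did))
                if rng.random() < frac_unlabelled:
                    truth["unlabelled"].append(did)
                    emb_rows[did] = rng.normal(0.0, 1.0, size=16) + np.array(
                        [6.0] + [0.0] * 15
                    ) * (rng.random() < 0.5)
                else:
                    code = _CODE_POOL[int(rng.integers(len(_CODE_POOL)))]
                    hit_rows.append((did, code, round(float(rng.uniform(0.7, 0.99)), 4), "structure_search"))
                    truth["labelled"].append(did)

    import pandas as pd

    pd.DataFrame(chop_rows, columns=["chain_id", "method", "chopping"]).to_csv(
        out / "choppings.tsv", sep="\t", index=False
    )
    pd.DataFrame(hit_rows, columns=["query_id", "target_code", "score", "kind"]).to_csv(
        out / "hits.tsv", sep="\t", index=False
    )
    pd.DataFrame(cluster_rows, columns=["cluster_id", "member_domain_id"]).to_csv(
        out / "clusters.tsv", sep="\t", index=False
    )
    from .io_formats import write_embeddings_tsv

    refs = make_embeddings(40, dim=16, seed=seed + 1)
    write_embeddings_tsv({e.domain_id: e.vector for e in refs}, out / "refs.tsv")
    write_embeddings_tsv(emb_rows, out / "embeddings.tsv")
    return truth
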