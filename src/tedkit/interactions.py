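"""Interacting domain pairs and the CIO orientation-conservation statistic.

Within a chain, two consensus domains that carry superfamily (H) labels form
an interacting-domain instance when they are in physical contact and the
inter-domain predicted aligned error is favourable.  Instances sharing the
same unordered pair of superfamily codes aggregate into an Interacting
Superfamily Pair (ISP).

For each ISP, the Conservation of Interaction Orientation (CIO) measures how
consistently the two domains adopt the same relative geometry across
instances: each instance's reference domain is superposed onto a designated
master, the companion ("tag-along") domain is carried along by the same rigid
motion, and the unit vectors between the two domain centres of mass are
averaged.  CIO is the mean resultant length of those unit vectors — 1 for a
perfectly conserved orientation, near 0 for isotropic orientations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .classification import CathCode, DomainLabel
from .consensus import ConsensusResult
from .geometry import center_of_mass, kabsch
from .io_formats import PAEMatrix, ResidueChain

__all__ = [
    "ISPInstance",
    "ISPSummary",
    "CIOResult",
    "isp_key",
    "detect_contact",
    "inter_domain_pae",
    "extract_isps",
    "summarize_isps",
    "cio",
    "enrichment",
    "classify_hub",
    "compare_isp_sets",
    "export_interaction_graph",
]

DIST_MAX_DEFAULT = 8.0
MIN_PAIRS_DEFAULT = 3
PAE_MAX_DEFAULT = 10.0


def isp_key(code_a: CathCode, code_b: CathCode) -> tuple[str, str]:
    """Canonical unordered key for a superfamily pair."""
    a, b = str(code_a), str(code_b)
    return (a, b) if a <= b else (b, a)


@dataclass
class ISPInstance:
    """One observed pair of contacting, H-labelled domains in one chain."""

    chain_id: str
    domain_a_id: str
    domain_b_id: str
    code_a: CathCode
    code_b: CathCode
    min_ca_dist: float
    inter_pae: float
    com_a: np.ndarray
    com_b: np.ndarray

    @property
    def key(self) -> tuple[str, str]:
        return isp_key(self.code_a, self.code_b)

    @property
    def homotypic(self) -> bool:
        return str(self.code_a) == str(self.code_b)

    @property
    def instance_id(self) -> str:
        return f"{self.chain_id}|{self.domain_a_id}|{self.domain_b_id}"


@dataclass
class ISPSummary:
    pair: tuple[str, str]
    n_instances: int
    homotypic: bool
    cio: float | None = None


@dataclass
class CIOResult:
    pair: tuple[str, str]
    n: int
    master_instance: str
    unit_vectors: list[np.ndarray] = field(default_factory=list)
    cio: float = 0.0


def detect_contact(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    dist_max: float = DIST_MAX_DEFAULT,
    min_pairs: int = MIN_PAIRS_DEFAULT,
) -> tuple[bool, float]:
    """Cα-contact test between two domains.

    Contact requires at least ``min_pairs`` Cα–Cα pairs within ``dist_max``
    Å.  Also returns the minimum inter-domain Cα distance.
    """
    coords_a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    coords_b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if coords_a.shape[0] == 0 or coords_b.shape[0] == 0:
        raise ValueError("detect_contact requires nonempty coordinate sets")
    d = cdist(coords_a, coords_b)
    n_close = int((d <= dist_max).sum())
    return n_close >= min_pairs, float(d.min())


def inter_domain_pae(
    pae: PAEMatrix,
    res_a: Iterable[int],
    res_b: Iterable[int],
) -> float:
    """Symmetrised mean PAE over the two inter-domain blocks (a→b and b→a)."""
    res_a, res_b = set(res_a), set(res_b)
    if res_a & res_b:
        raise ValueError("inter_domain_pae: residue sets overlap")
    ia = pae.indices_for(res_a)
    ib = pae.indices_for(res_b)
    block_ab = pae.values[np.ix_(ia, ib)]
    block_ba = pae.values[np.ix_(ib, ia)]
    return float((block_ab.mean() + block_ba.mean()) / 2.0)


def extract_isps(
    chains: Sequence[
        tuple[ResidueChain, ConsensusResult, Mapping[str, DomainLabel], PAEMatrix | None]
    ],
    dist_max: float = DIST_MAX_DEFAULT,
    min_pairs: int = MIN_PAIRS_DEFAULT,
    pae_max: float | None = PAE_MAX_DEFAULT,
) -> list[ISPInstance]:
    """Scan chains for interacting H-labelled domain pairs.

    For every unordered pair of consensus domains on a chain, the pair
    becomes an instance when both domains carry H-level labels, the domains
    are in contact, and (when a PAE filter is requested) the symmetrised
    inter-domain PAE is at most ``pae_max``.
    """
    instances: list[ISPInstance] = []
    for chain, cons, labels, pae in chains:
        if pae_max is not None and pae is None:
            raise ValueError(
                f"chain {chain.chain_id}: PAE filter requested but no PAE matrix given"
            )
        doms = []
        for idx, dom in enumerate(cons.domains):
            did = f"{cons.chain_id}_{idx + 1:02d}"
            lab = labels.get(did)
            if lab is None or lab.level != "H":
                continue
            doms.append((did, dom, lab))
        for i in range(len(doms)):
            for j in range(i + 1, len(doms)):
                did_a, dom_a, lab_a = doms[i]
                did_b, dom_b, lab_b = doms[j]
                ca = chain.coords_for(dom_a.residues)
                cb = chain.coords_for(dom_b.residues)
                in_contact, min_d = detect_contact(ca, cb, dist_max, min_pairs)
                if not in_contact:
                    continue
                if pae_max is not None:
                    ip = inter_domain_pae(pae, dom_a.residues, dom_b.residues)
                    if ip > pae_max:
                        continue
                else:
                    ip = math.nan
                instances.append(
                    ISPInstance(
                        chain_id=cons.chain_id,
                        domain_a_id=did_a,
                        domain_b_id=did_b,
                        code_a=lab_a.code,
                        code_b=lab_b.code,
                        min_ca_dist=min_d,
                        inter_pae=ip,
                        com_a=center_of_mass(ca),
                        com_b=center_of_mass(cb),
                    )
                )
    return instances


def summarize_isps(
    instances: Sequence[ISPInstance],
    cio_by_pair: Mapping[tuple[str, str], float] | None = None,
) -> list[ISPSummary]:
    """Group instances into ISPs with instance counts (sorted by key)."""
    by_key: dict[tuple[str, str], list[ISPInstance]] = {}
    for inst in instances:
        by_key.setdefault(inst.key, []).append(inst)
    out = []
    for key in sorted(by_key):
        insts = by_key[key]
        out.append(
            ISPSummary(
                pair=key,
                n_instances=len(insts),
                homotypic=key[0] == key[1],
                cio=None if cio_by_pair is None else cio_by_pair.get(key),
            )
        )
    return out


def _reference_first(inst: ISPInstance, coords: Mapping[str, np.ndarray]) -> bool:
    """True when domain A is the instance's reference domain.

    The reference is the domain whose superfamily code sorts first; for
    homotypic pairs, the domain with more residues, then the lexicographically
    smaller domain id.
    """
    a, b = str(inst.code_a), str(inst.code_b)
    if a != b:
        return a < b
    na = coords[inst.domain_a_id].shape[0]
    nb = coords[inst.domain_b_id].shape[0]
    if na != nb:
        return na > nb
    return inst.domain_a_id <= inst.domain_b_id


def cio(
    instances: Sequence[ISPInstance],
    domain_coords: Mapping[str, np.ndarray],
    min_len_fraction: float = 0.5,
) -> CIOResult:
    """Conservation of Interaction Orientation for one ISP.

    The master is the instance whose reference domain has the most residues
    (ties: lexicographically smallest instance id).  Each instance's
    reference domain is Kabsch-superposed onto the master reference (after
    trimming both to their common length prefix); the same rigid motion is
    applied to the tag-along domain, and the unit vector from the reference
    to the tag-along centre of mass is recorded.  CIO is the mean resultant
    length of these unit vectors.  Instances whose reference shares less
    than ``min_len_fraction`` of the master's length are dropped with a
    warning.
    """
    if len(instances) < 2:
        raise ValueError("cio requires at least 2 instances")
    keys = {inst.key for inst in instances}
    if len(keys) != 1:
        raise ValueError(f"cio instances span multiple ISP keys: {sorted(keys)}")

    prepared = []  # (inst, ref_coords, tag_coords)
    for inst in instances:
        if _reference_first(inst, domain_coords):
            ref_id, tag_id = inst.domain_a_id, inst.domain_b_id
        else:
            ref_id, tag_id = inst.domain_b_id, inst.domain_a_id
        prepared.append((inst, domain_coords[ref_id], domain_coords[tag_id]))

    master = min(prepared, key=lambda p: (-p[1].shape[0], p[0].instance_id))
    master_inst, master_ref, _ = master

    vectors: list[np.ndarray] = []
    n_used = 0
    for inst, ref, tag in prepared:
        m = min(ref.shape[0], master_ref.shape[0])
        if m < min_len_fraction * master_ref.shape[0]:
            warnings.warn(
                f"cio: instance {inst.instance_id} reference too short "
                f"({ref.shape[0]} vs master {master_ref.shape[0]}); dropped"
            )
            continue
        try:
            tr, _ = kabsch(ref[:m], master_ref[:m])
        except ValueError as exc:
            warnings.warn(f"cio: alignment failed for {inst.instance_id}: {exc}")
            continue
        ref_t = tr.apply(ref)
        tag_t = tr.apply(tag)
        v = center_of_mass(tag_t) - center_of_mass(ref_t)
        norm = np.linalg.norm(v)
        if norm == 0:
            warnings.warn(f"cio: coincident domain centres for {inst.instance_id}")
            continue
        vectors.append(v / norm)
        n_used += 1
    if n_used < 2:
        raise ValueError("cio: fewer than 2 instances survived alignment")
    resultant = np.sum(vectors, axis=0)
    return CIOResult(
        pair=master_inst.key,
        n=n_used,
        master_instance=master_inst.instance_id,
        unit_vectors=vectors,
        cio=float(np.linalg.norm(resultant) / n_used),
    )


def enrichment(n_ted: int, n_cath: int) -> float:
    """log2 fold change of instance counts between the two datasets."""
    if n_ted < 1 or n_cath < 1:
        raise ValueError("enrichment requires both counts >= 1 (pair must be common)")
    return float(math.log2(n_ted / n_cath))


def classify_hub(n_partners: int) -> str:
    """Hub class of a superfamily by its number of interaction partners:
    small (<4), medium (4-7), large (>=8)."""
    if n_partners < 0:
        raise ValueError("partner count cannot be negative")
    if n_partners < 4:
        return "small"
    if n_partners <= 7:
        return "medium"
    return "large"


def compare_isp_sets(
    set_a: Iterable[tuple[str, str]],
    set_b: Iterable[tuple[str, str]],
) -> dict:
    """Partition two ISP key sets into common / only-A / only-B.

    Keys are unordered pairs: (x, y) and (y, x) are the same ISP.
    """
    ka = {tuple(sorted(k)) for k in set_a}
    kb = {tuple(sorted(k)) for k in set_b}
    common = ka & kb
    only_a = ka - kb
    only_b = kb - ka
    return {
        "common": common,
        "only_a": only_a,
        "only_b": only_b,
        "n_common": len(common),
        "n_only_a": len(only_a),
        "n_only_b": len(only_b),
    }


def export_interaction_graph(summaries: Sequence[ISPSummary]):
    """Build the superfamily interaction graph and its deterministic export.

    Nodes are superfamily codes, edges are ISPs (self-loops for homotypic
    pairs).  Returns the graph plus a sorted edge list and per-node partner
    counts with hub classes, ready for TSV serialisation.
    """
    import networkx as nx

    g = nx.Graph()
    for s in summaries:
        a, b = s.pair
        g.add_edge(a, b, n_instances=s.n_instances, cio=s.cio)
    edges = [
        {
            "code_a": a,
            "code_b": b,
            "n_instances": g.edges[a, b]["n_instances"],
            "cio": g.edges[a, b]["cio"],
        }
        for a, b in sorted(tuple(sorted(e)) for e in g.edges)
    ]
    nodes = []
    for node in sorted(g.nodes):
        # a homotypic self-loop counts as one partner (the superfamily itself)
        partners = len(set(g.neighbors(node)))
        nodes.append(
            {
                "code": node,
                "n_partners": partners,
                "hub_class": classify_hub(partners),
            }
        )
    return g, edges, nodes
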