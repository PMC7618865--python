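"""End-to-end orchestration: consensus → classification → partition →
interactions on labelled domains / novelty triage on unlabelled ones.

The pipeline streams over a directory of inputs in a single process.  Every
stage is a pure function of (inputs, config): rerunning with the same inputs
and configuration produces byte-identical outputs, and the run summary
carries a hash of the configuration for provenance.

Expected input layout::

    input_dir/
      chains/<chain_id>.pdb      one single-chain PDB per target
      pae/<chain_id>.json        AFDB-dialect PAE (optional per chain)
      choppings.tsv              chain_id, method, chopping
      hits.tsv                   query_id, target_code, score, kind
      hmm.tsv                    query_id, hmm_code, evalue   (optional)
      clusters.tsv               cluster_id, member_domain_id (optional)
      embeddings.tsv             domain_id + embedding columns (optional)
      refs.tsv                   reference embeddings for novelty (optional)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classification, consensus, geometry, interactions, novelty
from .io_formats import (
    ResidueChain,
    parse_chopping,
    read_clusters_tsv,
    read_embeddings_tsv,
    read_hits_tsv,
    read_hmm_tsv,
    read_pae,
    read_structure,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A named per-stage failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with their defaults."""

    input_dir: str = "."
    output_dir: str = "ted_out"
    iou_min: float = consensus.IOU_MIN_DEFAULT
    min_len: int = consensus.MIN_LEN_DEFAULT
    score_min: float = classification.SCORE_MIN_DEFAULT
    dist_max: float = interactions.DIST_MAX_DEFAULT
    min_pairs: int = interactions.MIN_PAIRS_DEFAULT
    pae_max: float = interactions.PAE_MAX_DEFAULT
    k: int = novelty.K_DEFAULT
    z_min: float = novelty.Z_MIN_DEFAULT
    glob_max: float = novelty.GLOB_MAX_DEFAULT
    min_shift: int = 8
    dist_cutoff: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0.0 < self.iou_min <= 1.0, "iou_min in (0, 1]"),
            (self.min_len >= 1, "min_len >= 1"),
            (0.0 <= self.score_min <= 1.0, "score_min in [0, 1]"),
            (self.dist_max > 0, "dist_max > 0"),
            (self.min_pairs >= 1, "min_pairs >= 1"),
            (self.pae_max > 0, "pae_max > 0"),
            (self.k >= 1, "k >= 1"),
            (self.glob_max > 0, "glob_max > 0"),
            (self.min_shift >= 1, "min_shift >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"config violates {msg}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a flat ``key = value`` config file (# comments allowed)."""
        values: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            values[key] = val
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in values:
                kwargs[f.name] = _coerce(values.pop(f.name), f.default)
        if values:
            raise ValueError(f"unknown config keys: {sorted(values)}")
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _coerce(raw: str, default):
    if isinstance(default, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    return raw


def _fmt(x: float) -> str:
    return "nan" if isinstance(x, float) and math.isnan(x) else f"{x:.4f}"


def _domain_subchain(chain: ResidueChain, residues: frozenset[int]) -> ResidueChain:
    nums = tuple(sorted(residues))
    return ResidueChain(
        chain_id=chain.chain_id,
        residue_numbers=nums,
        ca_coords=chain.coords_for(residues),
        plddt=chain.plddt_for(residues),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full stage sequence over an input directory.

    Emits per-stage TSVs plus ``summary.json`` into ``config.output_dir``
    and returns the summary.  On any stage failure the partial outputs are
    removed and a :class:`PipelineError` naming the stage is raised.
    """
    inp = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, inp, out, written)
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as exc:  # pragma: no cover - defensive
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError("internal", str(exc)) from exc


def _run(config: RunConfig, inp: Path, out: Path, written: list[Path]) -> dict:
    chains_dir = inp / "chains"
    pdbs = sorted(chains_dir.glob("*.pdb")) if chains_dir.is_dir() else []
    if not pdbs:
        raise PipelineError("inputs", f"no chain PDBs found under {chains_dir}")
    chop_path = inp / "choppings.tsv"
    if not chop_path.is_file():
        raise PipelineError("inputs", f"missing {chop_path}")
    chop_df = pd.read_csv(chop_path, sep="\t", dtype=str)

    # --- stage 1: consensus ------------------------------------------------
    chains: dict[str, ResidueChain] = {}
    results: dict[str, consensus.ConsensusResult] = {}
    cons_rows = []
    for pdb in pdbs:
        chain = read_structure(pdb)
        chain_id = pdb.stem
        sub = chop_df[chop_df["chain_id"] == chain_id]
        if len(sub) != 3:
            raise PipelineError(
                "consensus", f"chain {chain_id}: expected 3 choppings, found {len(sub)}"
            )
        chops = [
            parse_chopping(row.chopping, source=row.method)
            for row in sub.itertuples()
        ]
        plddt_map = dict(zip(chain.residue_numbers, chain.plddt))
        res = consensus.consensus_assign(
            *chops,
            iou_min=config.iou_min,
            min_len=config.min_len,
            chain_id=chain_id,
            chain_residues=chain.residue_set,
            plddt=plddt_map,
        )
        chains[chain_id] = chain
        results[chain_id] = res
        for di, dom in enumerate(res.domains):
            cons_rows.append(
                {
                    "chain_id": chain_id,
                    "domain_idx": di + 1,
                    "chopping": dom.chopping_string(),
                    "confidence": dom.confidence,
                    "n_methods": dom.n_methods,
                    "avg_plddt": _fmt(dom.avg_plddt),
                    "ndr_fraction": _fmt(res.ndr_fraction()),
                }
            )
    _write_tsv(out / "consensus.tsv", cons_rows, written,
               ["chain_id", "domain_idx", "chopping", "confidence", "n_methods",
                "avg_plddt", "ndr_fraction"])

    # --- stage 2: classification ------------------------------------------
    hits_by_query: dict[str, list[dict]] = {}
    hits_path = inp / "hits.tsv"
    if hits_path.is_file():
        for row in read_hits_tsv(hits_path).to_dict("records"):
            hits_by_query.setdefault(str(row["query_id"]), []).append(row)
    hmm_by_query: dict[str, classification.CathCode] = {}
    hmm_path = inp / "hmm.tsv"
    if hmm_path.is_file():
        for row in read_hmm_tsv(hmm_path).to_dict("records"):
            hmm_by_query[str(row["query_id"])] = classification.CathCode.parse(
                str(row["hmm_code"])
            )

    labels: dict[str, classification.DomainLabel] = {}
    label_rows = []
    for chain_id in sorted(results):
        for di, dom in enumerate(results[chain_id].domains):
            did = f"{chain_id}_{di + 1:02d}"
            lab = classification.assign_label(
                did, hits_by_query.get(did, []), score_min=config.score_min
            )
            labels[did] = lab
            hmm_code = hmm_by_query.get(did)
            verdict = (
                classification.validate_with_hmm(lab, hmm_code)
                if lab.labelled
                else ""
            )
            label_rows.append(
                {
                    "domain_id": did,
                    "level": lab.level,
                    "code": "" if lab.code is None else str(lab.code),
                    "source": lab.source,
                    "hmm_verdict": verdict,
                }
            )
    _write_tsv(out / "labels.tsv", label_rows, written,
               ["domain_id", "level", "code", "source", "hmm_verdict"])

    # --- stage 3: cluster partition ---------------------------------------
    clusters_path = inp / "clusters.tsv"
    if clusters_path.is_file():
        cdf = read_clusters_tsv(clusters_path)
        grouped = cdf.groupby("cluster_id")["member_domain_id"].apply(list)
        clusters = [
            classification.ClusterRecord(cid, members)
            for cid, members in sorted(grouped.items())
        ]
        known = [
            c
            for c in clusters
            if all(m in labels for m in c.member_domain_ids)
        ]
        partition = classification.propagate_cluster_labels(known, labels)
    else:
        clusters = [
            classification.ClusterRecord(f"cl_{did}", [did]) for did in sorted(labels)
        ]
        partition = classification.propagate_cluster_labels(clusters, labels)

    # --- stage 4: interactions on labelled chains -------------------------
    isp_inputs = []
    domain_coords: dict[str, np.ndarray] = {}
    for chain_id in sorted(results):
        chain, res = chains[chain_id], results[chain_id]
        pae_path = inp / "pae" / f"{chain_id}.json"
        pae = read_pae(pae_path) if pae_path.is_file() else None
        isp_inputs.append((chain, res, labels, pae))
        for di, dom in enumerate(res.domains):
            domain_coords[f"{chain_id}_{di + 1:02d}"] = chain.coords_for(dom.residues)
    with_pae = [t for t in isp_inputs if t[3] is not None]
    without_pae = [t for t in isp_inputs if t[3] is None]
    instances = interactions.extract_isps(
        with_pae,
        dist_max=config.dist_max,
        min_pairs=config.min_pairs,
        pae_max=config.pae_max,
    ) + interactions.extract_isps(
        without_pae,
        dist_max=config.dist_max,
        min_pairs=config.min_pairs,
        pae_max=None,
    )
    inst_rows = [
        {
            "chain_id": i.chain_id,
            "domain_a": i.domain_a_id,
            "domain_b": i.domain_b_id,
            "code_a": str(i.code_a),
            "code_b": str(i.code_b),
            "min_ca_dist": _fmt(i.min_ca_dist),
            "inter_pae": _fmt(i.inter_pae),
        }
        for i in sorted(instances, key=lambda x: x.instance_id)
    ]
    _write_tsv(out / "isp_instances.tsv", inst_rows, written,
               ["chain_id", "domain_a", "domain_b", "code_a", "code_b",
                "min_ca_dist", "inter_pae"])

    by_key: dict[tuple[str, str], list[interactions.ISPInstance]] = {}
    for i in instances:
        by_key.setdefault(i.key, []).append(i)
    cio_by_pair: dict[tuple[str, str], float] = {}
    for key in sorted(by_key):
        if len(by_key[key]) >= 2:
            cio_by_pair[key] = interactions.cio(by_key[key], domain_coords).cio
    summaries = interactions.summarize_isps(instances, cio_by_pair)
    _write_tsv(out / "isp_summary.tsv",
               [
                   {
                       "code_a": s.pair[0],
                       "code_b": s.pair[1],
                       "n_instances": s.n_instances,
                       "homotypic": int(s.homotypic),
                       "cio": "" if s.cio is None else _fmt(s.cio),
                   }
                   for s in summaries
               ],
               written,
               ["code_a", "code_b", "n_instances", "homotypic", "cio"])
    _, edges, nodes = interactions.export_interaction_graph(summaries)
    _write_tsv(out / "graph_edges.tsv",
               [
                   {
                       "code_a": e["code_a"],
                       "code_b": e["code_b"],
                       "n_instances": e["n_instances"],
                       "cio": "" if e["cio"] is None else _fmt(e["cio"]),
                   }
                   for e in edges
               ],
               written, ["code_a", "code_b", "n_instances", "cio"])
    _write_tsv(out / "graph_nodes.tsv", nodes, written,
               ["code", "n_partners", "hub_class"])

    # --- stage 5: novelty triage on unlabelled domains --------------------
    novelty_rows = []
    triage_counts = {"discarded_poor_quality": 0, "repeat_category": 0, "novel": 0}
    refs_path = inp / "refs.tsv"
    emb_path = inp / "embeddings.tsv"
    if refs_path.is_file() and emb_path.is_file():
        ref_vecs = [
            novelty.EmbeddingVector(d, v)
            for d, v in sorted(read_embeddings_tsv(refs_path).items())
        ]
        emb = read_embeddings_tsv(emb_path)
        reps = []
        for did in sorted(labels):
            if labels[did].labelled or did not in emb:
                continue
            chain_id = did.rsplit("_", 1)[0]
            di = int(did.rsplit("_", 1)[1]) - 1
            dom = results[chain_id].domains[di]
            sub = _domain_subchain(chains[chain_id], dom.residues)
            if len(sub) < 2 * config.min_shift:
                continue
            sym = geometry.symmetry_scan(sub, config.min_shift, config.dist_cutoff)
            glob = geometry.globularity(sub, min_len=min(config.min_len, len(sub)))
            reps.append(
                {
                    "domain_id": did,
                    "symmetry": sym,
                    "globularity": glob,
                    "embedding": novelty.EmbeddingVector(did, emb[did]),
                }
            )
        if reps:
            routing = novelty.triage_unlabelled(
                reps, ref_vecs, k=config.k, z_min=config.z_min, glob_max=config.glob_max
            )
            triage_counts["discarded_poor_quality"] = len(routing["discarded_poor_quality"])
            triage_counts["repeat_category"] = len(routing["repeat_category"])
            triage_counts["novel"] = len(routing["novel_candidates"])
            for did in routing["discarded_poor_quality"]:
                novelty_rows.append({"domain_id": did, "route": "discarded_poor_quality",
                                     "novelty_score": "", "knn_dist": ""})
            for did in routing["repeat_category"]:
                novelty_rows.append({"domain_id": did, "route": "repeat_category",
                                     "novelty_score": "", "knn_dist": ""})
            for ns in routing["novel_candidates"]:
                novelty_rows.append({"domain_id": ns.domain_id, "route": "novel_candidate",
                                     "novelty_score": _fmt(ns.score),
                                     "knn_dist": _fmt(ns.knn_dist)})
    novelty_rows.sort(key=lambda r: r["domain_id"])
    _write_tsv(out / "novelty.tsv", novelty_rows, written,
               ["domain_id", "route", "novelty_score", "knn_dist"])

    # --- summary -----------------------------------------------------------
    seg_summary = consensus.summarize_targets(list(results.values()))
    seg_summary.pop("ndr_fraction")
    summary = {
        "config_digest": config.digest(),
        "config": dataclasses.asdict(config),
        "n_chains": len(results),
        "segmentation": seg_summary,
        "n_domains": sum(r.n_domains for r in results.values()),
        "n_labelled_domains": sum(1 for l in labels.values() if l.labelled),
        "n_unlabelled_domains": sum(1 for l in labels.values() if not l.labelled),
        "clusters": {
            "n_labelled": partition["n_labelled"],
            "n_unlabelled": partition["n_unlabelled"],
        },
        "n_isp_instances": len(instances),
        "n_isps": len(summaries),
        "novelty": triage_counts,
    }
    path = out / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(path)
    return summary


def _write_tsv(path: Path, rows: list[dict], written: list[Path], columns: list[str]) -> None:
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False)
    written.append(path)
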