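"""Readers, writers and core records for every external representation the
toolkit touches.

Structures are single-chain PDB files following the AlphaFold Database (AFDB)
convention: one model, Cα records present for every residue and the per-residue
plDDT confidence stored in the B-factor column.  Predicted aligned error (PAE)
comes as the AFDB JSON dialect.  Domain boundaries travel as "chopping"
strings: comma-separated domains, each an underscore-separated list of
inclusive 1-based residue ranges (``"1-50_120-180,51-119"`` is a discontinuous
first domain plus a contiguous second one).

All residue numbering is 1-based and inclusive; interval arithmetic is done on
explicit residue-number sets so numbering gaps in the input are safe.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "Chopping",
    "ResidueChain",
    "PAEMatrix",
    "parse_chopping",
    "format_chopping",
    "segments_from_residues",
    "read_structure",
    "write_structure",
    "read_pae",
    "write_pae",
    "read_hits_tsv",
    "read_hmm_tsv",
    "read_clusters_tsv",
    "read_embeddings_tsv",
    "write_embeddings_tsv",
]


class ChoppingError(ValueError):
    """Malformed or self-inconsistent chopping string."""


@dataclass(frozen=True, order=True)
class Segment:
    """A contiguous residue range, 1-based and inclusive at both ends."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ChoppingError(f"segment start {self.start} > end {self.end}")
        if self.start < 1:
            raise ChoppingError(f"segment start {self.start} < 1")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def residues(self) -> range:
        return range(self.start, self.end + 1)


@dataclass
class Chopping:
    """A partition of (part of) a chain into domains.

    Each domain is a sorted list of disjoint :class:`Segment` objects;
    discontinuous domains carry more than one segment.  No residue may belong
    to two domains.
    """

    domains: list[list[Segment]]
    source: str = ""

    def __post_init__(self) -> None:
        canon: list[list[Segment]] = []
        seen: dict[int, int] = {}
        for di, segs in enumerate(self.domains):
            segs = sorted(segs)
            for seg in segs:
                for r in seg.residues():
                    if r in seen:
                        raise ChoppingError(
                            f"residue {r} assigned to more than one domain "
                            f"(domains {seen[r]} and {di})"
                        )
                    seen[r] = di
            canon.append(segs)
        self.domains = canon

    def residue_sets(self) -> list[frozenset[int]]:
        return [
            frozenset(r for seg in segs for r in seg.residues())
            for segs in self.domains
        ]

    def all_residues(self) -> frozenset[int]:
        return frozenset(r for s in self.residue_sets() for r in s)

    def __len__(self) -> int:
        return len(self.domains)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Chopping):
            return NotImplemented
        return self.domains == other.domains


def parse_chopping(text: str, source: str = "") -> Chopping:
    """Parse a chopping string like ``"1-50_120-180,51-119"``.

    Raises :class:`ChoppingError` on malformed tokens, inverted ranges or
    residues claimed by two domains.  The empty string denotes zero domains.
    """
    text = text.strip()
    if not text:
        return Chopping([], source=source)
    domains: list[list[Segment]] = []
    for dom_tok in text.split(","):
        segs: list[Segment] = []
        for seg_tok in dom_tok.split("_"):
            parts = seg_tok.split("-")
            if len(parts) != 2:
                raise ChoppingError(f"malformed segment token {seg_tok!r}")
            try:
                start, end = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ChoppingError(f"malformed segment token {seg_tok!r}") from exc
            segs.append(Segment(start, end))
        domains.append(segs)
    return Chopping(domains, source=source)


def format_chopping(c: Chopping) -> str:
    """Inverse of :func:`parse_chopping` on canonical strings."""
    return ",".join(
        "_".join(f"{s.start}-{s.end}" for s in segs) for segs in c.domains
    )


def segments_from_residues(residues: Iterable[int]) -> list[Segment]:
    """Collapse a residue-number set into maximal contiguous segments."""
    res = sorted(set(residues))
    if not res:
        return []
    segs: list[Segment] = []
    start = prev = res[0]
    for r in res[1:]:
        if r == prev + 1:
            prev = r
            continue
        segs.append(Segment(start, prev))
        start = prev = r
    segs.append(Segment(start, prev))
    return segs


@dataclass
class ResidueChain:
    """Cα-level view of one protein chain with per-residue plDDT.

    plDDT lives on [0, 100]; under the AFDB convention it is read from the
    B-factor column of the PDB file.
    """

    chain_id: str
    residue_numbers: tuple[int, ...]
    ca_coords: np.ndarray  # (n, 3) Å
    plddt: np.ndarray  # (n,) in [0, 100]

    def __post_init__(self) -> None:
        self.residue_numbers = tuple(int(r) for r in self.residue_numbers)
        self.ca_coords = np.asarray(self.ca_coords, dtype=float).reshape(-1, 3)
        self.plddt = np.asarray(self.plddt, dtype=float).ravel()
        n = len(self.residue_numbers)
        if self.ca_coords.shape[0] != n or self.plddt.shape[0] != n:
            raise ValueError("residue_numbers, ca_coords and plddt lengths differ")
        diffs = np.diff(self.residue_numbers)
        if n > 1 and not np.all(diffs > 0):
            raise ValueError("residue numbers must be strictly increasing")
        if n and (self.plddt.min() < 0 or self.plddt.max() > 100):
            raise ValueError("plDDT outside [0, 100]")
        self._index = {r: i for i, r in enumerate(self.residue_numbers)}

    def __len__(self) -> int:
        return len(self.residue_numbers)

    @property
    def residue_set(self) -> frozenset[int]:
        return frozenset(self.residue_numbers)

    def indices_for(self, residues: Iterable[int]) -> np.ndarray:
        try:
            return np.array(sorted(self._index[r] for r in residues), dtype=int)
        except KeyError as exc:
            raise KeyError(f"residue {exc.args[0]} not in chain {self.chain_id}") from exc

    def coords_for(self, residues: Iterable[int]) -> np.ndarray:
        return self.ca_coords[self.indices_for(residues)]

    def plddt_for(self, residues: Iterable[int]) -> np.ndarray:
        return self.plddt[self.indices_for(residues)]


def read_structure(path: str | Path) -> ResidueChain:
    """Read a single-chain PDB file at Cα resolution.

    plDDT is taken from the B-factor column.  Residues lacking a Cα atom are
    skipped with a warning; multiple chains or duplicate residue numbers are
    errors.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    if len(model) != 1:
        raise ValueError(
            f"{path}: expected a single chain, found {len(model)}"
        )
    chain = model[0]
    nums: list[int] = []
    coords: list[list[float]] = []
    plddt: list[float] = []
    seen: set[int] = set()
    for res in chain:
        ca = res.find_atom("CA", "*")
        num = res.seqid.num
        if ca is None:
            warnings.warn(f"{path}: residue {num} has no CA atom; skipped")
            continue
        n_ca = sum(1 for a in res if a.name == "CA")
        if num in seen or n_ca > 1:
            raise ValueError(f"{path}: duplicate residue number {num}")
        seen.add(num)
        nums.append(num)
        coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        plddt.append(ca.b_iso)
    order = np.argsort(nums)
    return ResidueChain(
        chain_id=chain.name,
        residue_numbers=tuple(np.asarray(nums)[order]),
        ca_coords=np.asarray(coords)[order],
        plddt=np.asarray(plddt)[order],
    )


def write_structure(chain: ResidueChain, path: str | Path) -> None:
    """Write a Cα-only PDB file, plDDT in the B-factor column."""
    st = gemmi.Structure()
    st.name = chain.chain_id or "chain"
    model = gemmi.Model("1")
    # PDB chain identifiers are single characters; longer logical chain ids
    # live in the filename (the readers key chains by file stem)
    gchain = gemmi.Chain(chain.chain_id if len(chain.chain_id) == 1 else "A")
    for num, xyz, conf in zip(chain.residue_numbers, chain.ca_coords, chain.plddt):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(int(num), " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*map(float, xyz))
        atom.b_iso = float(conf)
        atom.occ = 1.0
        res.add_atom(atom)
        gchain.add_residue(res)
    model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


@dataclass
class PAEMatrix:
    """Square matrix of predicted aligned error (Å) over chain residues.

    Row/column index i corresponds to the i-th residue of the chain (in
    residue-number order); ``residue_numbers`` records that order so that
    chains with numbering gaps index correctly.
    """

    values: np.ndarray
    residue_numbers: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"PAE matrix must be square, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("PAE matrix has non-finite entries")
        if v.size and v.min() < 0:
            raise ValueError("PAE matrix has negative entries")
        self.values = v
        if self.residue_numbers is None:
            self.residue_numbers = tuple(range(1, v.shape[0] + 1))
        else:
            self.residue_numbers = tuple(int(r) for r in self.residue_numbers)
            if len(self.residue_numbers) != v.shape[0]:
                raise ValueError("residue_numbers length != matrix size")
        self._index = {r: i for i, r in enumerate(self.residue_numbers)}

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def indices_for(self, residues: Iterable[int]) -> np.ndarray:
        try:
            return np.array(sorted(self._index[r] for r in residues), dtype=int)
        except KeyError as exc:
            raise KeyError(f"residue {exc.args[0]} not covered by PAE matrix") from exc


def read_pae(path: str | Path) -> PAEMatrix:
    """Read an AFDB-dialect PAE JSON file.

    Accepts either ``{"predicted_aligned_error": [[...]]}`` (current AFDB
    dialect, possibly wrapped in a one-element list) or a bare 2-D array.
    """
    data = json.loads(Path(path).read_text())
    if isinstance(data, list) and data and isinstance(data[0], dict):
        data = data[0]
    if isinstance(data, dict):
        for key in ("predicted_aligned_error", "pae"):
            if key in data:
                arr = data[key]
                break
        else:
            raise ValueError(f"{path}: no PAE array found in JSON object")
    else:
        arr = data
    lengths = {len(row) for row in arr}
    if len(lengths) > 1:
        raise ValueError(f"{path}: ragged PAE rows")
    values = np.asarray(arr, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: PAE array is not square ({values.shape})")
    return PAEMatrix(values)


def write_pae(pae: PAEMatrix, path: str | Path) -> None:
    payload = {"predicted_aligned_error": pae.values.tolist()}
    Path(path).write_text(json.dumps(payload))


# --- TSV tables -----------------------------------------------------------
#
# All tables are tab-separated with a header row; writers emit a fixed column
# order so repeated runs are byte-identical.

HITS_COLUMNS = ["query_id", "target_code", "score", "kind"]
HMM_COLUMNS = ["query_id", "hmm_code", "evalue"]
CLUSTER_COLUMNS = ["cluster_id", "member_domain_id"]


def read_hits_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "target_code": str, "kind": str})
    missing = set(HITS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing hit-table columns {sorted(missing)}")
    return df


def read_hmm_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "hmm_code": str})
    missing = set(HMM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing HMM-table columns {sorted(missing)}")
    return df


def read_clusters_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(CLUSTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing cluster-table columns {sorted(missing)}")
    return df


def read_embeddings_tsv(path: str | Path) -> dict[str, np.ndarray]:
    """Read an embeddings table: domain_id column plus d numeric columns."""
    df = pd.read_csv(path, sep="\t")
    if "domain_id" not in df.columns:
        raise ValueError(f"{path}: missing domain_id column")
    mat = df.drop(columns=["domain_id"]).to_numpy(dtype=float)
    return {str(d): mat[i] for i, d in enumerate(df["domain_id"])}


def write_embeddings_tsv(embeddings: dict[str, np.ndarray], path: str | Path) -> None:
    ids = sorted(embeddings)
    dim = len(next(iter(embeddings.values()))) if ids else 0
    df = pd.DataFrame(
        [[i] + list(np.asarray(embeddings[i], dtype=float)) for i in ids],
        columns=["domain_id"] + [f"e{j}" for j in range(dim)],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
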