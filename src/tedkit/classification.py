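"""CATH label bookkeeping: turning structure-search hits into domain labels,
propagating labels over sequence clusters, HMM cross-validation, and plDDT
confidence binning.

Labels live at two depths of the CATH hierarchy: H (homologous superfamily,
"C.A.T.H") and T (topology/fold, "C.A.T").  Nearest-neighbour hits from
embedding search are trusted only to topology depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CathCode",
    "DomainLabel",
    "ClusterRecord",
    "assign_label",
    "propagate_cluster_labels",
    "validate_with_hmm",
    "plddt_bin",
]

SCORE_MIN_DEFAULT = 0.5


@dataclass(frozen=True, order=True)
class CathCode:
    """A CATH code at topology ("C.A.T") or superfamily ("C.A.T.H") depth."""

    c: int
    a: int
    t: int
    h: int | None = None

    @property
    def level(self) -> str:
        return "H" if self.h is not None else "T"

    def topology(self) -> "CathCode":
        return CathCode(self.c, self.a, self.t)

    @classmethod
    def parse(cls, text: str) -> "CathCode":
        parts = text.strip().split(".")
        if len(parts) not in (3, 4):
            raise ValueError(f"malformed CATH code {text!r}")
        try:
            nums = [int(p) for p in parts]
        except ValueError as exc:
            raise ValueError(f"malformed CATH code {text!r}") from exc
        return cls(*nums) if len(nums) == 4 else cls(*nums, None)

    def __str__(self) -> str:
        base = f"{self.c}.{self.a}.{self.t}"
        return base if self.h is None else f"{base}.{self.h}"

    def sort_key(self) -> tuple[int, int, int, int]:
        return (self.c, self.a, self.t, -1 if self.h is None else self.h)


@dataclass(frozen=True)
class DomainLabel:
    """Label state of one domain: level H, T or none."""

    domain_id: str
    level: str  # "H" | "T" | "none"
    code: CathCode | None = None
    source: str = ""  # "structure_search" | "nearest_neighbour" | ""

    def __post_init__(self) -> None:
        if self.level not in ("H", "T", "none"):
            raise ValueError(f"unknown label level {self.level!r}")
        if (self.level == "none") != (self.code is None):
            raise ValueError("level 'none' if and only if code is absent")
        if self.source == "nearest_neighbour" and self.level == "H":
            raise ValueError("nearest-neighbour matches are topology-level only")
        if self.level == "H" and self.code is not None and self.code.h is None:
            raise ValueError("H-level label requires a full C.A.T.H code")

    @property
    def labelled(self) -> bool:
        return self.level != "none"


@dataclass
class ClusterRecord:
    """A sequence cluster and its members."""

    cluster_id: str
    member_domain_ids: list[str]

    def __post_init__(self) -> None:
        if not self.member_domain_ids:
            raise ValueError(f"cluster {self.cluster_id} has no members")


def assign_label(
    domain_id: str,
    hits: Sequence[Mapping],
    score_min: float = SCORE_MIN_DEFAULT,
) -> DomainLabel:
    """Resolve a set of structure-search hits into a single domain label.

    Hit records carry ``target_code`` (CATH code string), ``score`` (a
    normalised similarity on [0, 1]) and ``kind``: ``structure_search``
    (Foldseek-style alignment hit) or ``nearest_neighbour`` (embedding
    nearest-neighbour, trusted only at topology level).

    The best structure-search hit with a full superfamily code scoring at
    least ``score_min`` yields an H label.  Failing that, the best
    structure-search hit at topology depth or any nearest-neighbour hit
    yields a T label.  Ties break on higher score, then on the lexicographic
    CATH code string.
    """
    parsed = []
    for h in hits:
        kind = h["kind"]
        if kind not in ("structure_search", "nearest_neighbour"):
            raise ValueError(f"unknown hit kind {kind!r}")
        code = CathCode.parse(str(h["target_code"]))
        parsed.append((kind, float(h["score"]), code))

    def best(cands):
        # ties: higher score first, then lexicographic on the code string
        return min(cands, key=lambda t: (-t[1], str(t[2])))

    h_cands = [
        p
        for p in parsed
        if p[0] == "structure_search" and p[2].h is not None and p[1] >= score_min
    ]
    if h_cands:
        _, _, code = best(h_cands)
        return DomainLabel(domain_id, "H", code, "structure_search")

    t_struct = [
        p
        for p in parsed
        if p[0] == "structure_search" and p[2].h is None and p[1] >= score_min
    ]
    if t_struct:
        _, _, code = best(t_struct)
        return DomainLabel(domain_id, "T", code, "structure_search")

    nn = [p for p in parsed if p[0] == "nearest_neighbour"]
    if nn:
        _, _, code = best(nn)
        return DomainLabel(domain_id, "T", code.topology(), "nearest_neighbour")

    return DomainLabel(domain_id, "none", None, "")


def propagate_cluster_labels(
    clusters: Sequence[ClusterRecord],
    labels: Mapping[str, DomainLabel],
) -> dict:
    """Partition sequence clusters by whether any member carries a CATH label.

    A cluster is labelled when at least one member has level H or T; the
    label itself is not pushed onto the unlabelled members (coverage is
    counted at cluster level).  Every member id must appear in ``labels``.
    """
    labelled: list[ClusterRecord] = []
    unlabelled: list[ClusterRecord] = []
    n_members_labelled = 0
    n_members_unlabelled = 0
    for cl in clusters:
        for mid in cl.member_domain_ids:
            if mid not in labels:
                raise KeyError(f"cluster {cl.cluster_id}: unknown member {mid!r}")
        if any(labels[mid].labelled for mid in cl.member_domain_ids):
            labelled.append(cl)
            n_members_labelled += len(cl.member_domain_ids)
        else:
            unlabelled.append(cl)
            n_members_unlabelled += len(cl.member_domain_ids)
    return {
        "labelled_clusters": labelled,
        "unlabelled_clusters": unlabelled,
        "n_labelled": len(labelled),
        "n_unlabelled": len(unlabelled),
        "n_members_labelled": n_members_labelled,
        "n_members_unlabelled": n_members_unlabelled,
    }


def validate_with_hmm(
    struct_label: DomainLabel,
    hmm_code: CathCode | None,
) -> str:
    """Cross-check a structure-derived label against an HMM-scan hit.

    Returns ``confirmed_superfamily`` on exact C.A.T.H agreement,
    ``confirmed_fold`` when the topologies (C.A.T) agree but the superfamily
    digit differs or is absent on either side, ``unconfirmed`` when even the
    topologies differ, and ``no_hmm_hit`` when no HMM hit exists.
    """
    if not struct_label.labelled or struct_label.code is None:
        raise ValueError("validate_with_hmm requires a labelled domain")
    if hmm_code is None:
        return "no_hmm_hit"
    sc, hc = struct_label.code, hmm_code
    if sc.topology() != hc.topology():
        return "unconfirmed"
    if sc.h is not None and hc.h is not None and sc.h == hc.h:
        return "confirmed_superfamily"
    return "confirmed_fold"


# plDDT confidence bins, AFDB colouring convention: closed lower bounds.
_PLDDT_BINS = (
    (90.0, "very_high"),
    (70.0, "high"),
    (50.0, "low"),
)


def plddt_bin(value: float) -> str:
    """Bin a plDDT value: very_high (>=90), high ([70,90)), low ([50,70)),
    very_low (<50)."""
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"plDDT {value} outside [0, 100]")
    for lo, name in _PLDDT_BINS:
        if value >= lo:
            return name
    return "very_low"
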