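"""Typed tripartite regulatory networks.

The data model distinguishes three node roles (miRNA, TF, gene) and five edge
classes: miRNA→gene and miRNA→TF repression, TF→miRNA and TF→gene
transcriptional regulation, and undirected gene–gene protein interactions.
A TF is itself a protein-coding gene, so a node carrying the TF role always
also carries the gene role; the miRNA role is exclusive of TF.

Edge tables are plain TSV with columns ``source  target  [score]
[provenance]``; lines starting with ``#`` are comments.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DomainError, FormatError, ValidationError

logger = logging.getLogger("fflrx")

Role = str  # "miRNA" | "TF" | "gene"


class EdgeType(str, enum.Enum):
    MIR_GENE = "MIR_GENE"
    MIR_TF = "MIR_TF"
    TF_MIR = "TF_MIR"
    TF_GENE = "TF_GENE"
    PPI = "PPI"


class Effect(str, enum.Enum):
    REPRESSION = "repression"
    REGULATION = "regulation"
    INTERACTION = "interaction"


#: effect implied by each edge class
EDGE_EFFECT: dict[EdgeType, Effect] = {
    EdgeType.MIR_GENE: Effect.REPRESSION,
    EdgeType.MIR_TF: Effect.REPRESSION,
    EdgeType.TF_MIR: Effect.REGULATION,
    EdgeType.TF_GENE: Effect.REGULATION,
    EdgeType.PPI: Effect.INTERACTION,
}

#: (source roles, target roles) implied by each edge class
EDGE_ROLES: dict[EdgeType, tuple[frozenset[Role], frozenset[Role]]] = {
    EdgeType.MIR_GENE: (frozenset({"miRNA"}), frozenset({"gene"})),
    EdgeType.MIR_TF: (frozenset({"miRNA"}), frozenset({"TF", "gene"})),
    EdgeType.TF_MIR: (frozenset({"TF", "gene"}), frozenset({"miRNA"})),
    EdgeType.TF_GENE: (frozenset({"TF", "gene"}), frozenset({"gene"})),
    EdgeType.PPI: (frozenset({"gene"}), frozenset({"gene"})),
}


@dataclass(frozen=True)
class Node:
    id: str
    roles: frozenset[Role]

    def __post_init__(self) -> None:
        if not self.roles:
            raise ValidationError(f"node {self.id!r} has no roles")
        bad = self.roles - {"miRNA", "TF", "gene"}
        if bad:
            raise ValidationError(f"node {self.id!r} has unknown roles {sorted(bad)}")
        if "miRNA" in self.roles and "TF" in self.roles:
            raise ValidationError(f"node {self.id!r} cannot be both miRNA and TF")
        if "TF" in self.roles and "gene" not in self.roles:
            raise ValidationError(f"TF node {self.id!r} must also carry the gene role")


@dataclass(frozen=True)
class RegEdge:
    source: str
    target: str
    edge_type: EdgeType
    effect: Effect = None  # type: ignore[assignment]
    score: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        et = EdgeType(self.edge_type)
        object.__setattr__(self, "edge_type", et)
        if self.effect is None:
            object.__setattr__(self, "effect", EDGE_EFFECT[et])
        elif Effect(self.effect) is not EDGE_EFFECT[et]:
            raise ValidationError(
                f"edge {self.source}->{self.target}: effect {self.effect} "
                f"inconsistent with {et.value}"
            )
        if self.source == self.target:
            raise ValidationError(
                f"self-edge {self.source!r} not allowed ({et.value})"
            )
        if et is EdgeType.PPI and self.source > self.target:
            raise ValidationError(
                f"PPI edge endpoints must be in lexicographic order: "
                f"{self.source!r} > {self.target!r}"
            )

    @property
    def key(self) -> tuple[str, str, EdgeType]:
        return (self.source, self.target, self.edge_type)


def _canonical_ppi(source: str, target: str) -> tuple[str, str]:
    return (source, target) if source < target else (target, source)


class RegulatoryNetwork:
    """Set of role-typed nodes plus five classes of regulatory edges.

    The container enforces closure (edge endpoints always exist as nodes),
    role consistency per edge class, and edge uniqueness per
    (source, target, edge_type). Duplicate insertions that disagree on the
    score keep the maximum-magnitude score and log the collision.
    """

    def __init__(self) -> None:
        self._roles: dict[str, set[Role]] = {}
        self._edges: dict[tuple[str, str, EdgeType], RegEdge] = {}

    # -- construction -----------------------------------------------------

    def add_roles(self, node_id: str, roles: Iterable[Role]) -> None:
        have = self._roles.setdefault(node_id, set())
        have.update(roles)
        if "miRNA" in have and "TF" in have:
            raise ValidationError(
                f"role conflict: {node_id!r} used as both miRNA and TF"
            )

    def add_edge(
        self,
        source: str,
        target: str,
        edge_type: EdgeType | str,
        score: float | None = None,
        provenance: str = "",
    ) -> RegEdge:
        et = EdgeType(edge_type)
        if et is EdgeType.PPI:
            source, target = _canonical_ppi(source, target)
        edge = RegEdge(source, target, et, score=score, provenance=provenance)
        src_roles, tgt_roles = EDGE_ROLES[et]
        self.add_roles(source, src_roles)
        self.add_roles(target, tgt_roles)
        prior = self._edges.get(edge.key)
        if prior is not None:
            score = _resolve_score_collision(prior, edge)
            edge = RegEdge(source, target, et, score=score,
                           provenance=prior.provenance or edge.provenance)
        self._edges[edge.key] = edge
        return edge

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> list[Node]:
        return [Node(i, frozenset(r)) for i, r in sorted(self._roles.items())]

    @property
    def edges(self) -> list[RegEdge]:
        return [self._edges[k] for k in sorted(self._edges, key=lambda k: (k[2].value, k[0], k[1]))]

    def roles_of(self, node_id: str) -> frozenset[Role]:
        return frozenset(self._roles.get(node_id, ()))

    def nodes_with_role(self, role: Role) -> list[str]:
        return sorted(i for i, r in self._roles.items() if role in r)

    def has_edge(self, source: str, target: str, edge_type: EdgeType | str) -> bool:
        et = EdgeType(edge_type)
        if et is EdgeType.PPI:
            source, target = _canonical_ppi(source, target)
        return (source, target, et) in self._edges

    def edges_of_type(self, edge_type: EdgeType | str) -> list[RegEdge]:
        et = EdgeType(edge_type)
        return [e for e in self.edges if e.edge_type is et]

    def targets_by_source(self, edge_type: EdgeType | str) -> dict[str, set[str]]:
        """Map each source id to its target set under one edge class."""
        et = EdgeType(edge_type)
        out: dict[str, set[str]] = {}
        for (s, t, k) in self._edges:
            if k is et:
                out.setdefault(s, set()).add(t)
        return out

    def counts(self) -> dict[str, int]:
        c = {f"edges.{et.value}": 0 for et in EdgeType}
        for (_, _, et) in self._edges:
            c[f"edges.{et.value}"] += 1
        for role in ("miRNA", "TF", "gene"):
            c[f"nodes.{role}"] = len(self.nodes_with_role(role))
        c["nodes.total"] = len(self._roles)
        c["edges.total"] = len(self._edges)
        return c

    def __len__(self) -> int:
        return len(self._edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return self._roles == other._roles and self._edges == other._edges


def _resolve_score_collision(prior: RegEdge, new: RegEdge) -> float | None:
    if prior.score is None:
        return new.score
    if new.score is None or prior.score == new.score:
        return prior.score
    # max magnitude wins; sign breaks exact-magnitude ties so the outcome
    # never depends on insertion order
    keep = max(prior.score, new.score, key=lambda s: (abs(s), s))
    logger.warning(
        "duplicate edge %s->%s (%s) with scores %s vs %s; keeping %s",
        prior.source, prior.target, prior.edge_type.value,
        prior.score, new.score, keep,
    )
    return keep


# ---------------------------------------------------------------------------
# TSV input/output


def read_edge_table(path, edge_type: EdgeType | str) -> RegulatoryNetwork:
    """Read one edge-class TSV into a network fragment.

    Required columns ``source`` and ``target``; optional ``score`` and
    ``provenance``. ``#``-prefixed lines are ignored. Rows violating role or
    self-edge constraints raise :class:`ValidationError`.
    """
    et = EdgeType(edge_type)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file (expected a header line)")
    missing = {"source", "target"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    net = RegulatoryNetwork()
    for row in df.itertuples(index=False):
        score = None
        if "score" in df.columns and pd.notna(getattr(row, "score", None)):
            score = float(row.score)
        prov = ""
        if "provenance" in df.columns and pd.notna(getattr(row, "provenance", None)):
            prov = str(row.provenance)
        net.add_edge(str(row.source), str(row.target), et, score=score, provenance=prov)
    return net


def write_edge_table(net: RegulatoryNetwork, path, edge_type: EdgeType | str,
                     header_comment: str | None = None) -> None:
    """Write one edge class of a network as TSV (sorted by source, target)."""
    et = EdgeType(edge_type)
    edges = sorted(net.edges_of_type(et), key=lambda e: (e.source, e.target))
    with_score = any(e.score is not None for e in edges)
    with_prov = any(e.provenance for e in edges)
    cols = ["source", "target"] + (["score"] if with_score else []) \
        + (["provenance"] if with_prov else [])
    rows = []
    for e in edges:
        r = {"source": e.source, "target": e.target}
        if with_score:
            r["score"] = "" if e.score is None else repr(e.score)
        if with_prov:
            r["provenance"] = e.provenance
        rows.append(r)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")


def merge_networks(fragments: Sequence[RegulatoryNetwork]) -> RegulatoryNetwork:
    """Union of nodes (roles unioned) and edges (duplicates collapsed).

    Deterministic regardless of fragment order; raises
    :class:`ValidationError` when merging makes one id both miRNA and TF.
    """
    merged = RegulatoryNetwork()
    # canonical order: collision resolution is itself order-independent, but
    # sorting keeps provenance selection deterministic too
    all_edges = sorted(
        (e for frag in fragments for e in frag.edges),
        key=lambda e: (e.edge_type.value, e.source, e.target, e.provenance),
    )
    for frag in fragments:
        for node_id, roles in sorted(frag._roles.items()):
            merged.add_roles(node_id, roles)
    for e in all_edges:
        merged.add_edge(e.source, e.target, e.edge_type,
                        score=e.score, provenance=e.provenance)
    return merged


# ---------------------------------------------------------------------------
# Differential-expression lists


@dataclass
class ExpressionList:
    """Differentially expressed genes or miRNAs with an up/down direction."""

    entity_kind: str  # "gene" | "miRNA"
    entries: dict[str, str] = field(default_factory=dict)  # id -> "up"|"down"
    label: str = ""

    def __post_init__(self) -> None:
        if self.entity_kind not in ("gene", "miRNA"):
            raise ValidationError(f"unknown entity_kind {self.entity_kind!r}")
        for ident, direction in self.entries.items():
            if direction not in ("up", "down"):
                raise ValidationError(
                    f"{self.label or 'expression list'}: id {ident!r} has "
                    f"direction {direction!r} (expected up/down)"
                )

    def __contains__(self, ident: str) -> bool:
        return ident in self.entries


def read_expression_list(path, entity_kind: str, label: str = "") -> ExpressionList:
    """Read an ``id<TAB>direction`` TSV; direction must be up or down."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file (expected a header line)")
    missing = {"id", "direction"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    entries: dict[str, str] = {}
    for row in df.itertuples(index=False):
        ident, direction = str(row.id), str(row.direction)
        if ident in entries and entries[ident] != direction:
            raise ValidationError(
                f"{path}: id {ident!r} listed with both directions"
            )
        entries[ident] = direction
    return ExpressionList(entity_kind, entries, label or str(path))


@dataclass(frozen=True)
class OverlapSummary:
    shared_up: int
    shared_down: int
    discordant: int

    @property
    def total_shared(self) -> int:
        return self.shared_up + self.shared_down + self.discordant


def directional_overlap(a: ExpressionList, b: ExpressionList) -> OverlapSummary:
    """Count ids shared up, shared down, and with opposite directions."""
    if a.entity_kind != b.entity_kind:
        raise ValidationError(
            f"cannot overlap {a.entity_kind} list with {b.entity_kind} list"
        )
    common = set(a.entries) & set(b.entries)
    up = sum(1 for i in common if a.entries[i] == "up" and b.entries[i] == "up")
    down = sum(1 for i in common if a.entries[i] == "down" and b.entries[i] == "down")
    return OverlapSummary(up, down, len(common) - up - down)


# ---------------------------------------------------------------------------
# Target-set similarity


def tanimoto_similarity(targets_a: set[str], targets_b: set[str]) -> float:
    """Jaccard/Tanimoto similarity |A∩B| / |A∪B| of two target-gene sets."""
    union = len(targets_a | targets_b)
    if union == 0:
        raise DomainError("tanimoto similarity undefined for two empty sets")
    return len(targets_a & targets_b) / union


def similarity_network(
    target_map: Mapping[str, set[str]], threshold: float
) -> list[tuple[str, str, float]]:
    """All miRNA pairs whose target-set Tanimoto similarity meets a threshold.

    miRNAs with empty target sets are excluded (their similarity to anything
    carries no information). Returns lexicographically ordered pairs.
    """
    if not 0.0 <= threshold <= 1.0:
        raise DomainError(f"threshold {threshold} outside [0, 1]")
    mirnas = sorted(m for m, ts in target_map.items() if ts)
    out: list[tuple[str, str, float]] = []
    for i, mi in enumerate(mirnas):
        for mj in mirnas[i + 1:]:
            s = tanimoto_similarity(target_map[mi], target_map[mj])
            if s >= threshold:
                out.append((mi, mj, s))
    return out
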