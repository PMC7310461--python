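"""Signaling-pathway topologies as Bayesian-network structures.

A pathway is read from KEGG KGML (or a SIF edge list), expanded to the gene
level, and reduced to a directed acyclic graph whose edges are the candidate
parent -> child relations of a linear-Gaussian Bayesian network.  Relation
labels (activation / inhibition) are carried along for reporting but play no
role in estimation: the sign of a relationship is estimated from data.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import networkx as nx
from lxml import etree

__all__ = [
    "PathwayGraph",
    "PathwayParseError",
    "parse_kgml",
    "parse_sif",
    "to_sif",
    "break_cycles",
    "removed_edges_report",
]


class PathwayParseError(ValueError):
    """Raised for malformed KGML/SIF input; the message names the offender."""


@dataclass
class PathwayGraph:
    """Directed gene network backing a Bayesian-network structure.

    Nodes are canonical gene symbols (with optional probe/alternate aliases);
    edges are ordered (parent, child) pairs with a relation label in
    {"activation", "inhibition", "unknown"}.  ``removed_edges`` records every
    edge deleted on the way to acyclicity, so the reduction is auditable.
    """

    pathway_id: str
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    removed_edges: list[tuple[str, str, str]] = field(default_factory=list)
    skipped_entries: list[tuple[str, str]] = field(default_factory=list)

    # -- construction -----------------------------------------------------
    def add_gene(self, gene_id: str, aliases: set[str] | None = None) -> None:
        if not gene_id:
            raise ValueError("gene_id must be non-empty")
        if gene_id in self.graph:
            if aliases:
                self.graph.nodes[gene_id]["aliases"].update(aliases)
        else:
            self.graph.add_node(gene_id, aliases=set(aliases or ()))

    def add_edge(self, parent: str, child: str, relation: str = "unknown") -> bool:
        """Add parent->child; self-loops are dropped (and recorded). Returns
        True if a new edge was inserted."""
        if parent == child:
            self.removed_edges.append((parent, child, "self-loop"))
            return False
        self.add_gene(parent)
        self.add_gene(child)
        if self.graph.has_edge(parent, child):
            return False
        self.graph.add_edge(parent, child, relation=relation)
        return True

    # -- queries ----------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def aliases(self, gene_id: str) -> set[str]:
        return set(self.graph.nodes[gene_id]["aliases"])

    def relation(self, parent: str, child: str) -> str:
        return self.graph.edges[parent, child]["relation"]

    def parents_of(self, gene_id: str) -> list[str]:
        """Lexicographically ordered parents of ``gene_id`` (the X_k of the
        child's regression); empty for root nodes."""
        if gene_id not in self.graph:
            raise KeyError(f"unknown gene {gene_id!r} in pathway {self.pathway_id}")
        return sorted(self.graph.predecessors(gene_id))

    def children_of(self, gene_id: str) -> list[str]:
        if gene_id not in self.graph:
            raise KeyError(f"unknown gene {gene_id!r} in pathway {self.pathway_id}")
        return sorted(self.graph.successors(gene_id))

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.graph)

    def topological_order(self) -> list[str]:
        """Kahn's algorithm with lexicographic tie-breaking (deterministic)."""
        indeg = {n: self.graph.in_degree(n) for n in self.graph}
        ready = [n for n, d in indeg.items() if d == 0]
        heapq.heapify(ready)
        order: list[str] = []
        while ready:
            n = heapq.heappop(ready)
            order.append(n)
            for c in self.graph.successors(n):
                indeg[c] -= 1
                if indeg[c] == 0:
                    heapq.heappush(ready, c)
        if len(order) != self.graph.number_of_nodes():
            raise ValueError(f"pathway {self.pathway_id} is cyclic")
        return order

    def copy(self) -> "PathwayGraph":
        return PathwayGraph(
            self.pathway_id,
            self.graph.copy(),
            list(self.removed_edges),
            list(self.skipped_entries),
        )


# -- SIF ------------------------------------------------------------------

def parse_sif(text: str, pathway_id: str = "pathway") -> PathwayGraph:
    """Parse a 3-column tab-separated edge list: parent <TAB> relation <TAB> child.

    Duplicate lines are deduplicated; the node set is the union of endpoints.
    """
    pg = PathwayGraph(pathway_id)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 3:
            raise PathwayParseError(
                f"SIF line {lineno}: expected 3 tab-separated fields, got {len(parts)}"
            )
        parent, relation, child = (p.strip() for p in parts)
        if not parent or not child:
            raise PathwayParseError(f"SIF line {lineno}: empty gene identifier")
        pg.add_edge(parent, child, relation=relation or "unknown")
    return pg


def to_sif(pg: PathwayGraph) -> str:
    lines = [
        f"{p}\t{pg.relation(p, c)}\t{c}" for p, c in sorted(pg.graph.edges)
    ]
    return "\n".join(lines) + ("\n" if lines else "")


# -- KGML -----------------------------------------------------------------

_ACTIVATING = {"activation", "expression"}
_INHIBITING = {"inhibition", "repression"}


def _relation_label(subtypes: list[str]) -> str:
    if any(s in _ACTIVATING for s in subtypes):
        return "activation"
    if any(s in _INHIBITING for s in subtypes):
        return "inhibition"
    return "unknown"


def parse_kgml(
    kgml_text: str | bytes,
    pathway_id: str | None = None,
    alias_map: dict[str, str] | None = None,
) -> PathwayGraph:
    """Parse a KGML document to a gene-level directed graph.

    Multi-gene entries are expanded to one node per gene symbol; group
    (complex) entries are expanded so each member inherits the group's in/out
    edges; compound-mediated relations are collapsed to direct gene->gene
    edges.  Cycles are NOT removed here (see :func:`break_cycles`).  Entries
    with no resolvable gene symbol are recorded in ``skipped_entries``.
    Symbols pass through ``alias_map`` (probe/alias -> canonical) when given.
    """
    data = kgml_text.encode() if isinstance(kgml_text, str) else kgml_text
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise PathwayParseError(f"malformed KGML document: {exc}") from exc
    if root.tag != "pathway":
        raise PathwayParseError(f"expected <pathway> root element, found <{root.tag}>")

    pid = pathway_id or root.get("name") or root.get("title") or "pathway"
    pg = PathwayGraph(pid)
    alias_map = alias_map or {}

    gene_entries: dict[str, list[str]] = {}
    group_members: dict[str, list[str]] = {}
    compound_ids: set[str] = set()
    for entry in root.findall("entry"):
        eid = entry.get("id")
        etype = entry.get("type")
        if eid is None or etype is None:
            raise PathwayParseError("entry element missing id/type attribute")
        if etype == "gene":
            graphics = entry.find("graphics")
            raw = (graphics.get("name") if graphics is not None else None) or ""
            symbols = []
            for tok in raw.split(","):
                sym = tok.strip().rstrip(".")
                if sym:
                    symbols.append(alias_map.get(sym, sym))
            if symbols:
                gene_entries[eid] = symbols
            else:
                pg.skipped_entries.append((eid, "no resolvable gene symbol"))
        elif etype == "group":
            group_members[eid] = [
                c.get("id") for c in entry.findall("component") if c.get("id")
            ]
        elif etype == "compound":
            compound_ids.add(eid)
        else:  # map links, orthologs, ... play no role in the BN structure
            pg.skipped_entries.append((eid, f"unsupported entry type {etype!r}"))

    def genes_of(eid: str) -> list[str]:
        if eid in gene_entries:
            return gene_entries[eid]
        if eid in group_members:
            out: list[str] = []
            for member in group_members[eid]:
                out.extend(genes_of(member))
            return out
        return []

    for eid, symbols in gene_entries.items():
        for sym in symbols:
            pg.add_gene(sym)

    # direct gene edges plus in/out stubs of compound nodes
    compound_in: dict[str, list[str]] = {c: [] for c in compound_ids}
    compound_out: dict[str, list[str]] = {c: [] for c in compound_ids}
    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        if e1 is None or e2 is None:
            raise PathwayParseError("relation element missing entry1/entry2")
        subtypes = [s.get("name") or "" for s in rel.findall("subtype")]
        label = _relation_label(subtypes)
        if e1 in compound_ids or e2 in compound_ids:
            if e1 in compound_ids:
                compound_out[e1].extend(genes_of(e2))
            if e2 in compound_ids:
                compound_in[e2].extend(genes_of(e1))
            continue
        for parent in genes_of(e1):
            for child in genes_of(e2):
                pg.add_edge(parent, child, relation=label)

    # collapse compound-mediated relations to direct gene->gene edges
    for cid in sorted(compound_ids):
        for parent in compound_in[cid]:
            for child in compound_out[cid]:
                pg.add_edge(parent, child, relation="unknown")

    return pg


# -- acyclicity -----------------------------------------------------------

def break_cycles(pg: PathwayGraph) -> PathwayGraph:
    """Return an acyclic copy, deleting DFS back-edges deterministically.

    Depth-first search starts from nodes in lexicographic gene_id order and
    visits successors in lexicographic order; every edge into a node on the
    current DFS stack is a back-edge and is deleted (a digraph is acyclic iff
    a DFS finds no back edge).  Deleted edges are appended to
    ``removed_edges`` with reason "cycle back-edge".
    """
    g = pg.graph
    kept = nx.DiGraph()
    kept.add_nodes_from(g.nodes(data=True))
    removed = list(pg.removed_edges)

    WHITE, GRAY, BLACK = 0, 1, 2
    color = {n: WHITE for n in g}
    for root in sorted(g.nodes):
        if color[root] != WHITE:
            continue
        color[root] = GRAY
        stack = [(root, iter(sorted(g.successors(root))))]
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if color[nxt] == GRAY:
                    removed.append((node, nxt, "cycle back-edge"))
                elif color[nxt] == WHITE:
                    kept.add_edge(node, nxt, **g.edges[node, nxt])
                    color[nxt] = GRAY
                    stack.append((nxt, iter(sorted(g.successors(nxt)))))
                    advanced = True
                    break
                else:  # forward/cross edge: cannot close a cycle
                    kept.add_edge(node, nxt, **g.edges[node, nxt])
            if not advanced:
                color[node] = BLACK
                stack.pop()

    out = PathwayGraph(pg.pathway_id, kept, removed, list(pg.skipped_entries))
    assert out.is_acyclic()
    return out


def removed_edges_report(pg: PathwayGraph) -> str:
    """TSV report (parent, child, reason) of edges deleted during reduction."""
    lines = ["parent\tchild\treason"]
    lines += [f"{p}\t{c}\t{r}" for p, c, r in pg.removed_edges]
    return "\n".join(lines) + "\n"
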