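"""Ontology handling: parse, validate, annotate and prune the GO-style DAG.

The pruned :class:`OntologyDAG` is the blueprint from which the
ontology-structured expression encoder is compiled: its child lists fix the
concatenation order of every term's inputs, its gene annotations fix which
expression values enter where, and its topological order fixes the forward
evaluation schedule. Determinism therefore matters everywhere — child and
gene lists are kept in lexicographic order, and the topological sort breaks
ties lexicographically.

Only ``is_a`` relationships define the hierarchy. ``part_of`` and other
relation types are ignored; the choice of namespace (biological process,
molecular function, ...) is the caller's — any valid OBO file is accepted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["OntologyDAG", "parse_obo", "annotate_and_prune",
           "load_annotations"]


@dataclass
class OntologyDAG:
    """A rooted DAG of ontology terms with direct gene annotations.

    Attributes
    ----------
    terms : set of term ids.
    root : the unique term with no parents.
    child_edges : term -> lexicographically ordered list of child terms.
    gene_annotations : term -> ordered list of directly annotated genes.
    depth : term -> shortest-path distance from the root (root is 0; a
        multi-parent term takes 1 + the minimum parent depth).
    topo_order : every term exactly once, children before parents.
    """

    terms: set[str]
    root: str
    child_edges: dict[str, list[str]]
    gene_annotations: dict[str, list[str]] = field(default_factory=dict)
    depth: dict[str, int] = field(default_factory=dict)
    topo_order: list[str] = field(default_factory=list)

    # ---- derived views ---------------------------------------------------
    def parents(self) -> dict[str, list[str]]:
        par: dict[str, list[str]] = {t: [] for t in self.terms}
        for p, kids in self.child_edges.items():
            for c in kids:
                par[c].append(p)
        return {t: sorted(ps) for t, ps in par.items()}

    def genes(self) -> list[str]:
        """All annotated genes, sorted."""
        out: set[str] = set()
        for gs in self.gene_annotations.values():
            out.update(gs)
        return sorted(out)

    def descendant_genes(self, term: str) -> set[str]:
        """Genes annotated anywhere in `term`'s descendant closure (incl. self)."""
        out: set[str] = set()
        stack = [term]
        seen = set()
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            out.update(self.gene_annotations.get(t, ()))
            stack.extend(self.child_edges.get(t, ()))
        return out

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        if sorted(self.topo_order) != sorted(self.terms):
            raise ValueError("topo_order must contain each term exactly once")
        pos = {t: i for i, t in enumerate(self.topo_order)}
        for p, kids in self.child_edges.items():
            for c in kids:
                if pos[c] >= pos[p]:
                    raise ValueError(
                        f"topological order violated: child {c!r} does not "
                        f"precede parent {p!r}")
        if self.depth.get(self.root) != 0:
            raise ValueError("root must have depth 0")
        par = self.parents()
        for t in self.terms:
            if t == self.root:
                continue
            if not par[t]:
                raise ValueError(f"non-root term {t!r} has no parent")
            want = 1 + min(self.depth[p] for p in par[t])
            if self.depth[t] != want:
                raise ValueError(f"depth[{t!r}] = {self.depth[t]} != {want}")

    def to_json(self, path: str) -> None:
        """Export terms, edges, annotations and depths for provenance."""
        payload = {
            "root": self.root,
            "terms": sorted(self.terms),
            "child_edges": {t: self.child_edges.get(t, [])
                            for t in sorted(self.terms)},
            "gene_annotations": {t: gs for t, gs
                                 in sorted(self.gene_annotations.items())},
            "depth": {t: self.depth[t] for t in sorted(self.terms)},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _toposort(terms: set[str], child_edges: dict[str, list[str]]) -> list[str]:
    """Deterministic Kahn's algorithm, children before parents.

    Processes the child->parent orientation with a lexicographic ready queue
    so the schedule is reproducible across runs.
    """
    import heapq

    n_unresolved = {t: len(child_edges.get(t, [])) for t in terms}
    parents_of: dict[str, list[str]] = {t: [] for t in terms}
    for p, kids in child_edges.items():
        for c in kids:
            parents_of[c].append(p)
    ready = [t for t in terms if n_unresolved[t] == 0]
    heapq.heapify(ready)
    order: list[str] = []
    while ready:
        t = heapq.heappop(ready)
        order.append(t)
        for p in parents_of[t]:
            n_unresolved[p] -= 1
            if n_unresolved[p] == 0:
                heapq.heappush(ready, p)
    if len(order) != len(terms):
        raise ValueError("cycle detected during topological sort")
    return order


def _depths(root: str, child_edges: dict[str, list[str]]) -> dict[str, int]:
    """Shortest-path depth from the root via BFS over child edges."""
    from collections import deque

    depth = {root: 0}
    q = deque([root])
    while q:
        t = q.popleft()
        for c in child_edges.get(t, ()):
            if c not in depth:
                depth[c] = depth[t] + 1
                q.append(c)
    return depth


def _assemble(terms: set[str], child_edges: dict[str, list[str]],
              gene_annotations: dict[str, list[str]]) -> OntologyDAG:
    roots = [t for t in sorted(terms)
             if not any(t in kids for kids in child_edges.values())]
    if len(roots) != 1:
        raise ValueError(f"expected exactly one root, found {roots}")
    root = roots[0]
    child_edges = {t: sorted(child_edges.get(t, [])) for t in terms
                   if child_edges.get(t)}
    dag = OntologyDAG(
        terms=terms, root=root, child_edges=child_edges,
        gene_annotations={t: sorted(g) for t, g in gene_annotations.items()
                          if g},
        depth=_depths(root, child_edges),
        topo_order=_toposort(terms, child_edges),
    )
    dag.validate()
    return dag


def parse_obo(path: str) -> OntologyDAG:
    """Parse an OBO file into an :class:`OntologyDAG`.

    Only ``is_a`` edges are used; obsolete terms are skipped (obonet's
    default). The graph must be acyclic and have exactly one root (a term
    with no ``is_a`` parent).
    """
    graph = obonet.read_obo(path)  # MultiDiGraph, edges child -> parent
    terms: set[str] = set(graph.nodes())
    # keep only is_a edges, reversed into child lists
    child_edges: dict[str, list[str]] = {}
    isa = nx.DiGraph()
    isa.add_nodes_from(terms)
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            isa.add_edge(child, parent)
            child_edges.setdefault(parent, []).append(child)
    if not nx.is_directed_acyclic_graph(isa):
        cycle = nx.find_cycle(isa)
        raise ValueError(f"ontology contains a cycle through {cycle[0][0]!r}")
    return _assemble(terms, child_edges, {})


def load_annotations(path: str) -> pd.DataFrame:
    """Read a 2-column TSV (gene_id, term_id) of direct annotations."""
    df = pd.read_csv(path, sep="\t", header=None, comment="!",
                     names=["gene_id", "term_id"], dtype=str)
    return df


def annotate_and_prune(dag: OntologyDAG, annotations: pd.DataFrame,
                       gene_list: list[str]) -> OntologyDAG:
    """Attach gene annotations and prune terms with no annotated descendant.

    Genes outside `gene_list`, and annotations to unknown terms, are dropped.
    Terms whose descendant closure contains no annotated gene are removed;
    root, depths and topological order are recomputed. Genes in `gene_list`
    lacking any annotation are logged. Idempotent.
    """
    if annotations.empty:
        raise ValueError("annotation table is empty")
    if not gene_list:
        raise ValueError("gene_list is empty")
    genes = set(gene_list)
    direct: dict[str, set[str]] = {}
    annotated_genes: set[str] = set()
    for gene, term in zip(annotations["gene_id"], annotations["term_id"]):
        if gene in genes and term in dag.terms:
            direct.setdefault(term, set()).add(gene)
            annotated_genes.add(gene)
    missing = sorted(genes - annotated_genes)
    if missing:
        logger.warning("%d gene(s) in gene_list have no ontology annotation "
                       "and are dropped: %s", len(missing),
                       ", ".join(missing[:10]))
    if not annotated_genes:
        raise ValueError("empty annotated ontology: no gene in gene_list is "
                         "annotated to any term")

    # a term survives iff its descendant closure contains an annotated gene
    has_gene: dict[str, bool] = {}
    for t in dag.topo_order:  # children first, so closure is incremental
        ok = bool(direct.get(t))
        for c in dag.child_edges.get(t, ()):
            ok = ok or has_gene[c]
        has_gene[t] = ok
    kept = {t for t in dag.terms if has_gene[t]}
    child_edges = {p: [c for c in kids if c in kept]
                   for p, kids in dag.child_edges.items() if p in kept}
    return _assemble(kept, child_edges,
                     {t: sorted(g) for t, g in direct.items()})
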