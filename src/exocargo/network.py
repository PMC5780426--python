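"""Tripartite miRNA-gene-term regulatory network.

Nodes are of three kinds: the selected cargo miRNAs, the genes of
significantly enriched terms that those miRNAs target, and the
significant terms themselves.  Edges are typed:

* ``targets`` — miRNA -> gene (a retained consensus prediction);
* ``annotated`` — gene -> term (term membership);
* ``summary`` — miRNA -> term, weighted by the number of distinct
  genes the miRNA targets inside the term.

The structure supports both an enrichment-map style view (miRNAs and
genes, with term membership as a gene attribute) and a summary view
(miRNAs and terms).  Export formats: GraphML (round-trip safe) and the
simple interaction format (SIF) used by network viewers.  Layout is
deliberately left to the viewer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .enrichment import AnnotationSet, EnrichmentResult
from .errors import ValidationError
from .targets import ConsensusTargetSet, canonical_mirna

EDGE_KINDS = ("targets", "annotated", "summary")
NODE_KINDS = ("mirna", "gene", "term")

#: GraphML-safe separator for list-valued node attributes.
LIST_SEP = "|"


@dataclass
class MirnaNetwork:
    """A typed tripartite graph plus upstream-stage provenance."""

    graph: nx.DiGraph
    provenance: dict = field(default_factory=dict)

    def nodes_of_kind(self, kind: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d.get("kind") == kind)

    def edges_of_kind(self, kind: str):
        return [(u, v, d) for u, v, d in self.graph.edges(data=True) if d.get("kind") == kind]

    def targets_of(self, mirna: str) -> set[str]:
        m = canonical_mirna(mirna)
        if m not in self.graph or self.graph.nodes[m].get("kind") != "mirna":
            raise ValidationError(f"unknown miRNA node '{mirna}'")
        return {v for _, v, d in self.graph.out_edges(m, data=True)
                if d.get("kind") == "targets"}

    def genes_of_term(self, term: str) -> set[str]:
        if term not in self.graph or self.graph.nodes[term].get("kind") != "term":
            raise ValidationError(f"unknown term node '{term}'")
        return {u for u, _, d in self.graph.in_edges(term, data=True)
                if d.get("kind") == "annotated"}

    def check_invariants(self) -> None:
        """Raise if any typing or weight invariant is violated."""
        g = self.graph
        for n, d in g.nodes(data=True):
            if d.get("kind") not in NODE_KINDS:
                raise ValidationError(f"node {n} has invalid kind {d.get('kind')}")
        expected_ends = {"targets": ("mirna", "gene"),
                         "annotated": ("gene", "term"),
                         "summary": ("mirna", "term")}
        for u, v, d in g.edges(data=True):
            kind = d.get("kind")
            if kind not in EDGE_KINDS:
                raise ValidationError(f"edge ({u},{v}) has invalid kind {kind}")
            su, sv = expected_ends[kind]
            if g.nodes[u]["kind"] != su or g.nodes[v]["kind"] != sv:
                raise ValidationError(f"edge ({u},{v}) of kind {kind} joins "
                                      f"{g.nodes[u]['kind']} -> {g.nodes[v]['kind']}")
            if kind == "summary":
                shared = self.targets_of(u) & self.genes_of_term(v)
                if d.get("weight") != len(shared) or d.get("weight", 0) < 1:
                    raise ValidationError(
                        f"summary edge ({u},{v}) weight {d.get('weight')} != "
                        f"{len(shared)} shared genes")


def build_network(
    cts: ConsensusTargetSet,
    sig: EnrichmentResult | list[str],
    annotations: AnnotationSet,
) -> MirnaNetwork:
    """Assemble the tripartite network from a consensus target set and
    the significant slice of an enrichment result.

    Gene nodes are restricted to genes of significant terms; miRNA
    nodes to cargo miRNAs with at least one retained target.  Each gene
    node carries a ``processes`` attribute listing the significant
    terms it belongs to (joined with ``|`` for export safety).
    """
    if isinstance(sig, EnrichmentResult):
        if "significant" not in sig.table.columns:
            raise ValidationError("enrichment result has no significance flags")
        sig_terms = list(sig.table.loc[sig.table["significant"], "term_id"])
    else:
        sig_terms = list(sig)
    if not sig_terms:
        raise ValidationError("no significant terms; nothing to build")
    unknown = [t for t in sig_terms if t not in annotations.terms]
    if unknown:
        raise ValidationError(f"significant terms missing from annotations: {unknown}")

    term_genes = {t: annotations.genes_of(t) for t in sig_terms}
    sig_gene_union = set().union(*term_genes.values())
    edges = cts.edges
    kept = edges[edges["gene"].isin(sig_gene_union)]
    if kept.empty:
        raise ValidationError(
            "no consensus target falls inside any significant term")

    g = nx.DiGraph()
    genes_kept = sorted(kept["gene"].unique())
    for t in sorted(sig_terms):
        name = annotations.terms[t][0]
        g.add_node(t, kind="term", name=name)
    for gene in genes_kept:
        procs = sorted(t for t in sig_terms if gene in term_genes[t])
        g.add_node(gene, kind="gene", processes=LIST_SEP.join(procs))
    for m in sorted(kept["mirna"].unique()):
        g.add_node(m, kind="mirna")
    for row in kept.itertuples(index=False):
        g.add_edge(row.mirna, row.gene, kind="targets",
                   support=int(row.support),
                   score=float(row.integrated_score))
    for gene in genes_kept:
        for t in sorted(sig_terms):
            if gene in term_genes[t]:
                g.add_edge(gene, t, kind="annotated")
    # summary edges: distinct targets of each miRNA inside each term
    by_mirna = kept.groupby("mirna")["gene"].agg(set)
    for m, targets in by_mirna.items():
        for t in sorted(sig_terms):
            w = len(targets & term_genes[t])
            if w > 0:
                g.add_edge(m, t, kind="summary", weight=int(w))
    net = MirnaNetwork(graph=g, provenance={
        "consensus_params": dict(cts.params),
        "n_significant_terms": len(sig_terms),
    })
    return net


def per_mirna_term_counts(net: MirnaNetwork) -> pd.DataFrame:
    """Summary-edge weights as a tidy table (mirna, term, n_genes);
    zero-weight pairs are omitted by construction."""
    rows = [{"mirna": u, "term": v, "n_genes": int(d["weight"])}
            for u, v, d in net.edges_of_kind("summary")]
    df = pd.DataFrame(rows, columns=["mirna", "term", "n_genes"])
    return df.sort_values(["mirna", "term"], kind="mergesort").reset_index(drop=True)


def unique_targets(net: MirnaNetwork, mirna: str, gene_scope=None) -> set[str]:
    """Genes targeted by ``mirna`` and by no other miRNA in the network,
    optionally restricted to the genes of a set of scope terms."""
    m = canonical_mirna(mirna)
    mine = net.targets_of(m)
    if gene_scope is not None:
        scope_genes = set().union(*(net.genes_of_term(t) for t in gene_scope))
        mine = mine & scope_genes
    others: set[str] = set()
    for other in net.nodes_of_kind("mirna"):
        if other != m:
            others |= net.targets_of(other)
    return mine - others


def rank_candidates(net: MirnaNetwork, term_scope) -> pd.DataFrame:
    """Rank cargo miRNAs by distinct targets within the scope terms.

    This reproduces the loading-candidate logic: the miRNA covering the
    most genes of the processes of interest is the top candidate for
    exosome loading.  Ties break lexicographically.
    """
    scope = list(term_scope)
    if not scope:
        raise ValidationError("term scope is empty")
    term_nodes = set(net.nodes_of_kind("term"))
    missing = [t for t in scope if t not in term_nodes]
    if missing:
        raise ValidationError(f"scope terms absent from network: {missing}")
    scope_genes = set().union(*(net.genes_of_term(t) for t in scope))
    rows = [{"mirna": m, "n_targets": len(net.targets_of(m) & scope_genes)}
            for m in net.nodes_of_kind("mirna")]
    df = pd.DataFrame(rows)
    df = df.sort_values(["n_targets", "mirna"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    return df


def export_graph(net: MirnaNetwork, fmt: str, path: str | Path) -> None:
    """Write the network as GraphML (typed attributes preserved) or SIF
    (``source<TAB>kind<TAB>target`` lines)."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net.graph, path)
    elif fmt == "sif":
        lines = [f"{u}\t{d['kind']}\t{v}" for u, v, d in net.graph.edges(data=True)]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValidationError(f"unknown export format '{fmt}' (use graphml or sif)")


def read_graphml(path: str | Path) -> MirnaNetwork:
    """Read a GraphML export back; round-trips :func:`export_graph`."""
    g = nx.read_graphml(Path(path))
    out = nx.DiGraph()
    for n, d in g.nodes(data=True):
        out.add_node(n, **d)
    for u, v, d in g.edges(data=True):
        if "weight" in d:
            d = dict(d, weight=int(d["weight"]))
        if "support" in d:
            d = dict(d, support=int(d["support"]))
        out.add_edge(u, v, **d)
    return MirnaNetwork(graph=out)
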