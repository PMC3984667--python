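"""Metabolite-enzyme-gene network linking.

Builds a typed tri-partite graph from a metabolite-enzyme annotation
table (HMDB-style, unscored) and a scored protein-protein interaction
table (STRING-style confidence scores), filters PPI edges below a
confidence threshold (default 0.7; scores given on a 0-1000 scale are
rescaled automatically), and reports the shortest metabolite -> gene
paths of the allowed topologies: metabolite - enzyme - gene, or
metabolite - enzyme - intermediate protein - gene.  A PPI edge incident
to a candidate gene's encoded protein counts as reaching the gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

DEFAULT_SCORE_THRESHOLD = 0.7


@dataclass(frozen=True)
class LinkPath:
    """One metabolite -> gene path (2 or 3 edges)."""

    nodes: tuple[str, ...]  # metabolite, enzyme, (intermediate)?, gene
    min_score: float

    @property
    def metabolite(self) -> str:
        return self.nodes[0]

    @property
    def gene(self) -> str:
        return self.nodes[-1]

    @property
    def n_edges(self) -> int:
        return len(self.nodes) - 1


def _normalize_scores(ppi: pd.DataFrame) -> pd.DataFrame:
    ppi = ppi.copy()
    if len(ppi) and ppi["score"].max() > 1.0:
        ppi["score"] = ppi["score"] / 1000.0
    if len(ppi) and ((ppi["score"] < 0) | (ppi["score"] > 1)).any():
        raise ValueError("PPI scores must lie in [0, 1] (or 0-1000)")
    return ppi


def build_graph(
    annotation: pd.DataFrame,
    ppi: pd.DataFrame,
    candidate_genes: Mapping[str, str] | Sequence[str],
) -> nx.Graph:
    """Assemble the typed graph.

    ``annotation`` needs columns (metabolite, enzyme); ``ppi`` needs
    (protein_a, protein_b, score).  ``candidate_genes`` maps gene
    symbol -> encoded protein id (a plain list means protein = symbol
    upper-cased).  Duplicate PPI edges collapse keeping the maximum
    score.  Gene nodes attach to their protein node with an identity
    edge so that reaching the protein reaches the gene.
    """
    if not len(candidate_genes):
        raise ValueError("candidate gene list must be non-empty")
    if not isinstance(candidate_genes, Mapping):
        candidate_genes = {g: g.upper() for g in candidate_genes}
    ppi = _normalize_scores(pd.DataFrame(ppi))
    annotation = pd.DataFrame(annotation)

    g = nx.Graph()
    metabolites = set(annotation["metabolite"])
    for m in metabolites:
        g.add_node(m, kind="metabolite")
    for _, row in annotation.iterrows():
        enz = row["enzyme"]
        if enz not in g:
            g.add_node(enz, kind="protein")
        g.add_edge(row["metabolite"], enz, kind="annotation")
    for _, row in ppi.iterrows():
        a, b, s = row["protein_a"], row["protein_b"], float(row["score"])
        if a in metabolites or b in metabolites:
            raise ValueError(
                f"metabolite id {a if a in metabolites else b!r} appears "
                "in the PPI table"
            )
        if a == b:
            continue  # self-loops carry no path information
        for node in (a, b):
            if node not in g:
                g.add_node(node, kind="protein")
        if g.has_edge(a, b) and g[a][b].get("kind") == "ppi":
            g[a][b]["score"] = max(g[a][b]["score"], s)
        else:
            g.add_edge(a, b, kind="ppi", score=s)
    for gene, protein in candidate_genes.items():
        if protein not in g:
            g.add_node(protein, kind="protein")
        g.add_node(gene, kind="gene", protein=protein)
        g.add_edge(gene, protein, kind="identity")
    return g


def filter_edges(
    graph: nx.Graph, threshold: float = DEFAULT_SCORE_THRESHOLD
) -> nx.Graph:
    """Drop PPI edges with score strictly below the threshold;
    annotation and gene-identity edges are untouched."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    g = graph.copy()
    drop = [
        (a, b)
        for a, b, d in g.edges(data=True)
        if d.get("kind") == "ppi" and d["score"] < threshold
    ]
    g.remove_edges_from(drop)
    return g


def find_paths(
    graph: nx.Graph,
    metabolites: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
    max_intermediates: int = 1,
) -> list[LinkPath]:
    """All minimum-edge-count metabolite -> gene paths.

    For each (metabolite, gene) pair the 2-edge topology
    (metabolite - enzyme - gene protein) is tried first; 3-edge paths
    through one intermediate protein are reported only when no 2-edge
    path exists for that pair.  Paths are sorted by descending minimum
    PPI edge score, then lexicographically by node ids.
    """
    if max_intermediates not in (0, 1):
        raise ValueError("at most one intermediate protein is supported")
    if metabolites is None:
        metabolites = sorted(
            n for n, d in graph.nodes(data=True) if d.get("kind") == "metabolite"
        )
    if genes is None:
        genes = sorted(
            n for n, d in graph.nodes(data=True) if d.get("kind") == "gene"
        )
    out: list[LinkPath] = []
    for m in metabolites:
        if m not in graph:
            continue
        enzymes = [
            e
            for e in graph.neighbors(m)
            if graph[m][e].get("kind") == "annotation"
        ]
        for gene in genes:
            protein = graph.nodes[gene].get("protein")
            if protein is None:
                continue
            two_edge: list[LinkPath] = []
            three_edge: list[LinkPath] = []
            for e in enzymes:
                if e == protein:
                    continue
                d = graph.get_edge_data(e, protein)
                if d and d.get("kind") == "ppi":
                    two_edge.append(
                        LinkPath((m, e, gene), float(d["score"]))
                    )
                elif max_intermediates >= 1:
                    for p in graph.neighbors(e):
                        if p in (m, protein, gene) or p == e:
                            continue
                        d1 = graph.get_edge_data(e, p)
                        if not d1 or d1.get("kind") != "ppi":
                            continue
                        d2 = graph.get_edge_data(p, protein)
                        if not d2 or d2.get("kind") != "ppi":
                            continue
                        three_edge.append(
                            LinkPath(
                                (m, e, p, gene),
                                min(float(d1["score"]), float(d2["score"])),
                            )
                        )
            chosen = two_edge if two_edge else three_edge
            out.extend(chosen)
    out.sort(key=lambda p: (-p.min_score, p.nodes))
    return out


def paths_to_frame(paths: Sequence[LinkPath]) -> pd.DataFrame:
    rows = [
        {
            "metabolite": p.metabolite,
            "enzyme": p.nodes[1],
            "intermediate": p.nodes[2] if p.n_edges == 3 else "",
            "gene": p.gene,
            "n_edges": p.n_edges,
            "min_score": p.min_score,
        }
        for p in paths
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "metabolite", "enzyme", "intermediate", "gene", "n_edges",
            "min_score",
        ],
    )


def write_sif(paths: Sequence[LinkPath], path: str) -> None:
    """Paths as SIF for graph viewers."""
    seen = set()
    with open(path, "w") as fh:
        for p in paths:
            for a, b in zip(p.nodes, p.nodes[1:]):
                if (a, b) in seen:
                    continue
                seen.add((a, b))
                fh.write(f"{a}\tlink\t{b}\n")


def link_metabolites(
    annotation: pd.DataFrame,
    ppi: pd.DataFrame,
    candidate_genes: Mapping[str, str] | Sequence[str],
    metabolites: Sequence[str] | None = None,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> list[LinkPath]:
    """Build, filter and search in one call."""
    g = filter_edges(build_graph(annotation, ppi, candidate_genes), threshold)
    return find_paths(g, metabolites=metabolites)
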