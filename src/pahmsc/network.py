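"""Protein-protein interaction subnetwork assembly over selected DEGs.

Interaction tables arrive as SIF files (``node <TAB> interaction <TAB>
node``), optionally in human gene ids that are translated to rat ids
through a two-column orthology table.  The induced subnetwork over the
selected genes is annotated per node with log2 fold changes (node
center = disease effect, node boundary = treatment effect) and a
stacked significance code saying which MSC arms called the gene a DEG
(e.g. ``"A|U"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "InteractionSet",
    "NetworkModel",
    "read_sif",
    "write_sif",
    "read_orthology",
    "map_orthologs",
    "build_subnetwork",
    "significance_code",
    "write_network",
    "read_network",
    "count_affected_components",
]

#: default letter per MSC arm used in the stacked significance code
MSC_LETTERS = {"AD": "A", "BM": "B", "UCB": "U"}


def _canonical(a: str, itype: str, b: str):
    return (a, itype, b) if a <= b else (b, itype, a)


@dataclass(frozen=True)
class InteractionSet:
    """Undirected interaction edges without self-loops or duplicates."""

    edges: tuple = ()
    source: str = ""

    @classmethod
    def from_edges(cls, edges, source: str = "") -> "InteractionSet":
        seen = set()
        for a, itype, b in edges:
            if a == b:
                continue  # self-loops dropped
            seen.add(_canonical(str(a), str(itype), str(b)))
        return cls(tuple(sorted(seen)), source)

    @property
    def nodes(self) -> set:
        return {n for a, _, b in self.edges for n in (a, b)}

    def __len__(self) -> int:
        return len(self.edges)

    def merged_with(self, other: "InteractionSet") -> "InteractionSet":
        src = "+".join(s for s in (self.source, other.source) if s)
        return InteractionSet.from_edges(self.edges + other.edges, src)


def write_sif(iset: InteractionSet, path) -> None:
    with open(path, "w") as fh:
        for a, itype, b in iset.edges:
            fh.write(f"{a}\t{itype}\t{b}\n")


def read_sif(path, source: str = "") -> InteractionSet:
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"malformed SIF line: {line!r}")
            edges.append(tuple(fields))
    return InteractionSet.from_edges(edges, source)


def read_orthology(path) -> dict:
    """Two-column TSV (source id, target id) -> mapping dict."""
    frame = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("orthology table needs two columns")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def map_orthologs(edges: InteractionSet, mapping: dict):
    """Translate both endpoints of every edge through ``mapping``.

    Edges with an unmapped endpoint are dropped; returns the translated
    (deduplicated) interaction set and the number of dropped edges.
    Many-to-one mappings may collapse several input edges into one.
    """
    if not mapping:
        raise ValueError("empty orthology map")
    kept, dropped = [], 0
    for a, itype, b in edges.edges:
        if a in mapping and b in mapping:
            ma, mb = mapping[a], mapping[b]
            if ma == mb:
                dropped += 1  # many-to-one collapse onto a self-loop
                continue
            kept.append((ma, itype, mb))
        else:
            dropped += 1
    return InteractionSet.from_edges(kept, edges.source), dropped


def significance_code(deg_flags: dict) -> str:
    """Stacked subset code of MSC arms calling the gene a DEG, e.g. 'A|U'."""
    letters = [MSC_LETTERS[m] for m in ("AD", "BM", "UCB")
               if deg_flags.get(m, False)]
    return "|".join(letters)


@dataclass
class NetworkModel:
    """Induced PPI subgraph with per-node fold-change annotations."""

    graph: nx.Graph
    comparisons: tuple = ("MCT/CON", "UCB/MCT")

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set:
        return {tuple(sorted(e)) for e in self.graph.edges}


def build_subnetwork(selected, edges: InteractionSet,
                     node_attrs: pd.DataFrame | None = None,
                     comparisons=("MCT/CON", "UCB/MCT")) -> NetworkModel:
    """Induced subgraph on ``selected`` genes, keeping isolated nodes.

    ``node_attrs`` (optional) is indexed by gene id; its columns are
    copied onto the nodes (typically ``log2fc_MCT``, ``log2fc_UCB``,
    ``group`` and ``significance``).
    """
    selected = list(dict.fromkeys(selected))
    if not selected:
        raise ValueError("empty gene selection")
    g = nx.Graph()
    g.add_nodes_from(selected)
    sel = set(selected)
    for a, itype, b in edges.edges:
        if a in sel and b in sel:
            g.add_edge(a, b, interaction=itype)
    if node_attrs is not None:
        for gene in selected:
            if gene in node_attrs.index:
                g.nodes[gene].update(node_attrs.loc[gene].to_dict())
    return NetworkModel(g, tuple(comparisons))


def write_network(model: NetworkModel, sif_path, attrs_path) -> None:
    """Export edges as SIF plus a node-attribute TSV."""
    iset = InteractionSet.from_edges(
        (a, d.get("interaction", "pp"), b) for a, b, d in
        model.graph.edges(data=True)
    )
    write_sif(iset, sif_path)
    rows = []
    for node in sorted(model.graph.nodes):
        row = {"gene": node}
        row.update(model.graph.nodes[node])
        rows.append(row)
    pd.DataFrame(rows).to_csv(attrs_path, sep="\t", index=False,
                              float_format="%.6f")


def read_network(sif_path, attrs_path,
                 comparisons=("MCT/CON", "UCB/MCT")) -> NetworkModel:
    attrs = pd.read_csv(attrs_path, sep="\t", dtype={"gene": str},
                        keep_default_na=False, na_values=[])
    attrs = attrs.set_index("gene")
    # empty strings in the significance column stay empty strings
    iset = read_sif(sif_path)
    return build_subnetwork(list(attrs.index), iset, attrs, comparisons)


def count_affected_components(model: NetworkModel, msc: str) -> int:
    """Connected components containing >= 1 gene significant for ``msc``.

    ``msc`` is an arm label (``"AD"``, ``"BM"``, ``"UCB"``); a node counts
    when its ``significance`` code contains the arm's letter.
    """
    letter = MSC_LETTERS[msc]
    count = 0
    for comp in nx.connected_components(model.graph):
        for node in comp:
            code = str(model.graph.nodes[node].get("significance", ""))
            if letter in code.split("|"):
                count += 1
                break
    return count
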