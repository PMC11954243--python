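"""Construction of the multi-channel gene graph.

Nodes are the distinct genes of the selected rules.  Four edge channels are
stacked into an m x m x 4 attribute tensor:

0. *information*: for gene pairs co-occurring in some selected rule, the mean
   of the two genes' mutual-information and class-correlation statistics;
   edges at or below a 0.3 threshold are dropped as uninformative,
1. *PPI*: STRING combined score / 1000 for pairs scoring >= 500,
2. *KEGG* and 3. *GO*: binary co-membership in an enriched (p < 0.05) term.

The three prior-knowledge channels are scaled by lambda, the mean nonzero
information-edge weight, so curated priors stay auxiliary to the mined
associations.  Node features are per-sample one-hot low/medium/high codes
over a shared static structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .arm import ClassAssociationRule, GeneStats
from .io_formats import AnnotationChart, OmicsType, PPITable
from .preprocess import DiscretizedDataset

CHANNELS = ("information", "ppi", "kegg", "go")


class PriorSource(str, Enum):
    PPI = "PPI"
    KEGG = "KEGG"
    GO = "GO"


def _check_square(nodes: list[str], w: np.ndarray) -> None:
    m = len(nodes)
    if w.shape != (m, m):
        raise ValueError("adjacency shape does not match node count")
    if not np.allclose(w, w.T):
        raise ValueError("adjacency must be symmetric")
    if np.abs(np.diag(w)).max(initial=0.0) > 0:
        raise ValueError("adjacency must have a zero diagonal")


@dataclass
class InformationAdjacency:
    nodes: list[str]
    weights: np.ndarray

    def __post_init__(self):
        _check_square(self.nodes, self.weights)


@dataclass
class PriorAdjacency:
    nodes: list[str]
    weights: np.ndarray
    source: PriorSource

    def __post_init__(self):
        _check_square(self.nodes, self.weights)


@dataclass
class FinalGraph:
    """Shared static graph with an m x m x 4 edge-attribute tensor."""

    nodes: list[str]
    edge_attr: np.ndarray
    lam: float

    def __post_init__(self):
        m = len(self.nodes)
        if self.edge_attr.shape != (m, m, len(CHANNELS)):
            raise ValueError("edge_attr must be m x m x 4")

    def directed_edges(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(src, dst, attr) arrays over the directed expansion of the edges.

        An edge exists wherever any channel is nonzero; both directions are
        returned, self-loops excluded (the attention layer adds its own
        explicit self term).
        """
        any_edge = (self.edge_attr != 0).any(axis=2)
        np.fill_diagonal(any_edge, False)
        src, dst = np.nonzero(any_edge)
        return src, dst, self.edge_attr[src, dst, :]

    @property
    def n_undirected_edges(self) -> int:
        return int(len(self.directed_edges()[0]) // 2)


@dataclass
class SampleGraph:
    """One sample's one-hot node features over the shared FinalGraph."""

    graph: FinalGraph
    node_features: np.ndarray  # m x 3
    label: str
    sample_id: str = ""

    def __post_init__(self):
        m = len(self.graph.nodes)
        if self.node_features.shape != (m, 3):
            raise ValueError("node_features must be m x 3")
        if not np.array_equal(self.node_features.sum(axis=1), np.ones(m)):
            raise ValueError("node features must be one-hot")


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_information_adjacency(cars: list[ClassAssociationRule], stats: GeneStats,
                                nodes: list[str], threshold: float = 0.3
                                ) -> InformationAdjacency:
    """Mined-association channel: rule co-occurrence weighted by gene statistics.

    e_ij = (infogain_i + infogain_j + correlation_i + correlation_j) / 4 for
    every unordered pair inside some rule antecedent; weights <= threshold
    are zeroed.
    """
    idx = {g: i for i, g in enumerate(nodes)}
    m = len(nodes)
    w = np.zeros((m, m))
    for rule in cars:
        feats = sorted({it.feature_uid for it in rule.antecedent})
        for a_pos in range(len(feats)):
            for b_pos in range(a_pos + 1, len(feats)):
                i, j = idx[feats[a_pos]], idx[feats[b_pos]]
                e = (stats.infogain[feats[a_pos]] + stats.infogain[feats[b_pos]]
                     + stats.correlation[feats[a_pos]] + stats.correlation[feats[b_pos]]) / 4.0
                if e > threshold:
                    w[i, j] = w[j, i] = e
    return InformationAdjacency(nodes, w)


def _node_symbol(uid: str) -> tuple[OmicsType, str]:
    omics, _, symbol = uid.partition(":")
    return OmicsType(omics), symbol


def build_ppi_adjacency(ppi: PPITable, nodes: list[str],
                        score_threshold: float = 500.0) -> PriorAdjacency:
    """PPI channel: combined score / 1000 for pairs scoring >= threshold.

    Matching is by raw gene symbol, bridging mRNA and methylation layers;
    miRNA nodes never connect.  Two nodes carrying the same symbol (the same
    gene seen in two omics layers) are linked with weight 1.0 whenever that
    symbol occurs in the retained PPI network.
    """
    m = len(nodes)
    w = np.zeros((m, m))
    kept = {pair: s for pair, s in ppi.pair_scores().items() if s >= score_threshold}
    in_network = {g for pair in kept for g in pair}
    info = [_node_symbol(u) for u in nodes]
    for i in range(m):
        om_i, sym_i = info[i]
        if om_i == OmicsType.MIRNA:
            continue
        for j in range(i + 1, m):
            om_j, sym_j = info[j]
            if om_j == OmicsType.MIRNA:
                continue
            if sym_i == sym_j:
                if sym_i in in_network:
                    w[i, j] = w[j, i] = 1.0
                continue
            pair = (sym_i, sym_j) if sym_i <= sym_j else (sym_j, sym_i)
            if pair in kept:
                w[i, j] = w[j, i] = kept[pair] / 1000.0
    return PriorAdjacency(nodes, w, PriorSource.PPI)


def build_term_adjacency(chart: AnnotationChart, nodes: list[str],
                         p_threshold: float = 0.05) -> PriorAdjacency:
    """KEGG/GO channel: binary co-membership in an enriched term (p < threshold)."""
    m = len(nodes)
    w = np.zeros((m, m))
    symbols = [_node_symbol(u)[1] for u in nodes]
    for _, p, genes in chart.records:
        if p >= p_threshold:
            continue
        members = [i for i, s in enumerate(symbols) if s in genes]
        for a_pos in range(len(members)):
            for b_pos in range(a_pos + 1, len(members)):
                i, j = members[a_pos], members[b_pos]
                if i != j:
                    w[i, j] = w[j, i] = 1.0
    source = PriorSource.GO if chart.source.value == "GO" else PriorSource.KEGG
    return PriorAdjacency(nodes, w, source)


def stack_final(info: InformationAdjacency, ppi: PriorAdjacency,
                kegg: PriorAdjacency, go: PriorAdjacency,
                lambda_mode: str = "nonzero_mean") -> FinalGraph:
    """Stack the four channels, scaling priors by lambda.

    lambda is the mean of the nonzero information-edge weights (default) or
    of all m^2 entries (``lambda_mode="all"``).
    """
    for adj in (ppi, kegg, go):
        if adj.nodes != info.nodes:
            raise ValueError("all adjacencies must share the node order")
    nz = info.weights[info.weights != 0]
    if nz.size == 0:
        raise ValueError("information adjacency has no edges; lambda undefined")
    lam = float(info.weights.mean()) if lambda_mode == "all" else float(nz.mean())
    edge_attr = np.stack(
        [info.weights, lam * ppi.weights, lam * kegg.weights, lam * go.weights], axis=2)
    return FinalGraph(info.nodes, edge_attr, lam)


def empty_prior(nodes: list[str], source: PriorSource) -> PriorAdjacency:
    """An all-zero prior channel (the no-prior ablation)."""
    m = len(nodes)
    return PriorAdjacency(nodes, np.zeros((m, m)), source)


def build_sample_graphs(fg: FinalGraph, dds: DiscretizedDataset,
                        nodes: list[str],
                        sample_ids: list[str] | None = None) -> list[SampleGraph]:
    """One-hot node features per sample over the shared static graph."""
    if nodes != fg.nodes:
        raise ValueError("node order must match the final graph")
    col = {u: j for j, u in enumerate(dds.feature_uids)}
    missing = [u for u in nodes if u not in col]
    if missing:
        raise ValueError(f"nodes absent from the discretized dataset: {missing[:3]}")
    cols = np.array([col[u] for u in nodes])
    if sample_ids is None:
        sample_ids = list(dds.sample_ids)
    rows = dds.rows_for(sample_ids)
    label_of = dict(zip(dds.sample_ids, dds.labels))
    graphs = []
    eye = np.eye(3)
    for sid, r in zip(sample_ids, rows):
        x = eye[dds.levels[r, cols]]
        graphs.append(SampleGraph(fg, x, label_of[sid], sid))
    return graphs


# ---------------------------------------------------------------------------
# Serialization (nodes JSON + COO edge TSV + metadata JSON)
# ---------------------------------------------------------------------------

def save_graph_bundle(fg: FinalGraph, out_dir: str | Path,
                      thresholds: dict | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "nodes.json").write_text(json.dumps(fg.nodes, indent=0))
    iu, ju = np.nonzero(np.triu((fg.edge_attr != 0).any(axis=2), k=1))
    df = pd.DataFrame({"i": iu, "j": ju})
    for c, name in enumerate(CHANNELS):
        df[name] = fg.edge_attr[iu, ju, c]
    df.to_csv(out / "edges.tsv", sep="\t", index=False)
    meta = {"lambda": fg.lam, "n_nodes": len(fg.nodes), "channels": list(CHANNELS)}
    meta.update(thresholds or {})
    (out / "meta.json").write_text(json.dumps(meta, indent=1))


def load_graph_bundle(in_dir: str | Path) -> FinalGraph:
    src = Path(in_dir)
    nodes = json.loads((src / "nodes.json").read_text())
    meta = json.loads((src / "meta.json").read_text())
    m = len(nodes)
    edge_attr = np.zeros((m, m, len(CHANNELS)))
    df = pd.read_csv(src / "edges.tsv", sep="\t")
    for _, row in df.iterrows():
        i, j = int(row["i"]), int(row["j"])
        for c, name in enumerate(CHANNELS):
            edge_attr[i, j, c] = edge_attr[j, i, c] = row[name]
    return FinalGraph(nodes, edge_attr, float(meta["lambda"]))
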