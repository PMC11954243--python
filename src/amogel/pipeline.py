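"""End-to-end orchestration: preprocess -> mine -> graph -> train -> evaluate -> rank.

Every stage is a pure function of its inputs and the single trial seed; the
filter-survival counts (features after variance/ANOVA filtering, rules per
class, nodes and edges per channel) are logged and returned so a run can be
audited against its configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arm, graph_build, io_formats, model as model_mod, preprocess, ranking_eval
from .io_formats import AnnotationSource, OmicsMatrix, OmicsType
from .model import ModelConfig

logger = logging.getLogger(__name__)


@dataclass
class ArmConfig:
    k: int = 1000                 # top-k rules kept per class
    min_confidence: float = 0.5
    max_antecedent_len: int | None = 3
    init_support: float = 0.9
    support_step: float = 0.05
    support_floor: float = 0.1
    init_mode: str = "fixed"      # or "scaled": 1 - 1/|db| per class


@dataclass
class GraphConfig:
    info_edge_threshold: float = 0.3
    ppi_score_threshold: float = 500.0
    term_p_threshold: float = 0.05
    lambda_mode: str = "nonzero_mean"


@dataclass
class PipelineConfig:
    variance_threshold: float = 0.001
    anova_k: dict = field(default_factory=lambda: {"mRNA": 20, "methylation": 15,
                                                   "miRNA": "all"})
    split_fraction: float = 0.7
    discretize_scheme: str = "quantile"
    arm: ArmConfig = field(default_factory=ArmConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    use_prior: bool = True
    use_gnn: bool = True
    use_dnn: bool = True
    n_trials: int = 5
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5)
    top_n_biomarkers: int = 100

    def __post_init__(self):
        if not (self.use_gnn or self.use_dnn):
            raise ValueError("at least one of use_gnn/use_dnn must be enabled")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (("arm", ArmConfig), ("graph", GraphConfig), ("model", ModelConfig)):
            if key in d and isinstance(d[key], dict):
                if key == "model" and "mlp_dims" in d[key]:
                    d[key]["mlp_dims"] = tuple(d[key]["mlp_dims"])
                d[key] = sub(**d[key])
        if "seeds" in d:
            d["seeds"] = tuple(d["seeds"])
        return cls(**d)


@dataclass
class TrialResult:
    seed: int
    metrics: dict[str, float]
    model: model_mod.TrainedModel
    ranking: ranking_eval.GeneRanking
    nodes: list[str]
    cars: list
    split: preprocess.SplitSpec
    final_graph: graph_build.FinalGraph
    counts: dict[str, int]
    dds: preprocess.DiscretizedDataset


@dataclass
class PriorTables:
    ppi: io_formats.PPITable | None = None
    kegg: io_formats.AnnotationChart | None = None
    go: io_formats.AnnotationChart | None = None


# ---------------------------------------------------------------------------
# Stage functions
# ---------------------------------------------------------------------------

def preprocess_stage(matrices: list[OmicsMatrix], labels: dict[str, str],
                     cfg: PipelineConfig, seed: int
                     ) -> tuple[preprocess.MultiOmicsDataset, preprocess.SplitSpec,
                                preprocess.DiscretizedDataset, dict[str, int]]:
    counts: dict[str, int] = {}
    aligned, labels = preprocess.intersect_samples(matrices, labels)
    counts["samples"] = aligned[0].n_samples
    filtered = []
    for m in aligned:
        filt = preprocess.variance_filter(m, cfg.variance_threshold)
        counts[f"{m.omics_type.value}_after_variance"] = filt.n_features
        filtered.append(filt)
    # the split precedes ANOVA selection so every fitted quantity — selected
    # features, cutpoints, rule statistics, model weights — is training-only
    split = preprocess.stratified_split(
        preprocess.concat_multiomics(filtered, labels), cfg.split_fraction, seed)
    selected = []
    for m in filtered:
        k = cfg.anova_k.get(m.omics_type.value, "all")
        if k != "all":
            rows = [m.sample_ids.index(s) for s in split.train_ids]
            train_view = OmicsMatrix(list(split.train_ids), list(m.feature_ids),
                                     m.values[rows], m.omics_type)
            picked = preprocess.anova_select(train_view, labels,
                                             min(int(k), m.n_features))
            cols = [m.feature_ids.index(f) for f in picked.feature_ids]
            m = OmicsMatrix(list(m.sample_ids), list(picked.feature_ids),
                            m.values[:, cols], m.omics_type)
        counts[f"{m.omics_type.value}_selected"] = m.n_features
        pc1 = preprocess.check_pc1_variance(m)
        if pc1 >= 0.5:
            logger.warning("%s: PC1 explains %.1f%% of variance (>= 50%%)",
                           m.omics_type.value, 100 * pc1)
        selected.append(m)
    ds = preprocess.concat_multiomics(selected, labels)
    counts["total_features"] = len(ds.feature_uids)
    dds = preprocess.discretize(ds, split, cfg.discretize_scheme)
    return ds, split, dds, counts


def mine_stage(dds: preprocess.DiscretizedDataset, split: preprocess.SplitSpec,
               cfg: ArmConfig) -> tuple[list, arm.GeneStats, dict[str, int]]:
    counts: dict[str, int] = {}
    classes = sorted(set(np.array(dds.labels)[dds.rows_for(split.train_ids)]))
    dbs = {c: arm.build_transactions(dds, split, c) for c in classes}
    stats = arm.gene_stats(dds, split)
    rules_by_class = {}
    for cls, db in dbs.items():
        init = (arm.initial_support_from_db(db) if cfg.init_mode == "scaled"
                else cfg.init_support)
        stop, itemsets = arm.iterative_min_support_search(
            db, max_rules=cfg.k, init_support=init, step=cfg.support_step,
            floor=cfg.support_floor, max_len=cfg.max_antecedent_len)
        cars = arm.generate_cars(itemsets, cls, dbs, cfg.min_confidence)
        for r in cars:
            arm.score_car(r, stats)
        rules_by_class[cls] = cars
        counts[f"itemsets_{cls}"] = len(itemsets)
        counts[f"rules_{cls}"] = len(cars)
        logger.info("class %s: stopped at support %.3f with %d itemsets, %d rules",
                    cls, stop, len(itemsets), len(cars))
    top = arm.select_top_k(rules_by_class, cfg.k)
    counts["rules_selected"] = len(top)
    return top, stats, counts


def graph_stage(cars: list, stats: arm.GeneStats, priors: PriorTables,
                cfg: GraphConfig, use_prior: bool
                ) -> tuple[graph_build.FinalGraph, list[str], dict[str, int]]:
    nodes = arm.selected_genes(cars)
    info = graph_build.build_information_adjacency(cars, stats, nodes,
                                                   cfg.info_edge_threshold)
    if use_prior:
        if priors.ppi is None or priors.kegg is None or priors.go is None:
            raise ValueError("use_prior=True but prior tables are missing")
        ppi = graph_build.build_ppi_adjacency(priors.ppi, nodes, cfg.ppi_score_threshold)
        kegg = graph_build.build_term_adjacency(priors.kegg, nodes, cfg.term_p_threshold)
        go = graph_build.build_term_adjacency(priors.go, nodes, cfg.term_p_threshold)
    else:
        ppi = graph_build.empty_prior(nodes, graph_build.PriorSource.PPI)
        kegg = graph_build.empty_prior(nodes, graph_build.PriorSource.KEGG)
        go = graph_build.empty_prior(nodes, graph_build.PriorSource.GO)
    fg = graph_build.stack_final(info, ppi, kegg, go, cfg.lambda_mode)
    counts = {
        "nodes": len(nodes),
        "info_edges": int((info.weights != 0).sum() // 2),
        "ppi_edges": int((ppi.weights != 0).sum() // 2),
        "kegg_edges": int((kegg.weights != 0).sum() // 2),
        "go_edges": int((go.weights != 0).sum() // 2),
    }
    return fg, nodes, counts


def run_single_trial(matrices: list[OmicsMatrix], labels: dict[str, str],
                     cfg: PipelineConfig, seed: int,
                     priors: PriorTables | None = None) -> TrialResult:
    """One full split -> mine -> graph -> train -> evaluate -> rank pass."""
    priors = priors or PriorTables()
    ds, split, dds, counts = preprocess_stage(matrices, labels, cfg, seed)
    cars, stats, mine_counts = mine_stage(dds, split, cfg.arm)
    counts.update(mine_counts)
    fg, nodes, graph_counts = graph_stage(cars, stats, priors, cfg.graph, cfg.use_prior)
    counts.update(graph_counts)

    col = {u: j for j, u in enumerate(ds.feature_uids)}
    node_cols = np.array([col[u] for u in nodes])
    sample_index = {s: i for i, s in enumerate(ds.sample_ids)}

    def subset(ids):
        rows = np.array([sample_index[s] for s in ids])
        graphs = graph_build.build_sample_graphs(fg, dds, nodes, list(ids))
        return graphs, ds.values[np.ix_(rows, node_cols)], [labels[s] for s in ids]

    train_graphs, train_x, train_y = subset(split.train_ids)
    test_graphs, test_x, test_y = subset(split.test_ids)

    mcfg = dataclasses.replace(cfg.model, seed=seed, use_gnn=cfg.use_gnn,
                               use_dnn=cfg.use_dnn)
    trained = model_mod.train(train_graphs, train_x, train_y, mcfg)

    probs = model_mod.predict_proba(trained, test_graphs, test_x)
    preds = [trained.classes[i] for i in probs.argmax(axis=1)]
    metrics = {
        "accuracy": ranking_eval.accuracy(test_y, preds),
        "macro_f1": ranking_eval.macro_f1(test_y, preds, trained.classes),
        "macro_auroc": ranking_eval.macro_auroc(test_y, probs, trained.classes),
        "final_train_loss": trained.loss_history[-1],
    }

    ranking = None
    if cfg.use_gnn:
        all_graphs = train_graphs + test_graphs
        att = model_mod.extract_attention(trained, all_graphs)
        ranking = ranking_eval.rank_genes(att, nodes, dds.omics_of)
    return TrialResult(seed, metrics, trained, ranking, nodes, cars, split, fg,
                       counts, dds)


# ---------------------------------------------------------------------------
# Directory-level entry point
# ---------------------------------------------------------------------------

DATA_FILES = {OmicsType.MRNA: "mrna.tsv", OmicsType.METHYLATION: "methylation.tsv",
              OmicsType.MIRNA: "mirna.tsv"}


def load_data_dir(data_dir: str | Path, use_prior: bool = True
                  ) -> tuple[list[OmicsMatrix], dict[str, str], PriorTables]:
    src = Path(data_dir)
    matrices = [io_formats.read_omics_matrix(src / fname, om)
                for om, fname in DATA_FILES.items()]
    labels = io_formats.read_labels(src / "labels.tsv")
    priors = PriorTables()
    if use_prior:
        for name in ("ppi.tsv", "kegg_chart.tsv", "go_chart.tsv"):
            if not (src / name).exists():
                raise FileNotFoundError(f"use_prior=True but {src / name} is missing")
        priors = PriorTables(
            ppi=io_formats.read_ppi_table(src / "ppi.tsv"),
            kegg=io_formats.read_annotation_chart(src / "kegg_chart.tsv",
                                                  AnnotationSource.KEGG),
            go=io_formats.read_annotation_chart(src / "go_chart.tsv", AnnotationSource.GO),
        )
    return matrices, labels, priors


def run_pipeline(cfg: PipelineConfig, data_dir: str | Path,
                 out_dir: str | Path) -> dict:
    """Full multi-trial run from a data directory; artifacts to `out_dir`.

    Writes report.json (per-trial and aggregate metrics), biomarkers.tsv from
    the best trial, the best trial's rules and graph bundle, the resolved
    configuration, and the filter-survival counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrices, labels, priors = load_data_dir(data_dir, cfg.use_prior)
    seeds = list(cfg.seeds)[: cfg.n_trials]
    results = []
    for seed in seeds:
        results.append(run_single_trial(matrices, labels, cfg, seed, priors))
    report = ranking_eval.MetricsReport([r.metrics for r in results])
    report.to_json(out / "report.json")
    best = ranking_eval.best_trial(results)
    best_result = results[best]
    if best_result.ranking is not None:
        n = min(cfg.top_n_biomarkers, len(best_result.ranking.table))
        ranking_eval.top_biomarkers(best_result.ranking, n).to_csv(
            out / "biomarkers.tsv", sep="\t", index=False)
    arm.save_rules(best_result.cars, out / "rules.json")
    graph_build.save_graph_bundle(best_result.final_graph, out / "graph",
                                  dataclasses.asdict(cfg.graph))
    cfg.to_yaml(out / "config.yaml")
    (out / "counts.json").write_text(json.dumps(
        {"best_trial_seed": best_result.seed, **best_result.counts},
        indent=1, sort_keys=True))
    return {"report": report, "results": results, "best": best}
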