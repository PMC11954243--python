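"""Synthetic multi-omics cohorts with planted subtype signal and priors.

The generator emulates the shape of the real inputs — three omics layers of
very different widths (mRNA > methylation > miRNA), a subtype label per
sample, a STRING-style PPI table and two DAVID-style annotation charts —
while planting known class-discriminative features so recovery can be scored
exactly.  Background features are Gaussian noise; each class's planted
features have their mean shifted by ``effect_size`` noise standard deviations
in that class.  A configurable fraction of planted genes is wired into the
synthetic priors; decoy PPI edges below the score threshold and decoy terms
above the p-value threshold are always included so every filter branch is
exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (AnnotationChart, AnnotationSource, OmicsMatrix, OmicsType,
                         PPITable, write_annotation_chart, write_labels,
                         write_omics_matrix, write_ppi_table)

OMICS_KEYS = (OmicsType.MRNA, OmicsType.METHYLATION, OmicsType.MIRNA)


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults model a small three-subtype cohort: 50 samples per class, 200
    features split 100/70/30 across mRNA/methylation/miRNA, five planted
    discriminative features per class shifted by three noise SDs, and half of
    the planted genes wired into the synthetic priors.
    """

    n_samples_per_class: int = 50
    n_classes: int = 3
    n_features: tuple[int, int, int] = (100, 70, 30)
    n_planted_per_class: int = 5
    effect_size: float = 3.0
    noise_sd: float = 1.0
    prior_overlap: float = 0.5
    n_decoy_ppi: int = 30
    n_decoy_terms: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_planted_per_class * self.n_classes > sum(self.n_features):
            raise ValueError("more planted features than features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.prior_overlap <= 1:
            raise ValueError("prior_overlap must be in [0, 1]")


@dataclass
class GroundTruth:
    planted: dict[str, list[str]] = field(default_factory=dict)  # class -> uids
    prior_edges: list[tuple[str, str]] = field(default_factory=list)

    @property
    def all_planted(self) -> list[str]:
        return sorted({u for uids in self.planted.values() for u in uids})


def _feature_names(cfg: SimConfig) -> dict[OmicsType, list[str]]:
    n_mrna, n_meth, n_mirna = cfg.n_features
    mrna = [f"GENE{i:04d}" for i in range(n_mrna)]
    # methylation reuses mRNA symbols so cross-omics uid disambiguation and
    # symbol-level prior matching are both exercised
    meth = [f"GENE{i:04d}" for i in range(n_meth)] if n_meth <= n_mrna else (
        mrna + [f"MGENE{i:04d}" for i in range(n_meth - n_mrna)])
    mirna = [f"MIR{i:04d}" for i in range(n_mirna)]
    return {OmicsType.MRNA: mrna, OmicsType.METHYLATION: meth, OmicsType.MIRNA: mirna}


def generate_multiomics(cfg: SimConfig
                        ) -> tuple[list[OmicsMatrix], dict[str, str], GroundTruth]:
    """Three omics matrices, labels and the planted-feature ground truth.

    Planted features are spread across the omics layers proportionally to the
    layer widths (at least one per layer when possible) so mined rules mix
    intra- and inter-omics items.
    """
    rng = np.random.default_rng(cfg.seed)
    names = _feature_names(cfg)
    n_total = cfg.n_samples_per_class * cfg.n_classes
    classes = [f"C{c}" for c in range(cfg.n_classes)]
    labels_arr = np.repeat(classes, cfg.n_samples_per_class)
    sample_ids = [f"S{i:04d}" for i in range(n_total)]

    # assign planted slots: round-robin over omics weighted by width
    per_omics_counts = np.array(cfg.n_features, dtype=float)
    gt = GroundTruth()
    slot_cursor = {om: 0 for om in OMICS_KEYS}
    order = np.argsort(-per_omics_counts)
    planted_cols: dict[OmicsType, list[tuple[int, int]]] = {om: [] for om in OMICS_KEYS}
    for c_idx, cls in enumerate(classes):
        uids = []
        for p in range(cfg.n_planted_per_class):
            om = OMICS_KEYS[order[p % len(OMICS_KEYS)]]
            col = slot_cursor[om]
            if col >= cfg.n_features[OMICS_KEYS.index(om)]:
                om = OmicsType.MRNA
                col = slot_cursor[om]
            slot_cursor[om] += 1
            planted_cols[om].append((col, c_idx))
            uids.append(f"{om.value}:{names[om][col]}")
        gt.planted[cls] = sorted(uids)

    matrices = []
    for om in OMICS_KEYS:
        n_feat = cfg.n_features[OMICS_KEYS.index(om)]
        vals = rng.normal(0.0, cfg.noise_sd, size=(n_total, n_feat))
        for col, c_idx in planted_cols[om]:
            rows = labels_arr == classes[c_idx]
            vals[rows, col] += cfg.effect_size * cfg.noise_sd
        matrices.append(OmicsMatrix(sample_ids, list(names[om]), vals, om))
    labels = dict(zip(sample_ids, labels_arr))
    return matrices, labels, gt


def generate_prior_tables(cfg: SimConfig, gt: GroundTruth
                          ) -> tuple[PPITable, AnnotationChart, AnnotationChart]:
    """Synthetic PPI + KEGG/GO charts partially overlapping the planted genes.

    A ``prior_overlap`` fraction of planted (non-miRNA) genes is wired into
    PPI edges with scores in [500, 1000] and into enriched terms (p < 0.05).
    Random decoy PPI edges (scores spanning [100, 1000]) and decoy terms
    (p >= 0.05) are added, including one fixed PPI decoy at score 400 and one
    fixed term decoy at p = 0.2 that downstream thresholds must reject.
    """
    rng = np.random.default_rng(cfg.seed + 104729)
    names = _feature_names(cfg)
    planted_symbols = sorted({u.split(":", 1)[1] for u in gt.all_planted
                              if not u.startswith(OmicsType.MIRNA.value + ":")})
    n_wired = int(round(cfg.prior_overlap * len(planted_symbols)))
    wired = list(rng.choice(planted_symbols, size=n_wired, replace=False)) if n_wired else []

    rows = []
    for a_pos in range(len(wired)):
        for b_pos in range(a_pos + 1, len(wired)):
            rows.append((wired[a_pos], wired[b_pos], float(rng.uniform(500, 1000))))
    pool = [g for g in names[OmicsType.MRNA] if g not in set(planted_symbols)]
    for _ in range(cfg.n_decoy_ppi):
        a, b = rng.choice(pool, size=2, replace=False)
        rows.append((a, b, float(rng.uniform(100, 1000))))
    if len(pool) >= 2:
        rows.append((pool[0], pool[1], 400.0))  # fixed sub-threshold decoy
    ppi = PPITable(_canonical_ppi_frame(rows))
    gt.prior_edges = [(a, b) for a, b, s in rows if s >= 500]

    charts = []
    for source, tag in ((AnnotationSource.KEGG, "hsa"), (AnnotationSource.GO, "GO:")):
        records = []
        if len(wired) >= 2:
            records.append((f"{tag}0001", float(rng.uniform(1e-6, 0.04)), frozenset(wired)))
        for t in range(cfg.n_decoy_terms):
            members = frozenset(rng.choice(pool, size=min(4, len(pool)), replace=False))
            records.append((f"{tag}1{t:03d}", float(rng.uniform(0.05, 1.0)), members))
        records.append((f"{tag}9999", 0.2,
                        frozenset(rng.choice(pool, size=min(3, len(pool)), replace=False))))
        records.sort(key=lambda r: r[0])
        charts.append(AnnotationChart(records, source))
    return ppi, charts[0], charts[1]


def _canonical_ppi_frame(rows: list[tuple[str, str, float]]) -> pd.DataFrame:
    canon = {}
    for a, b, s in rows:
        pair = (a, b) if a <= b else (b, a)
        canon[pair] = max(canon.get(pair, 0.0), s)
    data = sorted((a, b, s) for (a, b), s in canon.items())
    return pd.DataFrame(data, columns=["gene_a", "gene_b", "combined_score"])


def write_simulation(cfg: SimConfig, out_dir: str | Path) -> GroundTruth:
    """Emit a full synthetic data directory in the formats the readers accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrices, labels, gt = generate_multiomics(cfg)
    fnames = {OmicsType.MRNA: "mrna.tsv", OmicsType.METHYLATION: "methylation.tsv",
              OmicsType.MIRNA: "mirna.tsv"}
    for m in matrices:
        write_omics_matrix(m, out / fnames[m.omics_type])
    write_labels(labels, out / "labels.tsv")
    ppi, kegg, go = generate_prior_tables(cfg, gt)
    write_ppi_table(ppi, out / "ppi.tsv")
    write_annotation_chart(kegg, out / "kegg_chart.tsv")
    write_annotation_chart(go, out / "go_chart.tsv")
    import json
    (out / "ground_truth.json").write_text(json.dumps(
        {"planted": gt.planted, "prior_edges": gt.prior_edges}, indent=1, sort_keys=True))
    return gt


# ---------------------------------------------------------------------------
# Hand-enumerable worked example
# ---------------------------------------------------------------------------

def make_worked_example() -> tuple[list[OmicsMatrix], dict[str, str]]:
    """A fixed 12-sample, 8-feature, 2-class cohort small enough to mine by hand.

    Four mRNA features, two methylation features (symbols shared with mRNA)
    and two miRNA features.  GENE0 and GENE1 separate the classes cleanly;
    the remaining features are fixed low-amplitude fillers.  Byte-identical
    across runs: every value is a literal.
    """
    sample_ids = [f"W{i:02d}" for i in range(12)]
    labels = {s: ("A" if i < 6 else "B") for i, s in enumerate(sample_ids)}
    mrna = np.array([
        # GENE0 GENE1 GENE2 GENE3
        [5.0, 1.0, 0.10, 0.3],
        [5.5, 1.2, 0.20, 0.1],
        [6.0, 0.8, 0.30, 0.2],
        [5.2, 1.1, 0.40, 0.3],
        [5.8, 0.9, 0.50, 0.1],
        [5.4, 1.0, 0.60, 0.2],
        [1.0, 5.0, 0.70, 0.3],
        [1.2, 5.5, 0.80, 0.1],
        [0.8, 6.0, 0.90, 0.2],
        [1.1, 5.2, 1.00, 0.3],
        [0.9, 5.8, 1.10, 0.1],
        [1.0, 5.4, 1.20, 0.2],
    ])
    meth = np.array([
        [0.9, 0.2], [0.8, 0.3], [0.9, 0.2], [0.7, 0.3], [0.8, 0.2], [0.9, 0.3],
        [0.2, 0.2], [0.3, 0.3], [0.2, 0.2], [0.1, 0.3], [0.2, 0.2], [0.3, 0.3],
    ])
    mirna = np.array([
        [2.0, 0.5], [2.2, 0.6], [2.1, 0.4], [2.3, 0.5], [2.0, 0.6], [2.2, 0.4],
        [0.5, 0.5], [0.6, 0.6], [0.4, 0.4], [0.5, 0.5], [0.6, 0.6], [0.4, 0.4],
    ])
    return ([
        OmicsMatrix(sample_ids, ["GENE0", "GENE1", "GENE2", "GENE3"], mrna, OmicsType.MRNA),
        OmicsMatrix(sample_ids, ["GENE0", "GENE1"], meth, OmicsType.METHYLATION),
        OmicsMatrix(sample_ids, ["MIR0", "MIR1"], mirna, OmicsType.MIRNA),
    ], labels)
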