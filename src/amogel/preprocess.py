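"""Sample alignment, feature selection, early fusion and discretization.

The pipeline first restricts every omics layer to the samples present in all
layers, then filters low-variance features (threshold 0.001), selects the
top-k features per omics by one-way ANOVA F statistic against the subtype
labels, concatenates the layers into one ``<omics>:<symbol>``-indexed matrix,
splits samples 7:3 stratified by subtype, and finally discretizes every
feature into low / medium / high using tertile cutpoints learned from the
training rows only.  Test rows reuse the training cutpoints, so no test-set
information leaks into any fitted quantity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_classif

from .io_formats import OmicsMatrix, OmicsType

OMICS_ORDER = (OmicsType.MRNA, OmicsType.METHYLATION, OmicsType.MIRNA)


@dataclass
class MultiOmicsDataset:
    """Concatenated multi-omics matrix with per-feature omics provenance."""

    sample_ids: list[str]
    labels: list[str]
    feature_uids: list[str]
    values: np.ndarray
    omics_of: dict[str, OmicsType]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_uids)):
            raise ValueError("matrix shape does not match id lists")
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels length mismatch")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))


@dataclass
class SplitSpec:
    """A stratified train/test partition of the samples."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int
    fraction: float = 0.7

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"train_ids": self.train_ids, "test_ids": self.test_ids,
             "seed": self.seed, "fraction": self.fraction}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitSpec":
        d = json.loads(Path(path).read_text())
        return cls(d["train_ids"], d["test_ids"], d["seed"], d["fraction"])


@dataclass
class DiscretizedDataset:
    """Three-level (low/medium/high) view of a MultiOmicsDataset.

    ``levels`` holds integer codes 0/1/2; ``cutpoints`` is features x 2 with
    the training 33.33rd and 66.67th percentiles (c1 <= c2).
    """

    sample_ids: list[str]
    labels: list[str]
    feature_uids: list[str]
    levels: np.ndarray
    cutpoints: np.ndarray
    omics_of: dict[str, OmicsType] = field(default_factory=dict)

    def rows_for(self, sample_ids: list[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([index[s] for s in sample_ids], dtype=int)


def intersect_samples(matrices: list[OmicsMatrix],
                      labels: dict[str, str]) -> tuple[list[OmicsMatrix], dict[str, str]]:
    """Restrict all omics layers (and labels) to their common samples, sorted."""
    if len(matrices) < 2:
        raise ValueError("need at least two omics matrices")
    common = set(matrices[0].sample_ids).intersection(*[set(m.sample_ids) for m in matrices[1:]])
    common &= set(labels)
    if not common:
        raise ValueError("no samples shared by all omics layers and the label table")
    order = sorted(common)
    out = []
    for m in matrices:
        idx = [m.sample_ids.index(s) for s in order]
        out.append(OmicsMatrix(order, list(m.feature_ids), m.values[idx], m.omics_type))
    return out, {s: labels[s] for s in order}


def variance_filter(m: OmicsMatrix, threshold: float = 0.001) -> OmicsMatrix:
    """Keep features whose population variance exceeds `threshold`."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    var = m.values.var(axis=0, ddof=0)
    keep = np.flatnonzero(var > threshold)
    if keep.size == 0:
        raise ValueError("variance filter removed every feature")
    return OmicsMatrix(list(m.sample_ids), [m.feature_ids[j] for j in keep],
                       m.values[:, keep], m.omics_type)


def anova_select(m: OmicsMatrix, labels: dict[str, str], k: int) -> OmicsMatrix:
    """Keep the k features with the largest one-way ANOVA F against the labels.

    Ties (including all-NaN F for degenerate features, scored 0) break
    lexicographically by feature id so the selection is reproducible.
    """
    y = np.array([labels[s] for s in m.sample_ids])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("ANOVA selection needs at least two classes")
    if counts.min() < 2:
        raise ValueError(f"class {classes[counts.argmin()]!r} has fewer than 2 samples")
    if k > m.n_features:
        raise ValueError(f"k={k} exceeds feature count {m.n_features}")
    f, _ = f_classif(m.values, y)
    f = np.nan_to_num(f, nan=0.0, posinf=np.inf)
    order = sorted(range(m.n_features), key=lambda j: (-f[j], m.feature_ids[j]))
    keep = sorted(order[:k], key=lambda j: m.feature_ids[j])
    return OmicsMatrix(list(m.sample_ids), [m.feature_ids[j] for j in keep],
                       m.values[:, keep], m.omics_type)


def check_pc1_variance(m: OmicsMatrix) -> float:
    """Explained-variance ratio of PC1 of the standardized matrix.

    The selected feature set is considered acceptably diverse when the first
    principal component explains < 50% of the variance; the caller warns (but
    does not fail) above that.
    """
    if m.n_samples < 2 or m.n_features < 1:
        raise ValueError("need >= 2 samples and >= 1 feature")
    x = m.values - m.values.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    nonconst = sd > 0
    if not nonconst.any():
        raise ValueError("matrix has rank 0 after centering")
    x = x[:, nonconst] / sd[nonconst]
    if x.shape[1] == 1:
        return 1.0
    pca = PCA(n_components=1)
    pca.fit(x)
    return float(pca.explained_variance_ratio_[0])


def concat_multiomics(matrices: list[OmicsMatrix],
                      labels: dict[str, str]) -> MultiOmicsDataset:
    """Early-fuse sample-aligned omics layers into one uid-indexed matrix.

    Columns are ordered mRNA, methylation, miRNA; a symbol shared by two
    layers stays distinguishable through its ``<omics>:<symbol>`` uid.
    """
    if not matrices:
        raise ValueError("no matrices to concatenate")
    sample_ids = list(matrices[0].sample_ids)
    for m in matrices:
        if m.n_features == 0:
            raise ValueError(f"{m.omics_type.value} matrix has no features")
        if list(m.sample_ids) != sample_ids:
            raise ValueError("matrices are not sample-aligned; run intersect_samples first")
    ordered = sorted(matrices, key=lambda m: OMICS_ORDER.index(m.omics_type))
    uids, omics_of, blocks = [], {}, []
    for m in ordered:
        for f in m.feature_ids:
            uid = f"{m.omics_type.value}:{f}"
            if uid in omics_of:
                raise ValueError(f"duplicate feature uid {uid}")
            uids.append(uid)
            omics_of[uid] = m.omics_type
        blocks.append(m.values)
    return MultiOmicsDataset(sample_ids, [labels[s] for s in sample_ids],
                             uids, np.hstack(blocks), omics_of)


def stratified_split(ds: MultiOmicsDataset, fraction: float = 0.7,
                     seed: int = 0) -> SplitSpec:
    """Per-class random split with round(fraction * class size) training rows."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    y = np.array(ds.labels)
    train, test = [], []
    for cls in ds.classes:
        members = [ds.sample_ids[i] for i in np.flatnonzero(y == cls)]
        if len(members) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        n_train = int(np.floor(fraction * len(members) + 0.5))
        n_train = min(max(n_train, 1), len(members) - 1)
        perm = rng.permutation(len(members))
        train += [members[i] for i in perm[:n_train]]
        test += [members[i] for i in perm[n_train:]]
    return SplitSpec(sorted(train), sorted(test), seed, fraction)


def discretize(ds: MultiOmicsDataset, split: SplitSpec,
               scheme: str = "quantile") -> DiscretizedDataset:
    """Map every feature to low/medium/high with training-derived cutpoints.

    ``quantile`` (default) uses the 33.33rd/66.67th training percentiles with
    linear interpolation; ``width`` splits the training range into three equal
    bins.  level = low if v <= c1, medium if c1 < v <= c2, else high; a
    constant training feature maps everything to low.
    """
    index = {s: i for i, s in enumerate(ds.sample_ids)}
    train_rows = np.array([index[s] for s in split.train_ids], dtype=int)
    tr = ds.values[train_rows]
    if scheme == "quantile":
        c1 = np.percentile(tr, 100.0 / 3.0, axis=0, method="linear")
        c2 = np.percentile(tr, 200.0 / 3.0, axis=0, method="linear")
    elif scheme == "width":
        lo, hi = tr.min(axis=0), tr.max(axis=0)
        c1 = lo + (hi - lo) / 3.0
        c2 = lo + 2.0 * (hi - lo) / 3.0
    else:
        raise ValueError(f"unknown discretization scheme {scheme!r}")
    cutpoints = np.column_stack([c1, c2])
    levels = assign_levels(ds.values, cutpoints)
    return DiscretizedDataset(list(ds.sample_ids), list(ds.labels),
                              list(ds.feature_uids), levels, cutpoints,
                              dict(ds.omics_of))


def assign_levels(values: np.ndarray, cutpoints: np.ndarray) -> np.ndarray:
    """Pure (value, cutpoints) -> level map: 0 low, 1 medium, 2 high."""
    c1, c2 = cutpoints[:, 0], cutpoints[:, 1]
    levels = np.full(values.shape, 2, dtype=np.int8)
    levels[values <= c2] = 1
    levels[values <= c1] = 0
    return levels
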