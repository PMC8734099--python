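"""Gene labeling, feature construction, and the train/fine-tune/test splits.

Genes significant at the FDR cutoff are labeled by the sign of their log2
fold change: 0 = down-regulated (logFC < threshold), 1 = up-regulated
(logFC > threshold); everything not significant is neutral (label 2).
Significant genes that appear in a user-supplied biologically validated
list form the "bio" partition Q; neutral genes plus unvalidated
significant genes form the "non-bio" partition P. P splits 80:20 into
first-level training data T1 and held-out T2; Q splits 80:20 into the
fine-tune set F1 and the bio-test set T3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import DifferentialTable, ExpressionDataset

logger = logging.getLogger(__name__)

LABEL_DOWN = 0
LABEL_UP = 1
LABEL_NEUTRAL = 2


@dataclass
class LabeledGeneSet:
    """Genes with class labels, per-gene feature vectors, and bio flags."""

    gene_ids: list[str]
    features: np.ndarray  # (n_genes, n_samples) float32
    labels: np.ndarray  # int, in {0, 1, 2}
    bio_flags: np.ndarray  # bool
    name: str = "dataset"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.bio_flags = np.asarray(self.bio_flags, dtype=bool)
        n = len(self.gene_ids)
        if not (self.features.shape[0] == self.labels.shape[0]
                == self.bio_flags.shape[0] == n):
            raise ValueError("gene_ids, features, labels, bio_flags lengths differ")
        if not np.isin(self.labels, [0, 1, 2]).all():
            raise ValueError("labels must be in {0, 1, 2}")
        if np.any(self.bio_flags & (self.labels == LABEL_NEUTRAL)):
            raise ValueError("neutral genes can never be biologically validated")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def p_indices(self) -> np.ndarray:
        """Non-bio partition P: neutral genes plus unvalidated DEGs."""
        return np.flatnonzero(~self.bio_flags)

    @property
    def q_indices(self) -> np.ndarray:
        """Bio partition Q: validated up-/down-regulated genes."""
        return np.flatnonzero(self.bio_flags)

    def subset(self, indices: np.ndarray) -> "LabeledGeneSet":
        indices = np.asarray(indices)
        return LabeledGeneSet(
            gene_ids=[self.gene_ids[i] for i in indices],
            features=self.features[indices],
            labels=self.labels[indices],
            bio_flags=self.bio_flags[indices],
            name=self.name,
            meta=dict(self.meta),
        )


@dataclass
class DataSplit:
    """The T1/T2 (non-bio) and F1/T3 (bio) index partition of a gene set."""

    T1: np.ndarray
    T2: np.ndarray
    F1: np.ndarray
    T3: np.ndarray
    seed: int
    ratio: float = 0.8

    def __post_init__(self):
        for name in ("T1", "T2", "F1", "T3"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        parts = [self.T1, self.T2, self.F1, self.T3]
        allidx = np.concatenate(parts)
        if len(np.unique(allidx)) != len(allidx):
            raise ValueError("split parts overlap")

    def to_dict(self) -> dict:
        return {
            "T1": self.T1.tolist(), "T2": self.T2.tolist(),
            "F1": self.F1.tolist(), "T3": self.T3.tolist(),
            "seed": int(self.seed), "ratio": float(self.ratio),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DataSplit":
        return cls(T1=d["T1"], T2=d["T2"], F1=d["F1"], T3=d["T3"],
                   seed=int(d["seed"]), ratio=float(d.get("ratio", 0.8)))


# --------------------------------------------------------------------------
# Feature construction

def build_features(data: ExpressionDataset) -> tuple[np.ndarray, list[int]]:
    """Per-gene feature vectors: log2(x+1), per-gene standardized.

    Samples are interleaved across conditions by within-condition rank
    fraction (normal, tumor, normal, tumor, ... for balanced designs), so
    the normal-vs-tumor contrast shows up as a local alternation texture
    at every position of the reshaped input. Because samples within a
    condition are exchangeable, this ordering is a free convention — and
    a locally repeating layout is what lets one trained model transfer to
    datasets with different sample counts, where a block layout would put
    the condition boundary at a different spatial position for every n.
    Constant genes map to all-zero vectors. Returns
    (features, sample_order).
    """
    nidx = np.flatnonzero(data.conditions == "normal")
    tidx = np.flatnonzero(data.conditions == "tumor")
    keys = np.concatenate([
        (np.arange(len(nidx)) + 0.5) / max(len(nidx), 1),
        (np.arange(len(tidx)) + 1.0) / max(len(tidx), 1),
    ])
    order = np.concatenate([nidx, tidx])[np.argsort(keys, kind="stable")]
    x = np.log2(data.matrix[:, order] + 1.0)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return ((x - mu) / sd).astype(np.float32), order.tolist()


# --------------------------------------------------------------------------
# Differential expression stand-in

def compute_de_standin(data: ExpressionDataset, pseudocount: float = 1.0) -> DifferentialTable:
    """A simple two-group DE test for when no external DE table is supplied.

    logFC = log2((mean tumor + pc) / (mean normal + pc)) on the raw scale;
    p-values from Welch's unequal-variance t-test on log2(x + pc); FDR by
    Benjamini-Hochberg across all genes. This is a documented stand-in for
    a dedicated count-model DE package, not a replacement for one.
    """
    tmask = data.condition_mask("tumor")
    nmask = data.condition_mask("normal")
    if tmask.sum() < 2 or nmask.sum() < 2:
        raise ValueError("need at least 2 samples per condition for the DE stand-in")
    tumor = data.matrix[:, tmask]
    normal = data.matrix[:, nmask]
    logfc = np.log2((tumor.mean(axis=1) + pseudocount)
                    / (normal.mean(axis=1) + pseudocount))
    lt = np.log2(tumor + pseudocount)
    ln = np.log2(normal + pseudocount)
    res = stats.ttest_ind(lt, ln, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=np.float64)
    pvals[~np.isfinite(pvals)] = 1.0  # zero variance in both groups
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    return DifferentialTable(gene_ids=list(data.gene_ids), logfc=logfc, fdr=fdr)


# --------------------------------------------------------------------------
# Labeling

def label_genes(
    data: ExpressionDataset,
    de: DifferentialTable,
    bio: set[str] | None = None,
    fdr_cutoff: float = 0.01,
    logfc_threshold: float = 0.0,
) -> LabeledGeneSet:
    """Assign {0=down, 1=up, 2=neutral} labels and bio flags.

    A gene is significant when fdr < ``fdr_cutoff``; significant genes get
    the sign label of their logFC relative to ``logfc_threshold``. A
    significant gene whose logFC equals the threshold exactly is kept
    neutral and logged (the sign rule is strict). Genes in the matrix but
    absent from the DE table are dropped with a logged count; bio-list
    genes that are not significant keep bio_flag=False with a warning.
    """
    bio = bio or set()
    de_index = {g: i for i, g in enumerate(de.gene_ids)}
    keep, de_rows = [], []
    for i, g in enumerate(data.gene_ids):
        g = g.strip()
        j = de_index.get(g)
        if j is not None:
            keep.append(i)
            de_rows.append(j)
    if not keep:
        raise ValueError("no overlap between the DE table and the dataset's genes")
    dropped = data.n_genes - len(keep)
    if dropped:
        logger.info("dropping %d genes absent from the DE table", dropped)
    keep = np.asarray(keep)
    de_rows = np.asarray(de_rows)

    logfc = de.logfc[de_rows]
    fdr = de.fdr[de_rows]
    significant = fdr < fdr_cutoff
    labels = np.full(len(keep), LABEL_NEUTRAL, dtype=np.int64)
    labels[significant & (logfc > logfc_threshold)] = LABEL_UP
    labels[significant & (logfc < logfc_threshold)] = LABEL_DOWN
    boundary = int(np.sum(significant & (logfc == logfc_threshold)))
    if boundary:
        logger.info("%d significant genes at the exact logFC threshold kept neutral",
                    boundary)

    gene_ids = [data.gene_ids[i].strip() for i in keep]
    in_bio = np.array([g in bio for g in gene_ids])
    bio_flags = in_bio & (labels != LABEL_NEUTRAL)
    unvalidatable = int(np.sum(in_bio & (labels == LABEL_NEUTRAL)))
    if unvalidatable:
        logger.warning(
            "%d genes from the bio list are not significant and keep bio_flag=False",
            unvalidatable,
        )

    features, order = build_features(data)
    return LabeledGeneSet(
        gene_ids=gene_ids,
        features=features[keep],
        labels=labels,
        bio_flags=bio_flags,
        name=data.name,
        meta={
            "fdr_cutoff": fdr_cutoff,
            "logfc_threshold": logfc_threshold,
            "dropped_genes": dropped,
            "feature_transform": "log2p1_gene_zscore",
            "sample_order": order,
            "n_samples": data.n_samples,
        },
    )


# --------------------------------------------------------------------------
# Splits and folds

def _stratified_take(indices_by_class: list[np.ndarray], target_total: int,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Allocate ``target_total`` items across classes by largest remainder,
    then draw that many shuffled indices from each class."""
    total = sum(len(ix) for ix in indices_by_class)
    exact = [len(ix) * target_total / total for ix in indices_by_class]
    alloc = [int(np.floor(e)) for e in exact]
    remainder = target_total - sum(alloc)
    order = np.argsort([-(e - np.floor(e)) for e in exact], kind="stable")
    for j in order[:remainder]:
        alloc[j] += 1
    taken, left = [], []
    for ix, k in zip(indices_by_class, alloc):
        perm = rng.permutation(len(ix))
        taken.append(ix[perm[:k]])
        left.append(ix[perm[k:]])
    return np.sort(np.concatenate(taken)), np.sort(np.concatenate(left))


def make_split(labels: LabeledGeneSet, seed: int, ratio: float = 0.8) -> DataSplit:
    """Label-stratified random 80:20 partitions of P into (T1, T2) and of
    Q into (F1, T3); deterministic under ``seed``."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    p_idx = labels.p_indices
    q_idx = labels.q_indices
    if len(p_idx) == 0:
        raise ValueError("non-bio partition P is empty")
    if len(q_idx) < 5:
        raise ValueError(
            f"bio partition Q has {len(q_idx)} genes; at least 5 are needed "
            "for a meaningful 80:20 split"
        )
    rng = np.random.default_rng([int(seed), 0x5BD1])
    p_classes = [p_idx[labels.labels[p_idx] == c]
                 for c in (0, 1, 2) if np.any(labels.labels[p_idx] == c)]
    q_classes = [q_idx[labels.labels[q_idx] == c]
                 for c in (0, 1) if np.any(labels.labels[q_idx] == c)]
    t1, t2 = _stratified_take(p_classes, int(round(ratio * len(p_idx))), rng)
    f1, t3 = _stratified_take(q_classes, int(round(ratio * len(q_idx))), rng)
    return DataSplit(T1=t1, T2=t2, F1=f1, T3=t3, seed=int(seed), ratio=ratio)


def make_cv_folds(labels: np.ndarray, indices: np.ndarray, k: int = 5,
                  seed: int = 0) -> list[np.ndarray]:
    """k disjoint, label-stratified folds over ``indices``.

    Returns a list of k index arrays (the validation fold of each round);
    their union is ``indices``. Deterministic under ``seed``.
    """
    indices = np.asarray(indices)
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng([int(seed), 0xF01D])
    folds: list[list[int]] = [[] for _ in range(k)]
    y = np.asarray(labels)[indices]
    offset = 0
    for c in np.unique(y):
        members = indices[y == c]
        if len(members) < k:
            raise ValueError(
                f"class {c} has only {len(members)} genes; cannot form {k} folds"
            )
        perm = rng.permutation(members)
        for i, g in enumerate(perm):
            folds[(i + offset) % k].append(int(g))
        offset += len(members)  # rotate so small remainders spread across folds
    return [np.sort(np.array(f, dtype=np.int64)) for f in folds]


def quantile_filter(data: ExpressionDataset, q: float = 0.25) -> ExpressionDataset:
    """Keep genes whose mean expression strictly exceeds the q-quantile of
    all per-gene means (linear-interpolation quantile)."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    means = data.matrix.mean(axis=1)
    cutoff = float(np.quantile(means, q))
    keep = np.flatnonzero(means > cutoff)
    if keep.size == 0:
        raise ValueError(
            "quantile filter would remove every gene (all per-gene means tie "
            "at the cutoff); refusing to return an empty dataset"
        )
    return ExpressionDataset(
        gene_ids=[data.gene_ids[i] for i in keep],
        matrix=data.matrix[keep],
        sample_ids=list(data.sample_ids),
        conditions=data.conditions.copy(),
        name=data.name,
        meta={**data.meta, "quantile_filter": q},
    )
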