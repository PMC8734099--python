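"""Negative-binomial count simulator with planted up-/down-regulated genes.

Emulates the statistical structure of a two-condition (normal vs tumor)
RNA-seq experiment: per-gene baseline means drawn log-uniformly, counts
drawn from a negative binomial parameterized by mean mu and dispersion
phi (variance mu + phi * mu^2, the DESeq/edgeR convention), and a chosen
fraction of genes shifted up or down in the tumor condition by a known
log2 fold change. A random subset of the planted DEGs is designated the
"biologically validated" list, standing in for external disease
curation. Everything is deterministic under the spec's seed.

The simulator makes no attempt to mimic library-size heterogeneity,
batch effects, or gene-gene correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import ExpressionDataset
from .labeling import LABEL_DOWN, LABEL_NEUTRAL, LABEL_UP, LabeledGeneSet, build_features


@dataclass
class SyntheticSpec:
    """Generative parameters for one synthetic two-condition dataset.

    Defaults are the package's reference study conditions: 2000 genes,
    20 + 20 samples, 20% up- and 20% down-regulated genes at |log2FC| = 2,
    dispersion 0.2, and a quarter of the planted DEGs marked as
    biologically validated.
    """

    n_genes: int = 2000
    n_normal: int = 20
    n_tumor: int = 20
    frac_ur: float = 0.2
    frac_dr: float = 0.2
    effect_logfc: float = 2.0
    base_mean_log_range: tuple[float, float] = (3.0, 9.0)  # log2 of the mean
    dispersion: float = 0.2
    bio_frac: float = 0.25
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self):
        if self.n_genes < 1 or self.n_normal < 1 or self.n_tumor < 1:
            raise ValueError("all counts must be at least 1")
        if not (0 <= self.frac_ur <= 1 and 0 <= self.frac_dr <= 1):
            raise ValueError("frac_ur and frac_dr must lie in [0, 1]")
        if self.frac_ur + self.frac_dr > 1:
            raise ValueError("frac_ur + frac_dr must not exceed 1")
        if self.effect_logfc < 0:
            raise ValueError("effect_logfc must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 <= self.bio_frac <= 1:
            raise ValueError("bio_frac must lie in [0, 1]")
        lo, hi = self.base_mean_log_range
        if hi < lo:
            raise ValueError("base_mean_log_range must be (low, high)")

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes, "n_normal": self.n_normal,
            "n_tumor": self.n_tumor, "frac_ur": self.frac_ur,
            "frac_dr": self.frac_dr, "effect_logfc": self.effect_logfc,
            "base_mean_log_range": list(self.base_mean_log_range),
            "dispersion": self.dispersion, "bio_frac": self.bio_frac,
            "seed": self.seed, "name": self.name,
        }


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mean + dispersion * mean^2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(np.float64)


def simulate(spec: SyntheticSpec) -> tuple[ExpressionDataset, LabeledGeneSet, set[str]]:
    """Generate (dataset, ground-truth labels, bio gene list) from a spec."""
    rng = np.random.default_rng(int(spec.seed))
    g = spec.n_genes
    n_ur = int(round(spec.frac_ur * g))
    n_dr = int(round(spec.frac_dr * g))

    gene_ids = [f"G{i:05d}" for i in range(g)]
    perm = rng.permutation(g)
    ur_set = perm[:n_ur]
    dr_set = perm[n_ur:n_ur + n_dr]
    truth = np.full(g, LABEL_NEUTRAL, dtype=np.int64)
    truth[ur_set] = LABEL_UP
    truth[dr_set] = LABEL_DOWN

    lo, hi = spec.base_mean_log_range
    base_mean = np.exp2(rng.uniform(lo, hi, size=g))
    fold = np.ones(g)
    fold[ur_set] = 2.0 ** spec.effect_logfc
    fold[dr_set] = 2.0 ** -spec.effect_logfc
    tumor_mean = base_mean * fold

    normal = _nb_draw(rng, np.repeat(base_mean[:, None], spec.n_normal, axis=1),
                      spec.dispersion)
    tumor = _nb_draw(rng, np.repeat(tumor_mean[:, None], spec.n_tumor, axis=1),
                     spec.dispersion)
    matrix = np.concatenate([normal, tumor], axis=1)
    sample_ids = ([f"normal_{i}" for i in range(spec.n_normal)]
                  + [f"tumor_{i}" for i in range(spec.n_tumor)])
    conditions = np.array(["normal"] * spec.n_normal + ["tumor"] * spec.n_tumor,
                          dtype=object)
    dataset = ExpressionDataset(
        gene_ids=gene_ids, matrix=matrix, sample_ids=sample_ids,
        conditions=conditions, name=spec.name,
        meta={"synthetic_spec": spec.to_dict()},
    )

    planted = np.concatenate([ur_set, dr_set])
    n_bio = int(round(spec.bio_frac * planted.size))
    bio_idx = rng.choice(planted, size=n_bio, replace=False) if n_bio else np.array([], dtype=int)
    bio_list = {gene_ids[i] for i in bio_idx}

    features, order = build_features(dataset)
    bio_flags = np.zeros(g, dtype=bool)
    bio_flags[bio_idx] = True
    truth_set = LabeledGeneSet(
        gene_ids=gene_ids, features=features, labels=truth, bio_flags=bio_flags,
        name=spec.name,
        meta={"synthetic_spec": spec.to_dict(), "sample_order": order,
              "feature_transform": "log2p1_gene_zscore",
              "n_samples": dataset.n_samples},
    )
    return dataset, truth_set, bio_list


def simulate_family(
    base_spec: SyntheticSpec,
    n_datasets: int,
    seeds: list[int],
    sample_counts: list[tuple[int, int]] | None = None,
) -> list[tuple[ExpressionDataset, LabeledGeneSet, set[str]]]:
    """Generate related datasets sharing effect size and dispersion.

    Each member draws independent genes and samples from the same
    generative family; ``sample_counts`` optionally overrides
    (n_normal, n_tumor) per member, emulating smaller cohorts for
    transfer testing. Family parameters are recorded in every member's
    provenance metadata.
    """
    if n_datasets < 2:
        raise ValueError("a family needs at least 2 datasets")
    if len(seeds) < n_datasets:
        raise ValueError(f"need at least {n_datasets} seeds, got {len(seeds)}")
    family = {
        "effect_logfc": base_spec.effect_logfc,
        "dispersion": base_spec.dispersion,
        "base_mean_log_range": list(base_spec.base_mean_log_range),
    }
    out = []
    for i in range(n_datasets):
        spec = replace(base_spec, seed=int(seeds[i]),
                       name=f"{base_spec.name}_{i}")
        if sample_counts is not None:
            spec = replace(spec, n_normal=int(sample_counts[i][0]),
                           n_tumor=int(sample_counts[i][1]))
        dataset, truth, bio = simulate(spec)
        dataset.meta["family"] = family
        truth.meta["family"] = family
        out.append((dataset, truth, bio))
    return out
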