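import numpy as np
import pytest

from degsign.io import ExpressionDataset
from degsign.labeling import LabeledGeneSet


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 genes x 4 samples (2 normal + 2 tumor), fixed values."""
    return ExpressionDataset(
        gene_ids=["TP53", "BRCA1", "EGFR"],
        matrix=np.array([[10.0, 12.0, 40.0, 44.0],
                         [100.0, 90.0, 25.0, 20.0],
                         [5.0, 6.0, 5.0, 7.0]]),
        sample_ids=["n1", "n2", "t1", "t2"],
        conditions=np.array(["normal", "normal", "tumor", "tumor"], dtype=object),
        name="tiny",
    )


def random_labeled_set(rng: np.random.Generator, n_genes: int = 120,
                       n_samples: int = 16, min_per_class: int = 12,
                       min_bio_per_class: int = 6) -> LabeledGeneSet:
    """A random labeled gene set with all three classes in P and both
    up/down classes in Q, for split/fold property tests."""
    while True:
        labels = rng.integers(0, 3, size=n_genes)
        counts = np.bincount(labels, minlength=3)
        if (counts >= min_per_class).all():
            break
    bio_flags = np.zeros(n_genes, dtype=bool)
    for c in (0, 1):
        members = np.flatnonzero(labels == c)
        chosen = rng.choice(members, size=min_bio_per_class, replace=False)
        bio_flags[chosen] = True
    features = rng.normal(size=(n_genes, n_samples)).astype(np.float32)
    return LabeledGeneSet(
        gene_ids=[f"G{i}" for i in range(n_genes)],
        features=features, labels=labels, bio_flags=bio_flags,
        name="random",
    )
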