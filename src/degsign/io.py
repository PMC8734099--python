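"""Readers and writers for on-disk artifacts.

Formats are deliberately plain: delimited text for expression matrices
(genes in rows, a header row of sample ids), two-column text for the
sample-condition map, a three-column ``gene,logfc,fdr`` table for
differential-expression results, one gene symbol per line for the
biologically validated list, JSON for metrics, and NumPy ``.npz`` with a
JSON metadata block for model checkpoints. Tab is the canonical
delimiter; comma is accepted by sniffing the header line.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import GeneClassifierCNN, ModelConfig

logger = logging.getLogger(__name__)

VALID_CONDITIONS = ("normal", "tumor")
CHECKPOINT_FORMAT_VERSION = 1


class CheckpointError(RuntimeError):
    """Raised when a checkpoint file is corrupted or incompatible."""


@dataclass
class ExpressionDataset:
    """A gene-by-sample expression matrix with per-sample condition tags."""

    gene_ids: list[str]
    matrix: np.ndarray  # (n_genes, n_samples), non-negative reals
    sample_ids: list[str]
    conditions: np.ndarray  # per-sample, "normal" or "tumor"
    name: str = "dataset"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.matrix.ndim != 2:
            raise ValueError("expression matrix must be two-dimensional")
        if len(self.gene_ids) != self.matrix.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids but {self.matrix.shape[0]} matrix rows"
            )
        if len(self.sample_ids) != self.matrix.shape[1]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but "
                f"{self.matrix.shape[1]} matrix columns"
            )
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValueError(f"duplicate gene id {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"duplicate sample id {dup!r}")
        bad = set(self.conditions) - set(VALID_CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition tag {sorted(bad)[0]!r}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("expression matrix contains non-finite values")
        if np.any(self.matrix < 0):
            raise ValueError("expression matrix contains negative values")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def condition_mask(self, condition: str) -> np.ndarray:
        return self.conditions == condition


@dataclass
class DifferentialTable:
    """Per-gene log2 fold change (tumor over normal) and FDR."""

    gene_ids: list[str]
    logfc: np.ndarray
    fdr: np.ndarray

    def __post_init__(self):
        self.logfc = np.asarray(self.logfc, dtype=np.float64)
        self.fdr = np.asarray(self.fdr, dtype=np.float64)
        if not (len(self.gene_ids) == len(self.logfc) == len(self.fdr)):
            raise ValueError("gene_ids, logfc and fdr must have equal length")
        if len(self.gene_ids) == 0:
            raise ValueError("empty table")
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValueError(f"duplicate gene id {dup!r} in DE table")
        if not np.all(np.isfinite(self.logfc)):
            bad = self.gene_ids[int(np.flatnonzero(~np.isfinite(self.logfc))[0])]
            raise ValueError(f"non-finite logfc for gene {bad!r}")
        out = (self.fdr < 0) | (self.fdr > 1) | ~np.isfinite(self.fdr)
        if np.any(out):
            bad = self.gene_ids[int(np.flatnonzero(out)[0])]
            raise ValueError(f"fdr outside [0, 1] for gene {bad!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.gene_ids, "logfc": self.logfc, "fdr": self.fdr}
        )


def _first_duplicate(items) -> str | None:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def _sniff_delimiter(header_line: str) -> str:
    # tab canonical; fall back to comma when the header has no tabs
    if "\t" in header_line:
        return "\t"
    if "," in header_line:
        return ","
    return "\t"


def read_condition_map(path) -> dict[str, str]:
    """Two-column (sample_id, condition) delimited text; no header required."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            delim = _sniff_delimiter(line)
            parts = [p.strip() for p in line.split(delim)]
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two columns (sample_id, condition)"
                )
            sample, condition = parts[0], parts[1]
            if sample == "sample_id" and condition == "condition":
                continue  # tolerate an optional header line
            if condition not in VALID_CONDITIONS:
                raise ValueError(
                    f"{path}:{lineno}: unknown condition tag {condition!r} "
                    f"(expected one of {VALID_CONDITIONS})"
                )
            mapping[sample] = condition
    if not mapping:
        raise ValueError(f"{path}: no samples mapped")
    return mapping


def read_expression(path, condition_map, name: str | None = None) -> ExpressionDataset:
    """Read a genes-in-rows expression matrix plus its sample-condition map.

    ``condition_map`` may be a path to a two-column file or an already
    parsed ``{sample_id: condition}`` dict. Samples in the matrix that are
    absent from the map are an error.
    """
    if not isinstance(condition_map, dict):
        condition_map = read_condition_map(condition_map)
    with open(path) as fh:
        header = fh.readline()
    delim = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=delim, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    gene_ids = [str(g).strip() for g in df.index]
    sample_ids = [str(s).strip() for s in df.columns]
    dup = _first_duplicate(gene_ids)
    if dup is not None:
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    values = np.empty(df.shape, dtype=np.float64)
    raw = df.to_numpy()
    for j in range(raw.shape[1]):
        col = pd.to_numeric(pd.Series(raw[:, j]), errors="coerce").to_numpy()
        bad = np.flatnonzero(np.isnan(col))
        for i in bad:
            if str(raw[i, j]).strip().lower() not in ("nan", ""):
                raise ValueError(
                    f"{path}: non-numeric cell at gene {gene_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}: {raw[i, j]!r}"
                )
        if bad.size:
            i = bad[0]
            raise ValueError(
                f"{path}: missing value at gene {gene_ids[i]!r}, "
                f"sample {sample_ids[j]!r}"
            )
        values[:, j] = col
    missing = [s for s in sample_ids if s not in condition_map]
    if missing:
        raise ValueError(
            f"{path}: sample {missing[0]!r} not present in the condition map"
        )
    conditions = np.array([condition_map[s] for s in sample_ids], dtype=object)
    return ExpressionDataset(
        gene_ids=gene_ids,
        matrix=values,
        sample_ids=sample_ids,
        conditions=conditions,
        name=name or str(path),
    )


def write_expression(dataset: ExpressionDataset, matrix_path, map_path) -> None:
    df = pd.DataFrame(
        dataset.matrix, index=dataset.gene_ids, columns=dataset.sample_ids
    )
    df.index.name = "gene"
    df.to_csv(matrix_path, sep="\t")
    with open(map_path, "w") as fh:
        for s, c in zip(dataset.sample_ids, dataset.conditions):
            fh.write(f"{s}\t{c}\n")


def read_de_table(path) -> DifferentialTable:
    """Read a ``gene, logfc, fdr`` table (header required)."""
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty table")
    delim = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=delim)
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in ("gene", "logfc", "fdr"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty table")
    return DifferentialTable(
        gene_ids=[str(g).strip() for g in df["gene"]],
        logfc=pd.to_numeric(df["logfc"], errors="coerce").to_numpy(),
        fdr=pd.to_numeric(df["fdr"], errors="coerce").to_numpy(),
    )


def write_de_table(table: DifferentialTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_bio_list(path) -> set[str]:
    """One gene symbol per line; '#' comments ignored; duplicates dropped."""
    genes: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                genes.add(line)
    if not genes:
        raise ValueError(f"{path}: empty biologically validated gene list")
    return genes


def write_bio_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


# --------------------------------------------------------------------------
# Checkpoints

def state_hash(state: dict[str, np.ndarray]) -> str:
    """SHA-256 over all weight bytes, in sorted key order."""
    h = hashlib.sha256()
    for key in sorted(state):
        h.update(key.encode())
        h.update(np.ascontiguousarray(state[key]).tobytes())
    return h.hexdigest()


def save_checkpoint(model: GeneClassifierCNN, path, provenance: dict | None = None) -> None:
    """Persist architecture, weights and provenance; self-describing on load."""
    state = model.state_arrays()
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": model.config.to_dict(),
        "weights_sha256": state_hash(state),
        "provenance": provenance or {},
    }
    buf = _io.BytesIO()
    np.savez(buf, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_checkpoint(path) -> tuple[GeneClassifierCNN, dict]:
    """Load a checkpoint; returns (model, provenance).

    Any corruption (truncated file, checksum mismatch, unknown format
    version) raises :class:`CheckpointError` rather than silently loading
    a partial model.
    """
    try:
        with np.load(path) as npz:
            arrays = {k: npz[k] for k in npz.files}
    except Exception as exc:  # zipfile/pickle errors on truncation
        raise CheckpointError(f"{path}: corrupted checkpoint ({exc})") from exc
    if "__meta__" not in arrays:
        raise CheckpointError(f"{path}: missing checkpoint metadata")
    try:
        meta = json.loads(bytes(arrays.pop("__meta__")).decode())
    except Exception as exc:
        raise CheckpointError(f"{path}: unreadable checkpoint metadata") from exc
    if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
        raise CheckpointError(
            f"{path}: checkpoint format version {meta.get('format_version')!r} "
            f"is not supported (expected {CHECKPOINT_FORMAT_VERSION})"
        )
    if state_hash(arrays) != meta.get("weights_sha256"):
        raise CheckpointError(f"{path}: weight checksum mismatch")
    config = ModelConfig.from_dict(meta["config"])
    model = GeneClassifierCNN(config)
    try:
        model.load_state_arrays(arrays)
    except Exception as exc:
        raise CheckpointError(f"{path}: weights do not match architecture") from exc
    return model, meta.get("provenance", {})


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
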