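"""Count curation: filtering, NTPM normalization, log-transform, label encoding.

Raw gene x sample count tables are filtered (samples first, then genes),
length-normalized to transcripts-per-million (NTPM, each sample sums to 1e6),
and stored on the ``log10(NTPM + 1e-10) + 10`` scale, which maps a zero count
to 0.0 and keeps all values non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountsTable",
    "NormalizedExpression",
    "filter_counts",
    "normalize_ntpm",
    "log_transform",
    "encode_labels",
    "curate",
    "read_counts_tsv",
    "read_counts_mtx",
    "read_lengths_tsv",
    "read_labels",
    "write_expression_tsv",
    "read_expression_tsv",
]

LOG_OFFSET = 1e-10
LOG_SHIFT = 10.0
DEFAULT_GENE_MEAN_MIN = 5.0
DEFAULT_SAMPLE_TOTAL_MIN = 1e5


class EmptyResultError(ValueError):
    """Raised when a filtering step removes every gene or every sample."""


@dataclass
class CountsTable:
    """Raw counts, genes x samples, with per-sample binary phenotype labels."""

    values: np.ndarray  # genes x samples, non-negative
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray  # per-sample, 0 = baseline, 1 = variant

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2-D genes x samples matrix")
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match matrix rows")
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match matrix columns")
        if len(self.labels) != n_samples:
            raise ValueError("labels length does not match sample count")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("sample_ids must be unique")
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class NormalizedExpression:
    """Samples x genes matrix on the log-NTPM scale with binary labels."""

    values: np.ndarray  # samples x genes
    labels: np.ndarray  # per-sample binary
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("expression must be 2-D samples x genes")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length does not match sample count")
        if not self.gene_ids:
            self.gene_ids = [f"g{i}" for i in range(self.values.shape[1])]
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.values.shape[0])]

    @property
    def onehot(self) -> np.ndarray:
        """Labels one-hot encoded, column order (baseline, variant)."""
        return encode_labels(self.labels)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def filter_counts(
    counts: CountsTable,
    gene_mean_min: float = DEFAULT_GENE_MEAN_MIN,
    sample_total_min: float = DEFAULT_SAMPLE_TOTAL_MIN,
) -> CountsTable:
    """Drop low-coverage samples, then low-count genes.

    Samples are removed first (total count must be strictly greater than
    ``sample_total_min``); gene means are then taken over the surviving
    samples and must be strictly greater than ``gene_mean_min``.
    """
    sample_totals = counts.values.sum(axis=0)
    keep_samples = sample_totals > sample_total_min
    if not keep_samples.any():
        raise EmptyResultError("all samples removed by the total-count filter")
    values = counts.values[:, keep_samples]

    gene_means = values.mean(axis=1)
    keep_genes = gene_means > gene_mean_min
    if not keep_genes.any():
        raise EmptyResultError("all genes removed by the mean-count filter")

    return CountsTable(
        values=values[keep_genes, :],
        gene_ids=[g for g, k in zip(counts.gene_ids, keep_genes) if k],
        sample_ids=[s for s, k in zip(counts.sample_ids, keep_samples) if k],
        labels=counts.labels[keep_samples],
    )


def normalize_ntpm(
    counts: CountsTable, lengths: Mapping[str, float]
) -> np.ndarray:
    """Length-normalize counts to NTPM; returns a samples x genes matrix.

    Per sample, ``rate_g = count_g / length_g`` and
    ``NTPM_g = 1e6 * rate_g / sum(rate)``, so each sample sums to 1e6.
    """
    missing = [g for g in counts.gene_ids if g not in lengths]
    if missing:
        raise KeyError(
            f"missing transcript lengths for {len(missing)} genes: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    length_vec = np.array([float(lengths[g]) for g in counts.gene_ids])
    if np.any(length_vec <= 0):
        bad = [g for g, l in zip(counts.gene_ids, length_vec) if l <= 0]
        raise ValueError(f"non-positive transcript lengths for genes: {bad[:10]}")

    rates = counts.values / length_vec[:, None]  # genes x samples
    totals = rates.sum(axis=0)
    if np.any(totals <= 0):
        bad = [s for s, t in zip(counts.sample_ids, totals) if t <= 0]
        raise ValueError(f"zero total rate in samples: {bad[:10]}")
    ntpm = 1e6 * rates / totals
    return ntpm.T  # samples x genes


def log_transform(ntpm: np.ndarray) -> np.ndarray:
    """Elementwise ``log10(x + 1e-10) + 10``; maps 0 to 0.0 exactly."""
    ntpm = np.asarray(ntpm, dtype=float)
    if np.any(ntpm < 0):
        raise ValueError("NTPM values must be non-negative")
    return np.log10(ntpm + LOG_OFFSET) + LOG_SHIFT


def encode_labels(labels: Sequence[int] | np.ndarray) -> np.ndarray:
    """One-hot encode binary labels; columns are (baseline, variant)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return np.zeros((0, 2))
    if not np.isin(labels, (0, 1)).all():
        bad = np.unique(labels[~np.isin(labels, (0, 1))])
        raise ValueError(f"labels must be binary; found {bad.tolist()}")
    out = np.zeros((len(labels), 2))
    out[np.arange(len(labels)), labels.astype(int)] = 1.0
    return out


def curate(
    counts: CountsTable,
    lengths: Mapping[str, float],
    gene_mean_min: float = DEFAULT_GENE_MEAN_MIN,
    sample_total_min: float = DEFAULT_SAMPLE_TOTAL_MIN,
) -> NormalizedExpression:
    """Full curation path: filter -> NTPM -> log-transform."""
    kept = filter_counts(counts, gene_mean_min, sample_total_min)
    ntpm = normalize_ntpm(kept, lengths)
    return NormalizedExpression(
        values=log_transform(ntpm),
        labels=kept.labels,
        gene_ids=list(kept.gene_ids),
        sample_ids=list(kept.sample_ids),
    )


# ---------------------------------------------------------------------------
# File IO. Text formats carry full double precision (17 significant digits).


def read_counts_tsv(
    counts_path: str, labels_path: str, sep: str = "\t"
) -> CountsTable:
    """Read a gene x sample delimited counts table plus an aligned label file.

    The counts file has a header row of sample ids and gene ids in the first
    column. The label file is either one label per line (aligned to the
    counts column order) or two columns ``sample_id<TAB>label``.
    """
    df = pd.read_csv(counts_path, sep=sep, index_col=0)
    labels = read_labels(labels_path, list(df.columns))
    return CountsTable(
        values=df.to_numpy(),
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        labels=labels,
    )


def read_counts_mtx(
    mtx_path: str, genes_path: str, barcodes_path: str, labels_path: str
) -> CountsTable:
    """Read single-cell MatrixMarket triplet counts (genes x cells), densified."""
    from scipy.io import mmread

    values = np.asarray(mmread(mtx_path).todense())
    gene_ids = [line.split("\t")[0] for line in _read_lines(genes_path)]
    sample_ids = _read_lines(barcodes_path)
    labels = read_labels(labels_path, sample_ids)
    return CountsTable(values, gene_ids, sample_ids, labels)


def read_lengths_tsv(path: str) -> dict[str, float]:
    """Two-column TSV gene -> transcript length in bases."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "length"])
    return dict(zip(df["gene"].astype(str), df["length"].astype(float)))


def read_labels(path: str, sample_ids: Sequence[str]) -> np.ndarray:
    lines = _read_lines(path)
    if lines and "\t" in lines[0]:
        mapping = dict(line.split("\t")[:2] for line in lines)
        return np.array([int(mapping[s]) for s in sample_ids])
    if len(lines) != len(sample_ids):
        raise ValueError(
            f"label file has {len(lines)} rows but there are {len(sample_ids)} samples"
        )
    return np.array([int(x) for x in lines])


def write_expression_tsv(expr: NormalizedExpression, path: str) -> None:
    """Write samples x genes values with a ``label`` column, full precision."""
    df = pd.DataFrame(expr.values, index=expr.sample_ids, columns=expr.gene_ids)
    df.insert(0, "label", expr.labels)
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="sample_id")


def read_expression_tsv(path: str) -> NormalizedExpression:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    labels = df.pop("label").to_numpy(dtype=int)
    return NormalizedExpression(
        values=df.to_numpy(dtype=float),
        labels=labels,
        gene_ids=[str(g) for g in df.columns],
        sample_ids=[str(s) for s in df.index],
    )


def _read_lines(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
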