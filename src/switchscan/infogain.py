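"""Entropy-based evaluation of a gene's phenotype-prediction value.

The phenotype's uncertainty is the plug-in Shannon entropy
``H(X) = -sum p(x) log2 p(x)`` with frequencies as probabilities.  A
gene's continuous expression is discretized into equal-frequency bins;
the conditional entropy ``H(X|Y) = sum_y p(y) H(X | Y = y)`` measures the
uncertainty remaining once the gene's bin is known, and the percentage
information gain ``100 (H(X) - H(X|Y)) / H(X)`` is the fraction of
phenotype uncertainty the gene removes.  The percentage is independent of
the logarithm base, and the bin count shifts absolute entropies without
affecting comparisons between genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedGainError, ValidationError

__all__ = [
    "DiscretizedGene",
    "InfoGainResult",
    "entropy",
    "discretize_equal_frequency",
    "information_gain",
]


@dataclass(frozen=True)
class DiscretizedGene:
    """Equal-frequency discretization of one gene's expression values."""

    gene_id: str
    n_bins: int
    #: interior bin edges (ascending, duplicates collapsed); bin k is
    #: (edge[k-1], edge[k]] with open ends
    bin_edges: np.ndarray = field(repr=False)
    bin_labels: np.ndarray = field(repr=False)
    #: number of non-empty bins after tie collapsing
    effective_bins: int = 0
    collapsed: bool = False


@dataclass(frozen=True)
class InfoGainResult:
    gene_id: str
    H_X: float
    H_X_given_Y: float
    gain_percent: float
    effective_bins: int


def entropy(labels) -> float:
    """Plug-in Shannon entropy in bits; ``0 log 0 = 0``."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValidationError("entropy needs at least one label")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def discretize_equal_frequency(values, n_bins: int, gene_id: str = "") -> DiscretizedGene:
    """Quantile-cut a gene's values into ``n_bins`` equal-frequency bins.

    Edges sit at the i/n_bins quantiles; duplicated edge values collapse
    bins (fewer effective bins, flagged), and tied values always land in
    the same bin, so the assignment is deterministic.
    """
    if n_bins < 2:
        raise ValidationError(f"n_bins must be >= 2, got {n_bins}")
    x = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValidationError("discretize_equal_frequency requires finite values")
    if x.size < n_bins:
        raise ValidationError(f"need >= n_bins={n_bins} values, got {x.size}")
    qs = np.quantile(x, np.arange(1, n_bins) / n_bins)
    edges = np.unique(qs)
    labels = np.searchsorted(edges, x, side="left")
    occupied = np.unique(labels).size
    return DiscretizedGene(
        gene_id=gene_id,
        n_bins=n_bins,
        bin_edges=edges,
        bin_labels=labels,
        effective_bins=occupied,
        collapsed=occupied < n_bins,
    )


def information_gain(phenotype_labels, gene_values, n_bins: int = 4, gene_id: str = "") -> InfoGainResult:
    """Percentage information gain of a gene for phenotype prediction.

    Requires at least two phenotype classes — with a single class the
    phenotype entropy is zero and the gain ratio is undefined.
    """
    pheno = np.asarray(phenotype_labels)
    x = np.asarray(gene_values, dtype=float).ravel()
    if pheno.shape[0] != x.shape[0]:
        raise ValidationError("phenotype labels and gene values must align")
    keep = np.isfinite(x)
    pheno, x = pheno[keep], x[keep]
    if x.size < n_bins:
        raise ValidationError(f"need >= n_bins={n_bins} observed samples, got {x.size}")
    h_x = entropy(pheno)
    if h_x == 0.0:
        raise UndefinedGainError(
            "information gain undefined: phenotype has a single class (H(X) = 0)"
        )
    disc = discretize_equal_frequency(x, n_bins, gene_id=gene_id)
    h_cond = 0.0
    for b in np.unique(disc.bin_labels):
        in_bin = disc.bin_labels == b
        h_cond += in_bin.mean() * entropy(pheno[in_bin])
    h_cond = min(h_cond, h_x)  # guard float round-off; plug-in H(X|Y) <= H(X)
    gain = 100.0 * (h_x - h_cond) / h_x
    return InfoGainResult(
        gene_id=gene_id,
        H_X=h_x,
        H_X_given_Y=h_cond,
        gain_percent=float(min(max(gain, 0.0), 100.0)),
        effective_bins=disc.effective_bins,
    )
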