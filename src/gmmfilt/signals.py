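"""Per-gene filter signals for nonspecific gene filtering.

A two-group expression study is summarized, gene by gene, into a single
scalar *filter signal* that is blind to the sample class labels:

* ``S``  — mean of the log2 expression values across all samples,
* ``V``  — log of the unbiased sample variance on the *original* scale,
* ``LV`` — log of the unbiased sample variance on the log2 scale.

The distribution of this signal over all genes is what the mixture
decomposition in :mod:`gmmfilt.gmm` operates on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

Scale = Literal["log2", "original"]
SignalMethod = Literal["S", "V", "LV"]

#: offset (in log units) below the smallest finite signal value assigned to
#: genes whose sample variance is exactly zero, so that the log transform is
#: defined and such genes land in the lowest mixture component.
ZERO_VARIANCE_OFFSET = 6.0


class ScaleError(ValueError):
    """Raised when an operation receives a matrix on the wrong scale."""


@dataclass
class ExpressionMatrix:
    """Normalized expression values, genes x samples.

    Values are assumed to be RMA-style probe-set summaries, either on the
    log2 scale (the RMA default) or on the original intensity scale.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    scale: Scale = "log2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D genes x samples array")
        n, m = self.values.shape
        if n < 1 or m < 2:
            raise ValueError(f"need at least 1 gene and 2 samples, got {n} x {m}")
        if self.gene_ids.shape != (n,):
            raise ValueError("gene_ids length does not match number of rows")
        if self.sample_ids.shape != (m,):
            raise ValueError("sample_ids length does not match number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing or non-finite values")
        if self.scale not in ("log2", "original"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "original" and np.any(self.values <= 0):
            raise ValueError("original-scale expression values must be positive")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class FilterSignal:
    """Univariate per-gene signal x_n fed to the mixture decomposition."""

    x: np.ndarray
    method: SignalMethod
    gene_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 1 or self.x.size < 1:
            raise ValueError("signal must be a nonempty 1-D vector")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.x.size


def to_original_scale(m: ExpressionMatrix) -> ExpressionMatrix:
    """Invert the RMA log2 transform with the base-2 power function."""
    if m.scale != "log2":
        raise ScaleError("matrix is already on the original scale")
    return ExpressionMatrix(
        values=np.exp2(m.values),
        gene_ids=m.gene_ids,
        sample_ids=m.sample_ids,
        scale="original",
    )


def compute_signal(
    m: ExpressionMatrix,
    method: SignalMethod,
    variance_log_base: float = 2.0,
) -> FilterSignal:
    """Compute the per-gene filter signal for one of the methods S, V, LV.

    ``S`` is the sample mean of the log2 values; ``V`` and ``LV`` are the
    logarithm (base ``variance_log_base``) of the unbiased (M-1 denominator)
    sample variance on the original and log2 scales respectively.  Genes
    whose sample variance is exactly zero carry no information; their log
    variance is undefined and is replaced by (min finite signal) -
    ``ZERO_VARIANCE_OFFSET`` with a warning, which pins them to the bottom
    of the signal range.
    """
    if method not in ("S", "V", "LV"):
        raise ValueError(f"unknown signal method {method!r}")
    if method in ("S", "LV") and m.scale != "log2":
        raise ScaleError(f"method {method} requires a log2-scale matrix")
    if method == "V" and m.scale != "original":
        raise ScaleError(
            "method V requires the original scale; convert with to_original_scale()"
        )
    if method == "S":
        return FilterSignal(m.values.mean(axis=1), "S", m.gene_ids)

    if variance_log_base <= 0 or variance_log_base == 1:
        raise ValueError("variance_log_base must be positive and != 1")
    var = m.values.var(axis=1, ddof=1)
    zero = var <= 0
    with np.errstate(divide="ignore"):
        x = np.log(var) / np.log(variance_log_base)
    if np.any(zero):
        finite = x[~zero]
        if finite.size == 0:
            raise ValueError("all genes have zero sample variance; no usable signal")
        x[zero] = finite.min() - ZERO_VARIANCE_OFFSET
        warnings.warn(
            f"{int(zero.sum())} gene(s) with zero sample variance assigned the "
            f"floor signal value {finite.min() - ZERO_VARIANCE_OFFSET:.4g}",
            stacklevel=2,
        )
    return FilterSignal(x, method, m.gene_ids)
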