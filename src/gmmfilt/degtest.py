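"""DEG discovery on the retained genes: t-test plus q-value FDR correction.

Differential expression between the two sample classes is tested per gene
with the two-sample pooled-variance (equal-variance) t-test, and multiple
testing is corrected with Storey-Tibshirani q-values.  Correction is
applied to the retained genes only: filtering first, correction second is
the entire point of the two-step procedure, because a smaller pool of
tests at the same FDR constraint yields more discoveries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .filtering import GeneFilter
from .signals import ExpressionMatrix

DEFAULT_LAMBDA_GRID = np.arange(0.0, 0.901, 0.05)


@dataclass
class DEGResult:
    """Per-retained-gene test results and FDR-controlled calls."""

    gene_ids: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    fdr_level: float
    calls: np.ndarray
    pi0_hat: float

    def __post_init__(self) -> None:
        n = self.gene_ids.size
        for name in ("t_stats", "p_values", "q_values", "calls"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match gene_ids")

    @property
    def n_rejections(self) -> int:
        return int(self.calls.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "t": self.t_stats,
                "p": self.p_values,
                "q": self.q_values,
                "call": self.calls.astype(int),
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def split_groups(sample_ids: np.ndarray, labels: dict | pd.Series) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Column indices of the two groups, ordered by sorted label value."""
    lab = pd.Series(labels)
    values = [lab[s] for s in sample_ids]
    groups = sorted(set(values), key=str)
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    idx1 = np.array([i for i, v in enumerate(values) if v == groups[0]])
    idx2 = np.array([i for i, v in enumerate(values) if v == groups[1]])
    if idx1.size < 2 or idx2.size < 2:
        raise ValueError("each group needs at least 2 samples")
    return idx1, idx2, (groups[0], groups[1])


def equal_variance_t_test(
    m: ExpressionMatrix,
    labels: dict | pd.Series,
    mask: GeneFilter | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t statistic and two-sided p per retained gene.

    t is signed as mean(group 1) - mean(group 2), groups ordered by first
    appearance among the sample ids; df = M - 2.  A gene with zero pooled
    variance is uninformative for the test and gets t = 0, p = 1.
    """
    if m.scale != "log2":
        raise ValueError("t-tests are run on the log2-scale matrix")
    idx1, idx2, _ = split_groups(m.sample_ids, labels)
    values = m.values if mask is None else m.values[mask.retain_mask]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(values[:, idx1], values[:, idx2], axis=1, equal_var=True)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(t)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} gene(s) with zero pooled variance; t set to 0, p to 1",
            stacklevel=2,
        )
        t[bad] = 0.0
        p[bad] = 1.0
    return t, p


def estimate_pi0(p_values: np.ndarray, lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID) -> float:
    """Storey's pi0: tail proportions on a lambda grid, smoothed and read at max lambda.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is fitted with a cubic
    smoothing spline in lambda and evaluated at the largest grid value; the
    result is clipped into (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    lam = np.asarray(lambda_grid, dtype=float)
    m = p.size
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    if m < 2 or np.allclose(pi0_lam, pi0_lam[0]):
        pi0 = float(pi0_lam[-1])
    else:
        try:
            spline = UnivariateSpline(lam, pi0_lam, k=3)
            pi0 = float(spline(lam.max()))
        except Exception:
            pi0 = float(pi0_lam[-1])
    return float(np.clip(pi0, 1.0 / m if m else 1e-8, 1.0))


def qvalues(
    p_values: np.ndarray,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    pi0: float | None = None,
) -> tuple[np.ndarray, float]:
    """Storey-Tibshirani q-values.

    q(p_(i)) = min_{j >= i} pi0 * m * p_(j) / j over the ascending order
    statistics.  Pass ``pi0=1.0`` to force the Benjamini-Hochberg special
    case (used as an oracle check).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0), 1.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0_hat = float(pi0) if pi0 is not None else estimate_pi0(p, lambda_grid)
    if not 0 < pi0_hat <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = pi0_hat * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, pi0_hat


def call_degs(q_values: np.ndarray, fdr_level: float = 0.05) -> np.ndarray:
    """Boolean DEG calls at the FDR constraint (q <= level, boundary inclusive)."""
    return np.asarray(q_values, dtype=float) <= fdr_level


def discover_degs(
    m: ExpressionMatrix,
    labels: dict | pd.Series,
    mask: GeneFilter | None = None,
    fdr_level: float = 0.05,
    pi0: float | None = None,
) -> DEGResult:
    """Full second step: t-test, q-values and calls on the retained genes."""
    t, p = equal_variance_t_test(m, labels, mask)
    q, pi0_hat = qvalues(p, pi0=pi0)
    ids = m.gene_ids if mask is None else m.gene_ids[mask.retain_mask]
    return DEGResult(
        gene_ids=ids,
        t_stats=t,
        p_values=p,
        q_values=q,
        fdr_level=fdr_level,
        calls=call_degs(q, fdr_level),
        pi0_hat=pi0_hat,
    )
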