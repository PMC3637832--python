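"""Detection-power metrics for benchmarks with known truth.

When the true DEG status of every gene is known (simulations, spike-in
designs), a filter + test pipeline is scored by sweeping the significance
threshold over the retained genes and tracing sensitivity against the
realized FDR.  Genes removed by the filter count as not-called at every
threshold, so a filter that discards true DEGs caps the attainable
sensitivity — the denominator is always the total number of true DEGs.

When truth is unknown, methods are compared by the number of null
hypotheses rejected at a fixed FDR constraint (the rejection count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .degtest import DEGResult
from .filtering import GeneFilter


@dataclass
class RocCurve:
    """Attainable (FDR, sensitivity) envelope: both coordinates non-decreasing."""

    fdr: np.ndarray
    sensitivity: np.ndarray


@dataclass
class EvalMetrics:
    roc: RocCurve
    auc: float                  # partial area, percent units
    f1: float
    sensitivity_at_fdr: float   # percent
    fdr_cap: float
    n_rejections: int


def roc_fdr_sensitivity(
    p_values: np.ndarray,
    truth: np.ndarray,
    mask: GeneFilter | None = None,
) -> RocCurve:
    """Sensitivity-vs-FDR curve from a threshold sweep over retained genes.

    ``p_values`` covers the retained genes (ascending significance order is
    induced internally); ``truth`` covers all genes.  At each distinct
    p-value threshold, FDR = FP / max(1, FP + TP) and sensitivity =
    TP / (true DEGs among all genes).  The returned curve is the attainable
    envelope: for each FDR level, the best sensitivity reachable at or
    below it.
    """
    truth = np.asarray(truth, dtype=bool)
    n_pos = int(truth.sum())
    if n_pos == 0:
        raise ValueError("truth contains no true DEGs; sensitivity is undefined")
    p = np.asarray(p_values, dtype=float)
    truth_retained = truth if mask is None else truth[mask.retain_mask]
    if p.size != truth_retained.size:
        raise ValueError("p-values must cover exactly the retained genes")

    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    hits = truth_retained[order].astype(int)
    tp = np.cumsum(hits)
    fp = np.arange(1, p.size + 1) - tp
    # collapse ties: a threshold includes every gene with p <= threshold
    last_of_tie = np.r_[p_sorted[1:] != p_sorted[:-1], True]
    tp, fp = tp[last_of_tie], fp[last_of_tie]
    fdr = fp / np.maximum(1, fp + tp)
    sens = tp / n_pos
    # attainable envelope: sort by FDR, keep running max of sensitivity
    o = np.argsort(fdr, kind="stable")
    fdr, sens = fdr[o], np.maximum.accumulate(sens[o])
    keep = np.r_[True, (np.diff(fdr) > 0) | (np.diff(sens) > 0)]
    return RocCurve(np.r_[0.0, fdr[keep]], np.r_[0.0, sens[keep]])


def sensitivity_at_fdr(roc: RocCurve, fdr_cap: float = 0.05) -> float:
    """Best sensitivity attainable at realized FDR <= fdr_cap (fraction in [0,1])."""
    ok = roc.fdr <= fdr_cap
    return float(roc.sensitivity[ok].max()) if np.any(ok) else 0.0


def partial_auc(roc: RocCurve, fdr_cap: float = 0.20) -> float:
    """Trapezoidal area under sensitivity over FDR in [0, fdr_cap], times 100."""
    if fdr_cap <= 0:
        raise ValueError("fdr_cap must be positive")
    f, s = roc.fdr, roc.sensitivity
    inside = f <= fdr_cap
    fi, si = f[inside], s[inside]
    if fi.size == 0:
        return 0.0
    if fi[-1] < fdr_cap:
        # extend: sensitivity attainable at the last threshold persists
        nxt = np.flatnonzero(~inside)
        s_cap = np.interp(fdr_cap, f, s) if nxt.size else si[-1]
        fi = np.r_[fi, fdr_cap]
        si = np.r_[si, s_cap]
    return float(np.trapezoid(si, fi) * 100.0)


def f1_measure(sensitivity: float, fdr: float) -> float:
    """Harmonic mean of (1 - FDR) and sensitivity; 1 only at sens=1, FDR=0."""
    if not (0 <= sensitivity <= 1 and 0 <= fdr <= 1):
        raise ValueError("sensitivity and FDR must lie in [0, 1]")
    a, b = 1.0 - fdr, sensitivity
    return 0.0 if a + b == 0 else 2.0 * a * b / (a + b)


def rejection_count(deg: DEGResult) -> int:
    """Number of null hypotheses rejected at the DEG result's FDR constraint."""
    return deg.n_rejections


def evaluate(
    p_values: np.ndarray,
    truth: np.ndarray,
    mask: GeneFilter | None = None,
    deg: DEGResult | None = None,
    fdr_cap_auc: float = 0.20,
    fdr_cap_sens: float = 0.05,
) -> EvalMetrics:
    """Score one pipeline run against known truth."""
    roc = roc_fdr_sensitivity(p_values, truth, mask)
    sens = sensitivity_at_fdr(roc, fdr_cap_sens)
    return EvalMetrics(
        roc=roc,
        auc=partial_auc(roc, fdr_cap_auc),
        f1=f1_measure(sens, fdr_cap_sens),
        sensitivity_at_fdr=100.0 * sens,
        fdr_cap=fdr_cap_auc,
        n_rejections=deg.n_rejections if deg is not None else 0,
    )
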