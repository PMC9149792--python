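"""Permutation family-wise thresholds, genomic inflation λ, and
confusion-rate evaluation against known causal variants.

The significance threshold for one trait is the 5% quantile of the
genome-wide minimum p-values obtained by permuting phenotype values
across samples (the fifth lowest of 100 by default); a variant passing
it carries a 5% family-wise error rate.  λ is the median observed
1-d.f. statistic divided by the analytic χ²(1) median (≈ 0.4549).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .lmm import AssociationEngine, KinshipMatrix, NullModelFit, _P_FLOOR
from .population import GenotypePanel

logger = logging.getLogger(__name__)

#: Analytic median of the 1-d.f. chi-square distribution (λ denominator).
CHI2_1DF_MEDIAN = float(chi2.ppf(0.5, df=1))


@dataclass
class ConfusionSummary:
    """TP/FP/TN/FN counts and rates for one simulation run.

    TPR = TP/(TP+FN), TNR = TN/(TN+FP), FPR = FP/(FP+TN),
    FNR = FN/(FN+TP); undefined rates (empty denominator) are NaN.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float
    tnr: float
    fpr: float
    fnr: float
    threshold: float
    lambda_gc: float = math.nan
    run_id: str | None = None
    n_linked_excluded: int = 0


def genomic_inflation(statistics) -> float:
    """λ = median(observed 1-d.f. statistics) / median of χ²(1)."""
    stats = np.asarray(statistics, dtype=np.float64)
    if stats.size == 0:
        raise ValueError("cannot compute lambda from an empty statistic set")
    if not np.isfinite(stats).all():
        raise ValueError("statistics contain non-finite values")
    return float(np.median(stats) / CHI2_1DF_MEDIAN)


def permutation_threshold(panel: GenotypePanel | None,
                          phenotype: np.ndarray,
                          kinship: KinshipMatrix | None = None,
                          n_perm: int = 100,
                          fwer: float = 0.05,
                          rng: np.random.Generator | int | None = None,
                          engine: AssociationEngine | None = None,
                          null_fit: NullModelFit | None = None,
                          return_minima: bool = False):
    """Family-wise p-value threshold from phenotype permutations.

    Phenotype values are shuffled across samples ``n_perm`` times; each
    permutation is re-scanned with δ fixed at the unpermuted null-model
    optimum, and the genome-wide minimum p-value recorded.  The
    threshold is the ceil(fwer·n_perm)-th smallest of these minima.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0.0 < fwer < 1.0:
        raise ValueError("fwer must be in (0, 1)")
    if n_perm * fwer < 1.0 - 1e-12:
        raise ValueError(
            f"n_perm * fwer = {n_perm * fwer:.3g} < 1: the permutation "
            "quantile is undefined; raise n_perm")
    k = int(math.ceil(n_perm * fwer - 1e-9))
    if engine is None:
        if panel is None:
            raise ValueError("either a panel or an engine is required")
        engine = AssociationEngine(panel, kinship)
    y = np.asarray(phenotype, dtype=np.float64)
    if null_fit is None:
        null_fit = engine.fit_null(y)
    rng = np.random.default_rng(rng)
    n = y.size
    perms = np.column_stack([y[rng.permutation(n)] for _ in range(n_perm)])
    stats = engine.scan_statistics(perms, null_fit.delta)
    minima = np.maximum(chi2.sf(stats.max(axis=0), df=1), _P_FLOOR)
    threshold = float(np.sort(minima)[k - 1])
    return (threshold, minima) if return_minima else threshold


def confusion_rates(p_values, threshold: float, causal_ids,
                    variants=None,
                    linkage_window: float | None = None,
                    lambda_gc: float = math.nan,
                    run_id: str | None = None) -> ConfusionSummary:
    """Confusion table of significant calls against the causal set.

    A variant is significant iff p ≤ threshold.  With ``linkage_window``
    set (bp), non-causal variants within the window of any causal
    variant are excluded from the FP/TN tally (their significant calls
    plausibly tag the causal site) and counted in ``n_linked_excluded``;
    ``variants`` (chrom/pos table aligned with ``p_values``) is then
    required.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    m = p.size
    causal = np.zeros(m, dtype=bool)
    causal_ids = np.asarray(causal_ids, dtype=int)
    if causal_ids.size:
        if causal_ids.min() < 0 or causal_ids.max() >= m:
            raise ValueError("causal_ids outside the tested variant range")
        causal[causal_ids] = True

    keep = np.ones(m, dtype=bool)
    if linkage_window is not None and causal_ids.size:
        if variants is None:
            raise ValueError("linkage_window requires the variants table")
        chrom = np.asarray(variants["chrom"])
        pos = np.asarray(variants["pos"], dtype=np.int64)
        linked = np.zeros(m, dtype=bool)
        for c in causal_ids:
            linked |= (chrom == chrom[c]) & \
                (np.abs(pos - pos[c]) <= linkage_window)
        linked &= ~causal
        keep = ~linked

    sig = p <= threshold
    tp = int(np.sum(sig & causal))
    fn = int(np.sum(~sig & causal))
    fp = int(np.sum(sig & ~causal & keep))
    tn = int(np.sum(~sig & ~causal & keep))

    def rate(num: int, den: int) -> float:
        return num / den if den else math.nan

    return ConfusionSummary(
        tp=tp, fp=fp, tn=tn, fn=fn,
        tpr=rate(tp, tp + fn), tnr=rate(tn, tn + fp),
        fpr=rate(fp, fp + tn), fnr=rate(fn, fn + tp),
        threshold=float(threshold), lambda_gc=lambda_gc, run_id=run_id,
        n_linked_excluded=int(np.sum(~keep)),
    )
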