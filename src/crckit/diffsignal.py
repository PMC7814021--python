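"""Replicate-aware differential signal testing and enhancer reclassification.

Counts are modelled as negative binomial with per-region dispersion
estimated by method of moments and shrunk toward a mean-dispersion trend;
a Wald test on the log fold change with BH adjustment yields the
significance calls (defaults |log2FC| >= 1 and FDR < 0.05).  The same
engine serves ChIP region counts and gene counts.

With the default settings the per-region dispersion is the fitted
mean-dispersion trend itself (the per-region moment estimates only fit the
trend); this keeps the 2v2 Wald test calibrated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage import Coverage
from .intervals import GenomicInterval, overlap_bp
from .se_caller import EnhancerRanking, StitchedEnhancer

__all__ = [
    "size_factors",
    "bh_adjust",
    "test_differential",
    "classify_enhancer_transitions",
    "counts_from_coverage",
]

logger = logging.getLogger(__name__)

DEFAULT_LFC_MIN = 1.0
DEFAULT_FDR_MAX = 0.05
_MIN_DISP = 1e-8
_MAX_DISP = 10.0
# Weight of the fitted mean-dispersion trend in the log-space combination
# with the per-region method-of-moments value.  With two replicates per
# condition the per-region MoM estimate is extremely noisy and biases the
# Wald test anticonservative, so the default uses the trend alone; the raw
# MoM values still determine the trend coefficients.
_TREND_WEIGHT = 1.0


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors, geometric mean 1.

    Ratios are taken to the per-region geometric mean over regions with
    all-nonzero counts; if no such region exists, falls back to total-count
    scaling (with a logged warning).
    """
    mat = counts.to_numpy(dtype=float)
    if np.any((mat > 0).sum(axis=0) == 0):
        raise ValueError("each sample must have at least one nonzero region")
    all_nonzero = np.all(mat > 0, axis=1)
    if not all_nonzero.any():
        logger.warning(
            "no region with all-nonzero counts; falling back to total-count "
            "size factors"
        )
        totals = mat.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
    else:
        sub = mat[all_nonzero]
        geo = np.exp(np.mean(np.log(sub), axis=1))
        ratios = sub / geo[:, None]
        sf = np.median(ratios, axis=0)
        sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    NaN entries propagate as NaN and do not count toward the number of
    tests.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _dispersion_estimates(
    y: np.ndarray, groups: np.ndarray, inv_sf_mean: float
) -> np.ndarray:
    """Trend-shrunk method-of-moments NB dispersions per region.

    ``y`` is the size-factor-normalised count matrix (regions x samples).
    """
    n_regions = y.shape[0]
    labels = np.unique(groups)
    # per-condition moment matching: alpha_c = (var_c - q_c/sf) / q_c^2,
    # combined across conditions weighted by residual dof.  Using the
    # condition means keeps the estimate unbiased for regions with a true
    # fold change (a pooled mean would inflate it).
    num = np.zeros(n_regions)
    dof = 0
    for lab in labels:
        cols = groups == lab
        n_c = int(cols.sum())
        q_c = y[:, cols].mean(axis=1)
        var_c = y[:, cols].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a_c = (var_c - q_c * inv_sf_mean) / q_c**2
        a_c = np.where(np.isfinite(a_c), a_c, _MIN_DISP)
        num += (n_c - 1) * np.clip(a_c, _MIN_DISP, _MAX_DISP)
        dof += n_c - 1
    raw = num / max(dof, 1)
    mu = y.mean(axis=1)
    raw_c = np.clip(raw, _MIN_DISP, _MAX_DISP)

    # mean-dispersion trend a0 + a1/mu fitted on regions with signal
    use = mu > 0
    if use.sum() >= 10:
        X = np.column_stack([np.ones(use.sum()), 1.0 / mu[use]])
        coef, *_ = np.linalg.lstsq(X, raw_c[use], rcond=None)
        a0 = max(coef[0], _MIN_DISP)
        a1 = max(coef[1], 0.0)
    else:
        a0, a1 = max(float(np.median(raw_c)), _MIN_DISP), 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + np.where(mu > 0, a1 / np.maximum(mu, 1e-12), 0.0)
    trend = np.clip(trend, _MIN_DISP, _MAX_DISP)
    alpha = np.exp(
        _TREND_WEIGHT * np.log(trend) + (1 - _TREND_WEIGHT) * np.log(raw_c)
    )
    return np.clip(alpha, _MIN_DISP, _MAX_DISP)


def test_differential(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    lfc_min: float = DEFAULT_LFC_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
    sf: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """NB-Wald differential test of condition2 vs condition1.

    ``design`` needs columns sample, condition with exactly two conditions
    (>= 2 replicates each); the reference condition is the first to appear.
    Returns a per-region frame with baseMean, log2FC, pvalue, fdr and the
    significance call |log2FC| >= lfc_min AND fdr < fdr_max.  Regions with
    all-zero counts get missing statistics and are never significant.
    """
    samples = design["sample"].tolist()
    missing = set(samples) - set(counts.columns)
    if missing:
        raise ValueError(f"samples missing from count matrix: {sorted(missing)}")
    conds = design["condition"].tolist()
    levels = list(dict.fromkeys(conds))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {levels}")
    groups = np.array([levels.index(c) for c in conds])
    if min((groups == 0).sum(), (groups == 1).sum()) < 2:
        raise ValueError("need >= 2 replicates per condition")

    mat = counts[samples].to_numpy(dtype=float)
    if sf is None:
        sf = size_factors(counts[samples])
    sfv = sf[samples].to_numpy(dtype=float)
    y = mat / sfv
    inv_sf_mean = float(np.mean(1.0 / sfv))

    alpha = _dispersion_estimates(y, groups, inv_sf_mean)

    n1 = int((groups == 0).sum())
    n2 = int((groups == 1).sum())
    q1 = y[:, groups == 0].mean(axis=1)
    q2 = y[:, groups == 1].mean(axis=1)
    base_mean = y.mean(axis=1)
    all_zero = mat.sum(axis=1) == 0

    # moderate zero group means with half a normalised count
    delta = 0.5 * inv_sf_mean
    needs_delta = (q1 == 0) | (q2 == 0)
    q1a = np.where(needs_delta, q1 + delta, q1)
    q2a = np.where(needs_delta, q2 + delta, q2)

    inv_sf1 = np.sum(1.0 / sfv[groups == 0])
    inv_sf2 = np.sum(1.0 / sfv[groups == 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        var_ln1 = (inv_sf1 / q1a + n1 * alpha) / n1**2
        var_ln2 = (inv_sf2 / q2a + n2 * alpha) / n2**2
        lnfc = np.log(q2a) - np.log(q1a)
        se = np.sqrt(var_ln1 + var_ln2)
        z = lnfc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    log2fc = lnfc / np.log(2.0)

    pvalue = np.where(all_zero, np.nan, pvalue)
    log2fc = np.where(all_zero, np.nan, log2fc)
    fdr = bh_adjust(pvalue)
    significant = (
        ~np.isnan(fdr)
        & (np.abs(np.nan_to_num(log2fc)) >= lfc_min)
        & (np.nan_to_num(fdr, nan=1.0) < fdr_max)
    )
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "pvalue": pvalue,
            "fdr": fdr,
            "significant": significant,
        },
        index=counts.index,
    )


def counts_from_coverage(
    regions: Sequence[GenomicInterval],
    coverages: dict[str, Coverage],
    fragment_length: int = 200,
) -> pd.DataFrame:
    """Approximate read counts by integrating coverage / fragment length."""
    data = {
        sample: [cov.sum_over(r) / fragment_length for r in regions]
        for sample, cov in coverages.items()
    }
    idx = [r.name or f"{r.chrom}:{r.start}-{r.end}" for r in regions]
    return pd.DataFrame(data, index=idx).round().astype(int)


def _best_match(
    enh: StitchedEnhancer, candidates: Sequence[StitchedEnhancer]
) -> Optional[StitchedEnhancer]:
    best, best_ov = None, 0
    for c in candidates:
        ov = overlap_bp(enh.span, c.span)
        if ov > best_ov:
            best, best_ov = c, ov
    return best


def classify_enhancer_transitions(
    ranking_wt: EnhancerRanking,
    ranking_kd: EnhancerRanking,
    h3k4me1_cov: Optional[Coverage] = None,
    h3k27me3_cov: Optional[Coverage] = None,
    reduced_ratio: float = 0.5,
) -> pd.DataFrame:
    """Label each wild-type enhancer locus after knockdown.

    Labels: SE->SE, SE->TE, TE->TE, TE->primed, other.  Loci are matched
    by >= 1 bp span overlap.  TE->primed requires the TE to vanish from the
    KD H3K27ac enhancer set while keeping H3K4me1 above the enhancer-wide
    median and H3K27me3 below it (primed enhancers: high H3K4me1, no
    H3K27ac/H3K27me3).  A ``reduced`` column flags matched loci whose KD/WT
    signal ratio is <= ``reduced_ratio``.
    """
    kd_by_chrom: dict[str, list[StitchedEnhancer]] = {}
    for e in ranking_kd.enhancers:
        kd_by_chrom.setdefault(e.span.chrom, []).append(e)

    k4_means = {}
    k27me3_means = {}
    if h3k4me1_cov is not None:
        k4_means = {
            e.enhancer_id: h3k4me1_cov.mean_over(e.span)
            for e in ranking_wt.enhancers
            if h3k4me1_cov.has_chrom(e.span.chrom)
        }
    if h3k27me3_cov is not None:
        k27me3_means = {
            e.enhancer_id: h3k27me3_cov.mean_over(e.span)
            for e in ranking_wt.enhancers
            if h3k27me3_cov.has_chrom(e.span.chrom)
        }
    k4_median = float(np.median(list(k4_means.values()))) if k4_means else np.inf
    k27me3_median = (
        float(np.median(list(k27me3_means.values()))) if k27me3_means else np.inf
    )

    rows = []
    for e in ranking_wt.enhancers:
        match = _best_match(e, kd_by_chrom.get(e.span.chrom, []))
        ratio = (
            (match.signal / e.signal) if (match and e.signal > 0) else
            (np.nan if match else 0.0)
        )
        reason = ""
        if e.is_super:
            if match is None:
                label, reason = "other", "SE absent from KD enhancers"
            elif match.is_super:
                label = "SE->SE"
            else:
                label = "SE->TE"
        else:
            if match is None:
                k4 = k4_means.get(e.enhancer_id, -np.inf)
                k27 = k27me3_means.get(e.enhancer_id, np.inf)
                # ties at the H3K27me3 median count as "lacking" the mark
                # (the track is zero-inflated over enhancers)
                if k4 > k4_median and k27 <= k27me3_median:
                    label = "TE->primed"
                else:
                    label, reason = "other", "TE absent, not primed"
            elif match.is_super:
                label, reason = "other", "TE gained SE status"
            else:
                label = "TE->TE"
        rows.append(
            {
                "enhancer_id": e.enhancer_id,
                "chrom": e.span.chrom,
                "start": e.span.start,
                "end": e.span.end,
                "wt_is_super": e.is_super,
                "wt_signal": e.signal,
                "kd_signal": match.signal if match else 0.0,
                "signal_ratio": ratio,
                "label": label,
                "reduced": bool(
                    match is not None
                    and np.isfinite(ratio)
                    and ratio <= reduced_ratio
                ),
                "reason": reason,
            }
        )
    return pd.DataFrame(rows).set_index("enhancer_id")
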