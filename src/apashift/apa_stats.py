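"""Differential poly(A)-site usage statistics.

The APA score of a gene compares the distal/proximal segment-coverage
ratio between the test ("mut") and baseline ("wt") conditions:

    score = log2[ (mut_distal / mut_proximal) / (wt_distal / wt_proximal) ]

computed on replicate-averaged, size-factor-normalized mean depths of the
most distal and most proximal segments.  A negative score means the test
condition shifts usage toward the proximal PAS.  Significance comes from
a binomial GLM (logit link) of per-replicate distal counts out of
proximal + distal trials on condition, with a Wald test on the condition
coefficient; p-values are Benjamini-Hochberg adjusted.  A significant
event has |score| > 1 and FDR < 0.01 (both configurable).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .segmentation import GeneSegmentation, SegmentCountMatrix

__all__ = [
    "median_ratio_size_factors",
    "segment_fold_changes",
    "apa_score",
    "binomial_glm_test",
    "bh_fdr",
    "classify_events",
    "select_unaffected_controls",
    "overlap_enrichment",
    "run_apa_analysis",
]


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Per feature (row): geometric mean across samples; per sample: median
    over features of count / geometric mean, restricted to features whose
    geometric mean is positive (i.e. all-positive rows).
    """
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(arr)
    ok = np.isfinite(logc).all(axis=1)
    if not ok.any():
        raise ValueError(
            "no feature with all-positive counts across samples; "
            "add a pseudo-count or supply deeper coverage"
        )
    sub = arr[ok]
    geomean = np.exp(np.mean(np.log(sub), axis=1, keepdims=True))
    factors = np.median(sub / geomean, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def segment_fold_changes(matrix: SegmentCountMatrix) -> pd.Series:
    """Per-segment fold change: mean normalized depth in the test condition
    over the mean in the baseline; NaN where the baseline mean is zero."""
    sf = matrix.size_factors
    if sf is None:
        sf = median_ratio_size_factors(matrix.counts)
    norm = matrix.depth.div(sf, axis=1)
    base = norm[matrix.samples_of(matrix.baseline)].mean(axis=1)
    test = norm[matrix.samples_of(matrix.test_level)].mean(axis=1)
    fc = test / base
    fc[base == 0] = np.nan
    return fc.rename("fold_change")


def apa_score(
    wt_proximal: float,
    wt_distal: float,
    mut_proximal: float,
    mut_distal: float,
    pseudocount: float = 0.5,
) -> tuple[float, float, float]:
    """APA score from four replicate-averaged normalized mean depths.

    Returns ``(score, ratio_wt, ratio_mut)`` with ratio = distal/proximal.
    If any of the four depths is zero, ``pseudocount`` is added to all
    four (Haldane-Anscombe) so the score stays finite; otherwise the
    values are used as-is.
    """
    vals = [wt_proximal, wt_distal, mut_proximal, mut_distal]
    if any(v < 0 for v in vals):
        raise ValueError("segment depths must be non-negative")
    if min(vals) == 0:
        vals = [v + pseudocount for v in vals]
    wp, wd, mp, md = vals
    ratio_wt = wd / wp
    ratio_mut = md / mp
    return math.log2(ratio_mut / ratio_wt), ratio_wt, ratio_mut


def binomial_glm_test(
    proximal: Sequence[float],
    distal: Sequence[float],
    conditions: Sequence[str],
    baseline: str,
    test: str = "wald",
    family: str = "binomial",
    tol: float = 1e-8,
    maxiter: int = 50,
) -> tuple[float, str]:
    """Binomial GLM of per-replicate distal counts out of proximal+distal
    trials on condition; two-sided p-value for the condition effect.

    ``test`` selects a Wald z-test on the condition coefficient (default)
    or a likelihood-ratio test; ``family="quasibinomial"`` rescales the
    covariance by the Pearson dispersion.  Returns ``(p, flag)`` where
    flag is "" on a clean fit, "continuity_corrected" when separation or
    non-convergence forced a 0.5 correction on the four pooled
    condition-level totals, or "all_zero" (p = NaN) for an empty gene.
    """
    prox = np.asarray(proximal, dtype=float)
    dist = np.asarray(distal, dtype=float)
    cond = np.asarray(conditions)
    if test not in ("wald", "lrt"):
        raise ValueError(f"unknown test {test!r}")
    if family not in ("binomial", "quasibinomial"):
        raise ValueError(f"unknown family {family!r}")
    trials = prox + dist
    keep = trials > 0
    if not keep.any():
        return float("nan"), "all_zero"
    prox, dist, cond = prox[keep], dist[keep], cond[keep]
    x = (cond != baseline).astype(float)
    if len(set(cond)) == 2:
        p = _fit_glm(prox, dist, x, test=test, family=family, tol=tol, maxiter=maxiter)
        if p is not None:
            return p, ""
    # separation / non-convergence / a condition with zero trials:
    # pool to condition-level totals, add 0.5 to all four cells
    is_base = np.asarray(conditions) == baseline
    prox_all = np.asarray(proximal, dtype=float)
    dist_all = np.asarray(distal, dtype=float)
    pw = prox_all[is_base].sum() + 0.5
    dw = dist_all[is_base].sum() + 0.5
    pm = prox_all[~is_base].sum() + 0.5
    dm = dist_all[~is_base].sum() + 0.5
    beta = math.log((dm / pm) / (dw / pw))
    se = math.sqrt(1 / pw + 1 / dw + 1 / pm + 1 / dm)
    p = 2 * stats.norm.sf(abs(beta) / se)
    return float(p), "continuity_corrected"


def _fit_glm(
    prox: np.ndarray,
    dist: np.ndarray,
    x: np.ndarray,
    test: str,
    family: str,
    tol: float,
    maxiter: int,
) -> Optional[float]:
    endog = np.column_stack([dist, prox])  # successes = distal
    exog = sm.add_constant(x, has_constant="add")
    scale = "X2" if family == "quasibinomial" else 1.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # saturated fits warn but are valid
            model = sm.GLM(endog, exog, family=sm.families.Binomial())
            res = model.fit(maxiter=maxiter, tol=tol, scale=scale)
    except (PerfectSeparationError, ValueError, np.linalg.LinAlgError):
        return None
    if not res.converged or not np.isfinite(res.bse[1]) or abs(res.params[1]) > 30:
        return None
    if test == "wald":
        p = float(res.pvalues[1])
    else:
        null = sm.GLM(endog, exog[:, :1], family=sm.families.Binomial()).fit(
            maxiter=maxiter, tol=tol
        )
        lr = null.deviance - res.deviance
        if family == "quasibinomial":
            lr /= res.scale
        p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return p if np.isfinite(p) else None


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries propagate as NaN and do not count toward the number of
    tests.  Values outside [0, 1] raise.
    """
    p = np.asarray(p_values, dtype=float)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def classify_events(
    results: pd.DataFrame, score_threshold: float = 1.0, fdr_threshold: float = 0.01
) -> pd.Series:
    """Label each gene proximal / distal / unchanged.

    proximal: score < -threshold and FDR < fdr_threshold (the test
    condition favors the proximal PAS); distal mirrored; everything else,
    including NaN statistics, unchanged.
    """
    score = results["apa_score"]
    fdr = results["fdr"]
    cls = pd.Series("unchanged", index=results.index, name="class")
    sig = fdr < fdr_threshold
    cls[sig & (score < -score_threshold)] = "proximal"
    cls[sig & (score > score_threshold)] = "distal"
    return cls


def select_unaffected_controls(results: pd.DataFrame, n_affected: int) -> list[str]:
    """The ``n_affected`` non-significant genes whose APA scores sit closest
    to zero (rank by |score| ascending, ties by gene_id)."""
    if n_affected == 0:
        return []
    cand = results[(results["class"] == "unchanged") & results["apa_score"].notna()].copy()
    if n_affected > len(cand):
        raise ValueError(
            f"requested {n_affected} control genes but only {len(cand)} "
            "non-significant candidates are available"
        )
    cand["_abs"] = cand["apa_score"].abs()
    cand = cand.sort_values(["_abs", "gene_id"], kind="mergesort")
    return cand["gene_id"].head(n_affected).tolist()


def overlap_enrichment(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> tuple[float, float]:
    """Exact 2x2 over-representation test for the overlap of two gene sets.

    Returns the sample odds ratio (a*d)/(b*c) (inf when the off-diagonal
    is empty) and the one-sided hypergeometric tail p-value for an
    overlap at least as large as observed.
    """
    u = set(universe)
    if not u:
        raise ValueError("empty universe")
    a_set, b_set = set(set_a), set(set_b)
    if not a_set <= u or not b_set <= u:
        raise ValueError("both sets must be subsets of the universe")
    n_ab = len(a_set & b_set)
    n_a, n_b, n_u = len(a_set), len(b_set), len(u)
    a = n_ab
    b = n_a - n_ab
    c = n_b - n_ab
    d = n_u - n_a - n_b + n_ab
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    p = float(stats.hypergeom.sf(a - 1, n_u, n_a, n_b))
    return odds, p


# ---------------------------------------------------------------------------
# Orchestration


def run_apa_analysis(
    matrix: SegmentCountMatrix,
    segmentations: Optional[Mapping[str, GeneSegmentation]] = None,
    score_threshold: float = 1.0,
    fdr_threshold: float = 0.01,
    pseudocount: float = 0.5,
    test: str = "wald",
    family: str = "binomial",
) -> pd.DataFrame:
    """Full per-gene differential-usage analysis.

    Computes size factors, the APA score from the proximal-most and
    distal-most segments, the binomial-GLM p-value from per-replicate
    integer counts, BH FDR, and the event class.  Only genes with at
    least two segments enter; the returned frame has one row per eligible
    gene with columns gene_id, ratio_wt, ratio_mut, apa_score, p_value,
    fdr, class, glm_flag, proximal_pas_site, feature.
    """
    sf = median_ratio_size_factors(matrix.counts)
    matrix.size_factors = sf
    norm_depth = matrix.depth.div(sf, axis=1)
    wt_samples = matrix.samples_of(matrix.baseline)
    mut_samples = matrix.samples_of(matrix.test_level)

    rows = []
    for gene_id, sub in norm_depth.groupby(level=0, sort=False):
        seg_idx = sub.index.get_level_values(1)
        if len(sub) < 2:
            continue
        prox_i, dist_i = seg_idx.min(), seg_idx.max()
        wp = float(sub.loc[(gene_id, prox_i), wt_samples].mean())
        wd = float(sub.loc[(gene_id, dist_i), wt_samples].mean())
        mp = float(sub.loc[(gene_id, prox_i), mut_samples].mean())
        md = float(sub.loc[(gene_id, dist_i), mut_samples].mean())
        score, ratio_wt, ratio_mut = apa_score(wp, wd, mp, md, pseudocount)
        prox_counts = matrix.counts.loc[(gene_id, prox_i), matrix.samples].to_numpy(float)
        dist_counts = matrix.counts.loc[(gene_id, dist_i), matrix.samples].to_numpy(float)
        cond = [matrix.conditions[s] for s in matrix.samples]
        p, flag = binomial_glm_test(
            prox_counts, dist_counts, cond, matrix.baseline, test=test, family=family
        )
        site = None
        if segmentations is not None and gene_id in segmentations:
            site = segmentations[gene_id].proximal_site
        rows.append(
            {
                "gene_id": gene_id,
                "ratio_wt": ratio_wt,
                "ratio_mut": ratio_mut,
                "apa_score": score,
                "p_value": p,
                "glm_flag": flag,
                "proximal_pas_site": site,
            }
        )
    results = pd.DataFrame(rows)
    if results.empty:
        return results
    results["fdr"] = bh_fdr(results["p_value"].to_numpy())
    results["class"] = classify_events(results, score_threshold, fdr_threshold)
    results["feature"] = pd.NA
    return results
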