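"""Per-element regulatory-activity testing: cDNA vs plasmid abundance.

Re-implements the standard RNA-count testing stack so the pipeline is
self-contained: median-of-ratios size factors, method-of-moments dispersion
with shrinkage toward a parametric mean-dispersion trend, and a two-group
negative-binomial Wald test fitted by Newton iteration on the group log
means (exact MLE for the saturated two-group design with offsets).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mprakit.models import CDNA, PDNA, CountMatrix
from mprakit.prioritize import bh_adjust

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
LN2 = np.log(2.0)

ACTIVATOR = "activator"
REPRESSOR = "repressor"
INACTIVE = "inactive"


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------
def size_factors(counts: "pd.DataFrame | CountMatrix") -> pd.Series:
    """Median-of-ratios per-sample scale factors.

    factor_j = median over elements (restricted to elements whose counts are
    positive in every sample) of count_ij / geometric-mean_i.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no element has positive counts in every sample; filter the "
            "matrix or check sample quality"
        )
    log_values = np.log(values[positive])
    log_geomean = log_values.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_values - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(
    counts: "pd.DataFrame | CountMatrix", factors: Optional[pd.Series] = None
) -> pd.DataFrame:
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------
def _condition_groups(matrix: CountMatrix) -> dict:
    return {cond: matrix.condition_columns(cond) for cond in (PDNA, CDNA)}


def _moment_dispersions(
    normalized: np.ndarray, groups: Sequence[np.ndarray]
) -> np.ndarray:
    """Raw per-element MoM dispersion pooled across conditions.

    Treats normalized counts within a condition as NB draws on the common
    scale: Var(y) ~= mean(y) + alpha * mean(y)^2, solved for alpha.  A
    function of normalized counts only, so test statistics stay invariant
    under depth-preserving per-sample rescaling of the raw matrix.
    """
    num = np.zeros(normalized.shape[0])
    den = np.zeros(normalized.shape[0])
    for cols in groups:
        if len(cols) < 2:
            continue
        sub = normalized[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = (v - m) / np.square(m)
        raw = np.where(np.isfinite(raw), raw, 0.0)
        weight = len(cols) - 1
        num += weight * raw
        den += weight
    out = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    return np.maximum(out, DISPERSION_FLOOR)


def _fit_trend(mean_norm: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Parametric trend alpha(mu) = a0 + a1/mu fit on above-floor elements."""
    usable = (raw > 2 * DISPERSION_FLOOR) & (mean_norm > 0)
    if usable.sum() < 10:
        level = float(np.median(raw))
        return np.full_like(raw, max(level, DISPERSION_FLOOR))
    x = np.column_stack(
        [np.ones(usable.sum()), 1.0 / mean_norm[usable]]
    )
    coef, *_ = np.linalg.lstsq(x, raw[usable], rcond=None)
    a0, a1 = np.maximum(coef, 0.0)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mean_norm, 1e-12)
    return np.maximum(trend, DISPERSION_FLOOR)


def estimate_dispersion(
    matrix: CountMatrix, factors: Optional[pd.Series] = None
) -> pd.Series:
    """Per-element dispersion: geometric shrinkage of raw MoM toward trend."""
    matrix.require_both_conditions()
    for cond, cols in _condition_groups(matrix).items():
        if len(cols) < 2:
            raise ValueError(f"need >= 2 {cond} replicates to estimate dispersion")
    if factors is None:
        factors = size_factors(matrix)
    values = matrix.counts.to_numpy(dtype=float)
    fac = factors.loc[matrix.counts.columns].to_numpy()
    col_index = {c: i for i, c in enumerate(matrix.counts.columns)}
    groups = [
        np.array([col_index[c] for c in cols])
        for cols in _condition_groups(matrix).values()
    ]
    raw = _moment_dispersions(values / fac, groups)
    mean_norm = (values / fac).mean(axis=1)
    trend = _fit_trend(mean_norm, raw)
    # geometric blend, floored at the trend: moment estimates below the
    # trend at few replicates are dominated by sampling noise and would
    # make the Wald test anticonservative
    shrunk = np.exp(0.5 * np.log(raw) + 0.5 * np.log(trend))
    shrunk = np.maximum(np.maximum(shrunk, trend), DISPERSION_FLOOR)
    return pd.Series(shrunk, index=matrix.counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------
def _group_log_mean(y: np.ndarray, alpha: np.ndarray) -> tuple:
    """NB group fit on normalized counts y_ij ~ NB(q_i, alpha_i).

    The MLE of the group mean is the plain mean (the score
    sum_j (y - q)/(1 + alpha*q) = 0 is solved by q = mean(y)); the Fisher
    information of eta = log(q) is n * q / (1 + alpha * q).  Exact for
    equal sequencing depths; depends on normalized counts only.
    """
    q = y.mean(axis=1)
    with np.errstate(divide="ignore"):
        eta = np.log(q)
    info = y.shape[1] * q / (1.0 + alpha * q)
    return eta, info


def test_activity(
    matrix: CountMatrix,
    factors: Optional[pd.Series] = None,
    dispersions: Optional[pd.Series] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-element NB Wald test of cDNA vs pDNA abundance.

    Returns a frame with columns element_id, variant_id, allele, base_mean,
    log2_activity, se, stat, pvalue, padj, call.  Elements with zero counts
    in either condition get NA statistics and are excluded from the BH
    family.
    """
    matrix.require_both_conditions()
    if factors is None:
        factors = size_factors(matrix)
    if dispersions is None:
        dispersions = estimate_dispersion(matrix, factors)

    counts = matrix.counts
    values = counts.to_numpy(dtype=float)
    fac = factors.loc[counts.columns].to_numpy()
    disp = dispersions.loc[counts.index].to_numpy()
    col_index = {c: i for i, c in enumerate(counts.columns)}
    p_cols = np.array([col_index[c] for c in matrix.condition_columns(PDNA)])
    c_cols = np.array([col_index[c] for c in matrix.condition_columns(CDNA)])

    testable = (values[:, p_cols].sum(axis=1) > 0) & (values[:, c_cols].sum(axis=1) > 0)

    n = values.shape[0]
    log2_activity = np.full(n, np.nan)
    se = np.full(n, np.nan)
    stat = np.full(n, np.nan)
    pvalue = np.full(n, np.nan)

    if testable.any():
        sub = values[testable] / fac
        sub_disp = disp[testable]
        eta_p, info_p = _group_log_mean(sub[:, p_cols], sub_disp)
        eta_c, info_c = _group_log_mean(sub[:, c_cols], sub_disp)
        beta = eta_c - eta_p
        var = 1.0 / info_c + 1.0 / info_p
        wald = beta / np.sqrt(var)
        log2_activity[testable] = beta / LN2
        se[testable] = np.sqrt(var) / LN2
        stat[testable] = wald
        # clamp underflowed p so the BH domain check (p > 0) holds
        pvalue[testable] = np.maximum(2.0 * stats.norm.sf(np.abs(wald)), 1e-300)

    padj = np.full(n, np.nan)
    if testable.any():
        padj[testable] = bh_adjust(pvalue[testable])

    call = np.array([INACTIVE] * n, dtype=object)
    significant = testable & (padj < alpha)
    call[significant & (log2_activity > 0)] = ACTIVATOR
    call[significant & (log2_activity < 0)] = REPRESSOR

    elements = matrix.elements
    return pd.DataFrame(
        {
            "element_id": elements["element_id"].to_numpy(),
            "variant_id": elements["variant_id"].to_numpy(),
            "allele": elements["allele"].to_numpy(),
            "base_mean": (values / fac).mean(axis=1),
            "log2_activity": log2_activity,
            "se": se,
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
            "call": call,
        }
    )


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------
def summarize_activity(results: pd.DataFrame, variants) -> dict:
    """Reference-element activity summary: fractions, split, TSS correlation."""
    by_id = {v.variant_id: v for v in variants}
    ref_mask = results.apply(
        lambda r: r["variant_id"] in by_id
        and r["allele"] == by_id[r["variant_id"]].ref_allele,
        axis=1,
    )
    ref = results[ref_mask].copy()
    tested = ref[ref["pvalue"].notna()]
    significant = tested[tested["call"] != INACTIVE]

    frac = len(significant) / len(tested) if len(tested) else 0.0
    by_inheritance = {}
    for cls in ("de_novo", "inherited"):
        sub = tested[[by_id[v].inheritance == cls for v in tested["variant_id"]]]
        sig = sub[sub["call"] != INACTIVE]
        by_inheritance[cls] = len(sig) / len(sub) if len(sub) else 0.0

    dist = np.array([by_id[v].dist_to_tss for v in tested["variant_id"]], dtype=float)
    rho, rho_p = (np.nan, np.nan)
    if np.isfinite(dist).all() and len(tested) >= 3:
        rho, rho_p = stats.spearmanr(np.abs(dist), tested["log2_activity"])

    return {
        "n_tested": int(len(tested)),
        "n_significant": int(len(significant)),
        "frac_significant": frac,
        "frac_by_inheritance": by_inheritance,
        "n_activator": int((significant["call"] == ACTIVATOR).sum()),
        "n_repressor": int((significant["call"] == REPRESSOR).sum()),
        "tss_distance_spearman_rho": float(rho) if rho == rho else np.nan,
        "tss_distance_spearman_p": float(rho_p) if rho_p == rho_p else np.nan,
        "distance_activity": pd.DataFrame(
            {"dist_to_tss": dist, "log2_activity": tested["log2_activity"].to_numpy()}
        ),
    }
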