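"""Phenotype-term overlap testing and tiered candidate ranking.

Overlap between a proband's phenotype terms and the terms of a TF bound at
the variant site is scored with the hypergeometric upper tail; all
(variant, proband, TF) tests in a run form a single Benjamini-Hochberg
family.  Term matching is by exact accession identity.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Mapping, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from mprakit.models import TFBindingSite, Variant

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Interval intersection
# ---------------------------------------------------------------------------
def intersect_tf(
    variants: Sequence[Variant], sites: Sequence[TFBindingSite]
) -> Dict[str, Set[str]]:
    """Map each variant to the set of TFs whose intervals cover it.

    A variant's 1-based position converts to 0-based; a TF is assigned iff
    that coordinate lies in [start, end).  Lookup is vectorized over the
    per-contig interval arrays, restricted to starts <= position via a
    sorted index.
    """
    by_contig: Dict[str, tuple] = {}
    for contig in {s.contig for s in sites}:
        subset = [s for s in sites if s.contig == contig]
        starts = np.array([s.start for s in subset])
        order = np.argsort(starts, kind="stable")
        by_contig[contig] = (
            starts[order],
            np.array([s.end for s in subset])[order],
            np.array([s.tf_name for s in subset], dtype=object)[order],
        )
    out: Dict[str, Set[str]] = {}
    for v in variants:
        pos0 = v.pos - 1
        entry = by_contig.get(v.contig)
        if entry is None:
            logger.info("no TF sites on contig %s (variant %s)", v.contig, v.variant_id)
            out[v.variant_id] = set()
            continue
        starts, ends, names = entry
        hi = np.searchsorted(starts, pos0, side="right")
        hit = ends[:hi] > pos0
        out[v.variant_id] = set(names[:hi][hit])
    return out


# ---------------------------------------------------------------------------
# Hypergeometric overlap
# ---------------------------------------------------------------------------
def hypergeom_overlap(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N population, K successes, n draws)."""
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if K > N or n > N or N <= 0:
        raise ValueError(f"need K, n <= N and N > 0; got K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # survival function of scipy's frozen hypergeometric, stable in log space
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def gene_set_overlap(set_a: Set, set_b: Set, universe: int) -> float:
    """Hypergeometric p for the overlap of two sets drawn from ``universe``."""
    if len(set_a) > universe or len(set_b) > universe:
        raise ValueError("set larger than universe")
    return hypergeom_overlap(len(set_a & set_b), len(set_a), len(set_b), universe)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------
def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Step-up BH q-values, preserving input order.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Overlap tests
# ---------------------------------------------------------------------------
def build_overlap_tests(
    variants: Sequence[Variant],
    variant_tfs: Mapping[str, Set[str]],
    terms: Mapping[str, Set[str]],
    universe: int,
) -> pd.DataFrame:
    """One hypergeometric test per (variant, proband, bound TF) triple.

    Returns columns variant_id, proband_id, tf_name, k, K, n, N, shared,
    pvalue, qvalue (BH over the pooled family).
    """
    rows = []
    for v in variants:
        proband_terms = terms.get(v.proband_id)
        if proband_terms is None:
            logger.info("proband %s has no term annotation", v.proband_id)
            continue
        for tf in sorted(variant_tfs.get(v.variant_id, set())):
            tf_terms = terms.get(tf)
            if tf_terms is None:
                logger.info("TF %s has no term annotation", tf)
                continue
            shared = proband_terms & tf_terms
            p = hypergeom_overlap(
                len(shared), len(proband_terms), len(tf_terms), universe
            )
            rows.append(
                (v.variant_id, v.proband_id, tf, len(shared),
                 len(proband_terms), len(tf_terms), universe,
                 ",".join(sorted(shared)), p)
            )
    df = pd.DataFrame(
        rows,
        columns=["variant_id", "proband_id", "tf_name", "k", "K", "n", "N",
                 "shared", "pvalue"],
    )
    df["qvalue"] = bh_adjust(df["pvalue"]) if len(df) else []
    return df


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------
def prioritize(
    overlap_tests: pd.DataFrame,
    variant_effects: pd.DataFrame,
    q_threshold: float = 0.05,
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Tiered ranking of variants by HPO overlap and regulatory effect.

    Tier 1: >= 1 overlap test with q < threshold AND |z| > threshold;
    tier 2: overlap only; tier 3: effect only.  Within tiers, sorted by
    min q, then |z| (descending), then variant id.
    """
    eff = variant_effects.set_index("variant_id")
    if len(overlap_tests) and len(eff) and not (
        set(overlap_tests["variant_id"]) & set(eff.index)
    ):
        raise ValueError(
            "overlap tests and variant effects share no variants; "
            "were they computed on the same universe?"
        )
    by_variant = {}
    if len(overlap_tests):
        for vid, group in overlap_tests.groupby("variant_id"):
            best = group.loc[group["qvalue"].idxmin()]
            by_variant[vid] = {
                "min_q": float(best["qvalue"]),
                "best_tf": best["tf_name"],
                "proband_id": best["proband_id"],
                "bound_tfs": ",".join(sorted(group["tf_name"])),
                "shared_terms": best["shared"],
            }
    rows = []
    all_ids = set(eff.index) | set(by_variant)
    for vid in sorted(all_ids):
        z = float(eff.loc[vid, "z"]) if vid in eff.index else np.nan
        mech = eff.loc[vid, "mechanism"] if vid in eff.index else "none"
        info = by_variant.get(vid)
        hpo_sig = info is not None and info["min_q"] < q_threshold
        eff_sig = np.isfinite(z) and abs(z) > z_threshold
        if hpo_sig and eff_sig:
            tier = 1
        elif hpo_sig:
            tier = 2
        elif eff_sig:
            tier = 3
        else:
            continue
        rows.append(
            {
                "variant_id": vid,
                "tier": tier,
                "min_q": info["min_q"] if info else np.nan,
                "z": z,
                "mechanism": mech,
                "proband_id": info["proband_id"] if info else "",
                "bound_tfs": info["bound_tfs"] if info else "",
                "best_tf": info["best_tf"] if info else "",
                "shared_terms": info["shared_terms"] if info else "",
            }
        )
    ranked = pd.DataFrame(
        rows,
        columns=["variant_id", "tier", "min_q", "z", "mechanism", "proband_id",
                 "bound_tfs", "best_tf", "shared_terms"],
    )
    if len(ranked):
        ranked["_absz"] = ranked["z"].abs().fillna(-1.0)
        ranked["_q"] = ranked["min_q"].fillna(np.inf)
        ranked = ranked.sort_values(
            ["tier", "_q", "_absz", "variant_id"],
            ascending=[True, True, False, True],
        ).drop(columns=["_absz", "_q"]).reset_index(drop=True)
    return ranked
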