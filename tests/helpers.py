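"""Independent oracles shared by the unit and acceptance suites.

These deliberately use brute force / exhaustive enumeration, staying
independent of the library code paths they check.
"""

from itertools import combinations
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np


def enumerate_hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exhaustively enumerating all C(N, n) draws.

    The population is range(N) with the first K items marked as successes.
    """
    total = 0
    hits = 0
    for draw in combinations(range(N), n):
        total += 1
        overlap = sum(1 for x in draw if x < K)
        if overlap >= k:
            hits += 1
    return hits / total


def enumerate_hypergeom_distribution(K: int, n: int, N: int) -> Dict[int, int]:
    """Histogram of overlap counts over all C(N, n) draws."""
    hist: Dict[int, int] = {}
    for draw in combinations(range(N), n):
        overlap = sum(1 for x in draw if x < K)
        hist[overlap] = hist.get(overlap, 0) + 1
    return hist


def brute_force_intersect(variants, sites) -> Dict[str, Set[str]]:
    """Reference interval lookup: plain scan over every site."""
    out: Dict[str, Set[str]] = {}
    for v in variants:
        pos0 = v.pos - 1
        out[v.variant_id] = {
            s.tf_name
            for s in sites
            if s.contig == v.contig and s.start <= pos0 < s.end
        }
    return out


def true_active_elements(variants, truth, activity_log2fc=1.0,
                         allelic_log2fc=1.0) -> Set[str]:
    """Element ids whose planted net log2 effect is nonzero.

    The planted base activity applies to all 4 analogs of an active locus;
    the allelic effect adds on the alt allele of effect variants.
    """
    base = {eid.rsplit("|", 1)[0]: s for eid, s in truth.active_elements.items()}
    out: Set[str] = set()
    for v in variants:
        for allele in "ACGT":
            effect = base.get(v.variant_id, 0) * activity_log2fc
            if allele == v.alt_allele and v.variant_id in truth.effect_variants:
                effect += truth.effect_variants[v.variant_id] * allelic_log2fc
            if effect != 0:
                out.add(f"{v.variant_id}|{allele}")
    return out


def bh_reference(pvalues: Sequence[float]) -> np.ndarray:
    """Step-up BH q-values via the textbook formula (independent route)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, m * p[idx] / rank)
        q[idx] = min(running_min, 1.0)
    return q
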