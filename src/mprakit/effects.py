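"""Allelic regulatory effects: ref-vs-alt activity deltas and z-scores.

delta = alt log2 activity - ref log2 activity; z-scores standardize the
pooled delta distribution (de novo + inherited together, sample sd) and a
variant is called at |z| > 2.  Increased-activity calls on a repressive
reference element are labelled loss of repression.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from mprakit.activity import REPRESSOR
from mprakit.models import NUCLEOTIDES, Variant

logger = logging.getLogger(__name__)

CALL_DECREASED = "decreased"
CALL_INCREASED = "increased"
CALL_NONE = "none"

MECH_LOF = "loss_of_function"
MECH_LOR = "loss_of_repression"
MECH_NONE = "none"


def _activity_lookup(activity_results: pd.DataFrame) -> dict:
    return {
        (r.variant_id, r.allele): (r.log2_activity, r.call)
        for r in activity_results.itertuples(index=False)
    }


def compute_deltas(
    activity_results: pd.DataFrame, variants: Sequence[Variant]
) -> Tuple[pd.DataFrame, List[Tuple[str, str]]]:
    """Per-variant alt-minus-ref activity difference.

    Variants whose ref or alt element has no finite activity estimate are
    excluded and returned as (variant_id, reason) records.
    """
    lookup = _activity_lookup(activity_results)
    rows = []
    excluded: List[Tuple[str, str]] = []
    for v in variants:
        ref = lookup.get((v.variant_id, v.ref_allele))
        alt = lookup.get((v.variant_id, v.alt_allele))
        if ref is None and alt is None:
            excluded.append((v.variant_id, "missing both alleles"))
            continue
        if ref is None or not np.isfinite(ref[0]):
            excluded.append((v.variant_id, "reference allele activity NA"))
            continue
        if alt is None or not np.isfinite(alt[0]):
            excluded.append((v.variant_id, "variant allele activity NA"))
            continue
        rows.append(
            {
                "variant_id": v.variant_id,
                "ref_activity": float(ref[0]),
                "alt_activity": float(alt[0]),
                "delta": float(alt[0]) - float(ref[0]),
                "ref_call": ref[1],
            }
        )
    for vid, reason in excluded:
        logger.info("excluded %s: %s", vid, reason)
    return pd.DataFrame(
        rows, columns=["variant_id", "ref_activity", "alt_activity", "delta", "ref_call"]
    ), excluded


def standardize(deltas: np.ndarray) -> np.ndarray:
    """z_i = (delta_i - mean) / sample sd; errors on degenerate input."""
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size < 3:
        raise ValueError(f"need >= 3 deltas to standardize, got {deltas.size}")
    sd = deltas.std(ddof=1)
    if sd == 0:
        raise ValueError("delta distribution is degenerate (sd = 0)")
    return (deltas - deltas.mean()) / sd


def call_effects(
    deltas: pd.DataFrame, z_threshold: float = 2.0
) -> pd.DataFrame:
    """Standardize deltas and call variant effects with mechanism labels.

    ``deltas`` is the frame from :func:`compute_deltas` (needs columns
    variant_id, delta, ref_call).  Adds z, call, mechanism.
    """
    out = deltas.copy()
    out["z"] = standardize(out["delta"].to_numpy())
    calls = []
    mechanisms = []
    for row in out.itertuples(index=False):
        if row.z < -z_threshold:
            calls.append(CALL_DECREASED)
            mechanisms.append(MECH_LOF)
        elif row.z > z_threshold:
            calls.append(CALL_INCREASED)
            mechanisms.append(MECH_LOR if row.ref_call == REPRESSOR else MECH_NONE)
        else:
            calls.append(CALL_NONE)
            mechanisms.append(MECH_NONE)
    out["call"] = calls
    out["mechanism"] = mechanisms
    return out


# ---------------------------------------------------------------------------
# Analog profiles
# ---------------------------------------------------------------------------
LABEL_REF = "reference"
LABEL_VAR = "variant"
LABEL_ALT = "alternative"


def analog_summary(
    activity_results: pd.DataFrame,
    variants: Sequence[Variant],
    effect_variants: Optional[Set[str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-variant 4-allele activity profiles plus per-label aggregates.

    Each profile labels its alleles reference / variant / alternative (x2).
    The aggregate (mean, sd, n of activity per label) is restricted to
    ``effect_variants`` when given.  Variants missing any of the 4 measured
    alleles are skipped with a log entry.
    """
    lookup = _activity_lookup(activity_results)
    rows = []
    for v in variants:
        acts = {}
        complete = True
        for base in NUCLEOTIDES:
            entry = lookup.get((v.variant_id, base))
            if entry is None or not np.isfinite(entry[0]):
                complete = False
                break
            acts[base] = float(entry[0])
        if not complete:
            logger.info("analog profile skipped for %s: incomplete analog set",
                        v.variant_id)
            continue
        for base in NUCLEOTIDES:
            if base == v.ref_allele:
                label = LABEL_REF
            elif base == v.alt_allele:
                label = LABEL_VAR
            else:
                label = LABEL_ALT
            rows.append(
                {"variant_id": v.variant_id, "allele": base,
                 "log2_activity": acts[base], "label": label}
            )
    profile = pd.DataFrame(
        rows, columns=["variant_id", "allele", "log2_activity", "label"]
    )
    subset = profile
    if effect_variants is not None:
        subset = profile[profile["variant_id"].isin(effect_variants)]
    if len(subset):
        aggregate = (
            subset.groupby("label")["log2_activity"]
            .agg(mean="mean", sd="std", n="size")
            .reset_index()
        )
    else:
        aggregate = pd.DataFrame(columns=["label", "mean", "sd", "n"])
    return profile, aggregate
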