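"""Candidate variant selection and barcoded oligo library design.

Design conventions (fixed here because the assay description leaves them
open):

* inserts are 100 nt from the plus strand, 49 bases upstream + variant +
  50 bases downstream;
* the TSS-distance filter boundary is inclusive (<= window);
* barcodes are 12-mers that avoid the BsaI/Esp3I golden-gate recognition
  sites on either strand, homopolymer runs >= 5 and extreme GC, and carry a
  mod-4 checksum so any two barcodes differ at >= 2 positions.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from mprakit.models import NUCLEOTIDES, OligoRecord, Variant

logger = logging.getLogger(__name__)

BSAI = "GGTCTC"
ESP3I = "CGTCTC"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


#: recognition sites on either strand
FORBIDDEN_SITES = (BSAI, revcomp(BSAI), ESP3I, revcomp(ESP3I))

# Adapter5 ends in "AA" and spacer/adapter3 start with "TT": none of the
# forbidden 6-mers contains AA or TT or starts with A or ends with T, so no
# junction window into/out of the (unconstrained) genomic insert can create
# a site.  Placeholder sequences; real priming arms are vendor-specific.
ADAPTER5 = "ACCTGCAGGAA"
SPACER = "TTGGCCAGCAA"
ADAPTER3 = "TTGAGCTCGCT"

DEFAULT_INSERT_LEN = 100
DEFAULT_BARCODE_LEN = 12
DEFAULT_PER_SEQ = 5

_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}


def has_forbidden_site(seq: str) -> bool:
    return any(site in seq for site in FORBIDDEN_SITES)


def max_homopolymer(seq: str) -> int:
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best if seq else 0


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


# ---------------------------------------------------------------------------
# TSS distances
# ---------------------------------------------------------------------------
def nearest_tss_distance(variants: Sequence[Variant], tss: pd.DataFrame) -> np.ndarray:
    """Signed distance (variant pos - nearest TSS pos) per variant.

    ``tss`` needs columns ``contig`` and ``pos`` (1-based).  Variants on
    contigs without any TSS get distance ``2**62`` (effectively infinite).
    """
    by_contig: Dict[str, np.ndarray] = {
        contig: np.sort(group["pos"].to_numpy())
        for contig, group in tss.groupby("contig")
    }
    out = np.empty(len(variants), dtype=np.int64)
    far = np.int64(2**62)
    for i, v in enumerate(variants):
        positions = by_contig.get(v.contig)
        if positions is None or positions.size == 0:
            out[i] = far
            continue
        j = np.searchsorted(positions, v.pos)
        candidates = positions[max(0, j - 1): j + 1]
        deltas = v.pos - candidates
        out[i] = deltas[np.argmin(np.abs(deltas))]
    return out


def filter_variants(
    variants: Sequence[Variant],
    tss: pd.DataFrame,
    window_bp: int = 100_000,
    maf_max: float = 0.001,
) -> Tuple[List[Variant], List[Tuple[str, str]]]:
    """Apply the candidate-selection criteria; annotate TSS distances.

    Keeps variants with MAF strictly below ``maf_max``, detected by >= 2
    technologies, within ``window_bp`` (inclusive) of the nearest TSS, and
    not flagged recurrent / known-causative / coding.  Returns the kept
    variants plus (variant_id, reason) rejection records.
    """
    if tss.empty:
        raise ValueError("TSS annotation is empty")
    kept: List[Variant] = []
    rejected: List[Tuple[str, str]] = []
    distances = nearest_tss_distance(variants, tss)
    for v, dist in zip(variants, distances):
        try:
            v.validate()
        except ValueError as exc:
            rejected.append((v.variant_id, f"malformed: {exc}"))
            continue
        if not v.maf < maf_max:
            rejected.append((v.variant_id, f"maf {v.maf} >= {maf_max}"))
        elif v.n_technologies < 2:
            rejected.append((v.variant_id, "detected by < 2 technologies"))
        elif abs(int(dist)) > window_bp:
            rejected.append((v.variant_id, f"TSS distance {abs(int(dist))} > {window_bp}"))
        elif v.seen_in_multiple_probands:
            rejected.append((v.variant_id, "seen in multiple probands"))
        elif v.known_causative:
            rejected.append((v.variant_id, "known causative variant"))
        elif v.coding_impact:
            rejected.append((v.variant_id, "coding impact"))
        else:
            v.dist_to_tss = int(dist)
            kept.append(v)
    for variant_id, reason in rejected:
        logger.info("rejected %s: %s", variant_id, reason)
    return kept, rejected


# ---------------------------------------------------------------------------
# Inserts and analogs
# ---------------------------------------------------------------------------
def insert_offset(length: int = DEFAULT_INSERT_LEN) -> int:
    """0-based offset of the variant base within an insert of ``length``."""
    return length // 2 - 1 if length % 2 == 0 else length // 2


def extract_window(
    reference: Mapping[str, str], variant: Variant, length: int = DEFAULT_INSERT_LEN
) -> str:
    """Plus-strand insert centered on the variant (variant at 1-based 50)."""
    try:
        seq = reference[variant.contig]
    except KeyError:
        raise ValueError(f"{variant.variant_id}: contig {variant.contig} not in reference")
    up = insert_offset(length)
    start = variant.pos - 1 - up
    end = start + length
    if start < 0 or end > len(seq):
        raise ValueError(
            f"{variant.variant_id}: window [{start}, {end}) off contig "
            f"{variant.contig} (length {len(seq)})"
        )
    return seq[start:end].upper()


def make_analogs(insert: str, offset: int) -> Dict[str, str]:
    """The 4 single-position analogs of ``insert``, keyed by their base."""
    if not 0 <= offset < len(insert):
        raise ValueError(f"offset {offset} outside insert of length {len(insert)}")
    return {
        base: insert[:offset] + base + insert[offset + 1:] for base in NUCLEOTIDES
    }


# ---------------------------------------------------------------------------
# Barcodes
# ---------------------------------------------------------------------------
def barcode_checksum(barcode: str) -> int:
    """Sum of base indices mod 4; the generator pins this to 0.

    Two distinct equal-checksum words must differ in >= 2 positions, which
    gives the whole table minimum pairwise Hamming distance 2 for free.
    """
    return sum(_BASE_INDEX[b] for b in barcode) % 4


def barcode_is_valid(
    barcode: str, gc_bounds: Tuple[float, float] = (0.25, 0.75)
) -> bool:
    return (
        not has_forbidden_site(barcode)
        and max_homopolymer(barcode) < 5
        and gc_bounds[0] <= gc_fraction(barcode) <= gc_bounds[1]
    )


def barcode_stream(
    rng: np.random.Generator,
    length: int = DEFAULT_BARCODE_LEN,
    batch: int = 20_000,
    max_batches: int = 5_000,
) -> Iterator[str]:
    """Yield unique constraint-satisfying barcodes indefinitely."""
    seen = set()
    base_arr = np.array(list(NUCLEOTIDES))
    for _ in range(max_batches):
        draws = rng.integers(0, 4, size=(batch, length - 1))
        last = (-draws.sum(axis=1)) % 4
        codes = np.concatenate([draws, last[:, None]], axis=1)
        for row in base_arr[codes]:
            bc = "".join(row)
            if bc in seen or not barcode_is_valid(bc):
                continue
            seen.add(bc)
            yield bc
    raise RuntimeError(
        f"barcode space exhausted after {max_batches} batches "
        f"({len(seen)} produced; length={length})"
    )


def assign_barcodes(
    n_sequences: int,
    per_seq: int = DEFAULT_PER_SEQ,
    length: int = DEFAULT_BARCODE_LEN,
    rng_seed: int = 0,
) -> List[List[str]]:
    """Draw ``per_seq`` distinct barcodes for each of ``n_sequences``."""
    needed = n_sequences * per_seq
    if 4 ** length < 10 * needed:
        raise ValueError(
            f"barcode length {length} too short for {needed} barcodes"
        )
    rng = np.random.default_rng(rng_seed)
    stream = barcode_stream(rng, length=length)
    flat = [next(stream) for _ in range(needed)]
    return [flat[i * per_seq:(i + 1) * per_seq] for i in range(n_sequences)]


# ---------------------------------------------------------------------------
# Library assembly
# ---------------------------------------------------------------------------
def _junction_safe(full_oligo: str, insert_start: int, insert_end: int) -> bool:
    """True if no forbidden 6-mer lies outside the insert interior."""
    for i in range(len(full_oligo) - 5):
        word = full_oligo[i:i + 6]
        if word in FORBIDDEN_SITES:
            if not (insert_start <= i and i + 6 <= insert_end):
                return False
    return True


def build_library(
    variants: Sequence[Variant],
    reference: Mapping[str, str],
    per_seq: int = DEFAULT_PER_SEQ,
    insert_len: int = DEFAULT_INSERT_LEN,
    barcode_len: int = DEFAULT_BARCODE_LEN,
    seed: int = 0,
    adapter5: str = ADAPTER5,
    spacer: str = SPACER,
    adapter3: str = ADAPTER3,
) -> Tuple[List[OligoRecord], List[Tuple[str, str]]]:
    """Design the full oligo library: 4 analogs x ``per_seq`` barcodes each.

    Returns (oligo records, rejections).  Output cardinality is exactly
    ``(len(variants) - len(rejections)) * 4 * per_seq`` and the barcode ->
    (variant, allele) mapping is injective.
    """
    for arm in (adapter5, spacer, adapter3):
        if has_forbidden_site(arm):
            raise ValueError(f"adapter/spacer {arm} contains a forbidden site")
    rng = np.random.default_rng(seed)
    stream = barcode_stream(rng, length=barcode_len)
    offset = insert_offset(insert_len)
    insert_start = len(adapter5)
    insert_end = insert_start + insert_len

    oligos: List[OligoRecord] = []
    rejected: List[Tuple[str, str]] = []
    for v in variants:
        try:
            window = extract_window(reference, v, length=insert_len)
        except ValueError as exc:
            rejected.append((v.variant_id, str(exc)))
            logger.info("library design rejected %s: %s", v.variant_id, exc)
            continue
        if window[offset] != v.ref_allele:
            rejected.append(
                (v.variant_id,
                 f"reference base {window[offset]} != ref allele {v.ref_allele}")
            )
            continue
        analogs = make_analogs(window, offset)
        for allele in NUCLEOTIDES:
            insert = analogs[allele]
            for j in range(per_seq):
                for _ in range(50):
                    barcode = next(stream)
                    full = adapter5 + insert + spacer + barcode + adapter3
                    if _junction_safe(full, insert_start, insert_end):
                        break
                else:  # pragma: no cover - junction-safe arms preclude this
                    raise RuntimeError("could not find junction-safe barcode")
                oligos.append(
                    OligoRecord(
                        oligo_id=f"{v.variant_id}|{allele}|bc{j + 1}",
                        variant_id=v.variant_id,
                        allele=allele,
                        barcode=barcode,
                        insert=insert,
                        full_oligo=full,
                    )
                )
    return oligos, rejected


def barcode_frame(oligos: Iterable[OligoRecord]) -> pd.DataFrame:
    """Barcode table (barcode, variant_id, allele, oligo_id, element_id)."""
    rows = [
        (o.barcode, o.variant_id, o.allele, o.oligo_id, o.element_id)
        for o in oligos
    ]
    return pd.DataFrame(
        rows, columns=["barcode", "variant_id", "allele", "oligo_id", "element_id"]
    )
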