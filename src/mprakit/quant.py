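"""Targeted-read quantification: FASTQ tags -> element x sample counts.

The first ``tag_len`` (default 12) bases of every read are the barcode tag;
an element's count is the sum over its 5 barcode tags.  Matching is exact by
default; with ``max_mismatch=1`` a tag is rescued only when exactly one
barcode lies within Hamming distance 1.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import pandas as pd

from mprakit.io import open_maybe_gzip
from mprakit.models import CountMatrix

logger = logging.getLogger(__name__)

DEFAULT_TAG_LEN = 12


@dataclass
class TagStats:
    """Read-accounting for one FASTQ file; conserves total reads."""

    total: int = 0
    dropped_short: int = 0
    dropped_n: int = 0
    matched: int = 0
    ambiguous: int = 0
    unmatched: int = 0

    @property
    def dropped(self) -> int:
        return self.dropped_short + self.dropped_n

    @property
    def match_rate(self) -> float:
        usable = self.total - self.dropped
        return self.matched / usable if usable else 0.0

    def check_conservation(self) -> None:
        assert self.matched + self.ambiguous + self.unmatched + self.dropped == self.total


def parse_tags(fastq_path, tag_len: int = DEFAULT_TAG_LEN) -> Tuple[Counter, TagStats]:
    """Count 12-mer tags in a FASTQ file (plain or gzipped).

    Reads shorter than ``tag_len`` or with N in the tag are dropped and
    counted.  Raises on a structurally broken record, naming its number.
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    tags: Counter = Counter()
    stats = TagStats()
    with open_maybe_gzip(fastq_path) as fh:
        iterator = FastqGeneralIterator(fh)
        record_no = 0
        while True:
            try:
                item = next(iterator, None)
            except ValueError as exc:
                raise ValueError(
                    f"{fastq_path}: bad FASTQ record #{record_no + 1}: {exc}"
                ) from exc
            if item is None:
                break
            record_no += 1
            _title, seq, _qual = item
            stats.total += 1
            if len(seq) < tag_len:
                stats.dropped_short += 1
                continue
            tag = seq[:tag_len].upper()
            if "N" in tag:
                stats.dropped_n += 1
                continue
            tags[tag] += 1
    logger.info("%s: %d reads, %d tags, %d dropped",
                fastq_path, stats.total, len(tags), stats.dropped)
    return tags, stats


def _hamming1_neighbors(tag: str):
    for i, base in enumerate(tag):
        for b in "ACGT":
            if b != base:
                yield tag[:i] + b + tag[i + 1:]


def match_barcodes(
    tag_counts: Mapping[str, int],
    barcode_table: pd.DataFrame,
    max_mismatch: int = 0,
    stats: TagStats = None,
) -> Tuple[Dict[str, int], TagStats]:
    """Assign tag counts to barcodes; ambiguous 1-mismatch tags stay unmatched."""
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    barcodes = barcode_table["barcode"]
    if barcodes.duplicated().any():
        raise ValueError("barcode table is not injective")
    known = set(barcodes)
    stats = stats or TagStats(total=sum(tag_counts.values()))
    counts = {bc: 0 for bc in known}
    for tag, n in tag_counts.items():
        if tag in known:
            counts[tag] += n
            stats.matched += n
            continue
        if max_mismatch == 1:
            hits = [nb for nb in _hamming1_neighbors(tag) if nb in known]
            if len(hits) == 1:
                counts[hits[0]] += n
                stats.matched += n
                continue
            if len(hits) > 1:
                stats.ambiguous += n
                continue
        stats.unmatched += n
    return counts, stats


def collapse_elements(
    barcode_counts: Mapping[str, int],
    barcode_table: pd.DataFrame,
    per_seq: int = 5,
) -> pd.Series:
    """Element count = sum of its ``per_seq`` barcode counts (zeros kept)."""
    sizes = barcode_table.groupby("element_id", sort=False).size()
    bad = sizes[sizes != per_seq]
    if len(bad):
        raise ValueError(
            f"{len(bad)} elements do not have exactly {per_seq} barcodes "
            f"(e.g. {bad.index[0]}: {bad.iloc[0]})"
        )
    values = barcode_table["barcode"].map(lambda b: barcode_counts.get(b, 0))
    out = values.groupby(barcode_table["element_id"], sort=False).sum()
    out.index.name = None
    return out.astype(int)


def assemble_matrix(
    element_counts: Mapping[str, pd.Series],
    sample_sheet: pd.DataFrame,
) -> CountMatrix:
    """Stack per-sample element counts into a CountMatrix (stable order)."""
    ids = list(sample_sheet["sample_id"])
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in sample sheet")
    missing = [s for s in ids if s not in element_counts]
    if missing:
        raise ValueError(f"missing counts for samples: {missing}")
    first = element_counts[ids[0]]
    data = {}
    for sid in ids:
        series = element_counts[sid]
        if list(series.index) != list(first.index):
            series = series.reindex(first.index, fill_value=0)
        data[sid] = series.astype(int)
    counts = pd.DataFrame(data, index=first.index)
    samples = sample_sheet[["sample_id", "condition", "replicate"]].copy()
    return CountMatrix(counts, samples)


def quantify(
    sample_sheet: pd.DataFrame,
    barcode_table: pd.DataFrame,
    tag_len: int = DEFAULT_TAG_LEN,
    max_mismatch: int = 0,
    per_seq: int = 5,
) -> Tuple[CountMatrix, pd.DataFrame]:
    """Full per-sample pipeline from FASTQ paths to a CountMatrix + QC table.

    ``sample_sheet`` needs columns sample_id / condition / replicate /
    fastq.  A missing FASTQ file raises an error naming the path.
    """
    import os

    per_sample: Dict[str, pd.Series] = {}
    qc_rows = []
    for row in sample_sheet.itertuples(index=False):
        if not os.path.exists(row.fastq):
            raise FileNotFoundError(
                f"sample {row.sample_id}: FASTQ file not found: {row.fastq}"
            )
        tags, stats = parse_tags(row.fastq, tag_len=tag_len)
        bc_counts, stats = match_barcodes(
            tags, barcode_table, max_mismatch=max_mismatch, stats=stats
        )
        stats.check_conservation()
        per_sample[row.sample_id] = collapse_elements(
            bc_counts, barcode_table, per_seq=per_seq
        )
        qc_rows.append(
            (row.sample_id, stats.total, stats.matched, stats.ambiguous,
             stats.unmatched, stats.dropped, round(stats.match_rate, 6))
        )
    matrix = assemble_matrix(per_sample, sample_sheet)
    qc = pd.DataFrame(
        qc_rows,
        columns=["sample_id", "total_reads", "matched", "ambiguous",
                 "unmatched", "dropped", "match_rate"],
    )
    return matrix, qc
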