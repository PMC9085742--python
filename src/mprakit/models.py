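"""Core record types shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Set, Tuple

import numpy as np
import pandas as pd

NUCLEOTIDES = ("A", "C", "G", "T")

PDNA = "pDNA"
CDNA = "cDNA"


def element_id(variant_id: str, allele: str) -> str:
    """Stable id of one library element (variant x allele)."""
    return f"{variant_id}|{allele}"


def split_element_id(eid: str) -> Tuple[str, str]:
    variant_id, allele = eid.rsplit("|", 1)
    return variant_id, allele


@dataclass
class Variant:
    """One candidate rare single-nucleotide variant with cohort metadata."""

    variant_id: str
    contig: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    proband_id: str
    inheritance: str  # "de_novo" | "inherited"
    maf: float
    n_technologies: int
    seen_in_multiple_probands: bool = False
    known_causative: bool = False
    coding_impact: bool = False
    dist_to_tss: Optional[int] = None  # signed, pos - nearest TSS pos

    def validate(self) -> None:
        if self.ref_allele not in NUCLEOTIDES:
            raise ValueError(f"{self.variant_id}: bad ref allele {self.ref_allele!r}")
        if self.alt_allele not in NUCLEOTIDES:
            raise ValueError(f"{self.variant_id}: bad alt allele {self.alt_allele!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.variant_id}: ref == alt ({self.ref_allele})")
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1")
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"{self.variant_id}: MAF outside [0, 1]")
        if self.inheritance not in ("de_novo", "inherited"):
            raise ValueError(f"{self.variant_id}: bad inheritance {self.inheritance!r}")


@dataclass
class OligoRecord:
    """One designed library member: insert + allele + barcode + adapters."""

    oligo_id: str
    variant_id: str
    allele: str
    barcode: str
    insert: str
    full_oligo: str

    @property
    def element_id(self) -> str:
        return element_id(self.variant_id, self.allele)


@dataclass
class TFBindingSite:
    """One ChIP cluster interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    tf_name: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.tf_name} {self.contig}:{self.start}-{self.end}: start >= end"
            )


@dataclass
class GroundTruth:
    """Planted simulation truth used to score recovery downstream."""

    #: reference element id -> +1 (activator) / -1 (repressor)
    active_elements: Dict[str, int] = field(default_factory=dict)
    #: variant id -> +1 (increased) / -1 (decreased) allelic effect
    effect_variants: Dict[str, int] = field(default_factory=dict)
    #: forced phenotype-term overlaps
    planted_overlap_pairs: Set[Tuple[str, str]] = field(default_factory=set)
    #: (proband, tf) -> variant carrying the planted overlap
    overlap_variants: Dict[Tuple[str, str], str] = field(default_factory=dict)

    def active_variant_sign(self, variant_id: str) -> int:
        """Planted base-activity sign of a variant's locus (0 if inactive)."""
        for eid, sign in self.active_elements.items():
            if split_element_id(eid)[0] == variant_id:
                return sign
        return 0

    @property
    def doubly_planted_variants(self) -> Set[str]:
        """Variants with both an allelic effect and a planted HPO overlap."""
        return set(self.overlap_variants.values()) & set(self.effect_variants)


class CountMatrix:
    """Element x sample integer count matrix with sample metadata.

    ``counts`` is indexed by element id; ``elements`` maps element ids to
    (variant_id, allele); ``samples`` carries (sample_id, condition,
    replicate) with condition one of ``pDNA``/``cDNA``.
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame):
        if counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        if samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in sample sheet")
        if list(counts.columns) != list(samples["sample_id"]):
            samples = samples.set_index("sample_id").loc[list(counts.columns)]
            samples = samples.reset_index()
        self.counts = counts
        self.samples = samples.reset_index(drop=True)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("counts must be non-negative")
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integral")
        bad = set(self.samples["condition"]) - {PDNA, CDNA}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")

    # ------------------------------------------------------------------
    @property
    def element_ids(self) -> list:
        return list(self.counts.index)

    @property
    def elements(self) -> pd.DataFrame:
        ids = list(self.counts.index)
        pairs = [split_element_id(e) for e in ids]
        return pd.DataFrame(
            {"element_id": ids,
             "variant_id": [p[0] for p in pairs],
             "allele": [p[1] for p in pairs]}
        )

    def condition_columns(self, condition: str) -> list:
        mask = self.samples["condition"] == condition
        return list(self.samples.loc[mask, "sample_id"])

    def require_both_conditions(self) -> None:
        for cond in (PDNA, CDNA):
            if not self.condition_columns(cond):
                raise ValueError(f"no {cond} samples in count matrix")

    # ------------------------------------------------------------------
    def to_tsv(self, counts_path, samples_path) -> None:
        out = self.counts.copy()
        out.insert(0, "element_id", out.index)
        out.to_csv(counts_path, sep="\t", index=False)
        self.samples.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t")
        counts = counts.set_index("element_id")
        counts.index.name = None
        samples = pd.read_csv(samples_path, sep="\t")
        samples["replicate"] = samples["replicate"].astype(int)
        return cls(counts, samples)

    # ------------------------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.counts.shape == other.counts.shape
            and list(self.counts.index) == list(other.counts.index)
            and list(self.counts.columns) == list(other.counts.columns)
            and (self.counts.to_numpy() == other.counts.to_numpy()).all()
        )

    def __repr__(self) -> str:
        n_e, n_s = self.counts.shape
        return f"CountMatrix({n_e} elements x {n_s} samples)"
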