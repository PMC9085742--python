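"""Simulation configuration and deterministic planting arithmetic."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import yaml

#: bases a variant must keep clear of a contig edge so the 100-nt insert
#: window (49 up + variant + 50 down) always fits, with a little slack.
INSERT_MARGIN = 60


def planted_count(n: int, frac: float) -> int:
    """Number of items planted for a fraction ``frac`` of ``n``.

    Deterministic half-up rounding: ``floor(n * frac + 0.5)``.
    """
    return int(math.floor(n * frac + 0.5))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort + assay generator.

    Defaults mirror the cohort and assay scale of the study design this
    pipeline targets (111 probands; 1958 de novo + 1101 inherited rare
    variants within +/-100 kb of a TSS; ~20% active reference elements;
    ~4.5% allelic-effect variants).
    """

    seed: int = 0

    # cohort
    n_probands: int = 111
    n_de_novo: int = 1958
    n_inherited: int = 1101

    # reference genome stand-in
    contig_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 600_000, "chr2": 600_000}
    )
    n_tss: int = 40
    window_bp: int = 100_000
    #: weight of the near-TSS component of the distance mixture
    tss_enrichment: float = 0.3

    # planted truth
    frac_active_ref: float = 0.20
    frac_effect_variants: float = 0.045
    #: fraction of effect variants planted with decreased activity (51:40)
    frac_decrease: float = 51.0 / 91.0
    activity_log2fc: float = 1.0
    allelic_log2fc: float = 1.0

    # sequencing depth / noise
    mean_depth_per_oligo: float = 500.0
    abundance_sigma: float = 0.5
    nb_dispersion: float = 0.05
    n_cdna_reps: int = 3
    n_pdna_reps: int = 2

    # TF binding + phenotype terms
    n_tfs: int = 25
    frac_bound: float = 0.5
    hpo_universe: int = 5000
    terms_per_entity: int = 20
    n_planted_overlaps: int = 8
    planted_overlap_terms: Optional[int] = None

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        counts = {
            "n_probands": self.n_probands,
            "n_tss": self.n_tss,
            "window_bp": self.window_bp,
            "n_cdna_reps": self.n_cdna_reps,
            "n_pdna_reps": self.n_pdna_reps,
            "n_tfs": self.n_tfs,
            "hpo_universe": self.hpo_universe,
            "terms_per_entity": self.terms_per_entity,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name in ("n_de_novo", "n_inherited", "n_planted_overlaps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_active_ref", "frac_effect_variants",
                     "frac_decrease", "frac_bound", "tss_enrichment"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.mean_depth_per_oligo <= 0:
            raise ValueError("mean_depth_per_oligo must be positive")
        if self.n_cdna_reps < 2 or self.n_pdna_reps < 2:
            raise ValueError("need >= 2 replicates per condition")
        if self.terms_per_entity > self.hpo_universe:
            raise ValueError(
                "terms_per_entity exceeds the HPO term universe "
                f"({self.terms_per_entity} > {self.hpo_universe})"
            )
        min_len = 2 * (self.window_bp + INSERT_MARGIN) + 1
        for contig, length in self.contig_lengths.items():
            if length < min_len:
                raise ValueError(
                    f"contig {contig} ({length} bp) too short for TSS "
                    f"placement with window {self.window_bp} bp "
                    f"(need >= {min_len})"
                )

    # ------------------------------------------------------------------
    @property
    def n_variants(self) -> int:
        return self.n_de_novo + self.n_inherited

    @property
    def shared_terms_per_pair(self) -> int:
        """Forced term overlap for planted (proband, TF) pairs."""
        if self.planted_overlap_terms is not None:
            return self.planted_overlap_terms
        return max(2, self.terms_per_entity // 2)

    # ------------------------------------------------------------------
    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["contig_lengths"] = dict(self.contig_lengths)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
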