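"""Synthetic cohort, reference, counts, TF binding and phenotype terms.

Every generator is deterministic under ``SimulationConfig.seed``: each stage
derives its own :class:`numpy.random.Generator` from ``(seed, stage_tag)``
so stages can be re-run independently without perturbing one another.

Noise model: per-barcode plasmid abundance is lognormal around the mean
depth (uneven synthesis/cloning); observed counts are negative-binomial with
a single shared dispersion; planted regulatory effects act multiplicatively
(log2) on cDNA means at the element level, i.e. equally on all 5 barcodes of
an element.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from mprakit import io as mio
from mprakit.config import INSERT_MARGIN, SimulationConfig, planted_count
from mprakit.models import (
    CDNA,
    NUCLEOTIDES,
    PDNA,
    CountMatrix,
    GroundTruth,
    TFBindingSite,
    Variant,
    element_id,
)

logger = logging.getLogger(__name__)

_STAGE = {"reference": 11, "variants": 13, "truth": 17, "counts": 19, "tfhpo": 23}


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STAGE[stage]])


# ---------------------------------------------------------------------------
# Reference + TSS
# ---------------------------------------------------------------------------
def generate_reference(
    config: SimulationConfig,
) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Uniform-random reference sequences plus a TSS annotation table.

    Returns ``(sequences, tss)`` where ``tss`` has columns contig, pos
    (1-based), gene_id, strand.  TSSs sit at least ``window_bp`` (plus the
    insert margin) from contig ends so every in-window variant supports a
    full insert.
    """
    rng = _rng(config, "reference")
    bases = np.array(list(NUCLEOTIDES))
    sequences = {
        contig: "".join(bases[rng.integers(0, 4, size=length)])
        for contig, length in config.contig_lengths.items()
    }
    contigs = list(config.contig_lengths)
    rows = []
    margin = config.window_bp + INSERT_MARGIN
    for i in range(config.n_tss):
        contig = contigs[i % len(contigs)]
        length = config.contig_lengths[contig]
        if length < 2 * margin + 1:
            raise ValueError(
                f"contig {contig} too short ({length}) for TSS placement"
            )
        pos = int(rng.integers(margin + 1, length - margin + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((contig, pos, f"GENE{i:04d}", strand))
    tss = pd.DataFrame(rows, columns=["contig", "pos", "gene_id", "strand"])
    return sequences, tss


# ---------------------------------------------------------------------------
# Cohort variants
# ---------------------------------------------------------------------------
def generate_cohort_variants(
    config: SimulationConfig,
    reference: Mapping[str, str],
    tss: pd.DataFrame,
) -> List[Variant]:
    """Rare SNVs within ``window_bp`` of a TSS, mildly enriched near 0.

    All emitted variants satisfy the downstream selection criteria: ref
    allele matches the reference sequence, alt != ref, MAF < 0.001,
    detected by >= 2 technologies.  ``dist_to_tss`` is annotated (signed,
    relative to the nearest TSS).
    """
    from mprakit.design import nearest_tss_distance

    rng = _rng(config, "variants")
    n_total = config.n_variants
    tss_rows = list(tss.itertuples(index=False))
    if not tss_rows:
        raise ValueError("TSS table is empty")
    used_positions: Set[Tuple[str, int]] = set()
    variants: List[Variant] = []
    probands = [f"P{i:03d}" for i in range(config.n_probands)]
    for i in range(n_total):
        for _attempt in range(200):
            t = tss_rows[rng.integers(0, len(tss_rows))]
            # distance mixture: near-TSS component (Beta(1,3)) + uniform tail
            if rng.random() < config.tss_enrichment:
                magnitude = int(rng.beta(1.0, 3.0) * config.window_bp)
            else:
                magnitude = int(rng.integers(0, config.window_bp + 1))
            sign = 1 if rng.random() < 0.5 else -1
            pos = t.pos + sign * magnitude
            length = len(reference[t.contig])
            if not (INSERT_MARGIN < pos <= length - INSERT_MARGIN):
                continue
            if (t.contig, pos) in used_positions:
                continue
            used_positions.add((t.contig, pos))
            break
        else:
            raise RuntimeError(
                f"could not place variant {i} within the TSS window"
            )
        ref = reference[t.contig][pos - 1]
        alt = str(rng.choice([b for b in NUCLEOTIDES if b != ref]))
        inheritance = "de_novo" if i < config.n_de_novo else "inherited"
        variants.append(
            Variant(
                variant_id=f"var{i:05d}",
                contig=t.contig,
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                proband_id=probands[int(rng.integers(0, len(probands)))],
                inheritance=inheritance,
                maf=float(rng.uniform(0.0, 0.001) * 0.999),
                n_technologies=int(2 + (rng.random() < 0.5)),
            )
        )
    for v, dist in zip(variants, nearest_tss_distance(variants, tss)):
        v.dist_to_tss = int(dist)
    return variants


# ---------------------------------------------------------------------------
# Planted truth
# ---------------------------------------------------------------------------
def plant_truth(config: SimulationConfig, variants: Sequence[Variant]) -> GroundTruth:
    """Tag reference elements active and variants with allelic effects.

    Counts use deterministic half-up rounding; activators/repressors split
    ~50/50 and effect directions ~51:40 decrease:increase.
    """
    rng = _rng(config, "truth")
    n = len(variants)
    truth = GroundTruth()

    n_active = planted_count(n, config.frac_active_ref)
    active_idx = rng.choice(n, size=n_active, replace=False)
    n_activators = planted_count(n_active, 0.5)
    for rank, idx in enumerate(active_idx):
        v = variants[int(idx)]
        sign = 1 if rank < n_activators else -1
        truth.active_elements[element_id(v.variant_id, v.ref_allele)] = sign

    n_effect = planted_count(n, config.frac_effect_variants)
    effect_idx = rng.choice(n, size=n_effect, replace=False)
    n_decrease = planted_count(n_effect, config.frac_decrease)
    for rank, idx in enumerate(effect_idx):
        v = variants[int(idx)]
        truth.effect_variants[v.variant_id] = -1 if rank < n_decrease else 1
    return truth


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------
def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean, dispersion) with Var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _element_log2_effects(
    barcodes: pd.DataFrame,
    variants: Sequence[Variant],
    truth: GroundTruth,
    config: SimulationConfig,
) -> np.ndarray:
    """Planted cDNA log2 effect per barcode row of ``barcodes``."""
    by_id = {v.variant_id: v for v in variants}
    base_sign = {  # variant -> base activity sign of its locus
        vid: 0 for vid in by_id
    }
    for eid, sign in truth.active_elements.items():
        vid = eid.rsplit("|", 1)[0]
        base_sign[vid] = sign
    effects = np.zeros(len(barcodes))
    for i, row in enumerate(barcodes.itertuples(index=False)):
        v = by_id[row.variant_id]
        e = base_sign.get(v.variant_id, 0) * config.activity_log2fc
        if row.allele == v.alt_allele and v.variant_id in truth.effect_variants:
            e += truth.effect_variants[v.variant_id] * config.allelic_log2fc
        effects[i] = e
    return effects


def simulate_counts(
    config: SimulationConfig,
    barcodes: pd.DataFrame,
    variants: Sequence[Variant],
    truth: GroundTruth,
    fastq_dir=None,
    filler: str = "GATCTTAGCCAGTACGTCAT",
) -> Tuple[CountMatrix, pd.DataFrame]:
    """Simulate pDNA/cDNA counts for a designed barcode table.

    ``barcodes`` must carry columns barcode / variant_id / allele /
    element_id (see :func:`mprakit.design.barcode_frame`).  Returns the
    element-level :class:`CountMatrix` (5-barcode sums) and the barcode-level
    count table.  When ``fastq_dir`` is given, one plain FASTQ per sample is
    written at exact multiplicity (first 12 bases = barcode) along with a
    sample sheet.
    """
    required = {"barcode", "variant_id", "allele", "element_id"}
    if barcodes is None or not required.issubset(barcodes.columns):
        raise ValueError(f"barcode table must have columns {sorted(required)}")
    rng = _rng(config, "counts")
    n_bc = len(barcodes)

    mu = np.log(config.mean_depth_per_oligo) - config.abundance_sigma**2 / 2
    lam = rng.lognormal(mean=mu, sigma=config.abundance_sigma, size=n_bc)
    log2_effect = _element_log2_effects(barcodes, variants, truth, config)

    samples = []
    columns = {}
    for r in range(1, config.n_pdna_reps + 1):
        sid = f"{PDNA}_{r}"
        samples.append((sid, PDNA, r))
        columns[sid] = _nb_draw(rng, lam, config.nb_dispersion)
    for r in range(1, config.n_cdna_reps + 1):
        sid = f"{CDNA}_{r}"
        samples.append((sid, CDNA, r))
        columns[sid] = _nb_draw(rng, lam * 2.0**log2_effect, config.nb_dispersion)

    bc_counts = pd.DataFrame(columns, index=barcodes["barcode"].to_numpy())
    bc_counts.insert(0, "element_id", barcodes["element_id"].to_numpy())

    grouped = bc_counts.groupby("element_id", sort=False).sum()
    # keep design order of elements
    order = barcodes["element_id"].drop_duplicates().to_numpy()
    grouped = grouped.loc[order]
    sample_df = pd.DataFrame(samples, columns=["sample_id", "condition", "replicate"])
    matrix = CountMatrix(grouped, sample_df)

    if fastq_dir is not None:
        out = mio.ensure_dir(fastq_dir)
        bc_array = barcodes["barcode"].to_numpy()
        sheet_rows = []
        for sid, cond, rep in samples:
            path = out / f"{sid}.fastq"
            counts = np.asarray(columns[sid])
            reads = np.repeat(bc_array, counts)
            rng.shuffle(reads)
            mio.write_fastq((bc + filler for bc in reads), path)
            sheet_rows.append((sid, cond, rep, str(path)))
        pd.DataFrame(
            sheet_rows, columns=["sample_id", "condition", "replicate", "fastq"]
        ).to_csv(out / "samples.tsv", sep="\t", index=False)
    return matrix, bc_counts


# ---------------------------------------------------------------------------
# TF binding + HPO terms
# ---------------------------------------------------------------------------
def _term(i: int) -> str:
    return f"HP:{i:07d}"


def generate_tf_and_hpo(
    config: SimulationConfig,
    variants: Sequence[Variant],
    truth: GroundTruth,
) -> Tuple[List[TFBindingSite], Dict[str, Set[str]], GroundTruth]:
    """TF ChIP-like intervals plus proband/TF phenotype-term annotations.

    A ``frac_bound`` fraction of variants is covered by >= 1 TF interval.
    Planted (proband, TF) pairs sit on planted effect variants: the TF is
    forced to bind the variant site and the proband/TF term sets share
    ``config.shared_terms_per_pair`` accessions.  Updates and returns
    ``truth`` with the planted pairs recorded.
    """
    if config.terms_per_entity > config.hpo_universe:
        raise ValueError("terms_per_entity exceeds hpo_universe")
    rng = _rng(config, "tfhpo")
    tf_names = [f"TF{i:03d}" for i in range(config.n_tfs)]

    sites: List[TFBindingSite] = []

    def add_site(v: Variant, tf: str) -> None:
        pos0 = v.pos - 1
        start = max(0, pos0 - int(rng.integers(10, 200)))
        end = pos0 + int(rng.integers(10, 200))
        sites.append(TFBindingSite(v.contig, start, end, tf))

    n_bound = planted_count(len(variants), config.frac_bound)
    bound_idx = rng.choice(len(variants), size=n_bound, replace=False)
    bound_tfs: Dict[str, Set[str]] = {}
    for idx in bound_idx:
        v = variants[int(idx)]
        tfs = rng.choice(config.n_tfs, size=int(rng.integers(1, 3)), replace=False)
        bound_tfs[v.variant_id] = {tf_names[int(t)] for t in tfs}
        for t in bound_tfs[v.variant_id]:
            add_site(v, t)

    # planted overlaps ride on effect variants so the end-to-end tiering
    # has doubly-planted positives to recover
    effect_ids = sorted(truth.effect_variants)
    if config.n_planted_overlaps > len(effect_ids):
        raise ValueError(
            f"n_planted_overlaps={config.n_planted_overlaps} exceeds the "
            f"{len(effect_ids)} planted effect variants"
        )
    by_id = {v.variant_id: v for v in variants}
    chosen = rng.choice(len(effect_ids), size=config.n_planted_overlaps, replace=False)
    shared_sets: Dict[Tuple[str, str], Set[str]] = {}
    for idx in chosen:
        v = by_id[effect_ids[int(idx)]]
        tf = tf_names[int(rng.integers(0, config.n_tfs))]
        if tf not in bound_tfs.get(v.variant_id, set()):
            bound_tfs.setdefault(v.variant_id, set()).add(tf)
            add_site(v, tf)
        pair = (v.proband_id, tf)
        truth.planted_overlap_pairs.add(pair)
        truth.overlap_variants[pair] = v.variant_id
        shared = rng.choice(
            config.hpo_universe, size=config.shared_terms_per_pair, replace=False
        )
        shared_sets[pair] = {_term(int(t)) for t in shared}

    # decoy intervals away from any variant
    for _ in range(config.n_tfs * 2):
        contig = str(rng.choice(list(config.contig_lengths)))
        start = int(rng.integers(0, config.contig_lengths[contig] - 400))
        sites.append(
            TFBindingSite(
                contig, start, start + int(rng.integers(50, 400)),
                tf_names[int(rng.integers(0, config.n_tfs))],
            )
        )

    # term assignment: planted shared terms first, random fill to size
    entities = tf_names + sorted({v.proband_id for v in variants})
    forced: Dict[str, Set[str]] = {e: set() for e in entities}
    for (proband, tf), shared in shared_sets.items():
        forced[proband] |= shared
        forced[tf] |= shared
    terms: Dict[str, Set[str]] = {}
    for entity in entities:
        base = set(forced[entity])
        if len(base) > config.terms_per_entity:
            raise ValueError(
                f"{entity}: planted overlaps require {len(base)} terms "
                f"> terms_per_entity={config.terms_per_entity}"
            )
        while len(base) < config.terms_per_entity:
            need = config.terms_per_entity - len(base)
            draw = rng.choice(config.hpo_universe, size=need, replace=False)
            base |= {_term(int(t)) for t in draw}
        terms[entity] = base

    logger.info(
        "generated %d TF sites, %d entities, %d planted overlap pairs",
        len(sites), len(terms), len(shared_sets),
    )
    return sites, terms, truth


# ---------------------------------------------------------------------------
# One-call scenario
# ---------------------------------------------------------------------------
def simulate_scenario(
    config: SimulationConfig,
    fastq_dir=None,
    design_seed: Optional[int] = None,
):
    """Run every generator and the library design; return a dict of pieces."""
    from mprakit import design as mdesign

    reference, tss = generate_reference(config)
    variants = generate_cohort_variants(config, reference, tss)
    truth = plant_truth(config, variants)
    oligos, rejected = mdesign.build_library(
        variants, reference,
        seed=config.seed if design_seed is None else design_seed,
    )
    if rejected:  # generator guarantees in-bounds placement
        raise RuntimeError(f"library design rejected {len(rejected)} variants")
    barcodes = mdesign.barcode_frame(oligos)
    matrix, bc_counts = simulate_counts(
        config, barcodes, variants, truth, fastq_dir=fastq_dir
    )
    sites, terms, truth = generate_tf_and_hpo(config, variants, truth)
    return {
        "reference": reference,
        "tss": tss,
        "variants": variants,
        "truth": truth,
        "oligos": oligos,
        "barcodes": barcodes,
        "matrix": matrix,
        "barcode_counts": bc_counts,
        "sites": sites,
        "hpo_terms": terms,
    }
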