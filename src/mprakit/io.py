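"""Readers/writers for the plain-text formats the pipeline exchanges.

Coordinate conventions: variants are 1-based (VCF-like TSV); all interval
files (TSS, TF clusters) are 0-based half-open BED.
"""

from __future__ import annotations

import gzip
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Set

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mprakit.models import OligoRecord, TFBindingSite, Variant

VARIANT_COLUMNS = [
    "variant_id", "contig", "pos", "ref_allele", "alt_allele", "proband_id",
    "inheritance", "maf", "n_technologies", "seen_in_multiple_probands",
    "known_causative", "coding_impact", "dist_to_tss",
]


def open_maybe_gzip(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ----------------------------------------------------------------- FASTA
def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_oligo_fasta(oligos: Iterable[OligoRecord], path) -> None:
    records = [
        SeqRecord(Seq(o.full_oligo), id=o.oligo_id, description="")
        for o in oligos
    ]
    SeqIO.write(records, str(path), "fasta")


# ------------------------------------------------------------------- BED
def write_tss_bed(tss: pd.DataFrame, path) -> None:
    """TSS table (1-based ``pos``) -> 6-column BED."""
    out = pd.DataFrame(
        {
            "contig": tss["contig"],
            "start": tss["pos"] - 1,
            "end": tss["pos"],
            "name": tss["gene_id"],
            "score": 0,
            "strand": tss["strand"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_tss_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["contig", "start", "end", "name", "score", "strand"],
    )
    return pd.DataFrame(
        {
            "contig": bed["contig"],
            "pos": bed["start"] + 1,
            "gene_id": bed["name"],
            "strand": bed["strand"],
        }
    )


def write_sites_bed(sites: Iterable[TFBindingSite], path) -> None:
    rows = [(s.contig, s.start, s.end, s.tf_name) for s in sites]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_sites_bed(path) -> List[TFBindingSite]:
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["contig", "start", "end", "tf_name"]
    )
    return [
        TFBindingSite(r.contig, int(r.start), int(r.end), r.tf_name)
        for r in bed.itertuples()
    ]


# ---------------------------------------------------------------- variants
def variants_to_frame(variants: Iterable[Variant]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(v) for v in variants], columns=VARIANT_COLUMNS)
    return df


def write_variants(variants: Iterable[Variant], path) -> None:
    # %.17g keeps MAF round-trip exact
    variants_to_frame(variants).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_variants(path) -> List[Variant]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        dist = d.get("dist_to_tss")
        d["dist_to_tss"] = None if pd.isna(dist) else int(dist)
        d["pos"] = int(d["pos"])
        d["n_technologies"] = int(d["n_technologies"])
        for flag in ("seen_in_multiple_probands", "known_causative", "coding_impact"):
            d[flag] = bool(d[flag])
        out.append(Variant(**d))
    return out


# -------------------------------------------------------------------- HPO
def write_hpo_annotations(terms: Mapping[str, Set[str]], universe: int, path) -> None:
    """entity_id -> comma-joined accessions; universe in a header line."""
    with open(path, "w") as fh:
        fh.write(f"# universe={universe}\n")
        fh.write("entity_id\tterm_accessions\n")
        for entity in sorted(terms):
            fh.write(f"{entity}\t{','.join(sorted(terms[entity]))}\n")


def read_hpo_annotations(path):
    universe = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# universe="):
            universe = int(first.strip().split("=", 1)[1])
            df = pd.read_csv(fh, sep="\t")
        else:
            raise ValueError(f"{path}: missing '# universe=' header")
    terms = {
        row.entity_id: set(str(row.term_accessions).split(","))
        for row in df.itertuples()
        if isinstance(row.term_accessions, str) and row.term_accessions
    }
    return terms, universe


# ---------------------------------------------------------------- barcodes
def write_barcode_table(oligos: Iterable[OligoRecord], path) -> None:
    rows = [
        (o.barcode, o.variant_id, o.allele, o.oligo_id) for o in oligos
    ]
    pd.DataFrame(
        rows, columns=["barcode", "variant_id", "allele", "oligo_id"]
    ).to_csv(path, sep="\t", index=False)


def read_barcode_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


# ------------------------------------------------------------------- FASTQ
def write_fastq(read_seqs: Iterable[str], path) -> None:
    """Write reads with constant quality; plain text or gzip by suffix."""
    with open_maybe_gzip(path, "wt") as fh:
        for i, seq in enumerate(read_seqs):
            fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")


# ------------------------------------------------------------- ground truth
def write_ground_truth(truth, path) -> None:
    rows = []
    for eid, sign in sorted(truth.active_elements.items()):
        rows.append(("active_element", eid, sign, ""))
    for vid, sign in sorted(truth.effect_variants.items()):
        rows.append(("effect_variant", vid, sign, ""))
    for (proband, tf) in sorted(truth.planted_overlap_pairs):
        variant = truth.overlap_variants.get((proband, tf), "")
        rows.append(("planted_overlap", f"{proband}:{tf}", 0, variant))
    pd.DataFrame(
        rows, columns=["kind", "key", "sign", "extra"]
    ).to_csv(path, sep="\t", index=False)


def read_ground_truth(path):
    from mprakit.models import GroundTruth

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    truth = GroundTruth()
    for row in df.itertuples():
        if row.kind == "active_element":
            truth.active_elements[row.key] = int(row.sign)
        elif row.kind == "effect_variant":
            truth.effect_variants[row.key] = int(row.sign)
        elif row.kind == "planted_overlap":
            proband, tf = row.key.split(":", 1)
            truth.planted_overlap_pairs.add((proband, tf))
            if row.extra:
                truth.overlap_variants[(proband, tf)] = row.extra
    return truth


def ensure_dir(path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    return path
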