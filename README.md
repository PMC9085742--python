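# mprakit

Functional profiling and prioritization of rare noncoding variants with a
barcode-based massively parallel reporter assay (MPRA), end to end:

1. **simulate** (`mprakit.simulate`) — synthetic cohort of rare SNVs within
   ±100 kb of transcription start sites, a random reference genome, per-oligo
   plasmid abundances, replicate pDNA/cDNA counts under a negative-binomial
   noise model with planted regulatory and allelic effects, TF binding
   intervals and proband/TF phenotype-term (HPO) annotations with planted
   overlaps. Everything is deterministic under a single seed, so the whole
   pipeline is testable offline against known ground truth.
2. **design** (`mprakit.design`) — candidate selection (MAF < 0.001, ≥ 2
   detection technologies, ≤ 100 kb from a TSS, recurrence/causative/coding
   exclusions) and oligo library design: 100-nt inserts centered on the
   variant, all 4 single-position allele analogs, 5 unique 12-nt barcodes per
   analog. Barcodes avoid BsaI/Esp3I golden-gate sites on either strand,
   homopolymers ≥ 5 and extreme GC, and carry a mod-4 checksum guaranteeing
   pairwise Hamming distance ≥ 2.
3. **count** (`mprakit.quant`) — the first 12 bases of each read are the
   barcode tag; element counts are the sum over the 5 tags of an element;
   exact matching by default, optional unambiguous 1-mismatch rescue.
4. **activity** (`mprakit.activity`) — median-of-ratios size factors,
   method-of-moments dispersion shrunk toward a parametric trend, and a
   per-element negative-binomial Wald test of cDNA vs plasmid abundance with
   Benjamini–Hochberg correction (activator / repressor / inactive calls).
5. **effects** (`mprakit.effects`) — allelic effect per variant as the
   alt − ref log2 activity difference, standardized to z-scores over the
   pooled distribution; |z| > 2 calls with loss-of-function /
   loss-of-repression mechanism labels; 4-allele analog profiles.
6. **prioritize** (`mprakit.prioritize`) — TF binding at the variant site
   (BED interval intersection), hypergeometric overlap of proband vs TF HPO
   accessions against the annotated-term universe, one pooled BH family, and
   tiered ranking (tier 1: HPO-significant **and** |z| > 2).

## CLI

Every stage is a subcommand of `mprakit`; `run-all` chains them:

```bash
# generate all inputs (with FASTQ reads) and run the whole pipeline
mprakit run-all --seed 1 --out-dir out/ --fastq

# or stage by stage
mprakit simulate --seed 1 --out-dir sim/ --fastq
mprakit design --variants sim/variants.tsv --reference sim/reference.fasta \
    --tss sim/tss.bed --out-dir design/ --seed 1
mprakit count --sample-sheet sim/fastq/samples.tsv \
    --barcodes design/barcodes.tsv --out-dir counts/
mprakit activity --counts counts/counts.tsv --samples counts/samples.tsv \
    --out activity.tsv
mprakit effects --activity activity.tsv --variants sim/variants.tsv \
    --out-dir effects/ --z-threshold 2
mprakit prioritize --effects effects/variant_effects.tsv \
    --variants sim/variants.tsv --tf-sites sim/tf_sites.bed \
    --hpo sim/hpo_annotations.tsv --out-dir ranked/
```

Simulation parameters live in a YAML config (`mprakit simulate --config
cfg.yaml`); see `mprakit.config.SimulationConfig` for every knob and its
default.

All files are plain text: FASTA (reference, oligo library), BED (TSS and TF
clusters, 0-based half-open), TSV (variants with 1-based positions, barcode
table, count matrix, results), FASTQ (optionally gzipped on input).

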