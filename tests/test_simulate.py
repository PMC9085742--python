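import numpy as np
import pandas as pd
import pytest

from mprakit import io as mio
from mprakit import quant as mquant
from mprakit import simulate as msim
from mprakit.config import SimulationConfig, planted_count
from mprakit.design import barcode_frame, build_library
from mprakit.models import element_id


class TestGenerateReference:
    def test_sequence_length_and_alphabet(self):
        cfg = SimulationConfig(seed=1, contig_lengths={"chr1": 250_000})
        seqs, _ = msim.generate_reference(cfg)
        assert len(seqs["chr1"]) == 250_000
        assert set(seqs["chr1"]) <= set("ACGT")

    def test_deterministic_under_seed(self, small_config):
        a = msim.generate_reference(small_config)
        b = msim.generate_reference(small_config)
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_tss_count(self):
        cfg = SimulationConfig(seed=3, n_tss=5)
        _, tss = msim.generate_reference(cfg)
        assert len(tss) == 5
        assert set(tss["strand"]) <= {"+", "-"}

    def test_tss_placement_away_from_ends(self, small_config):
        _, tss = msim.generate_reference(small_config)
        for row in tss.itertuples():
            length = small_config.contig_lengths[row.contig]
            assert small_config.window_bp < row.pos <= length - small_config.window_bp

    def test_contig_too_short_is_config_error(self):
        with pytest.raises(ValueError, match="too short"):
            SimulationConfig(seed=1, contig_lengths={"chr1": 10})


class TestGenerateCohortVariants:
    def test_total_counts_match_cohort(self):
        # full-scale cohort: 1958 de novo + 1101 inherited
        cfg = SimulationConfig(seed=2)
        ref, tss = msim.generate_reference(cfg)
        variants = msim.generate_cohort_variants(cfg, ref, tss)
        assert len(variants) == 3059
        assert sum(v.inheritance == "de_novo" for v in variants) == 1958
        assert sum(v.inheritance == "inherited" for v in variants) == 1101

    def test_every_variant_satisfies_selection_criteria(self, small_scenario):
        ref = small_scenario["reference"]
        for v in small_scenario["variants"]:
            assert abs(v.dist_to_tss) <= 100_000
            assert v.ref_allele != v.alt_allele
            assert ref[v.contig][v.pos - 1] == v.ref_allele
            assert v.maf < 0.001
            assert v.n_technologies >= 2

    def test_distance_distribution_enriched_near_tss(self, null_scenario):
        _, scenario = null_scenario
        dist = np.abs([v.dist_to_tss for v in scenario["variants"]])
        near = (dist < 25_000).mean()
        # uniform placement would give ~0.25; the mixture should exceed it
        assert near > 0.30

    def test_deterministic(self, small_config):
        ref, tss = msim.generate_reference(small_config)
        a = msim.generate_cohort_variants(small_config, ref, tss)
        b = msim.generate_cohort_variants(small_config, ref, tss)
        assert a == b


class TestPlantTruth:
    def _variants(self, n, seed=4):
        cfg = SimulationConfig(seed=seed, n_de_novo=n, n_inherited=0, n_tss=20)
        ref, tss = msim.generate_reference(cfg)
        return cfg, msim.generate_cohort_variants(cfg, ref, tss)

    def test_planted_counts_deterministic_rounding(self):
        cfg, variants = self._variants(1000)
        truth = msim.plant_truth(cfg, variants)
        assert len(truth.active_elements) == 200  # floor(1000*0.2 + 0.5)
        assert len(truth.effect_variants) == planted_count(1000, 0.045) == 45

    def test_activator_repressor_split(self):
        cfg, variants = self._variants(1000)
        truth = msim.plant_truth(cfg, variants)
        signs = list(truth.active_elements.values())
        assert signs.count(1) == 100 and signs.count(-1) == 100

    def test_decrease_increase_mix(self):
        cfg, variants = self._variants(1000)
        truth = msim.plant_truth(cfg, variants)
        signs = list(truth.effect_variants.values())
        assert signs.count(-1) == planted_count(45, 51.0 / 91.0)

    def test_zero_fraction_gives_empty_set(self):
        cfg, variants = self._variants(200)
        cfg.frac_effect_variants = 0.0
        truth = msim.plant_truth(cfg, variants)
        assert truth.effect_variants == {}

    def test_deterministic(self):
        cfg, variants = self._variants(300)
        a = msim.plant_truth(cfg, variants)
        b = msim.plant_truth(cfg, variants)
        assert a.active_elements == b.active_elements
        assert a.effect_variants == b.effect_variants

    def test_active_reference_elements_exist_in_library(self, small_scenario):
        truth = small_scenario["truth"]
        library_elements = set(small_scenario["barcodes"]["element_id"])
        assert set(truth.active_elements) <= library_elements


class TestSimulateCounts:
    def test_missing_barcode_table_errors(self, small_config, small_scenario):
        with pytest.raises(ValueError, match="barcode table"):
            msim.simulate_counts(
                small_config, None, small_scenario["variants"],
                small_scenario["truth"],
            )

    def test_null_elements_have_unit_ratio(self, null_scenario):
        _, scenario = null_scenario
        matrix = scenario["matrix"]
        p_cols = matrix.condition_columns("pDNA")
        c_cols = matrix.condition_columns("cDNA")
        ratio = (
            matrix.counts[c_cols].mean(axis=1) / matrix.counts[p_cols].mean(axis=1)
        )
        mean_log2 = np.log2(ratio).mean()
        se = np.log2(ratio).std(ddof=1) / np.sqrt(len(ratio))
        assert abs(mean_log2) < 3 * se + 0.01

    def test_planted_effect_recovered_in_marginal_means(self, power_scenario):
        # Monte-Carlo check against the generating model: planted +1 log2
        cfg, scenario = power_scenario
        matrix, truth = scenario["matrix"], scenario["truth"]
        activators = [e for e, s in truth.active_elements.items() if s == 1]
        p_cols = matrix.condition_columns("pDNA")
        c_cols = matrix.condition_columns("cDNA")
        sub = matrix.counts.loc[activators]
        log2fc = np.log2(sub[c_cols].mean(axis=1) / sub[p_cols].mean(axis=1))
        se = log2fc.std(ddof=1) / np.sqrt(len(log2fc))
        assert abs(log2fc.mean() - cfg.activity_log2fc) < 3 * se + 0.02

    def test_fastq_round_trip_exact(self, small_config, tmp_path):
        scenario = msim.simulate_scenario(small_config, fastq_dir=tmp_path / "fq")
        sheet = pd.read_csv(tmp_path / "fq" / "samples.tsv", sep="\t")
        matrix, qc = mquant.quantify(sheet, scenario["barcodes"])
        assert matrix == scenario["matrix"]
        assert (qc["unmatched"] == 0).all()

    def test_deterministic(self, small_config, small_scenario):
        again = msim.simulate_counts(
            small_config, small_scenario["barcodes"],
            small_scenario["variants"], small_scenario["truth"],
        )[0]
        assert again == small_scenario["matrix"]


class TestGenerateTfAndHpo:
    def test_planted_pairs_share_terms_and_bind_variant(self, small_scenario):
        truth = small_scenario["truth"]
        terms = small_scenario["hpo_terms"]
        sites = small_scenario["sites"]
        variants = {v.variant_id: v for v in small_scenario["variants"]}
        assert len(truth.planted_overlap_pairs) == 3
        for (proband, tf) in truth.planted_overlap_pairs:
            shared = terms[proband] & terms[tf]
            assert len(shared) >= 10  # forced overlap, terms_per_entity // 2
            v = variants[truth.overlap_variants[(proband, tf)]]
            covering = [
                s for s in sites
                if s.tf_name == tf and s.contig == v.contig
                and s.start <= v.pos - 1 < s.end
            ]
            assert covering

    def test_term_sets_have_requested_size(self, small_config, small_scenario):
        for entity, terms in small_scenario["hpo_terms"].items():
            assert len(terms) == small_config.terms_per_entity

    def test_forced_full_overlap_reaches_minimum_p(self):
        from mprakit.prioritize import hypergeom_overlap

        cfg = SimulationConfig(
            seed=9, n_de_novo=50, n_inherited=0, n_tss=10,
            n_planted_overlaps=1, planted_overlap_terms=20,
            contig_lengths={"chr1": 300_000},
        )
        scenario = msim.simulate_scenario(cfg)
        truth, terms = scenario["truth"], scenario["hpo_terms"]
        (proband, tf) = next(iter(truth.planted_overlap_pairs))
        k = len(terms[proband] & terms[tf])
        assert k == 20  # complete overlap: minimum achievable p for these sizes
        p_full = hypergeom_overlap(20, 20, 20, cfg.hpo_universe)
        p_less = hypergeom_overlap(19, 20, 20, cfg.hpo_universe)
        assert p_full < p_less

    def test_bound_fraction_configurable(self, small_config, small_scenario):
        from mprakit.prioritize import intersect_tf

        bound = intersect_tf(small_scenario["variants"], small_scenario["sites"])
        frac = np.mean([len(tfs) > 0 for tfs in bound.values()])
        assert frac >= small_config.frac_bound  # planted pairs add a few

    def test_sites_bed_round_trip(self, small_scenario, tmp_path):
        path = tmp_path / "sites.bed"
        mio.write_sites_bed(small_scenario["sites"], path)
        again = mio.read_sites_bed(path)
        assert again == small_scenario["sites"]

    def test_too_many_terms_is_config_error(self):
        with pytest.raises(ValueError, match="terms_per_entity"):
            SimulationConfig(seed=1, hpo_universe=10, terms_per_entity=11)

    def test_planted_overlaps_exceeding_effect_variants_error(self):
        cfg = SimulationConfig(
            seed=5, n_de_novo=40, n_inherited=0, n_tss=5,
            contig_lengths={"chr1": 300_000}, n_planted_overlaps=10,
        )
        ref, tss = msim.generate_reference(cfg)
        variants = msim.generate_cohort_variants(cfg, ref, tss)
        truth = msim.plant_truth(cfg, variants)  # only ~2 effect variants
        with pytest.raises(ValueError, match="n_planted_overlaps"):
            msim.generate_tf_and_hpo(cfg, variants, truth)
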