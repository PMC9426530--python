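"""Size-abundance relations, per-rank enrichment, and the bootstrap
subsampling scheme, including calibration against an exchangeable null."""

from __future__ import annotations

import numpy as np
import pytest

from prophagekit.catalog import filter_predictions
from prophagekit.enrichment import (
    bootstrap_enrichment,
    count_count_correlation,
    rank_enrichment,
    size_abundance,
)
from prophagekit.stats import wilcoxon_greater
from prophagekit.synthetic import SimulationConfig, simulate_catalog

from conftest import make_host, make_record


def build_catalog(counts_by_genome, genus_by_genome, sizes=None):
    hosts = [make_host(g, genus=genus_by_genome[g],
                       size=(sizes or {}).get(g, 2_000_000))
             for g in counts_by_genome]
    records = [make_record(f"{g}_p{i}", g, start=1000 + 40_000 * i)
               for g, c in counts_by_genome.items() for i in range(c)]
    return hosts, records


class TestSizeAbundance:
    @pytest.mark.parametrize("counts,rho", [
        ([1, 2, 3], 1.0),
        ([3, 2, 1], -1.0),
    ])
    def test_perfect_monotone(self, counts, rho):
        genomes = [f"G{i}" for i in range(3)]
        hosts, records = build_catalog(
            dict(zip(genomes, counts)), {g: "GenusA" for g in genomes},
            sizes={g: (i + 1) * 1_000_000 for i, g in enumerate(genomes)})
        out = size_abundance(hosts, records)
        assert out["spearman_rho"] == pytest.approx(rho)

    def test_hand_ranked_rho(self):
        # sizes 1..4 Mb vs counts (2,1,4,3): rank correlation 0.6 by hand
        genomes = [f"G{i}" for i in range(4)]
        hosts, records = build_catalog(
            dict(zip(genomes, [2, 1, 4, 3])), {g: "GenusA" for g in genomes},
            sizes={g: (i + 1) * 1_000_000 for i, g in enumerate(genomes)})
        out = size_abundance(hosts, records)
        assert out["spearman_rho"] == pytest.approx(0.6)

    def test_too_few_genomes_flagged(self):
        hosts, records = build_catalog({"G0": 1}, {"G0": "GenusA"})
        out = size_abundance(hosts, records)
        assert out["correlation_defined"] is False

    def test_long_prophage_series(self):
        hosts = [make_host("G0", size=1_500_000)]
        records = [make_record("P1", "G0", length=10_000),
                   make_record("P2", "G0", length=50_000, start=200_000)]
        out = size_abundance(hosts, records, min_length_bp=30_000)
        bins = out["bins"]
        assert bins["total"].sum() == 2
        assert bins["total_long"].sum() == 1


class TestRankEnrichment:
    def test_exact_p_for_shifted_genus(self):
        hosts, records = build_catalog(
            {"G0": 5, "G1": 6, "G2": 7, "G3": 1, "G4": 2, "G5": 3},
            {"G0": "GenusA", "G1": "GenusA", "G2": "GenusA",
             "G3": "GenusB", "G4": "GenusB", "G5": "GenusB"})
        res = rank_enrichment(hosts, records, rank="genus", min_genomes=3)
        by_taxon = {r.taxon: r for r in res}
        assert by_taxon["GenusA"].p_value == pytest.approx(0.05)
        assert by_taxon["GenusA"].p_adjusted == pytest.approx(0.10)  # m = 2

    def test_identical_background_not_enriched(self):
        hosts, records = build_catalog(
            {"G0": 1, "G1": 2, "G2": 3, "G3": 1, "G4": 2, "G5": 3},
            {"G0": "GenusA", "G1": "GenusA", "G2": "GenusA",
             "G3": "GenusB", "G4": "GenusB", "G5": "GenusB"})
        res = rank_enrichment(hosts, records, rank="genus", min_genomes=3)
        assert all(r.p_value >= 0.5 for r in res)

    def test_planted_genus_recovered(self):
        conf = SimulationConfig(
            seed=13, n_phyla=2, orders_per_phylum=2, families_per_order=5,
            genera_per_family=1, genomes_per_genus=20,
            enriched_genera={7: 4.0}, pathogen_fraction=0.0)
        cat = simulate_catalog(conf)
        filt = filter_predictions(cat.records, cat.hosts)
        res = rank_enrichment(cat.hosts, filt, rank="genus", seed=1)
        planted = next(iter(cat.ground_truth.enriched_genera))
        assert res[0].taxon == planted
        assert res[0].p_adjusted < 0.05
        false_hits = [r for r in res[1:] if r.p_adjusted < 0.05]
        assert len(false_hits) <= 1

    def test_exclude_taxon_removes_clade(self):
        conf = SimulationConfig(seed=13, n_phyla=2, orders_per_phylum=2,
                                families_per_order=5, genera_per_family=1,
                                genomes_per_genus=20, enriched_genera={7: 4.0})
        cat = simulate_catalog(conf)
        planted = next(iter(cat.ground_truth.enriched_genera))
        planted_order = next(h.lineage.order for h in cat.hosts
                             if h.lineage.genus == planted)
        res = rank_enrichment(cat.hosts, cat.records, rank="genus",
                              exclude_taxon=("order", planted_order), seed=1)
        assert planted not in {r.taxon for r in res}

    def test_cap_rule_downsamples(self):
        counts = {f"G{i}": 1 for i in range(80)}
        genus = {f"G{i}": ("GenusBig" if i < 60 else "GenusSmall")
                 for i in range(80)}
        hosts, records = build_catalog(counts, genus)
        res = rank_enrichment(hosts, records, rank="genus",
                              cap_trigger=50, cap_sample=10, seed=0)
        assert {r.taxon: r.n_genomes for r in res}["GenusBig"] == 10

    def test_single_taxon_rank_rejected(self):
        hosts, records = build_catalog({"G0": 1, "G1": 2},
                                       {"G0": "GenusA", "G1": "GenusA"})
        with pytest.raises(ValueError):
            rank_enrichment(hosts, records, rank="genus")


class TestBootstrap:
    @staticmethod
    def null_catalog(seed=17, genomes_per_genus=30):
        conf = SimulationConfig(
            seed=seed, n_phyla=2, orders_per_phylum=2, families_per_order=5,
            genera_per_family=1, genomes_per_genus=genomes_per_genus,
            pathogen_fraction=0.0, category_probs=(1.0, 0.0, 0.0),
            plasmid_flag_prob=0.0, plasmid_replicon_prob=0.0)
        return simulate_catalog(conf)

    def test_type_one_error_calibrated(self):
        cat = self.null_catalog()
        boot, _ = bootstrap_enrichment(cat.hosts, cat.records, n_genomes=10,
                                       n_iter=100, min_genus_genomes=10, seed=3)
        pmat = np.array([b.p_values for b in boot])
        assert pmat.shape == (20, 100)
        rate = (pmat < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_planted_genus_low_median_p(self):
        conf = SimulationConfig(
            seed=19, n_phyla=2, orders_per_phylum=2, families_per_order=5,
            genera_per_family=1, genomes_per_genus=30,
            enriched_genera={4: 4.0}, pathogen_fraction=0.0)
        cat = simulate_catalog(conf)
        boot, _ = bootstrap_enrichment(cat.hosts, cat.records, n_genomes=10,
                                       n_iter=100, min_genus_genomes=10, seed=3)
        planted = next(iter(cat.ground_truth.enriched_genera))
        medians = {b.genus: np.median(b.p_values) for b in boot}
        assert medians[planted] < 0.05

    def test_single_iteration_matches_direct_wilcoxon(self):
        cat = self.null_catalog(seed=23)
        boot, _ = bootstrap_enrichment(cat.hosts, cat.records, n_genomes=10,
                                       n_iter=1, min_genus_genomes=10, seed=5)
        # regenerate the iteration's subsample with the same substream
        from prophagekit.catalog import per_genome_counts
        counts = per_genome_counts(cat.hosts, cat.records)
        genus_of = {h.genome_id: h.lineage.genus for h in cat.hosts}
        by_genus = {}
        for g in counts.index:
            by_genus.setdefault(genus_of[g], []).append(counts[g])
        eligible = sorted(by_genus)
        rng = np.random.default_rng(np.random.SeedSequence([5, 7, 0]))
        samples = {g: rng.choice(np.array(by_genus[g]), size=10, replace=False)
                   for g in eligible}
        for b in boot:
            rest = np.concatenate([samples[g] for g in eligible
                                   if g != b.genus])
            assert b.p_values[0] == pytest.approx(
                wilcoxon_greater(samples[b.genus], rest))

    def test_small_genera_skipped(self):
        cat = self.null_catalog(seed=29, genomes_per_genus=8)
        with pytest.raises(ValueError):
            bootstrap_enrichment(cat.hosts, cat.records, n_genomes=10,
                                 min_genus_genomes=10, seed=1)


class TestCountCorrelation:
    def test_examples(self):
        rho, _ = count_count_correlation([1, 2, 3], [10, 20, 30])
        assert rho == pytest.approx(1.0)
        rho, _ = count_count_correlation([1, 2, 3], [30, 20, 10])
        assert rho == pytest.approx(-1.0)
        rho, _ = count_count_correlation([2, 1, 4, 3], [1, 2, 3, 4])
        assert rho == pytest.approx(0.6)

    def test_errors(self):
        with pytest.raises(ValueError):
            count_count_correlation([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            count_count_correlation([1, 2], [1, 2])
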