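import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from holo import synthetic_data as sd
from holo.asv_processing import group_correlated_asvs
from holo.host_genetics import pairwise_fst


@pytest.fixture(scope="module")
def small_cfg():
    return sd.SimulationConfig(
        n_clusters=3, n_individuals=24, n_snps=100, n_asvs=20,
        library_size_log_mean=7.0, seed=5,
    )


class TestSimulationConfig:
    def test_rejects_bad_fst(self):
        with pytest.raises(ValueError, match="fst_target"):
            sd.SimulationConfig(fst_target=1.0)
        with pytest.raises(ValueError, match="fst_target"):
            sd.SimulationConfig(fst_target=0.0)

    def test_rejects_negative_effect(self):
        with pytest.raises(ValueError):
            sd.SimulationConfig(effect_site=-0.1)

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            sd.SimulationConfig(n_asvs=0)


class TestSimulateGenotypes:
    def test_deterministic(self, small_cfg):
        g1 = sd.simulate_genotypes(small_cfg)
        g2 = sd.simulate_genotypes(small_cfg)
        pd.testing.assert_frame_equal(g1.dosages, g2.dosages)
        pd.testing.assert_series_equal(g1.clusters, g2.clusters)

    def test_near_panmixia_at_tiny_f(self):
        cfg = sd.SimulationConfig(
            n_clusters=2, fst_target=1e-6, n_individuals=60, n_snps=4000, seed=2
        )
        g = sd.simulate_genotypes(cfg)
        assert pairwise_fst(g).values.max() < 0.01

    def test_recovers_target_f(self):
        cfg = sd.SimulationConfig(
            n_clusters=3, fst_target=0.25, n_individuals=100, n_snps=5000, seed=1
        )
        fst = sd_fst_mean(cfg)
        assert fst == pytest.approx(0.25, abs=0.05)

    def test_all_clusters_populated(self, small_cfg):
        g = sd.simulate_genotypes(small_cfg)
        assert g.clusters.nunique() == small_cfg.n_clusters

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_genotypes(sd.SimulationConfig(n_snps=49))


def sd_fst_mean(cfg):
    g = sd.simulate_genotypes(cfg)
    fst = pairwise_fst(g)
    vals = fst.values[np.triu_indices(len(fst.labels), 1)]
    return float(vals.mean())


class TestSimulateMetadata:
    def test_replicate_structure(self, small_cfg):
        g = sd.simulate_genotypes(small_cfg)
        meta = sd.simulate_metadata(small_cfg, g.clusters)
        per_colony = meta.groupby("colony_id").agg(
            n=("sample_id", "size"), size_class=("size_class", "first")
        )
        assert (per_colony.loc[per_colony["size_class"] == "large", "n"] == 3).all()
        assert (per_colony.loc[per_colony["size_class"] == "small", "n"] == 1).all()
        assert per_colony.shape[0] == small_cfg.n_individuals

    def test_all_large_expands_three_per_colony(self):
        cfg = sd.SimulationConfig(
            n_clusters=2, n_individuals=10, n_snps=60, size_classes=("large",), seed=0
        )
        g = sd.simulate_genotypes(cfg)
        meta = sd.simulate_metadata(cfg, g.clusters)
        assert len(meta) == 30
        assert meta["colony_id"].nunique() == 10

    def test_high_concentration_site_independent_of_cluster(self):
        """chi-square independence p should not reject much more than 5%."""
        rejected = 0
        n_seeds = 60
        for seed in range(n_seeds):
            cfg = sd.SimulationConfig(
                n_clusters=2, n_individuals=120, n_snps=60,
                cluster_site_concentration=1e6, seed=seed,
            )
            g = sd.simulate_genotypes(cfg)
            meta = sd.simulate_metadata(cfg, g.clusters).drop_duplicates("colony_id")
            ct = pd.crosstab(meta["cluster"], meta["site"])
            _, p, _, _ = sps.chi2_contingency(ct)
            rejected += p < 0.05
        assert rejected <= int(0.05 * n_seeds + 3 * np.sqrt(0.05 * 0.95 * n_seeds)) + 1

    def test_tiny_concentration_confines_clusters(self):
        cfg = sd.SimulationConfig(
            n_clusters=4, n_individuals=40, n_snps=60,
            cluster_site_concentration=1e-8, seed=3,
        )
        g = sd.simulate_genotypes(cfg)
        meta = sd.simulate_metadata(cfg, g.clusters)
        sites_per_cluster = meta.groupby("cluster")["site"].nunique()
        assert (sites_per_cluster == 1).all()


class TestSimulateCommunity:
    def test_counts_sum_to_library_size(self, small_cfg):
        g = sd.simulate_genotypes(small_cfg)
        meta = sd.simulate_metadata(small_cfg, g.clusters)
        table, truth = sd.simulate_community(meta, small_cfg)
        totals = table.counts.sum(axis=1)
        pd.testing.assert_series_equal(
            totals, truth["library_sizes"], check_names=False
        )

    def test_variant_reads_add_on_top_of_library(self, small_cfg):
        cfg = small_cfg.replace(n_variant_sets=2)
        g = sd.simulate_genotypes(cfg)
        meta = sd.simulate_metadata(cfg, g.clusters)
        table, truth = sd.simulate_community(meta, cfg)
        variant_cols = sum(truth["variant_map"].values(), [])
        base_cols = [c for c in table.counts.columns if c not in variant_cols]
        base_totals = table.counts[base_cols].sum(axis=1)
        pd.testing.assert_series_equal(base_totals, truth["library_sizes"], check_names=False)
        assert (table.counts[variant_cols].to_numpy().sum(axis=1) >= 0).all()

    def test_deterministic(self, small_cfg):
        g = sd.simulate_genotypes(small_cfg)
        meta = sd.simulate_metadata(small_cfg, g.clusters)
        t1, _ = sd.simulate_community(meta, small_cfg)
        t2, _ = sd.simulate_community(meta, small_cfg)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)

    def test_streams_independent(self, small_cfg):
        g = sd.simulate_genotypes(small_cfg)
        meta = sd.simulate_metadata(small_cfg, g.clusters)
        t0, _ = sd.simulate_community(meta, small_cfg, stream=0)
        t1, _ = sd.simulate_community(meta, small_cfg, stream=1)
        assert not t0.counts.equals(t1.counts)

    def test_variant_sets_share_presence_and_merge(self, small_cfg):
        cfg = small_cfg.replace(n_variant_sets=3)
        g = sd.simulate_genotypes(cfg)
        meta = sd.simulate_metadata(cfg, g.clusters)
        table, truth = sd.simulate_community(meta, cfg)
        assert len(truth["variant_map"]) == 3
        for parent, variants in truth["variant_map"].items():
            parent_presence = table.counts[parent] > 0
            for v in variants:
                assert ((table.counts[v] > 0) == parent_presence).all()
        gmap, _ = group_correlated_asvs(table)
        for parent, variants in truth["variant_map"].items():
            groups = {gmap.asv_to_group[v] for v in variants}
            assert groups == {gmap.asv_to_group[parent]}

    def test_null_effects_type_one_error(self):
        """PERMANOVA on effect-free communities rejects near nominal rate."""
        from holo.asv_processing import bray_curtis, hellinger
        from holo.community_stats import permanova_marginal

        rejected = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = sd.SimulationConfig(
                n_clusters=3, n_individuals=18, n_snps=60, n_asvs=15,
                effect_cluster=0.0, effect_site=0.0, effect_size=0.0,
                replicate_noise_sd=0.3, size_classes=("small",),
                library_size_log_mean=6.5, seed=seed,
            )
            g = sd.simulate_genotypes(cfg)
            meta = sd.simulate_metadata(cfg, g.clusters)
            table, _ = sd.simulate_community(meta, cfg)
            d = bray_curtis(hellinger(table.counts))
            res = permanova_marginal(d, meta, "cluster", n_perm=99, seed=seed)
            rejected += res.table.loc["cluster", "p"] <= 0.05
        # 3-sigma binomial envelope around 0.05
        assert rejected <= 0.05 * n_seeds + 3 * np.sqrt(n_seeds * 0.05 * 0.95)


class TestSimulateBlastHits:
    def test_outfmt6_columns(self):
        hits = sd.simulate_blast_hits("C15", 10, seed=0)
        assert list(hits.columns) == sd._BLAST_COLUMNS
        assert (hits["evalue"] < 1e-100).all()
        assert hits["pident"].between(96, 100).all()

    def test_zero_hits_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_blast_hits("C15", 0)

    def test_deterministic(self):
        h1 = sd.simulate_blast_hits("C15", 30, 0.2, seed=9)
        h2 = sd.simulate_blast_hits("C15", 30, 0.2, seed=9)
        pd.testing.assert_frame_equal(h1, h2)


class TestWriteOutputs:
    def test_files_written_and_readable(self, tmp_path, small_cfg):
        g = sd.simulate_genotypes(small_cfg)
        meta = sd.simulate_metadata(small_cfg, g.clusters)
        table, _ = sd.simulate_community(meta, small_cfg)
        written = sd.write_outputs(tmp_path, g, meta, {"com": table})
        names = {p.name for p in written}
        assert names == {"genotypes.tsv", "metadata.tsv", "counts_com.tsv"}
        reread = pd.read_csv(tmp_path / "counts_com.tsv", sep="\t", index_col=0)
        assert reread.to_numpy().sum() == table.counts.to_numpy().sum()
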