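"""Synthetic cohort generator: determinism, planted structure, round trips."""

import numpy as np
import pandas as pd
import pytest

from lncnet.config import SimulationConfig
from lncnet.annotation import read_gtf
from lncnet.simulate import (
    read_counts,
    read_ground_truth,
    read_metabolites,
    simulate_cohort,
    write_dataset,
)


class TestConfig:
    def test_group_sizes_must_sum(self):
        with pytest.raises(ValueError, match="group sizes"):
            SimulationConfig(group_sizes=(30, 30)).validate()

    def test_wiring_bounds(self):
        with pytest.raises(ValueError, match="wiring"):
            SimulationConfig(wiring_r_high=1.2).validate()

    def test_nonpositive_dimensions(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=0).validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_genes=500, seed=3)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert SimulationConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestDeterminism:
    def test_same_seed_same_dataset(self, small_config):
        a = simulate_cohort(small_config)
        b = simulate_cohort(small_config)
        for t in small_config.tissues:
            pd.testing.assert_frame_equal(a.counts[t], b.counts[t])
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        pd.testing.assert_frame_equal(a.metabolites, b.metabolites)
        assert [m.exons for m in a.annotation] == [m.exons for m in b.annotation]

    def test_written_files_byte_identical(self, small_config, tmp_path):
        m1 = write_dataset(simulate_cohort(small_config), tmp_path / "a")
        m2 = write_dataset(simulate_cohort(small_config), tmp_path / "b")
        assert m1 == m2
        for name in m1.values():
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_different_seed_differs(self, small_config):
        from dataclasses import replace
        a = simulate_cohort(small_config)
        b = simulate_cohort(replace(small_config, seed=small_config.seed + 1))
        assert not a.counts["liver"].equals(b.counts["liver"])


class TestStudyDesign:
    def test_cohort_metadata_matches_design(self, default_dataset):
        ph = default_dataset.phenotypes
        assert len(ph) == 48
        assert (ph["sex"] == "male").sum() == 24
        sizes = ph.groupby(["group_true", "sex"]).size()
        assert sizes[("high", "male")] == 12 and sizes[("high", "female")] == 13
        assert sizes[("low", "male")] == 12 and sizes[("low", "female")] == 11
        assert set(default_dataset.counts) == set(default_dataset.config.tissues)
        assert len(default_dataset.config.tissues) == 4

    def test_lncrna_baselines_lower_than_mrna(self, default_dataset, default_log2):
        gt = default_dataset.ground_truth
        means = default_log2.values.mean(axis=1)
        lnc = [g for g in gt.lncrna_ids if g not in gt.planted_regulator_ids]
        coding = default_dataset.gene_table.query("biotype == 'protein_coding'")["gene_id"]
        assert means.loc[lnc].mean() < means.loc[coding].mean() - 1.0

    def test_sample_keys_unique(self, default_dataset):
        cm = default_dataset.to_count_matrix()
        assert cm.sample_meta.index.is_unique
        assert cm.fragments.shape[1] == 4 * 48


class TestPlantedSignals:
    def test_wiring_correlation_oracle(self, default_dataset, default_log2):
        """Within-tissue sample correlation of regulator vs targets ~ wiring_r."""
        gt = default_dataset.ground_truth
        meta = default_log2.sample_meta
        cols_h = meta.index[(meta["group"] == "high") & (meta["tissue"] == "jejunum")]
        cols_l = meta.index[(meta["group"] == "low") & (meta["tissue"] == "jejunum")]
        reg = gt.planted_regulator_ids[0]
        vals = default_log2.values
        r_h = np.array([np.corrcoef(vals.loc[reg, cols_h], vals.loc[t, cols_h])[0, 1]
                        for t in gt.target_map[reg]])
        r_l = np.array([np.corrcoef(vals.loc[reg, cols_l], vals.loc[t, cols_l])[0, 1]
                        for t in gt.target_map[reg]])
        assert abs(r_h.mean() - 0.8) < 0.15
        assert abs(np.abs(r_h).mean() - np.abs(r_l).mean()) > 0.5

    def test_planted_de_exceeds_null_spread(self, default_dataset, default_log2):
        gt = default_dataset.ground_truth
        meta = default_log2.sample_meta
        tissue = "liver"
        cols = meta.index[meta["tissue"] == tissue]
        grp = meta.loc[cols, "group"]
        diff = (default_log2.values[cols[grp == "high"]].mean(axis=1)
                - default_log2.values[cols[grp == "low"]].mean(axis=1)).abs()
        de = [g for g in gt.de_gene_ids[tissue] if g in diff.index]
        planted_genes = {g for t in gt.de_gene_ids.values() for g in t}
        null = diff.drop(index=[g for g in planted_genes if g in diff.index])
        assert diff.loc[de].min() > np.quantile(null, 0.95)

    def test_no_de_planted_in_last_tissue(self, default_dataset):
        assert default_dataset.ground_truth.de_gene_ids["rumen"] == []

    def test_targets_partition_into_modules(self, default_dataset):
        gt = default_dataset.ground_truth
        all_targets = [g for ts in gt.target_map.values() for g in ts]
        assert len(all_targets) == len(set(all_targets))
        assert set(gt.planted_regulator_ids) <= set(gt.lncrna_ids)


class TestRoundTrip:
    def test_counts_and_metabolites_round_trip(self, small_config, tmp_path):
        ds = simulate_cohort(small_config)
        write_dataset(ds, tmp_path)
        back = read_counts(tmp_path / "counts_liver.tsv")
        pd.testing.assert_frame_equal(back, ds.counts["liver"].rename_axis("gene_id"),
                                      check_dtype=False)
        mets = read_metabolites(tmp_path / "metabolites.tsv")
        assert mets.isna().equals(ds.metabolites.isna())
        assert np.allclose(mets.fillna(0), ds.metabolites.fillna(0), atol=1e-4)

    def test_gtf_round_trip_preserves_models(self, small_config, tmp_path):
        ds = simulate_cohort(small_config)
        write_dataset(ds, tmp_path)
        back = {m.transcript_id: m for m in read_gtf(tmp_path / "annotation.gtf")}
        assert len(back) == len(ds.annotation)
        for m in ds.annotation:
            b = back[m.transcript_id]
            assert b.exons == m.exons
            assert (b.strand, b.chrom, b.biotype) == (m.strand, m.chrom, m.biotype)
            assert all(s <= e and s >= 1 for s, e in b.exons)

    def test_ground_truth_round_trip(self, small_config, tmp_path):
        ds = simulate_cohort(small_config)
        write_dataset(ds, tmp_path)
        gt = read_ground_truth(tmp_path / "ground_truth.tsv")
        assert gt.planted_regulator_ids == ds.ground_truth.planted_regulator_ids
        assert gt.target_map == ds.ground_truth.target_map
        assert gt.metabolite_links == ds.ground_truth.metabolite_links
        assert gt.de_gene_ids["liver"] == ds.ground_truth.de_gene_ids["liver"]


class TestMetabolites:
    def test_missingness_rate_plausible(self, default_dataset):
        rate = default_dataset.metabolites.isna().to_numpy().mean()
        assert abs(rate - default_dataset.config.metabolite_missing_rate) < 0.02

    def test_planted_links_correlate_with_regulator(self, default_dataset, default_log2):
        gt = default_dataset.ground_truth
        reg = gt.planted_regulator_ids[0]
        tissue = gt.regulator_best_tissue[reg]
        meta = default_log2.sample_meta
        cols = meta.index[meta["tissue"] == tissue]
        expr = default_log2.values.loc[reg, cols]
        expr.index = meta.loc[cols, "animal"]
        met_id, sign = gt.metabolite_links[reg][0]
        met = default_dataset.metabolites.loc[met_id].dropna()
        common = met.index.intersection(expr.index)
        r = np.corrcoef(expr.loc[common], met.loc[common])[0, 1]
        assert np.sign(r) == sign
        assert abs(r) > 0.15  # true |r| = 0.4 at n ~ 44
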