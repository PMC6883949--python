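"""DE stand-in test, BH adjustment, TS criterion, prioritized-set assembly."""

import numpy as np
import pandas as pd
import pytest

from lncnet import expression as ex
from lncnet import prioritize as pr
from tests.conftest import make_expression


class TestBH:
    def test_hand_run_step_up(self):
        # p = (.01,.02,.03,.04), m=4: q_(i) = min_{j>=i} p_(j)*m/j -> all 0.04
        q = pr.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_matches_manual_step_up_on_random_input(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 50)
        order = np.argsort(p)
        m = len(p)
        q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        manual = np.empty(m)
        manual[order] = np.clip(q_sorted, 0, 1)
        assert np.allclose(pr.bh_adjust(p), manual)


class TestDEStandin:
    def _values(self, n_genes=50, n=24, shift=None, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 1, size=(n_genes, n))
        groups = pd.Series(["high"] * (n // 2) + ["low"] * (n - n // 2),
                           index=[f"s{i}" for i in range(n)])
        if shift is not None:
            vals[:, : n // 2] += shift
        frame = pd.DataFrame(vals, index=[f"G{i}" for i in range(n_genes)],
                             columns=groups.index)
        return frame, groups

    def test_constant_gene_has_p_one(self):
        frame, groups = self._values()
        frame.iloc[0] = 3.0
        res = pr.de_standin_test(frame, groups)
        assert res.loc[res["gene_id"] == "G0", "p"].iloc[0] == 1.0

    def test_planted_shift_detected(self):
        frame, groups = self._values(shift=2.0)
        res = pr.de_standin_test(frame, groups)
        assert (res["q"] < 0.05).mean() > 0.9
        assert (res["log2fc"] > 0).all()

    def test_covariate_confounding_removed(self):
        # a covariate aligned with a nuisance batch: effect vanishes after
        # residualization
        rng = np.random.default_rng(1)
        n = 40
        groups = pd.Series(["high", "low"] * (n // 2), index=[f"s{i}" for i in range(n)])
        batch = pd.Series(["a"] * (n // 2) + ["b"] * (n // 2), index=groups.index)
        vals = rng.normal(0, 1, size=(200, n)) + np.where(batch == "a", 2.0, 0.0)
        frame = pd.DataFrame(vals, index=[f"G{i}" for i in range(200)],
                             columns=groups.index)
        res = pr.de_standin_test(frame, groups, covariates=batch.to_frame("batch"))
        assert 0.0 <= (res["p"] < 0.05).mean() < 0.12

    def test_small_group_rejected(self):
        frame, groups = self._values(n=4)
        groups[:] = ["high", "high", "high", "low"]
        with pytest.raises(ValueError, match="at least 2"):
            pr.de_standin_test(frame, groups)


class TestSelectDE:
    def test_strict_threshold_boundary(self):
        res = pd.DataFrame(
            {"gene_id": ["a", "b"], "tissue": ["t", "t"], "log2fc": [1, 1],
             "p": [0.01, 0.02], "q": [0.049, 0.050]}
        )
        per_tissue, union = pr.select_de(res)
        assert per_tissue["t"] == {"a"}
        assert union == {"a"}

    def test_empty_input(self):
        per_tissue, union = pr.select_de(pd.DataFrame(columns=["gene_id", "tissue", "q"]))
        assert union == set()

    def test_union_matches_inclusion_exclusion(self):
        sets = {"t1": {"a", "b", "c"}, "t2": {"b", "c", "d"}, "t3": {"c", "e"}}
        rows = [{"gene_id": g, "tissue": t, "q": 0.01}
                for t, genes in sets.items() for g in genes]
        _, union = pr.select_de(pd.DataFrame(rows))
        sizes = (sum(len(s) for s in sets.values())
                 - len(sets["t1"] & sets["t2"]) - len(sets["t1"] & sets["t3"])
                 - len(sets["t2"] & sets["t3"]) + len(sets["t1"] & sets["t2"] & sets["t3"]))
        assert len(union) == sizes == 5


class TestTissueSpecific:
    def test_hand_arithmetic_example(self):
        # tissue means (10,1,1,1): M=3.25, SD=4.5; others < 1.625, focal > 7.75
        vals = np.array([[10.0, 10.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]])
        em = make_expression(vals, ["a", "b", "c", "d"])
        out = pr.select_tissue_specific(em)
        assert out["a"] == {"G0"}
        assert out["b"] == out["c"] == out["d"] == set()

    def test_flat_gene_nowhere_specific(self):
        em = make_expression(np.full((1, 8), 5.0), ["a", "b", "c", "d"])
        out = pr.select_tissue_specific(em)
        assert all(len(v) == 0 for v in out.values())

    def test_specific_in_at_most_one_tissue(self):
        rng = np.random.default_rng(3)
        vals = np.repeat(rng.uniform(0, 12, size=(300, 4)), 2, axis=1)
        em = make_expression(vals, ["a", "b", "c", "d"])
        out = pr.select_tissue_specific(em)
        seen: dict[str, int] = {}
        for genes in out.values():
            for g in genes:
                seen[g] = seen.get(g, 0) + 1
        assert all(v == 1 for v in seen.values())

    def test_single_tissue_rejected(self):
        em = make_expression(np.ones((2, 4)), ["a"])
        with pytest.raises(ValueError, match="two tissues"):
            pr.select_tissue_specific(em)

    def test_recovers_planted_ts_genes(self, default_dataset, default_log2):
        keep = ex.filter_min_mean_fpkm(
            ex.ExpressionMatrix(2.0**default_log2.values - 0.001, "fpkm",
                                default_log2.sample_meta))
        em = ex.ExpressionMatrix(default_log2.values.loc[keep], "log2fpkm",
                                 default_log2.sample_meta)
        out = pr.select_tissue_specific(em)
        gt = default_dataset.ground_truth
        for tissue, planted in gt.ts_gene_ids.items():
            found = out[tissue] & set(planted)
            assert len(found) >= 0.9 * len(planted)


class TestAssemble:
    BIOTYPES = pd.Series({"g1": "protein_coding", "g2": "protein_coding",
                          "y1": "Y_RNA", "l1": "novel"})

    def test_flags_merged_for_multi_category_gene(self):
        qtl = pd.DataFrame({"MY": [True]}, index=pd.Index(["g1"], name="gene_id"))
        out = pr.assemble_prioritized_set(
            {"liver": {"g1"}}, {"liver": set()}, qtl, set(), self.BIOTYPES,
            expression_keep={"g1"})
        row = out.flags.loc["g1"]
        assert row["de_liver"] and row["qtl_MY"] and not row["is_lncrna"]
        assert len(out.flags) == 1

    def test_excluded_biotype_dropped_even_if_de(self):
        qtl = pd.DataFrame({"MY": []}, index=pd.Index([], name="gene_id"))
        out = pr.assemble_prioritized_set(
            {"liver": {"y1", "g1"}}, {}, qtl, set(), self.BIOTYPES,
            expression_keep={"y1", "g1"})
        assert list(out.flags.index) == ["g1"]

    def test_expression_filter_intersected(self):
        qtl = pd.DataFrame({"MY": []}, index=pd.Index([], name="gene_id"))
        out = pr.assemble_prioritized_set(
            {"liver": {"g1", "g2"}}, {}, qtl, {"l1"}, self.BIOTYPES,
            expression_keep={"g1", "l1"})
        assert set(out.flags.index) == {"g1", "l1"}
        assert out.lncrnas() == ["l1"]

    def test_empty_categories_empty_set(self):
        qtl = pd.DataFrame({"MY": []}, index=pd.Index([], name="gene_id"))
        out = pr.assemble_prioritized_set({}, {}, qtl, set(), self.BIOTYPES, set())
        assert len(out.flags) == 0

    def test_cardinality_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(60)]
        biotypes = pd.Series({g: ("Y_RNA" if i % 13 == 0 else "protein_coding")
                              for i, g in enumerate(genes)})
        de = {"t": set(rng.choice(genes, 20, replace=False))}
        ts = {"t": set(rng.choice(genes, 10, replace=False))}
        qtl_members = set(rng.choice(genes, 15, replace=False))
        qtl = pd.DataFrame({"RFI": [g in qtl_members for g in genes]},
                           index=pd.Index(genes, name="gene_id"))
        lnc = set(rng.choice(genes, 5, replace=False))
        keep = set(rng.choice(genes, 45, replace=False))
        out = pr.assemble_prioritized_set(de, ts, qtl, lnc, biotypes, keep)
        brute = {g for g in genes
                 if (g in de["t"] or g in ts["t"] or g in qtl_members or g in lnc)
                 and biotypes[g] != "Y_RNA" and g in keep}
        assert set(out.flags.index) == brute
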