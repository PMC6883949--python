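"""Regulatory impact factors: formulas, symmetries, planted-regulator recovery."""

import numpy as np
import pandas as pd
import pytest

from lncnet import rif
from lncnet.config import SimulationConfig
from lncnet import expression as ex
from lncnet.simulate import simulate_cohort


def _stats(e1, e2, r1, r2, regulators=("R",)):
    targets = [f"T{j}" for j in range(len(e1))]
    e1 = pd.Series(e1, index=targets, dtype=float)
    e2 = pd.Series(e2, index=targets, dtype=float)
    pif = 0.5 * (e1 + e2) * (e1 - e2)
    r1 = pd.DataFrame(np.atleast_2d(r1), index=list(regulators), columns=targets, dtype=float)
    r2 = pd.DataFrame(np.atleast_2d(r2), index=list(regulators), columns=targets, dtype=float)
    return rif.ConditionStats(list(regulators), targets, e1, e2, pif, r1, r2)


class TestFormulas:
    def test_worked_example_hand_arithmetic(self):
        # targets (e1,e2,r1,r2) = (2,1,.9,.1) and (3,3,.5,-.5):
        # PIF = (1.5, 0), DW = (.8, 1.0)
        # rif1 = (1.5*.64 + 0)/2 = 0.48
        # rif2 = ((1.8^2 - 0.1^2) + (1.5^2 - 1.5^2))/2 = 1.615
        cs = _stats([2, 3], [1, 3], [[0.9, 0.5]], [[0.1, -0.5]])
        scores = rif.compute_rif_scores(cs)
        assert scores["rif1_raw"].iloc[0] == pytest.approx(0.48, abs=1e-12)
        assert scores["rif2_raw"].iloc[0] == pytest.approx(1.615, abs=1e-12)

    def test_identical_wiring_gives_zero_rif1(self):
        cs = _stats([2, 3], [1, 2], [[0.5, 0.7]], [[0.5, 0.7]])
        assert rif.compute_rif_scores(cs)["rif1_raw"].iloc[0] == 0.0

    def test_symmetric_conditions_give_zero_rif2(self):
        cs = _stats([2, 3], [2, 3], [[0.5, 0.7]], [[0.5, 0.7]])
        out = rif.compute_rif_scores(cs)
        assert out["rif1_raw"].iloc[0] == 0.0
        assert out["rif2_raw"].iloc[0] == 0.0

    def test_empty_targets_rejected(self):
        cs = _stats([2], [1], [[0.5]], [[0.1]])
        cs.targets = []
        with pytest.raises(ValueError):
            rif.compute_rif_scores(cs)

    def test_self_pair_excluded_from_average(self):
        cs = _stats([2, 3], [1, 3], [[0.9, 0.5]], [[0.1, -0.5]], regulators=("T0",))
        out = rif.compute_rif_scores(cs)
        # only T1 contributes, denominator 1
        assert out["rif1_raw"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["rif2_raw"].iloc[0] == pytest.approx(0.0, abs=1e-12)


class TestConditionStats:
    def _em(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        cols = [f"s{i}" for i in range(n)]
        groups = pd.Series(["high"] * (n // 2) + ["low"] * (n // 2), index=cols)
        vals = pd.DataFrame(rng.normal(0, 1, (4, n)),
                            index=["R", "T0", "T1", "T2"], columns=cols)
        return vals, groups

    def test_identical_conditions_have_zero_dw(self):
        vals, groups = self._em()
        vals.loc[:, groups == "low"] = vals.loc[:, groups == "high"].to_numpy()
        cs = rif.condition_stats(vals, groups, ["R"], ["T0", "T1", "T2"])
        assert np.allclose(cs.dw.to_numpy(), 0.0)
        assert np.allclose(cs.pif.to_numpy(), 0.0)

    def test_collinear_vectors_give_unit_correlation(self):
        vals, groups = self._em()
        vals.loc["T0"] = 2.0 * vals.loc["R"] + 1.0
        cs = rif.condition_stats(vals, groups, ["R"], ["T0"])
        assert cs.r1.loc["R", "T0"] == pytest.approx(1.0)
        assert cs.r2.loc["R", "T0"] == pytest.approx(1.0)

    def test_constant_vector_warns_and_zeroes(self):
        vals, groups = self._em()
        vals.loc["T0"] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            cs = rif.condition_stats(vals, groups, ["R"], ["T0"])
        assert cs.r1.loc["R", "T0"] == 0.0

    def test_small_condition_rejected(self):
        vals, groups = self._em(n=4)
        with pytest.raises(ValueError, match="3 samples"):
            rif.condition_stats(vals, groups, ["R"], ["T0"])


class TestSymmetries:
    def _random_stats(self, seed=0, n_reg=5, n_tar=7):
        rng = np.random.default_rng(seed)
        return _stats(
            rng.uniform(0, 5, n_tar), rng.uniform(0, 5, n_tar),
            rng.uniform(-1, 1, (n_reg, n_tar)), rng.uniform(-1, 1, (n_reg, n_tar)),
            regulators=[f"R{i}" for i in range(n_reg)],
        )

    def test_condition_swap_flips_raw_scores(self):
        cs = self._random_stats()
        swapped = _stats(cs.e2.to_numpy(), cs.e1.to_numpy(),
                         cs.r2.to_numpy(), cs.r1.to_numpy(),
                         regulators=cs.regulators)
        a = rif.compute_rif_scores(cs)
        b = rif.compute_rif_scores(swapped)
        assert np.allclose(a["rif1_raw"], -b["rif1_raw"])
        assert np.allclose(a["rif2_raw"], -b["rif2_raw"])
        za = rif.select_significant_regulators(a)
        zb = rif.select_significant_regulators(b)
        assert list(za["rif2_z"].abs().rank()) == list(zb["rif2_z"].abs().rank())

    def test_target_order_invariance(self):
        cs = self._random_stats(seed=1)
        perm = np.random.default_rng(2).permutation(len(cs.targets))
        shuffled = _stats(cs.e1.to_numpy()[perm], cs.e2.to_numpy()[perm],
                          cs.r1.to_numpy()[:, perm], cs.r2.to_numpy()[:, perm],
                          regulators=cs.regulators)
        assert np.allclose(rif.compute_rif_scores(cs)["rif1_raw"],
                           rif.compute_rif_scores(shuffled)["rif1_raw"])

    def test_expression_doubling_quadruples_pif_and_rif1(self):
        cs = self._random_stats(seed=3)
        doubled = _stats(2 * cs.e1.to_numpy(), 2 * cs.e2.to_numpy(),
                         cs.r1.to_numpy(), cs.r2.to_numpy(), regulators=cs.regulators)
        assert np.allclose(4 * cs.pif.to_numpy(), doubled.pif.to_numpy())
        assert np.allclose(4 * rif.compute_rif_scores(cs)["rif1_raw"],
                           rif.compute_rif_scores(doubled)["rif1_raw"])


class TestSignificance:
    def test_threshold_rule(self):
        scores = pd.DataFrame({"regulator_id": [f"r{i}" for i in range(10)],
                               "rif1_raw": np.r_[0.0, np.linspace(-0.1, 0.1, 9)],
                               "rif2_raw": np.r_[10.0, np.zeros(9)]})
        out = rif.select_significant_regulators(scores)
        assert abs(out["rif1_z"].mean()) < 1e-12
        assert out["rif1_z"].std(ddof=1) == pytest.approx(1.0)
        # the single outlier regulator: z = 9/sqrt(10) = 2.85 >= 1.96
        assert out.loc[out["regulator_id"] == "r0", "significant"].iloc[0]
        assert not out.loc[out["regulator_id"] != "r0", "significant"].any()

    def test_degenerate_scores_not_significant(self):
        scores = pd.DataFrame({"regulator_id": list("abc"),
                               "rif1_raw": [1.0, 1.0, 1.0],
                               "rif2_raw": [2.0, 2.0, 2.0]})
        out = rif.select_significant_regulators(scores)
        assert (out[["rif1_z", "rif2_z"]] == 0).all().all()
        assert not out["significant"].any()

    def test_single_regulator_rejected(self):
        with pytest.raises(ValueError):
            rif.select_significant_regulators(
                pd.DataFrame({"regulator_id": ["a"], "rif1_raw": [1.0],
                              "rif2_raw": [1.0]}))


class TestPlantedRecovery:
    def test_planted_regulator_ranks_top_among_lncrnas(self):
        """Differential wiring puts planted regulators in the top |rif2_z| tail."""
        cfg = SimulationConfig(seed=101)
        ds = simulate_cohort(cfg)
        cm = ds.to_count_matrix()
        em = ex.log2_with_pseudocount(ex.compute_fpkm(cm))
        meta = em.sample_meta
        cols = meta.index[meta["tissue"] == "jejunum"]
        gt = ds.ground_truth
        targets = sorted({g for ts in gt.target_map.values() for g in ts})
        cs = rif.condition_stats(em.values[cols], meta.loc[cols, "group"],
                                 gt.lncrna_ids, targets)
        out = rif.select_significant_regulators(rif.compute_rif_scores(cs))
        ranks = out["rif2_z"].abs().rank(pct=True)
        planted = out["regulator_id"].isin(gt.planted_regulator_ids)
        assert (ranks[planted] > 0.95).all()
        assert out.loc[planted, "significant"].all()
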