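"""Calibration, precision-recall and the Poisson/BH baseline."""

import numpy as np
import pandas as pd
import pytest

from dnvprior.core_stats import bayesian_fdr, ppa
from dnvprior.evaluation import (
    poisson_baseline,
    precision_recall,
    realized_fdr,
    recall_by_mutation_rate,
)


def _table(ppas, genes=None):
    return bayesian_fdr(ppas, genes)


class TestRealizedFDR:
    def test_all_true_discoveries(self):
        tab = _table([0.99, 0.98, 0.97, 0.2], list("abcd"))
        truth = pd.Series([1, 1, 1, 0], index=list("abcd"))
        out = realized_fdr(tab, truth, cutoffs=[0.05])
        assert out.loc[0, "realized_fdp"] == 0.0
        assert out.loc[0, "n_discoveries"] == 3

    def test_no_discoveries_convention(self):
        tab = _table([0.5, 0.4], ["a", "b"])
        truth = pd.Series([1, 0], index=["a", "b"])
        out = realized_fdr(tab, truth, cutoffs=[0.01])
        assert out.loc[0, "realized_fdp"] == 0.0
        assert out.loc[0, "n_discoveries"] == 0

    def test_exclusions_removed_before_thresholding(self):
        tab = _table([0.99, 0.98, 0.2], list("abc"))
        truth = pd.Series([0, 1, 0], index=list("abc"))
        out = realized_fdr(tab, truth, cutoffs=[0.05], exclude=["a"])
        assert out.loc[0, "n_discoveries"] == 1
        assert out.loc[0, "realized_fdp"] == 0.0

    def test_no_overlap_errors(self):
        tab = _table([0.9], ["a"])
        with pytest.raises(ValueError, match="overlap"):
            realized_fdr(tab, pd.Series([1], index=["z"]))


class TestPrecisionRecall:
    def test_perfect_separation(self):
        tab = _table([0.99, 0.98, 0.01, 0.02], list("abcd"))
        truth = pd.Series([1, 1, 0, 0], index=list("abcd"))
        out = precision_recall(tab, truth)
        top2 = out.head(2)
        assert (top2["precision"] == 1.0).all()
        assert out["recall"].iloc[-1] == 1.0

    def test_uninformative_scores_give_prevalence_precision(self):
        rng = np.random.default_rng(0)
        n = 10_000
        genes = [f"g{i}" for i in range(n)]
        truth = pd.Series((rng.uniform(size=n) < 0.1).astype(int), index=genes)
        tab = _table(rng.uniform(size=n), genes)
        out = precision_recall(tab, truth)
        assert out["precision"].iloc[-1] == pytest.approx(0.1, abs=0.01)
        assert out["precision"].iloc[n // 2] == pytest.approx(0.1, abs=0.02)

    def test_all_negative_truth_errors(self):
        tab = _table([0.9, 0.1], ["a", "b"])
        with pytest.raises(ValueError, match="no risk genes"):
            precision_recall(tab, pd.Series([0, 0], index=["a", "b"]))

    def test_consistency_with_realized_fdp(self):
        """1 - precision at the FDR threshold equals the realized FDP there."""
        rng = np.random.default_rng(3)
        n = 2000
        genes = [f"g{i}" for i in range(n)]
        truth_v = (rng.uniform(size=n) < 0.05).astype(int)
        scores = np.clip(truth_v * rng.uniform(0.3, 1, n)
                         + (1 - truth_v) * rng.uniform(0, 0.4, n), 0, 1)
        tab = _table(scores, genes)
        truth = pd.Series(truth_v, index=genes)
        for cutoff in (0.05, 0.2):
            cal = realized_fdr(tab, truth, cutoffs=[cutoff])
            nd = int(cal.loc[0, "n_discoveries"])
            if nd == 0:
                continue
            pr = precision_recall(tab, truth)
            assert 1 - pr["precision"].iloc[nd - 1] == pytest.approx(
                cal.loc[0, "realized_fdp"], abs=1e-12
            )


class TestRecallByMutationRate:
    def test_everything_discovered(self):
        tab = _table([0.999] * 10, [f"g{i}" for i in range(10)])
        truth = pd.Series(1, index=[f"g{i}" for i in range(10)])
        rates = pd.Series(np.linspace(1e-6, 1e-4, 10),
                          index=[f"g{i}" for i in range(10)])
        out = recall_by_mutation_rate(tab, truth, rates, n_bins=2)
        assert (out["recall"].dropna() == 1.0).all()

    def test_zero_discoveries(self):
        tab = _table([0.5] * 10, [f"g{i}" for i in range(10)])
        truth = pd.Series(1, index=[f"g{i}" for i in range(10)])
        rates = pd.Series(np.linspace(1e-6, 1e-4, 10),
                          index=[f"g{i}" for i in range(10)])
        out = recall_by_mutation_rate(tab, truth, rates, n_bins=2)
        assert (out["recall"].dropna() == 0.0).all()

    def test_power_increases_with_mutation_rate(self, bulk_small, rr_chd):
        """At the generating parameters, big genes (high expected counts) are
        easier to discover, so recall rises across rate bins."""
        g = bulk_small.genes
        d = {v: g[f"d_{v}"].to_numpy(float) for v in ("LGD", "Dmis")}
        M = {v: g[f"M_{v}"].to_numpy(float) for v in ("LGD", "Dmis")}
        tab = bayesian_fdr(ppa(0.037, d, M, rr_chd), g["gene"])
        truth = pd.Series(bulk_small.y_true, index=g["gene"])
        rates = pd.Series((M["LGD"] + M["Dmis"]), index=g["gene"])
        out = recall_by_mutation_rate(tab, truth, rates, n_bins=5)
        rec = out["recall"].dropna()
        assert rec.iloc[-1] > rec.iloc[0]


class TestPoissonBaseline:
    def test_survival_values_and_bh(self):
        genes = pd.DataFrame(
            {
                "gene": list("abcd"),
                "d_LGD": [0, 2, 0, 0],
                "M_LGD": [0.05, 0.05, 0.05, 0.05],
            }
        )
        out = poisson_baseline(genes, classes=("LGD",))
        assert out.loc[0, "p_LGD"] == 1.0
        expected = 1 - np.exp(-0.05) * (1 + 0.05)
        assert out.loc[1, "p_LGD"] == pytest.approx(expected, rel=1e-6)
        assert out.loc[1, "p_LGD"] == pytest.approx(0.001209, abs=1e-6)

    def test_bh_hand_example(self):
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 1.0], method="fdr_bh")[1]
        assert q == pytest.approx([0.04, 0.04, 0.04, 1.0])

    def test_class_combination(self):
        genes = pd.DataFrame(
            {
                "gene": ["a"],
                "d_LGD": [1],
                "d_Dmis": [0],
                "M_LGD": [0.01],
                "M_Dmis": [0.01],
            }
        )
        out = poisson_baseline(genes)
        p_lgd = out.loc[0, "p_LGD"]
        assert out.loc[0, "p"] == pytest.approx(min(1.0, 2 * p_lgd))
        fisher = poisson_baseline(genes, combine="fisher")
        assert 0 < fisher.loc[0, "p"] <= 1

    def test_unknown_combine(self):
        genes = pd.DataFrame({"gene": ["a"], "d_LGD": [0], "M_LGD": [0.1]})
        with pytest.raises(ValueError, match="combine"):
            poisson_baseline(genes, classes=("LGD",), combine="wat")
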