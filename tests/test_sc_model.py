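"""Prior network, ELBO machinery and the single-cell training loop."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from dnvprior.core_stats import RelativeRiskParams, ppa
from dnvprior.sc_model import (
    LabelSet,
    PriorNetwork,
    TrainingConfig,
    _Adam,
    _PI_CLIP,
    celltype_association,
    elbo_loss,
    forward_prior,
    pseudo_bulk,
    supervised_loss,
    train_semisupervised,
)


def _zero_net(n_inputs, pi_bar=0.05):
    """All-zero weights: every gene gets pi = 0.5 regardless of input."""
    net = PriorNetwork(n_inputs, hidden=4, pi_bar=pi_bar, seed=0)
    for k in net.params:
        net.params[k] = np.zeros_like(net.params[k])
    net.params["g1"] = np.ones_like(net.params["g1"])
    return net


class TestForward:
    def test_deterministic_and_in_range(self):
        net = PriorNetwork(6, pi_bar=0.05, seed=3)
        x = np.full(6, 0.4)
        a, b = forward_prior(net, x), forward_prior(net, x)
        assert a == b
        assert 0.0 < a < 1.0
        batch = net.forward(np.vstack([x, x]))
        assert batch[0] == batch[1] == a

    def test_dimension_mismatch(self):
        net = PriorNetwork(6, seed=0)
        with pytest.raises(ValueError, match="features"):
            net.forward(np.zeros(5))

    def test_nonconstant_after_training(self, sc_setup):
        _, _, _, res = sc_setup
        net = res.net
        lo = net.forward(np.zeros(net.n_inputs))
        hi = net.forward(np.ones(net.n_inputs))
        assert lo != hi

    def test_invalid_pi_bar(self):
        with pytest.raises(ValueError):
            PriorNetwork(4, pi_bar=1.0)


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        """Hand-written backprop through linear/ELU/layernorm/softmax agrees
        with central finite differences on a BCE loss."""
        rng = np.random.default_rng(0)
        net = PriorNetwork(7, hidden=5, pi_bar=0.05, seed=1)
        X = rng.uniform(size=(6, 7))
        t = np.array([1.0, 0.0, 1.0, 0.0, 0.0, 1.0])

        def loss_fn():
            pic = np.clip(net.forward(X), _PI_CLIP, 1 - _PI_CLIP)
            return -np.mean(t * np.log(pic) + (1 - t) * np.log1p(-pic))

        pi, cache = net.forward(X, cache=True)
        pic = np.clip(pi, _PI_CLIP, 1 - _PI_CLIP)
        dpi = (pic - t) / (pic * (1 - pic)) / len(t)
        grads = net.backward(cache, dpi)
        for k, arr in net.params.items():
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                old = arr[idx]
                arr[idx] = old + 1e-6
                lp = loss_fn()
                arr[idx] = old - 1e-6
                lm = loss_fn()
                arr[idx] = old
                num = (lp - lm) / 2e-6
                assert grads[k][idx] == pytest.approx(num, rel=1e-4, abs=1e-9), k


class TestLosses:
    def test_elbo_hand_example(self):
        """One gene, pi = pi_bar = 0.3, logP_alt = -1, logP_null = -2:
        the KL vanishes and the loss is -(0.3*(-1) + 0.7*(-2)) = 1.7."""
        # d = 0, M = 2 gives logP_null = -2; gamma = 1/(beta*ln 3) with
        # beta = 1 gives logP_alt = r*log(beta/(beta+M)) = -1
        genes = pd.DataFrame({"gene": ["g0"], "d_LGD": [0], "M_LGD": [2.0]})
        rr = RelativeRiskParams({"LGD": 1.0 / np.log(3.0)}, {"LGD": 1.0})
        net = PriorNetwork(3, pi_bar=0.3, seed=0)
        loss = elbo_loss(net, genes, rr, pis=np.array([0.3]))
        assert loss == pytest.approx(1.7, abs=1e-9)

    def test_elbo_matches_two_point_enumeration(self, rr_chd):
        """Closed-form ELBO equals the brute-force sum over y in {0, 1} of
        q(y) [log q(y) - log p(y) - log p(d | y)]."""
        rng = np.random.default_rng(4)
        n = 10
        genes = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n)],
                "d_LGD": rng.poisson(0.5, n),
                "d_Dmis": rng.poisson(0.5, n),
                "M_LGD": rng.uniform(0.01, 0.3, n),
                "M_Dmis": rng.uniform(0.01, 0.3, n),
            }
        )
        pis = rng.uniform(0.05, 0.9, n)
        pi_bar = 0.04
        net = PriorNetwork(3, pi_bar=pi_bar, seed=0)
        expected = 0.0
        for i in range(n):
            pa = pn = 1.0
            for v in ("LGD", "Dmis"):
                r = rr_chd.gamma_bar[v] * rr_chd.beta_bar[v]
                p = rr_chd.beta_bar[v] / (rr_chd.beta_bar[v] + genes[f"M_{v}"][i])
                pa *= stats.nbinom.pmf(genes[f"d_{v}"][i], r, p)
                pn *= stats.poisson.pmf(genes[f"d_{v}"][i], genes[f"M_{v}"][i])
            for y, q, lpd in ((1, pis[i], np.log(pa)), (0, 1 - pis[i], np.log(pn))):
                prior = pi_bar if y else 1 - pi_bar
                expected += q * (np.log(q) - np.log(prior) - lpd)
        got = elbo_loss(net, genes, rr_chd, pis=pis)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_elbo_rejects_degenerate_anchor(self, rr_chd):
        genes = pd.DataFrame({"gene": ["a"], "d_LGD": [0], "M_LGD": [0.1]})
        net = PriorNetwork(3, pi_bar=0.5, seed=0)
        net.kl_weight_pi_bar = 1.0
        with pytest.raises(ValueError, match="KL"):
            elbo_loss(net, genes, rr_chd, pis=np.array([0.5]))

    def test_supervised_loss_half_everywhere_is_log2(self):
        expr = pd.DataFrame(np.random.default_rng(0).uniform(size=(6, 4)),
                            index=[f"g{i}" for i in range(6)])
        labels = LabelSet(["g0", "g1"], ["g2", "g3"])
        net = _zero_net(4)
        assert supervised_loss(net, labels, expr) == pytest.approx(np.log(2))

    def test_supervised_loss_missing_gene(self):
        expr = pd.DataFrame(np.zeros((2, 3)), index=["g0", "g1"])
        net = PriorNetwork(3, seed=0)
        with pytest.raises(ValueError, match="absent"):
            supervised_loss(net, LabelSet(["g0"], ["nope"]), expr)

    def test_gradient_steps_reduce_supervised_loss(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.uniform(size=(5, 6)),
                            index=[f"g{i}" for i in range(5)])
        labels = LabelSet(["g0", "g1"], ["g2", "g3", "g4"])
        net = PriorNetwork(6, hidden=8, pi_bar=0.3, seed=2)
        before = supervised_loss(net, labels, expr)
        opt = _Adam({k: v.shape for k, v in net.params.items()}, 1e-2)
        ids = labels.positives + labels.negatives
        t = np.array([1.0, 1.0, 0.0, 0.0, 0.0])
        X = expr.loc[ids].to_numpy()
        for _ in range(10):
            pi, cache = net.forward(X, cache=True)
            pic = np.clip(pi, _PI_CLIP, 1 - _PI_CLIP)
            dpi = (pic - t) / (pic * (1 - pic)) / len(t)
            opt.step(net.params, net.backward(cache, dpi))
        assert supervised_loss(net, labels, expr) < before


class TestTraining:
    def test_requires_pi_bar(self, sc_setup, rr_chd):
        expr, ds, _, _ = sc_setup
        with pytest.raises(ValueError, match="pi_bar"):
            train_semisupervised(expr, ds.genes, ds.labels, rr_chd)

    def test_seeded_runs_identical(self):
        rng = np.random.default_rng(9)
        n, C = 400, 8
        expr = pd.DataFrame(rng.uniform(size=(n, C)),
                            index=[f"g{i}" for i in range(n)])
        genes = pd.DataFrame(
            {
                "gene": expr.index,
                "d_LGD": rng.poisson(0.1, n),
                "d_Dmis": rng.poisson(0.1, n),
                "M_LGD": rng.uniform(0.01, 0.2, n),
                "M_Dmis": rng.uniform(0.01, 0.2, n),
            }
        )
        labels = LabelSet([f"g{i}" for i in range(10)],
                          [f"g{i}" for i in range(10, 40)])
        rr0 = RelativeRiskParams({"LGD": 10.0, "Dmis": 8.0},
                                 {"LGD": 1.0, "Dmis": 1.0})
        cfg = TrainingConfig(pretrain_epochs=5, unsup_epochs=5, seed=42)
        a = train_semisupervised(expr, genes, labels, rr0, cfg, pi_bar=0.05)
        b = train_semisupervised(expr, genes, labels, rr0, cfg, pi_bar=0.05)
        pd.testing.assert_frame_equal(a.posterior_table, b.posterior_table)
        assert a.rr.gamma_bar == b.rr.gamma_bar

    def test_elbo_history_improves_and_is_finite(self, sc_setup):
        _, _, _, res = sc_setup
        hist = res.history["elbo"]
        assert np.all(np.isfinite(hist))
        assert hist[-1] < hist[0]

    def test_prior_recovery_on_heldout_genes(self, sc_setup):
        """The trained network reconstructs the simulated risk prior
        (rank correlation > 0.5 outside the training labels)."""
        _, ds, _, res = sc_setup
        labelled = set(ds.labels.positives) | set(ds.labels.negatives)
        mask = ~ds.genes["gene"].isin(labelled).to_numpy()
        r = stats.spearmanr(res.pis.to_numpy()[mask], ds.pi_true[mask]).statistic
        assert r > 0.5

    def test_celltype_association_profile_matches_truth(self, sc_setup):
        """Per-cell-type Spearman association computed from the learned prior
        correlates with the one computed from the generating prior."""
        expr, ds, _, res = sc_setup
        got = celltype_association(expr, res.pis.to_numpy())["spearman_r"]
        want = celltype_association(expr, ds.pi_true)["spearman_r"]
        assert stats.spearmanr(got, want).statistic > 0.5

    def test_constant_network_reduces_to_uniform_prior_ppa(self, sc_setup):
        """With the prior pinned to a constant, the sc posterior path gives
        exactly the constant-prior mixture PPA."""
        _, ds, base, _ = sc_setup
        net = _zero_net(5, pi_bar=base.params["pi_bar"])
        pis = net.forward(np.random.default_rng(0).uniform(size=(4, 5)))
        assert np.allclose(pis, 0.5)
        d = {v: ds.genes[f"d_{v}"].to_numpy(float) for v in ("LGD", "Dmis")}
        M = {v: ds.genes[f"M_{v}"].to_numpy(float) for v in ("LGD", "Dmis")}
        sc_path = ppa(np.full(len(ds.genes), base.params["pi_bar"]), d, M, base.rr)
        bulk_path = base.posterior_table.set_index("gene")["PPA"].reindex(
            ds.genes["gene"]
        ).to_numpy()
        assert sc_path == pytest.approx(bulk_path, abs=1e-12)


class TestReadouts:
    def test_association_trivial_cases(self):
        rng = np.random.default_rng(2)
        pis = rng.uniform(size=1000)
        expr = pd.DataFrame(
            {
                "same": pis,
                "reversed": -pis,
                "shuffled": rng.permutation(pis),
                "flat": np.full(1000, 0.3),
            },
            index=[f"g{i}" for i in range(1000)],
        )
        out = celltype_association(expr, pis).set_index("cell_type")
        assert out.loc["same", "spearman_r"] == pytest.approx(1.0)
        assert out.loc["reversed", "spearman_r"] == pytest.approx(-1.0)
        assert abs(out.loc["shuffled", "spearman_r"]) < 0.1
        assert out.loc["flat", "spearman_r"] == 0.0
        assert bool(out.loc["flat", "constant"])

    def test_association_needs_three_genes(self):
        expr = pd.DataFrame(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="3 genes"):
            celltype_association(expr, [0.1, 0.2])

    def test_pseudo_bulk_fractions(self):
        mat = np.array([[0, 1], [0, 2], [0, 0], [0, 5], [0, 0],
                        [0, 0], [0, 0], [0, 1], [0, 0], [0, 0]])
        out = pseudo_bulk(mat, ["gA", "gB"])
        assert out.loc["gA", "all"] == 0.0
        assert out.loc["gB", "all"] == pytest.approx(0.4)

    def test_pseudo_bulk_sparse_and_batches(self):
        mat = sp.csr_matrix(np.array([[1, 0], [1, 0], [0, 0], [0, 1]]))
        out = pseudo_bulk(mat, ["gA", "gB"], batch_labels=["x", "x", "y", "y"])
        assert out.loc["gA", "x"] == 1.0
        assert out.loc["gA", "y"] == 0.0
        assert out.loc["gB", "y"] == 0.5

    def test_pseudo_bulk_empty(self):
        with pytest.raises(ValueError, match="empty"):
            pseudo_bulk(np.empty((0, 0)), [])
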