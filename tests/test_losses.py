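"""Loss algebra: MAE, the hinge margin, AHK bounds, routed total objective,
and the finite-difference check of the composite gradient."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from moeclock import LossConfig, ahk_loss, hinge_mae, mae, sample_pool_subset, total_loss
from moeclock import engine as E
from moeclock.losses import total_loss_graph
from moeclock.network import MoEConfig, init_model


class TestMAE:
    def test_arithmetic(self):
        assert mae([50, 60], [55, 60]) == pytest.approx(2.5)

    def test_identity(self, rng):
        v = rng.normal(size=20)
        assert mae(v, v) == 0.0

    def test_matches_loop(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        loop = sum(abs(x - y) for x, y in zip(a, b)) / 30
        assert mae(a, b) == pytest.approx(loop, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mae([], [])


class TestHingeMAE:
    def test_all_errors_below_margin_cost_nothing(self):
        assert hinge_mae([53, 64.9], [50, 60], margin=5.0) == 0.0

    def test_boundary_is_inclusive(self):
        # errors (5, 7) with margin 5: both count
        assert hinge_mae([55, 67], [50, 60], margin=5.0) == pytest.approx(6.0)

    def test_zero_margin_reduces_to_mae(self, rng):
        a, b = rng.normal(size=25), rng.normal(size=25)
        assert hinge_mae(a, b, 0.0) == pytest.approx(mae(a, b), abs=1e-12)

    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_never_exceeds_mae(self, seed, margin):
        r = np.random.default_rng(seed)
        a, b = r.normal(scale=5, size=10), r.normal(scale=5, size=10)
        assert hinge_mae(a, b, margin) <= mae(a, b) + 1e-12

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError):
            hinge_mae([1.0], [0.0], -1.0)


class TestAHK:
    def test_all_mass_on_pool_gives_minus_one(self):
        s = np.zeros(10)
        s[[1, 4, 7]] = [0.5, 1.0, 2.0]
        assert ahk_loss(s, pool_subset=[1, 4, 7], top_k=10) == pytest.approx(-1.0)

    def test_no_pool_gene_in_top_k_gives_zero(self):
        s = np.arange(10, dtype=float)  # top-3 are genes 7,8,9
        assert ahk_loss(s, pool_subset=[0, 1], top_k=3) == 0.0

    def test_hand_computed_two_gene_case(self):
        # saliency (3, 1) with gene 0 in the pool: -(3)/(3+1)
        assert ahk_loss([3.0, 1.0], pool_subset=[0], top_k=2) == pytest.approx(-0.75)

    def test_bounds_hold_on_random_input(self, rng):
        for _ in range(20):
            s = rng.normal(size=50)
            pool = rng.choice(50, size=10, replace=False)
            val = ahk_loss(s, pool, top_k=20)
            assert -1.0 <= val <= 0.0

    def test_moving_mass_to_pool_gene_never_increases_loss(self, rng):
        s = np.abs(rng.normal(size=30)) + 0.1
        pool = np.arange(5)
        before = ahk_loss(s, pool, top_k=10)
        order = np.argsort(-s)[:10]
        non_pool_top = [j for j in order if j not in set(pool.tolist())]
        if non_pool_top:
            s2 = s.copy()
            s2[pool[0]] += s2[non_pool_top[0]] - 0.05
            s2[non_pool_top[0]] = 0.05
            assert ahk_loss(s2, pool, top_k=10) <= before + 1e-12

    def test_all_zero_saliency_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning):
            assert ahk_loss(np.zeros(5), [0], top_k=5) == 0.0


class TestPoolSubset:
    def test_ten_percent_of_646_is_65(self):
        pool = np.arange(646)
        assert sample_pool_subset(pool, 0.10, seed=0).size == 65

    def test_fraction_one_returns_whole_pool(self):
        out = sample_pool_subset(np.arange(20), 1.0, seed=1)
        assert sorted(out.tolist()) == list(range(20))

    def test_deterministic_from_seed(self):
        a = sample_pool_subset(np.arange(100), 0.1, seed=5)
        b = sample_pool_subset(np.arange(100), 0.1, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            sample_pool_subset(np.array([]), 0.5, seed=0)


class TestTotalLoss:
    def test_reduces_to_lambda_mae_for_healthy_single_expert(self, rng):
        model = init_model(MoEConfig(input_dim=6, n_experts=1, hidden_widths=(4,),
                                     dropout_rate=0.0, seed=1))
        X = rng.normal(size=(10, 6))
        y = rng.uniform(30, 80, size=10)
        cfg = LossConfig(gamma=0.0, lam=30.0)
        bd = total_loss(model, X, y, ["healthy"] * 10, cfg)
        from moeclock.network import expert_forward
        pred = expert_forward(model, 0, X, mode="train")
        assert bd.total == pytest.approx(30.0 * mae(pred, y), rel=1e-9)
        assert bd.ahk_term == 0.0

    def test_unhealthy_inside_margin_costs_nothing(self, toy_model, rng):
        X = rng.normal(size=(8, 8))
        from moeclock.network import expert_forward
        preds = [expert_forward(toy_model, i, X, mode="train") for i in range(2)]
        y = np.mean(preds, axis=0)  # errors well within a wide margin
        cfg = LossConfig(margin=1e4, gamma=0.0)
        bd = total_loss(toy_model, X, y, ["unhealthy"] * 8, cfg)
        assert bd.total == 0.0

    def test_breakdown_composition_identity(self, toy_model, rng):
        X = rng.normal(size=(12, 8))
        y = rng.uniform(20, 90, size=12)
        status = rng.choice(["healthy", "unhealthy"], size=12)
        cfg = LossConfig()
        bd = total_loss(toy_model, X, y, status, cfg, pool_subset=np.arange(3), mode="train")
        assert bd.total == pytest.approx(cfg.lam * bd.prediction_term + cfg.gamma * bd.ahk_term,
                                         abs=1e-6)
        assert -1.0 <= bd.ahk_term <= 0.0
        assert len(bd.per_expert_D) == 2

    def test_unknown_status_rejected(self, toy_model, rng):
        with pytest.raises(ValueError, match="status"):
            total_loss(toy_model, rng.normal(size=(2, 8)), [50, 60], ["healthy", "dead"],
                       LossConfig())

    def test_gradient_matches_finite_differences_through_saliency(self, rng):
        """Central-difference check of the composite objective, including the
        double-differentiated saliency-alignment term."""
        model = init_model(MoEConfig(input_dim=5, n_experts=2, hidden_widths=(4, 3),
                                     dropout_rate=0.0, seed=3))
        X = rng.normal(size=(6, 5))
        y = rng.uniform(30, 80, size=6)
        status = ["healthy", "healthy", "unhealthy", "healthy", "unhealthy", "healthy"]
        cfg = LossConfig(margin=5.0, lam=30.0, gamma=100.0, top_k=4)
        pool = np.array([0, 2])
        params = model.parameters()

        def loss_value():
            return total_loss(model, X, y, status, cfg, pool_subset=pool, mode="train").total

        _, node = total_loss_graph(model, X, y, status, cfg, pool_subset=pool, mode="train")
        grads = E.grad(node, params)
        flat = [(p, g, tuple(rng.integers(0, s) for s in p.data.shape))
                for p, g in zip(params, grads)]
        order = rng.permutation(len(flat))[:20]
        checked = 0
        h = 1e-4
        for k in order:
            p, g, idx = flat[k]
            orig = p.data[idx]
            p.data[idx] = orig + h
            fp = loss_value()
            p.data[idx] = orig - h
            fm = loss_value()
            p.data[idx] = orig
            fd = (fp - fm) / (2 * h)
            ad = g.data[idx]
            denom = max(abs(fd), abs(ad), 1e-6)
            assert abs(fd - ad) / denom <= 1e-3, (idx, fd, ad)
            checked += 1
        assert checked == 20
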