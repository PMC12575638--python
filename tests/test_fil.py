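"""Federated incremental learning: PIM, importance scoring, caching,
local training and the round loop."""

import numpy as np
import pytest

from ppfil import fil, linear
from ppfil.fil import (
    FILConfig,
    GlobalModel,
    MemoryBuffer,
    PIM,
    RoundContext,
    accumulate_importance,
    global_round,
    local_train,
    mixing_coefficient,
    pim_update,
    sample_gradient_norm,
    select_cache,
)


class TestMixingCoefficient:
    @pytest.mark.parametrize("lam,expected", [(0.5, 0.5), (0.2, 2.0), (0.9, 1 / 18)])
    def test_hand_values(self, lam, expected):
        assert mixing_coefficient(lam) == pytest.approx(expected)

    def test_pure_local_limit(self):
        assert mixing_coefficient(0.999999) == pytest.approx(0.0, abs=1e-5)

    def test_strictly_decreasing_on_unit_interval(self):
        grid = np.linspace(0.05, 0.95, 19)
        vals = [mixing_coefficient(l) for l in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("lam", [0.0, 1.0, -0.1, 1.5])
    def test_domain_enforced(self, lam):
        with pytest.raises(ValueError):
            mixing_coefficient(lam)


class TestPIMUpdate:
    def _scalarish(self):
        # 1 feature, 2 classes: small enough to reason about by hand
        spec = linear.LinearModelSpec(1, 2)
        return spec

    def test_contraction_toward_global_with_zero_data_gradient(self):
        # symmetric two-sample set (same x, both labels) has zero summed
        # data gradient at the symmetric parameter point v
        spec = self._scalarish()
        X = np.array([[1.0], [1.0]])
        y = np.array([0, 1])
        v0 = np.zeros(spec.n_params)
        w = np.full(spec.n_params, 2.0)
        pim = PIM(params=v0.copy(), lam=0.5, lr=0.1, iters=1)
        new, _ = pim_update(pim, w, X, y, spec, momentum=0.0)
        # one step: v' = v - eta*q*(v - w) = 0 - 0.1*0.5*(0-2) = 0.1
        assert np.allclose(new.params, 0.1)
        assert np.all(np.abs(new.params - w) < np.abs(v0 - w))

    def test_fixed_point_when_v_equals_w(self):
        spec = self._scalarish()
        X = np.array([[1.0], [1.0]])
        y = np.array([0, 1])
        w = np.zeros(spec.n_params)
        pim = PIM(params=w.copy(), lam=0.5, lr=0.1, iters=3)
        new, _ = pim_update(pim, w, X, y, spec, momentum=0.0)
        assert np.allclose(new.params, w)

    def test_lambda_near_one_reduces_to_local_descent(self, rng):
        spec = linear.LinearModelSpec(3, 2)
        X = rng.uniform(0, 1, (10, 3))
        y = rng.integers(0, 2, 10)
        w = rng.normal(0, 1, spec.n_params)
        v0 = rng.normal(0, 1, spec.n_params)
        near_one = PIM(params=v0.copy(), lam=1 - 1e-9, lr=0.01, iters=1)
        got, _ = pim_update(near_one, w, X, y, spec, momentum=0.0)
        expected = v0 - 0.01 * linear.grad(v0, X, y, spec, mean=False)
        assert np.allclose(got.params, expected, atol=1e-7)

    def test_empty_buffer_rejected(self):
        spec = self._scalarish()
        pim = PIM(params=np.zeros(spec.n_params), lam=0.5, lr=0.1, iters=1)
        with pytest.raises(ValueError):
            pim_update(pim, np.zeros(spec.n_params), np.empty((0, 1)), np.empty(0, int), spec)


class TestGradientNorm:
    def test_matches_central_difference_oracle(self, rng):
        spec = linear.LinearModelSpec(3, 2)
        w = rng.normal(0, 0.5, spec.n_params)
        pim = PIM(params=w, lam=0.5, lr=0.1, iters=1)
        x = rng.uniform(0, 1, 3)
        y = 1
        got = sample_gradient_norm(pim, spec, x, y)
        eps = 1e-5
        g_fd = np.empty(spec.n_params)
        for i in range(spec.n_params):
            e = np.zeros(spec.n_params)
            e[i] = eps
            up = linear.nll_loss(w + e, x[None], np.array([y]), spec)
            dn = linear.nll_loss(w - e, x[None], np.array([y]), spec)
            g_fd[i] = (up - dn) / (2 * eps)
        assert got == pytest.approx(float(g_fd @ g_fd), rel=1e-4)

    def test_zero_at_perfectly_fit_sample(self):
        spec = linear.LinearModelSpec(1, 2)
        w = np.array([-50.0, 50.0, -50.0, 50.0])  # class 1 certain for x>0
        pim = PIM(params=w, lam=0.5, lr=0.1, iters=1)
        assert sample_gradient_norm(pim, spec, np.array([1.0]), 1) < 1e-12

    def test_squared_norm_homogeneity(self, rng):
        spec = linear.LinearModelSpec(4, 2)
        w = rng.normal(0, 0.3, spec.n_params)
        X = rng.uniform(0, 1, (1, 4))
        y = np.array([0])
        base = linear.per_sample_sq_grad_norm(w, X, y, spec)[0]
        g = linear.grad(w, X, y, spec)
        assert float((2 * g) @ (2 * g)) == pytest.approx(4 * base, rel=1e-10)


class TestImportance:
    def test_hand_arithmetic(self):
        hist = np.array([[4.0], [2.0], [1.0]])
        assert accumulate_importance(hist)[0] == pytest.approx(4 + 1 + 1 / 3)

    def test_zero_history_gives_zero(self):
        assert accumulate_importance(np.zeros((5, 3))).tolist() == [0, 0, 0]

    def test_single_record_passthrough(self):
        assert accumulate_importance(np.array([[7.0, 3.0]])).tolist() == [7.0, 3.0]

    def test_matches_independent_recomputation(self, rng):
        hist = rng.uniform(0, 5, (6, 9))
        got = accumulate_importance(hist)
        expected = sum(hist[p] / (p + 1) for p in range(6))
        assert np.allclose(got, expected, atol=1e-8)


class TestCacheSelection:
    def test_top_k(self):
        X = np.arange(3)[:, None].astype(float)
        buf = select_cache(X, np.array([0, 1, 0]), np.array([5.0, 1.0, 3.0]), 2)
        assert sorted(buf.X.ravel().tolist()) == [0.0, 2.0]

    def test_no_eviction_when_capacity_suffices(self):
        X = np.arange(3)[:, None].astype(float)
        buf = select_cache(X, np.zeros(3, int), np.array([1.0, 2.0, 3.0]), 10)
        assert buf.size == 3

    def test_tie_breaks_toward_recent(self):
        X = np.arange(3)[:, None].astype(float)
        buf = select_cache(X, np.zeros(3, int), np.array([2.0, 1.0, 1.0]), 2)
        # indices 1 and 2 tie at the cut; the more recent (2) is kept
        assert sorted(buf.X.ravel().tolist()) == [0.0, 2.0]

    def test_capacity_never_exceeded(self, rng):
        for _ in range(5):
            n = int(rng.integers(1, 30))
            m = int(rng.integers(1, 10))
            buf = select_cache(
                rng.normal(size=(n, 2)), rng.integers(0, 2, n), rng.uniform(size=n), m
            )
            assert buf.size == min(n, m)


class TestLocalTraining:
    def _client(self, rng, spec, n=40):
        X = rng.uniform(0, 1, (n, spec.n_features))
        y = rng.integers(0, spec.n_classes, n)
        client = fil.ClientState(
            client_id=0, spec=spec, local_w=linear.init_params(spec),
            pim=PIM(linear.init_params(spec), 0.5, 1e-3, 10),
            buffer=MemoryBuffer(capacity=10),
        )
        client.receive_task(X, y)
        client.new_task = False
        return client

    def test_zero_learning_rate_is_identity(self, rng):
        spec = linear.LinearModelSpec(4, 2)
        client = self._client(rng, spec)
        cfg = FILConfig(lr=1e-12, local_epochs=2, seed=0)
        start = np.ones(spec.n_params)
        w = local_train(client, start, cfg)
        assert np.allclose(w, start, atol=1e-9)

    def test_loss_non_increasing_on_convex_objective(self, rng):
        spec = linear.LinearModelSpec(3, 2)
        X = np.vstack([rng.normal(0.2, 0.05, (30, 3)), rng.normal(0.8, 0.05, (30, 3))])
        y = np.repeat([0, 1], 30)
        client = fil.ClientState(
            client_id=0, spec=spec, local_w=linear.init_params(spec),
            pim=PIM(linear.init_params(spec), 0.5, 1e-3, 10),
            buffer=MemoryBuffer(capacity=10),
        )
        client.receive_task(X, y)
        client.new_task = False
        cfg = FILConfig(lr=0.01, local_epochs=1, momentum=0.0, batch_size=60, seed=0)
        w = linear.init_params(spec)
        losses = [linear.nll_loss(w, X, y, spec)]
        for _ in range(5):
            w = local_train(client, w, cfg)
            losses.append(linear.nll_loss(w, X, y, spec))
        assert all(a >= b - 1e-12 for a, b in zip(losses, losses[1:]))


class TestGlobalRound:
    def _clients(self, rng, spec, k, n=30):
        clients = []
        X = rng.uniform(0, 1, (n, spec.n_features))
        y = rng.integers(0, spec.n_classes, n)
        for cid in range(k):
            c = fil.ClientState(
                client_id=cid, spec=spec, local_w=linear.init_params(spec),
                pim=PIM(linear.init_params(spec), 0.5, 1e-3, 10),
                buffer=MemoryBuffer(capacity=10),
            )
            c.receive_task(X.copy(), y.copy())
            clients.append(c)
        return clients

    def test_single_client_aggregation_identity(self, rng):
        spec = linear.LinearModelSpec(3, 2)
        clients = self._clients(rng, spec, 1)
        gm = GlobalModel(linear.init_params(spec), 0, spec)
        cfg = FILConfig(seed=0, lr=0.05)
        out = global_round(clients, gm, cfg, RoundContext(use_filter=False, weight_mode="samples"))
        assert np.allclose(out.params, clients[0].local_w)

    def test_identical_clients_average_to_shared_result(self, rng):
        spec = linear.LinearModelSpec(3, 2)
        clients = self._clients(rng, spec, 4)
        gm = GlobalModel(linear.init_params(spec), 0, spec)
        cfg = FILConfig(seed=0, lr=0.05)
        out = global_round(clients, gm, cfg, RoundContext(use_filter=False, weight_mode="samples"))
        for c in clients[1:]:
            assert np.allclose(c.local_w, clients[0].local_w)
        assert np.allclose(out.params, clients[0].local_w)

    def test_parameter_length_conserved(self, rng):
        spec = linear.LinearModelSpec(5, 3)
        clients = self._clients(rng, spec, 3)
        gm = GlobalModel(linear.init_params(spec), 0, spec)
        out = global_round(clients, gm, FILConfig(seed=1, lr=0.05),
                           RoundContext(use_filter=False, weight_mode="samples"))
        assert out.params.shape == gm.params.shape
        assert out.round_index == 1

    def test_buffer_importance_matches_recomputation(self, rng):
        # after a task switch, buffer contents agree with an independent
        # recomputation of the accumulated weighted gradient norms
        spec = linear.LinearModelSpec(3, 2)
        cfg = FILConfig(seed=0, lr=0.05, cache_size=5)
        client = fil.ClientState(
            client_id=0, spec=spec, local_w=linear.init_params(spec),
            pim=PIM(linear.init_params(spec), cfg.lam, cfg.lr, cfg.pim_iters),
            buffer=MemoryBuffer(capacity=cfg.cache_size),
        )
        X1 = rng.uniform(0, 1, (20, 3))
        y1 = rng.integers(0, 2, 20)
        client.receive_task(X1, y1)
        gm = np.zeros(spec.n_params)
        fil.handle_new_task(client, gm, cfg)
        assert client.buffer.size == 5
        # recompute importance independently
        pim0 = PIM(np.zeros(spec.n_params), cfg.lam, cfg.lr, cfg.pim_iters)
        _, norms = pim_update(pim0, gm, X1, y1, spec, momentum=cfg.momentum)
        imp = accumulate_importance(norms)
        top = np.sort(np.argsort(-imp)[:5])
        kept_rows = {tuple(r) for r in client.buffer.X}
        assert kept_rows == {tuple(r) for r in X1[top]}
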