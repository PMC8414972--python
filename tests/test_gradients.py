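"""Exact spike-time derivatives against finite differences, masking, the
no-spike penalty, and per-partial clipping."""

import numpy as np
import pytest

from spikeae.gradients import backprop, d_spike_d_input, d_spike_d_weight
from spikeae.network import NetworkSpec, forward_pass, init_weights
from spikeae.spike_core import ModelParams, NO_SPIKE, simulate_neuron
from spikeae.training import TrainConfig

from _oracles import central_difference, random_instance


def _spiking_instances(n, seed, tangency_guard=1e-3):
    """Random instances that spike, away from threshold tangency."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        times, weights, tau, theta = random_instance(rng)
        params = ModelParams(tau, theta)
        sol = simulate_neuron(times, weights, params)
        if sol is None or abs(1.0 + sol.lambert_w) < tangency_guard:
            continue
        # causal structure must be stable under the finite-difference step
        if np.any(np.abs(np.asarray(times) - sol.time) < 1e-4):
            continue
        out.append((times, weights, params, sol))
    return out


class TestPartialDerivatives:
    def test_input_time_partial_matches_finite_differences(self):
        for times, weights, params, sol in _spiking_instances(100, seed=1):
            j = int(sol.causal_set[0])

            def spike_time(tj):
                t = np.array(times, dtype=float)
                t[j] = tj
                return simulate_neuron(t, weights, params).time

            numeric = central_difference(spike_time, times[j], 1e-6)
            analytic = d_spike_d_input(sol, times[j], weights[j], params=params)
            assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7)

    def test_weight_partial_matches_finite_differences(self):
        for times, weights, params, sol in _spiking_instances(100, seed=2):
            j = int(sol.causal_set[-1])

            def spike_time(wj):
                w = np.array(weights, dtype=float)
                w[j] = wj
                return simulate_neuron(times, w, params).time

            numeric = central_difference(spike_time, weights[j], 1e-6)
            analytic = d_spike_d_weight(sol, times[j], params=params)
            assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7)

    def test_single_input_time_partial_is_one(self):
        params = ModelParams(tau=0.7, theta=0.2)
        sol = simulate_neuron([0.3], [2.0], params)
        assert d_spike_d_input(sol, 0.3, 2.0, params=params) == pytest.approx(1.0, abs=1e-12)

    def test_causal_partials_sum_to_one(self):
        """Time-translation equivariance differentiates to sum(dt/dt_i) = 1."""
        for times, weights, params, sol in _spiking_instances(50, seed=3):
            total = sum(
                d_spike_d_input(sol, times[i], weights[i], params=params)
                for i in sol.causal_set
            )
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_more_weight_spikes_earlier(self):
        params = ModelParams(tau=1.0, theta=0.2)
        sol = simulate_neuron([0.0], [1.5], params)
        assert d_spike_d_weight(sol, 0.0, params=params) < 0

    def test_non_causal_input_rejected(self):
        params = ModelParams(tau=1.0, theta=0.2)
        sol = simulate_neuron([0.0, 5.0], [1.5, 1.0], params)
        assert sol.time < 5.0
        with pytest.raises(ValueError):
            d_spike_d_input(sol, 5.0, 1.0, params=params)


def _tiny_net(seed=0, clip=1e9, penalty=0.0):
    params = ModelParams(tau=1.0, theta=0.3)
    spec = NetworkSpec([4, 2, 4], 2, params)
    cfg = TrainConfig(
        latency=1.0,
        clip_derivative=clip,
        penalty_no_spike=penalty,
        epochs=1,
        seed=seed,
    )
    layers = init_weights(spec, 2.0, 2.0, seed=seed)
    for lp in layers:  # keep pulse times interior so +/- steps stay valid
        lp.pulse_times = lp.pulse_times * 0.8 + 0.1
    return spec, layers, cfg


def _loss_of(spec, layers, x, target, cfg):
    trace = forward_pass(spec, layers, x)
    loss, _ = backprop(trace, layers, target, cfg, spec.params)
    return loss


class TestBackprop:
    def _stable_setup(self):
        """A 4-2-4 net (2 pulses/layer) where every neuron spikes and no
        input time sits near a spike time (finite differences valid)."""
        for seed in range(50):
            spec, layers, cfg = _tiny_net(seed=seed)
            x = np.array([0.05, 0.25, 0.55, 0.85])
            target = x.copy()
            trace = forward_pass(spec, layers, x)
            if not all(np.all(s.spiked) for s in trace.solutions):
                continue
            stable = True
            for sol, inp in zip(trace.solutions, trace.layer_inputs):
                gaps = np.abs(inp[:, None] - sol.times[None, :])
                if np.any(gaps < 1e-4):
                    stable = False
                if np.any(np.abs(1.0 + sol.lambert_w[sol.spiked]) < 1e-3):
                    stable = False
            if stable:
                return spec, layers, cfg, x, target
        raise RuntimeError("no stable configuration found")

    def test_whole_network_gradient_check(self):
        """Analytic dL/dw and dL/d(pulse) match end-to-end finite differences."""
        spec, layers, cfg, x, target = self._stable_setup()
        trace = forward_pass(spec, layers, x)
        _, grads = backprop(trace, layers, target, cfg, spec.params)
        rng = np.random.default_rng(0)
        for k, lp in enumerate(layers):
            rows, cols = lp.weights.shape
            picks = {(int(rng.integers(rows)), int(rng.integers(cols))) for _ in range(6)}
            for i, j in picks:
                def f(v, i=i, j=j, k=k):
                    lp.weights[i, j] += v
                    try:
                        return _loss_of(spec, layers, x, target, cfg)
                    finally:
                        lp.weights[i, j] -= v
                numeric = (f(1e-6) - f(-1e-6)) / 2e-6
                assert grads.d_weights[k][i, j] == pytest.approx(
                    numeric, rel=1e-3, abs=1e-6
                )
            for p in range(lp.n_pulses):
                def g(v, p=p, k=k):
                    lp.pulse_times[p] += v
                    try:
                        return _loss_of(spec, layers, x, target, cfg)
                    finally:
                        lp.pulse_times[p] -= v
                numeric = (g(1e-6) - g(-1e-6)) / 2e-6
                assert grads.d_pulse_times[k][p] == pytest.approx(
                    numeric, rel=1e-3, abs=1e-6
                )

    def test_silent_output_receives_negative_penalty(self):
        """Every incoming weight of a never-spiking output neuron gets
        -penalty, the direction that amplifies the weights."""
        spec, layers, cfg0 = _tiny_net(penalty=7.0)
        cfg = cfg0
        # silence output neuron 0 by making its incoming weights negative
        layers[1].weights[:, 0] = -5.0
        x = np.array([0.05, 0.25, 0.55, 0.85])
        trace = forward_pass(spec, layers, x)
        assert not trace.solutions[1].spiked[0]
        _, grads = backprop(trace, layers, x, cfg, spec.params)
        np.testing.assert_allclose(grads.d_weights[1][:, 0], -7.0)

    def test_silent_hidden_neuron_only_penalised(self):
        spec, layers, cfg = _tiny_net(penalty=7.0)
        layers[0].weights[:, 1] = -5.0  # silence hidden neuron 1
        x = np.array([0.05, 0.25, 0.55, 0.85])
        trace = forward_pass(spec, layers, x)
        assert not trace.solutions[0].spiked[1]
        _, grads = backprop(trace, layers, x, cfg, spec.params)
        np.testing.assert_allclose(grads.d_weights[0][:, 1], -7.0)
        # and the dead neuron contributes nothing downstream: the decoder
        # column reading from it gets zero gradient through the chain rule
        assert np.all(grads.d_weights[1][1, :] == 0.0)

    def test_zero_residual_gives_zero_gradients(self):
        """Perfect reconstruction: loss 0, every gradient exactly 0."""
        spec, layers, cfg, x, _ = self._stable_setup()
        trace = forward_pass(spec, layers, x)
        target = trace.output_times - cfg.latency  # residual forced to zero
        loss, grads = backprop(trace, layers, target, cfg, spec.params)
        assert loss == 0.0
        assert all(np.all(g == 0.0) for g in grads.d_weights)
        assert all(np.all(g == 0.0) for g in grads.d_pulse_times)

    def test_non_causal_inputs_get_exactly_zero_gradient(self):
        spec, layers, cfg, x, target = self._stable_setup()
        trace = forward_pass(spec, layers, x)
        _, grads = backprop(trace, layers, x, cfg, spec.params)
        for k, (sol, inp) in enumerate(zip(trace.solutions, trace.layer_inputs)):
            non_causal = inp[:, None] >= sol.times[None, :]
            assert np.all(grads.d_weights[k][non_causal] == 0.0)
        # and the spike time itself is insensitive to such inputs
        sol0 = trace.solutions[0]
        late = np.flatnonzero(x >= np.max(sol0.times))
        if late.size:
            x2 = x.copy()
            x2[late[0]] += 1e-7
            trace2 = forward_pass(spec, layers, x2)
            assert np.array_equal(trace2.solutions[0].times, sol0.times)

    def test_partials_respect_clip_bound(self):
        """With a small clip, no per-partial magnitude can exceed it; a
        threshold-tangent instance saturates at exactly the bound."""
        from spikeae.gradients import _layer_partials
        from spikeae.spike_core import simulate_layer

        params = ModelParams(tau=1.0, theta=0.3)
        rng = np.random.default_rng(4)
        clip = 2.0
        in_times = rng.uniform(0, 1, size=6)
        weights = rng.normal(1.0, 1.0, size=(6, 5))
        sol = simulate_layer(in_times, weights, params)
        pt, pw, causal = _layer_partials(sol, in_times, weights, params.tau, clip)
        assert np.all(np.abs(pt) <= clip) and np.all(np.abs(pw) <= clip)
        # tangency: theta at the kernel peak makes the partial blow up
        params2 = ModelParams(tau=1.0, theta=float(np.exp(-1.0)))
        sol2 = simulate_layer(np.array([0.0]), np.array([[1.0]]), params2)
        pt2, pw2, _ = _layer_partials(
            sol2, np.array([0.0]), np.array([[1.0]]), params2.tau, clip
        )
        assert abs(pw2[0, 0]) == clip

    def test_length_mismatch_rejected(self):
        spec, layers, cfg, x, target = self._stable_setup()
        trace = forward_pass(spec, layers, x)
        with pytest.raises(ValueError):
            backprop(trace, layers, np.zeros(3), cfg, spec.params)
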