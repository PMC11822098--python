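"""Clustering controller: activation, competition, readout, recruitment,
gradients and the compression score."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cplearn import controller as C


def _state(centers, assoc, attention):
    return C.ClusterState(np.asarray(centers, float),
                          np.asarray(assoc, float),
                          np.asarray(attention, float))


def _random_state(rng, n_clusters=4):
    return _state(rng.uniform(0.05, 0.95, (n_clusters, 3)),
                  rng.normal(0, 1, (2, n_clusters)),
                  C.project_attention(rng.uniform(0.1, 1.0, 3)))


class TestActivation:
    def test_zero_distance_gives_unit_activation(self):
        state = _state([[0.2, 0.7, 0.4]], np.zeros((2, 1)), [1 / 3] * 3)
        h = C.cluster_activation([0.2, 0.7, 0.4], state, C.ControllerParams())
        assert h[0] == pytest.approx(1.0)

    def test_hand_evaluated_euclidean_case(self):
        # r=2, q=1, c=1, uniform attention, opposite cube corners:
        # exp(-(3 * 1/3)^(1/2)) = exp(-1)
        params = C.ControllerParams(c=1.0, r=2.0, q=1.0)
        state = _state([[0, 0, 0]], np.zeros((2, 1)), [1 / 3] * 3)
        h = C.cluster_activation([1, 1, 1], state, params)
        assert h[0] == pytest.approx(np.exp(-1.0))

    def test_attention_masks_off_dimensions(self):
        params = C.ControllerParams()
        state = _state([[0, 0.5, 0.5]], np.zeros((2, 1)), [1.0, 0.0, 0.0])
        h1 = C.cluster_activation([0.3, 0.0, 0.9], state, params)
        h2 = C.cluster_activation([0.3, 1.0, 0.1], state, params)
        assert h1[0] == pytest.approx(h2[0])

    def test_empty_cluster_set_rejected(self):
        with pytest.raises(ValueError):
            C.cluster_activation([0, 0, 0], C.ClusterState(),
                                 C.ControllerParams())


class TestCompetitionAndReadout:
    def test_single_cluster_passthrough(self):
        _, out = C.compete(np.array([0.7]), t=5.0)
        assert out[0] == pytest.approx(0.7)
        _, out = C.readout(np.array([0.7]), u=5.0)
        assert out[0] == pytest.approx(0.7)

    def test_two_equal_activations_halved(self):
        _, out = C.compete(np.array([0.6, 0.6]), t=3.0)
        np.testing.assert_allclose(out, [0.3, 0.3])

    def test_never_amplifies_and_preserves_order(self, rng):
        for _ in range(50):
            h = rng.uniform(0, 1, rng.integers(2, 9))
            _, c = C.compete(h, t=rng.uniform(0, 20))
            _, o = C.readout(c, u=rng.uniform(0, 20))
            assert np.all(c <= h + 1e-12)
            assert np.all(o <= c + 1e-12)
            assert np.array_equal(np.argsort(h), np.argsort(c, kind="stable"))

    def test_u_zero_scales_uniformly(self):
        h = np.array([0.2, 0.5, 0.9])
        _, out = C.readout(h, u=0.0)
        np.testing.assert_allclose(out, h / 3)

    def test_wta_limit_matches_argmax_on_1000_random_vectors(self, rng):
        """u = 1e6 readout concentrates all output on the maximal cluster."""
        for _ in range(1000):
            h = rng.uniform(0, 1, rng.integers(2, 9))
            if np.min(np.diff(np.sort(h))) < 1e-4:   # exclude near-ties
                continue
            _, out = C.readout(h, u=1e6)
            winner = int(np.argmax(h))
            assert int(np.argmax(out)) == winner
            assert out[winner] == pytest.approx(h[winner], rel=1e-9)
            mask = np.ones_like(h, bool)
            mask[winner] = False
            assert np.all(out[mask] < 1e-9)


class TestOutputAndResponse:
    def test_zero_weights_give_zero_output_and_uniform_response(self):
        out = C.output_activation(np.array([0.5, 0.2]), np.zeros((2, 2)))
        np.testing.assert_allclose(out, 0.0)
        p = C.response_probability(out, d=3.0)
        np.testing.assert_allclose(p, [0.5, 0.5])

    def test_hand_evaluated_cases(self):
        out = C.output_activation(np.array([0.5]), np.array([[1.0], [-1.0]]))
        np.testing.assert_allclose(out, [0.5, -0.5])
        p = C.response_probability(np.array([1.0, 0.0]), d=1.0)
        assert p[0] == pytest.approx(np.e / (np.e + 1))

    def test_linearity_and_d_zero(self):
        w = np.array([[0.3, -1.2], [0.7, 0.4]])
        h = np.array([0.2, 0.9])
        np.testing.assert_allclose(C.output_activation(2 * h, w),
                                   2 * C.output_activation(h, w))
        np.testing.assert_allclose(
            C.response_probability(np.array([5.0, -3.0]), d=0.0), [0.5, 0.5])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            C.output_activation(np.array([0.5, 0.2, 0.1]), np.zeros((2, 2)))


class TestSupportAndRecruitment:
    @pytest.mark.parametrize("wc,wi,expected", [
        (1.0, 0.0, 1.0), (0.0, 0.0, 0.0), (1.0, 1.0, 0.0),
        (0.0, 1.0, -1.0), (-1.0, 1.0, -1.0), (0.5, -0.5, 1.0)])
    def test_support_values(self, wc, wi, expected):
        assoc = np.array([[wc], [wi]])
        assert C.cluster_support(assoc, 0)[0] == pytest.approx(expected)

    def test_total_support_weighted_mean(self):
        assert C.total_support([1.0, -1.0], [0.5, 0.5]) == pytest.approx(0.0)
        assert C.total_support([0.8], [0.1]) == pytest.approx(0.8)
        with pytest.raises(ValueError):
            C.total_support([1.0], [0.0])

    @given(st.integers(1, 8), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_total_support_bounded_under_fuzzing(self, n, seed):
        r = np.random.default_rng(seed)
        supports = C.cluster_support(r.normal(0, 2, (2, n)), int(r.integers(2)))
        h = r.uniform(1e-6, 1, n)
        ts = C.total_support(supports, h)
        assert -1.0 <= ts <= 1.0
        assert np.all(supports >= -1.0) and np.all(supports <= 1.0)

    def test_first_trial_always_recruits_on_stimulus(self):
        state, recruited = C.maybe_recruit(
            C.ClusterState(), [0.1, 0.9, 0.4], 1, C.ControllerParams())
        assert recruited and state.n_clusters == 1
        np.testing.assert_allclose(state.centers[0], [0.1, 0.9, 0.4])
        np.testing.assert_allclose(state.assoc, 0.0)

    def test_high_support_blocks_recruitment(self):
        params = C.ControllerParams(recruit_threshold=0.5)
        state = _state([[0.1, 0.9, 0.4]], [[1.0], [0.0]], [1 / 3] * 3)
        new, recruited = C.maybe_recruit(state, [0.1, 0.9, 0.4], 0, params)
        assert not recruited and new.n_clusters == 1

    def test_threshold_above_max_forces_recruitment_up_to_duplicates(self):
        from cplearn.stimuli import ALL_STIMULI, make_problem
        params = C.ControllerParams(recruit_threshold=1.01)
        problem = make_problem("VI")
        state = C.ClusterState()
        for _ in range(3):          # revisit the set three times
            for s in ALL_STIMULI:
                state, _ = C.maybe_recruit(state, s, problem.label_of(s),
                                           params)
        assert state.n_clusters == 8   # duplicate-center guard caps growth

    def test_guard_off_allows_duplicates(self):
        params = C.ControllerParams(recruit_threshold=1.01,
                                    duplicate_center_guard=False)
        state = C.ClusterState()
        for _ in range(3):
            state, rec = C.maybe_recruit(state, [0.0, 0.0, 0.0], 0, params)
            assert rec
        assert state.n_clusters == 3

    def test_single_cluster_reduces_to_wta_rule(self, rng):
        """With one cluster the decision matches that cluster's own support."""
        params = C.ControllerParams(recruit_threshold=0.0,
                                    duplicate_center_guard=False)
        for _ in range(25):
            state = _random_state(rng, n_clusters=1)
            label = int(rng.integers(2))
            support = C.cluster_support(state.assoc, label)[0]
            _, recruited = C.maybe_recruit(state, rng.uniform(0, 1, 3),
                                           label, params)
            assert recruited == (support < params.recruit_threshold)


class TestLossAndGradients:
    def test_exact_prediction_gives_zero_cross_entropy(self):
        params = C.ControllerParams(gamma=0.0)
        y = np.array([1.0, 0.0])
        assert C.controller_loss(y, y, np.array([1 / 3] * 3), params) == \
            pytest.approx(0.0, abs=1e-9)

    def test_gamma_zero_is_pure_cross_entropy(self):
        params = C.ControllerParams(gamma=0.0)
        p = np.array([0.7, 0.3])
        y = np.array([1.0, 0.0])
        expected = -np.mean([np.log(0.7), np.log(0.7)])
        assert C.controller_loss(p, y, np.array([0.9, 0.1, 0.0]), params) == \
            pytest.approx(expected)

    def test_positive_gamma_penalizes_entropy(self):
        params = C.ControllerParams(gamma=0.5)
        p = np.array([0.5, 0.5])
        y = np.array([1.0, 0.0])
        uniform = C.controller_loss(p, y, np.array([1 / 3] * 3), params)
        peaked = C.controller_loss(p, y, np.array([0.98, 0.01, 0.01]), params)
        assert peaked < uniform

    def test_gradients_match_finite_differences(self, rng):
        """Analytic gradients of the full loss vs central differences."""
        params = C.ControllerParams(c=2.0, t=4.0, u=6.0, d=3.0, gamma=0.05)
        state = _random_state(rng)
        stim = rng.uniform(0.05, 0.95, 3)
        y = np.array([0.0, 1.0])
        grads = C.loss_gradients(stim, state, params, y)

        def loss(centers, assoc, attention):
            st = C.ClusterState(centers, assoc, attention)
            out = C.forward(stim, st, params)
            return C.controller_loss(out.p, y, attention, params)

        h = 1e-6
        for name in ("centers", "assoc", "attention"):
            arr = getattr(state, {"centers": "centers", "assoc": "assoc",
                                  "attention": "attention"}[name])
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                up, dn = arr.copy(), arr.copy()
                up[i] += h
                dn[i] -= h
                args = {"centers": state.centers, "assoc": state.assoc,
                        "attention": state.attention}
                args[name] = up
                f_up = loss(**args)
                args[name] = dn
                f_dn = loss(**args)
                num[i] = (f_up - f_dn) / (2 * h)
            rel = np.abs(num - grads[name]) / (np.abs(num) + 1e-8)
            assert rel.max() < 1e-5, name

    def test_batch_forward_and_input_gradient_match_scalar_path(self, rng):
        params = C.ControllerParams(c=2.0, t=4.0, u=6.0, d=3.0)
        state = _random_state(rng)
        stims = rng.uniform(0.05, 0.95, (5, 3))
        cache = C.forward_batch(stims, state, params)
        for i, s in enumerate(stims):
            out = C.forward(s, state, params)
            np.testing.assert_allclose(cache["H_out"][i], out.H_out,
                                       rtol=1e-12)
        y = np.array([1.0, 0.0])
        g_scalar = np.stack([
            C.loss_gradients(s, state, params, y,
                             include_entropy=False)["stimulus"]
            for s in stims])
        # same upstream gradient, routed through the batched path
        upstream = np.stack([
            state.assoc.T @ _output_grad(C.forward(s, state, params), params, y)
            for s in stims])
        g_batch = C.input_gradient_batch(upstream, cache, state, params)
        np.testing.assert_allclose(g_batch, g_scalar, rtol=1e-9, atol=1e-12)

    def test_zero_learning_rates_leave_state_unchanged(self, rng):
        params = C.ControllerParams(lr_centers=0, lr_attention=0, lr_assoc=0)
        state = _random_state(rng)
        new = C.update_controller(state, rng.uniform(0, 1, 3), 0, params)
        np.testing.assert_allclose(new.centers, state.centers)
        np.testing.assert_allclose(new.assoc, state.assoc)
        np.testing.assert_allclose(new.attention, state.attention)

    def test_repeated_training_converges_to_label(self, rng):
        params = C.ControllerParams()
        stim = np.array([0.1, 0.8, 0.3])
        state, _ = C.maybe_recruit(C.ClusterState(), stim, 1, params)
        for _ in range(200):
            state = C.update_controller(state, stim, 1, params)
        p = C.forward(stim, state, params).p
        assert p[1] > 0.9

    def test_attention_selectivity_emerges_on_one_dimensional_task(self):
        """Entropy-regularized descent on a single-relevant-dimension task
        concentrates attention on that dimension."""
        from cplearn.stimuli import ALL_STIMULI, make_problem, generate_sequence
        params = C.ControllerParams(gamma=0.05)
        problem = make_problem("I")
        seq = generate_sequence(problem, seed=2, n_repetitions=12)
        state = C.ClusterState()
        for s, lab in zip(seq.stimuli, seq.labels):
            state, _ = C.maybe_recruit(state, s, int(lab), params)
            state = C.update_controller(state, s, int(lab), params)
        assert state.attention[0] > 1 / 3
        assert state.attention[0] == state.attention.max()

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_simplex_invariants_under_random_updates(self, seed):
        r = np.random.default_rng(seed)
        params = C.ControllerParams(
            lr_attention=float(r.uniform(0.01, 0.5)),
            lr_assoc=float(r.uniform(0.01, 1.0)))
        state = _random_state(r, n_clusters=int(r.integers(1, 7)))
        for _ in range(5):
            stim = r.uniform(0, 1, 3)
            label = int(r.integers(2))
            state, _ = C.maybe_recruit(state, stim, label, params)
            state = C.update_controller(state, stim, label, params)
            out = C.forward(stim, state, params)
            assert np.all(state.attention >= 0)
            assert state.attention.sum() == pytest.approx(1.0)
            assert np.all(out.H_act > 0) and np.all(out.H_act <= 1.0)
            assert np.all(out.p >= 0)
            assert out.p.sum() == pytest.approx(1.0)


def _output_grad(out, params, y):
    """dL/dC for the mean binary cross-entropy, for the batch-path test."""
    p = np.clip(out.p, 1e-12, 1 - 1e-12)
    dL_dp = -(y / p - (1 - y) / (1 - p)) / len(p)
    inner = (dL_dp * out.p).sum()
    return params.d * out.p * (dL_dp - inner)


class TestSerializationAndCompression:
    def test_state_json_round_trip(self, rng):
        state = _random_state(rng)
        back = C.ClusterState.from_json(state.to_json())
        np.testing.assert_allclose(back.centers, state.centers)
        np.testing.assert_allclose(back.assoc, state.assoc)
        np.testing.assert_allclose(back.attention, state.attention)

    @pytest.mark.parametrize("alpha,expected", [
        ([1 / 3, 1 / 3, 1 / 3], 0.0),
        ([1.0, 0.0, 0.0], 1.0),
        ([0.5, 0.5, 0.0], 1.0 - 1.0 / np.log2(3)),
    ])
    def test_compression_closed_forms(self, alpha, expected):
        assert C.compression(np.array(alpha)) == pytest.approx(expected,
                                                               abs=1e-9)
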