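import math

import numpy as np
import pytest
from scipy.stats import kstest

from deerlaterate.forward import (
    BackgroundModel,
    broaden,
    compose_trace,
    default_grid,
    distance_distribution,
    form_factor,
)
from deerlaterate.multilateration import (
    AnnealConfig,
    CoordinateModel,
    aicc,
    confidence_bands,
    log_likelihood,
    metropolis_accept,
    model_pair_distribution,
    predict_heldout,
    propose_move,
    run_replica,
    run_replicas,
    undo_move,
    _pair_sigma,
)
from deerlaterate.trace_io import DeerTrace


class TestAicc:
    def test_worked_example(self):
        assert aicc(0.0, 1, 100) == pytest.approx(2 + 4 / 98, abs=1e-12)

    def test_monotone_in_likelihood(self):
        assert aicc(-5.0, 10, 500) > aicc(-4.0, 10, 500)

    def test_large_sample_limit(self):
        assert aicc(-3.0, 4, 10**9) == pytest.approx(-2 * -3.0 + 8, abs=1e-6)

    def test_undefined_correction_rejected(self):
        with pytest.raises(ValueError):
            aicc(0.0, 99, 100)


def _planted_as_model(fixture):
    return fixture.planted


class TestLogLikelihood:
    def test_perfect_fit_hits_floor(self, small_fixture):
        # noiseless traces re-synthesized from the planted model itself
        model = _planted_as_model(small_fixture)
        noiseless = []
        for tr in small_fixture.traces:
            cu = model.clouds[tr.residue_u]
            cv = model.clouds[tr.residue_v]
            dist = broaden(distance_distribution(cu, cv), _pair_sigma(cu, cv))
            v = form_factor(dist, tr.time_us)
            y = compose_trace(v, model.backgrounds[tr.trace_id], tr.time_us)
            noiseless.append(
                DeerTrace(tr.trace_id, tr.residue_u, tr.residue_v,
                          tr.time_us, y, noise_sigma=0.01)
            )
        n = sum(t.n_points for t in noiseless)
        lnl = log_likelihood(model, noiseless)
        assert lnl == pytest.approx(-0.5 * n * math.log(1e-12), rel=1e-9)

    def test_noise_scaling_shifts_likelihood_analytically(self, small_network, small_model):
        # doubling every sigma divides the mean normalized SSR by 4, so
        # lnL must rise by exactly (n/2) ln 4; when the mean equals 1 the
        # log-likelihood is exactly zero by the same formula
        traces = small_network.traces
        n = sum(t.n_points for t in traces)
        base = log_likelihood(small_model, traces)
        doubled = [
            DeerTrace(t.trace_id, t.residue_u, t.residue_v, t.time_us, t.real,
                      t.imag, noise_sigma=2 * t.noise_sigma)
            for t in traces
        ]
        assert log_likelihood(small_model, doubled) == pytest.approx(
            base + 0.5 * n * math.log(4.0), rel=1e-9
        )

    def test_matches_brute_force(self, small_fixture, small_network, small_model):
        traces = small_network.traces
        ssr = 0.0
        n = 0
        for tr in traces:
            cu = small_model.clouds[tr.residue_u]
            cv = small_model.clouds[tr.residue_v]
            dist = broaden(distance_distribution(cu, cv), _pair_sigma(cu, cv))
            v = form_factor(dist, tr.time_us)
            y = compose_trace(v, small_model.backgrounds[tr.trace_id], tr.time_us)
            for i in range(tr.n_points):  # explicit double loop
                ssr += ((tr.real[i] - y[i]) / tr.noise_sigma) ** 2
            n += tr.n_points
        expected = -0.5 * n * math.log(max(ssr / n, 1e-12))
        assert log_likelihood(small_model, traces) == pytest.approx(expected, rel=1e-9)

    def test_engine_and_reference_path_agree(self, small_network, small_model):
        assert small_model.log_likelihood == pytest.approx(
            log_likelihood(small_model, small_network.traces), rel=1e-6
        )

    def test_aicc_reproducible_from_parts(self, small_network, small_model):
        assert small_model.aicc == pytest.approx(
            aicc(small_model.log_likelihood, small_model.k_params,
                 small_network.n_total),
            rel=1e-12,
        )


class TestProposeMove:
    def test_clipping_and_undo(self, small_fixture, rng):
        model = CoordinateModel(
            clouds={rid: c.with_weights(np.full(c.n_positions, 0.05))
                    for rid, c in small_fixture.clouds.items()},
            backgrounds={},
        )
        before = {rid: c.weights.copy() for rid, c in model.clouds.items()}
        for _ in range(200):
            _, undo = propose_move(model, 0.5, rng)
            rid, local, _old = undo
            assert model.clouds[rid].weights[local] >= 0.0  # clipped at zero
            undo_move(model, undo)
        for rid in before:
            np.testing.assert_array_equal(model.clouds[rid].weights, before[rid])

    def test_never_empties_a_residue(self, small_fixture, rng):
        model = CoordinateModel(
            clouds={rid: c.with_weights(
                np.eye(c.n_positions)[0] * 0.01)
                for rid, c in small_fixture.clouds.items()},
            backgrounds={},
        )
        for _ in range(500):
            propose_move(model, 0.05, rng)
            for rid, cloud in model.clouds.items():
                assert cloud.weights.sum() > 0.0

    def test_draw_distribution_uniform(self, small_fixture):
        rng = np.random.default_rng(7)
        model = CoordinateModel(
            clouds={rid: c.with_weights(np.full(c.n_positions, 100.0))
                    for rid, c in small_fixture.clouds.items()},
            backgrounds={},
        )
        mag = 0.1
        deltas = []
        for _ in range(10**5):
            _, undo = propose_move(model, mag, rng)
            rid, local, old = undo
            deltas.append(model.clouds[rid].weights[local] - old)
            undo_move(model, undo)
        stat = kstest(np.asarray(deltas), "uniform", args=(-mag, 2 * mag))
        assert stat.pvalue > 0.01


class TestMetropolis:
    def test_boundary_always_accepts(self, rng):
        assert all(metropolis_accept(-5.0, -5.0, 1.5, rng) for _ in range(100))
        assert all(metropolis_accept(-4.0, -5.0, 1.5, rng) for _ in range(100))

    def test_acceptance_frequency_at_minus_kt(self):
        rng = np.random.default_rng(123)
        kt = 1.5
        n = 10**5
        acc = sum(metropolis_accept(-1.0 - kt, -1.0, kt, rng) for _ in range(n))
        assert acc / n == pytest.approx(math.exp(-1.0), rel=0.01)

    def test_quench_limit(self, rng):
        assert not any(
            metropolis_accept(-1.001, -1.0, 1e-12, rng) for _ in range(1000)
        )


class TestRunReplica:
    def test_deterministic_under_fixed_seed(self, small_network, small_model):
        again = run_replica(small_network, AnnealConfig(seed=small_model.seed))
        for rid in small_model.clouds:
            np.testing.assert_array_equal(
                again.clouds[rid].weights, small_model.clouds[rid].weights
            )
        assert again.log_likelihood == small_model.log_likelihood
        assert again.aicc == small_model.aicc

    def test_descent_property(self, small_network):
        for seed in range(5):
            m = run_replica(small_network, AnnealConfig(seed=seed))
            assert m.ssr_final <= m.ssr_initial

    def test_pure_quench_never_worsens(self, small_network):
        # kT effectively zero from the first trial: strictly greedy descent
        m = run_replica(
            small_network, AnnealConfig(seed=3, kT_init=1e-9, max_rounds=2)
        )
        assert m.ssr_final <= m.ssr_initial

    def test_round_log_tracks_best_ssr_monotonically(self, small_model):
        log = small_model.round_ssr
        assert len(log) == small_model.n_rounds
        assert all(b <= a + 1e-9 for a, b in zip(log, log[1:]))

    def test_every_residue_keeps_weight(self, small_network, small_model):
        for cloud in small_model.clouds.values():
            assert cloud.weights.sum() > 0.0
            assert np.all(cloud.weights >= 0.0)

    def test_planted_solution_recovered(self, small_fixture, small_network, small_model):
        planted = small_fixture.planted_positions()
        for rid, cloud in small_model.clouds.items():
            assert np.linalg.norm(cloud.centroid() - planted[rid]) < 2.0


class TestRunReplicas:
    def test_single_replica(self, small_network):
        models = run_replicas(small_network, 1, base_seed=5)
        assert len(models) == 1

    def test_ranked_by_aicc(self, small_models):
        vals = [m.aicc for m in small_models]
        assert vals == sorted(vals)
        assert {m.seed for m in small_models} == {40, 41, 42, 43, 44, 45}


class TestOutputs:
    def test_confidence_bands_degenerate(self, small_network, small_model):
        tr = small_network.traces[0]
        pair = (tr.residue_u, tr.residue_v)
        single = confidence_bands([small_model], pair, n_top=1)
        direct = model_pair_distribution(small_model, pair)
        np.testing.assert_allclose(single.probabilities, direct.probabilities, atol=1e-12)
        np.testing.assert_allclose(single.band_lo, direct.probabilities, atol=1e-12)
        np.testing.assert_allclose(single.band_hi, direct.probabilities, atol=1e-12)

    def test_confidence_bands_match_percentiles(self, small_network, small_models):
        models = small_models
        tr = small_network.traces[1]
        pair = (tr.residue_u, tr.residue_v)
        bands = confidence_bands(models, pair, n_top=5)
        stack = np.array(
            [model_pair_distribution(m, pair).probabilities for m in models[:5]]
        )
        np.testing.assert_allclose(bands.band_lo, np.percentile(stack, 2.5, axis=0))
        np.testing.assert_allclose(bands.band_hi, np.percentile(stack, 97.5, axis=0))
        np.testing.assert_allclose(
            bands.probabilities, stack.mean(axis=0) / stack.mean(axis=0).sum()
        )

    def test_confidence_bands_requires_enough_models(self, small_network, small_model):
        tr = small_network.traces[0]
        with pytest.raises(ValueError):
            confidence_bands([small_model], (tr.residue_u, tr.residue_v), n_top=5)

    def test_heldout_prediction_near_planted_distance(self, small_fixture, small_model):
        # the (12, 4) pair is not a trace in the small fixture network
        planted = small_fixture.planted_positions()
        u, v = ("A", 12), ("A", 4)
        dist = predict_heldout(small_model, (u, v))
        true_d = float(np.linalg.norm(planted[u] - planted[v]))
        assert dist.mean() == pytest.approx(true_d, abs=2.0)

    def test_heldout_requires_refined_clouds(self, small_model):
        with pytest.raises(ValueError):
            predict_heldout(small_model, (("Z", 1), ("A", 4)))

    def test_prediction_local_to_the_two_clouds(self, small_model):
        pair = (("A", 4), ("A", 20))
        full = predict_heldout(small_model, pair)
        trimmed = CoordinateModel(
            clouds={rid: small_model.clouds[rid] for rid in pair},
            backgrounds={},
        )
        np.testing.assert_array_equal(
            full.probabilities, predict_heldout(trimmed, pair).probabilities
        )
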