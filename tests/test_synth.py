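"""Synthetic benchmark generator: integration accuracy, embedding, Poisson law."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import chisquare

from flownode.synth import (ARNEODO_PARAMS, ChaoticSystemSpec, EmbeddingSpec,
                            analytic_fixed_points, arneodo_field,
                            continuous_jacobian, discrete_update_map,
                            embed_latents, generate_dataset, integrate_system,
                            load_dataset, make_embedding, sample_spikes,
                            save_dataset, split_dataset, vector_field)


def test_rk4_trajectories_match_adaptive_reference():
    """70-step fixed-step RK4 segments agree with a high-accuracy adaptive
    integrator started from the same on-attractor state."""
    spec = ChaoticSystemSpec(burn_in_steps=200)
    Z = integrate_system(spec, n_traj=3, T=70, seed=0)
    f = arneodo_field(spec.params)
    for traj in Z:
        sol = solve_ivp(lambda t, s: f(np.asarray(s)), (0.0, 69 * spec.dt), traj[0],
                        t_eval=np.arange(70) * spec.dt, rtol=1e-11, atol=1e-11)
        # chaotic divergence amplifies truncation error ~e^(0.26 t); keep a
        # tolerance consistent with RK4 local error at dt=0.07 over 4.9 units
        assert np.abs(sol.y.T - traj).max() < 1e-3


def test_trajectories_bounded_and_on_attractor():
    spec = ChaoticSystemSpec()
    Z = integrate_system(spec, n_traj=8, T=70, seed=1)
    assert np.isfinite(Z).all()
    assert np.abs(Z).max() < 20.0


def test_zero_field_trajectory_constant():
    spec = ChaoticSystemSpec(name="zero", params={}, burn_in_steps=5)
    Z = integrate_system(spec, n_traj=2, T=10, seed=0)
    assert np.allclose(Z, Z[:, :1, :])


def test_integration_deterministic_given_seed():
    spec = ChaoticSystemSpec(burn_in_steps=100)
    A = integrate_system(spec, 4, 30, seed=7)
    B = integrate_system(spec, 4, 30, seed=7)
    assert np.array_equal(A, B)
    C = integrate_system(spec, 4, 30, seed=8)
    assert not np.allclose(A, C)


def test_unknown_system_rejected():
    with pytest.raises(ValueError):
        ChaoticSystemSpec(name="lorenz96")


def test_analytic_fixed_points_are_roots_of_field():
    spec = ChaoticSystemSpec()
    fps = analytic_fixed_points(spec)
    assert fps.shape == (3, 3)
    f = vector_field(spec)
    assert np.abs(f(fps)).max() < 1e-12
    a, d = ARNEODO_PARAMS["a"], ARNEODO_PARAMS["d"]
    assert np.allclose(sorted(fps[:, 0]), [-np.sqrt(a / d), 0.0, np.sqrt(a / d)])


def test_continuous_jacobian_matches_finite_differences():
    spec = ChaoticSystemSpec()
    f = vector_field(spec)
    p = np.array([0.7, -0.3, 1.1])
    J = continuous_jacobian(spec, p)
    eps = 1e-6
    for j in range(3):
        dp = np.zeros(3)
        dp[j] = eps
        col = (f(p + dp) - f(p - dp)) / (2 * eps)
        assert np.allclose(J[:, j], col, atol=1e-6)


def test_make_embedding_ranges_and_scales():
    emb = make_embedding(3, 12, seed=0)
    assert emb.encoding_matrix.shape == (3, 12)
    assert emb.encoding_matrix.min() >= -0.5 and emb.encoding_matrix.max() <= 0.5
    assert len(emb.sigmoid_scales) == 12
    assert np.isclose(emb.sigmoid_scales[0], 10 ** 0.2)
    assert np.isclose(emb.sigmoid_scales[-1], 10.0)
    # even spacing on the log scale
    assert np.allclose(np.diff(np.log10(emb.sigmoid_scales)),
                       np.diff(np.log10(emb.sigmoid_scales))[0])


def test_make_embedding_single_neuron_gets_range_start():
    emb = make_embedding(3, 1, seed=0)
    assert np.allclose(emb.sigmoid_scales, [10 ** 0.2])


def test_embedding_seeds_differ():
    a = make_embedding(3, 5, seed=1).encoding_matrix
    b = make_embedding(3, 5, seed=2).encoding_matrix
    assert not np.allclose(a, b)


def test_standardization_and_sigmoid_rates():
    spec = ChaoticSystemSpec(burn_in_steps=200)
    Z = integrate_system(spec, 20, 70, seed=3)
    emb = make_embedding(3, 12, seed=3, rate_scale=2.0)
    act, Y = embed_latents(Z, emb)
    flat = act.reshape(-1, 12)
    assert np.abs(flat.mean(axis=0)).max() < 1e-9
    assert np.abs(flat.std(axis=0) - 1.0).max() < 1e-6
    assert Y.min() >= 0.0 and Y.max() <= 2.0
    # activation 0 -> rate at half the ceiling, for every scale
    mid = emb.rate_scale / (1.0 + np.exp(-emb.sigmoid_scales * 0.0))
    assert np.allclose(mid, 1.0)


def test_large_scale_sigmoid_approaches_step():
    """At s=10 the sigmoid at a = +/-0.1 is within sigmoid(1) of the rails."""
    emb = EmbeddingSpec(encoding_matrix=np.eye(3), activation="scaled_sigmoid",
                        sigmoid_scales=np.array([10.0, 10.0, 10.0]), rate_scale=1.0)
    hi = emb.activation_curve(0, np.array([0.1]))[0]
    lo = emb.activation_curve(0, np.array([-0.1]))[0]
    expected_hi = 1.0 / (1.0 + np.exp(-1.0))
    assert np.isclose(hi, expected_hi)
    assert np.isclose(lo, 1.0 - expected_hi)


def test_lin_exp_embedding_log_linear():
    spec = ChaoticSystemSpec(burn_in_steps=200)
    Z = integrate_system(spec, 10, 70, seed=4)
    emb = make_embedding(3, 6, activation="lin_exp", seed=4, rate_scale=1.0)
    act, Y = embed_latents(Z, emb)
    # log-rates are affine in the standardized activations (slope 1)
    assert np.allclose(np.log(Y), act + np.log(0.5))


def test_sample_spikes_moments_and_poisson_gof():
    """Constant rate 5 over 1e5 bins: mean/variance near 5, chi-square GOF passes."""
    Y = np.full((1, 100_000, 1), 5.0)
    X = sample_spikes(Y, seed=0).ravel()
    assert 4.95 < X.mean() < 5.05
    assert 4.9 < X.var() < 5.1
    from scipy.stats import poisson
    kmax = 15
    obs = np.bincount(np.minimum(X, kmax), minlength=kmax + 1)
    probs = poisson.pmf(np.arange(kmax + 1), 5.0)
    probs[kmax] = 1.0 - probs[:kmax].sum()
    _, p = chisquare(obs, probs * X.size, ddof=0)
    assert p > 0.01


def test_sample_spikes_trivial_cases():
    assert np.all(sample_spikes(np.zeros((2, 3, 4)), seed=0) == 0)
    Y = np.random.default_rng(0).uniform(0, 2, size=(3, 4, 5))
    assert np.array_equal(sample_spikes(Y, seed=5), sample_spikes(Y, seed=5))
    with pytest.raises(ValueError):
        sample_spikes(-np.ones((2, 2)), seed=0)


def test_split_dataset_proportions_and_determinism():
    X = np.zeros((100, 70, 12), dtype=int)
    ds = split_dataset(X, 0.8, seed=0)
    assert len(ds.train_idx) == 80 and len(ds.valid_idx) == 20
    assert len(np.intersect1d(ds.train_idx, ds.valid_idx)) == 0
    assert len(np.union1d(ds.train_idx, ds.valid_idx)) == 100
    ds2 = split_dataset(X, 0.8, seed=0)
    assert np.array_equal(ds.train_idx, ds2.train_idx)
    tiny = split_dataset(np.zeros((2, 5, 3), dtype=int), 0.5, seed=0)
    assert len(tiny.train_idx) == 1 and len(tiny.valid_idx) == 1
    with pytest.raises(ValueError):
        split_dataset(np.zeros((1, 5, 3), dtype=int), 0.8, seed=0)


def test_generate_dataset_deterministic_and_rate_bounded():
    ds1 = generate_dataset(n_trials=10, seed=11)
    ds2 = generate_dataset(n_trials=10, seed=11)
    assert np.array_equal(ds1.X, ds2.X)
    assert np.array_equal(ds1.ground_truth.Z, ds2.ground_truth.Z)
    gt = ds1.ground_truth
    assert gt.Y.min() >= 0.0
    assert gt.Y.max() <= gt.embedding.rate_scale
    assert gt.X.dtype.kind == "i" and gt.X.min() >= 0


def test_hdf5_roundtrip(tmp_path):
    ds = generate_dataset(n_trials=6, seed=2)
    path = str(tmp_path / "data.h5")
    save_dataset(path, ds)
    back = load_dataset(path)
    assert np.array_equal(back.X, ds.X)
    assert np.array_equal(back.train_idx, ds.train_idx)
    assert np.allclose(back.ground_truth.Z, ds.ground_truth.Z)
    assert np.allclose(back.ground_truth.Y, ds.ground_truth.Y)
    assert back.ground_truth.system.params == ds.ground_truth.system.params
    assert np.allclose(back.ground_truth.embedding.standardization_mean,
                       ds.ground_truth.embedding.standardization_mean)


def test_discrete_update_map_consistent_with_integration():
    spec = ChaoticSystemSpec(burn_in_steps=100)
    Z = integrate_system(spec, 2, 10, seed=5)
    F = discrete_update_map(spec)
    assert np.allclose(F(Z[:, 0]), Z[:, 1], atol=1e-12)
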