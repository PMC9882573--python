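"""GP filter: sample statistics, noise estimation, both filter paths.

The diagonal path is checked against a literal dense-matrix evaluation of
the Gaussian posterior mean with diagonal covariances — an independent
oracle built from the explicit warping matrix.
"""

import numpy as np
import pytest

from gpecg import (
    GpModel,
    PhaseEnsemble,
    SynthSpec,
    add_noise,
    build_ensemble,
    build_map,
    build_map_r_aligned,
    dense_theta,
    estimate_noise_variance,
    filter_beat_diag,
    filter_beat_full,
    filter_record,
    fit,
    forward,
    generate_clean,
    segment_beats,
)
from gpecg.synthetic import DEFAULT_WAVES, WaveParams


def dense_diag_posterior(x, pmap, mu, k_diag, v_n):
    """Literal dense evaluation of the posterior mean with diagonal phase
    covariance and diagonal phase noise covariance (independent oracle)."""
    theta = dense_theta(pmap)
    g = pmap.g.astype(float)
    psi = theta.T / g[:, None]
    mu_s = psi @ mu
    k_x = psi @ np.diag(k_diag) @ psi.T
    k_s = psi @ (np.diag(k_diag) - v_n * np.eye(pmap.n_phase)) @ psi.T
    k_s = np.diag(np.maximum(np.diag(k_s), 0.0))  # same clamp as the filter
    gain = np.zeros_like(np.diag(k_x))
    nz = np.diag(k_x) > 0
    gain[nz] = np.diag(k_s)[nz] / np.diag(k_x)[nz]
    return mu_s + gain * (x - mu_s), mu_s


def random_instance(rng, r_aligned=False):
    n = int(rng.integers(4, 21))
    t = int(rng.integers(n, 61))
    if r_aligned:
        n_pre = int(rng.integers(1, n - 1))
        r_phase = int(rng.integers(n_pre, t - (n - n_pre) + 1))
        pmap = build_map_r_aligned(n_pre, n - n_pre, t, r_phase)
    else:
        pmap = build_map(n, t)
    mu = rng.normal(size=t)
    k_diag = rng.uniform(0.2, 2.0, size=t)
    v_n = float(rng.uniform(0.0, 1.0))
    x = rng.normal(size=n)
    return x, pmap, mu, k_diag, v_n


# ---------------------------------------------------------------- ensembles


def test_identical_beats_give_identical_rows(periodic_signal):
    x, seg = periodic_signal
    ens, maps = build_ensemble(x, seg, n_phase=120)
    assert np.all(ens.beats == ens.beats[0])


def test_unequal_beats_align_r_column(clean_record):
    rec, truth = clean_record
    seg = segment_beats(truth.r_peaks, rec.n_samples)
    ens, maps = build_ensemble(rec.lead(0), seg, n_phase=400)
    assert ens.beats.shape[1] == 400
    r_phase = maps[0].r_phase
    x = rec.lead(0)
    for i, (s, e) in enumerate(seg.bounds):
        assert ens.beats[i, r_phase] == x[seg.r_peaks[i]]


def test_too_short_phase_length_errors(clean_record):
    rec, truth = clean_record
    seg = segment_beats(truth.r_peaks, rec.n_samples)
    with pytest.raises(ValueError, match="beat"):
        build_ensemble(rec.lead(0), seg, n_phase=int(seg.beat_lengths().max()) - 1,
                       alignment="single")


# --------------------------------------------------------------- statistics


def test_fit_hand_examples():
    const = PhaseEnsemble(np.full((4, 6), 2.5), np.arange(4))
    m = fit(const)
    assert np.all(m.mu == 2.5) and np.all(m.k_diag == 0)

    two = PhaseEnsemble(np.array([[0.0, 2.0], [2.0, 0.0]]), np.arange(2))
    m2 = fit(two, mode="full")
    assert m2.mu.tolist() == [1.0, 1.0]
    assert np.array_equal(m2.K_full, np.array([[1.0, -1.0], [-1.0, 1.0]]))
    assert m2.k_diag.tolist() == [1.0, 1.0]


def test_fit_recovers_known_moments():
    rng = np.random.default_rng(12)
    t = 40
    mu_star = rng.normal(size=t)
    k_star = rng.uniform(0.5, 1.5, size=t)
    b = 2000
    rows = mu_star + rng.normal(size=(b, t)) * np.sqrt(k_star)
    m = fit(PhaseEnsemble(rows, np.arange(b)))
    bound = 5 * np.sqrt(k_star.max() / b)
    assert np.max(np.abs(m.mu - mu_star)) < bound
    assert np.max(np.abs(m.k_diag - k_star)) < 5 * k_star.max() * np.sqrt(2.0 / b)


# ---------------------------------------------------------- noise variance


def test_noise_variance_oracle_passthrough(clean_record, clean_seg):
    rec, _ = clean_record
    assert estimate_noise_variance(rec.lead(0), clean_seg, rec.fs,
                                   method="oracle", v_oracle=0.02) == 0.02


def test_noise_variance_recovery_within_30_percent():
    spec = SynthSpec(duration=90.0, seed=6)  # >= 100 beats
    rec, truth = generate_clean(spec)
    seg = segment_beats(truth.r_peaks, rec.n_samples)
    v_target = 0.01
    snr = 10 * np.log10(np.mean(rec.lead(0) ** 2) / v_target)
    for seed in (1, 2, 3):
        noisy, v = add_noise(rec, snr, seed)
        v_hat = estimate_noise_variance(noisy.lead(0), seg, rec.fs)
        assert abs(v_hat - v[0]) / v[0] < 0.30


def test_noise_variance_near_zero_on_clean_flat_pq():
    # morphology whose Q onset stays clear of the 60-20 ms window, no jitter
    waves = WaveParams({**DEFAULT_WAVES.waves, "Q": (-0.08, -0.09, 0.02)})
    spec = SynthSpec(wave_params=waves, rr_jitter_sd=0.0, amplitude_jitter_cv=0.0,
                     duration=30.0, seed=2)
    rec, truth = generate_clean(spec)
    seg = segment_beats(truth.r_peaks, rec.n_samples)
    assert estimate_noise_variance(rec.lead(0), seg, rec.fs) < 1e-8


# ------------------------------------------------------------- filter paths


def test_scalar_gain_hand_example():
    pmap = build_map(2, 2)
    model = GpModel(mu=np.array([2.0, 2.0]), k_diag=np.array([2.0, 2.0]), v_n=1.0)
    s_hat, mu_s, k_post = filter_beat_diag(np.array([4.0, 4.0]), pmap, model)
    assert s_hat.tolist() == [3.0, 3.0]  # 2 + (1/2)(4-2)
    assert mu_s.tolist() == [2.0, 2.0]
    assert k_post.tolist() == [0.5, 0.5]  # k_s (1 - k_s/k_x) = 1 * 1/2


def test_diag_filter_limits():
    rng = np.random.default_rng(3)
    x, pmap, mu, k_diag, _ = random_instance(rng)
    zero_noise = GpModel(mu=mu, k_diag=k_diag, v_n=0.0)
    s_hat, _, _ = filter_beat_diag(x, pmap, zero_noise)
    assert np.array_equal(s_hat, x)
    all_noise = GpModel(mu=mu, k_diag=k_diag, v_n=float(k_diag.max()))
    s_hat2, mu_s, _ = filter_beat_diag(x, pmap, all_noise)
    assert np.array_equal(s_hat2, mu_s)


@pytest.mark.parametrize("r_aligned", [False, True])
def test_diag_filter_matches_dense_oracle(r_aligned):
    rng = np.random.default_rng(17 + r_aligned)
    for _ in range(100):
        x, pmap, mu, k_diag, v_n = random_instance(rng, r_aligned)
        model = GpModel(mu=mu, k_diag=k_diag, v_n=v_n)
        s_hat, mu_s, _ = filter_beat_diag(x, pmap, model)
        s_ref, mu_ref = dense_diag_posterior(x, pmap, mu, k_diag, v_n)
        assert np.allclose(s_hat, s_ref, rtol=1e-9, atol=1e-12)
        assert np.allclose(mu_s, mu_ref, rtol=1e-12, atol=1e-14)


def test_posterior_is_convex_combination_of_x_and_prior():
    rng = np.random.default_rng(29)
    for _ in range(50):
        x, pmap, mu, k_diag, v_n = random_instance(rng)
        model = GpModel(mu=mu, k_diag=k_diag, v_n=v_n)
        s_hat, mu_s, k_post = filter_beat_diag(x, pmap, model)
        lo = np.minimum(x, mu_s) - 1e-12
        hi = np.maximum(x, mu_s) + 1e-12
        assert np.all((s_hat >= lo) & (s_hat <= hi))
        assert np.all(k_post >= 0)


def test_shrinkage_monotone_in_noise_variance():
    rng = np.random.default_rng(31)
    x, pmap, mu, k_diag, _ = random_instance(rng)
    prev = None
    mu_s = None
    for v in np.linspace(0, k_diag.max(), 8):
        model = GpModel(mu=mu, k_diag=k_diag, v_n=float(v))
        s_hat, mu_s, _ = filter_beat_diag(x, pmap, model)
        dist = np.abs(s_hat - mu_s)
        if prev is not None:
            assert np.all(dist <= prev + 1e-12)
        prev = dist


def test_full_filter_agrees_with_diag_on_identity_maps():
    rng = np.random.default_rng(41)
    for _ in range(20):
        n = int(rng.integers(3, 15))
        pmap = build_map(n, n)  # identity: both noise conventions coincide
        mu = rng.normal(size=n)
        k_diag = rng.uniform(0.5, 2.0, size=n)
        v_n = float(rng.uniform(0.0, 0.4))
        x = rng.normal(size=n)
        diag_model = GpModel(mu=mu, k_diag=k_diag, v_n=v_n)
        full_model = GpModel(mu=mu, k_diag=k_diag, v_n=v_n, mode="full",
                             K_full=np.diag(k_diag))
        s_d, mu_d, _ = filter_beat_diag(x, pmap, diag_model)
        s_f, mu_f, _ = filter_beat_full(x, pmap, full_model)
        assert np.allclose(s_f, s_d, rtol=1e-9, atol=1e-11)
        assert np.allclose(mu_f, mu_d, rtol=1e-12, atol=1e-14)


def test_full_filter_zero_noise_returns_measurement():
    rng = np.random.default_rng(43)
    n, t = 6, 11
    pmap = build_map(n, t)
    rows = rng.normal(size=(30, t))
    model = fit(PhaseEnsemble(rows, np.arange(30)), mode="full", v_n=0.0)
    x = rng.normal(size=n)
    s_hat, _, _ = filter_beat_full(x, pmap, model)
    assert np.allclose(s_hat, x, atol=1e-8)


def test_full_filter_matches_hand_built_two_sample_case():
    pmap = build_map(2, 2)
    k_full = np.array([[2.0, 0.5], [0.5, 1.0]])
    mu = np.array([1.0, -1.0])
    v_n = 0.3
    model = GpModel(mu=mu, k_diag=np.diag(k_full), v_n=v_n, mode="full", K_full=k_full)
    x = np.array([2.0, 0.5])
    k_x = k_full
    k_s = k_full - v_n * np.eye(2)
    expected = mu + k_s @ np.linalg.solve(k_x, x - mu)
    s_hat, _, _ = filter_beat_full(x, pmap, model)
    assert np.allclose(s_hat, expected, rtol=1e-12)


# ------------------------------------------------------------ whole records


def test_noiseless_record_with_zero_vn_passes_through(clean_record, clean_seg):
    rec, _ = clean_record
    res = filter_record(rec, clean_seg, v_n=0.0)
    assert np.allclose(res.posterior, rec.samples, atol=1e-12)
    assert res.posterior.shape == rec.samples.shape


def test_prior_equals_template_average_for_identical_beats(periodic_signal):
    x, seg = periodic_signal
    rng = np.random.default_rng(8)
    noisy = x + 0.05 * rng.standard_normal(x.size)
    from gpecg.records import EcgRecord

    res = filter_record(EcgRecord(noisy, 250.0), seg, n_phase=120, v_n=0.0025)
    # all beats share one map, so the prior beat is the plain beat average
    beats = noisy.reshape(seg.n_beats, -1)
    template = beats.mean(axis=0)
    for s, e in seg.bounds:
        assert np.allclose(res.prior[0, s:e], template, atol=1e-10)


def test_output_length_preserved_with_rr_jitter():
    spec = SynthSpec(duration=20.0, rr_jitter_sd=0.08, seed=9)
    rec, truth = generate_clean(spec)
    noisy, _ = add_noise(rec, 10.0, 2)
    seg = segment_beats(truth.r_peaks, rec.n_samples)
    res = filter_record(noisy, seg)
    assert res.posterior.shape == noisy.samples.shape
    assert np.isfinite(res.posterior).all()


def test_prior_template_rmse_decreases_with_beats():
    spec = SynthSpec(duration=170.0, rr_jitter_sd=0.0, amplitude_jitter_cv=0.0, seed=13)
    rec, truth = generate_clean(spec)
    noisy, _ = add_noise(rec, 5.0, seed=21)
    rmses = []
    for b in (10, 50, 200):
        n = int(b * spec.mean_rr * spec.fs)
        sub_peaks = truth.r_peaks[truth.r_peaks < n - 125]
        seg = segment_beats(sub_peaks, n)
        res = filter_record(noisy.copy_with(noisy.samples[:, :n]), seg, v_n=0.0)
        clean = rec.lead(0)[:n]
        interior = slice(seg.bounds[1][0], seg.bounds[-2][1])
        rmses.append(np.sqrt(np.mean((res.prior[0][interior] - clean[interior]) ** 2)))
    assert rmses[0] > rmses[1] > rmses[2]


def test_denoising_improves_snr_on_default_record(clean_record):
    from gpecg import snr_improvement

    rec, truth = clean_record
    for snr_db in (0.0, 10.0, 20.0):
        noisy, _ = add_noise(rec, snr_db, seed=77)
        seg = segment_beats(truth.r_peaks, rec.n_samples)
        res = filter_record(noisy, seg)
        imp = snr_improvement(rec.lead(0), noisy.lead(0), res.posterior[0])
        assert imp > 0
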