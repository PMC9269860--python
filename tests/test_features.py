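"""Feature-operator correctness: hand-worked window values, oracle
equivalence of the sliding engine, causality, equivariance and the Teager
closed form."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iemgprop import features
from _naive import (
    naive_spectrum,
    naive_ttd_window,
    naive_window_value,
)

FS = 10_000.0
W4 = [1.0, -2.0, 3.0, -1.0]


# ---------------------------------------------------------------------------
# hand-worked single-window values
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "func,args,expected",
    [
        (features.mav, (W4,), 1.75),
        (features.var, (W4,), 5.0),
        (features.wl, (W4,), 12.0),
        (features.env, (W4,), np.sqrt(3.75)),
        (features.ssc, (W4, 0.0), 2),
        (features.ssc, (W4, 16.0), 1),
        (features.zc, (W4, 0.0), 3),
        (features.zc, (W4, 4.5), 1),
        (features.wa, (W4, 3.5), 2),
        (features.wa, (W4, 0.0), 3),
    ],
)
def test_hand_worked_window_values(func, args, expected):
    assert func(*args) == pytest.approx(expected, rel=1e-12)


def test_constant_window_identities():
    c = [3.0] * 8
    assert features.mav(c) == pytest.approx(3.0)
    assert features.env(c) == pytest.approx(3.0)
    assert features.wl(c) == 0.0
    assert features.wa(c, 0.5) == 0
    assert features.var(c) == pytest.approx(8 * 9.0 / 7)  # no mean subtraction


def test_monotone_ramp_has_no_slope_sign_changes():
    ramp = np.linspace(0.0, 1.0, 50)
    assert features.ssc(ramp, 1e-12) == 0


def test_var_requires_two_samples():
    with pytest.raises(ValueError):
        features.var([1.0])


def test_zc_counts_sine_crossings():
    t = np.arange(int(FS)) / FS
    x = np.sin(2 * np.pi * 50.0 * t)
    assert abs(features.zc(x, 0.0) - 100) <= 1


# ---------------------------------------------------------------------------
# spectrum
# ---------------------------------------------------------------------------


def test_spectrum_matches_direct_dft(rng):
    x = rng.standard_normal(16)
    ps = features.power_spectrum(x, FS)
    P, f = naive_spectrum(list(x), FS)
    np.testing.assert_allclose(ps.P, P, rtol=1e-9, atol=1e-9)
    np.testing.assert_allclose(ps.f, f, rtol=1e-12)


def test_parseval_consistency(rng):
    for n in (64, 65):  # even and odd window lengths
        x = rng.standard_normal(n)
        ps = features.power_spectrum(x, FS)
        c_last = 1.0 if n % 2 == 0 else 2.0
        spectral = (ps.P[0] + 2.0 * ps.P[1:-1].sum() + c_last * ps.P[-1]) / n
        assert spectral == pytest.approx(float(np.sum(x * x)), rel=1e-9)


def test_pure_tone_mnf_mdf_within_one_bin():
    n = 1000
    f0 = 100.0  # exact bin: 100 = 10 * fs/n
    t = np.arange(n) / FS
    ps = features.power_spectrum(np.sin(2 * np.pi * f0 * t), FS)
    bin_width = FS / n
    assert abs(features.mnf(ps) - f0) <= bin_width
    assert abs(features.mdf(ps) - f0) <= bin_width


@pytest.mark.parametrize(
    "func,P,f,expected",
    [
        (features.etot, [0.0, 4.0, 4.0, 0.0], [0.0, 10.0, 20.0, 30.0], 8.0 / 3.0),
        (features.tf, [2.0, 0.0], [100.0, 200.0], 20000.0),
        (features.tf_mod, [2.0, 0.0], [100.0, 200.0], 200.0),
        (features.mnf, [1.0, 3.0], [50.0, 150.0], 125.0),
        (features.mdf, [1.0, 1.0, 2.0], [10.0, 20.0, 30.0], 20.0),
    ],
)
def test_hand_worked_spectral_values(func, P, f, expected):
    ps = features.PowerSpectrum(P=np.asarray(P), f=np.asarray(f))
    assert func(ps) == pytest.approx(expected, rel=1e-12)


def test_spectral_operators_reject_zero_spectrum():
    ps = features.PowerSpectrum(P=np.zeros(4), f=np.arange(4.0))
    assert features.etot(ps) == 0.0
    for func in (features.mnf, features.mdf):
        with pytest.raises(ValueError):
            func(ps)


def test_mnf_bracketed_by_spectrum_support(rng):
    x = rng.standard_normal(256)
    ps = features.power_spectrum(x, FS)
    assert ps.f[0] <= features.mnf(ps) <= ps.f[-1]
    assert ps.f[0] <= features.mdf(ps) <= ps.f[-1]


# ---------------------------------------------------------------------------
# Teager-Kaiser
# ---------------------------------------------------------------------------


def test_teager_closed_form_on_sinusoids():
    # psi = A^2 sin^2(omega) exactly at every interior sample
    n = np.arange(400)
    for amp, omega in [(1.0, np.pi / 2), (2.0, 0.1), (0.5, 1.3)]:
        x = amp * np.cos(omega * n)
        psi = features.teager_kaiser(x)
        np.testing.assert_allclose(psi, amp**2 * np.sin(omega) ** 2, rtol=0, atol=1e-9)


def test_teager_on_constant_signal_is_zero():
    assert np.allclose(features.teager_kaiser(np.full(50, 2.5)), 0.0)


def test_ttd_matches_naive_causal_average(rng):
    x = rng.standard_normal(400)
    w = features.WindowSpec(width_ms=3.2, sampling_rate=FS, increment_samples=7)
    series = features.ttd(x, w)
    n = w.width_samples
    for i, v in zip(series.sample_index, series.values):
        assert v == pytest.approx(naive_ttd_window(list(x), int(i), n), rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# FR
# ---------------------------------------------------------------------------


def test_fr_dead_time_merges_close_crossings():
    fs = 1000.0
    x = np.zeros(100)
    x[10] = x[11] = 1.0  # event
    x[13] = 1.0  # 2 ms later: inside the 5 ms dead time
    x[40] = 1.0  # well outside
    assert features.fr(x, 0.5, fs, dead_time_ms=5.0) == 2


def test_fr_zero_signal():
    assert features.fr(np.zeros(100), 1.0, FS) == 0


def test_fr_counts_template_spikes_through_noise(rng):
    # dense enough that the 95th amplitude quantile falls inside the spike
    # amplitudes (above the 2 uV noise), as during tracking
    from iemgprop import synth

    fs = FS
    n = int(fs)
    tpl = synth.gaussian_muap(50.0, sampling_rate=fs)
    x = rng.normal(0.0, 2.0, n)
    spikes = (np.arange(30) * (fs / 30) + 123).astype(int)
    for s in spikes:
        x[s : s + tpl.waveform.size] += tpl.waveform
    thr = np.percentile(np.abs(x), 95)
    assert abs(features.fr(x, thr, fs) - 30) <= 1


def test_fr_requires_positive_threshold():
    with pytest.raises(ValueError):
        features.fr(np.ones(10), 0.0, FS)


# ---------------------------------------------------------------------------
# threshold resolution
# ---------------------------------------------------------------------------


def test_dead_zone_resolution_scales_rest_mav():
    t = features.ThresholdSpec(kind="dead_zone", q_multiplier=2.0)
    assert t.resolve("ZC", rest_mav=3.0).resolved_value == pytest.approx(6.0)
    # SSC dead zone acts on a slope product, so the value is squared
    assert t.resolve("SSC", rest_mav=3.0).resolved_value == pytest.approx(36.0)


def test_quantile_resolution_uses_rectified_reference(rng):
    x = rng.standard_normal(5000)
    t = features.ThresholdSpec(kind="quantile", quantile=95)
    v = t.resolve("FR", reference_signal=x).resolved_value
    assert v == pytest.approx(np.percentile(np.abs(x), 95))


def test_threshold_spec_validation():
    with pytest.raises(ValueError):
        features.ThresholdSpec(kind="quantile", quantile=50)
    with pytest.raises(ValueError):
        features.ThresholdSpec(kind="dead_zone")
    with pytest.raises(ValueError):
        features.ThresholdSpec(kind="nope")


# ---------------------------------------------------------------------------
# sliding engine vs naive oracle
# ---------------------------------------------------------------------------


def _threshold_for(algorithm, x, rng):
    if algorithm in features.THRESHOLDED:
        return float(np.abs(x).mean() * rng.uniform(0.0, 2.0))
    if algorithm == "FR":
        return float(np.percentile(np.abs(x), 90))
    return None


@pytest.mark.parametrize("algorithm", features.ALGORITHMS)
@pytest.mark.parametrize("increment", [1, 7, 32])
def test_sliding_apply_matches_naive_oracle(algorithm, increment, rng):
    n_windows = 32
    w = features.WindowSpec(width_ms=3.2, sampling_rate=FS, increment_samples=increment)
    N = w.width_samples
    x = rng.standard_normal(300)
    thr = _threshold_for(algorithm, x, rng)
    series = features.sliding_apply(x, algorithm, w, thr)
    dead = max(1, int(round(5.0 * FS / 1000.0)))
    assert series.sample_index[0] == N - 1
    for i, v in list(zip(series.sample_index, series.values))[:n_windows]:
        win = list(x[i - N + 1 : i + 1])
        if algorithm == "Ttd":
            expected = naive_ttd_window(list(x), int(i), N)
        else:
            expected = naive_window_value(algorithm, win, FS, thr or 0.0, dead)
        if algorithm in ("SSC", "ZC", "WA", "FR"):
            assert v == expected, f"{algorithm} at {i}"
        else:
            assert v == pytest.approx(expected, rel=1e-9, abs=1e-12)


def test_non_overlapping_series_subsamples_increment_one(rng):
    x = rng.standard_normal(500)
    w1 = features.WindowSpec(width_ms=5.0, sampling_rate=FS, increment_samples=1)
    wN = features.WindowSpec(width_ms=5.0, sampling_rate=FS, increment_samples=50)
    s1 = features.sliding_apply(x, "MAV", w1)
    sN = features.sliding_apply(x, "MAV", wN)
    lookup = dict(zip(s1.sample_index, s1.values))
    for i, v in zip(sN.sample_index, sN.values):
        assert v == pytest.approx(lookup[i], rel=1e-12)


def test_causality_future_perturbation_leaves_past_unchanged(rng):
    x = rng.standard_normal(600)
    w = features.WindowSpec(width_ms=4.0, sampling_rate=FS, increment_samples=3)
    j = 300
    y = x.copy()
    y[j:] += rng.standard_normal(600 - j) * 5.0
    for algorithm in ("MAV", "SSC", "Ttd", "MNF", "FR"):
        thr = _threshold_for(algorithm, x, rng)
        a = features.sliding_apply(x, algorithm, w, thr)
        b = features.sliding_apply(y, algorithm, w, thr)
        past = a.sample_index < j
        np.testing.assert_array_equal(a.values[past], b.values[past], err_msg=algorithm)


def test_unknown_acronym_rejected(rng):
    w = features.WindowSpec(width_ms=5.0, sampling_rate=FS)
    with pytest.raises(ValueError):
        features.sliding_apply(rng.standard_normal(100), "RMS", w)


def test_sliding_spectral_set_matches_individual_calls(rng):
    x = rng.standard_normal(2000)
    w = features.WindowSpec(width_ms=10.0, sampling_rate=FS, increment_samples=40)
    bundle = features.sliding_spectral_set(x, w)
    for name in features.SPECTRAL:
        single = features.sliding_apply(x, name, w)
        np.testing.assert_allclose(bundle[name].values, single.values, rtol=1e-12)


# ---------------------------------------------------------------------------
# equivariance properties
# ---------------------------------------------------------------------------


@settings(max_examples=25, deadline=None)
@given(gain=st.floats(min_value=0.01, max_value=100.0), seed=st.integers(0, 10_000))
def test_amplitude_equivariance(gain, seed):
    r = np.random.default_rng(seed)
    x = r.standard_normal(64)
    lin = {"MAV": features.mav, "Env": features.env, "WL": features.wl}
    for name, op in lin.items():
        assert op(gain * x) == pytest.approx(gain * op(x), rel=1e-9), name
    ps1 = features.power_spectrum(x, FS)
    psg = features.power_spectrum(gain * x, FS)
    for op in (features.var,):
        assert op(gain * x) == pytest.approx(gain**2 * op(x), rel=1e-9)
    for op in (features.etot, features.tf, features.tf_mod):
        assert op(psg) == pytest.approx(gain**2 * op(ps1), rel=1e-9)
    for op in (features.mnf, features.mdf):
        assert op(psg) == pytest.approx(op(ps1), rel=1e-9)
    assert features.ssc(gain * x, 0.0) == features.ssc(x, 0.0)
    assert features.zc(gain * x, 0.0) == features.zc(x, 0.0)
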