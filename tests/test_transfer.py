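"""Transfer-function analysis: H(f), band averaging, phase delay, maps."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pulsemap as pm
from conftest import circ_dist

TR = 0.2


def spectrum_of(signal, tr=TR):
    return pm.amplitude_spectrum(np.asarray(signal, float), tr)


def bin_cosine(k, n=300, tr=TR, amplitude=1.0, delay=0.0):
    t = np.arange(n) * tr
    f = k / (n * tr)
    return amplitude * np.cos(2 * np.pi * f * (t - delay)), f


# ---------------------------------------------------------------------------
# transfer_function
# ---------------------------------------------------------------------------


def test_identity_transfer():
    x, _ = bin_cosine(24)
    sp = spectrum_of(x)
    H = pm.transfer_function(sp, sp)
    powered = np.abs(sp.values) > 1e-6
    assert np.allclose(np.abs(H[powered]), 1.0, atol=1e-6)
    assert np.allclose(np.angle(H[powered]), 0.0, atol=1e-6)


def test_inverted_signal_has_pi_phase():
    # an inverted waveform is indistinguishable from a half-period delay
    x, _ = bin_cosine(24)
    sx, sy = spectrum_of(x), spectrum_of(-x)
    H = pm.transfer_function(sx, sy)
    powered = np.abs(sx.values) > 1e-6
    assert np.allclose(np.abs(np.angle(H[powered])), np.pi, atol=1e-6)


@pytest.mark.parametrize("k, a, delay", [(24, 1.0, 0.4), (73, 2.5, -0.2), (10, 0.7, 1.0)])
def test_shift_theorem_at_bin_frequencies(k, a, delay):
    # y(t) = a x(t - dt) for a bin-frequency cosine: |H| = a,
    # phi = wrap(-2 pi f dt) at that bin.
    x, f = bin_cosine(k)
    y, _ = bin_cosine(k, amplitude=a, delay=delay)
    H = pm.transfer_function(spectrum_of(x), spectrum_of(y))
    assert np.abs(H[k]) == pytest.approx(a, rel=1e-9)
    expected = np.angle(np.exp(-2j * np.pi * f * delay))
    assert circ_dist(np.angle(H[k]), expected) == pytest.approx(0.0, abs=1e-9)


def test_mismatched_grids_rejected():
    x, _ = bin_cosine(10, n=300)
    y, _ = bin_cosine(10, n=200)
    with pytest.raises(ValueError, match="grids"):
        pm.transfer_function(spectrum_of(x), spectrum_of(y))


def test_reciprocity_where_power_exists():
    rng = np.random.default_rng(2)
    x = rng.normal(size=128)
    y = rng.normal(size=128)
    sx, sy = spectrum_of(x), spectrum_of(y)
    H_xy = pm.transfer_function(sx, sy)
    H_yx = pm.transfer_function(sy, sx)
    strong = (np.abs(sx.values) > 1e-3) & (np.abs(sy.values) > 1e-3)
    assert np.allclose(H_xy[strong], 1.0 / H_yx[strong], rtol=1e-6)


# ---------------------------------------------------------------------------
# band averaging
# ---------------------------------------------------------------------------

BAND = pm.BandSpec("respiratory", 0.3, 0.5)


def test_constant_H_band_average():
    freqs = np.fft.rfftfreq(300, d=TR)
    c = 2.0 * np.exp(1j * 0.7)
    H = np.full(freqs.size, c)
    mag, phase = pm.band_average(H, BAND, freqs)
    assert mag == pytest.approx(2.0)
    assert phase == pytest.approx(0.7)


def test_circular_mean_across_the_wrap():
    # phases +3.0 and -3.0 rad with equal magnitude: the unit-phasor sum
    # points at pi, not at the naive mean 0.
    freqs = np.array([0.0, 0.35, 0.45])
    H = np.array([0.0, np.exp(3.0j), np.exp(-3.0j)])
    _, phase = pm.band_average(H, BAND, freqs)
    assert phase == pytest.approx(np.pi)


def test_magnitude_is_arithmetic_mean():
    freqs = np.array([0.0, 0.35, 0.45])
    H = np.array([0.0, 1.0 + 0j, 3.0 + 0j])
    mag, _ = pm.band_average(H, BAND, freqs)
    assert mag == pytest.approx(2.0)


def test_empty_band_rejected():
    freqs = np.fft.rfftfreq(300, d=TR)
    with pytest.raises(ValueError, match="no frequency bins"):
        pm.band_average(np.ones(freqs.size, complex),
                        pm.BandSpec("other", 2.501, 2.6), freqs)


# ---------------------------------------------------------------------------
# phase delay + Nyquist arithmetic
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("phi, f, expected", [
    (0.0, 0.7, 0.0),
    (np.pi, 1.0, -0.5),
    (-np.pi / 2, 1.25, 0.2),
])
def test_phase_delay_values(phi, f, expected):
    assert pm.phase_delay(phi, f) == pytest.approx(expected)


def test_phase_delay_requires_positive_frequency():
    with pytest.raises(ValueError, match="> 0"):
        pm.phase_delay(1.0, 0.0)


@given(st.floats(-np.pi, np.pi, exclude_min=True), st.floats(0.01, 10.0))
def test_phase_delay_bounded_by_half_period(phi, f):
    assert abs(pm.phase_delay(phi, f)) <= 0.5 / f + 1e-12


@pytest.mark.parametrize("tr, nyq, hr_hz, hr_bpm", [
    (0.2, 2.5, 1.25, 75.0),
    (0.1, 5.0, 2.5, 150.0),
])
def test_nyquist_limit(tr, nyq, hr_hz, hr_bpm):
    info = pm.nyquist_limit(tr)
    assert info.nyquist_hz == pytest.approx(nyq)
    assert info.max_heart_rate_hz == pytest.approx(hr_hz)
    assert info.max_heart_rate_bpm == pytest.approx(hr_bpm)


def test_nyquist_rejects_nonpositive_tr():
    with pytest.raises(ValueError):
        pm.nyquist_limit(0.0)


# ---------------------------------------------------------------------------
# pixelwise maps
# ---------------------------------------------------------------------------


def delayed_phantom(delay_b, f=1.0, n=300, noise_sd=0.0, seed=0):
    """Two compartments at the same frequency; B delayed by ``delay_b``."""
    grid = (10, 10)
    a = pm.CompartmentSpec(mask=pm.rect_mask(grid, (0, 0), (5, 10)),
                           frequency=f, amplitude=2.0, delay=0.0)
    b = pm.CompartmentSpec(mask=pm.rect_mask(grid, (5, 0), (10, 10)),
                           frequency=f, amplitude=2.0, delay=delay_b)
    spec = pm.PhantomSpec(grid_shape=grid, n_frames=n, tr=TR,
                          compartments=[a, b], noise_sd=noise_sd,
                          baseline=0.0, seed=seed)
    series = pm.zero_mean(pm.generate_phantom(spec))
    t = np.arange(n) * TR
    reference = 2.0 * np.cos(2 * np.pi * f * t)
    return series, reference, a.mask, b.mask


def test_self_reference_gives_unit_gain_zero_phase():
    # with a pixel's own course as reference, every bin has Y = X, so the
    # band-averaged gain is 1 and the phase 0 wherever the reference has power
    series, _, mask_a, _ = delayed_phantom(0.3, noise_sd=0.2, seed=3)
    pixel = (1, 1)
    reference = series.data[pixel]
    band = pm.BandSpec("cardiac", 0.9, 1.1)
    (tm,) = pm.transfer_maps(series, reference, [band])
    assert tm.magnitude[pixel] == pytest.approx(1.0, abs=1e-6)
    assert tm.phase[pixel] == pytest.approx(0.0, abs=1e-6)
    assert tm.coherence[pixel] == pytest.approx(1.0, abs=1e-6)


def test_delayed_compartment_recovers_its_delay():
    series, reference, _, mask_b = delayed_phantom(0.3, noise_sd=0.2, seed=5)
    band = pm.BandSpec("cardiac", 0.9, 1.1)
    (tm,) = pm.transfer_maps(series, reference, [band])
    assert tm.reference_freq == pytest.approx(1.0)
    err = np.abs(tm.delay[mask_b] - 0.3)
    assert np.median(err) <= TR / 2


def test_inverted_compartment_has_pi_phase():
    series, reference, _, mask_b = delayed_phantom(0.5)  # T/2 at 1 Hz
    band = pm.BandSpec("cardiac", 0.9, 1.1)
    (tm,) = pm.transfer_maps(series, reference, [band])
    assert np.allclose(np.abs(tm.phase[mask_b]), np.pi, atol=1e-6)


def test_delay_aliases_by_whole_periods():
    # adding one full period to the phantom delay recovers the same map
    band = pm.BandSpec("cardiac", 0.9, 1.1)
    series0, ref, _, mask_b = delayed_phantom(0.3)
    series1, _, _, _ = delayed_phantom(1.3)
    (tm0,) = pm.transfer_maps(series0, ref, [band])
    (tm1,) = pm.transfer_maps(series1, ref, [band])
    assert np.allclose(tm0.delay[mask_b], tm1.delay[mask_b], atol=1e-6)
    T = 1.0 / tm0.reference_freq
    finite = np.isfinite(tm0.delay)
    assert np.all(np.abs(tm0.delay[finite]) <= T / 2 + 1e-12)


def test_linearity_scales_magnitude_not_phase():
    series, reference, _, mask_b = delayed_phantom(0.2)
    scaled = pm.DynamicSeries(series.data * 3.0, series.tr, mask=series.mask)
    band = pm.BandSpec("cardiac", 0.9, 1.1)
    (tm,) = pm.transfer_maps(series, reference, [band])
    (tm3,) = pm.transfer_maps(scaled, reference, [band])
    finite = np.isfinite(tm.magnitude)
    assert np.allclose(tm3.magnitude[finite], 3.0 * tm.magnitude[finite], rtol=1e-6)
    assert np.allclose(circ_dist(tm3.phase[finite], tm.phase[finite]), 0.0, atol=1e-6)


def test_reference_without_in_band_power_warns():
    series, reference, _, _ = delayed_phantom(0.2)  # power at 1.0 Hz only
    band = pm.BandSpec("respiratory", 0.3, 0.5)
    with pytest.warns(UserWarning, match="respiratory"):
        (tm,) = pm.transfer_maps(series, reference, [band])
    assert tm.warning is not None and "respiratory" in tm.warning


def test_reference_length_mismatch_rejected():
    series, reference, _, _ = delayed_phantom(0.2)
    with pytest.raises(ValueError, match="length"):
        pm.transfer_maps(series, reference[:-1], [pm.BandSpec("cardiac", 0.9, 1.1)])


# ---------------------------------------------------------------------------
# delay-recovery property (many compartments)
# ---------------------------------------------------------------------------


def test_multi_compartment_delay_rmse_within_one_frame():
    rng = np.random.default_rng(17)
    f, T, n = 1.0, 1.0, 300
    n_comp = 20
    grid = (4, 2 * n_comp)
    comps = []
    delays = rng.uniform(-T / 2, T / 2, size=n_comp)
    for i, d in enumerate(delays):
        comps.append(pm.CompartmentSpec(
            mask=pm.rect_mask(grid, (0, 2 * i), (4, 2 * i + 2)),
            frequency=f, amplitude=2.0, delay=float(d),
        ))
    spec = pm.PhantomSpec(grid_shape=grid, n_frames=n, tr=TR,
                          compartments=comps, noise_sd=0.2, baseline=0.0,
                          seed=23)
    series = pm.zero_mean(pm.generate_phantom(spec))
    t = np.arange(n) * TR
    reference = np.cos(2 * np.pi * f * t)
    (tm,) = pm.transfer_maps(series, reference, [pm.BandSpec("cardiac", 0.9, 1.1)])
    errors = []
    for comp, d in zip(comps, delays):
        rec = np.median(tm.delay[comp.mask])
        errors.append(circ_dist(rec, d, period=T))
    rmse = float(np.sqrt(np.mean(np.square(errors))))
    assert rmse <= TR


# ---------------------------------------------------------------------------
# global transfer
# ---------------------------------------------------------------------------


def _fake_icresult(courses, tr=TR):
    courses = np.asarray(courses, float)
    return pm.ICResult(
        maps=np.zeros((courses.shape[0], 1)),
        courses=courses,
        spectra=[pm.amplitude_spectrum(c, tr) for c in courses],
        tr=tr,
        spatial_shape=(1,),
    )


def test_component_against_itself_has_zero_phase():
    x, _ = bin_cosine(24)
    sp = spectrum_of(x)
    H = pm.transfer_function(sp, sp)
    powered = np.abs(sp.values) > 1e-6
    assert np.allclose(np.angle(H[powered]), 0.0, atol=1e-9)


def test_shared_band_fixed_lag_gives_near_constant_phase():
    # two sources with power across the whole band, one lagging the other by
    # a fixed 0.2 s: the per-bin phase is the near-constant ramp -2 pi f dt,
    # whose circular spread over a 0.15 Hz band stays well under 0.1 rad
    n = 300
    rng = np.random.default_rng(3)
    spectrum = np.zeros(n // 2 + 1, complex)
    freqs = np.fft.rfftfreq(n, d=TR)
    in_band = (freqs >= 0.9) & (freqs <= 1.05)
    spectrum[in_band] = np.exp(2j * np.pi * rng.uniform(size=in_band.sum()))
    base = np.fft.irfft(spectrum, n)
    lagged = np.roll(base, 1)  # exact circular lag of one frame = 0.2 s
    res = _fake_icresult([base + rng.normal(0, 1e-4, n),
                          lagged + rng.normal(0, 1e-4, n)])
    (curve,) = pm.global_transfer(res, 0)
    phasors = np.exp(1j * curve.phase[in_band])
    R = np.abs(phasors.mean())
    circ_std = np.sqrt(-2 * np.log(R))
    assert circ_std <= 0.1


def test_band_without_reference_power_has_low_coherence():
    # requesting a band where the reference spectrum is pure noise floor:
    # phases there are uninterpretable, so coherence drops below the display
    # threshold and the band output carries a warning
    grid = (6, 6)
    resp = pm.CompartmentSpec(mask=pm.rect_mask(grid, (0, 0), (3, 6)),
                              frequency=0.4, amplitude=2.0)
    card = pm.CompartmentSpec(mask=pm.rect_mask(grid, (3, 0), (6, 6)),
                              frequency=1.2, amplitude=2.0)
    spec = pm.PhantomSpec(grid_shape=grid, n_frames=300, tr=TR,
                          compartments=[resp, card], noise_sd=0.3,
                          baseline=0.0, seed=9)
    series = pm.zero_mean(pm.generate_phantom(spec))
    t = np.arange(300) * TR
    # cardiac-only reference with a broadband noise floor
    reference = np.cos(2 * np.pi * 1.2 * t) + \
        np.random.default_rng(4).normal(0, 0.05, 300)
    resp_band = pm.BandSpec("respiratory", 0.3, 0.5)
    card_band = pm.BandSpec("cardiac", 1.1, 1.3)
    with pytest.warns(UserWarning, match="respiratory"):
        tm_resp, tm_card = pm.transfer_maps(series, reference,
                                            [resp_band, card_band])
    # cardiac-compartment pixels carry only noise in the respiratory band:
    # noise phases are uniform across bins, so their coherence is low
    assert np.median(tm_resp.coherence[card.mask]) < 0.5
    assert tm_resp.warning is not None
    # where the reference does have power, coherent pixels score high
    assert np.median(tm_card.coherence[card.mask]) > 0.9
    assert tm_card.warning is None


def test_global_transfer_reference_index_validated():
    res = _fake_icresult(np.random.default_rng(0).normal(size=(2, 64)))
    with pytest.raises(ValueError, match="out of range"):
        pm.global_transfer(res, 5)
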