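import math

import numpy as np
import pytest
import pywt

import pupilload as pl
from pupilload.errors import SeriesTooShortError
from pupilload.ipa import (IPAParams, count_events, modulus_maxima,
                           universal_threshold, wavelet_detail)

PARAMS = IPAParams()


# -- wavelet detail --------------------------------------------------------

def test_constant_series_has_zero_details():
    detail = wavelet_detail(np.full(1024, 5.0), PARAMS)
    assert np.max(np.abs(detail)) < 1e-12


def test_detail_is_linear():
    rng = np.random.default_rng(1)
    x = rng.normal(size=512)
    np.testing.assert_allclose(wavelet_detail(3.0 * x, PARAMS),
                               3.0 * wavelet_detail(x, PARAMS),
                               rtol=0, atol=1e-12)


def _periodized_analysis_step(x, filt):
    """Mallat analysis step with periodic wrap-around.

    Circular convolution with the analysis filter, decimated with the
    phase aligned to the filter's group delay (offset len(filt)/2 - 1),
    which is the alignment convention of periodized DWTs.
    """
    n, m = len(x), len(filt)
    off = m // 2 - 1
    out = np.zeros(n // 2)
    for k in range(n // 2):
        acc = 0.0
        for j in range(m):
            acc += filt[j] * x[(2 * k + 1 - j + off) % n]
        out[k] = acc
    return out


def test_impulse_response_matches_convolve_and_decimate_oracle():
    x = np.zeros(1024)
    x[512] = 1.0
    w = pywt.Wavelet(PARAMS.wavelet)
    a1 = _periodized_analysis_step(x, np.array(w.dec_lo))
    d2 = _periodized_analysis_step(a1, np.array(w.dec_hi)) / 2.0
    detail = wavelet_detail(x + 1.0, PARAMS)   # constant offset is annihilated
    np.testing.assert_allclose(detail, d2, rtol=0, atol=1e-10)


def test_too_short_series_reports_required_minimum():
    with pytest.raises(SeriesTooShortError) as err:
        wavelet_detail(np.ones(100), PARAMS)
    assert err.value.required == 4 * 32        # sym16 filter length 32


# -- modulus maxima --------------------------------------------------------

def test_modulus_maxima_by_definition():
    out = modulus_maxima(np.array([0.0, 1.0, 0.0, -2.0, 0.0]))
    np.testing.assert_array_equal(out, [0.0, 1.0, 0.0, -2.0, 0.0])


def test_all_zero_input_has_no_maxima():
    assert np.count_nonzero(modulus_maxima(np.zeros(16))) == 0


def test_plateau_keeps_first_index_only():
    out = modulus_maxima(np.array([0.0, 2.0, 2.0, 0.0]))
    np.testing.assert_array_equal(out, [0.0, 2.0, 0.0, 0.0])


def _scan_maxima(c):
    """Exhaustive index-by-index scan; the independent oracle."""
    m = np.abs(c)
    out = np.zeros_like(c)
    for i in range(len(c)):
        left_ok = (i == 0) or (m[i] > m[i - 1])
        right_ok = (i == len(c) - 1) or (m[i] >= m[i + 1])
        if left_ok and right_ok and m[i] > 0:
            out[i] = c[i]
    return out


def test_seeded_sequence_matches_exhaustive_scan():
    rng = np.random.default_rng(123)
    c = rng.normal(size=256)
    np.testing.assert_array_equal(modulus_maxima(c), _scan_maxima(c))


# -- universal threshold ---------------------------------------------------

def test_zero_spread_maxima_give_zero_threshold():
    assert universal_threshold(np.zeros(64), PARAMS) == 0.0


def test_closed_form_and_factor_linearity():
    mm = np.tile([1.0, -1.0], 512)             # sd exactly 1, n = 1024
    lam1 = universal_threshold(mm, IPAParams(threshold_factor=1.0))
    assert lam1 == pytest.approx(math.sqrt(2 * math.log(1024)), abs=1e-12)
    lam_half = universal_threshold(mm, IPAParams(threshold_factor=0.5))
    assert lam_half == pytest.approx(0.5 * lam1, abs=1e-12)


def test_base2_log_option():
    mm = np.tile([1.0, -1.0], 512)
    lam = universal_threshold(mm, IPAParams(threshold_factor=1.0,
                                            log_base="base2"))
    assert lam == pytest.approx(math.sqrt(2 * math.log2(1024)), abs=1e-12)


def test_mad_sigma_estimator_needs_details():
    mm = np.array([0.0, 1.0, 0.0, -1.0])
    params = IPAParams(sigma_estimator="mad_of_detail")
    with pytest.raises(ValueError):
        universal_threshold(mm, params)
    lam = universal_threshold(mm, params, detail=np.array([0., 1., 0., -1.]))
    assert lam > 0


# -- compute_ipa -----------------------------------------------------------

def test_constant_series_yields_zero_ipa(make_series):
    result = pl.compute_ipa(make_series(np.full(900, 5.0)), PARAMS)
    assert result.event_count == 0 and result.ipa == 0.0


def test_ipa_is_count_over_duration(noisy_series):
    series = noisy_series(seed=2, rate=2.0)
    result = pl.compute_ipa(series, PARAMS)
    assert result.ipa == result.event_count / result.duration
    assert result.duration == pytest.approx(series.t[-1] - series.t[0])


@pytest.mark.parametrize("seed", range(5))
def test_amplitude_scale_and_offset_invariance(noisy_series, seed):
    series = noisy_series(seed=seed, rate=1.5)
    base = pl.compute_ipa(series, PARAMS).event_count
    scaled = pl.PupilSeries("left", series.t, 3.0 * series.d, series.valid)
    shifted = pl.PupilSeries("left", series.t, series.d + 2.0, series.valid)
    assert pl.compute_ipa(scaled, PARAMS).event_count == base
    assert pl.compute_ipa(shifted, PARAMS).event_count == base


@pytest.mark.parametrize("seed", range(5))
def test_event_count_monotone_in_threshold_factor(noisy_series, seed):
    series = noisy_series(seed=100 + seed, rate=2.0)
    loose = pl.compute_ipa(series, IPAParams(threshold_factor=0.8))
    tight = pl.compute_ipa(series, IPAParams(threshold_factor=1.0))
    assert loose.event_count >= tight.event_count


def _staged_ipa(series, factor=0.8):
    """Independent stage-by-stage reimplementation: transform, maxima,
    threshold, count — plain loops, no shared helpers."""
    coeffs = pywt.wavedec(series.d, "sym16", mode="periodization", level=2)
    cd2 = [c / 2.0 for c in coeffs[1]]
    n = len(cd2)
    mm = [0.0] * n
    for i in range(n):
        left = abs(cd2[i - 1]) if i >= 1 else -math.inf
        right = abs(cd2[i + 1]) if i < n - 1 else -math.inf
        if abs(cd2[i]) > left and abs(cd2[i]) >= right and abs(cd2[i]) > 0:
            mm[i] = cd2[i]
    mean = sum(mm) / n
    sigma = math.sqrt(sum((v - mean) ** 2 for v in mm) / n)
    lam = factor * sigma * math.sqrt(2.0 * math.log(n))
    count = sum(1 for v in mm if v != 0 and abs(v) >= lam)
    return count / (series.t[-1] - series.t[0])


def test_staged_oracle_agreement_on_synthetic_segments(noisy_series):
    for seed in range(10):
        series = noisy_series(seed=42 + seed, rate=1.2)
        assert pl.compute_ipa(series, PARAMS).ipa == _staged_ipa(series)
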