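"""Energy features, band filters, segmentation and the labeling rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfopipe.errors import ConfigurationError, DegenerateWindowError
from hfopipe.features import (BANDS, WindowSpec, bandpass, extract_features,
                              label_segment, label_segments, line_length,
                              rms, segment_indices, short_time_energy,
                              teager_energy)
from hfopipe.io import FEATURE_COLUMNS, EventAnnotation, Recording

# independent naive-loop oracles ---------------------------------------------


def _ll_oracle(x):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1)) / (len(x) - 1)


def _ste_oracle(x):
    return sum(v * v for v in x) / len(x)


def _teager_oracle(x):
    return sum(x[i] ** 2 - x[i - 1] * x[i + 1]
               for i in range(1, len(x) - 1)) / (len(x) - 2)


@pytest.mark.parametrize("func,x,expected", [
    (line_length, [5.0, 5.0, 5.0], 0.0),
    (line_length, [0.0, 1.0, 0.0, 1.0], 1.0),
    (short_time_energy, [0.0, 0.0, 0.0], 0.0),
    (short_time_energy, [1.0, -1.0, 1.0, -1.0], 1.0),
    (rms, [3.0, 4.0], np.sqrt(12.5)),
    (rms, [-2.0, -2.0], 2.0),
    (rms, [0.0, 0.0], 0.0),
    (teager_energy, [7.0, 7.0, 7.0], 0.0),
    (teager_energy, [0.0, 1.0, 0.0], 1.0),
])
def test_feature_examples(func, x, expected):
    assert func(np.array(x)) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("func,min_n", [
    (line_length, 2), (short_time_energy, 1), (rms, 1), (teager_energy, 3)])
def test_degenerate_windows_rejected(func, min_n):
    with pytest.raises(DegenerateWindowError):
        func(np.zeros(min_n - 1))


def test_features_match_naive_oracles():
    rng = np.random.default_rng(3)
    for _ in range(200):
        x = rng.standard_normal(rng.integers(3, 64))
        assert line_length(x) == pytest.approx(_ll_oracle(list(x)), rel=1e-9)
        assert short_time_energy(x) == pytest.approx(_ste_oracle(list(x)), rel=1e-9)
        assert rms(x) ** 2 == pytest.approx(short_time_energy(x), rel=1e-9)
        assert teager_energy(x) == pytest.approx(_teager_oracle(list(x)),
                                                 rel=1e-9, abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40),
       st.floats(-100, 100))
def test_homogeneity_and_shift(xs, alpha):
    """Scaling laws: |α| for line_length/rms, α² for energy features; only
    line_length is invariant under a constant offset."""
    x = np.array(xs)
    ax = alpha * x
    assert line_length(ax) == pytest.approx(abs(alpha) * line_length(x),
                                            rel=1e-9, abs=1e-9)
    assert rms(ax) == pytest.approx(abs(alpha) * rms(x), rel=1e-9, abs=1e-9)
    assert short_time_energy(ax) == pytest.approx(
        alpha ** 2 * short_time_energy(x), rel=1e-9, abs=1e-9)
    assert teager_energy(ax) == pytest.approx(
        alpha ** 2 * teager_energy(x), rel=1e-9, abs=1e-9)
    assert line_length(x + 42.0) == pytest.approx(line_length(x),
                                                  rel=1e-9, abs=1e-9)


def test_teager_sinusoid_closed_form():
    """For A·sin(ωn+φ) the per-sample Teager value is A²·sin²(ω)."""
    for freq, amp, phase in [(120.0, 2.0, 0.3), (400.0, 0.5, 1.1)]:
        omega = 2 * np.pi * freq / 2000.0
        n = np.arange(200)
        x = amp * np.sin(omega * n + phase)
        assert teager_energy(x) == pytest.approx(amp ** 2 * np.sin(omega) ** 2,
                                                 rel=1e-6)


# segmentation ---------------------------------------------------------------


@pytest.mark.parametrize("n,window_ms,expected_windows,width", [
    (600000, 10, 30000, 20),
    (600000, 50, 6000, 100),
    (600000, 100, 3000, 200),
    (19, 10, 0, 20),
])
def test_segment_indices(n, window_ms, expected_windows, width):
    segs = segment_indices(n, 2000.0, WindowSpec(window_ms))
    assert len(segs) == expected_windows
    assert all(b - a == width for a, b in segs)
    # non-overlapping and consecutive
    assert all(segs[i][1] == segs[i + 1][0] for i in range(len(segs) - 1))


def test_window_not_integer_samples_rejected():
    with pytest.raises(ConfigurationError):
        WindowSpec(10).n_samples(1111.0)


# labeling -------------------------------------------------------------------


def _ev(start, end, label, ch="ch01"):
    return EventAnnotation(ch, start, end, label)


@pytest.mark.parametrize("segment,events,expected", [
    ((0.050, 0.060), [_ev(0.010, 0.106, "R")], "R"),          # fully inside
    ((0.050, 0.060), [_ev(0.056, 0.080, "FR")], "noHFO"),     # 4 ms < half
    ((0.050, 0.060), [_ev(0.055, 0.080, "FR")], "FR"),        # exactly half
    ((0.050, 0.060), [_ev(0.0, 0.055, "R"), _ev(0.055, 0.1, "FRonR")], "FRonR"),
    ((0.050, 0.060), [_ev(0.0, 0.055, "FRonR"), _ev(0.055, 0.1, "R")], "FRonR"),
    ((0.050, 0.060), [], "noHFO"),
])
def test_label_segment_rule(segment, events, expected):
    assert label_segment(segment, events) == expected


def test_label_segments_matches_scalar_rule_exhaustively():
    """Vectorized labeling agrees with the scalar rule over an enumeration of
    small event layouts (varying offsets, durations, classes)."""
    width = 0.01
    bounds = np.array([[i * width, (i + 1) * width] for i in range(30)])
    for off1 in np.arange(0.0, 0.03, 0.004):
        for dur1 in (0.012, 0.05, 0.096):
            for lab1, lab2 in (("R", "FR"), ("FRonR", "R"), ("FR", "FRonR")):
                evs = [_ev(off1, off1 + dur1, lab1),
                       _ev(off1 + dur1 + 0.003, off1 + dur1 + 0.043, lab2)]
                vec = label_segments(bounds, evs)
                scal = [label_segment(tuple(b), evs) for b in bounds]
                assert list(vec) == scal


# filtering ------------------------------------------------------------------


def _probe(freq, band, fs=2000.0, seconds=3.0):
    t = np.arange(int(fs * seconds)) / fs
    rec = Recording(np.sin(2 * np.pi * freq * t)[None, :], fs, ["p"])
    out = bandpass(rec, band).signal[0]
    core = out[int(fs):int(2 * fs)]  # steady-state portion
    return np.sqrt(2) * core.std()


def test_bandpass_passband_and_stopband():
    ripple, fast, broad = BANDS
    assert _probe(150, ripple) == pytest.approx(1.0, abs=0.05)
    assert _probe(150, fast) < 10 ** (-40 / 20)
    assert _probe(350, fast) == pytest.approx(1.0, abs=0.05)
    assert _probe(350, ripple) < 10 ** (-40 / 20)
    assert _probe(150, broad) == pytest.approx(1.0, abs=0.05)


def test_bandpass_zero_in_zero_out():
    rec = Recording(np.zeros((2, 4000)), 2000.0, ["a", "b"])
    assert np.allclose(bandpass(rec, BANDS[0]).signal, 0.0)


def test_bandpass_nyquist_violation():
    rec = Recording(np.zeros((1, 4000)), 900.0, ["a"])
    with pytest.raises(ConfigurationError):
        bandpass(rec, BANDS[1])


# extraction -----------------------------------------------------------------


def test_extract_zero_recording_all_background():
    rec = Recording(np.zeros((2, 2000)), 2000.0, ["a", "b"], subject_id="z")
    table = extract_features(rec, [], WindowSpec(10))
    assert len(table) == 2 * 100
    assert (table["label"] == "noHFO").all()
    assert np.allclose(table[FEATURE_COLUMNS].to_numpy(), 0.0)


def test_extract_row_count_and_identity(small_recording):
    rec, anns = small_recording
    table = extract_features(rec, anns, WindowSpec(10))
    assert len(table) == rec.n_channels * 6000
    for band in ("band80_250", "band250_500", "band80_500"):
        assert np.allclose(table[f"{band}_rms"] ** 2,
                           table[f"{band}_short_time_energy"], rtol=1e-9)
        assert (table[f"{band}_line_length"] >= 0).all()
    assert set(table["label"]).issubset({"noHFO", "R", "FR", "FRonR"})


def test_fast_ripple_event_lights_up_fr_band_teager(small_recording):
    """Segments inside FR events carry fast-band Teager energy far above the
    background distribution."""
    rec, anns = small_recording
    table = extract_features(rec, anns, WindowSpec(10))
    fr = table[table["label"] == "FR"]
    assert not fr.empty  # fixture seed chosen to realize FR events
    background = table[table["label"] == "noHFO"]["band250_500_teager"]
    assert fr["band250_500_teager"].max() > background.quantile(0.99)
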