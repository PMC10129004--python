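"""Feature extractors: DCT oracle, bioacoustic landmarks, MFCC, templates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sungkit as sk
from sungkit.features import (
    BIOACOUSTIC_SET,
    bioacoustic_features,
    build_feature_table,
    dct_features,
    f0_template,
    mfcc_features,
    resample_contour,
)
from sungkit.simulate import synthesize_waveform

from conftest import make_call


def brute_force_dct(x: np.ndarray, n_coefs: int) -> np.ndarray:
    """O(N^2) orthonormal DCT-II with the package's odd-order sign flip."""
    N = len(x)
    out = np.empty(n_coefs)
    for k in range(n_coefs):
        scale = np.sqrt(1.0 / N) if k == 0 else np.sqrt(2.0 / N)
        basis = np.cos(np.pi * k * (2 * np.arange(N) + 1) / (2 * N))
        c = scale * float(x @ basis)
        out[k] = -c if k % 2 else c
    return out


class TestDct:
    def test_constant_contour(self):
        call = make_call(f0=np.full(50, 200.0))
        d = dct_features(call)
        assert d["dct0"] == pytest.approx(200.0 * np.sqrt(64))
        assert np.allclose(d[["dct1", "dct2", "dct3", "dct4"]], 0.0, atol=1e-9)

    def test_half_cosine_maps_to_first_coefficient(self):
        t = np.linspace(0.0, 0.2, 400)
        call = make_call(times=t, f0=300 + 80 * np.cos(np.pi * t / 0.2))
        d = dct_features(call)
        small = max(abs(d["dct2"]), abs(d["dct3"]), abs(d["dct4"]))
        assert small < 1e-6 * abs(d["dct1"])

    def test_rising_contour_has_positive_slope_coefficient(self):
        call = make_call(f0=np.linspace(100, 300, 50))
        assert dct_features(call)["dct1"] > 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = np.linspace(0.0, 0.3, 64)
        f = rng.uniform(80, 900, size=64)
        call = make_call(times=t, f0=f)
        d = dct_features(call)
        x = resample_contour(call.f0_contour, 64, call.duration)
        np.testing.assert_allclose(d.iloc[:5], brute_force_dct(x, 5), rtol=1e-9)

    def test_too_short_contour_raises(self):
        call = make_call(times=np.linspace(0, 0.1, 3), f0=np.full(3, 100.0))
        with pytest.raises(ValueError, match="n_coefs"):
            dct_features(call)


class TestBioacoustic:
    def test_symmetric_bell_landmarks(self):
        t = np.linspace(0.0, 0.4, 201)  # odd grid: exact midpoint sample
        f = 500 - 200 * (1 + np.cos(2 * np.pi * t / 0.4)) / 2
        vec = bioacoustic_features(make_call(times=t, f0=f), energy=False)
        v = vec.values
        assert v["tf0.max"] == pytest.approx(0.2, abs=1e-9)
        assert v["f0.slope.1st.half"] == pytest.approx(-v["f0.slope.2nd.half"], abs=1e-6)

    def test_linear_rise_closed_form(self):
        t = np.linspace(0.0, 0.2, 101)
        vec = bioacoustic_features(make_call(times=t, f0=100 + 1000 * t), energy=False)
        assert vec.values["f0.slope.asc"] == pytest.approx(1000.0, rel=1e-6)
        assert vec.values["f0.slope.desc"] == 0.0
        assert any("f0.slope.desc" in f for f in vec.flags)

    def test_flat_spectrum_quartiles(self):
        freqs = np.linspace(500, 12000, 200)
        times = np.linspace(0.0, 0.2, 50)
        S = np.ones((200, 50))
        vec = bioacoustic_features(
            make_call(), spectrogram=(freqs, times, S), energy=True
        )
        v = vec.values
        bin_f = freqs[1] - freqs[0]
        for key, frac in (("q1f", 0.25), ("q2f", 0.5), ("q3f", 0.75)):
            expected = 500 + frac * (12000 - 500)
            assert abs(v[key] - expected) <= 1.5 * bin_f

    def test_energy_quartiles_amplitude_invariant(self, rng):
        freqs = np.linspace(500, 12000, 100)
        times = np.linspace(0.0, 0.2, 30)
        S = rng.random((100, 30))
        v1 = bioacoustic_features(make_call(), spectrogram=(freqs, times, S)).values
        v2 = bioacoustic_features(make_call(), spectrogram=(freqs, times, 7.5 * S)).values
        for key in ("q1f", "q2f", "q3f", "f.max", "q1t", "q2t", "q3t", "t.max"):
            assert v1[key] == v2[key]

    def test_invariants_hold_on_synthetic_calls(self, small_corpus):
        corpus, _ = small_corpus
        for call in corpus.calls[:25]:
            v = bioacoustic_features(call).values
            assert v["f0.max"] >= max(v["f0.sta"], v["f0.mid"], v["f0.end"]) - 1e-9
            assert 0.0 <= v["tf0.max"] <= v["duration"]
            assert v["q1f"] <= v["q2f"] <= v["q3f"]
            assert v["q1t"] <= v["q2t"] <= v["q3t"]

    def test_missing_waveform_raises_for_energy(self):
        with pytest.raises(ValueError, match="waveform"):
            bioacoustic_features(make_call(), energy=True)


class TestMfcc:
    def _tone(self, seconds=0.4, rate=44100.0, f=800.0):
        t = np.arange(int(seconds * rate)) / rate
        return np.sin(2 * np.pi * f * t), rate

    def _call_with(self, samples, rate):
        dur = len(samples) / rate
        c = make_call(times=np.linspace(0, dur, 50), duration=dur)
        c.waveform = sk.Waveform(samples, rate)
        return c

    def test_dimensionality(self, small_corpus):
        corpus, _ = small_corpus
        vec = mfcc_features(corpus.calls[0])
        assert len(vec) == 192
        sds = vec[[n for n in vec.index if n.endswith(".sd")]]
        assert (sds >= 0).all()

    def test_stationary_tone_has_near_zero_deltas(self):
        # hop-periodic tone: every analysis frame sees the identical signal
        rate = 44100.0
        hop = int(round(0.023 * rate)) - int(round(0.023 * rate) * 0.5)
        f = 10 * rate / hop
        samples, rate = self._tone(seconds=0.4, rate=rate, f=f)
        vec = mfcc_features(self._call_with(samples, rate))
        cep_scale = np.abs(vec[[f"mfcc{k:02d}.mean" for k in range(1, 33)]]).max()
        deltas = vec[[n for n in vec.index if n.startswith(("d", "dd")) and n.endswith(".mean")]]
        assert np.abs(deltas).max() < 1e-3 * cep_scale

    def test_deterministic(self, small_corpus):
        corpus, _ = small_corpus
        v1 = mfcc_features(corpus.calls[0])
        v2 = mfcc_features(corpus.calls[0])
        np.testing.assert_array_equal(v1.to_numpy(), v2.to_numpy())

    def test_hop_translation_changes_means_little(self):
        samples, rate = self._tone(seconds=0.5)
        hop = int(round(0.023 * rate)) // 2
        v1 = mfcc_features(self._call_with(samples[: int(0.4 * rate)], rate))
        v2 = mfcc_features(self._call_with(samples[hop : hop + int(0.4 * rate)], rate))
        means = [n for n in v1.index if n.startswith("mfcc") and n.endswith(".mean")]
        scale = np.abs(v1[means]).max()
        assert np.abs(v1[means] - v2[means]).max() < 0.01 * scale

    def test_too_short_waveform_raises(self):
        samples, rate = self._tone(seconds=0.02)
        with pytest.raises(ValueError, match="too short"):
            mfcc_features(self._call_with(samples, rate))


class TestTemplate:
    def test_identical_calls_zero_band_width(self):
        calls = [make_call(f"c{i}", f0=np.linspace(200, 400, 50)) for i in range(5)]
        tpl = f0_template(calls)
        np.testing.assert_allclose(tpl.mean_f0, np.interp(tpl.grid, calls[0].f0_contour[:, 0], calls[0].f0_contour[:, 1]), rtol=1e-9)
        lo, hi = tpl.bands[80]
        np.testing.assert_allclose(hi - lo, 0.0, atol=1e-9)

    def test_two_constant_contours_average(self):
        calls = [
            make_call("a", f0=np.full(50, 100.0)),
            make_call("b", f0=np.full(50, 200.0)),
        ]
        tpl = f0_template(calls)
        np.testing.assert_allclose(tpl.mean_f0, 150.0)

    def test_bands_nested(self, small_corpus):
        corpus, _ = small_corpus
        calls = [c for c in corpus if c.call_type == "SB"]
        tpl = f0_template(calls)
        lo50, hi50 = tpl.bands[50]
        lo80, hi80 = tpl.bands[80]
        assert (lo80 <= lo50 + 1e-9).all() and (hi50 <= hi80 + 1e-9).all()

    def test_coverage_of_50_percent_band(self, rng):
        t = np.linspace(0.0, 0.2, 40)
        base = 300 + 100 * np.sin(np.pi * t / 0.2)
        calls = [
            make_call(f"c{i}", times=t, f0=base + rng.normal(0, 15, size=40))
            for i in range(100)
        ]
        tpl = f0_template(calls)
        lo, hi = tpl.bands[50]
        curves = np.stack(
            [np.interp(tpl.grid, t * tpl.mean_duration / 0.2, c.f0_contour[:, 1]) for c in calls]
        )
        inside = ((curves >= lo) & (curves <= hi)).mean(axis=0)
        assert np.all(np.abs(inside - 0.5) <= 0.10)

    def test_time_scaling_covariance(self):
        t = np.linspace(0.0, 0.2, 50)
        f = 300 + 100 * np.sin(np.pi * t / 0.2)
        calls = [make_call(f"c{i}", times=t, f0=f + 10 * i) for i in range(3)]
        scaled = [
            make_call(f"s{i}", times=2 * t, f0=f + 10 * i, duration=0.4) for i in range(3)
        ]
        tpl = f0_template(calls)
        tpl2 = f0_template(scaled)
        assert tpl2.mean_duration == pytest.approx(2 * tpl.mean_duration)
        np.testing.assert_allclose(tpl2.mean_f0, tpl.mean_f0, rtol=1e-9)

    def test_mixed_types_rejected(self):
        calls = [make_call("a", call_type="P"), make_call("b", call_type="B")]
        with pytest.raises(ValueError, match="share a type"):
            f0_template(calls)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            f0_template([])


class TestFeatureTableAssembly:
    def test_cardinalities(self, small_corpus):
        corpus, _ = small_corpus
        sub = corpus.subset(corpus.call_ids[:12])
        assert len(build_feature_table(sub, "bioacoustic").feature_names) == 20
        assert len(build_feature_table(sub, "dct").feature_names) == 7
        assert len(build_feature_table(sub, "mfcc").feature_names) == 192
        union = build_feature_table(sub, "union")
        assert len(union.feature_names) == 217  # duration & HNR deduplicated

    def test_default_bioacoustic_set_is_the_documented_one(self):
        assert len(BIOACOUSTIC_SET) == 20
        assert {"duration", "hnr"} <= set(BIOACOUSTIC_SET)
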