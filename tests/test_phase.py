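"""Phase extraction, order parameter, and synchronization/metastability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from phasesync import (
    BoldTimeSeries,
    OrderTrace,
    ParcellationMap,
    PhaseMatrix,
    bandpass,
    instantaneous_phase,
    network_metrics,
    order_parameter,
    sync_metrics,
)
from conftest import order_parameter_bruteforce


def fft_amplitude(x: np.ndarray, freq: float, tr: float) -> float:
    """Single-bin FFT amplitude oracle for a sinusoid of known frequency."""
    n = x.size
    spectrum = np.abs(np.fft.rfft(x)) * 2 / n
    freqs = np.fft.rfftfreq(n, d=tr)
    return spectrum[np.argmin(np.abs(freqs - freq))]


class TestBandpass:
    def _sine_ts(self, f, tr=2.0, n=400):
        t = np.arange(n) * tr
        return BoldTimeSeries(np.sin(2 * np.pi * f * t)[None, :], tr=tr)

    def test_in_band_amplitude_preserved(self):
        ts = self._sine_ts(0.05)
        out = bandpass(ts, 0.01, 0.1)
        before = fft_amplitude(ts.values[0], 0.05, ts.tr)
        after = fft_amplitude(out.values[0], 0.05, ts.tr)
        assert after == pytest.approx(before, rel=0.05)

    def test_out_of_band_attenuated(self):
        ts = self._sine_ts(0.2)
        out = bandpass(ts, 0.01, 0.1)
        before = fft_amplitude(ts.values[0], 0.2, ts.tr)
        after = fft_amplitude(out.values[0], 0.2, ts.tr)
        assert after <= 0.2 * before

    def test_dc_removed(self):
        ts = BoldTimeSeries(np.full((2, 100), 7.3), tr=2.0)
        out = bandpass(ts, 0.01, 0.1)
        assert np.abs(out.values).max() < 1e-6

    def test_band_outside_nyquist_names_admissible_range(self):
        ts = self._sine_ts(0.05)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(ts, 0.01, 0.3)  # Nyquist = 0.25 Hz at tr = 2 s
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(ts, 0.1, 0.01)


class TestInstantaneousPhase:
    def test_cosine_phase_slope(self, cosine_series):
        """Unwrapped phase of a 0.05 Hz cosine advances at 2*pi*0.05 rad/s."""
        phases = instantaneous_phase(cosine_series)
        L = phases.n_timepoints
        lo, hi = int(0.1 * L), int(0.9 * L)
        unwrapped = np.unwrap(phases.phases[0])[lo:hi]
        slope = np.polyfit(np.arange(unwrapped.size) * cosine_series.tr, unwrapped, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 0.05, rel=0.01)

    def test_cosine_sine_quadrature(self):
        tr, L, f = 2.0, 200, 0.05
        t = np.arange(L) * tr
        ts = BoldTimeSeries(
            np.vstack([np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t)]), tr=tr
        )
        phases = instantaneous_phase(ts)
        lo, hi = int(0.1 * L), int(0.9 * L)
        diff = phases.phases[0, lo:hi] - phases.phases[1, lo:hi]
        circ = np.angle(np.exp(1j * diff))
        assert np.allclose(circ, np.pi / 2, atol=0.05)

    def test_amplitude_invariance(self, cosine_series, rng):
        noisy = BoldTimeSeries(
            cosine_series.values + 0.1 * rng.standard_normal(cosine_series.values.shape),
            tr=cosine_series.tr,
            region_ids=cosine_series.region_ids,
        )
        scaled = BoldTimeSeries(5.0 * noisy.values, tr=noisy.tr, region_ids=noisy.region_ids)
        assert np.allclose(
            instantaneous_phase(noisy).phases, instantaneous_phase(scaled).phases
        )

    def test_zero_variance_region_named(self):
        values = np.vstack([np.ones(50), np.sin(np.arange(50.0))])
        ts = BoldTimeSeries(values, tr=2.0, region_ids=("flat", "ok"))
        with pytest.raises(ValueError, match="flat"):
            instantaneous_phase(ts)


class TestOrderParameter:
    def test_full_lock_gives_one(self):
        phases = PhaseMatrix(np.full((4, 10), 0.3), tr=2.0)
        assert np.allclose(order_parameter(phases).r, 1.0)

    def test_symmetric_phases_cancel(self):
        col = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        phases = PhaseMatrix(np.tile(col[:, None], (1, 5)), tr=2.0)
        assert np.allclose(order_parameter(phases).r, 0.0, atol=1e-12)

    def test_two_thirds_cancellation(self):
        col = np.array([0.0, 0.0, np.pi])
        phases = PhaseMatrix(np.tile(col[:, None], (1, 3)), tr=2.0)
        assert np.allclose(order_parameter(phases).r, 1.0 / 3.0, atol=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(2, 6)
            L = rng.integers(2, 11)
            raw = rng.uniform(-np.pi, np.pi, size=(n, L))
            phases = PhaseMatrix(raw, tr=2.0)
            expected = order_parameter_bruteforce(phases.phases)
            assert np.allclose(order_parameter(phases).r, expected, atol=1e-12)

    def test_unknown_region_listed(self, random_phases):
        with pytest.raises(KeyError, match="nope"):
            order_parameter(random_phases, subset=["R000", "nope"])

    def test_empty_subset_rejected(self, random_phases):
        with pytest.raises(ValueError):
            order_parameter(random_phases, subset=[])

    @given(
        hnp.arrays(
            np.float64,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=8),
            elements=st.floats(-10, 10),
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_r_bounded_in_unit_interval(self, raw):
        phases = PhaseMatrix(raw, tr=1.0)
        r = order_parameter(phases).r
        assert np.all(r >= 0.0) and np.all(r <= 1.0)


class TestSyncMetrics:
    def test_constant_trace(self):
        trace = OrderTrace(np.full(10, 0.7), tr=2.0)
        m = sync_metrics(trace)
        assert m.synchronization == pytest.approx(0.7)
        assert m.metastability == 0.0

    def test_alternating_trace_sample_sd(self):
        trace = OrderTrace(np.array([0.0, 1.0, 0.0, 1.0]), tr=2.0)
        m = sync_metrics(trace)
        assert m.synchronization == pytest.approx(0.5)
        assert m.metastability == pytest.approx(np.sqrt(1.0 / 3.0))

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            sync_metrics(OrderTrace(np.array([0.5]), tr=2.0))


class TestNetworkMetrics:
    def test_single_network_equals_global(self, random_phases):
        pmap = ParcellationMap({rid: "default" for rid in random_phases.region_ids})
        metrics = {m.scope_label: m for m in network_metrics(random_phases, pmap)}
        assert metrics["default"].synchronization == metrics["global"].synchronization
        assert metrics["default"].metastability == metrics["global"].metastability

    def test_locked_subnetworks_beat_global(self, rng):
        """Two internally locked but mutually independent networks."""
        L = 30
        theta_a = rng.uniform(-np.pi, np.pi, size=L)
        theta_b = np.angle(np.exp(1j * (theta_a + np.pi)))  # anti-phase
        raw = np.vstack([theta_a, theta_a, theta_b, theta_b])
        phases = PhaseMatrix(raw, tr=2.0, region_ids=("a1", "a2", "b1", "b2"))
        pmap = ParcellationMap({"a1": "visual", "a2": "visual", "b1": "default", "b2": "default"})
        metrics = {m.scope_label: m for m in network_metrics(phases, pmap)}
        assert metrics["visual"].synchronization == pytest.approx(1.0)
        assert metrics["default"].synchronization == pytest.approx(1.0)
        assert metrics["global"].synchronization == pytest.approx(0.0, abs=1e-12)

    def test_unmapped_parcel_excluded_with_warning(self, random_phases, caplog):
        ids = random_phases.region_ids
        pmap = ParcellationMap({rid: "visual" for rid in ids[:-1]})
        with caplog.at_level("WARNING"):
            metrics = network_metrics(random_phases, pmap)
        assert any(ids[-1] in rec.message for rec in caplog.records)
        assert {m.scope_label for m in metrics} == {"global", "visual"}
        assert metrics[0].n_regions == len(ids) - 1

    def test_small_network_skipped(self, random_phases, caplog):
        ids = random_phases.region_ids
        mapping = {rid: "visual" for rid in ids[:-1]}
        mapping[ids[-1]] = "limbic"  # one parcel only
        with caplog.at_level("WARNING"):
            metrics = network_metrics(random_phases, ParcellationMap(mapping))
        assert "limbic" not in {m.scope_label for m in metrics}

    def test_disjoint_map_rejected(self, random_phases):
        pmap = ParcellationMap({"other": "visual"})
        with pytest.raises(ValueError, match="overlap"):
            network_metrics(random_phases, pmap)

    def test_region_permutation_invariance(self, random_phases, rng):
        perm = rng.permutation(random_phases.n_regions)
        shuffled = PhaseMatrix(
            random_phases.phases[perm],
            tr=random_phases.tr,
            region_ids=tuple(random_phases.region_ids[i] for i in perm),
        )
        pmap = ParcellationMap(
            {rid: ("visual" if i % 2 else "default") for i, rid in enumerate(random_phases.region_ids)}
        )
        a = {m.scope_label: m for m in network_metrics(random_phases, pmap)}
        b = {m.scope_label: m for m in network_metrics(shuffled, pmap)}
        assert a.keys() == b.keys()
        for key in a:
            assert a[key].synchronization == pytest.approx(b[key].synchronization, abs=1e-12)

    def test_trim_drops_edges(self, random_phases):
        pmap = ParcellationMap({rid: "visual" for rid in random_phases.region_ids})
        full = order_parameter(random_phases).r
        trimmed = network_metrics(random_phases, pmap, trim=5)
        expected = full[5:-5]
        assert trimmed[0].synchronization == pytest.approx(expected.mean())


class TestValidation:
    def test_non_finite_rejected(self):
        values = np.ones((2, 30))
        values[1, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            BoldTimeSeries(values, tr=2.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            BoldTimeSeries(np.ones((2, 10)), tr=2.0)

    def test_duplicate_region_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            BoldTimeSeries(np.ones((2, 30)), tr=2.0, region_ids=("a", "a"))

    def test_phase_wrapping_range(self, rng):
        phases = PhaseMatrix(rng.uniform(-20, 20, size=(3, 25)), tr=1.0)
        assert (phases.phases > -np.pi).all() and (phases.phases <= np.pi).all()
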