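import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snnpart.emulator import (
    EventBatch,
    LIFParams,
    apply_bandwidth_limit,
    auto_scale,
    integrate_instance,
    itl_scale_factor,
    quantize_weights,
)
from snnpart.errors import UndefinedScaleError, ValidationError
from snnpart.substrate import ChipSpec


def single_event(n_neurons=1, t=0.0):
    return EventBatch([0], [t], [0], 1, n_neurons)


def closed_form_psp(t, w, p: LIFParams):
    """Analytic membrane response to one input spike at t=0 (subthreshold)."""
    return (
        (w / p.g_l)
        * p.tau_s / (p.tau_m - p.tau_s)
        * (np.exp(-t / p.tau_m) - np.exp(-t / p.tau_s))
    )


class TestDynamics:
    def test_zero_weights_mean_silence_at_leak(self):
        ev = EventBatch([0, 0, 0], [1.0, 2.0, 3.0], [0, 1, 2], 1, 3)
        out, tr, _ = integrate_instance(ev, np.zeros((3, 4)), LIFParams(), 30.0, 0.5)
        assert len(out) == 0
        assert np.all(tr.values == LIFParams().e_l)

    @pytest.mark.parametrize("dt", [0.5, 0.05])
    def test_single_event_subthreshold_matches_closed_form_on_grid(self, dt):
        p = LIFParams(tau_m=10.0, tau_s=5.0, v_th=100.0)
        _, tr, _ = integrate_instance(single_event(), np.array([[1.0]]), p, 30.0, dt)
        t = (np.arange(tr.n_bins) + 1) * dt  # recorded value is membrane at (t+1)dt
        assert np.abs(tr.values[0, :, 0] - closed_form_psp(t, 1.0, p)).max() < 1e-12

    def test_off_grid_event_error_shrinks_first_order(self):
        p = LIFParams(tau_m=10.0, tau_s=5.0, v_th=100.0)
        t0 = 0.37  # not a lattice point at either resolution
        errs = []
        for dt in (0.5, 0.05):
            _, tr, _ = integrate_instance(single_event(t=t0), np.array([[1.0]]), p, 30.0, dt)
            t = (np.arange(tr.n_bins) + 1) * dt
            ref = np.where(t > t0, closed_form_psp(np.maximum(t - t0, 0), 1.0, p), 0.0)
            errs.append(np.abs(tr.values[0, :, 0] - ref).max())
        assert errs[1] < errs[0] / 5  # ~10x for first-order convergence

    def test_spike_time_matches_fine_grid_reference_within_one_bin(self):
        p = LIFParams(tau_m=10.0, tau_s=5.0, v_th=0.2)
        dt = 0.5
        coarse, _, _ = integrate_instance(single_event(), np.array([[1.0]]), p, 30.0, dt)
        fine, _, _ = integrate_instance(single_event(), np.array([[1.0]]), p, 30.0, dt / 100)
        assert len(coarse) == len(fine) == 1
        assert abs(coarse.times[0] - fine.times[0]) <= dt

    def test_refractory_period_suppresses_immediate_respiking(self):
        p_ref = LIFParams(tau_m=10.0, tau_s=5.0, v_th=0.05, tau_ref=5.0)
        p_free = LIFParams(tau_m=10.0, tau_s=5.0, v_th=0.05, tau_ref=0.0)
        ev = single_event()
        out_ref, _, _ = integrate_instance(ev, np.array([[2.0]]), p_ref, 30.0, 0.5)
        out_free, _, _ = integrate_instance(ev, np.array([[2.0]]), p_free, 30.0, 0.5)
        assert len(out_ref) < len(out_free)
        if len(out_ref) > 1:
            assert np.diff(out_ref.times).min() >= p_ref.tau_ref

    def test_max_over_time_invariant_under_event_reordering_within_bin(self):
        p = LIFParams(leaky_integrate_only=True)
        w = np.array([[0.3], [0.5], [0.2]])
        # same bin occupancy, different arrival order within the bin
        ev1 = EventBatch([0, 0, 0], [1.0, 1.1, 1.3], [0, 1, 2], 1, 3)
        ev2 = EventBatch([0, 0, 0], [1.3, 1.0, 1.1], [2, 0, 1], 1, 3)
        _, tr1, _ = integrate_instance(ev1, w, p, 30.0, 0.5)
        _, tr2, _ = integrate_instance(ev2, w, p, 30.0, 0.5)
        assert tr1.values.max() == tr2.values.max()

    def test_non_finite_weights_rejected(self):
        with pytest.raises(ValidationError):
            integrate_instance(single_event(), np.array([[np.nan]]), LIFParams(), 30.0, 0.5)


class TestQuantization:
    def test_zero_maps_to_zero_and_saturation_clips(self):
        assert quantize_weights(np.array([0.0]), 10.0)[0] == 0
        assert quantize_weights(np.array([100.0]), 10.0)[0] == 63
        assert quantize_weights(np.array([-100.0]), 10.0)[0] == -63

    def test_round_half_even_at_boundaries(self):
        assert quantize_weights(np.array([0.5]), 100.0)[0] == 50
        # numpy round-half-to-even: 0.505*100 = 50.5 -> 50, 0.515*100 = 51.5 -> 52
        assert quantize_weights(np.array([0.505]), 100.0)[0] == 50
        assert quantize_weights(np.array([0.515]), 100.0)[0] == 52

    def test_fine_quantization_approaches_ideal_dynamics(self):
        rng = np.random.default_rng(3)
        w = rng.normal(0, 0.3, (5, 4))
        ev = EventBatch([0] * 5, [0.0, 1.0, 2.0, 3.0, 4.0], np.arange(5), 1, 5)
        p = LIFParams(v_th=0.4)
        _, tr_ideal, _ = integrate_instance(ev, w, p, 30.0, 0.5, mode="ideal")
        errs = []
        for levels in (64, 64 * 1024):
            spec = ChipSpec(weight_levels=levels, readout_range=(-100, 100))
            _, tr_q, _ = integrate_instance(
                ev, w, p, 30.0, 0.5, mode="constrained", spec=spec, bandwidth_limit=False
            )
            errs.append(np.abs(tr_q.values - tr_ideal.values).max())
        assert errs[1] < errs[0] / 100
        assert errs[1] < 1e-4


class TestBandwidthLimit:
    def test_sparse_stream_passes_untouched(self):
        ev = EventBatch([0, 0], [0.0, 1.0], [0, 1], 1, 2)
        kept, dropped = apply_bandwidth_limit(ev)
        assert dropped == 0
        assert np.array_equal(kept.times, ev.sorted().times)

    def test_burst_with_bounded_queue_enumerated_by_hand(self):
        # 10 simultaneous spikes, 2 per 8 ns cycle, queue depth 4:
        # 2 on time, 4 delayed into the next two cycles, 4 dropped.
        ev = EventBatch([0] * 10, [0.0] * 10, np.arange(10), 1, 10)
        kept, dropped = apply_bandwidth_limit(ev, ChipSpec(), queue_depth=4)
        assert dropped == 4
        assert len(kept) == 6
        assert np.allclose(sorted(kept.times), [0.0, 0.0, 0.008, 0.008, 0.016, 0.016])

    def test_empty_batch(self):
        kept, dropped = apply_bandwidth_limit(EventBatch.empty(2, 4))
        assert len(kept) == 0 and dropped == 0

    @settings(derandomize=True, max_examples=40)
    @given(
        times=st.lists(st.floats(0, 2.0, allow_nan=False), min_size=0, max_size=40),
        depth=st.integers(0, 8),
    )
    def test_conservation_never_creates_events(self, times, depth):
        ev = EventBatch([0] * len(times), times, [0] * len(times), 1, 1)
        kept, dropped = apply_bandwidth_limit(ev, queue_depth=depth)
        assert len(kept) + dropped == len(times)
        # delayed events are only ever moved later in time
        if len(kept):
            assert kept.times.min() >= min(times) - 1e-12


class TestItlScale:
    def test_identical_traces_give_unity(self):
        tr = np.linspace(0, 1, 50).reshape(1, 50, 1)
        assert itl_scale_factor(tr, tr) == pytest.approx(1.0)

    def test_half_amplitude_gives_two(self):
        ref = np.linspace(0, 1, 50).reshape(1, 50, 1)
        assert itl_scale_factor(0.5 * ref, ref) == pytest.approx(2.0)

    def test_noisy_proportional_traces_recovered(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(0, 1, (4, 100, 3))
        hw = ref / 1.7 + rng.normal(0, 0.01, ref.shape)
        assert itl_scale_factor(hw, ref) == pytest.approx(1.7, abs=0.05)

    def test_all_clipped_is_undefined(self):
        hw = np.full((1, 10, 1), 2.0)
        with pytest.raises(UndefinedScaleError):
            itl_scale_factor(hw, hw, readout_range=(-2.0, 2.0))


class TestEventBatch:
    @settings(derandomize=True, max_examples=40)
    @given(st.data())
    def test_raster_round_trip_for_grid_aligned_events(self, data):
        n_bins, n_neurons = 12, 5
        n_ev = data.draw(st.integers(0, 20))
        bins = data.draw(st.lists(st.integers(0, n_bins - 1), min_size=n_ev, max_size=n_ev))
        neurons = data.draw(st.lists(st.integers(0, n_neurons - 1), min_size=n_ev, max_size=n_ev))
        ev = EventBatch([0] * n_ev, [b * 0.5 for b in bins], neurons, 1, n_neurons)
        raster = ev.to_raster(n_bins, 0.5)
        back = EventBatch.from_raster(raster, 0.5)
        # round trip is identity up to duplicate collapse and ordering
        expect = {(b * 0.5, n) for b, n in zip(bins, neurons)}
        got = set(zip(back.times.tolist(), back.neurons.tolist()))
        assert got == expect
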