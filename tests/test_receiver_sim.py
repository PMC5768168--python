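import numpy as np
import pytest

from cpditools import (
    ArrivalEvent,
    Environment,
    FailureMode,
    MultipathArrival,
    PairGeometry,
    ReceiverSpec,
    decode,
    direct_path_length,
    enumerate_multipaths,
    impulse_response,
    make_ping_train,
    pairwise_overlap_probability,
    predict_cpdi_point,
    random_code_intervals,
    simulate_collisions,
    superpose,
)

C = 1530.0


def _mp(length: float, delay: float) -> MultipathArrival:
    return MultipathArrival(
        path_length=length, vertical_image_distance=length, surface_bounces=1,
        bottom_bounces=0, relative_delay=delay, amplitude_scalar=1.0 / length,
    )


class TestPingTrain:
    def test_uniform_half_second_intervals(self, deep_spec):
        train = make_ping_train(deep_spec, [0.5] * 7, start_time=0.0)
        assert train.ping_times == tuple(pytest.approx(0.5 * i) for i in range(8))
        assert train.duration == pytest.approx(3.5)
        assert train.sync_interval == pytest.approx(0.5)
        assert train.checksum_interval == pytest.approx(0.5)

    def test_seeded_intervals_deterministic(self, deep_spec):
        a = random_code_intervals(deep_spec, np.random.default_rng(7))
        b = random_code_intervals(deep_spec, np.random.default_rng(7))
        assert np.array_equal(a, b)
        assert np.all((a >= 0.3) & (a < 0.7))
        train = make_ping_train(deep_spec, a)
        # a full train with 0.3-0.7 s intervals lasts roughly 3-5 s
        assert 0.3 * 7 <= train.duration <= 0.7 * 7

    def test_interval_shorter_than_blanking_rejected(self, deep_spec):
        with pytest.raises(ValueError, match="self-blank"):
            make_ping_train(deep_spec, [0.5] * 6 + [0.2])

    def test_wrong_interval_count_rejected(self, deep_spec):
        with pytest.raises(ValueError, match="7 code intervals"):
            make_ping_train(deep_spec, [0.5] * 5)


class TestImpulseResponse:
    def test_inverse_path_length_amplitude(self):
        ir = impulse_response([_mp(100.0, 0.05)], direct_length=50.0)
        assert ir[0] == (0.0, pytest.approx(1 / 50))
        assert ir[1] == (pytest.approx(0.05), pytest.approx(0.01))

    def test_doubling_length_halves_amplitude(self):
        a = impulse_response([_mp(200.0, 0.1)], 50.0)[1][1]
        b = impulse_response([_mp(400.0, 0.1)], 50.0)[1][1]
        assert a == pytest.approx(2 * b)

    def test_direct_plus_surface_bounce_delay(self):
        delay = (598.0 - 500.0) / C
        ir = impulse_response([_mp(598.0, delay)], 500.0)
        assert ir == [
            (0.0, pytest.approx(1 / 500)),
            (pytest.approx(0.06405, abs=1e-4), pytest.approx(1 / 598)),
        ]

    def test_zero_direct_length_instructs_unit_mode(self):
        with pytest.raises(ValueError, match="unit_amplitude"):
            impulse_response([], direct_length=0.0)
        ir = impulse_response([_mp(2.0, 2 / C)], 0.0, unit_amplitude=True)
        assert ir[0] == (0.0, 1.0)


class TestSuperpose:
    def test_cardinality(self, deep_spec):
        train = make_ping_train(deep_spec, [0.5] * 7)
        assert len(superpose(train, [(0.0, 1.0)])) == 8
        ir21 = [(0.0, 1.0)] + [(0.01 * k, 0.1) for k in range(1, 21)]
        assert len(superpose(train, ir21)) == 168

    def test_sorted_and_grouped_by_ping_for_short_delays(self, deep_spec):
        train = make_ping_train(deep_spec, [0.5] * 7)
        events = superpose(train, [(0.0, 1.0), (0.1, 0.5), (0.2, 0.25)])
        times = [e.time for e in events]
        assert times == sorted(times)
        assert [e.source_ping for e in events] == sorted(e.source_ping for e in events)


class TestDecode:
    def _train(self, spec):
        return make_ping_train(spec, [0.5] * 7)

    def test_direct_only_detected(self, deep_spec):
        train = self._train(deep_spec)
        events = superpose(train, impulse_response([], 500.0))
        out = decode(events, deep_spec, train.intervals, threshold=1 / 843.0)
        assert out.detected
        assert out.failure_mode is FailureMode.NONE
        assert len(out.registered_times) == 8

    def test_late_multipath_causes_rejection(self, deep_spec):
        # category-2: delay beyond the 260 ms blanking, loud enough to register
        train = self._train(deep_spec)
        ir = impulse_response([_mp(600.0, 0.30)], 500.0)
        out = decode(superpose(train, ir), deep_spec, train.intervals,
                     threshold=1 / 843.0)
        assert not out.detected
        assert out.failure_mode is FailureMode.SPURIOUS_PING

    def test_blanked_multipath_harmless(self, deep_spec):
        # category-1: inside the blanking interval, absorbed
        train = self._train(deep_spec)
        ir = impulse_response([_mp(550.0, 0.10), _mp(580.0, 0.2)], 500.0)
        out = decode(superpose(train, ir), deep_spec, train.intervals,
                     threshold=1 / 843.0)
        assert out.detected

    def test_subthreshold_events_invariant(self, deep_spec):
        # category-3 analogue: quieter than a path of AMDR length
        train = self._train(deep_spec)
        base = superpose(train, impulse_response([], 500.0))
        noisy = superpose(train, impulse_response([_mp(900.0, 0.3)], 500.0))
        thr = 1 / 843.0
        assert decode(noisy, deep_spec, train.intervals, threshold=thr) == decode(
            base, deep_spec, train.intervals, threshold=thr
        )

    def test_missing_pings_reported(self, deep_spec):
        train = self._train(deep_spec)
        events = superpose(train, impulse_response([], 500.0))[:5]
        out = decode(events, deep_spec, train.intervals, threshold=0.0)
        assert out.failure_mode is FailureMode.MISSING_PING

    def test_interval_mismatch_reported(self, deep_spec):
        train = self._train(deep_spec)
        events = superpose(train, impulse_response([], 500.0))
        wrong = [0.5] * 6 + [0.6]
        out = decode(events, deep_spec, wrong, threshold=0.0)
        assert out.failure_mode is FailureMode.INTERVAL_MISMATCH

    def test_unsorted_events_rejected(self, deep_spec):
        events = [ArrivalEvent(1.0, 1.0, 0), ArrivalEvent(0.5, 1.0, 1)]
        with pytest.raises(ValueError, match="sorted"):
            decode(events, deep_spec, [0.5] * 7)


class TestCriterionAgreement:
    def test_decode_matches_cpdi_criterion(self):
        """Over randomized geometries, the waveform-free decoder and the
        category-2 criterion must reach the same verdict nearly always (both
        implement the same physics; divergence only at interval-tolerance
        edge cases)."""
        rng = np.random.default_rng(42)
        spec = ReceiverSpec(amdr=843.0)
        agree = total = 0
        for _ in range(500):
            depth = rng.uniform(25.0, 450.0)
            zt = depth - min(rng.uniform(1.0, 30.0), depth)
            zr = depth - min(rng.uniform(1.0, 30.0), depth)
            r = rng.uniform(0.0, spec.amdr)
            env = Environment(depth)
            geom = PairGeometry(zt, zr, r)
            flagged, _ = predict_cpdi_point(env, spec, zr, zt, r)
            arrivals = enumerate_multipaths(env, geom, max_path_length=2 * spec.amdr)
            direct = direct_path_length(geom)
            ir = impulse_response(arrivals, direct, unit_amplitude=direct == 0)
            intervals = random_code_intervals(spec, rng)
            train = make_ping_train(spec, intervals)
            out = decode(superpose(train, ir), spec, intervals,
                         threshold=1.0 / spec.amdr)
            agree += int(out.detected == (not flagged))
            total += 1
        assert agree / total >= 0.95


class TestCollisions:
    def test_single_tag_never_collides(self):
        per_hour, frac = simulate_collisions(1, hours=2, seed=0)
        assert frac == 1.0
        assert 3600 / 90 <= per_hour <= 3600 / 30

    def test_two_tags_match_analytic_overlap(self):
        hours = 300
        per_hour, frac = simulate_collisions(2, (30.0, 90.0), 3.5, hours, seed=1)
        expected = 1.0 - pairwise_overlap_probability(3.5, (30.0, 90.0))
        assert expected == pytest.approx(1 - 2 * 3.5 / 60)
        n_trans = 2 * hours * 60  # ~60 transmissions per tag-hour
        mc_se = np.sqrt(expected * (1 - expected) / n_trans)
        assert abs(frac - expected) <= 3 * mc_se

    def test_fraction_strictly_decreasing_in_tags(self):
        fracs = [simulate_collisions(n, hours=50, seed=3)[1] for n in (1, 5, 10, 20)]
        assert fracs == sorted(fracs, reverse=True)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_collisions(0)
        with pytest.raises(ValueError):
            simulate_collisions(2, (0.0, 10.0))
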