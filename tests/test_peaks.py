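"""Peak detector: baseline estimation, detection, FWHM, classification."""

import math

import numpy as np
import pytest

from astroca import core, io as aio, peaks


def _trace(values, dt=1.0):
    v = np.asarray(values, dtype=float)
    return core.SimulationTrace(time=np.arange(v.size) * dt, ca=v,
                                ip3=np.zeros_like(v),
                                open_count=np.zeros_like(v))


class TestBaseline:
    def test_constant_trace(self):
        est = peaks.estimate_baseline(np.full(500, 42.0))
        assert est.baseline == pytest.approx(42.0, abs=0.25)
        assert est.sigma == 0.0

    def test_gaussian_noise_recovers_mean_and_sd(self):
        rng = np.random.default_rng(5)
        m, s = 80.0, 3.0
        est = peaks.estimate_baseline(rng.normal(m, s, size=20_000),
                                      bin_width=0.25)
        assert est.baseline == pytest.approx(m, abs=2 * 0.25)
        assert est.sigma == pytest.approx(s, rel=0.1)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            peaks.estimate_baseline([])

    def test_n_outside_range_rejected(self):
        with pytest.raises(ValueError):
            peaks.estimate_baseline(np.ones(100), n=5.0)


class TestDetection:
    def test_flat_trace_has_no_peaks(self):
        tr = _trace(np.full(300, 50.0))
        est = peaks.estimate_baseline(tr.ca)
        assert peaks.detect_peaks(tr, est) == []

    def test_rectangular_pulse_amplitude_and_dff(self):
        """Height-150 pulse on a 50 baseline: A = 150, dFF = 2.0."""
        v = np.full(400, 50.0)
        v[100:120] = 150.0
        tr = _trace(v)
        est = peaks.estimate_baseline(tr.ca, n=3)
        found = peaks.detect_peaks(tr, est)
        assert len(found) == 1
        p = found[0]
        assert p.amplitude == 150.0
        assert p.dff == pytest.approx((150.0 - est.baseline) / est.baseline)
        assert p.dff == pytest.approx(2.0, abs=0.02)
        assert p.fwhm == pytest.approx(20.0, abs=1.0)
        assert p.fwhm <= p.t_end - p.t_start + 1.0

    def test_overlapping_excursions_merge(self):
        """No sub-threshold gap between two bumps -> one merged peak."""
        v = np.full(400, 50.0)
        v[100:140] = 120.0
        v[120:130] = 160.0  # second event inside the first
        tr = _trace(v)
        est = peaks.estimate_baseline(tr.ca, n=3)
        found = peaks.detect_peaks(tr, est)
        assert len(found) == 1
        assert found[0].amplitude == 160.0

    def test_threshold_monotone_in_n(self):
        rng = np.random.default_rng(9)
        v = 50 + rng.normal(0, 4, size=3000)
        v[::250] += 30
        counts = []
        for n in (2, 3, 4):
            est = peaks.estimate_baseline(v, n=n)
            counts.append(len(peaks.detect_peaks(_trace(v), est)))
        assert counts[0] >= counts[1] >= counts[2]

    def test_dff_invariant_under_rescaling(self):
        v = np.full(300, 50.0)
        v[100:110] = 130.0
        for scale in (1.0, 7.3):
            tr = _trace(v * scale)
            est = peaks.estimate_baseline(tr.ca, bin_width=0.25 * scale, n=3)
            p = peaks.detect_peaks(tr, est)[0]
            assert p.dff == pytest.approx((130 - 50) / 50, abs=0.03)

    def test_planted_peak_recovery_precision_recall(self):
        """On noisy fixtures with SNR >= 5, recall and precision >= 0.95."""
        hits = 0
        false_pos = 0
        total = 0
        recalled = 0
        for seed in range(6):
            spec = aio.FixtureSpec(baseline=50.0, noise_sd=2.0,
                                   peak_times=tuple(range(100, 1000, 180)),
                                   peak_amplitudes=(150, 120, 180, 140, 130),
                                   peak_fwhms=(10, 8, 15, 12, 9),
                                   duration=1000.0, seed=seed)
            trace, truth = aio.make_fixture(spec)
            est = peaks.estimate_baseline(trace.ca)
            found = peaks.detect_peaks(trace, est)
            total += len(truth)
            covered = set()
            for f in found:
                mid = (f.t_start + f.t_end) / 2
                inside = [k for k, t in enumerate(truth)
                          if t.t_start - 5 <= mid <= t.t_end + 5]
                if inside:
                    hits += 1
                    covered.update(inside)
                else:
                    false_pos += 1
            recalled += len(covered)
        recall = recalled / total
        precision = hits / (hits + false_pos)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_fwhm_exact_on_clean_gaussian_fixture(self):
        spec = aio.FixtureSpec(baseline=50.0, noise_sd=0.0,
                               peak_times=(300.0,), peak_amplitudes=(150.0,),
                               peak_fwhms=(12.0,), duration=600.0,
                               sample_dt=0.25)
        trace, truth = aio.make_fixture(spec)
        est = peaks.estimate_baseline(trace.ca, n=3)
        found = peaks.detect_peaks(trace, est)
        assert len(found) == 1
        assert found[0].fwhm == pytest.approx(12.0, abs=0.5)
        assert found[0].dff == pytest.approx(2.0, abs=0.01)


class TestClassification:
    def test_single_open_channel_is_blip(self):
        p = peaks.PeakRecord(0, 10, 100, 5, 1.0, max_open=1)
        assert peaks.classify_puff(p, np.zeros((3, 2)), 1.0) == "blip"

    def test_coincident_receptors_make_puff(self):
        p = peaks.PeakRecord(0, 10, 100, 5, 1.0, max_open=2,
                             open_receptors=(0, 1))
        pos = np.zeros((2, 2))
        assert peaks.classify_puff(p, pos, 0.5) == "puff"

    def test_infinite_diffusion_multi_open_is_puff(self):
        p = peaks.PeakRecord(0, 10, 100, 5, 1.0, max_open=3)
        assert peaks.classify_puff(p, None, math.inf) == "puff"

    def test_missing_positions_flagged_not_fatal(self):
        p = peaks.PeakRecord(0, 10, 100, 5, 1.0, max_open=2)
        assert peaks.classify_puff(p, None, 1.0) is None

    def test_diffusion_length_criterion_matches_hand_evaluation(self):
        """sqrt(2 d D FWHM) vs mean pairwise separation, both ways."""
        pos = np.array([[0.0, 0.0], [6.0, 0.0]])
        p = peaks.PeakRecord(0, 10, 100, 4.0, 1.0, max_open=2,
                             open_receptors=(0, 1))
        # 2D diffusion length sqrt(4*D*fwhm): D=1 -> 4.0 < 6.0 -> blip
        assert peaks.classify_puff(p, pos, 1.0) == "blip"
        # D=3 -> sqrt(48)=6.93 > 6.0 -> puff
        assert peaks.classify_puff(p, pos, 3.0) == "puff"


class TestStatistics:
    def test_frequency_arithmetic(self):
        ps = [peaks.PeakRecord(0, 1, 10, 1, 0.1)] * 3
        st = peaks.peak_statistics(ps, duration=600.0)
        assert st["frequency"] == pytest.approx(0.005)

    def test_zero_peaks(self):
        st = peaks.peak_statistics([], duration=100.0)
        assert st["frequency"] == 0.0
        assert math.isnan(st["mean_amplitude"])

    def test_bad_duration_rejected(self):
        with pytest.raises(ValueError):
            peaks.peak_statistics([], duration=0.0)
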