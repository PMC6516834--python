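"""Correction arithmetic, efficiency calculation, schedule segmentation,
bulk spectra, and photobleach verification."""

import dataclasses

import numpy as np
import pytest

from ndcfret import (
    CalibrationConstants,
    KineticsConfig,
    PhotophysicsConfig,
    default_schedule,
    simulate_control_trace,
    simulate_state_path,
    simulate_trace,
)
from ndcfret.fret import (
    build_fret_series,
    bulk_fret_from_spectrum,
    compute_fret,
    correct_acceptor,
    segment_schedule,
    subtract_background,
    verify_single_acceptor,
)


class TestBackgroundSubtraction:
    def test_zero_background_identity(self, clean_photo, schedule):
        tr = simulate_control_trace("negative", clean_photo, schedule, seed=0)
        out = subtract_background(tr, (0, 0, 0))
        np.testing.assert_array_equal(out.ch600, tr.ch600)

    def test_constant_subtraction(self, clean_photo, schedule):
        tr = simulate_control_trace("negative", clean_photo, schedule, seed=0)
        tr = tr.replace_channels(ch600=np.full(tr.n_frames, 100.0))
        out = subtract_background(tr, (0, 40, 0))
        np.testing.assert_allclose(out.ch600, 60.0)

    def test_residual_blank_mean_near_zero(self, schedule):
        photo = PhotophysicsConfig()
        tr = simulate_control_trace("acceptor_only", photo, schedule, seed=1)
        out = subtract_background(tr, photo.background_per_channel)
        blank = out.ch600[tr.laser_nm == 641]  # no donor, no 600 nm signal
        se = blank.std(ddof=1) / np.sqrt(len(blank))
        assert abs(blank.mean()) < 3 * se


class TestCorrectAcceptor:
    def test_worked_arithmetic(self):
        # I_A* = 100, S*donor_alone = 13, X*direct = 37 -> 50
        const = CalibrationConstants(S=0.13, n_S=1, X=0.37, n_X=1)
        out = correct_acceptor(np.array([100.0]), 100.0, 100.0, const)
        assert out[0] == pytest.approx(50.0)

    def test_zero_constants_identity(self):
        const = CalibrationConstants(S=0.0, n_S=1, X=0.0, n_X=1)
        series = np.array([10.0, 20.0, 30.0])
        np.testing.assert_array_equal(
            correct_acceptor(series, 100.0, 100.0, const), series
        )

    @pytest.mark.parametrize("S", [0.0, 0.13, 0.3])
    @pytest.mark.parametrize("X", [0.0, 0.37, 0.6])
    @pytest.mark.parametrize("e_closed", [0.5, 0.8, 0.95])
    def test_instantaneous_round_trip_exact(self, S, X, e_closed):
        """Noiseless forward simulation followed by instantaneous-mode
        correction recovers the generative sensitized emission and state
        efficiency to machine precision for any (S, X, E_closed)."""
        photo = PhotophysicsConfig(
            spillover_true=S, crossex_true=X, E_closed=e_closed,
            shot_noise=False, read_noise_sd=0.0, background_per_channel=(0, 0, 0),
            donor_bleach_rate=0.0, acceptor_bleach_rate=0.0,
        )
        sched = default_schedule(n_fret_frames=30)
        path = simulate_state_path(
            KineticsConfig(0.23, 0.96), sched.duration, sched.frame_rate, seed=11
        )
        tr = simulate_trace(path, photo, sched, seed=12)
        const = CalibrationConstants(S=S, S_sd=0.0, n_S=1, X=X, X_sd=0.0, n_X=1)
        series = build_fret_series(tr, const, instantaneous=True, check_acceptor=False)
        truth = tr.ground_truth["state_efficiency"][:30]
        np.testing.assert_allclose(
            series.I_A, truth * photo.donor_total_emission, atol=1e-9
        )
        ok = series.valid
        np.testing.assert_allclose(series.E[ok], truth[ok], atol=1e-12)


class TestComputeFret:
    @pytest.mark.parametrize(
        "ia, id_, expected",
        [(50.0, 50.0, 0.5), (0.0, 80.0, 0.0), (80.0, 0.0, 1.0)],
    )
    def test_simple_ratios(self, ia, id_, expected):
        E, valid = compute_fret(np.array([ia]), np.array([id_]))
        assert valid[0]
        assert E[0] == pytest.approx(expected)

    def test_nonpositive_total_flagged_invalid(self):
        E, valid = compute_fret(np.array([-5.0, 1.0]), np.array([5.0, 1.0]))
        assert not valid[0] and np.isnan(E[0])
        assert valid[1]


class TestBulkSpectrum:
    def test_paper_style_ratio(self):
        wl = np.array([560.0, 565.0, 670.0, 730.0])
        inten = np.array([700.0, 710.0, 290.0, 10.0])
        assert bulk_fret_from_spectrum(wl, inten) == pytest.approx(
            290.0 / (290.0 + 710.0)
        )

    def test_zero_acceptor(self):
        wl = np.linspace(560, 730, 50)
        inten = np.where(np.abs(wl - 565) < 5, 500.0, 0.0)
        assert bulk_fret_from_spectrum(wl, inten) == pytest.approx(0.0)

    def test_equal_peaks(self):
        wl = np.array([565.0, 670.0])
        assert bulk_fret_from_spectrum(wl, np.array([300.0, 300.0])) == 0.5

    def test_peak_outside_range_rejected(self):
        with pytest.raises(ValueError):
            bulk_fret_from_spectrum(np.array([600.0, 650.0]), np.array([1.0, 1.0]))


class TestSegmentSchedule:
    def test_default_segments(self, clean_photo):
        sched = default_schedule()
        tr = simulate_control_trace("negative", clean_photo, sched, seed=0)
        seg = segment_schedule(tr)
        assert (seg.fret.start, seg.fret.stop) == (0, 150)
        assert (seg.direct.start, seg.direct.stop) == (150, 200)
        assert (seg.bleach.start, seg.bleach.stop) == (200, 300)
        assert (seg.donor_alone.start, seg.donor_alone.stop) == (300, 400)

    def test_truncated_trace_rejected(self, clean_photo):
        sched = default_schedule()
        tr = simulate_control_trace("negative", clean_photo, sched, seed=0)
        short = dataclasses.replace(
            tr,
            time_s=tr.time_s[:-10], interval_id=tr.interval_id[:-10],
            laser_nm=tr.laser_nm[:-10], power_scale=tr.power_scale[:-10],
            ch525=tr.ch525[:-10], ch600=tr.ch600[:-10], ch700=tr.ch700[:-10],
        )
        with pytest.raises(ValueError):
            segment_schedule(short, sched)

    def test_fret_segment_ends_at_bleach(self, clean_photo, schedule):
        tr = simulate_control_trace("negative", clean_photo, schedule, seed=0)
        tr.ground_truth["acceptor_bleach_time"] = 7.23
        seg = segment_schedule(tr)
        assert seg.fret_end_frame == int(np.ceil(7.23 * 10))


class TestVerifySingleAcceptor:
    def test_one_step_trace(self):
        rng = np.random.default_rng(0)
        y = np.concatenate([np.full(40, 320.0), np.zeros(60)]) + rng.normal(0, 12, 100)
        ok, n = verify_single_acceptor(y)
        assert ok and n == 1

    def test_two_acceptor_trace(self):
        rng = np.random.default_rng(1)
        y = np.concatenate([np.full(30, 640.0), np.full(30, 320.0), np.zeros(40)])
        y = y + rng.normal(0, 12, 100)
        ok, n = verify_single_acceptor(y)
        assert not ok and n == 2

    def test_flat_background_trace(self):
        rng = np.random.default_rng(2)
        ok, n = verify_single_acceptor(rng.normal(0, 12, 100))
        assert not ok and n == 0

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            verify_single_acceptor(np.zeros(5))


class TestControlDistributions:
    def test_negative_control_centered_at_zero(self, true_constants, schedule):
        photo = PhotophysicsConfig()
        rng = np.random.default_rng(3)
        series = []
        for _ in range(40):
            tr = simulate_control_trace("negative", photo, schedule, rng)
            try:
                series.append(
                    build_fret_series(
                        tr, true_constants,
                        background=photo.background_per_channel,
                        check_acceptor=False,
                    )
                )
            except ValueError:  # dye verification failed
                continue
        pool = np.concatenate([s.valid_E for s in series])
        core = pool[np.abs(pool) < 0.45]  # exclude ratio-tail outliers
        se = core.std(ddof=1) / np.sqrt(len(core))
        assert abs(core.mean()) < 5 * se + 0.01

    def test_positive_control_centered_at_configured_e(self, clean_photo, schedule):
        # with S = X = 0 the scalar correction is exact for a static molecule
        photo = dataclasses.replace(clean_photo, spillover_true=0.0, crossex_true=0.0)
        const = CalibrationConstants(S=0.0, n_S=1, X=0.0, n_X=1)
        tr = simulate_control_trace("positive", photo, schedule, seed=4,
                                    positive_e=0.9)
        series = build_fret_series(tr, const, check_acceptor=False)
        np.testing.assert_allclose(series.valid_E, 0.9, atol=1e-12)

    def test_donor_enhanced_after_acceptor_bleach(self, paper_kinetics):
        # donor emission recovers once transfer stops: mean I_D in the
        # donor-alone interval exceeds the FRET-interval mean for
        # molecules that spend time in the closed state
        photo = PhotophysicsConfig(donor_bleach_rate=0.0)
        sched = default_schedule()
        rng = np.random.default_rng(5)
        gains = []
        for _ in range(30):
            path = simulate_state_path(
                paper_kinetics, sched.duration, sched.frame_rate, rng
            )
            if not path[:150].any():
                continue
            tr = simulate_trace(path, photo, sched, rng)
            if not np.isfinite(tr.ground_truth["acceptor_bleach_time"]):
                continue
            pre = tr.ch600[:150][
                tr.time_s[:150] < tr.ground_truth["acceptor_bleach_time"]
            ].mean()
            post = tr.ch600[300:].mean()
            gains.append(post - pre)
        assert np.mean(gains) > 0
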