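"""Detection, ROI integration, and colocalization on synthetic fields."""

import numpy as np
import pytest

from ndcfret import PhotophysicsConfig, default_schedule, simulate_control_trace
from ndcfret.imaging import (
    ParticleDetection,
    average_initial_frames,
    colocalize,
    detect_particles,
    integrate_roi,
)
from ndcfret.simulate import render_movie


def _grid_positions(n, spacing=10, start=8):
    pos = []
    i = 0
    while len(pos) < n:
        pos.append((start + spacing * (i % 8), start + spacing * (i // 8)))
        i += 1
    return pos


@pytest.fixture
def bright_photo():
    return PhotophysicsConfig(
        donor_total_emission=2000.0,
        acceptor_direct_emission=1000.0,
        background_per_channel=(0, 0, 0),
        read_noise_sd=0.0,
        donor_bleach_rate=0.0,
        acceptor_bleach_rate=0.0,
    )


class TestAverageInitialFrames:
    def test_constant_stack(self):
        stack = np.full((12, 8, 8), 3.0)
        np.testing.assert_allclose(average_initial_frames(stack), 3.0)

    def test_alternating_frames(self):
        stack = np.zeros((10, 4, 4))
        stack[1::2] = 2.0
        np.testing.assert_allclose(average_initial_frames(stack, 10), 1.0)

    def test_matches_brute_force_on_noise(self):
        rng = np.random.default_rng(0)
        stack = rng.poisson(50, size=(15, 16, 16)).astype(float)
        expected = sum(stack[i] for i in range(10)) / 10
        np.testing.assert_allclose(average_initial_frames(stack), expected)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            average_initial_frames(np.zeros((5, 4, 4)), 10)


class TestDetectParticles:
    def test_blank_image_empty(self):
        rng = np.random.default_rng(1)
        img = rng.normal(100, 3, size=(64, 64))
        assert detect_particles(img) == []

    def test_single_spot_subpixel_centroid(self, bright_photo):
        sched = default_schedule(n_fret_frames=10, n_direct_frames=1,
                                 n_bleach_frames=1, n_donor_alone_frames=1)
        tr = simulate_control_trace("donor_only", bright_photo, sched, seed=0)
        stacks, _ = render_movie([tr], [(20.4, 11.7)], fov=(40, 40),
                                 psf_sigma=1.0, background=10.0, noise=True, seed=2)
        img = average_initial_frames(stacks["ch600"])
        dets = detect_particles(img, min_snr=5)
        assert len(dets) == 1
        assert np.hypot(dets[0].x - 20.4, dets[0].y - 11.7) < 1.0

    def test_fifty_spots_all_found(self, bright_photo):
        sched = default_schedule(n_fret_frames=10, n_direct_frames=1,
                                 n_bleach_frames=1, n_donor_alone_frames=1)
        pos = _grid_positions(50)
        traces = [
            simulate_control_trace("donor_only", bright_photo, sched, seed=i)
            for i in range(50)
        ]
        stacks, sidecar = render_movie(traces, pos, fov=(88, 88), psf_sigma=1.0,
                                       background=10.0, noise=True, seed=3)
        img = average_initial_frames(stacks["ch600"])
        dets = detect_particles(img, min_snr=5, min_separation_px=5)
        assert len(dets) == len(sidecar["positions"]) == 50


class TestIntegrateRoi:
    def test_uniform_frame(self):
        stack = np.full((3, 20, 20), 2.0)
        np.testing.assert_allclose(integrate_roi(stack, (10, 10)), 49 * 2.0)

    def test_rendered_spot_mass(self, bright_photo):
        sched = default_schedule(n_fret_frames=5, n_direct_frames=1,
                                 n_bleach_frames=1, n_donor_alone_frames=1)
        tr = simulate_control_trace("donor_only", bright_photo, sched, seed=0)
        stacks, _ = render_movie([tr], [(16.0, 16.0)], fov=(32, 32), psf_sigma=1.0)
        roi = integrate_roi(stacks["ch600"], (16.0, 16.0))
        fret = tr.laser_nm == 561
        np.testing.assert_allclose(roi[:5], tr.ch600[:5], rtol=0.01)

    def test_edge_particle_rejected(self):
        stack = np.zeros((2, 20, 20))
        with pytest.raises(ValueError):
            integrate_roi(stack, (2, 10))


def _det(ch, x, y):
    return ParticleDetection(channel=ch, x=x, y=y, peak_intensity=1.0)


class TestColocalize:
    def test_identical_coordinates_two_color(self):
        classes = colocalize({"ch600": [_det("ch600", 5, 5)],
                              "ch700": [_det("ch700", 5, 5)]})
        assert [c.label for c in classes] == ["two_color"]

    def test_distant_detections_stay_single(self):
        classes = colocalize(
            {"ch600": [_det("ch600", 5, 5)], "ch700": [_det("ch700", 15, 5)]},
            max_dist_px=2.0,
        )
        assert sorted(c.label for c in classes) == ["acceptor_only", "donor_only"]

    def test_symmetric_in_channel_order(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(5, 55, size=(20, 2))
        d600 = [_det("ch600", x, y) for x, y in pts]
        d700 = [_det("ch700", x + rng.normal(0, 0.3), y + rng.normal(0, 0.3))
                for x, y in pts]
        a = colocalize({"ch600": d600, "ch700": d700})
        b = colocalize({"ch700": d700, "ch600": d600})
        assert sorted(c.label for c in a) == sorted(c.label for c in b)

    def test_stable_under_relabeling(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(5, 55, size=(15, 2))
        d600 = [_det("ch600", x, y) for x, y in pts]
        d700 = [_det("ch700", x, y) for x, y in pts]
        perm = rng.permutation(15)
        shuffled = [d700[i] for i in perm]
        a = colocalize({"ch600": d600, "ch700": d700})
        b = colocalize({"ch600": d600, "ch700": shuffled})
        assert sorted(c.label for c in a) == sorted(c.label for c in b)

    def test_mixed_field_recall(self):
        # 10 three-color, 20 two-color, 10 donor-only, 10 acceptor-only
        rng = np.random.default_rng(6)
        pos = _grid_positions(50, spacing=12)
        jitter = lambda: rng.normal(0, 0.2)
        d600, d700, d525 = [], [], []
        truth = []
        for i, (x, y) in enumerate(pos):
            if i < 10:
                truth.append("three_color")
                d525.append(_det("ch525", x + jitter(), y + jitter()))
                d600.append(_det("ch600", x + jitter(), y + jitter()))
                d700.append(_det("ch700", x + jitter(), y + jitter()))
            elif i < 30:
                truth.append("two_color")
                d600.append(_det("ch600", x + jitter(), y + jitter()))
                d700.append(_det("ch700", x + jitter(), y + jitter()))
            elif i < 40:
                truth.append("donor_only")
                d600.append(_det("ch600", x + jitter(), y + jitter()))
            else:
                truth.append("acceptor_only")
                d700.append(_det("ch700", x + jitter(), y + jitter()))
        classes = colocalize({"ch525": d525, "ch600": d600, "ch700": d700})
        from collections import Counter

        got = Counter(c.label for c in classes)
        want = Counter(truth)
        recall = sum(min(got[k], want[k]) for k in want) / sum(want.values())
        assert recall >= 0.95

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            colocalize({}, max_dist_px=0.0)
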