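import numpy as np
import pytest

from etsim.align import (
    FiducialTracks,
    apply_alignment,
    canonical_shift_gauge,
    detect_beads,
    solve_alignment,
    track_beads,
)
from etsim.tiltseries import (
    PerturbationSpec,
    TiltSchedule,
    default_schedule,
    perturb,
    render_bead_series,
)


def gaussian_spots(shape, centers, sigma=2.0, amplitude=100.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.zeros(shape)
    for cx, cy in centers:
        img += amplitude * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
    return img


def random_beads(rng, m, xy=60.0, z=35.0, min_sep_px=14.0):
    """Random 3D beads whose projections stay separated across a +-60 sweep,
    so rendered spots never merge and bias the detections."""
    t = np.deg2rad(np.linspace(-60, 60, 25))
    beads = []
    while len(beads) < m:
        c = np.array([rng.uniform(-xy, xy), rng.uniform(-xy, xy), rng.uniform(-z, z)])
        ok = True
        for b in beads:
            d = b - c
            px = d[0] * np.cos(t) - d[2] * np.sin(t)
            if np.min(np.hypot(px, d[1])) < min_sep_px:
                ok = False
                break
        if ok:
            beads.append(c)
    return np.asarray(beads)


class TestDetectBeads:
    def test_blank_image_gives_empty_set(self):
        assert len(detect_beads(np.zeros((64, 64)), 6)) == 0

    def test_synthetic_beads_found_subpixel(self):
        rng = np.random.default_rng(0)
        centers = np.stack([rng.uniform(10, 110, 10), rng.uniform(10, 110, 10)], axis=1)
        # enforce separation so spots do not merge
        keep = [centers[0]]
        for c in centers[1:]:
            if min(np.linalg.norm(c - k) for k in keep) > 12:
                keep.append(c)
        img = gaussian_spots((128, 128), keep)
        pts = detect_beads(img, 6)
        assert len(pts) == len(keep)
        for cx, cy in keep:
            d = np.hypot(pts.positions_px[:, 0] - cx, pts.positions_px[:, 1] - cy)
            assert d.min() < 0.5

    def test_deterministic(self):
        img = gaussian_spots((64, 64), [(20, 20), (40, 45)])
        a = detect_beads(img, 6)
        b = detect_beads(img, 6)
        assert np.array_equal(a.positions_px, b.positions_px)

    def test_small_diameter_rejected(self):
        with pytest.raises(ValueError):
            detect_beads(np.zeros((32, 32)), 1.0)


class TestTrackBeads:
    def test_unperturbed_tracks_match_forward_model(self):
        rng = np.random.default_rng(1)
        beads = random_beads(rng, 5)
        sch = default_schedule(step=5)
        series = render_bead_series(beads, sch, (160, 160))
        tracks = track_beads(series, diameter_px=5, gate_px=15)
        assert len(tracks) == 5
        c = (160 - 1) / 2.0
        t_rad = np.deg2rad(np.asarray(sch.angles_deg))
        for tr in tracks.tracks:
            # identify which bead by the zero-tilt-most observation
            i0 = min(tr, key=lambda i: abs(sch.angles_deg[i]))
            obs = tr[i0]
            d = np.hypot(beads[:, 0] * np.cos(t_rad[i0]) - beads[:, 2] * np.sin(t_rad[i0])
                         + c - obs[0], beads[:, 1] + c - obs[1])
            j = int(np.argmin(d))
            for i, p in tr.items():
                ex = beads[j, 0] * np.cos(t_rad[i]) - beads[j, 2] * np.sin(t_rad[i]) + c
                ey = beads[j, 1] + c
                assert np.hypot(p[0] - ex, p[1] - ey) < 0.5

    def test_separated_beads_give_exactly_their_tracks(self):
        beads = np.array([[-40.0, -40.0, 0.0], [40.0, 40.0, 0.0],
                          [0.0, 0.0, 10.0]])
        sch = default_schedule(step=10)
        series = render_bead_series(beads, sch, (160, 160))
        tracks = track_beads(series, diameter_px=5, gate_px=10)
        assert len(tracks) == 3
        assert all(len(t) == len(sch) for t in tracks.tracks)

    def test_single_blanked_image_is_bridged(self):
        beads = np.array([[-40.0, -30.0, 5.0], [40.0, 40.0, -5.0], [10.0, -20.0, 0.0]])
        sch = default_schedule(step=10)
        series = render_bead_series(beads, sch, (160, 160))
        mid = len(sch) // 2
        series.images[mid] = 0.0
        tracks = track_beads(series, diameter_px=5, gate_px=10)
        assert len(tracks) == 3
        for tr in tracks.tracks:
            assert mid not in tr               # no invented observation
            assert (mid - 1) in tr and (mid + 1) in tr   # but the gap is bridged

    def test_too_few_tracks_fail(self):
        sch = TiltSchedule(angles_deg=(10.0, 0.0, -10.0))
        series = render_bead_series(np.array([[0.0, 0.0, 0.0]]), sch, (64, 64))
        series.images[:] = 0.0
        with pytest.raises(ValueError, match="3"):
            track_beads(series, diameter_px=5)

    def test_track_needs_two_observations(self):
        with pytest.raises(ValueError, match=">= 2"):
            FiducialTracks(tracks=[{0: np.zeros(2)}], n_images=5)


class TestSolveAlignment:
    def test_zero_perturbation_gives_identity(self):
        rng = np.random.default_rng(2)
        beads = random_beads(rng, 6)
        sch = default_schedule(step=5)
        series = render_bead_series(beads, sch, (160, 160))
        tracks = track_beads(series, diameter_px=5, gate_px=15)
        model = solve_alignment(tracks, sch, (160, 160), model_order="shift+rot")
        assert np.abs(model.shifts_px).max() < 0.1
        assert np.abs(model.rotations_deg).max() < 0.05

    def test_known_shifts_recovered(self):
        rng = np.random.default_rng(3)
        beads = random_beads(rng, 7)
        sch = default_schedule(step=5)
        shifts = rng.uniform(-10, 10, (len(sch), 2))
        series = render_bead_series(beads, sch, (160, 160), shifts_px=shifts)
        tracks = track_beads(series, diameter_px=5, gate_px=25)
        model = solve_alignment(tracks, sch, (160, 160))
        inj = canonical_shift_gauge(shifts, sch)
        rec = canonical_shift_gauge(model.shifts_px, sch)
        assert np.sqrt(np.mean((inj - rec) ** 2)) <= 0.5

    def test_known_rotations_recovered(self):
        rng = np.random.default_rng(4)
        beads = random_beads(rng, 7)
        sch = default_schedule(step=5)
        rots = rng.uniform(-2, 2, len(sch))
        series = render_bead_series(beads, sch, (160, 160), rotations_deg=rots)
        tracks = track_beads(series, diameter_px=5, gate_px=25)
        model = solve_alignment(tracks, sch, (160, 160), model_order="shift+rot")
        err = (rots - rots.mean()) - (model.rotations_deg - model.rotations_deg.mean())
        assert np.sqrt(np.mean(err**2)) <= 0.1

    def test_residual_not_worse_than_identity_model(self):
        rng = np.random.default_rng(5)
        beads = random_beads(rng, 6)
        sch = default_schedule(step=10)
        shifts = rng.uniform(-5, 5, (len(sch), 2))
        series = render_bead_series(beads, sch, (160, 160), shifts_px=shifts)
        tracks = track_beads(series, diameter_px=5, gate_px=20)
        solved = solve_alignment(tracks, sch, (160, 160))
        identity = solve_alignment(tracks, sch, (160, 160), max_iter=0,
                                   trim_tracks=False)
        assert solved.residual_rms_px <= identity.residual_rms_px + 1e-9


class TestApplyAlignment:
    def test_identity_model_is_noop(self):
        rng = np.random.default_rng(6)
        beads = random_beads(rng, 4)
        sch = default_schedule(step=20)
        series = render_bead_series(beads, sch, (96, 96))
        from etsim.align import AlignmentModel
        n = len(sch)
        model = AlignmentModel(np.zeros((n, 2)), np.zeros(n), np.ones(n), 0.0, 0.0)
        out = apply_alignment(series, model)
        assert np.array_equal(out.images, series.images)

    def test_perturb_align_round_trip(self):
        # injected shifts are pre-projected to the identifiable subspace:
        # the component equivalent to a global specimen translation cannot
        # be recovered by any fiducial alignment (gauge freedom)
        rng = np.random.default_rng(7)
        beads = random_beads(rng, 7)
        sch = default_schedule(step=5)
        series = render_bead_series(beads, sch, (160, 160))
        shifts = canonical_shift_gauge(rng.uniform(-6, 6, (len(sch), 2)), sch)
        pert = render_bead_series(beads, sch, (160, 160), shifts_px=shifts)
        tracks = track_beads(pert, diameter_px=5, gate_px=20)
        model = solve_alignment(tracks, sch, (160, 160))
        aligned = apply_alignment(pert, model)
        for i in range(len(sch)):
            a = aligned.images[i].ravel() - aligned.images[i].mean()
            b = series.images[i].ravel() - series.images[i].mean()
            corr = float(a @ b / np.sqrt((a @ a) * (b @ b)))
            assert corr >= 0.98

    def test_double_application_is_not_idempotent(self):
        rng = np.random.default_rng(8)
        beads = random_beads(rng, 4)
        sch = default_schedule(step=20)
        series = render_bead_series(beads, sch, (96, 96))
        from etsim.align import AlignmentModel
        n = len(sch)
        model = AlignmentModel(np.full((n, 2), 3.0), np.zeros(n), np.ones(n), 0.0, 0.0)
        once = apply_alignment(series, model)
        twice = apply_alignment(once, model)
        assert not np.allclose(once.images, twice.images)


class TestParameterRecoveryProperty:
    def test_median_recovery_over_20_seeded_trials(self):
        # shifts up to 10 px and rotations up to 2 deg; median errors must
        # stay within half a pixel and a tenth of a degree
        sch = default_schedule(step=4)
        shift_errs, rot_errs = [], []
        for trial in range(20):
            rng = np.random.default_rng(1000 + trial)
            beads = random_beads(rng, 7)
            shifts = rng.uniform(-10, 10, (len(sch), 2))
            rots = rng.uniform(-2, 2, len(sch))
            series = render_bead_series(beads, sch, (160, 160), shifts, rots)
            tracks = track_beads(series, diameter_px=5, gate_px=25)
            model = solve_alignment(tracks, sch, (160, 160), model_order="shift+rot")
            inj = canonical_shift_gauge(shifts, sch)
            rec = canonical_shift_gauge(model.shifts_px, sch)
            shift_errs.append(np.sqrt(np.mean((inj - rec) ** 2)))
            dr = (rots - rots.mean()) - (model.rotations_deg - model.rotations_deg.mean())
            rot_errs.append(np.sqrt(np.mean(dr**2)))
        assert np.median(shift_errs) <= 0.5
        assert np.median(rot_errs) <= 0.1
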