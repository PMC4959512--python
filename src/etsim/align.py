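"""Fiducial-based tilt-series alignment.

Gold beads deposited on the section surfaces appear as small high-contrast
blobs in every projection.  Alignment proceeds in three steps: per-image
blob detection at the bead scale, nearest-neighbour linking of detections
across adjacent tilts into tracks, and an alternating least-squares fit of
per-image similarity transforms together with the 3D bead positions under
the known tilt schedule.

Identifiability note: per-image shifts are determined only up to a global
3D translation of the bead model — moving every bead by ``(dX, dY, dZ)``
changes the predicted detector positions by ``(dX cos t - dZ sin t, dY)``,
which is exactly absorbable into the shifts.  The solver therefore
canonicalises to the minimum-norm shift series (the component of the shift
series lying in that equivalent-motion subspace is moved into the bead
coordinates).  Comparisons of recovered against known applied shifts must
be made in the same gauge; :func:`canonical_shift_gauge` applies it to any
shift series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import blob_log
from skimage.registration import phase_cross_correlation

from .tiltseries import TiltSeries, TiltSchedule, _similarity_resample

logger = logging.getLogger(__name__)


@dataclass
class PointSet:
    """2D detections (x, y in px) with peak response, intensity-sorted."""

    positions_px: np.ndarray  # (n, 2) as (x, y)
    intensities: np.ndarray

    def __len__(self) -> int:
        return len(self.positions_px)


@dataclass
class FiducialTracks:
    """Per-bead maps image index -> (x, y) detector position."""

    tracks: list[dict[int, np.ndarray]]
    n_images: int

    def __post_init__(self):
        for t in self.tracks:
            if len(t) < 2:
                raise ValueError("each track needs >= 2 observations")

    @property
    def completeness(self) -> float:
        """Mean fraction of images on which a track is observed."""
        if not self.tracks:
            return 0.0
        return float(np.mean([len(t) / self.n_images for t in self.tracks]))

    def __len__(self) -> int:
        return len(self.tracks)


@dataclass
class AlignmentModel:
    """Per-image similarity transforms estimated from fiducial tracks.

    Convention matches the perturbation log: *observed = transform
    (projected)*, so applying the inverse transform aligns the series.
    """

    shifts_px: np.ndarray          # (n, 2) as (dx, dy)
    rotations_deg: np.ndarray      # (n,)
    scales: np.ndarray             # (n,)
    tilt_axis_azimuth_deg: float
    residual_rms_px: float
    bead_positions_px: np.ndarray | None = None  # (m, 3) centred (X, Y, Z)

    def __post_init__(self):
        if np.any(self.scales <= 0.5) or np.any(self.scales >= 2.0):
            raise ValueError("scales must lie in (0.5, 2)")
        if self.residual_rms_px < 0:
            raise ValueError("residual must be >= 0")


def detect_beads(image: np.ndarray, diameter_px: float,
                 threshold_rel: float = 0.05,
                 max_beads: int | None = None) -> PointSet:
    """Detect bead-scale blobs with sub-pixel centroid refinement.

    A Laplacian-of-Gaussian detector tuned to ``diameter_px`` suppresses
    both noise and structures much larger than a bead.  Detections are
    refined by intensity centroid over a bead-sized window on the
    background-subtracted image, and returned sorted by descending peak
    response (ties broken by row-major position).
    """
    if diameter_px < 2:
        raise ValueError("diameter_px must be >= 2")
    img = np.asarray(image, np.float64)
    rng_span = img.max() - img.min()
    if rng_span == 0:
        return PointSet(np.empty((0, 2)), np.empty(0))
    norm = (img - img.min()) / rng_span
    sigma = diameter_px / (2 * np.sqrt(2))
    blobs = blob_log(norm, min_sigma=sigma * 0.7, max_sigma=sigma * 1.5,
                     num_sigma=3, threshold=threshold_rel)
    if len(blobs) == 0:
        return PointSet(np.empty((0, 2)), np.empty(0))
    # sub-pixel refinement: centroid of the band-passed (DoG) response, which
    # suppresses slowly varying structural background under the window
    r = max(2, int(round(diameter_px / 2)) + 1)
    smooth = ndimage.gaussian_filter(img, sigma / 2) - ndimage.gaussian_filter(img, 3 * sigma)
    pts, peaks = [], []
    ny, nx = img.shape
    for by, bx, _ in blobs:
        y0, y1 = int(by) - r, int(by) + r + 1
        x0, x1 = int(bx) - r, int(bx) + r + 1
        if y0 < 0 or x0 < 0 or y1 > ny or x1 > nx:
            continue
        win = smooth[y0:y1, x0:x1]
        w0 = win - win.min()
        if w0.sum() <= 0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        cy = float((w0 * yy).sum() / w0.sum())
        cx = float((w0 * xx).sum() / w0.sum())
        # iterative Gaussian-weighted centroid: re-centring the weight window
        # removes the truncation bias of a plain windowed centroid
        for _ in range(3):
            g = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
            wg = w0 * g
            tot = wg.sum()
            if tot <= 0:
                break
            cy = float((wg * yy).sum() / tot)
            cx = float((wg * xx).sum() / tot)
        pts.append((cx, cy))
        peaks.append(float(smooth[int(round(cy)), int(round(cx))]))
    if not pts:
        return PointSet(np.empty((0, 2)), np.empty(0))
    pts_a = np.asarray(pts)
    peaks_a = np.asarray(peaks)
    order = np.lexsort((pts_a[:, 0], pts_a[:, 1], -peaks_a))
    pts_a, peaks_a = pts_a[order], peaks_a[order]
    if max_beads is not None:
        pts_a, peaks_a = pts_a[:max_beads], peaks_a[:max_beads]
    return PointSet(pts_a, peaks_a)


def detect_series(series: TiltSeries, diameter_px: float = 12.0,
                  threshold_rel: float = 0.05,
                  max_beads: int | None = None) -> list[PointSet]:
    """Run :func:`detect_beads` on every image of a series."""
    return [detect_beads(series.images[i], diameter_px,
                         threshold_rel=threshold_rel, max_beads=max_beads)
            for i in range(len(series))]


def track_beads(series: TiltSeries, diameter_px: float = 12.0,
                gate_px: float = 20.0, threshold_rel: float = 0.05,
                max_beads: int | None = None,
                detections: list[PointSet] | None = None) -> FiducialTracks:
    """Link per-image detections into fiducial tracks.

    Detections on adjacent tilt images are linked greedily by nearest
    neighbour to a constant-velocity prediction, within ``gate_px``.  A
    track may bridge one image with no matching detection (position
    linearly predicted, not recorded); a longer gap ends the track.
    Tracks shorter than two observations are discarded.
    """
    n = len(series)
    if detections is None:
        detections = [detect_beads(series.images[i], diameter_px,
                                   threshold_rel=threshold_rel, max_beads=max_beads)
                      for i in range(n)]
    # inter-frame drift estimate (phase correlation) so that linking happens
    # in drift-corrected coordinates; per-image shift jitter would otherwise
    # defeat the constant-velocity prediction
    cum_drift = np.zeros((n, 2))
    for i in range(1, n):
        if series.images[i - 1].any() and series.images[i].any():
            (dy, dx), _, _ = phase_cross_correlation(
                series.images[i - 1], series.images[i], upsample_factor=4,
                normalization=None)
        else:
            dy = dx = 0.0
        # content of image i sits at -(dy,dx) relative to image i-1
        cum_drift[i] = cum_drift[i - 1] + np.array([-dx, -dy])
    active: list[dict] = []   # {obs: {i: (x,y)}, last, pred, miss} in drift-corrected coords
    finished: list[dict[int, np.ndarray]] = []
    for i in range(n):
        raw = detections[i].positions_px
        pts = raw - cum_drift[i]
        used = np.zeros(len(pts), bool)
        for tr in active:
            pred = tr["pred"]
            best, best_d = -1, gate_px
            for k in range(len(pts)):
                if used[k]:
                    continue
                d = float(np.hypot(*(pts[k] - pred)))
                if d < best_d:
                    best, best_d = k, d
            if best >= 0:
                used[best] = True
                prev = tr["last"]
                tr["obs"][i] = raw[best].copy()
                tr["vel"] = pts[best] - prev if tr["miss"] == 0 else (pts[best] - prev) / 2
                tr["last"] = pts[best].copy()
                tr["pred"] = pts[best] + tr["vel"]
                tr["miss"] = 0
            else:
                tr["miss"] += 1
                tr["pred"] = tr["pred"] + tr["vel"]
        # retire tracks with a gap longer than one image
        still = []
        for tr in active:
            if tr["miss"] > 1:
                if len(tr["obs"]) >= 2:
                    finished.append(tr["obs"])
                logger.debug("track ended at image %d after gap", i)
            else:
                still.append(tr)
        active = still
        for k in range(len(pts)):
            if not used[k]:
                active.append({"obs": {i: raw[k].copy()}, "last": pts[k].copy(),
                               "pred": pts[k].copy(), "vel": np.zeros(2), "miss": 0})
    for tr in active:
        if len(tr["obs"]) >= 2:
            finished.append(tr["obs"])
    finished = [t for t in finished if len(t) >= 2]
    if len(finished) < 3:
        raise ValueError(
            f"only {len(finished)} usable fiducial tracks; >= 3 required for alignment"
        )
    return FiducialTracks(tracks=finished, n_images=n)


def _image_center(series_shape) -> np.ndarray:
    ny, nx = series_shape
    return np.array([(nx - 1) / 2.0, (ny - 1) / 2.0])


def canonical_shift_gauge(shifts_px: np.ndarray, schedule: TiltSchedule) -> np.ndarray:
    """Project a shift series to the minimum-norm gauge.

    Removes the component equivalent to a global 3D translation of the
    specimen: best-fit ``a*cos(t) + b*sin(t)`` from the x shifts and the
    mean from the y shifts.
    """
    t = np.deg2rad(np.asarray(schedule.angles_deg))
    out = np.array(shifts_px, float)
    A = np.stack([np.cos(t), np.sin(t)], axis=1)
    coef, *_ = np.linalg.lstsq(A, out[:, 0], rcond=None)
    out[:, 0] -= A @ coef
    out[:, 1] -= out[:, 1].mean()
    return out


def solve_alignment(tracks: FiducialTracks, schedule: TiltSchedule,
                    image_shape: tuple[int, int],
                    model_order: str = "shift",
                    max_iter: int = 100, tol_px: float = 1e-4,
                    trim_tracks: bool = True) -> AlignmentModel:
    """Fit per-image transforms and 3D bead positions to fiducial tracks.

    Alternates between (a) linear least-squares for each bead's centred 3D
    position given the transforms and (b) per-image restricted Procrustes
    (shift / shift+rotation / shift+rotation+magnification per
    ``model_order``) given the bead positions, until the reprojection RMS
    changes by less than ``tol_px`` or ``max_iter`` iterations.  Shifts are
    returned in the minimum-norm gauge (see module docstring).

    With ``trim_tracks`` (default), tracks whose own reprojection RMS is
    far above the median after a fit are discarded and the model refit —
    this rejects tracks corrupted by identity swaps when two beads cross
    in projection.  At least 3 tracks are always retained.
    """
    if model_order not in ("shift", "shift+rot", "shift+rot+mag"):
        raise ValueError(f"unknown model_order {model_order!r}")
    n = len(schedule)
    if tracks.n_images != n:
        raise ValueError("track image count does not match schedule")
    m = len(tracks)
    if m < 3:
        raise ValueError("need >= 3 tracks")
    span = max(len(t) for t in tracks.tracks) / n
    if span < 0.5:
        logger.warning("longest track spans only %.0f%% of images", 100 * span)
    t_rad = np.deg2rad(np.asarray(schedule.angles_deg))
    cos_t, sin_t = np.cos(t_rad), np.sin(t_rad)
    c = _image_center(image_shape)

    all_obs = [{i: np.asarray(p, float) - c for i, p in tr.items()} for tr in tracks.tracks]
    obs = list(all_obs)

    shifts = np.zeros((n, 2))
    rots = np.zeros(n)
    scales = np.ones(n)

    def solve_beads():
        beads = np.zeros((len(obs), 3))
        for j, tr in enumerate(obs):
            rows, rhs = [], []
            for i, p in tr.items():
                # undo transform: q = R(-rot) (p - shift) / scale
                q = p - shifts[i]
                tt = np.deg2rad(rots[i])
                R = np.array([[np.cos(tt), np.sin(tt)], [-np.sin(tt), np.cos(tt)]])
                q = R @ q / scales[i]
                rows.append([cos_t[i], 0.0, -sin_t[i]])
                rhs.append(q[0])
                rows.append([0.0, 1.0, 0.0])
                rhs.append(q[1])
            sol, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
            beads[j] = sol
        return beads

    def predict(beads):
        # centred detector positions before per-image transform
        px = beads[:, 0][None, :] * cos_t[:, None] - beads[:, 2][None, :] * sin_t[:, None]
        py = np.broadcast_to(beads[:, 1][None, :], px.shape)
        return px, np.array(py)

    def per_track_sq(beads):
        px, py = predict(beads)
        sums = np.zeros(len(obs))
        counts = np.zeros(len(obs), int)
        for j, tr in enumerate(obs):
            for i, p in tr.items():
                tt = np.deg2rad(rots[i])
                R = np.array([[np.cos(tt), -np.sin(tt)], [np.sin(tt), np.cos(tt)]])
                pred = scales[i] * (R @ np.array([px[i, j], py[i, j]])) + shifts[i]
                sums[j] += float(np.sum((pred - p) ** 2))
                counts[j] += 1
        return sums, counts

    def residual_rms(beads):
        sums, counts = per_track_sq(beads)
        return np.sqrt(sums.sum() / max(counts.sum(), 1))

    def run_fit():
        nonlocal shifts, rots, scales
        shifts = np.zeros((n, 2))
        rots = np.zeros(n)
        scales = np.ones(n)
        beads = solve_beads()
        prev = residual_rms(beads)
        for _ in range(max_iter):
            px, py = predict(beads)
            for i in range(n):
                P, Q = [], []   # predicted, observed
                for j, tr in enumerate(obs):
                    if i in tr:
                        P.append([px[i, j], py[i, j]])
                        Q.append(tr[i])
                if not P:
                    continue
                P = np.asarray(P)
                Q = np.asarray(Q)
                if len(P) >= 4:
                    # per-image robustness: a single mis-assigned detection
                    # must not poison this image's transform
                    d = Q - P
                    r = np.linalg.norm(d - np.median(d, axis=0), axis=1)
                    keep_o = r <= max(3.0 * float(np.median(r)), 0.75)
                    if keep_o.sum() >= 3:
                        P, Q = P[keep_o], Q[keep_o]
                if model_order == "shift":
                    shifts[i] = np.median(Q - P, axis=0)
                else:
                    Pm, Qm = P.mean(axis=0), Q.mean(axis=0)
                    P0, Q0 = P - Pm, Q - Qm
                    num = np.sum(P0[:, 0] * Q0[:, 1] - P0[:, 1] * Q0[:, 0])
                    den = np.sum(P0 * Q0)
                    ang = np.arctan2(num, den)
                    s = 1.0
                    if model_order == "shift+rot+mag":
                        s = float(np.sqrt(np.sum(Q0**2) / max(np.sum(P0**2), 1e-12)))
                        s = float(np.clip(s, 0.51, 1.99))
                    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
                    rots[i] = np.rad2deg(ang)
                    scales[i] = s
                    shifts[i] = Qm - s * (R @ Pm)
            beads = solve_beads()
            cur = residual_rms(beads)
            if abs(prev - cur) < tol_px:
                prev = cur
                break
            prev = cur
        return beads

    beads = run_fit()
    if trim_tracks:
        for _ in range(10):
            if len(obs) <= 3:
                break
            sums, counts = per_track_sq(beads)
            track_rms = np.sqrt(sums / np.maximum(counts, 1))
            med = float(np.median(track_rms))
            cut = max(2.5 * med, 1.0)
            keep = track_rms <= cut
            if keep.all():
                break
            # never drop below 3 tracks: keep the best ones
            if keep.sum() < 3:
                keep = np.argsort(track_rms) < 3
            dropped = int(len(obs) - keep.sum())
            obs = [o for o, k in zip(obs, keep) if k]
            logger.info("trimmed %d inconsistent track(s); %d remain", dropped, len(obs))
            beads = run_fit()

    # canonical gauge: move the equivalent-motion component into the beads
    A = np.stack([cos_t, np.sin(t_rad)], axis=1)
    coef, *_ = np.linalg.lstsq(A, shifts[:, 0], rcond=None)
    dX, negdZ = coef
    dY = shifts[:, 1].mean()
    shifts[:, 0] -= A @ coef
    shifts[:, 1] -= dY
    beads[:, 0] += dX
    beads[:, 2] -= negdZ
    beads[:, 1] += dY
    rms = residual_rms(beads)

    return AlignmentModel(
        shifts_px=shifts, rotations_deg=rots, scales=scales,
        tilt_axis_azimuth_deg=0.0, residual_rms_px=rms,
        bead_positions_px=beads,
    )


def _reassign_tracks(detections: list[PointSet], model: AlignmentModel,
                     schedule: TiltSchedule, image_shape: tuple[int, int],
                     radius_px: float = 4.0) -> FiducialTracks:
    """Rebuild tracks by assigning detections to model-predicted positions.

    Every 3D bead of the current model is reprojected into every image
    through the solved transforms; the nearest unused detection within
    ``radius_px`` is claimed.  Beads that end up sharing most observations
    (duplicate fragments of one physical bead) are merged.
    """
    beads = model.bead_positions_px
    # dedupe 3D beads first: fragments of one physical marker solve to nearby
    # positions and would otherwise compete for the same detections
    kept: list[int] = []
    for j in range(len(beads)):
        if all(np.linalg.norm(beads[j] - beads[k]) > 2 * radius_px for k in kept):
            kept.append(j)
    beads = beads[kept]
    n = len(schedule)
    t_rad = np.deg2rad(np.asarray(schedule.angles_deg))
    c = _image_center(image_shape)
    m = len(beads)
    obs_sets: list[dict[int, np.ndarray]] = [dict() for _ in range(m)]
    for i in range(n):
        pts = detections[i].positions_px
        if len(pts) == 0:
            continue
        px = beads[:, 0] * np.cos(t_rad[i]) - beads[:, 2] * np.sin(t_rad[i])
        py = beads[:, 1]
        tt = np.deg2rad(model.rotations_deg[i])
        R = np.array([[np.cos(tt), -np.sin(tt)], [np.sin(tt), np.cos(tt)]])
        pred = (model.scales[i] * (R @ np.stack([px, py])).T) + model.shifts_px[i] + c
        used = np.zeros(len(pts), bool)
        d = np.linalg.norm(pred[:, None, :] - pts[None, :, :], axis=2)
        for j in np.argsort(d.min(axis=1)):
            k = int(np.argmin(np.where(used, np.inf, d[j])))
            if not used[k] and d[j, k] <= radius_px:
                used[k] = True
                obs_sets[j][i] = pts[k].copy()
    tracks = [dict(o) for o in obs_sets if len(o) >= 2]
    if len(tracks) < 3:
        raise ValueError("model-guided reassignment left fewer than 3 tracks")
    return FiducialTracks(tracks=tracks, n_images=n)


def align_series(series: TiltSeries, diameter_px: float = 12.0,
                 gate_px: float = 20.0, threshold_rel: float = 0.05,
                 max_beads: int | None = None, model_order: str = "shift",
                 refine_rounds: int = 2,
                 radius_px: float = 4.0) -> tuple[TiltSeries, AlignmentModel]:
    """Full fiducial alignment: detect, track, solve, refine, resample.

    Initial nearest-neighbour tracks are often fragmented (a bead hidden
    behind dense structure for a stretch of tilts starts a new track),
    which leaves the least-squares system weakly constrained.  Each
    refinement round therefore reprojects the solved 3D beads into every
    image, reclaims detections near the predictions, merges duplicate
    fragments, and refits — the standard iterate-until-consistent scheme
    for marker-based tilt alignment.
    """
    detections = detect_series(series, diameter_px, threshold_rel, max_beads)
    tracks = track_beads(series, diameter_px, gate_px, threshold_rel,
                         max_beads, detections=detections)
    shape = series.images.shape[1:]
    model = solve_alignment(tracks, series.schedule, shape, model_order=model_order)
    for _ in range(refine_rounds):
        try:
            tracks = _reassign_tracks(detections, model, series.schedule, shape,
                                      radius_px=radius_px)
        except ValueError:
            break
        model = solve_alignment(tracks, series.schedule, shape, model_order=model_order)
    return apply_alignment(series, model), model


def erase_beads(series: TiltSeries, model: AlignmentModel,
                bead_radius_px: float = 3.75, aligned: bool = True,
                min_abs_z_px: float | None = None) -> TiltSeries:
    """Remove gold-bead signal from a series before reconstruction.

    The solved 3D bead positions are reprojected into every image (through
    the solved transforms unless ``aligned``, in which case the series is
    assumed already aligned and the identity transform is used).  At each
    predicted spot a disc of 1.2x the bead radius is filled with the
    median of the surrounding annulus — the usual gold-erasure step that
    prevents the dense markers from streaking through the tomogram.  The
    disc is kept tight so as little structural signal as possible is lost
    with the marker.

    Real fiducials sit on the section surfaces; passing ``min_abs_z_px``
    erases only model beads with |Z| at least that value, so structural
    features mistakenly tracked as markers (which live inside the section)
    are left untouched.
    """
    out = series.copy()
    beads = model.bead_positions_px
    if beads is None:
        return out
    if min_abs_z_px is not None:
        beads = beads[np.abs(beads[:, 2]) >= min_abs_z_px]
    n = len(series)
    ny, nx = series.images.shape[1:]
    c = _image_center((ny, nx))
    t_rad = np.deg2rad(np.asarray(series.schedule.angles_deg))
    r_fill = 1.2 * bead_radius_px
    yy, xx = np.mgrid[0:ny, 0:nx]
    for i in range(n):
        px = beads[:, 0] * np.cos(t_rad[i]) - beads[:, 2] * np.sin(t_rad[i])
        py = beads[:, 1]
        pred = np.stack([px, py], axis=1)
        if not aligned:
            tt = np.deg2rad(model.rotations_deg[i])
            R = np.array([[np.cos(tt), -np.sin(tt)], [np.sin(tt), np.cos(tt)]])
            pred = model.scales[i] * (pred @ R.T) + model.shifts_px[i]
        pred = pred + c
        img = out.images[i]
        for bx, by in pred:
            d2 = (xx - bx) ** 2 + (yy - by) ** 2
            disc = d2 <= r_fill**2
            ann = (d2 > r_fill**2) & (d2 <= (1.8 * r_fill) ** 2)
            if disc.any() and ann.any():
                img[disc] = np.median(img[ann])
    return out


def apply_alignment(series: TiltSeries, model: AlignmentModel) -> TiltSeries:
    """Resample each image through the inverse of its solved transform.

    Applying a model is destructive resampling, not a group action on
    metadata: applying the same model twice shifts content twice and is
    *not* idempotent.  The perturbation log is updated by subtracting the
    corrected transforms.
    """
    n = len(series)
    if len(model.shifts_px) != n:
        raise ValueError("model image count does not match series")
    out = series.copy()
    for i in range(n):
        if (model.shifts_px[i] == 0).all() and model.rotations_deg[i] == 0 \
                and model.scales[i] == 1.0:
            continue
        out.images[i] = _similarity_resample(
            series.images[i].astype(np.float64),
            model.shifts_px[i], model.rotations_deg[i], model.scales[i],
            inverse=True,
        )
    out.shifts_px = series.shifts_px - model.shifts_px
    out.rotations_deg = series.rotations_deg - model.rotations_deg
    out.scales = series.scales / model.scales
    return out
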