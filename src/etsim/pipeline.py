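"""End-to-end experiments: the standard study conditions in one place.

These functions wire the individual modules into the complete workflows —
simulate, acquire, align, reconstruct, combine, quantify — at the problem
sizes used for validation, so tests and reproduction scripts run the exact
same code paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import phantom as ph
from .align import align_series, canonical_shift_gauge, erase_beads, solve_alignment, track_beads
from .recon import (
    Tomogram,
    combine_dual_axis,
    fourier_coverage,
    masked_correlation,
    measure_psf_elongation,
    weighted_backprojection,
)
from .reslice import cross_section_series
from .tiltseries import (
    PerturbationSpec,
    default_schedule,
    make_second_axis,
    perturb,
    project,
    render_bead_series,
    undo_second_axis,
)


def standard_phantom(n: int = 96, voxel_nm: float = 2.0):
    """The reference cardiomyocyte-like phantom: a hollow T-tubule and a
    solid tubule traversing the section along z, plus an SR-scale sphere.

    Returns the structural volume (ground truth for fidelity metrics) and
    the phantom spec.  Section thickness is matched to the tube length so
    the structures span the section the way T-tubules do.
    """
    fov = n * voxel_nm
    # the tubes span the whole section thickness, the way T-tubules
    # traverse a semi-thick section
    thickness = 140.0
    tube = ph.Primitive(kind="hollow-tube", center=(0.36 * fov, 0.5 * fov, 0),
                        axis=(0, 0, 1), radius_nm=35, wall_thickness_nm=8,
                        length_nm=thickness)
    lum = ph.Primitive(kind="solid-cylinder", center=(0.68 * fov, 0.42 * fov, 0),
                       axis=(0, 0, 1), radius_nm=25, length_nm=thickness)
    sphere = ph.Primitive(kind="sphere", center=(0.52 * fov, 0.73 * fov, 10),
                          radius_nm=18, density=0.8)
    spec = ph.PhantomSpec(primitives=(tube, lum, sphere),
                          field_of_view_nm=(fov, fov),
                          section_thickness_nm=thickness)
    grid = ph.GridSpec(voxel_nm=voxel_nm, shape=(n, n, n))
    return ph.rasterize(spec, grid), spec


@dataclass
class FidelityResult:
    correlation: float
    shift_rms_px: float
    residual_rms_px: float
    n_tracks: int


def run_fidelity_experiment(seed: int = 0, n: int = 96,
                            shift_sigma_nm: float = 5.0,
                            n_beads: int = 6) -> FidelityResult:
    """Phantom -> +-60 deg 1 deg series -> perturb -> align -> gold-erase ->
    WBP; reports masked correlation against the structural phantom and the
    gauge-canonical shift recovery error."""
    structural, spec = standard_phantom(n=n)
    vol, beads = ph.add_fiducials(structural, n_beads, seed=seed + 1,
                                  section_thickness_nm=spec.section_thickness_nm,
                                  min_projected_separation_nm=1.5 * ph.DEFAULT_BEAD_DIAMETER_NM)
    sch = default_schedule(step=1)
    series = project(vol, sch)
    pert = perturb(series, PerturbationSpec(shift_sigma_nm=shift_sigma_nm),
                   seed=seed + 2)
    aligned, model = align_series(pert, diameter_px=beads.diameter_nm / vol.voxel_nm,
                                  gate_px=12, threshold_rel=0.1,
                                  max_beads=n_beads + 2, model_order="shift")
    half_z_px = spec.section_thickness_nm / 2 / vol.voxel_nm
    erased = erase_beads(aligned, model, min_abs_z_px=0.75 * half_z_px)
    tomo = weighted_backprojection(erased)
    corr = masked_correlation(tomo.volume, structural,
                              section_thickness_nm=spec.section_thickness_nm)
    inj = canonical_shift_gauge(pert.shifts_px, sch)
    rec = canonical_shift_gauge(model.shifts_px, sch)
    shift_rms = float(np.sqrt(np.mean((inj - rec) ** 2)))
    return FidelityResult(correlation=float(corr), shift_rms_px=shift_rms,
                          residual_rms_px=model.residual_rms_px,
                          n_tracks=len(model.bead_positions_px))


@dataclass
class RecoveryResult:
    shift_rms_px: list
    rotation_rms_deg: list

    @property
    def median_shift_rms_px(self) -> float:
        return float(np.median(self.shift_rms_px))

    @property
    def median_rotation_rms_deg(self) -> float:
        return float(np.median(self.rotation_rms_deg))


def run_recovery_trials(n_trials: int = 20, seed: int = 0,
                        shift_max_px: float = 10.0,
                        rotation_max_deg: float = 2.0) -> RecoveryResult:
    """Seeded alignment-recovery trials on analytically rendered bead
    series: inject per-image shifts and rotations, solve, and compare in
    the canonical gauge."""
    sch = default_schedule(step=4)
    shift_errs, rot_errs = [], []
    for trial in range(n_trials):
        rng = np.random.default_rng(seed * 10_000 + trial)
        beads = _separated_beads(rng, 7)
        shifts = rng.uniform(-shift_max_px, shift_max_px, (len(sch), 2))
        rots = rng.uniform(-rotation_max_deg, rotation_max_deg, len(sch))
        series = render_bead_series(beads, sch, (160, 160), shifts, rots)
        tracks = track_beads(series, diameter_px=5, gate_px=25)
        model = solve_alignment(tracks, sch, (160, 160), model_order="shift+rot")
        inj = canonical_shift_gauge(shifts, sch)
        rec = canonical_shift_gauge(model.shifts_px, sch)
        shift_errs.append(float(np.sqrt(np.mean((inj - rec) ** 2))))
        dr = (rots - rots.mean()) - (model.rotations_deg - model.rotations_deg.mean())
        rot_errs.append(float(np.sqrt(np.mean(dr**2))))
    return RecoveryResult(shift_rms_px=shift_errs, rotation_rms_deg=rot_errs)


def _separated_beads(rng, m, xy=60.0, z=35.0, min_sep_px=14.0):
    t = np.deg2rad(np.linspace(-60, 60, 25))
    beads = []
    while len(beads) < m:
        c = np.array([rng.uniform(-xy, xy), rng.uniform(-xy, xy),
                      rng.uniform(-z, z)])
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


@dataclass
class DualAxisResult:
    elongation_single: float
    elongation_dual: float
    coverage_single_3d: float
    coverage_dual_3d: float
    planar_single: float


def run_dual_axis_experiment(seed: int = 0, n: int = 96,
                             step_deg: float = 1.0,
                             n_directions: int = 1_000_000) -> DualAxisResult:
    """Bead-phantom PSF elongation for single vs dual axis, plus Fourier
    coverage fractions for the same schedules."""
    voxel = 2.0
    fov = n * voxel
    bead = ph.Primitive(kind="sphere", center=(fov / 2, fov / 2, 0),
                        radius_nm=6, density=10)
    spec = ph.PhantomSpec(primitives=(bead,), field_of_view_nm=(fov, fov))
    vol = ph.rasterize(spec, ph.GridSpec(voxel_nm=voxel, shape=(n, n, n)))
    schA = default_schedule("A", step=step_deg)
    schB = default_schedule("B", step=step_deg)
    tA = weighted_backprojection(project(vol, schA))
    tB_raw = weighted_backprojection(project(make_second_axis(vol), schB))
    tB = Tomogram(undo_second_axis(tB_raw.volume), "single-axis B",
                  tB_raw.schedules, tB_raw.filter_settings)
    dual = combine_dual_axis(tA, tB)
    eA = measure_psf_elongation(tA, (0.0, 0.0, 0.0))
    eD = measure_psf_elongation(dual, (0.0, 0.0, 0.0))
    cov1 = fourier_coverage([schA], n_directions=n_directions, seed=seed)
    cov2 = fourier_coverage([schA, schB], n_directions=n_directions, seed=seed)
    return DualAxisResult(
        elongation_single=float(eA), elongation_dual=float(eD),
        coverage_single_3d=cov1.direction_fraction_3d,
        coverage_dual_3d=cov2.direction_fraction_3d,
        planar_single=cov1.planar_fraction,
    )


@dataclass
class GeometryResult:
    tilts_deg: list
    minor_nm: list
    major_nm: list
    expected_major_nm: list


def run_oblique_geometry_experiment(d_nm: float = 200.0,
                                    tilts_deg=(30, 40, 50, 60, 70, 80, 90),
                                    n: int = 128) -> GeometryResult:
    """Rasterized-tube cross-sections across cutting angles vs d/sin(alpha)."""
    voxel = 4.0
    fov = n * voxel
    prim = ph.Primitive(kind="solid-cylinder", center=(fov / 2, fov / 2, 0),
                        axis=(1, 0, 0), radius_nm=d_nm / 2, length_nm=fov - 12)
    spec = ph.PhantomSpec(primitives=(prim,), field_of_view_nm=(fov, fov),
                          section_thickness_nm=fov)
    vol = ph.rasterize(spec, ph.GridSpec(voxel_nm=voxel, shape=(n, n, n)))
    ms = cross_section_series(vol, (fov / 2, fov / 2, 0.0), (1, 0, 0),
                              list(tilts_deg))
    return GeometryResult(
        tilts_deg=list(tilts_deg),
        minor_nm=[m.minor_diameter_nm for m in ms],
        major_nm=[m.major_diameter_nm for m in ms],
        expected_major_nm=[d_nm / np.sin(np.deg2rad(a)) for a in tilts_deg],
    )


@dataclass
class MeshResult:
    sphere_volume_err: float
    sphere_area_err: float
    cylinder_volume_err: float
    cylinder_area_err: float


def run_mesh_experiment() -> MeshResult:
    """Rasterize -> isosurface -> mesh measures against closed forms."""
    from .meshmod import isosurface, mesh_measures

    out = {}
    for name, prim, shape, voxel in (
        ("sphere", ph.Primitive(kind="sphere", center=(80, 80, 0), radius_nm=50),
         (80, 80, 80), 2.0),
        ("cylinder", ph.Primitive(kind="solid-cylinder", center=(100, 100, 0),
                                  axis=(0, 1, 0), radius_nm=40, length_nm=120),
         (100, 100, 60), 2.0),
    ):
        fov = (shape[0] * voxel, shape[1] * voxel)
        spec = ph.PhantomSpec(primitives=(prim,), field_of_view_nm=fov)
        vol = ph.rasterize(spec, ph.GridSpec(voxel_nm=voxel, shape=shape))
        mesh = isosurface(vol, 0.5)
        m = mesh_measures(mesh)
        truth = ph.analytic_measures(prim)
        out[name] = (m.volume_nm3 / truth.volume_nm3 - 1,
                     m.surface_area_nm2 / truth.surface_area_nm2 - 1)
    return MeshResult(sphere_volume_err=out["sphere"][0],
                      sphere_area_err=out["sphere"][1],
                      cylinder_volume_err=out["cylinder"][0],
                      cylinder_area_err=out["cylinder"][1])
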