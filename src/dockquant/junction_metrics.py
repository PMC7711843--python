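"""Per-site junction measurements.

All operations act on an *oriented* docking site (subtomogram with the
docking axis on +z and the inter-membrane midpoint at the box origin, as
produced by :func:`dockquant.site_detection.extract_oriented_subtomogram`)
and return physical quantities in nm:

* :func:`measure_separation` — outer-leaflet SUV to outer-leaflet GUV
  distance at closest approach, from a joint bilayer-profile fit along the
  docking axis; 0 when the leaflet ridges merge.
* :func:`detect_density_landmarks` — centres of protein densities on either
  membrane and in the inter-membrane space, found as local maxima of the
  smoothed, membrane-subtracted map.
* :func:`measure_contact_diameter` — equivalent-circle diameter of the
  flattened membrane-contact facet for touching membranes.
* :func:`detect_protrusion` — local GUV elevation toward the SUV versus the
  surrounding membrane baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel
from scipy import ndimage
from skimage.feature import peak_local_max

from .site_detection import DockingSite, bilayer_template
from .synthetic_scenes import missing_wedge_mask
from .tomo_io import Volume

__all__ = [
    "MeasurementParams",
    "JunctionMeasurement",
    "MembranesNotResolvableError",
    "measure_separation",
    "detect_density_landmarks",
    "measure_contact_diameter",
    "detect_protrusion",
    "measure_junction",
    "has_intermembrane_density",
]


class MembranesNotResolvableError(RuntimeError):
    """Membranes could not be located at the docking axis; the site must be
    flagged missing and excluded from statistics."""


class MeasurementParams(BaseModel):
    """Tunables of the junction measurements (lengths in nm)."""

    bilayer_thickness: float = 4.0
    leaflet_sigma: float = 1.8  # effective leaflet width incl. reconstruction blur
    axis_disk_radius: float = 4.0  # radius of the axial averaging disk
    max_separation: float = 50.0  # search reach for the SUV bilayer above the GUV
    merge_radius: float = 5.0  # density maxima closer than this are merged
    density_smooth_sigma_vox: float = 1.0  # ~3x3x3 Gaussian display filter
    density_threshold_nsd: float = 3.0  # threshold = bg mean + n*SD
    contact_epsilon: float | None = None  # nm; None = 1 voxel
    protrusion_min_height: float = 3.0
    protrusion_window: float = 25.0  # baseline exclusion radius about the axis
    density_max_radius: float = 32.0  # lateral reach of the density search
    density_slab: tuple[float, float] = (2.0, 30.0)  # z rel. GUV outer leaflet
    #: peaks closer than this to the SUV leaflet ridge are residual membrane
    #: signal, not protein (protein centres sit off the bilayer midline)
    min_suv_clearance: float = 1.8
    #: membrane-attached densities lie within this distance of a leaflet;
    #: farther peaks count only near the docking axis
    max_membrane_offset: float = 6.0
    #: wedge half-angle applied to the membrane model before subtraction so
    #: model and data share the same anisotropic attenuation; None disables
    wedge_half_angle: float | None = 60.0


@dataclass
class JunctionMeasurement:
    """Bundle of all per-site measurements (box-frame coordinates, nm)."""

    site_id: str
    separation: float
    density_points: np.ndarray
    density_compartments: list[str]
    contact_diameter: float
    protrusion_flag: int
    protrusion_height: float
    guv_outer_z: float  # z of the GUV outer leaflet on the axis
    suv_outer_z: float  # z of the SUV outer leaflet on the axis
    extras: dict = field(default_factory=dict)

    @property
    def n_densities(self) -> int:
        return len(self.density_points)


# ----------------------------------------------------------------------------
# membrane localisation along the axis
# ----------------------------------------------------------------------------

def _axial_profile(site_vol: Volume, disk_radius: float) -> np.ndarray:
    xs, ys, _ = site_vol.axes_nm()
    mask = (xs[None, :] ** 2 + ys[:, None] ** 2) <= disk_radius**2
    return site_vol.grid[:, mask].mean(axis=1)


def _baseline_corrected(prof: np.ndarray, vx: float) -> np.ndarray:
    """Remove the slowly varying background of a z-profile.

    Bright protein clusters combined with the missing wedge leave a broad
    negative bowl around the junction that offsets absolute thresholds; a
    smoothed rolling-minimum baseline tracks that bowl without touching the
    sharp leaflet peaks."""
    n = max(int(round(14.0 / vx)) | 1, 3)
    base = ndimage.minimum_filter1d(prof, size=n, mode="nearest")
    base = ndimage.gaussian_filter1d(base, sigma=2.0, mode="nearest")
    return prof - base


def _template_autocorr(vx: float, params: MeasurementParams
                       ) -> tuple[np.ndarray, np.ndarray]:
    tmpl, _ = bilayer_template(vx, params.bilayer_thickness, params.leaflet_sigma)
    full = np.correlate(tmpl, tmpl, mode="full")
    mid = len(tmpl) - 1
    return tmpl, full[mid:]  # a[d] = <T(z), T(z - d voxels)>


def _pair_energy(ci: np.ndarray, cj: np.ndarray, a0: float, ad: float
                 ) -> np.ndarray:
    """Explained energy of a two-bilayer model with optimally fitted
    non-negative amplitudes, given template correlations ci, cj at the two
    candidate positions and the template autocorrelation a(d)."""
    ci = np.maximum(ci, 0.0)
    cj = np.maximum(cj, 0.0)
    det = a0**2 - ad**2
    if det <= 1e-12 * a0**2:
        return np.maximum(ci, cj) ** 2 / a0
    alpha = (a0 * ci - ad * cj) / det
    beta = (a0 * cj - ad * ci) / det
    both = alpha * ci + beta * cj
    single = np.maximum(ci, cj) ** 2 / a0
    return np.where((alpha >= 0) & (beta >= 0), both, single)


def _two_bilayer_fit(corr: np.ndarray, g_lo: int, g_hi: int, dmax: int,
                     a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Joint grid fit of two bilayer positions per column.

    ``corr`` is (nz, ...) template correlation; the lower bilayer (GUV) is
    searched in rows [g_lo, g_hi) and the upper one at offsets 0..dmax
    voxels above it (offset 0 = merged leaflet ridges).  Modelling *both*
    membranes jointly resolves the leaflet-comb ambiguity at separations
    comparable to the bilayer thickness, where a single bilayer template
    happily locks onto the two facing leaflets of different membranes.
    Returns per-column sub-voxel (mg_idx, ms_idx) row indices.
    """
    nz = corr.shape[0]
    cols = corr.shape[1:]
    a0 = float(a[0])
    g_idx = np.arange(g_lo, g_hi)
    best_e = np.full(cols, -np.inf)
    best_g = np.zeros(cols, dtype=int)
    best_d = np.zeros(cols, dtype=int)
    for d in range(0, dmax + 1):
        ad = float(a[d]) if d < len(a) else 0.0
        j_idx = g_idx + d
        ok = j_idx <= nz - 1
        if not ok.any():
            break
        ci = corr[g_idx[ok]]
        cj = corr[j_idx[ok]]
        e = _pair_energy(ci, cj, a0, ad)  # (n_g, ...)
        am = np.argmax(e, axis=0)
        em = np.take_along_axis(e, am[None], axis=0)[0]
        upd = em > best_e
        best_e = np.where(upd, em, best_e)
        best_g = np.where(upd, g_idx[ok][am], best_g)
        best_d = np.where(upd, d, best_d)
    # sub-voxel: parabolic refinement of the correlation peak at each site
    mg = _parabolic_grid(corr, best_g)
    ms = np.where(best_d == 0, mg, _parabolic_grid(corr, best_g + best_d))
    return mg, ms


def _parabolic_grid(corr: np.ndarray, idx: np.ndarray) -> np.ndarray:
    nz = corr.shape[0]
    i0 = np.clip(idx, 1, nz - 2)
    take = lambda k: np.take_along_axis(corr, k[None], axis=0)[0]
    ym, y0, yp = take(i0 - 1), take(i0), take(i0 + 1)
    denom = ym - 2 * y0 + yp
    frac = np.where(denom < 0, 0.5 * (ym - yp) / np.where(denom == 0, 1, denom),
                    0.0)
    return i0 + np.clip(frac, -0.5, 0.5)


def _locate_bilayers(site_vol: Volume, params: MeasurementParams
                     ) -> tuple[float, float]:
    """(GUV, SUV) mid-bilayer z positions on the docking axis, nm.

    The disk-averaged axial profile is correlated with a bilayer template.
    The SUV bilayer is anchored by the detected sphere: its bottom is
    predicted at ``gap/2`` in the box frame (the box is centred on the
    inter-membrane midpoint) and only locally refined by template matching,
    which keeps on-axis protein stacks — which can out-correlate a bilayer
    — from being mistaken for the vesicle membrane.  The GUV is then the
    lowest strong bilayer peak below the SUV.  Without detection metadata a
    joint two-bilayer grid fit over the full window is used instead.
    """
    vx = site_vol.voxel_size
    tmpl, a = _template_autocorr(vx, params)
    prof = _baseline_corrected(_axial_profile(site_vol, params.axis_disk_radius),
                               vx)
    corr = np.correlate(prof, tmpl, mode="same")
    if corr.max() <= 0:
        raise MembranesNotResolvableError("no bilayer signature on the axis")
    zs = site_vol.origin[2] + vx * np.arange(len(corr))
    t = params.bilayer_thickness
    gap_est = site_vol.metadata.get("gap_estimate_nm")
    if gap_est is None:
        g_lo = int(np.searchsorted(zs, -(params.max_separation / 2 + t + 6.0)))
        g_hi = int(np.searchsorted(zs, 4.0))
        if g_hi <= g_lo:
            raise MembranesNotResolvableError("axis window outside the box")
        dmax = int(round((params.max_separation + t) / vx))
        mg_i, ms_i = _two_bilayer_fit(corr[:, None], g_lo, g_hi, dmax, a)
        mg = float(site_vol.origin[2] + mg_i[0] * vx)
        ms = float(site_vol.origin[2] + ms_i[0] * vx)
        if corr[int(round(mg_i[0]))] < 0.15 * corr.max():
            raise MembranesNotResolvableError("no credible bilayer pair")
        return mg, ms

    # membrane amplitude from an annulus clear of the junction densities
    amp = _membrane_amplitude(site_vol, params)
    thr = 0.5 * amp
    sigma = params.leaflet_sigma
    delta = _half_max_offset(t, sigma)
    ms_pred = float(gap_est) / 2 + t / 2
    radius = float(site_vol.metadata.get("suv_radius_nm", 40.0))

    # SUV bottom from the lumen side: scanning down from the empty vesicle
    # interior, the first half-maximum crossing sits on the upper flank of
    # the inner leaflet — protein clusters below the membrane cannot move it
    top = ms_pred + min(10.0, max(2 * (radius - 6.0), 4.0))
    i_top = min(int(np.searchsorted(zs, top)), len(prof) - 1)
    i_bot = max(int(np.searchsorted(zs, ms_pred - 5.0)), 0)
    z_up = _downward_crossing(prof, zs, i_top, i_bot, thr)
    if z_up is None:
        raise MembranesNotResolvableError("SUV leaflet edge not found")
    ms = z_up - t / 2 - delta

    # GUV from below: the region under the membrane is empty, so the first
    # upward half-maximum crossing sits on the lower flank of its inner
    # leaflet, immune to everything above (clusters, the SUV, protrusions)
    i_lo = max(int(np.searchsorted(zs, ms - 40.0)), 0)
    i_hi = min(int(np.searchsorted(zs, ms)), len(prof) - 1)
    z_dn = _upward_crossing(prof, zs, i_lo, i_hi, thr)
    if z_dn is None:
        return ms, ms  # no separate GUV edge below: merged leaflet ridges
    mg = z_dn + t / 2 + delta
    return min(mg, ms), ms


def _membrane_amplitude(site_vol: Volume, params: MeasurementParams) -> float:
    """Leaflet peak amplitude estimated from the GUV far from the axis."""
    xs, ys, _ = site_vol.axes_nm()
    rho2 = xs[None, :] ** 2 + ys[:, None] ** 2
    ann = (rho2 >= 18.0**2) & (rho2 <= 28.0**2)
    prof = _baseline_corrected(site_vol.grid[:, ann].mean(axis=1),
                               site_vol.voxel_size)
    amp = float(prof.max()) / (1.0 + np.exp(-params.bilayer_thickness**2
                                            / (2 * params.leaflet_sigma**2)))
    if amp <= 0:
        raise MembranesNotResolvableError("no membrane signal in the annulus")
    return amp


def _half_max_offset(t: float, sigma: float) -> float:
    """Distance below the outer flank of a leaflet pair at which the summed
    profile drops to half the single-leaflet peak."""
    d = np.linspace(0.0, 5.0 * sigma, 501)
    f = np.exp(-(d**2) / (2 * sigma**2)) + np.exp(-((d + t) ** 2) / (2 * sigma**2))
    return float(np.interp(0.5, f[::-1], d[::-1]))


def _upward_crossing(prof, zs, i_lo, i_hi, thr):
    """First sub-voxel upward threshold crossing scanning from below;
    requires two consecutive samples above threshold (noise guard)."""
    for i in range(i_lo, i_hi - 1):
        if prof[i] < thr <= prof[i + 1] and prof[min(i + 2, len(prof) - 1)] > thr:
            f = (thr - prof[i]) / (prof[i + 1] - prof[i])
            return float(zs[i] + f * (zs[i + 1] - zs[i]))
    return None


def _downward_crossing(prof, zs, i_top, i_bot, thr):
    """First sub-voxel threshold crossing scanning down from above."""
    for i in range(i_top, i_bot + 1, -1):
        if prof[i] < thr <= prof[i - 1] and prof[max(i - 2, 0)] > thr:
            f = (thr - prof[i]) / (prof[i - 1] - prof[i])
            return float(zs[i] + f * (zs[i - 1] - zs[i]))
    return None


def measure_separation(site_vol: Volume, params: MeasurementParams | None = None
                       ) -> float:
    """Membrane separation at closest approach: SUV outer leaflet to GUV
    outer leaflet along the docking axis, clamped at 0 for merged ridges."""
    params = params or MeasurementParams()
    mg, ms = _locate_bilayers(site_vol, params)
    t = params.bilayer_thickness
    return max(0.0, (ms - t / 2) - (mg + t / 2))


# ----------------------------------------------------------------------------
# GUV heightfield inside the box
# ----------------------------------------------------------------------------

def _bilayer_corr(site_vol: Volume, params: MeasurementParams) -> np.ndarray:
    tmpl, _ = bilayer_template(site_vol.voxel_size, params.bilayer_thickness,
                               params.leaflet_sigma)
    return ndimage.correlate1d(site_vol.grid.astype(np.float32), tmpl, axis=0,
                               mode="nearest")


def _track_lowest_peak_win(win: np.ndarray, rel_height: float = 0.6
                           ) -> np.ndarray:
    """Per-column sub-voxel row of the lowest strong bilayer match in a
    correlation window (rows x columns).

    Picking the lowest qualifying local maximum rather than the global
    argmax keeps the tracker on the GUV when the SUV bottom lies inside the
    search window (small membrane separations)."""
    nz = win.shape[0]
    colmax = win.max(axis=0)
    peaks = np.zeros_like(win, dtype=bool)
    peaks[1:-1] = (win[1:-1] >= win[:-2]) & (win[1:-1] > win[2:])
    peaks &= win >= rel_height * colmax[None]
    has = peaks.any(axis=0)
    first = np.where(has, np.argmax(peaks, axis=0), np.argmax(win, axis=0))
    return _parabolic_grid(win, np.clip(first, 1, nz - 2))


def _guv_heightfield(site_vol: Volume, mg: float, params: MeasurementParams,
                     corr: np.ndarray | None = None,
                     suv: tuple[float, float] | None = None,
                     cap_offset: float = 2.0) -> np.ndarray:
    """Outer-leaflet z (nm) per (y, x) column, tracked around the axial
    estimate ``mg`` and median-filtered against blob hijacking.

    When the SUV geometry ``(centre_z, radius)`` is given, the per-column
    search window is capped below the local SUV lower surface so the
    tracker cannot jump onto the vesicle membrane at small separations.
    """
    vx = site_vol.voxel_size
    if corr is None:
        corr = _bilayer_corr(site_vol, params)
    # asymmetric window: the axial estimate sits on the protrusion bump top,
    # so columns elsewhere can only be at or below it (minus bump height),
    # and protein clusters just above the membrane stay out of reach
    mg_i = int(round((mg - site_vol.origin[2]) / vx))
    lo = max(mg_i - max(int(round(12.0 / vx)), 2), 0)
    hi = min(mg_i + max(int(round(3.0 / vx)), 1) + 1, corr.shape[0])
    win = corr[lo:hi].copy()
    if suv is not None:
        cz, radius = suv
        xs, ys, _ = site_vol.axes_nm()
        rho2 = xs[None, :] ** 2 + ys[:, None] ** 2
        with np.errstate(invalid="ignore"):
            surf = cz - np.sqrt(np.maximum(radius**2 - rho2, 0.0))
        cap_nm = np.where(rho2 < radius**2, surf - cap_offset, np.inf)
        cap_nm = np.maximum(cap_nm, site_vol.origin[2] + (lo + 1) * vx)
        cap_idx = (cap_nm - site_vol.origin[2]) / vx - lo
        rows = np.arange(win.shape[0])[:, None, None]
        win[rows > cap_idx[None]] = -1e30  # finite sentinel keeps parabola sane
    mid_idx = lo + _track_lowest_peak_win(win)
    mid = site_vol.origin[2] + ndimage.median_filter(mid_idx, size=3) * vx
    # the protrusion bump peaks on the docking axis, so no column can sit
    # above the axial estimate; capping suppresses the upward bias the
    # tracker acquires under the vesicle at small separations
    mid = np.minimum(mid, mg + 1.0)
    return mid + params.bilayer_thickness / 2



# ----------------------------------------------------------------------------
# SUV sphere refinement
# ----------------------------------------------------------------------------

def _refine_sphere(site_vol: Volume, params: MeasurementParams,
                   c0: np.ndarray, r_out0: float
                   ) -> tuple[float, float, float, float]:
    """Refine the SUV centre and outer-leaflet radius on the subtomogram.

    Rays from the current centre estimate sample a smoothed map across the
    expected shell; the per-ray ridge position (the merged leaflet pair)
    feeds an algebraic least-squares sphere fit, iterated twice.
    Directions within ~45 degrees of -z are excluded (junction side:
    merged membranes and protein densities), and rays with a weak ridge are
    dropped (the missing wedge attenuates shell segments whose normal lies
    near the beam axis).  Returns ``(cx, cy, cz, r_outer)`` in box nm.
    """
    vx = site_vol.voxel_size
    t = params.bilayer_thickness
    grid = ndimage.gaussian_filter(site_vol.grid.astype(np.float32), 1.0)
    n = 256
    i = np.arange(n) + 0.5
    zd = 1.0 - 2.0 * i / n
    keep = zd > -0.7
    phi = np.pi * (1 + 5**0.5) * i
    sd = np.sqrt(np.maximum(1 - zd**2, 0))
    dirs = np.column_stack([sd * np.cos(phi), sd * np.sin(phi), zd])[keep]
    c = np.asarray(c0, float).copy()
    r_mid = r_out0 - t / 2
    for _ in range(2):
        rad = r_mid + np.arange(-6.0, 6.0 + 1e-9, vx / 2)
        pts = c[None, None, :] + dirs[:, None, :] * rad[None, :, None]
        idx = ((pts - site_vol.origin) / vx)[..., ::-1]
        vals = ndimage.map_coordinates(
            grid, idx.reshape(-1, 3).T, order=1, cval=0.0
        ).reshape(len(dirs), len(rad))
        k = np.clip(np.argmax(vals, axis=1), 1, len(rad) - 2)
        rows = np.arange(len(dirs))
        ym, y0, yp = vals[rows, k - 1], vals[rows, k], vals[rows, k + 1]
        denom = ym - 2 * y0 + yp
        frac = np.where(denom < 0,
                        0.5 * (ym - yp) / np.where(denom == 0, 1, denom), 0.0)
        rr = rad[k] + np.clip(frac, -0.5, 0.5) * (vx / 2)
        amp = y0
        floor = 0.35 * np.median(amp[amp > 0]) if np.any(amp > 0) else np.inf
        good = (amp > floor) & (np.abs(rr - r_mid) < 5.5)
        if good.sum() < 16:
            break
        P = c[None, :] + dirs[good] * rr[good, None]
        A = np.column_stack([2 * P, np.ones(len(P))])
        b = (P**2).sum(axis=1)
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        # large vesicles show only a spherical cap inside the box, where the
        # algebraic fit is ill-conditioned; keep the result near the priors
        c = np.clip(sol[:3], np.asarray(c0, float) - 3.0,
                    np.asarray(c0, float) + 3.0)
        r_mid = float(np.clip(np.sqrt(max(sol[3] + c @ c, 1.0)),
                              r_out0 - t / 2 - 2.0, r_out0 - t / 2 + 2.0))
    return float(c[0]), float(c[1]), float(c[2]), r_mid + t / 2


def _default_sphere(site_vol: Volume, params: MeasurementParams,
                    mg: float, ms: float, suv_radius: float
                    ) -> tuple[float, float, float, float]:
    c0 = np.array([0.0, 0.0, ms - params.bilayer_thickness / 2 + suv_radius])
    return _refine_sphere(site_vol, params, c0, suv_radius)


# ----------------------------------------------------------------------------
# density landmarks
# ----------------------------------------------------------------------------

def _membrane_model(site_vol: Volume, h_outer: np.ndarray,
                    sphere: tuple[float, float, float, float],
                    params: MeasurementParams, split: bool = False,
                    sep_est: float | None = None):
    """Synthetic membrane-only map from the tracked surfaces, used to
    subtract membrane signal before protein-density peak finding.

    With ``split=True`` the GUV sheet and SUV shell are returned separately
    so their amplitudes can be fitted independently (the missing wedge
    attenuates them differently).  Both components are passed through the
    same wedge mask as the data when the box is axis-aligned with the lab
    frame.  When ``sep_est`` is given, columns where the sphere would dip
    below the target membrane are flattened against it — a vesicle in
    direct contact forms a facet, and modelling it as an intact sphere
    leaves a dipole ring around the contact rim.
    """
    xs, ys, zsn = site_vol.axes_nm()
    sl = params.leaflet_sigma
    t = params.bilayer_thickness
    sd = zsn[:, None, None] - h_outer[None, :, :]
    model_g = (np.exp(-sd**2 / (2 * sl**2))
               + np.exp(-((sd + t) ** 2) / (2 * sl**2))).astype(np.float32)
    cx, cy, cz, r_out = sphere
    d = np.sqrt((xs[None, None, :] - cx) ** 2 + (ys[None, :, None] - cy) ** 2
                + (zsn[:, None, None] - cz) ** 2)
    if sep_est is not None:
        rho_c2 = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2
        with np.errstate(invalid="ignore"):
            sphere_lower = cz - np.sqrt(np.maximum(r_out**2 - rho_c2, 0.0))
        zfloor = h_outer + max(sep_est, 0.0)
        flat = (rho_c2 < (0.95 * r_out) ** 2) & (sphere_lower < zfloor - 0.3)
        if flat.any():
            d_flat = np.abs(zsn[:, None, None] - zfloor[None]) + r_out
            below = zsn[:, None, None] < cz
            d = np.where(flat[None] & below, d_flat, d)
    model_s = (np.exp(-((d - r_out) ** 2) / (2 * sl**2))
               + np.exp(-((d - r_out + t) ** 2) / (2 * sl**2))).astype(np.float32)
    if params.wedge_half_angle is not None:
        rot = np.asarray(site_vol.metadata.get("rotation_box_to_lab", np.eye(3)))
        if np.allclose(rot, np.eye(3), atol=1e-6):
            import scipy.fft
            mask = missing_wedge_mask(model_g.shape, params.wedge_half_angle)
            for m in (model_g, model_s):
                spec = scipy.fft.rfftn(m)
                spec *= mask
                m[:] = scipy.fft.irfftn(spec, s=m.shape)
    if split:
        return model_g, model_s
    return model_g + model_s


def detect_density_landmarks(site_vol: Volume, params: MeasurementParams | None = None,
                             suv_radius: float | None = None,
                             threshold: float | None = None,
                             sphere: tuple[float, float, float, float] | None = None,
                             ) -> tuple[np.ndarray, list[str]]:
    """Locate protein-density centres in an oriented subtomogram.

    The map is smoothed with a ~3x3x3-voxel Gaussian, a membrane model built
    from the tracked GUV heightfield and the detected SUV shell is scaled
    and subtracted, and local maxima of the residual above
    ``bg mean + density_threshold_nsd * bg SD`` (or an explicit
    ``threshold``) are kept; maxima closer than ``merge_radius`` are merged
    into the strongest.  Each point is tagged ``guv_membrane``,
    ``suv_membrane`` or ``intermembrane`` by proximity to the surfaces.
    """
    params = params or MeasurementParams()
    vx = site_vol.voxel_size
    mg, ms = _locate_bilayers(site_vol, params)
    if suv_radius is None:
        suv_radius = float(site_vol.metadata.get("suv_radius_nm", 40.0))
    if sphere is None:
        sphere = _default_sphere(site_vol, params, mg, ms, suv_radius)
    sep_est = max(0.0, (ms - mg) - params.bilayer_thickness)
    cap = 2.0 if sep_est > 3.0 else 0.0  # near contact the surfaces coincide
    h_outer = _guv_heightfield(site_vol, mg, params,
                               suv=(sphere[2], sphere[3]), cap_offset=cap)
    model_g, model_s = _membrane_model(site_vol, h_outer, sphere, params,
                                       split=True)
    grid = site_vol.grid.astype(np.float32)
    # separate amplitudes: the missing wedge attenuates the vesicle shell
    # but not the flat patch, so one global scale leaves ridge residuals.
    # Fitted away from the junction so protein densities hugging the
    # membranes there cannot inflate the scales.
    xs_f, ys_f, _ = site_vol.axes_nm()
    rho2_f = xs_f[None, None, :] ** 2 + ys_f[None, :, None] ** 2
    far = (rho2_f > 26.0**2) & (rho2_f < 50.0**2) & _inside_source(site_vol)
    mg_w = np.where(far, model_g, 0.0)
    ms_w = np.where(far, model_s, 0.0)
    gg = float((mg_w**2).sum())
    ss = float((ms_w**2).sum())
    gs = float((mg_w * ms_w).sum())
    bg_v = np.array([float((grid * mg_w).sum()), float((grid * ms_w).sum())])
    mat = np.array([[gg, gs], [gs, ss]])
    try:
        alpha_g, alpha_s = np.linalg.solve(mat, bg_v)
    except np.linalg.LinAlgError:
        alpha_g = alpha_s = bg_v.sum() / max(gg + ss + 2 * gs, 1e-9)
    model = alpha_g * model_g + alpha_s * model_s
    resid = grid - model
    resid = ndimage.gaussian_filter(resid, sigma=params.density_smooth_sigma_vox)

    # background for the detection threshold: everything outside the
    # junction cylinder except the leaflet-ridge cores, so the 3-sigma rule
    # reflects the membrane-subtraction artifact floor rather than the pure
    # noise floor
    model_ref = model_g + model_s
    bg = resid[(rho2_f > 36.0**2) & (np.abs(model_ref) < 0.3)]
    if bg.size < 1000:
        bg = resid[np.abs(model_ref) < 0.05]
    thr = threshold if threshold is not None else (
        float(bg.mean()) + params.density_threshold_nsd * float(bg.std()))
    del model_ref

    # geometric eligibility, evaluated voxelwise: the density search space is
    # the membrane apposition zone between the tracked surfaces
    cx, cy, cz, r_out = sphere
    t = params.bilayer_thickness
    prior = np.array([0.0, 0.0, ms - t / 2 + suv_radius])
    z_lo, z_hi = params.density_slab
    lo_m, hi_m = params.min_suv_clearance, params.max_membrane_offset
    xs3 = xs_f[None, None, :]
    ys3 = ys_f[None, :, None]
    zs3 = site_vol.axes_nm()[2][:, None, None]
    rho3 = np.sqrt(xs3**2 + ys3**2)
    dz3 = zs3 - h_outer[None]
    d_fit3 = np.abs(np.sqrt((xs3 - cx) ** 2 + (ys3 - cy) ** 2
                            + (zs3 - cz) ** 2) - r_out)
    d_pri3 = np.abs(np.sqrt(xs3**2 + ys3**2 + (zs3 - prior[2]) ** 2)
                    - suv_radius)
    d_suv3 = 0.5 * (d_fit3 + d_pri3)
    rho_c2 = (xs3 - cx) ** 2 + (ys3 - cy) ** 2
    with np.errstate(invalid="ignore"):
        z_cap3 = np.where(rho_c2 < r_out**2,
                          cz - np.sqrt(np.maximum(r_out**2 - rho_c2, 0.0)) + 3.0,
                          dz3 * 0 + h_outer[None] + 8.0)
    elig = ((rho3 <= params.density_max_radius)
            & (dz3 >= z_lo) & (dz3 <= z_hi) & (zs3 <= z_cap3)
            & (d_suv3 >= lo_m)
            & ((dz3 <= hi_m) | (d_suv3 <= hi_m) | (rho3 <= 14.0))
            & ((rho3 <= 12.0) | (dz3 + d_suv3 <= 15.0)))

    # landmark placement: local maxima of the residual within the
    # eligibility region, merged at merge_radius (strongest wins)
    min_dist = max(int(round(params.merge_radius / vx)), 1)
    peaks = peak_local_max(resid, min_distance=min_dist, threshold_abs=thr,
                           exclude_border=False)
    cand = peaks
    cand_vals = resid[tuple(cand.T)] if len(cand) else np.empty(0)
    picked = list(range(len(cand)))

    pts, comps, vals = [], [], []
    for i in picked:
        p = _com_refine(resid, cand[i], site_vol)
        if not bool(elig[tuple(cand[i])]):
            continue
        d_fit = abs(np.linalg.norm(p - np.array([cx, cy, cz])) - r_out)
        d_prior = abs(np.linalg.norm(p - prior) - suv_radius)
        d_suv = 0.5 * (d_fit + d_prior)
        if d_suv < 4.0 and _on_local_suv_ridge(site_vol, p, sphere, lo_m):
            continue
        h_here = float(_bilinear(h_outer, site_vol, p[0], p[1]))
        dz_guv = p[2] - h_here
        if dz_guv <= hi_m and dz_guv <= d_suv:
            comps.append("guv_membrane")
        elif d_suv <= hi_m and d_suv < dz_guv:
            comps.append("suv_membrane")
        else:
            comps.append("intermembrane")
        pts.append(p)
        vals.append(float(cand_vals[i]))
    pts_arr, comps = _suppress_cluster_satellites(
        np.array(pts).reshape(-1, 3), comps, np.array(vals), site_vol)
    has_central = (len(pts_arr) > 0
                   and bool(np.any(np.hypot(pts_arr[:, 0], pts_arr[:, 1]) <= 9.0)))
    if not has_central:
        rescue = _rescue_buried_central_density(resid, h_outer, mg, ms,
                                                site_vol, params)
        if rescue is not None:
            pts_arr = np.vstack([pts_arr.reshape(-1, 3), rescue[None]])
            comps = list(comps) + ["intermembrane"]
    rho_now = np.hypot(pts_arr[:, 0], pts_arr[:, 1]) if len(pts_arr) else np.empty(0)
    if int((rho_now > 10.0).sum()) < 3:
        arcs = _ring_arc_landmarks(resid, h_outer, site_vol, params, pts_arr)
        if len(arcs):
            pts_arr = np.vstack([pts_arr.reshape(-1, 3), arcs])
            comps = list(comps) + ["guv_membrane"] * len(arcs)
    return pts_arr.reshape(-1, 3), comps


def _ring_arc_landmarks(resid: np.ndarray, h_outer: np.ndarray,
                        site_vol: Volume, params: MeasurementParams,
                        existing: np.ndarray) -> np.ndarray:
    """Landmarks for a continuous density ring that yields few maxima.

    A closed or partial ring of overlapping densities hugging the target
    membrane forms a smooth torus with almost no discrete maxima.  The
    residual is averaged over a thin shell 2-6.5 nm above the tracked
    membrane; azimuthal sectors of the annulus just outside the exclusion
    cylinder whose mass clearly exceeds the matched far-annulus background
    count as ring arcs, one landmark each at the sector mass centroid.
    At least three occupied sectors are required — anything less is not a
    ring and contributes nothing, so isolated artifacts cannot fake one.
    """
    vx = site_vol.voxel_size
    xs, ys, zs = site_vol.axes_nm()
    # shell 2-6.5 nm above the local membrane
    nz = resid.shape[0]
    zi = (h_outer[None] + 2.0 <= zs[:, None, None]) & (
        zs[:, None, None] <= h_outer[None] + 6.5)
    counts = zi.sum(axis=0)
    slab = np.where(counts > 0, (resid * zi).sum(axis=0) / np.maximum(counts, 1),
                    0.0)
    rho = np.hypot(xs[None, :], ys[:, None])
    ang = np.arctan2(ys[:, None], xs[None, :])
    nsec = 12
    sec = (np.floor((ang + np.pi) / (2 * np.pi) * nsec + 1e-9).astype(int)
           % nsec)
    ring_band = (rho >= 11.0) & (rho <= 25.0)
    ctrl_band = (rho >= 27.0) & (rho <= 38.0)
    ctrl = np.array([slab[ctrl_band & (sec == k)].mean() for k in range(nsec)])
    med = float(np.median(ctrl))
    mad = float(np.median(np.abs(ctrl - med))) * 1.4826
    if mad <= 0:
        return np.empty((0, 3))
    # a ring arc must form a radial crest: the sector's radial profile peaks
    # in the ring band and rises from the exclusion-cylinder rim, whereas
    # the azimuthally uniform skirt of a central cluster decays outward
    edges = np.arange(8.0, 28.0, 2.0)
    occupied = []
    for k in range(nsec):
        msk = sec == k
        prof = np.array([
            slab[msk & (rho >= a) & (rho < b)].mean()
            if np.any(msk & (rho >= a) & (rho < b)) else 0.0
            for a, b in zip(edges[:-1], edges[1:])
        ])
        inner = prof[0]  # 8-10 nm: cluster-skirt reference
        crest_i = 1 + int(np.argmax(prof[1:]))
        crest = prof[crest_i]
        if crest > med + 4.0 * mad and crest >= inner + 2.0 * mad:
            occupied.append(k)
    if len(occupied) < 3:
        return np.empty((0, 3))
    out = []
    for k in occupied:
        m = ring_band & (sec == k)
        w = np.clip(slab[m], 0, None)
        if w.sum() <= 0:
            continue
        X = np.broadcast_to(xs[None, :], slab.shape)[m]
        Y = np.broadcast_to(ys[:, None], slab.shape)[m]
        px = float((X * w).sum() / w.sum())
        py = float((Y * w).sum() / w.sum())
        hz = float(_bilinear(h_outer, site_vol, px, py))
        p = np.array([px, py, hz + 3.5])
        if len(existing) and np.min(np.linalg.norm(existing - p, axis=1)) < params.merge_radius:
            continue
        out.append(p)
    return np.array(out).reshape(-1, 3)


def _rescue_buried_central_density(resid: np.ndarray, h_outer: np.ndarray,
                                   mg: float, ms: float, site_vol: Volume,
                                   params: MeasurementParams
                                   ) -> np.ndarray | None:
    """Second-chance detection of density buried between close membranes.

    At separations of a few nm a density squeezed between the leaflets
    overlaps both membranes and its 3D maximum can drop below threshold.
    Averaging the residual across the inter-membrane slab regains contrast;
    the central 2D maximum is accepted when it clearly exceeds the slab's
    own robust background level.
    """
    vx = site_vol.voxel_size
    t = params.bilayer_thickness
    zs = site_vol.axes_nm()[2]
    lo_z, hi_z = mg + t / 2 + 1.5, ms - t / 2 - 1.0
    if hi_z - lo_z < 1.2:
        return None
    sel = (zs >= lo_z) & (zs <= hi_z)
    if sel.sum() < 1:
        return None
    slab = resid[sel].mean(axis=0)
    xs, ys, _ = site_vol.axes_nm()
    rho2 = xs[None, :] ** 2 + ys[:, None] ** 2
    bg = slab[(rho2 > 26.0**2) & (rho2 < 40.0**2)]
    if bg.size < 50:
        return None
    med = float(np.median(bg))
    mad = float(np.median(np.abs(bg - med))) * 1.4826
    if mad <= 0:
        return None
    central = np.where(rho2 <= 12.0**2, slab, -np.inf)
    jy, jx = np.unravel_index(np.argmax(central), slab.shape)
    # a maximum sitting at the window rim is the inward tail of a ring
    # density, not a central cluster
    if rho2[jy, jx] > 7.0**2:
        return None
    if central[jy, jx] < med + 3.5 * mad:
        return None
    zsel = np.where(sel)[0]
    prof = resid[zsel, jy, jx]
    zc = float(zs[zsel[np.argmax(prof)]])
    return np.array([xs[jx], ys[jy], zc])


def _on_local_suv_ridge(site_vol: Volume, p: np.ndarray,
                        sphere: tuple[float, float, float, float],
                        clearance: float) -> bool:
    """Does a candidate peak sit on the locally measured SUV leaflet?

    The global sphere hypotheses carry ~1-2 nm error, which is comparable
    to the clearance between membrane-residual artifacts (on the leaflet)
    and genuine membrane-attached densities (a protein radius off it).  The
    leaflet position in the candidate's own column, refined from the
    density ridge near the sphere prediction, is accurate to a fraction of
    a voxel and separates the two cleanly.
    """
    cx, cy, cz, r_out = sphere
    vx = site_vol.voxel_size
    rho2 = (p[0] - cx) ** 2 + (p[1] - cy) ** 2
    if rho2 >= (0.95 * r_out) ** 2:
        return False
    z_pred = cz - np.sqrt(r_out**2 - rho2)
    zs = site_vol.axes_nm()[2]
    lo = int(np.searchsorted(zs, z_pred - 2.0))
    hi = int(np.searchsorted(zs, z_pred + 4.0)) + 1
    lo, hi = max(lo, 1), min(hi, len(zs) - 1)
    if hi - lo < 3:
        return False
    xi = (p[0] - site_vol.origin[0]) / vx
    yi = (p[1] - site_vol.origin[1]) / vx
    col = ndimage.map_coordinates(
        site_vol.grid, [np.arange(lo, hi), np.full(hi - lo, yi),
                        np.full(hi - lo, xi)], order=1, cval=0.0)
    col = col.copy()
    col[np.abs(zs[lo:hi] - p[2]) < 2.2] = -np.inf  # blind to the peak itself
    if not np.isfinite(col).any():
        return False
    k = int(np.argmax(col))
    if (not 0 < k < len(col) - 1 or not np.isfinite(col[k - 1])
            or not np.isfinite(col[k + 1])):
        surf = zs[lo + k]
    else:
        denom = col[k - 1] - 2 * col[k] + col[k + 1]
        frac = 0.5 * (col[k - 1] - col[k + 1]) / denom if denom < 0 else 0.0
        surf = zs[lo + k] + np.clip(frac, -0.5, 0.5) * vx
    return abs(p[2] - surf) < clearance


def _suppress_cluster_satellites(pts: np.ndarray, comps: list[str],
                                 vals: np.ndarray, site_vol: Volume,
                                 axis_radius: float = 12.0,
                                 ratio: float = 2.5) -> tuple[np.ndarray, list[str]]:
    """Drop radially outer peaks that are wedge satellites of the central
    density cluster.

    The missing wedge flanks every bright feature with weak satellite
    maxima displaced along the beam axis.  For a dense cluster at the
    docking axis these satellites land *outside* the exclusion cylinder and
    would mimic a ring.  An outer peak is discarded when a much stronger
    peak near the axis sits close to its beam-axis line.
    """
    if len(pts) <= 1:
        return pts, comps
    rot = np.asarray(site_vol.metadata.get("rotation_box_to_lab", np.eye(3)))
    beam = rot.T @ np.array([1.0, 0.0, 0.0])
    rho = np.hypot(pts[:, 0], pts[:, 1])
    inner = np.where(rho <= axis_radius)[0]
    keep = np.ones(len(pts), dtype=bool)
    for jx in np.where(rho > axis_radius)[0]:
        for ix in inner:
            if vals[ix] < ratio * vals[jx]:
                continue
            dvec = pts[jx] - pts[ix]
            along = float(dvec @ beam)
            perp = dvec - along * beam
            if abs(perp[1]) <= 7.0 and abs(perp[2]) <= 9.0:
                keep[jx] = False
                break
    return pts[keep], [c for c, k in zip(comps, keep) if k]


def _beam_elongated(resid: np.ndarray, p: np.ndarray, site_vol: Volume,
                    ratio: float = 0.45) -> bool:
    """Is a residual peak smeared along the beam axis?

    Missing-wedge streaks of bright features and leftover membrane-ridge
    signal are extended along the beam, while a genuine protein density is
    compact in every direction.  The peak is flagged when the residual
    ~6.5 nm away on *both* sides along the beam is still a large fraction
    of the peak value.
    """
    rot = np.asarray(site_vol.metadata.get("rotation_box_to_lab", np.eye(3)))
    beam = rot.T @ np.array([1.0, 0.0, 0.0])
    vx = site_vol.voxel_size
    d = 3.0 * vx
    v0 = _sample(resid, site_vol, p)
    if v0 <= 0:
        return True
    side = min(_sample(resid, site_vol, p + d * beam),
               _sample(resid, site_vol, p - d * beam))
    return side >= ratio * v0


def _sample(field: np.ndarray, vol: Volume, p: np.ndarray) -> float:
    idx = vol.xyz_to_index(p)[0]
    return float(ndimage.map_coordinates(field, idx[:, None], order=1,
                                         cval=0.0)[0])


def _inside_source(site_vol: Volume) -> np.ndarray:
    """Boolean mask of box voxels that map inside the source tomogram.

    Subtomogram boxes cut near a volume edge contain zero-filled regions;
    fitting the membrane-model amplitudes there would bias them low."""
    meta = site_vol.metadata
    if "source_origin_nm" not in meta:
        return np.ones(site_vol.grid.shape, dtype=bool)
    rot = np.asarray(meta.get("rotation_box_to_lab", np.eye(3)))
    mid = np.asarray(meta["midpoint_lab"], float)
    o = np.asarray(meta["source_origin_nm"], float)
    ext = np.asarray(meta["source_extent_nm"], float)
    xs, ys, zs = site_vol.axes_nm()
    if np.allclose(rot, np.eye(3), atol=1e-9):
        okx = (xs + mid[0] >= o[0]) & (xs + mid[0] <= o[0] + ext[0])
        oky = (ys + mid[1] >= o[1]) & (ys + mid[1] <= o[1] + ext[1])
        okz = (zs + mid[2] >= o[2]) & (zs + mid[2] <= o[2] + ext[2])
        return (okz[:, None, None] & oky[None, :, None] & okx[None, None, :])
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    lab = np.stack([X, Y, Z], axis=-1) @ rot.T + mid
    return np.all((lab >= o) & (lab <= o + ext), axis=-1)


def _com_refine(resid: np.ndarray, peak_zyx: np.ndarray, vol: Volume) -> np.ndarray:
    sl = tuple(slice(max(c - 1, 0), min(c + 2, s)) for c, s in
               zip(peak_zyx, resid.shape))
    patch = np.clip(resid[sl], 0, None)
    if patch.sum() > 0:
        com = ndimage.center_of_mass(patch)
        idx = np.array([s.start for s in sl], float) + np.asarray(com)
    else:
        idx = np.asarray(peak_zyx, float)
    return vol.index_to_xyz(idx)[0]


def _bilinear(field: np.ndarray, vol: Volume, x: float, y: float) -> float:
    xi = (x - vol.origin[0]) / vol.voxel_size
    yi = (y - vol.origin[1]) / vol.voxel_size
    return float(ndimage.map_coordinates(field, [[yi], [xi]], order=1,
                                         mode="nearest")[0])


def has_intermembrane_density(site: DockingSite,
                              params: MeasurementParams | None = None) -> bool:
    """Docking-rule predicate: is protein density visible at the junction?

    True iff the density detector finds at least one landmark within 30 nm
    of the docking axis in the inter-membrane slab of the site's oriented
    subtomogram.
    """
    params = params or MeasurementParams()
    if site.subtomogram is None:
        raise ValueError("site has no extracted subtomogram")
    try:
        pts, _ = detect_density_landmarks(site.subtomogram, params,
                                          suv_radius=site.suv_radius)
    except MembranesNotResolvableError:
        return False
    if len(pts) == 0:
        return False
    return bool(np.any(np.hypot(pts[:, 0], pts[:, 1])
                       <= params.density_max_radius))


# ----------------------------------------------------------------------------
# contact diameter
# ----------------------------------------------------------------------------

def measure_contact_diameter(site_vol: Volume,
                             params: MeasurementParams | None = None,
                             suv_radius: float | None = None,
                             sphere: tuple[float, float, float, float] | None = None,
                             ) -> float:
    """Diameter of the flattened membrane-contact region, nm.

    The per-column leaflet gap is measured from half-maximum edge
    crossings; membranes count as touching when the gap at the axis is at
    most ``contact_epsilon`` (default one voxel).  The facet is the
    connected plateau around the axis where the gap stays within 0.5 nm of
    its central floor — off the facet the spherical shoulder lifts the gap
    away immediately — and its equivalent-circle diameter is returned.
    Returns 0 when the membranes do not touch on the axis.  Facets smaller
    than ~2*sqrt(R) nm are overestimated: within measurement precision the
    shoulder of an R-nm vesicle is indistinguishable from a small flat
    patch (a point contact reads as a few-voxel plateau).
    """
    params = params or MeasurementParams()
    vx = site_vol.voxel_size
    eps = params.contact_epsilon if params.contact_epsilon is not None else vx
    if suv_radius is None:
        suv_radius = float(site_vol.metadata.get("suv_radius_nm", 40.0))
    mg, ms = _locate_bilayers(site_vol, params)
    t = params.bilayer_thickness
    # loose gate only: a merged double membrane widens the axial estimate
    # by up to ~2 nm, so the decisive test is the gap-map floor below
    if (ms - mg) - t > eps + 4.0:
        return 0.0
    if sphere is None:
        sphere = _default_sphere(site_vol, params, mg, ms, suv_radius)
    cx, cy, cz, r_out = sphere

    amp = _membrane_amplitude(site_vol, params)
    delta = _half_max_offset(t, params.leaflet_sigma)
    gap, valid = _gap_map(site_vol, params, sphere, 0.5 * amp, delta)
    ic = (int(round((cy - site_vol.origin[1]) / vx)),
          int(round((cx - site_vol.origin[0]) / vx)))
    ic = (int(np.clip(ic[0], 0, gap.shape[0] - 1)),
          int(np.clip(ic[1], 0, gap.shape[1] - 1)))
    centre = gap[max(ic[0] - 1, 0):ic[0] + 2, max(ic[1] - 1, 0):ic[1] + 2]
    centre = centre[np.isfinite(centre)]
    if centre.size == 0:
        return 0.0
    g_floor = float(np.median(centre))
    if g_floor > eps:
        return 0.0
    # the facet is the plateau where the gap sits at its central floor; off
    # the facet the spherical shoulder lifts the gap away immediately
    contact = ndimage.binary_closing(valid & (gap <= g_floor + 0.5))
    labels, _ = ndimage.label(contact)
    lab = labels[ic]
    if lab == 0:
        n0 = labels[max(ic[0] - 2, 0):ic[0] + 3, max(ic[1] - 2, 0):ic[1] + 3]
        vals = n0[n0 > 0]
        if len(vals) == 0:
            return 0.0
        lab = np.bincount(vals).argmax()
    area = float((labels == lab).sum()) * vx**2
    return float(2.0 * np.sqrt(area / np.pi))


def _gap_map(site_vol: Volume, params: MeasurementParams,
             sphere: tuple[float, float, float, float],
             thr: float, delta: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-column leaflet gap (nm) near the docking axis.

    Each column is scanned for half-maximum edges from below: the rising
    edge of the GUV slab, its falling edge, and — within a window around
    the sphere-predicted SUV lower surface — the rising edge of the SUV
    slab.  When the two membranes merge into one slab its total thickness
    carries the gap; a lone GUV slab (SUV far above) yields an infinite
    gap.  Returns (gap, valid-column mask).
    """
    vx = site_vol.voxel_size
    t = params.bilayer_thickness
    grid = site_vol.grid
    nz = grid.shape[0]
    xs, ys, zs = site_vol.axes_nm()
    cx, cy, cz, r_out = sphere
    rho2 = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2
    valid = rho2 <= min(0.9 * r_out, 30.0) ** 2
    with np.errstate(invalid="ignore"):
        suv_surf = cz - np.sqrt(np.maximum(r_out**2 - rho2, 0.0))

    rows = np.arange(nz)[:, None, None]
    pair_factor = 1.0 + np.exp(-(t**2) / (2 * params.leaflet_sigma**2))

    # pass 1: global threshold locates the membrane slab per column
    above = grid >= thr
    above2 = above & np.vstack([above[1:], above[-1:]])
    i1g = np.argmax(above2, axis=0)
    win = (rows >= i1g[None]) & (rows <= i1g[None] + int(round(16.0 / vx)))
    peak_col = np.where(win, grid, -np.inf).max(axis=0)
    # pass 2: per-column amplitude-normalised threshold — merged membranes
    # double the slab amplitude, which would otherwise widen the half-max
    # span and masquerade as extra separation
    # normalise per column, but never let the doubled mid-layer of a
    # membrane contact push the threshold above the single outer leaflets
    thr_col = np.clip(0.5 * peak_col / pair_factor, 0.8 * thr, 1.3 * thr)
    above = grid >= thr_col[None]
    above2 = above & np.vstack([above[1:], above[-1:]])

    def subvoxel(i_cross):
        i0 = np.clip(i_cross - 1, 0, nz - 1)
        i1_ = np.clip(i_cross, 0, nz - 1)
        v0 = np.take_along_axis(grid, i0[None], axis=0)[0]
        v1 = np.take_along_axis(grid, i1_[None], axis=0)[0]
        f = np.clip((thr_col - v0) / np.where(v1 != v0, v1 - v0, 1.0), 0.0, 1.0)
        return zs[0] + (i0 + f) * vx

    has1 = above2.any(axis=0)
    i1 = np.argmax(above2, axis=0)
    below = ~above
    m2 = below & np.vstack([below[1:], below[-1:]]) & (rows > i1[None])
    has2 = m2.any(axis=0)
    i2 = np.argmax(m2, axis=0)
    # SUV rising edge gated to the sphere prediction (blobs are rejected)
    pred = (suv_surf - delta - site_vol.origin[2]) / vx
    m3 = above2 & (rows > i2[None]) & (np.abs(rows - pred[None]) <= 3.5 / vx)
    has3 = m3.any(axis=0)
    i3 = np.argmax(m3, axis=0)

    z1, z2, z3 = subvoxel(i1), subvoxel(i2), subvoxel(i3)
    T = z2 - z1
    gap3 = np.maximum((z3 - z2) + 2 * delta, 0.0)
    gapT = np.maximum(T - (2 * t + 2 * delta), 0.0)
    gap = np.where(has3, gap3,
                   np.where(T >= t + 2 * delta + 2.0, gapT, np.inf))
    gap = np.where(has1 & has2, gap, np.inf)
    return gap, valid


# ----------------------------------------------------------------------------
# protrusion
# ----------------------------------------------------------------------------

def detect_protrusion(site_vol: Volume, params: MeasurementParams | None = None,
                      sphere: tuple[float, float, float, float] | None = None,
                      ) -> tuple[int, float]:
    """GUV protrusion flag and height at an oriented site.

    The GUV outer-leaflet heightfield is fitted with a baseline plane over
    the annulus outside ``protrusion_window`` (least squares; a degenerate
    annulus raises :class:`MembranesNotResolvableError`), and the elevation
    of the membrane on the docking axis above that baseline is reported;
    the flag is 1 iff the elevation exceeds ``protrusion_min_height``.
    """
    params = params or MeasurementParams()
    mg, ms = _locate_bilayers(site_vol, params)
    if sphere is None:
        suv_radius = float(site_vol.metadata.get("suv_radius_nm", 40.0))
        sphere = _default_sphere(site_vol, params, mg, ms, suv_radius)
    h = _guv_heightfield(site_vol, mg, params, suv=(sphere[2], sphere[3]))
    xs, ys, _ = site_vol.axes_nm()
    rho2 = xs[None, :] ** 2 + ys[:, None] ** 2
    ann = (rho2 >= params.protrusion_window**2) & (
        rho2 <= (params.protrusion_window + 15.0) ** 2)
    if ann.sum() < 8:
        raise MembranesNotResolvableError("baseline annulus empty")
    X = np.column_stack([xs[None, :].repeat(len(ys), 0)[ann],
                         ys[:, None].repeat(len(xs), 1)[ann],
                         np.ones(int(ann.sum()))])
    coef, _, rank, _ = np.linalg.lstsq(X, h[ann], rcond=None)
    if rank < 3:
        raise MembranesNotResolvableError("baseline plane fit rank-deficient")
    center = mg + params.bilayer_thickness / 2  # axial outer-leaflet estimate
    elevation = float(center - coef[2])
    return int(elevation > params.protrusion_min_height), elevation


# ----------------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------------

def measure_junction(site: DockingSite, params: MeasurementParams | None = None
                     ) -> JunctionMeasurement:
    """Run all measurements on one oriented docking site."""
    params = params or MeasurementParams()
    vol = site.subtomogram
    if vol is None:
        raise ValueError("site has no extracted subtomogram")
    mg, ms = _locate_bilayers(vol, params)
    t = params.bilayer_thickness
    sep = max(0.0, (ms - t / 2) - (mg + t / 2))
    sphere = _default_sphere(vol, params, mg, ms, site.suv_radius)
    pts, comps = detect_density_landmarks(vol, params,
                                          suv_radius=site.suv_radius,
                                          sphere=sphere)
    eps = params.contact_epsilon if params.contact_epsilon is not None else vol.voxel_size
    contact = (measure_contact_diameter(vol, params,
                                        suv_radius=site.suv_radius,
                                        sphere=sphere)
               if sep <= eps + 4.0 else 0.0)
    flag, height = detect_protrusion(vol, params, sphere=sphere)
    return JunctionMeasurement(
        site_id=site.site_id, separation=sep, density_points=pts,
        density_compartments=comps, contact_diameter=contact,
        protrusion_flag=flag, protrusion_height=height,
        guv_outer_z=mg + t / 2, suv_outer_z=ms - t / 2,
        extras={"suv_radius_nm": site.suv_radius,
                "sphere_fit": sphere})
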