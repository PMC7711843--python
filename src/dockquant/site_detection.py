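"""Detection of SUV-GUV docking sites and oriented subtomogram extraction.

The detector follows the field's operational definition of a docking site:
an SUV whose outer leaflet lies within ``docking_distance_cutoff`` (default
50 nm) of the GUV membrane, with visible protein density between the two
membranes.  SUVs are found by a spherical-shell matched filter over a
radius grid applied to the thresholded, smoothed volume; the GUV surface is
tracked as a heightfield by matching a bilayer profile along the beam-normal
axis.  Each accepted site is cut out as a ``box_size`` (default 150 nm) box
centred on the inter-membrane midpoint and rotated so the docking axis (GUV
surface towards SUV centre) lies on +z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
from pydantic import BaseModel, Field
from scipy import ndimage
from skimage.feature import peak_local_max

from .tomo_io import Volume

__all__ = [
    "DetectionParams",
    "SuvDetection",
    "DockingSite",
    "GuvSurface",
    "detect_suvs",
    "estimate_guv_surface",
    "find_docking_sites",
    "extract_oriented_subtomogram",
    "rotation_to_z",
    "bilayer_template",
]


class DetectionParams(BaseModel):
    """Tunables of the docking-site detector (lengths in nm)."""

    docking_distance_cutoff: float = Field(default=50.0, gt=0)
    box_size: float = Field(default=150.0, gt=0)
    suv_radius_range: tuple[float, float] = (10.0, 75.0)
    radius_step: float = 5.0
    #: absolute density threshold for membrane binarisation; None = automatic
    #: (half the ``membrane_quantile`` percentile of the smoothed map — a
    #: quantile matched to the typical membrane volume fraction, so bright
    #: compact protein densities cannot drag the threshold above the
    #: membrane intensity)
    membrane_threshold: float | None = None
    membrane_quantile: float = 98.0
    smooth_sigma: float = 2.0  # nm, pre-detection smoothing
    shell_score_threshold: float = 0.5  # min fraction of shell occupied
    interior_occupancy_max: float = 0.3  # solid interiors are not vesicles
    #: vesicle pairs with radii within this relative difference are treated
    #: as "no obvious size difference" and excluded from SUV-GUV pairing
    similar_size_fraction: float = 0.2
    bilayer_thickness: float = 4.0
    leaflet_sigma: float = 1.8  # nm, effective leaflet width incl. blur


@dataclass
class SuvDetection:
    center: np.ndarray  # (x, y, z) nm
    radius: float  # nm, outer-leaflet radius
    score: float


@dataclass
class DockingSite:
    """One oriented SUV-GUV junction."""

    site_id: str
    suv_center: np.ndarray
    suv_radius: float
    closest_approach_point_suv: np.ndarray
    closest_approach_point_guv: np.ndarray
    midpoint: np.ndarray
    docking_axis: np.ndarray  # unit vector, midpoint -> suv_center
    gap: float  # nm, initial outer-leaflet gap estimate
    has_intermembrane_density: bool = False
    subtomogram: Volume | None = None
    rotation: np.ndarray | None = None  # box -> lab rotation (columns = box axes)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ax = np.asarray(self.docking_axis, float)
        n = np.linalg.norm(ax)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("docking_axis must be a unit vector")
        self.docking_axis = ax


# ----------------------------------------------------------------------------
# SUV detection
# ----------------------------------------------------------------------------

_KERNEL_CACHE: dict[tuple, np.ndarray] = {}


def _shell_kernel_fft(shape: tuple[int, int, int], voxel: float, radius: float,
                      sigma: float) -> np.ndarray:
    """rfftn of a normalised Gaussian spherical shell, centred for circular
    convolution; cached per (shape, voxel, radius)."""
    key = (shape, round(voxel, 6), round(radius, 3), round(sigma, 3))
    if key in _KERNEL_CACHE:
        return _KERNEL_CACHE[key]
    nz, ny, nx = shape
    zs = np.fft.fftfreq(nz) * nz * voxel
    ys = np.fft.fftfreq(ny) * ny * voxel
    xs = np.fft.fftfreq(nx) * nx * voxel
    d = np.sqrt(zs[:, None, None] ** 2 + ys[None, :, None] ** 2
                + xs[None, None, :] ** 2)
    k = np.exp(-((d - radius) ** 2) / (2 * sigma**2)).astype(np.float32)
    k /= k.sum()
    out = scipy.fft.rfftn(k).astype(np.complex64)
    if len(_KERNEL_CACHE) > 64:
        _KERNEL_CACHE.clear()
    _KERNEL_CACHE[key] = out
    return out


def detect_suvs(volume: Volume, params: DetectionParams | None = None
                ) -> list[SuvDetection]:
    """Find spherical vesicles by a shell matched filter over a radius grid.

    The smoothed map is binarised at ``membrane_threshold`` and correlated
    with unit-mass spherical-shell kernels; the score at a voxel is the
    occupied fraction of the shell, so a complete vesicle of matching radius
    scores ~1 regardless of size.  Candidate peaks must exceed
    ``shell_score_threshold``, have a hollow interior (vesicle lumen), and
    survive non-maximum suppression across positions.  Detections are
    returned sorted by score; an empty list is a valid result.
    """
    params = params or DetectionParams()
    vx = volume.voxel_size
    grid = volume.grid.astype(np.float32)
    smoothed = ndimage.gaussian_filter(grid, sigma=params.smooth_sigma / vx)
    if params.membrane_threshold is not None:
        thr = params.membrane_threshold
    else:
        thr = 0.5 * np.percentile(smoothed, params.membrane_quantile)
    if thr <= 0:
        return []
    binary = (smoothed > thr).astype(np.float32)

    rmin, rmax = params.suv_radius_range
    radii = np.arange(rmin, rmax + 1e-9, params.radius_step)
    sigma_k = max(2.0, vx)
    spec = scipy.fft.rfftn(binary).astype(np.complex64)
    best = np.zeros_like(binary)
    best_r = np.zeros_like(binary)
    for r in radii:
        kf = _shell_kernel_fft(binary.shape, vx, float(r), sigma_k)
        score = scipy.fft.irfftn(spec * kf, s=binary.shape)
        upd = score > best
        best[upd] = score[upd]
        best_r[upd] = r

    min_dist = max(int(0.8 * rmin / vx), 1)
    peaks = peak_local_max(best, min_distance=min_dist,
                           threshold_abs=params.shell_score_threshold,
                           exclude_border=False)
    cand = sorted(
        ((best[tuple(p)], best_r[tuple(p)], p) for p in peaks),
        key=lambda t: -t[0])

    detections: list[SuvDetection] = []
    for score, r, pk in cand:
        center = volume.index_to_xyz(np.asarray(pk, float))[0]
        if any(np.linalg.norm(center - d.center) < 0.8 * max(r, d.radius)
               for d in detections):
            continue
        if _interior_occupancy(binary, pk, r, vx) > params.interior_occupancy_max:
            continue
        center = _refine_center(best, pk, volume)
        r = _refine_radius(smoothed, center, r, volume, params)
        if rmin - 1e-9 <= r <= rmax + 1e-9:
            detections.append(SuvDetection(center, float(r), float(score)))
    return detections


def _interior_occupancy(binary: np.ndarray, peak_zyx: np.ndarray, radius: float,
                        vx: float) -> float:
    """Occupied fraction of a ball well inside the candidate shell."""
    r_in = max(radius - 8.0, 0.4 * radius) / vx
    k, j, i = (int(v) for v in peak_zyx)
    n = int(np.ceil(r_in))
    sl = tuple(slice(max(c - n, 0), min(c + n + 1, s))
               for c, s in zip((k, j, i), binary.shape))
    sub = binary[sl]
    zz, yy, xx = np.ogrid[sl[0], sl[1], sl[2]]
    mask = (zz - k) ** 2 + (yy - j) ** 2 + (xx - i) ** 2 <= r_in**2
    if not mask.any():
        return 0.0
    return float(sub[mask].mean())


def _refine_center(score: np.ndarray, peak_zyx: np.ndarray, volume: Volume
                   ) -> np.ndarray:
    """Sub-voxel centre by centre of mass of the score in a 3^3 patch."""
    idx = np.asarray(peak_zyx, float)
    for ax in range(3):
        c = int(peak_zyx[ax])
        if 0 < c < score.shape[ax] - 1:
            sel: list = [int(v) for v in peak_zyx]
            sel[ax] = slice(c - 1, c + 2)
            y = score[tuple(sel)]
            denom = y[0] - 2 * y[1] + y[2]
            if denom < 0:
                idx[ax] = c + 0.5 * (y[0] - y[2]) / denom
    return volume.index_to_xyz(idx)[0]


def _refine_radius(smoothed: np.ndarray, center: np.ndarray, r_coarse: float,
                   volume: Volume, params: DetectionParams) -> float:
    """Outer-leaflet radius from the radial density centroid of the shell.

    Only the hemisphere away from the docking side (+z in the lab frame) is
    used, so the partner membrane and junction densities cannot skew the
    profile.  The density-weighted mean radius over ``r_coarse +/- 6`` nm
    locates the bilayer mid-line; half the bilayer thickness is added to
    report the outer-leaflet radius the separation measurement refers to.
    """
    vx = volume.voxel_size
    reach = r_coarse + 8.0
    i0 = np.maximum(((center - reach - volume.origin) / vx).astype(int), 0)
    i1 = np.minimum(np.ceil((center + reach - volume.origin) / vx).astype(int) + 1,
                    np.array(volume.grid.shape)[::-1])
    if np.any(i0 >= i1):
        return float(r_coarse)
    sl = (slice(i0[2], i1[2]), slice(i0[1], i1[1]), slice(i0[0], i1[0]))
    xs, ys, zs = volume.axes_nm()
    dx = xs[sl[2]][None, None, :] - center[0]
    dy = ys[sl[1]][None, :, None] - center[1]
    dz = zs[sl[0]][:, None, None] - center[2]
    upper = dz > 0.25 * r_coarse
    d = np.sqrt(dx**2 + dy**2 + dz**2)
    band = upper & (np.abs(d - (r_coarse - 2.0)) <= 6.0)
    if band.sum() < 16:
        return float(r_coarse)
    w = smoothed[sl][band]
    w = np.clip(w - 0.3 * w.max(), 0, None)  # suppress the noise floor
    if w.sum() <= 0:
        return float(r_coarse)
    mid = float((d[band] * w).sum() / w.sum())
    return mid + params.bilayer_thickness / 2


# ----------------------------------------------------------------------------
# GUV surface
# ----------------------------------------------------------------------------

def bilayer_template(voxel: float, thickness: float = 4.0, sigma: float = 1.8,
                     ) -> tuple[np.ndarray, int]:
    """Zero-mean 1D bilayer profile (two Gaussian leaflets ``thickness``
    apart) sampled at ``voxel`` nm; returns (kernel, centre index at the
    bilayer midpoint)."""
    half = thickness / 2 + 4 * sigma
    n = int(np.ceil(half / voxel))
    z = np.arange(-n, n + 1) * voxel
    k = (np.exp(-((z - thickness / 2) ** 2) / (2 * sigma**2))
         + np.exp(-((z + thickness / 2) ** 2) / (2 * sigma**2)))
    k -= k.mean()
    k /= np.linalg.norm(k)
    return k.astype(np.float32), n


@dataclass
class GuvSurface:
    """GUV outer-leaflet heightfield z = H(x, y) over the patch (nm)."""

    xs: np.ndarray
    ys: np.ndarray
    height_nm: np.ndarray  # (ny, nx)
    plane_z: float  # global outer-leaflet plane estimate

    def height(self, x, y) -> np.ndarray:
        scalar = np.isscalar(x) or np.ndim(x) == 0
        xi = np.interp(np.asarray(x, float), self.xs,
                       np.arange(len(self.xs)))
        yi = np.interp(np.asarray(y, float), self.ys,
                       np.arange(len(self.ys)))
        out = ndimage.map_coordinates(self.height_nm,
                                      np.vstack([np.atleast_1d(yi),
                                                 np.atleast_1d(xi)]),
                                      order=1, mode="nearest")
        return float(out[0]) if scalar else out

    def normal(self, x, y) -> np.ndarray:
        """Unit surface normal; the patch is treated as near-flat, so small
        local slopes are kept but the normal always points to +z."""
        eps = float(self.xs[1] - self.xs[0])
        dx = (self.height(x + eps, y) - self.height(x - eps, y)) / (2 * eps)
        dy = (self.height(x, y + eps) - self.height(x, y - eps)) / (2 * eps)
        n = np.stack([-dx, -dy, np.ones_like(dx)], axis=-1)
        return (n / np.linalg.norm(n, axis=-1, keepdims=True))[0]


def estimate_guv_surface(volume: Volume, params: DetectionParams | None = None
                         ) -> GuvSurface:
    """Track the GUV outer leaflet as a heightfield.

    The mean z-profile of the map locates the dominant bilayer plane; each
    (x, y) column is then correlated with the bilayer template and the match
    nearest the plane (within +/-10 nm) gives the local mid-bilayer height,
    median-filtered 3x3 to reject columns hijacked by protein blobs.
    """
    params = params or DetectionParams()
    vx = volume.voxel_size
    tmpl, _ = bilayer_template(vx, params.bilayer_thickness, params.leaflet_sigma)
    prof = volume.grid.mean(axis=(1, 2))
    corr0 = np.correlate(prof, tmpl, mode="same")
    z0_idx = int(np.argmax(corr0))

    corr = ndimage.correlate1d(volume.grid.astype(np.float32), tmpl, axis=0,
                               mode="nearest")
    w = max(int(round(10.0 / vx)), 2)
    lo = max(z0_idx - w, 0)
    hi = min(z0_idx + w + 1, corr.shape[0])
    win = corr[lo:hi]
    arg = np.argmax(win, axis=0)
    # parabolic sub-voxel refinement per column
    a0 = np.clip(arg, 1, win.shape[0] - 2)
    jj, ii = np.ogrid[:win.shape[1], :win.shape[2]]
    ym, y0, yp = win[a0 - 1, jj, ii], win[a0, jj, ii], win[a0 + 1, jj, ii]
    denom = ym - 2 * y0 + yp
    frac = np.where(denom < 0, 0.5 * (ym - yp) / np.where(denom == 0, 1, denom), 0.0)
    mid_idx = lo + a0 + np.clip(frac, -0.5, 0.5)
    mid_nm = volume.origin[2] + mid_idx * vx
    mid_nm = ndimage.median_filter(mid_nm, size=3)
    outer = mid_nm + params.bilayer_thickness / 2
    xs, ys, _ = volume.axes_nm()
    plane = float(volume.origin[2] + (lo + np.median(a0)) * vx
                  + params.bilayer_thickness / 2)
    return GuvSurface(xs, ys, outer, plane)


# ----------------------------------------------------------------------------
# docking sites
# ----------------------------------------------------------------------------

def find_docking_sites(volume: Volume, suvs: list[SuvDetection],
                       guv_surface: GuvSurface,
                       params: DetectionParams | None = None,
                       require_density: bool = True) -> list[DockingSite]:
    """Apply the docking-site rule to detected SUVs.

    A site is emitted iff the SUV outer leaflet lies within
    ``docking_distance_cutoff`` of the GUV outer leaflet *and* (when
    ``require_density``) protein density is detected between the membranes
    by the junction-measurement density detector.  SUV pairs with no obvious
    size difference (radii within ``similar_size_fraction`` of each other
    and mutually closer than their radius sum + cutoff) are excluded, as
    such contacts cannot be assigned an SUV-GUV polarity.
    """
    params = params or DetectionParams()
    sites: list[DockingSite] = []
    excluded = _similar_size_pairs(suvs, params)
    for i, suv in enumerate(suvs):
        if i in excluded:
            continue
        c = np.asarray(suv.center, float)
        hz = float(guv_surface.height(c[0], c[1]))
        normal = guv_surface.normal(c[0], c[1])
        guv_point = np.array([c[0], c[1], hz])
        axis = c - guv_point
        nrm = np.linalg.norm(axis)
        axis = axis / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
        if axis[2] < 0:
            axis = -axis
        gap = float(nrm - suv.radius)
        if gap > params.docking_distance_cutoff:
            continue
        suv_point = c - axis * suv.radius
        midpoint = 0.5 * (suv_point + guv_point)
        site = DockingSite(
            site_id=f"site{len(sites):04d}", suv_center=c, suv_radius=suv.radius,
            closest_approach_point_suv=suv_point,
            closest_approach_point_guv=guv_point, midpoint=midpoint,
            docking_axis=axis, gap=max(gap, 0.0),
            metadata={"surface_normal": normal, "score": suv.score})
        site.subtomogram = extract_oriented_subtomogram(volume, site, params)
        site.rotation = site.subtomogram.metadata["rotation_box_to_lab"]
        if require_density:
            from .junction_metrics import has_intermembrane_density
            site.has_intermembrane_density = has_intermembrane_density(site)
            if not site.has_intermembrane_density:
                continue
        sites.append(site)
    return sites


def _similar_size_pairs(suvs: list[SuvDetection], params: DetectionParams
                        ) -> set[int]:
    out: set[int] = set()
    for i in range(len(suvs)):
        for j in range(i + 1, len(suvs)):
            ri, rj = suvs[i].radius, suvs[j].radius
            close = (np.linalg.norm(np.asarray(suvs[i].center)
                                    - np.asarray(suvs[j].center))
                     < ri + rj + params.docking_distance_cutoff)
            similar = abs(ri - rj) <= params.similar_size_fraction * max(ri, rj)
            if close and similar:
                out.update((i, j))
    return out


# ----------------------------------------------------------------------------
# oriented extraction
# ----------------------------------------------------------------------------

def rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Minimal rotation R with R @ axis = +z (Rodrigues formula)."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, z)
    c = float(a @ z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        return np.diag([1.0, -1.0, -1.0])  # pi about x
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


_J = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])


def extract_oriented_subtomogram(volume: Volume, site: DockingSite,
                                 params: DetectionParams | None = None
                                 ) -> Volume:
    """Cut a ``box_size`` cube centred on the site midpoint, rotated so the
    docking axis lies on +z.

    The output volume's coordinates are physical nm in the *box frame*
    (origin at the midpoint landmark, axis = +z); the box->lab rotation
    (columns = box axes expressed in lab coordinates), the midpoint and the
    trilinear-interpolation note are recorded in metadata.  Regions sampled
    outside the source volume are zero-filled and an ``inside_fraction`` is
    recorded.
    """
    params = params or DetectionParams()
    vx = volume.voxel_size
    mid = np.asarray(site.midpoint, float)
    idx = (mid - volume.origin) / vx
    if np.any(idx < 0) or np.any(idx > np.array(volume.grid.shape)[::-1] - 1):
        raise ValueError(f"site midpoint {mid} lies outside the volume")
    n = int(round(params.box_size / vx))
    if n % 2 == 0:
        n += 1
    c = (n - 1) / 2.0
    R = rotation_to_z(site.docking_axis)
    M = R.T  # box -> lab
    A = _J @ M @ _J
    b = _J @ (mid - volume.origin) / vx - A @ np.full(3, c)
    out = ndimage.affine_transform(volume.grid.astype(np.float32), A, offset=b,
                                   output_shape=(n, n, n), order=1, cval=0.0)
    ones = ndimage.affine_transform(np.ones(volume.grid.shape, np.float32), A,
                                    offset=b, output_shape=(n, n, n), order=0,
                                    cval=0.0)
    meta = {
        "rotation_box_to_lab": M,
        "midpoint_lab": mid,
        "source_origin_nm": volume.origin.copy(),
        "source_extent_nm": (np.array(volume.grid.shape)[::-1] - 1) * vx,
        "box_size_nm": params.box_size,
        "interpolation": "trilinear",
        "inside_fraction": float(ones.mean()),
        "suv_radius_nm": site.suv_radius,
        "gap_estimate_nm": site.gap,
    }
    origin_box = -c * vx * np.ones(3)
    return Volume(out, vx, origin_box, meta)


def lab_to_box(site: DockingSite, points: np.ndarray) -> np.ndarray:
    """Map lab-frame points (nm) into a site's oriented box frame."""
    M = site.rotation
    if M is None:
        raise ValueError("site has no recorded orientation")
    p = np.atleast_2d(points) - site.midpoint
    return p @ M  # (M^T p^T)^T
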