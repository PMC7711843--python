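"""Synthetic SUV-GUV docking scenes and tomographic rendering.

The generator emulates the geometry the docking-site analysis assumes: a
large, nearly flat GUV membrane patch (plasma-membrane mimic), small
unilamellar vesicles (SUVs) docked to it at class-dependent membrane
separations, protein densities arranged per morphology class, optional GUV
protrusions under the docked vesicle, and rendering into a 3D density map
with bilayer leaflet shells, Gaussian protein blobs, a +/-60 degree missing
wedge and additive Gaussian noise.

Morphology classes follow the field's three-way scheme, coded
``0`` (clustered: densities inside the exclusion cylinder at the point of
closest approach), ``0.5`` (intermediate: some inside, some outside) and
``1`` (ring-like: all densities displaced radially outside the cylinder).
Class-conditional membrane separations default to the observed ranges:
clustered 5-26 nm, intermediate 3-8 nm, ring-like 0-7 nm.

Coordinate conventions: scenes are built in a canonical frame where the GUV
outer leaflet lies near the plane z = ``guv_plane_z`` and every docking axis
is +z; an optional rigid rotation maps the canonical frame to the lab frame
of the rendered volume.  The renderer's missing wedge uses tilt axis y and
beam axis x, so the default flat patch (normal z) stays outside the wedge,
as a membrane imaged edge-on does in a real tomogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import scipy.fft
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage

from .tomo_io import Volume

__all__ = [
    "SceneParams",
    "OpticsParams",
    "Junction",
    "Scene",
    "GroundTruth",
    "InfeasibleGeometryError",
    "generate_scene",
    "render_volume",
    "missing_wedge_mask",
]

CLASS_NAMES = ("clustered", "intermediate", "ring_like")
CLASS_CODES = {"clustered": 0.0, "intermediate": 0.5, "ring_like": 1.0}


class InfeasibleGeometryError(ValueError):
    """Requested junctions cannot be placed without overlap on the patch."""


class SceneParams(BaseModel):
    """Ground-truth population parameters for a docking scene."""

    n_junctions: int = Field(default=12, ge=0)
    class_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    #: per-class (min, max) membrane separation in nm
    separation_ranges: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "clustered": (5.0, 26.0),
            "intermediate": (3.0, 8.0),
            "ring_like": (0.0, 7.0),
        }
    )
    suv_diameter_mean: float = 80.0
    suv_diameter_sd: float = 25.0
    suv_diameter_range: tuple[float, float] = (20.0, 150.0)
    density_count_range: tuple[int, int] = (2, 34)
    protrusion_prob_given_class: tuple[float, float, float] = (0.8, 0.3, 0.0)
    protrusion_height: float = 5.0  # nm, mean bump height
    protrusion_height_sd: float = 1.0
    protrusion_fwhm: float = 20.0  # nm, lateral bump width
    ring_radius_mean: float = 15.0  # nm
    ring_radius_sd: float = 2.0
    #: radius of the exclusion cylinder used to arrange points (nm)
    exclusion_radius: float = 10.0
    #: hard-core repulsion between density points (proteins are solid), nm
    density_min_spacing: float = 3.5
    #: fraction of ring-like junctions in direct membrane contact
    contact_prob: float = 0.4
    contact_diameter_mean: float = 16.0  # nm, flattened facet diameter
    contact_diameter_sd: float = 8.0
    contact_diameter_range: tuple[float, float] = (4.0, 30.0)
    guv_shape: Literal["flat_patch", "sphere", "tubulated"] = "flat_patch"
    #: in-plane patch edge length (nm); None = auto-size to fit the junctions
    patch_size: float | None = None
    guv_plane_z: float = 24.0  # nm, canonical height of the GUV outer leaflet
    min_junction_margin: float = 12.0  # nm clearance between neighbouring SUVs
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SceneParams":
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1 within 1e-9")
        if any(p < 0 for p in self.class_probs):
            raise ValueError("class_probs must be non-negative")
        for name in CLASS_NAMES:
            lo, hi = self.separation_ranges[name]
            if lo < 0 or hi < lo:
                raise ValueError(f"separation range for {name} must satisfy 0 <= min <= max")
        lo, hi = self.density_count_range
        if lo < 1 or hi < lo:
            raise ValueError("density_count_range must satisfy 1 <= min <= max")
        if self.exclusion_radius <= 0:
            raise ValueError("exclusion_radius must be > 0")
        if not all(0 <= p <= 1 for p in self.protrusion_prob_given_class):
            raise ValueError("protrusion probabilities must be in [0, 1]")
        if self.guv_shape != "flat_patch":
            raise NotImplementedError(
                "only the flat_patch GUV shape is generated; spherical/tubulated "
                "surfaces are supported downstream via user-supplied surfaces"
            )
        return self


class OpticsParams(BaseModel):
    """Rendering parameters of the simulated tomogram."""

    voxel_size: float = Field(default=2.0, gt=0)  # nm
    bilayer_thickness: float = 4.0  # nm, leaflet-peak separation
    leaflet_sigma: float = 1.5  # nm, Gaussian width of one leaflet shell
    blur_sigma: float = 1.0  # nm, post-render low-pass (reconstruction PSF)
    density_blob_sigma: float = 2.0  # nm, protein density blob width
    wedge_half_angle: float = Field(default=60.0, gt=0, le=90)  # degrees
    noise_sigma: float = 0.2  # density units (membrane amplitude = 1)
    membrane_amplitude: float = 1.0
    blob_amplitude: float = 1.0
    apply_wedge: bool = True
    noise_seed: int = 0


@dataclass
class Junction:
    """Ground truth for one docking site, in the canonical scene frame."""

    class_name: str
    separation: float  # nm, outer leaflet to outer leaflet
    center_xy: np.ndarray  # (2,) axis position in the patch plane
    suv_outer_radius: float  # nm
    protrusion_flag: int
    protrusion_height: float  # nm (0 when flag == 0)
    density_points: np.ndarray  # (n, 3) canonical xyz nm
    density_compartments: list[str]
    contact_diameter: float = 0.0  # nm, flattened facet; 0 unless separation == 0
    ring_radius: float = float("nan")

    @property
    def class_code(self) -> float:
        return CLASS_CODES[self.class_name]

    @property
    def n_densities(self) -> int:
        return len(self.density_points)


@dataclass
class Scene:
    """Geometric description of a GUV patch with docked SUVs.

    ``guv_plane_z`` is the canonical height of the GUV *outer* leaflet
    (the leaflet facing the SUVs); protrusion bumps are added to it.
    ``rotation``/``offset`` map canonical to lab coordinates:
    ``p_lab = rotation @ p_canonical + offset``.
    """

    params: SceneParams
    junctions: list[Junction]
    guv_plane_z: float
    patch_half: float  # nm, half edge of the square patch
    protrusion_sigma: float  # nm, lateral sigma of protrusion bumps
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    # -- canonical-frame geometry -------------------------------------------------
    def guv_height(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Canonical z of the GUV outer leaflet at in-plane (x, y)."""
        h = np.full(np.broadcast(x, y).shape, self.guv_plane_z, dtype=float)
        for j in self.junctions:
            if j.protrusion_flag:
                r2 = (x - j.center_xy[0]) ** 2 + (y - j.center_xy[1]) ** 2
                h = h + j.protrusion_height * np.exp(-r2 / (2 * self.protrusion_sigma**2))
        return h

    def suv_center(self, j: Junction) -> np.ndarray:
        """Canonical xyz of an SUV centre (outer-leaflet sphere centre)."""
        z0 = self.guv_height(np.array(j.center_xy[0]), np.array(j.center_xy[1]))
        return np.array([j.center_xy[0], j.center_xy[1],
                         float(z0) + j.separation + j.suv_outer_radius])

    def docking_axis(self, j: Junction) -> np.ndarray:
        return self.rotation @ np.array([0.0, 0.0, 1.0])

    def to_lab(self, p: np.ndarray) -> np.ndarray:
        return (np.asarray(p, float) @ self.rotation.T) + self.offset

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Canonical axis-aligned bounds (lo, hi) with rendering margin."""
        hi_z = self.guv_plane_z + 10.0
        for j in self.junctions:
            c = self.suv_center(j)
            hi_z = max(hi_z, c[2] + j.suv_outer_radius + 12.0)
        half = self.patch_half
        return (np.array([-half, -half, 0.0]),
                np.array([half, half, hi_z]))

    def rotated(self, rotation: np.ndarray, offset: np.ndarray | None = None) -> "Scene":
        """Scene with an extra lab-frame rotation applied (for oblique axes)."""
        rot = np.asarray(rotation, float) @ self.rotation
        off = self.offset if offset is None else np.asarray(offset, float)
        return Scene(self.params, self.junctions, self.guv_plane_z,
                     self.patch_half, self.protrusion_sigma, rot, off)


@dataclass
class GroundTruth:
    """Per-junction ground truth in lab coordinates."""

    scene: Scene

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, j in enumerate(self.scene.junctions):
            c = self.scene.to_lab(self.scene.suv_center(j))
            ax = self.scene.docking_axis(j)
            rows.append(
                dict(
                    site_id=f"gt{i:04d}",
                    class_name=j.class_name,
                    class_code=j.class_code,
                    separation_nm=j.separation,
                    suv_center_x=c[0], suv_center_y=c[1], suv_center_z=c[2],
                    axis_x=ax[0], axis_y=ax[1], axis_z=ax[2],
                    suv_diameter_nm=2 * j.suv_outer_radius,
                    n_densities=j.n_densities,
                    protrusion_flag=j.protrusion_flag,
                    protrusion_height_nm=j.protrusion_height,
                    contact_diameter_nm=j.contact_diameter,
                    ring_radius_nm=j.ring_radius,
                )
            )
        cols = ["site_id", "class_name", "class_code", "separation_nm",
                "suv_center_x", "suv_center_y", "suv_center_z",
                "axis_x", "axis_y", "axis_z", "suv_diameter_nm", "n_densities",
                "protrusion_flag", "protrusion_height_nm", "contact_diameter_nm",
                "ring_radius_nm"]
        return pd.DataFrame(rows, columns=cols)

    def density_points_lab(self, i: int) -> np.ndarray:
        return self.scene.to_lab(self.scene.junctions[i].density_points)


# ----------------------------------------------------------------------------
# generation
# ----------------------------------------------------------------------------

def generate_scene(params: SceneParams) -> tuple[Scene, GroundTruth]:
    """Draw a ground-truth docking scene from ``params``.

    Deterministic given ``params.seed``.  Junction axis positions are laid
    out on a jittered grid so SUVs cannot interpenetrate; if an explicit
    ``patch_size`` cannot accommodate ``n_junctions`` an
    :class:`InfeasibleGeometryError` is raised rather than silently
    truncating the population.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_junctions
    sigma_bump = params.protrusion_fwhm / (2 * np.sqrt(2 * np.log(2)))

    radii = _clipped_normal(rng, params.suv_diameter_mean, params.suv_diameter_sd,
                            params.suv_diameter_range, n) / 2.0
    cell = (2 * radii.max() + params.min_junction_margin) if n else 60.0
    ncell = int(np.ceil(np.sqrt(n))) if n else 1
    if params.patch_size is not None:
        half = params.patch_size / 2.0
        ncell_fit = int(params.patch_size // cell)
        if ncell_fit * ncell_fit < n:
            raise InfeasibleGeometryError(
                f"patch of {params.patch_size:.0f} nm fits at most "
                f"{ncell_fit * ncell_fit} junctions of this SUV size, "
                f"{n} requested"
            )
        ncell = max(ncell, ncell_fit) if n else 1
    else:
        half = ncell * cell / 2.0 + 10.0

    # jittered grid of axis positions
    order = rng.permutation(ncell * ncell)[:n]
    centers = []
    for k, cell_idx in enumerate(order):
        gx, gy = divmod(int(cell_idx), ncell)
        base = (np.array([gx, gy]) + 0.5) * cell - ncell * cell / 2.0
        slack = max(cell / 2.0 - radii[k] - params.min_junction_margin / 2.0, 0.0)
        centers.append(base + rng.uniform(-slack, slack, size=2))

    class_idx = rng.choice(3, size=n, p=params.class_probs)
    junctions: list[Junction] = []
    for k in range(n):
        cname = CLASS_NAMES[class_idx[k]]
        lo, hi = params.separation_ranges[cname]
        sep = float(rng.uniform(lo, hi))
        contact_d = 0.0
        if cname == "ring_like" and rng.uniform() < params.contact_prob:
            sep = 0.0
            contact_d = float(_clipped_normal(
                rng, params.contact_diameter_mean, params.contact_diameter_sd,
                params.contact_diameter_range, 1)[0])
            contact_d = min(contact_d, 1.6 * radii[k])
        prot = int(rng.uniform() < params.protrusion_prob_given_class[class_idx[k]])
        height = 0.0
        if prot:
            height = float(_clipped_normal(rng, params.protrusion_height,
                                           params.protrusion_height_sd,
                                           (3.5, 2 * params.protrusion_height), 1)[0])
        count = int(rng.integers(params.density_count_range[0],
                                 params.density_count_range[1] + 1))
        ring_r = float("nan")
        if cname != "clustered":
            ring_r = float(_clipped_normal(
                rng, params.ring_radius_mean, params.ring_radius_sd,
                (params.exclusion_radius + 2.5, 25.0), 1)[0])
        pts, comps = _place_densities(
            rng, cname, count, sep, radii[k], height, sigma_bump,
            params.exclusion_radius, ring_r, contact_d / 2.0,
            params.density_min_spacing)
        pts = pts + np.array([centers[k][0], centers[k][1], params.guv_plane_z])
        junctions.append(Junction(
            class_name=cname, separation=sep, center_xy=np.asarray(centers[k]),
            suv_outer_radius=float(radii[k]), protrusion_flag=prot,
            protrusion_height=height, density_points=pts,
            density_compartments=comps, contact_diameter=contact_d,
            ring_radius=ring_r))

    scene = Scene(params=params, junctions=junctions,
                  guv_plane_z=params.guv_plane_z, patch_half=half,
                  protrusion_sigma=sigma_bump)
    return scene, GroundTruth(scene)


def _clipped_normal(rng, mean, sd, bounds, size):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, bounds[0], bounds[1])


def _place_densities(rng, cname, count, sep, radius, bump_h, bump_sigma,
                     r_ex, ring_r, facet_radius, min_spacing):
    """Density points in junction-local coordinates.

    Local origin: docking axis at (0, 0), z = 0 on the *nominal* GUV outer
    leaflet (the protrusion bump raises the actual surface).  Points inside
    the exclusion cylinder keep a ~30% radial margin and outside points a
    ~15% margin, so measurement jitter of ~1 voxel does not flip the in/out
    assignment the class labels are defined by.  Points repel each other at
    ``min_spacing`` (dart throwing): protein complexes are solid bodies, so
    densities pile up side by side rather than coinciding.
    """
    if cname == "clustered":
        n_in, n_out = count, 0
    elif cname == "ring_like":
        n_in, n_out = 0, count
    else:
        n_in = int(rng.integers(1, count))
        n_out = count - n_in

    cz = bump_h + sep + radius  # SUV centre height

    def surfaces(rho):
        guv_z = bump_h * np.exp(-(rho**2) / (2 * bump_sigma**2))
        with np.errstate(invalid="ignore"):
            sphere = cz - np.sqrt(max(radius**2 - rho**2, 0.0))
        suv_z = sphere if rho < radius else np.inf
        if facet_radius > 0 and rho <= facet_radius:
            depth = radius - np.sqrt(max(radius**2 - facet_radius**2, 0.0))
            suv_z = cz - (radius - depth)
        return guv_z, suv_z

    # radial reach at which the leaflet gap fits a protein-sized density:
    # a ~5 nm complex is sterically excluded from narrower gaps and must sit
    # further out on the vesicle shoulder (facet geometry included)
    clearance = max(0.0, 7.0 - sep)
    s0 = np.sqrt(max(radius**2 - facet_radius**2, 0.0))
    rho_fit = np.sqrt(max(radius**2 - max(s0 - clearance, 0.0) ** 2, 0.0))

    def suv_clear_z(rho):
        # highest z keeping >= 3.5 nm radial clearance from the SUV surface
        if facet_radius > 0 and rho <= facet_radius:
            depth = radius - np.sqrt(max(radius**2 - facet_radius**2, 0.0))
            return cz - (radius - depth) - 3.5
        rr = (radius + 3.5) ** 2 - rho**2
        return cz - np.sqrt(rr) if rr > 0 else np.inf

    def draw_one(inside: bool):
        if inside:
            rho = np.sqrt(rng.uniform()) * (0.7 * r_ex)
        else:
            lo_rho = max(r_ex + 1.5, rho_fit)
            rho = float(np.clip(ring_r + rng.normal(0, 1.5), lo_rho, None))
        phi = rng.uniform(0, 2 * np.pi)
        guv_z, suv_z = surfaces(rho)
        lo = guv_z + 2.8
        hi = min(suv_clear_z(rho),
                 guv_z + 6.0 if not np.isfinite(suv_z) else np.inf)
        # densities are membrane-anchored protein complexes: their centres
        # sit a protein radius off one of the leaflet surfaces
        if rng.uniform() < 0.5:
            z = guv_z + rng.uniform(2.8, 4.8)
        else:
            z = (suv_clear_z(rho) - rng.uniform(0.0, 2.0)
                 if np.isfinite(suv_z) else guv_z + rng.uniform(2.8, 4.8))
        z = min(max(z, lo), hi) if hi > lo else 0.5 * (lo + hi)
        z = max(z, guv_z + 2.5)
        return np.array([rho * np.cos(phi), rho * np.sin(phi), z]), guv_z, suv_z

    pts: list[np.ndarray] = []
    meta = []
    for k in range(count):
        inside = k < n_in
        best = None
        for _ in range(60):
            cand, guv_z, suv_z = draw_one(inside)
            if pts:
                dmin = min(float(np.linalg.norm(cand - q)) for q in pts)
            else:
                dmin = np.inf
            if best is None or dmin > best[1]:
                best = ((cand, guv_z, suv_z), dmin)
            if dmin >= min_spacing:
                break
        (cand, guv_z, suv_z), _ = best
        pts.append(cand)
        meta.append((guv_z, suv_z))

    comps = []
    for p, (gi, si) in zip(pts, meta):
        d_guv = p[2] - gi
        d_suv = (si - p[2]) if np.isfinite(si) else np.inf
        if d_guv <= 4.0 and d_guv <= d_suv:
            comps.append("guv_membrane")
        elif d_suv <= 4.0:
            comps.append("suv_membrane")
        else:
            comps.append("intermembrane")
    return np.array(pts).reshape(-1, 3), comps


# ----------------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------------

def missing_wedge_mask(shape: tuple[int, int, int], wedge_half_angle: float) -> np.ndarray:
    """Boolean keep-mask for the rfftn spectrum of a ``(z, y, x)`` grid.

    Tilt axis y, beam axis x: a spatial frequency is sampled iff the angle
    of its (kx, kz) component from the kz axis is within the tilt range,
    i.e. ``atan2(|kx|, |kz|) <= wedge_half_angle``.
    """
    nz, ny, nx = shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    kx = np.fft.rfftfreq(nx)[None, None, :]
    ang = np.degrees(np.arctan2(np.abs(kx), np.abs(kz)))
    return np.broadcast_to(ang <= wedge_half_angle + 1e-12, (nz, 1, nx // 2 + 1))


def render_volume(scene: Scene, optics: OpticsParams,
                  shape: tuple[int, int, int] | None = None,
                  origin: np.ndarray | None = None,
                  with_noise: bool = True) -> Volume:
    """Rasterise a scene into a noisy, wedge-filtered density map.

    Membranes are two Gaussian leaflet shells ``bilayer_thickness`` apart
    (peak positions: the scene's outer surface and one leaflet inward),
    protein densities are isotropic Gaussian blobs, the whole map is
    low-passed by ``blur_sigma``, the missing wedge is applied as a hard
    Fourier mask, and white Gaussian noise is added last.
    """
    vx = optics.voxel_size
    if vx > 2.0 * min(optics.leaflet_sigma, optics.density_blob_sigma):
        warnings.warn(
            f"voxel size {vx} nm exceeds 2x the leaflet/blob widths; "
            "membranes and densities will not be resolvable", stacklevel=2)
    lo, hi = scene.bounding_box()
    if origin is None:
        origin = lo.copy()
    origin = np.asarray(origin, float)
    if shape is None:
        nvox = np.ceil((hi - origin) / vx).astype(int) + 1
        shape = (int(nvox[2]), int(nvox[1]), int(nvox[0]))
    nz, ny, nx = shape

    identity = np.allclose(scene.rotation, np.eye(3)) and np.allclose(scene.offset, 0)
    xs = origin[0] + vx * np.arange(nx)
    ys = origin[1] + vx * np.arange(ny)
    zs = origin[2] + vx * np.arange(nz)
    if identity:
        X = xs[None, None, :]
        Y = ys[None, :, None]
        Z = zs[:, None, None]
    else:
        # canonical coords of every voxel: p_c = R^T (p_lab - offset)
        Zl, Yl, Xl = np.meshgrid(zs, ys, xs, indexing="ij")
        P = np.stack([Xl, Yl, Zl], axis=-1) - scene.offset
        Pc = P @ scene.rotation  # (R^T p)^T = p^T R
        X, Y, Z = Pc[..., 0], Pc[..., 1], Pc[..., 2]
        del Zl, Yl, Xl, P, Pc

    grid = np.zeros(shape, dtype=np.float32)
    t = optics.bilayer_thickness
    sl = optics.leaflet_sigma
    amp = optics.membrane_amplitude

    # GUV sheet (outer leaflet at the scene surface, inner one leaflet below)
    h = scene.guv_height(X, Y)
    sd = Z - h
    in_patch = (np.abs(X) <= scene.patch_half) & (np.abs(Y) <= scene.patch_half)
    band = np.abs(sd + t / 2) <= (t / 2 + 4 * sl)
    sheet = np.where(
        band & in_patch,
        np.exp(-sd**2 / (2 * sl**2)) + np.exp(-((sd + t) ** 2) / (2 * sl**2)),
        0.0,
    )
    grid += (amp * sheet).astype(np.float32)
    del sd, band, sheet, h

    # SUV shells, rendered in local crops
    for j in scene.junctions:
        c = scene.suv_center(j)
        _add_suv_shell(grid, scene, j, c, origin, vx, shape, t, sl, amp, identity,
                       xs, ys, zs)

    # protein blobs
    sb = optics.density_blob_sigma
    for j in scene.junctions:
        for p in j.density_points:
            _add_blob(grid, scene.to_lab(p) if not identity else p,
                      origin, vx, shape, sb, optics.blob_amplitude)

    if optics.blur_sigma > 0:
        ndimage.gaussian_filter(grid, sigma=optics.blur_sigma / vx, output=grid)

    if optics.apply_wedge:
        spec = scipy.fft.rfftn(grid)
        spec *= missing_wedge_mask(shape, optics.wedge_half_angle)
        grid = scipy.fft.irfftn(spec, s=shape).astype(np.float32)

    if with_noise and optics.noise_sigma > 0:
        rng = np.random.default_rng(optics.noise_seed)
        grid = grid + rng.normal(0.0, optics.noise_sigma, size=shape).astype(np.float32)

    meta = {
        "voxel_size_nm": vx,
        "optics": optics.model_dump(),
        "tilt_axis": "y",
        "beam_axis": "x",
        "frame_rotation": scene.rotation,
        "frame_offset": scene.offset,
    }
    return Volume(grid, vx, origin, meta)


def _add_suv_shell(grid, scene, j, c_canon, origin, vx, shape, t, sl, amp,
                   identity, xs, ys, zs):
    nz, ny, nx = shape
    c_lab = scene.to_lab(c_canon)
    r_out = j.suv_outer_radius
    reach = r_out + 4 * sl + 1
    i0 = np.maximum(((c_lab - reach - origin) / vx).astype(int), 0)
    i1 = np.minimum(np.ceil((c_lab + reach - origin) / vx).astype(int) + 1,
                    [nx, ny, nz])
    if np.any(i0 >= i1):
        return
    sx, sy, sz = (slice(i0[k], i1[k]) for k in range(3))
    Xc = xs[sx][None, None, :] - c_lab[0]
    Yc = ys[sy][None, :, None] - c_lab[1]
    Zc = zs[sz][:, None, None] - c_lab[2]
    if identity:
        lx, ly, lz = Xc, Yc, Zc
    else:
        # local = R^T (p - c_lab); broadcasting the three planes
        R = scene.rotation
        lx = Xc * R[0, 0] + Yc * R[1, 0] + Zc * R[2, 0]
        ly = Xc * R[0, 1] + Yc * R[1, 1] + Zc * R[2, 1]
        lz = Xc * R[0, 2] + Yc * R[1, 2] + Zc * R[2, 2]
    d = np.sqrt(lx**2 + ly**2 + lz**2)
    dist_out = np.abs(d - r_out)
    dist_in = np.abs(d - (r_out - t))
    if j.contact_diameter > 0:
        a = j.contact_diameter / 2.0
        rho2 = lx**2 + ly**2
        below = (lz < 0) & (rho2 <= a**2)
        depth_out = r_out - np.sqrt(max(r_out**2 - a**2, 0.0))
        r_in = r_out - t
        a_in = min(a, r_in * 0.99)
        depth_in = r_in - np.sqrt(max(r_in**2 - a_in**2, 0.0))
        dist_out = np.where(below, np.abs(lz + (r_out - depth_out)), dist_out)
        dist_in = np.where(below & (rho2 <= a_in**2),
                           np.abs(lz + (r_in - depth_in)), dist_in)
    shell = np.exp(-dist_out**2 / (2 * sl**2)) + np.exp(-dist_in**2 / (2 * sl**2))
    grid[sz, sy, sx] += (amp * shell).astype(np.float32)


def _add_blob(grid, p_lab, origin, vx, shape, sigma, amp):
    nz, ny, nx = shape
    reach = 4 * sigma
    i0 = np.maximum(((p_lab - reach - origin) / vx).astype(int), 0)
    i1 = np.minimum(np.ceil((p_lab + reach - origin) / vx).astype(int) + 1,
                    [nx, ny, nz])
    if np.any(i0 >= i1):
        return
    sx, sy, sz = (slice(i0[k], i1[k]) for k in range(3))
    gx = np.exp(-((origin[0] + vx * np.arange(i0[0], i1[0]) - p_lab[0]) ** 2)
                / (2 * sigma**2))
    gy = np.exp(-((origin[1] + vx * np.arange(i0[1], i1[1]) - p_lab[1]) ** 2)
                / (2 * sigma**2))
    gz = np.exp(-((origin[2] + vx * np.arange(i0[2], i1[2]) - p_lab[2]) ** 2)
                / (2 * sigma**2))
    grid[sz, sy, sx] += (amp * gz[:, None, None] * gy[None, :, None]
                         * gx[None, None, :]).astype(np.float32)
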