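"""Volume and landmark I/O.

On-disk formats
---------------
Volumes are stored as MRC/CCP4 maps (mode 2, float32) through :mod:`gemmi`.
The in-memory :class:`Volume` keeps the grid as a numpy array indexed
``[z, y, x]`` with physical coordinates in nm: the voxel at index
``(k, j, i)`` has centre ``origin + voxel_size * (i, j, k)`` (coordinates are
0-based, voxel centres at integer multiples of the voxel size).  The MRC
header stores the cell and origin in Angstrom, per EM convention.

Landmark tables are CSV files with the header
``site_id,kind,x_nm,y_nm,z_nm,compartment``; ``kind`` is one of
``suv_center``, ``midpoint``, ``suv_outer_leaflet`` or ``density`` and
``compartment`` tags density points as ``suv_membrane``, ``guv_membrane`` or
``intermembrane``.  A leading comment line ``# units: voxel; voxel_size_nm: V``
declares voxel-unit coordinates, which are converted to nm on read.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "LandmarkSet",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "COMPARTMENTS",
    "LANDMARK_KINDS",
]

COMPARTMENTS = ("suv_membrane", "guv_membrane", "intermembrane")
LANDMARK_KINDS = ("suv_center", "midpoint", "suv_outer_leaflet", "density")

_LANDMARK_COLUMNS = ["site_id", "kind", "x_nm", "y_nm", "z_nm", "compartment"]


@dataclass
class Volume:
    """A 3D density grid with physical metadata.

    Attributes
    ----------
    grid:
        float array indexed ``[z, y, x]``.
    voxel_size:
        isotropic voxel edge in nm.
    origin:
        physical position (x, y, z) in nm of voxel ``(0, 0, 0)``.
    metadata:
        free-form provenance (rendering parameters, transforms, ...).
    """

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError(
                f"grid must be 3D with all dimensions >= 1, got shape {self.grid.shape}"
            )
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        self.origin = np.asarray(self.origin, dtype=float)
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector (x, y, z) in nm")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def axes_nm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates (x, y, z) of voxel centres along each axis."""
        nz, ny, nx = self.grid.shape
        return (
            self.origin[0] + self.voxel_size * np.arange(nx),
            self.origin[1] + self.voxel_size * np.arange(ny),
            self.origin[2] + self.voxel_size * np.arange(nz),
        )

    def xyz_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map physical (x, y, z) nm points to fractional (z, y, x) indices."""
        p = (np.atleast_2d(points) - self.origin) / self.voxel_size
        return p[:, ::-1]

    def index_to_xyz(self, idx_zyx: np.ndarray) -> np.ndarray:
        """Map fractional (z, y, x) indices to physical (x, y, z) nm points."""
        idx = np.atleast_2d(idx_zyx).astype(float)
        return idx[:, ::-1] * self.voxel_size + self.origin

    def copy(self) -> "Volume":
        return Volume(self.grid.copy(), self.voxel_size, self.origin.copy(), dict(self.metadata))


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a :class:`Volume` as an MRC mode-2 map (header in Angstrom)."""
    path = Path(path)
    grid = np.ascontiguousarray(volume.grid.astype(np.float32).transpose(2, 1, 0))
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(grid)
    nz, ny, nx = volume.grid.shape
    ang = volume.voxel_size * 10.0
    m.grid.unit_cell = gemmi.UnitCell(nx * ang, ny * ang, nz * ang, 90.0, 90.0, 90.0)
    m.update_ccp4_header()
    ox, oy, oz = (volume.origin * 10.0).tolist()
    m.set_header_float(50, ox)  # ORIGIN record, Angstrom
    m.set_header_float(51, oy)
    m.set_header_float(52, oz)
    m.write_ccp4_map(str(path))
    meta_path = path.with_suffix(path.suffix + ".json")
    if volume.metadata:
        meta_path.write_text(json.dumps(_jsonable(volume.metadata), indent=1))


def read_volume(path: str | Path) -> Volume:
    """Read an MRC map written by :func:`write_volume` (or any mode 0/1/2 map)."""
    path = Path(path)
    m = gemmi.read_ccp4_map(str(path))
    mode = m.header_i32(4)
    if mode not in (0, 1, 2):
        raise ValueError(f"unsupported MRC mode field (word 4): {mode}")
    grid = np.array(m.grid, copy=True)  # (x, y, z) order
    nu = m.grid.nu
    if nu < 1:
        raise ValueError("invalid MRC header: NX (word 1) < 1")
    cell_a = m.grid.unit_cell.a
    if not cell_a > 0 or not math.isfinite(cell_a):
        raise ValueError("invalid MRC header: cell dimension a (word 11) must be > 0")
    voxel_nm = cell_a / nu / 10.0
    origin = np.array([m.header_float(i) for i in (50, 51, 52)]) / 10.0
    metadata: dict[str, Any] = {"source": str(path), "mrc_mode": mode}
    meta_path = path.with_suffix(path.suffix + ".json")
    if meta_path.exists():
        metadata.update(json.loads(meta_path.read_text()))
    return Volume(grid.transpose(2, 1, 0).astype(np.float32), voxel_nm, origin, metadata)


@dataclass
class LandmarkSet:
    """Landmarks annotating one docking site, all coordinates in nm.

    ``midpoint`` is the position midway between the SUV and GUV membranes at
    their point of closest approach — the centre used for subtomogram
    extraction.  ``density_points`` is an (n, 3) array with a parallel list
    of compartment tags.
    """

    site_id: str
    suv_center: np.ndarray | None = None
    midpoint: np.ndarray | None = None
    suv_outer_leaflet_point: np.ndarray | None = None
    density_points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    density_compartments: list[str] = field(default_factory=list)
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.density_points = np.asarray(self.density_points, dtype=float).reshape(-1, 3)
        for name in ("suv_center", "midpoint", "suv_outer_leaflet_point"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (3,) or not np.all(np.isfinite(v)):
                    raise ValueError(f"{name} must be a finite 3-vector")
                setattr(self, name, v)
        if not np.all(np.isfinite(self.density_points)):
            raise ValueError("density point coordinates must be finite")
        if len(self.density_compartments) != len(self.density_points):
            raise ValueError("one compartment tag per density point required")
        bad = set(self.density_compartments) - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartment tags: {sorted(bad)}")

    @property
    def n_densities(self) -> int:
        return len(self.density_points)


def write_landmarks(sets: Iterable[LandmarkSet], path: str | Path) -> None:
    rows = []
    for ls in sets:
        for kind in ("suv_center", "midpoint", "suv_outer_leaflet"):
            p = getattr(ls, kind if kind != "suv_outer_leaflet" else "suv_outer_leaflet_point")
            if p is not None:
                rows.append((ls.site_id, kind, p[0], p[1], p[2], ""))
        for p, comp in zip(ls.density_points, ls.density_compartments):
            rows.append((ls.site_id, "density", p[0], p[1], p[2], comp))
    df = pd.DataFrame(rows, columns=_LANDMARK_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_landmarks(path: str | Path, voxel_size: float | None = None) -> list[LandmarkSet]:
    """Read a landmark CSV into per-site :class:`LandmarkSet` objects.

    A leading ``# units: voxel; voxel_size_nm: V`` comment (or an explicit
    ``voxel_size`` argument) declares voxel-unit coordinates, converted to nm
    by multiplication.  Unknown columns are preserved per site in ``extra``.
    """
    path = Path(path)
    scale = 1.0
    header_meta = _parse_comment_header(path)
    if header_meta.get("units") == "voxel":
        vs = voxel_size if voxel_size is not None else header_meta.get("voxel_size_nm")
        if vs is None:
            raise ValueError("voxel-unit landmark file requires voxel_size_nm")
        scale = float(vs)
    elif voxel_size is not None:
        scale = float(voxel_size)

    df = pd.read_csv(path, comment="#", dtype={"site_id": str})
    if df.empty and df.columns.size == 0:
        return []
    missing = [c for c in _LANDMARK_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"landmark file missing mandatory columns: {missing}")
    extra_cols = [c for c in df.columns if c not in _LANDMARK_COLUMNS]

    out: list[LandmarkSet] = []
    for site_id, g in df.groupby("site_id", sort=False):
        kwargs: dict[str, Any] = {"site_id": str(site_id)}
        pts, comps = [], []
        for _, row in g.iterrows():
            p = np.array([row.x_nm, row.y_nm, row.z_nm], dtype=float) * scale
            kind = row.kind
            if kind == "suv_center":
                kwargs["suv_center"] = p
            elif kind == "midpoint":
                kwargs["midpoint"] = p
            elif kind == "suv_outer_leaflet":
                kwargs["suv_outer_leaflet_point"] = p
            elif kind == "density":
                pts.append(p)
                comps.append(row.get("compartment", "intermembrane"))
            else:
                raise ValueError(f"unknown landmark kind {kind!r} for site {site_id}")
        extra = {c: g[c].tolist() for c in extra_cols}
        out.append(
            LandmarkSet(
                density_points=np.array(pts).reshape(-1, 3),
                density_compartments=[str(c) for c in comps],
                extra=extra,
                **kwargs,
            )
        )
    return out


def _parse_comment_header(path: Path) -> dict[str, Any]:
    meta: dict[str, Any] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for part in line.lstrip("#").split(";"):
                if ":" in part:
                    k, v = part.split(":", 1)
                    k, v = k.strip(), v.strip()
                    try:
                        meta[k] = float(v)
                    except ValueError:
                        meta[k] = v
    return meta


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
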