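"""Landmark-based alignment and averaging of junction subtomograms.

Subtomograms are already axis-oriented (docking axis on +z); members of one
morphology class are brought into register by a pure translation that puts
the SUV-base landmark at the common origin — no angular search or iterative
refinement, so azimuthal heterogeneity averages out by design — and then
averaged voxelwise.  The density landmarks of all members, mapped by the
same translations, form an overlay point cloud on the average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .tomo_io import Volume

__all__ = ["ClassAverage", "align_to_reference", "average_class",
           "radial_profile"]


@dataclass
class ClassAverage:
    class_code: float
    n_subtomograms: int
    average: Volume
    overlay_points: np.ndarray  # (n, 3) nm, common frame (SUV base at origin)
    transforms: list[np.ndarray] = field(default_factory=list)  # translations, nm


def align_to_reference(subtomo: Volume, suv_base_point: np.ndarray
                       ) -> tuple[Volume, np.ndarray]:
    """Translate a subtomogram so the SUV-base landmark sits at the origin.

    ``suv_base_point`` is in the subtomogram's physical (box-frame) nm
    coordinates and must lie inside the box.  Returns the resampled volume
    (trilinear) on the same grid plus the applied translation ``T`` (nm),
    with ``p_common = p_box + T``.
    """
    p = np.asarray(suv_base_point, float)
    lo = subtomo.origin
    hi = subtomo.origin + (np.array(subtomo.grid.shape)[::-1] - 1) * subtomo.voxel_size
    if np.any(p < lo) or np.any(p > hi):
        raise ValueError(f"landmark {p} outside the subtomogram box [{lo}, {hi}]")
    t_nm = -p
    shift_vox = (t_nm / subtomo.voxel_size)[::-1]  # (z, y, x)
    out = ndimage.shift(subtomo.grid.astype(np.float32), shift_vox, order=1,
                        cval=0.0)
    meta = dict(subtomo.metadata)
    meta["alignment_translation_nm"] = t_nm
    return Volume(out, subtomo.voxel_size, subtomo.origin.copy(), meta), t_nm


def average_class(aligned: list[tuple[Volume, np.ndarray, np.ndarray]],
                  class_code: float = np.nan) -> ClassAverage:
    """Voxelwise mean of aligned members plus the pooled landmark overlay.

    ``aligned`` holds, per member, the aligned volume, its density points in
    the *original* box frame, and the translation from
    :func:`align_to_reference`.  All grids must be identical in shape and
    voxel size.
    """
    if not aligned:
        raise ValueError("average_class needs at least one member")
    v0 = aligned[0][0]
    acc = np.zeros(v0.grid.shape, dtype=np.float64)
    overlay = []
    transforms = []
    for vol, pts, t_nm in aligned:
        if vol.grid.shape != v0.grid.shape or vol.voxel_size != v0.voxel_size:
            raise ValueError("member grids must match in shape and voxel size")
        acc += vol.grid
        if len(pts):
            overlay.append(np.atleast_2d(pts) + t_nm)
        transforms.append(np.asarray(t_nm, float))
    avg = (acc / len(aligned)).astype(np.float32)
    pts = np.concatenate(overlay, axis=0) if overlay else np.empty((0, 3))
    meta = {"n_members": len(aligned), "class_code": class_code}
    return ClassAverage(class_code, len(aligned),
                        Volume(avg, v0.voxel_size, v0.origin.copy(), meta),
                        pts, transforms)


def radial_profile(class_average: ClassAverage | Volume,
                   z_range: tuple[float, float] = (-8.0, -0.5),
                   dr: float | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Cylindrical density average about the docking axis.

    Averages the map over azimuth and over the axial slab ``z_range`` (nm,
    common frame: SUV base at 0, inter-membrane space below), in radial
    bins of width ``dr`` (default one voxel).  For ring-like class
    averages of the default simulations the profile peaks outside the
    exclusion cylinder; for clustered averages it peaks on the axis.
    """
    vol = class_average.average if isinstance(class_average, ClassAverage) else class_average
    vx = vol.voxel_size
    dr = dr or vx
    xs, ys, zs = vol.axes_nm()
    zsel = (zs >= z_range[0]) & (zs <= z_range[1])
    if not zsel.any():
        raise ValueError("z_range selects no voxel layer")
    slab = vol.grid[zsel].mean(axis=0)
    rho = np.hypot(xs[None, :], ys[:, None])
    nbins = int(np.ceil(rho.max() / dr))
    idx = np.minimum((rho / dr).astype(int), nbins - 1)
    sums = np.bincount(idx.ravel(), weights=slab.ravel(), minlength=nbins)
    counts = np.bincount(idx.ravel(), minlength=nbins)
    prof = sums / np.maximum(counts, 1)
    radii = (np.arange(nbins) + 0.5) * dr
    return radii, prof
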