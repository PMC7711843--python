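"""Morphology classification of docking-site density arrangements.

Junctions are assigned one of three classes, coded on the conventional
0 / 0.5 / 1 scale:

* ``0`` clustered — densities gathered at the point of closest approach;
* ``0.5`` intermediate — some densities displaced radially outward, some
  still under the vesicle base;
* ``1`` ring-like — all densities excluded from the intermembrane space,
  arranged around the vesicle base.

The operational rule replaces the visual call with an exclusion cylinder of
radius ``exclusion_radius`` about the docking axis: a junction is clustered
if every density point lies inside the cylinder, ring-like if none does
(and at least ``min_ring_points`` lie outside), intermediate otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field

__all__ = ["ClassificationParams", "JunctionClass", "classify_junction",
           "ring_completeness"]


class ClassificationParams(BaseModel):
    exclusion_radius: float = Field(default=10.0, gt=0)  # nm
    min_ring_points: int = Field(default=3, ge=1)
    angular_bins: int = Field(default=12, ge=4)
    #: points farther than this from the axis are ignored (membrane-attached
    #: densities away from the junction); None = no lateral cut
    max_radius: float | None = 60.0


@dataclass(frozen=True)
class JunctionClass:
    class_code: float  # 0, 0.5 or 1
    n_inside: int
    n_outside: int
    ring_completeness: float

    @property
    def class_name(self) -> str:
        return {0.0: "clustered", 0.5: "intermediate", 1.0: "ring_like"}[self.class_code]


def _cylindrical_radii(density_points: np.ndarray, axis_point: np.ndarray | None) -> np.ndarray:
    pts = np.asarray(density_points, float).reshape(-1, 3)
    if axis_point is not None:
        pts = pts - np.asarray(axis_point, float)
    return pts, np.hypot(pts[:, 0], pts[:, 1])


def classify_junction(density_points: np.ndarray,
                      params: ClassificationParams | None = None,
                      axis_point: np.ndarray | None = None) -> JunctionClass:
    """Classify one junction from its density points.

    Parameters
    ----------
    density_points:
        (n, 3) points in the oriented frame: docking axis along +z, the axis
        passing through ``axis_point`` (default: the origin).  The caller
        restricts points to the slab between the membrane levels.
    params:
        classifier parameters; defaults used when omitted.

    Raises
    ------
    ValueError
        for an empty point set — a docking site is by definition marked by
        at least one density, so classless sites must be flagged upstream.
    """
    params = params or ClassificationParams()
    pts, radii = _cylindrical_radii(density_points, axis_point)
    if params.max_radius is not None:
        keep = radii <= params.max_radius
        pts, radii = pts[keep], radii[keep]
    if len(radii) == 0:
        raise ValueError("cannot classify a junction with zero density points")
    n_in = int(np.sum(radii <= params.exclusion_radius))
    n_out = int(len(radii) - n_in)
    if n_in >= 1 and n_out == 0:
        code = 0.0
    elif n_in == 0 and n_out >= params.min_ring_points:
        code = 1.0
    else:
        code = 0.5
    comp = ring_completeness(pts, params)
    return JunctionClass(code, n_in, n_out, comp)


def ring_completeness(density_points: np.ndarray,
                      params: ClassificationParams | None = None,
                      axis_point: np.ndarray | None = None) -> float:
    """Fraction of angular bins about the axis occupied by outside points.

    Measures how much of a full ring the radially displaced densities trace:
    1.0 for points spread over every ``angular_bins`` sector, 0.0 when no
    point lies outside the exclusion cylinder.
    """
    params = params or ClassificationParams()
    pts, radii = _cylindrical_radii(density_points, axis_point)
    out = radii > params.exclusion_radius
    if not np.any(out):
        return 0.0
    ang = np.arctan2(pts[out, 1], pts[out, 0])  # [-pi, pi]; +pi wraps to bin 0
    bins = np.floor((ang + np.pi) / (2 * np.pi) * params.angular_bins + 1e-9)
    bins = bins.astype(int) % params.angular_bins
    return len(np.unique(bins)) / params.angular_bins
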