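"""End-to-end orchestration: simulate, detect, measure, classify, tabulate.

Convenience drivers used by the command-line interface and by the
validation suite.  The central entry point,
:func:`simulate_and_analyze_population`, renders one scene per junction at
desk scale (104^3 voxels, 2.2 nm voxels by default, comfortably holding the
largest 150 nm vesicles) and runs the full blind pipeline — SUV detection,
GUV surface tracking, docking-rule filtering, orientation, measurement and
classification — returning ground truth and recovered values side by side.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import junction_classes, junction_metrics, site_detection
from .synthetic_scenes import (GroundTruth, OpticsParams, Scene, SceneParams,
                               generate_scene, render_volume)
from .tomo_io import Volume

__all__ = ["analyze_volume", "simulate_and_analyze_population",
           "DEFAULT_PIPELINE_SHAPE"]

#: rendering geometry of the per-junction desk-scale scenes
DEFAULT_PIPELINE_SHAPE = (104, 104, 104)
DEFAULT_PIPELINE_VOXEL = 2.2  # nm


def analyze_volume(volume: Volume,
                   det_params: site_detection.DetectionParams | None = None,
                   meas_params: junction_metrics.MeasurementParams | None = None,
                   cls_params: junction_classes.ClassificationParams | None = None,
                   condition_label: str = "",
                   ) -> tuple[pd.DataFrame, list[site_detection.DockingSite],
                              list[junction_metrics.JunctionMeasurement]]:
    """Run the full docking-site analysis on one tomogram.

    Returns the per-site measurement table (one row per accepted docking
    site) together with the site and measurement objects for downstream
    averaging.
    """
    det_params = det_params or site_detection.DetectionParams()
    meas_params = meas_params or junction_metrics.MeasurementParams()
    cls_params = cls_params or junction_classes.ClassificationParams()

    suvs = site_detection.detect_suvs(volume, det_params)
    rows, sites_out, meas_out = [], [], []
    if not suvs:
        return _empty_table(), sites_out, meas_out
    surface = site_detection.estimate_guv_surface(volume, det_params)
    sites = site_detection.find_docking_sites(volume, suvs, surface, det_params)
    for site in sites:
        try:
            m = junction_metrics.measure_junction(site, meas_params)
        except junction_metrics.MembranesNotResolvableError:
            continue
        try:
            jc = junction_classes.classify_junction(m.density_points, cls_params)
            code, n_in, n_out, comp = (jc.class_code, jc.n_inside, jc.n_outside,
                                       jc.ring_completeness)
        except ValueError:
            code, n_in, n_out, comp = np.nan, 0, 0, np.nan
        rows.append(dict(
            site_id=m.site_id, condition_label=condition_label,
            class_code=code, separation_nm=m.separation,
            protrusion_flag=m.protrusion_flag,
            protrusion_height_nm=m.protrusion_height,
            n_densities=m.n_densities,
            contact_diameter_nm=m.contact_diameter,
            n_inside=n_in, n_outside=n_out, ring_completeness=comp,
            suv_radius_nm=site.suv_radius,
        ))
        sites_out.append(site)
        meas_out.append(m)
    return (pd.DataFrame(rows) if rows else _empty_table()), sites_out, meas_out


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "site_id", "condition_label", "class_code", "separation_nm",
        "protrusion_flag", "protrusion_height_nm", "n_densities",
        "contact_diameter_nm", "n_inside", "n_outside", "ring_completeness",
        "suv_radius_nm"])


def single_junction_scene(seed: int,
                          scene_overrides: dict | None = None
                          ) -> tuple[Scene, GroundTruth]:
    """One default junction on its own patch, sized for the pipeline grid."""
    half = DEFAULT_PIPELINE_SHAPE[2] * DEFAULT_PIPELINE_VOXEL / 2
    kw = dict(n_junctions=1, seed=seed, patch_size=2 * half - 4)
    kw.update(scene_overrides or {})
    return generate_scene(SceneParams(**kw))


def render_single_junction(scene: Scene, optics: OpticsParams) -> Volume:
    half = DEFAULT_PIPELINE_SHAPE[2] * optics.voxel_size / 2
    return render_volume(scene, optics, shape=DEFAULT_PIPELINE_SHAPE,
                         origin=np.array([-half, -half, 0.0]))


def simulate_and_analyze_population(
        n_junctions: int, seed: int,
        scene_overrides: dict | None = None,
        optics_overrides: dict | None = None,
        det_params: site_detection.DetectionParams | None = None,
        meas_params: junction_metrics.MeasurementParams | None = None,
        cls_params: junction_classes.ClassificationParams | None = None,
        keep_sites: bool = False,
        ) -> tuple[pd.DataFrame, list]:
    """Simulate ``n_junctions`` single-junction tomograms and analyse each.

    Returns a table with one row per *ground-truth* junction carrying the
    ``gt_*`` truth columns and, where the blind pipeline recovered the
    site, the measured columns of :func:`analyze_volume` (NaN when the site
    was missed).  ``keep_sites`` additionally returns the per-junction
    (site, measurement, ground-truth) triples of recovered sites for
    class averaging.
    """
    rng = np.random.default_rng(seed)
    rows = []
    kept = []
    for i in range(n_junctions):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        scene, gt = single_junction_scene(sub_seed, scene_overrides)
        okw = dict(voxel_size=DEFAULT_PIPELINE_VOXEL, noise_seed=sub_seed + 1)
        okw.update(optics_overrides or {})
        optics = OpticsParams(**okw)
        vol = render_single_junction(scene, optics)
        table, sites, meas = analyze_volume(vol, det_params, meas_params,
                                            cls_params)
        j = scene.junctions[0]
        row = dict(
            junction_index=i,
            gt_class_code=j.class_code, gt_separation_nm=j.separation,
            gt_protrusion_flag=j.protrusion_flag,
            gt_protrusion_height_nm=j.protrusion_height,
            gt_n_densities=j.n_densities,
            gt_contact_diameter_nm=j.contact_diameter,
            gt_suv_radius_nm=j.suv_outer_radius,
            recovered=len(table) > 0,
        )
        if len(table) > 0:
            # closest detection to the true axis if several
            c_true = scene.to_lab(scene.suv_center(j))
            k = int(np.argmin([np.linalg.norm(s.suv_center - c_true)
                               for s in sites]))
            row.update({c: table.iloc[k][c] for c in table.columns
                        if c not in ("site_id", "condition_label")})
            if keep_sites:
                kept.append((sites[k], meas[k], j))
        rows.append(row)
    return pd.DataFrame(rows), kept
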