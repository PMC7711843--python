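import numpy as np
import pytest
from scipy import stats

from dockquant.synthetic_scenes import (InfeasibleGeometryError, OpticsParams,
                                        SceneParams, generate_scene,
                                        missing_wedge_mask, render_volume)


def test_empty_scene_is_valid():
    scene, gt = generate_scene(SceneParams(n_junctions=0, seed=1))
    assert scene.junctions == []
    assert len(gt.to_frame()) == 0
    vol = render_volume(scene, OpticsParams(noise_sigma=0.0))
    assert vol.grid.max() > 0  # the GUV patch alone is rendered


def test_forced_ring_class_and_separation():
    params = SceneParams(
        n_junctions=6, class_probs=(0.0, 0.0, 1.0),
        separation_ranges={"clustered": (5, 26), "intermediate": (3, 8),
                           "ring_like": (2.0, 2.0)},
        contact_prob=0.0, seed=3)
    scene, _ = generate_scene(params)
    for j in scene.junctions:
        assert j.class_code == 1.0
        assert j.separation == pytest.approx(2.0)
        local = j.density_points - np.array([*j.center_xy, 0.0])
        radii = np.hypot(local[:, 0], local[:, 1])
        assert np.all(radii > params.exclusion_radius)


def test_seed_reproducibility_bit_identical():
    p = SceneParams(n_junctions=4, seed=99)
    s1, g1 = generate_scene(p)
    s2, g2 = generate_scene(p)
    assert g1.to_frame().equals(g2.to_frame())
    o = OpticsParams(voxel_size=2.5, noise_seed=5)
    v1 = render_volume(s1, o)
    v2 = render_volume(s2, o)
    assert np.array_equal(v1.grid, v2.grid)


def test_separations_and_counts_within_configured_ranges():
    scene, gt = generate_scene(SceneParams(n_junctions=300, seed=42))
    df = gt.to_frame()
    ranges = scene.params.separation_ranges
    for name, (lo, hi) in ranges.items():
        sep = df.loc[df.class_name == name, "separation_nm"]
        assert sep.min() >= lo - 1e-9
        assert sep.max() <= hi + 1e-9
    assert df.n_densities.between(2, 34).all()
    assert df.suv_diameter_nm.between(20, 150).all()


def test_class_conditional_separations_uniform():
    """KS test against the configured uniform ranges (continuous part)."""
    scene, gt = generate_scene(SceneParams(n_junctions=3000, seed=7))
    df = gt.to_frame()
    for name, (lo, hi) in scene.params.separation_ranges.items():
        sep = df.loc[df.class_name == name, "separation_nm"]
        if name == "ring_like":
            sep = sep[sep > 0]  # direct-contact mixture mass sits at 0
            lo = 0.3
        p = stats.kstest(sep, stats.uniform(lo, hi - lo).cdf).pvalue
        assert p > 0.01, f"{name} separations not uniform (p={p:.4f})"


def test_density_hard_core_spacing():
    scene, _ = generate_scene(SceneParams(n_junctions=20, seed=5))
    violations = total_pairs = 0
    for j in scene.junctions:
        pts = j.density_points
        if len(pts) < 2:
            continue
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        iu = np.triu_indices(len(pts), 1)
        total_pairs += len(iu[0])
        violations += int((d[iu] < 3.5 - 1e-9).sum())
    # dart throwing accepts the best candidate when a site is crowded
    assert violations / total_pairs < 0.1


def test_infeasible_patch_raises():
    with pytest.raises(InfeasibleGeometryError):
        generate_scene(SceneParams(n_junctions=30, patch_size=150.0, seed=0))


def test_wedge_mask_zeroes_missing_region():
    mask = missing_wedge_mask((32, 32, 32), 60.0)
    kz = np.fft.fftfreq(32)[:, None, None]
    kx = np.fft.rfftfreq(32)[None, None, :]
    ang = np.degrees(np.arctan2(np.abs(kx), np.abs(np.broadcast_to(kz, mask.shape))))
    assert not mask[(ang > 60.5)].any()
    assert mask[(ang < 59.5)].all()
    assert mask[0, 0, 0]  # DC kept


def test_rendered_wedge_amplitude_suppressed():
    import scipy.fft
    scene, _ = generate_scene(SceneParams(n_junctions=1, seed=11))
    vol = render_volume(scene, OpticsParams(noise_sigma=0.0))
    spec = np.abs(scipy.fft.rfftn(vol.grid.astype(np.float64)))
    keep = missing_wedge_mask(vol.grid.shape, 60.0)
    missing = np.broadcast_to(~keep, spec.shape)
    assert spec[missing].max() <= 1e-6 * spec.max()


def test_suv_radial_profile_peaks_at_outer_leaflet():
    """A rendered 80 nm vesicle has its density ridge at 40 nm radius."""
    params = SceneParams(n_junctions=1, seed=2, suv_diameter_mean=80.0,
                         suv_diameter_sd=0.0, protrusion_prob_given_class=(0, 0, 0),
                         class_probs=(1.0, 0.0, 0.0), density_count_range=(2, 2))
    scene, _ = generate_scene(params)
    optics = OpticsParams(noise_sigma=0.0, apply_wedge=False)
    vol = render_volume(scene, optics)
    j = scene.junctions[0]
    c = scene.suv_center(j)
    xs, ys, zs = vol.axes_nm()
    d = np.sqrt((xs[None, None, :] - c[0]) ** 2 + (ys[None, :, None] - c[1]) ** 2
                + (zs[:, None, None] - c[2]) ** 2)
    upper = np.broadcast_to(zs[:, None, None] > c[2], d.shape)
    bins = np.round(d[upper]).astype(int)
    prof = np.bincount(bins, weights=vol.grid[upper]) / np.bincount(bins).clip(1)
    # the bilayer has two leaflet ridges (outer at R, inner at R - 4 nm); the
    # overall peak falls within the bilayer and the outer ridge sits at R
    peak_r = np.argmax(prof[20:60]) + 20
    R = j.suv_outer_radius
    assert R - 4.5 <= peak_r <= R + 1.5
    outer_lo = int(R - 2)
    outer_peak = outer_lo + np.argmax(prof[outer_lo:outer_lo + 8])
    assert abs(outer_peak - R) <= vol.voxel_size / 2 + 0.5


def test_noise_standard_deviation_matches_request():
    scene, _ = generate_scene(SceneParams(n_junctions=2, seed=13))
    o_clean = OpticsParams(noise_sigma=0.0)
    o_noisy = OpticsParams(noise_sigma=0.25, noise_seed=3)
    clean = render_volume(scene, o_clean)
    noisy = render_volume(scene, o_noisy)
    diff = noisy.grid - clean.grid
    assert diff.size >= 1e6
    assert np.std(diff) == pytest.approx(0.25, rel=0.05)


def test_rendering_linearity_before_noise():
    """Rendering two disjoint scenes and summing equals rendering the union."""
    base = dict(class_probs=(1.0, 0.0, 0.0), suv_diameter_sd=0.0,
                suv_diameter_mean=50.0, protrusion_prob_given_class=(0, 0, 0))
    p2 = SceneParams(n_junctions=2, seed=21, **base)
    scene_both, _ = generate_scene(p2)
    import copy
    scene_a = copy.copy(scene_both)
    scene_b = copy.copy(scene_both)
    scene_a.junctions = scene_both.junctions[:1]
    scene_b.junctions = scene_both.junctions[1:]
    optics = OpticsParams(noise_sigma=0.0)
    lo, hi = scene_both.bounding_box()
    kw = dict(shape=None, origin=lo)
    v_both = render_volume(scene_both, optics, **kw)
    kw["shape"] = v_both.grid.shape
    v_a = render_volume(scene_a, optics, **kw)
    v_b = render_volume(scene_b, optics, **kw)
    # the GUV sheet is shared; subtract one sheet-only rendering
    scene_none = copy.copy(scene_both)
    scene_none.junctions = []
    v_sheet = render_volume(scene_none, optics, **kw)
    lhs = v_a.grid.astype(np.float64) + v_b.grid.astype(np.float64) - v_sheet.grid
    assert np.allclose(lhs, v_both.grid, atol=2e-5)


def test_voxel_size_warning_for_unresolvable_features():
    scene, _ = generate_scene(SceneParams(n_junctions=1, seed=1))
    with pytest.warns(UserWarning, match="not be resolvable"):
        render_volume(scene, OpticsParams(voxel_size=8.0, noise_sigma=0.0))


def test_class_probs_must_sum_to_one():
    with pytest.raises(ValueError):
        SceneParams(class_probs=(0.5, 0.2, 0.2))
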