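import numpy as np
import pytest

from dockquant import junction_metrics as jm
from dockquant import pipeline, site_detection as sd
from dockquant.synthetic_scenes import OpticsParams, SceneParams, generate_scene


def analyze_one(seed, scene_overrides=None, noise=0.0):
    scene, gt = pipeline.single_junction_scene(seed, scene_overrides)
    optics = OpticsParams(voxel_size=2.2, noise_sigma=noise, noise_seed=seed + 1)
    vol = pipeline.render_single_junction(scene, optics)
    suvs = sd.detect_suvs(vol)
    surface = sd.estimate_guv_surface(vol)
    sites = sd.find_docking_sites(vol, suvs, surface, require_density=False)
    return scene.junctions[0], (sites[0] if sites else None)


def test_separation_error_below_voxel_over_full_range():
    """Noise-free phantoms across 0-27 nm: separation error <= 1 voxel."""
    errs = []
    rng = np.random.default_rng(55)
    for k in range(30):
        j, site = analyze_one(int(rng.integers(0, 2**31 - 1)))
        if site is None:
            continue
        sep = jm.measure_separation(site.subtomogram)
        errs.append(abs(sep - j.separation))
    assert len(errs) >= 25
    assert np.mean(errs) <= 2.2


def test_touching_membranes_measure_zero():
    overrides = {"class_probs": (0, 0, 1.0), "contact_prob": 1.0}
    found = 0
    for seed in range(40, 60):
        j, site = analyze_one(seed, overrides)
        if site is None or j.separation > 0:
            continue
        found += 1
        assert jm.measure_separation(site.subtomogram) <= 2.2
        if found >= 3:
            break
    assert found >= 2


def test_density_count_bias_on_sparse_phantoms():
    """Noise-free phantoms with blobs at least 2x merge radius apart:
    |mean(detected - true)| <= 1."""
    overrides = {"density_count_range": (2, 4), "density_min_spacing": 10.0,
                 "class_probs": (1.0, 0.0, 0.0),
                 "separation_ranges": {"clustered": (12, 22),
                                       "intermediate": (3, 8),
                                       "ring_like": (0, 7)},
                 "contact_prob": 0.0}
    diffs = []
    for seed in range(300, 330):
        j, site = analyze_one(seed, overrides)
        if site is None:
            continue
        pts, _ = jm.detect_density_landmarks(site.subtomogram,
                                             suv_radius=site.suv_radius)
        diffs.append(len(pts) - j.n_densities)
    assert len(diffs) >= 20
    assert abs(np.mean(diffs)) <= 1.0


def test_density_threshold_monotonicity():
    """Raising the detection threshold never increases the count."""
    j, site = analyze_one(77, noise=0.2)
    assert site is not None
    counts = []
    for thr in (0.08, 0.15, 0.3, 0.6):
        pts, _ = jm.detect_density_landmarks(site.subtomogram,
                                             suv_radius=site.suv_radius,
                                             threshold=thr)
        counts.append(len(pts))
    assert all(b <= a for a, b in zip(counts, counts[1:]))


def test_protrusion_detected_and_flat_rejected():
    hits = miss = 0
    checked_flat = checked_prot = 0
    for seed in range(500, 540):
        j, site = analyze_one(seed, noise=0.2)
        if site is None:
            continue
        flag, height = jm.detect_protrusion(site.subtomogram)
        if j.protrusion_flag:
            checked_prot += 1
            hits += flag == 1
            if flag:
                assert height == pytest.approx(j.protrusion_height, abs=2.0)
        else:
            checked_flat += 1
            miss += flag == 0
        if checked_flat >= 8 and checked_prot >= 8:
            break
    assert checked_prot >= 5 and checked_flat >= 5
    assert hits / checked_prot >= 0.8
    assert miss / checked_flat >= 0.8


def test_subthreshold_bump_not_flagged():
    overrides = {"protrusion_prob_given_class": (1.0, 1.0, 1.0),
                 "protrusion_height": 2.0, "protrusion_height_sd": 0.0,
                 "class_probs": (1.0, 0, 0)}
    # clip bounds in the generator keep the draw at 3.5 minimum; instead use
    # a taller threshold so a 3.5 nm bump is sub-threshold
    j, site = analyze_one(9, overrides)
    assert site is not None
    params = jm.MeasurementParams(protrusion_min_height=j.protrusion_height + 1)
    flag, height = jm.detect_protrusion(site.subtomogram, params)
    assert flag == 0
    assert height == pytest.approx(j.protrusion_height, abs=1.5)


def test_contact_diameter_recovery():
    """Flattened-facet phantoms: measured diameter within 2 voxels."""
    overrides = {"class_probs": (0, 0, 1.0), "contact_prob": 1.0,
                 "contact_diameter_mean": 16.0, "contact_diameter_sd": 0.0,
                 "contact_diameter_range": (16.0, 16.0),
                 "suv_diameter_mean": 80.0, "suv_diameter_sd": 0.0}
    errs = []
    for seed in range(700, 730):
        j, site = analyze_one(seed, overrides)
        if site is None or j.contact_diameter == 0:
            continue
        d = jm.measure_contact_diameter(site.subtomogram,
                                        suv_radius=site.suv_radius)
        errs.append(abs(d - j.contact_diameter))
        if len(errs) >= 8:
            break
    assert len(errs) >= 5
    assert np.mean(errs) <= 2 * 2.2


def test_separated_membranes_have_zero_contact():
    overrides = {"class_probs": (1.0, 0, 0)}  # clustered: 5-26 nm apart
    j, site = analyze_one(12, overrides)
    assert site is not None
    assert jm.measure_contact_diameter(site.subtomogram,
                                       suv_radius=site.suv_radius) == 0.0
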