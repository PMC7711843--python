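import numpy as np
import pytest

from dockquant.class_averaging import (align_to_reference, average_class,
                                       radial_profile)
from dockquant.tomo_io import Volume


def centered_volume(grid, vx=2.0):
    n = np.array(grid.shape)[::-1]
    origin = -(n - 1) / 2 * vx
    return Volume(grid.astype(np.float32), vx, origin)


def test_identity_alignment_for_origin_landmark():
    vol = centered_volume(np.random.default_rng(0).normal(size=(33, 33, 33)))
    aligned, t = align_to_reference(vol, np.zeros(3))
    assert np.allclose(t, 0.0)
    assert np.allclose(aligned.grid, vol.grid, atol=1e-6)


def test_translation_moves_landmark_to_origin():
    vol = centered_volume(np.zeros((41, 41, 41), np.float32))
    # a delta-like blob at a lattice-aligned landmark
    p = np.array([6.0, -4.0, 10.0])
    idx = vol.xyz_to_index(p)[0].round().astype(int)
    vol.grid[tuple(idx)] = 1.0
    aligned, t = align_to_reference(vol, p)
    c = vol.xyz_to_index(np.zeros(3))[0].round().astype(int)
    assert aligned.grid[tuple(c)] == pytest.approx(1.0, abs=1e-5)
    assert np.allclose(t, -p)


def test_landmark_outside_box_rejected():
    vol = centered_volume(np.zeros((17, 17, 17)))
    with pytest.raises(ValueError):
        align_to_reference(vol, np.array([100.0, 0.0, 0.0]))


def test_round_trip_translation_interpolation_error_small():
    rng = np.random.default_rng(3)
    from scipy import ndimage
    vol = centered_volume(ndimage.gaussian_filter(
        rng.normal(size=(41, 41, 41)), 2.0).astype(np.float32))
    dyn = vol.grid.max() - vol.grid.min()
    interior = (slice(8, -8),) * 3
    # lattice-aligned translation: trilinear resampling is exact
    p_int = np.array([4.0, -2.0, 6.0])
    fwd, _ = align_to_reference(vol, p_int)
    back, _ = align_to_reference(fwd, -p_int)
    err = np.abs(back.grid[interior] - vol.grid[interior]).max()
    assert err < 1e-5 * dyn
    # sub-voxel translation: bounded interpolation smoothing only
    p_frac = np.array([3.0, -2.0, 5.0])
    fwd, _ = align_to_reference(vol, p_frac)
    back, _ = align_to_reference(fwd, -p_frac)
    err = np.abs(back.grid[interior] - vol.grid[interior]).max()
    assert err < 5e-2 * dyn


def test_average_of_identical_volumes_is_the_volume():
    vol = centered_volume(np.random.default_rng(5).normal(size=(21, 21, 21)))
    members = [(vol, np.empty((0, 3)), np.zeros(3)) for _ in range(4)]
    avg = average_class(members, class_code=0.0)
    assert np.allclose(avg.average.grid, vol.grid, atol=1e-6)
    assert avg.n_subtomograms == 4


def test_averaging_reduces_noise_by_sqrt_n():
    """100 noisy copies of one phantom: residual SD = sigma/10 within 15%."""
    rng = np.random.default_rng(7)
    phantom = centered_volume(
        np.random.default_rng(11).normal(size=(41, 41, 41)).astype(np.float32))
    sigma = 0.5
    members = []
    for k in range(100):
        noisy = Volume(phantom.grid + rng.normal(0, sigma, phantom.grid.shape
                                                 ).astype(np.float32),
                       phantom.voxel_size, phantom.origin.copy())
        aligned, t = align_to_reference(noisy, np.zeros(3))
        members.append((aligned, np.empty((0, 3)), t))
    avg = average_class(members)
    resid_sd = float(np.std(avg.average.grid - phantom.grid))
    assert resid_sd == pytest.approx(sigma / 10, rel=0.15)


def test_averaging_is_order_invariant():
    rng = np.random.default_rng(9)
    vols = [centered_volume(rng.normal(size=(15, 15, 15))) for _ in range(5)]
    pts = [rng.uniform(-10, 10, (3, 3)) for _ in range(5)]
    members = [(v, p, np.zeros(3)) for v, p in zip(vols, pts)]
    a1 = average_class(members)
    a2 = average_class(members[::-1])
    assert np.allclose(a1.average.grid, a2.average.grid, atol=1e-12)
    assert len(a1.overlay_points) == sum(len(p) for p in pts)


def test_mismatched_grids_rejected():
    v1 = centered_volume(np.zeros((15, 15, 15)))
    v2 = centered_volume(np.zeros((17, 17, 17)))
    with pytest.raises(ValueError):
        average_class([(v1, np.empty((0, 3)), np.zeros(3)),
                       (v2, np.empty((0, 3)), np.zeros(3))])
    with pytest.raises(ValueError):
        average_class([])


def test_radial_profile_flat_for_uniform_volume():
    vol = centered_volume(np.ones((31, 31, 31)))
    radii, prof = radial_profile(vol, z_range=(-8, -1))
    inner = prof[radii < 25]
    assert np.allclose(inner, 1.0, atol=1e-6)


def test_radial_profile_peaks_at_ring_radius():
    """A synthetic ring of density at 15 nm radius peaks at 15 +/- 2 nm."""
    vx = 2.0
    n = 41
    vol = centered_volume(np.zeros((n, n, n), np.float32), vx)
    xs, ys, zs = vol.axes_nm()
    ang = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    for a in ang:
        p = np.array([15 * np.cos(a), 15 * np.sin(a), -4.0])
        d2 = ((xs[None, None, :] - p[0]) ** 2 + (ys[None, :, None] - p[1]) ** 2
              + (zs[:, None, None] - p[2]) ** 2)
        vol.grid += np.exp(-d2 / (2 * 2.0**2)).astype(np.float32)
    radii, prof = radial_profile(vol, z_range=(-8, -1))
    peak_r = radii[np.argmax(prof)]
    assert peak_r == pytest.approx(15.0, abs=2.0)
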