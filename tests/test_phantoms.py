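"""Phantom generators: bookkeeping, calibration and reproducibility."""

import numpy as np
import pytest

from ffsdoct.errors import InvalidParameterError
from ffsdoct.phantoms import (PhantomSpec, curved_surface_height,
                              endothelial_mosaic, hex_lattice_spacing_um,
                              keratocyte_field, nerve_plexus,
                              tear_film_decay_defaults, tear_film_sequence,
                              vessel_flow_sequence)

SMALL = PhantomSpec(field_of_view_mm=0.4, seed=42)


def test_hex_spacing_matches_cell_diameter():
    # 3096 cells/mm^2 corresponds to ~19.3 um spacing (~20 um cells)
    assert hex_lattice_spacing_um(3096.0) == pytest.approx(19.32, abs=0.05)


def test_mosaic_density_bookkeeping():
    img, gt = endothelial_mosaic(3096.0, 0.1, SMALL)
    assert gt.data["generated_density_per_mm2"] == pytest.approx(3096.0, rel=0.05)
    assert img.shape == SMALL.shape_px


def test_zero_jitter_lattice_is_periodic():
    from scipy.spatial import cKDTree
    _, gt = endothelial_mosaic(3096.0, 0.0, SMALL)
    pts = gt.data["centroids_um"]
    # interior points have 6 equidistant nearest neighbors
    tree = cKDTree(pts)
    a = gt.params["lattice_spacing_um"]
    center = pts[np.argmin(np.linalg.norm(pts - pts.mean(0), axis=1))]
    d, _ = tree.query(center, k=7)
    assert np.allclose(d[1:], a, rtol=1e-6)


def test_mosaic_rejects_sparse_density():
    with pytest.raises(InvalidParameterError):
        endothelial_mosaic(20.0, 0.1, PhantomSpec(field_of_view_mm=0.2))


def test_nerve_length_bookkeeping():
    img, gt = nerve_plexus(15.0, spec=SMALL)
    target = 15.0 * SMALL.area_mm2
    assert gt.data["total_length_mm"] == pytest.approx(target, rel=0.01)
    empty_img, empty_gt = nerve_plexus(0.0, spec=SMALL)
    assert empty_gt.data["total_length_mm"] == 0.0
    assert np.all(empty_img == 0)


def test_nerve_orientation_bias_vertical():
    _, gt = nerve_plexus(15.0, orientation_bias="vertical", spec=SMALL)
    angles = []
    for line in gt.data["polylines_um"]:
        d = np.diff(line, axis=0)
        angles.extend(np.arctan2(d[:, 0], d[:, 1]))
    angles = np.array(angles)
    # axial circular mean (orientations are pi-periodic)
    mean_axis = 0.5 * np.angle(np.mean(np.exp(2j * angles)))
    dev = np.abs(np.mod(mean_axis - np.pi / 2 + np.pi / 2, np.pi) - np.pi / 2)
    assert np.degrees(dev) < 10.0


def test_keratocyte_density_profile_and_elongation():
    profile = [(50.0, 1200.0), (200.0, 700.0), (350.0, 400.0), (480.0, 550.0)]
    scenes, gt = keratocyte_field(profile, spec=SMALL)
    assert len(scenes) == 4
    for (_, dens), n in zip(profile, gt.data["counts"]):
        expected = dens * SMALL.area_mm2
        assert abs(n - expected) < 4 * np.sqrt(expected) + 1
    elong = gt.params["elongation_profile"]
    assert all(b >= a for a, b in zip(elong, elong[1:]))
    empty_scenes, _ = keratocyte_field([], spec=SMALL)
    assert empty_scenes == []


def test_vessel_particle_displacement_bookkeeping():
    frames, gt = vessel_flow_sequence(n_frames=3, n_cells=12, spec=SMALL)
    rate = gt.params["frame_rate_fps"]
    speeds = gt.params["speeds_mm_s"][0] * 1e3  # um/s per particle
    p0 = gt.data["positions_um"][0][0]
    p1 = gt.data["positions_um"][1][0]
    fov = SMALL.field_of_view_mm * 1e3
    disp = np.linalg.norm((p1 - p0 + fov / 2) % fov - fov / 2, axis=1)
    assert np.allclose(disp, speeds / rate, atol=1e-6)


def test_vessel_zero_speed_static():
    frames, _ = vessel_flow_sequence(centerline_speed_mm_s=0.0, n_frames=4,
                                     n_cells=10, spec=SMALL)
    assert np.allclose(frames[0], frames[-1])


def test_crossing_geometry_flagged():
    _, gt = vessel_flow_sequence(crossing=True, lumen_width_um=30.0,
                                 n_frames=2, n_cells=5, spec=SMALL)
    overlap = gt.data["overlap_mask"]
    assert overlap.any()
    assert overlap.sum() < gt.data["lumen_mask"].sum()


def test_tear_film_two_point_calibration():
    v0, tau = tear_film_decay_defaults()
    assert tau == pytest.approx(0.513, abs=0.005)
    assert v0 * np.exp(-0.15 / tau) == pytest.approx(4.2, rel=1e-6)
    assert v0 * np.exp(-1.0 / tau) == pytest.approx(0.8, rel=1e-6)


def test_tear_film_velocity_monotone_and_stabilizes():
    _, gt = tear_film_sequence(n_particles=3, n_frames=5, spec=SMALL)
    v = gt.data["velocity_mm_s"]
    ts = np.linspace(0, 10, 200)
    vals = [v(t) for t in ts]
    assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))
    assert v(9.0) == 0.0 and v(12.0) == 0.0


def test_tear_film_zero_speed_static():
    frames, _ = tear_film_sequence(initial_speed_mm_s=0.0, n_particles=5,
                                   n_frames=4, spec=SMALL)
    assert np.allclose(frames[0], frames[-1])


def test_curved_surface_sag():
    sag = curved_surface_height(7.8, spec=SMALL)
    n = SMALL.shape_px[0]
    assert sag[n // 2, n // 2] == pytest.approx(0.0, abs=0.01)
    # paraxial r^2/2R check at r = 190 um
    pitch = SMALL.pixel_pitch_um
    r_um = 190.0
    col = n // 2 + int(round(r_um / pitch))
    r_exact = (col + 0.5) * pitch - SMALL.field_of_view_mm * 1e3 / 2
    paraxial = r_exact**2 / (2 * 7.8e3)
    assert sag[n // 2, col] == pytest.approx(paraxial, rel=0.01)
    flatter = curved_surface_height(15.6, spec=SMALL)
    assert flatter.max() < sag.max()


@pytest.mark.parametrize("gen", [
    lambda s: endothelial_mosaic(3096.0, 0.1, s)[0],
    lambda s: nerve_plexus(10.0, spec=s)[0],
    lambda s: vessel_flow_sequence(n_frames=2, n_cells=8, spec=s)[0],
    lambda s: tear_film_sequence(n_particles=5, n_frames=2, spec=s)[0],
])
def test_bit_exact_reproducibility(gen):
    a = gen(PhantomSpec(field_of_view_mm=0.3, seed=7))
    b = gen(PhantomSpec(field_of_view_mm=0.3, seed=7))
    assert np.array_equal(np.asarray(a), np.asarray(b))
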