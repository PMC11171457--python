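"""Interfacial water density, layer detection, hydrogen-bond statistics."""

import numpy as np
import pytest

from metadf import (DensityProfile, FrameSet, density_profile,
                    find_layers, hbond_distances, read_xyz,
                    simulate_hbond_frames, simulate_layered_frames,
                    surface_origin, write_xyz)
from metadf.hydration import WATER_BULK_DENSITY
from metadf.exceptions import ParameterError, SelectionError


def test_surface_origin_single_and_layered():
    coords = np.array([[0.0, 0.0, 0.0]])
    assert surface_origin(coords, ["Ti"]) == 0.0
    # only the topmost layer counts
    coords = np.array([[0, 0, 3.0], [1, 0, 5.05], [2, 0, 4.95]])
    origin = surface_origin(coords, ["Ti", "Ti", "Ti"])
    assert origin == pytest.approx(5.0)
    with pytest.raises(SelectionError):
        surface_origin(coords, ["O", "O", "O"])


def test_surface_origin_on_jittered_slab():
    fr = simulate_layered_frames(seed=3)
    for f in range(0, fr.n_frames, 50):
        origin = surface_origin(fr.coords[f], fr.elements)
        assert abs(origin - 2.0) < 0.05


def test_uniform_bulk_density_within_poisson_error():
    """Zero layers: the profile is flat at the requested bulk density
    (each bin within 3σ Poisson)."""
    fr = simulate_layered_frames(layer_positions=(), layer_widths=(),
                                 layer_occupancies=(), seed=0)
    prof = density_profile(fr, d_range=(2.0, 20.0), bin_width=0.5)
    area = fr.box[0] * fr.box[1]
    inner = (prof.centers > 2.0) & (prof.centers < 20.0)
    expected = WATER_BULK_DENSITY * area * 0.5 * fr.n_frames
    for c in prof.counts[inner]:
        assert abs(c - expected) < 3 * np.sqrt(expected)


def test_count_conservation_and_bin_width_halving():
    fr = simulate_layered_frames(seed=4)
    n_oxygen = sum(1 for e in fr.elements if e == "O")
    prof = density_profile(fr, d_range=(-1.0, 25.0))
    assert prof.counts.sum() == n_oxygen * fr.n_frames
    prof2 = density_profile(fr, d_range=(-1.0, 25.0), bin_width=0.2)
    assert prof2.counts.sum() == prof.counts.sum()
    assert abs(prof2.centers.size - prof.centers.size // 2) <= 1


def test_translation_invariance():
    fr = simulate_layered_frames(seed=6)
    shifted = FrameSet(fr.elements,
                       fr.coords + np.array([0.0, 0.0, 3.3]), fr.box)
    a = density_profile(fr)
    b = density_profile(shifted)
    assert np.array_equal(a.counts, b.counts)


def test_three_layer_fixture_peak_positions():
    """The layered generator is recovered: exactly three ordered peaks
    within 0.1 Å of 2.3, 3.0 and 5.0 Å."""
    fr = simulate_layered_frames(seed=1)
    prof = density_profile(fr)
    peaks, bounds = find_layers(prof)
    assert len(peaks) == 3
    assert np.all(np.diff(peaks) > 0)
    assert np.abs(np.asarray(peaks) - [2.3, 3.0, 5.0]).max() < 0.1
    assert len(bounds) == 2


def test_flat_profile_has_no_peaks():
    centers = np.arange(0.05, 10.0, 0.1)
    prof = DensityProfile(centers, np.full_like(centers, 0.03),
                          np.full_like(centers, 30.0), 10, 0.1)
    peaks, bounds = find_layers(prof)
    assert len(peaks) == 0 and bounds == []


def test_single_gaussian_bump_gives_one_peak():
    centers = np.arange(0.05, 10.0, 0.1)
    rho = 0.2 * np.exp(-0.5 * ((centers - 4.0) / 0.3) ** 2)
    prof = DensityProfile(centers, rho, rho * 100, 10, 0.1)
    peaks, _ = find_layers(prof, bulk_density=0.03)
    assert len(peaks) == 1
    assert peaks[0] == pytest.approx(4.0, abs=0.05)


def test_layer_occupancy_ratios_recovered():
    """Areas under the layer peaks reproduce the generator occupancies
    within 5%."""
    occ = (20, 16, 14)
    fr = simulate_layered_frames(layer_occupancies=occ, seed=7)
    # the uniform bulk begins at d = 6.0; stop the last window short
    prof = density_profile(fr, d_range=(0.0, 5.9))
    windows = [(1.8, 2.65), (2.65, 4.0), (4.0, 5.9)]
    for (lo, hi), n in zip(windows, occ):
        got = prof.counts[(prof.centers >= lo)
                          & (prof.centers < hi)].sum() / fr.n_frames
        assert got == pytest.approx(n, rel=0.05)


def test_hbond_exact_single_pair():
    coords = np.zeros((5, 2, 3))
    coords[:, 1, 0] = 1.6
    fr = FrameSet(["O", "H"], coords, (10, 10, 10))
    st = hbond_distances(fr, "H", "O")
    assert st.mean == pytest.approx(1.6) and st.count == 5
    assert st.defined


def test_hbond_beyond_cutoff_undefined():
    coords = np.zeros((3, 2, 3))
    coords[:, 1, 0] = 3.5
    fr = FrameSet(["O", "H"], coords, (10, 10, 10))
    st = hbond_distances(fr, "H", "O", cutoff=2.5)
    assert st.count == 0 and not st.defined
    assert np.isnan(st.mean)


def test_hbond_gaussian_fixture_mean():
    """The synthetic donor–acceptor fixture reproduces its 1.6 Å mean
    distance within 3 standard errors."""
    fr = simulate_hbond_frames(mean=1.6, sd=0.1, n_frames=400, seed=2)
    st = hbond_distances(fr, "H", "O")
    se = st.sd / np.sqrt(st.count)
    assert abs(st.mean - 1.6) < 3 * se
    assert st.mean <= st.cutoff


def test_generator_determinism_and_validation():
    a = simulate_layered_frames(seed=11)
    b = simulate_layered_frames(seed=11)
    assert np.array_equal(a.coords, b.coords)
    with pytest.raises(ParameterError):
        simulate_layered_frames(layer_positions=(30.0,),
                                layer_widths=(0.1,),
                                layer_occupancies=(5,))


def test_xyz_roundtrip(tmp_path):
    fr = simulate_layered_frames(n_frames=5, seed=8)
    path = tmp_path / "traj.xyz"
    write_xyz(fr, path)
    back = read_xyz(path, box=fr.box)
    assert back.n_frames == fr.n_frames
    assert back.elements == fr.elements
    assert np.abs(back.coords - fr.coords).max() < 5e-4  # format digits
    prof_a = density_profile(fr)
    prof_b = density_profile(back)
    assert np.array_equal(prof_a.counts, prof_b.counts)
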