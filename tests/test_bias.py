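"""Metadynamics bias: hill arithmetic, periodicity, projection estimate."""

import io

import numpy as np
import pytest

from metadf import (BiasState, deposit_hill, bias_value, bias_gradient,
                    metad_pmf_estimate)
from metadf.constants import KB
from metadf.exceptions import ParameterError


def test_single_hill_value_at_center_is_w0():
    state = BiasState(w0=1.3)
    deposit_hill(state, (3.0, 0.0), t=0.2, temperature=300.0)
    assert bias_value(state, 3.0, 0.0) == pytest.approx(1.3, rel=1e-12)


def test_two_identical_hills_double_the_bias():
    state = BiasState()
    for t in (0.2, 0.4):
        deposit_hill(state, (3.0, 0.5), t, 300.0)
    one = BiasState()
    deposit_hill(one, (3.0, 0.5), 0.2, 300.0)
    z = np.linspace(2.0, 4.0, 50)
    assert np.allclose(bias_value(state, z, 0.5),
                       2 * bias_value(one, z, 0.5), rtol=1e-12)


def test_well_tempered_second_hill_height_closed_form():
    T, bf = 300.0, 10.0
    state = BiasState(w0=1.0, biasfactor=bf)
    deposit_hill(state, (3.0, 0.0), 0.2, T)
    deposit_hill(state, (3.0, 0.0), 0.4, T)
    dT = (bf - 1) * T
    expected = 1.0 * np.exp(-1.0 / (KB * dT))
    assert state.hills[1].height == pytest.approx(expected, rel=1e-10)


def test_gaussian_tail_bound_at_five_sigma():
    state = BiasState(w0=2.0, sigma_z=0.2)
    deposit_hill(state, (5.0, 0.0), 0.1, 300.0)
    v = bias_value(state, 5.0 + 5 * 0.2, 0.0)
    assert v < 4e-6 * 2.0


def test_gamma_periodicity():
    state = BiasState()
    deposit_hill(state, (3.0, 2.9), 0.1, 300.0)
    g = np.linspace(-np.pi, np.pi, 17)
    assert np.allclose(bias_value(state, 3.2, g),
                       bias_value(state, 3.2, g + 2 * np.pi), rtol=1e-12)


def test_no_hills_bias_and_gradient_are_zero():
    state = BiasState()
    z = np.linspace(2, 10, 11)
    assert np.all(bias_value(state, z, 0.0) == 0.0)
    gz, gg = bias_gradient(state, z, 0.0)
    assert np.all(gz == 0.0) and np.all(gg == 0.0)


def test_gradient_matches_finite_differences():
    rng = np.random.default_rng(3)
    state = BiasState()
    for _ in range(30):
        deposit_hill(state, (rng.uniform(2, 8), rng.uniform(-3, 3)),
                     rng.uniform(0, 1), 300.0)
    z = rng.uniform(2.2, 7.8, 200)
    g = rng.uniform(-3, 3, 200)
    gz, gg = bias_gradient(state, z, g)
    h = 1e-6
    fd_z = (bias_value(state, z + h, g) - bias_value(state, z - h, g)) \
        / (2 * h)
    fd_g = (bias_value(state, z, g + h) - bias_value(state, z, g - h)) \
        / (2 * h)
    scale = np.abs(gz) + np.abs(gg) + 1.0
    assert np.max(np.abs(gz - fd_z) / scale) < 1e-6
    assert np.max(np.abs(gg - fd_g) / scale) < 1e-6


def test_nonpositive_base_height_rejected():
    with pytest.raises(ParameterError):
        BiasState(w0=0.0)
    with pytest.raises(ParameterError):
        BiasState(w0=-1.0)


def test_empty_hill_list_gives_flat_estimate():
    z = np.linspace(2, 10, 81)
    prof = metad_pmf_estimate(BiasState(), z, 300.0)
    assert np.all(prof.A == 0.0)


def test_single_hill_projection_matches_dense_quadrature():
    """Trapezoid γ-projection of one hill vs an independent high-order
    quadrature of the same integrand."""
    from scipy.integrate import quad
    state = BiasState(w0=1.7, sigma_z=0.3, sigma_gamma=0.4)
    deposit_hill(state, (4.0, 0.8), 0.1, 300.0)
    T = 300.0
    kT = KB * T
    z_grid = np.linspace(2.0, 10.0, 81)
    prof = metad_pmf_estimate(state, z_grid, T, n_gamma=256)

    def integrand(g, z):
        dg = (g - 0.8 + np.pi) % (2 * np.pi) - np.pi
        v = 1.7 * np.exp(-0.5 * ((z - 4.0) / 0.3) ** 2
                         - 0.5 * (dg / 0.4) ** 2)
        return np.exp(v / kT)

    ref = []
    for z in z_grid:
        val, _ = quad(integrand, -np.pi, np.pi, args=(z,), limit=200,
                      epsabs=1e-13, epsrel=1e-13)
        ref.append(-kT * np.log(val / (2 * np.pi)))
    ref = np.array(ref)
    mask = (z_grid >= 8.0)
    ref -= ref[mask].mean()
    assert np.abs(prof.A - ref).max() < 1e-8


def test_gamma_independent_bias_projects_to_minus_v():
    """For a γ-independent bias the estimate is −V up to a constant
    (the separable-projection identity)."""
    state = BiasState(use_gamma=False)
    rng = np.random.default_rng(8)
    for _ in range(20):
        deposit_hill(state, (rng.uniform(2.5, 7.5), 0.0),
                     rng.uniform(0, 1), 300.0)
    z = np.linspace(2.0, 10.0, 161)
    prof = metad_pmf_estimate(state, z, 300.0)
    v = bias_value(state, z, 0.0)
    resid = prof.A + v
    assert np.ptp(resid) < 1e-8


def test_bias_nonnegative_and_finite():
    rng = np.random.default_rng(1)
    state = BiasState()
    for _ in range(100):
        deposit_hill(state, (rng.uniform(2, 9), rng.uniform(-3, 3)),
                     rng.uniform(0, 10), 300.0)
    z = rng.uniform(2, 10, 500)
    g = rng.uniform(-np.pi, np.pi, 500)
    v = bias_value(state, z, g)
    assert np.all(v >= 0) and np.all(np.isfinite(v))


def test_grid_cache_agrees_with_exact_summation():
    rng = np.random.default_rng(5)
    state = BiasState()
    for _ in range(40):
        deposit_hill(state, (rng.uniform(2.5, 8.5), rng.uniform(-3, 3)),
                     rng.uniform(0, 4), 300.0)
    cache = state.grid_cache(2.0, 10.0)
    z = rng.uniform(2.1, 9.9, 300)
    g = rng.uniform(-np.pi, np.pi, 300)
    assert np.abs(cache.value(z, g) - bias_value(state, z, g)).max() < 1e-6


def test_hills_file_roundtrip():
    state = BiasState(w0=0.8)
    rng = np.random.default_rng(2)
    for i in range(15):
        deposit_hill(state, (rng.uniform(2, 9), rng.uniform(-3, 3)),
                     0.1 * (i + 1), 300.0)
    buf = io.StringIO()
    state.to_hills_file(buf)
    buf.seek(0)
    back = BiasState.from_hills_file(buf, w0=0.8)
    assert back.n_hills == state.n_hills
    for a, b in zip(state.hills, back.hills):
        assert a.z == pytest.approx(b.z, rel=1e-9)
        assert a.height == pytest.approx(b.height, rel=1e-9)
    z = np.linspace(2, 10, 50)
    # 10 significant digits in the file; the Gaussian exponent amplifies
    # center rounding by ~|Δz|·dist/σ², so compare at 1e-5 relative
    assert np.allclose(bias_value(back, z, 0.3),
                       bias_value(state, z, 0.3), rtol=1e-5, atol=1e-12)
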