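"""Force binning, bias reweighting and thermodynamic integration."""

import numpy as np
import pytest

from metadf import (BiasState, CVTrace, MeanForceAccumulator,
                    SamplerConfig, accumulate_mean_force, integrate_pmf,
                    run_sampler, pmf_rmse)
from metadf.profiles import MeanForceProfile
from metadf.exceptions import (ConsistencyError, EmptyProfileError,
                               GapError, ParameterError)


def _trace(z, f, vb=None, walker=0, T=300.0):
    z = np.asarray(z, dtype=float)
    n = z.size
    vb = np.zeros(n) if vb is None else np.asarray(vb, dtype=float)
    return CVTrace(0.002 * np.arange(1, n + 1), z, np.zeros(n),
                   np.asarray(f, dtype=float), vb, walker, T)


def test_constant_force_recovered_exactly():
    z = np.linspace(2.05, 9.95, 500)
    prof = accumulate_mean_force([_trace(z, np.full(500, 3.25))],
                                 weighting="uniform",
                                 equilibration_fraction=0.0)
    assert np.all(prof.mean_force[~prof.empty] == 3.25)
    assert prof.ess[~prof.empty].max() <= prof.count[~prof.empty].max()


def test_incremental_equals_concatenated_bitwise():
    rng = np.random.default_rng(0)
    z1, z2 = rng.uniform(2, 10, 400), rng.uniform(2, 10, 300)
    f1, f2 = rng.normal(size=400), rng.normal(size=300)
    v1, v2 = rng.uniform(0, 5, 400), rng.uniform(0, 5, 300)
    edges = np.arange(2.0, 10.01, 0.1)
    inc = MeanForceAccumulator(edges, "bias")
    inc.add(_trace(z1, f1, v1, walker=0))
    inc.add(_trace(z2, f2, v2, walker=1))
    one = MeanForceAccumulator(edges, "bias")
    one.add(_trace(np.concatenate([z1, z2]), np.concatenate([f1, f2]),
                   np.concatenate([v1, v2])))
    a, b = inc.profile(), one.profile()
    assert np.array_equal(a.mean_force, b.mean_force)
    assert np.array_equal(a.ess, b.ess)
    assert np.array_equal(a.count, b.count)


def test_bias_weighting_reduces_to_uniform_without_bias():
    rng = np.random.default_rng(4)
    z = rng.uniform(2, 10, 1000)
    f = rng.normal(size=1000)
    a = accumulate_mean_force([_trace(z, f)], weighting="bias",
                              equilibration_fraction=0.0)
    b = accumulate_mean_force([_trace(z, f)], weighting="uniform",
                              equilibration_fraction=0.0)
    assert np.allclose(a.mean_force, b.mean_force, rtol=1e-12)


def test_temperature_mismatch_rejected():
    acc = MeanForceAccumulator(np.arange(2.0, 10.1, 0.1), "uniform")
    acc.add(_trace([3.0], [1.0], T=300.0))
    with pytest.raises(ConsistencyError):
        acc.add(_trace([3.0], [1.0], T=310.0))


def test_empty_accumulation_raises():
    acc = MeanForceAccumulator(np.arange(2.0, 10.1, 0.1), "uniform")
    with pytest.raises(EmptyProfileError):
        acc.profile()
    # samples entirely out of range count as empty too
    acc.add(_trace([0.5, 11.0], [1.0, 1.0]))
    with pytest.raises(EmptyProfileError):
        acc.profile()


def test_equilibration_fraction_discards_leading_samples():
    z = np.concatenate([np.full(50, 2.55), np.full(50, 7.55)])
    f = np.concatenate([np.full(50, 1.0), np.full(50, 2.0)])
    prof = accumulate_mean_force([_trace(z, f)], weighting="uniform",
                                 equilibration_fraction=0.5)
    assert prof.count.sum() == 50
    assert prof.mean_force[prof.count > 0][0] == 2.0


def test_integrate_zero_force_gives_zero_pmf():
    edges = np.arange(2.0, 10.01, 0.1)
    n = edges.size - 1
    prof = MeanForceProfile(edges, np.zeros(n), np.ones(n), np.ones(n))
    pmf = integrate_pmf(prof)
    assert np.abs(pmf.A).max() < 1e-12


def test_integrate_constant_force_gives_linear_pmf():
    edges = np.arange(2.0, 10.01, 0.1)
    n = edges.size - 1
    fmag = 1.7
    prof = MeanForceProfile(edges, np.full(n, -fmag), np.ones(n),
                            np.ones(n))
    pmf = integrate_pmf(prof)
    a, b = pmf.z[0], pmf.z[-1]
    assert pmf.interp(b) - pmf.interp(a) == pytest.approx(
        fmag * (b - a), rel=1e-12)
    slope = np.diff(pmf.A) / np.diff(pmf.z)
    assert np.allclose(slope, fmag, rtol=1e-9)


def test_exact_gradient_sampling_recovers_landscape(land1d):
    """Mean forces taken exactly from −dA/dz on 0.05 Å bins integrate
    back to the landscape within 0.05 kJ/mol everywhere."""
    edges = np.arange(2.0, 10.0001, 0.05)
    centers = 0.5 * (edges[:-1] + edges[1:])
    f = -land1d.gradient(centers)[0]
    n = centers.size
    prof = MeanForceProfile(edges, f, np.ones(n), np.ones(n))
    pmf = integrate_pmf(prof, reference_window=(8.0, 10.0))
    exact = land1d.exact_pmf(centers)
    assert np.abs(pmf.A - exact.A).max() < 0.05


def test_gap_error_names_interval():
    edges = np.arange(2.0, 10.01, 0.1)
    n = edges.size - 1
    count = np.ones(n)
    count[20:30] = 0  # a 10-bin hole
    prof = MeanForceProfile(edges, np.zeros(n), count, count)
    with pytest.raises(GapError) as exc:
        integrate_pmf(prof, max_gap_bins=5)
    lo, hi = exc.value.interval
    assert 3.9 < lo < 4.2 and 4.8 < hi < 5.1


def test_short_gaps_interpolated():
    edges = np.arange(2.0, 10.01, 0.1)
    n = edges.size - 1
    count = np.ones(n)
    count[30:33] = 0
    f = np.full(n, -2.0)
    prof = MeanForceProfile(edges, np.where(count > 0, f, 0.0), count,
                            count)
    pmf = integrate_pmf(prof, max_gap_bins=5)
    slope = np.diff(pmf.A) / np.diff(pmf.z)
    assert np.allclose(slope, 2.0, rtol=1e-9)


def test_unbiased_uniform_estimator_consistency(shallow1d):
    """On a shallow 1-D landscape, uniform weighting of unbiased samples
    converges to the landscape (RMSE < 0.5 kJ/mol at 10^6 samples)."""
    cfg = SamplerConfig(n_steps=125_000, n_walkers=8, friction=0.5,
                        seed=17,
                        initial_positions=[(2.4 + 0.4 * w, 0.0)
                                           for w in range(8)])
    traces, _ = run_sampler(shallow1d, None, cfg)
    assert sum(len(t) for t in traces) == 10 ** 6
    prof = accumulate_mean_force(traces, bin_width=0.1,
                                 weighting="uniform",
                                 equilibration_fraction=0.1,
                                 z_range=(2.0, 7.0))
    pmf = integrate_pmf(prof, reference_window=(5.8, 6.8))
    exact = shallow1d.exact_pmf(pmf.z)
    exact = type(exact)(exact.z, exact.A, (5.8, 6.8),
                        "exact").bulk_referenced()
    assert pmf_rmse(pmf, exact, (2.1, 5.5)) < 0.5


def test_bias_weighting_beats_uniform_on_biased_run():
    """Once the bias has filled the surface (late-run samples only, a
    strongly γ-coupled landscape), only the bias-weighted mean force
    converges to −dA/dz of the exact PMF: uniform weighting averages
    −∂U/∂z over a flat γ-distribution and misses the γ-entropy, so its
    RMSE is measurably larger."""
    from metadf import make_glycine_landscape
    land = make_glycine_landscape(c_gamma=6.0)
    cfg = SamplerConfig(n_steps=60_000, n_walkers=4, seed=23)
    traces, _ = run_sampler(land, BiasState(), cfg)
    ref = (8.0, 10.0)
    exact = land.exact_pmf(np.arange(2.05, 10.0, 0.1))
    rmses = {}
    for mode in ("bias", "uniform"):
        prof = accumulate_mean_force(traces, weighting=mode,
                                     equilibration_fraction=0.5)
        pmf = integrate_pmf(prof, reference_window=ref,
                            strict_reference=False)
        rmses[mode] = pmf_rmse(pmf, exact, (2.0, 6.7))
    assert rmses["bias"] < 1.0
    assert rmses["uniform"] > 1.5 * rmses["bias"]


def test_invalid_weighting_mode_rejected():
    with pytest.raises(ParameterError):
        MeanForceAccumulator(np.arange(2, 10.1, 0.1), "nope")
    with pytest.raises(ParameterError):
        MeanForceAccumulator(np.arange(2, 10.1, 0.1), "final")
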