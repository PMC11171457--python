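"""Langevin sampler: determinism, thermostat correctness, walls, I/O."""

import io

import numpy as np
import pytest
from scipy import stats

from conftest import flat_landscape, single_well_landscape
from metadf import (BiasState, SamplerConfig, run_sampler, write_colvar,
                    read_colvar)
from metadf.constants import KB
from metadf.exceptions import ParameterError


@pytest.mark.parametrize("bad", [
    dict(timestep=0.0),
    dict(friction=-1.0),
    dict(mass_z=0.0),
    dict(equilibration_fraction=1.0),
    dict(n_walkers=0),
])
def test_invalid_sampler_config_rejected(bad):
    with pytest.raises(ParameterError):
        SamplerConfig(**bad)


def test_zero_temperature_stays_at_minimum():
    """At T = 0 with zero initial velocity a walker parked at the well
    bottom must not move."""
    from scipy.optimize import brentq
    land = single_well_landscape(depth=100.0, width=0.5)
    zmin = brentq(lambda z: land.gradient(z)[0], 2.5, 3.1, xtol=1e-14)
    cfg = SamplerConfig(n_steps=2000, n_walkers=1, temperature=0.0,
                        seed=4, initial_positions=[(zmin, 0.0)])
    traces, _ = run_sampler(land, None, cfg)
    assert np.abs(traces[0].z - zmin).max() < 1e-6


def test_equipartition_variance_in_deep_well():
    """Sample variance of z in a stiff near-harmonic well matches the
    equipartition value kBT/k within 3 standard errors (k = depth/width²
    for a Gaussian well)."""
    depth, width = 1000.0, 1.0
    land = single_well_landscape(depth=depth, width=width)
    T = 300.0
    cfg = SamplerConfig(n_steps=200_000, n_walkers=1, temperature=T,
                        seed=7, initial_positions=[(2.8, 0.0)])
    traces, _ = run_sampler(land, None, cfg)
    z = traces[0].z[20_000:]
    var = z.var()
    expected = KB * T / (depth / width ** 2)
    # standard error via block averaging (20 blocks)
    blocks = np.array_split(z, 20)
    bvars = np.array([b.var() for b in blocks])
    se = bvars.std(ddof=1) / np.sqrt(len(blocks))
    assert abs(var - expected) < 3 * se


def test_flat_landscape_histogram_is_uniform():
    """With U ≡ 0 between the soft walls the stationary distribution of z
    is uniform (chi-square GOF, α = 0.01, on decorrelated samples)."""
    land = flat_landscape(z_wall=5.0, switch_on=4.0, switch_off=4.5)
    cfg = SamplerConfig(n_steps=250_000, n_walkers=8, friction=0.5,
                        temperature=300.0, seed=12,
                        initial_positions=[(2.0 + 0.3 * w, 0.0)
                                           for w in range(8)])
    traces, _ = run_sampler(land, None, cfg)
    # decorrelation: diffusive crossing of the ~4 Å box takes ~0.8 ps
    # (400 steps) at this friction; thin far beyond that
    thin = 2500
    z = np.concatenate([t.z[5000::thin] for t in traces])
    lo, hi = 2.0, 4.0  # interior, away from the soft wall tails
    sel = z[(z >= lo) & (z < hi)]
    counts, _ = np.histogram(sel, bins=8, range=(lo, hi))
    assert sel.size > 300
    res = stats.chisquare(counts)
    assert res.pvalue > 0.01


def test_stationary_density_matches_boltzmann(shallow1d):
    """Detailed-balance proxy: binned occupation of an unbiased run on a
    shallow landscape matches exp(−A/kBT) (chi-square on decorrelated
    samples from ≥10^6 recorded)."""
    T = 300.0
    cfg = SamplerConfig(n_steps=150_000, n_walkers=8, friction=0.5,
                        temperature=T, seed=21,
                        initial_positions=[(2.5 + 0.4 * w, 0.0)
                                           for w in range(8)])
    traces, _ = run_sampler(shallow1d, None, cfg)
    thin = 2500
    z = np.concatenate([t.z[5000::thin] for t in traces])
    lo, hi = 2.0, 5.5
    sel = z[(z >= lo) & (z < hi)]
    edges = np.linspace(lo, hi, 11)
    counts, _ = np.histogram(sel, bins=edges)
    # expected probabilities from fine quadrature of the landscape
    zf = np.linspace(lo, hi, 3501)
    w = np.exp(-shallow1d.value(zf) / (KB * T))
    p = np.array([np.trapezoid(w[(zf >= a) & (zf <= b)],
                               zf[(zf >= a) & (zf <= b)])
                  for a, b in zip(edges[:-1], edges[1:])])
    p /= p.sum()
    res = stats.chisquare(counts, f_exp=p * counts.sum())
    assert res.pvalue > 0.01


def test_determinism_and_walker_substreams(land2d):
    cfg = SamplerConfig(n_steps=3000, n_walkers=3, seed=5)
    t1, b1 = run_sampler(land2d, BiasState(), cfg)
    t2, b2 = run_sampler(land2d, BiasState(), cfg)
    for a, b in zip(t1, t2):
        assert np.array_equal(a.z, b.z)
        assert np.array_equal(a.f_phys, b.f_phys)
    assert [h.height for h in b1.hills] == [h.height for h in b2.hills]
    # walkers are not clones of each other
    assert not np.array_equal(t1[0].z, t1[1].z)


def test_wall_containment(land2d):
    cfg = SamplerConfig(n_steps=50_000, n_walkers=2, seed=9)
    traces, _ = run_sampler(land2d, BiasState(), cfg)
    for t in traces:
        assert t.z.max() <= land2d.params.z_wall + 1.0
        assert t.z.min() > 0.0


def test_input_bias_state_not_mutated(land2d):
    bias = BiasState()
    cfg = SamplerConfig(n_steps=1000, n_walkers=1, seed=2)
    _, final = run_sampler(land2d, bias, cfg)
    assert bias.n_hills == 0
    assert final.n_hills == 10  # 1000 steps / stride 100


def test_f_phys_excludes_bias_and_wall(land2d):
    """Recorded physical force equals the landscape gradient at the
    recorded coordinates, even under a strong bias."""
    cfg = SamplerConfig(n_steps=2000, n_walkers=1, seed=3)
    traces, _ = run_sampler(land2d, BiasState(w0=3.0), cfg)
    t = traces[0]
    inside = (t.z > land2d.params.r_c) & (t.z < land2d.params.z_wall)
    dz, _ = land2d.gradient(t.z[inside], t.gamma[inside])
    assert np.allclose(t.f_phys[inside], -dz, rtol=1e-10, atol=1e-10)


def test_colvar_roundtrip(land2d):
    cfg = SamplerConfig(n_steps=500, n_walkers=2, seed=6)
    traces, _ = run_sampler(land2d, BiasState(), cfg)
    buf = io.StringIO()
    write_colvar(traces, buf, {"note": "test"})
    buf.seek(0)
    back = read_colvar(buf)
    assert len(back) == 2
    for a, b in zip(traces, back):
        assert b.walker == a.walker
        assert b.temperature == a.temperature
        assert np.allclose(a.z, b.z, rtol=1e-9)
        assert np.allclose(a.f_phys, b.f_phys, rtol=1e-9)


def test_colvar_reader_tolerates_comments_and_rejects_garbage():
    text = ("# a comment\n#! FIELDS time z gamma f_phys bias walker\n"
            "# temperature: 310\n"
            "0.002 3.0 0.1 -1.2 0.0 0\n0.004 3.1 0.2 -1.1 0.0 0\n")
    tr = read_colvar(io.StringIO(text))
    assert len(tr) == 1 and tr[0].temperature == 310.0
    with pytest.raises(ParameterError, match="line"):
        read_colvar(io.StringIO("0.1 2.0 3.0\n"))
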