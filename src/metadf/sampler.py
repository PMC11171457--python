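"""Langevin dynamics on the (z, γ) collective-variable space.

A BAOAB-split underdamped Langevin integrator evolves one or more walkers
under the total force −∇(landscape + bias + walls), while the *physical*
force along z (landscape only — no bias, no wall contribution) and the
instantaneous bias value are recorded every step.  These on-the-fly
unbiased forces are the raw material of the force-integration PMF
estimator; recording them "before the correction added by the bias" is
the whole point of the scheme.

Walls: a one-sided harmonic restraint beyond ``z_wall`` (the 1 nm bulk
boundary) and a soft reflective harmonic below ``r_c − 0.5 Å``.  Walkers
advance in lock-step and share a single hill history; hill deposition
happens every ``bias.stride`` steps for every walker in walker order.

Determinism: the run is bit-for-bit reproducible for a fixed seed; each
walker draws its noise from an independent child stream of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from .bias import BiasState, Hill
from .constants import DEFAULT_TEMPERATURE, KB
from .exceptions import IntegrationError, ParameterError
from .landscape import ModelLandscape


@dataclass
class SamplerConfig:
    """Langevin sampler settings (ps, u, K; see package unit conventions).

    ``mass_gamma`` is an effective moment of inertia in u·Å².  ``initial_
    positions`` may be a list of (z, γ) pairs, one per walker; by default
    walkers start in the contact well with staggered angles.
    """

    n_steps: int = 100_000
    timestep: float = 0.002
    friction: float = 2.0
    mass_z: float = 50.0
    mass_gamma: float = 10.0
    temperature: float = DEFAULT_TEMPERATURE
    n_walkers: int = 4
    seed: int = 0
    equilibration_fraction: float = 0.1
    wall_stiffness: float = 500.0
    lower_wall_stiffness: float = 500.0
    initial_positions: list | None = None
    record_stride: int = 1

    def __post_init__(self):
        if self.timestep <= 0:
            raise ParameterError("timestep must be positive")
        if self.friction < 0:
            raise ParameterError("friction must be non-negative")
        if self.mass_z <= 0 or self.mass_gamma <= 0:
            raise ParameterError("masses must be positive")
        if not (0 <= self.equilibration_fraction < 1):
            raise ParameterError("equilibration fraction must be in [0, 1)")
        if self.n_walkers < 1 or self.n_steps < 1:
            raise ParameterError("n_steps and n_walkers must be >= 1")
        if self.initial_positions is not None and \
                len(self.initial_positions) != self.n_walkers:
            raise ParameterError("need one initial position per walker")

    def to_dict(self):
        d = asdict(self)
        if d["initial_positions"] is not None:
            d["initial_positions"] = [list(p) for p in d["initial_positions"]]
        return d


@dataclass
class CVTrace:
    """Recorded collective-variable time series for one walker.

    ``f_phys`` is the landscape-only force along z (kJ/mol/Å), excluding
    bias and wall contributions; ``v_bias`` the instantaneous bias energy
    at the recorded (z, γ).
    """

    time: np.ndarray
    z: np.ndarray
    gamma: np.ndarray
    f_phys: np.ndarray
    v_bias: np.ndarray
    walker: int
    temperature: float = DEFAULT_TEMPERATURE
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.time)
        for name in ("z", "gamma", "f_phys", "v_bias"):
            if len(getattr(self, name)) != n:
                raise ParameterError(f"column {name} has mismatched length")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ParameterError("times must be strictly increasing")

    def __len__(self):
        return len(self.time)

    def after_equilibration(self, fraction: float) -> "CVTrace":
        """Drop the leading ``fraction`` of the trace."""
        k = int(np.floor(fraction * len(self)))
        return CVTrace(self.time[k:], self.z[k:], self.gamma[k:],
                       self.f_phys[k:], self.v_bias[k:], self.walker,
                       self.temperature, dict(self.meta))


def run_sampler(landscape: ModelLandscape, bias: BiasState | None,
                config: SamplerConfig):
    """Integrate Langevin dynamics, returning traces and the final bias.

    Returns (list of CVTrace, one per walker; final BiasState).  When
    ``bias`` is None a plain unbiased run is performed and the returned
    bias state is None.  The input bias state is not mutated.
    """
    p = landscape.params
    nw = config.n_walkers
    n_steps = config.n_steps
    dt = config.timestep

    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(nw)]
    noise = np.empty((nw, n_steps, 2))
    for w, rng in enumerate(streams):
        noise[w] = rng.normal(size=(n_steps, 2))

    kT = KB * config.temperature
    z = np.empty(nw)
    g = np.empty(nw)
    vz = np.empty(nw)
    vg = np.empty(nw)
    for w, rng in enumerate(streams):
        if config.initial_positions is not None:
            z[w], g[w] = config.initial_positions[w]
        else:
            z[w] = p.z_M1
            g[w] = -np.pi + (2 * np.pi) * (w + 0.5) / nw
        vz[w] = rng.normal() * np.sqrt(kT * _kernels.EC / config.mass_z)
        vg[w] = rng.normal() * np.sqrt(kT * _kernels.EC / config.mass_gamma)

    # hill arrays: existing history plus capacity for this run
    if bias is not None:
        hz0, hg0, hsz0, hsg0, hh0 = bias._arrays()
        ht0 = np.array([h.time for h in bias.hills])
        stride = bias.stride
        cap = len(bias.hills) + (n_steps // stride + 1) * nw \
            if stride > 0 else max(len(bias.hills), 1)
        w0, sigz, sigg = bias.w0, bias.sigma_z, bias.sigma_gamma
        wt_dT = ((bias.biasfactor - 1.0) * config.temperature
                 if np.isfinite(bias.biasfactor) else 0.0)
    else:
        hz0 = hg0 = hsz0 = hsg0 = hh0 = ht0 = np.empty(0)
        stride = 0
        cap = 1
        w0, sigz, sigg, wt_dT = 1.0, 0.2, 0.25, 0.0
    hz = np.zeros(cap); hz[:len(hz0)] = hz0
    hg = np.zeros(cap); hg[:len(hg0)] = hg0
    hsz = np.ones(cap); hsz[:len(hsz0)] = hsz0
    hsg = np.ones(cap); hsg[:len(hsg0)] = hsg0
    hh = np.zeros(cap); hh[:len(hh0)] = hh0
    ht = np.zeros(cap); ht[:len(ht0)] = ht0

    n_rec = n_steps // config.record_stride
    rec_t = np.empty(n_rec)
    rec_z = np.empty((nw, n_rec))
    rec_g = np.empty((nw, n_rec))
    rec_f = np.empty((nw, n_rec))
    rec_vb = np.empty((nw, n_rec))
    rec_ht = np.empty(n_rec)

    n_hills, err = _kernels.run_sampler_kernel(
        n_steps, dt, config.friction, config.mass_z, config.mass_gamma, kT,
        z, g, vz, vg, noise,
        *landscape._kargs()[:9], landscape.ndim == 2,
        p.z_wall, config.wall_stiffness, p.r_c - 0.5,
        config.lower_wall_stiffness,
        stride, w0, sigz, sigg, wt_dT,
        hz, hg, hsz, hsg, hh, ht, len(hz0),
        config.record_stride,
        rec_t, rec_z, rec_g, rec_f, rec_vb, rec_ht)

    if err >= 0:
        raise IntegrationError(
            f"non-finite force at step {err}, positions z={z.tolist()}")

    traces = [CVTrace(rec_t.copy(), rec_z[w], rec_g[w], rec_f[w], rec_vb[w],
                      walker=w, temperature=config.temperature,
                      meta={"seed": config.seed, "n_steps": n_steps})
              for w in range(nw)]

    final_bias = None
    if bias is not None:
        final_bias = BiasState(
            w0=bias.w0, sigma_z=bias.sigma_z, sigma_gamma=bias.sigma_gamma,
            stride=bias.stride, biasfactor=bias.biasfactor,
            periodic_gamma=bias.periodic_gamma, use_gamma=bias.use_gamma)
        final_bias.hills = [Hill(hz[i], hg[i], hsz[i], hsg[i], hh[i], ht[i])
                            for i in range(n_hills)]
    return traces, final_bias


# -- COLVAR-style I/O ------------------------------------------------------

COLVAR_HEADER = "#! FIELDS time z gamma f_phys bias walker"


def write_colvar(traces, path_or_buf, header_extra: dict | None = None):
    """Write traces as a COLVAR-style whitespace table."""
    lines = [COLVAR_HEADER]
    if traces:
        lines.append(f"# temperature: {traces[0].temperature}")
    for k, v in (header_extra or {}).items():
        lines.append(f"# {k}: {v}")
    for tr in traces:
        for i in range(len(tr)):
            lines.append(f"{tr.time[i]:.6f} {tr.z[i]:.10g} "
                         f"{tr.gamma[i]:.10g} {tr.f_phys[i]:.10g} "
                         f"{tr.v_bias[i]:.10g} {tr.walker:d}")
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_colvar(path_or_buf, temperature: float | None = None):
    """Read a COLVAR-style table back into a list of CVTrace.

    Comment lines starting with '#' are tolerated; a ``# temperature:``
    line, when present, sets the trace temperature unless overridden.
    """
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    T = temperature
    rows = []
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#! ")
            if body.startswith("temperature:") and temperature is None:
                T = float(body.split(":", 1)[1])
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ParameterError(
                f"line {ln}: expected 6 columns, got {len(parts)}")
        rows.append([float(x) for x in parts])
    if not rows:
        raise ParameterError("no data rows in COLVAR file")
    arr = np.array(rows)
    T = DEFAULT_TEMPERATURE if T is None else T
    traces = []
    for w in sorted(set(arr[:, 5].astype(int))):
        sub = arr[arr[:, 5].astype(int) == w]
        traces.append(CVTrace(sub[:, 0], sub[:, 1], sub[:, 2], sub[:, 3],
                              sub[:, 4], walker=int(w), temperature=T))
    return traces
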