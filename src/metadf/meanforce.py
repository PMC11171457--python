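"""Force-integration PMF estimator (the MetaDF scheme).

The estimator bins the on-the-fly *unbiased* forces F_phys recorded along
the biased trajectories, forms per-bin canonical mean forces weighted on
the instantaneous metadynamics bias,

    ⟨F⟩(z_bin) = Σ_i w_i F_i / Σ_i w_i,   w_i = exp(+V_bias(x_i, t_i)/kBT),

and integrates them by thermodynamic integration,

    A(z) = −∫_{r_c}^{z} ⟨F(z′)⟩ dz′,

referenced so the bulk-window mean of A is zero.  The weight restores the
unbiased conditional average at fixed z from the biased ensemble and
reduces to uniform weighting when no bias is present; weights are
normalized within each z-bin, so only relative weights matter.  A
"uniform" mode (w ≡ 1) and a "final"-bias mode (weights from the frozen
end-of-run bias) are provided for comparison.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .constants import KB
from .exceptions import (BulkReferenceError, ConsistencyError,
                         EmptyProfileError, GapError, ParameterError)
from .profiles import MeanForceProfile, PMFProfile

WEIGHTING_MODES = ("bias", "uniform", "final")


class MeanForceAccumulator:
    """Streaming accumulator of per-bin weighted force statistics.

    Adding traces one at a time gives results identical bit-for-bit to a
    single accumulation over their concatenation (per-bin sums are updated
    in sample order).
    """

    def __init__(self, edges, weighting: str = "bias",
                 bias_state=None):
        edges = np.asarray(edges, dtype=float)
        if edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ParameterError("need increasing bin edges")
        if weighting not in WEIGHTING_MODES:
            raise ParameterError(f"unknown weighting mode {weighting!r}")
        if weighting == "final" and bias_state is None:
            raise ParameterError("'final' weighting needs a bias state")
        self.edges = edges
        self.weighting = weighting
        self.bias_state = bias_state
        n = edges.size - 1
        self.sum_w = np.zeros(n)
        self.sum_wf = np.zeros(n)
        self.sum_w2 = np.zeros(n)
        self.count = np.zeros(n, dtype=np.int64)
        self.temperature = None
        self.n_samples = 0

    def add(self, trace, equilibration_fraction: float = 0.0):
        """Accumulate one CVTrace (after discarding its leading fraction)."""
        if self.temperature is None:
            self.temperature = trace.temperature
        elif trace.temperature != self.temperature:
            raise ConsistencyError(
                f"trace temperature {trace.temperature} K does not match "
                f"accumulated {self.temperature} K")
        tr = trace.after_equilibration(equilibration_fraction) \
            if equilibration_fraction > 0 else trace
        if len(tr) == 0:
            return self
        kT = KB * self.temperature
        if self.weighting == "uniform":
            w = np.ones(len(tr))
        elif self.weighting == "bias":
            w = np.exp(np.minimum(tr.v_bias / kT, 700.0))
        else:  # final
            vfin = self.bias_state.value(tr.z, tr.gamma)
            w = np.exp(np.minimum(vfin / kT, 700.0))
        idx = np.digitize(tr.z, self.edges) - 1
        ok = (idx >= 0) & (idx < self.edges.size - 1)
        idx = idx[ok]
        np.add.at(self.sum_w, idx, w[ok])
        np.add.at(self.sum_wf, idx, w[ok] * tr.f_phys[ok])
        np.add.at(self.sum_w2, idx, w[ok] ** 2)
        np.add.at(self.count, idx, 1)
        self.n_samples += len(tr)
        return self

    def profile(self) -> MeanForceProfile:
        if self.n_samples == 0 or not self.count.any():
            raise EmptyProfileError(
                "no samples accumulated (all discarded or out of range)")
        with np.errstate(invalid="ignore", divide="ignore"):
            mf = np.where(self.sum_w > 0, self.sum_wf / self.sum_w, 0.0)
            ess = np.where(self.sum_w2 > 0,
                           self.sum_w ** 2 / self.sum_w2, 0.0)
        return MeanForceProfile(self.edges, mf, self.count.copy(), ess,
                                weighting=self.weighting,
                                temperature=self.temperature)


def accumulate_mean_force(traces, bin_width: float = 0.1,
                          weighting: str = "bias",
                          equilibration_fraction: float = 0.1,
                          z_range: tuple = (2.0, 10.0),
                          bias_state=None) -> MeanForceProfile:
    """Bin and weight the recorded physical forces from one or more traces.

    ``z_range`` defaults to the default landscape's [r_c, z_wall]; pass
    the actual landscape bounds for other geometries.
    """
    if bin_width <= 0:
        raise ParameterError("bin width must be positive")
    lo, hi = z_range
    n = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n + 1)
    acc = MeanForceAccumulator(edges, weighting, bias_state)
    for tr in traces:
        acc.add(tr, equilibration_fraction)
    return acc.profile()


def integrate_pmf(profile: MeanForceProfile,
                  reference_window: tuple | None = None,
                  max_gap_bins: int = 5,
                  strict_reference: bool = True) -> PMFProfile:
    """Thermodynamic integration of a mean-force profile.

    A(z) = −∫⟨F⟩dz′ by the trapezoid rule on bin centers.  Empty interior
    bins are linearly interpolated provided no empty run exceeds
    ``max_gap_bins``; leading/trailing empty bins are dropped.  The PMF is
    shifted so its mean over ``reference_window`` (default: the last 2 Å
    of the binned range) is zero.
    """
    centers = profile.centers
    filled = ~profile.empty
    if filled.sum() < 2:
        raise EmptyProfileError("need at least two non-empty bins")
    first, last = np.flatnonzero(filled)[[0, -1]]
    inner = slice(first, last + 1)
    gaps = _empty_runs(filled[inner])
    for start, length in gaps:
        if length > max_gap_bins:
            a = centers[first + start]
            b = centers[first + start + length - 1]
            raise GapError(
                f"empty-bin run of {length} bins in [{a:.3f}, {b:.3f}] Å "
                f"exceeds max_gap_bins={max_gap_bins}", interval=(a, b))
    zc = centers[inner]
    F = profile.mean_force[inner].copy()
    m = filled[inner]
    if not m.all():
        F[~m] = np.interp(zc[~m], zc[m], F[m])
    A = -cumulative_trapezoid(F, zc, initial=0.0)
    if reference_window is None:
        reference_window = (profile.edges[-1] - 2.0, profile.edges[-1])
    prof = PMFProfile(zc, A, reference_window, "metadf")
    try:
        return prof.bulk_referenced()
    except BulkReferenceError:
        if strict_reference:
            raise
        # sampling never reached the bulk: anchor the covered end to zero
        return PMFProfile(zc, A - A[-1], reference_window, "metadf")


def _empty_runs(filled_mask):
    """(start, length) of runs of False in the mask."""
    runs = []
    start = None
    for i, f in enumerate(filled_mask):
        if not f and start is None:
            start = i
        elif f and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(filled_mask) - start))
    return runs
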