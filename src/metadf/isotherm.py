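"""Langmuir analysis of impedance-derived adsorption isotherms.

The experimental route to the adsorption free energy: the charge-transfer
resistance R_ct of a redox probe on an oxide-coated electrode grows with
the amount of adsorbate blocking the surface, so the fractional coverage
is the affine rescaling

    Θ(C) = (R_ct − R_ct0) / (R_ct∞ − R_ct0),

with R_ct0 the adsorbate-free (blank) value and R_ct∞ the saturation
asymptote.  Coverage follows the Langmuir isotherm Θ = K·C/(1 + K·C); the
raw R_ct data of all replicates are fitted jointly by nonlinear least
squares with K and (unless supplied) R_ct∞ free and R_ct0 fixed from the
blank.  The free energy then follows from the equilibrium constant via

    ΔG = −R·T·ln(K·C°),  C° = 1 mol/L (molar standard state).

Uncertainty is quantified by a seeded residual bootstrap plus
Jacobian-based standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import R_GAS
from .exceptions import (DegenerateScaleError, FitError, ParameterError)

DEFAULT_EIS_TEMPERATURE = 298.15  # K, ambient electrochemical cell


@dataclass
class IsothermData:
    """R_ct vs concentration replicates.

    ``rct`` has one row per replicate, one column per concentration
    (mol/L, strictly increasing).  ``rct0`` is the blank (oxide-coated,
    adsorbate-free) charge-transfer resistance in Ω.
    """

    concentrations: np.ndarray
    rct: np.ndarray
    rct0: float
    rct_inf: float | None = None
    temperature: float = DEFAULT_EIS_TEMPERATURE

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rct = np.atleast_2d(np.asarray(self.rct, dtype=float))
        c = self.concentrations
        if np.unique(c).size < 4:
            raise ParameterError("need at least 4 distinct concentrations")
        if np.any(c <= 0) or not np.all(np.diff(c) > 0):
            raise ParameterError(
                "concentrations must be positive and strictly increasing")
        if self.rct.shape[1] != c.size:
            raise ParameterError("R_ct matrix does not match concentrations")
        if not np.all(np.isfinite(self.rct)) or not np.isfinite(self.rct0):
            raise ParameterError("non-finite R_ct entries")
        if self.rct0 < 0:
            raise ParameterError("blank R_ct0 must be >= 0")

    @property
    def n_replicates(self) -> int:
        return self.rct.shape[0]


@dataclass
class LangmuirFitResult:
    """Fitted Langmuir parameters with bootstrap uncertainty."""

    K: float                    # 1/M
    dg: float                   # kJ/mol
    rct_inf: float              # Ω
    rss: float                  # Ω²
    ci_K: tuple                 # 95% bootstrap CI, 1/M
    ci_dg: tuple                # 95% bootstrap CI, kJ/mol
    se_K: float                 # Jacobian-based SE
    n_replicates: int
    n_bootstrap: int
    rct_inf_below_max: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.K <= 0:
            raise FitError("fitted K must be positive")
        if self.ci_K[0] > self.ci_K[1] or self.ci_dg[0] > self.ci_dg[1]:
            raise FitError("CI bounds out of order")


def theta_from_rct(data: IsothermData, rct_inf: float):
    """Coverage Θ per replicate/concentration from the affine R_ct scale.

    Returns (theta, outside_mask); values outside [0, 1] are retained —
    they are legitimate noise — but flagged in the mask.
    """
    if rct_inf == data.rct0:
        raise DegenerateScaleError(
            "R_ct∞ equals the blank R_ct0; coverage scale is degenerate")
    theta = (data.rct - data.rct0) / (rct_inf - data.rct0)
    outside = (theta < 0) | (theta > 1)
    return theta, outside


def langmuir_rct(C, K, rct0, rct_inf):
    """Langmuir-shaped R_ct response."""
    C = np.asarray(C, dtype=float)
    return rct0 + (rct_inf - rct0) * K * C / (1.0 + K * C)


def dg_from_k(K: float, temperature: float = DEFAULT_EIS_TEMPERATURE
              ) -> float:
    """ΔG = −R·T·ln(K·C°) with C° = 1 M, in kJ/mol."""
    if K <= 0:
        raise ParameterError("equilibrium constant K must be positive")
    return float(-R_GAS * temperature * np.log(K))


def _fit_once(C, R, rct0, x0, fix_rct_inf=None):
    """Least squares in (lnK, R_ct∞); returns the scipy result."""
    if fix_rct_inf is None:
        def resid(x):
            return langmuir_rct(C, np.exp(x[0]), rct0, x[1]) - R
    else:
        def resid(x):
            return langmuir_rct(C, np.exp(x[0]), rct0, fix_rct_inf) - R
        x0 = x0[:1]
    return least_squares(resid, x0, method="lm", max_nfev=2000)


def fit_langmuir(data: IsothermData, n_bootstrap: int = 2000,
                 seed: int = 0, n_starts: int = 8) -> LangmuirFitResult:
    """Pooled-replicate Langmuir fit of raw R_ct data.

    All replicates are fitted jointly with a single K; R_ct0 is fixed
    from the blank and R_ct∞ is free unless ``data.rct_inf`` is given.
    Multi-start (log-spaced K) nonlinear least squares, then a seeded
    residual bootstrap for the K and ΔG confidence intervals.
    """
    C = np.tile(data.concentrations, data.n_replicates)
    R = data.rct.ravel()
    fix = data.rct_inf
    rinf0 = fix if fix is not None else 1.05 * R.max()

    best = None
    for lnk in np.log(np.logspace(2, 8, n_starts)):
        try:
            res = _fit_once(C, R, data.rct0, np.array([lnk, rinf0]), fix)
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError(
            f"Langmuir fit failed to converge from {n_starts} starts "
            f"(C range {C.min():.3g}–{C.max():.3g} M)")

    K = float(np.exp(best.x[0]))
    rct_inf = float(fix if fix is not None else best.x[1])
    fitted = langmuir_rct(C, K, data.rct0, rct_inf)
    residuals = R - fitted
    rss = float(np.sum(residuals ** 2))

    # Jacobian-based SE of lnK -> K
    dof = max(len(R) - best.x.size, 1)
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        se_K = float(np.sqrt(cov[0, 0]) * K)  # delta method on lnK
    except np.linalg.LinAlgError:
        se_K = np.nan

    if n_bootstrap == 0:
        # Jacobian-only uncertainty (fast path for simulation sweeps)
        half = 1.96 * (se_K if np.isfinite(se_K) else 0.0)
        lo, hi = max(K - half, 1e-300), K + half
        dgs = sorted(dg_from_k(k, data.temperature) for k in (lo, hi))
        return LangmuirFitResult(
            K=K, dg=dg_from_k(K, data.temperature), rct_inf=rct_inf,
            rss=rss, ci_K=(float(lo), float(hi)),
            ci_dg=(dgs[0], dgs[1]), se_K=se_K,
            n_replicates=data.n_replicates, n_bootstrap=0,
            rct_inf_below_max=bool(rct_inf < R.max()),
            meta={"seed": seed, "rct0": data.rct0,
                  "temperature": data.temperature,
                  "rct_inf_fixed": fix is not None})

    rng = np.random.default_rng(seed)
    ks = np.empty(n_bootstrap)
    x0 = best.x.copy()
    for b in range(n_bootstrap):
        Rb = fitted + rng.choice(residuals, size=residuals.size,
                                 replace=True)
        try:
            resb = _fit_once(C, Rb, data.rct0, x0, fix)
            ks[b] = np.exp(resb.x[0])
        except Exception:
            ks[b] = np.nan
    ks = ks[np.isfinite(ks)]
    if ks.size < max(10, n_bootstrap // 10):
        raise FitError("residual bootstrap failed on most draws")
    lo, hi = np.percentile(ks, [2.5, 97.5])
    dgs = np.array([dg_from_k(k, data.temperature) for k in (hi, lo)])

    return LangmuirFitResult(
        K=K, dg=dg_from_k(K, data.temperature), rct_inf=rct_inf, rss=rss,
        ci_K=(float(lo), float(hi)),
        ci_dg=(float(min(dgs)), float(max(dgs))),
        se_K=se_K, n_replicates=data.n_replicates,
        n_bootstrap=int(ks.size),
        rct_inf_below_max=bool(rct_inf < R.max()),
        meta={"seed": seed, "rct0": data.rct0,
              "temperature": data.temperature,
              "rct_inf_fixed": fix is not None})


def fit_langmuir_per_replicate(data: IsothermData, **kwargs):
    """Diagnostic per-replicate fits (list of LangmuirFitResult)."""
    out = []
    for r in range(data.n_replicates):
        sub = IsothermData(data.concentrations, data.rct[r:r + 1],
                           data.rct0, data.rct_inf, data.temperature)
        out.append(fit_langmuir(sub, **kwargs))
    return out


def simulate_isotherm(K: float = 2.7e5, rct0: float = 200.0,
                      rct_inf: float = 1200.0,
                      concentrations=None,
                      noise: float = 0.02, replicates: int = 2,
                      seed: int = 0,
                      temperature: float = DEFAULT_EIS_TEMPERATURE
                      ) -> IsothermData:
    """Synthetic Langmuir-shaped R_ct response with replicate noise.

    Defaults emulate the experimental design: 12 log-spaced
    concentrations over 1–300 μM, two independent replicates,
    multiplicative Gaussian noise of relative sd ``noise``.
    """
    if K <= 0 or rct0 <= 0 or rct_inf <= 0 or noise < 0:
        raise ParameterError("K, R_ct values must be positive, noise >= 0")
    if concentrations is None:
        concentrations = np.logspace(np.log10(1e-6), np.log10(3e-4), 12)
    concentrations = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    mean = langmuir_rct(concentrations, K, rct0, rct_inf)
    rct = mean[None, :] * (1.0 + noise * rng.standard_normal(
        (replicates, concentrations.size)))
    return IsothermData(concentrations, rct, rct0, None, temperature)


# -- CSV I/O ---------------------------------------------------------------

def read_isotherm_csv(path, rct0: float | None = None,
                      temperature: float = DEFAULT_EIS_TEMPERATURE
                      ) -> IsothermData:
    """Read columns concentration_M, rct_ohm, replicate.

    Rows with concentration 0 provide the blank R_ct0 (averaged) unless
    ``rct0`` is passed explicitly.
    """
    df = pd.read_csv(path)
    required = {"concentration_M", "rct_ohm", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"isotherm CSV missing columns {missing}")
    blanks = df[df.concentration_M == 0]
    if rct0 is None:
        if blanks.empty:
            raise ParameterError(
                "no blank rows (concentration 0) and no rct0 given")
        rct0 = float(blanks.rct_ohm.mean())
    df = df[df.concentration_M > 0]
    conc = np.sort(df.concentration_M.unique())
    reps = np.sort(df.replicate.unique())
    rct = np.full((reps.size, conc.size), np.nan)
    for i, r in enumerate(reps):
        sub = df[df.replicate == r].sort_values("concentration_M")
        if not np.allclose(sub.concentration_M.to_numpy(), conc):
            raise ParameterError(
                f"replicate {r} does not cover all concentrations")
        rct[i] = sub.rct_ohm.to_numpy()
    return IsothermData(conc, rct, rct0, None, temperature)


def write_isotherm_csv(data: IsothermData, path):
    rows = [{"concentration_M": 0.0, "rct_ohm": data.rct0, "replicate": r}
            for r in range(data.n_replicates)]
    for r in range(data.n_replicates):
        for c, v in zip(data.concentrations, data.rct[r]):
            rows.append({"concentration_M": c, "rct_ohm": v,
                         "replicate": r})
    pd.DataFrame(rows).to_csv(path, index=False)
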