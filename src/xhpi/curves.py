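"""Two-state chemical denaturation: signal model, fitting, folding free energy.

A folded/unfolded equilibrium observed through a spectroscopic signal with
linear pre- and post-transition baselines:

    S(D) = (alpha_N + beta_N * D) * (1 - f_U) + (alpha_U + beta_U * D) * f_U
    f_U  = 1 / (1 + exp(-x)),   x = m * (D - D50) / (R * T)

where D is the denaturant concentration (M), m the denaturant dependence of
the folding free energy (kcal mol^-1 M^-1) and D50 the midpoint (M).  The
linear-extrapolation folding free energy is dG = m * D50 (positive = stable
folded state).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .constants import DEFAULT_TEMPERATURE, R_KCAL

__all__ = [
    "DenaturationCurve",
    "TwoStateFit",
    "FoldingEnergy",
    "NoTransitionError",
    "FitConvergenceError",
    "two_state_signal",
    "fit_two_state",
    "folding_free_energy",
    "bootstrap_folding_energy",
]

PARAM_NAMES = ("alpha_N", "beta_N", "alpha_U", "beta_U", "m_value", "d50")


class NoTransitionError(ValueError):
    """The data show no detectable sigmoidal folding transition."""


class FitConvergenceError(RuntimeError):
    """Nonlinear least squares failed; carries the initialization used."""

    def __init__(self, message: str, p0=None):
        super().__init__(message)
        self.p0 = None if p0 is None else tuple(p0)


@dataclass(frozen=True)
class DenaturationCurve:
    """One variant's melt: denaturant concentrations (M) vs signal."""

    variant_label: str
    denaturant: np.ndarray
    signal: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        d = np.asarray(self.denaturant, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if d.shape != s.shape or d.ndim != 1:
            raise ValueError("denaturant and signal must be 1-D arrays of equal length")
        if d.size < 8:
            raise ValueError(f"need >= 8 points, got {d.size}")
        if np.any(d < 0):
            raise ValueError("denaturant concentrations must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        object.__setattr__(self, "denaturant", d)
        object.__setattr__(self, "signal", s)

    @property
    def n_points(self) -> int:
        return self.denaturant.size


@dataclass(frozen=True)
class TwoStateFit:
    """Fitted two-state parameters with Jacobian-based covariance."""

    variant_label: str
    alpha_N: float
    beta_N: float
    alpha_U: float
    beta_U: float
    m_value: float
    d50: float
    covariance: np.ndarray  # 6x6, parameter order PARAM_NAMES
    residual_sd: float
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (6, 6):
            raise ValueError("covariance must be 6x6")
        if not np.allclose(cov, cov.T, atol=1e-8 * max(1.0, np.abs(cov).max())):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "covariance", cov)
        if self.m_value <= 0:
            raise ValueError("m_value must be positive after canonicalization")

    @property
    def parameters(self) -> np.ndarray:
        return np.array(
            [self.alpha_N, self.beta_N, self.alpha_U, self.beta_U, self.m_value, self.d50]
        )


@dataclass(frozen=True)
class FoldingEnergy:
    """Linear-extrapolation folding free energy dG = m * D50, kcal/mol."""

    variant_label: str
    dg: float
    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def two_state_signal(D, alpha_N, beta_N, alpha_U, beta_U, m_value, d50,
                     temperature=DEFAULT_TEMPERATURE):
    """Two-state signal with linear baselines.

    Numerically stable for arbitrarily large ``|m (D - d50) / RT|``: the
    unfolded fraction is evaluated with the logistic sigmoid, which saturates
    instead of overflowing.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    D = np.asarray(D, dtype=float)
    x = m_value * (D - d50) / (R_KCAL * temperature)
    f_u = special.expit(x)
    return (alpha_N + beta_N * D) * (1.0 - f_u) + (alpha_U + beta_U * D) * f_u


def _initial_guess(curve: DenaturationCurve):
    """Data-driven starting point: baselines from the outer 25% of points,
    midpoint from the half-unfolded crossing, m from the central logit slope."""
    order = np.argsort(curve.denaturant)
    d = curve.denaturant[order]
    s = curve.signal[order]
    n = d.size
    k = max(2, n // 4)
    bn, an = np.polyfit(d[:k], s[:k], 1)
    bu, au = np.polyfit(d[-k:], s[-k:], 1)
    base_n = an + bn * d
    base_u = au + bu * d
    span = base_u - base_n
    # avoid division blow-ups on featureless data
    tiny = 1e-12 * max(1.0, np.abs(s).max())
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(np.abs(span) > tiny, (s - base_n) / span, 0.5)
    f = np.clip(f, 1e-6, 1 - 1e-6)
    # midpoint: first crossing of f = 0.5, else median denaturant
    cross = np.nonzero(np.diff(np.sign(f - 0.5)))[0]
    if cross.size:
        i = cross[0]
        d50_0 = np.interp(0.5, [f[i], f[i + 1]], [d[i], d[i + 1]]) \
            if f[i + 1] != f[i] else d[i]
    else:
        d50_0 = float(np.median(d))
    d50_0 = float(np.clip(d50_0, d[0] + 1e-6, d[-1] - 1e-6)) if d[-1] > d[0] else d50_0
    # m from logit(f) slope on transition points
    rt = R_KCAL * curve.temperature
    sel = (f > 0.05) & (f < 0.95)
    m0 = 2.0
    if sel.sum() >= 2 and np.ptp(d[sel]) > 0:
        slope = np.polyfit(d[sel], np.log(f[sel] / (1 - f[sel])), 1)[0]
        if slope * rt > 0.05:
            m0 = float(slope * rt)
    return np.array([an, bn, au, bu, m0, d50_0])


def _canonicalize(popt, pcov):
    """Enforce m > 0.  The model is invariant under swapping the baselines
    together with m -> -m, so a negative-m solution is relabeled."""
    if popt[4] >= 0:
        return popt, pcov
    perm = [2, 3, 0, 1, 4, 5]          # swap N and U baselines
    flip = np.diag([1, 1, 1, 1, -1, 1]).astype(float)
    T = flip @ np.eye(6)[perm]
    return T @ popt, T @ pcov @ T.T


def fit_two_state(curve: DenaturationCurve, p0=None, max_nfev=20000) -> TwoStateFit:
    """Fit the six-parameter two-state model by nonlinear least squares.

    Raises :class:`NoTransitionError` when the fitted transition amplitude is
    indistinguishable from the residual noise (monotone / featureless data)
    and :class:`FitConvergenceError` on optimizer failure.
    """
    d, s, T = curve.denaturant, curve.signal, curve.temperature
    if p0 is None:
        p0 = _initial_guess(curve)
    p0 = np.asarray(p0, dtype=float)

    def model(dd, an, bn, au, bu, m, d50):
        return two_state_signal(dd, an, bn, au, bu, m, d50, temperature=T)

    try:
        popt, pcov = optimize.curve_fit(
            model, d, s, p0=p0, maxfev=max_nfev, method="lm"
        )
    except RuntimeError as exc:
        raise FitConvergenceError(
            f"two-state fit did not converge for {curve.variant_label!r} "
            f"(initialization {np.round(p0, 4).tolist()}): {exc}", p0=p0
        ) from exc

    popt, pcov = _canonicalize(popt, pcov)
    resid = s - model(d, *popt)
    dof = max(1, d.size - 6)
    residual_sd = float(np.sqrt(resid @ resid / dof))
    if not np.all(np.isfinite(pcov)):
        pcov = np.full((6, 6), np.nan)

    an, bn, au, bu, m, d50 = popt
    amplitude = abs((au + bu * d50) - (an + bn * d50))
    signal_span = np.ptp(s)
    if m <= 0 or not (amplitude > 3 * residual_sd and amplitude > 1e-9 * max(1.0, signal_span)):
        raise NoTransitionError(
            f"no sigmoidal transition detectable for {curve.variant_label!r}: "
            f"fitted amplitude {amplitude:.3g} vs residual sd {residual_sd:.3g}"
        )
    lo, hi = d.min(), d.max()
    if not (lo <= d50 <= hi):
        warnings.warn(
            f"fitted midpoint {d50:.3g} M outside observed range [{lo:g}, {hi:g}] M "
            f"for {curve.variant_label!r}", stacklevel=2)
    else:
        n_below = int(np.sum(d < d50))
        n_above = int(np.sum(d > d50))
        if min(n_below, n_above) < 3:
            warnings.warn(
                f"fewer than 3 points on one side of the midpoint for "
                f"{curve.variant_label!r} ({n_below} below, {n_above} above)",
                stacklevel=2)

    return TwoStateFit(
        variant_label=curve.variant_label,
        alpha_N=float(an), beta_N=float(bn), alpha_U=float(au), beta_U=float(bu),
        m_value=float(m), d50=float(d50),
        covariance=pcov, residual_sd=residual_sd, temperature=T,
    )


def folding_free_energy(fit: TwoStateFit) -> FoldingEnergy:
    """dG = m * D50 with first-order (delta-method) error propagation.

    sigma^2 = d50^2 var(m) + m^2 var(d50) + 2 m d50 cov(m, d50)
    """
    var_m = fit.covariance[4, 4]
    var_d = fit.covariance[5, 5]
    cov_md = fit.covariance[4, 5]
    dg = fit.m_value * fit.d50
    var = (fit.d50 ** 2 * var_m + fit.m_value ** 2 * var_d
           + 2.0 * fit.m_value * fit.d50 * cov_md)
    sigma = float(np.sqrt(max(0.0, var))) if np.isfinite(var) else float("nan")
    return FoldingEnergy(variant_label=fit.variant_label, dg=float(dg), sigma=sigma)


def bootstrap_folding_energy(curve: DenaturationCurve, fit: TwoStateFit,
                             n_boot: int = 200, seed: int = 0) -> FoldingEnergy:
    """Residual-resampling bootstrap alternative to the Jacobian sigma.

    Refits ``n_boot`` synthetic curves built from the fitted model plus
    resampled residuals and returns the empirical SD of dG.
    """
    rng = np.random.default_rng(seed)
    pred = two_state_signal(curve.denaturant, *fit.parameters, temperature=fit.temperature)
    resid = curve.signal - pred
    dgs = []
    for _ in range(n_boot):
        boot = pred + rng.choice(resid, size=resid.size, replace=True)
        c = DenaturationCurve(curve.variant_label, curve.denaturant, boot,
                              temperature=curve.temperature)
        try:
            f = fit_two_state(c, p0=fit.parameters)
        except (NoTransitionError, FitConvergenceError):
            continue
        dgs.append(f.m_value * f.d50)
    if len(dgs) < max(10, n_boot // 4):
        raise FitConvergenceError("too few successful bootstrap refits")
    return FoldingEnergy(variant_label=fit.variant_label,
                         dg=fit.m_value * fit.d50,
                         sigma=float(np.std(dgs, ddof=1)))
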