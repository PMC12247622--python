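"""Estimation procedures and model comparison.

Every fit is a bounded non-linear least-squares problem (scipy ``least_squares``,
trust-region reflective) run from a fixed multi-start grid, so results are
deterministic given (data, start grid).  Parameter uncertainties come from the
Jacobian-based local covariance; model comparison uses the Gaussian
small-sample corrected AIC

    cAIC = n ln(rss/n) + 2k + 2k(k+1)/(n-k-1).

Per-curve cumulant fits act on the un-logged signal; the NEXI fit acts on the
log-signal (that is how multi-shell exchange fits are usually posed).  Joint
fits of D(td) and K(td) scale each curve's residuals by the median of its
observed values so both contribute comparably.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, InsufficientDataError
from .models import (
    CumulantPoint,
    CumulantSeries,
    DecayCurve,
    GeometryParams,
    KargerParams,
    NexiParams,
    Protocol,
    geometry_model_series,
    karger_kurtosis,
    kurtosis_signal,
    nexi_signal,
    tail_ratio,
)

__all__ = [
    "FitResult",
    "caic",
    "fit_cumulant",
    "fit_powerlaw_fixed_theta",
    "fit_powerlaw_free_theta",
    "fit_log_singularity",
    "fit_karger",
    "fit_nexi",
    "fit_geometry",
    "tail_ratio_from_fits",
]

_LSQ_OPTS = dict(method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000)


def caic(rss: float, n_obs: int, n_params: int) -> float:
    """Corrected (small-sample) Akaike information criterion for Gaussian residuals."""
    if n_obs <= n_params + 1:
        raise DomainError("cAIC undefined: need n_obs > n_params + 1")
    if rss <= 0:
        raise DomainError("cAIC undefined for non-positive residual sum of squares")
    n, k = n_obs, n_params
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class FitResult:
    """Parameter estimates of one model fitted to one dataset."""

    model_name: str
    params: dict[str, float]
    se: dict[str, float]
    rss: float
    n_obs: int
    n_params: int
    caic: float              # nan when undefined (too few points or rss == 0)
    converged: bool
    n_starts: int
    seed: int = 0
    flags: tuple[str, ...] = ()
    cov: np.ndarray | None = field(default=None, repr=False)
    derived: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.rss < 0:
            raise DomainError("rss must be non-negative")
        if any(v < 0 for v in self.se.values() if np.isfinite(v)):
            raise DomainError("standard errors must be non-negative")


def _multistart(residual, starts, bounds, names, model_name, n_obs, seed=0,
                extra_flags=()):
    """Run bounded least squares from each start; keep the lowest-cost solution."""
    lo, hi = bounds
    best = None
    n_ok = 0
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
        try:
            res = least_squares(residual, x0, bounds=bounds, **_LSQ_OPTS)
        except Exception:
            continue
        if not np.all(np.isfinite(res.fun)):
            continue
        n_ok += 1
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    if best is None:
        raise RuntimeError(f"{model_name}: no start converged")
    k = len(names)
    rss = float(2.0 * best.cost)
    dof = n_obs - k
    cov = None
    se = dict.fromkeys(names, np.nan)
    if dof > 0:
        J = best.jac
        try:
            JTJ_inv = np.linalg.pinv(J.T @ J)
            s2 = rss / dof if rss > 0 else 0.0
            cov = s2 * JTJ_inv
            se = {nm: float(np.sqrt(max(cov[i, i], 0.0))) for i, nm in enumerate(names)}
        except np.linalg.LinAlgError:  # pragma: no cover
            pass
    flags = list(extra_flags)
    span = np.where(np.isfinite(hi - lo), hi - lo, np.maximum(np.abs(best.x), 1.0))
    for i, nm in enumerate(names):
        if (np.isfinite(lo[i]) and best.x[i] - lo[i] < 1e-6 * span[i]) or (
            np.isfinite(hi[i]) and hi[i] - best.x[i] < 1e-6 * span[i]
        ):
            flags.append(f"boundary:{nm}")
    try:
        ic = caic(rss, n_obs, k)
    except DomainError:
        ic = float("nan")
    return FitResult(
        model_name=model_name,
        params={nm: float(v) for nm, v in zip(names, best.x)},
        se=se,
        rss=rss,
        n_obs=n_obs,
        n_params=k,
        caic=ic,
        converged=bool(best.success and n_ok > 0),
        n_starts=len(starts),
        seed=seed,
        flags=tuple(flags),
        cov=cov,
    )


# ---------------------------------------------------------------------------
# per-td cumulant fit
# ---------------------------------------------------------------------------

def fit_cumulant(curve: DecayCurve, log_domain: bool = False) -> CumulantPoint:
    """Fit S(b) = S0 exp(-bD + K b^2 D^2/6) to one decay curve.

    S0 is a free scale parameter; residuals are on the un-logged signal by
    default (``log_domain=True`` switches to log residuals).  Returns the
    apparent (D, K) with Jacobian-based standard errors.  Requires at least 4
    distinct b-values and positive signals.
    """
    b, S = curve.b, curve.signal
    if np.unique(b).size < 4:
        raise InsufficientDataError("cumulant fit needs >= 4 distinct b-values")
    if np.any(S <= 0):
        raise DomainError("signals must be positive")

    # initial values from the log-quadratic representation
    coef = np.polyfit(b, np.log(S), 2)
    D0 = max(-coef[1], 1e-4)
    K0 = float(np.clip(6.0 * coef[0] / D0**2, -2.9, 40.0))
    S00 = float(np.exp(coef[2]))

    def residual(x):
        S0, D, K = x
        model = S0 * kurtosis_signal(b, D, K)
        return (np.log(model) - np.log(S)) if log_domain else (model - S)

    lo = np.array([1e-12, 1e-6, -3.0 + 1e-9])
    hi = np.array([np.inf, 50.0, 100.0])
    starts = [(S00, D0, K0), (S00, D0, 0.0), (max(S.max(), 1e-6), D0, 1.0)]
    fit = _multistart(residual, starts, (lo, hi), ("S0", "D", "K"),
                      "cumulant", n_obs=b.size)
    D, K = fit.params["D"], fit.params["K"]
    bmax = b.max()
    if abs(K) * bmax**2 * D**2 / 6.0 > bmax * D / 2.0:
        warnings.warn(
            f"cumulant-expansion guard: quartic term exceeds half the linear term "
            f"at b_max={bmax:g} (D={D:.3g}, K={K:.3g})",
            stacklevel=2,
        )
    if not fit.converged:
        warnings.warn(f"cumulant fit did not converge for td={curve.td}", stacklevel=2)
    return CumulantPoint(td=curve.td, D=D, K=K,
                         D_se=fit.se.get("D"), K_se=fit.se.get("K"))


# ---------------------------------------------------------------------------
# structural-disorder fits
# ---------------------------------------------------------------------------

def _linear_powerlaw_start(td, y, theta):
    X = np.column_stack([np.ones_like(td), td ** (-theta)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta  # (X_inf, C)


def fit_powerlaw_fixed_theta(series: CumulantSeries, theta: float,
                             allow_negative_K_inf: bool = True
                             ) -> tuple[FitResult, FitResult]:
    """Independent fits of X_inf + C td^(-theta) to D(td) and K(td), theta frozen.

    Returns (fit_D, fit_K); the tail ratio xi = C_K D_inf / C_D and its
    delta-method standard error are attached to ``fit_K.derived``.
    """
    td = series.td
    if td.size < 3:
        raise InsufficientDataError("need >= 3 diffusion times")
    results = []
    for y, name, lo_inf in (
        (series.D, f"powerlaw-D(theta={theta:g})", 0.0),
        (series.K, f"powerlaw-K(theta={theta:g})", -3.0 if allow_negative_K_inf else 0.0),
    ):
        def residual(x, y=y):
            return x[0] + x[1] * td ** (-theta) - y

        start = _linear_powerlaw_start(td, y, theta)
        lo = np.array([lo_inf, -np.inf])
        hi = np.array([np.inf, np.inf])
        results.append(
            _multistart(residual, [start], (lo, hi), ("X_inf", "C"), name, n_obs=td.size)
        )
    fd, fk = results
    xi, xi_se = tail_ratio_from_fits(fd, fk)
    fk.derived.update({"xi": xi, "xi_se": xi_se, "theta": float(theta)})
    return fd, fk


def tail_ratio_from_fits(fit_D: FitResult, fit_K: FitResult) -> tuple[float, float]:
    """xi = C_K D_inf / C_D from two independent power-law fits, with delta-method SE."""
    Dinf, CD = fit_D.params["X_inf"], fit_D.params["C"]
    CK = fit_K.params["C"]
    xi = tail_ratio(CK, CD, Dinf)
    grad_D = np.array([CK / CD, -CK * Dinf / CD**2])        # d xi / d(D_inf, C_D)
    grad_K = np.array([0.0, Dinf / CD])                     # d xi / d(K_inf, C_K)
    var = 0.0
    if fit_D.cov is not None:
        var += float(grad_D @ fit_D.cov @ grad_D)
    if fit_K.cov is not None:
        var += float(grad_K @ fit_K.cov @ grad_K)
    return float(xi), float(np.sqrt(max(var, 0.0)))


_THETA_STARTS = (0.1, 0.25, 0.5, 0.75, 1.0, 1.5)


def fit_powerlaw_free_theta(series: CumulantSeries) -> FitResult:
    """Joint power-law fit to D(td) and K(td) with a single shared free exponent.

    Parameters (D_inf, C_D, K_inf, C_K, theta), theta bounded in [0, 2];
    residuals of each curve scaled by the median of its observed values.
    xi and theta (with uncertainties) are reported in ``derived``.
    """
    td, D, K = series.td, series.D, series.K
    if td.size < 4:
        raise InsufficientDataError("need >= 4 diffusion times for the free-exponent fit")
    wD = 1.0 / max(float(np.median(np.abs(D))), 1e-12)
    wK = 1.0 / max(float(np.median(np.abs(K))), 1e-12)

    def residual(x):
        Dinf, CD, Kinf, CK, th = x
        rD = (Dinf + CD * td ** (-th) - D) * wD
        rK = (Kinf + CK * td ** (-th) - K) * wK
        return np.concatenate([rD, rK])

    starts = []
    for th in _THETA_STARTS:
        sD = _linear_powerlaw_start(td, D, th)
        sK = _linear_powerlaw_start(td, K, th)
        starts.append((max(sD[0], 0.0), sD[1], sK[0], sK[1], th))
    lo = np.array([0.0, -np.inf, -3.0, -np.inf, 0.0])
    hi = np.array([np.inf, np.inf, np.inf, np.inf, 2.0])
    names = ("D_inf", "C_D", "K_inf", "C_K", "theta")
    fit = _multistart(residual, starts, (lo, hi), names,
                      "powerlaw-joint-free-theta", n_obs=2 * td.size)
    Dinf, CD = fit.params["D_inf"], fit.params["C_D"]
    CK = fit.params["C_K"]
    xi = tail_ratio(CK, CD, Dinf)
    xi_se = np.nan
    if fit.cov is not None:
        grad = np.array([CK / CD, -CK * Dinf / CD**2, 0.0, Dinf / CD, 0.0])
        xi_se = float(np.sqrt(max(grad @ fit.cov @ grad, 0.0)))
    fit.derived.update({"xi": float(xi), "xi_se": xi_se})
    return fit


_TC_STARTS = (0.5, 2.0, 10.0, 50.0, 200.0)


def fit_log_singularity(series: CumulantSeries, component: str = "D") -> FitResult:
    """Fit A ln(td/tc)/td + B to one cumulant curve (component 'D' or 'K').

    tc is bounded in (1e-3, 1e3) ms.  A near-perfect correlation between A and
    tc (|corr| > 0.999) is flagged as an identifiability warning.
    """
    td = series.td
    if td.size < 4:
        raise InsufficientDataError("need >= 4 diffusion times")
    if component not in ("D", "K"):
        raise DomainError("component must be 'D' or 'K'")
    y = series.D if component == "D" else series.K

    def residual(x):
        A, tc, B = x
        return A * np.log(td / tc) / td + B - y

    starts = []
    for tc in _TC_STARTS:
        X = np.column_stack([np.log(td / tc) / td, np.ones_like(td)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        starts.append((beta[0], tc, beta[1]))
    lo = np.array([-np.inf, 1e-3, -np.inf])
    hi = np.array([np.inf, 1e3, np.inf])
    fit = _multistart(residual, starts, (lo, hi), ("A", "tc", "B"),
                      f"log-singularity-{component}", n_obs=td.size)
    if fit.cov is not None:
        denom = np.sqrt(fit.cov[0, 0] * fit.cov[1, 1])
        if denom > 0 and abs(fit.cov[0, 1]) / denom > 0.999:
            fit.flags = fit.flags + ("identifiability:A-tc",)
    return fit


# ---------------------------------------------------------------------------
# exchange fits
# ---------------------------------------------------------------------------

_TEX_STARTS = (1.0, 10.0, 50.0, 100.0, 500.0)


def fit_karger(series: CumulantSeries, variant: str = "eq6",
               td_min: float = 42.5) -> FitResult:
    """Fit the two-pool exchange kurtosis to K(td) for td >= td_min.

    variant 'eq5' freezes the long-time offset K_inf at 0; 'eq6' leaves it
    free (>= 0).  Only the kurtosis curve is fitted — the diffusion-time
    window is restricted so that D(td) is approximately constant, as the
    exchange model assumes.
    """
    if variant not in ("eq5", "eq6"):
        raise DomainError("variant must be 'eq5' or 'eq6'")
    keep = series.td >= td_min - 1e-9
    td, K = series.td[keep], series.K[keep]
    k_free = 2 if variant == "eq5" else 3
    if td.size < k_free + 1:
        raise InsufficientDataError(
            f"Karger {variant} fit needs >= {k_free + 1} points with td >= {td_min:g}"
        )

    if variant == "eq5":
        def residual(x):
            return karger_kurtosis(td, KargerParams(x[0], x[1])) - K
        names = ("K0", "tex")
        lo = np.array([0.0, 1e-3])
        hi = np.array([np.inf, 1e5])
        starts = [(max(K.max(), 1e-3), tex) for tex in _TEX_STARTS]
    else:
        def residual(x):
            return karger_kurtosis(td, KargerParams(x[0], x[1], x[2])) - K
        names = ("K0", "tex", "K_inf")
        lo = np.array([0.0, 1e-3, 0.0])
        hi = np.array([np.inf, 1e5, np.inf])
        starts = [(max(K.max() - K.min(), 1e-3), tex, max(K.min(), 0.0))
                  for tex in _TEX_STARTS]
    fitres = _multistart(residual, starts, (lo, hi), names,
                         f"karger-{variant}", n_obs=td.size)
    # a fitted exchange time far beyond the sampled window means the model
    # predicts essentially no decay: the exchange time is unidentifiable
    if fitres.params["tex"] > 20.0 * td.max():
        fitres.flags = fitres.flags + ("unidentifiable:tex",)
    return fitres


_NEXI_BOUNDS = (np.array([0.0, 1e-3, 1e-3, 0.1]), np.array([1.0, 4.0, 4.0, 1e3]))


def fit_nexi(signals: np.ndarray, protocol: Protocol, n_quad: int = 64,
             starts=None) -> FitResult:
    """Fit the two-compartment exchange signal to normalized S(b, td).

    ``signals`` has shape (n_td, n_b) following the protocol grids.  Residuals
    are on log(S), mirroring how multi-b exchange fits are usually posed.
    Bounds: f in [0,1], Di and De in (0, 4] um^2/ms, tex in (0.1, 1e3] ms;
    a fixed 16-point multi-start grid.  A boundary-pinned fraction or exchange
    time is flagged as unidentifiable.
    """
    td = np.asarray(protocol.diffusion_times)
    b = np.asarray(protocol.b_values)
    S = np.asarray(signals, dtype=float)
    if td.size < 2 or b.size < 4:
        raise InsufficientDataError("NEXI fit needs >= 2 diffusion times and >= 4 b-values")
    if S.shape != (td.size, b.size):
        raise DomainError(f"signals must have shape {(td.size, b.size)}")
    if np.any(S <= 0):
        raise DomainError("signals must be positive")
    B = np.broadcast_to(b, (td.size, b.size))
    T = np.broadcast_to(td[:, None], (td.size, b.size))
    logS = np.log(S).ravel()

    def residual(x):
        f, Di, De, tex = x
        model = nexi_signal(B, T, NexiParams(f, Di, De, tex), n_quad=n_quad)
        return np.log(np.maximum(model.ravel(), 1e-300)) - logS

    if starts is None:
        starts = [(f, Di, De, tex)
                  for f in (0.3, 0.7) for Di in (1.0, 2.0)
                  for De in (0.5, 1.0) for tex in (5.0, 50.0)]
    fit = _multistart(residual, starts, _NEXI_BOUNDS, ("f", "Di", "De", "tex"),
                      "nexi", n_obs=S.size)
    if any(fl in fit.flags for fl in ("boundary:f", "boundary:tex")):
        fit.flags = fit.flags + ("unidentifiable:exchange",)
    return fit


# ---------------------------------------------------------------------------
# restricted-geometry fit
# ---------------------------------------------------------------------------

_GEOM_STARTS = ((5.0, 1.0, 0.5), (8.0, 2.0, 0.3), (3.0, 0.5, 0.8), (10.0, 3.0, 1.0))


def fit_geometry(series: CumulantSeries, f_sphere: float = 0.2,
                 n_quad: int = 64) -> FitResult:
    """Fit the sphere + randomly-oriented-cylinder mixture to D(td), K(td).

    The sphere fraction is imposed (default 0.2) to avoid overfitting; free
    parameters are R_sphere in [1, 15] um, R_cyl in [0.1, 5] um and D0 in
    (0, 1.5] um^2/ms.  Joint residuals on D and K with median scaling.
    Boundary-pinned radii are flagged.
    """
    td, D, K = series.td, series.D, series.K
    if td.size < 2:
        raise InsufficientDataError("geometry fit needs >= 2 diffusion times")
    wD = 1.0 / max(float(np.median(np.abs(D))), 1e-12)
    wK = 1.0 / max(float(np.median(np.abs(K))), 1e-12)

    def residual(x):
        params = GeometryParams(R_sphere=x[0], R_cyl=x[1], D0=x[2],
                                f_sphere=f_sphere, f_cyl=1.0 - f_sphere)
        model = geometry_model_series(td, params, n_quad=n_quad)
        return np.concatenate([(model.D - D) * wD, (model.K - K) * wK])

    lo = np.array([1.0, 0.1, 1e-3])
    hi = np.array([15.0, 5.0, 1.5])
    fit = _multistart(residual, _GEOM_STARTS, (lo, hi),
                      ("R_sphere", "R_cyl", "D0"), "geometry", n_obs=2 * td.size)
    return fit
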