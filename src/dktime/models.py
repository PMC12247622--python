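"""Forward models of diffusion-kurtosis time-dependence.

Pure, deterministic functions covering:

* the cumulant (kurtosis) signal representation S(b) = S0 exp(-bD + K b^2 D^2 / 6);
* structural-disorder functional forms (power-law approach to the long-time
  limit with dynamical exponent theta = (p+d)/2, and the random-rod
  logarithmic singularity A ln(td/tc)/td + B);
* the Karger two-pool exchange kurtosis and the NEXI/SMEX two-compartment
  exchange signal (stick neurites + isotropic extra-neurite water);
* restricted-diffusion cumulants in spheres, cylinders and intervals under the
  narrow-pulse approximation, and the fixed-fraction sphere+cylinder mixture
  used to describe intracellular metabolite diffusion.

Units are fixed package-wide: times in ms, lengths in um, diffusivities in
um^2/ms and b-values in ms/um^2.  Kurtosis is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _spectral
from .errors import ConfigurationError, DomainError, UndefinedRatioError

__all__ = [
    "Protocol",
    "CumulantPoint",
    "CumulantSeries",
    "DecayCurve",
    "PowerLawParams",
    "LogSingularityParams",
    "KargerParams",
    "NexiParams",
    "GeometryParams",
    "kurtosis_signal",
    "powerlaw_value",
    "log_singularity_value",
    "dynamical_exponent",
    "tail_ratio",
    "karger_kurtosis",
    "nexi_signal",
    "restricted_compartment_cumulants",
    "mixture_cumulants",
    "geometry_model_series",
]

MIN_POWDER_ORDER = 8


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Protocol:
    """Acquisition grid: diffusion times, b-values, gradient timing.

    ``repetitions`` (optional, one entry per diffusion time) records how many
    single-shot acquisitions are averaged per (b, td) point; it is used by the
    synthetic-data generator to reproduce the effective noise level.
    """

    diffusion_times: tuple[float, ...]
    b_values: tuple[float, ...]
    delta: float
    big_delta: tuple[float, ...] | None = None
    label: str = ""
    repetitions: tuple[int, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "diffusion_times", tuple(float(t) for t in self.diffusion_times))
        object.__setattr__(self, "b_values", tuple(float(b) for b in self.b_values))
        if any(b < 0 for b in self.b_values):
            raise DomainError("b-values must be non-negative")
        if any(t <= 0 for t in self.diffusion_times):
            raise DomainError("diffusion times must be positive")
        if self.delta <= 0:
            raise DomainError("gradient duration delta must be positive")
        if self.big_delta is not None:
            bd = tuple(float(x) for x in self.big_delta)
            object.__setattr__(self, "big_delta", bd)
            if len(bd) != len(self.diffusion_times):
                raise DomainError("big_delta must have one entry per diffusion time")
            for td, Delta in zip(self.diffusion_times, bd):
                if abs(td - (Delta - self.delta / 3.0)) > 1e-9:
                    raise DomainError(
                        f"td = Delta - delta/3 violated: td={td}, Delta={Delta}, delta={self.delta}"
                    )
        if self.repetitions is not None:
            reps = tuple(int(r) for r in self.repetitions)
            object.__setattr__(self, "repetitions", reps)
            if len(reps) != len(self.diffusion_times) or any(r < 1 for r in reps):
                raise DomainError("repetitions must have one positive entry per diffusion time")


@dataclass
class CumulantPoint:
    """Apparent diffusivity and kurtosis at one diffusion time."""

    td: float
    D: float
    K: float
    D_se: float | None = None
    K_se: float | None = None

    def __post_init__(self):
        if self.td <= 0:
            raise DomainError("td must be positive")
        if self.D <= 0:
            raise DomainError("apparent diffusivity must be positive")
        if self.K <= -3.0:
            raise DomainError("kurtosis is bounded below by -3")
        for se in (self.D_se, self.K_se):
            if se is not None and se < 0:
                raise DomainError("standard errors must be non-negative")


@dataclass
class CumulantSeries:
    """D(td), K(td) with uncertainties; the central intermediate of the analysis."""

    points: list[CumulantPoint]
    species: str = "water"

    def __post_init__(self):
        td = [p.td for p in self.points]
        if any(b <= a for a, b in zip(td, td[1:])):
            raise DomainError("diffusion times must be strictly increasing (no duplicates)")

    @classmethod
    def from_arrays(cls, td, D, K, D_se=None, K_se=None, species="water") -> "CumulantSeries":
        n = len(td)
        D_se = [None] * n if D_se is None else D_se
        K_se = [None] * n if K_se is None else K_se
        pts = [
            CumulantPoint(float(t), float(d), float(k),
                          None if ds is None else float(ds),
                          None if ks is None else float(ks))
            for t, d, k, ds, ks in zip(td, D, K, D_se, K_se)
        ]
        return cls(points=pts, species=species)

    @property
    def td(self) -> np.ndarray:
        return np.array([p.td for p in self.points])

    @property
    def D(self) -> np.ndarray:
        return np.array([p.D for p in self.points])

    @property
    def K(self) -> np.ndarray:
        return np.array([p.K for p in self.points])

    @property
    def D_se(self) -> np.ndarray:
        return np.array([np.nan if p.D_se is None else p.D_se for p in self.points])

    @property
    def K_se(self) -> np.ndarray:
        return np.array([np.nan if p.K_se is None else p.K_se for p in self.points])

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class DecayCurve:
    """Signal vs b at one fixed td for one subject/species: the unit of cumulant fitting."""

    subject: str
    species: str
    td: float
    b: np.ndarray
    signal: np.ndarray
    signal_se: np.ndarray | None = None

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.td <= 0:
            raise DomainError("td must be positive")
        if np.any(self.b < 0):
            raise DomainError("b-values must be non-negative")
        if self.b.shape != self.signal.shape:
            raise DomainError("b and signal must have matching shapes")
        if self.signal_se is not None:
            self.signal_se = np.asarray(self.signal_se, dtype=float)


@dataclass(frozen=True)
class PowerLawParams:
    """X(td) = X_inf + C td^(-theta): long-time limit, amplitude, dynamical exponent."""

    X_inf: float
    C: float
    theta: float

    def __post_init__(self):
        if not (0.0 <= self.theta <= 2.0):
            raise DomainError("theta must lie in the fitting bounds [0, 2]")


@dataclass(frozen=True)
class LogSingularityParams:
    """X(td) = A ln(td/tc)/td + B (randomly oriented rod-like disorder)."""

    A: float
    B: float
    tc: float

    def __post_init__(self):
        if self.tc <= 0:
            raise DomainError("reference time tc must be positive")


@dataclass(frozen=True)
class KargerParams:
    """Barrier-limited two-pool exchange kurtosis: K0, exchange time, long-time offset."""

    K0: float
    tex: float
    K_inf: float = 0.0

    def __post_init__(self):
        if self.K0 < 0:
            raise DomainError("K0 must be non-negative")
        if self.tex <= 0:
            raise DomainError("exchange time must be positive")
        if self.K_inf < 0:
            raise DomainError("K_inf must be non-negative")


@dataclass(frozen=True)
class NexiParams:
    """Two-compartment exchange (stick neurites + isotropic extra-neurite space)."""

    f: float
    Di: float
    De: float
    tex: float

    def __post_init__(self):
        if not (0.0 <= self.f <= 1.0):
            raise DomainError("neurite fraction f must lie in [0, 1]")
        if self.Di <= 0 or self.De <= 0 or self.tex <= 0:
            raise DomainError("Di, De and tex must be positive")


@dataclass(frozen=True)
class GeometryParams:
    """Sphere (soma) + randomly oriented cylinder (projection) mixture."""

    R_sphere: float
    R_cyl: float
    D0: float
    f_sphere: float = 0.2
    f_cyl: float = 0.8
    D_axial: float | None = None  # axial cylinder diffusivity; defaults to D0

    def __post_init__(self):
        if abs(self.f_sphere + self.f_cyl - 1.0) > 1e-9:
            raise DomainError("f_sphere + f_cyl must equal 1")
        if min(self.f_sphere, self.f_cyl) < 0:
            raise DomainError("fractions must be non-negative")
        if self.R_sphere <= 0 or self.R_cyl <= 0:
            raise DomainError("radii must be positive")
        if self.D0 <= 0:
            raise DomainError("D0 must be positive")
        if self.D_axial is not None and self.D_axial <= 0:
            raise DomainError("D_axial must be positive")


# ---------------------------------------------------------------------------
# signal representation and disorder forms
# ---------------------------------------------------------------------------

def kurtosis_signal(b, D, K):
    """Normalized cumulant signal exp(-bD + K b^2 D^2 / 6).

    Equals 1 at b = 0; log-quadratic in b.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise DomainError("b must be non-negative")
    if np.any(np.asarray(D) <= 0):
        raise DomainError("D must be positive")
    out = np.exp(-b * D + (K * b**2 * D**2) / 6.0)
    return out if out.ndim else float(out)


def powerlaw_value(td, params: PowerLawParams):
    """X_inf + C td^(-theta); monotone decreasing in td for C, theta > 0."""
    td = np.asarray(td, dtype=float)
    if np.any(td <= 0):
        raise DomainError("td must be positive")
    out = params.X_inf + params.C * td ** (-params.theta)
    return out if out.ndim else float(out)


def log_singularity_value(td, params: LogSingularityParams):
    """A ln(td/tc)/td + B; equals B at td = tc and tends to B as td -> inf."""
    td = np.asarray(td, dtype=float)
    if np.any(td <= 0):
        raise DomainError("td must be positive")
    out = params.A * np.log(td / params.tc) / td + params.B
    return out if out.ndim else float(out)


def dynamical_exponent(p: float, d: int) -> float:
    """Universal dynamical exponent theta = (p + d)/2 of a structural-disorder class.

    p is the structural exponent of the disorder correlator and d the spatial
    dimensionality: (0, 1) -> 0.5 for 1D short-range disorder; (0, 2) and
    (-1, 3) both -> 1 (random disks / random rods).
    """
    if d not in (1, 2, 3):
        raise DomainError("dimensionality d must be 1, 2 or 3")
    if p < -d:
        raise DomainError("structural exponent must satisfy p >= -d")
    return (p + d) / 2.0


def tail_ratio(C_K: float, C_D: float, D_inf: float) -> float:
    """Dimensionless tail ratio xi = C_K / (C_D / D_inf); 2 for pure 1D short-range disorder."""
    if D_inf <= 0:
        raise UndefinedRatioError("D_inf must be positive")
    if C_D == 0:
        raise UndefinedRatioError("tail ratio undefined for C_D = 0")
    return C_K * D_inf / C_D


def karger_kurtosis(td, params: KargerParams):
    """Two-pool exchange kurtosis K0 (2 tex/td)[1 - (tex/td)(1 - exp(-td/tex))] + K_inf.

    Tends to K0 + K_inf as td -> 0 and to K_inf (with a 2 K0 tex/td tail) as
    td -> inf; monotone decreasing for K0 > 0.
    """
    td = np.asarray(td, dtype=float)
    if np.any(td <= 0):
        raise DomainError("td must be positive")
    x = td / params.tex
    small = x < 1e-4
    shape = np.empty_like(x)
    xs = x[small]
    # series: 1 - x/3 + x^2/12 - x^3/60
    shape[small] = 1.0 - xs / 3.0 + xs**2 / 12.0 - xs**3 / 60.0
    xl = x[~small]
    shape[~small] = (2.0 / xl) * (1.0 - (1.0 - np.exp(-xl)) / xl)
    out = params.K0 * shape + params.K_inf
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# NEXI / SMEX exchange signal
# ---------------------------------------------------------------------------

def _karger_two_pool_signal(b, td, Da, Db, fa, tex):
    """Summed magnetization of the two-pool Karger system at weighting b.

    Apparent diffusivities (Da, Db), equilibrium fractions (fa, 1-fa), exchange
    rates r_out_of_a = (1-fa)/tex, r_into_a = fa/tex (detailed balance; mean
    residence-weighted exchange time tex).  Broadcasts over numpy arrays.
    """
    fb = 1.0 - fa
    r_a = fb / tex  # rate out of pool a
    r_b = fa / tex  # rate out of pool b
    q2 = b / td
    a = q2 * Da + r_a
    d = q2 * Db + r_b
    m = 0.5 * (a + d)
    s = np.sqrt(0.25 * (a - d) ** 2 + r_a * r_b)
    det = a * d - r_a * r_b
    # slow/fast decay rates: m -+ s, with m - s computed as det/(m+s) for accuracy
    lam_slow = det / np.maximum(m + s, 1e-300)
    lam_fast = m + s
    num = (m - a + r_a) * fa + (m - d + r_b) * fb
    g = num / np.maximum(s, 1e-300)
    return 0.5 * (1.0 + g) * np.exp(-td * lam_slow) + 0.5 * (1.0 - g) * np.exp(-td * lam_fast)


def nexi_signal(b, td, params: NexiParams, n_quad: int = 64):
    """Powder-averaged NEXI/SMEX signal at diffusion weighting b and time td.

    Per stick orientation (cos psi = c), the intraneurite pool diffuses with
    Di c^2 and the extraneurite pool with De; the two exchange with mean time
    tex at equilibrium fractions (f, 1-f).  The per-orientation signal is the
    summed two-pool Karger solution, averaged over uniform orientations by
    Gauss-Legendre quadrature on c in [0, 1].  Returns 1 at b = 0.
    """
    if n_quad < MIN_POWDER_ORDER:
        raise ConfigurationError(f"powder quadrature order must be >= {MIN_POWDER_ORDER}")
    b = np.asarray(b, dtype=float)
    td_arr = np.asarray(td, dtype=float)
    if np.any(b < 0):
        raise DomainError("b must be non-negative")
    if np.any(td_arr <= 0):
        raise DomainError("td must be positive")
    scalar = b.ndim == 0 and td_arr.ndim == 0
    b, td_arr = np.broadcast_arrays(np.atleast_1d(b), np.atleast_1d(td_arr))
    c, w = np.polynomial.legendre.leggauss(n_quad)
    c = 0.5 * (c + 1.0)
    w = 0.5 * w
    sig = _karger_two_pool_signal(
        b[..., None], td_arr[..., None],
        params.Di * c**2, params.De, params.f, params.tex,
    )
    out = sig @ w
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# restricted geometries
# ---------------------------------------------------------------------------

def _powder_cylinder_moments(t, R, D0, D_axial, n_quad=64):
    """Orientation-averaged (<dx^2>, <dx^4>) of a cylinder: free axial diffusion
    D_axial plus restricted transverse (disk) diffusion, projected on the
    gradient axis and averaged over uniformly distributed orientations."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    m2p, m4p = _spectral.restricted_moments("disk", t, R, D0)
    m2z = 2.0 * D_axial * t
    m4z = 3.0 * m2z**2
    c, w = np.polynomial.legendre.leggauss(n_quad)
    c = 0.5 * (c + 1.0)
    w = 0.5 * w
    c2 = c**2
    s2 = 1.0 - c2
    m2 = np.outer(m2z, c2) + np.outer(m2p, s2)
    m4 = (
        np.outer(m4z, c2**2)
        + np.outer(m4p, s2**2)
        + 6.0 * np.outer(m2z * m2p, c2 * s2)
    )
    return m2 @ w, m4 @ w


def restricted_compartment_cumulants(td, geometry: str, R: float, D0: float,
                                     D_axial: float | None = None):
    """Narrow-pulse apparent (D, K) for restricted diffusion along the gradient axis.

    geometry: 'sphere', 'cylinder' (powder average of randomly oriented
    cylinders with free axial diffusion), 'cylinder-transverse' (disk) or
    'interval' (half-width R).  D_app = <dx^2>/(2 td), K_app = <dx^4>/<dx^2>^2 - 3.
    Short times give (D0, 0); long times give the uniform-difference limits
    (sphere: D -> R^2/(5 td), K -> -3/7; disk: R^2/(4 td), -1/2; interval: -0.6).
    """
    if R <= 0 or D0 <= 0:
        raise DomainError("R and D0 must be positive")
    td_arr = np.atleast_1d(np.asarray(td, dtype=float))
    if np.any(td_arr <= 0):
        raise DomainError("td must be positive")
    if geometry == "cylinder":
        m2, m4 = _powder_cylinder_moments(td_arr, R, D0, D0 if D_axial is None else D_axial)
    elif geometry in ("cylinder-transverse", "disk"):
        m2, m4 = _spectral.restricted_moments("disk", td_arr, R, D0)
    elif geometry in ("sphere", "interval"):
        m2, m4 = _spectral.restricted_moments(geometry, td_arr, R, D0)
    else:
        raise DomainError(f"unknown geometry {geometry!r}")
    D_app = m2 / (2.0 * td_arr)
    K_app = m4 / m2**2 - 3.0
    if np.isscalar(td) or np.ndim(td) == 0:
        return float(D_app[0]), float(K_app[0])
    return D_app, K_app


def mixture_cumulants(fractions: Sequence[float], Ds: Sequence[float], Ks: Sequence[float]):
    """Cumulants of a non-exchanging mixture via displacement-moment additivity.

    D = sum f_i D_i and K from fourth-moment additivity:
    K = [sum f_i D_i^2 (K_i + 3)] / D^2 - 3.
    """
    f = np.asarray(fractions, dtype=float)
    D = np.asarray(Ds, dtype=float)
    K = np.asarray(Ks, dtype=float)
    if not (f.shape[0] == D.shape[0] == K.shape[0]):
        raise DomainError("fractions, Ds and Ks must have the same length")
    if np.any(f < 0):
        raise DomainError("fractions must be non-negative")
    if abs(f.sum() - 1.0) > 1e-9:
        raise DomainError("fractions must sum to 1 within 1e-9")
    Dbar = np.tensordot(f, D, axes=(0, 0))
    if np.any(np.asarray(Dbar) == 0):
        raise UndefinedRatioError("mixture kurtosis undefined for zero mean diffusivity")
    m4 = np.tensordot(f, D**2 * (K + 3.0), axes=(0, 0))
    Kbar = m4 / Dbar**2 - 3.0
    if np.ndim(Dbar) == 0:
        return float(Dbar), float(Kbar)
    return Dbar, Kbar


def geometry_model_series(td_list, params: GeometryParams, n_quad: int = 64) -> CumulantSeries:
    """Sphere + powder-cylinder mixture cumulants on a diffusion-time grid.

    Models the intracellular compartment as f_sphere spheres (soma) and f_cyl
    randomly oriented cylinders (projections) sharing intrinsic diffusivity D0.
    """
    td = np.atleast_1d(np.asarray(td_list, dtype=float))
    Ds, Ks = restricted_compartment_cumulants(td, "sphere", params.R_sphere, params.D0)
    Dc, Kc = restricted_compartment_cumulants(
        td, "cylinder", params.R_cyl, params.D0, D_axial=params.D_axial
    )
    D = np.empty_like(td)
    K = np.empty_like(td)
    for i in range(td.size):
        D[i], K[i] = mixture_cumulants(
            [params.f_sphere, params.f_cyl], [Ds[i], Dc[i]], [Ks[i], Kc[i]]
        )
    return CumulantSeries.from_arrays(td, D, K, species="geometry-model")
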