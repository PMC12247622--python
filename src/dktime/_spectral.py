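"""Eigenmode evaluation of narrow-pulse displacement cumulants in closed geometries.

For reflecting-boundary diffusion started from the uniform (equilibrium)
distribution, the second and fourth moments of the displacement projected on a
fixed axis follow from the spectral expansion of the propagator,

    P(r0, r, t) = sum_k phi_k(r0) phi_k(r) exp(-lambda_k t),

with orthonormal Laplacian eigenmodes phi_k.  Writing a_k^(p) = int x^p phi_k dV
and mu_p for the uniform-measure moments of x (centered, symmetric domains):

    <dx^2>(t) = 2 mu2 - (2/V) sum_k exp(-lambda_k t) (a_k^(1))^2
    <dx^4>(t) = 2 mu4 + (6/V) [V mu2^2 + sum_k' exp(-lambda_k t) (a_k^(2))^2]
                       - (8/V) sum_k exp(-lambda_k t) a_k^(1) a_k^(3)

where the ground mode's x^2 coupling contributes the constant mu2^2 term and
sum_k' runs over excited modes only.  Everything is computed for unit radius
(half-width) and unit intrinsic diffusivity; physical values follow by scaling
tau = D0 t / R^2, <dx^2> -> R^2, <dx^4> -> R^4.

Only mode families that actually couple survive in the sums: x and x^3 pair
through the l=1 (m=1) sector, x^2 through l=0 and l=2 (m=0 and m=2 for the
disk; even modes for the interval).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import jnp_zeros, jv, roots_legendre, spherical_jn

from .errors import ConvergenceError, DomainError

#: dimensionless time below which the mode sum is replaced by the short-time
#: surface expansion D(t)/D0 = 1 - (4/(3 sqrt(pi))) (S/(V d)) sqrt(D0 t); the
#: coefficient (S R)/(V d) equals 1 for interval (half-width R), disk and sphere.
TAU_ASYMPTOTIC = 1.0e-6
_MITRA = 4.0 / (3.0 * np.sqrt(np.pi))
_LAMTAU_CUT = 36.0  # exp(-36) ~ 2e-16: modes beyond this are numerically silent
_MAX_MODES = 1600

GEOMETRIES = ("interval", "disk", "sphere")


@dataclass(frozen=True)
class ModeTable:
    """Dimensionless eigenmode couplings of one geometry (R = 1, D0 = 1)."""

    lam1: np.ndarray   # eigenvalues of modes coupling to x (and x^3)
    w1: np.ndarray     # (a^(1))^2 / V
    w13: np.ndarray    # a^(1) a^(3) / V  (same modes as lam1)
    lam2: np.ndarray   # eigenvalues of excited modes coupling to x^2
    w2: np.ndarray     # (a^(2))^2 / V  (l=2 multiplets summed over m)
    mu2: float
    mu4: float


@lru_cache(maxsize=8)
def _roots(n: int) -> tuple[np.ndarray, np.ndarray]:
    return roots_legendre(n)


def _leggauss(n: int, a: float, b: float) -> tuple[np.ndarray, np.ndarray]:
    x, w = _roots(n)
    return 0.5 * (b - a) * x + 0.5 * (b + a), 0.5 * (b - a) * w


def _sph_jnp_zeros(ell: int, n: int) -> np.ndarray:
    """First n positive roots of d/dx j_ell(x) (Neumann sphere eigenvalues)."""
    f = lambda x: spherical_jn(ell, x, derivative=True)
    roots = []
    x0, step = 0.5, 0.2
    f0 = f(x0)
    while len(roots) < n:
        x1 = x0 + step
        f1 = f(x1)
        if f0 == 0.0:
            roots.append(x0)
        elif f0 * f1 < 0.0:
            roots.append(brentq(f, x0, x1, xtol=1e-14))
        x0, f0 = x1, f1
        if x0 > 20.0 * (n + ell + 2):  # pragma: no cover - safety net
            raise ConvergenceError("root search for spherical Bessel derivative failed")
    return np.asarray(roots)


def _interval_table(n_modes: int) -> ModeTable:
    # x in [-1, 1], modes phi_n = cos(n pi (x+1)/2), lambda_n = (n pi / 2)^2
    n = np.arange(1, n_modes + 1)
    lam = (n * np.pi / 2.0) ** 2
    x, w = _leggauss(max(4000, 14 * n_modes), -1.0, 1.0)
    phase = np.cos(np.outer(n, np.pi * (x + 1.0) / 2.0))  # (n_modes, nq)
    norm = phase**2 @ w                                   # = 1 for every mode
    a1 = phase @ (w * x)
    a2 = phase @ (w * x**2)
    a3 = phase @ (w * x**3)
    V = 2.0
    inv = 1.0 / (norm * V)
    return ModeTable(
        lam1=lam, w1=a1**2 * inv, w13=a1 * a3 * inv,
        lam2=lam, w2=a2**2 * inv,
        mu2=1.0 / 3.0, mu4=1.0 / 5.0,
    )


def _disk_table(n_modes: int) -> ModeTable:
    # Unit disk, modes J_m(beta r) cos(m phi) with J_m'(beta) = 0.
    r, wr = _leggauss(max(4000, 14 * n_modes), 0.0, 1.0)
    V = np.pi

    def radial(m: int, beta: np.ndarray, kpow: int) -> tuple[np.ndarray, np.ndarray]:
        J = jv(m, np.outer(beta, r))
        norm = (J**2 * r) @ wr
        integ = (J * r ** (kpow + 1)) @ wr
        return integ, norm

    ang_norm = {0: 2.0 * np.pi, 1: np.pi, 2: np.pi}
    # angular overlaps of cos(phi)^k with cos(m phi)
    O1 = {1: np.pi}
    O2 = {0: np.pi, 2: np.pi / 2.0}
    O3 = {1: 3.0 * np.pi / 4.0}

    b1 = jnp_zeros(1, n_modes)
    i1, n1 = radial(1, b1, 1)
    i3, _ = radial(1, b1, 3)
    w1 = (i1 * O1[1]) ** 2 / (n1 * ang_norm[1]) / V
    w13 = (i1 * O1[1]) * (i3 * O3[1]) / (n1 * ang_norm[1]) / V

    b0 = jnp_zeros(0, n_modes)
    i20, n0 = radial(0, b0, 2)
    w2_0 = (i20 * O2[0]) ** 2 / (n0 * ang_norm[0]) / V

    b2 = jnp_zeros(2, n_modes)
    i22, n2 = radial(2, b2, 2)
    w2_2 = (i22 * O2[2]) ** 2 / (n2 * ang_norm[2]) / V

    lam2 = np.concatenate([b0**2, b2**2])
    w2 = np.concatenate([w2_0, w2_2])
    order = np.argsort(lam2)
    return ModeTable(
        lam1=b1**2, w1=w1, w13=w13,
        lam2=lam2[order], w2=w2[order],
        mu2=0.25, mu4=0.125,
    )


def _sphere_table(n_modes: int) -> ModeTable:
    # Unit ball, modes j_l(alpha r) Y_lm with j_l'(alpha) = 0.
    r, wr = _leggauss(max(4000, 14 * n_modes), 0.0, 1.0)
    V = 4.0 * np.pi / 3.0

    def radial(ell: int, alpha: np.ndarray, kpow: int) -> tuple[np.ndarray, np.ndarray]:
        J = spherical_jn(ell, np.outer(alpha, r))
        norm = (J**2 * r**2) @ wr
        integ = (J * r ** (kpow + 2)) @ wr
        return integ, norm

    # angular overlaps with g = sin(theta) cos(phi): int g^2 = 4pi/3,
    # int g^4 = 4pi/5; l=2 projection weight of g^2 is 16pi/45 and the l=0
    # weight (4pi/3)^2/(4pi) = 4pi/9 (together 4pi/5 = int g^4, completeness).
    a1r = _sph_jnp_zeros(1, n_modes)
    i1, n1 = radial(1, a1r, 1)
    i3, _ = radial(1, a1r, 3)
    ang1 = 4.0 * np.pi / 3.0
    w1 = (i1 * ang1) ** 2 / (n1 * ang1) / V
    w13 = (i1 * ang1) * (i3 * 4.0 * np.pi / 5.0) / (n1 * ang1) / V

    a0r = _sph_jnp_zeros(0, n_modes)
    i20, n0 = radial(0, a0r, 2)
    w2_0 = (i20 * 4.0 * np.pi / 3.0) ** 2 / (n0 * 4.0 * np.pi) / V

    a2r = _sph_jnp_zeros(2, n_modes)
    i22, n2 = radial(2, a2r, 2)
    W2 = 16.0 * np.pi / 45.0  # sum over the l=2 multiplet
    w2_2 = i22**2 / n2 * W2 / V

    lam2 = np.concatenate([a0r**2, a2r**2])
    w2 = np.concatenate([w2_0, w2_2])
    order = np.argsort(lam2)
    return ModeTable(
        lam1=a1r**2, w1=w1, w13=w13,
        lam2=lam2[order], w2=w2[order],
        mu2=0.2, mu4=3.0 / 35.0,
    )


@lru_cache(maxsize=64)
def mode_table(geometry: str, n_modes: int) -> ModeTable:
    if geometry == "interval":
        return _interval_table(n_modes)
    if geometry == "disk":
        return _disk_table(n_modes)
    if geometry == "sphere":
        return _sphere_table(n_modes)
    raise DomainError(f"unknown geometry {geometry!r}; expected one of {GEOMETRIES}")


def _modes_needed(geometry: str, tau_min: float) -> int:
    # eigenvalues grow like (n pi)^2 (interval: (n pi / 2)^2); pick n so the
    # smallest neglected term is exp(-lambda tau) < exp(-_LAMTAU_CUT)
    scale = 2.0 if geometry == "interval" else 1.0
    n = int(np.ceil(scale * np.sqrt(_LAMTAU_CUT / tau_min) / np.pi)) + 10
    n = max(n, 20)
    # quantize so the lru cache holds few distinct tables
    n = int(np.ceil(n / 25.0)) * 25
    if n > _MAX_MODES:
        raise ConvergenceError(
            f"tau={tau_min:g} needs more than {_MAX_MODES} modes for geometry {geometry!r}"
        )
    return n


def dimensionless_moments(geometry: str, tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (<dx^2>, <dx^4>) for unit radius and unit D0 at dimensionless times tau."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0.0):
        raise DomainError("diffusion times must be positive")
    msd = np.empty_like(tau)
    m4 = np.empty_like(tau)
    short = tau < TAU_ASYMPTOTIC
    if np.any(short):
        ts = tau[short]
        msd[short] = 2.0 * ts * (1.0 - _MITRA * np.sqrt(ts))
        m4[short] = 3.0 * msd[short] ** 2
    if np.any(~short):
        tl = tau[~short]
        tab = mode_table(geometry, _modes_needed(geometry, float(tl.min())))
        e1 = np.exp(-np.outer(tl, tab.lam1))
        e2 = np.exp(-np.outer(tl, tab.lam2))
        msd[~short] = 2.0 * tab.mu2 - 2.0 * (e1 @ tab.w1)
        m4[~short] = (
            2.0 * tab.mu4
            + 6.0 * (tab.mu2**2 + e2 @ tab.w2)
            - 8.0 * (e1 @ tab.w13)
        )
    return msd, m4


def restricted_moments(
    geometry: str, t: np.ndarray, R: float, D0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Physical (<dx^2>, <dx^4>) along one axis for radius/half-width R and intrinsic D0."""
    if R <= 0.0 or D0 <= 0.0:
        raise DomainError("R and D0 must be positive")
    t = np.asarray(t, dtype=float)
    tau = D0 * t / R**2
    msd, m4 = dimensionless_moments(geometry, tau)
    return R**2 * msd, R**4 * m4
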