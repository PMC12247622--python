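"""Monte-Carlo random-walk oracles.

Three walkers validate the analytic models independently of them:

* 1D diffusion through permeable membranes (regular or short-range-disordered
  placement) — the microscopic realization of 1D structural disorder;
* a two-pool exchange process with Markov pool switching — the microscopic
  realization of the Karger kurtosis decay;
* restricted diffusion in spheres, disks (transverse cylinder) and intervals
  with elastic (specular) boundary reflection.

All walkers take Gaussian steps of standard deviation sqrt(2 D dt), start from
the equilibrium (uniform) distribution, and report narrow-pulse-equivalent
cumulants D(t) = <dx^2>/(2t), K(t) = <dx^4>/<dx^2>^2 - 3 with bootstrap
standard errors over walkers.  Membrane transmission per encounter uses the
hybrid rule for Gaussian steps, P = q/(1+q) with q = kappa sqrt(pi dt / D0)
(the 1/(1+q) factor corrects for re-attempts by reflected walkers); it is
validated against the exact 1D homogenization plateau
D_inf = D0 / (1 + D0/(kappa a_mean)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ConfigurationError, DomainError
from .models import CumulantSeries

__all__ = [
    "MembraneSubstrate1D",
    "WalkEnsemble",
    "walk_membranes_1d",
    "walk_two_pool",
    "walk_restricted",
    "membrane_tail_ratio_experiment",
]


# ---------------------------------------------------------------------------
# substrates and ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MembraneSubstrate1D:
    """Permeable membranes on a periodic 1D domain.

    positions are sorted membrane coordinates in [0, domain_length); kappa is
    the membrane permeability in um/ms and D0 the free diffusivity between
    membranes.  placement records how the positions were generated.
    """

    positions: np.ndarray
    domain_length: float
    permeability: float
    D0: float
    placement: str = "regular"

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if self.permeability < 0:
            raise DomainError("permeability must be non-negative")
        if self.D0 <= 0:
            raise DomainError("D0 must be positive")
        if self.domain_length <= 0:
            raise DomainError("domain_length must be positive")
        if pos.size and (np.any(np.diff(pos) <= 0) or pos[0] < 0
                         or pos[-1] >= self.domain_length):
            raise DomainError("positions must be sorted and lie within [0, domain_length)")

    @property
    def mean_spacing(self) -> float:
        # an empty substrate (free diffusion) has infinite spacing
        if self.positions.size == 0:
            return math.inf
        return self.domain_length / self.positions.size

    @classmethod
    def regular(cls, n_membranes: int, spacing: float, kappa: float, D0: float
                ) -> "MembraneSubstrate1D":
        pos = spacing * np.arange(n_membranes, dtype=float)
        return cls(pos, n_membranes * spacing, kappa, D0, placement="regular")

    @classmethod
    def poisson(cls, n_membranes: int, mean_spacing: float, kappa: float, D0: float,
                seed: int, min_gap_fraction: float = 0.1) -> "MembraneSubstrate1D":
        """Short-range-disordered placement: renewal process with exponential
        gaps shifted by a minimum gap (hard-core Poisson).  Gap mean equals
        mean_spacing; the minimum gap keeps intervals resolvable by the walker
        step while preserving the short-range (p = 0) disorder class."""
        if not (0.0 <= min_gap_fraction < 1.0):
            raise ConfigurationError("min_gap_fraction must lie in [0, 1)")
        rng = np.random.default_rng(seed)
        gmin = min_gap_fraction * mean_spacing
        gaps = gmin + rng.exponential(mean_spacing - gmin, size=n_membranes)
        # normalize to the exact mean spacing so every realization shares the
        # same homogenized long-time diffusivity (fixed membrane density)
        gaps *= n_membranes * mean_spacing / gaps.sum()
        pos = np.concatenate([[0.0], np.cumsum(gaps[:-1])])
        return cls(pos, n_membranes * mean_spacing, kappa, D0,
                   placement="short-range-disordered")


@dataclass
class WalkEnsemble:
    """Displacement records of N walkers at the requested times."""

    times: np.ndarray            # (n_times,), ms (multiples of dt)
    displacements: np.ndarray    # (n_times, n_walkers), um
    dt: float
    seed: int

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("record times must be strictly increasing")
        if not np.all(np.isfinite(self.displacements)):
            raise DomainError("displacements must be finite")

    @property
    def n_walkers(self) -> int:
        return self.displacements.shape[1]

    def cumulant_series(self, n_boot: int = 200, species: str = "simulation"
                        ) -> CumulantSeries:
        """D(t), K(t) from displacement moments with bootstrap SEs over walkers.

        Kurtosis estimates below ~1e4 walkers are noise-dominated; a warning
        is emitted for smaller ensembles.
        """
        if self.n_walkers < 10_000:
            warnings.warn(
                f"{self.n_walkers} walkers is below the recommended 1e4 for "
                "cumulant estimates; kurtosis will be noisy",
                stacklevel=2,
            )
        x = self.displacements
        m2 = np.mean(x**2, axis=1)
        m4 = np.mean(x**4, axis=1)
        D = m2 / (2.0 * self.times)
        K = m4 / m2**2 - 3.0
        D_se = np.zeros_like(D)
        K_se = np.zeros_like(K)
        if n_boot > 0:
            rng = np.random.default_rng(self.seed + 987654321)
            n = self.n_walkers
            Db = np.empty((n_boot, D.size))
            Kb = np.empty((n_boot, K.size))
            x2 = x**2
            x4 = x**4
            for i in range(n_boot):
                idx = rng.integers(0, n, size=n)
                b2 = np.mean(x2[:, idx], axis=1)
                b4 = np.mean(x4[:, idx], axis=1)
                Db[i] = b2 / (2.0 * self.times)
                Kb[i] = b4 / b2**2 - 3.0
            D_se = Db.std(axis=0, ddof=1)
            K_se = Kb.std(axis=0, ddof=1)
        return CumulantSeries.from_arrays(self.times, D, K, D_se, K_se, species=species)


# ---------------------------------------------------------------------------
# numba kernels
#
# Random numbers come from an inline xorshift128+ generator (seeded per walker
# through splitmix64) with Box-Muller normal pairs: numba's built-in scalar
# normal draw is several times slower and would dominate the walk cost.
# ---------------------------------------------------------------------------

_U64 = np.uint64
_INV53 = 1.1102230246251565e-16  # 2^-53
_TWO_PI = 6.283185307179586


@njit(cache=True, inline="always")
def _splitmix64(z):
    z = z + _U64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    return z ^ (z >> _U64(31))


@njit(cache=True, inline="always")
def _init_state(seed, wlk):
    a = _splitmix64(_U64(seed) ^ (_U64(wlk) * _U64(0x9E3779B97F4A7C15)))
    b = _splitmix64(a ^ _U64(0xDEADBEEFCAFEF00D))
    if a == _U64(0) and b == _U64(0):
        a = _U64(0x853C49E6748FEA9B)
    return a, b


@njit(cache=True, inline="always")
def _xs128p(a, b):
    t = a ^ (a << _U64(23))
    nb = t ^ b ^ (t >> _U64(18)) ^ (b >> _U64(5))
    return b, nb, a + b


@njit(cache=True, inline="always")
def _u01(a, b):
    a, b, r = _xs128p(a, b)
    return a, b, (r >> _U64(11)) * _INV53


@njit(cache=True, inline="always")
def _norm_pair(a, b):
    a, b, u1 = _u01(a, b)
    a, b, u2 = _u01(a, b)
    r = math.sqrt(-2.0 * math.log(u1 + 5e-324))
    ang = _TWO_PI * u2
    return a, b, r * math.cos(ang), r * math.sin(ang)


@njit(cache=True)
def _mpos(mem, L, g):
    nm = mem.shape[0]
    q = g // nm
    return mem[g - q * nm] + q * L


@njit(cache=True)
def _kernel_membranes(mem, L, p_trans, sigma, n_steps, rec_steps, n_walkers, seed):
    nrec = rec_steps.shape[0]
    out = np.empty((nrec, n_walkers))
    for wlk in range(n_walkers):
        a, b = _init_state(seed, wlk)
        spare = 0.0
        has_spare = False
        if mem.shape[0] == 0:  # no membranes: free diffusion
            x = 0.0
            ir = 0
            for s in range(n_steps):
                if has_spare:
                    g1 = spare
                    has_spare = False
                else:
                    a, b, g1, spare = _norm_pair(a, b)
                    has_spare = True
                x += sigma * g1
                if ir < nrec and s + 1 == rec_steps[ir]:
                    out[ir, wlk] = x
                    ir += 1
            continue
        a, b, u = _u01(a, b)
        x = u * L
        g = np.searchsorted(mem, x) - 1
        left = _mpos(mem, L, g)
        right = _mpos(mem, L, g + 1)
        x0 = x
        ir = 0
        for s in range(n_steps):
            if has_spare:
                g1 = spare
                has_spare = False
            else:
                a, b, g1, spare = _norm_pair(a, b)
                has_spare = True
            prop = x + sigma * g1
            it = 0
            while it < 200:
                if prop >= right:
                    a, b, u = _u01(a, b)
                    if u < p_trans:
                        g += 1
                        left = right
                        right = _mpos(mem, L, g + 1)
                    else:
                        prop = 2.0 * right - prop
                elif prop < left:
                    a, b, u = _u01(a, b)
                    if u < p_trans:
                        g -= 1
                        right = left
                        left = _mpos(mem, L, g)
                    else:
                        prop = 2.0 * left - prop
                else:
                    break
                it += 1
            if it >= 200:
                prop = 0.5 * (left + right)
            x = prop
            if ir < nrec and s + 1 == rec_steps[ir]:
                out[ir, wlk] = x - x0
                ir += 1
    return out


@njit(cache=True)
def _kernel_two_pool(D1, D2, f1, tex, dt, n_steps, rec_steps, n_walkers, seed):
    nrec = rec_steps.shape[0]
    out = np.empty((nrec, n_walkers))
    sig1 = math.sqrt(2.0 * D1 * dt)
    sig2 = math.sqrt(2.0 * D2 * dt)
    p12 = (1.0 - f1) / tex * dt  # out of pool 1
    p21 = f1 / tex * dt          # out of pool 2
    for wlk in range(n_walkers):
        a, b = _init_state(seed, wlk)
        spare = 0.0
        has_spare = False
        a, b, u = _u01(a, b)
        pool = 1 if u < f1 else 2
        x = 0.0
        ir = 0
        for s in range(n_steps):
            if has_spare:
                g1 = spare
                has_spare = False
            else:
                a, b, g1, spare = _norm_pair(a, b)
                has_spare = True
            a, b, u = _u01(a, b)
            if pool == 1:
                x += sig1 * g1
                if u < p12:
                    pool = 2
            else:
                x += sig2 * g1
                if u < p21:
                    pool = 1
            if ir < nrec and s + 1 == rec_steps[ir]:
                out[ir, wlk] = x
                ir += 1
    return out


@njit(cache=True)
def _kernel_restricted(dim, R, sigma, n_steps, rec_steps, n_walkers, seed):
    nrec = rec_steps.shape[0]
    out = np.empty((nrec, n_walkers))
    for wlk in range(n_walkers):
        a, b = _init_state(seed, wlk)
        spare = 0.0
        has_spare = False
        p0 = 0.0
        p1 = 0.0
        p2 = 0.0
        # equilibrium (uniform) start by rejection sampling
        while True:
            a, b, u = _u01(a, b)
            p0 = (2.0 * u - 1.0) * R
            if dim >= 2:
                a, b, u = _u01(a, b)
                p1 = (2.0 * u - 1.0) * R
            if dim == 3:
                a, b, u = _u01(a, b)
                p2 = (2.0 * u - 1.0) * R
            if p0 * p0 + p1 * p1 + p2 * p2 <= R * R:
                break
        x0 = p0
        ir = 0
        for s in range(n_steps):
            if dim == 1:
                if has_spare:
                    g1 = spare
                    has_spare = False
                else:
                    a, b, g1, spare = _norm_pair(a, b)
                    has_spare = True
                x = p0 + sigma * g1
                it = 0
                while (x > R or x < -R) and it < 100:
                    if x > R:
                        x = 2.0 * R - x
                    else:
                        x = -2.0 * R - x
                    it += 1
                p0 = x
            else:
                a, b, g1, g2 = _norm_pair(a, b)
                q0 = p0 + sigma * g1
                q1 = p1 + sigma * g2
                q2c = 0.0
                if dim == 3:
                    if has_spare:
                        g3 = spare
                        has_spare = False
                    else:
                        a, b, g3, spare = _norm_pair(a, b)
                        has_spare = True
                    q2c = p2 + sigma * g3
                r2 = q0 * q0 + q1 * q1 + q2c * q2c
                it = 0
                while r2 > R * R and it < 100:
                    # exact specular reflection: find the boundary crossing
                    # point and mirror the overshoot across the tangent plane
                    d0 = q0 - p0
                    d1 = q1 - p1
                    d2 = q2c - p2
                    aa = d0 * d0 + d1 * d1 + d2 * d2
                    bq = p0 * d0 + p1 * d1 + p2 * d2
                    cc = p0 * p0 + p1 * p1 + p2 * p2 - R * R
                    disc = bq * bq - aa * cc
                    if aa < 1e-300 or disc < 0.0:
                        break
                    alpha = (-bq + math.sqrt(disc)) / aa
                    s0 = p0 + alpha * d0
                    s1 = p1 + alpha * d1
                    s2 = p2 + alpha * d2
                    vn = ((q0 - s0) * s0 + (q1 - s1) * s1 + (q2c - s2) * s2) / (R * R)
                    q0 -= 2.0 * vn * s0
                    q1 -= 2.0 * vn * s1
                    q2c -= 2.0 * vn * s2
                    p0 = s0
                    p1 = s1
                    p2 = s2
                    r2 = q0 * q0 + q1 * q1 + q2c * q2c
                    it += 1
                if r2 > R * R:  # pathological step: clamp just inside
                    r = math.sqrt(r2)
                    q0 *= 0.999 * R / r
                    q1 *= 0.999 * R / r
                    q2c *= 0.999 * R / r
                p0 = q0
                p1 = q1
                p2 = q2c
            if ir < nrec and s + 1 == rec_steps[ir]:
                out[ir, wlk] = p0 - x0
                ir += 1
    return out


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _record_steps(times, dt):
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0) or np.any(np.diff(times) <= 0):
        raise ConfigurationError("record times must be positive and strictly increasing")
    steps = np.unique(np.round(times / dt).astype(np.int64))
    steps = steps[steps >= 1]
    if steps.size != times.size:
        raise ConfigurationError("record times must be distinct multiples of at least one dt")
    return steps, steps * dt


def _check_seed(seed):
    seed = int(seed)
    if not (0 <= seed < 2**31):
        raise ConfigurationError("seed must lie in [0, 2^31)")
    return seed


def walk_membranes_1d(substrate: MembraneSubstrate1D, n_walkers: int, dt: float,
                      times, seed: int, n_boot: int = 200,
                      return_ensemble: bool = False):
    """Random walk through permeable 1D membranes; returns D(t), K(t) series.

    Preconditions: step sqrt(2 D0 dt) < mean_spacing/4 and transmission
    probability kappa sqrt(pi dt / D0) < 0.5.
    """
    seed = _check_seed(seed)
    sigma = math.sqrt(2.0 * substrate.D0 * dt)
    if sigma >= substrate.mean_spacing / 4.0:
        raise ConfigurationError(
            f"step size {sigma:.3g} um must be < mean spacing/4 = "
            f"{substrate.mean_spacing / 4.0:.3g} um; reduce dt"
        )
    q = substrate.permeability * math.sqrt(math.pi * dt / substrate.D0)
    # q/(1+q) corrects the hybrid rule P = kappa sqrt(pi dt/D0) for re-attempts
    # by reflected walkers; without it the realized permeability is kappa/(1-P).
    p_trans = q / (1.0 + q)
    if p_trans >= 0.5:
        raise ConfigurationError(
            f"per-encounter transmission probability {p_trans:.3g} must be < 0.5; reduce dt"
        )
    rec, actual = _record_steps(times, dt)
    disp = _kernel_membranes(
        substrate.positions, substrate.domain_length, p_trans, sigma,
        int(rec[-1]), rec, int(n_walkers), seed,
    )
    ens = WalkEnsemble(actual, disp, dt, seed)
    series = ens.cumulant_series(n_boot=n_boot, species="membranes-1d")
    return (series, ens) if return_ensemble else series


def walk_two_pool(D1: float, D2: float, f1: float, tex: float, times,
                  n_walkers: int, dt: float, seed: int, n_boot: int = 200,
                  return_ensemble: bool = False):
    """Two-pool exchange walk: Gaussian steps with Markov-switching diffusivity.

    Pool-switch probabilities per step are (1-f1) dt/tex out of pool 1 and
    f1 dt/tex out of pool 2 (equilibrium fraction f1, exchange time tex).
    Requires dt <= tex/20.
    """
    seed = _check_seed(seed)
    if not (0.0 < f1 < 1.0):
        raise DomainError("f1 must lie strictly between 0 and 1")
    if min(D1, D2) < 0 or tex <= 0:
        raise DomainError("diffusivities must be >= 0 and tex > 0")
    if dt > tex / 20.0:
        raise ConfigurationError("dt must be <= tex/20 to resolve exchange")
    rec, actual = _record_steps(times, dt)
    disp = _kernel_two_pool(float(D1), float(D2), float(f1), float(tex), float(dt),
                            int(rec[-1]), rec, int(n_walkers), seed)
    ens = WalkEnsemble(actual, disp, dt, seed)
    series = ens.cumulant_series(n_boot=n_boot, species="two-pool")
    return (series, ens) if return_ensemble else series


_GEOM_DIM = {"interval": 1, "cylinder-transverse": 2, "disk": 2, "sphere": 3}


def walk_restricted(geometry: str, R: float, D0: float, times, n_walkers: int,
                    dt: float, seed: int, n_boot: int = 200,
                    return_ensemble: bool = False):
    """Restricted walk with elastic reflection in a sphere, disk or interval.

    Requires sqrt(2 D0 dt) < R/10.  Reports cumulants of the displacement
    along one fixed axis (narrow-pulse measurement model).
    """
    seed = _check_seed(seed)
    if geometry not in _GEOM_DIM:
        raise DomainError(f"unknown geometry {geometry!r}")
    if R <= 0 or D0 <= 0:
        raise DomainError("R and D0 must be positive")
    sigma = math.sqrt(2.0 * D0 * dt)
    if sigma >= R / 10.0:
        raise ConfigurationError(f"step size {sigma:.3g} um must be < R/10; reduce dt")
    rec, actual = _record_steps(times, dt)
    disp = _kernel_restricted(_GEOM_DIM[geometry], float(R), sigma,
                              int(rec[-1]), rec, int(n_walkers), seed)
    ens = WalkEnsemble(actual, disp, dt, seed)
    series = ens.cumulant_series(n_boot=n_boot, species=f"restricted-{geometry}")
    return (series, ens) if return_ensemble else series


# ---------------------------------------------------------------------------
# 1D structural-disorder tail-ratio experiment
# ---------------------------------------------------------------------------

def membrane_tail_ratio_experiment(
    seed: int,
    n_realizations: int = 6,
    n_walkers: int = 40_000,
    n_membranes: int = 1500,
    mean_spacing: float = 1.0,
    kappa: float = 0.25,
    D0: float = 1.0,
    dt: float = 0.02,
    times=None,
) -> dict:
    """Estimate the universal 1D short-range-disorder tail ratio xi from walkers.

    Simulates diffusion through Poisson-placed permeable membranes in several
    independent disorder realizations, averages the measured D(t) and K(t)
    over realizations (the universal amplitudes describe the disorder
    ensemble, and a single finite box retains sample-to-sample fluctuations of
    the kurtosis amplitude), then jointly fits the theta = 0.5 power laws to
    the late-time window and returns xi = C_K D_inf / C_D.

    The default window (60-480 ms for mean spacing 1 um, kappa 0.25 um/ms,
    D0 = 1 um^2/ms) starts once the diffusion length exceeds several mean
    spacings and ends well inside the periodic box.  The kurtosis offset is
    constrained to K_inf >= 0: for permeable membranes the kurtosis is
    non-negative and decays to zero, and allowing a negative offset lets
    noise inflate the fitted tail amplitude.
    """
    from .fitting import fit_powerlaw_fixed_theta  # deferred: avoids import cycle

    seed = _check_seed(seed)
    if times is None:
        times = np.geomspace(60.0, 480.0, 10)
    times = np.asarray(times, dtype=float)
    m2_acc = np.zeros_like(times)
    m4_acc = np.zeros_like(times)
    actual_times = times
    for r in range(n_realizations):
        sub = MembraneSubstrate1D.poisson(
            n_membranes, mean_spacing, kappa, D0, seed=(seed + 7919 * r) % 2**31
        )
        _, ens = walk_membranes_1d(sub, n_walkers, dt, times,
                                   seed=(seed + 104729 * r + 1) % 2**31,
                                   n_boot=0, return_ensemble=True)
        # pool displacement moments over realizations: the estimator of the
        # disorder-ensemble propagator cumulants
        m2_acc += np.mean(ens.displacements**2, axis=1)
        m4_acc += np.mean(ens.displacements**4, axis=1)
        actual_times = ens.times
    m2 = m2_acc / n_realizations
    m4 = m4_acc / n_realizations
    avg = CumulantSeries.from_arrays(actual_times, m2 / (2.0 * actual_times),
                                     m4 / m2**2 - 3.0,
                                     species="membranes-1d-average")
    fd, fk = fit_powerlaw_fixed_theta(avg, 0.5, allow_negative_K_inf=False)
    return {
        "series": avg,
        "fit_D": fd,
        "fit_K": fk,
        "xi": fk.derived["xi"],
        "xi_se": fk.derived["xi_se"],
        "n_walkers_total": n_realizations * n_walkers,
    }
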