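"""Transit of migrant families between patches: killed Brownian motion.

A rare family of the allele outside its patch is a subcritical branching
process: a long-lived "trunk" lineage whose spatial motion is Brownian
(variance sigma^2 per generation) and whose lifetime is approximately
Exponential(s_m), decorated with short-lived side branches.  The family
colonizes a new patch at distance R if the trunk hits it before being
killed.  The transit time tau (conditioned on arrival) sets the genetic
length L of the ancestral haplotype that hitchhikes across: each
generation in transit is an opportunity for recombination onto a
non-carrier background, so L | tau is Exponential(tau) per side of the
selected locus.

All closed forms below follow from the Laplace transform of the hitting
time of killed Brownian motion; the Monte-Carlo simulators in this module
serve as independent oracles for them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import k0, k1

from .params import ParameterError

__all__ = [
    "TransitModel",
    "family_size_mean",
    "simulate_family",
    "transit_laplace",
    "transit_time_moments",
    "haplotype_survival",
    "haplotype_moments",
    "sample_haplotype_lengths",
    "patch_occupancy_g",
    "killed_bm_transit",
    "killed_bm_occupancy",
]


@dataclass(frozen=True)
class TransitModel:
    """Killed-Brownian trunk model between two patches.

    ``R`` is the shortest gap between the patches, ``s_m`` the killing
    rate (selection against the allele in transit), ``w`` the target-patch
    radius (entering the 2D hitting problem and the occupation time), and
    ``d`` the dimension.
    """

    R: float
    sigma: float
    s_m: float
    w: float = 1.0
    d: int = 1

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ParameterError(f"R must be >= 0, got {self.R}")
        if not (self.sigma > 0 and self.s_m > 0 and self.w > 0):
            raise ParameterError("sigma, s_m and w must be > 0")
        if self.d not in (1, 2):
            raise ParameterError(f"d must be 1 or 2, got {self.d}")


def family_size_mean(W, s_m: float) -> float:
    """Limiting mean family size E[K] conditioned on survival.

    ``E[W(W-1)] / (E[W] s_m)`` where ``W`` is the offspring-number
    distribution: accepts a frozen scipy.stats distribution (``mean``/``var``
    methods) or a ``(mean, variance)`` pair.  For Poisson offspring with
    mean near one this is approximately ``1/s_m``.
    """
    if s_m <= 0:
        raise ParameterError("E[K] diverges as s_m -> 0; need s_m > 0")
    if hasattr(W, "mean") and hasattr(W, "var"):
        mean, var = float(W.mean()), float(W.var())
    else:
        mean, var = map(float, W)
    if mean <= 0:
        raise ParameterError("offspring mean must be > 0")
    factorial2 = var + mean * mean - mean  # E[W(W-1)]
    return factorial2 / (mean * s_m)


def simulate_family(
    s_m: float,
    rng: np.random.Generator,
    t_max: int,
    n_replicates: int = 1,
    offspring_mean: float | None = None,
) -> np.ndarray:
    """Galton-Watson trajectories of migrant-family sizes.

    Each individual leaves a Poisson number of offspring with mean
    ``exp(-s_m)`` by default (slightly subcritical).  Returns an integer
    array of shape ``(n_replicates, t_max + 1)`` of family sizes ``Z_t``
    started from a single founder.  The unconditioned mean obeys
    ``E[Z_t] = mean^t``, equivalently the survival/size identity
    ``exp(-s_m t) = (1 - k_e(t)) E[K_t]``.
    """
    lam = math.exp(-s_m) if offspring_mean is None else offspring_mean
    Z = np.zeros((n_replicates, t_max + 1), dtype=np.int64)
    Z[:, 0] = 1
    for t in range(t_max):
        Z[:, t + 1] = rng.poisson(lam * Z[:, t])
    return Z


def _laplace_scalar(ell: float, model: TransitModel) -> float:
    arg = math.sqrt(2.0 * (model.s_m + ell)) / model.sigma
    if model.d == 1:
        return math.exp(-model.R * arg)
    return float(k0((model.R + model.w) * arg) / k0(model.w * arg))


def transit_laplace(ell, model: TransitModel):
    """Laplace transform E[exp(-ell * tau)] of the unconditioned hitting time.

    1D: ``exp(-R sqrt(2 (s_m + ell))/sigma)``.  2D (circular target of
    radius w): ``K0((R+w) z)/K0(w z)`` with ``z = sqrt(2 (s_m + ell))/sigma``.
    At ``ell = 0`` this is the probability the family ever reaches the
    patch; it is completely monotone in ``ell`` and decreasing in ``R``.
    """
    ell_arr = np.asarray(ell, dtype=float)
    if (ell_arr < 0).any():
        raise ParameterError("ell must be >= 0")
    out = np.vectorize(lambda l: _laplace_scalar(l, model))(ell_arr)
    return float(out) if ell_arr.ndim == 0 else out


def transit_time_moments(model: TransitModel) -> tuple[float, float]:
    """Mean and variance of the transit time conditioned on arrival (1D).

    ``E[tau | tau < inf] = (R sqrt(2 s_m)/sigma) / (2 s_m)`` and
    ``Var = (R sqrt(2 s_m)/sigma) / (2 s_m)^2``: successful lineages cover
    the gap at speed ``sigma sqrt(2 s_m)``.  The 2D conditioned moments
    have no closed form here; only the Laplace transform is exposed for 2D.
    """
    if model.d != 1:
        raise NotImplementedError("conditioned transit-time moments: 1D only")
    z = model.R * math.sqrt(2.0 * model.s_m) / model.sigma
    return z / (2.0 * model.s_m), z / (2.0 * model.s_m) ** 2


def haplotype_survival(ell, model: TransitModel):
    """P{L > ell}: survival function of the hitchhiking-haplotype length (1D).

    ``exp(-(R/sigma) (sqrt(2 (ell + s_m)) - sqrt(2 s_m)))`` -- the Laplace
    transform of tau conditioned on arrival, by Bayes' rule equal to
    ``transit_laplace(ell) / transit_laplace(0)``.  ``ell`` in Morgans.
    """
    if model.d != 1:
        raise NotImplementedError("haplotype length distribution: 1D only")
    ell_arr = np.asarray(ell, dtype=float)
    if (ell_arr < 0).any():
        raise ParameterError("ell must be >= 0")
    scalar = ell_arr.ndim == 0
    out = np.exp(
        -(model.R / model.sigma)
        * (np.sqrt(2.0 * (ell_arr + model.s_m)) - math.sqrt(2.0 * model.s_m))
    )
    return float(out) if scalar else out


def haplotype_moments(model: TransitModel) -> tuple[float, float]:
    """Mean and variance (Morgans) of the founding haplotype length per side.

    ``E[L] = sigma sqrt(2 s_m)/R + sigma^2/R^2`` and
    ``Var[L] = 2 s_m sigma^2/R^2 + 4 sigma^3 sqrt(2 s_m)/R^3 + 5 sigma^4/R^4``,
    both following from the representation ``L = (Y + sqrt(s_m))^2 - s_m``
    with ``Y ~ Exponential(rate R sqrt(2)/sigma)``.
    """
    if model.d != 1:
        raise NotImplementedError("haplotype length moments: 1D only")
    if model.R <= 0:
        raise ParameterError("haplotype moments require R > 0")
    R, sig, s_m = model.R, model.sigma, model.s_m
    mean = sig * math.sqrt(2.0 * s_m) / R + sig**2 / R**2
    var = (
        2.0 * s_m * sig**2 / R**2
        + 4.0 * sig**3 * math.sqrt(2.0 * s_m) / R**3
        + 5.0 * sig**4 / R**4
    )
    return mean, var


def sample_haplotype_lengths(
    model: TransitModel, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Draw haplotype lengths via the representation L = (Y + sqrt(s_m))^2 - s_m."""
    if model.d != 1:
        raise NotImplementedError("haplotype length sampling: 1D only")
    Y = rng.exponential(scale=model.sigma / (model.R * math.sqrt(2.0)), size=n)
    return (Y + math.sqrt(model.s_m)) ** 2 - model.s_m


def patch_occupancy_g(w: float, s_m: float, sigma: float, d: int = 1) -> float:
    """Expected time a killed Brownian motion started on the patch edge spends inside.

    1D (patch an interval of length 2w): ``(1 - exp(-2 w sqrt(2 s_m)/sigma))/(2 s_m)``.
    2D (disk of radius... diameter 2w): ``(1 - z K1(z))/(2 s_m)`` with
    ``z = 2 w sqrt(2 s_m)/sigma``.  Both tend to ``1/(2 s_m)`` -- the mean
    lifetime halved by the motion spending half its time outside -- as the
    patch grows.
    """
    if not (w > 0 and s_m > 0 and sigma > 0):
        raise ParameterError("w, s_m and sigma must be > 0")
    z = 2.0 * w * math.sqrt(2.0 * s_m) / sigma
    if d == 1:
        return (1.0 - math.exp(-z)) / (2.0 * s_m)
    if d == 2:
        return (1.0 - z * float(k1(z))) / (2.0 * s_m)
    raise ParameterError(f"d must be 1 or 2, got {d}")


def killed_bm_transit(
    model: TransitModel,
    rng: np.random.Generator,
    n_paths: int,
    dt: float = 0.01,
    t_max: float | None = None,
    bridge_correction: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo killed Brownian motion run against a target at distance R (1D).

    Euler-Maruyama with step ``dt``; killing applied per step with
    probability ``1 - exp(-s_m dt)``.  With ``bridge_correction`` the
    within-step crossing probability of the Brownian bridge,
    ``exp(-2 (R - x0)(R - x1) / (sigma^2 dt))``, removes the O(sqrt(dt))
    discrete-monitoring bias of the first-crossing detection; without it
    the bias is documented and of that order.

    Returns ``(hit, hit_time)``: a boolean array and the hitting times
    (``nan`` where the path was killed first).
    """
    if model.d != 1:
        raise NotImplementedError("transit Monte Carlo: 1D only")
    if t_max is None:
        t_max = 60.0 / model.s_m
    n_steps = int(math.ceil(t_max / dt))
    step_sd = model.sigma * math.sqrt(dt)
    p_kill = 1.0 - math.exp(-model.s_m * dt)

    hit = np.zeros(n_paths, dtype=bool)
    hit_time = np.full(n_paths, np.nan)
    x = np.zeros(n_paths)
    active = np.arange(n_paths)
    for step in range(1, n_steps + 1):
        if active.size == 0:
            break
        x_new = x + step_sd * rng.standard_normal(active.size)
        crossed = x_new >= model.R
        if bridge_correction:
            below = ~crossed
            if below.any():
                p_cross = np.exp(
                    -2.0
                    * (model.R - x[below])
                    * (model.R - x_new[below])
                    / (model.sigma**2 * dt)
                )
                crossed[below] = rng.random(below.sum()) < p_cross
        killed = (~crossed) & (rng.random(active.size) < p_kill)
        idx_hit = active[crossed]
        hit[idx_hit] = True
        hit_time[idx_hit] = step * dt
        keep = ~(crossed | killed)
        active = active[keep]
        x = x_new[keep]
    return hit, hit_time


def killed_bm_occupancy(
    w: float,
    s_m: float,
    sigma: float,
    rng: np.random.Generator,
    n_paths: int,
    dt: float = 0.01,
) -> np.ndarray:
    """Monte-Carlo occupation times of [0, 2w] for killed BM started at 0 (1D).

    Oracle for :func:`patch_occupancy_g`: accumulates ``dt`` whenever the
    path sits inside the interval, until an Exponential(s_m) killing time.
    """
    kill_time = rng.exponential(scale=1.0 / s_m, size=n_paths)
    n_steps = int(np.ceil(kill_time.max() / dt))
    occ = np.zeros(n_paths)
    x = np.zeros(n_paths)
    alive_time = kill_time.copy()
    step_sd = sigma * math.sqrt(dt)
    active = np.arange(n_paths)
    for step in range(n_steps):
        alive = alive_time > dt
        occ_now = (x >= 0.0) & (x <= 2.0 * w)
        occ[active[occ_now]] += np.minimum(alive_time[occ_now], dt)
        x = x[alive] + step_sd * rng.standard_normal(int(alive.sum()))
        alive_time = alive_time[alive] - dt
        active = active[alive]
        if active.size == 0:
            break
    return occ
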