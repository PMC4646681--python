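"""Closed-form rates and probabilities for adaptation to patchy landscapes.

Two routes bring the locally adaptive allele ``B`` into a not-yet-adapted
patch:

* **new mutation**, at rate ``lambda_mut = 2 s_p rho A mu / xi2`` (mutational
  influx ``rho A mu`` times the panmictic establishment probability
  ``p_e = 2 s_p / xi2``), and
* **migration** from an already adapted patch a distance ``R`` away, at a
  rate proportional to the migration-selection-balance equilibrium
  frequency ``q(R)``, which decays as ``exp(-R sqrt(2 s_m)/sigma)`` (with a
  square-root prefactor correction in two dimensions).

Comparing the two gives the probability that the second patch adapts by an
independent (parallel, convergent) mutation, which rises approximately
logistically in ``R`` on the scale of the characteristic length
``sigma/sqrt(2 s_m)``, and a critical gap distance at which the two routes
are equally fast.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .params import ParameterError, Patch, PatchLayout, PopulationParams

__all__ = [
    "panmictic_establishment_prob",
    "critical_patch_width",
    "lambda_mut",
    "equilibrium_frequency",
    "effective_area",
    "q_patch_integral",
    "lambda_mig",
    "exact_migration_factor",
    "CriticalGap",
    "critical_gap_distance",
    "prob_parallel",
    "fit_cline",
    "check_assumptions",
]


def panmictic_establishment_prob(s_p: float, xi2: float) -> float:
    """Probability that a single beneficial copy escapes initial loss.

    The classic branching-process approximation ``2 s_p / xi2`` for a
    well-mixed population, clipped to [0, 1].
    """
    if not xi2 > 0:
        raise ParameterError(f"xi2 must be > 0, got {xi2}")
    if s_p < 0:
        raise ParameterError(f"s_p must be >= 0, got {s_p}")
    return float(min(1.0, 2.0 * s_p / xi2))


def critical_patch_width(sigma: float, s_p: float, s_m: float) -> float:
    """Minimum patch width supporting a stable polymorphic equilibrium.

    Below ``(sigma / sqrt(2 s_p)) * arctan(sqrt(s_m / s_p))`` migrational
    swamping prevents the locally adapted allele from persisting (1D
    deterministic result).
    """
    for name, v in (("sigma", sigma), ("s_p", s_p)):
        if not v > 0:
            raise ParameterError(f"{name} must be > 0, got {v}")
    if s_m < 0:
        raise ParameterError(f"s_m must be >= 0, got {s_m}")
    return sigma / math.sqrt(2.0 * s_p) * math.atan(math.sqrt(s_m / s_p))


def lambda_mut(params: PopulationParams, A: float) -> float:
    """Rate of adaptation of a patch of area ``A`` by new mutation.

    ``2 s_p rho A mu / xi2`` per generation; the waiting time to the first
    establishing mutation is approximately Exponential(lambda_mut).
    """
    if not A > 0:
        raise ParameterError(f"patch area must be > 0, got {A}")
    return 2.0 * params.s_p * params.rho * A * params.mu / params.xi2


def equilibrium_frequency(x, params: PopulationParams):
    """Expected frequency q(x) of the allele at distance |x| from its patch.

    The migration-selection-balance tail

        q(x) = C * (|x|/ell)^(-(d-1)/2) * exp(-|x|/ell),   ell = sigma/sqrt(2 s_m)

    valid for ``|x|`` beyond a few multiples of ``sigma`` (not enforced).
    """
    x = np.abs(np.asarray(x, dtype=float))
    scalar = x.ndim == 0
    z = x * math.sqrt(2.0 * params.s_m) / params.sigma
    if params.d == 2 and np.any(z == 0):
        raise ParameterError("q(x) diverges at x = 0 in two dimensions")
    with np.errstate(divide="ignore"):
        q = params.C * z ** (-(params.d - 1) / 2.0) * np.exp(-z)
    return float(q) if scalar else q


def effective_area(patch: Patch, R: float, params: PopulationParams) -> float:
    """Area A' of the patch lying within one characteristic length of distance R.

    Only the strip of the new patch closest to the source (depth at most
    ``ell = sigma/sqrt(2 s_m)``) contributes appreciably to the migrant
    influx; a patch smaller than the strip contributes its whole area.
    """
    ell = params.char_length
    if params.d == 1:
        return min(patch.w_lin, ell)
    return patch.w_perp * min(patch.w_lin, ell)


def q_patch_integral(R: float, patch: Patch, params: PopulationParams) -> float:
    """Integral of the equilibrium frequency q(x) over a patch at distance R.

    1D: exact integral of the exponential tail over ``[R, R + w_lin]``.
    2D: rectangle bound ``w_perp * min(w_lin, ell) * q(R)`` with the
    constant ``pi`` absorbed into C.  Always bounded above by
    ``area * q(R)``.
    """
    if not R > 0:
        raise ParameterError(f"R must be > 0, got {R}")
    ell = params.char_length
    if params.d == 1:
        return (
            params.C
            * math.exp(-R / ell)
            * ell
            * (1.0 - math.exp(-patch.w_lin / ell))
        )
    return patch.w_perp * min(patch.w_lin, ell) * equilibrium_frequency(R, params)


def lambda_mig(R: float, params: PopulationParams, A_eff: float) -> float:
    """Rate of adaptation of a patch by migration from one adapted patch.

    ``C * A' * rho * s_m * min(s_m, p_e) * (R/ell)^(-(d-1)/2) * exp(-R/ell)``
    with ``A'`` from :func:`effective_area`.  Valid for ``R`` beyond one
    characteristic length (a warning is emitted otherwise) and, in ``s_m``,
    only on the decreasing branch ``s_m > R^2 / (2 sigma^2)``; outside that
    region the approximation is non-monotone in ``s_m`` and should not be
    trusted.
    """
    if not A_eff > 0:
        raise ParameterError(f"A_eff must be > 0, got {A_eff}")
    ell = params.char_length
    if R <= ell:
        warnings.warn(
            f"lambda_mig called with R = {R} <= characteristic length {ell:.3g}; "
            "the tail approximation is unreliable this close",
            stacklevel=2,
        )
    z = R / ell
    pref = z ** (-(params.d - 1) / 2.0)
    return (
        params.C
        * A_eff
        * params.rho
        * params.s_m
        * min(params.s_m, params.p_e)
        * pref
        * math.exp(-z)
    )


def exact_migration_factor(K_pmf, p_e: float, s_m: float) -> float:
    """Family-level establishment factor E[1-(1-p_e)^K] / (E[K]/(2 s_m)).

    ``K_pmf`` is the distribution of the migrant-family size on arrival: a
    mapping or sequence of (k, probability) pairs over nonnegative integers
    with finite mean.  Multiplying ``rho * q(S)`` by this factor gives the
    establishment rate of migrant families; when ``p_e * K`` is typically
    small it reduces to ``2 s_m p_e``.
    """
    items = list(K_pmf.items()) if hasattr(K_pmf, "items") else list(K_pmf)
    ks = np.array([k for k, _ in items], dtype=float)
    ps = np.array([p for _, p in items], dtype=float)
    if (ks < 0).any() or (ps < 0).any():
        raise ParameterError("K distribution needs nonnegative support and masses")
    ps = ps / ps.sum()
    mean_K = float(ks @ ps)
    if mean_K == 0:
        raise ParameterError("degenerate K distribution: E[K] = 0")
    p_est = float(((1.0 - (1.0 - p_e) ** ks) * ps).sum())
    return p_est / (mean_K / (2.0 * s_m))


@dataclass(frozen=True)
class CriticalGap:
    """Critical inter-patch gap in units of sigma, with a dominance flag."""

    R_over_sigma: float
    mutation_always_faster: bool

    def __float__(self) -> float:
        return self.R_over_sigma


def critical_gap_distance(
    s_m: float, mu: float, w: float, gamma: float = 1.0
) -> CriticalGap:
    """Gap distance (in units of sigma) where mutation and migration balance.

    ``R/sigma = log(2 gamma s_m / (w mu)) / sqrt(2 s_m)``, where ``w`` is
    the patch width in characteristic lengths and ``gamma = min(1,
    s_m/p_e)``.  Beyond this gap, convergent adaptation by independent
    mutation is the more likely route.  If ``2 gamma s_m <= w mu`` the
    mutational influx wins at any distance; the result is then 0 with
    ``mutation_always_faster=True`` rather than a negative length.
    """
    for name, v in (("s_m", s_m), ("mu", mu), ("w", w), ("gamma", gamma)):
        if not v > 0:
            raise ParameterError(f"{name} must be > 0, got {v}")
    arg = 2.0 * gamma * s_m / (w * mu)
    if arg <= 1.0:
        return CriticalGap(0.0, True)
    return CriticalGap(math.log(arg) / math.sqrt(2.0 * s_m), False)


def prob_parallel(R, params: PopulationParams, w: float, gamma: float | None = None):
    """Probability that a second patch adapts by an independent mutation.

    The ratio ``lambda_mut / (lambda_mut + lambda_mig)`` in its width-scaled
    form,

        P = [w mu/(2 s_m)] / ( [w mu/(2 s_m)]
              + C gamma (R/ell)^(-(d-1)/2) exp(-R/ell) ),

    with ``w = A/A'`` the patch width in characteristic lengths.  Increases
    approximately logistically in ``R`` and is invariant to ``rho`` and to
    joint rescaling of ``s_p rho`` (those only set the time scale).  With
    ``C = gamma = 1`` and ``d = 1`` it equals 1/2 exactly at the
    :func:`critical_gap_distance`.
    """
    if gamma is None:
        gamma = params.gamma
    R = np.asarray(R, dtype=float)
    scalar = R.ndim == 0
    z = R / params.char_length
    with np.errstate(divide="ignore"):
        mig = params.C * gamma * z ** (-(params.d - 1) / 2.0) * np.exp(-z)
    mut = w * params.mu / (2.0 * params.s_m)
    p = mut / (mut + mig)
    return float(p) if scalar else p


def fit_cline(distances, frequencies, d: int = 1) -> tuple[float, float]:
    """Fit the equilibrium-frequency tail to observed (distance, frequency) data.

    Ordinary least squares in log-frequency space of

        log q + ((d-1)/2) log x  =  a - x / ell,

    returning ``(C_hat, decay_length)`` where ``decay_length`` estimates
    ``ell = sigma/sqrt(2 s_m)`` and ``C_hat = exp(a) * ell^(-(d-1)/2)``.
    With exactly two points the fit is exact.  Frequencies must lie in
    (0, 1); zeros are rejected rather than pseudo-counted.
    """
    x = np.asarray(distances, dtype=float)
    f = np.asarray(frequencies, dtype=float)
    if x.shape != f.shape or x.size < 2:
        raise ParameterError("need >= 2 matching (distance, frequency) pairs")
    if np.unique(x).size != x.size:
        raise ParameterError("distances must be distinct")
    if ((f <= 0) | (f >= 1)).any():
        raise ParameterError("frequencies must lie strictly in (0, 1)")
    if d not in (1, 2):
        raise ParameterError(f"d must be 1 or 2, got {d}")
    if d == 2 and (x <= 0).any():
        raise ParameterError("distances must be > 0 for d = 2")
    y = np.log(f) + ((d - 1) / 2.0) * np.log(np.where(x > 0, x, 1.0))
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise ParameterError("frequencies do not decay with distance; no cline fit")
    ell = -1.0 / slope
    C_hat = math.exp(intercept) * ell ** (-(d - 1) / 2.0)
    return C_hat, ell


#: machine-readable flag names emitted by check_assumptions
ASSUMPTION_FLAGS = (
    "interpatch_distance_short",
    "patch_below_critical_width",
    "neighborhood_size_small",
    "p_e_degenerate",
)


def check_assumptions(params: PopulationParams, layout: PatchLayout) -> list[str]:
    """Flag parameter regimes where the asymptotic theory breaks down.

    Returns a (possibly empty) list of flag names:

    * ``interpatch_distance_short``: some inter-patch gap R <= sigma/sqrt(s_m)
      (tail approximation needs well separated patches);
    * ``patch_below_critical_width``: some patch narrower than
      :func:`critical_patch_width` (no stable local polymorphism);
    * ``neighborhood_size_small``: s_m <= 1/(rho sigma^d) (local drift too
      strong for the branching/equilibrium description);
    * ``p_e_degenerate``: 2 s_p / xi2 outside (0, 1).
    """
    flags: list[str] = []
    D = layout.distances
    off_diag = D[~np.eye(layout.n_patches, dtype=bool)]
    if off_diag.size and (off_diag <= params.sigma / math.sqrt(params.s_m)).any():
        flags.append("interpatch_distance_short")
    w_crit = critical_patch_width(params.sigma, params.s_p, params.s_m)
    if any(p.w_lin < w_crit for p in layout.patches):
        flags.append("patch_below_critical_width")
    if params.s_m <= 1.0 / (params.rho * params.sigma**params.d):
        flags.append("neighborhood_size_small")
    p_e = 2.0 * params.s_p / params.xi2
    if not 0.0 < p_e < 1.0:
        flags.append("p_e_degenerate")
    return flags
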