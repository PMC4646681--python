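"""Deterministic migration-selection clines: steady states and their tails.

The expected frequency xi(t, x) of the allele under weak selection and
Gaussian dispersal obeys the reaction-diffusion equation

    d xi/dt = (sigma^2/2) Laplacian(xi) + s(x) xi (1 - xi),

whose steady state is the equilibrium cline around a patch.  (The mean
offspring number multiplying the diffusion term is set to one -- a
near-critical population -- so sigma^2 alone carries the spatial scale.)
For a radially symmetric patch in d dimensions the Laplacian becomes
``d_rr + (d-1)/r d_r``; at the origin symmetry gives ``d_r xi(0) = 0`` and
the operator limit ``d * d_rr``.

Outside the patch, where ``s = -s_m`` and xi is small, the linearized
equation has Bessel-type solutions whose asymptotics give the tail

    q(r) ~ C r^((1-d)/2) exp(-r sqrt(2 s_m)/sigma),

the form used throughout the closed-form theory.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import k0

from .params import ParameterError

__all__ = [
    "ClineProblem",
    "ClineSolution",
    "solve_equilibrium_1d",
    "solve_equilibrium_radial",
    "linearized_tail",
]


@dataclass(frozen=True)
class ClineProblem:
    """Discretized steady-state problem on [0, L] (linear) or [0, r_max] (radial).

    ``s`` holds the signed selection coefficient on the uniform grid
    ``x_i = i * h``.  The grid spacing should be well below the
    characteristic length ``sigma / sqrt(2 max|s|)`` and the domain should
    extend several characteristic lengths past the patch.
    """

    s: np.ndarray
    h: float
    sigma: float
    d: int = 1

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        if s.ndim != 1 or s.size < 5:
            raise ParameterError("need a 1D selection profile with >= 5 nodes")
        if not (self.h > 0 and self.sigma > 0):
            raise ParameterError("h and sigma must be > 0")
        if self.d not in (1, 2):
            raise ParameterError(f"d must be 1 or 2, got {self.d}")
        smax = float(np.max(np.abs(s)))
        if smax > 0 and self.h > self.sigma / math.sqrt(2.0 * smax):
            warnings.warn(
                "grid spacing exceeds the characteristic length; refine the grid",
                stacklevel=2,
            )
        object.__setattr__(self, "s", s)

    @property
    def x(self) -> np.ndarray:
        return self.h * np.arange(self.s.size)

    @classmethod
    def patch_centered(
        cls,
        half_domain: float,
        patch_halfwidth: float,
        s_in: float,
        s_out: float,
        sigma: float,
        h: float,
        d: int = 1,
    ) -> "ClineProblem":
        """Patch of radius ``patch_halfwidth`` at the origin, solved on [0, half_domain].

        By symmetry only the half-line (or the radius) is discretized; the
        origin carries a reflecting condition in both geometries.
        """
        n = int(round(half_domain / h)) + 1
        x = h * np.arange(n)
        s = np.where(x <= patch_halfwidth, float(s_in), float(-abs(s_out)))
        return cls(s=s, h=h, sigma=sigma, d=d)


@dataclass(frozen=True)
class ClineSolution:
    """Steady-state frequency profile with its residual history."""

    x: np.ndarray
    xi: np.ndarray
    residual: float
    residual_history: np.ndarray


def _residual(xi: np.ndarray, prob: ClineProblem, radial: bool) -> np.ndarray:
    """Discrete residual of (sigma^2/2) Lap(xi) + s xi (1 - xi) with Neumann BCs."""
    h, sig2 = prob.h, prob.sigma**2
    # reflecting ghosts at both ends
    padded = np.concatenate(([xi[1]], xi, [xi[-2]]))
    d2 = (padded[:-2] - 2.0 * xi + padded[2:]) / h**2
    F = 0.5 * sig2 * d2 + prob.s * xi * (1.0 - xi)
    if radial and prob.d == 2:
        d1 = (padded[2:] - padded[:-2]) / (2.0 * h)
        r = prob.x
        F[1:] += 0.5 * sig2 * (prob.d - 1) / r[1:] * d1[1:]
        # r -> 0: (d-1)/r d_r -> (d-1) d_rr by symmetry
        F[0] = 0.5 * sig2 * prob.d * d2[0] + prob.s[0] * xi[0] * (1.0 - xi[0])
    return F


def _jacobian_banded(xi: np.ndarray, prob: ClineProblem, radial: bool) -> np.ndarray:
    """Tridiagonal Jacobian of the residual, in solve_banded (1,1) layout."""
    n = xi.size
    h, sig2 = prob.h, prob.sigma**2
    a = 0.5 * sig2 / h**2
    lower = np.full(n, a)
    main = np.full(n, -2.0 * a) + prob.s * (1.0 - 2.0 * xi)
    upper = np.full(n, a)
    # Neumann ghosts fold the off-grid node back in
    upper_first, lower_last = 2.0 * a, 2.0 * a
    if radial and prob.d == 2:
        r = prob.x
        b = 0.5 * sig2 * (prob.d - 1) / (2.0 * h)
        with np.errstate(divide="ignore"):
            binv = np.where(r > 0, b / np.where(r > 0, r, 1.0), 0.0)
        lower = lower - binv
        upper = upper + binv
        # origin row: sigma^2 d/2 * d2 with reflecting ghost
        main[0] = -2.0 * a * prob.d + prob.s[0] * (1.0 - 2.0 * xi[0])
        upper_first = 2.0 * a * prob.d
    ab = np.zeros((3, n))
    ab[0, 1:] = upper[:-1]
    ab[0, 1] = upper_first
    ab[1, :] = main
    ab[2, :-1] = lower[1:]
    ab[2, n - 2] = lower_last
    return ab


def _solve(prob: ClineProblem, tol: float, radial: bool, max_newton: int = 200) -> ClineSolution:
    xi = np.where(prob.s > 0, 0.95, 1e-4)
    history = []
    F = _residual(xi, prob, radial)
    res = float(np.max(np.abs(F)))
    for _ in range(max_newton):
        history.append(res)
        if res < tol:
            break
        ab = _jacobian_banded(xi, prob, radial)
        try:
            step = solve_banded((1, 1), ab, -F)
        except np.linalg.LinAlgError:
            step = None
        improved = False
        if step is not None:
            lam = 1.0
            for _ in range(30):  # damped Newton with backtracking
                trial = np.clip(xi + lam * step, 0.0, 1.0)
                Ft = _residual(trial, prob, radial)
                rt = float(np.max(np.abs(Ft)))
                if rt < res:
                    xi, F, res = trial, Ft, rt
                    improved = True
                    break
                lam *= 0.5
        if not improved:
            # pseudo-timestepping fallback: explicit relaxation steps
            dt = 0.2 * prob.h**2 / prob.sigma**2
            for _ in range(200):
                xi = np.clip(xi + dt * _residual(xi, prob, radial), 0.0, 1.0)
            F = _residual(xi, prob, radial)
            res = float(np.max(np.abs(F)))
    else:
        raise RuntimeError(
            "cline solver did not converge; residual history: "
            + ", ".join(f"{r:.3e}" for r in history[-10:])
        )
    if xi[-1] > 10 * tol:
        warnings.warn(
            "cline frequency is non-negligible at the outer boundary; "
            "enlarge the domain",
            stacklevel=3,
        )
    return ClineSolution(
        x=prob.x, xi=xi, residual=res, residual_history=np.asarray(history)
    )


def solve_equilibrium_1d(problem: ClineProblem, tol: float = 1e-10) -> ClineSolution:
    """Steady state of the 1D cline equation with reflecting boundaries.

    Damped Newton on the central-difference discretization, with explicit
    pseudo-timestepping as a fallback when a Newton step fails to reduce
    the residual.  The returned profile satisfies ``0 <= xi <= 1`` and has
    sup-norm residual below ``tol``.
    """
    return _solve(problem, tol, radial=False)


def solve_equilibrium_radial(problem: ClineProblem, tol: float = 1e-10) -> ClineSolution:
    """Steady state of the radial cline equation on [0, r_max].

    Uses the symmetry condition ``d_r xi(0) = 0`` and replaces the
    ``(d-1)/r`` drift at the origin by its L'Hopital limit.  Passing a
    ``d = 1`` problem through this solver reproduces
    :func:`solve_equilibrium_1d` (the drift term vanishes identically).
    """
    return _solve(problem, tol, radial=True)


def linearized_tail(r, s_m: float, sigma: float, d: int, C_prime: float, r1: float = 0.0):
    """Solution of the linearized (far-field) cline equation beyond the patch.

    For ``d = 1`` the pure exponential ``C' exp(-(r - r1) sqrt(2 s_m)/sigma)``
    (the half-order Bessel function collapses to it); for ``d = 2`` the
    modified Bessel form ``C' K0((r - r1) sqrt(2 s_m)/sigma)``.  Both decay
    at large r like ``r^((1-d)/2) exp(-r sqrt(2 s_m)/sigma)`` up to a
    constant, the tail shape used by the closed-form theory.
    """
    if not (s_m > 0 and sigma > 0):
        raise ParameterError("s_m and sigma must be > 0")
    if d not in (1, 2):
        raise ParameterError(f"d must be 1 or 2, got {d}")
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    if np.any(r <= r1):
        raise ParameterError("linearized tail requires r > r1")
    z = (r - r1) * math.sqrt(2.0 * s_m) / sigma
    u = C_prime * (np.exp(-z) if d == 1 else k0(z))
    return float(u) if scalar else u
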