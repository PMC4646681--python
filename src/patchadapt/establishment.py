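"""Numerical establishment probabilities for a spatial branching process.

A new copy of the allele at deme ``x`` on a 1D lattice founds a branching
process: it leaves a Poisson(1 + s(x)) number of offspring, each of which
independently migrates according to a nearest-neighbor kernel.  Whether
the allele escapes demographic stochasticity is decided while it is rare,
so its establishment probability ``p(x)`` is obtained from the extinction
probability ``q(x) = 1 - p(x)``, the minimal fixed point of the
per-deme generating map

    q_x  <-  exp( -(1 + s(x)) * sum_y m_xy (1 - q_y) ).

Offspring that migrate off the lattice perish (their lineages are extinct
with certainty), so sub-stochastic kernel rows at the boundary simply drop
the lost mass from the sum.  Iterating from ``q = 0`` gives a monotonically
increasing sequence converging to the minimal fixed point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .params import ParameterError

__all__ = [
    "LatticeSelectionProfile",
    "OffspringModel",
    "nearest_neighbor_kernel",
    "extinction_fixed_point",
    "homogeneous_establishment",
]


@dataclass(frozen=True)
class LatticeSelectionProfile:
    """Per-deme selection coefficients on a 1D lattice.

    ``s`` is signed: negative demes are deleterious for the allele.
    ``transition_width`` records how many demes the profile used to
    interpolate linearly between levels (0 for an abrupt step); it is
    informational -- the array ``s`` is what the solver consumes.
    """

    s: np.ndarray
    transition_width: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        if s.ndim != 1 or s.size < 3:
            raise ParameterError("selection profile needs >= 3 demes")
        if not np.isfinite(s).all():
            raise ParameterError("selection profile must be finite")
        object.__setattr__(self, "s", s)

    @property
    def n_demes(self) -> int:
        return self.s.size

    @classmethod
    def step(
        cls,
        n_demes: int,
        patch_start: int,
        patch_stop: int,
        s_in: float,
        s_out: float,
        transition_width: int = 0,
    ) -> "LatticeSelectionProfile":
        """Build a step (or linearly interpolated) profile.

        ``s_in`` applies on ``[patch_start, patch_stop)``, ``s_out``
        elsewhere; with ``transition_width > 0`` the profile ramps linearly
        over that many demes on each side of the patch edges.
        """
        s = np.full(n_demes, float(s_out))
        s[patch_start:patch_stop] = float(s_in)
        tw = int(transition_width)
        if tw > 0:
            ramp = np.linspace(s_out, s_in, tw + 2)[1:-1]
            lo = patch_start - (tw + 1) // 2
            for i, v in enumerate(ramp):
                j = lo + i
                if 0 <= j < n_demes:
                    s[j] = v
            hi = patch_stop - 1 - (tw - 1) // 2
            for i, v in enumerate(ramp[::-1]):
                j = hi + i
                if 0 <= j < n_demes:
                    s[j] = v
        return cls(s=s, transition_width=tw)


@dataclass(frozen=True)
class OffspringModel:
    """Offspring-number family for the branching process.

    Only the Poisson family (mean 1 + s per deme) is implemented for the
    generating-function map; the label is kept so the API can be extended.
    For Poisson offspring with mean ``m`` the variance -- hence the
    effective ``xi2`` -- equals ``m``.
    """

    family: str = "poisson"

    def __post_init__(self) -> None:
        if self.family != "poisson":
            raise NotImplementedError(
                f"only the Poisson offspring family is implemented, got {self.family!r}"
            )


def nearest_neighbor_kernel(n_demes: int, move_prob: float = 0.5) -> sp.csr_matrix:
    """Migration kernel: stay with prob 1 - move_prob, else one step either way.

    ``move_prob = 0.5`` gives stay 0.5 and 0.25 to each neighbor.  Boundary
    rows sum to less than one: offspring stepping off the lattice perish.
    """
    if not 0 <= move_prob <= 1:
        raise ParameterError(f"move_prob must be in [0, 1], got {move_prob}")
    half = move_prob / 2.0
    diags = [
        np.full(n_demes - 1, half),
        np.full(n_demes, 1.0 - move_prob),
        np.full(n_demes - 1, half),
    ]
    return sp.diags(diags, offsets=[-1, 0, 1], format="csr")


def extinction_fixed_point(
    profile: LatticeSelectionProfile,
    migration_kernel: sp.spmatrix | np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
    offspring: OffspringModel = OffspringModel(),
) -> np.ndarray:
    """Establishment probability profile p(x) on the lattice.

    Iterates the Poisson generating map from ``q = 0`` until the sup-norm
    change drops below ``tol`` and returns ``p = 1 - q``.  Raises if the
    iteration has not converged after ``max_iter`` sweeps, reporting the
    last residual.  A warning is emitted if ``p`` at either lattice end
    exceeds ``tol`` (the lattice should be wide enough that boundary losses
    do not touch the patch).
    """
    if not tol > 0:
        raise ParameterError(f"tol must be > 0, got {tol}")
    s = profile.s
    n = s.size
    if migration_kernel is None:
        migration_kernel = nearest_neighbor_kernel(n)
    M = sp.csr_matrix(migration_kernel)
    if M.shape != (n, n):
        raise ParameterError(f"kernel shape {M.shape} does not match {n} demes")
    row_sums = np.asarray(M.sum(axis=1)).ravel()
    if (row_sums > 1.0 + 1e-12).any():
        raise ParameterError("migration kernel rows must sum to <= 1")
    if (M < 0).nnz:
        raise ParameterError("migration kernel must be nonnegative")

    mean_offspring = 1.0 + s
    if (mean_offspring <= 0).any():
        raise ParameterError("offspring mean 1 + s must stay positive")

    q = np.zeros(n)
    resid = math.inf
    for _ in range(int(max_iter)):
        # sum_y m_xy (1 - q_y); lost boundary mass counts as extinct offspring
        survival_mass = row_sums - M @ q
        q_new = np.exp(-mean_offspring * survival_mass)
        resid = float(np.max(np.abs(q_new - q)))
        q = q_new
        if resid < tol:
            break
    else:
        raise RuntimeError(
            f"extinction fixed point did not converge in {max_iter} sweeps; "
            f"last sup-norm change {resid:.3e}"
        )
    p = 1.0 - q
    if p[0] > tol * 10 or p[-1] > tol * 10:
        warnings.warn(
            "establishment probability is nonzero at the lattice boundary; "
            "widen the lattice so boundaries do not affect the patch",
            stacklevel=2,
        )
    return p


def homogeneous_establishment(s: float, offspring: OffspringModel = OffspringModel()) -> float:
    """Scalar establishment probability p solving p = 1 - exp(-(1+s) p).

    The panmictic limit of the lattice fixed point: for a supercritical
    Poisson(1 + s) branching process the survival probability is the
    positive root; for ``s <= 0`` it is 0.  Lies between ``2s/(1+s)`` and
    ``2s`` for small positive ``s``.
    """
    if s <= 0:
        return 0.0
    p, last = 2.0 * s, 0.0
    while abs(p - last) > 1e-15:
        last, p = p, 1.0 - math.exp(-(1.0 + s) * p)
    return p
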