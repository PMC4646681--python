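"""Parameter containers for the patchy-landscape adaptation model.

The model: a single locus with allele ``B`` that is beneficial (selection
``+s_p``) inside discrete habitat patches and deleterious (``-s_m``)
everywhere else.  Dispersal is locally Gaussian with per-axis root mean
squared parent-offspring displacement ``sigma``.  All distances used
anywhere in the package are expressed in the same unit as ``sigma``; no
unit conversion happens internally.

The single most important derived quantity is the characteristic length

    ell = sigma / sqrt(2 * s_m),

the spatial scale over which the equilibrium frequency of ``B`` decays
outside a patch.  Every inter-patch distance in the theory enters only
through ``R / ell``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["ParameterError", "PopulationParams", "Patch", "PatchLayout", "C_PRESETS"]


class ParameterError(ValueError):
    """Raised when a parameter violates its domain constraints."""


#: Named presets for the cline constant C.  ``default`` is the pure-theory
#: convention C = 1; ``calibrated`` is the value (C = 5) that matches the
#: forward deme-lattice simulations of this package (and of the study the
#: model derives from) when predicting times to adaptation by migration.
C_PRESETS = {"default": 1.0, "calibrated": 5.0}


@dataclass(frozen=True)
class PopulationParams:
    """Global scalar parameters of the model.

    Parameters
    ----------
    sigma:
        Dispersal distance: per-axis root mean squared parent-offspring
        displacement per generation (distance units).
    s_m:
        Selective disadvantage of ``B`` outside patches, per generation.
        Stored positive by convention; applied as a disadvantage.
    s_p:
        Selective advantage of ``B`` inside a patch, per generation.
    mu:
        Mutation rate toward ``B``, per chromosome per generation.
    rho:
        Population density per unit area (or per deme, on a lattice).
    xi2:
        Variance in offspring number.
    C:
        Dimensionless cline constant multiplying the equilibrium-frequency
        tail.  Default 1.0; see :data:`C_PRESETS`.
    d:
        Spatial dimension, 1 or 2.
    """

    sigma: float
    s_m: float
    s_p: float
    mu: float
    rho: float
    xi2: float = 1.0
    C: float = 1.0
    d: int = 1

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")
        if not self.s_m > 0:
            raise ParameterError(f"s_m must be > 0, got {self.s_m}")
        if not self.s_p > 0:
            raise ParameterError(f"s_p must be > 0, got {self.s_p}")
        if not 0 <= self.mu < 1:
            raise ParameterError(f"mu must be in [0, 1), got {self.mu}")
        if not self.rho > 0:
            raise ParameterError(f"rho must be > 0, got {self.rho}")
        if not self.xi2 > 0:
            raise ParameterError(f"xi2 must be > 0, got {self.xi2}")
        if not self.C > 0:
            raise ParameterError(f"C must be > 0, got {self.C}")
        if self.d not in (1, 2):
            raise ParameterError(f"d must be 1 or 2, got {self.d}")

    @property
    def char_length(self) -> float:
        """Characteristic length sigma / sqrt(2 s_m)."""
        return self.sigma / math.sqrt(2.0 * self.s_m)

    @property
    def p_e(self) -> float:
        """Panmictic establishment probability, 2 s_p / xi2 clipped to [0, 1]."""
        return min(1.0, 2.0 * self.s_p / self.xi2)

    @property
    def gamma(self) -> float:
        """Family-establishment factor min(1, s_m / p_e)."""
        return min(1.0, self.s_m / self.p_e)

    def with_C(self, preset_or_value: str | float) -> "PopulationParams":
        """Return a copy with the cline constant replaced.

        Accepts a preset name from :data:`C_PRESETS` or a numeric value.
        """
        if isinstance(preset_or_value, str):
            try:
                value = C_PRESETS[preset_or_value]
            except KeyError:
                raise ParameterError(
                    f"unknown C preset {preset_or_value!r}; "
                    f"known presets: {sorted(C_PRESETS)}"
                ) from None
        else:
            value = float(preset_or_value)
        return replace(self, C=value)


@dataclass(frozen=True)
class Patch:
    """Geometry of a single habitat patch.

    ``w_lin`` is the extent of the patch along the axis toward a
    neighboring patch; ``w_perp`` the transverse extent (2D only; for a 1D
    landscape it is ignored and defaults to 1).
    """

    area: float
    w_lin: float
    w_perp: float = 1.0

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ParameterError(f"patch area must be > 0, got {self.area}")
        if not self.w_lin > 0:
            raise ParameterError(f"patch w_lin must be > 0, got {self.w_lin}")
        if not self.w_perp > 0:
            raise ParameterError(f"patch w_perp must be > 0, got {self.w_perp}")


@dataclass(frozen=True)
class PatchLayout:
    """A collection of patches and their pairwise shortest distances.

    ``distances[i, j]`` is the shortest gap between patches i and j, in the
    same unit as ``sigma``.
    """

    patches: tuple[Patch, ...]
    distances: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "patches", tuple(self.patches))
        n = len(self.patches)
        if n == 0:
            raise ParameterError("layout needs at least one patch")
        if self.distances is None:
            object.__setattr__(self, "distances", np.zeros((n, n)))
        else:
            D = np.asarray(self.distances, dtype=float)
            if D.shape != (n, n):
                raise ParameterError(
                    f"distance matrix shape {D.shape} does not match {n} patches"
                )
            if not np.allclose(D, D.T):
                raise ParameterError("distance matrix must be symmetric")
            if not np.allclose(np.diag(D), 0.0):
                raise ParameterError("distance matrix diagonal must be zero")
            if (D < 0).any():
                raise ParameterError("distances must be nonnegative")
            object.__setattr__(self, "distances", D)

    @property
    def n_patches(self) -> int:
        return len(self.patches)
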