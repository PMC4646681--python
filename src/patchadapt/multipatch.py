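"""Colonization of many patches: Markov chain and its Ewens-sampling limit.

With many habitat patches, each not-yet-adapted patch acquires the
adaptation either by a new mutation (rate ``2 s_p mu rho A / xi2``) or by
migration from each already adapted patch, at a rate decaying with the
pairwise gap as ``exp(-R sqrt(2 s_m)/sigma)``.  Patches are assumed not to
interfere (no migration shadowing).  The resulting labeled process is
simulated exactly by a Gillespie algorithm; the compound parameter
``s_p rho`` only rescales time, so the final partition of patches into
shared-origin classes does not depend on it.

In the symmetric island limit (equal areas, equal distances) the sequence
of colonizations is a Chinese restaurant process, and the final partition
of origins follows the Ewens sampling formula with concentration
``theta = w mu exp(R sqrt(2 s_m)/sigma) / (4 s_m)`` -- the effective
mutation-to-migration rate ratio.

The migration rate used by the chain is twice :func:`~patchadapt.theory.lambda_mig`:
the factor restores the family-establishment constant that the printed
single-pair rate absorbs, and makes the two-patch parallel-adaptation
probability of the chain agree exactly with
:func:`~patchadapt.theory.prob_parallel` (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .params import ParameterError, PatchLayout, PopulationParams
from .theory import effective_area, lambda_mig, lambda_mut

__all__ = [
    "PatchNetwork",
    "ColonizationEvent",
    "PartitionState",
    "gillespie_colonization",
    "origin_probabilities",
    "island_theta",
    "chain_theta",
    "ewens_partition_prob",
    "integer_partitions",
    "esf_class_probabilities",
    "expected_num_origins",
]

#: multiplier turning the printed single-pair migration rate into the
#: chain's family-establishment rate (see module docstring)
MIGRATION_RATE_FACTOR = 2.0


@dataclass(frozen=True)
class PatchNetwork:
    """A patch layout plus population parameters, with derived per-patch rates."""

    params: PopulationParams
    layout: PatchLayout

    @property
    def n_patches(self) -> int:
        return self.layout.n_patches

    def mutation_rate(self, j: int) -> float:
        return lambda_mut(self.params, self.layout.patches[j].area)

    def migration_rate(self, i: int, j: int) -> float:
        """Colonization rate of patch j from adapted patch i."""
        R = float(self.layout.distances[i, j])
        A_eff = effective_area(self.layout.patches[j], R, self.params)
        return MIGRATION_RATE_FACTOR * lambda_mig(R, self.params, A_eff)


@dataclass(frozen=True)
class ColonizationEvent:
    time: float
    patch: int
    source: str | int  # "mutation" or the index of the source patch
    label: int  # mutational-origin label carried by the colonizing allele


@dataclass
class PartitionState:
    """Assignment of each patch to a mutational-origin label.

    ``labels[j]`` is ``None`` while patch j is unadapted, otherwise the id
    of the mutation event whose descendants colonized it.  ``events`` is
    the time-ordered colonization log.
    """

    labels: list[int | None]
    events: list[ColonizationEvent] = field(default_factory=list)

    @property
    def n_origins(self) -> int:
        return len({l for l in self.labels if l is not None})

    def class_sizes(self) -> list[int]:
        """Sizes of the shared-origin classes, largest first."""
        sizes: dict[int, int] = {}
        for l in self.labels:
            if l is not None:
                sizes[l] = sizes.get(l, 0) + 1
        return sorted(sizes.values(), reverse=True)


def gillespie_colonization(
    network: PatchNetwork, rng: np.random.Generator
) -> PartitionState:
    """Exact stochastic simulation of the patch-colonization Markov chain.

    Runs until every patch is adapted.  Event times are exponential with
    the current total rate; each event colonizes one unadapted patch by
    either a fresh mutation (new origin label) or migration from one
    adapted patch (inheriting its label).
    """
    n = network.n_patches
    state = PartitionState(labels=[None] * n)
    mut_rates = np.array([network.mutation_rate(j) for j in range(n)])
    mig = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                mig[i, j] = network.migration_rate(i, j)
    t = 0.0
    next_label = 0
    unadapted = set(range(n))
    adapted: list[int] = []
    while unadapted:
        targets = sorted(unadapted)
        rate_mut = mut_rates[targets]
        rate_mig = (
            mig[np.ix_(adapted, targets)].sum(axis=0) if adapted else np.zeros(len(targets))
        )
        total = float(rate_mut.sum() + rate_mig.sum())
        if total <= 0:
            raise ParameterError("total colonization rate is zero; check parameters")
        t += rng.exponential(1.0 / total)
        per_target = rate_mut + rate_mig
        j = targets[rng.choice(len(targets), p=per_target / per_target.sum())]
        p_mut = mut_rates[j] / per_target[targets.index(j)]
        if rng.random() < p_mut:
            label, source = next_label, "mutation"
            next_label += 1
        else:
            weights = mig[adapted, j]
            i = adapted[rng.choice(len(adapted), p=weights / weights.sum())]
            label, source = state.labels[i], i
        state.labels[j] = label
        state.events.append(ColonizationEvent(t, j, source, label))
        unadapted.remove(j)
        adapted.append(j)
    return state


def origin_probabilities(
    network: PatchNetwork, adapted_set: list[int], focal: int
) -> np.ndarray:
    """Probability each adapted patch is the source, given colonization by migration.

    Proportional to ``R_i^(-(d-1)/2) exp(-R_i sqrt(2 s_m)/sigma)`` over the
    adapted patches; equidistant sources are equally likely.
    """
    if not adapted_set:
        raise ParameterError("adapted_set must be nonempty")
    p = network.params
    R = network.layout.distances[np.asarray(adapted_set), focal].astype(float)
    z = R * math.sqrt(2.0 * p.s_m) / p.sigma
    w = z ** (-(p.d - 1) / 2.0) * np.exp(-z)
    return w / w.sum()


def island_theta(w: float, mu: float, s_m: float, R: float, sigma: float) -> float:
    """Ewens concentration parameter of the island-model limit.

    ``theta = w mu exp(R sqrt(2 s_m)/sigma) / (4 s_m)``, with ``w`` the
    patch width in characteristic lengths; it doubles with the mutation
    rate and grows exponentially with the common gap R.
    """
    for name, v in (("w", w), ("mu", mu), ("s_m", s_m), ("sigma", sigma)):
        if not v > 0:
            raise ParameterError(f"{name} must be > 0, got {v}")
    if R < 0:
        raise ParameterError(f"R must be >= 0, got {R}")
    return w * mu * math.exp(R * math.sqrt(2.0 * s_m) / sigma) / (4.0 * s_m)


def chain_theta(network: PatchNetwork) -> float:
    """Concentration parameter implied by a symmetric network's own rates.

    ``lambda_mut / lambda_mig`` per source patch (with the chain's
    migration rate); for a symmetric island network the colonization
    sequence is a Chinese restaurant process with exactly this parameter.
    """
    n = network.n_patches
    if n < 2:
        raise ParameterError("need >= 2 patches")
    return network.mutation_rate(0) / network.migration_rate(0, 1)


def integer_partitions(n: int) -> Iterator[tuple[int, ...]]:
    """All partitions of n as nonincreasing tuples."""

    def rec(n: int, cap: int) -> Iterator[tuple[int, ...]]:
        if n == 0:
            yield ()
            return
        for first in range(min(n, cap), 0, -1):
            for rest in rec(n - first, first):
                yield (first,) + rest

    yield from rec(n, n)


def ewens_partition_prob(partition, theta: float, n: int) -> float:
    """Ewens sampling formula for an unordered partition of n.

    ``partition`` lists the class sizes.  With ``a_j`` classes of size j,

        P = n! / theta^(n) * prod_j (theta/j)^a_j / a_j!

    where ``theta^(n)`` is the rising factorial.  Probabilities over all
    partitions of n sum to one.
    """
    sizes = [int(k) for k in partition]
    if any(k < 1 for k in sizes) or sum(sizes) != n:
        raise ParameterError(f"{partition} is not a partition of {n}")
    if not theta > 0:
        raise ParameterError(f"theta must be > 0, got {theta}")
    a: dict[int, int] = {}
    for k in sizes:
        a[k] = a.get(k, 0) + 1
    rising = 1.0
    for i in range(n):
        rising *= theta + i
    prob = math.factorial(n) / rising
    for j, aj in a.items():
        prob *= (theta / j) ** aj / math.factorial(aj)
    return prob


def esf_class_probabilities(n: int, theta: float) -> dict[tuple[int, ...], float]:
    """Ewens probabilities of every partition class of n (small n)."""
    return {p: ewens_partition_prob(p, theta, n) for p in integer_partitions(n)}


def expected_num_origins(n: int, theta: float) -> float:
    """Expected number of distinct mutational origins among n island patches.

    ``sum_{i=0}^{n-1} theta/(theta + i)``; grows like ``theta log n``.
    """
    return float(sum(theta / (theta + i) for i in range(n)))
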