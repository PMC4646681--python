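"""Forward-time individual-based simulation on a deme lattice.

Demes of fixed size ``N`` sit on a 1D or 2D rectangular grid.  Each
generation:

1. **reproduction** -- every individual independently adds one offspring
   with probability ``r (1 + s(x))`` for carriers of the focal allele
   ``B`` (``s`` signed, from the per-deme selection map) and ``r`` for the
   wild type ``b``;
2. **migration** -- every individual stays with probability ``1 - m``,
   otherwise moves ``k`` steps (``P(k) proportional to 2^-k``,
   ``1 <= k <= 5`` by default) in a uniformly chosen direction (two
   directions in 1D; four cardinal plus four diagonal in 2D, diagonals
   displacing ``(+-k, +-k)``); migrants leaving the grid perish;
3. **resampling** -- each deme is uniformly resampled down to ``N``;
4. **mutation** -- each ``b`` copy mutates to ``B`` with probability ``mu``.

Only the per-deme counts of each type are tracked (the individual-level
description above is equivalent): reproduction is a binomial draw per deme
and type, migration a multinomial allocation over destination offsets,
resampling a hypergeometric draw.  Identical ``(config, seed)`` give
byte-identical results.

Backward in time, lineages of ``B`` alleles are traced by reverse
migration weighted by the ``B`` counts of the source demes, with uniform
within-deme coalescence, and the length of ancestral haplotype still
linked to the selected locus is eroded by one recombination opportunity
per generation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .params import ParameterError

__all__ = [
    "DemeGridConfig",
    "SimResult",
    "LineageSample",
    "default_step_kernel",
    "effective_selection",
    "offspring_variance",
    "dispersal_sigma",
    "run_forward",
    "time_to_adaptation",
    "trace_lineages",
    "shared_haplotype_decay",
]


def default_step_kernel(k_max: int = 5) -> np.ndarray:
    """Step-length distribution P(k) proportional to 2^-k for 1 <= k <= k_max."""
    p = 0.5 ** np.arange(1, k_max + 1)
    return p / p.sum()


@dataclass(frozen=True)
class DemeGridConfig:
    """Configuration of the lattice simulator.

    ``s_map`` is the signed per-deme selection multiplier for ``B`` (the
    allele reproduces with probability ``r (1 + s)``), ``init`` the initial
    ``B`` counts per deme, ``focal_mask`` the demes whose summed ``B``
    count defines "adaptation" (defaults to the demes with ``s > 0``).
    With ``stop_when_adapted`` the run ends as soon as the focal count
    reaches ``adapt_threshold``.
    """

    shape: tuple[int, ...]
    N: int
    s_map: np.ndarray
    mu: float
    t_max: int
    r: float = 0.3
    m: float = 0.2
    kernel: np.ndarray = field(default_factory=default_step_kernel)
    init: np.ndarray | None = None
    focal_mask: np.ndarray | None = None
    adapt_threshold: int = 100
    stop_when_adapted: bool = False

    def __post_init__(self) -> None:
        shape = (self.shape,) if isinstance(self.shape, int) else tuple(self.shape)
        if len(shape) not in (1, 2) or any(n < 1 for n in shape):
            raise ParameterError(f"shape must be 1D or 2D and positive, got {shape}")
        object.__setattr__(self, "shape", shape)
        if self.N < 1:
            raise ParameterError(f"N must be >= 1, got {self.N}")
        s = np.asarray(self.s_map, dtype=float).reshape(shape)
        object.__setattr__(self, "s_map", s)
        if not 0 <= self.mu < 1:
            raise ParameterError(f"mu must be in [0, 1), got {self.mu}")
        if not 0 <= self.m <= 1:
            raise ParameterError(f"m must be in [0, 1], got {self.m}")
        pmax = self.r * (1.0 + float(s.max()))
        if not 0 <= self.r <= 1 or pmax > 1 or self.r * (1.0 + float(s.min())) < 0:
            raise ParameterError(
                f"reproduction probabilities r(1+s) must lie in [0, 1]; "
                f"r = {self.r}, s in [{s.min()}, {s.max()}]"
            )
        kern = np.asarray(self.kernel, dtype=float)
        if (kern < 0).any() or kern.sum() <= 0:
            raise ParameterError("kernel masses must be nonnegative with positive sum")
        object.__setattr__(self, "kernel", kern / kern.sum())
        if self.init is None:
            object.__setattr__(self, "init", np.zeros(shape, dtype=np.int64))
        else:
            init = np.asarray(self.init, dtype=np.int64).reshape(shape)
            if (init < 0).any() or (init > self.N).any():
                raise ParameterError("init counts must lie in [0, N]")
            object.__setattr__(self, "init", init)
        if self.focal_mask is None:
            object.__setattr__(self, "focal_mask", s > 0)
        else:
            object.__setattr__(
                self, "focal_mask", np.asarray(self.focal_mask, dtype=bool).reshape(shape)
            )

    @property
    def d(self) -> int:
        return len(self.shape)

    def offsets(self) -> tuple[np.ndarray, np.ndarray]:
        """Destination offsets and their probabilities, including staying put."""
        ks = np.arange(1, self.kernel.size + 1)
        if self.d == 1:
            offs = [(0,)] + [(sgn * k,) for k in ks for sgn in (1, -1)]
            probs = [1.0 - self.m] + [
                self.m * self.kernel[k - 1] / 2.0 for k in ks for _ in (0, 1)
            ]
        else:
            dirs = [(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1)]
            offs = [(0, 0)] + [(dx * k, dy * k) for k in ks for dx, dy in dirs]
            probs = [1.0 - self.m] + [
                self.m * self.kernel[k - 1] / 8.0 for k in ks for _ in dirs
            ]
        return np.array(offs, dtype=np.int64), np.array(probs)


@dataclass(frozen=True)
class SimResult:
    """Per-generation ``B``-allele counts and the adaptation time.

    ``counts`` has shape ``(n_generations + 1, *shape)``; row 0 is the
    initial state.  ``adaptation_time`` is the first generation at which
    the focal demes held at least ``adapt_threshold`` copies, or ``None``.
    """

    counts: np.ndarray
    adaptation_time: int | None
    config: DemeGridConfig
    seed: int

    def tobytes(self) -> bytes:
        """Canonical byte serialization of the trajectory (for reproducibility checks)."""
        return self.counts.astype(np.int64).tobytes()


def effective_selection(r: float, s: float) -> float:
    """Intrinsic per-generation log growth rate of the rare allele.

    Before resampling, carriers multiply by ``1 + r (1 + s)`` per
    generation against ``1 + r`` for the wild type, so rare-copy numbers
    change by ``exp(s_eff t)`` with
    ``s_eff = log((1 + r (1 + s)) / (1 + r))``.  This is the selection
    coefficient to use when comparing lattice simulations with the
    continuum theory.
    """
    if r * (1.0 + s) > 1:
        raise ParameterError("r (1 + s) must be <= 1")
    return math.log((1.0 + r * (1.0 + s)) / (1.0 + r))


def offspring_variance(r: float, s: float = 0.0) -> float:
    """Effective offspring-number variance of the lattice life cycle.

    A rare allele's carrier survives and adds one offspring with
    probability ``r (1 + s)``; uniform resampling back to deme size then
    keeps each candidate with probability ``1/(1 + r)``, so the carrier's
    offspring number is Binomial(1 + Bernoulli(r(1+s)), 1/(1+r)) with
    variance ``2 r (1+s) / (1 + r)^2`` at neutrality-scale survival.  This
    is the ``xi2`` to use when applying the closed-form theory (e.g. the
    establishment probability ``2 s_eff / xi2``) to this simulator.
    """
    p_rep = r * (1.0 + s)
    if not 0 <= p_rep <= 1:
        raise ParameterError("r (1 + s) must lie in [0, 1]")
    return 2.0 * p_rep / (1.0 + r) ** 2


def dispersal_sigma(m: float, kernel: np.ndarray | None = None, d: int = 1) -> float:
    """Per-axis RMS parent-offspring displacement of the lattice kernel.

    ``sqrt(m E[k^2] c_d)`` in deme spacings, with ``c_1 = 1`` and, for the
    implemented 2D direction set (4 cardinal + 4 diagonal moves of
    displacement ``(+-k, +-k)``), ``c_2 = 3/4``.
    """
    kern = default_step_kernel() if kernel is None else np.asarray(kernel, dtype=float)
    kern = kern / kern.sum()
    ks = np.arange(1, kern.size + 1)
    Ek2 = float((kern * ks**2).sum())
    c_d = 1.0 if d == 1 else 0.75
    return math.sqrt(m * Ek2 * c_d)


def _migrate_pair(n_B: np.ndarray, n_b: np.ndarray, offs: np.ndarray,
                  probs: np.ndarray, shape: tuple[int, ...],
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial allocation of both type-count grids over destination offsets.

    One batched multinomial draw covers both types; off-grid migrants perish.
    """
    stacked = np.stack([n_B.ravel(), n_b.ravel()])
    alloc = rng.multinomial(stacked, probs)  # (2, n_demes, n_offsets)
    out = np.zeros((2,) + shape, dtype=n_B.dtype)
    def _span(n: int, off: int) -> tuple[int, int]:
        return max(0, off), n + min(0, off)

    if len(shape) == 1:
        n = shape[0]
        grid_alloc = alloc.reshape(2, n, -1)
        for j in range(offs.shape[0]):
            ox = int(offs[j, 0])
            lo, hi = _span(n, ox)
            if hi > lo:
                out[:, lo:hi] += grid_alloc[:, lo - ox : hi - ox, j]
    else:
        nx, ny = shape
        grid_alloc = alloc.reshape(2, nx, ny, -1)
        for j in range(offs.shape[0]):
            ox, oy = int(offs[j, 0]), int(offs[j, 1])
            lx, hx = _span(nx, ox)
            ly, hy = _span(ny, oy)
            if hx > lx and hy > ly:
                out[:, lx:hx, ly:hy] += grid_alloc[
                    :, lx - ox : hx - ox, ly - oy : hy - oy, j
                ]
    return out[0], out[1]


def run_forward(config: DemeGridConfig, seed: int) -> SimResult:
    """Run the forward lattice simulation; see the module docstring for the cycle.

    The generation cycle is reproduce -> migrate -> resample -> mutate
    (mutation last keeps ``mu`` per individual per surviving generation).
    """
    rng = np.random.default_rng(seed)
    shape = config.shape
    offs, probs = config.offsets()
    s = config.s_map
    p_B = np.clip(config.r * (1.0 + s), 0.0, 1.0)

    n_B = config.init.copy()
    n_b = config.N - n_B
    history = np.empty((config.t_max + 1,) + shape, dtype=np.int32)
    history[0] = n_B
    focal = config.focal_mask
    adaptation_time: int | None = None
    if int(n_B[focal].sum()) >= config.adapt_threshold:
        adaptation_time = 0

    t_stop = config.t_max
    for t in range(1, config.t_max + 1):
        # 1. reproduction (offspring added on top of parents)
        n_B = n_B + rng.binomial(n_B, p_B)
        n_b = n_b + rng.binomial(n_b, config.r)
        # 2. migration; off-grid migrants perish
        n_B, n_b = _migrate_pair(n_B, n_b, offs, probs, shape, rng)
        # 3. uniform resampling back down to N per deme
        total = n_B + n_b
        keep = np.minimum(total, config.N)
        empty = total == 0
        n_B = np.where(
            empty, 0, rng.hypergeometric(n_B, n_b + empty, keep)
        )
        n_b = keep - n_B
        # 4. mutation b -> B
        if config.mu > 0:
            mutants = rng.binomial(n_b, config.mu)
            n_B = n_B + mutants
            n_b = n_b - mutants
        history[t] = n_B
        if adaptation_time is None and int(n_B[focal].sum()) >= config.adapt_threshold:
            adaptation_time = t
            if config.stop_when_adapted:
                t_stop = t
                break

    return SimResult(
        counts=history[: t_stop + 1],
        adaptation_time=adaptation_time,
        config=config,
        seed=seed,
    )


def time_to_adaptation(
    result: SimResult, threshold: int | None = None, focal_mask: np.ndarray | None = None
) -> int | None:
    """First generation with at least ``threshold`` focal-patch B copies, or None.

    Defaults to the result's configured threshold and focal demes;
    lowering the threshold can only report an earlier (or equal) time.
    """
    thr = result.config.adapt_threshold if threshold is None else threshold
    mask = result.config.focal_mask if focal_mask is None else np.asarray(focal_mask, bool)
    totals = result.counts[:, mask].sum(axis=1)
    reached = np.nonzero(totals >= thr)[0]
    return int(reached[0]) if reached.size else None


@dataclass(frozen=True)
class LineageSample:
    """Backward-traced lineage locations and coalescence events.

    ``locations[g, i]`` is the deme of lineage ``i`` at generation ``g``
    (forward time; the trace runs from ``g = start`` down to 0), ``-1``
    where the lineage has terminated at a mutational origin or merged into
    another lineage.  ``coalescences`` holds ``(generation, deme, kept
    lineage, merged lineage)``; ``origins`` holds ``(generation, deme,
    lineage)`` where a lineage could no longer be traced back (the allele
    arose there by mutation).
    """

    locations: np.ndarray
    coalescences: list[tuple[int, int, int, int]]
    origins: list[tuple[int, int, int]]


def trace_lineages(
    result: SimResult,
    sample_demes: Sequence[int],
    rng: np.random.Generator,
    start_generation: int | None = None,
) -> LineageSample:
    """Trace sampled B-allele lineages backward through a 1D simulation.

    Each generation, a lineage in deme ``x`` steps to source deme ``y``
    with probability proportional to the forward migration probability of
    ``y -> x`` times the number of B alleles in ``y`` in the previous
    generation.  Lineages landing in the same source deme holding ``n``
    alleles each pick a uniform label in ``1..n``; equal labels coalesce.
    A lineage with no available source terminates: its allele arose by
    mutation at that point.
    """
    if result.config.d != 1:
        raise NotImplementedError("lineage tracing is implemented for 1D grids")
    counts = result.counts
    T = counts.shape[0] - 1
    g0 = T if start_generation is None else int(start_generation)
    if not 0 <= g0 <= T:
        raise ParameterError(f"start_generation must be in [0, {T}]")
    for x in sample_demes:
        if counts[g0, x] <= 0:
            raise ParameterError(f"cannot sample a lineage from empty deme {x} at {g0}")
    offs, probs = result.config.offsets()
    offs = offs[:, 0]
    n_demes = result.config.shape[0]
    n_lin = len(sample_demes)

    locations = np.full((g0 + 1, n_lin), -1, dtype=np.int64)
    locations[g0] = np.asarray(sample_demes, dtype=np.int64)
    alive = np.ones(n_lin, dtype=bool)
    coalescences: list[tuple[int, int, int, int]] = []
    origins: list[tuple[int, int, int]] = []

    for g in range(g0, 0, -1):
        prev = counts[g - 1]
        new_pos = np.full(n_lin, -1, dtype=np.int64)
        for i in np.nonzero(alive)[0]:
            x = locations[g, i]
            sources = x - offs
            ok = (sources >= 0) & (sources < n_demes)
            weights = np.where(ok, probs * prev[np.clip(sources, 0, n_demes - 1)], 0.0)
            wsum = weights.sum()
            if wsum == 0:
                origins.append((g, int(x), int(i)))
                alive[i] = False
                continue
            j = rng.choice(weights.size, p=weights / wsum)
            new_pos[i] = sources[j]
        # within-deme coalescence by uniform labels
        for y in np.unique(new_pos[new_pos >= 0]):
            here = np.nonzero(new_pos == y)[0]
            if here.size < 2:
                continue
            labels = rng.integers(0, prev[y], size=here.size)
            seen: dict[int, int] = {}
            for idx, i in enumerate(here):
                lab = int(labels[idx])
                if lab in seen:
                    coalescences.append((g - 1, int(y), seen[lab], int(i)))
                    alive[i] = False
                    new_pos[i] = -1
                else:
                    seen[lab] = int(i)
        locations[g - 1] = np.where(alive, new_pos, -1)
    return LineageSample(locations=locations, coalescences=coalescences, origins=origins)


def shared_haplotype_decay(
    deme_path: Sequence[int],
    local_freq: Sequence[float],
    rng: np.random.Generator,
    initial_length: float = 1.0,
) -> np.ndarray:
    """Erosion of the ancestral haplotype along a traced lineage.

    ``deme_path`` gives the lineage's deme per generation and
    ``local_freq`` the local B-allele frequency there (the probability the
    recombination partner carries the same background).  Per generation
    and per side of the selected locus, a crossover falls at distance
    ``X ~ Exponential(1)`` Morgans; with probability ``1 - q_local`` the
    partner is a non-carrier and the shared length drops to ``min(L, X)``.
    Returns the trajectory of the two flanking lengths, shape
    ``(len(deme_path) + 1, 2)``, starting from ``initial_length`` per side
    (a configured chromosome half-length).
    """
    q = np.asarray(local_freq, dtype=float)
    if len(deme_path) != q.size:
        raise ParameterError("deme_path and local_freq lengths differ")
    L = np.full(2, float(initial_length))
    out = np.empty((q.size + 1, 2))
    out[0] = L
    for t in range(q.size):
        X = rng.exponential(size=2)
        swap = rng.random(2) >= q[t]  # partner is a non-carrier background
        L = np.where(swap, np.minimum(L, X), L)
        out[t + 1] = L
    return out.copy()
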