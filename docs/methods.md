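# Methods

This note records the model, the conventions, the numerical choices, and
the known limits of validity of `patchadapt`, in the order a reader
checking results against the code is likely to need them.

## Model and assumptions

A single biallelic locus in a continuously distributed, effectively
haploid population: allele *B* has intrinsic growth advantage *s_p* inside
habitat patches, disadvantage *s_m* > 0 elsewhere. Density ρ is uniform
(patches included), offspring-number variance is ξ², dispersal is locally
Gaussian with per-axis RMS displacement σ per generation. The theory is
asymptotic in the regime where all of the following hold (they are
checked by `theory.check_assumptions`):

* patches wider than the swamping limit
  (σ/√(2 s_p))·arctan(√(s_m/s_p)), so a stable local polymorphism exists;
* inter-patch gaps R larger than σ/√s_m, so the cline tail is in its
  asymptotic regime;
* neighborhood size large relative to selection, s_m > 1/(ρ σ^d), so
  local drift does not overwhelm the branching-process description of the
  allele where it is rare;
* 0 < 2 s_p/ξ² < 1, so the establishment probability is a probability.

Dominance is ignored (dynamics while rare are heterozygote dynamics;
recessives behave qualitatively differently and are out of scope), as are
heavy-tailed dispersal, standing variation, and polygenic architectures.

## The two colonization rates and the factor-of-two convention

`lambda_mut = 2 s_p ρ A μ / ξ²` is the mutational influx times the
establishment probability p_e ≈ 2 s_p/ξ².

`lambda_mig(R) = C A′ ρ s_m min(s_m, p_e) (R/ℓ)^{-(d-1)/2} e^{-R/ℓ}`,
with ℓ = σ/√(2 s_m) and A′ the area of the target patch within one ℓ of
the gap, is the single-pair migration rate in its conventional printed
form. Its derivation from the migrant-family decomposition — the rate is
ρ·q(S) times the family-establishment factor
E[1−(1−p_e)^K]·2s_m/E[K] (exposed as `theory.exact_migration_factor`) —
carries an additional factor of 2 in the small-p_e limit that the printed
form absorbs into the constant. The package resolves this consistently:

* `lambda_mig` implements the printed form;
* `prob_parallel` implements the width-scaled ratio
  [wμ/(2 s_m)] / ([wμ/(2 s_m)] + C γ (R/ℓ)^{-(d-1)/2} e^{-R/ℓ}), which is
  exactly ½ at `critical_gap_distance`;
* the colonization chain (`multipatch`) uses 2·`lambda_mig` as its
  migration rate (`MIGRATION_RATE_FACTOR = 2`), which makes the chain's
  two-patch parallel-adaptation fraction agree identically with
  `prob_parallel`.

The Ewens concentration of the island limit is implemented as printed,
θ = wμ e^{R/ℓ}/(4 s_m); the chain's own concentration is
λ_mut/(2 λ_mig) = wμ e^{R/ℓ}/(2 C γ s_m), so the printed constant
corresponds to C γ = 2. Tests of the Ewens limit therefore use the
chain's own rate ratio (`chain_theta`), plus the algebraic identity at
C γ = 2.

## The cline constant C

C is not derived from first principles anywhere; it is the amplitude
matching the nonlinear cline to its exponential tail, and it depends on
patch geometry and on which corrections it is asked to absorb. Three
anchor points computed by this package:

* deterministic PDE solution, 10-deme patch, raw multipliers 0.1/−0.02 on
  the lattice life cycle: C ≈ 0.84 (the occupancy-profile convention);
* deterministic PDE, 99-deme patch, same s_out: C ≈ 0.44; at weaker
  s_out = −0.005, C ≈ 0.77;
* the **calibrated preset C = 5** (`C_PRESETS["calibrated"]`) is the
  value used for predicting *times to adaptation by migration* from
  `lambda_mig`. It is much larger than the tail amplitude because it also
  absorbs the factor-of-two above, the gap between min(s_m, p_e) and the
  exact family-establishment factor, and transit/growth delays. Measured
  end to end against this package's simulator, the C = 5 prediction is
  accurate (within a factor of 2) only in the weak-selection regime where
  those corrections are mild — p_e·E[K] ≲ a few, waiting time ≫ transit
  time — which is also the regime the theory's own applicability
  conditions select. Outside it (e.g. s_m,eff ≥ p_e) the C = 5 convention
  overpredicts the migration rate several-fold; `lambda_mig`'s docstring
  and `check_assumptions` delimit the trusted region.

`fit_cline` estimates (C, ℓ) from field frequencies by ordinary least
squares on log q + ((d−1)/2)·log x against x; zero frequencies are
rejected rather than pseudo-counted, and with two points the fit is
exact. This is the package's own convention; published cline widths fit
under other conventions can differ by factors of order √2–2.

## Establishment probabilities (lattice fixed point)

A new copy at deme x founds a branching process with Poisson(1 + s(x))
offspring and nearest-neighbor migration (stay 0.5, 0.25 to each side —
the interpretation adopted for "migration rate 0.5 between neighboring
demes"; the alternative reading, 0.25 total movement, shifts p(x) only
slightly). The extinction profile is the minimal fixed point of
q_x ← exp(−(1+s(x))·Σ_y m_xy(1−q_y)), iterated from q ≡ 0 (monotone,
damping-independent), tolerance 1e−12 sup-norm, max 10⁶ sweeps.
Off-lattice offspring perish, i.e. count as extinct lineages; this is why
the sum runs over (1−q_y) rather than the spec-sheet shorthand
1 − Σ m q, which coincides with it on interior rows. Only the Poisson
family is implemented; the `OffspringModel.family` label is reserved.
The scalar (panmictic) limit solves p = 1 − e^{−(1+s)p}; note this lies
slightly *below* 2s/(1+s), and well below 2s.

## Cline solver

Steady states of (σ²/2)ξ″ + ((d−1)/r)(σ²/2)ξ′ + s(x)ξ(1−ξ) = 0 with
reflecting boundaries, by damped Newton on the second-order central
discretization with banded Jacobian; iterates are clipped to [0,1], and
200 explicit pseudo-timesteps (dt = 0.2 h²/σ²) are taken whenever a
Newton step fails to reduce the residual. At r = 0 the symmetric
L'Hôpital stencil σ²d/2·ξ″ replaces the singular drift. The
mean-offspring factor in front of the diffusion term is set to one
(near-critical reproduction); σ² alone carries the scale. Convergence
under mesh refinement is O(h²) for smooth s(x); a discontinuous
selection step degrades the sup-norm rate to O(h) locally at the jump,
so step profiles should be resolved with h ≪ ℓ and interpreted
accordingly. The domain must extend several ℓ past the patch; the solver
warns when the boundary value exceeds 10× the tolerance.

## Transit theory and its Monte-Carlo oracles

The trunk of a migrant family is Brownian (variance σ²/generation),
killed at rate s_m (the family-lifetime approximation
1 − k_e(t) ≈ e^{−s_m t}/E[K]). Closed forms: Laplace transform of the
hitting time (exponential in 1D, K₀ ratio in 2D with target radius w),
conditioned transit-time mean (R/ℓ)/(2 s_m) and variance (R/ℓ)/(2 s_m)²
(1D only; no closed conditioned moments are exposed for 2D), haplotype
survival P{L>ℓ} = exp(−(R/σ)(√(2(ℓ+s_m)) − √(2 s_m))), and the
within-patch occupation time g. The printed variance expansion
Var[L] = 2 s_m σ²/R² + 4σ³√(2 s_m)/R³ + 5σ⁴/R⁴ was re-derived from the
representation L = (Y+√s_m)² − s_m, Y ~ Exp(R√2/σ), and is exact.

The Monte-Carlo oracle is Euler–Maruyama with Δt = 0.01 generations and
per-step killing probability 1 − e^{−s_m Δt}. By default a Brownian-bridge
within-step crossing correction (probability
e^{−2(R−x₀)(R−x₁)/(σ²Δt)}) removes the O(√Δt) discrete-monitoring bias
of first-crossing detection; without it that bias is present. Default
family offspring distribution: Poisson with mean e^{−s_m}.

## Forward simulator

Demes of fixed size N on a 1D/2D grid; per generation: (1) each
individual adds one offspring with probability r(1+s(x)) (r = 0.3
default; s signed per deme); (2) each individual stays with probability
1 − m (m = 0.2) or moves k steps, P(k) ∝ 2^{−k}, k ≤ 5, in a uniform
direction — 2 directions in 1D, 8 in 2D with diagonal displacement
(±k, ±k); off-grid migrants perish; (3) uniform resampling down to N;
(4) b→B mutation with probability μ. Mutation is placed last in the
cycle (the original ordering is not fixed by the source description;
last keeps μ per individual per generation). All updates are
counts-level: binomial reproduction, one batched multinomial migration
allocation per generation, multivariate-hypergeometric resampling —
equivalent to the individual description. Identical (config, seed) give
byte-identical trajectories.

Calibrations connecting the lattice to the continuum theory:

* dispersal: σ = √(m·E[k²]·c_d) per axis, = 0.95 deme spacings in 1D at
  the defaults; the implemented 2D direction set gives c₂ = 3/4 and
  σ ≈ 0.83 — the package reports its computed value and asserts no other;
* selection: s_eff = log((1 + r(1+s))/(1 + r)), e.g. raw 0.01 → 0.0023;
* offspring variance: the life cycle (survive + Bernoulli(r(1+s)) birth,
  then resample) has ξ² = 2r(1+s)/(1+r)² ≈ 0.355 at the defaults
  (`offspring_variance`), under a with-replacement approximation of the
  resampling. Measured directly, single-copy establishment is ≈ 0.018
  versus 2s_eff/ξ² ≈ 0.013 — without-replacement resampling reduces the
  variance further — a ~35% approximation consistent with the factor-2
  tolerances used wherever simulator and theory are compared.

Backward lineage tracing (1D) follows the reverse-migration weights
m(y→x)·n_B(y, t−1); lineages in a deme with n copies draw uniform labels
1..n and coalesce on collision; a lineage with no occupied source
terminates at its mutational origin. Haplotype erosion applies one
Exp(1)-Morgan crossover opportunity per generation per side, truncating
the shared length with probability 1 − q_local.

## Study conditions for the validation experiments

The adaptation-time experiments mirror the standard design: a 501-deme
line, 99-deme patches, threshold 100 copies, 20 replicates, raw
in-patch multiplier 0.01 (s_p,eff = 0.0023).

* Mutation route: ρ = 1000, μ = 10⁻⁵, raw s_out = −0.02, horizon 25 000
  generations. Predicted waiting time 1/λ_mut ≈ 78 generations using the
  lattice's own ξ²; observed median ≈ 85.
* Migration route: chosen inside the validity region of the C = 5
  calibration (see above): raw s_out = −0.005 (s_m,eff = 0.00116,
  ℓ ≈ 19.9 demes), N = 1500, gap 150 demes ≈ 7.6 ℓ, μ = 0 to isolate
  the route, horizon 30 000. Here the waiting time (≈10⁴ generations)
  dominates the ≈3000-generation conditioned transit, and the
  neighborhood-size condition holds (s_m·ρσ ≈ 1.7).

What the simulator emulates — discrete demes, fixed N, truncated
geometric step kernel, haploid selection — and what it does not: real
landscapes' heterogeneous density, long-distance dispersal, diploidy
and dominance, linked selection beyond the single tracked locus.
Passing validation therefore shows the *theory tracks this class of
stepping-stone dynamics*, not that field systems obey factor-2
predictions.

## Numerical conventions

Distances share σ's unit throughout; no internal conversion. Haplotype
lengths are in Morgans (centimorgans only in display columns). All
randomness flows through `numpy.random.Generator` seeded per replicate;
CLI runs record config hash, seeds, version and outputs in a manifest.
TSV outputs are headered, deterministic in order, and C-locale formatted.
`critical_gap_distance` returns 0 with a machine-readable
`mutation_always_faster` flag when the mutational influx wins at any
distance, rather than a negative length. γ = min(1, s_m/p_e) is computed
from the parameters and can be overridden where a calculation calls for
a fixed γ = 1 convention (the worked pocket-mouse example does).

## Known limitations

* 2D is supported in the closed forms, the radial cline solver, and the
  forward simulator, but establishment profiles, conditioned
  transit-time moments, and lineage tracing are 1D (matching what the
  theory provides in closed form).
* `lambda_mig` is non-monotone in s_m outside s_m > R²/(2σ²); this is a
  property of the approximation, documented rather than patched.
* The Ewens island limit ignores migration shadowing between adapted
  patches (patch non-interference), as the chain construction assumes.
* The C = 5 time-to-adaptation calibration is regime-limited, as
  detailed above; for quantitative work fit C to your own system via
  `fit_cline` or the PDE solver.
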