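# patchadapt

Theory and simulation of **convergent local adaptation to patchy
landscapes**: when a species spans several patches of unusual habitat
(lava flows, serpentine outcrops, mine tailings), does each patch adapt by
its own new mutation — convergently — or does one adaptive allele spread
between patches by migration, despite being selected against in between?

The package is for population geneticists and evolutionary ecologists who
want to put numbers on that question: the rates of the two routes, the
probability of parallel adaptation as a function of inter-patch distance,
the genomic signature (shared haplotype length) left when migration wins,
and forward simulations to check all of it.

## Model

A single allele *B* has advantage *s*<sub>p</sub> inside habitat patches
and disadvantage *s*<sub>m</sub> elsewhere; mutation toward *B* occurs at
rate *μ* per chromosome per generation, density is *ρ*, offspring-number
variance is *ξ*², and dispersal is locally Gaussian with per-axis RMS
displacement *σ*. Every distance in the theory enters through the
**characteristic length** ℓ = *σ*/√(2*s*<sub>m</sub>), the decay scale of
the migration–selection cline

> *q*(*x*) ≈ *C* (*x*/ℓ)<sup>−(d−1)/2</sup> e<sup>−*x*/ℓ</sup>.

An unadapted patch of area *A* gains the allele

* by **mutation** at rate λ<sub>mut</sub> = 2*s*<sub>p</sub>*ρAμ*/*ξ*², and
* by **migration** from an adapted patch at gap *R* at rate
  λ<sub>mig</sub>(*R*) = *C A*′*ρ s*<sub>m</sub> min(*s*<sub>m</sub>, *p*<sub>e</sub>)
  (*R*/ℓ)<sup>−(d−1)/2</sup> e<sup>−*R*/ℓ</sup>,

where *p*<sub>e</sub> ≈ 2*s*<sub>p</sub>/*ξ*² is the establishment
probability and *A*′ the area of the patch within one ℓ of the gap. The
probability the patch adapts by an independent mutation rises
logistically in *R* and crosses ½ at the **critical gap**

> *R*/*σ* = log(2*γs*<sub>m</sub>/(*wμ*)) / √(2*s*<sub>m</sub>),

with *w* = *A*/*A*′ the patch width in characteristic lengths and
*γ* = min(1, *s*<sub>m</sub>/*p*<sub>e</sub>). Migrant alleles that do
cross arrive carrying an ancestral haplotype of expected genetic length
E[*L*] = *σ*√(2*s*<sub>m</sub>)/*R* + *σ*²/*R*² per side (in Morgans),
because the successful "trunk" lineage behaves as Brownian motion killed
at rate *s*<sub>m</sub>.

Modules: `theory` (closed forms above), `establishment` (branching-process
fixed point for *p*(*x*) on a lattice), `cline` (steady-state PDE solver,
linear and radial), `transit` (killed-Brownian hitting times and
haplotype lengths, with Monte-Carlo oracles), `simulator` (forward
deme-lattice simulation, backward lineage tracing, haplotype erosion),
`multipatch` (Gillespie colonization chain and its Ewens-sampling island
limit), plus JSON config plumbing and a CLI (`patchadapt --help`).

## Worked example: rock pocket mice on lava flows

Dark-pelage *Chaetodipus intermedius* populations occupy dark lava flows
separated by light rock. With *σ* ≈ 1 km, cline widths bracketing
*s*<sub>m</sub> ∈ {1/9, 1/900}, mutational target bracketing
*μ* ∈ {10⁻⁸, 10⁻⁵}, and a 100 km² patch:

```python
import numpy as np
from patchadapt.applications import pocket_mouse_grid

df = pocket_mouse_grid(R_km=np.array([30.0, 100.0]))
print(df.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
```

```
 R_km     s_m    mu  cline_width_km  prob_parallel  mean_haplotype_cM
   30   0.111 1e-08               3          0.227               1.68
  100   0.111 1e-08               3              1              0.481
   30   0.111 1e-05               3          0.997               1.68
  100   0.111 1e-05               3          1                  0.481
   30 0.00111 1e-08              30       1.85e-05              0.268
  100 0.00111 1e-08              30       0.000502             0.0571
   30 0.00111 1e-05              30         0.0182              0.268
  100 0.00111 1e-05              30          0.334             0.0571
```

Reading the table: with a steep cline (width 3 km) and a kilobase-scale
mutational target (*μ* = 10⁻⁵), outcrops even 30 km apart almost surely
adapt by independent mutations (`prob_parallel` ≈ 1) — convergent
evolution is the expectation. With a shallow cline (30 km) and a
single-base target, migration dominates out to 100 km and beyond — but the
shared haplotype it leaves (`mean_haplotype_cM` ≈ 0.06 cM at 100 km,
roughly 60 kb in a typical mammal) would be hard to detect.

The same sweep is available from the shell:

```bash
patchadapt pocketmouse --out mouse.tsv
patchadapt transit --R 100 --sigma 1 --s-m 0.05 --out transit_summary
```

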