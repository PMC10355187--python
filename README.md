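# oceanhsrl

Forward simulation and inversion for a **triple-field-of-view oceanic
high-spectral-resolution lidar (HSRL)** — an active remote-sensing technique
that measures vertical profiles of seawater inherent optical properties.
The package is for ocean-optics and marine-biogeochemistry researchers who
want to study, stress-test or extend multi-FOV lidar retrievals without an
instrument: every stage of the measurement chain is simulated.

## The technique

A shipborne 532 nm lidar looks into the water with three nested receiver
fields of view (40/80/200 mrad). An iodine filter splits each return into a
*combined* channel (everything) and *molecular* channels that keep only the
Brillouin-shifted molecular backscatter. Wider FOVs accept more multiply
forward-scattered photons, so the effective lidar attenuation slides from
the beam attenuation c = a + b at the narrow FOV toward the diffuse
attenuation K_d at the wide FOV. That FOV dependence carries enough
information to retrieve, simultaneously and per depth bin,

* the absorption coefficient **a** (m⁻¹),
* the scattering coefficient **b** (m⁻¹),
* the particle-size-distribution slope **ξ** (Junge exponent; the particle
  phase function and backscatter fraction follow from ξ through the
  Fournier–Forand model with m = 1.01 + 0.1542(ξ − 3)).

The inversion minimizes the relative signal mismatch over the three
molecular channels,

    X = (a_r, b_r, ξ_r) = argmin ‖(B_M − B_S)/B_M‖₂ ,
    ΔX/X = S⁻¹ · ΔB/B ,

iterating a fast analytic multiple-scattering forward model B_S = F(C₀,
a₁…a_i, b₁…b_i, ξ₁…ξ_i, FOV_n) with finite-difference sensitivities S,
stopping when the pooled root-mean-square relative difference (RMSRD)
reaches the noise level (10 % by default). A semianalytic Monte Carlo
engine provides reference signals for validation, and wide-FOV products
(K_d, b_bp, lidar ratio R, single-scattering albedo ω₀) complete the chain.
`docs/methods.md` details the models, defaults and limitations.

## Worked example

```python
import numpy as np
from oceanhsrl import (LidarConfig, ScenarioSpec, make_profile,
                       simulate_mc, iterate_retrieval, rmsrd)

cfg = LidarConfig()                               # 40/80/200 mrad, 532 nm
truth = make_profile(ScenarioSpec.preset("L2", depth_max=20.0))
signals = simulate_mc(truth, cfg, n_photons=2_000_000, seed=42)
result = iterate_retrieval(signals, cfg)
print(result.summary())
m = len(result.iop)
for p in ("a", "b", "xi"):
    print(p, f"{rmsrd(getattr(result.iop, p), getattr(truth, p)[:m]):.2f}%")
```

prints (exact numbers vary with the seed):

```
converged after 0 iterations; pooled signal RMSRD 5.99% (per channel: 6.48%, 7.12%, 3.84%)
a 2.88%
b 14.10%
xi 1.20%
```

i.e. for this moderately turbid water (a = 0.085, b = 0.55 m⁻¹, ξ = 3.35)
the Monte Carlo "measurement" is inverted to a within ~3 %, b within ~14 %
and ξ within ~1 % over the usable depth range (the narrow-FOV three-decade
dynamic range, here 11 one-metre bins). Absorption is the best-determined
parameter; b and ξ share a soft trade-off direction that widens the errors
in turbid water.

The `examples/` scripts walk through each capability (phase-function
optics, forward models, retrieval, derived products); the `oceanhsrl` CLI
chains them from a shell:

```bash
oceanhsrl simulate --scenario L3 --photons 2e6 --seed 7 --out l3.nc
oceanhsrl retrieve --signals l3.nc --out retrieved.csv
oceanhsrl evaluate --retrieved retrieved.csv --truth l3.truth.csv
```

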