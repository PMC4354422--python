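# chondrosim

Simulation of articular cartilage lesion formation after a single blunt
impact, for researchers modelling post-traumatic osteoarthritis and the
pro-/anti-inflammatory "balancing act" in injured cartilage.

A blunt impact kills the chondrocytes in the impact region outright
(necrosis) and triggers a signaling cascade in the surrounding tissue:
reactive oxygen species (ROS, `R`) released by dying cells signal
healthy chondrocytes; alarmins (DAMPs, `M`) from the necrotic debris and
the pro-inflammatory cytokine IL-6 (`F`) push signaled cells into a
catabolic state; catabolic cells produce more ROS, IL-6 and DAMPs,
spreading the lesion; after a delay, signaled healthy cells start
producing the anti-inflammatory cytokine erythropoietin (EPO, `P`),
which can rescue receptor-active sick cells and — above a threshold
`P_c` — shut down the inflammatory routes. The extracellular matrix
(`U`) is slowly degraded by IL-6. Whether the lesion stabilizes or
spreads is decided by this cytokine balance in the "penumbra" around the
impact.

The model is an age- and space-structured reaction–diffusion system on a
circularly symmetric explant. Chemicals obey

    ∂_t u = (1/r) ∂_r (r D_u ∂_r u) − δ_u u + (production),

with zero-flux boundaries; cells do not move. Two cell compartments
carry an age structure `a` (time since signaling) replacing discrete
delays: transport `∂_t + ∂_a` with a smoothed transition kernel
`γ(a − a_max) = (γ₀/σ)[tanh((a − a_max)/σ) + 1]` concentrating the
delayed transitions near `a_max` (1 day for the EPO-producing switch,
half a day for receptor activation). Saturating responses are Hill
factors `x/(λ + x)`; threshold behavior uses Heaviside gates in `P`.
See `docs/methods.md` for the full model, the discretization (IMEX with
adaptive step doubling; finite-volume space and age grids; exact
per-radius cell-count bookkeeping) and verification strategy.

## Worked example

```python
import numpy as np
from chondrosim import (DomainConfig, NumericsConfig, default_params,
                        simulate, make_grids, tracked_outputs)
from chondrosim.experiments import radial_binning

params = default_params()
dom = DomainConfig()          # 2.5 cm explant, 0.25 cm impact, 14 days
num = NumericsConfig(n_r=100) # coarser radial grid for a quick look
traj = simulate(params, dom, num)

d = traj.diagnostics
print(f"accepted steps: {d['n_steps']}")
print(f"max EPO over space and time: {d['max_P']:.4f} nM (threshold P_c = 1 nM)")
print(f"EPO gate ever fired: {d['gate_fired']}")
print(f"worst cell-conservation residual: {max(d['conservation_residuals']):.2e}")

grids = make_grids(dom, num)
day14 = tracked_outputs(traj.snapshots[-1], grids)
r = grids.radial.centers
print(f"day-14 healthy density at r=0.3 cm: {day14['C_U'][r > 0.3][0]:,.0f} cells/cm^2")
print(f"day-14 EPO peak location: r = {r[np.argmax(day14['P'])]:.2f} cm")
print(f"day-14 ECM minimum: {day14['U'].min():.3f} (initially 30)")
```

prints (about half a minute):

```
accepted steps: 30212
max EPO over space and time: 0.0413 nM (threshold P_c = 1 nM)
EPO gate ever fired: False
worst cell-conservation residual: 1.00e-13
day-14 healthy density at r=0.3 cm: 4,320 cells/cm^2
day-14 EPO peak location: r = 1.56 cm
day-14 ECM minimum: 29.972 (initially 30)
```

Reading these numbers: EPO stays almost two orders of magnitude below
its threshold — chondrocytes alone cannot produce enough EPO to halt the
inflammation, so the lesion keeps spreading slowly (healthy density
collapses next to the impact) while EPO concentrates outside the
inflamed region and matrix degradation stays minimal over two weeks.
Every radial cell still accounts for exactly 100,000 cells/cm² across
the live compartments and the apoptotic/cleared/aged-out accumulators.

`radial_binning(day14["F"], grids.radial, bin_width=0.15)` averages a
profile over 0.15-cm annuli, the format used for immunohistochemistry
cell counts, for side-by-side comparison with experimental data.

## Command line

```
chondrosim run --out results/baseline          # snapshot CSVs + manifest
chondrosim run --config my.yaml --out out --plots
chondrosim converge --out results/convergence --counts 100,200,400,800
chondrosim sensitivity --out results/sensitivity --parameters lambda_M,kappa_1
```

Configuration files are YAML with three sections (`model`, `domain`,
`numerics`); omitted keys take the baseline defaults, unknown keys are
an error.

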