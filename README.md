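# capdomain

Quantitative analysis of skeletal-muscle capillary supply and its
functional consequences. Given capillary coordinates from stained
muscle cross-sections (or the bundled synthetic generators), the
package computes:

* **Capillary domains** — the Voronoi tessellation of the sampling
  frame with capillaries as sites. Each domain ("trapping region") is
  the tissue closer to its capillary than to any other and is treated
  as a closed unit of oxygen supply.
* **Supply indices** — capillary density (CD, mm⁻²),
  capillary-to-fibre ratio (C:F, via an unbiased forbidden-line
  counting frame), mean fibre cross-sectional area (CSA, µm²), mean
  capillary domain area (CDA, µm²), and the spacing-heterogeneity
  index logSD = SD(ln CDA).
* **Tissue oxygenation** — the steady-state reaction–diffusion model
  `D·α·∇²P = M₀·P/(P₅₀+P)` solved independently on each trapping
  region (Dirichlet `P = P_cap` on the capillary lumen, zero flux on
  domain boundaries), yielding per-frame mean PO₂, minimum PO₂ and
  the hypoxic tissue fraction at resting and exercise consumption
  rates. The solver is validated against the Krogh–Erlang closed-form
  disc solution.
* **Function metrics** — the fatigue index FI = final/peak tension
  (each the mean of five consecutive twitches) from stimulated
  tension traces, and functional hyperaemia (peak/resting blood flow,
  relative vascular conductance) from flow/pressure recordings.
* **Group statistics** — one-way ANOVA with Tukey HSD for structural
  and functional indices; fold change + Student's t-test +
  Benjamini–Hochberg FDR ("volcano" tables) for metabolite matrices;
  and the accurate-mass / retention-time / isotope-pattern compound
  identification filter (<5 ppm, <30 s, >90 %).

The synthetic module generates every input with planted ground truth
(capillary patterns on 0.145 mm² frames emulating the oxidative
**core** and glycolytic **cortex** of rat tibialis anterior, twitch
trains with planted FI, hyperaemia traces, log-normal metabolomes),
so the full pipeline runs and is testable with no external data.

## Worked example

```python
from capdomain import (generate_cross_section, tessellate,
                       compute_global_indices, compute_local_indices,
                       solve_frame)
from capdomain.synth import CORE_PRESET
from capdomain.oxygen import params_for_mode

cmap = generate_cross_section(CORE_PRESET, seed=1)   # control core frame
tess = tessellate(cmap)
g, l = compute_global_indices(cmap), compute_local_indices(tess)
print(g.CD, g.CF, l.CDA_mean, l.logSD)
field = solve_frame(tess, cmap, params_for_mode("exercise"), h=1.5)
print(field.mean_PO2, field.hypoxic_fraction)
```

prints (seed 1)

```
972.4 per mm²   C:F 1.81   CDA 1028 µm²   logSD 0.499
mean PO₂ 32.3 mmHg   hypoxic fraction 0.005 %
```

i.e. the generated frame recovers the planted control-core phenotype
(CD ≈ 984 mm⁻², C:F ≈ 1.84), each capillary supplies ≈ 1/CD of
tissue, and at the exercise consumption rate the densely
capillarised core stays well oxygenated. The scripts in `examples/`
walk through each capability (tessellation/indices, oxygen model,
fatigue/hyperaemia, volcano statistics, full pipeline); a thin CLI
(`capdomain synth|tessellate|indices|oxygen|fatigue|hyperaemia|
volcano|compare|pipeline`) wraps the same functions for shell use.

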