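"""Tissue PO2 predicted from a capillary distribution.

Solves the Michaelis-Menten oxygen diffusion-consumption model on
every trapping region of a synthetic core and cortex frame at the
high-consumption (exercise) rate and prints the summary statistics.
"""

from capdomain import generate_cross_section, solve_frame, tessellate
from capdomain.oxygen import params_for_mode
from capdomain.synth import CORE_PRESET, CORTEX_PRESET

params = params_for_mode("exercise")
for name, preset in (("core", CORE_PRESET), ("cortex", CORTEX_PRESET)):
    cmap = generate_cross_section(preset, seed=3)
    field = solve_frame(tessellate(cmap), cmap, params, h=1.5)
    print(
        f"{name:7s} CD target {preset.target_CD:6.0f}/mm^2 | "
        f"mean PO2 {field.mean_PO2:5.2f} mmHg | min {field.min_PO2:5.2f} | "
        f"hypoxic (<{field.hypoxia_threshold:g} mmHg) "
        f"{field.hypoxic_fraction:.4f}%"
    )
print()
print("The densely capillarised core keeps higher tissue PO2 than the")
print("sparse cortex at the same consumption rate: larger capillary")
print("domains mean longer diffusion distances and deeper PO2 troughs.")
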