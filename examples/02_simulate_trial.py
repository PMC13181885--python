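"""Simulate the replicated field trial and compute N-use efficiency.

Draws replicate-level soil variables around the published group means
(SD = SE * sqrt(3)) and per-plot grain yields from the configured
treatment multipliers, then converts yields to N partial factor
productivity (PFP_N = Y/225) and agronomic efficiency
(AE_N = (Y - Y0)/225).
"""

from milletsoil.indices import compute_aen, compute_pfp
from milletsoil.synth import TrialConfig, generate_soil_dataset, \
    generate_yields

cfg = TrialConfig()
soil = generate_soil_dataset(cfg, seed=1)
print(f"simulated soil table: {len(soil.data)} samples x "
      f"{len(soil.variables)} variables")

y = generate_yields(cfg, seed=1)
y["PFP_N"] = compute_pfp(y["yield_kg_ha"], cfg.n_rate)
y["AE_N"] = compute_aen(y["yield_kg_ha"], y["y0_kg_ha"], cfg.n_rate)
g = y.groupby(["year", "treatment"], sort=False)[
    ["yield_kg_ha", "PFP_N", "AE_N"]].mean().round(2)
print(g.to_string())
print()
print("PFP_N ~ 18-20 kg grain per kg N; AE_N is smaller because it nets")
print("out the assumed unfertilized-control yield (60 % of the control).")
print("The pig-manure rows carry the configured +4.81 % (2022) and")
print("+7.87 % (2023) gains over the chemical-fertilizer control.")
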