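"""Soil quality index and multifunctionality from the published means.

Builds the 8-row table of treatment means (4 fertilization regimes x 2
years), min-max scores the ten physicochemical indicators per year, and
combines them with the radar-area formula; EMF z-averages the six enzyme
activities over the same per-year pool.
"""

from milletsoil import table1
from milletsoil.indices import index_summary
from milletsoil.io import SoilSampleTable

pool = SoilSampleTable(table1.treatment_mean_table())
summary = index_summary(pool)
print(summary[["treatment", "year", "SQI", "EMF"]].round(3).to_string(
    index=False))
print()
print("SQI rises from the chemical-fertilizer control (~0.3) to ~1.2-2.0")
print("under manure replacement; EMF is a per-year z-average, so the four")
print("treatment values of each year sum to 0 and the control sits ~1.2 SD")
print("below the yearly mean.")
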