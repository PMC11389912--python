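"""Simulate a five-year district registry and summarize it year by year.

The generator emulates daily ischemic-stroke counts (Poisson, mean ~2.6,
so roughly 7-9% of days see no stroke) alongside an eleven-variable
meteorological table with an annual cycle and AR(1) weather noise.
"""

from strokecast import SyntheticConfig, generate_dataset, yearly_descriptives

cfg = SyntheticConfig(seed=1, n_days=1826)  # 2015-2019
counts, meteo = generate_dataset(cfg)

print("Yearly descriptive statistics of the simulated stroke counts:")
print(yearly_descriptives(counts).round(1).to_string())
print()
print("Each row summarizes one year: mean daily count, spread, quartiles,")
print("the percentage of stroke-free days (percZero) and the annual total.")
print()
print("Meteorological table (first 3 days):")
print(meteo.head(3).round(1).to_string())
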