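"""The great plate count anomaly: cells that grow on plates vs cells counted.

Per station, cultivability is 100 * cfu/ml / cells/ml (colony counts over
flow-cytometry counts of heterotrophic prokaryotes). The classic "<1%
culturable" rule tends to hold in photic waters and relax in the deep sea.
"""

from culturematch.cultivability import cultivability_records, layer_summary
from culturematch.synthetic import SimConfig, simulate_station_counts

stations, drawn = simulate_station_counts(SimConfig(seed=8))
records = cultivability_records(stations)
print("per-station cultivability (first rows):")
print(records.head(5).round(4).to_string(index=False))

summary = layer_summary(records)
print("\nper-layer summary (% of cells recovered as colonies):")
print(summary.round(3))
print("\nphotic stations sit well under 1% while mesopelagic and bathypelagic")
print("stations can exceed it — the plate count anomaly is depth-dependent.")
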