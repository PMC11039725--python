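"""Compute the eight-indicator device-month panel and the correlation screen.

X1 utilization, X2 daily working hours, X3 operating cost, X4 cost/exam
(inputs); X5 revenue, X6 appointment wait, X7 cost-benefit ratio, X8 report
wait (outputs).
"""

from fleetdea import (FleetConfig, build_panel, correlation_matrix,
                      generate_dataset)

events, costs = generate_dataset(FleetConfig(n_months=12, seed=42))
panel = build_panel(events, costs)

print(f"{len(panel)} device-months in the panel")
print("\nper-device means:")
cols = ["X1", "X2", "X3", "X4", "X5", "X6", "X7", "X8"]
print(panel.groupby("device_id")[cols].mean().round(2).to_string())

rep = correlation_matrix(panel)
print("\nPearson correlations between indicators (moderate values mean the "
      "indicators describe complementary dimensions):")
print(rep.r.round(2).to_string())
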