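"""The seven production-performance metrics for one cage cycle.

Computes specific growth rate, gross/net yield, feed conversion ratio and
efficiency, feeding rate and survival for the study-mean cage, and shows the
waste fraction implied by the feed conversion efficiency.
"""

from cageload import compute_metrics, study_mean_cage, waste_per_kg_feed

record, _ = study_mean_cage()
m = compute_metrics(record)

print(f"cage {record.cage_id} ({record.volume_m3:.0f} m3, "
      f"{record.stock_count} fish stocked, {record.cycle_days:.0f} days)\n")
print(f"specific growth rate : {m.sgr_pct_per_day:6.3f} %/day")
print(f"gross fish yield     : {m.gross_yield_kg_m3:6.2f} kg/m3/cycle")
print(f"net fish yield       : {m.net_yield_kg_m3:6.2f} kg/m3/cycle")
print(f"feed conversion ratio: {m.fcr:6.3f}")
print(f"feed conv. efficiency: {m.fce:6.3f}")
print(f"feeding rate         : {m.feeding_rate_pct_per_day:6.3f} %/day")
print(f"survival             : {m.survival_pct:6.2f} %")
print(f"\nAt FCE {m.fce:.2f}, each kg of feed leaves "
      f"{waste_per_kg_feed(round(m.fce, 2)):.2f} kg unconverted — the waste "
      "entering the waterbody per kg fed.")
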