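"""Per-cage C/N/P mass balance for the study-mean cage.

Builds the deterministic study-mean cage (75 m3, 5625 juveniles of 50 g,
2023 kg feed, 1226 kg harvested over 170 days), runs the nutrient balance
with the measured feed/fish compositions, and prints each nutrient's budget:
what entered via feed and juveniles, what left in harvested and dead fish,
and the loss — the mass released to the waterbody over one cycle.
"""

from cageload import cage_nutrient_loss, loading_per_tonne_feed, study_mean_cage

record, comp = study_mean_cage()
result = cage_nutrient_loss(record, comp)
per_tonne = loading_per_tonne_feed(result)

print(f"cage {record.cage_id}: {record.feed_supplied_kg:.0f} kg feed, "
      f"{record.harvest_total_weight_kg:.0f} kg harvested over {record.cycle_days:.0f} days\n")
print(f"{'':3} {'feed in':>9} {'juv. in':>9} {'harv. out':>9} {'dead out':>9} "
      f"{'loss':>9} {'kg/t feed':>10}")
for nutrient, bal in result.nutrients.items():
    print(f"{nutrient:3} {bal.input_feed:9.2f} {bal.input_juvenile:9.2f} "
          f"{bal.output_harvest:9.2f} {bal.output_dead:9.2f} {bal.loss:9.2f} "
          f"{per_tonne[nutrient]:10.2f}")

print("\nAll masses in kg per cage per cycle. The loss column is the nutrient")
print("load to the lake; the last column scales it per tonne of feed fed —")
print("the figure used to compare species and feeds for eutrophication risk.")
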