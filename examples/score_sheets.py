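"""Lobar structural scoring: build a score sheet and total it three ways.

Each of six regions (five lobes + lingula) is graded 0/1/2 per feature
(absent / <=50% of the lobe / >50%).  The total score is the sum of all
cells and is reachable per feature or per region.
"""

from petmiv import DEFAULT_FEATURES, REGIONS, EichingerSheet

# Lower-lobe-predominant bronchiectasis with some mucus plugging: the
# classic distribution in primary ciliary dyskinesia.
ratings = {(r, f): 0 for r in REGIONS for f in DEFAULT_FEATURES}
ratings[("right_lower", "bronchiectasis")] = 2
ratings[("left_lower", "bronchiectasis")] = 2
ratings[("middle", "bronchiectasis")] = 1
ratings[("lingula", "mucus_plugging")] = 1
ratings[("right_lower", "mucus_plugging")] = 1

sheet = EichingerSheet("P001", "HRCT", ratings)

print(f"total score: {sheet.total_score()} / {sheet.max_score}")
for feature in DEFAULT_FEATURES:
    print(f"  {feature:15s} -> {sheet.feature_score(feature)}")
for region in REGIONS:
    print(f"  {region:12s} -> {sheet.region_score(region)}")
# The three routes always agree (double-counting identity):
assert sheet.total_score() == sum(sheet.feature_score(f) for f in DEFAULT_FEATURES)
assert sheet.total_score() == sum(sheet.region_score(r) for r in REGIONS)
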