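"""Engineer the 68 features for one animal-day.

Builds a small population, computes the movement & timing, habitat and
history feature sets for one day, and prints a few with their meaning.
Coordinates are mean-centred first, so every feature describes relative
geometry — the classifier never sees absolute positions.
"""

from darpipe import SyntheticConfig, simulate_population, featurize_days
from darpipe.features import FEATURE_SCHEMA

pop = simulate_population(SyntheticConfig(n_animals=4, days_per_animal=20, seed=2))
table = featurize_days(pop.labeled_days, pop.grid)

counts = FEATURE_SCHEMA["set"].value_counts()
print("feature sets:", dict(counts), "-> total",
      int(counts.sum()), "features\n")

row = table[table["label"] == "Local"].iloc[-1]
print(f"one {row['label']} day ({row['animal_id']}, {row['date']}):")
for name, meaning in [
    ("total_path", "daily path length (m)"),
    ("net_displacement", "first-to-last fix distance (m)"),
    ("radius_gyration", "spread of fixes around the daily centroid (m)"),
    ("day_night_path_ratio", "share of movement done in daylight"),
    ("hab_mean", "mean water index at fixes (>0 = on water)"),
    ("water_fraction", "fraction of fixes on water cells"),
    ("hist_lag1_centroid_dist", "distance to yesterday's centroid (m)"),
    ("hist_lag1_overlap", "fraction of today's fixes inside yesterday's range"),
]:
    print(f"  {name:<26s} {row[name]:10.2f}   {meaning}")
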