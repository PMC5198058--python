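"""Filter trial facilities by great-circle distance from a zip code.

A trial spread across five states is reduced to the facilities within 50
miles of Easton, PA (zip 18042).  Facilities abroad, and US facilities
with unknown zips, are always kept.
"""

import tempfile
from pathlib import Path

from oncomatch import KM, MILES, facilities_within, haversine_distance, load_zip_table
from oncomatch.trials import TrialLocation
from oncomatch.fixtures import make_zip_table

with tempfile.TemporaryDirectory() as tmp:
    table = load_zip_table(make_zip_table(Path(tmp) / "zips.csv"))

d_miles = haversine_distance(table["18042"], table["19019"], MILES)
d_km = haversine_distance(table["18042"], table["19019"], KM)
print(f"Easton -> Philadelphia centroid distance: {d_miles:.1f} miles = {d_km:.1f} km")

facilities = [
    TrialLocation(facility="California site", zip="94305", country="United States"),
    TrialLocation(facility="Massachusetts site", zip="02114", country="United States"),
    TrialLocation(facility="New York site", zip="12550", country="United States"),
    TrialLocation(facility="Pennsylvania site", zip="18015", country="United States"),
    TrialLocation(facility="Texas site", zip="77030", country="United States"),
]
kept = facilities_within(facilities, "18042", 50, MILES, table)
print(f"facilities within 50 miles of 18042: {[l.facility for l in kept]}")

# The centroid pair prints ~50.5 miles (~81.3 km); the five-state spread
# keeps only the New York and Pennsylvania facilities.
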