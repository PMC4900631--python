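"""Level 1: LoCoH core areas and spatial gregariousness.

Builds each individual's seasonal 60% isopleth core area with the adaptive-a
local convex hull estimator, then summarises how much the core areas
coincide (gSGI for the group, iSGI per individual).
"""

import json
import warnings

import numpy as np

from fisofus import SyntheticConfig, generate_scan_data
from fisofus.space_use import (
    a_selection_diagnostics, core_area, core_area_to_geojson,
    group_spatial_gregariousness, individual_spatial_gregariousness,
    overlap_decomposition,
)

warnings.simplefilter("ignore")

cfg = SyntheticConfig(n_individuals=11, seasons=("dry-2013", "wet-2013"),
                      scans_per_day=10, days_per_season=30,
                      range_scale={"dry": 1.0, "wet": 0.6}, seed=42)
table, _ = generate_scan_data(cfg)

# pick the adaptive bound a: prefer few patches, no barrier intrusion
pts = table.df.loc[table.df["individual_id"] == "ID01", ["x", "y"]].to_numpy()
for row in a_selection_diagnostics(pts, [500, 1000, 1500, 3000]):
    print(f"a={row['a']:>5.0f}  patches={row['patch_count']}  "
          f"area={row['total_area_ha']:.1f} ha")

a = 1500.0  # one global a for every individual and season
for season in ("dry-2013", "wet-2013"):
    cas = [core_area(table, ind, season, a) for ind in table.roster]
    dec = overlap_decomposition(cas)
    gsgi = group_spatial_gregariousness(dec)
    areas = [ca.area_ha for ca in cas]
    isgi_01 = individual_spatial_gregariousness(
        cas[0], cas[1:])
    print(f"{season}: median core area {np.median(areas):.1f} ha, "
          f"union {dec.union_area_ha:.1f} ha, gSGI {gsgi:.3f}, "
          f"iSGI(ID01) {isgi_01:.3f}")
    if season == "wet-2013":
        with open("core_areas_wet.geojson", "w") as fh:
            json.dump(core_area_to_geojson(cas), fh)
# Expect wet-season core areas markedly smaller than dry (ranges contracted
# to 0.6x) while gSGI stays high: everyone still shares the same ground.
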