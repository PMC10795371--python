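#!/usr/bin/env python
"""Movement ranges and the used/available design at the broad scale.

Per individual: 95%-isopleth KDE movement range (ad hoc bandwidth),
100% MCP, an availability region (MCP buffered by the largest observed
range radius minus the focal radius), five random equal-area circular
available ranges, and zonal summaries of all ranges against the
landscape layers.  Also runs the sequential-area asymptote check.

Writes results/study/{range_summaries.csv, ranges.geojson,
asymptote.csv}.
"""

import json
import os

import numpy as np
import pandas as pd

from quollmove import StudyConfig
from quollmove.homerange import asymptote_check
from quollmove.io import read_fixes
from quollmove.landscape import Landscape
from quollmove.pipeline import broad_scale_ranges

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "study")
SEED = 42


def main() -> None:
    config = StudyConfig()
    fixes = read_fixes(os.path.join(OUT, "fixes.csv"), config)
    land = Landscape.read(os.path.join(OUT, "landscape"))
    ranges, summaries = broad_scale_ranges(fixes, land, config, SEED)
    summaries.to_csv(os.path.join(OUT, "range_summaries.csv"), index=False,
                     float_format="%.10g", lineterminator="\n")

    features = []
    for r in ranges:
        geom = {"type": "Point",
                "coordinates": list(r.centre if r.centre is not None else r.centroid)}
        features.append({"type": "Feature", "geometry": geom,
                         "properties": {"individual_id": r.individual_id,
                                        "range_type": r.range_type,
                                        "area_ha": r.area_ha,
                                        "equal_area_radius_m": r.equal_area_radius}})
    with open(os.path.join(OUT, "ranges.geojson"), "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=2)

    rows = []
    for ind, grp in fixes.groupby("individual_id"):
        pts = grp[["x", "y"]].to_numpy()
        areas, reached = asymptote_check(pts, interval=10)
        rows.append({"individual_id": ind, "n_fixes": len(pts),
                     "reached_asymptote": reached,
                     "final_area_ha": areas[~np.isnan(areas)][-1] / 1e4
                     if np.isfinite(areas).any() else np.nan})
    asym = pd.DataFrame(rows)
    asym.to_csv(os.path.join(OUT, "asymptote.csv"), index=False,
                float_format="%.6g", lineterminator="\n")

    obs = summaries[summaries["range_type"] == "observed"]
    print(f"{len(obs)} observed ranges, {len(summaries) - len(obs)} available ranges")
    obs_ha = [r.area_ha for r in ranges if r.range_type == "observed"]
    print(f"  observed range areas (ha): min {min(obs_ha):.1f}, "
          f"max {max(obs_ha):.1f}")
    print(f"  asymptote reached for {asym['reached_asymptote'].sum()} / "
          f"{len(asym)} individuals")


if __name__ == "__main__":
    main()
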