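#!/usr/bin/env python
"""Screen the GPS fixes and build movement steps.

Applies the screening cascade — HDOP > 10, implied speed > 4.5 m/s,
exclusion windows (none in the simulated study), gaps > 30 min + 3 min
tolerance, bursts shorter than 3 locations — and converts the surviving
bursts into observed 30-min steps with lengths and turning angles.

Writes results/study/{steps.csv, cleaning_report.json}.
"""

import json
import os

from quollmove import StudyConfig
from quollmove.cleaning import clean_fixes
from quollmove.io import read_fixes

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "study")


def main() -> None:
    config = StudyConfig()
    fixes = read_fixes(os.path.join(OUT, "fixes.csv"), config)
    import pandas as pd

    meta_df = pd.read_csv(os.path.join(OUT, "individuals.csv"), dtype={"id": str})
    meta = {r["id"]: {"season": r["season"], "age": r["age"]}
            for _, r in meta_df.iterrows()}
    steps, bursted, report = clean_fixes(fixes, config, individuals_meta=meta)

    with open(os.path.join(OUT, "cleaning_report.json"), "w") as fh:
        json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
    out = steps.copy()
    for col in ("t_start", "t_end"):
        out[col] = pd.to_datetime(out[col], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(os.path.join(OUT, "steps.csv"), index=False,
               float_format="%.10g", lineterminator="\n")

    r = report.as_dict()
    print(f"screened {r['n_input']} fixes -> {r['n_output']} "
          f"({r['n_removed_hdop']} HDOP, {r['n_removed_speed']} speed, "
          f"{r['n_removed_short_bursts']} in short bursts)")
    print(f"observed steps: {len(steps)} "
          f"({steps['ta'].notna().sum()} with defined turning angles)")


if __name__ == "__main__":
    main()
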