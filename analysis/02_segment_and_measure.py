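"""Segment the simulated cohort and extract per-eye vascular metrics.

Reads the scenes written by 01_simulate_cohort.py, runs the classical
segmentation chain (vesselness mask, disc/cup ellipses, artery/vein
labels), builds centerline graphs, and measures the nine parameters
globally and per peripapillary zone.  Writes results/metrics.csv and a
segmentation QC summary against the ground truth.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from retinavasc.graph import build_graph, skeletonize
from retinavasc.morphometry import region_metrics
from retinavasc.segmentation import FundusImage, mask_quality, segment
from retinavasc.zones import default_zones, zone_region

ROOT = Path(__file__).resolve().parents[1] / "results"
COHORT = ROOT / "cohort"


def main() -> None:
    covars = pd.read_csv(COHORT / "covariates.csv")
    rows, qc = [], []
    for _, cv in covars.iterrows():
        sid = f"{cv.subject_id}_{cv.eye}"
        pixels = np.asarray(Image.open(COHORT / "images" / f"{sid}.png").convert("RGB"))
        img = FundusImage(pixels=pixels, eye=cv.eye, subject_id=cv.subject_id)
        truth_v = np.asarray(Image.open(COHORT / "truth" / f"{sid}_vessel.png")) > 127
        truth_a = np.asarray(Image.open(COHORT / "truth" / f"{sid}_artery.png")) > 127
        truth_vn = np.asarray(Image.open(COHORT / "truth" / f"{sid}_vein.png")) > 127
        res = segment(img, truth_masks=(truth_a, truth_vn), truth_vessel_mask=truth_v)
        qc.append({"scene": sid, **{k: res.quality[k] for k in ("sensitivity", "specificity")}})
        skel = skeletonize(res.vessel_mask, 5)
        graph = build_graph(skel, res.vessel_mask, res.artery_mask, res.vein_mask)
        for zone in default_zones(cv.eye):
            region = zone_region(zone, res.disc_ellipse, truth_v.shape)
            rec = region_metrics(
                graph, res.vessel_mask, img.pixel_pitch, zone.label,
                region=region, disc_ellipse=res.disc_ellipse, cup_ellipse=res.cup_ellipse,
            )
            rows.append({"subject_id": cv.subject_id, "eye": cv.eye, **rec.as_dict()})
    metrics = pd.DataFrame(rows)
    metrics.to_csv(ROOT / "metrics.csv", index=False)
    qc_df = pd.DataFrame(qc)
    qc_df.to_csv(ROOT / "segmentation_qc.csv", index=False)
    print(f"measured {qc_df.shape[0]} eyes -> {ROOT/'metrics.csv'}")
    print(
        "segmentation vs truth: sensitivity %.3f, specificity %.3f (means)"
        % (qc_df.sensitivity.mean(), qc_df.specificity.mean())
    )
    g = metrics[metrics.scope == "Global"]
    print("global means:", {k: round(float(g[k].mean()), 3) for k in ("VDf", "VC", "VD", "VBA", "AVR", "CDR")})


if __name__ == "__main__":
    main()
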