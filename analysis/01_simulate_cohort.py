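"""Simulate a small two-cohort fundus study with exact ground truth.

Generates highland (HLC) and lowland (LLC) children's eyes — disc-centered
fundus photographs plus truth masks, graphs, and covariates — and writes
them under results/cohort/.  Group effects (smaller caliber and branching
angle, larger disc and cup in HLC) are injected at the truth level.
"""

import sys
from pathlib import Path

import numpy as np
from PIL import Image

from retinavasc.simulate import CohortSpec, generate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
N_PER_GROUP = 3  # rendered eyes are for the imaging pipeline demo; the
# statistical analysis (04) draws its own large truth-level cohort

def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
    (OUT / "images").mkdir(parents=True, exist_ok=True)
    (OUT / "truth").mkdir(exist_ok=True)
    spec = CohortSpec(n_per_group=N_PER_GROUP, seed=seed)
    images, truths, covars = generate_cohort(spec)
    for img, truth in zip(images, truths):
        sid = f"{img.subject_id}_{img.eye}"
        Image.fromarray(img.pixels).save(OUT / "images" / f"{sid}.png")
        for name, m in (
            ("vessel", truth.vessel_mask),
            ("artery", truth.artery_mask),
            ("vein", truth.vein_mask),
        ):
            Image.fromarray(m.astype(np.uint8) * 255).save(OUT / "truth" / f"{sid}_{name}.png")
        (OUT / "truth" / f"{sid}_graph.json").write_text(truth.graph.to_json())
        truth.per_segment_truth.to_csv(OUT / "truth" / f"{sid}_segments.csv", index=False)
        truth.per_branch_truth.to_csv(OUT / "truth" / f"{sid}_branches.csv", index=False)
    covars.to_csv(OUT / "covariates.csv", index=False)
    print(f"simulated {len(images)} eyes ({N_PER_GROUP} subjects/group, both eyes) -> {OUT}")
    print(covars.groupby("group")[["age", "axl_mm"]].mean().round(2).to_string())


if __name__ == "__main__":
    main()
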