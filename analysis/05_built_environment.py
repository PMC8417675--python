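"""Compute per-patient built-environment indicators: 500 m Euclidean-buffer
counts (bus stops, subway stations, intersections), bike-path length,
green-space and sidewalk area, light/heavy VKT, the entropy land-use-mix
index, retail floor-area ratio at 250 m, and census-tract joins (PM2.5,
O3, GINI, college %, poverty, uninsured %, food access)."""

import pandas as pd
from common import OUT_DIR, RUN_CONFIG

from carepath.pipeline import run_pipeline

run_pipeline({**RUN_CONFIG, "stages": ["simulate", "cohort", "features"]}, out_dir=OUT_DIR, resume=True)
feats = pd.read_csv(OUT_DIR / "features" / "built_env.csv")
print(f"built-environment vectors for {len(feats)} patients")
desc = feats.drop(columns=["patient_id"]).describe().T[["mean", "std"]]
print(desc.round(2).to_string())
print(f"\npatients with missing LUM (no parcel land in buffer): {feats['lum_500'].isna().sum()}")
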