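"""Cluster patients by longest-common-subsequence distance between their
prenatal event sequences: average-linkage agglomeration on the pairwise
LCS distance matrix, number of clusters chosen by mean silhouette width."""

import json

import pandas as pd
from common import OUT_DIR, RUN_CONFIG

from carepath.pipeline import run_pipeline

manifest = run_pipeline({**RUN_CONFIG, "stages": ["simulate", "cohort", "cluster"]}, out_dir=OUT_DIR, resume=True)
sil = json.loads((OUT_DIR / "cluster" / "silhouette.json").read_text())
labels = pd.read_csv(OUT_DIR / "cluster" / "labels.csv")
print(f"clustering: selected k={sil['k']} ({sil['linkage']} linkage)")
print("mean silhouette by k:", {k: round(v, 3) for k, v in sil["silhouette_by_k"].items()})
print("cluster sizes:", labels["cluster"].value_counts().sort_index().to_dict())

# recovery against the simulation's planted labels
truth = pd.read_csv(OUT_DIR / "sim" / "truth.csv")
merged = labels.merge(truth, on="patient_id")
from sklearn.metrics import adjusted_rand_score

ari = adjusted_rand_score(merged["latent_cluster"], merged["cluster"])
print(f"adjusted Rand index vs planted clusters: {ari:.3f}")
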