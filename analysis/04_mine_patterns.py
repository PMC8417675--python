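"""Mine frequent sequential care patterns within each cluster with the
SPADE miner (vertical id-lists, S/I-extension joins) and stratify each
pattern's supporting patients by PPD outcome."""

import pandas as pd
from common import OUT_DIR, RUN_CONFIG

from carepath.pipeline import run_pipeline

run_pipeline({**RUN_CONFIG, "stages": ["simulate", "cohort", "cluster", "mine"]}, out_dir=OUT_DIR, resume=True)
pats = pd.read_csv(OUT_DIR / "patterns" / "patterns.tsv", sep="\t")
print(f"mined {len(pats)} frequent patterns (minsup={RUN_CONFIG['minsup']}, max_len={RUN_CONFIG['max_len']})")
for cl, grp in pats.groupby("cluster"):
    top = grp.sort_values(["support", "pattern"], ascending=[False, True]).head(5)
    print(f"\ncluster {cl} — top patterns:")
    for _, r in top.iterrows():
        print(f"  {r['pattern']}  support={r['support']} ({100 * r['support_frac']:.0f}%), "
              f"PPD {r['ppd_n']}/{r['support']}")
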