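"""Apply inclusion/exclusion (age 18-45, an encounter within the study
window, known home location), label PPD from postpartum diagnosis codes,
and build the ordered prenatal token sequences used for clustering."""

import json

from common import OUT_DIR, RUN_CONFIG

from carepath.pipeline import run_pipeline

manifest = run_pipeline({**RUN_CONFIG, "stages": ["simulate", "cohort"]}, out_dir=OUT_DIR, resume=True)
st = manifest["stages"]["cohort"]
if st.get("skipped"):
    print(f"cohort: outputs already present under {OUT_DIR}/cohort (resume)")
else:
    print(f"cohort: kept {st['patients_kept']} of {st['patients_in']} patients")
    print(f"  excluded — age: {st['age']}, no encounter in window: {st['no_encounter_in_window']}, "
          f"missing home: {st['missing_home']}")
summary = (OUT_DIR / "cohort" / "cohort_summary.tsv").read_text()
print("cohort summary (Table-1 analogue):")
print(summary)
excl = json.loads((OUT_DIR / "cohort" / "exclusions.json").read_text())
print("exclusion tally:", excl)
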