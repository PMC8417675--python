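"""Generate the synthetic study: a 2,000-patient cohort with three latent
care-pattern clusters, trimester-stamped event sequences, spatial layers
over a 6 km planar region, tract attributes, and PPD outcomes planted with
odds ratios 6.3 and 2.43 against the routine-care cluster."""

from common import OUT_DIR, RUN_CONFIG

from carepath.pipeline import run_pipeline

manifest = run_pipeline({**RUN_CONFIG, "stages": ["simulate"]}, out_dir=OUT_DIR, resume=True)
st = manifest["stages"]["simulate"]
if st.get("skipped"):
    print(f"simulate: outputs already present under {OUT_DIR}/sim (resume)")
else:
    print(f"simulate: wrote {st['patients']} patients and {st['events']} events to {OUT_DIR}/sim")
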