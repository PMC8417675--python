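"""Render the consolidated run report (cohort summary, cluster sizes and
PPD rates, top patterns, model odds-ratio tables)."""

from common import OUT_DIR

from carepath.pipeline import report

print(report(OUT_DIR))
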