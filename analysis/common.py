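"""Shared run configuration for the numbered analysis drivers."""

from pathlib import Path

OUT_DIR = Path(__file__).resolve().parent.parent / "results" / "run"

RUN_CONFIG = {
    "seed": 1,
    "sim": {"n_patients": 2000},
    "k_range": [2, 8],
    "minsup": 0.10,
    "max_len": 5,
}
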