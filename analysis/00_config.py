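"""Shared settings for the numbered analysis drivers.

The demo study mirrors the clinical design (15 patients, 13 with both
tissue classes) at a desk-friendly scale of 600 points per class per
phase. Every driver reads and writes under results/run/.
"""

from pathlib import Path

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "run"
PHASES = ("in_vivo", "ex_vivo")
SEED = 1
POINTS_PER_CLASS = 600
INTERFACE_BUFFER_MM = 0.5
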