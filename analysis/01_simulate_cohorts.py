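"""Simulate the two study cohorts (in vivo and ex vivo scans).

Generates a 15-patient cohort per phase — 13 patients with adjoining
cancer and healthy regions, 2 with healthy tissue only — with per-pulse
waveform records, a pathology label raster per patient, and the
ground-truth table. Class separations are calibrated to the per-phase
headline effect sizes (in vivo: channel-1 lifetime d = -0.74; ex vivo:
channel-3 intensity ratio d = +1.0).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import importlib

cfg = importlib.import_module("00_config")

from flimpipe import io as fio
from flimpipe.instrument import InstrumentModel
from flimpipe.synthetic import CohortConfig, generate_cohort


def main() -> None:
    instrument = InstrumentModel()
    for i, phase in enumerate(cfg.PHASES):
        config = CohortConfig(
            phase=phase, points_per_class=cfg.POINTS_PER_CLASS, rng_seed=cfg.SEED + i
        )
        cohort = generate_cohort(config, instrument)
        out = cfg.RUN_DIR / phase / "cohort"
        fio.write_cohort(cohort, out)
        fio.write_manifest(out, config.rng_seed, fio.config_digest(config))
        counts = cohort.truth.groupby("label").size()
        print(
            f"[{phase}] {len(cohort.patients)} patients, "
            f"{counts.get('cancer', 0)} cancer + {counts.get('healthy', 0)} healthy points "
            f"-> {out}"
        )


if __name__ == "__main__":
    main()
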