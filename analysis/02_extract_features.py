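"""Preprocess raw waveforms and extract per-point spectral features.

For each scan: subtract the gain-scaled fiber-background template,
upsample 2.5 -> 12.5 GS/s, apply the gain/SNR quality filters, then
compute per channel the Laguerre-deconvolved decay, average lifetime,
intensity ratio, 12 Laguerre coefficients and 4 phasor values.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import importlib

import pandas as pd

cfg = importlib.import_module("00_config")

from flimpipe import io as fio
from flimpipe.features import extract_features
from flimpipe.instrument import InstrumentModel
from flimpipe.preprocess import QualityThresholds, apply_quality_filters, subtract_background, upsample
from flimpipe.synthetic import CohortConfig, _background_template


def main() -> None:
    instrument = InstrumentModel()
    thresholds = QualityThresholds()
    for i, phase in enumerate(cfg.PHASES):
        cohort_dir = cfg.RUN_DIR / phase / "cohort"
        scans = fio.read_waveforms(cohort_dir / "scans.h5")
        template = _background_template(
            instrument, CohortConfig(phase=phase, rng_seed=cfg.SEED + i)
        )
        frames = []
        n_in = n_kept = 0
        for pid, ws in scans.items():
            ws = subtract_background(ws, (ws.gains / 100.0)[:, :, None] * template[None])
            ws = upsample(ws, instrument.sample_rate_up)
            kept, rejected = apply_quality_filters(ws, thresholds)
            n_in += ws.n_points
            n_kept += kept.n_points
            if kept.n_points:
                frames.append(extract_features(kept, instrument))
        features = pd.concat(frames, ignore_index=True)
        out = cfg.RUN_DIR / phase / "features.csv"
        fio.write_table(features, out, cfg.SEED)
        print(f"[{phase}] {n_kept}/{n_in} points passed quality filters -> {out}")


if __name__ == "__main__":
    main()
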