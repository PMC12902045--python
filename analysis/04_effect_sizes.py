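"""Univariable weighted mixed-model screen of every spectral feature.

Computes inverse-cell-count analysis weights, applies the skew/
standardization transforms, fits the weighted linear mixed model (tissue
fixed effect, patient random intercept) per feature, and reports Cohen's
d with Benjamini-Hochberg-adjusted p-values — the per-phase effect-size
table of the discrimination analysis.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import importlib

cfg = importlib.import_module("00_config")

from flimpipe import io as fio
from flimpipe.features import FEATURE_GROUPS, feature_columns
from flimpipe.screen import univariable_screen
from flimpipe.transforms import transform_features
from flimpipe.weights import compute_weights


def main() -> None:
    for phase in cfg.PHASES:
        phase_dir = cfg.RUN_DIR / phase
        labeled = fio.read_table(phase_dir / "features_labeled.csv")
        analysis = labeled[
            (~labeled["excluded"].astype(bool)) & (~labeled["incomplete"].astype(bool))
        ].reset_index(drop=True)
        scheme = compute_weights(analysis)
        cols = feature_columns(analysis.columns, FEATURE_GROUPS)
        transformed, tlog = transform_features(analysis, cols, scheme.weights)
        effects = univariable_screen(transformed, cols, scheme.weights)
        fio.write_table(transformed, phase_dir / "features_transformed.csv", cfg.SEED)
        fio.write_table(tlog, phase_dir / "transform_log.csv", cfg.SEED)
        fio.write_table(effects, phase_dir / "effect_sizes.csv", cfg.SEED)
        top = effects.reindex(effects["cohens_d"].abs().sort_values(ascending=False).index)
        print(f"[{phase}] strongest tissue discriminators (Cohen's d, BH-adjusted p):")
        print(
            top.head(6)[["feature", "cohens_d", "p_adjusted", "magnitude"]]
            .to_string(index=False, float_format=lambda v: f"{v:.3g}")
        )


if __name__ == "__main__":
    main()
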