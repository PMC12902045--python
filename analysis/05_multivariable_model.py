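"""Multivariable weighted logistic mixed model with backward selection.

Laguerre and phasor blocks are first reduced per channel by multilevel
weighted PCA (between-/within-subject components, 2 each); the logistic
mixed model then starts from all intensity ratios, lifetimes and PCs and
is pruned by the VIF-then-p backward procedure. Writes the coefficient
table and the removal audit trail.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import importlib

import pandas as pd

cfg = importlib.import_module("00_config")

from flimpipe import io as fio
from flimpipe.features import feature_columns
from flimpipe.mlwpca import mlwpca_feature_blocks, multilevel_weighted_pca
from flimpipe.selection import backward_select
from flimpipe.weights import compute_weights


def main() -> None:
    for phase in cfg.PHASES:
        phase_dir = cfg.RUN_DIR / phase
        table = fio.read_table(phase_dir / "features_transformed.csv")
        scheme = compute_weights(table)

        pca_report, pc_scores = {}, {}
        for name, cols in mlwpca_feature_blocks(table.columns).items():
            model = multilevel_weighted_pca(table, cols, scheme.weights)
            scores = model.transform(table, scheme.weights)
            for c in scores.columns:
                pc_scores[f"{name}_{c}"] = scores[c].to_numpy()
            pca_report[name] = {
                "between_varexp": model.between_varexp.tolist(),
                "within_varexp": model.within_varexp.tolist(),
            }
        (phase_dir / "mlwpca.json").write_text(json.dumps(pca_report, indent=2))

        design = pd.DataFrame(
            {
                **{c: table[c] for c in feature_columns(table.columns, ("intensity_ratios", "lifetimes"))},
                **pc_scores,
            }
        )
        y = (table["label"].astype(str) == "cancer").to_numpy(dtype=int)
        sel = backward_select(y, design, table["patient_id"].to_numpy(), scheme.weights)
        (phase_dir / "selection_audit.json").write_text(json.dumps(sel.audit_trail, indent=2))
        if sel.model is not None:
            coef = sel.model.summary_frame().reset_index(names="predictor")
            fio.write_table(coef, phase_dir / "logistic_model.csv", cfg.SEED)
        removed = [f"{r['removed']} ({r['phase']})" for r in sel.audit_trail]
        print(f"[{phase}] retained {len(sel.retained)}/{len(design.columns)} predictors; "
              f"removed: {', '.join(removed) if removed else 'none'}")


if __name__ == "__main__":
    main()
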