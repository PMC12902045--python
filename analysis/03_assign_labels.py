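"""Co-register feature points with the pathology label rasters.

Each point takes the label of the raster pixel it falls in; points within
0.5 mm of the cancer-healthy interface, on unlabeled or dysplastic
pixels, or outside the raster are excluded with a reason code. Prints the
per-patient accounting and writes the analysis-ready labeled table.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import importlib

import pandas as pd

cfg = importlib.import_module("00_config")

from flimpipe import io as fio
from flimpipe.coregister import assign_labels, label_summary


def main() -> None:
    for phase in cfg.PHASES:
        phase_dir = cfg.RUN_DIR / phase
        features = fio.read_table(phase_dir / "features.csv")
        parts = []
        for pid, part in features.groupby("patient_id", observed=True):
            mask = fio.read_mask(
                phase_dir / "cohort" / "masks" / f"{pid}_mask.png",
                phase_dir / "cohort" / "masks" / f"{pid}_legend.json",
            )
            part = part.copy()
            lab = assign_labels(
                part[["x_mm", "y_mm"]].to_numpy(), mask, cfg.INTERFACE_BUFFER_MM
            )
            part[["label", "excluded", "exclusion_reason"]] = lab.to_numpy()
            parts.append(part)
        labeled = pd.concat(parts, ignore_index=True)
        summary = label_summary(labeled)
        fio.write_table(labeled, phase_dir / "features_labeled.csv", cfg.SEED)
        fio.write_table(summary, phase_dir / "label_summary.csv", cfg.SEED)
        cohort_row = summary[summary["patient_id"] == "cohort"].iloc[0]
        print(
            f"[{phase}] {cohort_row['n_cancer']} cancer, {cohort_row['n_healthy']} healthy, "
            f"{cohort_row['n_excluded']} excluded "
            f"(interface {cohort_row['excluded_interface_buffer']})"
        )


if __name__ == "__main__":
    main()
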