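"""Analysis weights balancing subjects and tissue classes.

Point counts vary widely across patients and tissue types, so every
observation gets a weight inversely proportional to the size of its
subject x tissue cell: w_i = (N / C) / n_{s(i), t(i)}, where N is the total
number of observations and C the number of populated subject x tissue
cells. Weights sum to N, every cell carries equal total mass, each
two-tissue subject contributes half cancer / half healthy, and a
healthy-only subject carries exactly half the mass of a two-tissue one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WeightScheme", "compute_weights"]


@dataclass
class WeightScheme:
    """Per-observation weights plus the cell table they derive from."""

    weights: np.ndarray
    cell_table: pd.DataFrame  # subject, tissue, n, cell_mass
    total_n: int

    def validate(self, atol_factor: float = 1e-9) -> None:
        if abs(self.weights.sum() - self.total_n) > atol_factor * self.total_n:
            raise AssertionError("weights do not sum to the sample size")


def compute_weights(table: pd.DataFrame, subject: str = "patient_id", tissue: str = "label") -> WeightScheme:
    """Compute inverse-cell-count analysis weights for a labeled table.

    Rows with a missing subject or tissue label are not weighted (they
    should have been excluded upstream); their presence raises an error so
    silent imbalance cannot slip through.
    """
    for col in (subject, tissue):
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from table")
    labels = table[tissue].astype(str)
    bad = labels.isin(("", "nan")) | table[subject].isna()
    if bad.any():
        raise ValueError(f"{int(bad.sum())} rows have missing subject or tissue labels")

    counts = table.groupby([subject, tissue], observed=True).size()
    n_total = len(table)
    n_cells = len(counts)
    cell_mass = n_total / n_cells
    per_row_cell_n = counts.loc[list(zip(table[subject], labels))].to_numpy()
    weights = cell_mass / per_row_cell_n

    cell_table = counts.rename("n").reset_index()
    cell_table["cell_mass"] = cell_mass
    return WeightScheme(weights=weights, cell_table=cell_table, total_n=n_total)
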