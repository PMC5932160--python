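"""Bait-level normalization and a median-centering LFQ surrogate.

Bait normalization subtracts the bait's per-sample log2 intensity from every
protein, re-expressing each prey as its log2 ratio to the bait. For a bait
that degrades under treatment, a prey bound at constant stoichiometry then
shows no difference between conditions, while a prey whose absolute level is
unchanged appears treatment-enriched by exactly the bait's drop — the device
that surfaces interactors of a degrading bait which plain abundance testing
misses.

``median_center`` is a deliberately simple stand-in for run-level LFQ
normalization, used to produce LFQ-like columns for synthetic data; it
equalizes per-sample medians and nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ConfigError
from .tables_io import ProteinTable, SampleDesign


@dataclass(frozen=True)
class BaitNormState:
    """Per-sample bait log2 intensity subtracted during normalization."""

    bait_log2: pd.Series            # indexed by sample name; NaN where bait missing
    masked_samples: tuple[str, ...]  # samples blanked under the "mask" policy

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.bait_log2.index,
                "bait_log2": self.bait_log2.to_numpy(),
                "subtracted": (~self.bait_log2.isna()).to_numpy(),
            }
        )


def bait_normalize(
    table: ProteinTable,
    design: SampleDesign,
    *,
    on_missing_bait: Literal["error", "mask"] = "error",
) -> tuple[ProteinTable, BaitNormState]:
    """Subtract the bait's log2 intensity from every protein, per sample.

    Runs on the log2 scale before imputation. The bait row becomes exactly 0
    in every sample where it was observed. Samples in which the bait itself
    was not quantified either raise (default) or, under ``on_missing_bait=
    "mask"``, have all their values marked missing with a warning recorded in
    the returned state.
    """
    if table.scale != "log2":
        raise ConfigError("bait_normalize expects a log2-scale table")
    bait = table.bait_row
    if bait is None:
        raise ConfigError("no bait row flagged in the table; bait normalization impossible")
    bait_vals = table.values.loc[bait]
    missing_in = [s for s in table.sample_columns if np.isnan(bait_vals[s])]
    if missing_in and on_missing_bait == "error":
        raise ConfigError(
            f"bait {bait!r} not quantified in samples {missing_in}; "
            "cannot normalize (use on_missing_bait='mask' to blank those samples)"
        )
    values = table.values.sub(bait_vals, axis=1)
    if missing_in:  # mask policy: the whole sample becomes missing
        values[missing_in] = np.nan
    state = BaitNormState(bait_log2=bait_vals.copy(), masked_samples=tuple(missing_in))
    return ProteinTable(table.records.copy(), values, scale="log2"), state


def bait_denormalize(table: ProteinTable, state: BaitNormState) -> ProteinTable:
    """Add the recorded bait intensities back (inverse of :func:`bait_normalize`)."""
    if table.scale != "log2":
        raise ConfigError("bait_denormalize expects a log2-scale table")
    values = table.values.add(state.bait_log2, axis=1)
    return ProteinTable(table.records.copy(), values, scale="log2")


def median_center(table: ProteinTable) -> ProteinTable:
    """Shift each sample so its median equals the grand median of medians."""
    if table.scale != "log2":
        raise ConfigError("median_center expects a log2-scale table")
    medians = table.values.median(axis=0, skipna=True)
    if medians.isna().any():
        empty = list(medians.index[medians.isna()])
        raise ConfigError(f"samples with no present values: {empty}")
    target = float(np.median(medians.to_numpy()))
    values = table.values.sub(medians - target, axis=1)
    return ProteinTable(table.records.copy(), values, scale="log2")
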