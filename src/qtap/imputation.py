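"""Left-censored imputation of missing log2 intensities.

Missing AP-MS quantifications are overwhelmingly below-detection-limit
events, so missing cells are replaced by draws from a normal distribution
placed low in the observed intensity range:

* ``downshift_normal`` (default): Normal(mu - d*sigma, (w*sigma)^2) with mu
  and sigma the observed mean and standard deviation of the imputation scope
  and the widely used downshift d = 1.8, width w = 0.3 (in units of sigma).
* ``min_centered``: Normal(m, (w*sigma)^2) centered on the observed minimum
  m of the scope — a distribution centered around the lowest measured value.

The scope is each sample column (default) or the whole matrix. Draws are
keyed by a per-cell counter-based substream derived from (seed, group_id,
sample), so results do not depend on row order and observed cells are never
touched.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ConfigError, ImputationError
from .tables_io import ProteinTable


@dataclass(frozen=True)
class ImputeParams:
    downshift: float = 1.8
    width: float = 0.3
    scope: Literal["per_sample", "global"] = "per_sample"
    mode: Literal["downshift_normal", "min_centered"] = "downshift_normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError("imputation width must be > 0")
        if self.downshift < 0:
            raise ConfigError("imputation downshift must be >= 0")
        if self.scope not in ("per_sample", "global"):
            raise ConfigError(f"unknown imputation scope {self.scope!r}")
        if self.mode not in ("downshift_normal", "min_centered"):
            raise ConfigError(f"unknown imputation mode {self.mode!r}")


@dataclass
class ImputationRecord:
    """Audit trail: which cells were imputed, with what, from which stats."""

    cells: pd.DataFrame        # columns group_id, sample, imputed_value
    scope_stats: pd.DataFrame  # columns scope, n_observed, mean, sd, center

    def to_frame(self) -> pd.DataFrame:
        return self.cells.copy()


def _cell_rng(seed: int, group_id: str, sample: str) -> np.random.Generator:
    """Deterministic per-cell substream, independent of row order."""
    digest = hashlib.blake2b(
        f"{group_id}\t{sample}".encode("utf-8"), digest_size=8
    ).digest()
    key = int.from_bytes(digest, "little")
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))


def impute_missing(
    table: ProteinTable, params: ImputeParams
) -> tuple[ProteinTable, ImputationRecord]:
    """Replace every missing cell by a left-shifted normal draw.

    Identical (seed, params, input) produce a bit-identical output. Raises
    :class:`ImputationError` when a scope has fewer than two observed values
    or zero spread, since mean/sd of the observed distribution are then
    undefined or degenerate.
    """
    if table.scale != "log2":
        raise ConfigError("impute_missing expects a log2-scale table")
    values = table.values.copy()
    arr = values.to_numpy(dtype=float)
    missing = np.isnan(arr)

    def scope_params(obs: np.ndarray, label: str) -> tuple[float, float, float]:
        obs = np.sort(obs[~np.isnan(obs)])  # row-order-invariant statistics
        if obs.size < 2:
            raise ImputationError(f"scope {label!r} has {obs.size} observed values (< 2)")
        mu = float(np.mean(obs))
        sigma = float(np.std(obs, ddof=1))
        if sigma == 0:
            raise ImputationError(f"scope {label!r} has zero observed spread")
        if params.mode == "downshift_normal":
            center = mu - params.downshift * sigma
        else:
            center = float(np.min(obs))
        return mu, sigma, center

    stats_rows = []
    cells = []
    columns = list(values.columns)
    index = list(values.index)
    if params.scope == "global":
        mu, sigma, center = scope_params(arr, "global")
        stats_rows.append(("global", int((~np.isnan(arr)).sum()), mu, sigma, center))
        col_center = {c: center for c in columns}
        col_width = {c: params.width * sigma for c in columns}
    else:
        col_center, col_width = {}, {}
        for j, c in enumerate(columns):
            col = arr[:, j]
            if not np.isnan(col).any():
                continue  # nothing to impute in this sample
            mu, sigma, center = scope_params(col, c)
            stats_rows.append((c, int((~np.isnan(col)).sum()), mu, sigma, center))
            col_center[c] = center
            col_width[c] = params.width * sigma

    for j, c in enumerate(columns):
        rows = np.nonzero(missing[:, j])[0]
        for i in rows:
            rng = _cell_rng(params.seed, str(index[i]), c)
            draw = col_center[c] + col_width[c] * rng.standard_normal()
            arr[i, j] = draw
            cells.append((index[i], c, draw))

    out = pd.DataFrame(arr, index=values.index, columns=values.columns)
    record = ImputationRecord(
        cells=pd.DataFrame(cells, columns=["group_id", "sample", "imputed_value"]),
        scope_stats=pd.DataFrame(
            stats_rows, columns=["scope", "n_observed", "mean", "sd", "center"]
        ),
    )
    return ProteinTable(table.records.copy(), out, scale="log2"), record


def write_imputation_record(record: ImputationRecord, path) -> None:
    record.cells.to_csv(path, sep="\t", index=False)
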