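"""Row filters, the log2 transform, and replicate quality control.

Stage order in the standard analysis: decoy/contaminant/site-only removal,
log2 transform, (bait normalization when analyzing raw intensities), the
valid-value filter, then QC. Replicate correlations are computed on
pairwise-complete observed values only — QC always precedes imputation, so
imputed draws can never inflate the reported reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .tables_io import GROUPS, ProteinTable, SampleDesign


def filter_flagged_rows(table: ProteinTable) -> ProteinTable:
    """Drop reverse-database hits, contaminants and site-only identifications.

    Row order is preserved. A bait row carrying any removal flag indicates a
    mis-specified design and raises instead of being dropped silently.
    """
    rec = table.records
    bad = rec["is_reverse"] | rec["is_contaminant"] | rec["only_by_site"]
    if bool((bad & rec["is_bait"]).any()):
        raise ConfigError("bait row carries a decoy/contaminant/site flag; check the design")
    keep = rec.index[~bad]
    return table.subset(keep)


def log2_transform(table: ProteinTable) -> ProteinTable:
    """Raw intensities -> log2 intensities; missing cells stay missing."""
    if table.scale != "raw":
        raise ConfigError("log2_transform expects a raw-scale table")
    vals = table.values.to_numpy(dtype=float)
    if np.any(vals[~np.isnan(vals)] <= 0):
        raise ConfigError("raw table contains non-positive present values")
    out = pd.DataFrame(np.log2(vals), index=table.values.index, columns=table.values.columns)
    return ProteinTable(table.records.copy(), out, scale="log2")


def unlog2_transform(table: ProteinTable) -> ProteinTable:
    """Pointwise 2**x back to the raw scale (inverse of :func:`log2_transform`)."""
    if table.scale != "log2":
        raise ConfigError("unlog2_transform expects a log2-scale table")
    out = pd.DataFrame(
        np.exp2(table.values.to_numpy(dtype=float)),
        index=table.values.index,
        columns=table.values.columns,
    )
    return ProteinTable(table.records.copy(), out, scale="raw")


@dataclass(frozen=True)
class ValidFilterParams:
    """Minimum count of observed values required in at least one group."""

    min_valid: int = 4

    def __post_init__(self) -> None:
        if self.min_valid < 1:
            raise ConfigError("min_valid must be a positive integer")


def filter_valid_values(
    table: ProteinTable, design: SampleDesign, params: ValidFilterParams
) -> ProteinTable:
    """Keep rows with >= min_valid observed values in mock OR in treatment.

    With min_valid equal to the group size (the 4-of-4 setting of a 4+4
    design) every retained row has one group fully observed, so at least one
    group mean never rests on imputed values. One-sided presence — fully
    observed under treatment, fully missing under mock — survives, which is
    what lets a treatment-recruited interactor reach the test at all.
    """
    sizes = design.group_sizes()
    if all(params.min_valid > n for n in sizes.values()):
        raise ConfigError(
            f"min_valid={params.min_valid} exceeds both group sizes {sizes}"
        )
    present = table.values.notna()
    keep_mask = np.zeros(table.n_rows, dtype=bool)
    for group in GROUPS:
        cols = design.group_samples(group)
        keep_mask |= present[cols].sum(axis=1).to_numpy() >= params.min_valid
    return table.subset(table.records.index[keep_mask])


@dataclass
class QCReport:
    """Pairwise replicate correlations and per-sample missingness.

    ``correlations`` is a full sample x sample matrix (unit diagonal, NaN
    where not computed); ``pairs`` lists each computed pair with its group,
    shared-row count and Pearson r.
    """

    correlations: pd.DataFrame
    pairs: pd.DataFrame
    missing_fraction: pd.Series
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def min_within_group_r(self) -> float:
        r = self.pairs.loc[self.pairs["within_group"], "pearson_r"]
        return float(r.min()) if len(r) else float("nan")

    @property
    def max_within_group_r(self) -> float:
        r = self.pairs.loc[self.pairs["within_group"], "pearson_r"]
        return float(r.max()) if len(r) else float("nan")

    def summary(self) -> str:
        return (
            f"within-group Pearson r: min={self.min_within_group_r:.3f} "
            f"max={self.max_within_group_r:.3f} "
            f"({int(self.pairs['within_group'].sum())} pairs)"
        )


def replicate_qc(
    table: ProteinTable,
    design: SampleDesign,
    *,
    include_cross_group: bool = False,
    min_shared: int = 3,
) -> QCReport:
    """Pearson correlations between replicate sample columns.

    Each pair is computed on rows where both samples are observed
    (pairwise-complete); pairs sharing fewer than ``min_shared`` rows are
    reported as undefined with a warning.
    """
    if table.scale != "log2":
        raise ConfigError("replicate_qc expects a log2-scale table")
    names = table.sample_columns
    vals = table.values
    group_of = {s.name: s.group for s in design.samples}
    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    corr[corr == 0] = np.nan
    rows: list[dict] = []
    undefined: list[tuple[str, str]] = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            within = group_of[a] == group_of[b]
            if not within and not include_cross_group:
                continue
            both = vals[a].notna() & vals[b].notna()
            n_shared = int(both.sum())
            if n_shared < min_shared:
                warnings.warn(
                    f"replicate pair ({a}, {b}) shares only {n_shared} rows; "
                    "correlation undefined"
                )
                undefined.append((a, b))
                r = float("nan")
            else:
                x = vals.loc[both, a].to_numpy()
                y = vals.loc[both, b].to_numpy()
                r = float(np.corrcoef(x, y)[0, 1])
            corr.loc[a, b] = corr.loc[b, a] = r
            rows.append(
                {
                    "sample_a": a,
                    "sample_b": b,
                    "group": group_of[a] if within else "cross",
                    "within_group": within,
                    "n_shared": n_shared,
                    "pearson_r": r,
                }
            )
    missing = table.values.isna().mean(axis=0)
    return QCReport(
        correlations=corr,
        pairs=pd.DataFrame(rows),
        missing_fraction=missing,
        undefined_pairs=undefined,
    )


def write_qc_report(report: QCReport, matrix_path, summary_path) -> None:
    """Correlation matrix as TSV plus a short text summary with missingness."""
    report.correlations.to_csv(matrix_path, sep="\t")
    lines = [report.summary()]
    for sample, frac in report.missing_fraction.items():
        lines.append(f"missing_fraction\t{sample}\t{frac:.6g}")
    with open(summary_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
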