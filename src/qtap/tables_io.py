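"""Reading and writing MaxQuant-style protein-group tables.

The central in-memory container is :class:`ProteinTable`: a metadata frame
(one row per protein group, carrying decoy/contaminant/site flags and the
bait marker) aligned with an intensity matrix (protein groups x samples).
Missing quantifications are held as NaN; in the MaxQuant export dialect a
raw-scale cell of ``0`` or an empty cell both mean "not quantified", never
an intensity of zero.

A :class:`SampleDesign` assigns every sample column to the ``mock`` or
``treatment`` group and names the bait protein; all downstream stages take
the pair (table, design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import BaitNotFoundError, ConfigError, FormatError

MOCK = "mock"
TREATMENT = "treatment"
GROUPS = (MOCK, TREATMENT)

#: MaxQuant column headers (configurable to tolerate dialect drift).
LFQ_PREFIX = "LFQ intensity "
INTENSITY_PREFIX = "Intensity "
ID_COLUMN = "Majority protein IDs"
GENE_COLUMN = "Gene names"
PEPTIDE_COLUMN = "Unique peptides"
REVERSE_COLUMN = "Reverse"
CONTAMINANT_COLUMNS = ("Potential contaminant", "Contaminant")
SITE_COLUMN = "Only identified by site"

#: Metadata columns of ``ProteinTable.records`` (index = group_id).
RECORD_COLUMNS = (
    "gene_label",
    "unique_peptides",
    "is_reverse",
    "is_contaminant",
    "only_by_site",
    "is_bait",
)


@dataclass(frozen=True)
class SampleInfo:
    name: str
    group: str
    replicate: int


@dataclass(frozen=True)
class SampleDesign:
    """Ordered samples with their mock/treatment assignment and the bait name."""

    samples: tuple[SampleInfo, ...]
    bait_id: str

    def __post_init__(self) -> None:
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate sample names in design")
        for s in self.samples:
            if s.group not in GROUPS:
                raise ConfigError(
                    f"sample {s.name!r} has group {s.group!r}; expected one of {GROUPS}"
                )
        for group in GROUPS:
            reps = [s.replicate for s in self.samples if s.group == group]
            if not reps:
                raise ConfigError(f"group {group!r} has no samples")
            if len(set(reps)) != len(reps):
                raise ConfigError(f"replicate indices not unique within group {group!r}")

    @property
    def sample_names(self) -> list[str]:
        return [s.name for s in self.samples]

    def group_samples(self, group: str) -> list[str]:
        return [s.name for s in self.samples if s.group == group]

    @property
    def mock_samples(self) -> list[str]:
        return self.group_samples(MOCK)

    @property
    def treatment_samples(self) -> list[str]:
        return self.group_samples(TREATMENT)

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.group_samples(g)) for g in GROUPS}


@dataclass
class ProteinTable:
    """Protein groups x samples intensity matrix plus per-row metadata.

    ``records`` and ``values`` share the same index (the protein-group
    identifier); ``values`` columns are the sample names in design order.
    ``scale`` is ``"raw"`` (strictly positive MS intensities) or ``"log2"``.
    """

    records: pd.DataFrame
    values: pd.DataFrame
    scale: Literal["raw", "log2"] = "raw"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise FormatError(f"unknown scale {self.scale!r}")
        if not self.records.index.equals(self.values.index):
            raise FormatError("records and values indexes differ")
        if self.records.index.has_duplicates:
            dupes = self.records.index[self.records.index.duplicated()].tolist()
            raise FormatError(f"duplicate protein group identifiers: {dupes}")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate sample columns")
        missing_meta = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing_meta:
            raise FormatError(f"records frame lacks columns {missing_meta}")
        if int(self.records["is_bait"].sum()) > 1:
            raise FormatError("more than one row flagged as bait")
        vals = self.values.to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if self.scale == "raw":
            if np.any(vals[present] <= 0):
                raise FormatError("raw-scale table contains non-positive present values")
        else:
            if np.any(~np.isfinite(vals[present])):
                raise FormatError("log2-scale table contains non-finite present values")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def sample_columns(self) -> list[str]:
        return list(self.values.columns)

    @property
    def bait_row(self) -> str | None:
        hits = self.records.index[self.records["is_bait"]]
        return None if len(hits) == 0 else hits[0]

    def copy(self) -> "ProteinTable":
        return ProteinTable(self.records.copy(), self.values.copy(), self.scale)

    def subset(self, ids: Sequence[str]) -> "ProteinTable":
        """Row-subset preserving order of ``ids``."""
        return ProteinTable(self.records.loc[ids].copy(), self.values.loc[ids].copy(), self.scale)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_sample_design(path: str | Path, bait_id: str) -> SampleDesign:
    """Read a ``sample<TAB>group<TAB>replicate`` design file (header required)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str})
    for col in ("sample", "group", "replicate"):
        if col not in df.columns:
            raise FormatError(f"design file lacks column {col!r}")
    samples = tuple(
        SampleInfo(str(r["sample"]), str(r["group"]), int(r["replicate"]))
        for _, r in df.iterrows()
    )
    return SampleDesign(samples=samples, bait_id=bait_id)


def _flag_series(df: pd.DataFrame, candidates: Iterable[str]) -> pd.Series:
    for name in candidates:
        if name in df.columns:
            return df[name].fillna("").astype(str).str.strip() == "+"
    return pd.Series(False, index=df.index)


def flag_bait(
    records: pd.DataFrame,
    bait_id: str,
    match: Literal["substring", "exact"] = "substring",
    require: bool = True,
) -> pd.DataFrame:
    """Set ``is_bait`` on the row whose group id matches ``bait_id``.

    Protein groups concatenate accessions, so the default is substring
    matching against the identifier; ``exact`` compares the whole field.
    """
    ids = records.index.astype(str)
    if match == "exact":
        hits = ids == bait_id
    else:
        hits = ids.str.contains(bait_id, regex=False)
    n = int(hits.sum())
    records = records.copy()
    records["is_bait"] = False
    if n == 0:
        if require:
            raise BaitNotFoundError(f"no protein group matches bait id {bait_id!r}")
        warnings.warn(f"no protein group matches bait id {bait_id!r}; no bait flagged")
    elif n > 1:
        raise FormatError(
            f"bait id {bait_id!r} matches {n} protein groups: {list(ids[hits])[:5]}"
        )
    else:
        records.loc[hits, "is_bait"] = True
    return records


def read_protein_groups(
    path: str | Path,
    intensity_kind: Literal["lfq", "raw"],
    design: SampleDesign,
    *,
    lfq_prefix: str = LFQ_PREFIX,
    intensity_prefix: str = INTENSITY_PREFIX,
    bait_match: Literal["substring", "exact"] = "substring",
    require_bait: bool = True,
) -> ProteinTable:
    """Parse a tab-separated ``proteinGroups.txt`` into a raw-scale table.

    ``intensity_kind`` selects the ``LFQ intensity <sample>`` or
    ``Intensity <sample>`` column family. Cells equal to 0 or empty are
    marked missing (NaN). Flag columns using "+" map onto the record
    booleans; the bait is located via ``design.bait_id``.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip", dtype={ID_COLUMN: str})
    if ID_COLUMN not in df.columns:
        raise FormatError(f"missing required column {ID_COLUMN!r}")
    prefix = lfq_prefix if intensity_kind == "lfq" else intensity_prefix
    sample_cols = {}
    for name in design.sample_names:
        col = f"{prefix}{name}"
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
        sample_cols[name] = col

    ids = df[ID_COLUMN].astype(str)
    if ids.duplicated().any():
        raise FormatError(
            f"duplicate protein group identifiers: {ids[ids.duplicated()].tolist()[:5]}"
        )

    records = pd.DataFrame(index=pd.Index(ids, name="group_id"))
    records["gene_label"] = (
        df[GENE_COLUMN].fillna("").astype(str).values if GENE_COLUMN in df.columns else ""
    )
    if PEPTIDE_COLUMN in df.columns:
        records["unique_peptides"] = (
            pd.to_numeric(df[PEPTIDE_COLUMN], errors="coerce").fillna(0).astype(int).values
        )
    else:
        records["unique_peptides"] = 1
    records["is_reverse"] = _flag_series(df, [REVERSE_COLUMN]).values
    records["is_contaminant"] = _flag_series(df, CONTAMINANT_COLUMNS).values
    records["only_by_site"] = _flag_series(df, [SITE_COLUMN]).values
    records = flag_bait(records, design.bait_id, match=bait_match, require=require_bait)

    values = pd.DataFrame(index=records.index)
    for name, col in sample_cols.items():
        v = pd.to_numeric(df[col], errors="coerce").astype(float)
        v[v == 0] = np.nan
        values[name] = v.values
    return ProteinTable(records=records, values=values, scale="raw")


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_protein_groups(
    table: ProteinTable,
    path: str | Path,
    *,
    lfq_values: pd.DataFrame | None = None,
    lfq_prefix: str = LFQ_PREFIX,
    intensity_prefix: str = INTENSITY_PREFIX,
) -> None:
    """Write a raw-scale table in the proteinGroups dialect (missing -> 0).

    ``Intensity <sample>`` columns carry ``table.values``; if ``lfq_values``
    is given (same shape/index) it fills the ``LFQ intensity <sample>``
    columns, otherwise those repeat the raw intensities.
    """
    if table.scale != "raw":
        raise FormatError("write_protein_groups expects a raw-scale table")
    if lfq_values is None:
        lfq_values = table.values
    out = pd.DataFrame(index=range(table.n_rows))
    out[ID_COLUMN] = table.records.index.to_numpy()
    out[GENE_COLUMN] = table.records["gene_label"].to_numpy()
    out[PEPTIDE_COLUMN] = table.records["unique_peptides"].to_numpy()
    out[REVERSE_COLUMN] = np.where(table.records["is_reverse"], "+", "")
    out[CONTAMINANT_COLUMNS[0]] = np.where(table.records["is_contaminant"], "+", "")
    out[SITE_COLUMN] = np.where(table.records["only_by_site"], "+", "")
    for name in table.sample_columns:
        out[f"{intensity_prefix}{name}"] = table.values[name].fillna(0.0).to_numpy()
    for name in table.sample_columns:
        out[f"{lfq_prefix}{name}"] = lfq_values[name].fillna(0.0).to_numpy()
    out.to_csv(path, sep="\t", index=False)


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    rows = [(s.name, s.group, s.replicate) for s in design.samples]
    pd.DataFrame(rows, columns=["sample", "group", "replicate"]).to_csv(
        path, sep="\t", index=False
    )


RESULT_COLUMNS = (
    "group_id",
    "gene_label",
    "mean_mock",
    "mean_treatment",
    "difference",
    "t_statistic",
    "p_value",
    "neg_log10_p",
    "significant",
)


def sort_results(results: pd.DataFrame) -> pd.DataFrame:
    """Descending |difference|, ties broken by ascending p-value."""
    key = results.assign(_absd=results["difference"].abs())
    key = key.sort_values(["_absd", "p_value"], ascending=[False, True], kind="mergesort")
    return key.drop(columns="_absd").reset_index(drop=True)


def write_results_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write the per-protein test results as tab-separated text."""
    if len(results) == 0:
        raise FormatError("refusing to write an empty results table")
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise FormatError(f"results frame lacks columns {missing}")
    sort_results(results)[list(RESULT_COLUMNS)].to_csv(path, sep="\t", index=False)
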