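"""Ground-truthed AP-MS simulator: a degrading bait, mock vs treatment.

The generator emulates a tandem-affinity pulldown of an overexpressed bait
that is degraded under treatment, quantified label-free over 4+4 replicates:

* ``bait``          — abundant in mock, dropped by ``bait_drop`` log2 units
                      under treatment;
* ``constitutive``  — preys bound at constant stoichiometry, co-varying with
                      the bait (their absolute level drops with it);
* ``recruited``     — treatment-only interactors, below the detection limit
                      in mock (D14-like);
* ``released``      — mock-enriched interactors that leave the complex under
                      treatment (TPR2-like);
* ``machinery``     — degradation-machinery preys whose treatment level
                      rises with the bait's loss (26S-proteasome-like);
* ``background``    — stable non-specific binders;
* ``decoy`` / ``contaminant`` — background-like rows with the corresponding
                      QC flags set.

Per-protein base abundances are log-normal (normal on the log2 scale),
replicate noise is Gaussian on log2, and missingness is left-censored:
an observed log2 value x is lost with probability
logistic(missing_slope * (L - x)) around the detection limit L, and always
below L - 2. Raw-scale output is 2**x with missing cells absent, emitted as
a fully valid proteinGroups-dialect table when written to disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path


import numpy as np
import pandas as pd

from .errors import ConfigError
from .normalization import median_center
from .preprocess import log2_transform, unlog2_transform
from .tables_io import (
    MOCK,
    TREATMENT,
    ProteinTable,
    SampleDesign,
    SampleInfo,
    write_protein_groups,
    write_sample_design,
)

CLASSES = (
    "bait",
    "background",
    "constitutive",
    "recruited",
    "released",
    "machinery",
    "decoy",
    "contaminant",
)

BAIT_ID = "SMXL7"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated pulldown (log2 units throughout)."""

    n_background: int = 250
    n_constitutive: int = 10
    n_recruited: int = 5
    n_released: int = 5
    n_machinery: int = 10
    n_decoy: int = 5
    n_contaminant: int = 5
    replicates: int = 4
    base_mean: float = 25.0        # mean of per-protein log2 abundance
    base_sd: float = 2.0           # spread of per-protein log2 abundance
    bait_mean: float = 28.0        # overexpressed bait dominates the eluate
    bait_drop: float = 1.5         # log2 lost by the bait under treatment
    effect: float = 2.0            # recruited/released effect size
    machinery_coupling: float = 1.0
    noise_sd: float = 0.6          # replicate noise on log2
    detection_limit: float = 21.0  # may be -inf to disable missingness
    missing_slope: float = 2.0     # logistic steepness below the limit
    recruited_floor_offset: float = 4.0  # recruited mock level = L - offset
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_background",
            "n_constitutive",
            "n_recruited",
            "n_released",
            "n_machinery",
            "n_decoy",
            "n_contaminant",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.replicates < 2:
            raise ConfigError("need at least 2 replicates per condition")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.bait_drop < 0:
            raise ConfigError("bait_drop must be >= 0 (the bait degrades or is stable)")
        if self.effect < 0:
            raise ConfigError("effect must be >= 0 (directions are fixed by class)")


def default_design(config: SimConfig) -> SampleDesign:
    samples = [
        SampleInfo(f"mock_r{i + 1}", MOCK, i + 1) for i in range(config.replicates)
    ] + [
        SampleInfo(f"treat_r{i + 1}", TREATMENT, i + 1) for i in range(config.replicates)
    ]
    return SampleDesign(samples=tuple(samples), bait_id=BAIT_ID)


@dataclass
class SimulationTruth:
    """Per-row ground-truth class and planted mock-minus-treatment effect."""

    frame: pd.DataFrame  # index group_id; columns: class, effect, true levels

    def effect_rows(self) -> pd.Index:
        return self.frame.index[self.frame["effect"] != 0.0]

    def rows_of(self, *classes: str) -> pd.Index:
        return self.frame.index[self.frame["class"].isin(classes)]


def _row_ids(config: SimConfig) -> tuple[list[str], list[str], list[str]]:
    """(group_ids, gene_labels, classes) in emission order (bait first)."""
    ids, genes, classes = [f"AT2G29970_{BAIT_ID}"], [BAIT_ID], ["bait"]

    def add(n: int, prefix: str, cls: str, id_prefix: str = "") -> None:
        for i in range(n):
            ids.append(f"{id_prefix}{prefix}{i + 1:04d}")
            genes.append(f"{prefix}{i + 1:04d}")
            classes.append(cls)

    add(config.n_constitutive, "CONST", "constitutive")
    add(config.n_recruited, "RECR", "recruited")
    add(config.n_released, "RELS", "released")
    add(config.n_machinery, "MACH", "machinery")
    add(config.n_background, "BG", "background")
    add(config.n_decoy, "DECOY", "decoy", id_prefix="REV__")
    add(config.n_contaminant, "CONT", "contaminant", id_prefix="CON__")
    return ids, genes, classes


def simulate_apms(config: SimConfig) -> tuple[ProteinTable, SimulationTruth]:
    """Draw one simulated experiment; deterministic under ``config.seed``.

    Returns the raw-scale protein table (missing cells NaN) and the
    ground-truth class/effect per row.
    """
    rng = np.random.default_rng(config.seed)
    ids, genes, classes = _row_ids(config)
    n_rows = len(ids)
    design = default_design(config)
    cls = np.array(classes)

    base = rng.normal(config.base_mean, config.base_sd, size=n_rows)
    level_mock = base.copy()
    level_treat = base.copy()
    L = config.detection_limit

    level_mock[cls == "bait"] = config.bait_mean
    level_treat[cls == "bait"] = config.bait_mean - config.bait_drop
    level_treat[cls == "constitutive"] = base[cls == "constitutive"] - config.bait_drop
    level_treat[cls == "machinery"] = (
        base[cls == "machinery"] + config.bait_drop * config.machinery_coupling
    )
    rec = cls == "recruited"
    if math.isfinite(L):
        level_mock[rec] = L - config.recruited_floor_offset
    else:
        level_mock[rec] = base[rec] - config.effect
    level_treat[cls == "released"] = base[cls == "released"] - config.effect

    effect = level_mock - level_treat
    effect[np.isin(cls, ["background", "decoy", "contaminant"])] = 0.0

    n_rep = config.replicates
    truth_levels = np.concatenate(
        [np.repeat(level_mock[:, None], n_rep, axis=1),
         np.repeat(level_treat[:, None], n_rep, axis=1)],
        axis=1,
    )
    x = truth_levels + rng.normal(0.0, config.noise_sd, size=truth_levels.shape)

    if math.isfinite(L):
        p_missing = 1.0 / (1.0 + np.exp(-config.missing_slope * (L - x)))
        missing = rng.random(size=x.shape) < p_missing
        missing |= x < L - 2.0  # hard floor: never detected this far below L
    else:
        missing = np.zeros_like(x, dtype=bool)

    raw = np.exp2(x)
    raw[missing] = np.nan

    records = pd.DataFrame(
        {
            "gene_label": genes,
            "unique_peptides": rng.integers(1, 20, size=n_rows),
            "is_reverse": cls == "decoy",
            "is_contaminant": cls == "contaminant",
            "only_by_site": np.zeros(n_rows, dtype=bool),
            "is_bait": cls == "bait",
        },
        index=pd.Index(ids, name="group_id"),
    )
    values = pd.DataFrame(raw, index=records.index, columns=design.sample_names)
    table = ProteinTable(records=records, values=values, scale="raw")
    truth = SimulationTruth(
        frame=pd.DataFrame(
            {
                "class": cls,
                "effect": effect,
                "level_mock": level_mock,
                "level_treatment": level_treat,
            },
            index=records.index,
        )
    )
    return table, truth


def lfq_surrogate(table: ProteinTable) -> ProteinTable:
    """Median-centered raw-scale table standing in for run-level LFQ output."""
    return unlog2_transform(median_center(log2_transform(table)))


def write_simulated_experiment(
    config: SimConfig, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Emit proteinGroups.txt, design.tsv and truth.tsv for one simulation."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_apms(config)
    design = default_design(config)
    pg = out / "proteinGroups.txt"
    write_protein_groups(table, pg, lfq_values=lfq_surrogate(table).values)
    ds = out / "design.tsv"
    write_sample_design(design, ds)
    tr = out / "truth.tsv"
    truth.frame.to_csv(tr, sep="\t")
    return pg, ds, tr


def truth_eval(
    flags: pd.Series, truth: SimulationTruth
) -> tuple[float, float]:
    """(sensitivity, false-discovery proportion) of significance calls.

    ``flags`` is a boolean series indexed by group_id; it must cover exactly
    the same rows as the truth table (order-insensitive).
    """
    want = set(truth.frame.index)
    got = set(flags.index)
    if want != got:
        raise ConfigError(
            f"flags and truth cover different rows ({len(got ^ want)} mismatches)"
        )
    aligned = flags.reindex(truth.frame.index).astype(bool)
    is_effect = truth.frame["effect"] != 0.0
    n_effect = int(is_effect.sum())
    n_flagged = int(aligned.sum())
    tp = int((aligned & is_effect).sum())
    fp = int((aligned & ~is_effect).sum())
    sensitivity = tp / n_effect if n_effect else 0.0
    fdp = fp / max(1, n_flagged)
    return sensitivity, fdp
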