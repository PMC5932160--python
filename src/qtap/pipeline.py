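"""End-to-end orchestration of the two analysis arms.

Stage order (fixed, not configurable): read -> flagged-row filter -> log2 ->
[bait normalization, intensity arm only] -> valid-value filter -> replicate
QC -> imputation -> moderated testing with permutation FDR -> volcano and
writers. The LFQ arm tests normalized label-free intensities as they come;
the intensity arm re-expresses raw intensities relative to the bait before
imputation, which is what surfaces interactors of a degrading bait.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml

from . import diffstats, imputation, normalization, preprocess, synthetic, tables_io
from .diffstats import FdrParams, FdrResult
from .errors import ConfigError, QtapError
from .imputation import ImputationRecord, ImputeParams
from .normalization import BaitNormState
from .preprocess import QCReport, ValidFilterParams
from .synthetic import SimConfig
from .tables_io import ProteinTable, SampleDesign

log = logging.getLogger("qtap")

Mode = Literal["lfq", "intensity", "both"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of a run; serializable so a run re-executes from its copy.

    Defaults follow common Perseus-style practice:
    min_valid 4 (of 4 replicates), FDR alpha 0.05, S0 0.1.
    """

    protein_groups: Optional[str] = None
    design: Optional[str] = None
    simulate: Optional[SimConfig] = None
    bait_id: str = synthetic.BAIT_ID
    mode: Mode = "both"
    min_valid: int = 4
    impute: ImputeParams = field(default_factory=ImputeParams)
    fdr: FdrParams = field(default_factory=FdrParams)
    keep_bait: bool = True
    on_missing_bait: Literal["error", "mask"] = "error"
    bait_match: Literal["substring", "exact"] = "substring"
    lfq_prefix: str = tables_io.LFQ_PREFIX
    intensity_prefix: str = tables_io.INTENSITY_PREFIX
    out_dir: str = "qtap_run"
    seed: int = 0

    # -- serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = SimConfig(**d["simulate"])
        if d.get("impute") is not None and not isinstance(d["impute"], ImputeParams):
            d["impute"] = ImputeParams(**d["impute"])
        if d.get("fdr") is not None and not isinstance(d["fdr"], FdrParams):
            d["fdr"] = FdrParams(**d["fdr"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def resolved(self) -> "PipelineConfig":
        """Fill derived seeds so the saved copy re-runs identically."""
        impute = self.impute
        fdr = self.fdr
        sim = self.simulate
        # stage seeds derive from the top-level seed unless set explicitly
        if impute.seed == 0:
            impute = replace(impute, seed=(self.seed * 2654435761 + 1) % (2**31))
        if fdr.seed == 0:
            fdr = replace(fdr, seed=(self.seed * 2654435761 + 2) % (2**31))
        if sim is not None and sim.seed == 0:
            sim = replace(sim, seed=(self.seed * 2654435761 + 3) % (2**31))
        return replace(self, impute=impute, fdr=fdr, simulate=sim)


@dataclass
class Finding:
    level: Literal["error", "warning"]
    code: str
    message: str


def validate_config(config: PipelineConfig) -> list[Finding]:
    """Machine-readable findings; errors mean the run would fail."""
    findings: list[Finding] = []
    if config.simulate is None and (config.protein_groups is None or config.design is None):
        findings.append(
            Finding("error", "no-input", "need protein_groups+design paths or a simulate block")
        )
    n_rep = None
    if config.simulate is not None:
        n_rep = config.simulate.replicates
    elif config.design is not None and Path(config.design).exists():
        try:
            design = tables_io.read_sample_design(config.design, config.bait_id)
            n_rep = min(design.group_sizes().values())
        except QtapError as exc:
            findings.append(Finding("error", "bad-design", str(exc)))
    if n_rep is not None:
        if config.min_valid > n_rep:
            findings.append(
                Finding(
                    "error",
                    "min-valid-too-large",
                    f"min_valid={config.min_valid} exceeds the replicate count {n_rep}",
                )
            )
        total = math.comb(2 * n_rep, n_rep)
        if config.fdr.n_perm == "exhaustive" and total - 1 > config.fdr.exhaustive_cap:
            findings.append(
                Finding(
                    "warning",
                    "exhaustive-infeasible",
                    f"{total - 1} label assignments exceed the exhaustive cap "
                    f"({config.fdr.exhaustive_cap}); use a sampled null",
                )
            )
        if config.fdr.s0 == 0 and n_rep <= 4:
            findings.append(
                Finding(
                    "warning",
                    "s0-zero-small-groups",
                    "s0=0 with small groups lets tiny-variance rows dominate the calls",
                )
            )
    return findings


# ---------------------------------------------------------------------------
# single-arm analysis (in memory)
# ---------------------------------------------------------------------------


@dataclass
class ArmResult:
    """Everything one analysis arm produces, before any file is written."""

    mode: str
    results: pd.DataFrame
    fdr: FdrResult
    qc: QCReport
    imputation: ImputationRecord
    bait_norm: Optional[BaitNormState]
    n_input_rows: int
    n_after_flag_filter: int
    n_after_valid_filter: int

    def significant_ids(self) -> pd.Index:
        r = self.results
        return pd.Index(r.loc[r["significant"], "group_id"])

    def flags_over(self, index: pd.Index) -> pd.Series:
        """Significance flags expanded to ``index`` (filtered rows = False)."""
        s = self.results.set_index("group_id")["significant"]
        return s.reindex(index, fill_value=False).astype(bool)


def analyze_arm(
    table_raw: ProteinTable,
    design: SampleDesign,
    config: PipelineConfig,
    mode: Literal["lfq", "intensity"],
) -> ArmResult:
    """Run the full stage sequence on a raw-scale table for one arm."""
    n_input = table_raw.n_rows
    table = preprocess.filter_flagged_rows(table_raw)
    n_flagged = table.n_rows
    log.info("%s arm: flagged-row filter %d -> %d rows", mode, n_input, n_flagged)
    table = preprocess.log2_transform(table)

    bait_state: Optional[BaitNormState] = None
    if mode == "intensity":
        table, bait_state = normalization.bait_normalize(
            table, design, on_missing_bait=config.on_missing_bait
        )
        if not config.keep_bait:
            keep = table.records.index[~table.records["is_bait"]]
            table = table.subset(keep)

    table = preprocess.filter_valid_values(
        table, design, ValidFilterParams(min_valid=config.min_valid)
    )
    n_valid = table.n_rows
    log.info("%s arm: valid-value filter %d -> %d rows", mode, n_flagged, n_valid)

    qc = preprocess.replicate_qc(table, design)
    table, imp_record = imputation.impute_missing(table, config.impute)
    results, fdr = diffstats.differential_analysis(table, design, config.fdr)
    log.info(
        "%s arm: %d/%d rows significant (|d*| >= %.4g)",
        mode,
        int(results["significant"].sum()),
        n_valid,
        fdr.threshold,
    )
    return ArmResult(
        mode=mode,
        results=results,
        fdr=fdr,
        qc=qc,
        imputation=imp_record,
        bait_norm=bait_state,
        n_input_rows=n_input,
        n_after_flag_filter=n_flagged,
        n_after_valid_filter=n_valid,
    )


def load_inputs(config: PipelineConfig) -> dict[str, object]:
    """Resolve the input tables for each requested arm.

    Returns a dict with the design, per-arm raw-scale tables, and (for
    simulated inputs) the ground truth.
    """
    modes = ["lfq", "intensity"] if config.mode == "both" else [config.mode]
    out: dict[str, object] = {"modes": modes, "truth": None}
    if config.simulate is not None:
        table, truth = synthetic.simulate_apms(config.simulate)
        design = synthetic.default_design(config.simulate)
        out["truth"] = truth
        out["design"] = design
        if "lfq" in modes:
            out["lfq_table"] = synthetic.lfq_surrogate(table)
        if "intensity" in modes:
            out["intensity_table"] = table
        out["raw_table"] = table
    else:
        design = tables_io.read_sample_design(config.design, config.bait_id)
        out["design"] = design
        for mode, kind in (("lfq", "lfq"), ("intensity", "raw")):
            if mode in modes:
                out[f"{mode}_table"] = tables_io.read_protein_groups(
                    config.protein_groups,
                    kind,
                    design,
                    lfq_prefix=config.lfq_prefix,
                    intensity_prefix=config.intensity_prefix,
                    bait_match=config.bait_match,
                    require_bait=(mode == "intensity"),
                )
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured run and write all artifacts to a run directory.

    Per arm: results table, QC matrix + summary, imputation record, volcano
    image, and (intensity arm) the bait-normalization state; at the top
    level the resolved config with all effective seeds.
    """
    config = config.resolved()
    errors = [f for f in validate_config(config) if f.level == "error"]
    if errors:
        raise ConfigError("; ".join(f"{f.code}: {f.message}" for f in errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    inputs = load_inputs(config)
    design: SampleDesign = inputs["design"]  # type: ignore[assignment]
    if config.simulate is not None:
        synthetic.write_simulated_experiment(config.simulate, out / "simulated")

    marker = out / "INCOMPLETE"
    marker.write_text("run in progress\n")
    for mode in inputs["modes"]:  # type: ignore[union-attr]
        table = inputs[f"{mode}_table"]
        try:
            arm = analyze_arm(table, design, config, mode)  # type: ignore[arg-type]
        except QtapError as exc:
            raise type(exc)(f"[{mode} arm] {exc}") from exc
        arm_dir = out / mode
        arm_dir.mkdir(exist_ok=True)
        tables_io.write_results_table(arm.results, arm_dir / "results.tsv")
        preprocess.write_qc_report(
            arm.qc, arm_dir / "qc_correlations.tsv", arm_dir / "qc_summary.txt"
        )
        imputation.write_imputation_record(arm.imputation, arm_dir / "imputed_values.tsv")
        diffstats.volcano_plot(
            arm.results,
            arm_dir / "volcano.png",
            title=f"{mode} arm (FDR={config.fdr.alpha}, S0={config.fdr.s0})",
        )
        if arm.bait_norm is not None:
            arm.bait_norm.to_frame().to_csv(
                arm_dir / "bait_normalization.tsv", sep="\t", index=False
            )
    marker.unlink()
    return out
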