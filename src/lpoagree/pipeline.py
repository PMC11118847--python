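"""End-to-end run orchestration: quantify -> inference -> agreement.

A run consumes either a raw optical-density table or a pre-computed
concentrations table, and writes:

* ``concentrations.csv``  (only when the input was OD readings)
* ``ttests.tsv``          pre-vs-post paired t-tests per analyte x phase x fluid
* ``agreement.tsv``       the regression/correlation summary, one row per
                          analyte x phase x timepoint stratum
* ``bland_altman.tsv``    the Bland-Altman summary for the same strata
* ``summary.json``        every statistic in machine-readable form
* ``manifest.json``       config echo, package version, row counts, warnings

Outputs are deterministic for a fixed config and input (no timestamps),
so re-runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (agreement_suite, agreement_table, bland_altman_table,
                        paired_datasets_from_long, pivot_concentrations)
from .errors import ConfigError, SchemaError
from .inference import PairedComparison, paired_t, shapiro_wilk
from .quantify import CONC_OUTPUT_COLUMNS, quantify_table, read_od_csv

logger = logging.getLogger(__name__)

LONG_COLUMNS = ["subject_id", "cycle_phase", "timepoint", "analyte",
                "plasma", "saliva"]


@dataclass(frozen=True)
class RunConfig:
    input_path: Union[str, Path]
    input_kind: str                      # "od" | "concentrations" | "long"
    output_dir: Union[str, Path]
    seed: int = 0
    alpha: float = 0.05
    bonferroni_family: int = 1
    ci_method: str = "analytic"
    bootstrap_reps: int = 20_000
    clamp_negative_od: bool = False
    emit_plots: bool = False

    def validate(self) -> None:
        bad = []
        if not 0 < self.alpha < 1:
            bad.append("alpha must be in (0, 1)")
        if self.input_kind not in ("od", "concentrations", "long"):
            bad.append("input_kind must be od, concentrations or long")
        if self.ci_method not in ("analytic", "bootstrap"):
            bad.append("ci_method must be analytic or bootstrap")
        if self.ci_method == "bootstrap" and self.bootstrap_reps < 1000:
            bad.append("bootstrap_reps must be >= 1000 for bootstrap CIs")
        if self.bonferroni_family < 1:
            bad.append("bonferroni_family must be >= 1")
        if bad:
            raise ConfigError("invalid RunConfig: " + "; ".join(bad))


@dataclass
class RunReport:
    config: RunConfig
    n_input_rows: int
    n_strata: int
    ttests: pd.DataFrame = field(repr=False, default=None)
    agreement: pd.DataFrame = field(repr=False, default=None)
    bland_altman: pd.DataFrame = field(repr=False, default=None)
    warnings: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)


def _load_long_table(cfg: RunConfig) -> tuple:
    """Read the input and reduce it to the long paired layout.

    Returns (long_df, conc_df_or_None, n_input_rows).
    """
    path = Path(cfg.input_path)
    if cfg.input_kind == "od":
        od = read_od_csv(path, clamp_negative_od=cfg.clamp_negative_od)
        conc = quantify_table(od)
        return pivot_concentrations(conc), conc, len(od)
    df = pd.read_csv(path)
    if cfg.input_kind == "long":
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"long table missing columns: {missing}")
        return df[LONG_COLUMNS], None, len(df)
    missing = [c for c in CONC_OUTPUT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"concentrations table missing columns: {missing}")
    return pivot_concentrations(df), None, len(df)


def _pre_post_ttests(long: pd.DataFrame, alpha: float,
                     warnings: list) -> pd.DataFrame:
    """Paired pre-vs-post t-tests per analyte x phase x fluid.

    Subjects missing either timepoint in a stratum are dropped; strata with
    fewer than 2 complete subjects are skipped with a warning.  Differences
    failing the Shapiro-Wilk gate (p < 0.05) are annotated, not dropped.
    """
    recs = []
    melted = long.melt(
        id_vars=["subject_id", "cycle_phase", "timepoint", "analyte"],
        value_vars=["plasma", "saliva"], var_name="fluid", value_name="value",
    )
    for (analyte, phase, fluid), grp in melted.groupby(
            ["analyte", "cycle_phase", "fluid"], sort=False):
        wide = grp.pivot_table(index="subject_id", columns="timepoint",
                               values="value", aggfunc="mean")
        if "pre" not in wide.columns or "post" not in wide.columns:
            warnings.append(
                f"{analyte}/{phase}/{fluid}: missing pre or post; stratum skipped"
            )
            continue
        wide = wide.dropna(subset=["pre", "post"])
        if len(wide) < 2:
            warnings.append(
                f"{analyte}/{phase}/{fluid}: <2 complete subjects; stratum skipped"
            )
            continue
        comp = PairedComparison(
            label=f"{analyte}/{phase}/{fluid} post-vs-pre",
            values_a=wide["pre"].to_numpy(),
            values_b=wide["post"].to_numpy(),
        )
        res = paired_t(comp)
        diffs = comp.values_b - comp.values_a
        normal_p = None
        if diffs.size >= 3 and np.ptp(diffs) > 0:
            _, normal_p = shapiro_wilk(diffs)
            if normal_p < alpha:
                warnings.append(
                    f"{comp.label}: differences fail Shapiro-Wilk (p={normal_p:.3g})"
                )
        recs.append({
            "analyte": analyte, "phase": phase, "fluid": fluid,
            "n": res.n, "mean_diff": res.mean_diff, "t": res.t, "df": res.df,
            "p": res.p, "cohens_dz": res.d, "shapiro_p": normal_p,
        })
    return pd.DataFrame.from_records(recs)


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the full analysis and write all report files."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: list = []
    rng = np.random.default_rng(cfg.seed)

    logger.info("stage=load input=%s kind=%s", cfg.input_path, cfg.input_kind)
    long, conc, n_input = _load_long_table(cfg)
    outputs = {}
    if conc is not None:
        p = outdir / "concentrations.csv"
        conc.to_csv(p, index=False)
        outputs["concentrations"] = str(p)

    logger.info("stage=ttests")
    ttests = _pre_post_ttests(long, cfg.alpha, warnings)

    logger.info("stage=agreement strata=%d", long.groupby(
        ["analyte", "cycle_phase", "timepoint"]).ngroups)
    datasets = paired_datasets_from_long(long)
    rows = agreement_suite(
        datasets, alpha=cfg.alpha, bonferroni_family=cfg.bonferroni_family,
        ci_method=cfg.ci_method, n_boot=cfg.bootstrap_reps, rng=rng,
    )
    for row in rows:
        if row.error:
            warnings.append(f"{row.dataset.label}: {row.error}")
        elif row.ba is not None and row.ba.degenerate:
            warnings.append(f"{row.dataset.label}: LoA degenerate (sd_diff = 0)")
    agree_df = agreement_table(rows)
    ba_df = bland_altman_table(rows)

    paths = {
        "ttests": outdir / "ttests.tsv",
        "agreement": outdir / "agreement.tsv",
        "bland_altman": outdir / "bland_altman.tsv",
    }
    ttests.to_csv(paths["ttests"], sep="\t", index=False)
    agree_df.to_csv(paths["agreement"], sep="\t", index=False)
    ba_df.to_csv(paths["bland_altman"], sep="\t", index=False)
    outputs.update({k: str(v) for k, v in paths.items()})

    summary = {
        "ttests": json.loads(ttests.to_json(orient="records")),
        "agreement": json.loads(agree_df.to_json(orient="records")),
        "bland_altman": json.loads(ba_df.to_json(orient="records")),
    }
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    outputs["summary"] = str(summary_path)

    if cfg.emit_plots:
        from .plots import emit_run_plots
        outputs["plots"] = emit_run_plots(rows, outdir)

    manifest = {
        "package": "lpoagree",
        "version": __version__,
        "config": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "n_input_rows": n_input,
        "n_strata": len(datasets),
        "warnings": warnings,
        "outputs": sorted(outputs),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    outputs["manifest"] = str(manifest_path)

    return RunReport(
        config=cfg, n_input_rows=n_input, n_strata=len(datasets),
        ttests=ttests, agreement=agree_df, bland_altman=ba_df,
        warnings=warnings, outputs=outputs,
    )
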