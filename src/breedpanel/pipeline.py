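"""End-to-end pipeline: QC -> diversity -> HWE -> distances -> outlier scan
-> DAPC panel selection, with machine-readable outputs.

Every stage writes TSV/JSON into the output directory; identical config and
seed give byte-identical outputs.  Stages can be toggled individually; the
run report records per-stage wall-clock and headline numbers.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import GenotypeTable, QCConfig, apply_qc, read_plink, read_vcf
from . import diversity as dv
from . import differentiation as df
from . import hwe as hw
from . import dapc as dp

log = logging.getLogger("breedpanel")

ALL_STAGES = ("qc", "diversity", "hwe", "distances", "outliers", "dapc")


@dataclass
class RunConfig:
    ped: str | None = None
    map: str | None = None
    vcf: str | None = None
    population_map: dict[str, str] | None = None
    out_dir: str = "breedpanel_out"
    stages: tuple[str, ...] = ALL_STAGES
    qc: QCConfig = field(default_factory=QCConfig)
    hwe_alpha: float = 0.05
    hwe_midp: bool = False
    outlier_alpha: float = 0.05
    outlier_trim: tuple[float, float] = (0.05, 0.05)
    outlier_hmin: float = 0.1
    dapc_threshold: float = 0.01
    seed: int = 42

    def load_table(self) -> GenotypeTable:
        if self.ped and self.map:
            return read_plink(self.ped, self.map)
        if self.vcf:
            if not self.population_map:
                raise ValueError("VCF input requires a population_map")
            return read_vcf(self.vcf, self.population_map)
        raise ValueError("config must provide either ped+map or vcf input")


@dataclass
class RunReport:
    version: str
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"version": self.version, "config": self.config, "stages": self.stages},
            indent=2,
            default=_jsonable,
        )


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig, table: GenotypeTable | None = None) -> RunReport:
    """Run the enabled stages in order on the QC-passed table.

    ``table`` may be supplied directly (e.g. from the simulator) instead of
    reading from the configured input files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        version=__version__,
        config={
            "seed": config.seed,
            "stages": list(config.stages),
            "hwe_alpha": config.hwe_alpha,
            "outlier_alpha": config.outlier_alpha,
            "dapc_threshold": config.dapc_threshold,
        },
    )
    if table is None:
        table = config.load_table()

    current_stage = "input"
    try:
        if "qc" in config.stages:
            current_stage = "qc"
            t0 = time.perf_counter()
            table, qc_report = apply_qc(table, config.qc)
            (out / "qc_report.json").write_text(json.dumps(qc_report.to_dict(), indent=2))
            report.stages["qc"] = {
                "seconds": time.perf_counter() - t0,
                "snps_removed": qc_report.n_snps_removed,
                "samples_removed": qc_report.n_samples_removed,
                "snps_kept": table.n_loci,
                "samples_kept": table.n_samples,
            }
            log.info(
                "qc: removed %d SNPs, %d samples; kept %dx%d",
                qc_report.n_snps_removed,
                qc_report.n_samples_removed,
                table.n_samples,
                table.n_loci,
            )

        if "diversity" in config.stages:
            current_stage = "diversity"
            t0 = time.perf_counter()
            het, overall_fis = dv.fis(table, by_population=True)
            het_pooled, fis_pooled = dv.fis(table, by_population=False)
            _write_tsv(pd.concat([het, het_pooled], ignore_index=True), out / "diversity.tsv")
            means = dv.hill_means(table, by_population=True)
            means_pooled = dv.hill_means(table, by_population=False)
            _write_tsv(pd.concat([means, means_pooled], ignore_index=True), out / "hill_means.tsv")
            summary = {
                "overall_fis": {**overall_fis, **fis_pooled},
                "hill_means_pooled": {
                    str(q): v for q, v in zip(means_pooled["q"], means_pooled["mean_qD"])
                },
            }
            (out / "diversity_summary.json").write_text(
                json.dumps(summary, indent=2, default=_jsonable)
            )
            report.stages["diversity"] = {"seconds": time.perf_counter() - t0, **summary}

        if "hwe" in config.stages:
            current_stage = "hwe"
            t0 = time.perf_counter()
            hwe_table, n_dev = hw.hwe_scan(
                table, per_population=True, alpha=config.hwe_alpha, midp=config.hwe_midp
            )
            _write_tsv(hwe_table, out / "hwe.tsv")
            report.stages["hwe"] = {
                "seconds": time.perf_counter() - t0,
                "deviating_loci": n_dev,
                "alpha": config.hwe_alpha,
            }
            log.info("hwe: %d loci deviating at alpha=%g", n_dev, config.hwe_alpha)

        if "distances" in config.stages:
            current_stage = "distances"
            t0 = time.perf_counter()
            fst = df.pairwise_fst(table)
            gst = df.nei_gst_pairwise(table)
            euc = df.euclidean_pairwise(table)
            for name, mat in (("fst", fst), ("gst", gst), ("euclidean", euc)):
                mat.to_csv(out / f"distances_{name}.tsv", sep="\t", float_format="%.10g")
            _write_tsv(df.wc_components_table(table), out / "fst_components.tsv")
            report.stages["distances"] = {
                "seconds": time.perf_counter() - t0,
                "fst": fst.to_numpy(),
                "gst": gst.to_numpy(),
                "euclidean": euc.to_numpy(),
                "populations": list(fst.index),
            }

        if "outliers" in config.stages:
            current_stage = "outliers"
            t0 = time.perf_counter()
            scan = df.outflank_scan(
                table,
                trim=config.outlier_trim,
                h_min=config.outlier_hmin,
                alpha=config.outlier_alpha,
            )
            _write_tsv(scan.table, out / "outliers.tsv")
            report.stages["outliers"] = {
                "seconds": time.perf_counter() - t0,
                "n_outliers": scan.n_outliers,
                "df_inferred": scan.df_inferred,
                "fst_bar": scan.fst_bar,
            }
            log.info("outliers: %d flagged (df=%.2f)", scan.n_outliers, scan.df_inferred)

        if "dapc" in config.stages:
            current_stage = "dapc"
            t0 = time.perf_counter()
            cmp = dp.compare_panels(table, threshold=config.dapc_threshold, seed=config.seed)
            (out / "dapc_model.json").write_text(
                json.dumps(cmp.full_results.to_json_dict(), default=_jsonable)
            )
            _write_tsv(cmp.panel.table, out / "panel.tsv")
            scatter = pd.DataFrame(
                cmp.full_results.scores[:, : min(2, cmp.full_results.n_da)],
                index=table.sample_ids,
            )
            scatter.insert(0, "population", table.population_labels)
            scatter.to_csv(out / "dapc_scatter.tsv", sep="\t", float_format="%.10g")
            assignment = {
                "full": {
                    "overall": cmp.full.overall,
                    "per_population": cmp.full.per_population,
                    "mean_posterior_true": cmp.full.mean_posterior_true,
                },
                "reduced": {
                    "overall": cmp.reduced.overall,
                    "per_population": cmp.reduced.per_population,
                    "mean_posterior_true": cmp.reduced.mean_posterior_true,
                },
                "panel_size": len(cmp.panel),
                "n_pca_full": cmp.full_results.n_pca,
                "n_pca_reduced": cmp.reduced_results.n_pca,
            }
            (out / "assignment.json").write_text(json.dumps(assignment, indent=2))
            report.stages["dapc"] = {"seconds": time.perf_counter() - t0, **assignment}
            log.info(
                "dapc: panel of %d SNPs; assignment full=%.3f reduced=%.3f",
                len(cmp.panel),
                cmp.full.overall,
                cmp.reduced.overall,
            )

        for stage in ALL_STAGES:
            if stage not in config.stages:
                report.stages[stage] = {"skipped": True}
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {current_stage} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage '{current_stage}' failed: {exc}") from exc

    (out / "run_report.json").write_text(report.to_json())
    return report
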