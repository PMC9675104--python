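"""End-to-end orchestration: stratify -> screen -> aggregate -> survival -> compare.

A run is configured either from real input files or from a ``simulate``
block; every stage writes its output table into the run directory and the
run report collects per-stage record counts, thresholds and the
enrichment/difference summaries. Outputs are pure functions of the
configuration (and seed), so identical configs reproduce byte-identical
reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import consistency, correlation, isoform, stepminer, survival
from .io import ClinicalTable, ExpressionMatrix, FeatureMap, MethylationMatrix, SampleTable
from .simulate import SimConfig, simulate_dataset, write_truth

__all__ = ["PipelineConfig", "run_pipeline", "load_inputs"]

logger = logging.getLogger(__name__)

INPUT_KEYS = (
    "methylation",
    "gene_expr",
    "exon_expr",
    "isoform_expr",
    "feature_map",
    "samples",
    "clinical",
)


@dataclass
class PipelineConfig:
    out_dir: str = "methsplice_run"
    seed: int = 0
    adjust_method: str = "bh"
    alpha: float = 0.05
    min_cohort: int = 10
    simulate: SimConfig | None = None
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"significance threshold {self.alpha} outside (0, 1)")
        if self.min_cohort < 3:
            raise ValueError(f"min_cohort {self.min_cohort} < 3")
        if self.adjust_method not in ("bh", "bonferroni"):
            raise ValueError(f"adjust_method must be 'bh' or 'bonferroni'")
        if self.simulate is None and not self.inputs:
            raise ValueError("config needs either a simulate block or input paths")
        if self.inputs:
            missing = [k for k in INPUT_KEYS if k not in self.inputs]
            if missing:
                raise ValueError(f"input paths missing keys: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(
            out_dir=raw.pop("out_dir", "methsplice_run"),
            seed=int(raw.pop("seed", 0)),
            adjust_method=raw.pop("adjust_method", "bh"),
            alpha=float(raw.pop("alpha", 0.05)),
            min_cohort=int(raw.pop("min_cohort", 10)),
            simulate=SimConfig(**sim) if sim is not None else None,
            inputs=raw.pop("inputs", {}) or {},
        )
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cfg


def load_inputs(paths: dict):
    return dict(
        samples=SampleTable.from_tsv(paths["samples"]),
        meth=MethylationMatrix.from_tsv(paths["methylation"]),
        gene_expr=ExpressionMatrix.from_tsv(paths["gene_expr"], kind="gene"),
        exon_expr=ExpressionMatrix.from_tsv(paths["exon_expr"], kind="exon"),
        isoform_expr=ExpressionMatrix.from_tsv(paths["isoform_expr"], kind="isoform"),
        feature_map=FeatureMap.from_tsv(paths["feature_map"]),
        clinical=ClinicalTable.from_tsv(paths["clinical"]),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "parameters": {
            "adjust_method": config.adjust_method,
            "alpha": config.alpha,
            "min_cohort": config.min_cohort,
            "seed": config.seed,
        },
        "stages": {},
    }

    # -- inputs ---------------------------------------------------------
    if config.simulate is not None:
        sim_cfg = config.simulate.with_(seed=config.seed)
        data = simulate_dataset(sim_cfg)
        data.samples.to_tsv(out / "samples.tsv")
        data.meth.to_tsv(out / "methylation.tsv")
        data.gene_expr.to_tsv(out / "gene_expr.tsv")
        data.exon_expr.to_tsv(out / "exon_expr.tsv")
        data.isoform_expr.to_tsv(out / "isoform_expr.tsv")
        data.feature_map.to_tsv(out / "feature_map.tsv")
        data.clinical.to_tsv(out / "clinical.tsv")
        write_truth(data.truth, out / "truth.tsv", data.feature_map)
        samples, meth, feature_map, clinical = (
            data.samples,
            data.meth,
            data.feature_map,
            data.clinical,
        )
        gene_expr, exon_expr, isoform_expr = data.gene_expr, data.exon_expr, data.isoform_expr
        report["stages"]["simulate"] = {
            "n_samples": len(samples.sample_ids),
            "n_genes": len(gene_expr.feature_ids),
            "n_cpgs": len(meth.cpg_ids),
            "n_planted_pairs": len(data.truth.planted_pairs),
            "n_driver_cpgs": len(data.truth.driver_cpgs),
        }
    else:
        loaded = load_inputs(config.inputs)
        samples, meth, feature_map, clinical = (
            loaded["samples"],
            loaded["meth"],
            loaded["feature_map"],
            loaded["clinical"],
        )
        gene_expr, exon_expr, isoform_expr = (
            loaded["gene_expr"],
            loaded["exon_expr"],
            loaded["isoform_expr"],
        )

    # -- stratification -------------------------------------------------
    label_table, fits = stepminer.stratify_matrix(gene_expr)
    label_table.to_csv(out / "labels.tsv", sep="\t", index=False, na_rep="NA")
    cohorts = stepminer.cohorts_from_labels(label_table)
    n_degenerate = sum(1 for f in fits.values() if f.degenerate)
    report["stages"]["stratify"] = {
        "n_genes": len(fits),
        "n_degenerate_skipped": n_degenerate,
        "n_high_labels": int((label_table["label"] == stepminer.HIGH).sum()),
    }

    # -- correlation screens --------------------------------------------
    screens = {}
    for kind, expr in (("exon", exon_expr), ("isoform", isoform_expr)):
        table, summary = correlation.run_screen(
            samples,
            meth,
            expr,
            feature_map,
            cohorts,
            kind,
            method=config.adjust_method,
            alpha=config.alpha,
            min_cohort=config.min_cohort,
        )
        table.to_csv(out / f"screen_{kind}.tsv", sep="\t", index=False)
        screens[kind] = table
        report["stages"][f"screen_{kind}"] = summary

    # -- multi-cancer aggregation ---------------------------------------
    pairs = consistency.rank_pairs(consistency.collect_pairs(screens["exon"]))
    pairs.to_csv(out / "multicancer_pairs.tsv", sep="\t", index=False)
    agg = {"n_multicancer_pairs": int(len(pairs))}
    if len(pairs):
        perfect, above_07 = consistency.consistency_summary(pairs)
        agg |= {"frac_consistency_1": perfect, "frac_consistency_gt_0.7": above_07}
    report["stages"]["aggregate"] = agg

    # -- survival scan + enrichment -------------------------------------
    scan = survival.survival_scan(
        samples, meth, clinical, cohorts, feature_map, min_cohort=config.min_cohort,
        alpha=config.alpha,
    )
    scan.to_csv(out / "survival.tsv", sep="\t", index=False)
    sig_exon = screens["exon"][screens["exon"]["significant"]]
    exon_units = set(zip(sig_exon["cancer"], sig_exon["cpg"]))
    sig_surv = scan[scan["significant"]] if len(scan) else scan
    surv_units = set(zip(sig_surv["cancer"], sig_surv["cpg"])) if len(sig_surv) else set()
    enrich = survival.overlap_enrichment(
        exon_units, surv_units, n_cpg_total=len(meth.cpg_ids), n_cancers=len(samples.cancer_types)
    )
    enrich_dict = {
        k: (None if v is None else (float(v) if isinstance(v, float) else int(v)))
        for k, v in enrich.__dict__.items()
    }
    pd_rows = [(k, v) for k, v in enrich_dict.items()]
    import pandas as pd

    pd.DataFrame(pd_rows, columns=["key", "value"]).to_csv(
        out / "enrichment.tsv", sep="\t", index=False
    )
    report["stages"]["survival"] = {
        "n_records": int(len(scan)),
        "n_significant": int(len(sig_surv)),
        "enrichment": enrich_dict,
    }

    # -- exon vs isoform comparison --------------------------------------
    diffs = isoform.build_diff_table(screens["exon"], screens["isoform"], feature_map)
    diffs.to_csv(out / "isoform_diffs.tsv", sep="\t", index=False, na_rep="NA")
    comp: dict = {"n_exon_records": int(len(diffs)), "n_matched": int(diffs["diff"].notna().sum())}
    if comp["n_matched"]:
        summary = isoform.diff_distribution(diffs)
        summary["histogram"].to_csv(out / "diff_histogram.tsv", sep="\t", index=False)
        comp["per_record"] = summary["per_record"]
        comp["per_pair"] = summary["per_pair"]
    report["stages"]["compare"] = comp

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
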