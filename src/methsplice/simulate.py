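"""Multi-cancer methylation / expression / survival simulator with planted truth.

The generator emulates the statistical structure the analysis exploits,
not the empirical distributions of any real cohort:

* gene expression is a two-component mixture — a silent mode near zero
  and an expressed mode well above it — so a one-step least-squares fit
  recovers the mode boundary and the expressed samples form the
  high-expression cohort;
* beta values are logistic transforms of Gaussian latents, hence in
  (0, 1) and roughly bimodal around 0.5;
* a chosen fraction of CpG-exon pairs carries a planted linear effect:
  within each cancer's expressed samples the exon value is
  baseline + sign * a * z(beta) + noise, with ``a`` scaled so the
  population correlation is ±effect_r exactly. Each exon has at most one
  planted CpG regulator so the planted correlation is not contaminated;
* with probability ``sign_consistency`` a planted pair keeps one sign in
  every cancer; otherwise its per-cancer signs are drawn uniformly among
  non-constant sign vectors, so the expected fraction of perfectly
  consistent planted pairs equals ``sign_consistency``;
* isoforms are noisy means of their member exons, which dilutes any
  single-exon effect — the structure behind the exon-vs-isoform
  correlation-strength comparison;
* survival is exponential with per-sample hazard
  baseline_hazard * hazard_ratio ** (number of methylated driver CpGs),
  a driver being methylated in a sample when its beta exceeds 0.5;
  censoring is exponential at ``censor_rate``. Driver CpGs are sampled
  globally (a small absolute number keeps each individually detectable).

Per-gene RNG substreams are derived from (seed, gene index), so the
matrices for a subset of genes are reproducible; driver selection and
survival draws use dedicated global substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, FeatureMap, MethylationMatrix, SampleTable

__all__ = ["SimConfig", "SimTruth", "SimDataset", "simulate_dataset", "write_truth", "read_truth"]

_DRIVER_STREAM = 999_979
_SURVIVAL_STREAM = 999_983


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the pan-cancer setting at demo scale: 3 cancer types
    of 60 patients, 200 genes averaging 22 CpGs and 10 exons each.
    """

    n_cancers: int = 3
    samples_per_cancer: int = 60
    n_genes: int = 200
    cpgs_per_gene: int = 22
    exons_per_gene: int = 10
    isoforms_per_gene: int = 3
    frac_expressed: float = 0.7
    effect_r: float = 0.7
    frac_planted: float = 0.05
    sign_consistency: float = 0.9
    frac_driver_cpgs: float = 0.002
    hazard_ratio: float = 3.0
    censor_rate: float = 0.01
    baseline_hazard: float = 0.02
    noise_sd: float = 1.0
    iso_noise_sd: float = 0.5
    high_mean: float = 8.0
    low_scale: float = 0.3
    beta_latent_sd: float = 1.5
    exon_membership_p: float = 0.5
    driver_mode: str = "planted"  # or "independent"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_expressed",
            "frac_planted",
            "sign_consistency",
            "frac_driver_cpgs",
            "exon_membership_p",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.effect_r < 1.0:
            raise ValueError(f"effect_r={self.effect_r} outside (0, 1)")
        for name in (
            "n_cancers",
            "samples_per_cancer",
            "n_genes",
            "cpgs_per_gene",
            "exons_per_gene",
            "isoforms_per_gene",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.driver_mode not in ("planted", "independent"):
            raise ValueError(f"driver_mode must be 'planted' or 'independent', got {self.driver_mode!r}")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class SimTruth:
    """Planted structure: per-cancer signed CpG-exon effects, driver CpGs,
    and the latent expression-mode label of every (gene, sample)."""

    planted_pairs: set = field(default_factory=set)  # (cancer, gene, cpg, exon, sign)
    driver_cpgs: set = field(default_factory=set)  # (gene, cpg)
    mode_labels: pd.DataFrame | None = None  # genes x samples, bool (True = expressed)

    def validate(self, feature_map: FeatureMap) -> None:
        genes = set(feature_map.genes)
        for cancer, gene, cpg, exon, sign in self.planted_pairs:
            if gene not in genes:
                raise ValueError(f"planted pair references unknown gene {gene!r}")
            if cpg not in feature_map.gene_cpgs.get(gene, []):
                raise ValueError(f"planted CpG {cpg!r} not mapped to gene {gene!r}")
            if exon not in feature_map.gene_exons.get(gene, []):
                raise ValueError(f"planted exon {exon!r} not mapped to gene {gene!r}")
        for gene, cpg in self.driver_cpgs:
            if gene not in genes:
                raise ValueError(f"driver CpG references unknown gene {gene!r}")


class SimDataset(NamedTuple):
    samples: SampleTable
    meth: MethylationMatrix
    gene_expr: ExpressionMatrix
    exon_expr: ExpressionMatrix
    isoform_expr: ExpressionMatrix
    feature_map: FeatureMap
    clinical: ClinicalTable
    truth: SimTruth


def _nonconstant_signs(rng, n: int) -> np.ndarray:
    """Uniform draw among sign vectors of length n that are not all equal."""
    while True:
        s = rng.choice([-1, 1], size=n)
        if not np.all(s == s[0]):
            return s


def simulate_dataset(config: SimConfig) -> SimDataset:
    cfg = config
    cancers = [f"cancer{k + 1:02d}" for k in range(cfg.n_cancers)]
    samples = [f"{c}_p{i + 1:03d}" for c in cancers for i in range(cfg.samples_per_cancer)]
    n_samples = len(samples)
    cancer_of = np.repeat(np.arange(cfg.n_cancers), cfg.samples_per_cancer)
    cancer_idx = [np.flatnonzero(cancer_of == k) for k in range(cfg.n_cancers)]

    gene_ids, cpg_rows, exon_rows, iso_rows = [], [], [], []
    gene_cpgs: dict = {}
    gene_exons: dict = {}
    gene_isoforms: dict = {}
    isoform_exons: dict = {}
    meth_blocks, exon_blocks, iso_blocks = [], [], []
    gene_values = np.empty((cfg.n_genes, n_samples))
    mode = np.empty((cfg.n_genes, n_samples), dtype=bool)
    planted_pairs: set = set()
    planted_cpg_pool: list[tuple[str, str]] = []  # (gene, cpg), for driver draws
    all_cpg_pool: list[tuple[str, str]] = []

    a_effect = cfg.effect_r / np.sqrt(1.0 - cfg.effect_r**2) * cfg.noise_sd

    for j in range(cfg.n_genes):
        rng = np.random.default_rng([cfg.seed, j])
        gene = f"g{j:04d}"
        gene_ids.append(gene)
        cpgs = [f"cg{j:04d}{i:03d}" for i in range(cfg.cpgs_per_gene)]
        chrom = f"chr{(j % 22) + 1}"
        strand = rng.choice(["+", "-"])
        gstart = 1_000_000 + j * 1_000_000
        exons = []
        for i in range(cfg.exons_per_gene):
            start = gstart + i * 3_000
            end = start + int(rng.integers(100, 2_000))
            exons.append(f"{chrom}:{start}-{end}:{strand}")
        isoforms = [f"iso{j:04d}_{t}" for t in range(cfg.isoforms_per_gene)]
        gene_cpgs[gene] = cpgs
        gene_exons[gene] = exons
        gene_isoforms[gene] = isoforms
        all_cpg_pool += [(gene, c) for c in cpgs]

        # expression mode and gene-level values
        expressed = rng.random(n_samples) < cfg.frac_expressed
        gvals = np.where(
            expressed,
            rng.normal(cfg.high_mean, 1.0, n_samples),
            np.abs(rng.normal(0.0, cfg.low_scale, n_samples)),
        )
        mode[j] = expressed
        gene_values[j] = np.clip(gvals, 0.0, None)

        # methylation: logistic of Gaussian latent
        latent = rng.normal(0.0, cfg.beta_latent_sd, (cfg.cpgs_per_gene, n_samples))
        betas = 1.0 / (1.0 + np.exp(-latent))

        # exon baselines
        evals = np.where(
            expressed[None, :],
            rng.normal(cfg.high_mean, cfg.noise_sd, (cfg.exons_per_gene, n_samples)),
            np.abs(rng.normal(0.0, cfg.low_scale, (cfg.exons_per_gene, n_samples))),
        )

        # planted CpG -> exon effects (distinct exons; at most one regulator each)
        n_pairs = cfg.cpgs_per_gene * cfg.exons_per_gene
        n_planted = min(
            int(round(cfg.frac_planted * n_pairs)), cfg.exons_per_gene, cfg.cpgs_per_gene
        )
        if n_planted > 0:
            exon_pick = rng.choice(cfg.exons_per_gene, size=n_planted, replace=False)
            cpg_pick = rng.choice(cfg.cpgs_per_gene, size=n_planted, replace=False)
            for ei, ci in zip(exon_pick, cpg_pick):
                base_sign = int(rng.choice([-1, 1]))
                if cfg.n_cancers == 1 or rng.random() < cfg.sign_consistency:
                    signs = np.full(cfg.n_cancers, base_sign)
                else:
                    signs = _nonconstant_signs(rng, cfg.n_cancers)
                for k in range(cfg.n_cancers):
                    idx = cancer_idx[k][expressed[cancer_idx[k]]]
                    if idx.size < 3:
                        continue
                    b = betas[ci, idx]
                    sd = b.std()
                    if sd == 0:
                        continue
                    z = (b - b.mean()) / sd
                    evals[ei, idx] = (
                        cfg.high_mean
                        + signs[k] * a_effect * z
                        + rng.normal(0.0, cfg.noise_sd, idx.size)
                    )
                    planted_pairs.add((cancers[k], gene, cpgs[ci], exons[ei], int(signs[k])))
                planted_cpg_pool.append((gene, cpgs[ci]))
        evals = np.clip(evals, 0.0, None)

        # isoforms: noisy means of member exons
        ivals = np.empty((cfg.isoforms_per_gene, n_samples))
        for t, iso in enumerate(isoforms):
            member_mask = rng.random(cfg.exons_per_gene) < cfg.exon_membership_p
            if not member_mask.any():
                member_mask[int(rng.integers(cfg.exons_per_gene))] = True
            members = [exons[i] for i in np.flatnonzero(member_mask)]
            isoform_exons[iso] = members
            ivals[t] = evals[member_mask].mean(axis=0) + rng.normal(
                0.0, cfg.iso_noise_sd, n_samples
            )
        ivals = np.clip(ivals, 0.0, None)

        meth_blocks.append(pd.DataFrame(betas, index=cpgs, columns=samples))
        exon_blocks.append(pd.DataFrame(evals, index=exons, columns=samples))
        iso_blocks.append(pd.DataFrame(ivals, index=isoforms, columns=samples))
        cpg_rows += cpgs
        exon_rows += exons
        iso_rows += isoforms

    meth_df = pd.concat(meth_blocks)
    exon_df = pd.concat(exon_blocks)
    iso_df = pd.concat(iso_blocks)
    gene_df = pd.DataFrame(gene_values, index=gene_ids, columns=samples)

    # global driver selection (kept few so each is individually detectable)
    drng = np.random.default_rng([cfg.seed, _DRIVER_STREAM])
    planted_unique = sorted(set(planted_cpg_pool))
    n_drivers = int(round(cfg.frac_driver_cpgs * len(planted_unique)))
    pool = planted_unique if cfg.driver_mode == "planted" else sorted(set(all_cpg_pool))
    n_drivers = min(n_drivers, len(pool))
    driver_cpgs: set = set()
    if n_drivers > 0:
        pick = drng.choice(len(pool), size=n_drivers, replace=False)
        driver_cpgs = {pool[i] for i in sorted(pick)}

    # survival: exponential with hazard scaled by methylated driver count
    srng = np.random.default_rng([cfg.seed, _SURVIVAL_STREAM])
    if driver_cpgs:
        driver_ids = [c for _, c in sorted(driver_cpgs)]
        meth_count = (meth_df.loc[driver_ids].to_numpy() > 0.5).sum(axis=0)
    else:
        meth_count = np.zeros(n_samples, dtype=int)
    hazard = cfg.baseline_hazard * cfg.hazard_ratio ** meth_count
    t_event = srng.exponential(1.0 / hazard)
    t_censor = srng.exponential(1.0 / cfg.censor_rate, n_samples)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    sample_table = SampleTable(
        pd.DataFrame({"sample_id": samples, "cancer_type": [cancers[k] for k in cancer_of]})
    )
    clinical = ClinicalTable(
        pd.DataFrame({"sample_id": samples, "time": np.round(time, 6), "event": event})
    )
    feature_map = FeatureMap(gene_cpgs, gene_exons, gene_isoforms, isoform_exons)
    truth = SimTruth(
        planted_pairs=planted_pairs,
        driver_cpgs=driver_cpgs,
        mode_labels=pd.DataFrame(mode, index=gene_ids, columns=samples),
    )
    return SimDataset(
        samples=sample_table,
        meth=MethylationMatrix(meth_df),
        gene_expr=ExpressionMatrix(gene_df, kind="gene"),
        exon_expr=ExpressionMatrix(exon_df, kind="exon"),
        isoform_expr=ExpressionMatrix(iso_df, kind="isoform"),
        feature_map=feature_map,
        clinical=clinical,
        truth=truth,
    )


TRUTH_COLUMNS = ["record_kind", "cancer", "gene", "cpg", "exon", "sign", "sample", "label"]


def write_truth(truth: SimTruth, path, feature_map: FeatureMap | None = None) -> None:
    """Lossless TSV dump of the planted structure (long format, one record per row)."""
    if feature_map is not None:
        truth.validate(feature_map)
    rows = []
    for cancer, gene, cpg, exon, sign in sorted(truth.planted_pairs):
        rows.append(("planted", cancer, gene, cpg, exon, sign, "", ""))
    for gene, cpg in sorted(truth.driver_cpgs):
        rows.append(("driver", "", gene, cpg, "", "", "", ""))
    if truth.mode_labels is not None:
        for gene in truth.mode_labels.index:
            row = truth.mode_labels.loc[gene]
            for sample, expressed in row.items():
                rows.append(("mode", "", gene, "", "", "", sample, "high" if expressed else "low"))
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth(path) -> SimTruth:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != TRUTH_COLUMNS:
        raise ValueError(f"truth file columns {list(df.columns)} != {TRUTH_COLUMNS}")
    planted = {
        (r.cancer, r.gene, r.cpg, r.exon, int(r.sign))
        for r in df[df["record_kind"] == "planted"].itertuples(index=False)
    }
    drivers = {
        (r.gene, r.cpg) for r in df[df["record_kind"] == "driver"].itertuples(index=False)
    }
    modes = df[df["record_kind"] == "mode"]
    mode_labels = None
    if len(modes):
        mode_labels = (
            modes.assign(expressed=modes["label"] == "high")
            .pivot(index="gene", columns="sample", values="expressed")
            .astype(bool)
        )
        mode_labels.index.name = None
        mode_labels.columns.name = None
    return SimTruth(planted_pairs=planted, driver_cpgs=drivers, mode_labels=mode_labels)
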