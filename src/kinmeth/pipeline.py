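"""End-to-end orchestration of the four sample contrasts.

A contrast selects samples (by tissue/timepoint), runs the filter cascade,
fits the kinship mixed model at every retained site, applies q-value FDR,
calls DMCs and DMRs, annotates them against gene models, runs gene-set
enrichment, and computes global-pattern summaries.  The four canonical
contrasts of a split-rearing design are:

- immediate: rearing group as predictor, age-1 liver samples
- persistent: rearing group as predictor, age-2 liver samples
- developmental: timepoint as predictor with rearing group as covariate,
  all liver samples
- intergenerational: rearing group as predictor, sperm samples
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import dmr as dmr_mod
from . import dmtest, filtering, patterns
from .kinship import KinshipMatrix
from .matrix import MethylationMatrix

logger = logging.getLogger(__name__)

CANONICAL_CONTRASTS = {
    "immediate": dict(predictor="group", tissue="liver", timepoint="age1"),
    "persistent": dict(predictor="group", tissue="liver", timepoint="age2"),
    "developmental": dict(
        predictor="timepoint", covariates=("group",), tissue="liver", timepoint=None
    ),
    "intergenerational": dict(predictor="group", tissue="sperm", timepoint=None),
}


@dataclass
class ContrastConfig:
    name: str = "immediate"
    predictor: str = "group"
    predictor_level: str = None          # defaults: hatchery / age2
    covariates: tuple = ()
    tissue: str = "liver"
    timepoint: str = "age1"              # None = all timepoints
    filter_params: filtering.FilterParams = field(default_factory=filtering.FilterParams)
    fdr: float = 0.10
    dmr_window_bp: int = 2000
    dmr_p_thresh: float = 0.001
    annotation_window_bp: int = 10000
    cluster_metric: str = "correlation"
    cluster_linkage: str = "average"
    n_perm: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.predictor not in ("group", "timepoint"):
            raise ValueError("predictor must be 'group' or 'timepoint'")
        if self.name == "developmental":
            if self.predictor != "timepoint" or "group" not in self.covariates:
                raise ValueError(
                    "developmental contrast requires predictor='timepoint' "
                    "with 'group' among the covariates"
                )
        if self.predictor_level is None:
            self.predictor_level = "hatchery" if self.predictor == "group" else "age2"

    @classmethod
    def canonical(cls, name: str, **overrides) -> "ContrastConfig":
        base = dict(CANONICAL_CONTRASTS[name])
        base.update(overrides)
        return cls(name=name, **base)


@dataclass
class ContrastBundle:
    config: ContrastConfig
    filter_report: filtering.FilterReport
    fits: pd.DataFrame                    # incl. q_value, meth_diff, is_dmc
    dmrs: list
    annotations: list
    enrichment: list
    anosim: patterns.AnosimResult
    pca_scores: np.ndarray
    pca_variance: np.ndarray
    newick: str
    analyzed_sites: set                   # (chrom, pos) passing all filters
    covered_sites: set                    # (chrom, pos) passing coverage step
    log_lines: list

    @property
    def dmcs(self) -> pd.DataFrame:
        return self.fits[self.fits["is_dmc"]].reset_index(drop=True)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "filter_report.tsv").write_text(self.filter_report.to_tsv())
        self.fits.to_csv(out / "site_results.tsv", sep="\t", index=False)
        self.dmcs.to_csv(out / "dmc_table.tsv", sep="\t", index=False)
        (out / "dmc.bed").write_text(dmtest.dmc_table_to_bed(self.fits))
        dmr_mod.dmrs_to_table(self.dmrs).to_csv(out / "dmr_table.tsv", sep="\t", index=False)
        (out / "dmr.bed").write_text(dmr_mod.dmrs_to_bed(self.dmrs))
        pd.DataFrame(
            [(a.feature_id, a.gene_id, a.signed_distance) for a in self.annotations],
            columns=["feature_id", "gene_id", "signed_distance"],
        ).to_csv(out / "annotations.tsv", sep="\t", index=False)
        pd.DataFrame([asdict(e) for e in self.enrichment]).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
        np.savetxt(out / "pca_scores.tsv", self.pca_scores, delimiter="\t")
        np.savetxt(out / "pca_variance.tsv", self.pca_variance, delimiter="\t")
        (out / "dendrogram.nwk").write_text(self.newick + "\n")
        (out / "anosim.txt").write_text(
            f"R\t{self.anosim.R:.6g}\np\t{self.anosim.p_value:.6g}\n"
            f"n_perm\t{self.anosim.n_permutations}\nseed\t{self.anosim.seed}\n"
        )
        (out / "run_log.txt").write_text("\n".join(self.log_lines) + "\n")


def select_samples(matrix: MethylationMatrix, config: ContrastConfig) -> MethylationMatrix:
    keep = [
        s.tissue == config.tissue
        and (config.timepoint is None or s.timepoint == config.timepoint)
        for s in matrix.samples
    ]
    return matrix.subset_samples(np.array(keep, dtype=bool))


def run_contrast(
    config: ContrastConfig,
    matrix: MethylationMatrix,
    kinship: KinshipMatrix,
    snp_positions: set = frozenset(),
    genes=None,
    gene_sets: dict = None,
) -> ContrastBundle:
    """Execute the full pipeline for one contrast."""
    t0 = time.time()
    log_lines = [f"contrast: {config.name}", f"config: {config}"]
    sub = select_samples(matrix, config)
    levels = {}
    for s in sub.samples:
        levels.setdefault(getattr(s, config.predictor), []).append(s.sample_id)
    if len(levels) < 2 or min(len(v) for v in levels.values()) < 4:
        raise ValueError(
            f"contrast {config.name}: needs >= 4 samples per predictor level, "
            f"got {({k: len(v) for k, v in levels.items()})}"
        )
    log_lines.append(f"samples: {sub.n_samples} ({ {k: len(v) for k, v in levels.items()} })")

    covered, _ = filtering.filter_coverage(
        sub, config.predictor,
        config.filter_params.min_frac_per_group, config.filter_params.min_depth,
    )
    covered_sites = set(zip(covered.sites["chrom"], covered.sites["pos"]))
    filtered, report = filtering.run_cascade(
        sub, snp_positions, config.filter_params, group_field=config.predictor
    )
    for step in report.steps:
        log_lines.append(f"filter {step.name} ({step.threshold}): {step.n_remaining} CG remain")
    analyzed_sites = set(zip(filtered.sites["chrom"], filtered.sites["pos"]))

    fits = dmtest.fit_all(
        filtered, kinship,
        predictor_field=config.predictor,
        predictor_level=config.predictor_level,
        covariate_fields=config.covariates,
    )
    fits = dmtest.call_dmcs(
        fits, filtered, config.predictor, config.predictor_level, config.fdr
    )
    n_dmc = int(fits["is_dmc"].sum())
    log_lines.append(f"DMCs at q<{config.fdr:g}: {n_dmc}")

    dmrs = dmr_mod.call_dmrs(fits, config.dmr_window_bp, config.dmr_p_thresh)
    log_lines.append(f"DMRs: {len(dmrs)}")

    annotations, enrichment = [], []
    if genes:
        feats = pd.DataFrame(
            {
                "feature_id": [f"DMC_{c}_{p}" for c, p in
                               zip(fits.loc[fits["is_dmc"], "chrom"],
                                   fits.loc[fits["is_dmc"], "pos"])],
                "chrom": fits.loc[fits["is_dmc"], "chrom"].to_numpy(),
                "start": fits.loc[fits["is_dmc"], "pos"].to_numpy(),
                "stop": fits.loc[fits["is_dmc"], "pos"].to_numpy(),
            }
        )
        dmr_feats = pd.DataFrame(
            {
                "feature_id": [d.dmr_id for d in dmrs],
                "chrom": [d.chrom for d in dmrs],
                "start": [d.start for d in dmrs],
                "stop": [d.stop for d in dmrs],
            }
        )
        annotations = dmr_mod.annotate(
            pd.concat([feats, dmr_feats], ignore_index=True), genes,
            config.annotation_window_bp,
        )
        if gene_sets:
            all_sites = pd.DataFrame(
                {
                    "feature_id": [f"CG_{c}_{p}" for c, p in analyzed_sites],
                    "chrom": [c for c, _ in analyzed_sites],
                    "start": [p for _, p in analyzed_sites],
                    "stop": [p for _, p in analyzed_sites],
                }
            )
            background = {a.gene_id for a in dmr_mod.annotate(
                all_sites, genes, config.annotation_window_bp)}
            foreground = {a.gene_id for a in annotations} & background
            enrichment = dmr_mod.enrich(foreground, background, gene_sets)
            log_lines.append(
                f"enrichment: {sum(e.passes for e in enrichment)} passing sets"
            )

    D = patterns.distance_matrix(filtered, config.cluster_metric)
    Z = patterns.hierarchical_cluster(D, config.cluster_linkage)
    newick = patterns.linkage_to_newick(Z, D.sample_ids)
    scores, variance = patterns.pca(filtered)
    if config.name == "developmental":
        labels = [f"{s.group}|{s.timepoint}" for s in filtered.samples]
    else:
        labels = [getattr(s, config.predictor) for s in filtered.samples]
    ano = patterns.anosim(D, labels, n_perm=config.n_perm, seed=config.seed)
    log_lines.append(f"ANOSIM R={ano.R:.4f} p={ano.p_value:.4g}")
    log_lines.append(f"elapsed: {time.time() - t0:.1f}s")
    for line in log_lines:
        logger.info("%s", line)

    return ContrastBundle(
        config=config,
        filter_report=report,
        fits=fits,
        dmrs=dmrs,
        annotations=annotations,
        enrichment=enrichment,
        anosim=ano,
        pca_scores=scores,
        pca_variance=variance,
        newick=newick,
        analyzed_sites=analyzed_sites,
        covered_sites=covered_sites,
        log_lines=log_lines,
    )


def compare_contrasts(bundle_a: ContrastBundle, bundle_b: ContrastBundle,
                      proximity_bp: int = 10000) -> dict:
    """Cross-contrast DMC overlap, proximity, direction concordance, and
    the fraction of each contrast's DMCs meeting the other's coverage
    criteria."""
    report = dmtest.compare_dmc_sets(bundle_a.dmcs, bundle_b.dmcs, proximity_bp)
    a_sites = set(zip(bundle_a.dmcs["chrom"], bundle_a.dmcs["pos"]))
    b_sites = set(zip(bundle_b.dmcs["chrom"], bundle_b.dmcs["pos"]))
    report["frac_a_covered_in_b"] = (
        len(a_sites & bundle_b.covered_sites) / len(a_sites) if a_sites else np.nan
    )
    report["frac_b_covered_in_a"] = (
        len(b_sites & bundle_a.covered_sites) / len(b_sites) if b_sites else np.nan
    )
    return report
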