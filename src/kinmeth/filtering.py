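"""Pre-modelling CG-site filter cascade and bisulfite QC.

The cascade retains sites that are adequately covered in each predictor
group, then removes the lowest-variance sites, constitutively hypo- and
hyper-methylated sites, and sites overlapping known C/T SNPs.  Each step's
remaining site count is recorded in a :class:`FilterReport` so the output
mirrors the familiar per-contrast filtering tables of RRBS studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .matrix import MethylationMatrix


@dataclass
class FilterStep:
    name: str
    threshold: str
    n_remaining: int


@dataclass
class FilterReport:
    n_input: int
    steps: list = field(default_factory=list)

    def add(self, name: str, threshold: str, n_remaining: int) -> None:
        prev = self.steps[-1].n_remaining if self.steps else self.n_input
        if n_remaining > prev:
            raise ValueError("filter cascade counts must be non-increasing")
        self.steps.append(FilterStep(name, threshold, n_remaining))

    def to_tsv(self) -> str:
        lines = ["step\tthreshold\tCG_remaining"]
        lines.append(f"input\t-\t{self.n_input}")
        for s in self.steps:
            lines.append(f"{s.name}\t{s.threshold}\t{s.n_remaining}")
        return "\n".join(lines) + "\n"


def filter_coverage(
    matrix: MethylationMatrix,
    group_field: str = "group",
    min_frac_per_group: float = 0.5,
    min_depth: int = 11,
) -> tuple:
    """Retain sites covered at >= min_depth in at least min_frac_per_group
    of the samples within *each* predictor group.

    The default depth of 11 implements a strict '> 10x' coverage rule.
    """
    levels = sorted({getattr(s, group_field) for s in matrix.samples})
    keep = np.ones(matrix.n_sites, dtype=bool)
    for lev in levels:
        cols = np.array([getattr(s, group_field) == lev for s in matrix.samples])
        if cols.sum() == 0:
            raise ValueError(f"group {lev!r} has no samples")
        depth_ok = (matrix.total[:, cols] >= min_depth) & (
            matrix.total[:, cols] > 0
        )
        frac = depth_ok.sum(axis=1) / cols.sum()
        keep &= frac >= min_frac_per_group
    out = matrix.subset_sites(keep)
    return out, out.n_sites


def filter_low_variance(matrix: MethylationMatrix, drop_frac: float = 0.05) -> tuple:
    """Drop sites at or below the drop_frac empirical quantile of per-site
    sample variance of methylation proportions (ddof=1 over observed cells).

    Ties at the quantile are dropped together (inclusive convention).
    """
    if drop_frac == 0.0 or matrix.n_sites == 0:
        return matrix.subset_sites(np.ones(matrix.n_sites, dtype=bool)), matrix.n_sites
    props = matrix.proportions()
    n_obs = np.sum(~np.isnan(props), axis=1)
    if np.any(n_obs < 2):
        raise ValueError("every site needs >= 2 observed proportions")
    var = np.nanvar(props, axis=1, ddof=1)
    cutoff = np.quantile(var, drop_frac, method="lower")
    keep = var > cutoff
    out = matrix.subset_sites(keep)
    return out, out.n_sites


def filter_extreme_methylation(
    matrix: MethylationMatrix, low: float = 0.10, high: float = 0.90
) -> tuple:
    """Two-step removal of constitutively unmethylated / methylated sites.

    Site means are unweighted means of per-sample proportions over observed
    cells.  Bounds are inclusive: mean <= low is dropped at the hypo step,
    mean >= high at the hyper step.  Returns (matrix, n_after_hypo,
    n_after_hyper).
    """
    props = matrix.proportions()
    mean = np.nanmean(props, axis=1)
    keep_hypo = mean > low
    n_after_hypo = int(keep_hypo.sum())
    keep_both = keep_hypo & (mean < high)
    out = matrix.subset_sites(keep_both)
    return out, n_after_hypo, out.n_sites


def mask_snp_sites(matrix: MethylationMatrix, snp_positions: set) -> tuple:
    """Remove CG sites overlapping known C/T SNP positions.

    Both positions of the CG dinucleotide are covered: a site at pos is
    removed if (chrom, pos) or (chrom, pos+1) is in the SNP set.
    """
    chroms = matrix.sites["chrom"].to_numpy()
    poss = matrix.sites["pos"].to_numpy()
    keep = np.array(
        [
            (c, p) not in snp_positions and (c, p + 1) not in snp_positions
            for c, p in zip(chroms, poss)
        ]
    ) if matrix.n_sites else np.ones(0, dtype=bool)
    out = matrix.subset_sites(keep)
    return out, out.n_sites


@dataclass
class FilterParams:
    min_frac_per_group: float = 0.5
    min_depth: int = 11
    var_quantile: float = 0.05
    low: float = 0.10
    high: float = 0.90


def run_cascade(
    matrix: MethylationMatrix,
    snp_positions: set = frozenset(),
    params: FilterParams = None,
    group_field: str = "group",
) -> tuple:
    """Apply the full filter cascade in its canonical order
    (coverage -> low variance -> hypo -> hyper -> CG SNPs) and report the
    per-step remaining counts."""
    params = params or FilterParams()
    report = FilterReport(n_input=matrix.n_sites)

    m, n = filter_coverage(matrix, group_field, params.min_frac_per_group, params.min_depth)
    report.add(
        "coverage",
        f">={params.min_depth}x in >={params.min_frac_per_group:g} of each group",
        n,
    )
    m, n = filter_low_variance(m, params.var_quantile)
    report.add("low_variance", f"lowest {params.var_quantile:g} quantile", n)
    m, n_hypo, n_hyper = filter_extreme_methylation(m, params.low, params.high)
    report.add("hypo_methylation", f"mean <= {params.low:g}", n_hypo)
    report.add("hyper_methylation", f"mean >= {params.high:g}", n_hyper)
    m, n = mask_snp_sites(m, snp_positions)
    report.add("cg_snps", "site or site+1 in SNP set", n)
    return m, report


# ---------------------------------------------------------------------------
# Bisulfite-conversion QC
# ---------------------------------------------------------------------------


def conversion_efficiency(non_cpg_records) -> float:
    """Estimate bisulfite conversion efficiency from non-CpG-context counts.

    efficiency = 1 - (sum methylated non-CpG) / (sum total non-CpG); non-CpG
    cytosines are essentially unmethylated in vertebrates, so residual
    'methylation' there measures failed conversion.
    """
    n_meth = sum(r.n_meth for r in non_cpg_records)
    n_total = sum(r.total for r in non_cpg_records)
    if n_total == 0:
        raise ValueError("no non-CpG reads; conversion efficiency undefined")
    return 1.0 - n_meth / n_total


def compare_batches(efficiencies, batch_labels) -> tuple:
    """Welch two-sided t-test of per-sample conversion efficiencies between
    two sequencing batches.  Returns (t statistic, p-value)."""
    eff = np.asarray(efficiencies, dtype=float)
    labels = np.asarray(batch_labels)
    levels = sorted(set(labels.tolist()))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 batches, got {len(levels)}")
    a = eff[labels == levels[0]]
    b = eff[labels == levels[1]]
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
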