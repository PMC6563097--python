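"""Synthetic split-family RRBS datasets with known ground truth.

The generator emulates a split-family rearing experiment: families of
full-sib offspring (plus one shared-sire and one shared-dam half-sib family
pair) divided between a hatchery and a simulated stream rearing group, a
small SNP panel for parentage and relatedness estimation, and per-CpG
methylation counts produced by the same beta-binomial-style mixed model the
analysis fits: a logit-scale site baseline plus a treatment fixed effect, a
kinship-structured genetic random effect, an independent residual, binomial
read sampling on top, and negative-binomial per-cell coverage.  A minority
of CG sites are contaminated by a segregating C/T SNP, whose apparent
methylation is driven by genotype instead of the model.

Every draw is governed by ``SimulationConfig.seed``; identical configs give
identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import write_bismark_coverage, write_sample_sheet
from .matrix import MISSING, MethylationMatrix, SampleMeta
from .kinship import KinshipMatrix, kinship_from_pedigree


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 22 families split evenly across two
    rearing groups and genotyped at 95 SNPs.  Logit-scale variance
    components default to 0.5 each; coverage is negative-binomial with mean
    30.
    """

    n_families: int = 22
    offspring_per_family: int = 4
    split: float = 0.5
    confounded_families: int = 0
    n_snps: int = 95
    snp_maf_range: tuple = (0.2, 0.5)
    n_sites: int = 2000
    frac_effect_sites: float = 0.1
    beta_effect: float = 1.0
    frac_age_effect_sites: float = 0.0
    beta_age: float = 1.0
    sigma_g2: float = 0.5
    sigma_e2: float = 0.5
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    dropout: float = 0.05
    tissue_profile: str = "liver"
    timepoints: tuple = ("age1",)
    frac_snp_sites: float = 0.02
    non_conversion: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("split", "frac_effect_sites", "frac_age_effect_sites",
                     "frac_snp_sites", "dropout", "non_conversion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be >= 0")
        if self.n_families < 1:
            raise ValueError("need at least one family")
        if not 0 <= self.confounded_families <= self.n_families:
            raise ValueError("confounded_families must be in [0, n_families]")
        lo, hi = self.snp_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("snp_maf_range must lie in (0, 0.5]")
        if self.tissue_profile not in ("liver", "sperm"):
            raise ValueError(f"unknown tissue profile {self.tissue_profile!r}")


@dataclass
class Pedigree:
    """Founder pairs, offspring, and their family/group/timepoint labels."""

    parents: dict                 # id -> (dam, sire); founders -> (None, None)
    dams: list
    sires: list
    offspring: list
    family_of: dict               # offspring id -> family id
    group_of: dict                # offspring id -> 'hatchery' | 'stream'
    timepoint_of: dict            # offspring id -> 'age1' | 'age2'
    sex_of: dict = field(default_factory=dict)  # parent id -> 'F' | 'M'

    @property
    def families(self) -> list:
        seen: dict = {}
        for o in self.offspring:
            seen.setdefault(self.family_of[o], None)
        return list(seen)

    def sample_meta(self, tissue: str) -> list:
        return [
            SampleMeta(
                sample_id=o,
                group=self.group_of[o],
                timepoint=self.timepoint_of[o],
                tissue=tissue,
                family_id=self.family_of[o],
            )
            for o in self.offspring
        ]


@dataclass
class TruthTable:
    """Ground truth of one simulated methylation dataset."""

    sites: pd.DataFrame           # site_index, chrom, pos, mu, beta_group,
                                  # beta_age, is_effect, is_snp_site
    true_kinship: KinshipMatrix

    @property
    def effect_sites(self) -> np.ndarray:
        return self.sites.index[self.sites["is_effect"]].to_numpy()

    @property
    def snp_sites(self) -> np.ndarray:
        return self.sites.index[self.sites["is_snp_site"]].to_numpy()


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Build the split-family pedigree.

    All but four families are single-pair matings; families 0/1 share a sire
    (paternal half sibs) and families 2/3 share a dam (maternal half sibs).
    Each family's offspring are divided between rearing groups so the
    overall hatchery fraction tracks ``split``, and assigned timepoints
    round-robin from ``config.timepoints``.

    ``confounded_families`` assigns that many leading families wholly to
    alternating rearing groups (family nested in group), which is the
    regime where ignoring kinship inflates false positives; the remaining
    families are split as usual.
    """
    if config.n_families < 4:
        raise ValueError("need >= 4 families to include both half-sib pairs")
    nf = config.n_families
    dams = [f"D{f:02d}" for f in range(nf)]
    sires = [f"S{f:02d}" for f in range(nf)]
    sires[1] = sires[0]       # paternal half-sib family pair
    dams[3] = dams[2]         # maternal half-sib family pair
    parents: dict = {}
    sex_of: dict = {}
    for d in dams:
        parents[d] = (None, None)
        sex_of[d] = "F"
    for s in sires:
        parents[s] = (None, None)
        sex_of[s] = "M"

    offspring, family_of, group_of, timepoint_of = [], {}, {}, {}
    off = config.offspring_per_family
    assigned_h = 0
    n_split_seen = 0
    for f in range(nf):
        fam = f"F{f:02d}"
        if f < config.confounded_families:
            n_h = off if f % 2 == 0 else 0
        else:
            n_split_seen += 1
            target_h = int(np.floor(config.split * off * n_split_seen + 0.5))
            n_h = min(off, max(0, target_h - assigned_h))
            assigned_h += n_h
        for k in range(off):
            oid = f"{fam}_o{k}"
            offspring.append(oid)
            parents[oid] = (dams[f], sires[f])
            family_of[oid] = fam
            group_of[oid] = "hatchery" if k < n_h else "stream"
        # timepoints cycle within each family x group so both levels are
        # represented in every group
        for grp in ("hatchery", "stream"):
            members = [o for o in offspring
                       if family_of[o] == fam and group_of[o] == grp]
            for j, o in enumerate(members):
                timepoint_of[o] = config.timepoints[j % len(config.timepoints)]
    return Pedigree(
        parents=parents,
        dams=sorted(set(dams)),
        sires=sorted(set(sires)),
        offspring=offspring,
        family_of=family_of,
        group_of=group_of,
        timepoint_of=timepoint_of,
        sex_of=sex_of,
    )


def simulate_genotypes(pedigree: Pedigree, config: SimulationConfig) -> pd.DataFrame:
    """Mendelian gene dropping over the pedigree.

    Per-SNP minor-allele frequencies are uniform on ``snp_maf_range``;
    founders are drawn from Hardy-Weinberg proportions and each offspring
    receives one allele per parent.  Returns a (parents + offspring) x SNP
    dosage table.
    """
    rng = _rng(config, 1)
    mafs = rng.uniform(*config.snp_maf_range, size=config.n_snps)
    founders = sorted(set(pedigree.dams) | set(pedigree.sires))
    geno = {f: rng.binomial(2, mafs) for f in founders}
    for o in pedigree.offspring:
        dam, sire = pedigree.parents[o]
        from_dam = rng.binomial(1, geno[dam] / 2.0)
        from_sire = rng.binomial(1, geno[sire] / 2.0)
        geno[o] = from_dam + from_sire
    cols = [f"snp{j:03d}" for j in range(config.n_snps)]
    ids = founders + pedigree.offspring
    return pd.DataFrame([geno[i] for i in ids], index=ids, columns=cols)


def _baseline_logits(rng, n: int, profile: str) -> np.ndarray:
    """Per-site baseline methylation on the logit scale.

    Liver: bimodal mixture concentrated near logit(0.05) and logit(0.95)
    with a minority of intermediate sites.  Sperm: constitutively
    hypermethylated, 95% of sites above logit(0.9).
    """
    if profile == "liver":
        comp = rng.choice(3, size=n, p=[0.4, 0.4, 0.2])
        mu = np.empty(n)
        lo = comp == 0
        hi = comp == 1
        mid = comp == 2
        mu[lo] = logit(rng.uniform(0.02, 0.10, lo.sum()))
        mu[hi] = logit(rng.uniform(0.90, 0.98, hi.sum()))
        mu[mid] = rng.normal(0.0, 1.0, mid.sum())
        return mu
    # sperm
    comp = rng.random(n) < 0.95
    mu = np.empty(n)
    mu[comp] = logit(rng.uniform(0.96, 0.998, comp.sum()))
    k = (~comp).sum()
    sub = np.random.default_rng(rng.integers(2**31))
    mu[~comp] = _baseline_logits(sub, k, "liver")
    return mu


def _site_positions(rng, n: int) -> tuple:
    """CpG positions with RRBS-like clustering: short within-cluster gaps
    and occasional long jumps, on a single scaffold."""
    gaps = np.where(
        rng.random(n) < 0.85,
        rng.integers(10, 200, size=n),
        rng.integers(3000, 30000, size=n),
    )
    pos = 1000 + np.cumsum(gaps)
    return np.array(["chr1"] * n), pos.astype(np.int64)


def simulate_methylation_counts(
    pedigree: Pedigree, config: SimulationConfig
) -> tuple:
    """Draw the methylation count matrix and its ground truth.

    For site s and individual i:
    ``logit(pi) = mu_s + x_i * beta_s + z_i * beta_age_s + g_si + e_si`` with
    ``g_s ~ MVN(0, sigma_g2 * K)`` over individuals (K the pedigree numerator
    matrix), ``e ~ N(0, sigma_e2)``; coverage is zero-truncated negative
    binomial with independent per-cell dropout; ``y ~ Binomial(r, pi)`` after
    adding a scalar bisulfite non-conversion rate.  SNP-contaminated sites
    override the model: apparent methylation tracks a segregating C/T
    genotype (approximately 1, 0.5, 0 for 0/1/2 copies of T).
    """
    rng = _rng(config, 2)
    n = len(pedigree.offspring)
    ns = config.n_sites

    K = kinship_from_pedigree(pedigree.parents, order=pedigree.offspring)
    L = np.linalg.cholesky(K.values + 1e-10 * np.eye(n))

    chroms, pos = _site_positions(rng, ns)
    mu = _baseline_logits(rng, ns, config.tissue_profile)

    # SNP-contaminated sites first, then treatment/age effects among the rest
    n_snp_sites = int(round(config.frac_snp_sites * ns))
    snp_sites = rng.choice(ns, size=n_snp_sites, replace=False)
    is_snp = np.zeros(ns, dtype=bool)
    is_snp[snp_sites] = True

    eligible = np.flatnonzero(~is_snp)
    n_eff = int(round(config.frac_effect_sites * ns))
    eff_sites = rng.choice(eligible, size=min(n_eff, len(eligible)), replace=False)
    beta = np.zeros(ns)
    beta[eff_sites] = config.beta_effect * rng.choice([-1.0, 1.0], size=len(eff_sites))

    beta_age = np.zeros(ns)
    if len(config.timepoints) > 1 and config.frac_age_effect_sites > 0:
        n_age = int(round(config.frac_age_effect_sites * ns))
        age_sites = rng.choice(eligible, size=min(n_age, len(eligible)), replace=False)
        beta_age[age_sites] = config.beta_age * rng.choice([-1.0, 1.0], size=len(age_sites))

    x = np.array([1.0 if pedigree.group_of[o] == "hatchery" else 0.0
                  for o in pedigree.offspring])
    z = np.array([1.0 if pedigree.timepoint_of[o] == "age2" else 0.0
                  for o in pedigree.offspring])

    g = np.sqrt(config.sigma_g2) * (L @ rng.standard_normal((n, ns))).T
    e = np.sqrt(config.sigma_e2) * rng.standard_normal((ns, n))
    eta = mu[:, None] + np.outer(beta, x) + np.outer(beta_age, z) + g + e
    pi = expit(eta)

    # C/T-SNP contamination: genotype-driven apparent methylation
    for s in snp_sites:
        maf = rng.uniform(0.1, 0.5)
        founders = {}
        for f in sorted(set(pedigree.dams) | set(pedigree.sires)):
            founders[f] = rng.binomial(2, maf)
        geno = np.empty(n, dtype=int)
        for i, o in enumerate(pedigree.offspring):
            dam, sire = pedigree.parents[o]
            geno[i] = rng.binomial(1, founders[dam] / 2.0) + rng.binomial(
                1, founders[sire] / 2.0
            )
        pi[s] = np.array([0.99, 0.5, 0.01])[geno]

    # non-conversion adds spurious methylation signal
    pi_obs = pi + (1.0 - pi) * config.non_conversion

    p_nb = config.coverage_dispersion / (config.coverage_dispersion + config.coverage_mean)
    r = rng.negative_binomial(config.coverage_dispersion, p_nb, size=(ns, n))
    r = np.maximum(r, 1)  # zero-truncation
    y = rng.binomial(r, pi_obs)

    drop = rng.random((ns, n)) < config.dropout
    meth = np.where(drop, MISSING, y).astype(np.int64)
    total = np.where(drop, MISSING, r).astype(np.int64)

    sites = pd.DataFrame({"chrom": chroms, "pos": pos, "strand": ["."] * ns})
    matrix = MethylationMatrix(sites, pedigree.sample_meta(config.tissue_profile),
                               meth, total)
    truth_sites = pd.DataFrame(
        {
            "site_index": np.arange(ns),
            "chrom": chroms,
            "pos": pos,
            "mu": mu,
            "beta_group": beta,
            "beta_age": beta_age,
            "is_effect": beta != 0.0,
            "is_snp_site": is_snp,
        }
    )
    return matrix, TruthTable(sites=truth_sites, true_kinship=K)


def simulate_dataset(config: SimulationConfig) -> dict:
    """Convenience wrapper: pedigree + genotypes + counts + truth."""
    ped = simulate_pedigree(config)
    geno = simulate_genotypes(ped, config)
    matrix, truth = simulate_methylation_counts(ped, config)
    return {"pedigree": ped, "genotypes": geno, "matrix": matrix, "truth": truth}


def write_dataset(matrix: MethylationMatrix, pedigree: Pedigree,
                  genotypes: pd.DataFrame, truth: TruthTable,
                  out_dir, overwrite: bool = False) -> None:
    """Write a dataset as per-sample coverage files, a sample sheet, the
    genotype table, the pedigree and the truth tables.  All files round-trip
    through the package's readers losslessly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty (pass overwrite=True)")
    from .io import matrix_to_records

    paths = []
    for j, meta in enumerate(matrix.samples):
        fname = f"{meta.sample_id}.cov"
        write_bismark_coverage(out / fname, matrix_to_records(matrix, j))
        paths.append(fname)
    write_sample_sheet(out / "samples.csv", matrix.samples, paths)
    genotypes.to_csv(out / "genotypes.csv", index_label="id")
    truth.sites.to_csv(out / "truth_sites.csv", index=False)
    pd.DataFrame(
        truth.true_kinship.values,
        index=truth.true_kinship.sample_ids,
        columns=truth.true_kinship.sample_ids,
    ).to_csv(out / "truth_kinship.csv", index_label="id")
    with open(out / "pedigree.csv", "w") as fh:
        fh.write("id,dam,sire,family,group,timepoint\n")
        for o in pedigree.offspring:
            dam, sire = pedigree.parents[o]
            fh.write(
                f"{o},{dam},{sire},{pedigree.family_of[o]},"
                f"{pedigree.group_of[o]},{pedigree.timepoint_of[o]}\n"
            )
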