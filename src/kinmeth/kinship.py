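"""Pedigree- and genotype-based relatedness, and SNP parentage assignment.

The relatedness matrix produced here is used downstream as the covariance of
the genetic random effect in the differential-methylation mixed model.  Two
estimators are provided: the pedigree numerator relationship matrix (tabular
method) and the allele-frequency-centered genomic relationship matrix (GRM)
computed from a SNP panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class KinshipMatrix:
    """Symmetric relatedness matrix over a fixed sample order."""

    sample_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match sample list")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    def subset(self, ids) -> "KinshipMatrix":
        lut = {sid: i for i, sid in enumerate(self.sample_ids)}
        idx = np.array([lut[s] for s in ids], dtype=int)
        return KinshipMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def is_psd(self, tol: float = 1e-8) -> bool:
        w = np.linalg.eigvalsh(self.values)
        return bool(w.min() >= -tol * max(1.0, w.max()))


def kinship_from_pedigree(parents: dict, order=None) -> KinshipMatrix:
    """Numerator relationship matrix by the recursive tabular method.

    Parameters
    ----------
    parents : dict
        Maps individual id -> (dam id or None, sire id or None).  Founders
        have (None, None).  Parents referenced but absent from the dict are
        treated as founders.
    order : list, optional
        Restrict/reorder the output to these ids (ancestors are still used
        in the recursion).

    Founders get diagonal 1 and off-diagonal 0; full sibs 0.5, half sibs
    0.25, parent-offspring 0.5 (numerator convention).
    """
    # topological order: parents before offspring
    all_ids: dict = {}

    def visit(i, stack):
        if i in all_ids or i is None:
            return
        if i in stack:
            raise ValueError(f"pedigree cycle involving {i!r}")
        stack = stack | {i}
        dam, sire = parents.get(i, (None, None))
        visit(dam, stack)
        visit(sire, stack)
        all_ids[i] = len(all_ids)

    for i in list(parents):
        visit(i, frozenset())
    if order is not None:
        for i in order:
            visit(i, frozenset())

    ids = list(all_ids)
    n = len(ids)
    A = np.zeros((n, n))
    idx = {i: k for k, i in enumerate(ids)}
    for k, i in enumerate(ids):
        dam, sire = parents.get(i, (None, None))
        d = idx.get(dam)
        s = idx.get(sire)
        a_ds = A[d, s] if (d is not None and s is not None) else 0.0
        A[k, k] = 1.0 + 0.5 * a_ds
        for j in range(k):
            a = 0.0
            if d is not None:
                a += 0.5 * A[j, d]
            if s is not None:
                a += 0.5 * A[j, s]
            A[k, j] = A[j, k] = a
    if order is None:
        order = ids
    sel = np.array([idx[i] for i in order], dtype=int)
    return KinshipMatrix(list(order), A[np.ix_(sel, sel)])


def stabilize_psd(values: np.ndarray, deltas=(0.0, 1e-6, 1e-4, 1e-2, 1.0)) -> np.ndarray:
    """Add the smallest diagonal inflation from `deltas` that makes the
    matrix positive semidefinite (needed for use as a mixed-model
    covariance)."""
    scale = max(1.0, float(np.abs(values).max()))
    for d in deltas:
        cand = values + d * np.eye(len(values))
        if np.linalg.eigvalsh(cand).min() >= -1e-10 * scale:
            return cand
    raise ValueError("matrix could not be stabilized to PSD")


def kinship_from_genotypes(genotypes: pd.DataFrame) -> KinshipMatrix:
    """Genomic relationship matrix from a 0/1/2 dosage table.

    Rows are individuals, columns SNPs, entries in {0, 1, 2, NaN}.  Genotypes
    are centered by twice the sample allele frequency per SNP and the matrix
    is normalized by 2*sum(p(1-p)) over retained SNPs (VanRaden's first
    method).  Monomorphic SNPs are dropped; missing genotypes contribute
    zero after centering.  The result is PSD-stabilized by minimal diagonal
    inflation.
    """
    if genotypes.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    G = genotypes.to_numpy(dtype=float)
    p_hat = np.nanmean(G, axis=0) / 2.0
    poly = (p_hat > 0.0) & (p_hat < 1.0)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic")
    G = G[:, poly]
    p_hat = p_hat[poly]
    Z = G - 2.0 * p_hat
    Z[np.isnan(Z)] = 0.0
    denom = 2.0 * np.sum(p_hat * (1.0 - p_hat))
    values = Z @ Z.T / denom
    return KinshipMatrix(list(genotypes.index), stabilize_psd(values))


# ---------------------------------------------------------------------------
# Parentage assignment
# ---------------------------------------------------------------------------


@dataclass
class ParentageAssignment:
    offspring_id: str
    assigned_dam: str
    assigned_sire: str
    n_mendelian_mismatches: int
    log_likelihood: float
    tied: bool = False
    tied_pairs: list = field(default_factory=list)


def _transmission_probs(g_dam: int, g_sire: int) -> np.ndarray:
    """P(offspring dosage = 0,1,2 | parental dosages), error-free."""
    pd_ = g_dam / 2.0  # P(dam transmits alt allele)
    ps = g_sire / 2.0
    return np.array(
        [
            (1 - pd_) * (1 - ps),
            pd_ * (1 - ps) + (1 - pd_) * ps,
            pd_ * ps,
        ]
    )


def assign_parentage(
    offspring_genotypes: pd.DataFrame,
    dam_genotypes: pd.DataFrame,
    sire_genotypes: pd.DataFrame,
    genotyping_error_rate: float = 0.01,
) -> list:
    """Maximum-likelihood parent-pair assignment over all dam x sire pairs.

    For each offspring and each candidate pair the likelihood is the product
    over SNPs of Mendelian transmission probabilities under a per-genotype
    error model: the observed offspring genotype equals the true one with
    probability 1-eps, otherwise it is uniform over the other two states.
    The Mendelian exclusion count (SNPs impossible under the error-free
    model) is reported alongside.  Exact likelihood ties are broken by
    exclusion count, then lexicographic parent ids, and flagged.
    """
    if dam_genotypes.shape[0] == 0 or sire_genotypes.shape[0] == 0:
        raise ValueError("no candidate parent pairs")
    eps = genotyping_error_rate
    snps = [c for c in offspring_genotypes.columns
            if c in dam_genotypes.columns and c in sire_genotypes.columns]
    if not snps:
        raise ValueError("no shared SNP panel between offspring and candidates")

    # error kernel: rows true genotype, cols observed
    E = np.full((3, 3), eps / 2.0)
    np.fill_diagonal(E, 1.0 - eps)

    # precompute, per (dam, sire, snp): the 3-vector of P(obs | pair)
    dams = list(dam_genotypes.index)
    sires = list(sire_genotypes.index)
    results = []
    n_snps = len(snps)

    Gd = dam_genotypes[snps].to_numpy(dtype=float)
    Gs = sire_genotypes[snps].to_numpy(dtype=float)
    Go = offspring_genotypes[snps].to_numpy(dtype=float)

    # transmission cube T[di, si, snp, obs]
    pd_ = Gd / 2.0  # (n_dams, n_snps)
    ps = Gs / 2.0
    pdx = pd_[:, None, :]
    psx = ps[None, :, :]
    true_probs = np.stack(
        [
            (1 - pdx) * (1 - psx),
            pdx * (1 - psx) + (1 - pdx) * psx,
            pdx * psx,
        ],
        axis=-1,
    )  # (n_dams, n_sires, n_snps, 3)
    obs_probs = true_probs @ E  # P(obs | pair, snp)
    valid_pair_snp = ~(np.isnan(pd_[:, None, :]) | np.isnan(ps[None, :, :]))

    for o_i, oid in enumerate(offspring_genotypes.index):
        go = Go[o_i]
        obs_ok = ~np.isnan(go)
        go_int = np.where(obs_ok, go, 0).astype(int)
        # gather per-pair log-likelihood and exclusion counts
        sel = np.arange(n_snps)
        lik = obs_probs[:, :, sel, go_int]          # (nd, ns, n_snps)
        tru = true_probs[:, :, sel, go_int]
        use = valid_pair_snp & obs_ok[None, None, :]
        with np.errstate(divide="ignore"):
            loglik = np.where(use, np.log(np.maximum(lik, 1e-300)), 0.0).sum(axis=2)
        excl = (use & (tru == 0.0)).sum(axis=2)

        best = loglik.max()
        cand = np.argwhere(np.isclose(loglik, best, rtol=0, atol=1e-9))
        tied = len(cand) > 1
        # tie-break: exclusion count, then lexicographic ids
        cand_list = sorted(
            [(excl[d, s], dams[d], sires[s]) for d, s in cand]
        )
        n_ex, dam_id, sire_id = cand_list[0]
        results.append(
            ParentageAssignment(
                offspring_id=str(oid),
                assigned_dam=dam_id,
                assigned_sire=sire_id,
                n_mendelian_mismatches=int(n_ex),
                log_likelihood=float(best),
                tied=tied,
                tied_pairs=[(d, s) for _, d, s in cand_list] if tied else [],
            )
        )
    return results
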