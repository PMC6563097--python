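"""Independent reference implementations used only to check the package.

Everything here is deliberately written by a different route than the
library code: brute-force enumeration, exact quadrature, or naive loops.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize
from scipy.special import betaln, expit, gammaln


# ---------------------------------------------------------------------------
# Exact marginal likelihood for the binomial mixed model (Gauss-Hermite)
# ---------------------------------------------------------------------------


def exact_marginal_beta(y, r, X, Sigma, n_nodes=7):
    """ML fixed effects by maximizing the marginal likelihood with the
    n-dimensional random effect integrated out by adaptive Gauss-Hermite
    quadrature (tensor-product rule recentered at the integrand mode and
    rescaled by its curvature).  Returns the estimated coefficient vector."""
    y = np.asarray(y, float)
    r = np.asarray(r, float)
    X = np.asarray(X, float)
    n = len(y)
    Sigma_inv = np.linalg.inv(Sigma + 1e-12 * np.eye(n))
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    grids = np.array(list(itertools.product(range(n_nodes), repeat=n)))
    Z = nodes[grids]                               # (n_points, n)
    logw = np.log(weights)[grids].sum(axis=1)
    # the e^{z'z/2} substitution factor folded into the log-weights
    logw = logw + 0.5 * np.sum(Z**2, axis=1)

    def logh(u, b):
        eta = X @ b + u
        return np.sum(y * eta - r * np.logaddexp(0.0, eta)) - 0.5 * u @ Sigma_inv @ u

    u_start = {"u": np.zeros(n)}

    def negll(b):
        # integrand mode and curvature for this b (BFGS with analytic grad)
        def f(u):
            return -logh(u, b)

        def grad(u):
            eta = X @ b + u
            return -(y - r * expit(eta)) + Sigma_inv @ u

        sol = optimize.minimize(f, u_start["u"], jac=grad, method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 500})
        m = sol.x
        u_start["u"] = m
        eta_m = X @ b + m
        w_m = r * expit(eta_m) * expit(-eta_m)
        H = np.diag(w_m) + Sigma_inv
        C = np.linalg.cholesky(np.linalg.inv(H))
        U = m[None, :] + Z @ C.T
        eta = U + (X @ b)[None, :]
        ll_pts = (
            np.sum(y * eta - r * np.logaddexp(0.0, eta), axis=1)
            - 0.5 * np.einsum("ij,jk,ik->i", U, Sigma_inv, U)
        )
        s = ll_pts + logw
        mx = s.max()
        logdet_c = float(np.sum(np.log(np.diag(C))))
        return -(mx + np.log(np.sum(np.exp(s - mx))) + logdet_c)

    res = optimize.minimize(negll, np.zeros(X.shape[1]), method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 200,
                                     "maxfev": 200})
    return res.x


# ---------------------------------------------------------------------------
# Beta-binomial regression (logit mean link, common dispersion)
# ---------------------------------------------------------------------------


def betabinom_regression_beta(y, r, X):
    """ML fit of a beta-binomial regression: mean pi = expit(X b), scalar
    intra-class correlation rho.  Returns the coefficient vector."""
    y = np.asarray(y, float)
    r = np.asarray(r, float)
    X = np.asarray(X, float)

    def negll(params):
        b = params[:-1]
        rho = expit(params[-1]) * 0.999 + 5e-4
        pi = expit(X @ b)
        s = (1.0 - rho) / rho
        a = np.maximum(pi * s, 1e-10)
        bb = np.maximum((1.0 - pi) * s, 1e-10)
        ll = (
            gammaln(r + 1) - gammaln(y + 1) - gammaln(r - y + 1)
            + betaln(y + a, r - y + bb) - betaln(a, bb)
        )
        return -np.sum(ll)

    p = X.shape[1]
    res = optimize.minimize(negll, np.zeros(p + 1), method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-10,
                                     "maxiter": 8000, "maxfev": 8000})
    return res.x[:p]


# ---------------------------------------------------------------------------
# Brute-force DMR enumeration
# ---------------------------------------------------------------------------


def brute_force_dmrs(chrom, pos, pval, is_dmc, window_bp=2000, p_thresh=0.001):
    """O(n^2) enumeration of the two-criterion DMR rule.

    Returns a sorted list of (chrom, start, stop, n_cg, frozenset of
    positions, criteria frozenset).
    """
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    pval = np.asarray(pval, float)
    is_dmc = np.asarray(is_dmc, bool)
    out = []
    for c in sorted(set(chrom.tolist())):
        sel = chrom == c
        p_ = pos[sel]
        pv = pval[sel]
        dm = is_dmc[sel]
        ok = ~np.isnan(pv)
        candidates = []
        # criterion 1: window centered on each DMC, >=2 CGs at p <= thresh
        half = window_bp // 2
        for i in range(len(p_)):
            if not (dm[i] and ok[i] and pv[i] <= p_thresh):
                continue
            members = {
                int(p_[j])
                for j in range(len(p_))
                if ok[j] and pv[j] <= p_thresh and abs(p_[j] - p_[i]) <= half
            }
            if len(members) >= 2:
                candidates.append((frozenset(members), "1"))
        # criterion 2: every >=3-element set of sub-threshold CGs spanning
        # <= window_bp, reduced to maximal sets
        strict = [int(p_[j]) for j in range(len(p_)) if ok[j] and pv[j] < p_thresh]
        strict.sort()
        sets = []
        for i in range(len(strict)):
            for j in range(i + 2, len(strict)):
                if strict[j] - strict[i] <= window_bp:
                    sets.append(frozenset(strict[i : j + 1]))
        maximal = [s for s in sets if not any(s < t for t in sets)]
        for s in set(maximal):
            candidates.append((s, "2"))
        # merge candidates sharing any CG (repeated pairwise union)
        merged = [(set(s), {cr}) for s, cr in candidates]
        changed = True
        while changed:
            changed = False
            for a in range(len(merged)):
                for b in range(a + 1, len(merged)):
                    if merged[a][0] & merged[b][0]:
                        merged[a] = (
                            merged[a][0] | merged[b][0],
                            merged[a][1] | merged[b][1],
                        )
                        del merged[b]
                        changed = True
                        break
                if changed:
                    break
        for s, crs in merged:
            ss = sorted(s)
            out.append((c, ss[0], ss[-1], len(ss), frozenset(s), frozenset(crs)))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


# ---------------------------------------------------------------------------
# Naive filter-cascade counts
# ---------------------------------------------------------------------------


def naive_cascade_counts(meth, total, groups, snp_keys, site_keys,
                         min_frac=0.5, min_depth=11, var_q=0.05,
                         low=0.10, high=0.90):
    """Per-step remaining counts of the filter cascade, computed with plain
    loops.  ``groups`` is a list of group labels per sample; ``site_keys``
    a list of (chrom, pos) per site; missing cells have total == -1."""
    n_sites, n_samples = np.shape(total)
    levels = sorted(set(groups))
    sites = list(range(n_sites))

    # coverage
    keep = []
    for i in sites:
        ok = True
        for lev in levels:
            idx = [j for j in range(n_samples) if groups[j] == lev]
            n_cov = sum(1 for j in idx if total[i][j] >= min_depth)
            if n_cov / len(idx) < min_frac:
                ok = False
        if ok:
            keep.append(i)
    counts = [len(keep)]

    def props(i):
        return [
            meth[i][j] / total[i][j]
            for j in range(n_samples)
            if total[i][j] != -1
        ]

    # low variance: drop sites at or below the var_q quantile ('lower'
    # interpolation), ties dropped together
    variances = {}
    for i in keep:
        pr = props(i)
        mean = sum(pr) / len(pr)
        variances[i] = sum((x - mean) ** 2 for x in pr) / (len(pr) - 1)
    svals = sorted(variances.values())
    cut_idx = int(np.floor(var_q * (len(svals) - 1)))
    cutoff = svals[cut_idx]
    keep = [i for i in keep if variances[i] > cutoff]
    counts.append(len(keep))

    # hypo then hyper
    means = {i: sum(props(i)) / len(props(i)) for i in keep}
    keep = [i for i in keep if means[i] > low]
    counts.append(len(keep))
    keep = [i for i in keep if means[i] < high]
    counts.append(len(keep))

    # CG SNPs (dinucleotide rule)
    keep = [
        i
        for i in keep
        if (site_keys[i][0], site_keys[i][1]) not in snp_keys
        and (site_keys[i][0], site_keys[i][1] + 1) not in snp_keys
    ]
    counts.append(len(keep))
    return counts


# ---------------------------------------------------------------------------
# Nested-loop gene association
# ---------------------------------------------------------------------------


def naive_annotate(features, genes, window_bp=10000):
    """features: list of (feature_id, chrom, start, stop).  Returns a set of
    (feature_id, gene_id, signed_distance)."""
    out = set()
    for fid, fc, fs, fe in features:
        for g in genes:
            if g.chrom != fc:
                continue
            if fe < g.start - window_bp or fs > g.end + window_bp:
                continue
            if fe >= g.start and fs <= g.end:
                d = 0
            elif fe < g.start:
                gap = g.start - fe
                d = -gap if g.strand == "+" else gap
            else:
                gap = fs - g.end
                d = gap if g.strand == "+" else -gap
            out.add((fid, g.gene_id, d))
    return out
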