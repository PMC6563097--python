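"""Per-site differential methylation testing with a kinship random effect.

Each CG site is modelled as binomial counts with a logit link and two
Gaussian random components:

    y_i ~ Binomial(r_i, pi_i),  logit(pi_i) = W_i a + x_i b + g_i + e_i
    g ~ MVN(0, sigma_g2 * K),   e ~ N(0, sigma_e2 * I)

where K is the genetic relatedness matrix.  The independent component e
absorbs extra-binomial dispersion, so the marginal count model is
beta-binomial-like; the correlated component g accounts for resemblance
among relatives, which otherwise inflates false positives when rearing
groups are unevenly composed of families.

Estimation maximizes the Laplace-approximated marginal likelihood: an inner
damped-Newton solve for the joint mode of the fixed effects and the random
effect vector, and an outer Nelder-Mead search over the two log variance
components.  Inference on the predictor effect b is a Wald test with a
t(n - p) reference distribution.

Multiple testing uses Storey's q-value with pi0 estimated on a lambda grid
and cubic-smoother extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .matrix import MethylationMatrix
from .kinship import KinshipMatrix

logger = logging.getLogger(__name__)

_INNER_GTOL = 1e-8
_OUTER_FTOL = 1e-6
_MAX_OUTER = 100


@dataclass
class SiteModelSpec:
    """Inputs for one site's fit.

    y, r : arrays of methylated/total counts (complete cases only)
    x : 0/1 predictor indicator
    W : covariate design incl. intercept, shape (n, p_w)
    K : relatedness matrix over the same samples (ndarray or KinshipMatrix)
    """

    y: np.ndarray
    r: np.ndarray
    x: np.ndarray
    W: np.ndarray
    K: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        if isinstance(self.K, KinshipMatrix):
            self.K = self.K.values
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.y)
        if self.W.shape[0] != n:
            self.W = self.W.T
        if not (len(self.r) == len(self.x) == self.W.shape[0] == n):
            raise ValueError("inconsistent dimensions")
        if np.any(self.y < 0) or np.any(self.y > self.r):
            raise ValueError("need 0 <= y <= r")
        if self.K.shape != (n, n):
            raise ValueError("K shape does not match sample count")
        w = np.linalg.eigvalsh(self.K)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError("K is not positive semidefinite")


@dataclass
class SiteFit:
    beta_hat: float
    se_beta: float
    alpha_hat: np.ndarray
    sigma_g2_hat: float
    sigma_e2_hat: float
    p_value: float
    converged: bool
    n_used: int
    loglik: float = np.nan
    message: str = ""


def _binom_loglik(y, r, eta):
    # log C(r, y) omitted: constant in parameters
    return float(np.sum(y * eta - r * np.logaddexp(0.0, eta)))


def _newton_mode(y, r, X, Sigma_inv, b0, u0):
    """Joint penalized-likelihood mode over (fixed effects b, random u).

    Returns (b, u, converged, H) with H the Hessian of the negative
    penalized log-likelihood at the mode.
    """
    n, p = X.shape
    b, u = b0.copy(), u0.copy()

    def fval(b, u):
        eta = X @ b + u
        return -_binom_loglik(y, r, eta) + 0.5 * u @ Sigma_inv @ u

    f = fval(b, u)
    converged = False
    H = None
    for _ in range(100):
        eta = X @ b + u
        mu = r * expit(eta)
        s = y - mu
        grad_b = -X.T @ s
        grad_u = -s + Sigma_inv @ u
        gnorm = np.sqrt(np.sum(grad_b**2) + np.sum(grad_u**2))
        w = np.maximum(r * expit(eta) * expit(-eta), 1e-12)
        H = np.zeros((p + n, p + n))
        H[:p, :p] = (X.T * w) @ X + 1e-10 * np.eye(p)
        H[:p, p:] = X.T * w
        H[p:, :p] = H[:p, p:].T
        H[p:, p:] = np.diag(w) + Sigma_inv
        if gnorm < _INNER_GTOL * (1.0 + abs(f)):
            converged = True
            break
        try:
            step = np.linalg.solve(H, np.concatenate([grad_b, grad_u]))
        except np.linalg.LinAlgError:
            break
        t = 1.0
        for _ls in range(30):
            b_new = b - t * step[:p]
            u_new = u - t * step[p:]
            f_new = fval(b_new, u_new)
            if f_new <= f + 1e-12:
                break
            t *= 0.5
        else:
            converged = True  # no further improvement possible
            break
        b, u, f = b_new, u_new, f_new
    return b, u, converged, H


def _newton_u(y, r, offset, Sigma_inv, u0):
    """Mode of the random-effect vector for a fixed linear predictor offset."""
    u = u0.copy()
    for _ in range(100):
        eta = offset + u
        s = y - r * expit(eta)
        g = -s + Sigma_inv @ u
        w = np.maximum(r * expit(eta) * expit(-eta), 1e-12)
        H = np.diag(w) + Sigma_inv
        if np.linalg.norm(g) < _INNER_GTOL:
            break
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        u = u - step
        if np.linalg.norm(step) < 1e-13:
            break
    return u


def _profile_fixed_effects(y, r, X, Sigma_inv, logdet_S, b0, u0):
    """Maximize the Laplace marginal log-likelihood over the fixed effects,
    with the random-effect mode profiled out.

    Unlike the joint penalized mode, this keeps the b-dependence of the
    0.5*logdet(W + Sigma^-1) curvature term, which removes most of the
    small-sample bias of mode-based estimation.
    """
    state = {"u": u0.copy()}

    def negll(b):
        u = _newton_u(y, r, X @ b, Sigma_inv, state["u"])
        state["u"] = u
        eta = X @ b + u
        w = np.maximum(r * expit(eta) * expit(-eta), 1e-12)
        _sign, ld = np.linalg.slogdet(np.diag(w) + Sigma_inv)
        ll = (
            _binom_loglik(y, r, eta)
            - 0.5 * u @ Sigma_inv @ u
            - 0.5 * (ld + logdet_S)
        )
        return -ll

    res = optimize.minimize(
        negll, b0, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 800, "maxfev": 800},
    )
    b = res.x
    u = _newton_u(y, r, X @ b, Sigma_inv, state["u"])
    return b, u, -res.fun, bool(res.success)


def _glm_mode(y, r, X, b0):
    """Plain binomial GLM Newton fit (no random effects)."""
    n, p = X.shape
    b = b0.copy()

    def fv(b):
        return -_binom_loglik(y, r, X @ b)

    f = fv(b)
    H = np.eye(p)
    converged = False
    for _ in range(100):
        eta = X @ b
        mu = r * expit(eta)
        grad = -X.T @ (y - mu)
        w = np.maximum(r * expit(eta) * expit(-eta), 1e-12)
        H = (X.T * w) @ X + 1e-10 * np.eye(p)
        if np.linalg.norm(grad) < _INNER_GTOL * (1.0 + abs(f)):
            converged = True
            break
        step = np.linalg.solve(H, grad)
        t = 1.0
        for _ls in range(30):
            b_new = b - t * step
            f_new = fv(b_new)
            if f_new <= f + 1e-12:
                break
            t *= 0.5
        else:
            converged = True
            break
        # guard against divergence under separation
        if np.max(np.abs(b_new)) > 30:
            b = np.clip(b_new, -30, 30)
            converged = True
            break
        b, f = b_new, f_new
    return b, converged, H


def _satterthwaite_df(phi_hat, negll_fn, d, Q, y, r, X, state, beta_idx, n, p):
    """Satterthwaite degrees of freedom for the predictor-effect Wald test.

    df = 2 v^2 / (g' A g) with v = Var(beta_hat) as a function of the log
    variance components, g its finite-difference gradient at the optimum,
    and A the inverse finite-difference Hessian of the REML criterion.
    Falls back to n - p when the curvature is not usable (e.g. variance
    components at the boundary).
    """
    fallback = max(n - p, 1)

    def var_beta(phi):
        sg2 = float(np.clip(np.exp(phi[0]), 0.0, 1e3))
        se2 = float(np.clip(np.exp(phi[1]), 0.0, 1e3))
        svals = np.maximum(sg2 * d + se2, 1e-10)
        Sigma_inv = (Q / svals) @ Q.T
        b, u, _ok, H = _newton_mode(y, r, X, Sigma_inv, state["b"], state["u"])
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.nan
        return cov[beta_idx, beta_idx]

    # variance components driven to the boundary contribute no usable
    # curvature; restrict to the active (interior) log-variance directions
    active = np.flatnonzero(phi_hat > np.log(1e-6))
    if len(active) == 0:
        return fallback

    h = 0.05
    try:
        v0 = var_beta(phi_hat)
        grad = np.empty(len(active))
        for gi, k in enumerate(active):
            e = np.zeros(2)
            e[k] = h
            grad[gi] = (var_beta(phi_hat + e) - var_beta(phi_hat - e)) / (2 * h)
        # finite-difference Hessian of the REML criterion (active block)
        Hm = np.empty((len(active), len(active)))
        f0 = negll_fn(phi_hat)
        for gi, k in enumerate(active):
            e = np.zeros(2)
            e[k] = h
            Hm[gi, gi] = (negll_fn(phi_hat + e) - 2 * f0 + negll_fn(phi_hat - e)) / h**2
        if len(active) == 2:
            e01 = np.array([h, h])
            e10 = np.array([h, -h])
            Hm[0, 1] = Hm[1, 0] = (
                negll_fn(phi_hat + e01) - negll_fn(phi_hat + e10)
                - negll_fn(phi_hat - e10) + negll_fn(phi_hat - e01)
            ) / (4 * h**2)
        w = np.linalg.eigvalsh(Hm)
        if not np.isfinite(v0) or v0 <= 0 or w.min() <= 1e-10:
            return fallback
        A = np.linalg.inv(Hm)
        denom = float(grad @ A @ grad)
        if denom <= 0 or not np.isfinite(denom):
            return fallback
        df = 2.0 * v0**2 / denom
    except (np.linalg.LinAlgError, FloatingPointError):
        return fallback
    if not np.isfinite(df):
        return fallback
    return float(np.clip(df, 1.0, fallback))


def fit_site(
    spec: SiteModelSpec,
    fix_sigma_g2: float = None,
    fix_sigma_e2: float = None,
) -> SiteFit:
    """Fit the mixed model at one site.

    The predictor coefficient is the last column of the design
    [W | x]; its Wald p-value uses a t(n - p) reference.  Pass
    ``fix_sigma_g2``/``fix_sigma_e2`` to skip the outer variance-component
    search (both must be given together).
    """
    y, r, x, W, K = spec.y, spec.r, spec.x, spec.W, spec.K
    n = len(y)
    if n < 4:
        raise ValueError("need >= 4 samples with data")
    if np.ptp(x) == 0:
        raise ValueError("inestimable effect: predictor constant among samples")
    X = np.column_stack([W, x])
    p = X.shape[1]
    beta_idx = p - 1

    d, Q = np.linalg.eigh(K)
    d = np.maximum(d, 0.0)

    fixed = fix_sigma_g2 is not None and fix_sigma_e2 is not None
    if (fix_sigma_g2 is None) != (fix_sigma_e2 is None):
        raise ValueError("fix both variance components or neither")

    state = {"b": np.zeros(p), "u": np.zeros(n)}

    def laplace_negll(phi, reml=True):
        sg2 = float(np.clip(np.exp(phi[0]), 0.0, 1e3))
        se2 = float(np.clip(np.exp(phi[1]), 0.0, 1e3))
        svals = np.maximum(sg2 * d + se2, 1e-10)
        Sigma = (Q * svals) @ Q.T
        Sigma_inv = (Q / svals) @ Q.T
        b, u, ok, H = _newton_mode(y, r, X, Sigma_inv, state["b"], state["u"])
        if ok:
            state["b"], state["u"] = b, u
        eta = X @ b + u
        w = np.maximum(r * expit(eta) * expit(-eta), 1e-12)
        _sign, logdet_inner = np.linalg.slogdet(np.diag(w) + Sigma_inv)
        ll = (
            _binom_loglik(y, r, eta)
            - 0.5 * u @ Sigma_inv @ u
            - 0.5 * (logdet_inner + np.sum(np.log(svals)))
        )
        if reml:
            # integrate out the fixed effects as well (REML-style Laplace):
            # penalizes variance components collapsing toward zero when the
            # predictor is collinear with the random-effect space
            V = Sigma + np.diag(1.0 / w)
            M = X.T @ np.linalg.solve(V, X)
            _sign, logdet_m = np.linalg.slogdet(M)
            ll -= 0.5 * logdet_m
        return -ll

    if fixed and fix_sigma_g2 <= 1e-12 and fix_sigma_e2 <= 1e-12:
        # degenerate: no random effects -> plain binomial GLM
        b, ok, H = _glm_mode(y, r, X, np.zeros(p))
        cov = np.linalg.inv(H)
        se = float(np.sqrt(max(cov[beta_idx, beta_idx], 0.0)))
        beta = float(b[beta_idx])
        tstat = beta / se if se > 0 else 0.0
        pv = float(2.0 * stats.t.sf(abs(tstat), df=max(n - p, 1))) if se > 0 else 1.0
        return SiteFit(beta, se, b[:beta_idx].copy(), 0.0, 0.0,
                       min(max(pv, np.finfo(float).tiny), 1.0), ok, n,
                       _binom_loglik(y, r, X @ b))

    if fixed:
        phi_hat = np.log(np.maximum([fix_sigma_g2, fix_sigma_e2], 1e-10))
        negll = laplace_negll(phi_hat, reml=False)
        outer_ok = True
    else:
        phi0 = np.log([0.2, 0.2])
        res = optimize.minimize(
            laplace_negll,
            phi0,
            method="Nelder-Mead",
            options={"fatol": _OUTER_FTOL, "xatol": 1e-3, "maxiter": 2 * _MAX_OUTER,
                     "maxfev": 2 * _MAX_OUTER},
        )
        phi_hat = res.x
        negll = res.fun
        outer_ok = bool(res.success) or res.fun < laplace_negll(phi0)

    sg2 = float(np.clip(np.exp(phi_hat[0]), 0.0, 1e3))
    se2 = float(np.clip(np.exp(phi_hat[1]), 0.0, 1e3))
    svals = np.maximum(sg2 * d + se2, 1e-10)
    Sigma_inv = (Q / svals) @ Q.T
    b, u, inner_ok, H = _newton_mode(y, r, X, Sigma_inv, state["b"], state["u"])
    # refine the fixed effects on the Laplace profile (bias correction
    # relative to the joint penalized mode)
    b, u, _ll_prof, _prof_ok = _profile_fixed_effects(
        y, r, X, Sigma_inv, float(np.sum(np.log(svals))), b, u
    )
    eta = X @ b + u
    w = np.maximum(r * expit(eta) * expit(-eta), 1e-12)
    H = np.zeros((p + n, p + n))
    H[:p, :p] = (X.T * w) @ X + 1e-10 * np.eye(p)
    H[:p, p:] = X.T * w
    H[p:, :p] = H[:p, p:].T
    H[p:, p:] = np.diag(w) + Sigma_inv
    converged = bool(outer_ok and inner_ok)

    try:
        cov = np.linalg.inv(H)
        se = float(np.sqrt(max(cov[beta_idx, beta_idx], 0.0)))
    except np.linalg.LinAlgError:
        se = np.nan
        converged = False
    beta = float(b[beta_idx])
    if converged and np.isfinite(se) and se > 0:
        if fixed:
            df = max(n - p, 1)
        else:
            df = _satterthwaite_df(
                phi_hat, laplace_negll, d, Q, y, r, X, state, beta_idx, n, p
            )
        tstat = beta / se
        pv = float(2.0 * stats.t.sf(abs(tstat), df=df))
        pv = min(max(pv, np.finfo(float).tiny), 1.0)
    else:
        pv = np.nan
        converged = False
    return SiteFit(
        beta_hat=beta,
        se_beta=se,
        alpha_hat=b[:beta_idx].copy(),
        sigma_g2_hat=sg2,
        sigma_e2_hat=se2,
        p_value=pv,
        converged=converged,
        n_used=n,
        loglik=-negll,
        message="" if converged else "non-convergence",
    )


def fit_all(
    matrix: MethylationMatrix,
    K: KinshipMatrix,
    predictor_field: str = "group",
    predictor_level: str = "hatchery",
    covariate_fields=(),
    covariate_levels=None,
    min_samples: int = 4,
    progress_every: int = 500,
) -> pd.DataFrame:
    """Fit every site in the matrix; complete-case per site with the K
    sub-matrix re-extracted for the samples observed at that site.

    Returns a DataFrame with one row per site: chrom, pos, beta_hat, se,
    sigma_g2, sigma_e2, p_value, n_used, converged.  Sites that cannot be
    fit (too few samples, constant predictor, non-convergence) get NaN
    p-values and are meant to be excluded from FDR control.
    """
    covariate_levels = covariate_levels or {}
    Kfull = K.subset(matrix.sample_ids).values
    x_full = matrix.group_indicator(predictor_field, predictor_level)
    cov_cols = [
        matrix.group_indicator(f, covariate_levels.get(f) or _first_level(matrix, f))
        for f in covariate_fields
    ]
    obs = matrix.observed()
    n_sites = matrix.n_sites
    rows = []
    eig_cache: dict = {}
    n_failed = 0
    for i in range(n_sites):
        mask = obs[i]
        n = int(mask.sum())
        rec = {
            "chrom": matrix.sites["chrom"].iloc[i],
            "pos": int(matrix.sites["pos"].iloc[i]),
            "beta_hat": np.nan, "se": np.nan, "sigma_g2": np.nan,
            "sigma_e2": np.nan, "p_value": np.nan, "n_used": n,
            "converged": False,
        }
        x = x_full[mask]
        if n < min_samples or np.ptp(x) == 0:
            rows.append(rec)
            n_failed += 1
            continue
        W = np.column_stack([np.ones(n)] + [c[mask] for c in cov_cols])
        key = mask.tobytes()
        Ksub = eig_cache.get(key)
        if Ksub is None:
            Ksub = Kfull[np.ix_(mask, mask)]
            eig_cache[key] = Ksub
        spec = SiteModelSpec(matrix.meth[i, mask], matrix.total[i, mask], x, W, Ksub)
        try:
            fit = fit_site(spec)
        except (ValueError, np.linalg.LinAlgError) as exc:
            rec["converged"] = False
            rows.append(rec)
            n_failed += 1
            logger.warning("site %s:%s unfit: %s", rec["chrom"], rec["pos"], exc)
            continue
        rec.update(
            beta_hat=fit.beta_hat, se=fit.se_beta, sigma_g2=fit.sigma_g2_hat,
            sigma_e2=fit.sigma_e2_hat,
            p_value=fit.p_value if fit.converged else np.nan,
            converged=fit.converged,
        )
        if not fit.converged:
            n_failed += 1
        rows.append(rec)
        if progress_every and (i + 1) % progress_every == 0:
            logger.info("fitted %d/%d sites", i + 1, n_sites)
    if n_failed:
        logger.warning("%d/%d sites not fit or not converged", n_failed, n_sites)
    return pd.DataFrame(rows)


def _first_level(matrix, field_name):
    levels = sorted({getattr(s, field_name) for s in matrix.samples})
    if len(levels) < 2:
        raise ValueError(f"covariate {field_name!r} has < 2 levels")
    return levels[-1]


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------


def estimate_pi0(p_values, lambdas=None) -> float:
    """Storey's pi0: grid estimates pi0(lambda) = #{p > lambda}/(m(1-lambda))
    smoothed with a cubic fit and extrapolated at the largest lambda,
    bounded to (0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    m = len(p)
    pi0s = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0s, deg=3)
    pi0 = float(np.polyval(coef, lambdas[-1]))
    return min(max(pi0, 1.0 / m if m else 1e-8), 1.0)


def qvalues(p_values, pi0: float = None) -> np.ndarray:
    """Storey q-values.  With pi0 forced to 1 this reduces exactly to
    Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    if pi0 is None:
        pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# DMC calling and cross-contrast comparison
# ---------------------------------------------------------------------------


def group_meth_diff(matrix: MethylationMatrix, group1_mask, group0_mask) -> np.ndarray:
    """Per-site signed methylation difference: unweighted mean of per-sample
    proportions in group1 minus the same in group0 (observed cells only)."""
    props = matrix.proportions()
    with np.errstate(invalid="ignore"):
        m1 = np.nanmean(props[:, group1_mask], axis=1)
        m0 = np.nanmean(props[:, group0_mask], axis=1)
    return m1 - m0


def call_dmcs(
    fits: pd.DataFrame,
    matrix: MethylationMatrix,
    predictor_field: str = "group",
    predictor_level: str = "hatchery",
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Attach q-values and methylation differences; call DMCs at q < fdr.

    Only converged fits with finite p-values enter FDR control.  The
    threshold is strict: q exactly equal to fdr is not called.
    """
    fits = fits.copy().reset_index(drop=True)
    testable = fits["p_value"].notna().to_numpy()
    q = np.full(len(fits), np.nan)
    if testable.any():
        q[testable] = qvalues(fits.loc[testable, "p_value"].to_numpy())
    fits["q_value"] = q

    g1 = matrix.group_indicator(predictor_field, predictor_level).astype(bool)
    diff = group_meth_diff(matrix, g1, ~g1)
    fits["meth_diff"] = diff
    fits["direction"] = np.where(diff >= 0, "hyper", "hypo")
    fits["is_dmc"] = testable & (q < fdr)
    return fits


def compare_dmc_sets(
    dmcs_a: pd.DataFrame, dmcs_b: pd.DataFrame, proximity_bp: int = 10000
) -> dict:
    """Overlap report between two DMC tables (rows with chrom/pos/meth_diff).

    exact = identical (chrom, pos); proximal = within proximity_bp on the
    same chromosome, exact matches excluded; concordant = same meth_diff
    sign among exact + proximal pairs.
    """
    a = dmcs_a.reset_index(drop=True)
    b = dmcs_b.reset_index(drop=True)
    a_sites = {(c, p) for c, p in zip(a["chrom"], a["pos"])}
    b_sites = {(c, p) for c, p in zip(b["chrom"], b["pos"])}
    exact = sorted(a_sites & b_sites)

    sign_a = {(c, p): np.sign(d) for c, p, d in zip(a["chrom"], a["pos"], a["meth_diff"])}
    sign_b = {(c, p): np.sign(d) for c, p, d in zip(b["chrom"], b["pos"], b["meth_diff"])}

    proximal = []
    for c1, p1 in sorted(a_sites):
        for c2, p2 in sorted(b_sites):
            if c1 == c2 and (c1, p1) != (c2, p2) and abs(p1 - p2) <= proximity_bp:
                proximal.append(((c1, p1), (c2, p2)))
    pairs = [((c, p), (c, p)) for c, p in exact] + proximal
    concordant = sum(
        1 for sa, sb in pairs if sign_a[sa] == sign_b[sb] and sign_a[sa] != 0
    )
    return {
        "n_exact": len(exact),
        "exact_sites": exact,
        "n_proximal": len(proximal),
        "proximal_pairs": proximal,
        "n_pairs": len(pairs),
        "n_concordant": concordant,
    }


def dmc_table_to_bed(fits: pd.DataFrame) -> str:
    """Export called DMCs as BED (0-based half-open)."""
    lines = []
    for _, row in fits[fits["is_dmc"]].iterrows():
        lines.append(
            f"{row['chrom']}\t{row['pos'] - 1}\t{row['pos']}\t"
            f"dmc\t{row['q_value']:.4g}\t."
        )
    return "\n".join(lines) + ("\n" if lines else "")
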