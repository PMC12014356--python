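"""Firth-penalized logistic regression.

Maximizes the Jeffreys-prior-penalized log-likelihood

    pll(beta) = sum_i m_i [ y_i eta_i - log(1 + e^{eta_i}) ] + 1/2 log det I(beta)

by Newton-Raphson on the hat-value-adjusted score, with step-halving so the
penalized likelihood never decreases.  Estimates stay finite under complete
or quasi-complete separation, which is why this is the engine for very
sparse carrier exposures.  P-values come from the penalized likelihood-ratio
test (refit with the coefficient fixed at zero, penalty still computed from
the full design, as in R's logistf); confidence intervals from the profile
penalized likelihood.

Two entry points:

* :func:`firth_fit` — general design matrix, profile CIs, used for locus
  tests and anywhere a full fit is reported.
* :func:`firth_scan_columns` — a batched scanner for many carrier columns
  sharing one covariate block (the breakpoint GWAS inner loop); column
  entries may be masked out (missing genotype under the one-type encoding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import chi2
from scipy.optimize import brentq

_CHI2_95 = chi2.ppf(0.95, 1)


class RankError(np.linalg.LinAlgError):
    """Design matrix is rank deficient (perfectly collinear columns)."""


@dataclass
class FirthFit:
    """Result of one penalized-likelihood logistic fit."""

    coef: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_two_sided: np.ndarray
    p_one_sided: np.ndarray
    loglik: float          # penalized log-likelihood at the maximum
    converged: bool
    n_iter: int
    names: Sequence[str] = field(default_factory=list)

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)


@dataclass
class AssocResult:
    """One carrier-versus-status association (locus or breakpoint)."""

    or_: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    p_one_sided: float
    beta: float
    se: float
    n_carriers: int
    n_case_carriers: int
    n_control_carriers: int
    status: str = "tested"          # tested | unobserved | collinear
    converged: bool = True
    sided: str = "two"

    @property
    def p_sided(self) -> float:
        return self.p_one_sided if self.sided == "one" else self.p_two_sided


# ---------------------------------------------------------------------------
# scalar-path internals

def _penalized_loglik(X, y, beta, weights):
    eta = X @ beta
    ll = np.sum(weights * (y * eta - np.logaddexp(0.0, eta)))
    p = expit(eta)
    w = weights * p * (1.0 - p)
    A = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _newton(X, y, beta, free, weights, max_iter=50, tol=1e-5):
    """Firth Newton-Raphson updating only ``free`` coordinates.

    The penalty (and the hat values in the adjusted score) always uses the
    full design, so fits with fixed coordinates are the restricted fits of
    the penalized likelihood-ratio test.
    """
    free = np.asarray(free)
    pll = _penalized_loglik(X, y, beta, weights)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        w = weights * p * (1.0 - p)
        A = (X * w[:, None]).T @ X
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            break
        h = w * np.einsum("nk,kl,nl->n", X, Ainv, X)
        U = X.T @ (weights * (y - p) + h * (0.5 - p))
        if np.max(np.abs(U[free])) < tol:
            converged = True
            break
        Aff = A[np.ix_(free, free)]
        try:
            delta = np.linalg.solve(Aff, U[free])
        except np.linalg.LinAlgError:
            break
        # step-halving: never let the penalized likelihood decrease
        for _ in range(25):
            cand = beta.copy()
            cand[free] += delta
            pll_new = _penalized_loglik(X, y, cand, weights)
            if pll_new >= pll - 1e-12:
                break
            delta = delta / 2.0
        else:
            converged = True  # no improving direction left: at the optimum
            beta_new = beta
            break
        beta = cand
        pll = pll_new
    return beta, pll, converged, n_iter


def _check_design(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, k) aligned with y")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("y contains a single class; nothing to fit")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankError("design matrix is rank deficient (collinear columns)")
    return X, y


def firth_fit(X, y, names: Optional[Sequence[str]] = None,
              test_idx: Optional[Sequence[int]] = None,
              ci: bool = True, alpha: float = 0.05,
              max_iter: int = 50, tol: float = 1e-5,
              weights: Optional[np.ndarray] = None) -> FirthFit:
    """Fit a Firth logistic regression of binary ``y`` on design ``X``.

    ``X`` should include an intercept column.  ``test_idx`` selects the
    coefficients for which penalized-LRT p-values and profile CIs are
    computed (default: all).  ``weights`` are 0/1 inclusion masks (used by
    the one-type breakpoint encodings); fractional weights also work.
    """
    X, y = _check_design(X, y)
    n, k = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    beta0 = np.zeros(k)
    beta, pll_full, converged, n_iter = _newton(
        X, y, beta0, np.arange(k), w, max_iter=max_iter, tol=tol)

    eta = X @ beta
    p = expit(eta)
    wdiag = w * p * (1.0 - p)
    A = (X * wdiag[:, None]).T @ X
    cov = np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))

    idx = np.arange(k) if test_idx is None else np.asarray(test_idx)
    p_two = np.full(k, np.nan)
    p_one = np.full(k, np.nan)
    ci_lo = np.full(k, np.nan)
    ci_hi = np.full(k, np.nan)
    crit = chi2.ppf(1.0 - alpha, 1)

    def pll_fixed(j, value):
        b = beta.copy()
        b[j] = value
        free = np.array([i for i in range(k) if i != j])
        _, pllv, _, _ = _newton(X, y, b, free, w, max_iter=max_iter, tol=tol)
        return pllv

    for j in idx:
        stat = max(0.0, 2.0 * (pll_full - pll_fixed(j, 0.0)))
        p_two[j] = chi2.sf(stat, 1)
        p_one[j] = p_two[j] / 2.0 if beta[j] > 0 else 1.0 - p_two[j] / 2.0
        if ci:
            ci_lo[j], ci_hi[j] = _profile_ci(pll_fixed, j, beta[j], se[j],
                                             pll_full, crit)

    return FirthFit(coef=beta, se=se, ci_low=ci_lo, ci_high=ci_hi,
                    p_two_sided=p_two, p_one_sided=p_one, loglik=pll_full,
                    converged=converged, n_iter=n_iter,
                    names=list(names) if names is not None else [f"b{i}" for i in range(k)])


def _profile_ci(pll_fixed, j, bhat, se_j, pll_full, crit):
    """Profile-penalized-likelihood interval endpoints by bracketing + brentq."""

    def g(v):
        return 2.0 * (pll_full - pll_fixed(j, v)) - crit

    bounds = []
    for direction in (-1.0, 1.0):
        step = max(2.0 * se_j, 0.5) if np.isfinite(se_j) else 0.5
        lo, hi = bhat, bhat
        found = False
        for _ in range(60):
            hi = hi + direction * step
            if g(hi) > 0:
                found = True
                break
            step *= 1.6
        if not found:
            bounds.append(direction * np.inf)
            continue
        a, b = (hi, lo) if direction < 0 else (lo, hi)
        bounds.append(brentq(g, a, b, xtol=1e-6))
    return bounds[0], bounds[1]


# ---------------------------------------------------------------------------
# design-matrix helper shared by the association front-ends

def build_design(samples, covariates=("cohort", "pc1")) -> tuple[np.ndarray, list]:
    """Intercept + covariate columns from the sample table.

    Categorical covariates (object/category dtype) are dummy-coded dropping
    the first level; numeric covariates enter as-is.
    """
    cols = [np.ones(len(samples))]
    names = ["intercept"]
    for cov in covariates:
        if cov not in samples.columns:
            continue
        col = samples[cov]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(float))
                names.append(f"{cov}[{lev}]")
        else:
            cols.append(col.to_numpy(float))
            names.append(cov)
    return np.column_stack(cols), names


def firth_test(carrier, samples, covariates=("cohort", "pc1"),
               sided: str = "two", ci: bool = True) -> AssocResult:
    """Firth test of case/control status on a binary carrier indicator.

    Fits ``status ~ carrier + covariates``.  Zero carriers gives an
    ``unobserved`` result (no test); a carrier column collinear with the
    covariates is flagged rather than raised.
    """
    carrier = np.asarray(carrier, dtype=float)
    y = samples["status"].to_numpy(float)
    n_case = int(carrier[y == 1].sum())
    n_ctrl = int(carrier[y == 0].sum())
    if carrier.sum() == 0:
        return AssocResult(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                           np.nan, 0, 0, 0, status="unobserved", sided=sided)
    Z, names = build_design(samples, covariates)
    X = np.column_stack([Z[:, :1], carrier, Z[:, 1:]])
    names = [names[0], "carrier"] + names[1:]
    try:
        fit = firth_fit(X, y, names=names, test_idx=[1], ci=ci)
    except RankError:
        return AssocResult(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                           np.nan, int(carrier.sum()), n_case, n_ctrl,
                           status="collinear", sided=sided)
    j = 1
    return AssocResult(
        or_=float(np.exp(fit.coef[j])),
        ci_low=float(np.exp(fit.ci_low[j])),
        ci_high=float(np.exp(fit.ci_high[j])),
        p_two_sided=float(fit.p_two_sided[j]),
        p_one_sided=float(fit.p_one_sided[j]),
        beta=float(fit.coef[j]), se=float(fit.se[j]),
        n_carriers=int(carrier.sum()), n_case_carriers=n_case,
        n_control_carriers=n_ctrl, status="tested",
        converged=fit.converged, sided=sided)


# ---------------------------------------------------------------------------
# batched carrier-column scanner

class _SparseCols:
    """Sparse carrier/missing structure for a set of scan columns.

    The carrier design column is 0/1 with few ones, so every term involving
    it is a gather/scatter over the nonzeros rather than a dense (B, n) op;
    the missing mask is materialized only when any column has missing
    entries.
    """

    def __init__(self, Z, alt_sets, miss_sets):
        n, k0 = Z.shape
        B = len(alt_sets)
        counts = np.array([len(a) for a in alt_sets], dtype=np.int64)
        self.rows = np.repeat(np.arange(B), counts)
        self.cols = (np.concatenate(alt_sets).astype(np.int64)
                     if counts.sum() else np.empty(0, dtype=np.int64))
        self.Zalt = Z[self.cols]
        self.B, self.n, self.k0 = B, n, k0
        if any(len(m) for m in miss_sets):
            M = np.ones((B, n))
            for b, m in enumerate(miss_sets):
                M[b, m] = 0.0
            self.M = M
        else:
            self.M = None

    @property
    def nnz(self):
        return len(self.cols)


def _batch_state(Z, P9, beta, sp: _SparseCols, y):
    """Per-iteration quantities for a chunk: information, hat values, score, pll."""
    n, k0 = Z.shape
    B = beta.shape[0]
    rows, cols, Zalt, M = sp.rows, sp.cols, sp.Zalt, sp.M
    eta = beta[:, :k0] @ Z.T
    np.add.at(eta, (rows, cols), beta[rows, k0])
    p = expit(eta)
    w = p * (1.0 - p)
    if M is not None:
        w *= M
    Azz = (w @ P9).reshape(B, k0, k0)
    wv = w[rows, cols]
    Azc = np.zeros((B, k0))
    np.add.at(Azc, rows, wv[:, None] * Zalt)
    Acc = np.bincount(rows, weights=wv, minlength=B)
    A = np.empty((B, k0 + 1, k0 + 1))
    A[:, :k0, :k0] = Azz
    A[:, :k0, k0] = Azc
    A[:, k0, :k0] = Azc
    A[:, k0, k0] = Acc
    sign, logdet = np.linalg.slogdet(A)
    ll_terms = y * eta
    ll_terms -= np.logaddexp(0.0, eta)
    if M is not None:
        ll_terms *= M
    pll = np.where(sign > 0, ll_terms.sum(axis=1) + 0.5 * logdet, -np.inf)
    Ainv = np.linalg.inv(A)
    G = Ainv[:, :k0, :k0].reshape(B, k0 * k0)
    g = Ainv[:, :k0, k0]
    q = Ainv[:, k0, k0]
    quad = G @ P9.T
    np.add.at(quad, (rows, cols), 2.0 * (g[rows] * Zalt).sum(axis=1) + q[rows])
    h = w * quad
    resid = y - p
    if M is not None:
        resid *= M
    resid += h * (0.5 - p)
    U = np.empty((B, k0 + 1))
    U[:, :k0] = resid @ Z
    U[:, k0] = np.bincount(rows, weights=resid[rows, cols], minlength=B)
    return A, U, pll


def _batch_newton(Z, P9, y, alt_sets, miss_sets, beta, fit_carrier,
                  max_iter=30, tol=1e-5):
    """Vectorized Firth Newton over a chunk of carrier columns.

    ``fit_carrier=False`` keeps the carrier coefficient fixed at its current
    value (zero for the restricted fits of the penalized LRT) while the
    penalty still includes the carrier column.
    """
    B = beta.shape[0]
    k0 = Z.shape[1]
    free_hi = k0 + 1 if fit_carrier else k0
    pll_out = np.full(B, -np.inf)
    pll_prev = np.full(B, -np.inf)
    beta_prev = beta.copy()
    n_iter = np.zeros(B, dtype=np.int64)
    converged = np.zeros(B, dtype=bool)
    idx = np.arange(B)  # active columns; converged ones leave the working set

    def state(which):
        sp = _SparseCols(Z, [alt_sets[i] for i in which],
                         [miss_sets[i] for i in which])
        return _batch_state(Z, P9, beta[which], sp, y)

    for _ in range(max_iter):
        A, U, pll = state(idx)
        # step-halving: columns whose last step decreased pll back off
        for _ in range(8):
            worse = pll < pll_prev[idx] - 1e-12
            if not worse.any():
                break
            w_idx = idx[worse]
            beta[w_idx] = 0.5 * (beta[w_idx] + beta_prev[w_idx])
            A[worse], U[worse], pll[worse] = state(w_idx)
        pll_out[idx] = pll
        grad = np.max(np.abs(U[:, :free_hi]), axis=1)
        done = grad < tol
        converged[idx[done]] = True
        keep = ~done
        idx = idx[keep]
        if len(idx) == 0:
            break
        Aff = A[keep][:, :free_hi, :free_hi]
        delta = np.linalg.solve(Aff, U[keep][:, :free_hi, None])[..., 0]
        beta_prev[idx] = beta[idx]
        pll_prev[idx] = pll[keep]
        beta[idx, :free_hi] += delta
        n_iter[idx] += 1
    if len(idx):
        # final state for columns that ran out of iterations
        _, _, pll = state(idx)
        pll_out[idx] = pll
    return beta, pll_out, converged, n_iter


def firth_scan_columns(Z, y, alt_sets, miss_sets=None, chunk: int = 256,
                       max_iter: int = 30, tol: float = 1e-5):
    """Firth-test many binary carrier columns against a shared covariate block.

    Parameters
    ----------
    Z : (n, k0) float array, covariates including the intercept column.
    y : (n,) binary outcome.
    alt_sets / miss_sets : sequences of integer index arrays; samples in a
        miss set are excluded (weight 0) from that column's likelihood.

    Returns a dict of per-column arrays: beta, se, or_, p_two, p_one,
    converged, n_iter, alt_case, alt_control, n_eff.  P-values are penalized
    LRTs (restricted fit per column, penalty from the full design); the SE is
    the Wald SE from the penalized information.  Profile CIs are not
    computed here — refit interesting columns with :func:`firth_fit`.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k0 = Z.shape
    ncols = len(alt_sets)
    if miss_sets is None:
        miss_sets = [np.empty(0, dtype=np.int64)] * ncols
    P9 = (Z[:, :, None] * Z[:, None, :]).reshape(n, k0 * k0)

    out = {key: np.full(ncols, np.nan) for key in ("beta", "se", "or_", "p_two", "p_one")}
    out["converged"] = np.zeros(ncols, dtype=bool)
    out["n_iter"] = np.zeros(ncols, dtype=np.int64)
    out["alt_case"] = np.zeros(ncols, dtype=np.int64)
    out["alt_control"] = np.zeros(ncols, dtype=np.int64)
    out["n_eff"] = np.zeros(ncols, dtype=np.int64)

    # warm start from the covariate-only Firth fit on all samples
    base = firth_fit(Z, y, ci=False, test_idx=[])
    gamma0 = base.coef

    n_cases = y.sum()
    n_controls = len(y) - n_cases
    for lo in range(0, ncols, chunk):
        hi = min(lo + chunk, ncols)
        B = hi - lo
        alts, misses = [], []
        for b in range(B):
            alt = np.asarray(alt_sets[lo + b], dtype=np.int64)
            mis = np.asarray(miss_sets[lo + b], dtype=np.int64)
            mis = np.setdiff1d(mis, alt)  # model-type call takes precedence
            alts.append(alt)
            misses.append(mis)
            out["alt_case"][lo + b] = int(y[alt].sum())
            out["alt_control"][lo + b] = len(alt) - int(y[alt].sum())
            out["n_eff"][lo + b] = n - len(mis)

        # warm start: covariate coefficients from the base fit, carrier
        # coefficient at the Haldane-corrected 2x2 log cross-ratio
        a = out["alt_case"][lo:hi].astype(float)
        bexp = out["alt_control"][lo:hi].astype(float)
        b0 = np.log(((a + 0.5) * (n_controls - bexp + 0.5))
                    / ((bexp + 0.5) * (n_cases - a + 0.5)))
        beta = np.tile(np.r_[gamma0, 0.0], (B, 1))
        beta[:, k0] = b0
        beta, pll_full, conv_full, n_iter = _batch_newton(
            Z, P9, y, alts, misses, beta, fit_carrier=True,
            max_iter=max_iter, tol=tol)

        beta_r = np.tile(np.r_[gamma0, 0.0], (B, 1))
        _, pll_restr, conv_restr, _ = _batch_newton(
            Z, P9, y, alts, misses, beta_r, fit_carrier=False,
            max_iter=max_iter, tol=tol)

        A, _, _ = _batch_state(Z, P9, beta, _SparseCols(Z, alts, misses), y)
        cov = np.linalg.inv(A)
        se = np.sqrt(np.maximum(cov[:, k0, k0], 0.0))

        stat = np.maximum(0.0, 2.0 * (pll_full - pll_restr))
        p_two = chi2.sf(stat, 1)
        bcar = beta[:, k0]
        out["beta"][lo:hi] = bcar
        out["se"][lo:hi] = se
        out["or_"][lo:hi] = np.exp(bcar)
        out["p_two"][lo:hi] = p_two
        out["p_one"][lo:hi] = np.where(bcar > 0, p_two / 2.0, 1.0 - p_two / 2.0)
        out["converged"][lo:hi] = conv_full & conv_restr
        out["n_iter"][lo:hi] = n_iter
    return out
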