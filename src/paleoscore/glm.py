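"""Binomial-logit fitting with fractional successes.

The score of individual i is modelled as the proportion of successes in a
binomial sample of size m_i (the number of panel SNPs genotyped in that
individual):

    m_i S_i ~ Binomial(m_i, p_i),   logit(p_i) = x_i' beta.

For weighted scores m_i S_i is non-integer; the likelihood is evaluated the
same way with the combinatorial constant omitted (it does not depend on beta).
Maximization is by iteratively reweighted least squares (IRLS) with trials m_i
as prior weights; standard errors come from the observed information.  A
batched fitter solves many responses sharing one design matrix at once, which
is what makes genome-wide empirical nulls cheap.

Columns are standardized internally (an exact reparametrization) so that
year-scale covariates such as date BP do not degrade the normal-equation
conditioning; coefficients and standard errors are returned on the original
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

_TOL = 1e-8
_MAXITER = 100


@dataclass
class RegressionResult:
    """MLE of a (possibly fractional) binomial logit model."""

    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    llf: float
    n_samples: int
    converged: bool
    n_iter: int = 0

    def coef(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.bse[self.terms.index(term)])

    def as_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "params": {t: float(b) for t, b in zip(self.terms, self.params)},
            "bse": {t: float(s) for t, s in zip(self.terms, self.bse)},
            "llf": float(self.llf),
            "n_samples": int(self.n_samples),
            "converged": bool(self.converged),
        }


def check_design(X: np.ndarray, terms) -> None:
    """Raise on rank deficiency, naming the collinear terms via QR pivoting."""
    n, p = X.shape
    if n <= p:
        raise ValueError(f"design has {n} rows for {p} terms; need n > p")
    norms = np.linalg.norm(X, axis=0)
    Xn = X / np.where(norms > 0, norms, 1.0)  # scale-free rank check
    _, r, piv = scipy.linalg.qr(Xn, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < p:
        bad = [terms[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")


def _standardize(X: np.ndarray):
    """Scale non-constant columns to unit SD (exact linear reparametrization)."""
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return X / scale, scale


def _loglik(eta: np.ndarray, s: np.ndarray, m: np.ndarray) -> np.ndarray:
    # s*log(mu) + (m-s)*log(1-mu), written in eta for stability:
    #   = s*eta - m*log(1+exp(eta))
    return (s * eta - m * np.logaddexp(0.0, eta)).sum(axis=-1)


def fit_binomial_logit(
    X: np.ndarray,
    successes: np.ndarray,
    trials: np.ndarray,
    terms=None,
    tol: float = _TOL,
    maxiter: int = _MAXITER,
) -> RegressionResult:
    """IRLS fit of ``successes/trials`` on design ``X`` (with intercept column).

    Convergence: max absolute coefficient change below ``tol`` (default 1e-8)
    or ``maxiter`` iterations, in which case ``converged`` is False (which is
    also how complete separation manifests).
    """
    X = np.asarray(X, dtype=float)
    s = np.asarray(successes, dtype=float)
    m = np.asarray(trials, dtype=float)
    terms = list(terms) if terms is not None else [f"x{j}" for j in range(X.shape[1])]
    check_design(X, terms)
    if (m <= 0).any():
        raise ValueError("all trial counts must be positive")
    if ((s < 0) | (s > m)).any():
        raise ValueError("successes must lie in [0, trials]")

    beta, llf, converged, n_iter = _irls_batch(X, s[None, :], m[None, :], tol, maxiter)
    b = beta[0]
    eta = X @ b
    mu = _expit(eta)
    w = m * mu * (1.0 - mu)
    # Observed information on the standardized scale for conditioning, then
    # mapped back (cov_orig = D^-1 cov_std D^-1 with D = diag(column SDs)).
    Xs, scale = _standardize(X)
    info = (Xs * w[:, None]).T @ Xs
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        # quasi-separation can flatten the information matrix; pseudo-inverse
        # keeps the coefficient estimates usable while SEs become approximate
        cov = np.linalg.pinv(info)
    cov = cov / np.outer(scale, scale)
    with np.errstate(invalid="ignore"):
        bse = np.sqrt(np.diag(cov))
    return RegressionResult(
        terms=terms, params=b, bse=bse, llf=float(llf[0]),
        n_samples=X.shape[0], converged=bool(converged[0]), n_iter=int(n_iter),
    )


def _expit(eta):
    return 0.5 * (1.0 + np.tanh(0.5 * eta))


def _irls_batch(X, S, M, tol=_TOL, maxiter=_MAXITER):
    """IRLS over a batch of responses sharing the design matrix.

    Parameters
    ----------
    X : (n, p) design.
    S : (B, n) fractional success counts.
    M : (B, n) or (n,) trials.

    Returns (beta (B, p), llf (B,), converged (B,), n_iter).
    """
    Xs, scale = _standardize(X)
    B, n = S.shape
    p = Xs.shape[1]
    M = np.broadcast_to(M, S.shape)
    # zero-trial entries (e.g. an all-missing sample in one null replicate)
    # get weight 0 and a neutral working response
    y = np.where(M > 0, S / np.where(M > 0, M, 1.0), 0.0)

    beta = np.zeros((B, p))
    # Intercept-ish start: put the pooled logit on the (scaled) constant column.
    const = np.flatnonzero(X.std(axis=0) == 0)
    pbar = np.clip(S.sum(axis=1) / np.maximum(M.sum(axis=1), 1e-12), 1e-6, 1 - 1e-6)
    if const.size:
        beta[:, const[0]] = np.log(pbar / (1 - pbar)) / Xs[0, const[0]]

    active = np.ones(B, dtype=bool)
    n_iter = 0
    for n_iter in range(1, maxiter + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        eta = beta[idx] @ Xs.T                      # (b, n)
        mu = _expit(eta)
        v = np.clip(mu * (1.0 - mu), 1e-12, None)
        w = M[idx] * v
        z = eta + (y[idx] - mu) / v
        XtWX = np.einsum("bn,np,nq->bpq", w, Xs, Xs, optimize=True)
        XtWz = np.einsum("bn,np->bp", w * z, Xs, optimize=True)
        new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        delta = np.abs(new - beta[idx]).max(axis=1)
        beta[idx] = new
        done = delta < tol
        active[idx[done]] = False

    converged = ~active
    eta = beta @ Xs.T
    llf = _loglik(eta, S, M)
    return beta / scale[None, :], llf, converged, n_iter
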