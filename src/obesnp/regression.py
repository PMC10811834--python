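"""Maximum-likelihood logistic regression (unconditional, with optional
cluster-robust variance) and conditional logistic regression for 1:1 matched
pairs.

Both fits share a damped Newton-Raphson core: full Newton steps with
step-halving whenever a step would decrease the log-likelihood, convergence
declared when the score norm falls below ``tol`` (default 1e-8).  The 1:1
conditional likelihood

    prod_i exp(b'x_case_i) / (exp(b'x_case_i) + exp(b'x_control_i))

is maximized as an intercept-free binary likelihood on the per-pair
case-minus-control covariate differences, the classical reduction for pair-
matched data.  Pairs concordant on every covariate carry no information and
are dropped (with a count recorded on the fit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MAX_ITER = 50
TOL = 1e-8
SEPARATION_BOUND = 15.0

#: Dummy coding of the categorical covariates.  The first level of each list
#: is the reference: female sex, youngest age band, urban residence, low
#: income, lowest education, never smoke/drink, light activity.
CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "sex": ["female", "male"],
    "age_band": ["20-29", "30-39", "40-49", "50-59", "60-80"],
    "residence": ["urban", "rural"],
    "income": ["low", "high"],
    "education": ["primary_or_below", "junior_or_senior_high", "college_or_above"],
    "smoking": ["never", "former", "current"],
    "drinking": ["never", "former", "current"],
    "occupational_pa": ["light", "moderate", "heavy"],
    "leisure_exercise": ["light", "moderate", "heavy"],
}


class SeparationError(RuntimeError):
    """Raised when the likelihood appears monotone (perfect separation)."""


class RankDeficiencyError(ValueError):
    """Raised when the design matrix is not of full column rank."""


@dataclass
class RegressionFit:
    """A fitted logistic-type model on the log-odds scale."""

    names: list[str]
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    converged: bool
    n_iter: int
    n_dropped_concordant: int = 0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def wald(self, name: str) -> tuple[float, float]:
        """Wald z statistic and two-sided p for one term."""
        z = self.coef(name) / self.coef_se(name)
        return float(z), float(2 * stats.norm.sf(abs(z)))

    def subcov(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.names.index(n) for n in names]
        return self.cov[np.ix_(idx, idx)]


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the collinearity via QR pivoting
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[j] for j in range(len(names)) if diag[j] < 1e-8 * max(diag.max(), 1.0)]
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"collinear or constant columns: {bad or 'undetermined'}"
        )


def _newton(
    X: np.ndarray,
    y: np.ndarray,
    offset_loglik,
    names: Sequence[str],
    tol: float = TOL,
    max_iter: int = MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """Damped Newton ascent of the Bernoulli log-likelihood with success
    probability sigmoid(X b); used by both fit variants (the conditional fit
    passes differences with y = 1)."""
    n, k = X.shape
    beta = np.zeros(k)

    def loglik(b: np.ndarray) -> float:
        eta = X @ b
        # log sigma(eta) for y=1, log(1-sigma) for y=0, numerically stable
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    ll = loglik(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - mu)
        if np.linalg.norm(score) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step-halving: never accept a likelihood decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = loglik(beta)
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            raise SeparationError(
                "coefficient exceeded "
                f"{SEPARATION_BOUND} on the log-odds scale before the score "
                "converged; the data are (quasi-)separated"
            )
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    if not converged:
        score = X.T @ (y - mu)
        converged = bool(np.linalg.norm(score) < tol)
    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.inv(info)
    return beta, cov, ll, converged, it


def fit_logistic(
    design: pd.DataFrame | np.ndarray,
    outcome: Sequence[int] | np.ndarray,
    names: Optional[Sequence[str]] = None,
    cluster_ids: Optional[Sequence] = None,
    add_intercept: bool = True,
    tol: float = TOL,
    max_iter: int = MAX_ITER,
) -> RegressionFit:
    """Fit a binary logistic regression by maximum likelihood.

    Parameters
    ----------
    design
        Covariate matrix (DataFrame column names become coefficient names).
    outcome
        Binary 0/1 outcome vector.
    cluster_ids
        Optional cluster labels (e.g. survey site).  When given, the
        model-based covariance is replaced by the cluster-sandwich estimator
        — a pragmatic account of a clustered sampling design that leaves the
        point estimates untouched.
    add_intercept
        Prepend an intercept column (named ``"(intercept)"``).
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["(intercept)"] + names
    _check_rank(X, names)
    beta, cov, ll, converged, it = _newton(X, y, None, names, tol=tol, max_iter=max_iter)
    if cluster_ids is not None:
        cov = _cluster_sandwich(X, y, beta, cov, np.asarray(cluster_ids))
    return RegressionFit(
        names=names, beta=beta, cov=cov, loglik=ll, n=len(y), converged=converged, n_iter=it
    )


def _cluster_sandwich(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, bread: np.ndarray, clusters: np.ndarray
) -> np.ndarray:
    """Cluster-robust (sandwich) covariance, summing score contributions
    within clusters, with the Stata-style small-sample factor
    G/(G-1) * (n-1)/(n-k)."""
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    scores = X * (y - mu)[:, None]
    labels, inverse = np.unique(clusters, return_inverse=True)
    g = len(labels)
    if g < 2:
        raise ValueError("cluster-robust variance needs at least 2 clusters")
    cluster_scores = np.zeros((g, X.shape[1]))
    np.add.at(cluster_scores, inverse, scores)
    meat = cluster_scores.T @ cluster_scores
    n, k = X.shape
    factor = (g / (g - 1)) * ((n - 1) / (n - k))
    return bread @ meat @ bread * factor


def fit_conditional_logistic(
    pair_differences: pd.DataFrame | np.ndarray,
    names: Optional[Sequence[str]] = None,
    tol: float = TOL,
    max_iter: int = MAX_ITER,
) -> RegressionFit:
    """Fit the 1:1 matched-pair conditional logistic likelihood.

    ``pair_differences`` holds one row per pair: case covariates minus
    control covariates.  Rows that are zero in every column (pairs
    concordant on all covariates) contribute no information and are dropped;
    their count is recorded on the returned fit.
    """
    if isinstance(pair_differences, pd.DataFrame):
        names = list(pair_differences.columns)
        D = pair_differences.to_numpy(dtype=float)
    else:
        D = np.asarray(pair_differences, dtype=float)
        if D.ndim == 1:
            D = D[:, None]
        names = list(names) if names is not None else [f"x{j}" for j in range(D.shape[1])]
    keep = ~np.all(D == 0.0, axis=1)
    n_dropped = int((~keep).sum())
    D = D[keep]
    if len(D) == 0:
        raise ValueError("no discordant pairs: every pair is concordant on all covariates")
    _check_rank(D, names)
    y = np.ones(len(D))
    beta, cov, ll, converged, it = _newton(D, y, None, names, tol=tol, max_iter=max_iter)
    return RegressionFit(
        names=names,
        beta=beta,
        cov=cov,
        loglik=ll,
        n=len(D),
        converged=converged,
        n_iter=it,
        n_dropped_concordant=n_dropped,
    )


def model_report(fit: RegressionFit, alpha: float = 0.05) -> pd.DataFrame:
    """Per-term odds ratios with Wald confidence limits and p-values."""
    if not fit.converged:
        raise ValueError("refusing to report a non-converged fit")
    z = stats.norm.ppf(1 - alpha / 2)
    se = fit.se
    rows = []
    for j, name in enumerate(fit.names):
        b = fit.beta[j]
        zstat = b / se[j] if se[j] > 0 else np.inf * np.sign(b) if b else 0.0
        p = 2 * stats.norm.sf(abs(zstat)) if np.isfinite(zstat) else 0.0
        rows.append(
            {
                "term": name,
                "beta": b,
                "se": se[j],
                "or": np.exp(b),
                "ci_low": np.exp(b - z * se[j]),
                "ci_high": np.exp(b + z * se[j]),
                "z": zstat,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# design construction

def build_design(
    frame: pd.DataFrame,
    covariates: Sequence[str],
    extra_columns: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Dummy-code categorical covariates against their reference levels.

    ``covariates`` may name categorical columns from
    :data:`CATEGORICAL_LEVELS` (expanded to indicator columns named
    ``covariate_level``) or numeric columns (passed through).  ``age`` may
    be requested as ``age_band`` provided the frame carries that column.
    """
    pieces: list[pd.Series] = []
    for cov in covariates:
        if cov not in frame.columns:
            raise ValueError(f"covariate {cov!r} not present in the data")
        if cov in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[cov]
            col = frame[cov]
            unknown = set(col.unique()) - set(levels)
            if unknown:
                raise ValueError(f"column {cov!r} has unknown levels {sorted(unknown)}")
            for level in levels[1:]:
                name = f"{cov}_{level.replace('-', '_')}"
                pieces.append((col == level).astype(float).rename(name))
        else:
            pieces.append(frame[cov].astype(float).rename(cov))
    design = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=frame.index)
    if extra_columns is not None:
        design = pd.concat([extra_columns.astype(float), design], axis=1)
    return design


def pair_design(
    pairs: Sequence,
    covariates: Sequence[str] = (),
    extra_case: Optional[pd.DataFrame] = None,
    extra_control: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Case-minus-control covariate differences for matched pairs, ready for
    :func:`fit_conditional_logistic`.

    ``extra_case`` / ``extra_control`` supply additional pre-built design
    columns aligned with ``pairs`` (e.g. an inheritance-model coding of a
    SNP, risk-score tertile indicators, or joint-exposure indicators).
    """
    from .datamodel import subjects_to_frame

    case_frame = subjects_to_frame([p.case for p in pairs])
    control_frame = subjects_to_frame([p.control for p in pairs])
    x_case = build_design(case_frame, covariates)
    x_control = build_design(control_frame, covariates)
    diff = x_case.to_numpy() - x_control.to_numpy()
    out = pd.DataFrame(diff, columns=x_case.columns)
    if extra_case is not None or extra_control is not None:
        if extra_case is None or extra_control is None:
            raise ValueError("extra_case and extra_control must be supplied together")
        extra = extra_case.reset_index(drop=True).astype(float) - extra_control.reset_index(
            drop=True
        ).astype(float)
        out = pd.concat([extra, out], axis=1)
    return out
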