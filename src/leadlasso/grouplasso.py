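"""Group-Lasso logistic regression by group descent, written from scratch.

The estimator minimizes the per-observation penalized negative
log-likelihood

    f(b0, beta) = (1/n) * sum_i [ log(1 + exp(eta_i)) - y_i * eta_i ]
                  + lambda * sum_g sqrt(df_g) * ||beta_g||_2,

with eta = b0 + X beta and the columns of X partitioned into covariate
groups g of size df_g.  The penalty zeroes whole groups, so a categorical
item's dummies enter or leave the model together.

Optimization is block-coordinate descent with a majorize-minimize step per
block: the logistic loss curvature is bounded by 1/4, and with group blocks
orthonormalized (block' block / n = I) each group update is the exact
closed-form group soft-threshold

    z_g    = beta_g + 4 * X_g'(y - p)/n
    beta_g = max(0, 1 - 4*lambda*sqrt(df_g)/||z_g||) * z_g.

Every block update decreases the objective, so the iteration is globally
convergent for this convex problem.  An active-set strategy (full sweep,
then inner sweeps over currently nonzero groups) keeps path fits fast.

The unpenalized maximum-likelihood reference fit (for odds ratios with Wald
intervals) is delegated to statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .encode import EncodedDataset


class SeparationError(RuntimeError):
    """Unpenalized logistic fit diverged (quasi-separation); penalize instead."""


def predict_prob(fit, x) -> np.ndarray | float:
    """P(y=1 | x) under a fitted model; stable for large |eta|.

    ``x`` is one covariate row or a matrix of rows on the original scale.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != len(fit.coef):
        raise ValueError(f"x has {x.shape[1]} columns, fit expects {len(fit.coef)}")
    eta = fit.intercept + x @ fit.coef
    p = expit(eta)
    return p if p.size > 1 else float(p[0])


def _nll(y: np.ndarray, eta: np.ndarray) -> float:
    """Per-observation negative binomial log-likelihood, overflow-safe."""
    # log(1+exp(eta)) = max(eta,0) + log1p(exp(-|eta|))
    return float(np.mean(np.maximum(eta, 0.0) + np.log1p(np.exp(-np.abs(eta))) - y * eta))


def penalized_objective(
    intercept: float, beta: np.ndarray, encoded: EncodedDataset, lam: float
) -> float:
    """Objective on the scale of the fit: mean NLL + lambda * sum sqrt(df)*||beta_g||."""
    eta = intercept + encoded.X @ beta
    pen = sum(
        np.sqrt(int(encoded.df[g])) * np.linalg.norm(beta[sl])
        for g, sl in enumerate(encoded.slices)
    )
    return _nll(encoded.y, eta) + lam * float(pen)


def lambda_max(encoded: EncodedDataset) -> float:
    """Smallest lambda at which every penalized group is zero.

    On standardized data this is max_g ||X_g'(y - ybar)||_2 / (n sqrt(df_g)).
    """
    _require_standardized(encoded)
    y = encoded.y
    r = y - y.mean()
    vals = [
        np.linalg.norm(encoded.X[:, sl].T @ r) / (encoded.n * np.sqrt(int(encoded.df[g])))
        for g, sl in enumerate(encoded.slices)
    ]
    return float(max(vals))


def _require_standardized(encoded: EncodedDataset) -> None:
    if encoded.standardization is None:
        raise ValueError("encoded dataset must be group-standardized first")


@dataclass
class GroupLassoFit:
    """Solution of the penalized problem at one lambda.

    Coefficients are stored on both the standardized scale (the optimization
    scale) and the original covariate scale (for interpretation; odds ratio
    per dummy = exp(coef)).
    """

    intercept: float
    coef: np.ndarray
    intercept_std: float
    coef_std: np.ndarray
    lam: float
    objective: float
    n_iter: int
    converged: bool
    group_names: list
    slices: list
    df: np.ndarray
    column_names: list
    objective_path: list = field(default_factory=list, repr=False)

    @property
    def group_norms(self) -> dict:
        return {
            name: float(np.linalg.norm(self.coef_std[sl]))
            for name, sl in zip(self.group_names, self.slices)
        }

    @property
    def active_groups(self) -> set:
        return {name for name, nrm in self.group_norms.items() if nrm > 0.0}

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "intercept": self.intercept,
            "coefficients": dict(zip(self.column_names, map(float, self.coef))),
            "active_groups": sorted(self.active_groups),
            "objective": self.objective,
            "iterations": self.n_iter,
            "converged": self.converged,
        }


def fit_group_lasso(
    encoded: EncodedDataset,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 1000,
    warm_start: tuple[float, np.ndarray] | None = None,
    track_objective: bool = False,
) -> GroupLassoFit:
    """Solve the penalized problem at one lambda by group descent.

    ``warm_start`` is (intercept_std, coef_std) from a nearby lambda.
    Convergence: max absolute standardized-coefficient change over a full
    sweep < ``tol``.  A non-converged fit is returned with
    ``converged=False``.
    """
    _require_standardized(encoded)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X, y, n = encoded.X, encoded.y, encoded.n
    slices = encoded.slices
    thresh = 4.0 * lam * np.sqrt(encoded.df.astype(float))  # per-group threshold

    if warm_start is not None:
        b0 = float(warm_start[0])
        beta = np.array(warm_start[1], dtype=float, copy=True)
    else:
        ybar = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
        b0 = float(logit(ybar))
        beta = np.zeros(encoded.p)
    eta = b0 + X @ beta

    obj_path: list[float] = []
    if track_objective:
        obj_path.append(_nll(y, eta) + _penalty(beta, slices, encoded.df, lam))

    def sweep(groups: list[int]) -> float:
        nonlocal b0, eta
        # intercept: MM step with curvature bound 1/4
        p = expit(eta)
        d0 = 4.0 * float(np.mean(y - p))
        b0 += d0
        eta += d0
        dmax = abs(d0)
        for g in groups:
            sl = slices[g]
            p = expit(eta)
            z = beta[sl] + 4.0 * (X[:, sl].T @ (y - p)) / n
            nz = np.linalg.norm(z)
            new = np.zeros_like(z) if nz <= thresh[g] else (1.0 - thresh[g] / nz) * z
            delta = new - beta[sl]
            adel = np.max(np.abs(delta)) if delta.size else 0.0
            if adel > 0:
                eta += X[:, sl] @ delta
                beta[sl] = new
                dmax = max(dmax, float(adel))
        return dmax

    all_groups = list(range(encoded.n_groups))
    it = 0
    converged = False
    while it < max_iter:
        dmax = sweep(all_groups)
        it += 1
        if track_objective:
            obj_path.append(_nll(y, eta) + _penalty(beta, slices, encoded.df, lam))
        if dmax < tol:
            converged = True
            break
        # inner sweeps over the active set until it stabilizes
        while it < max_iter:
            active = [g for g in all_groups if np.any(beta[slices[g]])]
            if not active:
                break
            dmax = sweep(active)
            it += 1
            if track_objective:
                obj_path.append(_nll(y, eta) + _penalty(beta, slices, encoded.df, lam))
            if dmax < tol:
                break

    obj = _nll(y, eta) + _penalty(beta, slices, encoded.df, lam)
    b0_orig, beta_orig = encoded.standardization.to_original(b0, beta, slices)
    return GroupLassoFit(
        intercept=b0_orig,
        coef=beta_orig,
        intercept_std=b0,
        coef_std=beta.copy(),
        lam=float(lam),
        objective=obj,
        n_iter=it,
        converged=converged,
        group_names=list(encoded.group_names),
        slices=slices,
        df=encoded.df,
        column_names=list(encoded.column_names),
        objective_path=obj_path,
    )


def _penalty(beta: np.ndarray, slices, df, lam: float) -> float:
    return lam * float(
        sum(np.sqrt(int(df[g])) * np.linalg.norm(beta[sl]) for g, sl in enumerate(slices))
    )


def kkt_violation(fit: GroupLassoFit, encoded: EncodedDataset) -> float:
    """Worst-case violation of the optimality conditions, standardized scale.

    Active groups: || (1/n) X_g'(p - y) + lam*sqrt(df_g)*beta_g/||beta_g|| || ~ 0.
    Inactive groups: || (1/n) X_g'(p - y) || <= lam*sqrt(df_g).
    Intercept: |mean(p - y)| ~ 0.
    """
    _require_standardized(encoded)
    X, y, n = encoded.X, encoded.y, encoded.n
    eta = fit.intercept_std + X @ fit.coef_std
    p = expit(eta)
    worst = abs(float(np.mean(p - y)))
    for g, sl in enumerate(encoded.slices):
        grad = X[:, sl].T @ (p - y) / n
        w = fit.lam * np.sqrt(int(encoded.df[g]))
        bg = fit.coef_std[sl]
        nrm = np.linalg.norm(bg)
        if nrm > 0:
            worst = max(worst, float(np.linalg.norm(grad + w * bg / nrm)))
        else:
            worst = max(worst, float(max(0.0, np.linalg.norm(grad) - w)))
    return worst


@dataclass
class LambdaPath:
    """Warm-started solutions over a decreasing lambda grid."""

    lambdas: np.ndarray
    fits: list
    lambda_max: float

    def coefficient_table(self) -> pd.DataFrame:
        """Tidy per-lambda original-scale coefficients (coefficient-path data)."""
        rows = []
        for lam, fit in zip(self.lambdas, self.fits):
            for name, val in zip(fit.column_names, fit.coef):
                rows.append({"lambda": float(lam), "column": name, "coef": float(val)})
        return pd.DataFrame(rows)

    def group_norm_table(self) -> pd.DataFrame:
        rows = []
        for lam, fit in zip(self.lambdas, self.fits):
            for name, nrm in fit.group_norms.items():
                rows.append({"lambda": float(lam), "group": name, "norm": nrm})
        return pd.DataFrame(rows)


def lambda_grid(lmax: float, n_lambda: int = 100, lambda_min_ratio: float = 0.001) -> np.ndarray:
    if lmax <= 0:
        raise ValueError("lambda_max must be positive to build a grid")
    return lmax * np.logspace(0.0, np.log10(lambda_min_ratio), n_lambda)


def solve_path(
    encoded: EncodedDataset,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.001,
    lambdas=None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    engine: str = "auto",
) -> LambdaPath:
    """Fit the whole regularization path, warm-starting each lambda.

    ``engine="auto"`` uses the compiled kernel when numba is importable,
    ``engine="python"`` forces the reference implementation; both run the
    same group-descent algorithm and agree to within the tolerance.
    """
    from ._solver import HAVE_NUMBA, path_solutions

    _require_standardized(encoded)
    lmax = lambda_max(encoded)
    if lambdas is None:
        lambdas = lambda_grid(lmax, n_lambda, lambda_min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)

    if engine == "python" or (engine == "auto" and not HAVE_NUMBA):
        fits = []
        warm = None
        for lam in lambdas:
            fit = fit_group_lasso(encoded, lam, tol=tol, max_iter=max_iter, warm_start=warm)
            warm = (fit.intercept_std, fit.coef_std)
            fits.append(fit)
        return LambdaPath(lambdas=lambdas, fits=fits, lambda_max=float(lmax))

    slices = encoded.slices
    starts = np.array([sl.start for sl in slices])
    ends = np.array([sl.stop for sl in slices])
    ybar = float(np.clip(encoded.y.mean(), 1e-12, 1 - 1e-12))
    b0s, betas, iters, conv = path_solutions(
        encoded.X,
        encoded.y,
        starts,
        ends,
        np.sqrt(encoded.df.astype(float)),
        lambdas,
        tol,
        max_iter,
        float(logit(ybar)),
        np.zeros(encoded.p),
    )
    fits = []
    for l, lam in enumerate(lambdas):
        b0, beta = float(b0s[l]), betas[l]
        obj = _nll(encoded.y, b0 + encoded.X @ beta) + _penalty(beta, slices, encoded.df, lam)
        b0_orig, beta_orig = encoded.standardization.to_original(b0, beta, slices)
        fits.append(
            GroupLassoFit(
                intercept=b0_orig,
                coef=beta_orig,
                intercept_std=b0,
                coef_std=beta.copy(),
                lam=float(lam),
                objective=obj,
                n_iter=int(iters[l]),
                converged=bool(conv[l]),
                group_names=list(encoded.group_names),
                slices=slices,
                df=encoded.df,
                column_names=list(encoded.column_names),
            )
        )
    return LambdaPath(lambdas=lambdas, fits=fits, lambda_max=float(lmax))


@dataclass
class LogisticMLEFit:
    """Unpenalized logistic reference fit with Wald inference."""

    intercept: float
    coef: np.ndarray
    column_names: list
    se: np.ndarray
    z: np.ndarray
    p_values: np.ndarray
    converged: bool
    llf: float

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def summary_table(self) -> pd.DataFrame:
        lo = np.exp(self.coef - 1.96 * self.se)
        hi = np.exp(self.coef + 1.96 * self.se)
        return pd.DataFrame(
            {
                "column": self.column_names,
                "coef": self.coef,
                "se": self.se,
                "z": self.z,
                "p_value": self.p_values,
                "odds_ratio": self.odds_ratios,
                "ci_low": lo,
                "ci_high": hi,
            }
        )


def fit_logistic_mle(encoded: EncodedDataset) -> LogisticMLEFit:
    """Newton/IRLS maximum likelihood on the (unstandardized) design.

    Raises :class:`SeparationError` when the likelihood has no finite
    maximizer (quasi-separated data).
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    if encoded.standardization is not None:
        raise ValueError("fit the MLE on the unstandardized encoding")
    if encoded.n <= encoded.p:
        raise ValueError("MLE needs n > p")
    import warnings

    Xc = sm.add_constant(encoded.X, has_constant="add")
    model = sm.Logit(encoded.y, Xc)
    try:
        with warnings.catch_warnings():
            # the Newton attempt may warn before the L-BFGS retry succeeds;
            # convergence is judged from mle_retvals below
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200, method="newton")
            if not res.mle_retvals.get("converged", False):
                res = model.fit(disp=0, maxiter=5000, method="lbfgs")
    except (PerfectSeparationError, np.linalg.LinAlgError) as e:
        raise SeparationError(
            "logistic MLE diverged (separation); use the penalized fit"
        ) from e
    params = np.asarray(res.params, dtype=float)
    if not res.mle_retvals.get("converged", False) or np.max(np.abs(params)) > 50:
        raise SeparationError(
            "logistic MLE did not converge (possible separation); use the penalized fit"
        )
    se = np.asarray(res.bse, dtype=float)
    return LogisticMLEFit(
        intercept=float(params[0]),
        coef=params[1:],
        column_names=list(encoded.column_names),
        se=se[1:],
        z=np.asarray(res.tvalues, dtype=float)[1:],
        p_values=np.asarray(res.pvalues, dtype=float)[1:],
        converged=True,
        llf=float(res.llf),
    )
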