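"""Association models: ZINB race x BV interaction tests and elastic nets.

Two model families link the microbiota to host variables:

* Per-taxon zero-inflated negative binomial (ZINB) regressions of read
  counts on race, BV status and their interaction. The zero component is
  intercept-only (every zero count has the same probability of belonging
  to it); the count component uses a log link with NB dispersion theta. A
  likelihood-ratio test compares the full model against the reduced model
  without the interaction, with Benjamini-Hochberg adjustment across taxa.

* Elastic-net linear models of each Amsel clinical sign on the
  log-transformed counts of all taxa, fit by cyclic coordinate descent
  over a log-spaced penalty path with the penalty chosen by k-fold
  cross-validation; taxa with non-zero coefficients at the selected
  penalty are reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix
from .errors import DataError, ParameterError

# ---------------------------------------------------------------------------
# ZINB
# ---------------------------------------------------------------------------


def _nb_logpmf(y: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    return (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1.0)
        + theta * (np.log(theta) - np.log(theta + mu))
        + y * (np.log(mu) - np.log(theta + mu))
    )


def zinb_loglik(
    beta: np.ndarray, pi: float, theta: float, y: np.ndarray, X: np.ndarray
) -> float:
    """Log-likelihood of the intercept-only-zero-component ZINB model.

    l = sum_i log[ pi * 1{y_i = 0} + (1 - pi) * NB(y_i; mu_i, theta) ]
    with mu_i = exp(x_i' beta); pi is constant across observations.
    """
    if theta <= 0:
        raise ParameterError("theta must be positive")
    if not (0.0 <= pi < 1.0):
        raise ParameterError("pi must lie in [0, 1)")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    mu = np.exp(np.clip(X @ beta, -30.0, 30.0))
    nb = _nb_logpmf(y, mu, theta)
    ll = np.where(
        y == 0,
        np.logaddexp(
            np.log(pi) if pi > 0 else -np.inf,
            math.log1p(-pi) + nb,
        ),
        math.log1p(-pi) + nb,
    )
    return float(ll.sum())


@dataclass
class ZinbFit:
    """A fitted ZINB model."""

    beta: np.ndarray
    pi: float
    theta: float
    loglik: float
    converged: bool
    start_used: int = 0


def fit_zinb(y: Sequence[int], X: np.ndarray, rel_tol: float = 1e-8) -> ZinbFit:
    """Maximize the ZINB likelihood by multi-start quasi-Newton search.

    Starts combine a moment estimate of beta (least squares on
    log(y + 0.5)) and theta with zero-inflation starts pi in {0.1, 0.5}.
    The best converged start wins; if no start converges the best fit is
    returned flagged so callers can exclude it.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < p + 3:
        raise ParameterError("need n >= p + 3 observations")
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise DataError("y must be nonnegative integers")

    beta0, *_ = np.linalg.lstsq(X, np.log(y + 0.5), rcond=None)
    m, v = y.mean(), y.var()
    theta0 = m * m / (v - m) if v > m > 0 else 1.0
    theta0 = float(np.clip(theta0, 0.1, 10.0))

    def negll(params: np.ndarray) -> float:
        beta = params[:p]
        theta = math.exp(min(max(params[p], -12.0), 12.0))
        pi = 1.0 / (1.0 + math.exp(-min(max(params[p + 1], -30.0), 30.0)))
        pi = min(max(pi, 1e-10), 1.0 - 1e-10)
        return -zinb_loglik(beta, pi, theta, y, X)

    best: Optional[ZinbFit] = None
    for k, pi0 in enumerate((0.1, 0.5)):
        x0 = np.concatenate([beta0, [math.log(theta0)], [math.log(pi0 / (1 - pi0))]])
        res = optimize.minimize(
            negll, x0, method="L-BFGS-B",
            options={"ftol": rel_tol, "gtol": 1e-7, "maxiter": 500},
        )
        fit = ZinbFit(
            beta=res.x[:p],
            pi=float(1.0 / (1.0 + math.exp(-min(max(res.x[p + 1], -30.0), 30.0)))),
            theta=float(math.exp(min(max(res.x[p], -12.0), 12.0))),
            loglik=float(-res.fun),
            converged=bool(res.success),
            start_used=k,
        )
        if best is None or (fit.converged and not best.converged) or (
            fit.converged == best.converged and fit.loglik > best.loglik
        ):
            best = fit
    return best


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotonicity enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ParameterError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def interaction_lrt(
    matrix: CountMatrix,
    meta: pd.DataFrame,
    bv_definition: str = "nugent",
    race_levels: Tuple[str, str] = ("White", "Black"),
    min_nonzero: int = 10,
) -> pd.DataFrame:
    """Per-taxon ZINB likelihood-ratio test of the race x BV interaction.

    Full model: log mu = b0 + b_race + b_BV + b_{race x BV}; the reduced
    model drops the interaction. D = 2(l_full - l_reduced) ~ chi2(1).
    Samples outside the two contrasted race levels are excluded; taxa with
    fewer than ``min_nonzero`` nonzero counts, an all-zero race x BV cell,
    or a non-converged fit are skipped with a reason. q-values are BH
    adjusted over the tested taxa.
    """
    m = meta.set_index("sample_id").loc[matrix.samples]
    if bv_definition == "nugent":
        bv = (m["nugent"] >= 7).astype(int).to_numpy()
    elif bv_definition == "amsel":
        bv = m["bv_amsel"].astype(int).to_numpy()
    else:
        raise ParameterError("bv_definition must be 'nugent' or 'amsel'")
    race_raw = m["race"].to_numpy()
    keep = np.isin(race_raw, race_levels)
    if keep.sum() < 12:
        raise DataError("too few samples in the contrasted race levels")
    race = (race_raw[keep] == race_levels[1]).astype(int)
    bv = bv[keep]
    counts = matrix.counts.to_numpy()[keep]

    x_full = np.column_stack([np.ones(len(race)), race, bv, race * bv])
    x_red = x_full[:, :3]
    rows = []
    for t, taxon in enumerate(matrix.taxa):
        y = counts[:, t]
        row = {"taxon": taxon, "deviance": np.nan, "df": 1, "p": np.nan,
               "interaction": np.nan, "reason": ""}
        if (y > 0).sum() < min_nonzero:
            row["reason"] = "too_few_nonzero"
            rows.append(row)
            continue
        cells_ok = all(
            y[(race == r) & (bv == b)].sum() > 0
            for r in (0, 1) for b in (0, 1)
        )
        if not cells_ok:
            row["reason"] = "all_zero_cell"
            rows.append(row)
            continue
        full = fit_zinb(y, x_full)
        red = fit_zinb(y, x_red)
        if not (full.converged and red.converged):
            row["reason"] = "non_convergence"
            warnings.warn(f"taxon {taxon}: ZINB did not converge; excluded")
            rows.append(row)
            continue
        d = max(0.0, 2.0 * (full.loglik - red.loglik))
        row.update({
            "deviance": d,
            "p": float(stats.chi2.sf(d, 1)),
            "interaction": float(full.beta[3]),
        })
        rows.append(row)
    table = pd.DataFrame(rows)
    tested = table["reason"] == ""
    table["q"] = np.nan
    if tested.any():
        table.loc[tested, "q"] = bh_adjust(table.loc[tested, "p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# Elastic net
# ---------------------------------------------------------------------------


def _soft(z: float, g: float) -> float:
    return math.copysign(max(abs(z) - g, 0.0), z)


def _enet_objective(xs, yc, beta, lam, alpha):
    n = len(yc)
    resid = yc - xs @ beta
    return (
        0.5 / n * float(resid @ resid)
        + lam * (alpha * float(np.abs(beta).sum())
                 + 0.5 * (1 - alpha) * float(beta @ beta))
    )


def _coordinate_descent(
    xs: np.ndarray,
    yc: np.ndarray,
    lam: float,
    alpha: float,
    beta: np.ndarray,
    tol: float = 1e-7,
    max_sweeps: int = 1000,
    check_monotone: bool = True,
) -> np.ndarray:
    """Cyclic coordinate descent on the standardized elastic-net problem.

    The penalized objective is checked to be non-increasing across sweeps
    (an invariant of exact coordinate minimization).
    """
    n, p = xs.shape
    col_ss = (xs * xs).sum(axis=0) / n
    resid = yc - xs @ beta
    prev_obj = _enet_objective(xs, yc, beta, lam, alpha)
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            if col_ss[j] == 0.0:
                continue
            bj = beta[j]
            rho = (xs[:, j] @ resid) / n + col_ss[j] * bj
            new = _soft(rho, lam * alpha) / (col_ss[j] + lam * (1 - alpha))
            if new != bj:
                resid += xs[:, j] * (bj - new)
                beta[j] = new
                max_delta = max(max_delta, abs(new - bj))
        if check_monotone:
            obj = _enet_objective(xs, yc, beta, lam, alpha)
            if obj > prev_obj + 1e-10:
                raise AssertionError("coordinate descent objective increased")
            prev_obj = obj
        if max_delta < tol:
            break
    return beta


@dataclass
class SignModelResult:
    """A fitted, cross-validated elastic-net sign model."""

    criterion: str
    alpha: float
    selected_lambda: float
    coefficients: pd.Series        # all taxa, original scale
    intercept: float
    cv_curve: pd.DataFrame         # lambda, mean CV MSE, se
    selection_rule: str = "min"

    @property
    def nonzero(self) -> pd.Series:
        return self.coefficients[self.coefficients != 0.0]


def _lambda_path(xs, yc, alpha, n_lambda, min_ratio):
    n = len(yc)
    lam_max = float(np.max(np.abs(xs.T @ yc)) / (n * max(alpha, 1e-3)))
    lam_max = max(lam_max, 1e-10)
    return np.logspace(math.log10(lam_max), math.log10(lam_max * min_ratio), n_lambda)


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def elasticnet_fit(
    X: pd.DataFrame,
    y: Sequence[float],
    alpha: float = 0.5,
    lambda_path: Optional[np.ndarray] = None,
    k_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    standardize: bool = True,
    selection_rule: str = "min",
    criterion: str = "sign",
) -> SignModelResult:
    """Cross-validated elastic-net linear model of a clinical sign.

    ``X`` holds log-transformed counts (one column per taxon) and is
    standardized internally; ``y`` is the sign (pH as a real value, binary
    signs as 0/1, modeled with the squared-error objective either way).
    The penalty is chosen on a log-spaced path by k-fold CV (fold
    assignment seeded, stratified on y for binary signs); ``'1se'``
    selects the sparsest penalty within one standard error of the
    minimum. Coefficients are reported on the original scale.
    """
    if not (0.0 < alpha <= 1.0):
        raise ParameterError("alpha must lie in (0, 1]")
    if selection_rule not in ("min", "1se"):
        raise ParameterError("selection_rule must be 'min' or '1se'")
    taxa = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if k_folds > n:
        raise ParameterError("k_folds cannot exceed the number of samples")
    if k_folds < 2:
        raise ParameterError("k_folds must be >= 2")

    def prepare(xm):
        if standardize:
            return _standardize(xm)
        return xm, np.zeros(xm.shape[1]), np.ones(xm.shape[1])

    xs_all, mean_all, sd_all = prepare(Xv)
    yc_all = yv - yv.mean()
    if lambda_path is None:
        lambda_path = _lambda_path(xs_all, yc_all, alpha, n_lambda, lambda_min_ratio)
    lambda_path = np.asarray(sorted(lambda_path, reverse=True), dtype=float)

    # seeded, optionally stratified fold assignment
    rng = np.random.default_rng(seed)
    binary = set(np.unique(yv)) <= {0.0, 1.0}
    folds = np.empty(n, dtype=int)
    if binary:
        for value in (0.0, 1.0):
            idx = np.flatnonzero(yv == value)
            rng.shuffle(idx)
            folds[idx] = np.arange(len(idx)) % k_folds
    else:
        idx = rng.permutation(n)
        folds[idx] = np.arange(n) % k_folds

    errors = np.zeros((k_folds, len(lambda_path)))
    for f in range(k_folds):
        train, test = folds != f, folds == f
        if test.sum() == 0 or train.sum() < 2:
            raise ParameterError("a CV fold is empty; reduce k_folds")
        xs_tr, mean_tr, sd_tr = prepare(Xv[train])
        ybar = yv[train].mean()
        yc_tr = yv[train] - ybar
        xs_te = (Xv[test] - mean_tr) / sd_tr
        beta = np.zeros(Xv.shape[1])
        for li, lam in enumerate(lambda_path):
            beta = _coordinate_descent(xs_tr, yc_tr, lam, alpha, beta)
            pred = ybar + xs_te @ beta
            errors[f, li] = float(np.mean((yv[test] - pred) ** 2))
    mean_err = errors.mean(axis=0)
    se_err = errors.std(axis=0, ddof=1) / math.sqrt(k_folds)
    i_min = int(np.argmin(mean_err))
    if selection_rule == "1se":
        ok = np.flatnonzero(mean_err <= mean_err[i_min] + se_err[i_min])
        i_sel = int(ok[0])  # path is decreasing: first index = largest penalty
    else:
        i_sel = i_min
    lam_sel = float(lambda_path[i_sel])

    beta = np.zeros(Xv.shape[1])
    for lam in lambda_path[: i_sel + 1]:  # warm start down to the selection
        beta = _coordinate_descent(xs_all, yc_all, lam, alpha, beta)
    coef = beta / sd_all
    intercept = float(yv.mean() - coef @ mean_all)
    cv_curve = pd.DataFrame({"lambda": lambda_path, "cv_mse": mean_err, "se": se_err})
    return SignModelResult(
        criterion=criterion,
        alpha=alpha,
        selected_lambda=lam_sel,
        coefficients=pd.Series(coef, index=taxa, name=criterion),
        intercept=intercept,
        cv_curve=cv_curve,
        selection_rule=selection_rule,
    )


CLUE_NUMERIC = {"none": 0.0, "<20%": 1.0, ">20%": 2.0}


def sign_association_table(
    matrix: CountMatrix,
    meta: pd.DataFrame,
    alpha: float = 0.5,
    k_folds: int = 10,
    seed: int = 0,
    pseudocount: float = 0.5,
    **kwargs,
) -> Tuple[Dict[str, SignModelResult], pd.DataFrame]:
    """Elastic-net models for each Amsel sign plus the composite diagnosis.

    Returns the per-criterion fits and a cross-criterion membership table
    (taxa x criteria signed coefficients with a count of the four signs
    each taxon associates with).
    """
    m = meta.set_index("sample_id").loc[matrix.samples]
    signs = {
        "ph": m["ph"].astype(float).to_numpy(),
        "amsel_whiff": m["amsel_whiff"].astype(float).to_numpy(),
        "clue_cells": m["clue_cells"].map(CLUE_NUMERIC).to_numpy(dtype=float),
        "amsel_discharge": m["amsel_discharge"].astype(float).to_numpy(),
        "bv_amsel": m["bv_amsel"].astype(float).to_numpy(),
    }
    for name, vec in signs.items():
        if np.isnan(vec).any():
            raise DataError(f"sign column {name} has missing values")
    logX = pd.DataFrame(
        np.log(matrix.counts.to_numpy(dtype=float) + pseudocount),
        index=matrix.samples, columns=matrix.taxa,
    )
    fits = {}
    for i, (name, vec) in enumerate(signs.items()):
        fits[name] = elasticnet_fit(
            logX, vec, alpha=alpha, k_folds=k_folds, seed=seed + i,
            criterion=name, **kwargs,
        )
    four = ["ph", "amsel_whiff", "clue_cells", "amsel_discharge"]
    member = pd.DataFrame({name: fits[name].coefficients for name in signs})
    member["n_criteria"] = (member[four] != 0).sum(axis=1)
    member = member[member.drop(columns="n_criteria").ne(0).any(axis=1)]
    return fits, member
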