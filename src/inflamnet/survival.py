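"""Cox proportional-hazards screening, risk scoring and survival comparison.

Interface genes are screened one at a time with univariate Cox regression on
standardized expression; genes whose high expression increases hazard
(HR > 1, p < 0.05) enter a multivariate Cox model.  The linear predictor
sum(beta_g * expr_g) is each sample's risk score; samples are split at the
median score (ties to the low-risk group) and compared with a log-rank test
and Kaplan-Meier curves.

The Cox engine maximizes the Breslow partial likelihood by Newton's method
with step halving, to gradient norm < 1e-8; a small ridge penalty (1e-6) is
the fallback for collinear covariates.  Kaplan-Meier estimation, the
log-rank test and Harrell's concordance index come from lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index
from scipy import stats

logger = logging.getLogger(__name__)

MAX_ITER = 100
GTOL = 1e-8
RIDGE = 1e-6


class ConvergenceError(RuntimeError):
    pass


def _breslow_neg_loglik(beta, x, time, event, ridge=0.0):
    """Negative Breslow log partial likelihood with gradient and Hessian.

    Samples are assumed sorted by ascending time; ties share a risk set.
    """
    n, p = x.shape
    eta = x @ beta
    w = np.exp(eta)
    # suffix sums over the risk set {j : t_j >= t_i}
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * x)[::-1], axis=0)[::-1]
    s2 = np.cumsum((w[:, None, None] * x[:, :, None] * x[:, None, :])[::-1], axis=0)[
        ::-1
    ]
    # Breslow: tied event times use the risk set at the first index of the tie
    first = np.zeros(n, dtype=int)
    for i in range(1, n):
        first[i] = first[i - 1] if time[i] == time[i - 1] else i
    ev = event.astype(bool)
    f = first[ev]
    ll = eta[ev].sum() - np.log(s0[f]).sum()
    grad = x[ev].sum(axis=0) - (s1[f] / s0[f, None]).sum(axis=0)
    mean = s1[f] / s0[f, None]
    hess = -(s2[f] / s0[f, None, None]).sum(axis=0) + np.einsum(
        "ij,ik->jk", mean, mean
    )
    if ridge > 0:
        ll -= 0.5 * ridge * beta @ beta
        grad -= ridge * beta
        hess -= ridge * np.eye(p)
    return -ll, -grad, -hess


def _newton_cox(x, time, event, ridge=0.0):
    order = np.argsort(time, kind="mergesort")
    xs, ts, es = x[order], time[order], event[order]
    beta = np.zeros(x.shape[1])
    nll, grad, hess = _breslow_neg_loglik(beta, xs, ts, es, ridge)
    for _ in range(MAX_ITER):
        if np.linalg.norm(grad) < GTOL:
            cov = np.linalg.inv(hess)
            return beta, cov
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            raise ConvergenceError("singular Hessian") from None
        # step halving
        t = 1.0
        for _ in range(40):
            cand = beta - t * step
            c_nll, c_grad, c_hess = _breslow_neg_loglik(cand, xs, ts, es, ridge)
            if c_nll <= nll + 1e-12:
                beta, nll, grad, hess = cand, c_nll, c_grad, c_hess
                break
            t /= 2
        else:
            raise ConvergenceError("step halving failed")
        if np.abs(beta).max() > 50:
            raise ConvergenceError(
                "monotone likelihood (perfect separation) suspected"
            )
    raise ConvergenceError(f"no convergence in {MAX_ITER} iterations")


def fit_cox(
    covariates: np.ndarray, time: np.ndarray, event: np.ndarray, ridge: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a Cox model; returns (beta, covariance). Ridge fallback on failure."""
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    if x.shape[0] != len(time):
        x = x.T
    try:
        return _newton_cox(x, np.asarray(time, float), np.asarray(event, int), ridge)
    except ConvergenceError:
        if ridge > 0:
            raise
        logger.warning("Cox fit failed; retrying with ridge penalty %g", RIDGE)
        return _newton_cox(x, np.asarray(time, float), np.asarray(event, int), RIDGE)


def cox_univariate(expression: pd.Series, survival: pd.DataFrame) -> dict:
    """Univariate Cox fit of one standardized covariate.

    Returns beta, HR = exp(beta), SE and the Wald p-value.  Requires >= 10
    events and a non-constant covariate.
    """
    shared = expression.index.intersection(survival.index)
    x = expression.loc[shared].to_numpy(dtype=float)
    surv = survival.loc[shared]
    if surv["event"].sum() < 10:
        raise ValueError("fewer than 10 events")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    x = (x - x.mean()) / x.std()
    beta, cov = fit_cox(
        x[:, None], surv["time"].to_numpy(), surv["event"].to_numpy()
    )
    se = float(np.sqrt(cov[0, 0]))
    b = float(beta[0])
    p = 2 * stats.norm.sf(abs(b) / se)
    return {"beta": b, "hr": float(np.exp(b)), "se": se, "pvalue": float(p)}


def screen_genes(
    expr: pd.DataFrame, genes: list[str], survival: pd.DataFrame
) -> pd.DataFrame:
    """Univariate Cox screen of a gene list; one row per testable gene."""
    rows = []
    for g in genes:
        if g not in expr.index:
            logger.warning("gene %s not in expression; skipped", g)
            continue
        try:
            res = cox_univariate(expr.loc[g], survival)
        except (ValueError, ConvergenceError) as exc:
            logger.warning("gene %s: %s; skipped", g, exc)
            continue
        rows.append({"gene": g, **res})
    return pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["beta", "hr", "se", "pvalue"]
    )


def select_risk_genes(results: pd.DataFrame, p_threshold: float = 0.05) -> list[str]:
    """Genes whose high expression increases hazard: HR > 1 and p < threshold,
    sorted by ascending p."""
    if results.empty:
        raise ValueError("no univariate results to select from")
    hits = results[(results["hr"] > 1.0) & (results["pvalue"] < p_threshold)]
    return list(hits.sort_values("pvalue").index)


@dataclass
class RiskModel:
    genes: list[str]
    betas: np.ndarray
    se: np.ndarray
    concordance: float
    scores: pd.Series

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.betas)

    def score(self, expr: pd.DataFrame) -> pd.Series:
        x = expr.loc[self.genes].to_numpy(dtype=float)
        x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        return pd.Series(self.betas @ x, index=expr.columns, name="risk_score")


def fit_risk_model(
    genes: list[str], expr: pd.DataFrame, survival: pd.DataFrame
) -> RiskModel:
    """Multivariate Cox fit of selected genes; risk score = sum(beta * expr).

    Expression is standardized per gene so hazard ratios are per SD.  Reports
    Harrell's concordance index on the training data.
    """
    if not genes:
        raise ValueError("gene list is empty")
    shared = expr.columns.intersection(survival.index)
    if len(shared) < 10 * len(genes):
        logger.warning(
            "%d samples for %d genes (< 10x rule of thumb)", len(shared), len(genes)
        )
    x = expr.loc[genes, shared].to_numpy(dtype=float)
    sd = x.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("constant gene among model covariates")
    x = (x - x.mean(axis=1, keepdims=True)) / sd
    surv = survival.loc[shared]
    beta, cov = fit_cox(x.T, surv["time"].to_numpy(), surv["event"].to_numpy())
    scores = pd.Series(beta @ x, index=shared, name="risk_score")
    cindex = concordance_index(surv["time"], -scores, surv["event"])
    return RiskModel(
        genes=list(genes),
        betas=beta,
        se=np.sqrt(np.diag(cov)),
        concordance=float(cindex),
        scores=scores,
    )


def stratify_and_compare(
    scores: pd.Series, survival: pd.DataFrame
) -> tuple[pd.Series, float, float, pd.DataFrame]:
    """Median-split risk stratification with a log-rank comparison.

    High-risk group: score > median; ties go to the low-risk group.  Returns
    (group labels, log-rank statistic, p, Kaplan-Meier survival table with
    one column per group).
    """
    shared = scores.index.intersection(survival.index)
    sc = scores.loc[shared]
    med = float(sc.median())
    labels = pd.Series(
        np.where(sc > med, "high", "low"), index=shared, name="risk_group"
    )
    if labels.nunique() < 2:
        raise ValueError("all scores equal: no median split possible")
    if (labels == "high").sum() < 2 or (labels == "low").sum() < 2:
        raise ValueError("fewer than 2 samples in a risk group after split")
    surv = survival.loc[shared]
    hi, lo = labels == "high", labels == "low"
    lr = logrank_test(
        surv.loc[hi.values, "time"],
        surv.loc[lo.values, "time"],
        event_observed_A=surv.loc[hi.values, "event"],
        event_observed_B=surv.loc[lo.values, "event"],
    )
    km_cols = {}
    for name, mask in (("high", hi), ("low", lo)):
        kmf = KaplanMeierFitter()
        kmf.fit(surv.loc[mask.values, "time"], surv.loc[mask.values, "event"])
        km_cols[name] = kmf.survival_function_.iloc[:, 0]
    km = pd.DataFrame(km_cols).sort_index().ffill()
    km.index.name = "time"
    return labels, float(lr.test_statistic), float(lr.p_value), km
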