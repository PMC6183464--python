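"""Environmental correlates of introgression: hierarchical logistic models.

Models the probability that a wild-caught fish is introgressed as a
function of site- and watershed-level covariates, with sample site as a
random intercept.  Fish that assigned to pure hatchery origin are expected
to have been removed before fitting.  Candidate covariate sets (multiscale,
site-level, watershed-level, literature-supported) are compared by AICc and
the best-supported models are combined by Akaike-weight averaging.

The marginal likelihood integrates the random intercept out by adaptive
Gauss-Hermite quadrature: for each site the integrand is recentred on its
conditional mode (found by Newton steps) and rescaled by the local
curvature before applying the Hermite rule, so a modest number of nodes
(default 9) is accurate even for unbalanced sites.

Covariates are z-scored with the sample (n-1) standard deviation; pairs
with |Pearson r| above the collinearity cutoff (default 0.7) may not enter
the same model — the first-listed covariate of a flagged pair is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize

__all__ = [
    "SITE_COVARIATES", "WATERSHED_COVARIATES", "DEFAULT_MODEL_SETS",
    "prepare_covariates", "screen_model_covariates", "CandidateModel",
    "fit_logistic_mixed", "fit_candidate_models", "ModelComparison",
    "compare_and_average",
]

SITE_COVARIATES = (
    "temperature", "dissolved_oxygen", "conductivity", "hardness",
    "total_alkalinity", "pH", "stream_width", "adult_density",
)
WATERSHED_COVARIATES = ("watershed_area", "distance_to_stocking")
# land use is excluded from every candidate set by default (nearly constant
# across forested sites)
DEFAULT_MODEL_SETS = {
    "multiscale": list(SITE_COVARIATES) + list(WATERSHED_COVARIATES),
    "site_level": list(SITE_COVARIATES),
    "watershed_level": list(WATERSHED_COVARIATES),
    "literature_supported": [
        "temperature", "pH", "adult_density", "stream_width",
        "watershed_area",
    ],
}


def prepare_covariates(raw: pd.DataFrame, r_cut: float = 0.7):
    """Z-score covariate columns and flag collinear pairs.

    ``raw`` has one row per site (site id as index or a ``site`` column).
    Returns ``(zscored, flagged_pairs)``; ``flagged_pairs`` lists column
    pairs with |Pearson r| > ``r_cut`` (in column order).  A constant
    column cannot be z-scored and raises.
    """
    table = raw.set_index("site") if "site" in raw.columns else raw.copy()
    num = table.select_dtypes("number")
    sd = num.std(ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        raise ValueError(f"constant columns cannot be z-scored: {constant}")
    z = (num - num.mean()) / sd
    corr = z.corr()
    cols = list(z.columns)
    flagged = [
        (cols[i], cols[j])
        for i in range(len(cols))
        for j in range(i + 1, len(cols))
        if abs(corr.iloc[i, j]) > r_cut
    ]
    return z, flagged


def screen_model_covariates(covariates: list[str], flagged_pairs) -> tuple:
    """Apply the collinearity policy to one candidate model's list.

    Of a flagged pair present in the list, the first-listed covariate is
    retained and the other dropped.  Returns ``(kept, dropped)``.
    """
    dropped = []
    kept = []
    for name in covariates:
        clash = any(
            (a == name and b in kept) or (b == name and a in kept)
            for a, b in flagged_pairs
        )
        (dropped if clash else kept).append(name)
    return kept, dropped


# ---------------------------------------------------------------------------
# random-intercept logistic likelihood (adaptive Gauss-Hermite)
# ---------------------------------------------------------------------------

def _site_loglik(eta, y, sigma, nodes, weights):
    """log marginal likelihood of one site's responses.

    ``eta`` is the fixed-effect linear predictor for the site's fish.
    Integrates over u ~ N(0, sigma^2) after recentring on the conditional
    mode (Newton) and rescaling by the curvature there.
    """
    if sigma < 1e-8:
        lp = eta * y - np.logaddexp(0.0, eta)
        return float(lp.sum())
    # Newton search for the mode of h(v) = sum_i log p(y_i | eta_i + sigma v)
    # - v^2/2, v standard normal
    v_hat = 0.0
    hess = -1.0
    for _ in range(50):
        mu = 1.0 / (1.0 + np.exp(-(eta + sigma * v_hat)))
        grad = sigma * float((y - mu).sum()) - v_hat
        hess = -(sigma**2) * float((mu * (1 - mu)).sum()) - 1.0
        v_new = v_hat - grad / hess
        if abs(v_new - v_hat) < 1e-10:
            v_hat = v_new
            break
        v_hat = v_new
    mu = 1.0 / (1.0 + np.exp(-(eta + sigma * v_hat)))
    hess = -(sigma**2) * float((mu * (1 - mu)).sum()) - 1.0
    s = 1.0 / np.sqrt(-hess)
    # adaptive rule: int e^h dv ~= sqrt(2) s sum_t w_t e^{x_t^2} e^{h(v_t)}
    v = v_hat + np.sqrt(2.0) * s * nodes
    lin = eta[None, :] + sigma * v[:, None]
    lp = (lin * y[None, :] - np.logaddexp(0.0, lin)).sum(axis=1)
    h = lp - 0.5 * v**2
    m = h.max()
    log_int = m + np.log(np.sum(weights * np.exp(h - m + nodes**2)))
    return float(log_int + np.log(np.sqrt(2.0) * s) - 0.5 * np.log(2.0 * np.pi))


def _total_loglik(params, X, y, site_idx, n_sites, nodes, weights):
    beta = params[:-1]
    sigma = np.exp(params[-1])
    eta = X @ beta
    total = 0.0
    for j in range(n_sites):
        m = site_idx == j
        total += _site_loglik(eta[m], y[m], sigma, nodes, weights)
    return total


@dataclass
class CandidateModel:
    """A fitted hierarchical logistic model for one covariate set."""

    name: str
    covariates: list[str]
    dropped: list[str]
    coefficients: pd.DataFrame      # estimate, se, ci_low, ci_high per term
    sigma_site: float               # random-intercept SD
    log_likelihood: float
    k: int                          # fixed effects (incl. intercept) + 1
    n: int
    aic: float
    aicc: float
    marginal_r2: float
    converged: bool = True
    penalized: bool = False

    @property
    def beta(self) -> pd.Series:
        return self.coefficients["estimate"]


def fit_logistic_mixed(
    y, X: pd.DataFrame, site, n_nodes: int = 9, ridge: float = 0.0
):
    """Maximum-likelihood logistic regression with a site random intercept.

    Returns ``(beta_series, se_series, sigma, loglik, converged, penalized)``
    where the design gains an intercept column.  ``ridge > 0`` adds a small
    quadratic penalty on the coefficients (the fallback under complete
    separation; the reported log-likelihood is still the unpenalized one).
    """
    y = np.asarray(y, dtype=float)
    sites, site_idx = np.unique(np.asarray(site), return_inverse=True)
    Xd = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    names = ["intercept"] + list(X.columns)
    nodes, weights = hermgauss(n_nodes)

    def negll(params):
        val = -_total_loglik(params, Xd, y, site_idx, len(sites), nodes, weights)
        if ridge > 0:
            val += 0.5 * ridge * float(params[:-1] @ params[:-1])
        return val

    x0 = np.zeros(Xd.shape[1] + 1)
    x0[-1] = np.log(0.5)
    res = optimize.minimize(negll, x0, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-6})
    # BFGS can report precision loss at a flat optimum (e.g. the sigma -> 0
    # boundary); accept any stationary point with a small gradient
    grad_ok = res.jac is not None and np.max(np.abs(res.jac)) < 1e-2
    converged = (bool(res.success) or grad_ok) and np.all(
        np.abs(res.x[:-1]) < 15
    )
    penalized = False
    if not converged and ridge == 0.0:
        # separation fallback: weak ridge stabilises the fit
        return fit_logistic_mixed(y, X, site, n_nodes, ridge=1e-2)
    if ridge > 0:
        penalized = True
    params = res.x
    loglik = _total_loglik(params, Xd, y, site_idx, len(sites), nodes, weights)

    # observed information by central finite differences
    p = len(params)
    hess = np.zeros((p, p))
    h = 1e-4
    for a in range(p):
        for b in range(a, p):
            pp = params.copy(); pp[a] += h; pp[b] += h
            pm = params.copy(); pm[a] += h; pm[b] -= h
            mp = params.copy(); mp[a] -= h; mp[b] += h
            mm = params.copy(); mm[a] -= h; mm[b] -= h
            hess[a, b] = hess[b, a] = (
                negll(pp) - negll(pm) - negll(mp) + negll(mm)
            ) / (4 * h * h)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))[:-1]
    except np.linalg.LinAlgError:
        se = np.full(p - 1, np.nan)
    beta = pd.Series(params[:-1], index=names)
    se = pd.Series(se, index=names)
    sigma = float(np.exp(params[-1]))
    return beta, se, sigma, float(loglik), converged or penalized, penalized


def fit_candidate_models(
    data: pd.DataFrame,
    covariates: pd.DataFrame,
    model_sets: dict | None = None,
    r_cut: float = 0.7,
    n_nodes: int = 9,
    zscore: bool = True,
) -> list[CandidateModel]:
    """Fit every candidate covariate set to the introgression flags.

    ``data`` needs columns ``site`` and ``introgressed`` (0/1), one row per
    wild-caught fish after removal of hatchery-assigned individuals;
    ``covariates`` one row per site.  ``model_sets`` maps model name ->
    covariate list (defaults to the four standard candidates).  Each set is
    screened for collinearity before fitting.
    """
    if model_sets is None:
        model_sets = {
            name: [c for c in cols if c in covariates.columns]
            for name, cols in DEFAULT_MODEL_SETS.items()
        }
    if zscore:
        z, flagged = prepare_covariates(covariates, r_cut)
    else:
        z = covariates.set_index("site") if "site" in covariates.columns else covariates
        flagged = prepare_covariates(covariates, r_cut)[1]
    missing_sites = set(data["site"]) - set(z.index)
    if missing_sites:
        raise ValueError(f"sites without covariates: {sorted(missing_sites)}")
    y = data["introgressed"].to_numpy(dtype=float)
    n = len(y)
    models = []
    for name, cols in model_sets.items():
        kept, dropped = screen_model_covariates(list(cols), flagged)
        X = z.loc[data["site"], kept].reset_index(drop=True)
        beta, se, sigma, ll, converged, penalized = fit_logistic_mixed(
            y, X, data["site"], n_nodes=n_nodes
        )
        k = len(beta) + 1   # fixed effects (incl. intercept) + RE variance
        aic = -2 * ll + 2 * k
        denom = n - k - 1
        if denom <= 0:
            raise ValueError(
                f"model {name!r}: AICc undefined (n - k - 1 = {denom})"
            )
        aicc = aic + 2 * k * (k + 1) / denom
        eta_fix = beta["intercept"] + (
            np.asarray(X) @ beta.drop("intercept").to_numpy()
            if kept else 0.0
        )
        var_f = float(np.var(eta_fix)) if kept else 0.0
        r2 = var_f / (var_f + sigma**2 + np.pi**2 / 3)
        coef = pd.DataFrame({
            "estimate": beta,
            "se": se,
            "ci_low": beta - 1.959963984540054 * se,
            "ci_high": beta + 1.959963984540054 * se,
        })
        models.append(CandidateModel(
            name=name, covariates=kept, dropped=dropped, coefficients=coef,
            sigma_site=sigma, log_likelihood=ll, k=k, n=n, aic=aic,
            aicc=aicc, marginal_r2=r2, converged=converged,
            penalized=penalized,
        ))
    return models


@dataclass
class ModelComparison:
    """AICc ranking and consensus (averaged) coefficients."""

    table: pd.DataFrame             # name, k, logLik, AICc, dAICc, weight, R2
    consensus: pd.DataFrame         # estimate, unconditional se, CI per term
    averaged_models: list[str] = field(default_factory=list)


def compare_and_average(
    models: list[CandidateModel],
    average_top: int | None = 2,
    delta_cutoff: float | None = None,
) -> ModelComparison:
    """Rank candidate models by AICc and build a consensus model.

    Akaike weights are computed over all models
    (``w_i = exp(-d_i/2) / sum_j exp(-d_j/2)``).  The averaged set is either
    the ``average_top`` best models or all models with ΔAICc ≤
    ``delta_cutoff``; within it, weights are renormalized and coefficients
    averaged with zero substituted for covariates absent from a model (full
    averaging).  Unconditional standard errors follow the usual
    model-averaging formula ``sum_i w_i sqrt(se_i^2 + (b_i - b_avg)^2)``.
    """
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    aiccs = np.array([m.aicc for m in models])
    delta = aiccs - aiccs.min()
    w = np.exp(-delta / 2)
    w = w / w.sum()
    order = np.argsort(aiccs, kind="stable")
    table = pd.DataFrame({
        "model": [models[i].name for i in order],
        "k": [models[i].k for i in order],
        "log_likelihood": [models[i].log_likelihood for i in order],
        "AICc": aiccs[order],
        "dAICc": delta[order],
        "weight": w[order],
        "marginal_R2": [models[i].marginal_r2 for i in order],
    }).set_index("model")

    if delta_cutoff is not None:
        avg_idx = [i for i in order if delta[i] <= delta_cutoff]
    else:
        avg_idx = list(order[: average_top or len(models)])
    w_avg = w[avg_idx] / w[avg_idx].sum()

    terms: list[str] = []
    for i in avg_idx:
        for t in models[i].coefficients.index:
            if t not in terms:
                terms.append(t)
    est = np.zeros(len(terms))
    b_mat = np.zeros((len(avg_idx), len(terms)))
    se_mat = np.zeros((len(avg_idx), len(terms)))
    for r, i in enumerate(avg_idx):
        coef = models[i].coefficients
        for c, t in enumerate(terms):
            if t in coef.index:
                b_mat[r, c] = coef.loc[t, "estimate"]
                se_mat[r, c] = coef.loc[t, "se"]
    est = w_avg @ b_mat
    unc_se = np.array([
        float(w_avg @ np.sqrt(se_mat[:, c] ** 2 + (b_mat[:, c] - est[c]) ** 2))
        for c in range(len(terms))
    ])
    consensus = pd.DataFrame({
        "estimate": est,
        "unconditional_se": unc_se,
        "ci_low": est - 1.959963984540054 * unc_se,
        "ci_high": est + 1.959963984540054 * unc_se,
    }, index=terms)
    return ModelComparison(
        table=table,
        consensus=consensus,
        averaged_models=[models[i].name for i in avg_idx],
    )
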