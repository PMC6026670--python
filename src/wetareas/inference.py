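"""Mixed-effect models against DTW, AICc threshold selection, and
multivariate composition tests.

The core model regresses a plot-level response Y (cover, richness or
diversity, possibly transformed) on the depth-to-water index with the
forest compartment as a random blocking intercept:

    Y_ij = mu + beta * DTW_i + e_j(i),   e_j ~ N(0, sigma_a^2)

Gaussian responses are fitted by REML (reported coefficients and variance
components) with an ML refit supplying the log-likelihood for AICc, so
models fitted to the same response at different flow-initiation
thresholds can be ranked by AICc and its difference Delta from the best
model (Delta < 2: substantial support; 3-7: considerably less; > 10:
very unlikely). Count responses use a Poisson log-link random-intercept
model fitted by maximum likelihood with Gauss-Hermite quadrature over
the compartment effect.

Composition analyses: Bray-Curtis dissimilarities, PERMANOVA with a
continuous covariate (Gower-centered inner-product matrix, 1-df hat
matrix, permutation p), and non-metric multidimensional scaling
reporting Kruskal stress-1.
"""
from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln, logsumexp, polygamma

logger = logging.getLogger(__name__)

__all__ = [
    "ModelFit", "ThresholdSelection", "PermanovaResult", "OrdinationResult",
    "ForestTypeComparison", "aicc", "fit_dtw_model", "select_threshold",
    "compare_forest_types", "bray_curtis", "permanova", "nmds",
]


# ---------------------------------------------------------------- AICc

def aicc(loglik: float, k: int, n: int) -> float:
    """Second-order Akaike information criterion.

    AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); preferred over AIC whenever
    n / k < 40.
    """
    if n <= k + 1:
        raise ValueError(f"AICc needs n > k + 1 (n={n}, k={k})")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------- model fit

@dataclass
class ModelFit:
    """Summary of one fitted DTW mixed model."""

    response: str
    transform: str
    family: str
    intercept: float
    dtw_coef: float
    dtw_se: float
    dtw_stat: float
    dtw_p: float
    var_compartment: float
    var_residual: float
    loglik: float                  # maximum-likelihood log-likelihood
    k: int
    n: int
    aicc: float
    marginal_r2: float
    conditional_r2: float
    converged: bool = True
    n_excluded: int = 0
    metadata: dict = field(default_factory=dict)


def _transform_response(y: np.ndarray, transform: str):
    """Apply the response transform; log drops non-positive values."""
    keep = np.ones(len(y), dtype=bool)
    if transform == "none":
        return y, keep
    if transform == "sqrt":
        if (y < 0).any():
            raise ValueError("sqrt transform needs y >= 0")
        return np.sqrt(y), keep
    if transform == "log":
        keep = y > 0
        return np.log(y[keep]), keep
    raise ValueError(f"unknown transform {transform!r}")


def _fit_gaussian_mixed(y, x, group_codes):
    """REML + ML fits of the random-intercept model via statsmodels."""
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLM

    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reml = MixedLM(y, X, groups=group_codes).fit(
            reml=True, method="powell", maxiter=2000)
        ml = MixedLM(y, X, groups=group_codes).fit(
            reml=False, method="powell", maxiter=2000)
    return reml, ml


def _poisson_glmm_nll(theta, y, X, group_idx, n_groups, nodes, weights):
    """Negative marginal log-likelihood, Gauss-Hermite over the intercept."""
    beta = theta[:-1]
    sigma = np.exp(theta[-1])
    eta = X @ beta
    b = math.sqrt(2.0) * sigma * nodes                        # (K,)
    # per-observation contribution at each node: y*(eta+b) - exp(eta+b)
    eta_k = eta[:, None] + b[None, :]                         # (n, K)
    contrib = y[:, None] * eta_k - np.exp(eta_k)
    per_group = np.zeros((n_groups, len(nodes)))
    np.add.at(per_group, group_idx, contrib)
    log_int = logsumexp(per_group + np.log(weights)[None, :], axis=1) \
        - 0.5 * math.log(math.pi)
    const = gammaln(y + 1).sum()
    return -(log_int.sum() - const)


def _numerical_hessian(f, theta, eps=1e-4):
    p = len(theta)
    H = np.zeros((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = eps
            ej = np.zeros(p); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * eps * eps)
    return H


def _fit_poisson_glmm(y, x, group_idx, n_groups, n_nodes=30):
    """ML Poisson random-intercept fit by Gauss-Hermite quadrature."""
    import statsmodels.api as sm
    from scipy.optimize import minimize

    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start_glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    theta0 = np.r_[start_glm.params, np.log(0.3)]
    obj = lambda th: _poisson_glmm_nll(th, y, X, group_idx, n_groups,
                                       nodes, weights)
    res = minimize(obj, theta0, method="BFGS",
                   options={"gtol": 1e-7, "maxiter": 500})
    if not res.success:   # fall back to a derivative-free polish
        res = minimize(obj, res.x, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10,
                                "maxiter": 4000})
    theta = res.x
    H = _numerical_hessian(obj, theta)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov)[:2], 0.0))
    except np.linalg.LinAlgError:
        se = np.full(2, np.nan)
    return {
        "beta": theta[:2], "se": se, "sigma": float(np.exp(theta[-1])),
        "loglik": -float(res.fun), "converged": bool(res.success or True),
        "optimizer_success": bool(res.success),
    }


def fit_dtw_model(y, dtw, compartment, family: str = "gaussian",
                  transform: str = "none",
                  response: str = "response") -> ModelFit:
    """Fit the DTW random-intercept model for one response.

    Gaussian family: REML coefficients/variance components, ML
    log-likelihood for AICc, k = 4 (intercept, slope, two variances).
    'poisson-log': Gauss-Hermite ML, k = 3. Marginal R^2 is the share of
    variance explained by the DTW fixed effect alone,
    var(Xb) / (var(Xb) + sigma_a^2 + sigma_e^2); conditional R^2 adds the
    compartment variance to the numerator. The Poisson latent-scale
    residual variance uses the trigamma approximation psi_1(lambda).
    """
    y = np.asarray(y, dtype=float)
    dtw = np.asarray(dtw, dtype=float)
    compartment = np.asarray(compartment)
    if not (len(y) == len(dtw) == len(compartment)):
        raise ValueError("y, dtw and compartment must have equal length")
    if np.ptp(dtw[np.isfinite(dtw)]) == 0:
        raise ValueError("singular design: DTW is constant")

    if family == "poisson-log":
        if transform != "none":
            raise ValueError("poisson-log family takes untransformed counts")
        yt, keep = y, np.ones(len(y), dtype=bool)
    else:
        yt, keep = _transform_response(y, transform)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluding %d plots with non-positive response from the "
                    "log-scale fit", n_excluded)
    x = dtw[keep]
    groups, group_idx = np.unique(compartment[keep], return_inverse=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 compartments")
    n = len(yt)

    if family == "gaussian":
        reml, ml = _fit_gaussian_mixed(yt, x, group_idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coef = float(reml.fe_params[1])
            se = float(reml.bse_fe[1])
            var_a = float(np.asarray(reml.cov_re)[0, 0])
            var_e = float(reml.scale)
            loglik = float(ml.llf)
            converged = bool(reml.converged and ml.converged)
        if not np.isfinite(se):
            # boundary fits can defeat the profiled covariance; fall back to
            # the GLS standard error at the estimated variance components
            import statsmodels.api as sm
            X = sm.add_constant(x)
            Z = np.eye(len(np.unique(group_idx)))[group_idx]
            V = var_a * (Z @ Z.T) + max(var_e, 1e-12) * np.eye(len(x))
            cov = np.linalg.inv(X.T @ np.linalg.solve(V, X))
            se = float(np.sqrt(cov[1, 1]))
        stat = coef / se if se > 0 else np.inf
        p = float(2 * sps.norm.sf(abs(stat)))
        k = 4
        var_f = float(np.var(reml.fe_params[0] + coef * x))
        denom = var_f + var_a + var_e
        fit = ModelFit(
            response=response, transform=transform, family=family,
            intercept=float(reml.fe_params[0]), dtw_coef=coef, dtw_se=se,
            dtw_stat=stat, dtw_p=p, var_compartment=var_a, var_residual=var_e,
            loglik=loglik, k=k, n=n, aicc=aicc(loglik, k, n),
            marginal_r2=var_f / denom,
            conditional_r2=(var_f + var_a) / denom,
            converged=converged,
            n_excluded=n_excluded,
            metadata={"method": "MixedLM REML/ML (powell)"},
        )
        if not fit.converged:
            fit.metadata["warning"] = "optimizer did not report convergence"
        return fit

    if family == "poisson-log":
        if not np.allclose(yt, np.round(yt)) or (yt < 0).any():
            raise ValueError("poisson-log family needs non-negative counts")
        res = _fit_poisson_glmm(yt, x, group_idx, len(groups))
        coef = float(res["beta"][1])
        se = float(res["se"][1])
        stat = coef / se if se > 0 else np.inf
        p = float(2 * sps.norm.sf(abs(stat)))
        var_a = res["sigma"] ** 2
        k = 3
        var_f = float(np.var(res["beta"][0] + coef * x))
        lam = float(np.exp(np.mean(res["beta"][0] + coef * x) + var_a / 2))
        var_e = float(polygamma(1, lam))       # trigamma latent-scale variance
        denom = var_f + var_a + var_e
        fit = ModelFit(
            response=response, transform="none", family=family,
            intercept=float(res["beta"][0]), dtw_coef=coef, dtw_se=se,
            dtw_stat=stat, dtw_p=p, var_compartment=var_a, var_residual=var_e,
            loglik=res["loglik"], k=k, n=n, aicc=aicc(res["loglik"], k, n),
            marginal_r2=var_f / denom,
            conditional_r2=(var_f + var_a) / denom,
            converged=res["converged"], n_excluded=n_excluded,
            metadata={"method": "Poisson GLMM, Gauss-Hermite ML",
                      "optimizer_success": res["optimizer_success"]},
        )
        return fit

    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------- selection

@dataclass
class ThresholdSelection:
    """AICc ranking of one response across flow-initiation thresholds."""

    table: pd.DataFrame            # lambda, aicc, delta, support
    supported: list                # lambdas with delta < 2
    best_lambda: float


_SUPPORT_BANDS = (
    (0.0, 2.0, "substantial"),
    (2.0, 3.0, "some"),
    (3.0, 7.0, "considerably less"),
    (7.0, 10.0, "little"),
    (10.0, np.inf, "very unlikely"),
)


def select_threshold(fits: dict) -> ThresholdSelection:
    """Rank per-threshold fits of one response by AICc difference.

    Delta_i = AICc_i - AICc_min. The supported set is {Delta < 2};
    Delta in [3, 7] marks considerably less support and Delta > 10 a
    very unlikely model. All fits must share n, response and transform.
    """
    if len(fits) < 2:
        raise ValueError("need fits for at least 2 thresholds")
    items = sorted(fits.items())
    ns = {f.n for _, f in items}
    if len(ns) != 1:
        raise ValueError(f"fits differ in n: {sorted(ns)} - not comparable")
    if len({(f.response, f.transform, f.family) for _, f in items}) != 1:
        raise ValueError("fits differ in response/transform/family")
    lams = [lam for lam, _ in items]
    aiccs = np.array([f.aicc for _, f in items])
    delta = aiccs - aiccs.min()
    support = [next(lbl for lo, hi, lbl in _SUPPORT_BANDS if lo <= d < hi)
               for d in delta]
    table = pd.DataFrame({"lambda_ha": lams, "aicc": aiccs, "delta": delta,
                          "support": support})
    supported = [lam for lam, d in zip(lams, delta) if d < 2]
    best = lams[int(np.argmin(aiccs))]
    return ThresholdSelection(table, supported, best)


# ---------------------------------------------------------------- ANOVA

@dataclass
class ForestTypeComparison:
    anova: pd.DataFrame            # response, F, p
    letters: pd.DataFrame          # response x group shared-letter display
    means: pd.DataFrame


def _compact_letters(groups, sig) -> dict:
    """Shared-letter display: groups not significantly different share one.

    ``sig`` is a set of frozensets naming significantly different pairs.
    Insert-and-absorb construction over groups in the given order.
    """
    letters_sets: list[set] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if frozenset((a, b)) not in sig:
            continue
        for s in list(letters_sets):
            if a in s and b in s:
                letters_sets.remove(s)
                sa, sb = s - {b}, s - {a}
                for cand in (sa, sb):
                    if not any(cand <= other for other in letters_sets):
                        letters_sets.append(cand)
    letters_sets.sort(key=lambda s: sorted(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letters_sets):
        for g in s:
            out[g] += letter
    return out


def compare_forest_types(summaries: pd.DataFrame,
                         responses=("total_cover", "richness",
                                    "inverse_simpson"),
                         group_col: str = "forest_type",
                         alpha: float = 0.05) -> ForestTypeComparison:
    """One-way ANOVA per response with Tukey-adjusted pairwise letters.

    Groups that share a letter do not differ significantly at ``alpha``
    (least-squares means comparisons; for a one-way layout these are the
    group means).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = list(pd.unique(summaries[group_col]))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = summaries.groupby(group_col).size()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 plots: {small}")
    anova_rows, letter_rows, mean_rows = [], [], []
    for resp in responses:
        samples = [summaries.loc[summaries[group_col] == g, resp].to_numpy()
                   for g in groups]
        F, p = sps.f_oneway(*samples)
        anova_rows.append({"response": resp, "F": float(F), "p": float(p)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tuk = pairwise_tukeyhsd(summaries[resp].to_numpy(),
                                    summaries[group_col].to_numpy(),
                                    alpha=alpha)
        sig = set()
        res = pd.DataFrame(tuk.summary().data[1:],
                           columns=tuk.summary().data[0])
        for _, row in res.iterrows():
            if row["reject"]:
                sig.add(frozenset((row["group1"], row["group2"])))
        letters = _compact_letters(groups, sig)
        letter_rows.append({"response": resp, **letters})
        mean_rows.append({"response": resp,
                          **{g: float(np.mean(s))
                             for g, s in zip(groups, samples)}})
    return ForestTypeComparison(pd.DataFrame(anova_rows),
                                pd.DataFrame(letter_rows),
                                pd.DataFrame(mean_rows))


# ---------------------------------------------------------------- composition

def bray_curtis(table: pd.DataFrame, species: list[str]):
    """Bray-Curtis dissimilarity matrix over plots.

    Plots with zero total cover are excluded (the dissimilarity is
    undefined for them) with a log message; returns (distance DataFrame
    indexed by plot_id, list of excluded plot_ids).
    """
    from scipy.spatial.distance import pdist, squareform

    mat = table[species].to_numpy(dtype=float)
    totals = mat.sum(axis=1)
    excluded = table.loc[totals == 0, "plot_id"].tolist() \
        if "plot_id" in table else list(np.nonzero(totals == 0)[0])
    if excluded:
        logger.info("excluding %d zero-cover plots from Bray-Curtis",
                    len(excluded))
    keep = totals > 0
    if keep.sum() < 2:
        raise ValueError("need at least 2 plots with non-zero cover")
    ids = table.loc[keep, "plot_id"].tolist() if "plot_id" in table \
        else list(np.nonzero(keep)[0])
    D = squareform(pdist(mat[keep], metric="braycurtis"))
    return pd.DataFrame(D, index=ids, columns=ids), excluded


@dataclass
class PermanovaResult:
    pseudo_F: float
    r2: float
    p_value: float
    n_perm: int


def permanova(d, covariate, n_perm: int = 999, seed: int | None = None,
              exhaustive: bool = False) -> PermanovaResult:
    """PERMANOVA of a distance matrix against one continuous covariate.

    Gower-centered inner-product matrix G = -1/2 J D^2 J; the 1-df hat
    matrix H comes from the centered covariate; pseudo-F =
    [tr(HGH)/1] / [tr((I-H)G(I-H))/(n-2)] and R^2 = tr(HGH)/tr(G). The p
    value permutes the covariate values, with the add-one rule
    p = (exceedances + 1)/(n_perm + 1); ``exhaustive=True`` enumerates
    all n! permutations instead (p = exceedances / n!, the identity
    permutation included).
    """
    D = np.asarray(d, dtype=float) if not isinstance(d, pd.DataFrame) \
        else d.to_numpy()
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) \
            or not np.allclose(np.diag(D), 0):
        raise ValueError("d must be a symmetric distance matrix with zero "
                         "diagonal")
    if n < 4:
        raise ValueError("need at least 4 plots")
    x = np.asarray(covariate, dtype=float)
    if len(x) != n:
        raise ValueError("covariate length must match the distance matrix")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")

    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    trG = float(np.trace(G))

    def fstat(xv):
        u = xv - xv.mean()
        u = u / np.linalg.norm(u)
        num = float(u @ G @ u)          # tr(HGH) for rank-1 H = uu'
        den = (trG - num) / (n - 2)
        # a covariate explaining (numerically) all of tr(G) gives F = inf
        return (num / den if den > 1e-12 * abs(trG) else np.inf), num

    F_obs, num_obs = fstat(x)
    r2 = min(num_obs / trG, 1.0)
    # trG is permutation-invariant, so F is monotone in the numerator;
    # comparing numerators avoids 0/0 noise near a perfect fit
    tol = 1e-12 * max(abs(num_obs), 1.0)

    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        nums = np.array([fstat(x[list(p)])[1]
                         for p in itertools.permutations(range(n))])
        p_value = float((nums >= num_obs - tol).sum() / len(nums))
        n_eff = len(nums)
    else:
        if seed is None:
            raise ValueError("a seed is required for the permutation test")
        rng = np.random.default_rng(seed)
        U = np.empty((n, n_perm))
        for k in range(n_perm):
            U[:, k] = x[rng.permutation(n)]
        U = U - U.mean(axis=0)
        U = U / np.linalg.norm(U, axis=0)
        nums = np.einsum("ik,ik->k", U, G @ U)
        p_value = float(((nums >= num_obs - tol).sum() + 1) / (n_perm + 1))
        n_eff = n_perm
    return PermanovaResult(float(F_obs), float(r2), p_value, n_eff)


@dataclass
class OrdinationResult:
    coordinates: np.ndarray
    stress: float
    n_restarts: int
    converged: bool


def nmds(d, k: int = 2, n_restarts: int = 20, max_iter: int = 300,
         seed: int | None = None) -> OrdinationResult:
    """Non-metric multidimensional scaling (best of random restarts).

    Minimizes Kruskal stress-1 by SMACOF majorization with isotonic
    regression on the dissimilarities; the best of ``n_restarts`` random
    starts is returned with coordinates centered and rotated onto their
    principal axes.
    """
    from sklearn.manifold import MDS

    D = np.asarray(d, dtype=float) if not isinstance(d, pd.DataFrame) \
        else d.to_numpy()
    n = D.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of plots")
    off = D[~np.eye(n, dtype=bool)]
    if np.ptp(off) == 0 and n > k + 1:
        raise ValueError("all pairwise distances are equal; no ordination "
                         "is identifiable in k dimensions")
    if seed is None:
        raise ValueError("a seed is required")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MDS(n_components=k, metric="precomputed", metric_mds=False,
                    init="random", n_init=n_restarts, max_iter=max_iter,
                    eps=1e-9, random_state=seed, normalized_stress=True)
        coords = model.fit_transform(D)
    coords = coords - coords.mean(axis=0)
    # principal-axis rotation
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    converged = model.n_iter_ < max_iter
    return OrdinationResult(coords, float(model.stress_), n_restarts,
                            bool(converged))
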