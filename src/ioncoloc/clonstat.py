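"""Shared statistics for clonal spatial metabolomics.

Beta regression of tissue-level proportions on covariates (optionally with
random intercepts for acquisition run and tissue section), Benjamini-Hochberg
adjustment, conditional-probability coexpression tables, coefficient-of-
variation filtering, and a Fisher-scaled pathway enrichment score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.othermod.betareg import BetaModel
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BetaFit",
    "CondProbTable",
    "beta_regression",
    "bh_adjust",
    "conditional_coexpression",
    "cov_filter",
    "pathway_enrichment",
    "shrink_proportions",
]


@dataclass
class BetaFit:
    """Result of a beta regression fit (logit mean link, log precision link).

    Coefficients are on the logit scale.  ``phi`` is the precision parameter
    of the Beta(mu*phi, (1-mu)*phi) parameterization.  ``random_variances``
    holds the estimated random-intercept variances keyed by grouping factor,
    empty for a fixed-effects fit.
    """

    params: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    phi: float
    loglik: float
    converged: bool
    random_variances: dict[str, float] = field(default_factory=dict)
    method: str = "ml"
    n_obs: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.se, "z": self.z, "p": self.p}
        )


@dataclass
class CondProbTable:
    """P(intensity level | genotype) with the percentile thresholds used.

    ``probs`` is a 3x2 table, rows (low, mid, high) x columns (low, high
    genotype); each column sums to 1.
    """

    probs: pd.DataFrame
    t1: float
    t2: float


def shrink_proportions(y: np.ndarray) -> np.ndarray:
    """Shrink proportions off the {0,1} boundary by (y*(n-1)+0.5)/n.

    The beta likelihood is undefined at the boundary; this is the standard
    continuity correction for proportion responses.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if np.any((y < 0) | (y > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if np.any(y <= 0) or np.any(y >= 1):
        y = (y * (n - 1) + 0.5) / n
    return y


def _as_design(covariates, n: int) -> tuple[np.ndarray, list[str]]:
    """Build a design matrix with an explicit intercept column."""
    if covariates is None:
        return np.ones((n, 1)), ["intercept"]
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    elif isinstance(covariates, pd.Series):
        names = [covariates.name or "x"]
        X = covariates.to_numpy(dtype=float)[:, None]
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != n:
            X = X.T
        names = [f"x{j}" for j in range(X.shape[1])]
    X = np.column_stack([np.ones(n), X])
    return X, ["intercept"] + names


def _fit_fixed(y: np.ndarray, X: np.ndarray, names: list[str]) -> BetaFit:
    model = BetaModel(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=False, maxiter=500)
    k = X.shape[1]
    params = pd.Series(res.params[:k], index=names)
    se = pd.Series(res.bse[:k], index=names)
    z = params / se
    p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names).clip(lower=1e-300)
    if not np.isfinite(se.to_numpy()[1:]).all():
        # near-saturated fits can leave a singular Hessian; fall back to a
        # likelihood-ratio test per covariate so strong effects still score
        for j in range(1, k):
            if np.isfinite(se.iloc[j]):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res0 = BetaModel(y, np.delete(X, j, axis=1)).fit(disp=False, maxiter=500)
            lr = max(2.0 * (res.llf - res0.llf), 0.0)
            p.iloc[j] = max(float(stats.chi2.sf(lr, 1)), 1e-300)
    phi = float(np.exp(res.params[k]))
    return BetaFit(
        params=params,
        se=se,
        z=z,
        p=p,
        phi=phi,
        loglik=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)),
        method="ml",
        n_obs=y.size,
    )


def _beta_loglik(y, eta, phi):
    mu = special.expit(eta)
    mu = np.clip(mu, 1e-10, 1 - 1e-10)
    a = mu * phi
    b = (1.0 - mu) * phi
    return (
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )


def _dll_deta(y, eta, phi):
    """d log-beta-density / d eta (logit mean link)."""
    mu = np.clip(special.expit(eta), 1e-10, 1 - 1e-10)
    a, b = mu * phi, (1 - mu) * phi
    ystar = np.log(y) - np.log1p(-y)
    t = ystar - special.digamma(a) + special.digamma(b)
    return phi * mu * (1 - mu) * t


def _d2ll_deta2(y, eta, phi):
    mu = np.clip(special.expit(eta), 1e-10, 1 - 1e-10)
    a, b = mu * phi, (1 - mu) * phi
    ystar = np.log(y) - np.log1p(-y)
    t = ystar - special.digamma(a) + special.digamma(b)
    v = special.polygamma(1, a) + special.polygamma(1, b)
    return phi * (1 - 2 * mu) * mu * (1 - mu) * t - (phi * mu * (1 - mu)) ** 2 * v


def _fit_mixed(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str],
    groups: dict[str, np.ndarray],
) -> BetaFit:
    """Beta GLMM by maximum marginal likelihood.

    One grouping factor: adaptive Gauss-Hermite quadrature (7 nodes) per
    group.  Several (crossed) factors: Laplace approximation around the
    joint random-effect mode.
    """
    factor_names = list(groups)
    codes = {}
    n_levels = {}
    for f in factor_names:
        _, inv = np.unique(np.asarray(groups[f]), return_inverse=True)
        codes[f] = inv
        n_levels[f] = inv.max() + 1

    k = X.shape[1]
    nodes, weights = np.polynomial.hermite_e.hermegauss(7)  # probabilists'

    def neg_marginal(theta, X_design=X):
        k_ = X_design.shape[1]
        beta = theta[:k_]
        phi = np.exp(theta[k_])
        # floor keeps the prior precision finite when a variance collapses
        sigmas = np.maximum(np.exp(theta[k_ + 1 :]), 1e-6)
        eta0 = X_design @ beta
        if len(factor_names) == 1:
            f = factor_names[0]
            sig = sigmas[0]
            ll = 0.0
            for g in range(n_levels[f]):
                idx = codes[f] == g
                yg, eg = y[idx], eta0[idx]

                def h(b):  # log integrand
                    return (
                        _beta_loglik(yg, eg + b, phi).sum()
                        - 0.5 * b * b / sig**2
                        - np.log(sig)
                        - 0.5 * np.log(2 * np.pi)
                    )

                # adaptive: centre quadrature at the conditional mode
                bhat = optimize.minimize_scalar(
                    lambda b: -h(b), bounds=(-6 * sig, 6 * sig), method="bounded"
                ).x
                eps = 1e-4 + 1e-3 * abs(bhat)
                curv = -(h(bhat + eps) - 2 * h(bhat) + h(bhat - eps)) / eps**2
                s = 1.0 / np.sqrt(max(curv, 1e-8))
                # adaptive GH: int exp(h) db = s * sum_k w_k exp(h(b^ + s x_k) + x_k^2/2)
                pts = bhat + s * nodes
                vals = np.array([h(b) for b in pts]) + 0.5 * nodes**2
                m = vals.max()
                ll += m + np.log(np.sum(weights * np.exp(vals - m)) * s)
            return -ll
        # crossed factors: joint Laplace with analytic Newton inner loop
        offsets = np.cumsum([0] + [n_levels[f] for f in factor_names])
        q = offsets[-1]
        Zcols = [offsets[i] + codes[f] for i, f in enumerate(factor_names)]
        prior_prec = np.concatenate([
            np.full(n_levels[f], 1.0 / sigmas[i] ** 2)
            for i, f in enumerate(factor_names)
        ])

        def eta_of(b):
            eta = eta0.copy()
            for cols in Zcols:
                eta = eta + b[cols]
            return eta

        b = np.zeros(q)
        for _ in range(60):
            eta = eta_of(b)
            g_obs = _dll_deta(y, eta, phi)
            w = np.clip(-_d2ll_deta2(y, eta, phi), 1e-8, None)
            grad = -np.concatenate([
                np.bincount(cols, weights=g_obs, minlength=q)[
                    offsets[i]: offsets[i + 1]]
                for i, cols in enumerate(Zcols)
            ]) + prior_prec * b
            H = np.diag(prior_prec.copy())
            for i, ci in enumerate(Zcols):
                for jf, cj in enumerate(Zcols):
                    np.add.at(H, (ci, cj), w)
            step = np.linalg.solve(H, grad)
            b = b - step
            if np.abs(grad).max() < 1e-8:
                break
        eta = eta_of(b)
        w = np.clip(-_d2ll_deta2(y, eta, phi), 1e-8, None)
        H = np.diag(prior_prec.copy())
        for ci in Zcols:
            for cj in Zcols:
                np.add.at(H, (ci, cj), w)
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            logdet = np.log(np.abs(np.diag(H)) + 1e-8).sum()
        ll = (
            _beta_loglik(y, eta, phi).sum()
            - 0.5 * np.sum(prior_prec * b**2)
            - sum(n_levels[f] * np.log(sigmas[i]) for i, f in enumerate(factor_names))
            - 0.5 * logdet
        )
        return -ll

    def run_opt(X_design, names_):
        start = _fit_fixed(y, X_design, names_)
        theta0 = np.concatenate([
            start.params.to_numpy(), [np.log(start.phi)],
            np.full(len(factor_names), np.log(0.3)),
        ])
        return optimize.minimize(
            lambda th: neg_marginal(th, X_design), theta0,
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-5, "fatol": 1e-7},
        )

    opt = run_opt(X, names)
    theta = opt.x
    # observed-information SEs via central differences on the marginal NLL
    m = theta.size
    H = np.zeros((m, m))
    step = 1e-4 * np.maximum(1.0, np.abs(theta))
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = step[i]
            ej = np.zeros(m); ej[j] = step[j]
            fpp = neg_marginal(theta + ei + ej)
            fpm = neg_marginal(theta + ei - ej)
            fmp = neg_marginal(theta - ei + ej)
            fmm = neg_marginal(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * step[i] * step[j])
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(m, np.nan)

    params = pd.Series(theta[:k], index=names)
    se = pd.Series(se_all[:k], index=names)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = params / se
    p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names).clip(lower=1e-300)
    # collapsed variance components flatten the observed information; score
    # affected covariates by likelihood ratio instead of a NaN Wald test
    for j in range(1, k):
        if not np.isfinite(se.iloc[j]):
            red = run_opt(np.delete(X, j, axis=1),
                          [n for i2, n in enumerate(names) if i2 != j])
            lr = max(2.0 * (red.fun - opt.fun), 0.0)
            p.iloc[j] = max(float(stats.chi2.sf(lr, 1)), 1e-300)
    sigmas = np.exp(theta[k + 1 :])
    return BetaFit(
        params=params,
        se=se,
        z=z,
        p=p,
        phi=float(np.exp(theta[k])),
        loglik=float(-opt.fun),
        converged=bool(opt.success),
        random_variances={f: float(s**2) for f, s in zip(factor_names, sigmas)},
        method="agq" if len(factor_names) == 1 else "laplace",
        n_obs=y.size,
    )


def beta_regression(
    proportions,
    covariates=None,
    random_intercepts: dict[str, np.ndarray] | None = None,
) -> BetaFit:
    """Fit a beta regression of proportions on covariates.

    The mean is modeled through a logit link, mu = expit(X @ beta), with a
    Beta(mu*phi, (1-mu)*phi) likelihood and a partial Wald test per
    coefficient.  Boundary proportions (exactly 0 or 1) are shrunk by
    (y*(n-1)+0.5)/n before likelihood evaluation.

    Parameters
    ----------
    proportions
        Response values in [0, 1], one per experimental unit.
    covariates
        Design columns (no intercept; one is added).  ``None`` fits an
        intercept-only model.
    random_intercepts
        Optional mapping of factor name to per-unit group labels; each
        factor contributes a normal random intercept.  One factor is
        integrated by adaptive Gauss-Hermite quadrature, several crossed
        factors by a Laplace approximation.
    """
    y = shrink_proportions(proportions)
    if y.size < 3:
        raise ValueError("need at least 3 units to fit a beta regression")
    X, names = _as_design(covariates, y.size)
    for j, name in enumerate(names[1:], start=1):
        levels = np.unique(X[:, j])
        if levels.size == 2:
            for lev in levels:
                if np.sum(X[:, j] == lev) < 2:
                    raise ValueError(
                        f"covariate {name!r}: need >= 2 units per level"
                    )
    if not random_intercepts:
        fit = _fit_fixed(y, X, names)
    else:
        fit = _fit_mixed(y, X, names, random_intercepts)
    if not fit.converged:
        warnings.warn("beta regression did not report convergence", RuntimeWarning)
    return fit


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def conditional_coexpression(
    intensities: np.ndarray,
    genotype: np.ndarray,
    t1: float = 33.0,
    t2: float = 66.0,
    feature_names=None,
) -> dict[str, CondProbTable]:
    """P(low/mid/high intensity | genotype) per feature.

    Intensities are discretized at the pooled t1-th and t2-th percentiles of
    the pure-genotype pixels (y <= t1 -> low, t1 < y <= t2 -> mid,
    y > t2 -> high); only 'high' and 'low' genotype pixels enter, and the
    fractions are computed within each genotype.  Percentiles use linear
    interpolation.
    """
    X = np.asarray(intensities, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    genotype = np.asarray(genotype)
    keep = np.isin(genotype, ("high", "low"))
    if not np.any(genotype[keep] == "high") or not np.any(genotype[keep] == "low"):
        raise ValueError("both 'high' and 'low' genotype pixels are required")
    Xp = X[keep]
    gp = genotype[keep]
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(Xp.shape[1])]
    out = {}
    for j, name in enumerate(feature_names):
        y = Xp[:, j]
        lo, hi = np.percentile(y, [t1, t2])
        levels = np.where(y <= lo, 0, np.where(y <= hi, 1, 2))
        probs = np.empty((3, 2))
        for c, g in enumerate(("low", "high")):
            sel = levels[gp == g]
            probs[:, c] = np.bincount(sel, minlength=3) / sel.size
        out[name] = CondProbTable(
            probs=pd.DataFrame(
                probs, index=["low", "mid", "high"], columns=["low", "high"]
            ),
            t1=float(lo),
            t2=float(hi),
        )
    return out


def cov_filter(
    values: pd.DataFrame,
    class_labels,
    cov_max: float = 0.30,
) -> list:
    """Keep features whose coefficient of variation is below ``cov_max``
    within at least one replicate class.

    ``values`` is features x samples; ``class_labels`` assigns each sample
    column to a class.  A class with zero mean for a feature is skipped for
    that feature.
    """
    class_labels = np.asarray(class_labels)
    kept = []
    for feat, row in values.iterrows():
        x = row.to_numpy(dtype=float)
        for cls in np.unique(class_labels):
            v = x[class_labels == cls]
            if v.size < 2:
                continue
            m = v.mean()
            if m == 0:
                continue
            if v.std(ddof=1) / m < cov_max:
                kept.append(feat)
                break
    return kept


def pathway_enrichment(
    significance: pd.DataFrame,
    membership: pd.DataFrame,
    p_cut: float = 0.05,
    min_size: int = 2,
) -> pd.DataFrame:
    """Direction-stratified pathway enrichment with a Fisher-scaled score.

    ``significance`` needs columns ``feature``, ``p`` and ``direction``
    (which class the feature's fold change favors, e.g. 'high'/'low');
    ``membership`` maps ``feature`` to ``pathway``.  For each pathway and
    direction the hits are the significant features of that direction in the
    pathway; the Fisher exact (hypergeometric) p comes from the 2x2 table
    in-pathway x significant-in-direction, and the reported score is
    (hits / expected hits) * (-log10 p).  Both factors are also returned so
    the score can be recomposed.  Pathways with fewer than ``min_size``
    mapped features are dropped.
    """
    if membership.empty:
        raise ValueError("empty pathway membership table")
    sig = significance.set_index("feature")
    universe = sig.index
    n = universe.size
    memb = membership[membership["feature"].isin(universe)]
    rows = []
    for pw, grp in memb.groupby("pathway"):
        feats = pd.Index(grp["feature"].unique())
        size = feats.size
        if size < min_size:
            continue
        for direction in pd.unique(sig["direction"]):
            in_dir = (sig["p"] < p_cut) & (sig["direction"] == direction)
            n_dir = int(in_dir.sum())
            hits = int(in_dir.loc[feats].sum())
            expected = size * n_dir / n if n else 0.0
            table = [
                [hits, size - hits],
                [n_dir - hits, n - size - (n_dir - hits)],
            ]
            _, fisher_p = stats.fisher_exact(table, alternative="greater")
            ratio = hits / expected if expected > 0 else 0.0
            score = ratio * (-np.log10(fisher_p)) if hits else 0.0
            rows.append(
                {
                    "pathway": pw,
                    "direction": direction,
                    "size": size,
                    "hits": hits,
                    "expected": expected,
                    "enrichment_ratio": ratio,
                    "fisher_p": fisher_p,
                    "score": score,
                }
            )
    return pd.DataFrame(rows)
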