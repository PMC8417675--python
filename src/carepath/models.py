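"""Statistical stage: chained-equation imputation, multicollinearity
screening, cluster comparison tests, and the recursive two-equation path
model linking built environment → care-pattern cluster → postpartum
depression.

The "structural equation model" here is a generalized recursive path model
with a categorical mediator: (1) multinomial logistic regression of cluster
membership (vs a reference cluster) on built-environment and adjustment
covariates, and (2) binary logistic regression of PPD on cluster
indicators.  For a fully observed recursive system the joint likelihood
factorizes, so the two equations are estimated separately by maximum
likelihood; odds ratios are exp(coefficients).  Fits across multiple
imputations are pooled by Rubin's rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "chained_imputation",
    "vif_screen",
    "ModelSpec",
    "PathModelFit",
    "fit_path_model",
    "group_compare",
    "unadjusted_env_associations",
]


# ---------------------------------------------------------------------------
# multiple imputation by chained equations


def _draw_linear(rng, X_obs, y_obs, X_mis):
    """Stochastic-regression draw for a numeric column: OLS fit on observed
    rows, prediction plus residual-scale Gaussian noise for missing rows."""
    Xd = np.column_stack([np.ones(len(X_obs)), X_obs])
    beta, *_ = np.linalg.lstsq(Xd, y_obs, rcond=None)
    resid = y_obs - Xd @ beta
    dof = max(len(y_obs) - Xd.shape[1], 1)
    sigma = float(np.sqrt(resid @ resid / dof))
    Xm = np.column_stack([np.ones(len(X_mis)), X_mis])
    return Xm @ beta + rng.normal(0.0, sigma, size=len(X_mis))


def _draw_binary(rng, X_obs, y_obs, X_mis):
    """Logistic draw for a binary column; falls back to the observed rate if
    the logistic fit is degenerate (single class)."""
    if len(np.unique(y_obs)) < 2:
        p = np.full(len(X_mis), float(np.mean(y_obs)))
    else:
        try:
            fit = sm.Logit(y_obs, sm.add_constant(X_obs, has_constant="add")).fit(disp=0, maxiter=100)
            p = fit.predict(sm.add_constant(X_mis, has_constant="add"))
        except Exception:
            p = np.full(len(X_mis), float(np.mean(y_obs)))
    return (rng.random(len(X_mis)) < p).astype(float)


def chained_imputation(
    table: pd.DataFrame,
    m: int = 5,
    n_iter: int = 10,
    seed: int = 0,
    columns: list[str] | None = None,
) -> list[pd.DataFrame]:
    """Multivariate imputation by chained equations.

    Missing cells in ``columns`` (default: every numeric column with any
    missingness) are first filled by sampling observed values, then updated
    for ``n_iter`` sweeps of conditional draws — linear-model draws for
    numeric columns, logistic draws for binary ones — conditioning on all
    other numeric columns.  Returns ``m`` independently imputed copies;
    observed cells are never altered.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    num = table.select_dtypes(include=[np.number])
    targets = columns if columns is not None else [c for c in num.columns if table[c].isna().any()]
    for c in targets:
        if table[c].isna().all():
            raise ValueError(f"column {c!r} is 100% missing and cannot be imputed")
    if not targets:
        return [table.copy() for _ in range(m)]
    predictors = [c for c in num.columns if c not in targets] + targets
    binary = {c for c in targets if set(table[c].dropna().unique()) <= {0, 1, 0.0, 1.0, True, False}}

    out = []
    master = np.random.SeedSequence(seed)
    for child in master.spawn(m):
        rng = np.random.default_rng(child)
        work = table.copy()
        for c in targets:
            miss = work[c].isna()
            obs = work.loc[~miss, c].to_numpy(dtype=float)
            work.loc[miss, c] = rng.choice(obs, size=int(miss.sum()), replace=True)
        for _ in range(n_iter):
            for c in targets:
                miss = table[c].isna()
                if not miss.any():
                    continue
                others = [p for p in predictors if p != c]
                X = work[others].to_numpy(dtype=float)
                y = work[c].to_numpy(dtype=float)
                if c in binary:
                    drawn = _draw_binary(rng, X[~miss], y[~miss], X[miss])
                else:
                    drawn = _draw_linear(rng, X[~miss], y[~miss], X[miss])
                work.loc[miss, c] = drawn
        out.append(work)
    return out


# ---------------------------------------------------------------------------
# multicollinearity screen


def _vif(X: np.ndarray, j: int) -> float:
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    Xd = np.column_stack([np.ones(len(X)), others])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - ss_res / ss_tot
    return np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)


def vif_screen(design: pd.DataFrame, threshold: float = 10.0) -> tuple[list[str], dict[str, float]]:
    """Iteratively drop the variable with the largest variance inflation
    factor while any VIF exceeds the threshold (exact ties drop the
    later-listed variable, for determinism).  Returns the retained column
    names and the final VIFs."""
    if threshold <= 1:
        raise ValueError("vif threshold must exceed 1")
    cols = list(design.columns)
    if len(cols) < 2:
        return cols, {c: 1.0 for c in cols}
    while len(cols) > 1:
        X = design[cols].to_numpy(dtype=float)
        vifs = [_vif(X, j) for j in range(len(cols))]
        worst = int(np.argmax([v if np.isfinite(v) else np.inf for v in vifs]))
        # ties (incl. exact collinearity giving several inf) -> drop the later-listed
        wv = vifs[worst]
        for j in range(len(cols) - 1, -1, -1):
            if vifs[j] == wv or (np.isinf(vifs[j]) and np.isinf(wv)):
                worst = j
                break
        if not (vifs[worst] > threshold):
            break
        cols.pop(worst)
    X = design[cols].to_numpy(dtype=float)
    final = {c: (_vif(X, j) if len(cols) > 1 else 1.0) for j, c in enumerate(cols)}
    return cols, final


# ---------------------------------------------------------------------------
# path model


@dataclass
class ModelSpec:
    mediator_covariates: list[str] = field(default_factory=list)
    reference_cluster: int = 3
    vif_threshold: float = 10.0
    alpha: float = 0.05
    n_imputations: int = 5

    def __post_init__(self):
        if self.vif_threshold <= 1:
            raise ValueError("vif_threshold must exceed 1")


@dataclass
class PathModelFit:
    mediator_eq: pd.DataFrame  # columns: cluster, variable, coef, or_, se, p
    outcome_eq: pd.DataFrame  # columns: variable, coef, or_, se, p
    n_used: int
    m: int
    converged: bool


class SeparationError(RuntimeError):
    pass


def _pool(coefs: np.ndarray, ses: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rubin's rules across m imputations: pooled point estimate, total SE,
    and Wald p-values (normal reference)."""
    m = coefs.shape[0]
    qbar = coefs.mean(axis=0)
    ubar = (ses**2).mean(axis=0)
    if m > 1:
        b = coefs.var(axis=0, ddof=1)
        total = ubar + (1 + 1 / m) * b
    else:
        total = ubar
    se = np.sqrt(total)
    z = qbar / se
    p = 2 * stats.norm.sf(np.abs(z))
    return qbar, se, p


def fit_path_model(data: pd.DataFrame, spec: ModelSpec, imputed: list[pd.DataFrame] | None = None) -> PathModelFit:
    """Fit the two-equation path model by equation-wise maximum likelihood.

    ``data`` needs a ``cluster`` column (integer labels), a binary ``ppd``
    column, and the mediator covariates.  When ``imputed`` is given (m
    completed copies of ``data``), each copy is fitted and the estimates are
    pooled by Rubin's rules; with m = 1 the pooled fit equals the single
    fit.  Odds ratios are exp(coefficients) exactly.
    """
    datasets = imputed if imputed is not None else [data]
    ref = spec.reference_cluster
    clusters0 = datasets[0]["cluster"].to_numpy()
    levels = sorted(set(int(c) for c in clusters0))
    if ref not in levels:
        raise ValueError(f"reference cluster {ref} not among observed labels {levels}")
    nonref = [c for c in levels if c != ref]
    covs = list(spec.mediator_covariates)

    med_coefs, med_ses = [], []
    out_coefs, out_ses = [], []
    converged = True
    out_names = None
    for df in datasets:
        clusters = df["cluster"].to_numpy(dtype=int)
        # outcome equation: PPD on cluster indicators (reference omitted)
        X = np.column_stack([np.ones(len(df))] + [(clusters == c).astype(float) for c in nonref])
        y = df["ppd"].to_numpy(dtype=float)
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # pragma: no cover - separation is data-dependent
            raise SeparationError(f"outcome equation failed: {exc}") from exc
        converged &= bool(fit.mle_retvals.get("converged", True))
        out_names = ["intercept"] + [f"cluster_{c}" for c in nonref]
        out_coefs.append(fit.params)
        out_ses.append(fit.bse)

        if covs:
            # mediator equation: multinomial logit, reference cluster first
            order = [ref] + nonref
            code = np.array([order.index(int(c)) for c in clusters])
            Xm = sm.add_constant(df[covs].to_numpy(dtype=float), has_constant="add")
            mfit = sm.MNLogit(code, Xm).fit(disp=0, maxiter=300, method="newton")
            converged &= bool(mfit.mle_retvals.get("converged", True))
            med_coefs.append(np.asarray(mfit.params).T.ravel())  # (k-1, p) row-major by cluster
            med_ses.append(np.asarray(mfit.bse).T.ravel())

    oc, ose, op = _pool(np.asarray(out_coefs), np.asarray(out_ses))
    outcome_eq = pd.DataFrame(
        {"variable": out_names, "coef": oc, "or_": np.exp(oc), "se": ose, "p": op}
    )

    if covs:
        mc, mse, mp = _pool(np.asarray(med_coefs), np.asarray(med_ses))
        names = ["intercept"] + covs
        rows = []
        i = 0
        for c in nonref:
            for v in names:
                rows.append({"cluster": c, "variable": v, "coef": mc[i], "or_": float(np.exp(mc[i])), "se": mse[i], "p": mp[i]})
                i += 1
        mediator_eq = pd.DataFrame(rows)
    else:
        mediator_eq = pd.DataFrame(columns=["cluster", "variable", "coef", "or_", "se", "p"])

    return PathModelFit(
        mediator_eq=mediator_eq,
        outcome_eq=outcome_eq,
        n_used=len(datasets[0]),
        m=len(datasets),
        converged=bool(converged),
    )


# ---------------------------------------------------------------------------
# cluster comparison tests


def group_compare(
    table: pd.DataFrame,
    cluster_labels,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Chi-square tests (no continuity correction, so the statistic equals
    Σ(O−E)²/E) for categorical variables and one-way ANOVA for continuous
    variables, comparing distributions across clusters.

    Variables with a single observed level or zero variance are skipped
    (test name 'skipped').
    """
    labels = np.asarray(cluster_labels)
    if len(labels) != len(table):
        raise ValueError("cluster_labels must align with table rows")
    if len(set(labels)) < 2:
        raise ValueError("need at least two non-empty clusters")
    variables = variables if variables is not None else [c for c in table.columns]
    rows = []
    for var in variables:
        col = table[var]
        is_cat = col.dtype == object or col.dtype == bool or isinstance(col.dtype, pd.CategoricalDtype)
        if is_cat:
            ct = pd.crosstab(col, labels)
            if ct.shape[0] < 2:
                rows.append({"variable": var, "test": "skipped", "statistic": np.nan, "df": np.nan, "p": np.nan})
                continue
            chi2, p, dof, _ = stats.chi2_contingency(ct.to_numpy(), correction=False)
            rows.append({"variable": var, "test": "chi-square", "statistic": chi2, "df": dof, "p": p})
        else:
            groups = [col[labels == g].dropna().to_numpy(dtype=float) for g in sorted(set(labels))]
            if any(len(g) < 2 for g in groups) or all(np.var(g) == 0 for g in groups):
                rows.append({"variable": var, "test": "skipped", "statistic": np.nan, "df": np.nan, "p": np.nan})
                continue
            f, p = stats.f_oneway(*groups)
            rows.append(
                {"variable": var, "test": "ANOVA", "statistic": f, "df": len(groups) - 1, "p": p}
            )
    return pd.DataFrame(rows)


def unadjusted_env_associations(
    built_env: pd.DataFrame,
    ppd,
    adjust_for: str = "gini",
    variables: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variable logistic model of PPD on one built-environment variable
    at a time, adjusted for income inequality (GINI).  Variables collinear
    with the adjustment covariate are dropped by the collinearity guard."""
    y = np.asarray(ppd, dtype=float)
    g = built_env[adjust_for].to_numpy(dtype=float)
    if variables is None:
        variables = [c for c in built_env.columns if c not in (adjust_for, "patient_id")]
    rows = []
    for var in variables:
        x = built_env[var].to_numpy(dtype=float)
        if np.var(x) == 0 or abs(np.corrcoef(x, g)[0, 1]) > 0.999:
            rows.append({"variable": var, "or_": np.nan, "ci_lo": np.nan, "ci_hi": np.nan, "p": np.nan, "note": "dropped (collinear/constant)"})
            continue
        X = np.column_stack([np.ones(len(y)), x, g])
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        coef, se = fit.params[1], fit.bse[1]
        z = stats.norm.ppf(1 - alpha / 2)
        rows.append(
            {
                "variable": var,
                "or_": float(np.exp(coef)),
                "ci_lo": float(np.exp(coef - z * se)),
                "ci_hi": float(np.exp(coef + z * se)),
                "p": float(fit.pvalues[1]),
                "note": "",
            }
        )
    return pd.DataFrame(rows)
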