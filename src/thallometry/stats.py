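"""Group discrimination statistics for a per-specimen measurement table.

Input is a tidy table with one row per specimen, numeric columns for the
morphological variables (da, db, dc, bl, bs, ba by default) and one
categorical group column.  The layer provides:

* per-group descriptives (mean +/- sample SD),
* one-way ANOVA per variable with all-pairs Tukey HSD comparisons,
* the Pearson correlation matrix with two-sided p-values,
* MANOVA via Wilks' Lambda = det(W)/det(W+B) with Rao's F approximation,
* canonical discriminant analysis (CDA): the eigen-decomposition of
  W^-1 B, where W and B are the within- and between-group
  sum-of-squares-and-cross-products matrices.  With g groups and p
  variables there are f = min(g-1, p) canonical functions; for function
  i with eigenvalue lambda_i, the canonical correlation is
  sqrt(lambda_i / (1 + lambda_i)) and the residual Wilks' Lambda is
  prod_{j >= i} 1/(1 + lambda_j).  Raw coefficients are scaled so each
  canonical variable has unit pooled within-group variance.
* resubstitution classification: each specimen is assigned to the group
  whose mean is nearest in canonical space (Euclidean distance, equal
  priors), summarised as a g x g count matrix and an overall rate.

Shapiro-Wilk normality checks are delegated to scipy and merely
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

DEFAULT_VARIABLES = ["da", "db", "dc", "bl", "bs", "ba"]


class StatsError(ValueError):
    pass


def significance_code(p: float) -> str:
    """R-style stars: *** 0.001, ** 0.01, * 0.05, . 0.1, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return "ns"


def _check_table(df: pd.DataFrame, variables, group_col: str):
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise StatsError(f"missing variable columns: {missing}")
    if group_col not in df.columns:
        raise StatsError(f"missing group column {group_col!r}")
    sub = df[list(variables)]
    if sub.isna().any().any():
        raise StatsError("NaN values in measurement columns")
    groups = df[group_col].astype(str)
    return sub.to_numpy(float), groups


def descriptives(df: pd.DataFrame, variables=DEFAULT_VARIABLES,
                 group_col: str = "group") -> pd.DataFrame:
    """Per variable x group: n, mean and sample SD (n-1 denominator)."""
    _check_table(df, variables, group_col)
    counts = df.groupby(group_col).size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise StatsError(f"groups with n < 2 have undefined SD: {bad}")
    rows = []
    for grp, sub in df.groupby(group_col, sort=True):
        for var in variables:
            vals = sub[var].to_numpy(float)
            rows.append({"group": grp, "variable": var, "n": len(vals),
                         "mean": float(np.mean(vals)),
                         "sd": float(np.std(vals, ddof=1))})
    return pd.DataFrame(rows)


def anova_pairwise(df: pd.DataFrame, variable: str,
                   group_col: str = "group", alpha: float = 0.05
                   ) -> pd.DataFrame:
    """One-way ANOVA plus all-pairs Tukey HSD for one variable.

    Returns one row per group pair with the family-wise adjusted
    p-value and its significance code; the overall F statistic and
    p-value are attached as data-frame attrs.
    """
    _check_table(df, [variable], group_col)
    grouped = [sub[variable].to_numpy(float)
               for _, sub in df.groupby(group_col, sort=True)]
    if len(grouped) < 2:
        raise StatsError("need at least two groups")
    if all(np.ptp(g) == 0 for g in grouped):
        raise StatsError("zero within-group variance everywhere")
    f_stat, f_p = sps.f_oneway(*grouped)
    tk = pairwise_tukeyhsd(df[variable].to_numpy(float),
                           df[group_col].astype(str).to_numpy(), alpha=alpha)
    res = pd.DataFrame(tk.summary().data[1:],
                       columns=[c.strip() for c in tk.summary().data[0]])
    out = pd.DataFrame({
        "group1": res["group1"], "group2": res["group2"],
        "p_adj": res["p-adj"].astype(float),
    })
    out["code"] = out["p_adj"].map(significance_code)
    out.attrs["F"] = float(f_stat)
    out.attrs["p"] = float(f_p)
    out.attrs["variable"] = variable
    return out


def correlation_matrix(df: pd.DataFrame, variables=DEFAULT_VARIABLES
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r matrix and two-sided p-values (t-distribution)."""
    X = df[list(variables)].to_numpy(float)
    if X.shape[0] < 3:
        raise StatsError("need at least three rows")
    if (X.std(axis=0) == 0).any():
        zero = [v for v, s in zip(variables, X.std(axis=0)) if s == 0]
        raise StatsError(f"zero-variance columns: {zero}")
    p = len(variables)
    r = np.eye(p)
    pv = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            rr, pp = sps.pearsonr(X[:, i], X[:, j])
            r[i, j] = r[j, i] = rr
            pv[i, j] = pv[j, i] = pp
    idx = list(variables)
    return (pd.DataFrame(r, index=idx, columns=idx),
            pd.DataFrame(pv, index=idx, columns=idx))


def _scatter_matrices(X: np.ndarray, groups: pd.Series):
    grand = X.mean(axis=0)
    W = np.zeros((X.shape[1], X.shape[1]))
    B = np.zeros_like(W)
    labels = sorted(groups.unique())
    means = {}
    for grp in labels:
        sub = X[(groups == grp).to_numpy()]
        m = sub.mean(axis=0)
        means[grp] = m
        centred = sub - m
        W += centred.T @ centred
        d = (m - grand)[:, None]
        B += len(sub) * (d @ d.T)
    return W, B, grand, means, labels


def _rao_f(lmbda: float, p: int, g: int, n: int, k: int = 0):
    """Rao's F approximation for a (residual) Wilks' Lambda.

    ``k`` functions already removed; tests functions k+1..f jointly.
    """
    pp = p - k
    qq = g - k - 1
    m = n - 1 - (p + g) / 2.0
    df1 = pp * qq
    denom = pp * pp + qq * qq - 5
    if denom > 0:
        s = np.sqrt((pp * pp * qq * qq - 4.0) / denom)
    else:
        s = 1.0
    df2 = m * s - df1 / 2.0 + 1.0
    lam_s = lmbda ** (1.0 / s)
    F = (1.0 - lam_s) / lam_s * df2 / df1
    pval = float(sps.f.sf(F, df1, df2))
    return float(F), float(df1), float(df2), pval


def manova_wilks(df: pd.DataFrame, variables=DEFAULT_VARIABLES,
                 group_col: str = "group") -> dict:
    """Wilks' Lambda = det(W)/det(W+B) with Rao's F approximation."""
    X, groups = _check_table(df, variables, group_col)
    g = groups.nunique()
    n, p = X.shape
    if n - g <= p:
        raise StatsError("need n - g > p observations")
    W, B, _, _, _ = _scatter_matrices(X, groups)
    sign, logdet_w = np.linalg.slogdet(W)
    if sign <= 0:
        raise StatsError("singular within-group matrix; reduce variables")
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    lmbda = float(np.exp(logdet_w - logdet_t))
    F, df1, df2, pval = _rao_f(lmbda, p, g, n)
    return {"wilks_lambda": lmbda, "F": F, "df1": df1, "df2": df2,
            "p_value": pval, "n": n, "groups": g, "variables": list(variables)}


@dataclass
class CDAResult:
    variables: list
    group_labels: list
    eigenvalues: np.ndarray            # descending, length f
    canonical_correlations: np.ndarray
    wilks: np.ndarray                  # residual Lambda per function
    proportions: np.ndarray            # of the eigenvalue trace
    F: np.ndarray
    df1: np.ndarray
    df2: np.ndarray
    p_values: np.ndarray
    raw_coefficients: np.ndarray       # p x f, unit within-group variance
    standardized_coefficients: np.ndarray
    group_means: np.ndarray            # g x f, canonical space
    grand_mean: np.ndarray

    @property
    def n_functions(self) -> int:
        return len(self.eigenvalues)

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        X = df[list(self.variables)].to_numpy(float)
        return (X - self.grand_mean) @ self.raw_coefficients


def cda_fit(df: pd.DataFrame, variables=DEFAULT_VARIABLES,
            group_col: str = "group") -> CDAResult:
    """Canonical discriminant analysis of a grouped measurement table."""
    X, groups = _check_table(df, variables, group_col)
    n, p = X.shape
    g = groups.nunique()
    if g < 2:
        raise StatsError("need at least two groups")
    if n - g <= p:
        raise StatsError("need n - g > p observations")
    W, B, grand, means, labels = _scatter_matrices(X, groups)
    try:
        evals, evecs = linalg.eigh(B, W)
    except linalg.LinAlgError as exc:
        raise StatsError("singular within-group matrix; "
                         "reduce variables") from exc
    order = np.argsort(evals)[::-1]
    f = min(g - 1, p)
    evals = np.clip(evals[order][:f], 0, None)
    V = evecs[:, order][:, :f]

    # scale: unit pooled within-group variance of each canonical variable
    Sw = W / (n - g)
    norm = np.sqrt(np.einsum("ij,jk,ki->i", V.T, Sw, V))
    V = V / norm
    # deterministic sign: largest-magnitude coefficient positive
    for j in range(f):
        k = int(np.argmax(np.abs(V[:, j])))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]

    canon_r = np.sqrt(evals / (1.0 + evals))
    wilks = np.array([np.prod(1.0 / (1.0 + evals[i:])) for i in range(f)])
    total = evals.sum()
    if total > 0:
        proportions = evals / total
    else:
        proportions = np.full(f, np.nan)  # no between-group signal
    F = np.zeros(f)
    df1 = np.zeros(f)
    df2 = np.zeros(f)
    pv = np.zeros(f)
    for i in range(f):
        F[i], df1[i], df2[i], pv[i] = _rao_f(wilks[i], p, g, n, k=i)
    group_means = np.array([(means[l] - grand) @ V for l in labels])
    standardized = V * np.sqrt(np.diag(Sw))[:, None]
    return CDAResult(list(variables), labels, evals, canon_r, wilks,
                     proportions, F, df1, df2, pv, V, standardized,
                     group_means, grand)


def cda_classify(model: CDAResult, df: pd.DataFrame,
                 group_col: str = "group") -> tuple[pd.DataFrame, float]:
    """Nearest-group-mean classification in canonical space (equal priors).

    Returns the g x g count matrix (rows: true group, columns: assigned)
    and the overall correct rate trace/n.
    """
    missing = [v for v in model.variables if v not in df.columns]
    if missing:
        raise StatsError(f"variable mismatch; missing columns {missing}")
    scores = model.transform(df)
    d2 = ((scores[:, None, :] - model.group_means[None, :, :]) ** 2).sum(axis=2)
    assigned = np.argmin(d2, axis=1)
    labels = model.group_labels
    mat = pd.DataFrame(0, index=labels, columns=labels)
    truth = df[group_col].astype(str).to_numpy()
    for t, a in zip(truth, assigned):
        mat.loc[t, labels[a]] += 1
    rate = float(np.trace(mat.to_numpy()) / len(df))
    return mat, rate


def cda_summary_table(model: CDAResult) -> pd.DataFrame:
    """Per-function summary: canonical correlation, eigenvalue, Wilks,
    proportion of trace, F approximation and p-value."""
    return pd.DataFrame({
        "function": np.arange(1, model.n_functions + 1),
        "canonical_correlation": model.canonical_correlations,
        "eigenvalue": model.eigenvalues,
        "wilks_lambda": model.wilks,
        "proportion": model.proportions,
        "F": model.F,
        "df1": model.df1,
        "df2": model.df2,
        "p_value": model.p_values,
        "code": [significance_code(p) for p in model.p_values],
    })


def normality(df: pd.DataFrame, variables=DEFAULT_VARIABLES,
              group_col: str = "group") -> pd.DataFrame:
    """Shapiro-Wilk W and p per variable x group (reported, not judged)."""
    rows = []
    for grp, sub in df.groupby(group_col, sort=True):
        for var in variables:
            vals = sub[var].to_numpy(float)
            if len(vals) < 3:
                continue
            w, p = sps.shapiro(vals)
            rows.append({"group": grp, "variable": var,
                         "W": float(w), "p_value": float(p)})
    return pd.DataFrame(rows)
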