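"""Group-level inference on residual FC matrices and network summaries.

Edge-wise unpaired permutation tests (t statistic, 2000 relabelings shared
across edges), control-referenced z-score maps for patient subgroups,
standard effect sizes (Cohen's d, Vargha-Delaney A, partial eta squared),
univariate group comparisons with a normality screen, moderation
(interaction) regression with post-hoc simple slopes, and exploratory
clinical-factor correlations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import FCMatrix

__all__ = [
    "EdgeStatsResult",
    "ZScoreMap",
    "ModerationResult",
    "edgewise_permutation_test",
    "zscore_subgroup_maps",
    "cohens_d",
    "vargha_delaney_a",
    "effect_sizes",
    "univariate_group_tests",
    "moderation_regression",
    "simple_slopes",
    "clinical_correlations",
]

CLINICAL_CODING = {
    "epilepsy_type": {"FLE": 0, "TLE": 1},
    "lateralization": {"left": 0, "right": 1, "bilateral": 2},
    "seizure_control": {"yes": 1, "no": 0},
}


def _stack(matrices) -> np.ndarray:
    return np.stack([m.values if isinstance(m, FCMatrix) else np.asarray(m) for m in matrices])


def _student_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized two-sample (pooled-variance Student) t along axis 0."""
    nx, ny = x.shape[0], y.shape[0]
    mx, my = x.mean(axis=0), y.mean(axis=0)
    vx = x.var(axis=0, ddof=1)
    vy = y.var(axis=0, ddof=1)
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (mx - my) / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))


@dataclass
class EdgeStatsResult:
    """Edge-wise two-group comparison (symmetric matrices throughout)."""

    t: np.ndarray
    p: np.ndarray
    d: np.ndarray
    n_permutations: int
    seed: int

    @property
    def significant(self) -> np.ndarray:
        sig = self.p < 0.05
        np.fill_diagonal(sig, False)
        return sig

    def edge_table(self, channels: list[str] | None = None, alpha: float = 0.05) -> pd.DataFrame:
        """Tidy edge list of significant differences (connectogram-ready)."""
        n = self.t.shape[0]
        names = channels or [f"CH{i + 1:02d}" for i in range(n)]
        rows = []
        iu = zip(*np.triu_indices(n, k=1))
        for i, j in iu:
            if self.p[i, j] < alpha:
                rows.append(
                    {
                        "ch_i": names[i],
                        "ch_j": names[j],
                        "t": self.t[i, j],
                        "p": self.p[i, j],
                        "d": self.d[i, j],
                        "direction": "patients>controls" if self.t[i, j] > 0 else "patients<controls",
                    }
                )
        return pd.DataFrame(rows)


def edgewise_permutation_test(
    r_patients,
    r_controls,
    n_perm: int = 2000,
    seed: int = 0,
    exact: bool | None = None,
) -> EdgeStatsResult:
    """Unpaired permutation tests on residual matrices, one per edge.

    The observed statistic is the two-sample Student t (patients minus
    controls); the null is built from ``n_perm`` random group relabelings,
    with the same permutation sequence applied to every edge so the
    cross-edge dependence of the null is preserved. Two-sided
    p = (#{|t_perm| >= |t_obs|} + 1) / (n_perm + 1). With ``exact=True``
    (or automatically when feasible within ``n_perm``) all distinct group
    splits are enumerated instead and p = #{|t| >= |t_obs|} / n_splits.
    Zero-variance edges get p = 1 and t = d = 0 with a warning.
    """
    xp = _stack(r_patients)
    xc = _stack(r_controls)
    if xp.shape[0] < 2 or xc.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    n_p, n_c = xp.shape[0], xc.shape[0]
    shape = xp.shape[1:]
    pooled = np.concatenate([xp, xc], axis=0).reshape(n_p + n_c, -1)
    t_obs = _student_t(xp.reshape(n_p, -1), xc.reshape(n_c, -1))

    from math import comb

    n_total = n_p + n_c
    n_splits = comb(n_total, n_p)
    if exact is None:
        exact = n_splits <= n_perm
    rng = np.random.default_rng(seed)

    if exact:
        from itertools import combinations

        count = np.zeros(pooled.shape[1])
        for idx in combinations(range(n_total), n_p):
            sel = np.zeros(n_total, dtype=bool)
            sel[list(idx)] = True
            t_perm = _student_t(pooled[sel], pooled[~sel])
            count += np.abs(np.nan_to_num(t_perm)) >= np.abs(np.nan_to_num(t_obs)) - 1e-12
        p = count / n_splits
        n_used = n_splits
    else:
        count = np.zeros(pooled.shape[1])
        for _ in range(n_perm):
            perm = rng.permutation(n_total)
            t_perm = _student_t(pooled[perm[:n_p]], pooled[perm[n_p:]])
            count += np.abs(np.nan_to_num(t_perm)) >= np.abs(np.nan_to_num(t_obs))
        p = (count + 1.0) / (n_perm + 1.0)
        n_used = n_perm

    bad = ~np.isfinite(t_obs)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance edges skipped (p set to 1)")
        t_obs = np.nan_to_num(t_obs)
        p[bad] = 1.0

    d = cohens_d(xp.reshape(n_p, -1), xc.reshape(n_c, -1), axis=0)
    t_m = t_obs.reshape(shape)
    p_m = p.reshape(shape)
    d_m = np.nan_to_num(d.reshape(shape))
    if len(shape) == 2 and shape[0] == shape[1]:
        np.fill_diagonal(p_m, 1.0)
        np.fill_diagonal(t_m, 0.0)
        np.fill_diagonal(d_m, 0.0)
    return EdgeStatsResult(t=t_m, p=p_m, d=d_m, n_permutations=n_used, seed=seed)


@dataclass
class ZScoreMap:
    """Control-referenced mean z map for a patient subgroup."""

    z: np.ndarray
    subgroup: str
    mask_low: np.ndarray
    mask_high: np.ndarray
    undefined: np.ndarray

    def edge_table(self, channels: list[str] | None = None) -> pd.DataFrame:
        n = self.z.shape[0]
        names = channels or [f"CH{i + 1:02d}" for i in range(n)]
        rows = []
        for i, j in zip(*np.triu_indices(n, k=1)):
            if self.mask_low[i, j] or self.mask_high[i, j]:
                rows.append(
                    {
                        "subgroup": self.subgroup,
                        "ch_i": names[i],
                        "ch_j": names[j],
                        "z": self.z[i, j],
                        "direction": "low" if self.mask_low[i, j] else "high",
                    }
                )
        return pd.DataFrame(rows)


def zscore_subgroup_maps(
    r_subgroup, control_mean: np.ndarray, control_sd: np.ndarray, subgroup: str = ""
) -> ZScoreMap:
    """Patients' residual matrices as z relative to the control distribution.

    z_n = (R_n - mu_ctrl) / sigma_ctrl per edge, averaged over the
    subgroup; edges at least 2 SD below/above the controls are masked
    separately (disjoint by construction). Edges with zero control SD are
    flagged undefined.
    """
    stack = _stack(r_subgroup)
    sd = np.asarray(control_sd, dtype=float)
    undefined = sd <= 0
    safe_sd = np.where(undefined, np.nan, sd)
    z = (stack - control_mean[None]) / safe_sd[None]
    zbar = z.mean(axis=0)
    np.fill_diagonal(zbar, 0.0)
    mask_low = np.nan_to_num(zbar) <= -2.0
    mask_high = np.nan_to_num(zbar) >= 2.0
    np.fill_diagonal(mask_low, False)
    np.fill_diagonal(mask_high, False)
    return ZScoreMap(z=zbar, subgroup=subgroup, mask_low=mask_low, mask_high=mask_high, undefined=undefined)


def cohens_d(x, y, axis: int | None = None) -> np.ndarray | float:
    """Cohen's d with the pooled standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if axis is None:
        x, y, axis = x.ravel(), y.ravel(), 0
    nx = x.shape[axis]
    ny = y.shape[axis]
    sp2 = ((nx - 1) * x.var(axis=axis, ddof=1) + (ny - 1) * y.var(axis=axis, ddof=1)) / (
        nx + ny - 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        return (x.mean(axis=axis) - y.mean(axis=axis)) / np.sqrt(sp2)


def vargha_delaney_a(x, y) -> float:
    """Probability-of-superiority effect size A(x, y), ties counted half."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    greater = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float((greater + 0.5 * ties) / (x.size * y.size))


def effect_sizes(x, y) -> tuple[float, float]:
    """(Cohen's d, Vargha-Delaney A) for two samples."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    return float(cohens_d(x, y)), vargha_delaney_a(x, y)


def univariate_group_tests(
    table: pd.DataFrame,
    variables: list[str],
    group_col: str = "group",
    groups: tuple[str, str] = ("epilepsy", "control"),
    alpha_normality: float = 0.05,
) -> pd.DataFrame:
    """Per-variable two-group comparison with automatic test selection.

    Continuous variables: Shapiro-Wilk screen in each group; Student's t
    when both pass, Mann-Whitney U otherwise. Categorical (non-numeric)
    variables: Fisher's exact test on the 2xK contingency table (2x2 via
    scipy; larger tables fall back to chi-squared with a note). Cohen's d
    and Vargha-Delaney A accompany continuous tests.
    """
    rows = []
    g1 = table[table[group_col] == groups[0]]
    g2 = table[table[group_col] == groups[1]]
    for var in variables:
        s1 = g1[var].dropna()
        s2 = g2[var].dropna()
        if s1.empty or s2.empty:
            continue
        if pd.api.types.is_numeric_dtype(table[var]):
            x, y = s1.to_numpy(float), s2.to_numpy(float)
            normal = (
                stats.shapiro(x).pvalue > alpha_normality
                and stats.shapiro(y).pvalue > alpha_normality
                if min(x.size, y.size) >= 3
                else False
            )
            if normal:
                res = stats.ttest_ind(x, y)
                test, stat = "t", float(res.statistic)
            else:
                res = stats.mannwhitneyu(x, y, alternative="two-sided")
                test, stat = "mannwhitney", float(res.statistic)
            d, a = effect_sizes(x, y) if min(x.size, y.size) >= 2 else (np.nan, np.nan)
            rows.append(
                {"variable": var, "test": test, "statistic": stat, "p": float(res.pvalue), "d": d, "A": a}
            )
        else:
            contingency = pd.crosstab(table[group_col], table[var])
            if contingency.shape == (2, 2):
                _, pval = stats.fisher_exact(contingency.to_numpy())
                test = "fisher"
            else:
                _, pval, _, _ = stats.chi2_contingency(contingency.to_numpy())
                test = "chi2"
            rows.append(
                {"variable": var, "test": test, "statistic": np.nan, "p": float(pval), "d": np.nan, "A": np.nan}
            )
    return pd.DataFrame(rows)


@dataclass
class ModerationResult:
    """OLS moderation model: y = b0 + b1*x_c + b2*group + b3*x_c*group.

    ``x_c`` is the predictor centered on the pooled mean and ``group`` is
    coded control = 0, epilepsy (patients) = 1, so b1 is the control-group
    simple slope and b1 + b3 the patient-group slope.
    """

    params: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    cov_params: pd.DataFrame
    f_stat: float
    f_pvalue: float
    adj_r2: float
    partial_eta_sq: pd.Series
    x_mean: float
    nobs: int


def moderation_regression(
    outcome: np.ndarray,
    predictor: np.ndarray,
    group: np.ndarray,
    patient_label="epilepsy",
) -> ModerationResult:
    """Fit the group-moderation model by OLS.

    ``group`` may be string labels (entries equal to ``patient_label``
    become 1) or a 0/1 indicator. The predictor is centered on the pooled
    mean before forming the interaction. Partial eta squared per effect is
    SS_effect / (SS_effect + SS_residual) with type-III SS (drop-one
    refits).
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    g = np.asarray(group)
    if g.dtype.kind in "UOS":
        g = (g == patient_label).astype(float)
    else:
        g = g.astype(float)
    if np.unique(g).size < 2 or min((g == 0).sum(), (g == 1).sum()) < 3:
        raise ValueError("need at least 3 subjects per group")
    if x.var() <= 0:
        raise ValueError("predictor has zero variance")
    x_mean = float(x.mean())
    xc = x - x_mean
    X = pd.DataFrame(
        {"const": 1.0, "x": xc, "group": g, "x:group": xc * g}
    )
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    ss_res = float(fit.ssr)
    eta = {}
    for term in ("x", "group", "x:group"):
        reduced = sm.OLS(y, X.drop(columns=[term])).fit()
        ss_effect = float(reduced.ssr) - ss_res
        eta[term] = ss_effect / (ss_effect + ss_res) if (ss_effect + ss_res) > 0 else np.nan
    return ModerationResult(
        params=fit.params,
        pvalues=fit.pvalues,
        conf_int=fit.conf_int(),
        cov_params=fit.cov_params(),
        f_stat=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        adj_r2=float(fit.rsquared_adj),
        partial_eta_sq=pd.Series(eta),
        x_mean=x_mean,
        nobs=int(fit.nobs),
    )


def simple_slopes(result: ModerationResult) -> pd.DataFrame:
    """Per-group predictor slopes with SE and two-sided p.

    Control slope = b1; patient slope = b1 + b3 with
    Var = Var(b1) + Var(b3) + 2 Cov(b1, b3). Degrees of freedom are
    n - 4 (the model's residual df).
    """
    b = result.params
    cov = result.cov_params
    df = result.nobs - 4
    rows = []
    for label, slope, var in (
        ("control", b["x"], cov.loc["x", "x"]),
        (
            "epilepsy",
            b["x"] + b["x:group"],
            cov.loc["x", "x"] + cov.loc["x:group", "x:group"] + 2 * cov.loc["x", "x:group"],
        ),
    ):
        se = float(np.sqrt(var))
        t = slope / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
        rows.append({"group": label, "slope": float(slope), "se": se, "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


def clinical_correlations(
    auc_table: pd.DataFrame,
    cohort: pd.DataFrame,
    factors: dict[str, str] | None = None,
    metrics: list[str] | None = None,
) -> pd.DataFrame:
    """Clinical factor x network metric correlation table (patients only).

    ``factors`` maps column name -> 'continuous' (Pearson) or
    'categorical' (Spearman on the numeric coding in CLINICAL_CODING).
    Entries with a constant factor or fewer than 3 complete pairs are left
    undefined (NaN).
    """
    factors = factors or {
        "epilepsy_type": "categorical",
        "lateralization": "categorical",
        "onset_age": "continuous",
        "duration": "continuous",
        "seizure_control": "categorical",
    }
    patients = cohort[cohort["group"] == "epilepsy"].set_index("subject")
    wide = auc_table.pivot(index="subject", columns="metric", values="auc")
    wide = wide.loc[wide.index.intersection(patients.index)]
    metrics = metrics or list(wide.columns)
    rows = []
    for factor, kind in factors.items():
        raw = patients.loc[wide.index, factor]
        if kind == "categorical" and factor in CLINICAL_CODING:
            coded = raw.map(CLINICAL_CODING[factor]).astype(float)
        else:
            # already-numeric factors (rank correlation only uses the order)
            coded = raw.astype(float)
        for metric in metrics:
            pair = pd.DataFrame({"f": coded, "m": wide[metric]}).dropna()
            if len(pair) < 3 or pair["f"].nunique() < 2 or pair["m"].nunique() < 2:
                r, p = np.nan, np.nan
            elif kind == "categorical":
                r, p = stats.spearmanr(pair["f"], pair["m"])
            else:
                r, p = stats.pearsonr(pair["f"], pair["m"])
            rows.append(
                {"factor": factor, "metric": metric, "kind": kind, "r": float(r) if np.isfinite(r) else np.nan, "p": float(p) if np.isfinite(p) else np.nan, "n": len(pair)}
            )
    return pd.DataFrame(rows)
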