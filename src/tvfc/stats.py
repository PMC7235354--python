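"""Group comparison of variability features and clinical correlations.

The inference chain per feature: (1) ANCOVA — an F-test for a group
main effect in a linear model adjusting for age, sex, education and
mean framewise displacement; (2) when the main effect is significant
(p < gate alpha, uncorrected across features), covariate-adjusted
pairwise contrasts between all group pairs with Bonferroni correction
within the family of pairs; (3) Spearman rank correlations between
significant features and clinical/cognitive scores, per group and
pooled, uncorrected.

Missing feature values (undefined variability) and missing covariates
are removed listwise per feature and the per-feature N is reported;
they never enter a test silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "DEFAULT_COVARIATES",
    "AncovaResult",
    "ancova_main_effect",
    "posthoc_pairwise",
    "spearman_assoc",
    "group_comparison",
    "clinical_correlations",
]

DEFAULT_COVARIATES = ("age", "sex", "education", "mean_fd")


@dataclass
class AncovaResult:
    f_stat: float
    p_value: float
    df_num: int
    df_den: int
    n_used: int


def _design(
    table: pd.DataFrame, covariates: Sequence[str]
) -> np.ndarray:
    """Covariate design matrix (no intercept, no group columns).

    Non-numeric columns (e.g. sex labels) are coded as integer
    categories; with two levels this is a single indicator.
    """
    cols = []
    for c in covariates:
        col = table[c]
        if not pd.api.types.is_numeric_dtype(col):
            col = pd.Categorical(col).codes.astype(float)
        cols.append(np.asarray(col, dtype=float))
    if not cols:
        return np.empty((len(table), 0))
    return np.column_stack(cols)


def _complete_cases(
    y: pd.Series | np.ndarray,
    table: pd.DataFrame,
    covariates: Sequence[str],
    group_col: str,
) -> tuple[np.ndarray, np.ndarray, pd.Series]:
    y = np.asarray(y, dtype=float)
    if len(y) != len(table):
        raise ValueError("feature vector and cohort table lengths differ")
    X = _design(table, covariates)
    groups = table[group_col]
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1) & groups.notna().values
    return y[keep], X[keep], groups[keep].reset_index(drop=True)


def ancova_main_effect(
    y: pd.Series | np.ndarray,
    table: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    group_col: str = "group",
) -> AncovaResult:
    """F-test for the group main effect, adjusting for covariates.

    Compares [1 | covariates | group dummies] against [1 | covariates];
    degrees of freedom (G-1, N-G-C).  Rows with missing data are
    dropped listwise.
    """
    yv, X, groups = _complete_cases(y, table, covariates, group_col)
    levels = sorted(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups with data")
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ValueError(f"every group needs >= 2 subjects; got {dict(counts)}")
    n = len(yv)
    dummies = np.column_stack(
        [(groups == lev).astype(float) for lev in levels[1:]]
    )
    X_red = sm.add_constant(X, has_constant="add")
    X_full = np.column_stack([X_red, dummies])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError(
            "rank-deficient ANCOVA design; check covariates "
            f"{list(covariates)} for collinearity with the intercept/group"
        )
    fit_full = sm.OLS(yv, X_full).fit()
    fit_red = sm.OLS(yv, X_red).fit()
    f_stat, p_value, df_num = fit_full.compare_f_test(fit_red)
    df_den = n - X_full.shape[1]
    return AncovaResult(float(f_stat), float(p_value), int(df_num), int(df_den), n)


def posthoc_pairwise(
    y: pd.Series | np.ndarray,
    table: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    group_col: str = "group",
    bonferroni_factor: int | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted two-group contrasts for every group pair.

    Each pair is tested on its two-group subset by the t-test on the
    group indicator in [1 | covariates | indicator]; corrected p =
    min(1, raw p x number of pairs).  Returns one row per pair with
    columns group_a, group_b, diff, p_raw, p_bonferroni, n.
    """
    yv, X, groups = _complete_cases(y, table, covariates, group_col)
    levels = sorted(pd.unique(groups))
    pairs = list(combinations(levels, 2))
    factor = bonferroni_factor if bonferroni_factor is not None else len(pairs)
    rows = []
    for a, b in pairs:
        sel = (groups == a) | (groups == b)
        if (groups[sel] == a).sum() == 0 or (groups[sel] == b).sum() == 0:
            continue  # degenerate pair
        ys = yv[sel.values]
        ind = (groups[sel] == b).astype(float).values
        Xs = sm.add_constant(
            np.column_stack([X[sel.values], ind]), has_constant="add"
        )
        fit = sm.OLS(ys, Xs).fit()
        p_raw = float(fit.pvalues[-1])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "diff": float(fit.params[-1]),
                "p_raw": p_raw,
                "p_bonferroni": min(1.0, p_raw * factor),
                "n": int(sel.sum()),
            }
        )
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "diff", "p_raw", "p_bonferroni", "n"]
    )


def spearman_assoc(x, y, min_pairs: int = 5) -> tuple[float, float, int]:
    """Spearman rank correlation with average-rank ties and two-sided
    t-approximation p, on complete pairs.

    Returns (rho, p, n); (nan, nan, n) when fewer than ``min_pairs``
    complete pairs remain or either side is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    n = int(keep.sum())
    if n < min_pairs:
        return float("nan"), float("nan"), n
    xs, ys = x[keep], y[keep]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return float("nan"), float("nan"), n
    rho, p = sps.spearmanr(xs, ys)
    return float(rho), float(p), n


def group_comparison(
    features: pd.DataFrame,
    table: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    group_col: str = "group",
    gate_alpha: float = 0.05,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """ANCOVA per feature, post-hoc contrasts where gated.

    ``features`` rows must align with ``table`` rows.  One output row
    per (feature, group pair), plus pairs left NaN for features whose
    main effect did not pass the gate.  ``fdr`` optionally
    Benjamini-Hochberg-adjusts the ANCOVA p-values across features
    (off by default; the primary analysis applies no correction across
    ROIs/networks).
    """
    results = []
    anc: dict[str, AncovaResult] = {}
    for feat in features.columns:
        y = features[feat]
        if np.isfinite(np.asarray(y, float)).sum() < 4:
            continue  # undefined feature (e.g. 2-ROI network): skipped, reported absent
        anc[feat] = ancova_main_effect(y, table, covariates, group_col)
    gate_p = {f: r.p_value for f, r in anc.items()}
    if fdr and anc:
        from statsmodels.stats.multitest import multipletests

        feats = list(anc)
        _, p_adj, *_ = multipletests([anc[f].p_value for f in feats], method="fdr_bh")
        gate_p = dict(zip(feats, p_adj))
    for feat, res in anc.items():
        gated_in = gate_p[feat] < gate_alpha
        if gated_in:
            ph = posthoc_pairwise(features[feat], table, covariates, group_col)
        else:
            ph = pd.DataFrame()
        if ph.empty:
            results.append(
                {
                    "feature": feat,
                    "ancova_f": res.f_stat,
                    "ancova_p": res.p_value,
                    "df_num": res.df_num,
                    "df_den": res.df_den,
                    "n": res.n_used,
                    "group_a": None,
                    "group_b": None,
                    "diff": np.nan,
                    "p_raw": np.nan,
                    "p_bonferroni": np.nan,
                    "significant": False,
                }
            )
        else:
            for _, row in ph.iterrows():
                results.append(
                    {
                        "feature": feat,
                        "ancova_f": res.f_stat,
                        "ancova_p": res.p_value,
                        "df_num": res.df_num,
                        "df_den": res.df_den,
                        "n": res.n_used,
                        "group_a": row["group_a"],
                        "group_b": row["group_b"],
                        "diff": row["diff"],
                        "p_raw": row["p_raw"],
                        "p_bonferroni": row["p_bonferroni"],
                        "significant": bool(row["p_bonferroni"] < alpha),
                    }
                )
    return pd.DataFrame(results)


def clinical_correlations(
    features: pd.DataFrame,
    table: pd.DataFrame,
    scores: Sequence[str],
    feature_names: Sequence[str] | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Spearman correlations of features with clinical scores, pooled
    and within each group; uncorrected p-values."""
    feats = list(feature_names) if feature_names is not None else list(features.columns)
    scopes = ["pooled"] + sorted(pd.unique(table[group_col].dropna()))
    rows = []
    for score in scores:
        if score not in table.columns:
            continue
        for feat in feats:
            for scope in scopes:
                if scope == "pooled":
                    mask = np.ones(len(table), dtype=bool)
                else:
                    mask = (table[group_col] == scope).values
                rho, p, n = spearman_assoc(
                    table.loc[mask, score], features.loc[mask, feat]
                )
                rows.append(
                    {
                        "score": score,
                        "feature": feat,
                        "scope": scope,
                        "rho": rho,
                        "p": p,
                        "n": n,
                    }
                )
    return pd.DataFrame(rows, columns=["score", "feature", "scope", "rho", "p", "n"])
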