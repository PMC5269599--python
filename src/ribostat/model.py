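"""Linear models relating TE change to sequence features.

Univariate scans, bidirectional stepwise selection by information
criterion with an optional interaction term, quartile-bin one-way ANOVA,
and direction-by-Kozak-count chi-square tests.  The response throughout
is the log2 TE fold change of transcripts with significant TE regulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import RibostatError

#: default stepwise candidates: the decorrelated predictor set plus the
#: (normalized 5'UTR structure x upstream Kozak) interaction
DEFAULT_CANDIDATES = (
    "n_upstream_kozak",
    "norm_ss_utr5",
    "ss_cds",
    "short_utr3",
    "utr5_gc",
    "norm_ss_utr3",
)
DEFAULT_INTERACTIONS = (("norm_ss_utr5", "n_upstream_kozak"),)


@dataclass
class ModelFit:
    """Summary of one fitted linear model."""

    predictors: tuple[str, ...]
    params: pd.DataFrame            # coef, se, p per term (incl. intercept)
    r2: float
    adj_r2: float
    f_pvalue: float
    n: int
    criterion: str = "ols"
    criterion_value: float = field(default=float("nan"))


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    if X.shape[1] == 0:
        return sm.OLS(y, np.ones((len(y), 1))).fit()
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def _summarize(fit, predictors, criterion="ols", crit_value=float("nan")) -> ModelFit:
    params = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "p": fit.pvalues}
    )
    return ModelFit(
        predictors=tuple(predictors),
        params=params,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        f_pvalue=float(fit.f_pvalue) if len(predictors) else float("nan"),
        n=int(fit.nobs),
        criterion=criterion,
        criterion_value=crit_value,
    )


def _complete_rows(features: pd.DataFrame, response: pd.Series, cols) -> tuple[pd.DataFrame, np.ndarray]:
    df = features.reindex(response.index)[list(cols)].copy()
    df["__y"] = response
    df = df.dropna()
    return df[list(cols)], df["__y"].to_numpy()


def univariate_scan(
    features: pd.DataFrame,
    response: pd.Series,
    predictors: list[str] | None = None,
) -> pd.DataFrame:
    """One OLS fit per predictor, sorted by adjusted R^2 (descending).

    Returns a table with predictor, coef, adj_r2, r2, p (F-test), n.
    Constant predictors are skipped with a warning.
    """
    preds = list(predictors) if predictors is not None else list(features.columns)
    rows = []
    for name in preds:
        X, y = _complete_rows(features, response, [name])
        if len(X) < 3 or X[name].nunique() <= 1:
            warnings.warn(f"skipping constant/degenerate predictor {name!r}")
            continue
        fit = _fit_ols(y, X)
        rows.append(
            (name, float(fit.params[name]), float(fit.rsquared_adj),
             float(fit.rsquared), float(fit.f_pvalue), int(fit.nobs))
        )
    return (
        pd.DataFrame(rows, columns=["predictor", "coef", "adj_r2", "r2", "p", "n"])
        .sort_values("adj_r2", ascending=False)
        .reset_index(drop=True)
    )


def _interaction_name(a: str, b: str) -> str:
    return f"{a}:{b}"


def build_design(
    features: pd.DataFrame,
    candidates=DEFAULT_CANDIDATES,
    interactions=DEFAULT_INTERACTIONS,
) -> pd.DataFrame:
    """Candidate design matrix with product columns for interactions.

    Interaction factors are mean-centered before multiplying so the
    product measures the interaction itself rather than aliasing the main
    effects (a raw product with a nonzero-mean factor is nearly collinear
    with the other factor's main effect).
    """
    X = features[list(candidates)].copy()
    for a, b in interactions or ():
        ca = features[a] - features[a].mean()
        cb = features[b] - features[b].mean()
        X[_interaction_name(a, b)] = ca * cb
    return X


def _criterion_value(fit, kind: str) -> float:
    if kind == "bic":
        return float(fit.bic)
    if kind == "aic":
        return float(fit.aic)
    if kind == "aicc":
        k = fit.df_model + 1
        n = fit.nobs
        corr = 2 * k * (k + 1) / max(n - k - 1, 1e-9)
        return float(fit.aic + corr)
    raise RibostatError(f"unknown criterion {kind!r}")


def stepwise_select(
    features: pd.DataFrame,
    response: pd.Series,
    candidates=DEFAULT_CANDIDATES,
    interactions=DEFAULT_INTERACTIONS,
    criterion: str = "bic",
) -> ModelFit:
    """Bidirectional stepwise regression from the intercept-only model.

    At each step the single add/drop move that most improves the
    information criterion is taken; the search stops when no move helps.
    BIC is the default for its selection consistency; "aicc"/"aic" are
    available.
    """
    X_all = build_design(features, candidates, interactions)
    X_all, y = _complete_rows(X_all, response, X_all.columns)
    n = len(X_all)
    if n <= X_all.shape[1]:
        raise RibostatError(
            f"n = {n} rows with complete predictors <= {X_all.shape[1]} candidates"
        )
    current: list[str] = []
    fit = _fit_ols(y, X_all[current])
    best = _criterion_value(fit, criterion)
    while True:
        moves = []
        for c in X_all.columns:
            trial = current + [c] if c not in current else [x for x in current if x != c]
            f = _fit_ols(y, X_all[trial])
            moves.append((_criterion_value(f, criterion), trial, f))
        moves.sort(key=lambda m: m[0])
        if moves and moves[0][0] < best - 1e-10:
            best, current, fit = moves[0][0], moves[0][1], moves[0][2]
        else:
            break
    return _summarize(fit, current, criterion, best)


def collinearity_report(
    features: pd.DataFrame,
    candidates: list[str] | None = None,
    threshold: float = 0.9,
) -> pd.DataFrame:
    """Pairwise Pearson correlations with a high-collinearity flag."""
    cols = list(candidates) if candidates else list(features.columns)
    sub = features[cols].dropna()
    if len(sub) < 3:
        raise RibostatError("need >= 3 complete rows")
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = float(np.corrcoef(sub[a], sub[b])[0, 1])
            rows.append((a, b, r, abs(r) > threshold))
    return pd.DataFrame(rows, columns=["a", "b", "r", "flagged"])


def quartile_anova(predictor, response) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA of the response across predictor quartile bins.

    Bin edges are the sample quartiles; values equal to an edge fall in the
    lower bin.  Bins emptied by ties are merged into their lower neighbour
    with a warning.
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(response, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 8:
        raise RibostatError("need n >= 8")
    if np.unique(x).size < 4:
        raise RibostatError("predictor needs >= 4 distinct values")
    edges = np.quantile(x, [0.25, 0.5, 0.75])
    bins = np.searchsorted(edges, x, side="left")  # == edge -> lower bin
    groups = [y[bins == b] for b in range(4)]
    if any(len(g) == 0 for g in groups):
        warnings.warn("empty quartile bin after ties; merging with neighbour")
        groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise RibostatError("fewer than 2 non-empty bins")
    if np.ptp(np.concatenate(groups)) == 0:
        F, p = 0.0, 1.0
    else:
        F, p = stats.f_oneway(*groups)
        if np.isnan(F):  # degenerate within-bin variance
            F, p = 0.0, 1.0
    means = pd.DataFrame(
        {
            "bin": range(len(groups)),
            "n": [len(g) for g in groups],
            "mean": [float(np.mean(g)) for g in groups],
        }
    )
    return float(F), float(p), means


def direction_chisq(
    kozak_counts,
    directions,
    bins=(0, 1, 2),
) -> tuple[float, float, pd.DataFrame]:
    """Pearson chi-square of TE direction vs binned upstream-Kozak count.

    Counts are binned as {0, 1, 2, >=3} by default; bins with expected
    cell counts < 1 are collapsed into the previous bin with a warning.
    ``directions`` holds 'up'/'down' labels.
    """
    k = np.asarray(kozak_counts)
    d = np.asarray(directions)
    if k.size != d.size or k.size == 0:
        raise RibostatError("kozak counts and directions must align")
    edges = list(bins)
    labels = [str(b) for b in edges] + [f">={edges[-1] + 1}"]
    binned = np.searchsorted(edges, k, side="left")  # 0..len(edges)
    table = pd.crosstab(
        pd.Categorical.from_codes(binned, categories=labels), d
    )
    table = table.loc[[l for l in labels if l in table.index]]
    while len(table) > 1:
        expected = (
            np.outer(table.sum(1), table.sum(0)) / table.to_numpy().sum()
        )
        if (expected >= 1).all():
            break
        warnings.warn("expected cell < 1; collapsing highest Kozak bins")
        last = table.iloc[-1]
        table = table.iloc[:-1]
        table.iloc[-1] += last
    if len(table) < 2 or table.shape[1] < 2:
        raise RibostatError("contingency table degenerate after collapsing")
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), float(p), table
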