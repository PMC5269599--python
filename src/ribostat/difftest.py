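"""Permutation-style differential testing and regulatory-pattern calls.

Each transcript is tested for differential RNA abundance, ribosomal
occupancy (RF) and translation efficiency (TE) between two conditions.
The observed statistic is the Welch t on log2 values; the null is built
by resampling with replacement from the pooled within-group-centered
residuals (rescaled by sqrt(n_g/(n_g-1)) to undo the centering bias),
with the small-sample correction p = (1 + #{|t*| >= |t|}) / (1 + B).
With 3 vs 2 replicates exhaustive label permutation offers only 10
distinct splits (p can never reach 0.05), which is why a with-replacement
null is used; exhaustive permutation remains available via
scheme="exhaustive".

Significant transcripts are classified into regulatory patterns:
"forwarded" (RNA and RF move together, TE unchanged), "TE-only",
"homeostatic" (TE opposes RNA, RF flat) and "synergistic" (TE amplifies
RNA).
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .core import RibostatError

PATTERN_LABELS = (
    "forwarded_up", "forwarded_down",
    "te_only_up", "te_only_down",
    "homeostatic",
    "synergistic_up", "synergistic_down",
    "unclassified",
)

_CHUNK = 256  # transcripts per vectorized resampling block


def welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Welch (unequal-variance) t along the last axis; 0/0 -> 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    den = np.sqrt(a.var(-1, ddof=1) / a.shape[-1] + b.var(-1, ddof=1) / b.shape[-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(-1) - b.mean(-1)) / den
    return np.where(den == 0, 0.0, t)


def _null_pool(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pooled centered residuals, rescaled for the centering ddof."""
    na, nb = A.shape[-1], B.shape[-1]
    ra = (A - A.mean(-1, keepdims=True)) * np.sqrt(na / (na - 1.0))
    rb = (B - B.mean(-1, keepdims=True)) * np.sqrt(nb / (nb - 1.0))
    return np.concatenate([ra, rb], axis=-1)


def permuted_t_matrix(
    A: np.ndarray,
    B: np.ndarray,
    n_resamples: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized resampling test for many transcripts at once.

    ``A`` (n_t, n_a) and ``B`` (n_t, n_b) hold log-scale values; returns
    (t, p) arrays of length n_t.  Resampling indices are drawn
    independently per transcript.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise RibostatError("each group needs >= 2 values")
    if n_resamples < 100:
        warnings.warn("n_resamples < 100 gives a very coarse p-value grid")
    na, nb = A.shape[1], B.shape[1]
    n = na + nb
    t_obs = welch_t(A, B)
    pool = _null_pool(A, B)
    k = np.zeros(A.shape[0], dtype=np.int64)
    for lo in range(0, A.shape[0], _CHUNK):
        hi = min(lo + _CHUNK, A.shape[0])
        idx = rng.integers(0, n, size=(hi - lo, n_resamples, n))
        g = np.take_along_axis(pool[lo:hi, None, :], idx, axis=2)
        ts = welch_t(g[:, :, :na], g[:, :, na:])
        k[lo:hi] = (np.abs(ts) >= np.abs(t_obs[lo:hi])[:, None]).sum(axis=1)
    p = (1.0 + k) / (1.0 + n_resamples)
    return t_obs, p


def permuted_t_test(
    values_a,
    values_b,
    n_resamples: int = 10000,
    seed: int | np.random.Generator | None = None,
    scheme: str = "resample",
) -> tuple[float, float]:
    """Two-sided permuted t-test for one transcript.

    scheme="resample" uses the with-replacement null described in the
    module docstring; scheme="exhaustive" enumerates all distinct label
    assignments (exact but very coarse at small n).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise RibostatError("each group needs >= 2 values")
    if scheme == "resample":
        t, p = permuted_t_matrix(a[None, :], b[None, :], n_resamples, seed)
        return float(t[0]), float(p[0])
    if scheme != "exhaustive":
        raise RibostatError(f"unknown scheme {scheme!r}")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    t_obs = float(welch_t(a, b))
    stats = []
    for combo in itertools.combinations(range(n), na):
        sel = np.zeros(n, dtype=bool)
        sel[list(combo)] = True
        stats.append(float(welch_t(pooled[sel], pooled[~sel])))
    stats = np.array(stats)
    p = (1.0 + (np.abs(stats) >= abs(t_obs)).sum()) / (1.0 + stats.size)
    return t_obs, float(p)


def classify_pattern(
    sig_rna: bool, dir_rna: int,
    sig_rf: bool, dir_rf: int,
    sig_te: bool, dir_te: int,
) -> str:
    """One regulatory-pattern label from significance flags and directions.

    forwarded: RNA and RF significant in the same direction, TE not;
    te_only: TE significant, RNA not; homeostatic: RNA and TE significant
    in opposite directions with RF not significant; synergistic: RNA and
    TE significant in the same direction; otherwise unclassified.
    """
    if sig_rna and sig_te:
        if dir_rna == dir_te and dir_te != 0:
            return "synergistic_up" if dir_te > 0 else "synergistic_down"
        if dir_rna == -dir_te and not sig_rf and dir_te != 0:
            return "homeostatic"
        return "unclassified"
    if sig_rna and sig_rf and not sig_te and dir_rna == dir_rf and dir_rna != 0:
        return "forwarded_up" if dir_rna > 0 else "forwarded_down"
    if sig_te and not sig_rna and dir_te != 0:
        return "te_only_up" if dir_te > 0 else "te_only_down"
    return "unclassified"


def _log2_matrix(
    expr: pd.DataFrame, design: pd.DataFrame, assay: str, region: str,
    pseudocount: float,
) -> tuple[pd.DataFrame, np.ndarray]:
    """(log2 RPKM matrix transcripts x replicates, treated indicator)."""
    sub = expr[(expr["assay"] == assay) & (expr["region"] == region)]
    d = design[design["assay"] == assay].set_index("sample")
    piv = sub.pivot_table(
        index="transcript_id", columns="sample", values="rpkm", aggfunc="first"
    )
    order = [s for s in d.index if s in piv.columns]
    piv = piv[order].rename(columns=d["replicate"].to_dict())
    treated = (d.loc[order, "condition"] == "treated").to_numpy()
    return np.log2(piv + pseudocount), treated


def differential_table(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
    n_resamples: int = 10000,
    seed: int | None = 0,
    pseudocount: float = 0.5,
    rna_region: str = "exonic",
    rf_region: str = "cds",
    te_region: str = "cds",
) -> pd.DataFrame:
    """Per-transcript log2 fold changes, resampling p-values and patterns.

    log2FC = mean(log2 treated) - mean(log2 control) of pseudocounted RPKM
    (RNA on ``rna_region``, RF on ``rf_region``); per-replicate log2 TE =
    log2(RF RPKM + pc) - log2(RNA RPKM + pc) on ``te_region``.  Significance
    is unadjusted p < alpha; BH q-values are reported alongside.  Transcripts
    whose RNA RPKM is 0 in some replicate of ``te_region`` have their TE
    entries flagged missing (NaN).
    """
    if len(expr) == 0:
        return pd.DataFrame(
            columns=["transcript_id", "gene_id",
                     "log2fc_rna", "p_rna", "q_rna",
                     "log2fc_rf", "p_rf", "q_rf",
                     "log2fc_te", "p_te", "q_te",
                     "sig_rna", "sig_rf", "sig_te", "pattern"]
        )
    rng = np.random.default_rng(seed)
    rna, treated_rna = _log2_matrix(expr, design, "rna", rna_region, pseudocount)
    rf, treated_rf = _log2_matrix(expr, design, "rf", rf_region, pseudocount)
    rna_te, _ = _log2_matrix(expr, design, "rna", te_region, pseudocount)
    rf_te, _ = _log2_matrix(expr, design, "rf", te_region, pseudocount)
    rna_te = rna_te.reindex(index=rf_te.index, columns=rf_te.columns)
    te = rf_te - rna_te  # replicates paired by name

    # TE undefined where the unlogged RNA RPKM was 0 in any replicate
    rna_raw = expr[(expr["assay"] == "rna") & (expr["region"] == te_region)]
    zero_rna = set(
        rna_raw.loc[rna_raw["rpkm"].fillna(0) <= 0, "transcript_id"]
    )

    ids = rf.index
    genes = (
        expr.drop_duplicates("transcript_id")
        .set_index("transcript_id")["gene_id"]
        .reindex(ids)
    )
    out = pd.DataFrame({"transcript_id": ids, "gene_id": genes.to_numpy()})

    for name, mat, treated in (
        ("rna", rna.reindex(ids), treated_rna),
        ("rf", rf.reindex(ids), treated_rf),
        ("te", te.reindex(ids), treated_rf),
    ):
        X = mat.to_numpy()
        A = X[:, treated]      # treated group first for sign convention
        B = X[:, ~treated]
        fc = A.mean(1) - B.mean(1)
        _, p = permuted_t_matrix(A, B, n_resamples, rng)
        if name == "te":
            miss = np.array([tid in zero_rna for tid in ids])
            fc = np.where(miss, np.nan, fc)
            p = np.where(miss, np.nan, p)
        good = np.isfinite(p)
        q = np.full_like(p, np.nan)
        if good.any():
            q[good] = multipletests(p[good], method="fdr_bh")[1]
        out[f"log2fc_{name}"] = fc
        out[f"p_{name}"] = p
        out[f"q_{name}"] = q
        out[f"sig_{name}"] = (p < alpha) & np.isfinite(p)

    out["pattern"] = [
        classify_pattern(
            bool(r.sig_rna), int(np.sign(r.log2fc_rna)) if np.isfinite(r.log2fc_rna) else 0,
            bool(r.sig_rf), int(np.sign(r.log2fc_rf)) if np.isfinite(r.log2fc_rf) else 0,
            bool(r.sig_te), int(np.sign(r.log2fc_te)) if np.isfinite(r.log2fc_te) else 0,
        )
        for r in out.itertuples()
    ]
    return out.reset_index(drop=True)


def count_regulated_genes(diff: pd.DataFrame, which: str = "te") -> int:
    """Unique gene_ids among transcripts significant for one measure."""
    return diff.loc[diff[f"sig_{which}"], "gene_id"].nunique()


def fc_variance_explained(rna_log2fc, rf_log2fc) -> tuple[float, float]:
    """OLS of RF log2FC on RNA log2FC: (R^2, F-test p)."""
    x = np.asarray(rna_log2fc, dtype=float)
    y = np.asarray(rf_log2fc, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise RibostatError("need >= 3 paired finite values")
    if np.ptp(x) == 0:
        raise RibostatError("constant predictor")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.rsquared), float(fit.f_pvalue)


def baseline_variance_explained(rna_rpkm, rf_rpkm) -> float:
    """Gamma-GLM (log link) pseudo-R^2 of RF on RNA abundance.

    Fits RF ~ log(RNA) under a Gamma response and returns
    1 - SS_error/SS_total evaluated on the response scale.
    """
    x = np.asarray(rna_rpkm, dtype=float)
    y = np.asarray(rf_rpkm, dtype=float)
    if (x <= 0).any() or (y <= 0).any():
        raise RibostatError("values must be strictly positive")
    fit = sm.GLM(
        y,
        sm.add_constant(np.log(x)),
        family=sm.families.Gamma(link=sm.families.links.Log()),
    ).fit()
    mu = fit.fittedvalues
    ss_err = float(((y - mu) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_err / ss_tot
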