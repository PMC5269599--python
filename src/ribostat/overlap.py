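"""Gene-set overlap testing with bias diagnostics.

Tests whether translationally regulated genes are enriched in externally
supplied target sets (miRNA predictions, RBP CLIP targets, disease gene
lists).  All sets are first restricted to the measurable universe so
unmeasured genes cannot inflate the statistics.  The one-tailed
enrichment p is the hypergeometric upper tail, identical to a one-tailed
Fisher's exact test; the odds ratio and one-sided confidence bound come
from the conditional maximum-likelihood estimate on the 2x2 table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cml_odds_ratio
from statsmodels.stats.multitest import multipletests

from .core import RibostatError
from .difftest import baseline_variance_explained


def hypergeom_tail_p(overlap: int, n_query: int, n_target: int, n_universe: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, target, query draws)."""
    return float(stats.hypergeom.sf(overlap - 1, n_universe, n_target, n_query))


@dataclass
class OverlapResult:
    set_name: str
    n_query: int
    n_target: int
    overlap: int
    n_universe: int
    odds_ratio: float
    p: float
    ci_low: float

    @property
    def table(self) -> np.ndarray:
        a = self.overlap
        b = self.n_query - a
        c = self.n_target - a
        d = self.n_universe - self.n_query - c
        return np.array([[a, b], [c, d]])


def fisher_overlap(
    query: Iterable[str],
    target: Iterable[str],
    universe: Iterable[str],
    alternative: str = "greater",
    set_name: str = "",
) -> OverlapResult:
    """One-tailed exact overlap test of two gene sets within a universe.

    Query and target are intersected with the universe before testing.
    Empty query or target yields p = 1 with an undefined (NaN) odds ratio.
    """
    uni = set(universe)
    q = set(query) & uni
    t = set(target) & uni
    ov = len(q & t)
    res = OverlapResult(
        set_name=set_name,
        n_query=len(q),
        n_target=len(t),
        overlap=ov,
        n_universe=len(uni),
        odds_ratio=float("nan"),
        p=1.0,
        ci_low=float("nan"),
    )
    if not q or not t:
        return res
    if alternative != "greater":
        raise RibostatError("only the one-tailed enrichment test is supported")
    res.p = hypergeom_tail_p(ov, len(q), len(t), len(uni))
    orr = _cml_odds_ratio(res.table, kind="conditional")
    res.odds_ratio = float(orr.statistic)
    try:
        res.ci_low = float(
            orr.confidence_interval(confidence_level=0.95, alternative="greater").low
        )
    except Exception:  # degenerate tables
        res.ci_low = float("nan")
    return res


def mirna_scan(
    predictions: pd.DataFrame,
    query: Iterable[str],
    universe: Iterable[str],
    confidence_min: float = 80.0,
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-set overlap tests for scored target predictions.

    ``predictions`` needs columns set_name, gene_id and optionally
    confidence; predictions below ``confidence_min`` are dropped (>= keeps),
    sets are restricted to the universe, and p-values are BH-adjusted
    across the sets that retain at least one measurable target.
    """
    df = predictions.copy()
    if "confidence" in df.columns:
        df = df[df["confidence"] >= confidence_min]
    uni = set(universe)
    df = df[df["gene_id"].isin(uni)]
    rows = []
    for name, grp in df.groupby("set_name"):
        r = fisher_overlap(query, set(grp["gene_id"]), uni, set_name=str(name))
        rows.append(
            (r.set_name, r.n_query, r.n_target, r.overlap, r.odds_ratio, r.p, r.ci_low)
        )
    out = pd.DataFrame(
        rows,
        columns=["set_name", "n_query", "n_target", "overlap", "odds_ratio", "p",
                 "or_ci_low"],
    )
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method=fdr_method)[1]
    else:
        out["q"] = []
    return out.sort_values("p").reset_index(drop=True)


def bias_diagnostics(
    query: Iterable[str],
    background: Iterable[str],
    lengths: Mapping[str, float] | pd.Series,
    expression: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """KS comparisons of log10 CDS length and log10 expression, query vs background.

    Target sets with strong length or abundance bias (e.g. CLIP targets of
    proteins binding long CDSs) can masquerade as enrichment; this reports
    whether the query shares such a bias.
    """
    lengths = pd.Series(lengths)
    expression = pd.Series(expression)
    q = [g for g in set(query)]
    b = [g for g in set(background)]
    if len(q) < 5 or len(b) < 5:
        warnings.warn("fewer than 5 genes in query or background; KS unreliable")
    rows = []
    for label, series in (("log10_length", lengths), ("log10_expression", expression)):
        qs = np.log10(series.reindex(q).dropna().to_numpy(dtype=float))
        bs = np.log10(series.reindex(b).dropna().to_numpy(dtype=float))
        if qs.size and bs.size and qs.size >= 2 and bs.size >= 2:
            D, p = stats.ks_2samp(qs, bs)
        else:
            D, p = float("nan"), float("nan")
        rows.append((label, len(qs), len(bs), float(D), float(p)))
    return pd.DataFrame(rows, columns=["metric", "n_query", "n_background", "D", "p"])


def per_set_variance_explained(
    gene_sets: Mapping[str, Iterable[str]],
    rna: pd.Series,
    rf: pd.Series,
) -> pd.DataFrame:
    """Gamma-GLM pseudo-R^2 of RF on RNA within each gene set.

    Values must be strictly positive and indexed by gene; sets smaller
    than 10 genes trigger a warning.  When exactly two sets are given the
    returned frame's ``attrs['delta']`` holds their pseudo-R^2 difference.
    """
    rows = []
    for name, genes in gene_sets.items():
        ids = [g for g in set(genes) if g in rna.index and g in rf.index]
        if len(ids) < 10:
            warnings.warn(f"gene set {name!r} has only {len(ids)} measurable genes")
        if len(ids) < 3:
            rows.append((name, len(ids), float("nan")))
            continue
        r2 = baseline_variance_explained(
            rna.loc[ids].to_numpy(), rf.loc[ids].to_numpy()
        )
        rows.append((name, len(ids), float(r2)))
    out = pd.DataFrame(rows, columns=["set_name", "n", "pseudo_r2"])
    if len(out) == 2 and out["pseudo_r2"].notna().all():
        out.attrs["delta"] = float(out["pseudo_r2"].iloc[0] - out["pseudo_r2"].iloc[1])
    return out


def read_gene_sets(path) -> pd.DataFrame:
    """Gene sets as TSV (set_name, gene_id[, confidence])."""
    df = pd.read_csv(path, sep="\t", dtype={"set_name": str, "gene_id": str})
    missing = {"set_name", "gene_id"} - set(df.columns)
    if missing:
        raise RibostatError(f"gene-set file missing columns: {sorted(missing)}")
    return df
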