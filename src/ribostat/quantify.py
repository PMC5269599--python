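"""Region counting, CPM/RPKM normalization, expression filter and TE.

Counts are sums of nucleotide depth over a transcript region, optionally
excluding a deterministic mask of positions around the start and stop
codons where initiating/terminating ribosomes pile up: 9 nt upstream of
the start codon, 15 nt downstream of it, 15 nt upstream of the stop codon
and 15 nt downstream of it.  The start and stop codon trinucleotides
themselves are kept.  The mask is applied symmetrically to both assays so
the footprint/RNA ratio (translation efficiency, TE) stays unbiased.

Expression units: CPM = count * 1e6 / library size, with one library per
(sample, assay) equal to that sample's total exonic counted reads; RPKM =
CPM / (effective region length in kb), where the effective length counts
only unmasked positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CoverageSet, RibostatError, TranscriptModel

MASK_UPSTREAM_START = 9
MASK_DOWNSTREAM_START = 15
MASK_UPSTREAM_STOP = 15
MASK_DOWNSTREAM_STOP = 15

QUANT_REGIONS = ("utr5", "cds", "utr3", "exonic")


@dataclass(frozen=True)
class PositionMask:
    """Excluded transcript positions, derived from the CDS interval."""

    transcript_id: str
    positions: tuple[int, ...]

    def as_bool(self, length: int) -> np.ndarray:
        out = np.zeros(length, dtype=bool)
        if self.positions:
            out[np.asarray(self.positions)] = True
        return out


def build_mask(model: TranscriptModel) -> PositionMask:
    """Mask = [s-9,s) U [s+3,s+18) U [t-15,t) U [t+3,t+18), clipped.

    s and t are the first nt of the start and stop codons; neither codon
    is masked.
    """
    if model.cds[1] - model.cds[0] < 6:
        raise RibostatError(f"{model.transcript_id}: CDS shorter than 6 nt")
    s = model.start_codon_pos
    t = model.stop_codon_pos
    L = model.length
    segments = (
        (s - MASK_UPSTREAM_START, s),
        (s + 3, s + 3 + MASK_DOWNSTREAM_START),
        (t - MASK_UPSTREAM_STOP, t),
        (t + 3, t + 3 + MASK_DOWNSTREAM_STOP),
    )
    pos: set[int] = set()
    for lo, hi in segments:
        pos.update(range(max(lo, 0), min(hi, L)))
    # the start and stop codons themselves are never masked, even when a
    # short CDS makes the windows reach across them
    pos -= set(range(s, s + 3)) | set(range(t, t + 3))
    return PositionMask(model.transcript_id, tuple(sorted(pos)))


def count_region(
    coverage: np.ndarray,
    model: TranscriptModel,
    region: str,
    mask: PositionMask | None = None,
    apply_mask: bool = True,
) -> tuple[float, int]:
    """Sum of depth over a region; returns (count, effective_length).

    Masked positions are excluded from both the sum and the effective
    length when ``apply_mask`` is set and a mask is given.
    """
    if region not in QUANT_REGIONS:
        raise RibostatError(f"unknown region {region!r}")
    lo, hi = model.region_interval(region)
    v = np.asarray(coverage)
    if v.shape[0] != model.length:
        raise RibostatError(
            f"{model.transcript_id}: coverage length {v.shape[0]} != "
            f"transcript length {model.length}"
        )
    if apply_mask and mask is not None and mask.positions:
        keep = ~mask.as_bool(model.length)[lo:hi]
        return float(v[lo:hi][keep].sum()), int(keep.sum())
    return float(v[lo:hi].sum()), hi - lo


def normalize(
    counts: np.ndarray | Sequence[float],
    library_size: float,
    effective_lengths: np.ndarray | Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """CPM and RPKM from raw counts.

    CPM = count * 1e6 / library_size; RPKM = CPM / (effective length / 1000).
    Zero-length units get RPKM NaN; zero library size is an error.
    """
    if library_size <= 0:
        raise RibostatError("library size must be > 0")
    c = np.asarray(counts, dtype=float)
    L = np.asarray(effective_lengths, dtype=float)
    cpm = c * 1e6 / library_size
    with np.errstate(divide="ignore", invalid="ignore"):
        rpkm = np.where(L > 0, cpm / (L / 1000.0), np.nan)
    return cpm, rpkm


def expression_table(
    models: Iterable[TranscriptModel],
    coverage_sets: Iterable[CoverageSet],
    apply_mask: bool = True,
    regions: Sequence[str] = QUANT_REGIONS,
) -> pd.DataFrame:
    """Long-format counts + CPM/RPKM per transcript x region x sample x assay."""
    models = list(models)
    masks = {m.transcript_id: build_mask(m) if apply_mask else None for m in models}
    records = []
    for cov in coverage_sets:
        for sample, depth in cov.samples.items():
            for m in models:
                if m.transcript_id not in depth:
                    raise RibostatError(
                        f"sample {sample}: no coverage for {m.transcript_id}"
                    )
                v = depth[m.transcript_id]
                for region in regions:
                    cnt, eff = count_region(
                        v, m, region, masks[m.transcript_id], apply_mask
                    )
                    records.append(
                        (m.transcript_id, m.gene_id, region, sample, cov.assay,
                         cnt, eff)
                    )
    df = pd.DataFrame(
        records,
        columns=["transcript_id", "gene_id", "region", "sample", "assay",
                 "count", "effective_length"],
    )
    return add_normalization(df)


def add_normalization(expr: pd.DataFrame) -> pd.DataFrame:
    """(Re)compute cpm/rpkm columns from counts in a long-format table.

    Library size per (sample, assay) is the total exonic count over the
    transcripts present, so re-running after filtering yields post-filter
    totals.
    """
    df = expr.copy()
    if len(df) == 0:
        df["cpm"] = []
        df["rpkm"] = []
        return df
    exonic = df[df["region"] == "exonic"]
    source = exonic if len(exonic) else df
    lib = source.groupby(["sample", "assay"])["count"].sum()
    if (lib <= 0).any():
        bad = lib[lib <= 0].index.tolist()
        raise RibostatError(f"zero library size for {bad}")
    sizes = df.set_index(["sample", "assay"]).index.map(lib)
    df["cpm"] = df["count"].to_numpy() * 1e6 / np.asarray(sizes, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = df["effective_length"].to_numpy(dtype=float)
        df["rpkm"] = np.where(eff > 0, df["cpm"].to_numpy() / (eff / 1000.0), np.nan)
    return df


def filter_expressed(
    expr: pd.DataFrame,
    threshold: float = 10.0,
    min_samples: int = 2,
    rna_region: str = "exonic",
    rf_region: str = "cds",
) -> list[str]:
    """Transcripts with RPKM >= threshold in >= min_samples samples, both assays.

    The RNA-seq criterion is evaluated on ``rna_region`` and the footprint
    criterion on ``rf_region``.  Result is sorted and independent of row
    order.
    """
    keep: set[str] | None = None
    for assay, region in (("rna", rna_region), ("rf", rf_region)):
        sub = expr[(expr["assay"] == assay) & (expr["region"] == region)]
        ok = (
            sub.assign(hit=sub["rpkm"] >= threshold)
            .groupby("transcript_id")["hit"]
            .sum()
        )
        ids = set(ok[ok >= min_samples].index)
        keep = ids if keep is None else keep & ids
    return sorted(keep or set())


def compute_te(rf_rpkm, rna_rpkm):
    """TE = RF RPKM / RNA RPKM; NaN where RNA RPKM is 0 (undefined, not 0)."""
    rf = np.asarray(rf_rpkm, dtype=float)
    rna = np.asarray(rna_rpkm, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        te = np.where(rna > 0, rf / rna, np.nan)
    return te if te.ndim else float(te)


def condition_te(replicate_tes) -> float:
    """Condition-level TE: geometric mean of defined replicate TEs."""
    v = np.asarray(replicate_tes, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return float("nan")
    return float(stats.gmean(v))


def te_table(
    expr: pd.DataFrame, design: pd.DataFrame, region: str = "cds"
) -> pd.DataFrame:
    """Per-replicate TE for one region, pairing RF and RNA libraries.

    ``design`` needs columns sample, replicate, condition, assay; RF and
    RNA samples of the same replicate are ratioed.
    """
    sub = expr[expr["region"] == region].merge(
        design[["sample", "replicate", "condition", "assay"]],
        on=["sample", "assay"] if "assay" in design else "sample",
        how="inner",
    )
    piv = sub.pivot_table(
        index=["transcript_id", "replicate", "condition"],
        columns="assay",
        values="rpkm",
        aggfunc="first",
    ).reset_index()
    if not {"rf", "rna"} <= set(piv.columns):
        raise RibostatError("te_table needs both 'rf' and 'rna' assays")
    piv["te"] = compute_te(piv["rf"].to_numpy(), piv["rna"].to_numpy())
    return piv.rename(columns={"rf": "rf_rpkm", "rna": "rna_rpkm"})
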