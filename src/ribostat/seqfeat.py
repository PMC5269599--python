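"""Per-transcript primary-sequence predictors of translation.

Extracts the cis-regulatory features that the downstream regression
relates to translation-efficiency change: GC content, region lengths,
upstream AUG (uAUG) counts, uAUGs in strong Kozak context, and a
secondary-structure score per region (built-in weighted base-pair DP,
or a pluggable external folding engine such as RNAfold).

Internally sequences are handled as RNA (T -> U on input).
"""

from __future__ import annotations

import shutil
import subprocess
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .core import RibostatError, TranscriptModel
from .fold import max_pair_weight, tiled_pair_weight

#: 3'UTRs shorter than this many nt count as "short" (indicator feature)
SHORT_UTR3_NT = 492

#: default tile size for folding long regions (see feature_table)
DEFAULT_FOLD_WINDOW = 150

FEATURE_COLUMNS = (
    "utr5_gc", "cds_gc", "utr3_gc",
    "utr5_len", "cds_len", "utr3_len",
    "n_uaug", "n_upstream_kozak",
    "ss_utr5", "ss_cds", "ss_utr3",
    "norm_ss_utr5", "norm_ss_cds", "norm_ss_utr3",
    "short_utr3",
)

PURINES = frozenset("AG")


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def gc_content(seq: str) -> float:
    """Fraction (#G + #C) / (length excluding N); NaN for empty/all-N."""
    s = _rna(seq)
    denom = len(s) - s.count("N")
    if denom == 0:
        return float("nan")
    return (s.count("G") + s.count("C")) / denom


def count_uaugs(utr5_seq: str) -> int:
    """Number of AUG trinucleotides in the 5'UTR, any frame, overlaps allowed."""
    s = _rna(utr5_seq)
    count = 0
    start = 0
    while True:
        i = s.find("AUG", start)
        if i == -1:
            return count
        count += 1
        start = i + 1


def count_upstream_kozak(utr5_seq: str, downstream_context: str = "") -> int:
    """Number of uAUGs in strong Kozak context: purine at -3, G at +4.

    Positions follow the 1-based Kozak convention (A of AUG = +1, so +4 is
    the base immediately after the G).  The -3 base must lie within the
    5'UTR; a uAUG without it is not counted.  The +4 base may extend into
    ``downstream_context`` (CDS-adjacent sequence) when the uAUG sits at
    the UTR's 3' end.
    """
    s = _rna(utr5_seq)
    ext = s + _rna(downstream_context)
    count = 0
    start = 0
    while True:
        i = s.find("AUG", start)
        if i == -1:
            return count
        start = i + 1
        if i < 3:
            continue  # insufficient -3 context
        if i + 3 >= len(ext):
            continue  # +4 base unavailable
        if s[i - 3] in PURINES and ext[i + 3] == "G":
            count += 1


def fold_energy(
    seq: str,
    engine: str | Callable[[str], float] = "builtin",
    window: int | None = None,
) -> float:
    """Secondary-structure score of a sequence; <= 0, lower = more stable.

    engine="builtin" runs the weighted Nussinov DP (GC=3, AU=2, GU=1,
    minimum loop 3) and returns the negated optimal pair weight.  With
    ``window`` set, sequences longer than the window are folded in
    non-overlapping tiles and the tile scores summed.  engine="external"
    shells out to RNAfold and returns the MFE in kcal/mol; a callable is
    used as-is (sequence -> energy).
    """
    if callable(engine):
        return float(engine(seq))
    if engine == "builtin":
        if window is not None and len(seq) > window:
            return -float(tiled_pair_weight(seq, window))
        return -float(max_pair_weight(seq))
    if engine == "external":
        return rnafold_mfe(seq)
    raise RibostatError(f"unknown folding engine {engine!r}")


def rnafold_mfe(seq: str) -> float:
    """Minimum free energy from the RNAfold command-line tool (kcal/mol)."""
    if not seq:
        return 0.0
    if shutil.which("RNAfold") is None:
        raise RibostatError("RNAfold not found on PATH for engine='external'")
    out = subprocess.run(
        ["RNAfold", "--noPS"],
        input=_rna(seq) + "\n",
        capture_output=True,
        text=True,
        check=True,
    ).stdout
    # last line: "....structure.... ( -1.20)"
    tail = out.strip().splitlines()[-1]
    return float(tail[tail.rindex("(") + 1 : tail.rindex(")")])


def feature_table(
    transcripts: Iterable[TranscriptModel],
    engine: str | Callable[[str], float] = "builtin",
    fold_window: int | None = DEFAULT_FOLD_WINDOW,
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Feature matrix indexed by transcript_id.

    ``features`` restricts computation to the named columns (plus the
    primitives they need); default computes all of FEATURE_COLUMNS.
    Zero-length regions get length 0, ss 0 and NaN for GC and normalized
    structure.  The folding engine used is recorded in ``df.attrs``.
    """
    wanted = set(FEATURE_COLUMNS if features is None else features)
    unknown = wanted - set(FEATURE_COLUMNS)
    if unknown:
        raise RibostatError(f"unknown feature(s): {sorted(unknown)}")

    need_ss = {r for r in ("utr5", "cds", "utr3")
               if {f"ss_{r}", f"norm_ss_{r}"} & wanted}

    rows = []
    for t in transcripts:
        row: dict[str, object] = {"transcript_id": t.transcript_id}
        seqs = {r: t.region_sequence(r) for r in ("utr5", "cds", "utr3")}
        for r in ("utr5", "cds", "utr3"):
            if f"{r}_len" in wanted or f"norm_ss_{r}" in wanted or (
                r == "utr3" and "short_utr3" in wanted
            ):
                row[f"{r}_len"] = len(seqs[r])
            if f"{r}_gc" in wanted:
                row[f"{r}_gc"] = gc_content(seqs[r])
            if r in need_ss:
                ss = fold_energy(seqs[r], engine, fold_window) if seqs[r] else 0.0
                if f"ss_{r}" in wanted:
                    row[f"ss_{r}"] = ss
                if f"norm_ss_{r}" in wanted:
                    row[f"norm_ss_{r}"] = ss / len(seqs[r]) if seqs[r] else float("nan")
        if "n_uaug" in wanted:
            row["n_uaug"] = count_uaugs(seqs["utr5"])
        if "n_upstream_kozak" in wanted:
            row["n_upstream_kozak"] = count_upstream_kozak(seqs["utr5"], seqs["cds"][:4])
        if "short_utr3" in wanted:
            row["short_utr3"] = int(len(seqs["utr3"]) < SHORT_UTR3_NT)
        rows.append(row)

    cols = [c for c in FEATURE_COLUMNS if any(c in r for r in rows)] if rows else []
    df = pd.DataFrame(rows).set_index("transcript_id") if rows else pd.DataFrame(
        columns=["transcript_id", *sorted(wanted)]
    ).set_index("transcript_id")
    if rows:
        df = df[[c for c in FEATURE_COLUMNS if c in df.columns]]
    df.attrs["engine"] = engine if isinstance(engine, str) else "callable"
    df.attrs["fold_window"] = fold_window
    return df
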