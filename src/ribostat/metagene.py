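"""Average footprint-density profiles anchored at start/stop codons.

Each retained transcript's depth vector is normalized to within-transcript
CPM (depth * 1e6 / total depth) before averaging, so every transcript
contributes equal weight regardless of expression or length.  Offset 0 is
the first nucleotide of the anchor codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .core import CoverageSet, RibostatError, TranscriptModel

DEFAULT_MIN_CDS_LENGTH = 2000
DEFAULT_WINDOWS = {"start": (-50, 200), "stop": (-200, 50)}


@dataclass
class MetageneProfile:
    anchor: str
    offsets: np.ndarray          # nt relative to the anchor codon's first nt
    mean_cpm: np.ndarray         # mean per-transcript CPM at each offset
    n_transcripts: int           # transcripts passing the CDS-length filter
    n_per_offset: np.ndarray     # transcripts contributing at each offset


def _as_depth_dict(coverages) -> Mapping[str, np.ndarray]:
    if isinstance(coverages, CoverageSet):
        return coverages.pooled()
    return coverages


def metagene_profile(
    coverages,
    models: Iterable[TranscriptModel],
    anchor: str = "start",
    window: tuple[int, int] | None = None,
    min_cds_length: int = DEFAULT_MIN_CDS_LENGTH,
) -> MetageneProfile:
    """Mean CPM-normalized depth per offset around the anchor codon.

    ``coverages`` is a CoverageSet (samples pooled per transcript) or a
    plain {transcript_id: depth} mapping.  Transcripts with CDS shorter
    than ``min_cds_length`` or zero total depth are excluded; offsets that
    fall outside a transcript simply do not receive its contribution.
    """
    if anchor not in ("start", "stop"):
        raise RibostatError(f"anchor must be 'start' or 'stop', got {anchor!r}")
    lo, hi = window if window is not None else DEFAULT_WINDOWS[anchor]
    if lo >= hi:
        raise RibostatError("empty metagene window")
    depth = _as_depth_dict(coverages)

    offsets = np.arange(lo, hi)
    total = np.zeros(offsets.size)
    n_at = np.zeros(offsets.size, dtype=np.int64)
    n_kept = 0
    for m in models:
        if m.cds[1] - m.cds[0] < min_cds_length:
            continue
        if m.transcript_id not in depth:
            continue
        v = np.asarray(depth[m.transcript_id], dtype=float)
        tot = v.sum()
        if tot <= 0:
            continue
        n_kept += 1
        cpm = v * 1e6 / tot
        a = m.start_codon_pos if anchor == "start" else m.stop_codon_pos
        pos = a + offsets
        ok = (pos >= 0) & (pos < m.length)
        total[ok] += cpm[pos[ok]]
        n_at[ok] += 1
    if n_kept == 0:
        raise RibostatError(
            f"no transcripts retained (CDS >= {min_cds_length} nt with coverage)"
        )
    with np.errstate(invalid="ignore"):
        mean = np.where(n_at > 0, total / np.maximum(n_at, 1), np.nan)
    return MetageneProfile(anchor, offsets, mean, n_kept, n_at)


def peak_score(
    profile: MetageneProfile,
    peak_window: tuple[int, int],
    background_window: tuple[int, int],
) -> float:
    """Mean profile value in the peak window over the background window."""
    def mean_in(win):
        lo, hi = win
        sel = (profile.offsets >= lo) & (profile.offsets < hi)
        vals = profile.mean_cpm[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise RibostatError(f"window {win} selects no profiled offsets")
        return float(vals.mean())

    p_lo, p_hi = peak_window
    b_lo, b_hi = background_window
    if max(p_lo, b_lo) < min(p_hi, b_hi):
        raise RibostatError("peak and background windows must be disjoint")
    bg = mean_in(background_window)
    if bg == 0:
        raise RibostatError("zero background signal")
    return mean_in(peak_window) / bg
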