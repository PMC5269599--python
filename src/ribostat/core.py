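"""Core data containers shared across the pipeline.

A transcript is represented in transcript coordinates (0-based, half-open)
as three contiguous regions: 5'UTR, CDS, 3'UTR.  Nucleotide-resolution
coverage is held per assay (ribosome footprints or RNA-seq) as one depth
vector per transcript per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

REGIONS = ("utr5", "cds", "utr3")
STOP_CODONS = ("TAA", "TAG", "TGA")


class RibostatError(ValueError):
    """Base error for invalid inputs or configuration."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: sequence plus region intervals in transcript coordinates.

    Intervals are 0-based half-open and must tile the transcript:
    ``utr5 = [0, a)``, ``cds = [a, b)``, ``utr3 = [b, L)`` with ``L`` the
    sequence length.  The CDS begins with the start codon and ends with the
    stop codon (the stop codon is the final 3 nt of the CDS interval).
    """

    transcript_id: str
    gene_id: str
    sequence: str
    utr5: tuple[int, int]
    cds: tuple[int, int]
    utr3: tuple[int, int]

    def __post_init__(self) -> None:
        L = len(self.sequence)
        a0, a1 = self.utr5
        b0, b1 = self.cds
        c0, c1 = self.utr3
        if not (0 == a0 <= a1 == b0 <= b1 == c0 <= c1 == L):
            raise RibostatError(
                f"{self.transcript_id}: regions must be contiguous and tile "
                f"the {L} nt transcript (got utr5={self.utr5}, cds={self.cds}, "
                f"utr3={self.utr3})"
            )
        cds_len = b1 - b0
        if cds_len < 6:
            raise RibostatError(
                f"{self.transcript_id}: CDS length {cds_len} must be >= 6"
            )
        if cds_len % 3:
            # real annotations occasionally carry incomplete codons; the
            # stop codon is still taken as the final 3 nt of the interval
            warnings.warn(
                f"{self.transcript_id}: CDS length {cds_len} is not a "
                "multiple of 3"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def start_codon_pos(self) -> int:
        """First nt of the start codon."""
        return self.cds[0]

    @property
    def stop_codon_pos(self) -> int:
        """First nt of the stop codon (final 3 nt of the CDS interval)."""
        return self.cds[1] - 3

    def region_interval(self, region: str) -> tuple[int, int]:
        if region == "exonic":
            return (0, self.length)
        if region not in REGIONS:
            raise RibostatError(f"unknown region {region!r}")
        return getattr(self, region)

    def region_sequence(self, region: str) -> str:
        lo, hi = self.region_interval(region)
        return self.sequence[lo:hi]


@dataclass
class CoverageSet:
    """Per-sample nucleotide-depth vectors for one assay.

    ``samples`` maps sample name -> {transcript_id -> depth vector}.  For
    ribosome footprints the depth is the count of footprint 5' ends at each
    position; for RNA-seq it is read-start depth.
    """

    assay: str
    samples: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @property
    def sample_names(self) -> list[str]:
        return list(self.samples)

    def depth(self, sample: str, transcript_id: str) -> np.ndarray:
        return self.samples[sample][transcript_id]

    def pooled(self) -> dict[str, np.ndarray]:
        """Sum depth over samples, per transcript."""
        out: dict[str, np.ndarray] = {}
        for cov in self.samples.values():
            for tid, vec in cov.items():
                if tid in out:
                    out[tid] = out[tid] + vec
                else:
                    out[tid] = vec.astype(np.int64, copy=True)
        return out
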