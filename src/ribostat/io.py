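"""Readers and writers for the plain-text interchange formats.

Annotation TSV columns: transcript_id, gene_id, length, utr5_start,
utr5_end, cds_start, cds_end, utr3_start, utr3_end (0-based half-open,
transcript coordinates).  Coverage is 4-column bedGraph in transcript
coordinates (transcript_id, start, end, depth), nonzero runs only.
Design TSV columns: sample, replicate, condition, assay.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CoverageSet, RibostatError, TranscriptModel

ANNOTATION_COLUMNS = [
    "transcript_id", "gene_id", "length",
    "utr5_start", "utr5_end", "cds_start", "cds_end",
    "utr3_start", "utr3_end",
]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=tid, description="") for tid, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_annotation(path: str | os.PathLike) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise RibostatError(f"annotation missing columns: {sorted(missing)}")
    return ann


def write_annotation(models: Iterable[TranscriptModel], path: str | os.PathLike) -> None:
    rows = [
        (m.transcript_id, m.gene_id, m.length,
         m.utr5[0], m.utr5[1], m.cds[0], m.cds[1], m.utr3[0], m.utr3[1])
        for m in models
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def models_from_annotation(ann: pd.DataFrame) -> list[TranscriptModel]:
    """TranscriptModels from an annotation table alone (placeholder sequence).

    Useful for counting, where only the intervals matter.
    """
    return [
        TranscriptModel(
            transcript_id=r.transcript_id,
            gene_id=r.gene_id,
            sequence="A" * int(r.length),
            utr5=(int(r.utr5_start), int(r.utr5_end)),
            cds=(int(r.cds_start), int(r.cds_end)),
            utr3=(int(r.utr3_start), int(r.utr3_end)),
        )
        for r in ann.itertuples()
    ]


def load_transcripts(
    fasta_path: str | os.PathLike, annotation_path: str | os.PathLike
) -> list[TranscriptModel]:
    seqs = read_fasta(fasta_path)
    ann = read_annotation(annotation_path)
    models = []
    for row in ann.itertuples():
        tid = row.transcript_id
        if tid not in seqs:
            raise RibostatError(f"{tid} in annotation but not in FASTA")
        if len(seqs[tid]) != row.length:
            raise RibostatError(f"{tid}: sequence/annotation length mismatch")
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=row.gene_id,
                sequence=seqs[tid],
                utr5=(int(row.utr5_start), int(row.utr5_end)),
                cds=(int(row.cds_start), int(row.cds_end)),
                utr3=(int(row.utr3_start), int(row.utr3_end)),
            )
        )
    return models


def write_bedgraph(depths: Mapping[str, np.ndarray], path: str | os.PathLike) -> None:
    """Write per-transcript depth vectors as nonzero runs."""
    with open(path, "w") as fh:
        for tid, v in depths.items():
            v = np.asarray(v)
            if v.size == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [v.size]))
            for lo, hi in zip(starts, ends):
                d = v[lo]
                if d != 0:
                    fh.write(f"{tid}\t{lo}\t{hi}\t{d}\n")


def read_bedgraph(
    path: str | os.PathLike, lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Dense depth vectors from a bedGraph; absent transcripts get zeros."""
    out = {tid: np.zeros(L, dtype=np.int64) for tid, L in lengths.items()}
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["transcript_id", "start", "end", "depth"],
        dtype={"transcript_id": str},
    )
    for row in bed.itertuples():
        if row.transcript_id not in out:
            continue
        v = out[row.transcript_id]
        if not (0 <= row.start < row.end <= v.size):
            raise RibostatError(
                f"bedGraph interval [{row.start},{row.end}) outside "
                f"{row.transcript_id} (length {v.size})"
            )
        v[row.start : row.end] += int(row.depth)
    return out


def read_design(path: str | os.PathLike) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample", "condition", "assay"} - set(design.columns)
    if missing:
        raise RibostatError(f"design missing columns: {sorted(missing)}")
    if "replicate" not in design.columns:
        design["replicate"] = design["sample"]
    return design


def read_coverage_dir(
    directory: str | os.PathLike,
    design: pd.DataFrame,
    lengths: Mapping[str, int],
) -> list[CoverageSet]:
    """One CoverageSet per assay; expects <sample>.bedgraph files."""
    sets: dict[str, CoverageSet] = {}
    for row in design.itertuples():
        path = os.path.join(str(directory), f"{row.sample}.bedgraph")
        if not os.path.exists(path):
            raise RibostatError(f"missing coverage file {path}")
        cov = sets.setdefault(row.assay, CoverageSet(assay=row.assay))
        cov.samples[row.sample] = read_bedgraph(path, lengths)
    return list(sets.values())
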