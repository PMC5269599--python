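"""Synthetic transcriptomes and coverage with planted, known effects.

The generator emulates a depolarization-style ribosome-profiling study:
replicated control and treated conditions (default 3 vs 2, matching a
design where one treated replicate was dropped for low library size),
negative-binomial count noise, footprint coverage confined to the 5'UTR
and CDS with pause peaks at the start and stop codons, planted
transcriptional fold changes, and planted translation-efficiency (TE)
fold changes that are a linear function of sequence features plus noise.

Every planted quantity is recorded in a GroundTruth table so downstream
estimates can be scored against what was actually simulated.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import io, seqfeat
from .core import CoverageSet, RibostatError, STOP_CODONS, TranscriptModel

_BASES = np.array(list("ACGT"))

#: planted TE coefficients of the default study conditions: upstream Kozak
#: matches repress, relaxed (less negative) normalized 5'UTR structure and a
#: short 3'UTR favour up-regulation.  Coefficients act on z-scored features.
DEFAULT_TE_COEFFICIENTS = {
    "n_upstream_kozak": -0.30,
    "norm_ss_utr5": 0.30,
    "short_utr3": 0.25,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data generator.

    Lengths are nt; CDS lengths are rounded to multiples of 3 (>= 6).
    ``planted_te_coefficients`` maps feature name -> effect (log2 TE change
    per standard deviation of the feature); ``te_noise_sd`` is the residual
    sd of the planted log2 TE change.  The defaults are calibrated so the
    planted coefficients explain roughly 17% of the TE-change variance.
    """

    n_transcripts: int = 2000
    utr5_length_range: tuple[int, int] = (30, 180)
    cds_length_range: tuple[int, int] = (150, 600)
    utr3_length_range: tuple[int, int] = (120, 900)
    gc_range: tuple[float, float] = (0.35, 0.65)
    uaug_rate: float = 1.5
    strong_kozak_frac: float = 0.5
    n_control: int = 3
    n_treated: int = 2
    mean_depth: float = 2000.0
    nb_dispersion: float = 0.05
    planted_te_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TE_COEFFICIENTS)
    )
    te_noise_sd: float = 1.09
    frac_rna_up: float = 0.10
    frac_rna_down: float = 0.10
    rna_effect_log2: float = 1.0
    utr5_occupancy: float = 0.3
    pause_enrichment: float = 5.0
    footprint_length_range: tuple[int, int] = (26, 34)
    depth_log_sd: float = 0.5
    te_baseline_log_sd: float = 0.25
    fold_window: int | None = seqfeat.DEFAULT_FOLD_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("utr5_length_range", "cds_length_range",
                     "utr3_length_range", "gc_range", "footprint_length_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise RibostatError(f"degenerate range {name}={lo, hi}")
        if self.cds_length_range[0] < 6:
            raise RibostatError("CDS lengths must be >= 6")
        if self.n_control < 2 or self.n_treated < 2:
            raise RibostatError("need >= 2 replicates per condition")
        if self.nb_dispersion <= 0:
            raise RibostatError("nb_dispersion must be > 0")
        if not 0 <= self.frac_rna_up + self.frac_rna_down <= 1:
            raise RibostatError("frac_rna_up + frac_rna_down must be in [0,1]")

    def design(self) -> pd.DataFrame:
        rows = []
        for cond, n in (("control", self.n_control), ("treated", self.n_treated)):
            for r in range(1, n + 1):
                for assay in ("rf", "rna"):
                    rows.append(
                        (f"{cond}_{r}_{assay}", f"{cond}_{r}", cond, assay)
                    )
        return pd.DataFrame(rows, columns=["sample", "replicate", "condition", "assay"])

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("utr5_length_range", "cds_length_range", "utr3_length_range",
                    "gc_range", "footprint_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted per-transcript effects and the feature values they used.

    ``table`` is indexed by transcript_id with columns gene_id, log2fc_rna,
    log2fc_te, log2fc_rf (= rna + te by construction), te_signal, te_noise,
    te_baseline, depth_scale, plus f_<name> (raw planted feature values) and
    z_<name> (the z-scores the linear model was applied to).
    """

    table: pd.DataFrame
    coefficients: dict[str, float]

    @property
    def feature_names(self) -> list[str]:
        return list(self.coefficients)

    def planted_r2(self, subset: Iterable[str] | None = None) -> float:
        """OLS R^2 of the planted log2 TE change on the planted z-features."""
        t = self.table if subset is None else self.table.loc[list(subset)]
        y = t["log2fc_te"].to_numpy()
        if not self.coefficients or len(t) < 3 or np.var(y) == 0:
            return 0.0
        X = np.column_stack(
            [np.ones(len(t))] + [t[f"z_{f}"].to_numpy() for f in self.coefficients]
        )
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return 1.0 - resid.var() / y.var()

    def planted_adj_r2(self, subset: Iterable[str] | None = None) -> float:
        t = self.table if subset is None else self.table.loc[list(subset)]
        n, k = len(t), len(self.coefficients)
        r2 = self.planted_r2(subset)
        if n - k - 1 <= 0:
            return float("nan")
        return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _scrub_augs(seq: np.ndarray, protected_starts: set[int]) -> None:
    """Replace the T of every unprotected ATG with A, in place.

    Replacing T with A cannot create a new ATG (the change removes a T and
    the neighbouring windows cannot gain one), so one left-to-right sweep
    per round terminates quickly.
    """
    # codes: A=0, C=1, G=2, T=3
    while True:
        hits = np.flatnonzero(
            (seq[:-2] == 0) & (seq[1:-1] == 3) & (seq[2:] == 2)
        )
        hits = [i for i in hits if i not in protected_starts]
        if not hits:
            return
        for i in hits:
            seq[i + 1] = 0


def _make_utr5(
    rng: np.random.Generator, length: int, gc: float,
    n_uaug: int, strong_frac: float,
) -> np.ndarray:
    seq = _random_seq(rng, length, gc)
    protected: set[int] = set()
    starts: list[int] = []
    # candidate uAUG starts leave room for -3 and +4 context inside the UTR
    candidates = list(range(3, length - 3))
    rng.shuffle(candidates)
    for i in candidates:
        if len(starts) == n_uaug:
            break
        if all(abs(i - j) >= 7 for j in starts):
            starts.append(i)
    for i in starts:
        seq[i : i + 3] = (0, 3, 2)  # ATG
        protected.add(i)
        if rng.random() < strong_frac:
            seq[i - 3] = rng.choice((0, 2))  # purine at -3
            seq[i + 3] = 2                   # G at +4
        else:
            seq[i - 3] = 1                   # C at -3
            seq[i + 3] = 1                   # C at +4
    _scrub_augs(seq, protected)
    return seq


def _make_cds(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    seq = _random_seq(rng, length, gc)
    seq[:3] = (0, 3, 2)  # ATG
    stops = [tuple("ACGT".index(c) for c in s) for s in STOP_CODONS]
    codons = seq[3:-3].reshape(-1, 3)
    while True:  # resample internal in-frame stop codons
        bad = np.zeros(len(codons), dtype=bool)
        for s in stops:
            bad |= (codons[:, 0] == s[0]) & (codons[:, 1] == s[1]) & (codons[:, 2] == s[2])
        if not bad.any():
            break
        codons[bad] = _random_seq(rng, int(bad.sum()) * 3, gc).reshape(-1, 3)
    seq[-3:] = stops[rng.integers(len(stops))]
    return seq


def _sample_length(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def simulate_transcriptome(
    config: SimulationConfig,
) -> tuple[list[TranscriptModel], GroundTruth]:
    """Generate transcripts and the planted ground truth in one pass.

    Planted TE change = sum_j beta_j * z_j + N(0, te_noise_sd), where z_j
    are z-scores of the realized sequence features named in
    ``planted_te_coefficients`` (recomputed exactly as the seqfeat module
    computes them).  Planted RF change = RNA change + TE change.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts
    models: list[TranscriptModel] = []
    for i in range(n):
        gc = rng.uniform(*config.gc_range)
        lu5 = _sample_length(rng, *config.utr5_length_range)
        lcds = _sample_length(rng, *config.cds_length_range)
        lcds = max(6, lcds - lcds % 3)
        lu3 = _sample_length(rng, *config.utr3_length_range)
        n_uaug = int(rng.poisson(config.uaug_rate))
        utr5 = _make_utr5(rng, lu5, gc, n_uaug, config.strong_kozak_frac)
        cds = _make_cds(rng, lcds, gc)
        utr3 = _random_seq(rng, lu3, gc)
        seq = "".join(_BASES[np.concatenate([utr5, cds, utr3])])
        tid = f"T{i + 1:05d}"
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=f"G{i + 1:05d}",
                sequence=seq,
                utr5=(0, lu5),
                cds=(lu5, lu5 + lcds),
                utr3=(lu5 + lcds, lu5 + lcds + lu3),
            )
        )

    coeffs = dict(config.planted_te_coefficients)
    truth = pd.DataFrame(index=pd.Index([m.transcript_id for m in models],
                                        name="transcript_id"))
    truth["gene_id"] = [m.gene_id for m in models]

    signal = np.zeros(n)
    if coeffs:
        feats = seqfeat.feature_table(
            models, features=list(coeffs), fold_window=config.fold_window
        )
        for name, beta in coeffs.items():
            x = feats[name].to_numpy(dtype=float)
            sd = x.std()
            if sd == 0:
                raise RibostatError(
                    f"planted feature {name!r} has zero variance under this "
                    "configuration"
                )
            z = (x - x.mean()) / sd
            truth[f"f_{name}"] = x
            truth[f"z_{name}"] = z
            signal = signal + beta * z

    noise = rng.normal(0.0, config.te_noise_sd, n) if config.te_noise_sd > 0 else np.zeros(n)
    truth["te_signal"] = signal
    truth["te_noise"] = noise
    truth["log2fc_te"] = signal + noise

    rna = np.zeros(n)
    n_up = int(round(config.frac_rna_up * n))
    n_down = int(round(config.frac_rna_down * n))
    if n_up + n_down:
        changed = rng.choice(n, size=n_up + n_down, replace=False)
        rna[changed[:n_up]] = config.rna_effect_log2
        rna[changed[n_up:]] = -config.rna_effect_log2
    truth["log2fc_rna"] = rna
    truth["log2fc_rf"] = truth["log2fc_rna"] + truth["log2fc_te"]

    truth["te_baseline"] = np.exp(rng.normal(0.0, config.te_baseline_log_sd, n))
    truth["depth_scale"] = np.exp(rng.normal(0.0, config.depth_log_sd, n))
    return models, GroundTruth(table=truth, coefficients=coeffs)


def _rf_weights(model: TranscriptModel, config: SimulationConfig) -> np.ndarray:
    """Positional sampling weights for footprint 5' ends.

    Uniform over 5'UTR (at reduced occupancy) and CDS, zero over the 3'UTR,
    with a multiplicative pause over the start- and stop-codon windows.
    """
    w = np.zeros(model.length)
    a, b = model.utr5
    c, d = model.cds
    w[a:b] = config.utr5_occupancy
    w[c:d] = 1.0
    s, t = model.start_codon_pos, model.stop_codon_pos
    w[s : s + 3] *= config.pause_enrichment
    w[t : t + 3] *= config.pause_enrichment
    return w


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial with variance mu + phi * mu^2."""
    r = 1.0 / phi
    mean = np.asarray(mean, dtype=float)
    p = r / (r + np.maximum(mean, 1e-12))
    return rng.negative_binomial(r, p)


def simulate_coverage(
    transcripts: list[TranscriptModel],
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[CoverageSet, CoverageSet]:
    """Draw (RF, RNA) coverage for every sample of the design.

    Expected RNA reads per transcript: depth_scale * mean_depth-relative
    level, times 2^log2fc_rna in the treated condition.  Expected RF reads
    additionally carry te_baseline and 2^log2fc_te, so the treated/control
    expected RF/RNA ratio differs by exactly the planted TE change.  Totals
    are negative-binomial; positions multinomial within the transcript.
    """
    ids = [m.transcript_id for m in transcripts]
    if list(truth.table.index) != ids:
        missing = set(ids) ^ set(truth.table.index)
        raise RibostatError(f"transcripts and truth disagree on ids: {sorted(missing)[:5]} ...")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    t = truth.table
    base = config.mean_depth * t["depth_scale"].to_numpy()
    fc_rna = 2.0 ** t["log2fc_rna"].to_numpy()
    fc_rf = 2.0 ** t["log2fc_rf"].to_numpy()
    te0 = t["te_baseline"].to_numpy()

    rna_w = [np.full(m.length, 1.0 / m.length) for m in transcripts]
    rf_w = []
    for m in transcripts:
        w = _rf_weights(m, config)
        rf_w.append(w / w.sum())

    cov_rf = CoverageSet(assay="rf")
    cov_rna = CoverageSet(assay="rna")
    for row in config.design().itertuples():
        treated = row.condition == "treated"
        if row.assay == "rna":
            mu = base * (fc_rna if treated else 1.0)
            weights = rna_w
            target = cov_rna
        else:
            mu = base * te0 * (fc_rf if treated else 1.0)
            weights = rf_w
            target = cov_rf
        totals = _nb_draw(rng, mu, config.nb_dispersion)
        sample = {}
        for m, w, n_reads in zip(transcripts, weights, totals):
            sample[m.transcript_id] = rng.multinomial(int(n_reads), w).astype(np.int32)
        target.samples[row.sample] = sample
    return cov_rf, cov_rna


def write_fixtures(
    transcripts: list[TranscriptModel],
    coverages: Iterable[CoverageSet],
    truth: GroundTruth,
    out_dir: str | os.PathLike,
    config: SimulationConfig | None = None,
) -> dict[str, str]:
    """Emit FASTA, annotation TSV, per-sample bedGraph, truth and design TSVs."""
    out_dir = str(out_dir)
    cov_dir = os.path.join(out_dir, "coverage")
    os.makedirs(cov_dir, exist_ok=True)
    paths = {
        "fasta": os.path.join(out_dir, "transcripts.fasta"),
        "annotation": os.path.join(out_dir, "annotation.tsv"),
        "ground_truth": os.path.join(out_dir, "ground_truth.tsv"),
        "coverage_dir": cov_dir,
    }
    io.write_fasta({m.transcript_id: m.sequence for m in transcripts}, paths["fasta"])
    io.write_annotation(transcripts, paths["annotation"])
    truth.table.reset_index().to_csv(paths["ground_truth"], sep="\t", index=False)
    for cov in coverages:
        for sample, depths in cov.samples.items():
            io.write_bedgraph(depths, os.path.join(cov_dir, f"{sample}.bedgraph"))
    if config is not None:
        paths["design"] = os.path.join(out_dir, "design.tsv")
        config.design().to_csv(paths["design"], sep="\t", index=False)
    return paths
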