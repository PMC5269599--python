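"""Planted-truth generator: sequences, coverage, fixtures."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from ribostat import io, quantify, simulate
from ribostat.core import RibostatError
from ribostat.simulate import GroundTruth, SimulationConfig


def small_config(**kw):
    base = dict(
        n_transcripts=40,
        utr5_length_range=(30, 120),
        cds_length_range=(90, 240),
        utr3_length_range=(60, 600),
        mean_depth=800.0,
        seed=11,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestTranscriptome:
    def test_zero_uaug_rate_gives_aug_free_utr5(self):
        cfg = small_config(uaug_rate=0.0, n_transcripts=80, seed=2,
                           planted_te_coefficients={})
        transcripts, _ = simulate.simulate_transcriptome(cfg)
        for t in transcripts:
            assert "ATG" not in t.region_sequence("utr5")

    def test_fixed_cds_length_and_codons(self):
        cfg = small_config(cds_length_range=(300, 300))
        transcripts, _ = simulate.simulate_transcriptome(cfg)
        for t in transcripts:
            cds = t.region_sequence("cds")
            assert len(cds) == 300
            assert cds.startswith("ATG")
            assert cds[-3:] in ("TAA", "TAG", "TGA")
            internal = [cds[i:i + 3] for i in range(3, len(cds) - 3, 3)]
            assert not set(internal) & {"TAA", "TAG", "TGA"}

    def test_seeded_determinism_byte_identical(self, tmp_path):
        cfg = small_config(n_transcripts=30)
        outs = []
        for name in ("a", "b"):
            transcripts, truth = simulate.simulate_transcriptome(cfg)
            cov = simulate.simulate_coverage(transcripts, truth, cfg)
            paths = simulate.write_fixtures(
                transcripts, cov, truth, tmp_path / name, cfg
            )
            outs.append(paths)
        assert filecmp.cmp(outs[0]["fasta"], outs[1]["fasta"], shallow=False)
        assert filecmp.cmp(outs[0]["annotation"], outs[1]["annotation"], shallow=False)
        sample = cfg.design()["sample"].iloc[0]
        assert filecmp.cmp(
            f"{outs[0]['coverage_dir']}/{sample}.bedgraph",
            f"{outs[1]['coverage_dir']}/{sample}.bedgraph",
            shallow=False,
        )

    def test_degenerate_range_rejected(self):
        with pytest.raises(RibostatError):
            small_config(utr5_length_range=(100, 50))
        with pytest.raises(RibostatError):
            small_config(nb_dispersion=0.0)
        with pytest.raises(RibostatError):
            small_config(n_treated=1)

    def test_truth_features_match_seqfeat_recomputation(self, demo_study):
        from ribostat import seqfeat

        truth = demo_study.truth
        models = {t.transcript_id: t for t in
                  simulate.simulate_transcriptome(demo_study.config)[0]}
        feats = seqfeat.feature_table(
            list(models.values()), features=list(truth.coefficients),
            fold_window=demo_study.config.fold_window,
        )
        for name in truth.coefficients:
            np.testing.assert_allclose(
                truth.table[f"f_{name}"].to_numpy(),
                feats[name].reindex(truth.table.index).to_numpy(dtype=float),
            )

    def test_rf_equals_rna_plus_te_by_construction(self, demo_study):
        t = demo_study.truth.table
        np.testing.assert_allclose(
            t["log2fc_rf"], t["log2fc_rna"] + t["log2fc_te"], atol=1e-12
        )

    def test_noise_free_coefficient_recovery(self):
        cfg = small_config(
            n_transcripts=200,
            te_noise_sd=0.0,
            planted_te_coefficients={"n_upstream_kozak": -0.4, "short_utr3": 0.3},
        )
        _, truth = simulate.simulate_transcriptome(cfg)
        t = truth.table
        X = np.column_stack(
            [np.ones(len(t)), t["z_n_upstream_kozak"], t["z_short_utr3"]]
        )
        beta = np.linalg.lstsq(X, t["log2fc_te"].to_numpy(), rcond=None)[0]
        assert beta[1] == pytest.approx(-0.4, abs=1e-6)
        assert beta[2] == pytest.approx(0.3, abs=1e-6)

    def test_constant_planted_feature_rejected(self):
        cfg = small_config(
            utr3_length_range=(50, 60),  # every 3'UTR short -> indicator constant
            planted_te_coefficients={"short_utr3": 0.3},
        )
        with pytest.raises(RibostatError):
            simulate.simulate_transcriptome(cfg)


def _estimated_te_fc(cfg, planted_te):
    """Estimated log2 TE change per transcript for a forced planted TE vector."""
    transcripts, truth = simulate.simulate_transcriptome(cfg)
    t = truth.table
    t["log2fc_te"] = planted_te
    t["log2fc_rf"] = t["log2fc_rna"] + t["log2fc_te"]
    cov_rf, cov_rna = simulate.simulate_coverage(transcripts, truth, cfg)
    expr = quantify.expression_table(transcripts, [cov_rf, cov_rna])
    te = quantify.te_table(expr, cfg.design())
    piv = te.pivot_table(index="transcript_id", columns="condition", values="te",
                        aggfunc=lambda v: np.exp(np.log(v).mean()))
    return np.log2(piv["treated"] / piv["control"])


class TestCoverage:
    def test_planted_te_recovered_from_counts(self):
        """One transcript planted at log2 TE change +2 among 50 unchanged;
        the mean estimate over independent count draws lands within 0.2."""
        ests = []
        for rep in range(30):
            cfg = small_config(
                n_transcripts=51, mean_depth=1e4, depth_log_sd=0.0,
                planted_te_coefficients={}, te_noise_sd=0.0,
                frac_rna_up=0.0, frac_rna_down=0.0, n_control=2, n_treated=2,
                seed=500 + rep,
            )
            planted = np.zeros(51)
            planted[0] = 2.0
            ests.append(_estimated_te_fc(cfg, planted).loc["T00001"])
        assert np.mean(ests) == pytest.approx(2.0, abs=0.2)

    def test_null_te_estimates_center_on_zero(self):
        cfg = small_config(
            n_transcripts=50, mean_depth=1e4, depth_log_sd=0.0,
            planted_te_coefficients={}, te_noise_sd=0.0,
            frac_rna_up=0.0, frac_rna_down=0.0,
        )
        est = _estimated_te_fc(cfg, 0.0)
        assert abs(est.mean()) < 0.15

    def test_no_footprints_in_utr3(self):
        cfg = small_config()
        transcripts, truth = simulate.simulate_transcriptome(cfg)
        cov_rf, _ = simulate.simulate_coverage(transcripts, truth, cfg)
        utr3_total = cds_total = 0
        for depths in cov_rf.samples.values():
            for t in transcripts:
                v = depths[t.transcript_id]
                utr3_total += v[t.utr3[0]:t.utr3[1]].sum()
                cds_total += v[t.cds[0]:t.cds[1]].sum()
        assert utr3_total <= 0.01 * cds_total

    def test_mismatched_ids_rejected(self):
        cfg = small_config()
        transcripts, truth = simulate.simulate_transcriptome(cfg)
        with pytest.raises(RibostatError):
            simulate.simulate_coverage(transcripts[:-1], truth, cfg)


class TestFixtures:
    def test_annotation_round_trip(self, tmp_path):
        cfg = small_config(n_transcripts=20)
        transcripts, truth = simulate.simulate_transcriptome(cfg)
        cov = simulate.simulate_coverage(transcripts, truth, cfg)
        paths = simulate.write_fixtures(transcripts, cov, truth, tmp_path, cfg)
        loaded = io.load_transcripts(paths["fasta"], paths["annotation"])
        assert [(t.transcript_id, t.utr5, t.cds, t.utr3) for t in loaded] == [
            (t.transcript_id, t.utr5, t.cds, t.utr3) for t in transcripts
        ]
        assert all(a.sequence == b.sequence for a, b in zip(loaded, transcripts))

    def test_coverage_round_trip(self, tmp_path):
        cfg = small_config(n_transcripts=15)
        transcripts, truth = simulate.simulate_transcriptome(cfg)
        cov_rf, cov_rna = simulate.simulate_coverage(transcripts, truth, cfg)
        simulate.write_fixtures(transcripts, [cov_rf, cov_rna], truth, tmp_path, cfg)
        lengths = {t.transcript_id: t.length for t in transcripts}
        sets = {
            c.assay: c
            for c in io.read_coverage_dir(tmp_path / "coverage", cfg.design(), lengths)
        }
        for assay, orig in (("rf", cov_rf), ("rna", cov_rna)):
            for sample, depths in orig.samples.items():
                for tid, v in depths.items():
                    np.testing.assert_array_equal(
                        sets[assay].samples[sample][tid], v
                    )

    def test_bedgraph_line_count_equals_nonzero_runs(self, tmp_path):
        rng = np.random.default_rng(0)
        v = rng.integers(0, 3, 200).astype(np.int64)
        runs = 0
        prev = 0
        for x in v:
            if x != 0 and x != prev:
                runs += 1
            prev = x
        io.write_bedgraph({"t": v}, tmp_path / "x.bedgraph")
        lines = (tmp_path / "x.bedgraph").read_text().strip().splitlines()
        assert len(lines) == runs
        back = io.read_bedgraph(tmp_path / "x.bedgraph", {"t": 200})
        np.testing.assert_array_equal(back["t"], v)

    def test_empty_transcript_set(self, tmp_path):
        cfg = small_config(n_transcripts=0, frac_rna_up=0, frac_rna_down=0,
                           planted_te_coefficients={})
        transcripts, truth = simulate.simulate_transcriptome(cfg)
        paths = simulate.write_fixtures(transcripts, [], truth, tmp_path, cfg)
        ann = io.read_annotation(paths["annotation"])
        assert len(ann) == 0
        gt = pd.read_csv(paths["ground_truth"], sep="\t")
        assert "transcript_id" in gt.columns and len(gt) == 0
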