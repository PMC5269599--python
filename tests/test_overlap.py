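"""Gene-set overlap tests, FDR behaviour and bias diagnostics."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ribostat import overlap
from ribostat.difftest import baseline_variance_explained


def genes(prefix, n):
    return [f"{prefix}{i}" for i in range(n)]


class TestFisherOverlap:
    def test_worked_example_exact(self):
        universe = genes("g", 20)
        target = universe[:5]
        query = universe[:3] + [universe[7]]  # overlap 3
        res = overlap.fisher_overlap(query, target, universe)
        assert res.overlap == 3
        expected = Fraction(155, 4845)
        assert res.p == pytest.approx(float(expected), abs=1e-15)
        # independent cross-check through scipy's exact test
        assert res.p == pytest.approx(
            sps.fisher_exact(res.table, alternative="greater")[1], abs=1e-12
        )

    def test_saturated_table(self):
        u = genes("g", 12)
        res = overlap.fisher_overlap(u, u, u)
        assert res.p == pytest.approx(1.0)
        assert res.overlap == len(u)

    def test_no_overlap_near_one(self):
        u = genes("g", 40)
        res = overlap.fisher_overlap(u[:4], u[10:14], u)
        assert res.p > 0.5

    def test_empty_query_flagged(self):
        u = genes("g", 10)
        res = overlap.fisher_overlap([], u[:3], u)
        assert res.p == 1.0
        assert np.isnan(res.odds_ratio)

    def test_outside_universe_ignored(self):
        u = genes("g", 10)
        res = overlap.fisher_overlap(u[:3] + ["alien"], u[:5] + ["alien"], u)
        assert res.n_query == 3
        assert res.n_target == 5

    def test_matches_hypergeometric_tail_small_sweep(self):
        for N in range(2, 26):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        p = overlap.hypergeom_tail_p(k, n, K, N)
                        tail = sum(
                            comb(K, j) * comb(N - K, n - j)
                            for j in range(k, min(K, n) + 1)
                        ) / comb(N, n)
                        assert abs(p - tail) < 1e-12

    def test_ci_bounds_odds_ratio(self):
        u = genes("g", 200)
        res = overlap.fisher_overlap(u[:40], u[:30] + u[100:120], u)
        assert res.odds_ratio > 1
        assert res.ci_low <= res.odds_ratio


class TestMirnaScan:
    def _preds(self, rows):
        return pd.DataFrame(rows, columns=["set_name", "gene_id", "confidence"])

    def test_confidence_threshold_is_inclusive(self):
        u = genes("g", 30)
        preds = self._preds(
            [("m1", u[0], 80.0), ("m1", u[1], 79.9), ("m1", u[2], 95.0)]
        )
        res = overlap.mirna_scan(preds, u[:5], u)
        assert res["n_target"].iloc[0] == 2

    def test_single_set_q_equals_p(self):
        u = genes("g", 50)
        preds = self._preds([("m1", g, 90.0) for g in u[:10]])
        res = overlap.mirna_scan(preds, u[5:15], u)
        assert res["q"].iloc[0] == pytest.approx(res["p"].iloc[0])

    def test_null_sets_controlled_by_fdr(self):
        rng = np.random.default_rng(4)
        u = genes("g", 400)
        rows = []
        for s in range(200):
            for g in rng.choice(u, size=20, replace=False):
                rows.append((f"m{s}", g, 90.0))
        preds = self._preds(rows)
        query = list(rng.choice(u, size=60, replace=False))
        res = overlap.mirna_scan(preds, query, u)
        assert (res["q"] < 0.05).mean() <= 0.05

    def test_bh_monotone_in_p(self):
        rng = np.random.default_rng(9)
        u = genes("g", 300)
        rows = []
        for s in range(40):
            for g in rng.choice(u, size=15, replace=False):
                rows.append((f"m{s}", g, 99.0))
        res = overlap.mirna_scan(self._preds(rows), list(u[:50]), u)
        assert (res.sort_values("p")["q"].diff().dropna() >= -1e-12).all()

    def test_universe_restriction_never_increases_overlap(self):
        rng = np.random.default_rng(2)
        u = genes("g", 100)
        q = list(rng.choice(u, 30, replace=False))
        t = list(rng.choice(u, 30, replace=False))
        full = overlap.fisher_overlap(q, t, u)
        small = overlap.fisher_overlap(q, t, u[:60])
        assert small.overlap <= full.overlap


class TestBiasDiagnostics:
    def _tables(self, rng, n=500):
        bg = genes("g", n)
        lengths = pd.Series(10 ** rng.normal(3, 0.4, n), index=bg)
        expr = pd.Series(10 ** rng.normal(1, 0.5, n), index=bg)
        return bg, lengths, expr

    def test_uniform_query_shows_no_bias(self):
        rng = np.random.default_rng(6)
        bg, lengths, expr = self._tables(rng)
        q = list(rng.choice(bg, 80, replace=False))
        rep = overlap.bias_diagnostics(q, bg, lengths, expr)
        assert (rep["p"] > 0.05).all()

    def test_longest_genes_flagged(self):
        rng = np.random.default_rng(8)
        bg, lengths, expr = self._tables(rng)
        q = list(lengths.sort_values().index[-50:])
        rep = overlap.bias_diagnostics(q, bg, lengths, expr).set_index("metric")
        assert rep.loc["log10_length", "p"] < 1e-6

    def test_identical_samples_d_zero(self):
        rng = np.random.default_rng(1)
        bg, lengths, expr = self._tables(rng, 50)
        rep = overlap.bias_diagnostics(bg, bg, lengths, expr)
        assert (rep["D"] == 0).all()

    def test_tiny_query_warns(self):
        rng = np.random.default_rng(3)
        bg, lengths, expr = self._tables(rng, 30)
        with pytest.warns(UserWarning):
            overlap.bias_diagnostics(bg[:2], bg, lengths, expr)


class TestPerSetVarianceExplained:
    @staticmethod
    def _gamma_set(rng, n, frac):
        x = np.exp(rng.normal(0, 0.8, n))
        mu = 2.0 * x
        shape = (mu ** 2).mean() / (mu.var() * (1 - frac) / frac)
        return x, rng.gamma(shape, mu / shape)

    def test_planted_per_set_split_recovered(self):
        rng = np.random.default_rng(12)
        ids_a, ids_b = genes("a", 1000), genes("b", 1000)
        xa, ya = self._gamma_set(rng, 1000, 0.7)
        xb, yb = self._gamma_set(rng, 1000, 0.4)
        rna = pd.Series(np.r_[xa, xb], index=ids_a + ids_b)
        rf = pd.Series(np.r_[ya, yb], index=ids_a + ids_b)
        res = overlap.per_set_variance_explained(
            {"setA": ids_a, "setB": ids_b}, rna, rf
        ).set_index("set_name")
        assert res.loc["setA", "pseudo_r2"] == pytest.approx(0.7, abs=0.05)
        assert res.loc["setB", "pseudo_r2"] == pytest.approx(0.4, abs=0.05)

    def test_identical_process_small_delta(self):
        rng = np.random.default_rng(21)
        ids_a, ids_b = genes("a", 2000), genes("b", 2000)
        xa, ya = self._gamma_set(rng, 2000, 0.6)
        xb, yb = self._gamma_set(rng, 2000, 0.6)
        rna = pd.Series(np.r_[xa, xb], index=ids_a + ids_b)
        rf = pd.Series(np.r_[ya, yb], index=ids_a + ids_b)
        res = overlap.per_set_variance_explained(
            {"setA": ids_a, "setB": ids_b}, rna, rf
        )
        assert abs(res.attrs["delta"]) < 0.05

    def test_tiny_set_warns_and_yields_nan(self):
        rng = np.random.default_rng(5)
        ids = genes("a", 100)
        x = np.exp(rng.normal(0, 0.5, 100))
        rna = pd.Series(x, index=ids)
        rf = pd.Series(2 * x, index=ids)
        with pytest.warns(UserWarning):
            res = overlap.per_set_variance_explained(
                {"empty": [], "full": ids}, rna, rf
            ).set_index("set_name")
        assert np.isnan(res.loc["empty", "pseudo_r2"])
        assert res.loc["full", "pseudo_r2"] > 0.99
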