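"""Genetic-model encodings, mixed-model scoring and GWAS diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tetragwas import gwas
from tetragwas import popstructure as ps
from tetragwas import simulate as sm
from tests.conftest import make_genotypes


def ols_score(y, enc):
    """Independent OLS F-test of the encoded columns over an intercept."""
    n = len(y)
    X0 = np.ones((n, 1))
    X1 = np.hstack([X0, enc])
    b0, _, _, _ = np.linalg.lstsq(X0, y, rcond=None)
    rss0 = float(((y - X0 @ b0) ** 2).sum())
    b1, _, _, _ = np.linalg.lstsq(X1, y, rcond=None)
    rss1 = float(((y - X1 @ b1) ** 2).sum())
    rank1 = np.linalg.matrix_rank(X1)
    q = rank1 - 1
    if q == 0:
        return None
    F = ((rss0 - rss1) / q) / (rss1 / (n - rank1))
    return -np.log10(stats.f.sf(F, q, n - rank1))


class TestEncodeDosage:
    @pytest.mark.parametrize("model,expected", [
        ("additive", [0, 1, 2, 3, 4]),
        ("1-dom-ref", [1, 1, 1, 1, 0]),
        ("1-dom-alt", [0, 1, 1, 1, 1]),
        ("2-dom-ref", [1, 1, 1, 0, 0]),
        ("2-dom-alt", [0, 0, 1, 1, 1]),
        ("diplo-additive", [0, 1, 1, 1, 2]),
    ])
    def test_single_column_models(self, model, expected):
        enc = gwas.encode_dosage(model, np.arange(5.0))
        np.testing.assert_array_equal(enc[:, 0], expected)

    def test_diplo_general_indicators(self):
        enc = gwas.encode_dosage("diplo-general", np.arange(5.0))
        np.testing.assert_array_equal(enc[:, 0], [0, 1, 1, 1, 0])  # het
        np.testing.assert_array_equal(enc[:, 1], [0, 0, 0, 0, 1])  # hom-alt

    def test_general_contrasts_observed_levels(self):
        enc = gwas.encode_dosage("general", np.array([0.0, 2, 2, 4]))
        assert enc.shape == (4, 2)
        np.testing.assert_array_equal(enc[:, 0], [0, 1, 1, 0])
        np.testing.assert_array_equal(enc[:, 1], [0, 0, 0, 1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="dosage"):
            gwas.encode_dosage("additive", np.array([5.0]))

    def test_additive_uses_fractional_dosages_raw(self):
        enc = gwas.encode_dosage("additive", np.array([0.3, 2.7]))
        np.testing.assert_array_equal(enc[:, 0], [0.3, 2.7])
        enc2 = gwas.encode_dosage("1-dom-alt", np.array([0.3, 2.7]))
        np.testing.assert_array_equal(enc2[:, 0], [0, 1])


class TestNullModel:
    def test_naive_collapses_to_iid_residual_variance(self, rng):
        y = rng.normal(size=40)
        setting = gwas.PopulationSetting.naive()
        fit = gwas.fit_null_model(y, setting, None,
                                  [f"s{i}" for i in range(40)])
        assert fit.ratio == 0.0
        resid = y - y.mean()
        expect = (resid @ resid) / (len(y) - 1)
        assert fit.sigma_e2 == pytest.approx(expect, rel=1e-10)

    def test_reml_matches_grid_oracle_on_small_instance(self, rng):
        n = 12
        d = rng.integers(0, 5, size=(n, 30)).astype(float)
        g = make_genotypes(d, positions=list(range(1, 31)))
        kin = ps.compute_kinship(g, loco=False)
        L = np.linalg.cholesky(kin.global_ + 1e-6 * np.eye(n))
        y = L @ rng.normal(size=n) * 1.5 + rng.normal(size=n)
        setting = gwas.PopulationSetting.k_only()
        fit = gwas.fit_null_model(y, setting, kin, g.samples)
        eigvals, U = np.linalg.eigh(kin.global_)
        eigvals = np.clip(eigvals, 0, None)
        ys = U.T @ y
        X = np.ones((n, 1))
        Xs = U.T @ X

        def reml(ratio):
            w = 1.0 / (ratio * eigvals + 1.0)
            Xw = Xs * w[:, None]
            beta = np.linalg.solve(Xs.T @ Xw, Xw.T @ ys)
            r = ys - Xs @ beta
            rss = float(r @ (w * r))
            _, ld = np.linalg.slogdet(Xs.T @ Xw)
            return 0.5 * ((n - 1) * np.log(rss) - np.sum(np.log(w)) + ld)

        grid = np.arange(1e-3, 60.0, 1e-3)
        best = grid[np.argmin([reml(r) for r in grid])]
        assert reml(fit.ratio) <= reml(best) + 1e-8

    def test_variance_ratio_recovery(self, rng):
        # data simulated with sg2/se2 = 3 on a family-structured kinship
        # (half-sib panel; eigenvalue spread makes the ratio identifiable)
        # is recovered within 50% relative error in most replicates
        hits = 0
        reps = 20
        for rep in range(reps):
            cfg = sm.SimulationConfig(n_chromosomes=2,
                                      markers_per_chromosome=100,
                                      seed=700 + rep)
            design = sm.CrossDesign([("A", "B", 50), ("A", "C", 50),
                                     ("D", "E", 50), ("D", "F", 50)])
            g, _ = sm.simulate_panel(design, cfg)
            kin = ps.compute_kinship(g, loco=False)
            n = g.n_samples
            L = np.linalg.cholesky(kin.global_ + 1e-6 * np.eye(n))
            y = L @ rng.normal(size=n) * np.sqrt(3.0) + rng.normal(size=n)
            fit = gwas.fit_null_model(y, gwas.PopulationSetting.k_only(),
                                      kin, g.samples)
            if abs(fit.ratio - 3.0) / 3.0 < 0.5:
                hits += 1
        assert hits >= 17

    def test_collinear_covariates_rejected(self, rng):
        samples = [f"s{i}" for i in range(10)]
        q = np.full((10, 3), 1 / 3)
        member = ps.MembershipMatrix(samples=samples,
                                     groups=["a", "b", "c"], probs=q)
        setting = gwas.PopulationSetting.q_only(member)
        with pytest.raises(ValueError, match="collinear"):
            gwas.fit_null_model(rng.normal(size=10), setting, None, samples)


class TestScoreMarkers:
    def test_perfect_marker_has_smallest_p(self, rng):
        d = rng.integers(0, 5, size=(30, 20)).astype(float)
        g = make_genotypes(d, positions=list(range(1, 21)))
        y = pd.Series(d[:, 7], index=g.samples)  # phenotype = marker 7
        res = gwas.score_markers(g, y, "additive",
                                 gwas.PopulationSetting.naive())
        assert res.scores.idxmax() == "m7"

    def test_monomorphic_marker_skipped(self, rng):
        d = rng.integers(0, 5, size=(20, 3)).astype(float)
        d[:, 1] = 2.0
        g = make_genotypes(d, positions=[1, 2, 3])
        y = pd.Series(rng.normal(size=20), index=g.samples)
        res = gwas.score_markers(g, y, "additive",
                                 gwas.PopulationSetting.naive())
        row = res.table.set_index("marker").loc["m1"]
        assert row["skipped_reason"] == "constant_encoding"
        assert np.isnan(row["score"])

    @pytest.mark.parametrize("model", gwas.GENETIC_MODELS)
    def test_naive_setting_matches_ols_oracle(self, model, rng):
        d = rng.integers(0, 5, size=(50, 25)).astype(float)
        g = make_genotypes(d, positions=list(range(1, 26)))
        y = pd.Series(rng.normal(size=50), index=g.samples)
        res = gwas.score_markers(g, y, model,
                                 gwas.PopulationSetting.naive())
        for j, mid in enumerate(g.marker_ids):
            expect = ols_score(y.to_numpy(),
                               gwas.encode_dosage(model, d[:, j]))
            row = res.table.set_index("marker").loc[mid]
            if expect is None:
                assert row["skipped_reason"] is not None
            else:
                assert row["score"] == pytest.approx(expect, abs=1e-6)

    def test_loco_uses_per_chromosome_kinship(self, rng):
        d = rng.integers(0, 5, size=(40, 40)).astype(float)
        chroms = ["chr1"] * 20 + ["chr2"] * 20
        g = make_genotypes(d, chromosomes=chroms,
                           positions=list(range(1, 21)) * 2)
        y = pd.Series(rng.normal(size=40), index=g.samples)
        kin = ps.compute_kinship(g, loco=True)
        res = gwas.score_markers(g, y, "additive",
                                 gwas.PopulationSetting.k_only(), kin)
        assert res.table["score"].notna().sum() >= 35


class TestInflationFactor:
    def test_identity_and_linearity(self):
        m = 1000
        expected = -np.log10(np.arange(1, m + 1) / (m + 1))
        assert gwas.inflation_factor(expected) == pytest.approx(1.0)
        assert gwas.inflation_factor(2 * expected) == pytest.approx(2.0)

    def test_null_uniform_p_calibrated(self, rng):
        ok = 0
        for _ in range(50):
            scores = -np.log10(rng.uniform(size=5000))
            if 0.95 <= gwas.inflation_factor(scores) <= 1.05:
                ok += 1
        assert ok >= 45

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            gwas.inflation_factor(np.arange(5.0))
        with pytest.raises(ValueError, match="constant"):
            gwas.inflation_factor(np.full(20, 1.0))


class TestSelectPopulationSetting:
    def test_closest_above_one(self):
        choice = gwas.select_population_setting(
            {"A": 1.53, "B": 1.13, "C": 1.08})
        assert choice.name == "C" and not choice.below_one

    def test_below_one_excluded(self):
        choice = gwas.select_population_setting(
            {"A": 1.5, "B": 0.95, "C": 1.05})
        assert choice.name == "C"

    def test_fallback_flags_below_one(self):
        choice = gwas.select_population_setting({"A": 0.9, "B": 0.8})
        assert choice.name == "A" and choice.below_one

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gwas.select_population_setting({})


class TestFdrThreshold:
    def test_hand_computed_example(self):
        p = pd.Series([0.005, 0.009, 0.02, 0.4, 0.9],
                      index=list("abcde"))
        thr, sig = gwas.fdr_score_threshold(p, alpha=0.05)
        assert sorted(sig) == ["a", "b", "c"]
        assert thr == pytest.approx(-np.log10(0.02))

    def test_no_significant(self):
        thr, sig = gwas.fdr_score_threshold(np.ones(10))
        assert sig == [] and thr == float("inf")

    def test_single_test_equals_raw(self):
        thr, sig = gwas.fdr_score_threshold(np.array([0.04]), alpha=0.05)
        assert len(sig) == 1 and thr == pytest.approx(-np.log10(0.04))


class TestHighScoring:
    def test_strictly_above_four(self):
        s = pd.Series({"a": 4.01, "b": 4.0, "c": 7.0, "d": np.nan})
        assert sorted(gwas.select_high_scoring(s)) == ["a", "c"]

    def test_empty(self):
        assert gwas.select_high_scoring(pd.Series(dtype=float)) == []

    def test_null_count_binomial_bound(self, rng):
        # on a 10,000-marker null, scores above 4 are ~ Binomial(m, 1e-4)
        exceed = []
        for _ in range(30):
            scores = pd.Series(-np.log10(rng.uniform(size=10_000)))
            exceed.append(len(gwas.select_high_scoring(scores)))
        assert np.mean(exceed) < 3
        assert max(exceed) <= 8


class TestScoreCorrelation:
    @staticmethod
    def result_from_scores(name, scores):
        table = pd.DataFrame({
            "marker": [f"m{i}" for i in range(len(scores))],
            "chromosome": "chr1",
            "position": np.arange(1, len(scores) + 1),
            "score": scores, "F": np.nan, "df": 1,
            "pvalue": 10.0 ** -np.asarray(scores), "skipped_reason": None,
        })
        setting, model = name.split("|")
        return gwas.GwasResult(model=model, setting=setting, table=table)

    def test_self_correlation_unit_diagonal_symmetry(self, rng):
        s1 = rng.uniform(0, 5, 50)
        s2 = s1 + rng.normal(scale=0.01, size=50)
        r1 = self.result_from_scores("naive|additive", s1)
        r2 = self.result_from_scores("K|additive", s2)
        corr, order = gwas.score_correlation_matrix([r1, r2])
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T)
        assert corr.iloc[0, 1] > 0.99
        assert set(order) == set(corr.columns)

    def test_requires_two_results(self, rng):
        r = self.result_from_scores("naive|additive", rng.uniform(0, 5, 20))
        with pytest.raises(ValueError):
            gwas.score_correlation_matrix([r])


class TestFullGrid:
    def test_48_result_sets(self, rng):
        d = rng.integers(0, 5, size=(30, 12)).astype(float)
        chroms = ["chr1"] * 6 + ["chr2"] * 6
        g = make_genotypes(d, chromosomes=chroms,
                           positions=list(range(1, 7)) * 2)
        y = pd.Series(rng.normal(size=30), index=g.samples)
        kin = ps.compute_kinship(g, loco=True)
        q = rng.dirichlet(np.ones(2), size=30)
        member = ps.MembershipMatrix(samples=g.samples, groups=["S1", "S2"],
                                     probs=q)
        settings = [
            gwas.PopulationSetting.naive(),
            gwas.PopulationSetting.k_only(),
            gwas.PopulationSetting.q_only(member, "struct"),
            gwas.PopulationSetting.q_only(member, "dapc"),
            gwas.PopulationSetting.k_plus_q(member, "struct"),
            gwas.PopulationSetting.k_plus_q(member, "dapc"),
        ]
        results = [gwas.score_markers(g, y, model, s, kin)
                   for s in settings for model in gwas.GENETIC_MODELS]
        assert len(results) == 48
        assert len({(r.setting, r.model) for r in results}) == 48
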