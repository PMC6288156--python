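import numpy as np
import pandas as pd
import pytest

from seedtrace import signature_eval as se
from seedtrace import synthetic_data as sd
from seedtrace.io_prep import ExpressionMatrix, to_log2
from seedtrace.progression import GenePanel
from seedtrace.survival_stats import fit_cox


@pytest.fixture(scope="module")
def fitted(survival_cohort):
    panel_genes, beta, expr, clinical, truth = survival_cohort
    panel = GenePanel(panel_genes)
    model = se.fit_weighted_model(expr, panel, clinical, reference_cohort="ref")
    return panel, beta, expr, clinical, truth, model


class TestFitWeightedModel:
    def test_single_gene_weight_is_univariate_beta(self, survival_cohort):
        _, _, expr, clinical, _ = survival_cohort
        panel = GenePanel(["GA"])
        model = se.fit_weighted_model(expr, panel, clinical)
        x = to_log2(expr).data.loc["GA"].to_numpy()
        clin = clinical.assign(GA=x)
        uni = fit_cox(clin, ["GA"])
        assert model.weights["GA"] == pytest.approx(uni.beta["GA"], abs=1e-8)

    def test_scores_have_unit_sd_in_fitting_cohort(self, fitted):
        *_, clinical, _, model = fitted
        expr = fitted[2]
        scores = se.score_patients(model, expr, clinical)
        assert scores.std(ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_recovered_weight_signs_match_truth(self, fitted):
        _, beta, *_rest, model = fitted
        for g, b in beta.items():
            assert np.sign(model.weights[g]) == np.sign(b)

    def test_json_round_trip(self, tmp_path, fitted):
        *_, model = fitted
        model.cutoff_fraction = 0.4
        path = tmp_path / "model.json"
        model.to_json(path)
        back = se.SignatureModel.from_json(path)
        assert back.weights == model.weights
        assert back.score_sd == model.score_sd
        assert back.cutoff_fraction == 0.4
        assert back.panel.gene_ids == model.panel.gene_ids


class TestScorePatients:
    def test_linearity_in_one_gene(self, fitted):
        _, _, expr, clinical, _, model = fitted
        bumped = expr.data.copy()
        bumped.loc["GA"] *= 2  # log2 expression rises by exactly 1
        s0 = se.score_patients(model, expr, clinical)
        s1 = se.score_patients(model, ExpressionMatrix(bumped, unit="fpkm"), clinical)
        dx = (np.log2(bumped.loc["GA"] + 1) - np.log2(expr.data.loc["GA"] + 1)).to_numpy()
        expected = model.weights["GA"] * dx / model.score_sd
        np.testing.assert_allclose((s1 - s0).to_numpy(), expected, atol=1e-9)

    def test_high_risk_patients_score_higher(self, fitted):
        _, _, expr, clinical, truth, model = fitted
        scores = se.score_patients(model, expr, clinical)
        eta = truth.linear_predictor
        hi = scores[(eta > eta.median()).to_numpy()]
        lo = scores[(eta <= eta.median()).to_numpy()]
        from seedtrace.survival_stats import wilcoxon_ranksum

        assert wilcoxon_ranksum(hi, lo).p < 0.01
        assert hi.mean() > lo.mean()

    def test_zero_overlap_rejected(self, fitted):
        *_, clinical, _, model = fitted
        other = ExpressionMatrix(
            pd.DataFrame(
                np.ones((1, len(clinical))), index=["zzz"],
                columns=clinical["patient_id"],
            ),
            unit="fpkm",
        )
        with pytest.raises(ValueError):
            se.score_patients(model, other, clinical)


class TestTransferCutoff:
    def test_half_split_top_scores(self):
        scores = pd.Series(np.arange(1.0, 11.0), index=[f"p{i}" for i in range(10)])
        labels = se.transfer_cutoff(0.5, scores)
        assert (labels[scores >= 6] == "high").all()
        assert (labels[scores < 6] == "low").all()

    def test_reference_split_reproduced(self, fitted):
        _, _, expr, clinical, _, model = fitted
        scores = se.score_patients(model, expr, clinical)
        a = se.transfer_cutoff(0.3, scores)
        b = se.transfer_cutoff(0.3, scores)
        pd.testing.assert_series_equal(a, b)

    def test_invariant_to_monotone_transform(self, fitted):
        _, _, expr, clinical, _, model = fitted
        scores = se.score_patients(model, expr, clinical)
        a = se.transfer_cutoff(0.35, scores)
        b = se.transfer_cutoff(0.35, np.exp(scores * 3))
        pd.testing.assert_series_equal(a, b)

    def test_fraction_bounds(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        for frac in (0.0, 1.0, 1.5):
            with pytest.raises(ValueError):
                se.transfer_cutoff(frac, scores)


class TestChooseCutoffFraction:
    def test_two_component_population_found(self):
        """30% of patients carry a strong planted hazard: the best split lands
        within 0.1 of 0.3."""
        rng = np.random.default_rng(8)
        n = 400
        high = rng.random(n) < 0.3
        lam = np.where(high, 5.0, 0.5)
        t = rng.exponential(1 / lam)
        c = rng.exponential(2.0, n)
        clinical = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "time": np.minimum(t, c) + 1e-3,
                "event": t <= c,
            }
        )
        scores = pd.Series(
            high * 2.0 + rng.normal(0, 0.3, n), index=clinical["patient_id"].to_numpy()
        )
        frac, p = se.choose_cutoff_fraction(scores, clinical)
        assert abs(frac - 0.3) <= 0.1
        assert p < 1e-6

    def test_deterministic_and_null_flagged(self, caplog):
        import logging

        rng = np.random.default_rng(12)
        n = 80
        clinical = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "time": rng.exponential(1, n) + 0.01,
                "event": rng.random(n) < 0.7,
            }
        )
        scores = pd.Series(rng.normal(size=n), index=clinical["patient_id"].to_numpy())
        with caplog.at_level(logging.WARNING):
            a = se.choose_cutoff_fraction(scores, clinical)
        b = se.choose_cutoff_fraction(scores, clinical)
        assert a == b

    def test_empty_grid_rejected(self, fitted):
        _, _, expr, clinical, _, model = fitted
        scores = se.score_patients(model, expr, clinical)
        with pytest.raises(ValueError):
            se.choose_cutoff_fraction(scores, clinical, grid=())


COVARIATES = ["psa", "gleason_gt7", "stage_pt3", "margin_pos"]


class TestEvaluateModel:
    def test_score_only_signal(self, fitted):
        """Covariates are pure noise; the final multivariate model keeps just
        the score and the score adds concordance."""
        _, _, expr, clinical, _, model = fitted
        model.cutoff_fraction = 0.5
        report = se.evaluate_model(model, expr, clinical, COVARIATES)
        assert list(report.multivariate.beta.index)[-1] == "score"
        assert report.selected_covariates == [] or all(
            report.multivariate.wald_p[c] < 0.05 for c in report.selected_covariates
        )
        assert report.c_index_with > report.c_index_without
        assert report.logrank is not None and report.logrank.p < 0.05
        assert report.univariate["score"].hr.iloc[0] > 1

    def test_backward_selection_matches_manual_trace(self):
        """Fixed fixture: run the elimination by hand and compare the path."""
        rng = np.random.default_rng(21)
        n = 250
        x1 = rng.normal(size=n)          # real effect
        x2 = rng.normal(size=n)          # univariate-significant via x1? no: noise
        score = rng.normal(size=n)
        t = rng.exponential(np.exp(-(0.8 * x1 + 0.02 * x2)))
        c = rng.exponential(2.0, n)
        clinical = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "time": np.minimum(t, c) + 1e-3,
                "event": t <= c,
                "x1": x1,
                "x2": x2,
            }
        )
        work = clinical.assign(score=score)
        # manual: univariate gate
        candidates = [
            c_ for c_ in ["x1", "x2"] if fit_cox(work, [c_]).wald_p.iloc[0] < 0.05
        ]
        current = candidates + ["score"]
        while True:
            fit = fit_cox(work, current)
            removable = [c_ for c_ in current if c_ != "score"]
            if not removable:
                break
            worst = max(removable, key=lambda c_: fit.wald_p[c_])
            if fit.wald_p[worst] >= 0.05:
                current.remove(worst)
            else:
                break
        expr = ExpressionMatrix(
            pd.DataFrame(
                2.0 ** rng.normal(5, 1, (1, n)), index=["G"], columns=work["patient_id"]
            ),
            unit="fpkm",
        )
        model = se.SignatureModel(
            panel=GenePanel(["G"]), weights={"G": 0.0001}, score_sd=1.0
        )
        report = se.evaluate_model(model, expr, clinical, ["x1", "x2"])
        assert sorted(report.selected_covariates) == sorted(
            [c_ for c_ in current if c_ != "score"]
        )

    def test_null_score_univariate_p_looks_uniform(self):
        """Frozen arbitrary weights scored on independent null cohorts: the
        score's univariate Cox p over seeds should not pile up near 0."""
        ps = []
        for seed in range(60):
            expr, clinical, _ = sd.gen_survival_cohort(
                120, ["GA", "GB"], {"GA": 0.0, "GB": 0.0},
                censoring_rate=0.3, seed=seed, covariate_association=0.0,
                n_background_genes=0,
            )
            model = se.SignatureModel(
                panel=GenePanel(["GA", "GB"]), weights={"GA": 0.4, "GB": -0.3},
                score_sd=1.0,
            )
            scores = se.score_patients(model, expr, clinical)
            work = clinical.assign(score=scores.to_numpy())
            ps.append(fit_cox(work, ["score"]).wald_p.iloc[0])
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01
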