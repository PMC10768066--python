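"""Mixed-effects psychometric models: null cases, exact polynomial recovery,
parameter recovery under the generative model, and a glmer cross-check for
the quadrature logistic fitter."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from pupileffort._glmm import SeparationError, fit_binomial_glmm
from pupileffort.cohort import (
    EffectConfig,
    generate_profiles,
    profiles_to_frame,
    simulate_ppd_cells,
)
from pupileffort.models import (
    code_snr,
    fit_accuracy_model,
    fit_condition_model,
    fit_polynomial_model,
    fit_tlx_model,
    median_split,
    participant_shape,
    shape_table,
    wordgroup_analysis,
)
from pupileffort.types import SNR_LEVELS


def grid_frame(values_fn, participants=("P01", "P02", "P03")):
    rows = [(p, float(s), float(values_fn(p, s)))
            for p in participants for s in SNR_LEVELS]
    return pd.DataFrame(rows, columns=["participant_id", "snr", "ppd"])


class TestConditionModel:
    def test_flat_data_gives_null_lrt(self):
        offsets = {"P01": 0.0, "P02": 0.4, "P03": 1.1}
        cells = grid_frame(lambda p, s: 2.0 + offsets[p])
        fit = fit_condition_model(cells)
        assert fit.lrt.chi2 == pytest.approx(0.0, abs=1e-5)
        assert (fit.contrasts["p"] > 0.9).all()

    def test_two_level_balanced_contrast_equals_mean_difference(self):
        # two participants, two conditions: the condition beta is the
        # difference of condition means (closed form for a balanced design)
        cells = pd.DataFrame({
            "participant_id": ["A", "A", "B", "B"],
            "snr": [0.0, 4.0, 0.0, 4.0],
            "ppd": [2.0, 5.0, 4.0, 9.0],
        })
        fit = fit_condition_model(cells)
        beta = fit.fixed_effects.set_index("term")["beta"]
        assert beta["C(snr)[T.4.0]"] == pytest.approx((5 + 9) / 2 - (2 + 4) / 2)

    def test_common_high_tip_shows_snr16_above_low_snrs(self):
        hits = 0
        for seed in range(10):
            profs = generate_profiles(8, seed=seed)
            for p in profs:
                p.latent.tip_snr = 16.0
            cells = simulate_ppd_cells(profs, ppd_noise_sd=2.0, seed=seed)
            fit = fit_condition_model(cells)
            c = fit.contrasts.set_index("contrast")
            ok = all(c.loc[f"SNR16 - SNR{lo}", "beta"] > 0 and
                     c.loc[f"SNR16 - SNR{lo}", "p"] < 0.05
                     for lo in (0, 4))
            hits += ok
        assert hits >= 9

    def test_single_participant_rejected(self):
        cells = grid_frame(lambda p, s: s, participants=("P01",))
        with pytest.raises(ValueError):
            fit_condition_model(cells)


class TestPolynomialModel:
    def test_pure_linear_has_null_quadratic(self):
        cells = grid_frame(lambda p, s: 1.0 + 0.2 * s)
        fit = fit_polynomial_model(cells)
        assert fit.lrt["quadratic"].chi2 == pytest.approx(0.0, abs=1e-4)

    def test_exact_quadratic_recovery_with_centered_coding(self):
        cells = grid_frame(lambda p, s: -((s - 10.0) ** 2) / 20.0 + 5.0)
        fit = fit_polynomial_model(cells)
        beta = fit.fixed_effects.set_index("term")["beta"]
        # -((10x)^2)/20 = -5 x^2 on the coded scale; no linear part
        assert beta["quadratic"] == pytest.approx(-5.0, abs=1e-3)
        assert beta["linear"] == pytest.approx(0.0, abs=1e-3)

    def test_flat_data_null_everywhere(self):
        cells = grid_frame(lambda p, s: 3.0)
        fit = fit_polynomial_model(cells)
        assert fit.lrt["linear"].chi2 == pytest.approx(0.0, abs=1e-4)
        assert fit.lrt["quadratic"].chi2 == pytest.approx(0.0, abs=1e-4)


class TestAccuracyModel:
    @staticmethod
    def _trials(p_fn, n_trials=40, n_kw=4, seed=0, n_participants=6):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_participants):
            for s in SNR_LEVELS:
                p = p_fn(i, s)
                for _ in range(n_trials):
                    rows.append((f"P{i}", float(s), rng.binomial(n_kw, p), n_kw))
        return pd.DataFrame(rows, columns=["participant_id", "snr",
                                           "keywords_correct", "n_keywords"])

    def test_constant_half_accuracy_gives_null_lrt(self):
        # LRT p under a no-effect generator should look uniform: across a
        # few replicates most must clear the nominal level
        ps = [fit_accuracy_model(self._trials(lambda i, s: 0.5, seed=s)).lrt.p
              for s in range(5)]
        assert sum(p > 0.05 for p in ps) >= 4

    def test_recovers_monotone_contrast_pattern(self):
        from scipy.special import expit
        fit = fit_accuracy_model(
            self._trials(lambda i, s: expit(0.3 * (s - 8.0)), seed=5))
        c = fit.contrasts.set_index("contrast")
        for lo, hi in [(0, 8), (0, 16), (4, 12), (8, 20)]:
            assert c.loc[f"SNR{hi} - SNR{lo}", "beta"] > 0
        # spacing on the logit scale ~ slope * dB difference
        assert c.loc["SNR16 - SNR0", "beta"] == pytest.approx(0.3 * 16, rel=0.2)

    def test_all_correct_raises_separation_error(self):
        with pytest.raises(SeparationError):
            fit_accuracy_model(self._trials(lambda i, s: 1.0))

    def test_quadrature_matches_glmer_reference(self, tmp_path):
        """Independent oracle: lme4::glmer with adaptive quadrature on a
        small two-predictor fixture must agree on coefficients and the
        random-intercept SD."""
        rng = np.random.default_rng(42)
        G, T = 12, 30
        u = rng.normal(0, 0.8, G)
        x = rng.choice([0.0, 1.0, 2.0], size=(G, T))
        eta = -0.5 + 0.9 * x + u[:, None]
        n = np.full((G, T), 5)
        y = rng.binomial(n, 1.0 / (1.0 + np.exp(-eta)))
        df = pd.DataFrame({"g": np.repeat(np.arange(G), T),
                           "x": x.ravel(), "y": y.ravel(), "n": n.ravel()})
        X = np.column_stack([np.ones(len(df)), df["x"]])
        fit = fit_binomial_glmm(df["y"].to_numpy(), df["n"].to_numpy(), X,
                                df["g"].to_numpy())

        csv = tmp_path / "glmm.csv"
        df.to_csv(csv, index=False)
        rcode = f"""
        d <- read.csv("{csv}")
        suppressMessages(library(lme4))
        m <- glmer(cbind(y, n - y) ~ x + (1 | g), data = d,
                   family = binomial, nAGQ = 25)
        cat(fixef(m)[1], fixef(m)[2],
            sqrt(unlist(VarCorr(m))[1]),
            summary(m)$coefficients[, 2], sep = ",")
        """
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, check=True).stdout.strip()
        b0, b1, sigma, se0, se1 = map(float, out.split(","))
        assert fit.params[0] == pytest.approx(b0, abs=2e-3)
        assert fit.params[1] == pytest.approx(b1, abs=2e-3)
        assert fit.sigma_u == pytest.approx(sigma, abs=5e-3)
        assert fit.se[0] == pytest.approx(se0, rel=0.02)
        assert fit.se[1] == pytest.approx(se1, rel=0.02)


class TestTlxModel:
    def test_decreasing_workload_detected(self):
        rng = np.random.default_rng(0)
        rows = [(f"P{i}", float(s), np.clip(75 - 2 * s + rng.normal(0, 5), 0, 100))
                for i in range(10) for s in SNR_LEVELS]
        fit = fit_tlx_model(pd.DataFrame(rows, columns=["participant_id", "snr", "tlx"]))
        assert fit.family == "logistic"
        assert fit.lrt.p < 0.001
        c = fit.contrasts.set_index("contrast")
        assert c.loc["SNR20 - SNR0", "beta"] < 0


class TestParticipantShape:
    def test_constant_cells(self):
        cm = pd.DataFrame({"snr": list(SNR_LEVELS), "ppd": [2.0] * 6})
        sp = participant_shape(cm, "P")
        assert (sp.mean_ppd, sp.linear_coef, sp.quad_coef) == \
            (pytest.approx(2.0), pytest.approx(0.0, abs=1e-9),
             pytest.approx(0.0, abs=1e-9))

    def test_known_parabola_recovered(self):
        cm = pd.DataFrame({"snr": list(SNR_LEVELS),
                           "ppd": [-(s - 10.0) ** 2 / 20.0 + 5.0 for s in SNR_LEVELS]})
        sp = participant_shape(cm, "P")
        assert sp.quad_coef == pytest.approx(-5.0, abs=1e-9)

    def test_strict_line_has_zero_quadratic(self):
        cm = pd.DataFrame({"snr": list(SNR_LEVELS),
                           "ppd": [1.0 + 0.5 * s for s in SNR_LEVELS]})
        sp = participant_shape(cm, "P")
        assert sp.quad_coef == pytest.approx(0.0, abs=1e-9)
        assert sp.linear_coef > 0

    def test_too_few_cells_leaves_coefficients_missing(self):
        cm = pd.DataFrame({"snr": [0.0, 4.0], "ppd": [1.0, 2.0]})
        sp = participant_shape(cm, "P")
        assert np.isfinite(sp.mean_ppd)
        assert np.isnan(sp.quad_coef) and np.isnan(sp.linear_coef)

    def test_mean_invariant_to_coding_and_quad_sign_stable(self):
        # affine recoding of SNR cannot change mean_ppd or the sign of the
        # quadratic coefficient
        vals = [-(s - 12.0) ** 2 / 15.0 + 6.0 for s in SNR_LEVELS]
        cm = pd.DataFrame({"snr": list(SNR_LEVELS), "ppd": vals})
        sp = participant_shape(cm, "P")
        recoded = pd.DataFrame({"snr": [2 * s + 3 for s in SNR_LEVELS], "ppd": vals})
        sp2 = participant_shape(recoded, "P")
        assert sp.mean_ppd == pytest.approx(sp2.mean_ppd)
        assert np.sign(sp.quad_coef) == np.sign(sp2.quad_coef)


class TestWordgroupAnalysis:
    def test_median_split_puts_ties_in_lower_group(self):
        profiles = pd.DataFrame({
            "participant_id": ["A", "B", "C", "D", "E"],
            "word_recognition": [50.0, 60.0, 70.0, 70.0, 90.0],
        })
        groups = median_split(profiles).set_index("participant_id")["wordgroup"]
        assert groups["C"] == "low" and groups["D"] == "low"
        assert groups["E"] == "high"

    def test_shared_curve_gives_null_interaction(self):
        profs = generate_profiles(12, seed=2)
        for p in profs:
            p.latent.tip_snr, p.latent.peak_amp, p.latent.curve_width = 10.0, 8.0, 6.0
        cells = simulate_ppd_cells(profs, ppd_noise_sd=1.0, seed=3)
        wg = wordgroup_analysis(shape_table(cells), profiles_to_frame(profs), cells)
        assert wg.interaction.lrt.p > 0.01

    def test_distinct_tipping_points_detected(self):
        cfg = EffectConfig(bimodal_tips=(16.0, 4.0))
        profs = generate_profiles(17, cfg, seed=0)
        cells = simulate_ppd_cells(profs, seed=1)
        wg = wordgroup_analysis(shape_table(cells), profiles_to_frame(profs), cells)
        assert wg.interaction.lrt.p < 0.05
        merged = cells.merge(wg.groups, on="participant_id")
        per = merged.groupby(["wordgroup", "snr"])["ppd"].mean()
        assert per["low"].idxmax() == 16.0
        assert per["high"].idxmax() == 4.0

    def test_identical_covariates_give_null_welch(self):
        profs = generate_profiles(10, seed=4)
        pf = profiles_to_frame(profs)
        pf["age"] = 50.0 + np.tile([0.0, 1.0, 2.0, 3.0, 4.0], 2)[: len(pf)]
        cells = simulate_ppd_cells(profs, seed=5)
        wg = wordgroup_analysis(shape_table(cells), pf, cells)
        row = wg.covariate_tests.set_index("covariate").loc["age"]
        assert abs(row["t"]) < 2.5  # same distribution, no systematic difference


class TestShapeRecoveryProperty:
    def test_quad_coef_tracks_tipping_point_sign(self):
        """Across seeds, the fitted per-participant quadratic coefficient
        correlates with the generated tipping point with the configured
        (negative word-recognition) sign."""
        from scipy.stats import spearmanr
        hits = 0
        for seed in range(10):
            profs = generate_profiles(17, seed=seed)
            cells = simulate_ppd_cells(profs, seed=seed + 300)
            merged = profiles_to_frame(profs).merge(
                shape_table(cells), on="participant_id")
            rho, _ = spearmanr(merged["word_recognition"], merged["quad_coef"])
            hits += rho < 0
        assert hits >= 9
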