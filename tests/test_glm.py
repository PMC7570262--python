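from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from seedfate.glm import (
    build_design,
    fit_irls,
    fit_quasibinomial_glm,
    full_factorial,
    sum_contrast,
)


def simulate_dataset(rng, n=80, factors=("a", "b"), levels=(2, 3)):
    data = {}
    for name, k in zip(factors, levels):
        data[name] = rng.choice([f"{name}{i}" for i in range(k)], n)
    frame = pd.DataFrame(data)
    eta = rng.normal(0, 0.8, n)
    for name in factors:
        codes = pd.Categorical(frame[name]).codes
        eta += rng.normal(0, 0.5) * (codes - codes.mean())
    p = 1 / (1 + np.exp(-eta))
    frame["trials"] = rng.integers(5, 60, n).astype(float)
    frame["y"] = rng.binomial(frame.trials.astype(int), p) / frame.trials
    return frame


class TestDesign:
    def test_sum_contrast_columns_sum_to_zero_over_levels(self):
        s = pd.Series(["x", "y", "z", "x", "z"])
        cols, names = sum_contrast(s, "f")
        assert cols.shape == (5, 2)
        # each level's code row summed over levels is zero
        level_rows = {lvl: cols[list(s).index(lvl)] for lvl in "xyz"}
        assert np.allclose(sum(level_rows.values()), 0.0)

    def test_full_factorial_term_count(self):
        terms = full_factorial(["a", "b", "c", "d"])
        assert len(terms) == 15
        assert full_factorial(["a", "b"], max_order=1) == [("a",), ("b",)]

    def test_four_factor_design_has_24_columns(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({
            "year": rng.choice(["2017", "2018"], 200),
            "species": rng.choice(["r", "c"], 200),
            "micro": rng.choice(["control", "runoff", "shade"], 200),
            "cohort": rng.choice(["2015", "2016"], 200),
        })
        X, names, spans = build_design(
            frame, full_factorial(["year", "species", "micro", "cohort"])
        )
        assert X.shape[1] == 24  # intercept + 23 term df


class TestFit:
    def test_null_effect_gives_f_near_zero(self):
        frame = pd.DataFrame({
            "g": ["a"] * 10 + ["b"] * 10,
            "y": [0.4] * 20,
            "trials": [50.0] * 20,
        })
        # add tiny balanced noise so the fit is not fully degenerate
        frame.loc[::2, "y"] = 0.42
        frame.loc[1::2, "y"] = 0.38
        table = fit_quasibinomial_glm(frame, "y", ["g"], weights="trials")
        row = table.table.iloc[0]
        assert row.f_value == pytest.approx(0.0, abs=1e-8)
        assert row.p_value == pytest.approx(1.0, abs=1e-6)

    def test_deviance_nonincreasing_and_fitted_in_unit_interval(self):
        rng = np.random.default_rng(5)
        frame = simulate_dataset(rng)
        X, names, _ = build_design(frame, full_factorial(["a", "b"]))
        fit = fit_irls(frame.y.to_numpy(), X, frame.trials.to_numpy(), names)
        # trace[0] is the initialization (mu shrunk toward the data, not a
        # model fit); monotone decrease holds across the model iterates
        diffs = np.diff(fit.deviance_trace[1:])
        assert np.all(diffs <= 1e-8)
        assert np.all((fit.fitted > 0) & (fit.fitted < 1))

    def test_agreement_with_statsmodels_reference(self):
        """Coefficients and Type III F agree with an independent fit engine."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(12)
        for _ in range(20):
            frame = simulate_dataset(rng)
            terms = full_factorial(["a", "b"])
            X, names, spans = build_design(frame, terms)
            y, w = frame.y.to_numpy(), frame.trials.to_numpy()
            mine = fit_irls(y, X, w, names)
            ref_full = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit()
            np.testing.assert_allclose(
                mine.coefficients, ref_full.params, rtol=1e-6, atol=1e-9
            )
            phi_ref = ref_full.pearson_chi2 / ref_full.df_resid
            table = fit_quasibinomial_glm(frame, "y", ["a", "b"], weights="trials")
            for term in terms:
                keep = np.ones(X.shape[1], dtype=bool)
                keep[spans[term]] = False
                ref_red = sm.GLM(
                    y, X[:, keep], family=sm.families.Binomial(), var_weights=w
                ).fit()
                df_t = spans[term].stop - spans[term].start
                f_ref = ((ref_red.deviance - ref_full.deviance) / df_t) / phi_ref
                f_mine = table.table.set_index("term").loc[
                    " x ".join(term), "f_value"
                ]
                assert f_mine == pytest.approx(f_ref, rel=1e-6)

    def test_metadata_records_model_choices(self):
        rng = np.random.default_rng(8)
        frame = simulate_dataset(rng)
        table = fit_quasibinomial_glm(frame, "y", ["a", "b"], weights="trials")
        assert table.link == "logit"
        assert table.family == "quasibinomial"
        assert table.contrasts == "sum-to-zero"
        assert table.dispersion > 0
        assert table.table.iloc[-1]["term"] == "residuals"

    def test_separation_is_flagged_not_fatal(self):
        frame = pd.DataFrame({
            "g": ["a"] * 8 + ["b"] * 8,
            "y": [0.0] * 8 + [1.0] * 8,
            "trials": [10.0] * 16,
        })
        with pytest.warns(UserWarning, match="separation"):
            fit_quasibinomial_glm(frame, "y", ["g"], weights="trials")

    def test_bad_inputs_rejected(self):
        frame = pd.DataFrame({"g": ["a", "b"] * 4, "y": [1.5] * 8, "w": [5.0] * 8})
        with pytest.raises(ValueError, match="proportion"):
            fit_quasibinomial_glm(frame, "y", ["g"], weights="w")
        frame["y"] = 0.5
        frame["w"] = 0.0
        with pytest.raises(ValueError, match="weights"):
            fit_quasibinomial_glm(frame, "y", ["g"], weights="w")
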