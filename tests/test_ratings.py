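import dataclasses

import numpy as np
import pandas as pd
import pytest

from groovemap.ratings import (
    compare_models,
    fit_entropy_model,
    fit_genre_model,
    fit_null_model,
    posthoc_pairwise,
    similarity_matrix,
)
from groovemap.synthetic_data import default_design, default_truth, gen_ratings


def _noise_free_truth(**fixed):
    t = default_truth().with_fixed(**fixed)
    return dataclasses.replace(
        t, residual_sd=0.0, random_sd={k: 0.0 for k in t.random_sd}
    )


def _tiny_table():
    """Two participants, two stimuli, one component, hand-chosen ratings."""
    rows = []
    for pid, ra, rb in [("p1", 1, 4), ("p2", 1, 5)]:
        for stim, genre, r in [("s1", "funk", ra), ("s2", "rock", rb)]:
            rows.append(
                dict(participant_id=pid, stimulus_id=stim, genre=genre,
                     component="wanting_to_move", rating=r, familiarity=2,
                     formal_training_years=0, informal_training_years=0,
                     pulse_entropy=0.7)
            )
    return pd.DataFrame(rows)


class TestSimilarity:
    def test_hand_worked_distance(self):
        """Participant vectors (1,1) vs (4,5) are sqrt(9+16)=5 apart."""
        d = similarity_matrix(_tiny_table(), "wanting_to_move")
        assert d.loc["s1", "s2"] == pytest.approx(5.0)
        assert d.loc["s1", "s1"] == 0.0

    def test_identical_vectors_distance_zero(self):
        t = _tiny_table()
        t.loc[t.stimulus_id == "s2", "rating"] = t.loc[
            t.stimulus_id == "s1", "rating"
        ].to_numpy()
        d = similarity_matrix(t, "wanting_to_move")
        assert d.loc["s1", "s2"] == 0.0

    def test_metric_properties_on_simulated_table(self):
        table = gen_ratings(default_design(10), default_truth(), seed=5)
        d = similarity_matrix(table, "pleasure").to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        # triangle inequality spot-check on a few triples
        n = d.shape[0]
        rng = np.random.default_rng(0)
        for _ in range(20):
            i, j, k = rng.choice(n, 3, replace=False)
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_missing_cell_rejected(self):
        t = _tiny_table().iloc[:-1]
        with pytest.raises(ValueError, match="missing cells"):
            similarity_matrix(t, "wanting_to_move")


class TestGenreModel:
    def test_noise_free_exact_recovery(self):
        """Integer-valued deterministic latent: the fit reproduces the
        generating coefficients to numerical tolerance."""
        truth = _noise_free_truth(
            intercept=1.0,
            genre={"jazz_funk": -1.0, "rock": -2.0},
            familiarity=1.0,
        )
        truth = dataclasses.replace(truth, familiarity_sd=0.4,
                                    familiarity_mean={"funk": 3.0, "jazz_funk": 3.0,
                                                      "rock": 3.0})
        table = gen_ratings(default_design(12), truth, seed=21)
        fit = fit_genre_model(table, "wanting_to_move",
                              random_structure=("participant", "stimulus"))
        coefs = fit.fixed_estimates
        assert coefs["C(genre, Treatment('funk'))[T.jazz_funk]"]["estimate"] == pytest.approx(-1.0, abs=1e-6)
        assert coefs["C(genre, Treatment('funk'))[T.rock]"]["estimate"] == pytest.approx(-2.0, abs=1e-6)
        assert coefs["familiarity"]["estimate"] == pytest.approx(1.0, abs=1e-6)
        assert coefs["Intercept"]["estimate"] == pytest.approx(1.0, abs=1e-5)

    def test_row_order_invariance(self):
        table = gen_ratings(default_design(15), default_truth(), seed=8)
        fit1 = fit_genre_model(table, "pleasure",
                               random_structure=("participant", "stimulus"))
        shuffled = table.sample(frac=1.0, random_state=99).reset_index(drop=True)
        fit2 = fit_genre_model(shuffled, "pleasure",
                               random_structure=("participant", "stimulus"))
        for name in fit1.fixed_estimates:
            assert fit1.fixed_estimates[name]["estimate"] == pytest.approx(
                fit2.fixed_estimates[name]["estimate"], abs=1e-6
            )

    def test_between_within_df_assignment(self):
        table = gen_ratings(default_design(10), default_truth(), seed=4)
        fit = fit_genre_model(table, "wanting_to_move",
                              random_structure=("participant", "stimulus"))
        assert fit.fixed_estimates["C(genre, Treatment('funk'))[T.rock]"]["df"] == 9.0
        assert fit.fixed_estimates["formal_training_years"]["df"] == 7.0
        assert fit.df_method == "between-within"

    def test_component_must_exist(self):
        table = gen_ratings(default_design(4), default_truth(), seed=0)
        with pytest.raises(ValueError, match="no rows"):
            fit_genre_model(table, "arousal")


class TestModelComparison:
    def test_identical_models_chi2_zero(self):
        table = gen_ratings(default_design(10), default_truth(), seed=13)
        a = fit_null_model(table, "wanting_to_move", reml=False)
        b = fit_null_model(table, "wanting_to_move", reml=False)
        chi2, df, p = compare_models(a, b)
        assert chi2 == pytest.approx(0.0, abs=1e-6)
        assert df == 0 and p == 1.0

    def test_reml_fits_rejected(self):
        table = gen_ratings(default_design(6), default_truth(), seed=13)
        a = fit_null_model(table, "wanting_to_move", reml=True)
        b = fit_null_model(table, "wanting_to_move", reml=False)
        with pytest.raises(ValueError, match="ML"):
            compare_models(a, b)

    def test_genre_effect_detected_at_study_scale(self):
        """The Table-1-magnitude genre effect produces a decisive LRT."""
        table = gen_ratings(default_design(108), default_truth(), seed=30)
        null = fit_null_model(table, "wanting_to_move", reml=False)
        full = fit_genre_model(table, "wanting_to_move", reml=False,
                               random_structure=("participant", "stimulus"))
        chi2, df, p = compare_models(null, full)
        assert df == 2
        assert chi2 > 10 and p < 0.01


@pytest.fixture(scope="module")
def posthoc_fit():
    table = gen_ratings(default_design(30), default_truth(), seed=17)
    return fit_genre_model(table, "wanting_to_move",
                           random_structure=("participant", "stimulus"))


class TestPosthoc:

    def test_single_contrast_unadjusted(self, posthoc_fit):
        out = posthoc_pairwise(posthoc_fit, levels=("funk", "jazz_funk"))
        assert len(out) == 1
        assert out["p_adjusted"].iloc[0] == pytest.approx(
            out["p_unadjusted"].iloc[0]
        )

    def test_adjustment_never_decreases_p(self, posthoc_fit):
        out = posthoc_pairwise(posthoc_fit)
        assert len(out) == 3
        assert (out["p_adjusted"] >= out["p_unadjusted"] - 1e-12).all()

    def test_zero_differences_in_noise_free_equal_means(self):
        truth = _noise_free_truth(
            intercept=0.0, genre={"jazz_funk": 0.0, "rock": 0.0}, familiarity=1.0
        )
        truth = dataclasses.replace(truth, familiarity_sd=0.4,
                                    familiarity_mean={g: 3.0 for g in
                                                      ("funk", "jazz_funk", "rock")})
        table = gen_ratings(default_design(10), truth, seed=2)
        fit = fit_genre_model(table, "pleasure",
                              random_structure=("participant", "stimulus"))
        out = posthoc_pairwise(fit)
        assert np.allclose(out["estimate"], 0.0, atol=1e-6)


class TestEntropyModel:
    def test_noise_free_parabola_interpolated_exactly(self):
        """Ratings lying exactly on a parabola in standardized entropy are
        reproduced by the quadratic fit (exact interpolation, any basis)."""
        rows = []
        ent_of = {"s1": 0.3, "s2": 0.5, "s3": 0.7}
        for pid in ("p1", "p2", "p3", "p4"):
            for stim, ent in ent_of.items():
                z = (ent - 0.5) / np.std([0.3, 0.5, 0.7])
                rating = int(round(5 - 2 * z**2))  # 2, 5, 2
                rows.append(
                    dict(participant_id=pid, stimulus_id=stim, genre="funk",
                         component="pleasure", rating=rating, familiarity=2,
                         formal_training_years=0, informal_training_years=0,
                         pulse_entropy=ent)
                )
        table = pd.DataFrame(rows)
        fit = fit_entropy_model(table, "pleasure", order="quadratic")
        assert fit.variance_components["residual"] == pytest.approx(0.0, abs=1e-4)
        assert fit.fixed_estimates["entropy_quad"]["estimate"] < 0
        assert fit.fixed_estimates["entropy_lin"]["estimate"] == pytest.approx(0.0, abs=1e-5)
        assert fit.basis["degree"] == 2

    def test_quadratic_truth_recovered_in_sign(self):
        truth = default_truth().with_fixed(entropy_linear=-0.3, entropy_quadratic=-0.5)
        table = gen_ratings(default_design(40), truth, seed=44)
        fit = fit_entropy_model(table, "wanting_to_move", order="quadratic")
        quad = fit.fixed_estimates["entropy_quad"]
        assert quad["estimate"] < 0 and quad["p"] < 0.01

    def test_constant_entropy_rejected(self):
        table = gen_ratings(default_design(4), default_truth(), seed=0)
        table["pulse_entropy"] = 0.7
        with pytest.raises(ValueError, match="constant"):
            fit_entropy_model(table, "pleasure")

    def test_genre_interaction_terms_present(self):
        table = gen_ratings(default_design(15), default_truth(), seed=3)
        fit = fit_entropy_model(table, "pleasure", with_genre_interaction=True)
        names = list(fit.fixed_estimates)
        assert any("entropy_lin:" in n for n in names)
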