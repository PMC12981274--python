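"""Effect assignment, implantation, labelling and calibration."""

import numpy as np
import pytest

from cdr3bench._exceptions import ConfigurationError, ValidationError
from cdr3bench.binding import (
    _mc_design,
    assign_effects,
    bayes_error,
    calibrate_intercept,
    calibrate_scale,
    discriminative_response,
    generative_sample,
    implant_motif,
    motif_match,
    response_probability,
)
from cdr3bench.seqsim import SequenceSet, one_hot_encode, sample_sequences


class TestAssignEffects:
    @pytest.mark.parametrize("hierarchy", ["strong", "weak", "none"])
    def test_hierarchy_invariants(self, all_columns, hierarchy):
        for seed in range(5):
            spec = assign_effects(all_columns, orders=(2,), hierarchy=hierarchy, seed=seed)
            inter = set(spec.interactions[0])
            inside = inter & set(spec.mains)
            if hierarchy == "strong":
                assert inside == inter
            elif hierarchy == "weak":
                assert len(inside) >= 1
            else:
                assert not inside

    def test_no_hierarchy_order3_uses_weak_covariates(self, all_columns):
        spec = assign_effects(all_columns, orders=(3,), hierarchy="none", seed=4)
        assert all(c in set(spec.weak) for c in spec.interactions[0])

    def test_coefficient_plumbing(self, all_columns):
        spec = assign_effects(all_columns, strength=8, scale=1.0, seed=0)
        assert spec.inter_coef == 8.0
        assert set(np.unique(spec.main_coefs)) <= {-1.0, 1.0}

    def test_positions_distinct_and_in_core(self, all_columns):
        spec = assign_effects(all_columns, orders=(2,), hierarchy="none", seed=1)
        positions = [p for p, _ in spec.mains] + [p for p, _ in spec.interactions[0]]
        assert len(set(positions)) == len(positions)
        assert all(4 <= p <= 12 for p in positions)

    def test_unsatisfiable_hierarchy_is_error(self, all_columns):
        with pytest.raises(ConfigurationError):
            assign_effects(all_columns, n_main=3, orders=(4,), hierarchy="strong", seed=0)


class TestImplantation:
    def test_worked_example(self):
        seqs = SequenceSet.from_strings(["CAGCAGCAGCAGCAG"])
        out, plan = implant_motif(seqs, ((5, 6), "TT"), rate=1.0, seed=0)
        assert out.sequences == ["CAGCTTCAGCAGCAG"]
        assert plan.selected_rows.tolist() == [0]

    def test_zero_rows_selected_leaves_input_unchanged(self, pwm):
        seqs = sample_sequences(pwm, 100, seed=0)
        out, plan = implant_motif(seqs, ((5, 6), "TT"), rate=0.004, seed=0)
        assert len(plan.selected_rows) == 0  # round(0.004 * 100) = 0
        assert np.array_equal(out.codes, seqs.codes)

    def test_motif_fraction_at_least_rate(self, pwm):
        seqs = sample_sequences(pwm, 10_000, seed=2)
        motif = ((5, 6), "TT")
        before = motif_match(seqs, motif).mean()
        out, _ = implant_motif(seqs, motif, rate=0.2, seed=3)
        after = motif_match(out, motif).mean()
        assert after >= 0.2
        assert after <= 0.2 + before + 0.01  # pre-existing hits add a few points

    def test_exact_count_implanted(self, pwm):
        seqs = sample_sequences(pwm, 1000, seed=2)
        out, plan = implant_motif(seqs, ((7, 9), "WW"), rate=0.2, seed=3)
        assert len(plan.selected_rows) == 200
        assert out.implanted.sum() == 200

    def test_invalid_motifs(self, pwm):
        seqs = sample_sequences(pwm, 10, seed=0)
        with pytest.raises(ValidationError):
            implant_motif(seqs, ((5, 5), "TT"), rate=0.5, seed=0)
        with pytest.raises(ValidationError):
            implant_motif(seqs, ((5, 16), "TT"), rate=0.5, seed=0)
        with pytest.raises(ValidationError):
            implant_motif(seqs, ((5, 6), "TT"), rate=1.5, seed=0)


class TestDiscriminativeResponse:
    def test_all_zero_coefficients_give_half(self, pwm, all_columns):
        spec = assign_effects(all_columns, seed=0)
        spec.main_signs[:] = 0.0
        spec.weak_z[:] = 0.0
        spec.strength = 0.0
        X = _mc_design(spec, pwm, 0.5, 2000, seed=1)
        assert np.allclose(response_probability(X, spec), 0.5, atol=1e-9)

    def test_closed_form_interaction_probability(self, pwm, all_columns):
        # b0 = -4, s*L = 8, mains and weak zeroed: motif rows get logistic(4)
        spec = assign_effects(all_columns, strength=8.0, scale=1.0, seed=0)
        spec.main_signs[:] = 0.0
        spec.weak_z[:] = 0.0
        spec = spec.with_calibration(intercept=-4.0)
        spec.noise_sd = 0.0
        X = _mc_design(spec, pwm, 0.5, 4000, seed=1)
        p = response_probability(X, spec)
        idx = [X.col(c) for c in spec.interactions[0]]
        has_motif = X.X[:, idx].all(axis=1)
        assert np.allclose(p[has_motif], 1 / (1 + np.exp(-4)), atol=1e-9)
        assert np.allclose(p[~has_motif], 1 / (1 + np.exp(4)), atol=1e-9)

    def test_main_contribution_is_plus_minus_one_or_zero(self, all_columns):
        spec = assign_effects(all_columns, scale=1.0, seed=5)
        contribs = set(np.unique(spec.main_coefs)) | {0.0}
        assert contribs <= {-1.0, 0.0, 1.0}

    def test_determinism_and_probability_range(self, pwm, calibrated_spec):
        X = _mc_design(calibrated_spec, pwm, 0.2, 2000, seed=9)
        y1, p1 = discriminative_response(X, calibrated_spec, seed=11)
        y2, p2 = discriminative_response(X, calibrated_spec, seed=11)
        assert np.array_equal(y1, y2) and np.allclose(p1, p2)
        assert (p1 > 0).all() and (p1 < 1).all()

    def test_nonadditivity_identity(self, all_columns):
        # on the 4-point truth table of the two interacting covariates:
        # F(1,1) - F(1,0) - F(0,1) + F(0,0) = beta_i exactly
        spec = assign_effects(all_columns, strength=4.0, scale=1.5, seed=2)
        a, b = spec.interactions[0]

        def F(xa, xb):
            main = sum(
                s * spec.scale * (xa if c == a else xb if c == b else 0)
                for c, s in zip(spec.mains, spec.main_signs)
            )
            inter = spec.inter_coef * xa * xb
            return spec.intercept + main + inter

        assert F(1, 1) - F(1, 0) - F(0, 1) + F(0, 0) == pytest.approx(spec.inter_coef)


class TestCalibration:
    def test_symmetric_case_gives_minus_four(self, pwm, all_columns):
        # mains and weak zeroed, s*L = 8, rate 0.5: logistic symmetry pins b0 = -4
        spec = assign_effects(all_columns, strength=8.0, scale=1.0, seed=0)
        spec.main_signs[:] = 0.0
        spec.weak_z[:] = 0.0
        b0 = calibrate_intercept(spec, pwm, rate=0.5, mc_n=20_000, seed=1)
        assert b0 == pytest.approx(-4.0, abs=0.15)  # background motif hits shift it slightly

    def test_balance_recheck_with_fresh_seed(self, pwm, calibrated_spec):
        X = _mc_design(calibrated_spec, pwm, 0.5, 50_000, seed=999)
        y, _ = discriminative_response(X, calibrated_spec, seed=1000)
        assert abs(y.mean() - 0.5) < 0.01

    def test_intercept_monotone_in_strength(self, pwm, all_columns):
        b0s = []
        for s in (1, 2, 4, 8):
            spec = assign_effects(all_columns, strength=float(s), scale=1.0, seed=0)
            b0s.append(calibrate_intercept(spec, pwm, rate=0.5, mc_n=10_000, seed=1))
        assert all(b0s[i + 1] < b0s[i] for i in range(3))

    def test_bayes_error_monotone_in_scale(self, pwm, all_columns):
        spec = assign_effects(all_columns, strength=8.0, seed=0)
        X = _mc_design(spec, pwm, 0.5, 10_000, seed=2)
        errs = []
        for L in (0.25, 0.5, 1.0, 2.0, 4.0):
            trial = spec.with_calibration(scale=L)
            b0 = calibrate_intercept(trial, pwm, mc_n=10_000, seed=2, _design=X)
            errs.append(bayes_error(X, trial.with_calibration(intercept=b0)))
        assert all(errs[i + 1] <= errs[i] + 1e-6 for i in range(len(errs) - 1))

    def test_tiny_scale_gives_coin_flip(self, pwm, all_columns):
        spec = assign_effects(all_columns, strength=8.0, scale=1e-4, seed=0)
        X = _mc_design(spec, pwm, 0.5, 5000, seed=3)
        b0 = calibrate_intercept(spec, pwm, mc_n=5000, seed=3, _design=X)
        assert bayes_error(X, spec.with_calibration(intercept=b0)) > 0.45

    def test_class_proportion_exceeds_low_rates_by_at_most_bayes_plus_background(
        self, pwm, calibrated_spec
    ):
        from cdr3bench.binding import motif_match

        for rate in (0.2, 0.1, 0.05):
            X = _mc_design(calibrated_spec, pwm, rate, 30_000, seed=50)
            y, _ = discriminative_response(X, calibrated_spec, seed=51)
            seqs = sample_sequences(pwm, 30_000, seed=52)
            background = motif_match(seqs, calibrated_spec.motifs()[0]).mean()
            assert y.mean() > rate
            assert y.mean() <= rate + 0.025 + background + 0.01


class TestGenerativeModel:
    def test_contamination_counts(self, pwm):
        motif = ((5, 6, 7), "TTW")
        out = generative_sample(pwm, motif, n_pos=1000, n_neg=1000, contamination=0.025, seed=4)
        pos = out.labels == 1
        carries = motif_match(out, motif)
        assert carries[pos].sum() == 975
        assert out.implanted[pos].sum() == 975
        assert out.implanted[~pos].sum() == 25

    def test_zero_contamination_is_clean_separation(self, pwm):
        motif = ((5, 6), "TT")
        out = generative_sample(pwm, motif, n_pos=400, n_neg=400, contamination=0.0, seed=5)
        carries = motif_match(out, motif)
        assert carries[out.labels == 1].all()
        assert not carries[out.labels == 0].any()

    def test_rejection_mode_preserves_background_distribution(self, pwm):
        # non-motif positions of rejection-kept binders follow the plain PWM
        from scipy.stats import chisquare

        motif = ((5, 6), "AA")  # common residues keep acceptance workable
        out = generative_sample(
            pwm, motif, n_pos=2000, n_neg=10, contamination=0.0, mode="reject", seed=6
        )
        binders = out.codes[out.labels == 1]
        plain = sample_sequences(pwm, 4000, seed=7).codes
        for pos in (8, 11):  # core positions away from the motif
            obs = np.bincount(binders[:, pos - 1].astype(int), minlength=20)
            exp_p = np.bincount(plain[:, pos - 1].astype(int), minlength=20) / len(plain)
            keep = exp_p > 0.005
            stat, pval = chisquare(obs[keep], obs[keep].sum() * exp_p[keep] / exp_p[keep].sum())
            assert pval > 1e-4

    def test_rejection_budget_error(self, pwm):
        from cdr3bench._exceptions import ResourceError

        motif = ((5, 6, 7, 8), "WWWW")  # vanishingly rare naturally
        with pytest.raises(ResourceError, match="acceptance rate"):
            generative_sample(
                pwm, motif, n_pos=500, n_neg=10, mode="reject", seed=8, max_draws=20_000
            )
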