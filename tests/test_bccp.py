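"""Compound covariate classifier: weights, posteriors, LOOCV, multi-class."""

import math

import numpy as np
import pandas as pd
import pytest

from actsig.bccp import (
    BCCPModel,
    TrainingClasses,
    fit_bccp,
    loocv_misclassification,
    make_training_classes,
    multiclass_bccp,
    posterior_active,
    predict_bccp,
    read_model,
    write_model,
)
from actsig.datamodel import (
    ClinicalTable,
    CohortBundle,
    CopyNumberMatrix,
    GeneExpressionMatrix,
    GeneSet,
    standardize_genes,
)


def _expr(values, genes=None, samples=None, standardized=True):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return GeneExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        standardized=standardized)


def _classes(labels, samples=None):
    samples = samples or [f"S{i}" for i in range(len(labels))]
    return TrainingClasses(pd.Series(labels, index=samples))


def _separated(rng, n_per=10, n_genes=12, shift=10.0):
    """Two classes separated by `shift` noise-SDs on every gene."""
    a = rng.normal(shift, 1, (n_genes, n_per))
    b = rng.normal(0, 1, (n_genes, n_per))
    expr = _expr(np.hstack([a, b]))
    classes = _classes(["active"] * n_per + ["inactive"] * n_per)
    return expr, classes


class TestTrainingClasses:
    def _cohort(self, scores):
        samples = [f"S{i}" for i in range(len(scores))]
        expr = _expr(np.zeros((2, len(scores))), samples=samples,
                     standardized=False)
        cn = CopyNumberMatrix(pd.DataFrame(
            [scores], index=["YAP1"], columns=samples))
        clin = ClinicalTable(pd.DataFrame({"os_time": 1.0, "os_event": 1},
                                          index=samples))
        return CohortBundle(name="c", expression=expr, clinical=clin, cn=cn)

    def test_threshold_rule(self):
        cohort = self._cohort([2, 1, 0, -1, 2, 2, 0, 0, 1, -2])
        classes = make_training_classes(cohort, "YAP1")
        assert classes.labels.tolist() == [
            "active", "inactive", "inactive", "inactive", "active", "active",
            "inactive", "inactive", "inactive", "inactive"]

    def test_no_amplified_samples_is_an_error(self):
        with pytest.raises(ValueError, match="active class empty"):
            make_training_classes(self._cohort([0] * 8), "YAP1")

    def test_amplified_count_tracks_amp_fraction(self):
        from actsig.simulate import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(seed=21, n_tumors=500, n_genes=120,
                               n_signature_genes=20, amp_fraction=0.1)
        bundle, _ = simulate_cohort(cfg)
        classes = make_training_classes(bundle, "YAP1")
        n_active = len(classes.active_ids)
        assert 50 - 2.58 * math.sqrt(45) < n_active < 50 + 2.58 * math.sqrt(45)


class TestFit:
    def test_sign_convention(self, rng):
        x = np.vstack([np.r_[rng.normal(1, 1, 15), rng.normal(-1, 1, 15)]])
        expr = _expr(x)
        classes = _classes(["active"] * 15 + ["inactive"] * 15)
        model = fit_bccp(expr, classes, GeneSet("s", ("G0",)))
        assert model.weights[0] > 0
        assert model.mu_active > model.mu_inactive

    def test_weights_match_direct_t_statistic(self, rng):
        """Pooled-variance t recomputed gene by gene with the textbook
        formula agrees to 1e-10."""
        x = rng.normal(0, 1, (20, 30))
        expr = _expr(x)
        labels = ["active"] * 12 + ["inactive"] * 18
        classes = _classes(labels)
        model = fit_bccp(expr, classes, GeneSet("s", tuple(expr.gene_ids)))
        for i in range(20):
            a, b = x[i, :12], x[i, 12:]
            sp = math.sqrt(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
            sp /= math.sqrt(12 + 18 - 2)
            t_ref = (a.mean() - b.mean()) / (sp * math.sqrt(1 / 12 + 1 / 18))
            assert model.weights[i] == pytest.approx(t_ref, abs=1e-10)

    def test_label_swap_negates_weights_and_swaps_gaussians(self, rng):
        x = rng.normal(0, 1, (8, 20))
        expr = _expr(x)
        labels = ["active"] * 9 + ["inactive"] * 11
        flipped = ["inactive" if l == "active" else "active" for l in labels]
        sig = GeneSet("s", tuple(expr.gene_ids))
        m1 = fit_bccp(expr, _classes(labels), sig)
        m2 = fit_bccp(expr, _classes(flipped), sig)
        assert np.allclose(m1.weights, -m2.weights, atol=1e-10)
        assert m1.mu_active == pytest.approx(-m2.mu_inactive, abs=1e-10)
        p1 = [c.p_active for c in predict_bccp(m1, expr)]
        p2 = [c.p_active for c in predict_bccp(m2, expr)]
        assert np.allclose(np.array(p1) + np.array(p2), 1.0, atol=1e-9)

    def test_requires_standardized_expression(self, rng):
        expr = _expr(rng.normal(0, 1, (4, 12)), standardized=False)
        with pytest.raises(ValueError, match="standardized"):
            fit_bccp(expr, _classes(["active"] * 6 + ["inactive"] * 6),
                     GeneSet("s", ("G0",)))


class TestPosterior:
    def test_closed_form_gaussian_posterior(self):
        # mu_A=1, mu_I=-1, sigma=1, s=0.5 -> 1/(1+exp(-2*0.5))
        p = posterior_active(0.5, 1.0, -1.0, 1.0)
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-1.0)), abs=1e-12)

    def test_midpoint_gives_half_and_label_inactive(self):
        model = BCCPModel(("G0",), np.array([1.0]), mu_active=2.0,
                          mu_inactive=-4.0, sigma=1.5)
        expr = _expr([[-1.0]])  # score = -1 = (2 + -4)/2
        call = predict_bccp(model, expr)[0]
        assert call.p_active == pytest.approx(0.5, abs=1e-12)
        assert call.label == "YI"  # activation is strictly > 0.5

    def test_strong_separation_saturates(self):
        p = posterior_active(10.0, 10.0, 0.0, 1.0)
        assert p > 1 - 1e-10

    def test_matches_density_ratio_on_random_draws(self, rng):
        from scipy.stats import norm

        for _ in range(200):
            mu_a, mu_i = rng.normal(0, 3, 2)
            sigma = rng.uniform(0.2, 3)
            s = rng.normal(0, 4)
            direct = 0.5 * norm.pdf(s, mu_a, sigma) / (
                0.5 * norm.pdf(s, mu_a, sigma) + 0.5 * norm.pdf(s, mu_i, sigma))
            assert posterior_active(s, mu_a, mu_i, sigma) == pytest.approx(
                direct, abs=1e-12)

    def test_decision_boundary_is_score_midpoint(self, rng):
        """With equal priors and shared sigma, YA iff s > (mu_A+mu_I)/2."""
        for _ in range(50):
            mu_a, mu_i = sorted(rng.normal(0, 2, 2))[::-1]
            sigma = rng.uniform(0.2, 2)
            s = rng.normal(0, 3)
            p = posterior_active(s, mu_a, mu_i, sigma)
            assert (p > 0.5) == (s > (mu_a + mu_i) / 2) or \
                s == pytest.approx((mu_a + mu_i) / 2)

    def test_weight_rescaling_leaves_posteriors_unchanged(self, rng):
        expr, classes = _separated(rng, shift=2.0)
        sig = GeneSet("s", tuple(expr.gene_ids))
        model = fit_bccp(expr, classes, sig)
        c = 3.7
        scaled = BCCPModel(
            model.gene_ids, model.weights * c, model.mu_active * c,
            model.mu_inactive * c, model.sigma * c)
        p1 = [x.p_active for x in predict_bccp(model, expr)]
        p2 = [x.p_active for x in predict_bccp(scaled, expr)]
        assert np.allclose(p1, p2, atol=1e-9)


class TestReducedGenePrediction:
    def test_refits_gaussians_for_platform_subset(self, rng):
        expr, classes = _separated(rng, n_genes=20, shift=3.0)
        sig = GeneSet("s", tuple(expr.gene_ids))
        model = fit_bccp(expr, classes, sig)
        subset = GeneExpressionMatrix(expr.values.iloc[:12], standardized=True)
        calls = predict_bccp(model, subset)
        # separation is strong on any 12-gene subset: labels preserved
        labels = [c.label for c in calls]
        assert labels == ["YA"] * 10 + ["YI"] * 10
        # scores use only 12 genes, so magnitudes shrink relative to full model
        full_scores = [c.score for c in predict_bccp(model, expr)]
        sub_scores = [c.score for c in calls]
        assert abs(np.mean(sub_scores)) < abs(np.mean(full_scores))

    def test_coverage_floor(self, rng):
        expr, classes = _separated(rng, n_genes=20)
        model = fit_bccp(expr, classes, GeneSet("s", tuple(expr.gene_ids)))
        tiny = GeneExpressionMatrix(expr.values.iloc[:5], standardized=True)
        with pytest.raises(ValueError, match="coverage"):
            predict_bccp(model, tiny, coverage_floor=0.5)


class TestLOOCV:
    def test_perfect_separation_gives_zero_rate(self, rng):
        expr, classes = _separated(rng, shift=10.0)
        rate, n = loocv_misclassification(
            expr, classes, GeneSet("s", tuple(expr.gene_ids)))
        assert rate == 0.0
        assert n == 20

    def test_matches_fold_by_fold_enumeration_on_six_samples(self, rng):
        """Independent oracle: enumerate all 6 folds with scalar formulas."""
        x = rng.normal(0, 1, (3, 6))
        expr = _expr(x)
        labels = ["active", "active", "active", "inactive", "inactive",
                  "inactive"]
        classes = _classes(labels)
        sig = GeneSet("s", tuple(expr.gene_ids))

        errors = 0
        for held in range(6):
            rest = [j for j in range(6) if j != held]
            ids_a = [j for j in rest if labels[j] == "active"]
            ids_i = [j for j in rest if labels[j] == "inactive"]
            w = []
            for g in range(3):
                a, b = x[g, ids_a], x[g, ids_i]
                sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) \
                    / (len(a) + len(b) - 2)
                w.append((a.mean() - b.mean())
                         / math.sqrt(sp2 * (1 / len(a) + 1 / len(b))))
            w = np.array(w)
            scores = w @ x[:, rest]
            s_a = scores[[rest.index(j) for j in ids_a]]
            s_i = scores[[rest.index(j) for j in ids_i]]
            mu_a, mu_i = s_a.mean(), s_i.mean()
            sigma = math.sqrt((((s_a - mu_a) ** 2).sum()
                               + ((s_i - mu_i) ** 2).sum()) / (5 - 2))
            s_h = float(w @ x[:, held])
            p = posterior_active(s_h, mu_a, mu_i, sigma)
            call = "active" if p > 0.5 else "inactive"
            if call != labels[held]:
                errors += 1

        rate, n = loocv_misclassification(expr, classes, sig)
        assert n == 6
        assert rate == pytest.approx(errors / 6)

    def test_skips_folds_that_empty_a_class(self, rng):
        x = rng.normal(0, 1, (3, 7))
        expr = _expr(x)
        classes = _classes(["active"] * 3 + ["inactive"] * 4)
        # removing one of 3 actives still leaves 2; make a 1-active case
        classes1 = _classes(["active"] + ["inactive"] * 6)
        with pytest.warns(UserWarning, match="skipped"):
            rate, n = loocv_misclassification(
                expr, classes1, GeneSet("s", tuple(expr.gene_ids)))
        assert n == 6  # the single active sample's fold was skipped


class TestMulticlass:
    def test_two_classes_reduce_to_binary_labels(self, rng):
        expr, classes = _separated(rng, shift=3.0)
        sig = GeneSet("s", tuple(expr.gene_ids))
        model = fit_bccp(expr, classes, sig)
        binary = [c.label for c in predict_bccp(model, expr)]
        multi = multiclass_bccp(expr, classes.labels, sig)
        mapped = ["YA" if l == "active" else "YI" for l in multi["label"]]
        assert mapped == binary

    def test_four_separated_classes_recovered(self, rng):
        centers = np.eye(4) * 6
        blocks = []
        for k in range(4):
            blocks.append(rng.normal(0, 1, (4, 15)) + centers[k][:, None])
        x = np.hstack(blocks)
        expr = _expr(x)
        labels = pd.Series(
            [f"C{k}" for k in range(4) for _ in range(15)],
            index=expr.sample_ids)
        out = multiclass_bccp(expr, labels, GeneSet("s", tuple(expr.gene_ids)))
        assert (out["label"] == labels).mean() >= 0.95

    def test_tie_breaks_to_first_declared_class(self, rng):
        """A sample equidistant from perfectly symmetric class axes takes
        the earliest class in declared order."""
        base = rng.normal(0, 1, (6, 3))
        base -= base.mean(axis=1, keepdims=True)
        # classes A and B are mirror images; S6 sits exactly between
        x = np.hstack([base + 2, base - 2, np.zeros((6, 1))])
        expr = _expr(x)
        labels = pd.Series(["A"] * 3 + ["B"] * 3,
                           index=expr.sample_ids[:6])
        out = multiclass_bccp(expr, labels, GeneSet("s", tuple(expr.gene_ids)))
        mid = out.iloc[6]
        assert mid["A"] == pytest.approx(mid["B"], abs=1e-9)
        assert mid["label"] == "A"


class TestSerialization:
    def test_round_trip_preserves_predictions(self, rng, tmp_path):
        expr, classes = _separated(rng, n_genes=15, shift=2.0)
        sig = GeneSet("s", tuple(expr.gene_ids))
        model = fit_bccp(expr, classes, sig)
        path = tmp_path / "model.txt"
        write_model(model, path)
        back = read_model(path)
        p1 = [c.p_active for c in predict_bccp(model, expr)]
        p2 = [c.p_active for c in predict_bccp(back, expr)]
        assert np.allclose(p1, p2, atol=0)
        # reduced-gene refits survive the round trip
        subset = GeneExpressionMatrix(expr.values.iloc[:10], standardized=True)
        q1 = [c.p_active for c in predict_bccp(model, subset)]
        q2 = [c.p_active for c in predict_bccp(back, subset)]
        assert np.allclose(q1, q2, atol=0)
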