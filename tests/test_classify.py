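"""LDA, LLGMN, leave-one-fish-out CV and the F-score machinery."""

import warnings

import numpy as np
import pandas as pd
import pytest

import ventrack as vt
from ventrack.classify import (
    LDAModel,
    f_scores,
    fit_lda,
    fit_llgmn,
    posterior_shift_analysis,
    predict_lda,
    predict_llgmn,
)
from ventrack.indices import INDEX_COLUMNS


def make_index_table(class_means, n_fish_per_state=4, windows=60, noise=1.0,
                     seed=0, mixture=None):
    """Synthetic index-window table: Gaussian clusters per state in index space.

    ``mixture[state]`` optionally lists several means; each window draws one
    (bimodal states).  Fish of a state share its distribution.
    """
    rng = np.random.default_rng(seed)
    rows = []
    fish_no = 0
    for state, mean in class_means.items():
        means = mixture.get(state, [mean]) if mixture else [mean]
        for _ in range(n_fish_per_state):
            fish_no += 1
            for w in range(windows):
                mu = means[rng.integers(len(means))]
                x = np.asarray(mu, dtype=float) + noise * rng.standard_normal(6)
                rows.append({"fish_id": f"sf{fish_no:02d}", "state": state,
                             "t0": float(5 * w),
                             **dict(zip(INDEX_COLUMNS, x)), "standardised": True})
    return pd.DataFrame(rows)


class TestLDA:
    def test_separated_1d_classes_near_perfect(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-5, 1, 200), rng.normal(5, 1, 200)])[:, None]
        y = np.array(["a"] * 200 + ["b"] * 200)
        model = fit_lda(x, y)
        acc = (predict_lda(model, x) == y).mean()
        assert acc >= 0.99

    def test_shuffled_labels_chance_level(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((3000, 2))
        y = np.array(["a", "b", "c"] * 1000)
        rng.shuffle(y)
        model = fit_lda(x, y)
        acc = (predict_lda(model, x) == y).mean()
        assert abs(acc - 1 / 3) <= 0.05

    def test_projection_matches_grid_search_fisher_maximiser(self):
        rng = np.random.default_rng(2)
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        chol = np.linalg.cholesky(cov)
        a = rng.standard_normal((400, 2)) @ chol.T
        b = rng.standard_normal((400, 2)) @ chol.T + [2.0, 1.0]
        x = np.vstack([a, b])
        y = np.array(["a"] * 400 + ["b"] * 400)
        model = fit_lda(x, y)
        direction = model.weights[0, 1:] - model.weights[1, 1:]
        direction /= np.linalg.norm(direction)

        # brute-force Fisher ratio over 3600 angles
        diff = a.mean(0) - b.mean(0)
        sw = (np.cov(a.T) * 399 + np.cov(b.T) * 399) / 798
        angles = np.linspace(0, np.pi, 3600, endpoint=False)
        ws = np.column_stack([np.cos(angles), np.sin(angles)])
        ratio = (ws @ diff) ** 2 / np.einsum("ij,jk,ik->i", ws, sw, ws)
        best = ws[np.argmax(ratio)]
        cosang = abs(float(direction @ best))
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= 1.0

    def test_agrees_with_sklearn(self):
        sk = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(3)
        x = np.vstack([rng.normal(0, 1, (200, 3)), rng.normal(1.2, 1, (200, 3)),
                       rng.normal(-1.2, 1, (200, 3))])
        y = np.array(["a"] * 200 + ["b"] * 200 + ["c"] * 200)
        ours = predict_lda(fit_lda(x, y), x)
        ref = sk.LinearDiscriminantAnalysis().fit(x, y).predict(x)
        assert (ours == ref).mean() >= 0.98

    def test_decision_invariant_to_constant_shift(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.normal(-2, 1, (50, 2)), rng.normal(2, 1, (50, 2))])
        y = np.array(["a"] * 50 + ["b"] * 50)
        model = fit_lda(x, y)
        shifted = LDAModel(classes=model.classes, weights=model.weights.copy())
        shifted.weights[:, 0] += 7.5  # same constant added to every y_k
        assert np.array_equal(predict_lda(model, x), predict_lda(shifted, x))

    def test_tie_breaks_to_lowest_class_index(self):
        model = LDAModel(classes=["normal", "fear"], weights=np.zeros((2, 3)))
        assert predict_lda(model, np.array([[1.0, -1.0]]))[0] == "normal"

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((40, 2))
        y = np.array(["a", "b"] * 20)
        model = fit_lda(x, y)
        with pytest.raises(ValueError):
            predict_lda(model, np.ones((3, 5)))


def bayes_posterior_two_gaussians(x, mu=2.0):
    """Exact posterior of class '+' for equal-prior N(+mu,1) vs N(-mu,1)."""
    return 1.0 / (1.0 + np.exp(-2.0 * mu * x))


@pytest.fixture(scope="module")
def gaussian_toy_model():
    rng = np.random.default_rng(6)
    x = np.concatenate([rng.normal(-2, 1, 2000), rng.normal(2, 1, 2000)])[:, None]
    y = np.array(["neg"] * 2000 + ["pos"] * 2000)
    return fit_llgmn(x, y, n_components=1, seed=0)


class TestLLGMN:
    def test_posteriors_sum_to_one(self, gaussian_toy_model):
        probe = np.linspace(-5, 5, 201)[:, None]
        post = gaussian_toy_model.posteriors(probe)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(post >= 0.0)

    def test_training_log_likelihood_monotone(self, gaussian_toy_model):
        trace = np.asarray(gaussian_toy_model.log_likelihood)
        assert len(trace) > 2
        assert np.all(np.diff(trace) >= -1e-8)

    def test_posterior_close_to_bayes(self, gaussian_toy_model):
        probe = np.linspace(-5, 5, 201)
        post = gaussian_toy_model.posteriors(probe[:, None])
        pos_col = gaussian_toy_model.classes.index("pos")
        gap = np.abs(post[:, pos_col] - bayes_posterior_two_gaussians(probe))
        assert gap.mean() <= 0.05

    def test_symmetric_probe_splits_evenly(self, gaussian_toy_model):
        labels, post = predict_llgmn(gaussian_toy_model, np.array([[0.0]]))
        assert post[0, 0] == pytest.approx(0.5, abs=0.02)

    def test_xor_style_data_beats_linear_model(self):
        rng = np.random.default_rng(7)
        n = 100
        corners = {
            "same": [(3, 3), (-3, -3)],
            "diff": [(3, -3), (-3, 3)],
        }
        xs, ys = [], []
        for label, pts in corners.items():
            for p in pts:
                xs.append(rng.standard_normal((n, 2)) + p)
                ys += [label] * n
        x = np.vstack(xs)
        y = np.array(ys)
        llgmn = fit_llgmn(x, y, n_components=2, seed=1)
        acc_llgmn = (predict_llgmn(llgmn, x)[0] == y).mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            acc_lda = (predict_lda(fit_lda(x, y), x) == y).mean()
        assert acc_llgmn >= 0.9
        assert acc_lda <= 0.65

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            fit_llgmn(np.array([[np.nan], [1.0]]), np.array(["a", "b"]))


class TestFScores:
    def test_diagonal_confusion_perfect(self):
        out = f_scores(np.diag([5, 7, 9]))
        assert np.allclose(out["f"], 1.0) and out["macro_f"] == 1.0

    def test_hand_computed_confusion(self):
        out = f_scores(np.array([[8, 2, 0], [1, 7, 2], [1, 1, 8]]))
        assert out["f"][0] == pytest.approx(0.8)

    def test_half_precision_half_recall(self):
        # P = R = 0.5 for the first class
        out = f_scores(np.array([[1, 1], [1, 1]]))
        assert out["f"][0] == pytest.approx(0.5)

    def test_degenerate_class_scores_zero(self):
        out = f_scores(np.array([[0, 3], [0, 5]]))
        assert out["f"][0] == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            f_scores(np.array([[1, -1], [0, 2]]))


SEPARATED = {
    "normal": np.array([0, 0, 0, 0, 0, 0.0]),
    "fear": np.array([8, 0, 0, 0, 0, 0.0]),
    "appetitive": np.array([0, 8, 0, 0, 0, 0.0]),
}


class TestCrossValidation:
    def test_fold_and_prediction_counts(self, cohort_table, lda_report_4pc):
        assert len(lda_report_4pc.per_fold_macro_f) == 23
        assert len(lda_report_4pc.predictions) == 2760
        assert lda_report_4pc.confusion.sum() == 2760

    def test_perfectly_separated_states_score_one(self):
        table = make_index_table(SEPARATED, noise=0.3, seed=8)
        report = vt.loo_fish_cv(table, {"kind": "lda"}, n_pcs=4)
        assert report.macro_f == 1.0

    def test_label_shuffled_cohort_chance_level(self):
        table = make_index_table(SEPARATED, noise=0.3, seed=9)
        rng = np.random.default_rng(10)
        table["state"] = rng.permutation(table["state"].to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = vt.loo_fish_cv(table, {"kind": "lda"}, n_pcs=4)
        assert abs(report.macro_f - 1 / 3) <= 0.05

    def test_no_leakage_from_held_out_labels(self):
        table = make_index_table(SEPARATED, noise=1.5, seed=11)
        report = vt.loo_fish_cv(table, {"kind": "lda"}, n_pcs=3)
        permuted = table.copy()
        fish = permuted["fish_id"] == "sf01"
        rng = np.random.default_rng(12)
        permuted.loc[fish, "state"] = rng.permutation(
            permuted.loc[fish, "state"].to_numpy())
        report2 = vt.loo_fish_cv(permuted, {"kind": "lda"}, n_pcs=3)
        a = report.predictions[report.predictions["fish_id"] == "sf01"]
        b = report2.predictions[report2.predictions["fish_id"] == "sf01"]
        assert np.array_equal(a["prediction"].to_numpy(), b["prediction"].to_numpy())

    def test_n_pcs_bounded_by_index_count(self, cohort_table):
        with pytest.raises(ValueError):
            vt.loo_fish_cv(cohort_table, {"kind": "lda"}, n_pcs=7)
        with pytest.raises(ValueError):
            vt.compare_pc_counts(cohort_table, {"kind": "lda"}, n_pcs_range=[6, 7])

    def test_class_separable_only_in_fourth_pc(self):
        """A state hidden in a low-variance direction is found once PC4 is fed."""
        rng = np.random.default_rng(13)
        q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        # latent dim 4 has tiny within-state noise, so the (small) appetitive
        # shift along it stays cleanly separable yet its pooled variance
        # still ranks fourth
        scales = np.array([4.0, 3.0, 2.5, 0.05, 0.2, 0.1])

        def draw(mean_latent, n):
            latent = rng.standard_normal((n, 6)) * np.sqrt(scales) + mean_latent
            return latent @ q.T

        rows = []
        fish_no = 0
        shift_fear = np.array([6, 0, 0, 0, 0, 0.0])
        shift_app4 = np.array([0, 0, 0, 1.2, 0, 0.0])
        for state, makers in {
            "normal": lambda n: draw(np.zeros(6), n),
            "fear": lambda n: draw(shift_fear, n),
            "appetitive": lambda n: np.vstack([
                draw(shift_app4, n - n // 2), draw(shift_fear + shift_app4, n // 2)]),
        }.items():
            for _ in range(6):
                fish_no += 1
                x = makers(50)
                for w in range(50):
                    rows.append({"fish_id": f"cf{fish_no:02d}", "state": state,
                                 "t0": 5.0 * w, **dict(zip(INDEX_COLUMNS, x[w])),
                                 "standardised": True})
        table = pd.DataFrame(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports, pairwise = vt.compare_pc_counts(
                table, {"kind": "llgmn", "n_components": 2}, n_pcs_range=[3, 4])
        assert reports[4].macro_f > reports[3].macro_f
        row = pairwise[(pairwise.group_a == "pc1-3") & (pairwise.group_b == "pc1-4")]
        assert float(row["pvalue"].iloc[0]) < 1e-3


class TestPosteriorShift:
    def _frame(self, rng, shift=0.0):
        n = 100
        before = pd.DataFrame({
            "fish_id": "f", "state": "normal", "t0": np.arange(n, dtype=float),
            "p_normal": rng.uniform(0.5, 0.9, n)})
        after = pd.DataFrame({
            "fish_id": "f", "state": "fear", "t0": np.arange(n, dtype=float),
            "p_normal": rng.uniform(0.5, 0.9, n) - shift})
        return pd.concat([before, after], ignore_index=True)

    def test_identical_distributions_zero_effect(self):
        rng = np.random.default_rng(14)
        frame = self._frame(rng, shift=0.0)
        frame.loc[frame["state"] == "fear", "p_normal"] = (
            frame.loc[frame["state"] == "normal", "p_normal"].to_numpy())
        out = posterior_shift_analysis(frame, "normal", "fear")
        assert out["cohens_d"].iloc[0] == 0.0

    def test_shifted_posterior_detected_with_sign(self):
        out = posterior_shift_analysis(
            self._frame(np.random.default_rng(15), shift=0.4), "normal", "fear")
        assert out["cohens_d"].iloc[0] < -1.0 and out["pvalue"].iloc[0] < 1e-3

    def test_missing_group_rejected(self):
        frame = self._frame(np.random.default_rng(16))
        with pytest.raises(ValueError):
            posterior_shift_analysis(frame, "normal", "appetitive")
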