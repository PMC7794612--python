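"""Emotional-state discrimination from PC scores.

Two classifiers operate on the first N principal-component scores of the
six evaluation indices:

* A multi-class Fisher/Gaussian linear discriminant: one linear discriminant
  function ``y_k(x) = w_k^T [1, x]`` per class (shared pooled within-class
  covariance), decision by the largest discriminant value.  For two classes
  the implied projection ``w_1 - w_2`` is exactly the Fisher-ratio maximiser.
* A log-linearised Gaussian mixture network (LLGMN): the input is expanded to
  ``(1, x_i, x_i x_j for i <= j)``, mapped linearly onto K x M component
  units, pooled by a normalised exponential, and each class posterior is the
  sum of its component units.  Trained by full-batch maximum likelihood with
  a backtracking step size, so the training log-likelihood is monotone.

Evaluation follows leave-one-fish-out cross-validation: the PCA and the
classifier are refitted on the windows of all other fish for every fold, so
no information from the held-out animal leaks into the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indices import INDEX_COLUMNS
from .stats import TestResult, cohens_d, pca_fit, pca_scores, tukey_kramer, welch_t

__all__ = [
    "CLASS_ORDER",
    "LDAModel",
    "LLGMNModel",
    "ClassifierReport",
    "fit_lda",
    "predict_lda",
    "fit_llgmn",
    "predict_llgmn",
    "f_scores",
    "loo_fish_cv",
    "compare_pc_counts",
    "posterior_shift_analysis",
]

#: canonical class order (also the tie-break order: lowest index wins)
CLASS_ORDER = ("normal", "fear", "appetitive")


# ---------------------------------------------------------------------------
# linear discriminant
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class LDAModel:
    classes: list
    weights: np.ndarray      # (K, N+1): bias first, then the N input weights

    @property
    def n_features(self) -> int:
        return int(self.weights.shape[1] - 1)

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_features:
            raise ValueError("input dimension does not match the model")
        aug = np.hstack([np.ones((x.shape[0], 1)), x])
        return aug @ self.weights.T


def fit_lda(x: np.ndarray, labels, ridge: float = 1e-8) -> LDAModel:
    """Fit per-class linear discriminant functions (pooled covariance).

    Maximises the between-class to within-class variance ratio; a singular
    within-class scatter is ridge-regularised with a warning.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    labels = np.asarray(labels)
    classes = [c for c in CLASS_ORDER if c in set(labels)]
    if not classes:  # non-state labels (toy data): keep sorted unique order
        classes = sorted(set(labels.tolist()))
    else:
        classes += sorted(set(labels.tolist()) - set(classes))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n, p = x.shape
    mus, priors = [], []
    sw = np.zeros((p, p))
    for c in classes:
        xc = x[labels == c]
        if len(xc) <= p:
            raise ValueError(f"class {c!r} needs more than {p} samples")
        mus.append(xc.mean(axis=0))
        priors.append(len(xc) / n)
        d = xc - xc.mean(axis=0)
        sw += d.T @ d
    sw /= n - len(classes)
    cond = np.linalg.cond(sw)
    if not np.isfinite(cond) or cond > 1e10:
        warnings.warn("within-class scatter is (near-)singular; applying ridge",
                      stacklevel=2)
        sw = sw + max(ridge, ridge * np.trace(sw) / p) * np.eye(p)
    sw_inv = np.linalg.inv(sw)
    weights = np.empty((len(classes), p + 1))
    for k, (mu, pi) in enumerate(zip(mus, priors)):
        w = sw_inv @ mu
        weights[k, 1:] = w
        weights[k, 0] = -0.5 * mu @ w + np.log(pi)
    return LDAModel(classes=classes, weights=weights)


def predict_lda(model: LDAModel, x: np.ndarray,
                return_posteriors: bool = False):
    """Classify by the largest discriminant value (ties -> lowest class index)."""
    y = model.decision_values(x)
    idx = np.argmax(y, axis=1)  # argmax takes the first maximum: the tie rule
    labels = np.asarray(model.classes, dtype=object)[idx]
    if not return_posteriors:
        return labels
    z = y - y.max(axis=1, keepdims=True)
    post = np.exp(z)
    post /= post.sum(axis=1, keepdims=True)
    return labels, post


# ---------------------------------------------------------------------------
# LLGMN
# ---------------------------------------------------------------------------

def _llgmn_expand(x: np.ndarray) -> np.ndarray:
    """Nonlinear input expansion: (1, x_i, x_i x_j for i <= j)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, d = x.shape
    iu, ju = np.triu_indices(d)
    return np.hstack([np.ones((n, 1)), x, x[:, iu] * x[:, ju]])


@dataclass(eq=False)
class LLGMNModel:
    classes: list
    n_components: int
    weights: np.ndarray          # (H, K*M); the last unit's column is fixed 0
    n_features: int
    log_likelihood: list[float] = field(default_factory=list)

    @property
    def expansion_dim(self) -> int:
        n = self.n_features
        return 1 + n + n * (n + 1) // 2

    def _unit_posteriors(self, x: np.ndarray) -> np.ndarray:
        xe = _llgmn_expand(x)
        if xe.shape[1] != self.expansion_dim:
            raise ValueError("input dimension does not match the model")
        a = xe @ self.weights
        a -= a.max(axis=1, keepdims=True)
        y = np.exp(a)
        y /= y.sum(axis=1, keepdims=True)
        return y

    def posteriors(self, x: np.ndarray) -> np.ndarray:
        """Per-class posterior probabilities, shape ``(n, K)``."""
        y = self._unit_posteriors(x)
        k = len(self.classes)
        return y.reshape(-1, k, self.n_components).sum(axis=2)


def fit_llgmn(
    x: np.ndarray,
    labels,
    n_components: int = 2,
    learning_rate: float = 0.01,
    max_epochs: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> LLGMNModel:
    """Train an LLGMN by full-batch maximum likelihood.

    Gradient ascent on the mean log posterior of the true class, with
    backtracking (the step is halved until the log-likelihood does not
    decrease), so the recorded training trace is monotone non-decreasing.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("inputs must be finite")
    labels = np.asarray(labels)
    classes = [c for c in CLASS_ORDER if c in set(labels)]
    classes += sorted(set(labels.tolist()) - set(classes))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    k, m = len(classes), n_components
    n, d = x.shape
    h = 1 + d + d * (d + 1) // 2
    xe = _llgmn_expand(x)
    y_idx = np.array([classes.index(c) for c in labels])
    onehot = np.zeros((n, k))
    onehot[np.arange(n), y_idx] = 1.0

    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, 1e-3, size=(h, k * m))
    w[:, -1] = 0.0  # reference unit pinned for identifiability

    def forward(wts):
        a = xe @ wts
        a -= a.max(axis=1, keepdims=True)
        yu = np.exp(a)
        yu /= yu.sum(axis=1, keepdims=True)
        yc = yu.reshape(n, k, m).sum(axis=2)
        ll = float(np.log(np.maximum(yc[np.arange(n), y_idx], 1e-300)).mean())
        return yu, yc, ll

    yu, yc, ll = forward(w)
    trace = [ll]
    lr = learning_rate
    for epoch in range(max_epochs):
        # d(mean ll)/d a_km = y_km * (1[k = true]/Y_true - 1) / n
        ratio = onehot / np.maximum(yc, 1e-300)
        g_a = yu * (np.repeat(ratio, m, axis=1) - 1.0)
        grad = xe.T @ g_a / n
        grad[:, -1] = 0.0
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError(f"non-finite gradient at epoch {epoch}")
        improved = False
        for _ in range(40):
            w_new = w + lr * grad
            yu_n, yc_n, ll_new = forward(w_new)
            if ll_new >= ll:
                improved = True
                break
            lr *= 0.5
        if not improved:
            break
        w, yu, yc = w_new, yu_n, yc_n
        delta = ll_new - ll
        ll = ll_new
        trace.append(ll)
        lr = min(lr * 1.2, 10.0)
        if delta < tol * max(abs(ll), 1.0) and epoch > 10:
            break
    return LLGMNModel(classes=classes, n_components=m, weights=w,
                      n_features=d, log_likelihood=trace)


def predict_llgmn(model: LLGMNModel, x: np.ndarray):
    """Posterior triplet per window plus the argmax label."""
    post = model.posteriors(x)
    idx = np.argmax(post, axis=1)
    labels = np.asarray(model.classes, dtype=object)[idx]
    return labels, post


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def f_scores(confusion: np.ndarray) -> dict:
    """Per-class precision/recall/F plus macro F from a confusion matrix.

    Rows are the true classes, columns the predictions.  Degenerate cells
    (no predictions or no truth for a class) yield F = 0.
    """
    c = np.asarray(confusion, dtype=float)
    if np.any(c < 0):
        raise ValueError("confusion counts must be non-negative")
    tp = np.diag(c)
    col = c.sum(axis=0)
    row = c.sum(axis=1)
    precision = np.divide(tp, col, out=np.zeros_like(tp), where=col > 0)
    recall = np.divide(tp, row, out=np.zeros_like(tp), where=row > 0)
    pr = precision + recall
    f = np.divide(2 * precision * recall, pr, out=np.zeros_like(tp), where=pr > 0)
    return {
        "precision": precision,
        "recall": recall,
        "f": f,
        "macro_f": float(f.mean()),
    }


@dataclass(eq=False)
class ClassifierReport:
    """Pooled leave-one-fish-out results."""

    classes: list
    n_pcs: int
    confusion: np.ndarray            # (K, K), rows = truth
    precision: np.ndarray
    recall: np.ndarray
    f: np.ndarray
    macro_f: float
    per_fold_macro_f: pd.Series      # indexed by held-out fish id
    per_fold_f: pd.DataFrame         # per-fold per-class F (NaN if class absent)
    predictions: pd.DataFrame        # fish_id, state, t0, prediction, p_<class>...

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "n_pcs": self.n_pcs,
            "confusion": self.confusion.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f": self.f.tolist(),
            "macro_f": self.macro_f,
            "per_fold_macro_f": self.per_fold_macro_f.to_dict(),
        }


def _fit_predict(spec: dict, x_train, y_train, x_test, fold_seed: int):
    kind = spec.get("kind", "llgmn")
    if kind == "lda":
        model = fit_lda(x_train, y_train)
        return predict_lda(model, x_test, return_posteriors=True)
    if kind == "llgmn":
        model = fit_llgmn(
            x_train, y_train,
            n_components=spec.get("n_components", 2),
            learning_rate=spec.get("learning_rate", 0.01),
            max_epochs=spec.get("max_epochs", 2000),
            tol=spec.get("tol", 1e-6),
            seed=spec.get("seed", 0) + fold_seed,
        )
        return predict_llgmn(model, x_test)
    raise ValueError(f"unknown classifier kind {kind!r}")


def loo_fish_cv(table: pd.DataFrame, classifier: dict | None = None,
                n_pcs: int = 4) -> ClassifierReport:
    """Leave-one-fish-out cross-validation on an index-window table.

    PCA (correlation matrix of the pooled training windows) and the
    classifier are refitted for every fold; the held-out fish's windows are
    projected with the fold's PC model and classified.  Folds whose training
    set misses a class are skipped with a warning.
    """
    classifier = classifier if classifier is not None else {"kind": "llgmn"}
    if not (1 <= n_pcs <= len(INDEX_COLUMNS)):
        raise ValueError(f"n_pcs must be in 1..{len(INDEX_COLUMNS)}")
    classes = [c for c in CLASS_ORDER if c in set(table["state"])]
    if len(classes) < 2:
        raise ValueError("table must contain at least 2 states")
    fish_ids = list(dict.fromkeys(table["fish_id"]))
    k = len(classes)
    confusion = np.zeros((k, k), dtype=int)
    pred_frames = []
    fold_macro = {}
    fold_f = {}
    for fold, fish in enumerate(fish_ids):
        train = table[table["fish_id"] != fish]
        test = table[table["fish_id"] == fish]
        if set(classes) - set(train["state"]):
            warnings.warn(f"fold {fish!r}: training set misses a class; skipped",
                          stacklevel=2)
            continue
        pc = pca_fit(train)
        x_train = pca_scores(pc, train).to_numpy()[:, :n_pcs]
        x_test = pca_scores(pc, test).to_numpy()[:, :n_pcs]
        labels, post = _fit_predict(classifier, x_train,
                                    train["state"].to_numpy(), x_test, fold)
        truth = test["state"].to_numpy()
        fold_conf = np.zeros((k, k), dtype=int)
        for tr, pr in zip(truth, labels):
            fold_conf[classes.index(tr), classes.index(pr)] += 1
        confusion += fold_conf
        # fold macro-F over the classes this fish actually has: each fish
        # only experiences two of the three states, and a structural zero
        # for the missing class would swamp between-fold comparisons
        present = fold_conf.sum(axis=1) > 0
        fold_scores = f_scores(fold_conf)["f"]
        fold_macro[fish] = float(fold_scores[present].mean())
        fold_f[fish] = np.where(present, fold_scores, np.nan)
        frame = test[["fish_id", "state", "t0"]].copy()
        frame["prediction"] = labels
        for j, c in enumerate(classes):
            frame[f"p_{c}"] = post[:, j]
        pred_frames.append(frame)
    scores = f_scores(confusion)
    return ClassifierReport(
        classes=classes, n_pcs=n_pcs, confusion=confusion,
        precision=scores["precision"], recall=scores["recall"], f=scores["f"],
        macro_f=scores["macro_f"],
        per_fold_macro_f=pd.Series(fold_macro, name="macro_f"),
        per_fold_f=pd.DataFrame.from_dict(fold_f, orient="index", columns=classes),
        predictions=pd.concat(pred_frames, ignore_index=True),
    )


def compare_pc_counts(table: pd.DataFrame, classifier: dict | None = None,
                      n_pcs_range=range(1, 7)) -> tuple[dict, pd.DataFrame]:
    """Cross-validated reports per PC count plus Tukey-Kramer on fold macro-F.

    Returns ``(reports, pairwise)`` where ``reports[N]`` is the
    :class:`ClassifierReport` using the first N PCs and ``pairwise`` compares
    the per-fold macro-F distributions between all PC counts.
    """
    n_pcs_range = list(n_pcs_range)
    if max(n_pcs_range) > len(INDEX_COLUMNS):
        raise ValueError("at most 6 PCs are available (6 indices)")
    reports = {n: loo_fish_cv(table, classifier, n_pcs=n) for n in n_pcs_range}
    groups = [reports[n].per_fold_macro_f.to_numpy() for n in n_pcs_range]
    pairwise = tukey_kramer(groups, labels=[f"pc1-{n}" for n in n_pcs_range])
    return reports, pairwise


def posterior_shift_analysis(predictions: pd.DataFrame, before: str,
                             after: str) -> pd.DataFrame:
    """Welch test + Cohen's d on each state's posterior, before vs after.

    ``predictions`` is a :class:`ClassifierReport` prediction frame;
    ``before``/``after`` name the two treatment groups in its ``state``
    column.  Rows are ordered by decreasing |d| (the treatment-matched state
    should lead).
    """
    rows = []
    grp_a = predictions[predictions["state"] == before]
    grp_b = predictions[predictions["state"] == after]
    if len(grp_a) == 0 or len(grp_b) == 0:
        raise ValueError("both treatment groups must be present")
    post_cols = [c for c in predictions.columns if c.startswith("p_")]
    for col in post_cols:
        res = welch_t(grp_b[col], grp_a[col])
        d = cohens_d(grp_b[col], grp_a[col])
        rows.append(
            {
                "state_posterior": col[2:],
                "t": res.statistic,
                "df": res.df,
                "pvalue": res.pvalue,
                "cohens_d": d,
            }
        )
    out = pd.DataFrame(rows)
    return out.reindex(out["cohens_d"].abs().sort_values(ascending=False).index
                       ).reset_index(drop=True)
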