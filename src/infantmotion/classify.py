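"""Risk-group classification under leave-one-out cross-validation.

Four classifiers are supported: linear discriminant analysis (LDA) and
logistic regression (LR) as linear baselines, and two non-linear models —
a single-hidden-layer ReLU multilayer perceptron (MLP) and the
log-linearised Gaussian mixture network (LLGMN).

The LLGMN embeds a Gaussian-mixture Bayes posterior in a single linear
layer: the input is expanded to the quadratic monomials
(1, x_i, x_i x_j for i <= j), one score unit is allocated per
class/component pair (the last unit's weights are pinned at zero for
identifiability), a softmax is taken over all units, and unit
probabilities are summed within a class.  Because any Gaussian mixture
discriminant is log-quadratic, suitable weights reproduce the mixture's
posterior exactly; training by maximum likelihood searches this family
directly.

The MLP and LLGMN are trained with full-batch Adam on the cross-entropy
loss.  Both are implemented on plain numpy arrays so that all folds of a
leave-one-out evaluation can be trained simultaneously as one batched
tensor computation; nested hyperparameter tuning (inner leave-one-out on
each outer training set, selecting the grid value with the highest inner
F1, ties toward the smaller value) is otherwise prohibitively slow at
cohort sizes of a few dozen.  Per-fold random initialisations are seeded
by held-out sample identity, not position, so fold results do not depend
on the ordering of the cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score

from .stats import fisher_exact, yules_q

KINDS = ("lda", "lr", "mlp", "llgmn")


@dataclass
class ClassifierSpec:
    kind: str
    hyper: int | None = None   # MLP: hidden nodes; LLGMN: components/class
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.hyper is not None and self.hyper < 1:
            raise ValueError("hyperparameter must be >= 1")


# ---------------------------------------------------------------------------
# quadratic expansion and LLGMN posterior


def quadratic_expansion(X: np.ndarray) -> np.ndarray:
    """Map (n, d) inputs to (n, 1 + d + d(d+1)/2) monomials.

    Column order: constant 1, then x_1..x_d, then x_i * x_j for i <= j in
    row-major order ((1,1), (1,2), .., (1,d), (2,2), ..).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    iu, ju = np.triu_indices(d)
    return np.concatenate(
        [np.ones((n, 1)), X, X[:, iu] * X[:, ju]], axis=1)


def llgmn_posterior(weights: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Class posteriors of an LLGMN given its weight tensor.

    ``weights`` has shape (D, n_classes, M): one weight vector per
    class/component unit over the expanded input of dimension D.
    Softmax is taken over all units and unit probabilities are summed
    within each class, so the output rows sum to 1.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 3:
        raise ValueError("weights must have shape (D, n_classes, M)")
    D, C, M = weights.shape
    xe = quadratic_expansion(x)
    if xe.shape[1] != D:
        raise ValueError(
            f"expanded input dimension {xe.shape[1]} != weight rows {D}")
    scores = xe @ weights.reshape(D, C * M)          # (n, C*M)
    scores -= scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    unit_p = e / e.sum(axis=1, keepdims=True)
    return unit_p.reshape(-1, C, M).sum(axis=2)


# ---------------------------------------------------------------------------
# batched Adam trainers
#
# All tensors carry a leading batch axis so that the B folds of a
# leave-one-out run train as one vectorised computation.


def _adam_step(params, grads, state, lr, t, beta1=0.9, beta2=0.999, eps=1e-8):
    for key, g in grads.items():
        m, v = state[key]
        m[:] = beta1 * m + (1 - beta1) * g
        v[:] = beta2 * v + (1 - beta2) * g * g
        mhat = m / (1 - beta1 ** t)
        vhat = v / (1 - beta2 ** t)
        params[key] -= lr * mhat / (np.sqrt(vhat) + eps)


def _train_mlp_batch(Xtr: np.ndarray, ytr: np.ndarray, hidden: int,
                     seeds: list[int], epochs: int = 400, lr: float = 0.05,
                     tol: float = 1e-6) -> dict[str, np.ndarray]:
    """Train B independent MLPs on (B, n, d) training sets."""
    B, n, d = Xtr.shape
    W1 = np.empty((B, d, hidden))
    b1 = np.zeros((B, hidden))
    W2 = np.empty((B, hidden))
    b2 = np.zeros(B)
    for b, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        W1[b] = rng.standard_normal((d, hidden)) * np.sqrt(2.0 / d)
        W2[b] = rng.standard_normal(hidden) * np.sqrt(1.0 / hidden)
    params = {"W1": W1, "b1": b1, "W2": W2, "b2": b2}
    state = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in params.items()}
    prev_loss = np.inf
    for t in range(1, epochs + 1):
        Z1 = Xtr @ params["W1"] + params["b1"][:, None, :]
        A1 = np.maximum(Z1, 0.0)
        logit = np.einsum("bnh,bh->bn", A1, params["W2"]) + params["b2"][:, None]
        p = 1.0 / (1.0 + np.exp(-logit))
        g = (p - ytr) / n                                    # (B, n)
        grads = {
            "W2": np.einsum("bnh,bn->bh", A1, g),
            "b2": g.sum(axis=1),
        }
        dZ1 = (g[:, :, None] * params["W2"][:, None, :]) * (Z1 > 0)
        grads["W1"] = np.einsum("bnd,bnh->bdh", Xtr, dZ1)
        grads["b1"] = dZ1.sum(axis=1)
        _adam_step(params, grads, state, lr, t)
        if t % 25 == 0:
            eps = 1e-12
            loss = float(-np.mean(ytr * np.log(p + eps)
                                  + (1 - ytr) * np.log(1 - p + eps)))
            if abs(prev_loss - loss) <= tol * max(abs(prev_loss), 1.0):
                break
            prev_loss = loss
    return params


def _mlp_forward(params: dict[str, np.ndarray], X: np.ndarray) -> np.ndarray:
    """Posterior of the positive class for (B, d) inputs, one per batch."""
    Z1 = np.einsum("bd,bdh->bh", X, params["W1"]) + params["b1"]
    A1 = np.maximum(Z1, 0.0)
    logit = np.einsum("bh,bh->b", A1, params["W2"]) + params["b2"]
    return 1.0 / (1.0 + np.exp(-logit))


def _train_llgmn_batch(Xe: np.ndarray, ytr: np.ndarray, M: int,
                       seeds: list[int], epochs: int = 400, lr: float = 0.05,
                       tol: float = 1e-6) -> np.ndarray:
    """Train B LLGMNs on (B, n, D) expanded inputs; returns (B, D, 2, M)."""
    B, n, D = Xe.shape
    U = 2 * M
    W = np.empty((B, D, U))
    for b, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        W[b] = rng.standard_normal((D, U)) * 0.1
    W[:, :, U - 1] = 0.0          # pinned unit for identifiability
    state = {"W": (np.zeros_like(W), np.zeros_like(W))}
    params = {"W": W}
    Y = np.stack([1.0 - ytr, ytr], axis=-1)              # (B, n, 2)
    prev_loss = np.inf
    for t in range(1, epochs + 1):
        scores = Xe @ params["W"]                        # (B, n, U)
        scores = scores - scores.max(axis=2, keepdims=True)
        e = np.exp(scores)
        unit_p = e / e.sum(axis=2, keepdims=True)
        class_p = unit_p.reshape(B, n, 2, M).sum(axis=3)  # (B, n, 2)
        ratio = Y / np.maximum(class_p, 1e-12)
        scale = np.repeat(ratio, M, axis=2)               # (B, n, U)
        dscore = (unit_p - unit_p * scale) / n
        gW = np.einsum("bnD,bnU->bDU", Xe, dscore)
        gW[:, :, U - 1] = 0.0
        _adam_step(params, {"W": gW}, state, lr, t)
        params["W"][:, :, U - 1] = 0.0
        if t % 25 == 0:
            loss = float(-np.mean(np.log(np.maximum(
                (Y * class_p).sum(axis=2), 1e-12))))
            if abs(prev_loss - loss) <= tol * max(abs(prev_loss), 1.0):
                break
            prev_loss = loss
    return params["W"].reshape(B, D, 2, M)


def _llgmn_forward(W: np.ndarray, Xe: np.ndarray) -> np.ndarray:
    """Positive-class posterior for (B, D) expanded inputs."""
    B, D, C, M = W.shape
    scores = np.einsum("bD,bDU->bU", Xe, W.reshape(B, D, C * M))
    scores -= scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    unit_p = e / e.sum(axis=1, keepdims=True)
    return unit_p.reshape(B, C, M).sum(axis=2)[:, 1]


def _standardize(Xtr: np.ndarray, Xte: np.ndarray):
    mu = Xtr.mean(axis=-2, keepdims=True)
    sd = Xtr.std(axis=-2, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (Xtr - mu) / sd, (Xte - mu.squeeze(-2)) / sd.squeeze(-2)


# ---------------------------------------------------------------------------
# single-model fit/predict


def fit_predict(spec: ClassifierSpec, X_train: np.ndarray, y_train: np.ndarray,
                X_test: np.ndarray, epochs: int = 400,
                threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Train one classifier and return (posteriors, labels) on X_test."""
    X_train = np.asarray(X_train, float)
    y_train = np.asarray(y_train).astype(float)
    X_test = np.atleast_2d(np.asarray(X_test, float))
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class")
    if spec.kind == "lda":
        model = LinearDiscriminantAnalysis()
        model.fit(X_train, y_train)
        post = model.predict_proba(X_test)[:, list(model.classes_).index(1.0)]
    elif spec.kind == "lr":
        model = LogisticRegression(C=np.inf, max_iter=2000)
        model.fit(X_train, y_train)
        post = model.predict_proba(X_test)[:, list(model.classes_).index(1.0)]
    elif spec.kind == "mlp":
        h = spec.hyper or 10
        Xtr, Xte = _standardize(X_train[None], X_test)
        params = _train_mlp_batch(Xtr, y_train[None], h, [spec.seed],
                                  epochs=epochs)
        post = np.array([
            _mlp_forward(params, Xte[i:i + 1])[0] for i in range(len(Xte))])
    elif spec.kind == "llgmn":
        M = spec.hyper or 2
        Xtr, Xte = _standardize(X_train[None], X_test)
        W = _train_llgmn_batch(quadratic_expansion(Xtr[0])[None],
                               y_train[None], M, [spec.seed], epochs=epochs)
        Xe_te = quadratic_expansion(Xte)
        post = np.array([
            _llgmn_forward(W, Xe_te[i:i + 1])[0] for i in range(len(Xe_te))])
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ValueError(spec.kind)
    return post, post > threshold


# ---------------------------------------------------------------------------
# metrics


@dataclass
class CVResult:
    y_true: np.ndarray
    scores: np.ndarray
    labels: np.ndarray
    confusion: dict[str, int]
    metrics: dict[str, float]
    fold_hyper: list[int] | None = None
    tuned_mean: float | None = None
    tuned_sd: float | None = None
    repetition: int | None = None


def metrics(y_true, scores, labels) -> tuple[dict[str, int], dict[str, float]]:
    """Pooled screening metrics for the high-risk (positive) class."""
    y = np.asarray(y_true).astype(bool)
    pred = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if not (y.any() and (~y).any()):
        raise ValueError("need at least one positive and one negative")
    tp = int(np.count_nonzero(y & pred))
    fn = int(np.count_nonzero(y & ~pred))
    fp = int(np.count_nonzero(~y & pred))
    tn = int(np.count_nonzero(~y & ~pred))
    conf = {"tp": tp, "fn": fn, "fp": fp, "tn": tn}
    out = {
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "f1": 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0,
    }
    if np.ptp(scores) == 0:
        warnings.warn("degenerate score vector; AUCs set to 0.5")
        out["roc_auc"] = out["pr_auc"] = 0.5
    else:
        out["roc_auc"] = float(roc_auc_score(y, scores))
        out["pr_auc"] = float(average_precision_score(y, scores))
    table = np.array([[tp, fn], [fp, tn]])
    out["fisher_p"] = fisher_exact(table)
    try:
        out["yules_q"] = yules_q(table)
    except ValueError:
        warnings.warn("Yule's Q undefined for this confusion matrix")
        out["yules_q"] = np.nan
    return conf, out


# ---------------------------------------------------------------------------
# leave-one-out machinery


def _fold_seed(base_seed: int, sample_id: int, rep: int = 0) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(sample_id), int(rep)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _loo_posteriors(kind: str, hyper: int | None, X: np.ndarray,
                    y: np.ndarray, sample_ids, base_seed: int, rep: int,
                    epochs: int) -> np.ndarray:
    """Held-out posteriors for every leave-one-out fold (batched models)."""
    n = len(y)
    idx = np.arange(n)
    for i in range(n):
        if len(np.unique(y[idx != i])) < 2:
            raise ValueError(f"training fold {i} contains a single class")
    if kind in ("lda", "lr"):
        post = np.empty(n)
        for i in range(n):
            tr = idx != i
            p, _ = fit_predict(ClassifierSpec(kind), X[tr], y[tr], X[i:i + 1])
            post[i] = p[0]
        return post
    seeds = [_fold_seed(base_seed, sample_ids[i], rep) for i in range(n)]
    Xtr = np.stack([X[idx != i] for i in range(n)])          # (n, n-1, d)
    ytr = np.stack([y[idx != i] for i in range(n)]).astype(float)
    Xtr_s, Xte_s = _standardize(Xtr, X)
    if kind == "mlp":
        params = _train_mlp_batch(Xtr_s, ytr, hyper or 10, seeds, epochs=epochs)
        return _mlp_forward(params, Xte_s)
    Xe_tr = np.stack([quadratic_expansion(Xtr_s[i]) for i in range(n)])
    W = _train_llgmn_batch(Xe_tr, ytr, hyper or 2, seeds, epochs=epochs)
    return _llgmn_forward(W, quadratic_expansion(Xte_s))


def loo_evaluate(spec: ClassifierSpec, X, y, sample_ids=None,
                 epochs: int = 400, threshold: float = 0.5) -> CVResult:
    """Leave-one-out evaluation of a fixed classifier specification."""
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if sample_ids is None:
        sample_ids = np.arange(n)
    post = _loo_posteriors(spec.kind, spec.hyper, X, y, sample_ids,
                           spec.seed, 0, epochs)
    labels = post > threshold
    conf, mets = metrics(y, post, labels)
    return CVResult(y_true=y, scores=post, labels=labels,
                    confusion=conf, metrics=mets)


def _f1(y_true: np.ndarray, pred: np.ndarray) -> float:
    tp = np.count_nonzero(y_true & pred)
    denom = 2 * tp + np.count_nonzero(~y_true & pred) \
        + np.count_nonzero(y_true & ~pred)
    return 2 * tp / denom if denom else 0.0


def nested_tune(kind: str, grid, X, y, sample_ids=None, seed: int = 0,
                repetitions: int = 1, epochs: int = 400,
                threshold: float = 0.5) -> CVResult:
    """Nested leave-one-out hyperparameter tuning and outer evaluation.

    For every outer fold, an inner leave-one-out on the outer training set
    scores each grid value by pooled F1; the best value (ties toward the
    smaller) trains the outer model.  The whole procedure is repeated
    ``repetitions`` times with distinct seeds and the repetition with the
    highest outer F1 (then PR-AUC) is reported, along with the mean and SD
    of tuned values across all folds and repetitions.
    """
    grid = sorted(set(int(g) for g in grid))
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    n = len(y)
    if sample_ids is None:
        sample_ids = np.arange(n)
    idx = np.arange(n)
    best: CVResult | None = None
    all_tuned: list[int] = []
    for rep in range(repetitions):
        post = np.empty(n)
        fold_hyper = []
        for i in range(n):
            tr = idx != i
            X_in, y_in = X[tr], y[tr]
            ids_in = np.asarray(sample_ids)[tr]
            best_g, best_f1 = None, -1.0
            for g in grid:
                try:
                    p_in = _loo_posteriors(kind, g, X_in, y_in, ids_in,
                                           seed, rep, epochs)
                except ValueError as err:
                    warnings.warn(f"grid value {g} skipped: {err}")
                    continue
                f1 = _f1(y_in.astype(bool), p_in > threshold)
                if f1 > best_f1:
                    best_g, best_f1 = g, f1
            if best_g is None:
                raise ValueError("no feasible grid value in inner loop")
            fold_hyper.append(best_g)
            spec = ClassifierSpec(kind, hyper=best_g,
                                  seed=_fold_seed(seed, sample_ids[i], rep))
            p, _ = fit_predict(spec, X_in, y_in, X[i:i + 1], epochs=epochs)
            post[i] = p[0]
        labels = post > threshold
        conf, mets = metrics(y, post, labels)
        res = CVResult(y_true=y, scores=post, labels=labels, confusion=conf,
                       metrics=mets, fold_hyper=fold_hyper, repetition=rep)
        all_tuned.extend(fold_hyper)
        if best is None or (
                (res.metrics["f1"], res.metrics["pr_auc"])
                > (best.metrics["f1"], best.metrics["pr_auc"])):
            best = res
    assert best is not None
    best.tuned_mean = float(np.mean(all_tuned))
    best.tuned_sd = float(np.std(all_tuned, ddof=1)) if len(all_tuned) > 1 else 0.0
    return best
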