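"""Calibration engines: PLS regression with grouped cross-validation and
latent-variable selection, PCA score extraction, and an automated
single-hidden-layer MLP architecture search.

All estimators follow scikit-learn conventions (``fit``/``predict``, fitted
attributes with trailing underscores) so they compose with pipelines and
model selection utilities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DegenerateTargetError",
    "split_calibration",
    "PLSCalibrator",
    "fit_pls",
    "predict_pls",
    "PCAScores",
    "fit_pca_scores",
    "ACTIVATIONS",
    "ANNSearchRegressor",
    "ann_search",
    "predict_ann",
]


class DegenerateTargetError(ValueError):
    """The target has zero variance and cannot be calibrated."""


def split_calibration(dataset, fraction: float = 0.8, seed: int = 0):
    """Random calibration/validation split of sample ids, stratified by run
    so that every run contributes to calibration.

    Within each run, ``round(fraction * n_run)`` samples go to calibration
    (at least one); the remainder to validation.  Seed-reproducible.
    """
    rng = np.random.default_rng(seed)
    runs = dataset.run_ids or ["run"] * dataset.n_samples
    cal, val = [], []
    for run in dict.fromkeys(runs):  # preserve first-seen order
        idx = [i for i, r in enumerate(runs) if r == run]
        n_cal = max(1, int(round(fraction * len(idx))))
        perm = rng.permutation(len(idx))
        chosen = {idx[j] for j in perm[:n_cal]}
        cal += [dataset.sample_ids[i] for i in sorted(chosen)]
        val += [dataset.sample_ids[i] for i in sorted(set(idx) - chosen)]
    return cal, val


def _cv_groups(n: int, n_groups: int, seed: int) -> np.ndarray:
    """Group labels by seeded shuffle + round-robin assignment."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    groups = np.empty(n, dtype=int)
    groups[order] = np.arange(n) % n_groups
    return groups


def _pls1_components(X: np.ndarray, y: np.ndarray, n_comp: int):
    """PLS1 by NIPALS on centred data.

    For a single response NIPALS needs no inner iteration: per component
    w = X'y / ||X'y||, t = Xw, p = X't / t't, q = y't / t't, deflate X.
    Returns (W, P, Q) from which the k-component regression vector is
    W (P'W)^-1 q_{1..k}.
    """
    n, m = X.shape
    Xd = X.copy()
    W = np.empty((m, n_comp))
    P = np.empty((m, n_comp))
    Q = np.empty(n_comp)
    for a in range(n_comp):
        w = Xd.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            # Residual X carries no covariance with y; truncate.
            return W[:, :a], P[:, :a], Q[:a]
        w /= norm
        t = Xd @ w
        tt = t @ t
        if tt < 1e-14:
            return W[:, :a], P[:, :a], Q[:a]
        p = Xd.T @ t / tt
        q = y @ t / tt
        Xd -= np.outer(t, p)
        W[:, a] = w
        P[:, a] = p
        Q[a] = q
    return W, P, Q


def _pls1_coefs(W, P, Q):
    """Regression vectors b_k (columns) for k = 1..n_comp components."""
    n_comp = W.shape[1]
    R = np.linalg.solve((P.T @ W), np.eye(n_comp))  # (P'W)^-1, upper triangular
    WR = W @ R  # x-rotations
    coefs = np.cumsum(WR * Q[None, :], axis=1)  # b_k = sum_{a<=k} r_a q_a
    return coefs


class PLSCalibrator(RegressorMixin, BaseEstimator):
    """PLS1 regression with grouped cross-validation and automatic
    latent-variable selection.

    Components are extracted by NIPALS on mean-centred data.  ``Q2cum`` is
    estimated by k-group cross-validation (groups assigned round-robin after
    a seeded shuffle); the retained component count is the last one whose
    cumulative Q2 gain exceeds ``q2_gain_threshold``, capped at ``max_lv``.

    Attributes
    ----------
    n_lv_ : selected number of latent variables.
    coef_ : regression vector for ``n_lv_`` components.
    r2cum_, q2cum_ : cumulative explained / cross-validated Y variance.
    """

    def __init__(self, max_lv: int = 10, cv_groups: int = 7,
                 q2_gain_threshold: float = 0.01, random_state: int = 0):
        self.max_lv = max_lv
        self.cv_groups = cv_groups
        self.q2_gain_threshold = q2_gain_threshold
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, m = X.shape
        if np.ptp(y) == 0:
            raise DegenerateTargetError("target has zero variance")
        if n <= self.cv_groups:
            raise ValueError("need more calibration samples than CV groups")
        max_lv = min(self.max_lv, n - 1, m)
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = y.mean()
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        ss_tot = yc @ yc

        W, P, Q = _pls1_components(Xc, yc, max_lv)
        n_avail = W.shape[1]
        if n_avail == 0:
            raise DegenerateTargetError("no covariance between X and y")
        coefs = _pls1_coefs(W, P, Q)  # m x n_avail
        resid = yc[:, None] - Xc @ coefs
        self.r2cum_ = 1.0 - (resid**2).sum(axis=0) / ss_tot

        groups = _cv_groups(n, self.cv_groups, self.random_state)
        press = np.zeros(n_avail)
        for g in range(self.cv_groups):
            tr, te = groups != g, groups == g
            xm, ym = X[tr].mean(axis=0), y[tr].mean()
            Wg, Pg, Qg = _pls1_components(X[tr] - xm, y[tr] - ym, n_avail)
            k = Wg.shape[1]
            if k == 0:
                press += np.sum((y[te] - ym) ** 2)
                continue
            cg = _pls1_coefs(Wg, Pg, Qg)
            pred = (X[te] - xm) @ cg + ym
            err2 = ((y[te, None] - pred) ** 2).sum(axis=0)
            press[:k] += err2
            press[k:] += err2[-1]  # folds with fewer components keep last
        self.q2cum_ = 1.0 - press / ss_tot

        gains = np.diff(np.concatenate([[0.0], self.q2cum_]))
        n_lv = 1
        for a in range(n_avail):
            if gains[a] > self.q2_gain_threshold:
                n_lv = a + 1
            else:
                break
        self.n_lv_ = n_lv
        self.coef_ = coefs[:, n_lv - 1]
        self.weights_ = W[:, :n_lv]
        self.loadings_ = P[:, :n_lv]
        self.y_loadings_ = Q[:n_lv]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_


def fit_pls(X, y, max_lv: int = 10, cv_groups: int = 7, seed: int = 0,
            q2_gain_threshold: float = 0.01) -> PLSCalibrator:
    return PLSCalibrator(
        max_lv=max_lv, cv_groups=cv_groups,
        q2_gain_threshold=q2_gain_threshold, random_state=seed,
    ).fit(X, y)


def predict_pls(model: PLSCalibrator, X) -> np.ndarray:
    return model.predict(X)


class PCAScores(TransformerMixin, BaseEstimator):
    """PCA score extraction retaining the smallest component count that
    reaches ``variance_target`` (capped by ``n_pc_max`` and n_samples - 1)."""

    def __init__(self, variance_target: float = 0.99, n_pc_max: int = 30):
        self.variance_target = variance_target
        self.n_pc_max = n_pc_max

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        cap = min(self.n_pc_max, X.shape[0] - 1, X.shape[1])
        self._pca = PCA(n_components=cap, svd_solver="randomized",
                        random_state=0)
        self._pca.fit(X)
        frac = np.cumsum(self._pca.explained_variance_ratio_)
        reached = np.flatnonzero(frac >= self.variance_target)
        self.n_pc_ = int(reached[0] + 1) if reached.size else cap
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_[
            : self.n_pc_
        ]
        self.components_ = self._pca.components_[: self.n_pc_]
        self.mean_ = self._pca.mean_
        return self

    def transform(self, X):
        check_is_fitted(self, "n_pc_")
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_.T


def fit_pca_scores(X, variance_target: float = 0.99, n_pc_max: int = 30) -> PCAScores:
    return PCAScores(variance_target=variance_target, n_pc_max=n_pc_max).fit(X)


# ---------------------------------------------------------------------------
# ANN search
# ---------------------------------------------------------------------------

_EXP_CLIP = 30.0

ACTIVATIONS = {
    "identity": (lambda x: x, lambda x, a: np.ones_like(x)),
    "logistic": (lambda x: 1.0 / (1.0 + np.exp(-np.clip(x, -_EXP_CLIP, _EXP_CLIP))),
                 lambda x, a: a * (1.0 - a)),
    "tanh": (np.tanh, lambda x, a: 1.0 - a**2),
    "exponential": (lambda x: np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP)),
                    lambda x, a: a),
    "sine": (np.sin, lambda x, a: np.cos(x)),
}

ACTIVATION_ORDER = ("identity", "logistic", "tanh", "exponential", "sine")


@dataclass
class _CandidateRecord:
    n_hidden: int
    hidden_activation: str
    output_activation: str
    train_r: float
    test_r: float
    validation_r: float
    converged: bool


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0 or not np.all(np.isfinite(b)):
        return -np.inf
    return float(np.corrcoef(a, b)[0, 1])


class _TinyMLP:
    """Single-hidden-layer perceptron, one output neuron, sum-of-squares
    loss, full-batch Adam, early stopping on test loss."""

    def __init__(self, n_hidden, hidden_act, out_act, rng, max_epochs=500,
                 patience=20, lr=0.02):
        self.n_hidden = n_hidden
        self.hidden_act = hidden_act
        self.out_act = out_act
        self.rng = rng
        self.max_epochs = max_epochs
        self.patience = patience
        self.lr = lr

    def init(self, n_in):
        rng = self.rng
        self.W1 = rng.normal(0, 1.0 / np.sqrt(n_in), (n_in, self.n_hidden))
        self.b1 = np.zeros(self.n_hidden)
        self.W2 = rng.normal(0, 1.0 / np.sqrt(self.n_hidden), (self.n_hidden, 1))
        self.b2 = np.zeros(1)

    def forward(self, X):
        f1, _ = ACTIVATIONS[self.hidden_act]
        f2, _ = ACTIVATIONS[self.out_act]
        z1 = X @ self.W1 + self.b1
        a1 = f1(z1)
        z2 = a1 @ self.W2 + self.b2
        return f2(z2).ravel(), (z1, a1, z2)

    def train(self, Xtr, ytr, Xte, yte):
        self.init(Xtr.shape[1])
        params = [self.W1, self.b1, self.W2, self.b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        best_loss, best_state, wait = np.inf, None, 0
        _, d1 = ACTIVATIONS[self.hidden_act]
        f1 = ACTIVATIONS[self.hidden_act][0]
        _, d2 = ACTIVATIONS[self.out_act]
        n = Xtr.shape[0]
        converged = True
        for epoch in range(1, self.max_epochs + 1):
            out, (z1, a1, z2) = self.forward(Xtr)
            if not np.all(np.isfinite(out)):
                converged = False
                break
            err = out - ytr
            a2 = out[:, None]
            delta2 = (err[:, None]) * d2(z2, a2)
            gW2 = a1.T @ delta2 / n
            gb2 = delta2.mean(axis=0)
            delta1 = (delta2 @ self.W2.T) * d1(z1, a1)
            gW1 = Xtr.T @ delta1 / n
            gb1 = delta1.mean(axis=0)
            grads = [gW1, gb1, gW2, gb2]
            if not all(np.all(np.isfinite(g)) for g in grads):
                converged = False
                break
            for i, (p, g) in enumerate(zip(params, grads)):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g**2
                mh = m[i] / (1 - beta1**epoch)
                vh = v[i] / (1 - beta2**epoch)
                p -= self.lr * mh / (np.sqrt(vh) + eps)
            te_out, _ = self.forward(Xte)
            te_loss = np.sum((te_out - yte) ** 2)
            if not np.isfinite(te_loss):
                converged = False
                break
            if te_loss < best_loss - 1e-12:
                best_loss = te_loss
                best_state = [p.copy() for p in params]
                wait = 0
            else:
                wait += 1
                if wait >= self.patience:
                    break
        if best_state is not None:
            self.W1, self.b1, self.W2, self.b2 = best_state
        return converged and best_state is not None


class ANNSearchRegressor(RegressorMixin, BaseEstimator):
    """Automated network search over single-hidden-layer MLP topologies.

    Trains the full grid ``N_HN in 1..N+1`` x 5 hidden x 5 output activation
    functions (exactly ``25 * (N + 1)`` candidates, N = number of inputs) on
    a seeded 70/15/15 train/test/validation row split, and keeps the network
    with the highest test-set Pearson correlation between target and output.
    Ties prefer fewer hidden neurons, then the earlier activation pair in
    the canonical order.  Non-convergent candidates are recorded and
    skipped.
    """

    def __init__(self, random_state: int = 0, max_epochs: int = 500,
                 patience: int = 20, learning_rate: float = 0.02,
                 split=(0.70, 0.15, 0.15), select_on: str = "test"):
        self.random_state = random_state
        self.max_epochs = max_epochs
        self.patience = patience
        self.learning_rate = learning_rate
        self.split = split
        self.select_on = select_on

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, n_in = X.shape
        if n < 10:
            raise ValueError("need at least 10 samples for a 70/15/15 split")
        rng = np.random.default_rng(self.random_state)
        order = rng.permutation(n)
        n_te = max(1, int(round(self.split[1] * n)))
        n_va = max(1, int(round(self.split[2] * n)))
        n_tr = n - n_te - n_va
        self.train_idx_ = np.sort(order[:n_tr])
        self.test_idx_ = np.sort(order[n_tr : n_tr + n_te])
        self.val_idx_ = np.sort(order[n_tr + n_te :])

        # Standardize inputs and target on the training rows for stable
        # optimization; predictions are mapped back to target units.
        self.x_center_ = X[self.train_idx_].mean(axis=0)
        self.x_scale_ = X[self.train_idx_].std(axis=0)
        self.x_scale_[self.x_scale_ == 0] = 1.0
        self.y_center_ = y[self.train_idx_].mean()
        self.y_scale_ = y[self.train_idx_].std() or 1.0
        Z = (X - self.x_center_) / self.x_scale_
        t = (y - self.y_center_) / self.y_scale_

        subsets = {
            "train": self.train_idx_, "test": self.test_idx_,
            "validation": self.val_idx_,
        }
        self.search_log_ = []
        best_key, best_net, best_rec = None, None, None
        grid = list(itertools.product(
            range(1, n_in + 2), ACTIVATION_ORDER, ACTIVATION_ORDER))
        for gi, (n_hidden, h_act, o_act) in enumerate(grid):
            net = _TinyMLP(
                n_hidden, h_act, o_act,
                rng=np.random.default_rng(
                    np.random.default_rng((self.random_state, gi)).integers(2**31)
                ),
                max_epochs=self.max_epochs, patience=self.patience,
                lr=self.learning_rate,
            )
            ok = net.train(Z[self.train_idx_], t[self.train_idx_],
                           Z[self.test_idx_], t[self.test_idx_])
            rs = {}
            for name, idx in subsets.items():
                out, _ = net.forward(Z[idx])
                rs[name] = _safe_corr(t[idx], out)
            rec = _CandidateRecord(n_hidden, h_act, o_act,
                                   rs["train"], rs["test"], rs["validation"],
                                   converged=ok)
            self.search_log_.append(rec)
            if not ok:
                continue
            sel_r = rs[self.select_on]
            if not np.isfinite(sel_r):
                continue
            # Ties broken by grid position: fewer hidden neurons, then the
            # earlier activation pair (grid enumerates in that order).
            key = (sel_r, -gi)
            if best_key is None or key > best_key:
                best_key, best_net, best_rec = key, net, rec
        if best_net is None:
            raise RuntimeError("no ANN candidate converged")
        self.n_networks_ = len(grid)
        self.network_ = best_net
        self.n_hidden_ = best_rec.n_hidden
        self.hidden_activation_ = best_rec.hidden_activation
        self.output_activation_ = best_rec.output_activation
        self.correlations_ = (best_rec.train_r, best_rec.test_r,
                              best_rec.validation_r)
        return self

    def predict(self, X):
        check_is_fitted(self, "network_")
        Z = (np.asarray(X, dtype=float) - self.x_center_) / self.x_scale_
        out, _ = self.network_.forward(Z)
        return out * self.y_scale_ + self.y_center_


def ann_search(scores, y, seed: int = 0, **kwargs) -> ANNSearchRegressor:
    return ANNSearchRegressor(random_state=seed, **kwargs).fit(scores, y)


def predict_ann(model: ANNSearchRegressor, basis: PCAScores, X_new) -> np.ndarray:
    """Project new spectra onto the stored PCA basis and forward-pass the
    winning network."""
    return model.predict(basis.transform(X_new))
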