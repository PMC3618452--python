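"""Orthogonal projections to latent structures discriminant analysis.

Single-response O-PLS in the Trygg & Wold formulation: the predictor
variation is split into one component predictive of the class response
and ``n_orth`` components orthogonal to it.  The class response is coded
1 (treated) / 2 (control) and centered internally.  Model quality is
summarised by R2X (fraction of X sum of squares captured by predictive
plus orthogonal components), R2Y (fraction of response sum of squares
explained) and Q2 (1 - PRESS/SSY under k-fold cross-validation with a
full refit — including scaling — per fold).

Variable influence on projection (VIP) uses the standard PLS formula

    VIP_j = sqrt( p * sum_a (w_aj / ||w_a||)^2 * SSY_a / sum_a SSY_a )

in which orthogonal components carry no explained response sum of
squares, so for O-PLS it collapses to ``sqrt(p) * |w_j|`` for the
unit-norm predictive weight vector; mean(VIP^2) = 1 by construction.

The estimators follow the scikit-learn fit/predict/transform protocol
(get_params/set_params, trailing-underscore fitted attributes) and
compose with sklearn pipelines, without depending on scikit-learn.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass

import numpy as np

from .bucketing import BucketTable

__all__ = [
    "UnitVarianceScaler",
    "OPLSDA",
    "ScaledMatrix",
    "uv_scale",
    "fit_oplsda",
    "vip",
    "backscaled_coefficients",
    "predict",
]


class _BaseEstimator:
    """Minimal sklearn-compatible parameter protocol."""

    @classmethod
    def _param_names(cls):
        sig = inspect.signature(cls.__init__)
        return [n for n in sig.parameters if n != "self"]

    def get_params(self, deep: bool = True) -> dict:
        return {n: getattr(self, n) for n in self._param_names()}

    def set_params(self, **params):
        valid = set(self._param_names())
        for key, value in params.items():
            if key not in valid:
                raise ValueError(f"invalid parameter {key!r} for {type(self).__name__}")
            setattr(self, key, value)
        return self

    def __repr__(self) -> str:
        args = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({args})"

    def __sklearn_tags__(self):
        # only invoked from sklearn meta-estimators; sklearn itself is not
        # a dependency of this package
        from sklearn.utils._tags import Tags, TargetTags

        return Tags(
            estimator_type=None,
            target_tags=TargetTags(required=False),
            transformer_tags=None,
            classifier_tags=None,
            regressor_tags=None,
        )


class UnitVarianceScaler(_BaseEstimator):
    """Mean-center each column and divide by its (n-1) standard deviation.

    Zero-variance columns cannot be scaled and are dropped; their indices
    are recorded in ``dropped_columns_`` and transform removes them, so a
    constant column neither contributes nor breaks downstream models.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples to estimate a variance")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.any():
            raise ValueError("all columns have zero variance")
        self.n_features_in_ = X.shape[1]
        self.retained_ = np.where(keep)[0]
        self.dropped_columns_ = np.where(~keep)[0]
        self.mean_ = mean[keep]
        self.scale_ = sd[keep]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, scaler was fitted with "
                f"{self.n_features_in_}"
            )
        return (X[:, self.retained_] - self.mean_) / self.scale_

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


@dataclass
class ScaledMatrix:
    """Unit-variance-scaled matrix with the statistics used to scale it."""

    values: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    dropped_columns: np.ndarray
    column_labels: np.ndarray | None = None


def uv_scale(data) -> ScaledMatrix:
    """Unit-variance scale a matrix or BucketTable (columns = buckets)."""
    if isinstance(data, BucketTable):
        X = data.matrix
        labels = data.bin_centers_ppm
    else:
        X = np.asarray(data, dtype=float)
        labels = None
    scaler = UnitVarianceScaler().fit(X)
    return ScaledMatrix(
        values=scaler.transform(X),
        column_means=scaler.mean_,
        column_sds=scaler.scale_,
        dropped_columns=scaler.dropped_columns_,
        column_labels=None if labels is None else np.asarray(labels)[scaler.retained_],
    )


class OPLSDA(_BaseEstimator):
    """Two-class O-PLS discriminant analysis with 1/2 class coding.

    Parameters
    ----------
    n_orth : number of orthogonal (class-uncorrelated) components.
    scale : unit-variance scale X internally; when False, X is taken as
        already centered/scaled and cross-validation refits skip scaling.
    cv_folds : folds for the Q2 cross-validation (0 disables Q2).
    cutoff : decision boundary on the 1/2 prediction scale; a score
        strictly below it is classified as treated.
    treated_label, control_label : class labels mapped to codes 1 and 2.
    seed : governs the fold assignment shuffle.

    Fitted attributes (suffix ``_``): ``w_`` (unit-norm predictive
    weights), ``t_``, ``p_``, ``c_``, ``W_o_``, ``P_o_``, ``T_o_``,
    ``r2x_``, ``r2y_``, ``q2_``, ``vip_``, ``coef_`` (regression vector
    in scaled space), ``y_mean_``.
    """

    def __init__(
        self,
        n_orth: int = 1,
        scale: bool = True,
        cv_folds: int = 7,
        cutoff: float = 1.5,
        treated_label="treated",
        control_label="control",
        seed: int = 0,
    ):
        self.n_orth = n_orth
        self.scale = scale
        self.cv_folds = cv_folds
        self.cutoff = cutoff
        self.treated_label = treated_label
        self.control_label = control_label
        self.seed = seed

    # -- internals ---------------------------------------------------------

    def _code_y(self, y) -> np.ndarray:
        y = np.asarray(y)
        coded = np.full(y.shape, np.nan)
        coded[y == self.treated_label] = 1.0
        coded[y == self.control_label] = 2.0
        if np.isnan(coded).any():
            labels = sorted(set(y.tolist()) - {self.treated_label, self.control_label})
            raise ValueError(f"unknown class labels {labels}")
        if not (np.any(coded == 1.0) and np.any(coded == 2.0)):
            raise ValueError("both classes must be present")
        return coded

    @staticmethod
    def _nipals_opls(X: np.ndarray, yc: np.ndarray, n_orth: int):
        """Core O-PLS decomposition on centered X and centered y."""
        Xd = X.copy()
        W_o, P_o, T_o = [], [], []
        for _ in range(n_orth):
            w = Xd.T @ yc
            nw = np.linalg.norm(w)
            if nw < 1e-12:
                raise ValueError("response has no covariance with X (rank deficiency)")
            w /= nw
            t = Xd @ w
            p = Xd.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            n_wo = np.linalg.norm(w_o)
            if n_wo < 1e-10:
                raise ValueError(
                    "requested more orthogonal components than X supports"
                )
            w_o /= n_wo
            t_o = Xd @ w_o
            p_o = Xd.T @ t_o / (t_o @ t_o)
            Xd = Xd - np.outer(t_o, p_o)
            W_o.append(w_o)
            P_o.append(p_o)
            T_o.append(t_o)
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            raise ValueError("response has no covariance with X after filtering")
        w /= nw
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        c = (yc @ t) / (t @ t)
        return w, t, p, c, W_o, P_o, T_o

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        yc_coded = self._code_y(y)
        if self.n_orth < 0:
            raise ValueError("n_orth must be >= 0")
        if self.scale:
            self.scaler_ = UnitVarianceScaler().fit(X)
            Xs = self.scaler_.transform(X)
            self.x_mean_ = None
        else:
            self.scaler_ = None
            self.x_mean_ = X.mean(axis=0)
            Xs = X - self.x_mean_
        self.y_mean_ = float(yc_coded.mean())
        yc = yc_coded - self.y_mean_
        ssx = float(np.sum(Xs**2))
        ssy = float(np.sum(yc**2))

        w, t, p, c, W_o, P_o, T_o = self._nipals_opls(Xs, yc, self.n_orth)
        self.w_, self.t_, self.p_, self.c_ = w, t, p, c
        self.W_o_ = np.array(W_o) if W_o else np.empty((0, Xs.shape[1]))
        self.P_o_ = np.array(P_o) if P_o else np.empty((0, Xs.shape[1]))
        self.T_o_ = np.array(T_o) if T_o else np.empty((0, Xs.shape[0]))

        resid = yc - t * c
        self.r2y_ = 1.0 - float(np.sum(resid**2)) / ssy
        explained_x = float(t @ t) * float(p @ p)
        for t_o, p_o in zip(self.T_o_, self.P_o_):
            explained_x += float(t_o @ t_o) * float(p_o @ p_o)
        self.r2x_ = explained_x / ssx
        self.n_features_in_ = X.shape[1]

        # regression vector in scaled space: beta = prod(I - w_o p_o^T) w c
        beta = w * c
        for w_o, p_o in zip(reversed(self.W_o_), reversed(self.P_o_)):
            beta = beta - w_o * (p_o @ beta)
        self.coef_ = beta

        self.vip_ = self._vip()

        if self.cv_folds and self.cv_folds >= 2:
            self.q2_ = self._q2(X, np.asarray(y))
        else:
            self.q2_ = None
        return self

    def _vip(self) -> np.ndarray:
        # general multi-component VIP; orthogonal components have SSY_a = 0
        # so only the unit-norm predictive weight survives
        p_feat = self.w_.size
        return np.sqrt(p_feat) * np.abs(self.w_)

    def _filter(self, Xs: np.ndarray) -> np.ndarray:
        Xf = Xs.copy()
        for w_o, p_o in zip(self.W_o_, self.P_o_):
            t_o = Xf @ w_o
            Xf = Xf - np.outer(t_o, p_o)
        return Xf

    def _prepare(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scale:
            return self.scaler_.transform(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, model was fitted with "
                f"{self.n_features_in_}"
            )
        return X - (self.x_mean_ if self.x_mean_ is not None else 0.0)

    def scores(self, X) -> np.ndarray:
        """Predictive component scores t for new observations."""
        return self._filter(self._prepare(X)) @ self.w_

    def predict(self, X) -> np.ndarray:
        """Continuous class prediction on the 1/2 coding scale."""
        return self.scores(X) * self.c_ + self.y_mean_

    def predict_class(self, X) -> np.ndarray:
        """Hard labels: treated below the cutoff, control at or above it."""
        pred = self.predict(X)
        return np.where(pred < self.cutoff, self.treated_label, self.control_label)

    def transform(self, X) -> np.ndarray:
        """Predictive score followed by orthogonal scores, as columns."""
        Xs = self._prepare(X)
        t_orth = []
        Xf = Xs.copy()
        for w_o, p_o in zip(self.W_o_, self.P_o_):
            t_o = Xf @ w_o
            Xf = Xf - np.outer(t_o, p_o)
            t_orth.append(t_o)
        t_pred = Xf @ self.w_
        return np.column_stack([t_pred] + t_orth) if t_orth else t_pred[:, None]

    def _q2(self, X: np.ndarray, y_labels: np.ndarray) -> float:
        """k-fold cross-validated Q2 with a full refit per fold.

        Fold assignment: seeded shuffle, then round-robin.  Scaling (when
        enabled) is learned on the training folds only.
        """
        n = X.shape[0]
        k = self.cv_folds
        if k > n:
            raise ValueError(f"cv_folds={k} exceeds n={n}")
        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[perm] = np.arange(n) % k

        coded = self._code_y(y_labels)
        ssy = float(np.sum((coded - coded.mean()) ** 2))
        press = 0.0
        for fold in range(k):
            test = fold_of == fold
            train = ~test
            if test.sum() == 0:
                continue
            if train.sum() < 3:
                raise ValueError("cross-validation training fold too small")
            sub = OPLSDA(
                n_orth=self.n_orth,
                scale=self.scale,
                cv_folds=0,
                cutoff=self.cutoff,
                treated_label=self.treated_label,
                control_label=self.control_label,
                seed=self.seed,
            )
            sub.fit(X[train], y_labels[train])
            pred = sub.predict(X[test])
            press += float(np.sum((coded[test] - pred) ** 2))
        return 1.0 - press / ssy


# -- functional wrappers ----------------------------------------------------


def fit_oplsda(
    X,
    y,
    n_orth: int = 1,
    cv_folds: int = 7,
    seed: int = 0,
    scale: bool = True,
    treated_label="treated",
    control_label="control",
) -> OPLSDA:
    """Fit an OPLS-DA model (thin wrapper over the estimator class)."""
    return OPLSDA(
        n_orth=n_orth,
        scale=scale,
        cv_folds=cv_folds,
        treated_label=treated_label,
        control_label=control_label,
        seed=seed,
    ).fit(X, y)


def vip(model: OPLSDA) -> np.ndarray:
    """VIP of a fitted model; mean(VIP^2) = 1."""
    return model.vip_


def predict(model: OPLSDA, X_new) -> np.ndarray:
    """Continuous predictions on the 1/2 coding scale."""
    return model.predict(X_new)


def backscaled_coefficients(model: OPLSDA, bin_centers=None):
    """Back-transform model coefficients to the spectral scale.

    Multiplies the predictive-component regression coefficients by each
    retained column's original standard deviation, restoring spectral
    appearance, and derives a 0-1 color value from min-max-normalized VIP
    (all-equal VIPs map to 0.5).

    Returns ``(ppm, back_coef, vip, color_value)``; ppm is None when no
    bin centers are available.
    """
    if model.scaler_ is not None:
        sds = model.scaler_.scale_
        retained = model.scaler_.retained_
    else:
        sds = np.ones_like(model.coef_)
        retained = np.arange(model.coef_.size)
    back = model.coef_ * sds
    v = model.vip_
    vmin, vmax = float(v.min()), float(v.max())
    if vmax - vmin < 1e-15:
        color = np.full_like(v, 0.5)
    else:
        color = (v - vmin) / (vmax - vmin)
    ppm = None
    if bin_centers is not None:
        ppm = np.asarray(bin_centers, dtype=float)[retained]
    return ppm, back, v, color
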