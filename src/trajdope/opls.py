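"""PLS and OPLS-DA fitted from scratch by NIPALS, with VIP feature ranking.

:class:`PLSNipals` is a standard NIPALS partial-least-squares regression
with X-deflation. :class:`OPLS` implements orthogonal projections to latent
structures for a single response: class-orthogonal X-variation is deflated
into separate components, leaving one predictive component whose weight
vector carries all class-discriminating information. For a fixed total
number of components the two give identical training predictions — a known
equivalence the test suite exploits as an internal oracle.

:class:`OplsDaClassifier` is a one-vs-rest ensemble of OPLS models on
centered {1, 0} class dummies, with argmax class assignment and per-class
prediction scores for ROC analysis; a single multi-response PLS2 model is
available as an alternative strategy.

VIP (variable importance in projection) is computed over predictive
components only: ``VIP_j = sqrt(K * sum_a SSY_a w_aj^2 / sum_a SSY_a)``
with K the feature count and SSY_a the response variation captured by
component a. By construction ``mean(VIP^2) = 1``.
"""

from __future__ import annotations

import numpy as np


class ConvergenceError(RuntimeError):
    """NIPALS failed to converge; carries the iteration count."""

    def __init__(self, n_iter: int):
        super().__init__(f"NIPALS did not converge within {n_iter} iterations")
        self.n_iter = n_iter


class DegenerateResponseError(ValueError):
    """The response vector has no variation (single class)."""


def _as_2d(Y):
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


class PLSNipals:
    """NIPALS partial least squares (PLS1/PLS2) with X-deflation.

    Parameters
    ----------
    n_components : number of latent components.
    center : center X and Y internally (default True); disable when inputs
        are already column-centered.
    max_iter, tol : inner-loop convergence control; the loop stops when the
        score vector changes by less than ``tol`` (relative). For a single
        response the loop is exact after one pass.

    Attributes (after fit)
    ----------------------
    x_weights_ W (K, A), x_scores_ T (n, A), x_loadings_ P (K, A),
    y_loadings_ C (M, A), coef_ (K, M), x_mean_, y_mean_.
    """

    def __init__(self, n_components=2, center=True, max_iter=500, tol=1e-10):
        self.n_components = n_components
        self.center = center
        self.max_iter = max_iter
        self.tol = tol

    def get_params(self, deep=True):
        return {
            "n_components": self.n_components,
            "center": self.center,
            "max_iter": self.max_iter,
            "tol": self.tol,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, Y) -> "PLSNipals":
        X = np.asarray(X, dtype=float)
        Y = _as_2d(Y)
        n, k = X.shape
        m = Y.shape[1]
        self.x_mean_ = X.mean(axis=0) if self.center else np.zeros(k)
        self.y_mean_ = Y.mean(axis=0) if self.center else np.zeros(m)
        Xa = X - self.x_mean_
        Ya = Y - self.y_mean_

        A = int(self.n_components)
        W = np.empty((k, A))
        T = np.empty((n, A))
        P = np.empty((k, A))
        C = np.empty((m, A))

        for a in range(A):
            # deterministic start: the first response column
            u = Ya[:, 0].copy()
            t_old = None
            for _ in range(self.max_iter):
                w = Xa.T @ u
                norm = np.linalg.norm(w)
                if norm == 0:
                    raise DegenerateResponseError(
                        "X carries no covariance with Y at component "
                        f"{a + 1}; reduce n_components"
                    )
                w /= norm
                t = Xa @ w
                c = Ya.T @ t / (t @ t)
                u = Ya @ c / (c @ c)
                if t_old is not None and np.linalg.norm(t - t_old) <= (
                    self.tol * np.linalg.norm(t)
                ):
                    break
                t_old = t
            else:
                raise ConvergenceError(self.max_iter)
            p = Xa.T @ t / (t @ t)
            Xa = Xa - np.outer(t, p)
            Ya = Ya - np.outer(t, c)
            W[:, a], T[:, a], P[:, a], C[:, a] = w, t, p, c

        self.x_weights_, self.x_scores_ = W, T
        self.x_loadings_, self.y_loadings_ = P, C
        # regression coefficients via the weight rotation W (P'W)^-1 C'
        self.coef_ = W @ np.linalg.solve(P.T @ W, C.T)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        R = self.x_weights_ @ np.linalg.inv(
            self.x_loadings_.T @ self.x_weights_
        )
        return (X - self.x_mean_) @ R


class OPLS:
    """Orthogonal projections to latent structures for a single response.

    Fits ``n_orthogonal`` response-orthogonal components followed by one
    predictive component. New samples are orthogonal-filtered with the
    training loadings before scoring.

    Attributes (after fit)
    ----------------------
    w_ : unit predictive weight vector (K,)
    t_, p_, c_ : predictive scores (n,), X-loadings (K,), y-loading (float)
    ortho_weights_, ortho_scores_, ortho_loadings_ : (K, n_orth), (n, n_orth), (K, n_orth)
    vip_ : per-feature VIP over the predictive component (K,)
    """

    def __init__(self, n_orthogonal=1, center=True):
        self.n_orthogonal = n_orthogonal
        self.center = center

    def get_params(self, deep=True):
        return {"n_orthogonal": self.n_orthogonal, "center": self.center}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "OPLS":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, k = X.shape
        if np.ptp(y) == 0:
            raise DegenerateResponseError(
                "response has no variation (single class)"
            )
        self.x_mean_ = X.mean(axis=0) if self.center else np.zeros(k)
        self.y_mean_ = float(y.mean()) if self.center else 0.0
        Xr = X - self.x_mean_
        yc = y - self.y_mean_

        w = Xr.T @ yc / (yc @ yc)
        w /= np.linalg.norm(w)

        n_orth = int(self.n_orthogonal)
        W_o = np.empty((k, n_orth))
        T_o = np.empty((n, n_orth))
        P_o = np.empty((k, n_orth))
        for j in range(n_orth):
            t = Xr @ w
            p = Xr.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            norm = np.linalg.norm(w_o)
            if norm <= 1e-14:
                raise DegenerateResponseError(
                    f"no orthogonal variation left for component {j + 1}; "
                    "reduce n_orthogonal"
                )
            w_o /= norm
            t_o = Xr @ w_o
            p_o = Xr.T @ t_o / (t_o @ t_o)
            Xr = Xr - np.outer(t_o, p_o)
            W_o[:, j], T_o[:, j], P_o[:, j] = w_o, t_o, p_o

        t = Xr @ w
        self.w_ = w
        self.t_ = t
        self.p_ = Xr.T @ t / (t @ t)
        self.c_ = float(yc @ t / (t @ t))
        self.ortho_weights_, self.ortho_scores_, self.ortho_loadings_ = W_o, T_o, P_o
        self.y_ = y
        self.vip_ = np.sqrt(k) * np.abs(w)  # single predictive component
        return self

    def _filter(self, X) -> np.ndarray:
        """Remove the fitted orthogonal variation from new samples."""
        Xr = np.asarray(X, dtype=float) - self.x_mean_
        for j in range(self.ortho_weights_.shape[1]):
            t_o = Xr @ self.ortho_weights_[:, j]
            Xr = Xr - np.outer(t_o, self.ortho_loadings_[:, j])
        return Xr

    def transform(self, X):
        """Predictive and orthogonal scores for new samples."""
        Xr = np.asarray(X, dtype=float) - self.x_mean_
        T_o = np.empty((Xr.shape[0], self.ortho_weights_.shape[1]))
        for j in range(self.ortho_weights_.shape[1]):
            t_o = Xr @ self.ortho_weights_[:, j]
            T_o[:, j] = t_o
            Xr = Xr - np.outer(t_o, self.ortho_loadings_[:, j])
        return Xr @ self.w_, T_o

    def predict(self, X) -> np.ndarray:
        return self._filter(X) @ self.w_ * self.c_ + self.y_mean_


def vip(model) -> np.ndarray:
    """VIP over the predictive component(s) of a fitted model.

    For :class:`OPLS` this is ``sqrt(K) * |w|``; for :class:`PLSNipals` the
    components are weighted by the response variation SSY_a each captures.
    """
    if isinstance(model, OPLS):
        return model.vip_
    W, T, C = model.x_weights_, model.x_scores_, model.y_loadings_
    k = W.shape[0]
    ssy = np.einsum("ma,ma->a", C, C) * np.einsum("na,na->a", T, T)
    return np.sqrt(k * (W**2 @ ssy) / ssy.sum())


class OplsDaClassifier:
    """One-vs-rest OPLS-DA ensemble with argmax class assignment.

    Each class gets its own OPLS model on a centered {1, 0} dummy response.
    Ties in the argmax resolve to the lexicographically first class label
    (``classes_`` is sorted). ``strategy="pls2"`` fits a single
    multi-response PLS model with ``1 + n_orthogonal`` components instead.

    Attributes (after fit)
    ----------------------
    classes_ : sorted class labels
    models_ : dict class -> fitted OPLS (ovr strategy)
    vip_ : dict class -> per-feature VIP (ovr strategy)
    """

    def __init__(self, n_orthogonal=1, strategy="ovr"):
        self.n_orthogonal = n_orthogonal
        self.strategy = strategy

    def get_params(self, deep=True):
        return {"n_orthogonal": self.n_orthogonal, "strategy": self.strategy}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, labels) -> "OplsDaClassifier":
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels)
        self.classes_ = sorted(set(labels.tolist()))
        if len(self.classes_) < 2:
            raise DegenerateResponseError(
                "training labels contain fewer than two classes"
            )
        if self.strategy == "ovr":
            self.models_ = {
                cls: OPLS(n_orthogonal=self.n_orthogonal).fit(
                    X, (labels == cls).astype(float)
                )
                for cls in self.classes_
            }
            self.vip_ = {cls: m.vip_ for cls, m in self.models_.items()}
        elif self.strategy == "pls2":
            dummy = np.column_stack(
                [(labels == cls).astype(float) for cls in self.classes_]
            )
            self.model_ = PLSNipals(
                n_components=1 + int(self.n_orthogonal)
            ).fit(X, dummy)
            self.vip_ = None
        else:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        return self

    def decision_function(self, X) -> np.ndarray:
        """Per-class predicted dummy responses, columns ordered as classes_."""
        X = np.asarray(X, dtype=float)
        if self.strategy == "ovr":
            return np.column_stack(
                [self.models_[cls].predict(X) for cls in self.classes_]
            )
        return self.model_.predict(X)

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        idx = np.argmax(scores, axis=1)  # first max -> lexicographic tie-break
        return np.asarray(self.classes_, dtype=object)[idx]


# --------------------------------------------------------------------------
# Functional wrappers over the estimators (the module-level operation surface)

def fit_pls_nipals(X, Y, n_components: int) -> PLSNipals:
    return PLSNipals(n_components=n_components).fit(X, Y)


def fit_opls(X, y, n_orth: int) -> OPLS:
    return OPLS(n_orthogonal=n_orth).fit(X, y)


def predict_opls(model: OPLS, X_new):
    """(predictive scores, predicted response) for new samples."""
    t, _ = model.transform(X_new)
    return t, model.predict(X_new)


def fit_oplsda_multiclass(X, labels, n_orth: int = 1) -> OplsDaClassifier:
    return OplsDaClassifier(n_orthogonal=n_orth).fit(X, labels)


def predict_class(ensemble: OplsDaClassifier, X_new):
    """(assigned labels, per-class scores) for new samples."""
    return ensemble.predict(X_new), ensemble.decision_function(X_new)
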