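"""Low-overhead SVC used in Monte-Carlo hot loops.

The sweeps fit hundreds of thousands of SVMs on matrices with 8-1000 rows;
at that size scikit-learn's per-``fit`` input validation costs an order of
magnitude more than libsvm itself.  :class:`FastSVC` calls scikit-learn's
bundled libsvm bindings directly (same solver, same defaults: ``tol=1e-3``,
``shrinking=1``, unlimited iterations), skipping the validation layer.

An import-time self-check compares predictions against the public
:class:`sklearn.svm.SVC` on a small random problem; if the private binding is
unavailable or disagrees, the module transparently falls back to the public
estimator, trading speed for safety.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FastSVC", "USING_FAST_PATH"]


class _PublicSVC:
    """Fallback with the same minimal surface as FastSVC."""

    def __init__(self, C: float = 1.0, gamma: float = 0.1, kernel: str = "rbf"):
        self.C, self.gamma, self.kernel = C, gamma, kernel

    def fit(self, X, y):
        from sklearn.svm import SVC

        self._est = SVC(kernel=self.kernel, C=self.C, gamma=self.gamma)
        self._est.fit(X, y)
        self.n_features_in_ = self._est.n_features_in_
        self.fit_status_ = self._est.fit_status_
        return self

    def predict(self, X):
        return self._est.predict(X)

    @property
    def coef_(self):
        return np.asarray(self._est.coef_)


class _LibsvmSVC:
    """Direct C-SVC via the libsvm bindings (binary 0/1 labels only)."""

    def __init__(self, C: float = 1.0, gamma: float = 0.1, kernel: str = "rbf"):
        self.C = float(C)
        self.gamma = float(gamma)
        self.kernel = kernel

    def fit(self, X, y):
        from sklearn.svm import _libsvm

        X = np.ascontiguousarray(X, dtype=np.float64)
        y64 = np.ascontiguousarray(y, dtype=np.float64)
        self._model = _libsvm.fit(
            X,
            y64,
            svm_type=0,
            kernel=self.kernel,
            C=self.C,
            gamma=self.gamma,
        )
        self.n_features_in_ = X.shape[1]
        self.fit_status_ = int(self._model[7])
        return self

    def predict(self, X):
        from sklearn.svm import _libsvm

        X = np.ascontiguousarray(X, dtype=np.float64)
        support, sv, n_sv, sv_coef, intercept, prob_a, prob_b = self._model[:7]
        pred = _libsvm.predict(
            X,
            support,
            sv,
            n_sv,
            sv_coef,
            intercept,
            prob_a,
            prob_b,
            svm_type=0,
            kernel=self.kernel,
            gamma=self.gamma,
        )
        return pred.astype(np.int64)

    @property
    def coef_(self):
        # sign may be flipped relative to sklearn's class-ordering convention;
        # callers rank by squared weights, so only magnitudes are contractual
        if self.kernel != "linear":
            raise AttributeError("coef_ is only defined for the linear kernel")
        _, sv, _, sv_coef, *_ = self._model
        return np.asarray(sv_coef) @ np.asarray(sv)


def _self_check() -> bool:
    try:
        from sklearn.svm import SVC, _libsvm

        _libsvm.set_verbosity_wrap(0)
        rng = np.random.default_rng(12345)
        X = rng.standard_normal((24, 4))
        y = np.repeat([0, 1], 12)
        X[y == 1, 0] += 1.0
        Xt = rng.standard_normal((40, 4))
        for kernel, gamma, c in (("rbf", 0.25, 4.0), ("linear", 0.1, 1.0)):
            ref = SVC(kernel=kernel, C=c, gamma=gamma).fit(X, y)
            fast = _LibsvmSVC(C=c, gamma=gamma, kernel=kernel).fit(X, y)
            if not np.array_equal(ref.predict(Xt), fast.predict(Xt)):
                return False
            if kernel == "linear" and not np.allclose(
                np.abs(ref.coef_), np.abs(fast.coef_)
            ):
                return False
        return True
    except Exception:
        return False


USING_FAST_PATH = _self_check()
FastSVC = _LibsvmSVC if USING_FAST_PATH else _PublicSVC
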