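"""Scikit-learn style estimator wrapping GREML + GBLUP.

:class:`GBLUPRegressor` follows the precomputed-kernel convention: ``fit``
takes a stack of relationship (kernel) matrices over the training
individuals plus the phenotype vector, estimates the variance components by
AI-REML, and ``predict`` takes the cross-relationship blocks between new
and training individuals and returns predicted total genetic values.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .gblup import gblup_components, total_genetic_value
from .greml import fit_greml

__all__ = ["GBLUPRegressor"]


def _kernel_list(K) -> list[np.ndarray]:
    if isinstance(K, np.ndarray) and K.ndim == 3:
        return [K[i] for i in range(K.shape[0])]
    if isinstance(K, np.ndarray) and K.ndim == 2:
        return [K]
    return [np.asarray(k, dtype=float) for k in K]


class GBLUPRegressor(RegressorMixin, BaseEstimator):
    """Multi-kernel genomic BLUP with REML variance components.

    Parameters
    ----------
    effect_labels : sequence of str, optional
        Names of the kernels, e.g. ``("A", "D", "AA")``.
    max_iter, tol, var_floor_frac
        Passed to the AI-REML optimizer.

    Attributes (after ``fit``)
    --------------------------
    sigma2_ : ndarray of shape (f,)
        Variance component per kernel.
    sigma2_e_ : float
        Residual variance.
    heritability_ : dict label -> fraction of phenotypic variance.
    beta_ : ndarray
        GLS fixed-effect estimates.
    alpha_ : ndarray
        ``V^-1 (y - X beta)`` over the training individuals; the linear
        weights every prediction is a kernel combination of.
    loglik_, converged_, n_iter_ : optimizer diagnostics.

    Examples
    --------
    >>> reg = GBLUPRegressor(effect_labels=("A",))
    >>> reg.fit([K_train], y)            # doctest: +SKIP
    >>> ghat = reg.predict([K_new_train])  # doctest: +SKIP
    """

    def __init__(self, effect_labels=None, max_iter=200, tol=1e-6,
                 var_floor_frac=1e-6):
        self.effect_labels = effect_labels
        self.max_iter = max_iter
        self.tol = tol
        self.var_floor_frac = var_floor_frac

    def fit(self, K, y, X=None):
        """Estimate variance components and training-set BLUP weights.

        ``K`` is a list (or (f, n, n) stack) of symmetric kernel matrices
        over the n training individuals; ``X`` is an optional fixed-effect
        design (default: intercept only).
        """
        mats = _kernel_list(K)
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        if X is None:
            X = np.ones((n, 1))
        X = np.asarray(X, dtype=float)
        vce = fit_greml(
            y, X, mats,
            effect_labels=self.effect_labels,
            max_iter=self.max_iter, tol=self.tol,
            var_floor_frac=self.var_floor_frac,
        )
        self.vce_ = vce
        self.sigma2_ = vce.sigma2
        self.sigma2_e_ = vce.sigma2_e
        self.heritability_ = vce.heritability_by_label
        self.total_heritability_ = vce.total_heritability
        self.loglik_ = vce.loglik
        self.converged_ = vce.converged
        self.n_iter_ = vce.n_iterations
        idx = np.arange(n)
        cp = gblup_components(y, X, mats, vce, idx, idx)
        self.beta_ = cp.fixed_effects
        # recover alpha = V^-1 (y - X beta) from the component predictions
        # by solving once more; cheap relative to the REML fit
        from scipy.linalg import cho_factor, cho_solve

        V = np.zeros((n, n))
        for s2, M in zip(vce.sigma2, mats):
            V += s2 * M
        V[np.diag_indices(n)] += vce.sigma2_e
        cf = cho_factor(V, lower=True, check_finite=False)
        self.alpha_ = cho_solve(cf, y - X @ self.beta_, check_finite=False)
        self._n_train = n
        return self

    def predict(self, K, X=None):
        """Predicted total genetic values for new individuals.

        ``K`` lists the (n_new, n_train) cross-kernel blocks, one per
        fitted component.  When ``X`` is given, fixed effects are added.
        """
        mats = _kernel_list(K)
        if len(mats) != self.sigma2_.size:
            raise ValueError("need one cross-kernel per fitted component")
        out = np.zeros(mats[0].shape[0])
        for s2, M in zip(self.sigma2_, mats):
            if M.shape[1] != self._n_train:
                raise ValueError("cross-kernel columns must match the "
                                 "training individuals")
            out += s2 * (M @ self.alpha_)
        if X is not None:
            out = out + np.asarray(X, dtype=float) @ self.beta_
        return out
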