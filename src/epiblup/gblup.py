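"""Genomic BLUP of per-effect-type and total genetic values.

Prediction uses the V-inverse form of the mixed-model equations on the
training individuals: with V_t = sum_i sigma_i^2 S_i[train, train] +
sigma_e^2 I,

    b_hat   = (X' V_t^-1 X)^-1 X' V_t^-1 y          (GLS fixed effects)
    u_hat_i = sigma_i^2 S_i[target, train] V_t^-1 (y - X b_hat)

Target individuals never enter V_t, so phenotypes of the individuals being
predicted cannot leak into their predictions.  The predicted quantity is
the genetic value only; fixed effects are estimated but not added.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .greml import VarianceComponentEstimate, _as_matrices

__all__ = ["ComponentPredictions", "gblup_components", "total_genetic_value"]


@dataclass
class ComponentPredictions:
    """Per-effect-type predicted genetic values for the target individuals."""

    effect_labels: tuple[str, ...]
    components: dict[str, np.ndarray]
    fixed_effects: np.ndarray
    target_index: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return total_genetic_value(self)


def gblup_components(
    y_train: np.ndarray,
    X_train: np.ndarray,
    S_list_full: Sequence,
    vce: VarianceComponentEstimate,
    train_index: np.ndarray,
    target_index: np.ndarray,
) -> ComponentPredictions:
    """BLUP of every effect type's genetic values for the target individuals.

    ``S_list_full`` holds relationship matrices over the union of training
    and target individuals (any superset); ``train_index``/``target_index``
    are integer positions into those matrices.  ``vce`` must come from the
    same training individuals.
    """
    y_train = np.asarray(y_train, dtype=float).ravel()
    X_train = np.asarray(X_train, dtype=float)
    train_index = np.asarray(train_index, dtype=int)
    target_index = np.asarray(target_index, dtype=int)
    mats = _as_matrices(S_list_full)
    if len(mats) != len(vce.effect_labels):
        raise ValueError("number of relationship matrices must match the "
                         "variance-component estimate")
    n_full = mats[0].shape[0]
    for idx in (train_index, target_index):
        if idx.size and (idx.min() < 0 or idx.max() >= n_full):
            raise ValueError("an index falls outside the relationship matrices")
    if y_train.size != train_index.size:
        raise ValueError("y_train must match train_index")

    nt = train_index.size
    Vt = np.zeros((nt, nt))
    for s2, S in zip(vce.sigma2, mats):
        Vt += s2 * S[np.ix_(train_index, train_index)]
    Vt[np.diag_indices(nt)] += vce.sigma2_e
    cf = cho_factor(Vt, lower=True, check_finite=False)
    ViX = cho_solve(cf, X_train, check_finite=False)
    bhat = np.linalg.solve(X_train.T @ ViX, ViX.T @ y_train)
    resid = y_train - X_train @ bhat
    alpha = cho_solve(cf, resid, check_finite=False)

    comps = {}
    for lab, s2, S in zip(vce.effect_labels, vce.sigma2, mats):
        comps[lab] = s2 * (S[np.ix_(target_index, train_index)] @ alpha)
    return ComponentPredictions(
        effect_labels=tuple(vce.effect_labels),
        components=comps,
        fixed_effects=bhat,
        target_index=target_index,
    )


def total_genetic_value(cp: ComponentPredictions) -> np.ndarray:
    """Elementwise sum of the per-effect-type predictions."""
    if not cp.components:
        raise ValueError("no components to sum")
    out = np.zeros_like(next(iter(cp.components.values())))
    for v in cp.components.values():
        out = out + v
    return out
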