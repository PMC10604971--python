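"""Multi-component GREML: restricted maximum likelihood variance components.

The mixed model is y = Xb + sum_i u_i + e with u_i ~ N(0, sigma_i^2 S_i)
for f normalized relationship matrices S_i and e ~ N(0, sigma_e^2 I).  The
phenotypic covariance is V = sum_i sigma_i^2 S_i + sigma_e^2 I and the
restricted log-likelihood (up to a constant) is

    l(theta) = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.

Maximization uses average-information (AI) updates with an EM-REML
fallback: an AI step is only accepted when it stays in the feasible region
and does not decrease the restricted log-likelihood; otherwise the EM
update (which can never decrease it) is taken.  Components are floored at
``var_floor_frac * var(y)`` and flagged as boundary solutions.  Convergence
is declared when the accepted-step log-likelihood change falls below
``tol``.

Everything is dense; the intended scale is n up to ~10^4 individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Sequence

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .core_data import EffectType

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "VarianceComponentEstimate",
    "reml_loglik",
    "fit_greml",
    "heritability_table",
]


@dataclass(frozen=True)
class ModelSpec:
    """An ordered set of effect types entering the mixed model."""

    effect_types: tuple[EffectType, ...]

    def __post_init__(self) -> None:
        if len(self.effect_types) < 1:
            raise ValueError("a model needs at least one effect type")
        if len(set(self.effect_types)) != len(self.effect_types):
            raise ValueError("duplicate effect type in model")

    @property
    def f(self) -> int:
        return len(self.effect_types)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(et.label for et in self.effect_types)

    @property
    def name(self) -> str:
        return "+".join(self.labels)

    @classmethod
    def parse(cls, text: str) -> "ModelSpec":
        """Parse a model string such as ``"A+D+AA+H"``."""
        parts = [p for p in text.replace(" ", "").split("+") if p]
        return cls(tuple(EffectType.from_label(p) for p in parts))

    def __str__(self) -> str:  # pragma: no cover
        return self.name


@dataclass
class VarianceComponentEstimate:
    """REML estimates: one variance per effect type plus the residual.

    Heritability of effect type i is sigma_i^2 / (sum_j sigma_j^2 +
    sigma_e^2); the total is the sum over effect types.
    """

    effect_labels: tuple[str, ...]
    sigma2: np.ndarray
    sigma2_e: float
    loglik: float = float("nan")
    n_iterations: int = 0
    converged: bool = True
    boundary_flags: np.ndarray | None = None
    ai_covariance: np.ndarray | None = None
    #: mean diagonal of each relationship matrix; the variance a component
    #: contributes to an average individual is sigma_i^2 * diag_mean_i, so
    #: heritabilities stay invariant to rescaling a kernel (all ones for
    #: matrices normalized to mean diagonal 1)
    diag_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.sigma2.shape != (len(self.effect_labels),):
            raise ValueError("sigma2 length must match effect_labels")
        if (self.sigma2 < 0).any() or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")
        if self.boundary_flags is None:
            self.boundary_flags = np.zeros(len(self.effect_labels) + 1, dtype=bool)
        if self.diag_means is None:
            self.diag_means = np.ones(len(self.effect_labels))
        else:
            self.diag_means = np.asarray(self.diag_means, dtype=float)

    @property
    def total_variance(self) -> float:
        return float((self.sigma2 * self.diag_means).sum() + self.sigma2_e)

    @property
    def heritability(self) -> np.ndarray:
        return self.sigma2 * self.diag_means / self.total_variance

    @property
    def total_heritability(self) -> float:
        return float(self.heritability.sum())

    @property
    def heritability_by_label(self) -> dict[str, float]:
        return dict(zip(self.effect_labels, self.heritability))


def _as_matrices(S_list: Sequence) -> list[np.ndarray]:
    from .core_data import GRM

    out = []
    for S in S_list:
        M = S.matrix if isinstance(S, GRM) else np.asarray(S, dtype=float)
        out.append(M)
    return out


def _reml_pieces(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
                 S_list: list[np.ndarray]) -> SimpleNamespace:
    """V, P, Py and restricted log-likelihood at theta = (sigma2_1..f, sigma2_e)."""
    n = y.size
    V = np.zeros((n, n))
    for t, S in zip(theta[:-1], S_list):
        V += t * S
    V[np.diag_indices(n)] += theta[-1]
    cf = cho_factor(V, lower=True, check_finite=False)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    Vinv = cho_solve(cf, np.eye(n), check_finite=False)
    ViX = Vinv @ X
    XtViX = X.T @ ViX
    cf2 = cho_factor(XtViX, check_finite=False)
    logdet_x = 2.0 * float(np.sum(np.log(np.diag(cf2[0]))))
    P = Vinv - ViX @ cho_solve(cf2, ViX.T, check_finite=False)
    P = (P + P.T) / 2.0
    Py = P @ y
    ll = -0.5 * (logdet_v + logdet_x + float(y @ Py))
    return SimpleNamespace(ll=ll, P=P, Py=Py)


def reml_loglik(theta: Sequence[float], y: np.ndarray, X: np.ndarray,
                S_list: Sequence) -> float:
    """Restricted log-likelihood (up to constant) at the given components.

    ``theta`` holds the f effect-type variances followed by the residual
    variance, all strictly positive.
    """
    theta = np.asarray(theta, dtype=float)
    if (theta <= 0).any():
        raise ValueError("all variance components must be > 0")
    mats = _as_matrices(S_list)
    if len(theta) != len(mats) + 1:
        raise ValueError("theta must hold f component variances + residual")
    try:
        return _reml_pieces(theta, np.asarray(y, float), np.asarray(X, float),
                            mats).ll
    except LinAlgError as err:
        raise ValueError("V is not positive definite at theta") from err


def _derivatives(pieces: SimpleNamespace, theta: np.ndarray,
                 S_list: list[np.ndarray], n: int):
    """Gradient, AI matrix and the EM-REML proposal at the current point."""
    f = len(S_list)
    P, Py = pieces.P, pieces.Py
    grad = np.empty(f + 1)
    em = np.empty(f + 1)
    vmat = np.empty((f + 1, n))
    for i, S in enumerate(S_list):
        tr_ps = float(np.vdot(P, S))  # = tr(P S) for symmetric P, S
        u = S @ Py
        quad = float(Py @ u)
        grad[i] = -0.5 * (tr_ps - quad)
        em[i] = theta[i] + theta[i] ** 2 * (quad - tr_ps) / n
        vmat[i] = u
    tr_p = float(np.trace(P))
    quad_e = float(Py @ Py)
    grad[-1] = -0.5 * (tr_p - quad_e)
    em[-1] = theta[-1] + theta[-1] ** 2 * (quad_e - tr_p) / n
    vmat[-1] = Py
    pv = vmat @ P
    ai = 0.5 * (pv @ vmat.T)
    ai = (ai + ai.T) / 2.0
    return grad, ai, em


def fit_greml(
    y: np.ndarray,
    X: np.ndarray,
    S_list: Sequence,
    effect_labels: Sequence[str] | None = None,
    *,
    max_iter: int = 200,
    tol: float = 1e-6,
    var_floor_frac: float = 1e-6,
    start: Sequence[float] | None = None,
    em_only: bool = False,
) -> VarianceComponentEstimate:
    """Estimate the variance components of the multi-component mixed model.

    Parameters
    ----------
    y, X
        Phenotype vector and fixed-effect design (one row per individual).
    S_list
        Normalized relationship matrices (GRM objects or arrays), aligned
        to ``y``.
    effect_labels
        Names for the components; defaults to V1..Vf.
    start
        Optional starting values (f+1,); default splits var(y) equally.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    mats = _as_matrices(S_list)
    labels = tuple(effect_labels) if effect_labels is not None else tuple(
        f"V{i + 1}" for i in range(len(mats))
    )
    n = y.size
    f = len(mats)
    c = X.shape[1]
    if X.shape[0] != n:
        raise ValueError("X rows must match y")
    if n < f + c + 2:
        raise ValueError(f"n={n} too small for f={f} components and c={c} "
                         "fixed effects")
    eye = np.eye(n)
    if all(np.abs(S - eye).max() < 1e-9 for S in mats):
        raise ValueError(
            "model is non-identifiable: every relationship matrix is the "
            "identity, so genetic and residual variances cannot be separated"
        )
    var_y = float(np.var(y))
    if var_y <= 0:
        raise ValueError("y has zero variance")
    floor = max(var_floor_frac * var_y, 1e-12)
    if start is not None:
        theta = np.asarray(start, dtype=float).copy()
        if theta.shape != (f + 1,):
            raise ValueError("start must have length f+1")
    else:
        theta = np.full(f + 1, var_y / (f + 1))
    theta = np.maximum(theta, floor)

    pieces = _reml_pieces(theta, y, X, mats)
    converged = False
    it = 0
    ai = None
    stall = 0
    for it in range(1, max_iter + 1):
        grad, ai, em = _derivatives(pieces, theta, mats, n)
        # active set: components pinned at the floor with a gradient pushing
        # further down are excluded from the Newton system
        pinned = (theta <= floor * (1 + 1e-9)) & (grad < 0)
        free = ~pinned
        decrement = np.inf
        cand = None
        cand_pieces = None
        if free.any() and not em_only:
            ai_free = ai[np.ix_(free, free)]
            scale = float(np.abs(np.diag(ai_free)).mean()) or 1.0
            # Levenberg-Marquardt escalation: the undamped AI (Newton) step
            # first, then increasingly damped steps when the AI system is
            # ill-conditioned (near-collinear relationship matrices); each
            # direction gets a short step-halving line search
            for lam in (0.0, 1e-4, 1e-2, 1.0, 10.0):
                try:
                    delta_f = np.linalg.solve(
                        ai_free + lam * scale * np.eye(ai_free.shape[0]),
                        grad[free])
                except np.linalg.LinAlgError:
                    continue
                if lam == 0.0:
                    decrement = 0.5 * float(grad[free] @ delta_f)
                delta = np.zeros_like(theta)
                delta[free] = delta_f
                fracs = (1.0, 0.5, 0.25) if lam == 0.0 else (1.0, 0.5)
                for frac in fracs:
                    trial = np.maximum(theta + frac * delta, floor)
                    try:
                        trial_pieces = _reml_pieces(trial, y, X, mats)
                    except LinAlgError:
                        continue
                    if trial_pieces.ll >= pieces.ll - 1e-10:
                        cand, cand_pieces = trial, trial_pieces
                        break
                if cand is not None:
                    break
        if cand is None:  # EM fallback: monotone
            cand = np.maximum(em, floor)
            try:
                cand_pieces = _reml_pieces(cand, y, X, mats)
            except LinAlgError:
                logger.warning("EM step left the PD region; stopping early")
                break
        delta_ll = cand_pieces.ll - pieces.ll
        theta, pieces = cand, cand_pieces
        # a small likelihood change alone is not convergence: on a flat
        # ridge the Newton decrement stays large while the likelihood
        # barely moves, and stopping there would leave the estimate at an
        # arbitrary ridge point
        if abs(delta_ll) < tol and (decrement < max(100 * tol, 1e-4)
                                    or not np.isfinite(decrement)):
            converged = True
            break
        # budget guard: a long run of negligible likelihood changes means
        # the surface is flat in every remaining direction worth taking;
        # stop early (convergence status reflects the Newton decrement)
        stall = stall + 1 if abs(delta_ll) < tol else 0
        if stall >= 8:
            converged = bool(decrement < max(100 * tol, 1e-4))
            break
    if not converged:
        logger.warning("GREML did not converge in %d iterations", it)

    boundary = theta <= floor * (1 + 1e-9)
    ai_cov = None
    if ai is not None:
        try:
            ai_cov = np.linalg.inv(ai)
        except np.linalg.LinAlgError:
            ai_cov = None
    return VarianceComponentEstimate(
        effect_labels=labels,
        sigma2=theta[:-1].copy(),
        sigma2_e=float(theta[-1]),
        loglik=pieces.ll,
        n_iterations=it,
        converged=converged,
        boundary_flags=boundary,
        ai_covariance=ai_cov,
        diag_means=np.array([float(np.diag(S).mean()) for S in mats]),
    )


def heritability_table(vce: VarianceComponentEstimate,
                       model: ModelSpec | None = None):
    """One row per effect type plus a Total row (sum of component h2)."""
    import pandas as pd

    labels = list(model.labels) if model is not None else list(vce.effect_labels)
    h = vce.heritability_by_label
    s = dict(zip(vce.effect_labels, vce.sigma2))
    rows = [(lab, s.get(lab, 0.0), h.get(lab, 0.0)) for lab in labels]
    rows.append(("Total", float(vce.sigma2.sum()), vce.total_heritability))
    return pd.DataFrame(rows, columns=["effect_type", "sigma2", "heritability"]
                        ).set_index("effect_type")
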