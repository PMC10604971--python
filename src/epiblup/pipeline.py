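"""10-fold cross-validation, predictive ability, and two-stage model selection.

Predictive ability of a model is the mean over folds of the Pearson
correlation between predicted total genetic values and the observed
phenotypes of the validation individuals (never the pooled correlation).
Model selection runs in two stages: an initial screen keeps every effect
type whose full-model heritability estimate exceeds 1%, and the final stage
picks, among the cross-validated candidate models, the one with the highest
predictive ability and the smallest number of effect types.  Accuracies are
compared at 3-decimal precision (the reporting precision), which is what
turns near-identical candidates into ties resolved by model size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import SNP_EPISTASIS_COMPOSITIONS, EffectType
from .gblup import gblup_components, total_genetic_value
from .greml import ModelSpec, VarianceComponentEstimate, fit_greml

logger = logging.getLogger(__name__)

__all__ = [
    "FoldAssignment",
    "PredictionResult",
    "make_folds",
    "cross_validate",
    "percent_change",
    "effect_type_catalog",
    "initial_model_selection",
    "candidate_models",
    "final_model_selection",
    "run_model_selection",
    "SelectionResult",
    "make_report",
]


@dataclass
class FoldAssignment:
    """Seeded k-fold partition: folds 1..k-1 of size floor(n/k), fold k the rest."""

    seed: int
    fold_index: np.ndarray  # 1-based fold label per individual
    k: int

    @property
    def n(self) -> int:
        return self.fold_index.size

    @property
    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.fold_index, minlength=self.k + 1)[1:]

    def indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)


def make_folds(ids: Sequence | int, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Randomly partition individuals into k validation folds.

    The first k-1 folds have floor(n/k) individuals each; the last takes
    the remainder (so it is the largest when n is not a multiple of k).
    """
    n = ids if isinstance(ids, (int, np.integer)) else len(ids)
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} individuals")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base = n // k
    fold_index = np.empty(n, dtype=int)
    for j in range(k):
        lo = j * base
        hi = (j + 1) * base if j < k - 1 else n
        fold_index[perm[lo:hi]] = j + 1
    return FoldAssignment(seed=seed, fold_index=fold_index, k=k)


@dataclass
class PredictionResult:
    """Cross-validation outcome for one model."""

    model_name: str
    fold_correlations: np.ndarray  # nan where undefined
    predictions: np.ndarray        # total predicted genetic value, all individuals
    fold_assignment: FoldAssignment
    fold_heritabilities: list[dict[str, float]] = field(default_factory=list)
    fold_vce: list[VarianceComponentEstimate] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        r = self.fold_correlations
        return float(np.nanmean(r))

    @property
    def sd_accuracy(self) -> float:
        r = self.fold_correlations[~np.isnan(self.fold_correlations)]
        return float(np.std(r, ddof=1)) if r.size > 1 else float("nan")


def cross_validate(
    y: np.ndarray,
    X: np.ndarray,
    S_list: Sequence,
    effect_labels: Sequence[str],
    folds: FoldAssignment,
    *,
    adjust_fixed: bool = False,
    model_name: str | None = None,
    reml_opts: Mapping | None = None,
) -> PredictionResult:
    """k-fold cross-validated predictive ability of one model.

    Variance components are re-estimated within every training fold;
    validation phenotypes are never seen by REML or BLUP.  Folds where the
    correlation is undefined (constant predictions or phenotypes) are
    recorded as missing with a warning and dropped from the average.
    """
    from .greml import _as_matrices

    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    mats = _as_matrices(S_list)
    opts = dict(reml_opts or {})
    n = y.size
    name = model_name or "+".join(effect_labels)
    corr = np.full(folds.k, np.nan)
    preds = np.full(n, np.nan)
    herits: list[dict[str, float]] = []
    vces: list[VarianceComponentEstimate] = []
    for kf in range(1, folds.k + 1):
        val = folds.indices(kf)
        train = np.flatnonzero(folds.fold_index != kf)
        sub = [M[np.ix_(train, train)] for M in mats]
        vce = fit_greml(y[train], X[train], sub, effect_labels=effect_labels,
                        **opts)
        cp = gblup_components(y[train], X[train], mats, vce, train, val)
        ghat = total_genetic_value(cp)
        if adjust_fixed:
            ghat = ghat + X[val] @ cp.fixed_effects
        preds[val] = ghat
        y0 = y[val]
        if np.std(ghat) == 0 or np.std(y0) == 0:
            warnings.warn(f"fold {kf}: correlation undefined (constant values); "
                          "recorded as missing", stacklevel=2)
        else:
            corr[kf - 1] = float(np.corrcoef(ghat, y0)[0, 1])
        herits.append(vce.heritability_by_label)
        vces.append(vce)
    return PredictionResult(
        model_name=name,
        fold_correlations=corr,
        predictions=preds,
        fold_assignment=folds,
        fold_heritabilities=herits,
        fold_vce=vces,
    )


def percent_change(r_model: float, r_base: float, digits: int = 2) -> float:
    """Accuracy change of a model over a baseline, in percent (rounded)."""
    if r_base == 0:
        raise ValueError("baseline accuracy is zero; percent change undefined")
    return round(100.0 * (r_model - r_base) / r_base, digits)


def effect_type_catalog(max_order: int = 4) -> list[EffectType]:
    """All SNP/epistasis effect types up to ``max_order`` in canonical order."""
    if not 1 <= max_order <= 4:
        raise ValueError("max_order must be in 1..4")
    return [EffectType(a, d) for a, d in SNP_EPISTASIS_COMPOSITIONS
            if a + d <= max_order]


def initial_model_selection(
    vce: VarianceComponentEstimate, threshold: float = 0.01
) -> ModelSpec:
    """Keep effect types whose full-model heritability exceeds the threshold.

    The comparison is strict (> threshold); no effect type is special-cased.
    """
    kept = [lab for lab, h in vce.heritability_by_label.items() if h > threshold]
    if not kept:
        raise ValueError(
            f"no effect type has heritability above {threshold}; "
            "the initial model is empty"
        )
    ets = sorted((EffectType.from_label(lab) for lab in kept),
                 key=lambda e: e.subscript)
    return ModelSpec(tuple(ets))


def candidate_models(initial: ModelSpec) -> list[ModelSpec]:
    """Candidate models derived from the initial screen.

    Nested prefixes of the initial model in subscript order, plus — for
    every prefix containing the SNP dominance term — the same model with D
    dropped (trait comparisons routinely find the best model without D,
    e.g. an A+AD-type model, so dominance must be droppable rather than
    carried along by nesting).
    """
    ets = sorted(initial.effect_types, key=lambda e: e.subscript)
    d_term = EffectType(0, 1)
    cands: list[ModelSpec] = []
    seen: set[tuple] = set()
    for j in range(len(ets)):
        for drop_d in (False, True):
            chosen = tuple(et for et in ets[: j + 1]
                           if not (drop_d and et == d_term))
            if not chosen or chosen in seen:
                continue
            seen.add(chosen)
            cands.append(ModelSpec(chosen))
    return cands


def final_model_selection(
    candidates: Sequence[ModelSpec],
    cv_results: Sequence[PredictionResult | float],
    digits: int = 3,
) -> ModelSpec:
    """Highest predictive ability, then fewest effect types, then subscript order.

    Accuracies are compared after rounding to ``digits`` decimals so that
    models indistinguishable at reporting precision count as ties and the
    smaller model wins.
    """
    if len(candidates) != len(cv_results):
        raise ValueError("need one CV result per candidate")
    if not candidates:
        raise ValueError("no candidate models")

    def acc(r) -> float:
        return r.mean_accuracy if isinstance(r, PredictionResult) else float(r)

    def key(i: int):
        ms = candidates[i]
        subs = tuple(sorted(et.subscript for et in ms.effect_types))
        return (-round(acc(cv_results[i]), digits), ms.f, subs)

    best = min(range(len(candidates)), key=key)
    return candidates[best]


@dataclass
class SelectionResult:
    """End-to-end two-stage selection output."""

    full_vce: VarianceComponentEstimate
    initial_model: ModelSpec
    candidates: list[ModelSpec]
    cv_results: dict[str, PredictionResult]
    final_model: ModelSpec


def run_model_selection(
    y: np.ndarray,
    X: np.ndarray,
    S_by_label: Mapping[str, np.ndarray],
    folds: FoldAssignment,
    *,
    threshold: float = 0.01,
    max_order: int = 4,
    reml_opts: Mapping | None = None,
    cv_reml_opts: Mapping | None = None,
) -> SelectionResult:
    """Full-model GREML screen, then cross-validated final selection.

    ``S_by_label`` must provide a relationship matrix for every SNP and
    epistasis effect type up to ``max_order`` (the haplotype component, if
    present, enters candidate models only after the SNP/epistasis screen).
    All candidates are evaluated under the same fold assignment.
    ``cv_reml_opts`` lets the many per-fold refits run under a smaller
    iteration budget than the screening fit (defaults to ``reml_opts``).
    """
    full = effect_type_catalog(max_order)
    missing = [et.label for et in full if et.label not in S_by_label]
    if missing:
        raise ValueError(f"missing relationship matrices for: {missing}")
    labels = [et.label for et in full]
    opts = dict(reml_opts or {})
    cv_opts = dict(cv_reml_opts) if cv_reml_opts is not None else opts
    full_vce = fit_greml(y, X, [S_by_label[l] for l in labels],
                         effect_labels=labels, **opts)
    initial = initial_model_selection(full_vce, threshold=threshold)
    cands = candidate_models(initial)
    results: dict[str, PredictionResult] = {}
    for ms in cands:
        results[ms.name] = cross_validate(
            y, X, [S_by_label[l] for l in ms.labels], ms.labels, folds,
            model_name=ms.name, reml_opts=cv_opts,
        )
    final = final_model_selection(cands, [results[ms.name] for ms in cands])
    return SelectionResult(
        full_vce=full_vce,
        initial_model=initial,
        candidates=cands,
        cv_results=results,
        final_model=final,
    )


def make_report(
    full_vce: VarianceComponentEstimate | None = None,
    cv_results: Mapping[str, PredictionResult] | None = None,
    base_model: str | None = None,
    threshold: float = 0.01,
    out_dir=None,
) -> dict[str, pd.DataFrame]:
    """Assemble report tables.

    * ``heritability`` - full-model heritability per effect type, a Total
      row, and the initial model implied by the screening threshold.
    * ``accuracy`` - predictive ability per model with percent increase
      over ``base_model``.
    * ``fold_heritability`` - per-model heritabilities averaged over folds.

    Tables are written as TSV files when ``out_dir`` is given.
    """
    tables: dict[str, pd.DataFrame] = {}
    if full_vce is not None:
        h = full_vce.heritability_by_label
        rows = [(lab, val) for lab, val in h.items()]
        rows.append(("Total", full_vce.total_heritability))
        try:
            initial = initial_model_selection(full_vce, threshold).name
        except ValueError:
            initial = "(none)"
        rows.append(("Initial model", initial))
        tables["heritability"] = pd.DataFrame(
            rows, columns=["effect_type", "value"]).set_index("effect_type")
    if cv_results:
        base_acc = None
        if base_model is not None:
            if base_model not in cv_results:
                warnings.warn(f"baseline model {base_model!r} missing from "
                              "results; percent increases omitted", stacklevel=2)
            else:
                base_acc = cv_results[base_model].mean_accuracy
        rows = []
        for name, res in cv_results.items():
            inc = (percent_change(res.mean_accuracy, base_acc)
                   if base_acc not in (None, 0) and name != base_model else
                   (0.0 if name == base_model and base_acc is not None else np.nan))
            rows.append((name, res.mean_accuracy, res.sd_accuracy, inc))
        tables["accuracy"] = pd.DataFrame(
            rows, columns=["model", "accuracy", "sd", "pct_increase_vs_base"]
        ).set_index("model")
        fold_rows = {}
        for name, res in cv_results.items():
            if not res.fold_heritabilities:
                continue
            labs = res.fold_heritabilities[0].keys()
            fold_rows[name] = {
                lab: float(np.mean([fh[lab] for fh in res.fold_heritabilities]))
                for lab in labs
            }
        if fold_rows:
            df = pd.DataFrame(fold_rows)
            df.loc["Total"] = df.sum(axis=0)
            tables["fold_heritability"] = df
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t")
    return tables
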