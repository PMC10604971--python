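"""Genomic relationship matrices for SNP and epistasis effect types.

First-order matrices use the classical codings: additive = mean-centered
alt-allele dosage, dominance = mean-centered heterozygosity indicator.
Under Hardy-Weinberg proportions these keep the additive and dominance
components orthogonal.

Epistasis matrices of order 2-4 are built two ways:

* **Approximate (Hadamard)** - elementwise products of the normalized
  first-order matrices.  Fast, but the product of a locus with itself
  contributes same-locus ("intra-locus") terms that do not correspond to
  any real interaction.
* **Exact** - the Gram matrix of the interaction design restricted to
  *distinct* loci only.  For an individual pair (x, y) write the per-locus
  additive and dominance products a_k = w_xk * w_yk and d_k = h_xk * h_yk.
  The exact entry for a composition with alpha additive and delta dominance
  factors is the sum of prod(a over S_A) * prod(d over S_D) over all
  disjoint unordered locus sets of sizes alpha and delta.  That sum is the
  coefficient of t^alpha * u^delta in prod_k (1 + t a_k + u d_k), which we
  extract with a truncated exp(log(.)) expansion in the mixed power sums
  P(s, t) = sum_k a_k^s d_k^t - each P(s, t) is a single Gram matrix of
  elementwise code powers, so the whole construction needs only a handful
  of n x n matrix products regardless of the number of loci.  For purely
  additive (or purely dominance) compositions the expansion reduces to
  Newton's identities for elementary symmetric polynomials; for mixed
  compositions it is the inclusion-exclusion expansion over shared loci.

A brute-force builder that enumerates every distinct-locus tuple serves as
the verification oracle at small m.

Every matrix is scaled to mean diagonal 1 so variance components of
heterogeneous effect types live on a common (phenotypic-fraction) scale.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core_data import GRM, EffectType, GenotypeData

__all__ = [
    "CodeMatrix",
    "center_additive",
    "center_dominance",
    "grm_first_order",
    "grm_epistasis_hadamard",
    "grm_epistasis_exact",
    "grm_epistasis_bruteforce",
    "normalize_grm",
    "build_snp_grms",
]


@dataclass
class CodeMatrix:
    """Centered per-locus codes (columns sum to zero)."""

    kind: str  # "additive" | "dominance"
    values: np.ndarray  # (n, m)
    snp_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "dominance"):
            raise ValueError("kind must be 'additive' or 'dominance'")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("values shape does not match ids")


def center_additive(gd: GenotypeData) -> CodeMatrix:
    """Additive codes: dosage centered on its observed mean (x - 2p)."""
    vals = gd.dosage - gd.dosage.mean(axis=0, keepdims=True)
    return CodeMatrix("additive", vals, gd.variants["id"].tolist(),
                      list(gd.sample_ids))


def center_dominance(gd: GenotypeData) -> CodeMatrix:
    """Dominance codes: heterozygosity indicator centered on its mean."""
    het = (np.rint(gd.dosage) == 1).astype(float)
    vals = het - het.mean(axis=0, keepdims=True)
    return CodeMatrix("dominance", vals, gd.variants["id"].tolist(),
                      list(gd.sample_ids))


def normalize_grm(grm: GRM) -> GRM:
    """Scale a GRM to mean diagonal 1; records the divisor applied."""
    md = float(np.diag(grm.matrix).mean())
    if not np.isfinite(md) or md <= 0:
        raise ValueError(
            f"cannot normalize GRM '{grm.label}': mean diagonal {md!r} is not positive"
        )
    return GRM(
        label=grm.label,
        matrix=grm.matrix / md,
        sample_ids=list(grm.sample_ids),
        normalizer=md if np.isnan(grm.normalizer) else grm.normalizer * md,
        method=grm.method,
    )


def grm_first_order(cm: CodeMatrix) -> GRM:
    """Additive or dominance GRM: Gram matrix of the codes, mean diagonal 1."""
    if cm.values.shape[1] < 1:
        raise ValueError("code matrix has no SNPs")
    raw = cm.values @ cm.values.T
    label = "A" if cm.kind == "additive" else "D"
    return normalize_grm(GRM(label=label, matrix=raw,
                             sample_ids=list(cm.sample_ids),
                             method="first_order"))


def _check_epistasis_order(et: EffectType) -> None:
    if et.is_haplotype or not 2 <= et.order <= 4:
        raise ValueError(f"epistasis effect type must have order 2-4, got {et!r}")


def grm_epistasis_hadamard(
    et: EffectType,
    grm_A: GRM | None = None,
    grm_D: GRM | None = None,
) -> GRM:
    """Approximate epistasis GRM by repeated Hadamard products.

    ``grm_A``/``grm_D`` must be pre-normalized first-order matrices of the
    same samples; the elementwise product is renormalized to mean diagonal 1.
    """
    _check_epistasis_order(et)
    if et.n_additive and grm_A is None:
        raise ValueError("composition needs the additive GRM")
    if et.n_dominance and grm_D is None:
        raise ValueError("composition needs the dominance GRM")
    base = grm_A if et.n_additive else grm_D
    ids = list(base.sample_ids)
    M = np.ones_like(base.matrix)
    if et.n_additive:
        M = M * grm_A.matrix ** et.n_additive
    if et.n_dominance:
        if et.n_additive and grm_D.sample_ids != ids:
            raise ValueError("A and D GRMs cover different samples")
        M = M * grm_D.matrix ** et.n_dominance
    return normalize_grm(GRM(label=et.label, matrix=M, sample_ids=ids,
                             method="hadamard_approx"))


def _exact_raw(W: np.ndarray | None, H: np.ndarray | None,
               n_add: int, n_dom: int) -> np.ndarray:
    """Unnormalized exact epistasis Gram matrix over distinct loci.

    Coefficient of t^n_add * u^n_dom in prod_k (1 + t a_k + u d_k),
    extracted through a truncated bivariate exp(log) series whose inputs
    are the mixed power-sum Gram matrices P(s, t).
    """
    order = n_add + n_dom
    ref = W if W is not None else H
    n = ref.shape[0]

    P: dict[tuple[int, int], np.ndarray] = {}
    for s in range(n_add + 1):
        for t in range(n_dom + 1):
            if not 1 <= s + t <= order:
                continue
            U = np.ones((n, ref.shape[1]))
            if s:
                U = U * W ** s
            if t:
                U = U * H ** t
            P[(s, t)] = U @ U.T

    # log-series: L = sum_r (-1)^(r+1)/r * sum_{j+l=r} C(r,j) t^j u^l P(j,l)
    L: dict[tuple[int, int], np.ndarray] = {}
    for r in range(1, order + 1):
        c_r = (-1.0) ** (r + 1) / r
        for j in range(r + 1):
            l = r - j
            if j > n_add or l > n_dom:
                continue
            term = c_r * math.comb(r, j) * P[(j, l)]
            L[(j, l)] = L[(j, l)] + term if (j, l) in L else term

    # exp-series truncated at (n_add, n_dom): E = sum_k L^k / k!
    def polymul(a: dict, b: dict) -> dict:
        out: dict[tuple[int, int], np.ndarray] = {}
        for (j1, l1), va in a.items():
            for (j2, l2), vb in b.items():
                j, l = j1 + j2, l1 + l2
                if j > n_add or l > n_dom:
                    continue
                prod = va * vb
                out[(j, l)] = out[(j, l)] + prod if (j, l) in out else prod
        return out

    total: dict[tuple[int, int], np.ndarray] = {}
    term: dict[tuple[int, int], np.ndarray] = {(0, 0): np.ones((n, n))}
    for k in range(1, order + 1):
        term = polymul(term, L)
        if not term:
            break
        scaled = {key: v / k for key, v in term.items()}
        term = scaled
        for key, v in scaled.items():
            total[key] = total[key] + v if key in total else v

    M = total.get((n_add, n_dom))
    if M is None:
        M = np.zeros((n, n))
    return (M + M.T) / 2.0


def grm_epistasis_exact(
    et: EffectType,
    W: CodeMatrix | None = None,
    H: CodeMatrix | None = None,
) -> GRM:
    """Exact epistasis GRM: intra-locus (same-locus) terms removed.

    When fewer loci than the interaction order exist no distinct-locus
    tuple can be formed: an all-zero unnormalized GRM is returned with a
    warning, and :func:`normalize_grm` on it raises.
    """
    _check_epistasis_order(et)
    if et.n_additive and W is None:
        raise ValueError("composition needs additive codes W")
    if et.n_dominance and H is None:
        raise ValueError("composition needs dominance codes H")
    ref = W if et.n_additive else H
    if W is not None and H is not None and W.sample_ids != H.sample_ids:
        raise ValueError("W and H cover different samples")
    ids = list(ref.sample_ids)
    m = ref.values.shape[1]
    if m < et.order:
        warnings.warn(
            f"only {m} loci available for order-{et.order} composition "
            f"{et.label}: no distinct-locus tuple exists, returning a zero matrix",
            stacklevel=2,
        )
        n = len(ids)
        return GRM(label=et.label, matrix=np.zeros((n, n)), sample_ids=ids,
                   method="exact")
    raw = _exact_raw(W.values if W is not None else None,
                     H.values if H is not None else None,
                     et.n_additive, et.n_dominance)
    return normalize_grm(GRM(label=et.label, matrix=raw, sample_ids=ids,
                             method="exact"))


def grm_epistasis_bruteforce(
    et: EffectType,
    W: CodeMatrix | None = None,
    H: CodeMatrix | None = None,
) -> GRM:
    """Oracle: explicit tuple-level interaction design, one column per
    unordered set of distinct loci with assigned A/D roles."""
    _check_epistasis_order(et)
    ref = W if et.n_additive else H
    m = ref.values.shape[1]
    n = ref.values.shape[0]
    if m > 30:
        raise ValueError("brute-force builder is guarded to m <= 30")
    cols = []
    for sa in itertools.combinations(range(m), et.n_additive):
        rest = [j for j in range(m) if j not in sa]
        for sd in itertools.combinations(rest, et.n_dominance):
            col = np.ones(n)
            for j in sa:
                col = col * W.values[:, j]
            for j in sd:
                col = col * H.values[:, j]
            cols.append(col)
    ids = list(ref.sample_ids)
    if not cols:
        warnings.warn("no distinct-locus tuple exists, returning a zero matrix",
                      stacklevel=2)
        return GRM(label=et.label, matrix=np.zeros((n, n)), sample_ids=ids,
                   method="bruteforce")
    C = np.column_stack(cols)
    return normalize_grm(GRM(label=et.label, matrix=C @ C.T, sample_ids=ids,
                             method="bruteforce"))


def build_snp_grms(
    gd: GenotypeData,
    effect_types: list[EffectType],
    method: str = "exact",
) -> dict[str, GRM]:
    """Build the requested SNP/epistasis GRMs from a genotype panel.

    ``method`` selects ``exact`` or ``hadamard`` for the order>=2 types;
    first-order A and D are always the code Gram matrices.
    """
    if method not in ("exact", "hadamard"):
        raise ValueError("method must be 'exact' or 'hadamard'")
    W = center_additive(gd)
    H = center_dominance(gd)
    out: dict[str, GRM] = {}
    first: dict[str, GRM] = {}
    need_first = method == "hadamard" or any(et.order == 1 for et in effect_types)
    if need_first:
        first["A"] = grm_first_order(W)
        first["D"] = grm_first_order(H)
    for et in effect_types:
        if et.is_haplotype:
            raise ValueError("haplotype GRMs are built by the haplotypes module")
        if et.order == 1:
            out[et.label] = first["A" if et.n_additive else "D"]
        elif method == "exact":
            out[et.label] = grm_epistasis_exact(et, W, H)
        else:
            out[et.label] = grm_epistasis_hadamard(et, first["A"], first["D"])
    return out
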