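"""Genotype, phenotype and relationship-matrix containers and I/O.

The containers here are deliberately plain: a phased genotype panel
(:class:`GenotypeData`), a one-record-per-individual phenotype table
(:class:`PhenotypeTable`), a full-rank fixed-effect design matrix
(:class:`DesignMatrix`), and a named genomic relationship matrix
(:class:`GRM`).  Relationship matrices are written in the GCTA binary
dialect (``.grm.bin`` float32 lower triangle + ``.grm.id``) with a JSON
metadata sidecar so they interoperate with existing REML tools.

Effect types (SNP additive ``A``, dominance ``D``, epistasis compositions
``AA`` … ``DDDD`` and the haplotype additive component ``H``) are described
by :class:`EffectType`; the canonical ordering of the 14 SNP/epistasis
compositions (order 1 to 4, additive factors before dominance factors
within an order) defines each type's subscript, with ``H`` as subscript 15.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EffectType",
    "GenotypeData",
    "PhenotypeTable",
    "DesignMatrix",
    "GRM",
    "read_genotypes",
    "filter_by_maf",
    "read_phenotypes",
    "build_design_matrix",
    "write_grm",
    "read_grm",
]

#: (n_additive, n_dominance) for subscripts 1..14: orders 1..4, within an
#: order additive factors first.
SNP_EPISTASIS_COMPOSITIONS: tuple[tuple[int, int], ...] = (
    (1, 0), (0, 1),
    (2, 0), (1, 1), (0, 2),
    (3, 0), (2, 1), (1, 2), (0, 3),
    (4, 0), (3, 1), (2, 2), (1, 3), (0, 4),
)


@dataclass(frozen=True)
class EffectType:
    """One variance component: a SNP/epistasis composition or the haplotype term.

    ``n_additive`` and ``n_dominance`` count the additive and dominance
    factors of the interaction (``AA`` has ``n_additive=2``); the haplotype
    additive component is flagged by ``is_haplotype`` and carries no factor
    counts.
    """

    n_additive: int = 0
    n_dominance: int = 0
    is_haplotype: bool = False

    def __post_init__(self) -> None:
        if self.is_haplotype:
            if self.n_additive or self.n_dominance:
                raise ValueError("haplotype effect type carries no A/D factors")
            return
        if self.n_additive < 0 or self.n_dominance < 0:
            raise ValueError("factor counts must be non-negative")
        if not 1 <= self.order <= 4:
            raise ValueError(
                f"effect order must be between 1 and 4, got {self.order}"
            )

    @property
    def order(self) -> int:
        return self.n_additive + self.n_dominance

    @property
    def label(self) -> str:
        if self.is_haplotype:
            return "H"
        return "A" * self.n_additive + "D" * self.n_dominance

    @property
    def display(self) -> str:
        """Human-readable name, e.g. ``A x A x D``."""
        if self.is_haplotype:
            return "H"
        return " x ".join(self.label)

    @property
    def subscript(self) -> int:
        """Position in the canonical component ordering (1..15)."""
        if self.is_haplotype:
            return 15
        return SNP_EPISTASIS_COMPOSITIONS.index(
            (self.n_additive, self.n_dominance)
        ) + 1

    @classmethod
    def from_label(cls, label: str) -> "EffectType":
        s = label.strip().upper().replace("×", "").replace("X", "")
        s = s.replace("*", "").replace(" ", "")
        if s == "H":
            return cls(is_haplotype=True)
        if not s or set(s) - {"A", "D"}:
            raise ValueError(f"cannot parse effect type label {label!r}")
        return cls(n_additive=s.count("A"), n_dominance=s.count("D"))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


# ---------------------------------------------------------------------------
# Genotypes


@dataclass
class GenotypeData:
    """Phased biallelic genotype panel.

    Attributes
    ----------
    sample_ids
        Unique sample identifiers, length ``n``.
    variants
        Per-SNP records with columns ``chrom, pos, id, ref, alt`` sorted by
        (chrom, pos); positions are 1-based.
    haplotypes
        ``(n, m, 2)`` int8 array of phased allele indicators (0=ref, 1=alt,
        -1=missing).
    dosage
        ``(n, m)`` alt-allele counts; fractional only where mean-imputed.
    phased
        ``(m,)`` bool, True where every call at the SNP is phased.
    alt_freq
        ``(m,)`` alt-allele frequency computed from non-missing calls.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    haplotypes: np.ndarray
    dosage: np.ndarray
    phased: np.ndarray | None = None
    alt_freq: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, m = len(self.sample_ids), len(self.variants)
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if self.haplotypes.shape != (n, m, 2):
            raise ValueError("haplotypes must have shape (n, m, 2)")
        if self.dosage.shape != (n, m):
            raise ValueError("dosage must have shape (n, m)")
        if self.phased is None:
            self.phased = np.ones(m, dtype=bool)
        # keep variants sorted by (chrom, pos)
        order = np.lexsort(
            (self.variants["pos"].to_numpy(),
             self.variants["chrom"].astype(str).to_numpy())
        )
        if not np.array_equal(order, np.arange(m)):
            self.variants = self.variants.iloc[order].reset_index(drop=True)
            self.haplotypes = self.haplotypes[:, order, :]
            self.dosage = self.dosage[:, order]
            self.phased = self.phased[order]
            if self.alt_freq is not None:
                self.alt_freq = self.alt_freq[order]
        if self.alt_freq is None:
            valid = self.haplotypes >= 0
            alt = np.where(valid, self.haplotypes, 0).sum(axis=(0, 2))
            denom = valid.sum(axis=(0, 2))
            with np.errstate(invalid="ignore"):
                self.alt_freq = np.where(denom > 0, alt / np.maximum(denom, 1), 0.0)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.alt_freq, 1.0 - self.alt_freq)

    def subset_variants(self, index: np.ndarray) -> "GenotypeData":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeData(
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[index].reset_index(drop=True),
            haplotypes=self.haplotypes[:, index, :],
            dosage=self.dosage[:, index],
            phased=self.phased[index],
            alt_freq=self.alt_freq[index],
        )


def read_genotypes(path: str | Path, *, impute_missing: bool = False) -> GenotypeData:
    """Read phased biallelic SNPs from a VCF into a :class:`GenotypeData`.

    Multiallelic or non-SNP records raise; missing genotypes raise unless
    ``impute_missing`` is set, in which case the dosage is mean-imputed and
    the SNP stays unusable for haplotype analysis (its haplotype codes keep
    the -1 missing marker).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    rows: list[tuple] = []
    haps: list[np.ndarray] = []
    phased_flags: list[bool] = []
    for var in vcf:
        name = f"{var.CHROM}:{var.POS} ({var.ID or '.'})"
        if len(var.ALT) != 1:
            raise ValueError(f"multiallelic record not supported: {name}")
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            raise ValueError(f"non-SNP record not supported: {name}")
        g = np.asarray(var.genotypes, dtype=object)
        alleles = np.array([[int(row[0]), int(row[1])] for row in g], dtype=np.int8)
        phased = bool(all(bool(row[2]) for row in g))
        missing = (alleles < 0).any(axis=1)
        if missing.any() and not impute_missing:
            raise ValueError(
                f"missing genotype at {name}; pass impute_missing=True "
                "to mean-impute dosages"
            )
        alleles[missing] = -1
        haps.append(alleles)
        phased_flags.append(phased)
        rows.append((var.CHROM, var.POS, var.ID or f"{var.CHROM}_{var.POS}",
                     var.REF, var.ALT[0]))
    if not rows:
        raise ValueError(f"no variant records in {path}")
    hap_arr = np.stack(haps, axis=1)  # (n, m, 2)
    dosage = hap_arr.clip(min=0).sum(axis=2).astype(float)
    miss_mask = (hap_arr < 0).any(axis=2)
    if miss_mask.any():
        for k in np.flatnonzero(miss_mask.any(axis=0)):
            obs = ~miss_mask[:, k]
            dosage[~obs, k] = dosage[obs, k].mean() if obs.any() else 0.0
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    return GenotypeData(
        sample_ids=samples,
        variants=variants,
        haplotypes=hap_arr,
        dosage=dosage,
        phased=np.asarray(phased_flags, dtype=bool),
    )


def filter_by_maf(gd: GenotypeData, threshold: float) -> GenotypeData:
    """Retain SNPs with minor allele frequency >= ``threshold`` (boundary kept)."""
    if not 0 <= threshold < 0.5:
        raise ValueError("MAF threshold must be in [0, 0.5)")
    keep = gd.maf >= threshold
    if not keep.any():
        raise ValueError(f"MAF filter at {threshold} removed every SNP")
    if keep.all():
        return gd
    return gd.subset_variants(keep)


# ---------------------------------------------------------------------------
# Phenotypes and fixed effects


@dataclass
class PhenotypeTable:
    """One phenotype record per individual plus fixed-effect variables."""

    sample_ids: list[str]
    y: np.ndarray
    class_vars: dict[str, np.ndarray] = field(default_factory=dict)
    covars: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample id in phenotype table "
                             "(repeated records are not supported)")
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (n,):
            raise ValueError("y must be one value per individual")
        if np.isnan(self.y).any():
            raise ValueError("missing trait values remain after filtering")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        data: dict = {"id": self.sample_ids, "y": self.y}
        data.update(self.class_vars)
        data.update(self.covars)
        return pd.DataFrame(data)


def read_phenotypes(
    path: str | Path,
    trait: str,
    class_vars: Sequence[str] = (),
    covars: Sequence[str] = (),
    genotypes: GenotypeData | None = None,
) -> PhenotypeTable:
    """Read a tab-separated phenotype table.

    The file must have a header with an ``id`` column.  When ``genotypes``
    is given the table is restricted to (and ordered by) the genotyped
    samples; samples absent from the genotype panel are dropped with a
    logged count.  Rows with a missing trait value are dropped likewise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    needed = ["id", trait, *class_vars, *covars]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ValueError(f"phenotype table lacks columns: {missing_cols}")
    if df["id"].duplicated().any():
        dups = df["id"][df["id"].duplicated()].tolist()
        raise ValueError(f"duplicate sample id(s) in phenotype table: {dups[:5]}")
    n_missing = df[trait].isna().sum()
    if n_missing:
        logger.info("dropping %d records with missing %s", n_missing, trait)
        df = df[df[trait].notna()]
    if genotypes is not None:
        before = len(df)
        df = df.set_index("id")
        present = [s for s in genotypes.sample_ids if s in df.index]
        dropped = before - len(present)
        if dropped:
            logger.info("dropping %d phenotyped samples absent from genotypes",
                        dropped)
        df = df.loc[present].reset_index()
    return PhenotypeTable(
        sample_ids=df["id"].tolist(),
        y=df[trait].to_numpy(dtype=float),
        class_vars={c: df[c].to_numpy() for c in class_vars},
        covars={c: df[c].to_numpy(dtype=float) for c in covars},
    )


@dataclass
class DesignMatrix:
    """Fixed-effect design: intercept, dummy-coded class variables, covariables."""

    X: np.ndarray
    column_labels: list[str]

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != len(self.column_labels):
            raise ValueError("X/labels shape mismatch")


def build_design_matrix(pt: PhenotypeTable) -> DesignMatrix:
    """Intercept + (levels-1) indicators per class variable + covariables.

    Raises if the result is rank deficient, naming the collinear columns.
    """
    from scipy.linalg import qr

    n = pt.n
    cols = [np.ones(n)]
    labels = ["intercept"]
    for name, values in pt.class_vars.items():
        values = np.asarray(values).astype(str)
        levels = sorted(set(values))
        for lev in levels[1:]:  # first level is the reference
            cols.append((values == lev).astype(float))
            labels.append(f"{name}[{lev}]")
    for name, values in pt.covars.items():
        cols.append(np.asarray(values, dtype=float))
        labels.append(name)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R, piv = qr(X, mode="economic", pivoting=True)
        d = np.abs(np.diag(R))
        bad = [labels[j] for j in piv[rank:]] if rank < len(piv) else []
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return DesignMatrix(X=X, column_labels=labels)


# ---------------------------------------------------------------------------
# Relationship matrices


@dataclass
class GRM:
    """A named n x n genomic relationship matrix for one effect type."""

    label: str
    matrix: np.ndarray
    sample_ids: list[str]
    normalizer: float = float("nan")
    method: str = "first_order"

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if M.shape != (n, n):
            raise ValueError("GRM matrix shape does not match sample_ids")
        scale = max(1.0, float(np.abs(M).max()) if M.size else 1.0)
        if np.abs(M - M.T).max() > 1e-12 * scale:
            raise ValueError("GRM matrix is not symmetric")
        self.matrix = (M + M.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.sample_ids)


def write_grm(grm: GRM, prefix: str | Path) -> None:
    """Write a GRM in the GCTA binary dialect plus a JSON metadata sidecar.

    Files written: ``<prefix>.grm.bin`` (float32 row-major lower triangle
    including the diagonal), ``<prefix>.grm.id`` (two tab-separated id
    columns) and ``<prefix>.grm.json``.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = grm.n
    tri = grm.matrix[np.tril_indices(n)].astype(np.float32)
    tri.tofile(prefix.with_suffix(".grm.bin"))
    with open(prefix.with_suffix(".grm.id"), "w") as fh:
        for s in grm.sample_ids:
            fh.write(f"{s}\t{s}\n")
    meta = {
        "label": grm.label,
        "normalizer": None if np.isnan(grm.normalizer) else grm.normalizer,
        "method": grm.method,
        "n": n,
    }
    with open(prefix.with_suffix(".grm.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_grm(prefix: str | Path) -> GRM:
    """Read a GRM written by :func:`write_grm`; inverts the writer."""
    prefix = Path(prefix)
    id_path = prefix.with_suffix(".grm.id")
    bin_path = prefix.with_suffix(".grm.bin")
    meta_path = prefix.with_suffix(".grm.json")
    if not id_path.exists() or not bin_path.exists():
        raise FileNotFoundError(f"missing .grm.bin/.grm.id at prefix {prefix}")
    ids = [line.split("\t")[1].strip() for line in id_path.read_text().splitlines()
           if line.strip()]
    n = len(ids)
    tri = np.fromfile(bin_path, dtype=np.float32)
    expected = n * (n + 1) // 2
    if tri.size != expected:
        raise ValueError(
            f"GRM file {bin_path} holds {tri.size} values, expected {expected} "
            f"for the {n} ids in {id_path}"
        )
    M = np.zeros((n, n))
    M[np.tril_indices(n)] = tri.astype(float)
    M = M + np.tril(M, -1).T
    meta = {"label": "?", "normalizer": None, "method": "file", "n": n}
    if meta_path.exists():
        meta.update(json.loads(meta_path.read_text()))
        if meta.get("n") != n:
            raise ValueError("GRM metadata sidecar disagrees with id file length")
    return GRM(
        label=str(meta["label"]),
        matrix=M,
        sample_ids=ids,
        normalizer=float("nan") if meta["normalizer"] is None else float(meta["normalizer"]),
        method=str(meta["method"]),
    )
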