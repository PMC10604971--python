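"""Synthetic phased genotypes and multifactorial phenotypes.

The generator emulates the data shape the analysis assumes: an LD-blocked
biallelic SNP panel (MAF >= 0.05) on a family-structured sample, and one
phenotype record per individual composed of fixed effects, additive,
dominance, global pairwise/third-order epistatic and block-local high-order
epistatic genetic values, plus a Gaussian residual, at configured variance
fractions.

Genotypes follow a founder-mosaic pedigree model.  Each haplotype block
carries a small pool of founder haplotypes; founder gametes are mosaics of
those haplotypes with a per-SNP switch rate, and the sample is organized
into three-generation pedigrees (grandparent couples, their children, an
in-marrying spouse, grandchildren and cousins) whose gametes segregate from
the parental haplotypes block by block.  This creates strong within-block
LD with enumerable block alleles and - crucially - a *spectrum* of
relatedness (parent-offspring and full sibs at 1/2, grandparent-grandchild
and avuncular pairs at 1/4, first cousins at 1/8, across-family pairs near
0).  The spectrum matters: with a single relationship class the elementwise
powers of the additive relationship matrix are linearly dependent with the
identity, and epistatic variance components of different orders cannot be
separated; a family cohort's mixture of relationship classes is what makes
them estimable at these sample sizes.  Genetic
values are built from the same centered codings the relationship matrices
use; each component (and the residual) is standardized empirically so the
configured variance fractions are met exactly in-sample.  Block-local
high-order epistasis is realized as products of three within-block additive
codes - the kind of signal haplotype alleles tag but global pairwise
matrices do not.

All outputs are pure functions of the configuration (including its seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core_data import GenotypeData, PhenotypeTable
from .grm_builders import center_additive, center_dominance

__all__ = [
    "ArchitectureConfig",
    "SimulationTruth",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_phenotypes",
    "simulate_dataset",
    "write_fixture",
]

_GLOBAL_TYPES = ("A", "D", "AA", "AD", "DD", "AAA", "AAD", "ADD", "DDD")


@dataclass
class ArchitectureConfig:
    """Genetic architecture and panel shape for one simulated dataset.

    ``variance_fractions`` maps effect labels (``A``, ``D``, ``AA``, ``AD``,
    ``DD``, ``AAA`` ... and ``local3`` for within-block three-locus
    interactions) to fractions of the unit phenotypic variance; the residual
    fraction is the complement.  ``n_causal`` overrides the number of causal
    loci/pairs/triples per type.
    """

    n: int = 1000
    n_blocks: int = 100
    snps_per_block: int = 20
    n_founders: int = 8
    switch_rate: float = 0.01
    variance_fractions: dict[str, float] = field(
        default_factory=lambda: {"A": 0.3, "D": 0.1, "AA": 0.2}
    )
    n_causal: dict[str, int] = field(default_factory=dict)
    class_effect: float = 0.5
    covar_coef: float = 0.2
    intercept: float = 1.0
    maf_min: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for lab, frac in self.variance_fractions.items():
            if frac < 0:
                raise ValueError(f"negative variance fraction for {lab}")
            if lab != "local3" and lab not in _GLOBAL_TYPES and not set(lab) <= {"A", "D"}:
                raise ValueError(f"unknown effect label {lab!r}")
        if sum(self.variance_fractions.values()) > 1 + 1e-9:
            raise ValueError("variance fractions exceed 1")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founder haplotypes per block")

    @property
    def residual_fraction(self) -> float:
        return 1.0 - sum(self.variance_fractions.values())

    def causal_count(self, label: str) -> int:
        # Defaults are polygenic: enough causal units that each component's
        # realized covariance approximates its relationship matrix.  The
        # block-local term stays sparse by design (a few loci per block).
        if label in self.n_causal:
            return self.n_causal[label]
        m = self.n_blocks * self.snps_per_block
        if label in ("A", "D"):
            return min(400, m)
        if label == "local3":
            return min(100, self.n_blocks)
        return 2000  # interactions: pairs/triples


@dataclass
class SimulationTruth:
    """Causal architecture and realized per-individual genetic values."""

    causal: dict[str, list]            # per type: loci / tuples (SNP indices)
    effects: dict[str, np.ndarray]     # per type: scaled effect sizes
    genetic_values: dict[str, np.ndarray]  # per type: n-vector
    realized_fractions: dict[str, float]
    fixed_coefficients: dict[str, float]
    residual_fraction: float

    @property
    def total_genetic_value(self) -> np.ndarray:
        out = None
        for v in self.genetic_values.values():
            out = v.copy() if out is None else out + v
        return out if out is not None else np.zeros(0)


def _rng(cfg: ArchitectureConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


# Three-generation pedigree template (13 members per family).
# Members 0-4 are founders: two grandparent couples (0,1) and (2,3) plus an
# in-marrying spouse 4.  Descent rows are (child, mother, father):
#   5, 6 = children of couple (0,1); 7 = child of couple (2,3);
#   8, 9, 10 = children of (5, 7): grandchildren of all four grandparents;
#   11, 12 = children of (6, 4): first cousins of 8-10.
_PED_FOUNDERS = (0, 1, 2, 3, 4)
_PED_DESCENT = ((5, 0, 1), (6, 0, 1), (7, 2, 3),
                (8, 5, 7), (9, 5, 7), (10, 5, 7),
                (11, 6, 4), (12, 6, 4))
_PED_SIZE = 13


def simulate_genotypes(cfg: ArchitectureConfig) -> GenotypeData:
    """Founder-mosaic phased genotypes with block LD, pedigree structure and
    sample MAF >= ``maf_min``.

    Founders (and any leftover unrelated individuals) receive gametes that
    start from a random founder haplotype and switch to a random founder
    with probability ``switch_rate`` at each SNP step.  Non-founder family
    members inherit, block by block, one of each parent's two block
    haplotypes.  SNPs whose founder-gamete MAF falls below the floor have
    their founder alleles resampled (up to 20 times); SNPs whose final
    sample MAF still fails are dropped.
    """
    rng = _rng(cfg, 0)
    n, k = cfg.n, cfg.snps_per_block
    n_fam = n // _PED_SIZE
    n_extra = n - n_fam * _PED_SIZE
    n_founder_ind = n_fam * len(_PED_FOUNDERS) + n_extra
    n_gam = 2 * n_founder_ind

    hap_cols: list[np.ndarray] = []
    rows: list[tuple] = []
    col = 0
    block_of_snp: list[int] = []
    for b in range(cfg.n_blocks):
        founders = (rng.random((cfg.n_founders, k))
                    < rng.uniform(0.2, 0.8, size=k)).astype(np.int8)
        assign = np.empty((n_gam, k), dtype=np.int64)
        assign[:, 0] = rng.integers(cfg.n_founders, size=n_gam)
        for j in range(1, k):
            switch = rng.random(n_gam) < cfg.switch_rate
            assign[:, j] = np.where(switch,
                                    rng.integers(cfg.n_founders, size=n_gam),
                                    assign[:, j - 1])
        alleles = founders[assign, np.arange(k)]
        # hold the founder-gamete MAF above the floor by resampling founders
        for j in range(k):
            for _ in range(20):
                p = alleles[:, j].mean()
                if cfg.maf_min <= min(p, 1 - p):
                    break
                founders[:, j] = (rng.random(cfg.n_founders)
                                  < rng.uniform(0.2, 0.8)).astype(np.int8)
                alleles[:, j] = founders[assign[:, j], j]
        for j in range(k):
            rows.append(("1", b * 100_000 + (j + 1) * 1000,
                         f"b{b}_s{j}", "A", "G"))
        hap_cols.append(alleles)
        block_of_snp.extend([b] * k)
        col += k
    alleles = np.hstack(hap_cols)  # (2 * n_founder_ind, m)
    m = alleles.shape[1]
    founder_haps = alleles.reshape(n_founder_ind, 2, m)
    block_of_snp = np.asarray(block_of_snp)

    haps2 = np.empty((n, 2, m), dtype=np.int8)
    fam_base = np.arange(n_fam) * _PED_SIZE
    if n_fam:
        founder_rows = (fam_base[:, None] + np.array(_PED_FOUNDERS)).ravel()
        haps2[founder_rows] = founder_haps[: n_fam * len(_PED_FOUNDERS)]
    if n_extra:
        haps2[n_fam * _PED_SIZE:] = founder_haps[n_fam * len(_PED_FOUNDERS):]
    snp_idx = np.arange(m)
    for child, mo, fa in _PED_DESCENT:
        if not n_fam:
            break
        fam_idx = np.arange(n_fam)
        for g, parent in enumerate((mo, fa)):
            P = haps2[fam_base + parent]  # (n_fam, 2, m)
            choice = rng.integers(2, size=(n_fam, cfg.n_blocks))
            choice_snp = choice[:, block_of_snp]  # (n_fam, m)
            haps2[fam_base + child, g, :] = P[fam_idx[:, None], choice_snp,
                                              snp_idx[None, :]]
    haps = haps2.transpose(0, 2, 1)  # (n, m, 2)

    freq = haps.mean(axis=(0, 2))
    keep = np.minimum(freq, 1 - freq) >= cfg.maf_min
    haps = haps[:, keep, :]
    rows = [r for r, kf in zip(rows, keep) if kf]
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    return GenotypeData(
        sample_ids=[f"ind{i:05d}" for i in range(n)],
        variants=variants,
        haplotypes=haps,
        dosage=haps.sum(axis=2).astype(float),
    )


def _block_index(gd: GenotypeData) -> dict[int, np.ndarray]:
    """SNP indices per simulated block, recovered from the variant ids."""
    blocks: dict[int, list[int]] = {}
    for i, vid in enumerate(gd.variants["id"]):
        b = int(str(vid).split("_")[0][1:])
        blocks.setdefault(b, []).append(i)
    return {b: np.asarray(ix) for b, ix in blocks.items()}


def _sample_tuples(rng: np.random.Generator, m: int, r: int, count: int,
                   ordered_roles: bool) -> list[tuple[int, ...]]:
    """Distinct-locus index tuples; canonicalized to avoid duplicates."""
    import math

    cap = math.comb(m, r) * (math.factorial(r) if ordered_roles else 1)
    if count > cap:
        raise ValueError(f"requested {count} causal tuples, only {cap} exist")
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    while len(out) < count:
        t = tuple(rng.choice(m, size=r, replace=False))
        key = t if ordered_roles else tuple(sorted(t))
        if key in seen:
            continue
        seen.add(key)
        out.append(t)
    return out


def _scale(g: np.ndarray, target_var: float) -> tuple[np.ndarray, float]:
    sd = float(np.std(g))
    if sd == 0:
        raise ValueError("degenerate genetic component with zero variance")
    factor = np.sqrt(target_var) / sd
    return g * factor, factor


def simulate_effects(gd: GenotypeData, cfg: ArchitectureConfig) -> SimulationTruth:
    """Draw causal effects and realize per-individual genetic values.

    Global components use the same centered additive/dominance codings as
    the relationship matrices; ``local3`` draws one within-block triple of
    additive codes per causal unit.  Every component is scaled so its
    in-sample variance equals the configured fraction of a unit phenotypic
    variance.
    """
    rng = _rng(cfg, 1)
    W = center_additive(gd).values
    H = center_dominance(gd).values
    m = W.shape[1]
    causal: dict[str, list] = {}
    effects: dict[str, np.ndarray] = {}
    gvals: dict[str, np.ndarray] = {}
    realized: dict[str, float] = {}
    for lab, frac in cfg.variance_fractions.items():
        if frac == 0:
            continue
        count = cfg.causal_count(lab)
        if lab not in cfg.n_causal and lab != "local3":
            # defaults are capped at availability; explicit requests error
            r = max(lab.count("A") + lab.count("D"), 1)
            cap = math.comb(m, r)
            if lab.count("A") and lab.count("D"):
                cap *= math.factorial(r)
            count = min(count, cap)
        beta = rng.standard_normal(count)
        if lab == "local3":
            # cis interaction: the product of three centered allele
            # indicators on the SAME gamete, summed over the two gametes.
            # This is the kind of local high-order epistasis a haplotype
            # allele carries; a genotype-level (cross-gamete) product would
            # be invisible to haplotype-additive effects.
            blocks = {b: ix for b, ix in _block_index(gd).items() if ix.size >= 3}
            if not blocks:
                raise ValueError("no block has 3 SNPs for local interactions")
            keys = sorted(blocks)
            picks = rng.choice(len(keys), size=count, replace=True)
            p = gd.alt_freq
            tuples = []
            g = np.zeros(gd.n_samples)
            for i, pi in enumerate(picks):
                ix = blocks[keys[pi]]
                trip = tuple(int(j) for j in rng.choice(ix, size=3, replace=False))
                tuples.append(trip)
                term = np.ones((gd.n_samples, 2))
                for j in trip:
                    term = term * (gd.haplotypes[:, j, :] - p[j])
                g += beta[i] * term.sum(axis=1)
            causal[lab] = tuples
        else:
            na = lab.count("A")
            nd = lab.count("D")
            r = na + nd
            if r == 1:
                if count > m:
                    raise ValueError(f"requested {count} causal SNPs, have {m}")
                loci = rng.choice(m, size=count, replace=False)
                codes = W if lab == "A" else H
                g = codes[:, loci] @ beta
                causal[lab] = [(int(j),) for j in loci]
            else:
                ordered = na > 0 and nd > 0  # roles differ between positions
                tuples = _sample_tuples(rng, m, r, count, ordered)
                g = np.zeros(gd.n_samples)
                for i, t in enumerate(tuples):
                    col = np.ones(gd.n_samples)
                    for pos, j in enumerate(t):
                        col = col * (W[:, j] if pos < na else H[:, j])
                    g += beta[i] * col
                causal[lab] = tuples
        g, factor = _scale(g, frac)
        effects[lab] = beta * factor
        gvals[lab] = g
        realized[lab] = float(np.var(g))
    return SimulationTruth(
        causal=causal,
        effects=effects,
        genetic_values=gvals,
        realized_fractions=realized,
        fixed_coefficients={
            "intercept": cfg.intercept,
            "sex": cfg.class_effect,
            "age": cfg.covar_coef,
        },
        residual_fraction=cfg.residual_fraction,
    )


def simulate_phenotypes(
    gd: GenotypeData, truth: SimulationTruth, cfg: ArchitectureConfig
) -> PhenotypeTable:
    """y = intercept + sex effect + age coefficient + genetic values + residual."""
    rng = _rng(cfg, 2)
    n = gd.n_samples
    sex = rng.integers(0, 2, size=n)
    age = rng.standard_normal(n)
    y = cfg.intercept + cfg.class_effect * sex + cfg.covar_coef * age
    total_g = truth.total_genetic_value
    if total_g.size:
        y = y + total_g
    res = cfg.residual_fraction
    if res > 0:
        e = rng.standard_normal(n)
        e, _ = _scale(e, res)
        y = y + e
    return PhenotypeTable(
        sample_ids=list(gd.sample_ids),
        y=y,
        class_vars={"sex": np.where(sex == 1, "M", "F")},
        covars={"age": age},
    )


def simulate_dataset(cfg: ArchitectureConfig):
    """Convenience: genotypes, truth, phenotypes in one call."""
    gd = simulate_genotypes(cfg)
    truth = simulate_effects(gd, cfg)
    pt = simulate_phenotypes(gd, truth, cfg)
    return gd, pt, truth


def write_fixture(
    gd: GenotypeData,
    pt: PhenotypeTable,
    truth: SimulationTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a phased VCF, phenotype TSV, block BED, and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "pheno": out / "phenotypes.tsv",
        "bed": out / "blocks.bed",
        "truth": out / "truth.json",
    }
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(gd.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gd.sample_ids) + "\n")
        H = gd.haplotypes
        for j, row in enumerate(gd.variants.itertuples(index=False)):
            gts = "\t".join(f"{H[i, j, 0]}|{H[i, j, 1]}"
                            for i in range(gd.n_samples))
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")
    pt.to_frame().to_csv(paths["pheno"], sep="\t", index=False)
    with open(paths["bed"], "w") as fh:
        for b, ix in sorted(_block_index(gd).items()):
            pos = gd.variants["pos"].to_numpy()[ix]
            chrom = gd.variants["chrom"].iloc[ix[0]]
            fh.write(f"{chrom}\t{pos.min() - 1}\t{pos.max()}\tblock{b}\n")
    payload = {
        "causal": {k: [list(map(int, t)) for t in v]
                   for k, v in truth.causal.items()},
        "effects": {k: v.tolist() for k, v in truth.effects.items()},
        "realized_fractions": truth.realized_fractions,
        "fixed_coefficients": truth.fixed_coefficients,
        "residual_fraction": truth.residual_fraction,
        "variance_fractions_sum": sum(truth.realized_fractions.values())
        + truth.residual_fraction,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1)
    return paths
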