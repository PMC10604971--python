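# epiblup

Multifactorial genomic prediction for quantitative traits: SNP additive
and dominance effects, **global epistasis** up to fourth order (exact or
Hadamard-approximate relationship matrices), and **haplotype-block
additive effects**, estimated by multi-component GREML and predicted by
GBLUP, with 10-fold cross-validated predictive ability and a two-stage
model-selection procedure.

## The problem

Haplotypes carry *local* high-order epistasis — interaction effects among
alleles on the same physical haplotype — while genome-wide products of
SNP codes capture *global* pairwise and higher-order interactions between
loci anywhere in the genome.  Which matters more for predicting a trait,
and does combining them help?  `epiblup` provides the machinery to ask
that question on any phased SNP dataset with phenotypes: it builds a
relationship matrix S_i per effect type, fits the mixed model

    y = Xb + Σᵢ uᵢ + e,   uᵢ ~ N(0, σᵢ² Sᵢ),   V = Σᵢ σᵢ² Sᵢ + σₑ² I

by AI-REML, predicts masked individuals' genetic values by GBLUP, scores
models by the mean over folds of corr(ĝ, y) in the validation set, and
selects a final model by a heritability screen (keep types with ĥ² > 1%)
followed by cross-validated comparison (highest accuracy, fewest effect
types, at 3-decimal reporting precision).

Epistasis matrices come in two constructions: the classical Hadamard
product of first-order matrices, and an **exact** construction that
removes intra-locus (same-locus) terms — for A×A,
M = ½[(WW′)∘(WW′) − (W∘W)(W∘W)′] — generalized to every composition of
orders 2–4 through a power-sum expansion (Newton's identities and
inclusion–exclusion; see `docs/methods.md`).

A built-in generator simulates phased, LD-blocked genotypes on
three-generation pedigrees plus phenotypes with configurable additive /
dominance / epistatic / local-cis-interaction variance fractions, so the
entire pipeline is testable without any restricted-access data.

## Worked example

```python
import numpy as np
from epiblup import (ArchitectureConfig, simulate_dataset,
                     build_design_matrix, center_additive, center_dominance,
                     grm_first_order, grm_epistasis_exact, EffectType,
                     fit_greml, make_folds, cross_validate, percent_change)

cfg = ArchitectureConfig(n=400, n_blocks=25, snps_per_block=12,
                         variance_fractions={"A": 0.3, "AA": 0.25}, seed=7)
gd, pheno, truth = simulate_dataset(cfg)

W, H = center_additive(gd), center_dominance(gd)
GA, GD = grm_first_order(W), grm_first_order(H)
GAA = grm_epistasis_exact(EffectType(2, 0), W, H)
X = build_design_matrix(pheno).X

vce = fit_greml(pheno.y, X, [GA, GD, GAA], effect_labels=("A", "D", "AA"))
print({k: round(v, 3) for k, v in vce.heritability_by_label.items()})

folds = make_folds(gd.n_samples, k=10, seed=1)
snp = cross_validate(pheno.y, X, [GA, GD], ("A", "D"), folds)
epi = cross_validate(pheno.y, X, [GA, GD, GAA], ("A", "D", "AA"), folds)
print(round(snp.mean_accuracy, 3), round(epi.mean_accuracy, 3),
      percent_change(epi.mean_accuracy, snp.mean_accuracy))
```

Output:

```
{'A': 0.346, 'D': 0.0, 'AA': 0.33}
0.479 0.526 9.83
```

The fitted heritabilities recover the simulated architecture (truth
A = 0.30, AA = 0.25; at n = 400 the estimates carry sampling noise of a
few hundredths and the absent dominance component sits at its boundary),
and adding the pairwise-epistasis component raises the 10-fold predictive
ability from 0.479 to 0.526 — a 9.83% accuracy increase over the SNP
model, the same comparison the selection pipeline automates.

There is also a scikit-learn-style estimator over precomputed kernels:

```python
from epiblup import GBLUPRegressor
reg = GBLUPRegressor(effect_labels=("A", "AA"))
reg.fit([K_train_A, K_train_AA], y_train)      # kernels over training set
ghat = reg.predict([K_new_A, K_new_AA])        # cross-kernels new x train
```

and a CLI (`epiblup simulate | grm | blocks | reml | predict | cv |
select`) for shell workflows over VCF / TSV / BED / GCTA-format GRM
files.

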