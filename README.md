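# tetragwas

A toolkit for dissecting quantitative traits in autotetraploid crops, built
around the workflow used for tuber bruising in breeding-programme potato
panels: dosage-based variant filtering, windowed LD pruning, population
structure (PCA / DAPC / STRUCTURE post-processing), a mixed-model GWAS over
eight genetic models and six population settings, differential-expression
integration with functional-class-scoring enrichment, and the HIDECAN plot
that lays high-scoring markers, differentially expressed genes and
literature candidate genes on a common chromosome track.

## Who this is for

Breeders and quantitative geneticists working with autotetraploids
(potato, alfalfa, rose, ...) whose genotypes come as allele dosages 0–4
rather than diploid calls, and who want to run association analyses on
related material (half-sib panels, breeding populations) where population
structure and kinship corrections decide whether results are interpretable.

## The model

Genotypes enter as dosages (alternate-allele copies, 0–4). The per-marker
association model is

    y = Xβ + Sτ + Qv + Zu + ε,    Var(u) = σ²g K,   Var(ε) = σ²e I

where `S` encodes the marker's dosage under one of eight genetic models
(general, additive, simplex/duplex dominant for either allele, and the two
diploidized models), `Q` holds subpopulation membership probabilities and
`K` is the realized relationship matrix `MMᵀ` from centered dosages,
computed leave-one-chromosome-out. Variance components are estimated once
per chromosome under the null by REML on the eigenbasis of `K` (the P3D
approximation) and each marker is tested with a GLS F-test; the marker
score is −log₁₀ p. Population settings (naive, K, Q, K+Q with either
membership source) are compared through the genomic inflation factor — the
through-the-origin regression slope of sorted observed scores on their null
expectation — and the setting with mean inflation closest to one from
above is selected. Phenotypes are genotype BLUEs from a replicate-nested
mixed model, normalized with a standardized Yeo–Johnson transformation.

A synthetic-data module simulates the whole study design: a multi-cross
half-sib panel (gamete dosages from `Hypergeometric(4, dosage, 2)`, i.e.
random bivalent pairing), planted QTLs under any genetic model, a 0–5
bruising score with replicate/tuber structure, and negative-binomial
expression counts with planted DE genes.

## Worked example

```python
import pandas as pd
from tetragwas import simulate as sm
from tetragwas import phenotype, popstructure, gwas

# a 158-progeny half-sib panel with one planted additive QTL (20% of
# phenotypic variance), 12 chromosomes x 100 markers
qtl = sm.QtlSpec(marker_index=250, model="additive", pve=0.2)
cfg = sm.SimulationConfig(seed=1, qtls=[qtl])
g, truth = sm.simulate_panel(sm.table1_design(), cfg)
scores = sm.simulate_phenotype(g, [qtl], heritability=0.5, seed=2)

blues = phenotype.compute_blues(scores)
z, lam = phenotype.yeo_johnson_standardize(blues["blue"].to_numpy())
y = pd.Series(z, index=blues["genotype"])

kin = popstructure.compute_kinship(g, loco=True)
res = gwas.score_markers(g, y, "additive",
                         gwas.PopulationSetting.k_only(), kin)
print(truth.qtls[0]["marker_id"], res.scores.idxmax(),
      round(res.scores.max(), 2), round(res.inflation_factor, 2))
```

prints

```
chr03_29169899 chr03_29169899 10.1 1.06
```

the planted QTL is the top-scoring marker (score 10.1, i.e. p ≈ 8·10⁻¹¹)
and the inflation factor under the kinship model is close to one, as
expected when relatedness is properly accounted for.

The same workflow is scriptable from the shell:

```bash
tetragwas simulate --seed 1 --out sim/
tetragwas phenotype --scores sim/scores.csv --out pheno.csv
tetragwas prune --geno sim/geno.csv --seed 17 --out pruned.csv
tetragwas gwas --geno pruned.csv --pheno pheno.csv --settings naive,K \
    --models all --out results/
tetragwas run --config pipeline.yaml     # full end-to-end pipeline
```

## Layout

| module | contents |
| --- | --- |
| `tetragwas.geno` | VCF / dosage-CSV ingestion, QD and variant/sample filters |
| `tetragwas.ldprune` | bidirectional windowed LD pruning |
| `tetragwas.popstructure` | PCA, k-means+BIC, DAPC, Evanno Δ, run alignment, kinship (LOCO) |
| `tetragwas.phenotype` | BLUEs, Yeo–Johnson normalization, bruising groups |
| `tetragwas.gwas` | genetic-model encodings, P3D mixed model, inflation, FDR |
| `tetragwas.de` | expression filtering, convenience DE test, FCS enrichment |
| `tetragwas.hidecan` | HIDECAN data/plot and colocalization windows |
| `tetragwas.simulate` | half-sib panel, phenotype and expression simulator |
| `tetragwas.pipeline` / `tetragwas.cli` | end-to-end orchestration and CLI |

See `docs/methods.md` for the statistical details and design decisions.
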