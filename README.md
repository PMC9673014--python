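# aesig

Adverse-event (AE) signature extraction and drug safety-cluster prediction
from fused multi-source drug–drug similarity networks.

## The problem

Post-marketing surveillance systems collect spontaneous AE reports for
drugs already in wide use, but drugs still in clinical trials have almost
no safety feedback. `aesig` addresses both sides of that imbalance for a
cohort of drugs treating one disease:

1. **Signature extraction.** Given a drug-by-AE report count matrix
   `X ∈ ℝ^(p×n)` (p AE terms, n drugs with rich feedback), non-negative
   matrix factorization `X ≈ WH` decomposes the AE landscape into k
   *AE signatures* (columns of `W`, probability distributions over AEs)
   and per-drug *abundance fractions* (normalized columns of `H`). The
   signature count k is chosen by consensus-clustering stability
   (cophenetic correlation over repeated seeded factorizations), and each
   drug is clustered by its argmax signature.
2. **Profile prediction.** Drugs lacking AE feedback are placed in the
   same clusters through a fused drug–drug similarity network. Per-source
   networks (AE profiles, bioassay and chemical fingerprints, expression)
   rarely cover the same drugs, so networks with coverage gaps are
   *imputed*: each network is embedded by classical MDS
   (`C = -½·H·D²·H`, eigendecomposition, coordinates `ξ_ℓ·√λ_ℓ`), a linear
   map between embeddings is fitted by least squares on the shared drugs,
   and missing drugs' coordinates are predicted through the map and turned
   back into similarities (`s = 1 − d²/2`). The completed networks are
   merged by similarity network fusion (cross-diffusion through K-nearest-
   neighbor kernels), and cluster labels propagate to unlabeled drugs by a
   similarity-weighted 5-nearest-neighbor vote.
3. **Cluster explanation.** Signatures and clusters are characterized by
   (a) one-sided Wilcoxon rank tests and effect sizes
   `ES = (mean(ω_v) − mean(ω_v^c)) / sd(ω_v^c)` for accumulation of
   system-organ-class (SOC) categories in each signature, (b) drug–tissue
   interactome proximity `d_jt` (size-normalized closest-pair shortest
   paths between target modules and tissue-specific gene modules, with
   permutation significance), and (c) sparse linear discriminant analysis:
   with clusters coded `y = −n/n₁` / `+n/n₂`, the l1-penalized least
   squares problem selects discriminant genes between cluster pairs.

Because the original data sources are proprietary or licensed, the package
ships a first-class synthetic-data module that generates every input with
the statistical structure the analysis assumes, plus the ground truth
needed for recovery testing.

## Worked example

```python
from aesig.synthetic import SyntheticConfig, gen_ae_counts, gen_soc_mapping
from aesig.nmf import nmf_factorize, abundance_fractions, assign_clusters, select_k
from aesig.enrichment import enrichment_table

cfg = SyntheticConfig(seed=1, n_drugs=15, n_aes=134, k_true=4, count_scale=650)
X, truth = gen_ae_counts(cfg)
print("count matrix:", X.shape, "total reports:", int(X.to_numpy().sum()))

report = select_k(X, range(2, 7), seed=1)
print("selected k:", report.selected_k)

model = nmf_factorize(X, report.selected_k, n_init=50, seed=1)
clusters = assign_clusters(abundance_fractions(model))
print("cluster sizes:", clusters.labels.value_counts().sort_index().to_dict())

table = enrichment_table(model.W, gen_soc_mapping(cfg, truth))
print(table.head(4).round(4).to_string(index=False))
```

prints

```
count matrix: (134, 15) total reports: 9812
selected k: 4
cluster sizes: {1: 4, 2: 4, 3: 3, 4: 4}
category signature  m   p      ES  p_adj  significant
  SOC_04        S3 26 0.0 18.2094    0.0         True
  SOC_02        S2 26 0.0 18.5024    0.0         True
  SOC_03        S1 21 0.0 19.9085    0.0         True
  SOC_01        S4 26 0.0 22.0382    0.0         True
```

A cohort of 15 drugs with ~9,800 reports over 134 AE terms decomposes into
four stable signatures; each planted SOC category is recovered as the top
enriched category of exactly one signature (the rank-test p-values
underflow at this separation, and the effect sizes of ~18–22 pooled
standard deviations reflect the planted block structure).

The ten-stage pipeline (network construction → imputation → fusion →
NMF → clustering → propagation → enrichment → proximity → discriminant
genes) runs end to end from a fixture directory:

```sh
aesig generate --seed 1 --outdir fixture/
aesig run --config config.json
```

where `config.json` points at the fixture files (see
`aesig.pipeline.PipelineConfig`). Every stage is also exposed as its own
subcommand (`build-networks`, `impute`, `fuse`, `signatures`, `enrich`,
`proximity`, `slda`, `propagate`).

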