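# protfeat

Sequence-based protein feature extraction, exploration, and classification.

`protfeat` maps labeled sets of protein sequences to numeric feature
matrices (17 feature categories: compositions, property-profile features,
and amino-acid-distance features), provides exploratory statistics on the
matrix (Welch t per feature, histogram/scatter exports, hierarchically
clustered heat-map orderings), and trains/tests classifiers under a
stratified double-loop (nested) cross-validation protocol optimizing AUC.

## Feature categories

| category      | parameters                          | features            |
|---------------|-------------------------------------|---------------------|
| `aac`         | number of segments                  | 20 × segments       |
| `dpc`         | number of segments                  | 400 × segments      |
| `tec`         | end (N/C), length                   | 20                  |
| `ssc` / `sac` | number of segments (needs SS/SA)    | 3 × / 2 × segments  |
| `ssaac` / `saaac` | – (needs SS/SA)                 | 60 / 40             |
| `codon_comp` / `codon_usage` | – (needs ORF)        | 64 / 64             |
| `length`      | –                                   | 1                   |
| `sigavg`      | scales, window, edge                | 1 per scale         |
| `sigpeak`     | scales, window, edge, threshold     | 2 per scale         |
| `autocorr`    | type, scales, lag(s)                | 1 per scale per lag |
| `paac1` / `paac2` | scales, λ, weight               | 20+λ / 20+Γ·λ       |
| `ctd`         | property clustering(s)              | 21 per property     |
| `qso`         | distance matrix, λ, weight          | 20+λ                |

Built-in data: a set of 19 low-redundancy amino-acid scales (AAIndex
accession ids documented in the data file), a physicochemical amino-acid
distance matrix, and the seven standard 3-group CTD property partitions.
Additional scales can be loaded from AAIndex1 flat files.

Note: the series-correlation pseudo composition (`paac2`) yields
20 + Γ·λ features for Γ selected scales, which reduces to 20 + λ when a
single scale is selected.

## CLI workflow

```bash
# 1. create a project from FASTA (+ optional ORF/SS/SA/labels)
protfeat init proteins.fasta --project myproj \
    --orf orfs.fasta --labels expression.tsv

# 2. compute feature categories (appended to the project feature matrix)
protfeat features myproj aac --num-segments 2
protfeat features myproj qso --lam 10

# 3. export exploration data (t-statistics, cluster orders, histograms)
protfeat explore myproj --labeling expression

# 4. train with nested 10-fold stratified CV optimizing AUC
protfeat train myproj --labeling expression --classifier svm_linear \
    --k 10 --seed 0

# 5. predict labels for another project with the trained model
protfeat predict myproj/classify/expression_svm_linear_k10_s0/model.pkl \
    otherproj
```

Classifiers: `svm_linear` (C = 10⁻³…10³), `svm_rbf` (C, γ ∈ {0.1, 1, 10}),
`knn_uniform`/`knn_distance` (k = 1…5, 10, 20…50, 100), `nearest_centroid`
(shrink 1…10), `lda`, `qda`, `gaussian_nb`, `decision_tree`,
`random_forest`.  Hyperparameters are selected in an inner stratified CV
loop by mean AUC; standardization (zero mean, unit population sd) is
estimated inside each training portion only, so held-out folds never leak
into the transform.

## Tests

```bash
python -m pytest tests/
```

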