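# mdgan

Microbe–disease association prediction with an adversarially trained
residual graph-convolutional network.

Imbalances of the human microbiota are implicated in a wide range of
conditions, from asthma to inflammatory bowel disease, but experimentally
testing which microbe is involved in which disease is slow and expensive.
Curated databases record a few hundred to a few thousand verified
microbe–disease associations — a tiny, sparse corner of all plausible
pairs.  `mdgan` is a link-prediction toolkit for exactly this setting: it
scores every unobserved (disease, microbe) pair so that the most promising
candidates can be prioritised for experimental follow-up.  It is aimed at
computational biologists who have an association edge list (HMDAD- or
Disbiome-style) and, optionally, disease–gene annotations with a scored
gene-interaction network and/or a disease-ontology DAG.

## Model

Let `A ∈ {0,1}^{nd×nm}` be the known association matrix.  Three similarity
views are computed per axis and averaged:

* **GIP kernel** — `GD(di,dj) = exp(−λ_d ‖A(i,:) − A(j,:)‖²)` with
  bandwidth `λ_d = 1 / (mean_i ‖A(i,:)‖²)`, and symmetrically for microbe
  columns;
* **cosine** — the angle between binary association profiles (zero
  profiles score 0);
* **functional** — for diseases, best-match agreement of annotated gene
  sets through min–max-normalised log-likelihood scores (LLS) of a
  HumanNet-style gene network; for microbes, best-match agreement of their
  associated disease sets under Wang-style DAG semantic similarity
  (ancestor contributions decaying by 0.5 per generation).

The fused blocks assemble into a heterogeneous network

```
Y = [ DS   A  ]
    [ Aᵀ   MS ]
```

The **generator** is an L-layer GCN over the normalised graph
`Ỹ = D^{−1/2}(Y+I)D^{−1/2}`: layers `F^l = ReLU(Ỹ F^{l−1} W^{l−1})` with
`F^0 = Y`, aggregated with fixed cross-level weights `w_l = 1/L` plus a
learned linear skip of the input, `h = Y P + Σ_l w_l F^l` — the residual
aggregation that keeps deep stacks from over-smoothing.  Pair scores are
the bilinear decoder `S = h_d h_mᵀ`.  The **critic** (one ReLU hidden
layer, linear output, weights clipped to ±0.01) scores rows of the real
`Y` against rows of the reconstruction `h hᵀ`, Wasserstein-GAN style; the
generator minimises the negative critic value plus a binary-cross-entropy
reconstruction term on the association block.  Evaluation is leak-free
k-fold cross-validation over the known positives, with every similarity
view recomputed from the masked training matrix each fold, and AUC
computed from a threshold sweep of TPR/FPR.

Everything runs in double-precision NumPy on one thread, so results are
bit-for-bit reproducible from a seed.

## Worked example

Generate synthetic study conditions (planted-block associations, scored
gene network, annotations, ontology DAG), cross-validate, train on the
full matrix, and rank candidates:

```
$ mdgan synth --seed 1 --out inputs
$ mdgan cv --associations inputs/associations.tsv \
           --gene-net inputs/gene_network.tsv \
           --annotations inputs/annotations.tsv \
           --dag inputs/disease_dag.tsv \
           --k 5 --epochs 200 --seed 1 --baseline degree --report cv
mean AUC 0.7750 over 1 repeat(s); report at cv_report.json
$ mdgan train --associations inputs/associations.tsv \
              --gene-net inputs/gene_network.tsv \
              --annotations inputs/annotations.tsv \
              --dag inputs/disease_dag.tsv --epochs 200 --seed 1 --out run
trained 200 epochs; scores at run/scores.tsv
$ mdgan rank --associations inputs/associations.tsv \
             --scores run/scores.tsv --disease disease_003 --top-k 5
rank    microbe score
1       microbe_009     0.37945108435556774
2       microbe_010     0.2900274354468173
3       microbe_005     0.2723244251523868
4       microbe_001     0.23460714742315245
5       microbe_000     0.20561886723954798
```

The cross-validated mean AUC of 0.7750 (sd 0.0386 across the five folds;
`cv_report.json`) says that a held-out true association outranks a random
unknown pair about 78% of the time; the degree-product baseline on the
same folds reaches only 0.4676, so the signal comes from the learned
structure, not from node popularity.  The ranked list contains only
microbes *not* already associated with `disease_003`, sorted by predicted
score — the candidates one would take to the literature or the lab first.

The library mirrors scikit-learn conventions, so the same run is three
lines of Python:

```python
from mdgan import FixtureSpec, GANLinkPredictor, make_full_fixture, run_cv
am, gene_net, annotations, dag = make_full_fixture(FixtureSpec(seed=1))
report = run_cv(am, GANLinkPredictor(), k=5, seed=1,
                gene_net=gene_net, annotations=annotations, dag=dag)
print(report.mean_auc, report.std_auc)
```

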