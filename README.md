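# dtialign

Contrastive alignment of pre-computed protein and drug embeddings for
zero-shot drug–target interaction (DTI) ranking.

## The problem

Network-based DTI predictors learn from a heterogeneous biomedical graph
(drugs, proteins, diseases; DTI, drug–disease and drug–drug edge layers)
and work well for entities inside that graph — but a newly synthesized
compound or an understudied protein has no edges, so graph methods have
nothing to propagate.  Representation models do cover such entities: a
molecular VAE embeds any SMILES, a protein language model embeds any
sequence, an LLM embeds a text description.  `dtialign` bridges the two
worlds: it takes *frozen* embedding tables from any such upstream models
plus the observed DTI edges, and learns two small projection heads — one
per modality — into a shared space where interacting pairs have high cosine
similarity.  Scoring then needs only an embedding, not graph membership, so
novel drugs and cold-start proteins are ranked exactly like known ones.

## The objective

For a batch of N observed pairs (pᵢ, mᵢ), project both sides, L2-normalize,
and form the cosine matrix S.  Only the diagonal is labelled positive
(weak labels — off-diagonal cells are *unconstrained*, serving purely as
in-batch negatives), and the loss is the bidirectional cross-entropy

```
L = ½ (L_P→M + L_M→P)
L_P→M = −(1/N) Σᵢ log [softmax over row i of S/τ]ᵢᵢ
L_M→P = −(1/N) Σᵢ log [softmax over column i of S/τ]ᵢᵢ
```

Each head is a single affine map ("linear", depth 0) or an n-layer MLP.
Training uses Adam on hand-derived gradients (numpy only — no autodiff
framework), verified against finite differences in the test suite.  See
`docs/methods.md` for the model, the synthetic-world generator, and all
numerical choices.

## Worked example

Everything below is reproducible from a shell (the library API offers the
same steps via `ContrastiveAligner` — a scikit-learn style estimator with
`fit(X, Y)` / `transform` — and the `dtialign.training` / `inference` /
`metrics` modules).

```yaml
# sim.yaml — a planted-structure world: 200 proteins, 200 drugs,
# shared 8-dim latent, 10% of drugs held out as "novel" (embeddings
# but no training edges)
world:
  n_proteins: 200
  n_drugs: 200
  latent_dim: 8
  noise_sd: 0.05
  fraction_novel_drugs: 0.1
  seed: 7
```

```yaml
# train.yaml
data:
  edges: data/edges.tsv
  protein_embeddings: data/protein_embeddings.tsv
  drug_embeddings: data/drug_embeddings.tsv
  split_manifest: data/split.tsv
  checkpoint: run/checkpoint.json
protein_projection: {depth: 2, output_dim: 32, hidden_dim: 64}
drug_projection: {depth: 2, output_dim: 32, hidden_dim: 64}
training: {epochs: 50, batch_size: 64, learning_rate: 0.003, temperature: 0.1, seed: 7}
evaluation: {n_negatives: 4, ks: [1, 3], seed: 7, partition: test}
```

```
$ dtialign simulate --config sim.yaml --out data
$ dtialign train    --config train.yaml --out run
$ head -2 run/training_log.tsv ; tail -1 run/training_log.tsv
#epoch  mean_loss       valid_top1
0       2.811278643     0.911111
49      0.8312358161    1.000000
```

The mean contrastive loss falls from 2.81 to 0.83 over 50 epochs while
validation Top-1 (picking the true drug against 4 sampled non-interacting
drugs) reaches 1.0.  Evaluating on the **test partition — the novel drugs,
which contributed no training edge**:

```
$ dtialign evaluate --config train.yaml --out eval
$ cat eval/report.tsv
MAP@1   0.708333
MAR@5   0.800000
top1_accuracy   0.980769
top3_accuracy   1.000000
AUROC   0.983952
AUPR    0.264151
```

`top1_accuracy` 0.98 means the true novel drug beat all 4 distractors in
98% of the ranking cases; MAP@1 0.71 is the stricter all-drugs ranking
(the true drug must outrank *all 200* candidates); AUROC pools every
(protein, drug) pair.  Ranking every drug for one protein:

```
$ dtialign score --config train.yaml --protein P00007 --all-drugs --out scores
$ head -3 scores/scores.tsv
#protein_id     drug_id cosine  likelihood      rank
P00007  D00076  0.8902547531    0.01176561518   1
P00007  D00091  0.8229358529    0.01099963851   2
```

P00007's two true interaction partners in this world are exactly D00076
and D00091 — ranked 1 and 2 out of 200, with likelihoods (softmax of
cosines over the candidate set) well above the uniform 1/200 = 0.005.

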