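# calpsite

Prediction of calpain cleavage sites from protein sequence, and analysis of
how missense variants alter predicted cleavage.

Calpains (the calcium-dependent cysteine proteases μ-calpain/calpain-1 and
m-calpain/calpain-2) cleave their substrates at specific peptide bonds,
regulating proliferation, differentiation, cytoskeletal remodelling and
apoptosis. Experimentally mapped cleavage sites are scarce, so sequence-based
prediction is the practical route to candidate substrates. `calpsite` is for
computational biologists who want a self-contained, reproducible
implementation of that pipeline: window encoding, a neural classifier,
hyperparameter search, cross-validated evaluation, and variant-impact
analysis, with a seeded synthetic-data generator so every stage is testable
without downloads.

## The model

A cleavage site is a peptide **bond**, indexed by its N-terminal (P1)
residue; a protein of length *L* has *L* − 1 candidate bonds. Each bond is
represented by a 30-residue window (15 residues per side, `-`-padded at the
termini) and encoded four ways over the 21-symbol alphabet
`ACDEFGHIKLMNPQRSTVWY-`:

| encoding | content | length |
|---|---|---|
| AAC | residue composition of the window | 21 |
| BE | one-hot encoding of every position | 630 |
| PSFM | per-position frequencies of the positive and negative training windows, looked up at the window's own residues | 60 |
| CKSAAP | counts of ordered residue pairs at spacings *k* = 0…3 | 441 × 4 = 1764 |

The classifier is a four-branch feed-forward network — one input branch per
encoding, each with its own hidden layers, concatenated into shared dense
layers and a 2-unit softmax. The positive-class probability is the cleavage
score, Sn = TP/(TP+FN), Sp = TN/(TN+FP), Pr = TP/(TP+FP) and
Ac = (TP+TN)/N summarize thresholded calls, and ROC/AUC summarizes ranking.
Hyperparameters can be tuned by particle swarm optimization (PSO) against an
inner-cross-validated AUC objective. Subtype models (μ- vs m-calpain) are
built by transfer learning: branch layers are initialized from the general
model and optionally frozen while the merged head retrains.

A missense variant is scored on the original and the mutated sequence over
the bonds whose windows cover the mutated residue, and classified by
comparing the two predicted site sets: **gain** (all old sites kept, new
ones created), **loss** (sites existed, none survive), **change** (anything
else), **no change**. A seeded bootstrap tests whether observed variants sit
within ±15 residues of annotated cleavage bonds more often than uniform
placement over the same proteins would put them.

## Worked example

```python
from calpsite import CalpainCleavageModel
from calpsite import synthetic_data as sd

proteins, sites = sd.generate_proteins(100, sites_per_protein=2, seed=7)
variants = sd.generate_variants(proteins, sites, n_near=60, n_far=60, seed=8)

model = CalpainCleavageModel(proteins, sites, negative_subsample=200, seed=7)
results = model.fit(seed=7)
print(results.summary())
```

```
Calpain cleavage-site classifier
================================================
windows:            400 (200 positive, 200 negative)
flank / window:     15 / 30 residues
kmax (CKSAAP):      3
branch layers:      ((8,), (128, 64), (128, 64), (4,))
merged layers:      (32,)
dropout rate:       0.2
learning rate:      0.001
epochs / batch:     80 / 64
parameters:         116902
seed:               7
loss (first->last): 0.6708 -> 0.0003
training AUC:       1.0000
```

The training AUC of 1.0 is in-sample and optimistic; cross-validation gives
the honest estimate:

```python
print(model.cross_validate(k=5, seed=7).report().to_string(index=False))
```

```
  fold  n_test    sn    sp       pr     ac      auc
     1      80 1.000 0.900 0.909091 0.9500 0.980625
     2      80 0.950 0.900 0.904762 0.9250 0.984375
     3      80 0.900 0.925 0.923077 0.9125 0.986250
     4      80 1.000 0.900 0.909091 0.9500 0.982500
     5      80 0.975 0.850 0.866667 0.9125 0.964375
pooled     400 0.965 0.895 0.901869 0.9300 0.979225
```

Each fold refits the frequency profile and the network on its own training
folds, so the pooled AUC of 0.979 reflects genuinely held-out windows: the
planted P2 = {L,T,V} / P1 = {K,Y,R} motif is recovered almost perfectly.
Variant impact and positional enrichment:

```python
calls, table = results.classify_variants(variants)
print(table["category"].value_counts().to_string())
enr = results.site_enrichment(variants, seed=9)
print(f"ratio={enr.ratio:.2f} p={enr.p_value:.2e}")
```

```
no_change    61
change       31
gain         26
loss          2
```

On a cohort deliberately concentrated near sites (100 near, 25 far over
proteins whose site windows cover ~22% of residues) the bootstrap reports
`observed=0.800 null=0.217 ratio=3.69 p=1.00e-04` — the floor of the
+1-corrected empirical p at 10,000 iterations.

The same workflow is available from the shell:

```bash
calpsite simulate --out sim --n-proteins 100 --seed 7
calpsite train    --fasta sim/proteins.fasta --sites sim/sites.tsv --out run --seed 7
calpsite predict  --fasta sim/proteins.fasta --checkpoint run/checkpoint --out scores.tsv
calpsite evaluate --fasta sim/proteins.fasta --sites sim/sites.tsv --out eval --k 5
calpsite scan     --fasta sim/proteins.fasta --sites sim/sites.tsv \
                  --variants sim/variants.tsv --checkpoint run/checkpoint --out scan
calpsite tune     --fasta sim/proteins.fasta --sites sim/sites.tsv --out tuned
```

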