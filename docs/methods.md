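# Methods

## Problem and coordinate conventions

The package predicts which peptide bonds of a protein are cleaved by
calpain. A bond is identified by the 1-based index of its N-terminal (P1)
residue, so cleavage at bond *b* separates residues *b* and *b* + 1 and a
protein of length *L* has exactly *L* − 1 candidate bonds. Annotated bonds
form the positive class; every other bond of the same proteins forms the
negative class, so the two classes partition the candidate set. The
per-bond observation is a window of `flank` residues on each side of the
bond (default 15, window length 30), padded with `-` where the protein
ends, which puts the P1 residue at window position `flank` (1-based). An
alternative convention centering windows on a residue rather than a bond
(odd window lengths) exists in the literature; the bond-centered, even
window was adopted because the feature dimensionalities below follow from
it exactly.

## Feature encodings

All encoders share the ordered 21-symbol alphabet `ACDEFGHIKLMNPQRSTVWY-`
(`A` first, pad last). For window length *W* = 2·flank and maximum pair
spacing `kmax`:

* **AAC** — symbol frequencies over the window; length 21, sums to 1.
* **BE** — concatenated one-hot blocks, one per position; length 21·W with
  exactly W ones. Decoding by per-block argmax inverts it exactly.
* **PSFM** — a per-position frequency profile is fit separately on the
  positive and negative *training* windows: `pos_freq[j, s]` is the
  fraction of positive windows with symbol `s` at position `j`. A window is
  encoded by looking up its own residues, positive block then negative
  block; length 2·W, entries in [0, 1]. This is a plain occurrence-frequency
  profile, not a log-odds substitution matrix, and by default carries no
  pseudocounts — a zero is a legal, informative feature value. An optional
  additive-smoothing parameter exists for experimentation. The profile is
  part of the model: it is always fit on the training split only and is
  bundled with the trained network, so evaluation windows never contribute
  to their own features.
* **CKSAAP** — for each spacing k = 0..kmax, counts of ordered symbol pairs
  `(window[i], window[i+k+1])`; blocks concatenated by increasing k, pairs
  in row-major alphabet order; length 441·(kmax+1). Values are raw counts
  (the k-block sums are W−k−1 by construction); an optional normalization
  is deliberately not the default because counts are the literal reading of
  the encoding's definition.

At the defaults (flank 15, kmax 3) the four lengths are 21 / 630 / 60 /
1764.

## Classifier

A four-branch feed-forward network, one input branch per encoding, each a
stack of fully connected ReLU layers with inverted dropout; branch outputs
are concatenated into shared dense layers ending in a 2-unit softmax whose
positive-class probability is the cleavage score (the two probabilities sum
to one by construction). Training minimizes 2-class cross-entropy with Adam
(β₁ = 0.9, β₂ = 0.999) plus decoupled weight decay on the weight matrices.
Weights use He initialization; all randomness — initialization, batch
order, dropout masks, class rebalancing — flows from one integer seed, so
train→predict runs are bit-reproducible on one machine.

Default hyperparameters: branch hidden widths (8), (128, 64), (128, 64),
(4) for AAC/BE/PSFM/CKSAAP, merged width 32, dropout 0.2, learning rate
1e-3, weight decay 3e-2, batch 64, epochs 80. The asymmetry is deliberate:
AAC and CKSAAP are position-free composition summaries, so against a
position-specific cleavage signal their high-dimensional inputs contribute
mostly variance; bottlenecking those branches (4–8 units) while giving the
position-aware BE/PSFM branches capacity regularizes the merged
representation far more effectively than dropout or weight decay alone.
With ~10² training windows per class this moved held-out AUC from ~0.80
(symmetric widths) to ~0.97. All of this is configuration, not architecture:
any widths can be supplied, and PSO can tune them.

Class imbalance (hundreds of true sites among 10⁵ candidate bonds in real
corpora) is handled explicitly by the `"balanced"` training mode, which each
epoch pairs the full minority class with a fresh seeded subsample of the
majority class. Dropout is applied as ordinary regularization, independent
of balancing; the two mechanisms are deliberately kept separate rather than
conflated. Exhaustive negative sets can additionally be capped at dataset
assembly (`negative_subsample`), which is a training convenience —
evaluation should see the full candidate set whenever feasible.

Binary calls use a configurable score threshold, default 0.5; a calibration
helper picks the threshold achieving a target specificity on training
scores instead. Early stopping is off: the epoch budget is a tuned
hyperparameter.

## Subtype transfer learning

Isoform-specific models (μ- vs m-calpain) start from the general model's
weights; with `freeze_policy="branches"` the branch stacks stay fixed and
only the merged head and output retrain on the subtype sites. The
pretrained frequency profile is reused — refitting it on the subtype data
would shift the PSFM features out from under the frozen branch weights.
Fine-tuning with zero epochs returns a model scoring identically to the
pretrained one (identity contract).

## Particle swarm optimization

Standard global-best PSO: v ← ωv + c₁r₁(pbest − x) + c₂r₂(gbest − x),
x ← clip(x + v, bounds), with the velocity component zeroed where the clip
bites. Defaults ω = 0.729, c₁ = c₂ = 1.49445 (constriction-equivalent), 20
particles × 30 iterations. Initial velocities are clamped to ±(range/10)
per dimension; full-range initial velocities threw most particles onto the
box boundary in the first step. Integer dimensions (layer widths, batch,
epochs) decode by half-up rounding; the decode is idempotent on integral
positions. Hyperparameter search minimizes 1 − mean inner-CV AUC, training
candidates at a reduced epoch budget (default 8) and returning the winner
for full-budget retraining. The best-so-far trace is non-increasing by
construction.

## Evaluation

Sn, Sp, Pr and Ac come from the confusion matrix at a threshold; a zero
denominator flags the metric as undefined rather than propagating NaN. ROC
curves sweep every score threshold (no intermediate-point dropping), so the
trapezoidal AUC equals the Mann–Whitney statistic with ties counted half.
Cross-validation is stratified and seeded; each fold refits the frequency
profile and trains the network on the k−1 training folds only and scores
the held-out fold. The per-fold report and the pooled ROC over all held-out
scores are both exposed. The flank sweep re-extracts windows and rebuilds
encoders per flank (dimensions 21 / 42f / 4f / 441·(kmax+1)) and reruns the
same CV.

## Variant impact and enrichment

A substitution at residue `pos` can only move scores of bonds whose window
covers it: bonds b with b − flank + 1 ≤ pos ≤ b + flank, clipped to
[1, L−1]. Those bonds are scored on the original and mutated sequences and
thresholded into before/after site sets. Categories: identical sets →
**no change**; proper superset → **gain** (this includes creation from
nothing, and requires every old site to survive); non-empty before, empty
after → **loss**; everything else → **change**. The residual definition of
"change" (shifts, partial losses, mixed gain+loss) makes the four
categories a provable partition of all set pairs, verified exhaustively in
the tests. Per-protein summaries count a protein once in every category it
appears in.

The enrichment statistic is the fraction of variants lying within ±flank of
any annotated bond of their protein. The null redraws every variant's
position uniformly over its own protein (with replacement), preserving
per-protein variant counts and thereby protein length and mutation burden;
resampling site positions or whole proteins would have been defensible
alternative nulls, and the choice is documented rather than claimed
canonical. p = (1 + #{null ≥ observed}) / (n_iterations + 1), so p is never
below 1/(n+1) and never exactly zero; default 10,000 iterations gives
stable three-decimal p on one CPU in under a second. Because the statistic
is discrete, ties between null draws and the observed value make p slightly
conservative for small cohorts; with ≥100 variants the effect is negligible
(null p-values are uniform to KS < 0.1 in the tests).

## Synthetic data

The generator plants a cleavage motif at known bonds: by default Leu/Thr/Val
at P2 (probabilities 0.5/0.25/0.25) and Lys/Tyr/Arg at P1 (0.4/0.3/0.3),
the canonical calpain subsite preferences, plus a mild alanine bias at P1'
and P2' (0.24 vs 0.04 background) echoing the enrichment seen downstream of
real cleavage bonds. Background residues are i.i.d. uniform over the 20
standard residues — chosen over a SwissProt-like composition (available via
a flag) because uniform backgrounds make test expectations exact.
`signal_strength` s overwrites each motif position with probability s, so
s = 1 plants deterministically and s = 0 yields pure background. Site
placements avoid overlapping motif footprints; variants are placed uniformly
within (near) or outside (far) the ±flank windows of true sites.

What the generator does *not* emulate: homology between proteins,
real amino-acid composition and local sequence correlation, structural
context (disorder, surface accessibility), subsite preferences beyond
P2/P1/P1'/P2', and cohort structure or mutational signatures in the variant
tables. Passing tests therefore demonstrate that the pipeline recovers a
planted position-specific signal under clean conditions — correctness of
the machinery, not expected performance on curated substrate corpora, which
must be measured on those corpora directly.
Note one consequence of the clean design: the planted motif is purely
positional, so the position-free AAC/CKSAAP features carry almost no signal
here, whereas on real substrates compositional context is informative.

## Problem sizes and numerical choices

The default study conditions used throughout tests and the acceptance
script: 400 balanced windows (200 planted positives, 200 background bonds)
for training/CV; 3–5-fold CV in sweeps and 4/5/6/8/10-fold for the CV
ladder; 10,000 bootstrap iterations for headline p-values (500 for the
uniformity replicates); PSO at 20×30 for the sphere benchmark and small
swarms for hyperparameter smoke tests. Softmax is computed with max
subtraction; cross-entropy adds 1e-12 inside the log; profile rows sum to 1
within 1e-9; non-finite losses or PSO objectives raise immediately with
their epoch or position. Frequency profiles serialize to TSV via `repr`,
which round-trips doubles bit-exactly.

## Known limitations

* The network is a dense multi-branch classifier; convolutional or
  attention variants are out of scope.
* Binary checkpoints (`weights.npz` + sidecar config + profile TSV) are a
  runtime artifact; no cross-version weight compatibility is promised.
* The bootstrap null resamples variant positions only; it does not model
  nucleotide-level mutability (e.g. C>T bias mapping unevenly onto codons).
* `negative_subsample` changes the training class prior; scores are
  comparable within one model but not calibrated probabilities across
  models trained with different subsampling.
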