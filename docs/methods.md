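# Methods

## Model

The predictor maps a one-hot DNA window of `input_length` bp to per-track
Poisson rates on `crop_length / bin_size` centered bins. The trunk follows
the published Enformer design wherever this package does not deliberately
deviate:

* **Stem** — Conv(4 → C/2, kernel 15), a residual pointwise conv block
  (BatchNorm → GELU → Conv), and learned two-fold softmax pooling whose
  logits come from a channels×channels linear map initialized to 2·I
  (biasing it toward max-pooling).
* **Tower** — `n_conv_blocks − 1` stages of ConvBlock(kernel 5) →
  residual pointwise ConvBlock → softmax pooling, with channel widths
  exponentially spaced from C/2 to C and rounded to a fixed multiple
  (128 at full scale). The total two-fold poolings (stem + tower) equal
  log2(`bin_size`), so toy geometries shrink the tower and the bin size
  together.
* **Attention stack** — pre-norm transformer blocks: LayerNorm →
  multi-head attention → dropout → residual; LayerNorm → 2C-wide MLP
  (ReLU) → residual. Attention logits add a content term and a
  relative-position term. Two positional schemes are provided:
  `enformer_basis` (exponential, central-mask and gamma basis functions of
  the signed distance, projected by a learned linear map, with per-head
  content/position bias vectors r_w and r_r) and `simple_relative_bias`
  (one learned scalar per head per relative offset), the latter the default
  for toy configs where sequences are ≤ a few dozen bins.
* **Crop, pointwise, heads** — center crop to the label geometry; an
  optional BatchNorm → GELU → Conv(C → 2C, kernel 1); one linear head per
  task family with softplus output guaranteeing strictly positive rates.

**Ablation switches.** `include_attention_linear` controls the
post-attention output projection inside every block (when absent, the
concatenated heads — sized to C — feed the residual sum directly);
`include_final_pointwise` controls the final channel-doubling convolution
(when absent, heads read C features instead of 2C). Both removals strictly
reduce the parameter count; the removed shapes are asserted against hand
counts in the tests. Which exact linear layer the simplification removes is
an open design point; the output projection is the interpretation
implemented, chosen because it is the block's only per-locus linear map
outside the MLP, and the flag keeps alternatives one line away.

**Parameter count.** At the full published geometry — 1536 trunk channels,
8 heads with key size 64 and value size 192, positional features of
dimension C/heads = 192, 11 attention blocks, final pointwise to 3072 — the
trunk counts 229,845,504 trainable parameters; adding the 5313-track head
(3072·5313 + 5313) gives 246,172,353, i.e. 246M to the nearest million,
matching the printed figure for the human-trained model. A second
1643-track head would add ~5.0M.

**Normalization and batch size 1.** BatchNorm statistics are computed over
batch × position, so the recipe's batch size of 1 remains well-posed (each
step normalizes over the window's positions); running means/variances with
momentum 0.1 are used at evaluation.

## Numerics

The network and its training loop are implemented on a small in-package
reverse-mode autodiff engine over float64 NumPy arrays (tape of closures,
topological backward). Convolutions are same-padded sliding-window
unfoldings followed by a matmul; the relative-position logits use a
two-operand einsum plus a constant scatter tensor. Every structural
operator and the full network gradient are checked against central finite
differences in the test suite. Near-zero true gradients (e.g. a conv bias
immediately renormalized by the following BatchNorm) are compared with a
mixed relative/absolute tolerance because finite differences are pure
rounding noise there.

Initialization is He-normal for conv/linear weights, zeros for biases,
N(0, 0.02) for positional bias vectors, drawn in fixed module order from a
single seeded generator — two builds with the same config and seed are
bit-identical, as are forward passes and training runs (data order and
dropout draw from seeds derived via `SeedSequence`).

## Training recipe

Poisson NLL `mean(λ − y log λ)` over bins × tracks (the `log y!` constant
is omitted; a flag adds it for likelihood reporting). AdamW with β =
(0.9, 0.999), ε = 1e−8, decoupled weight decay (default 1e−4), batch size
1, 10 epochs, and the piecewise-linear schedule: linear warm-up 0 → peak
across epoch 1, linear decay peak → 0 across the remaining epochs, defined
in optimizer steps so other batch sizes generalize. Gradient clipping is
off by default behind a flag. Multi-track mode averages the loss over all
tracks; single-track mode selects one column of the labels. Fine-tuning
loads a checkpoint, replaces every head with one freshly initialized
n-track head (trunk bitwise untouched), optionally freezes all non-head
parameters, and trains; frozen training provably leaves the trunk
bit-identical (checksum-tested).

Full-scale peak learning rate defaults to 3e−5, the value grid search
selects for the full-size model (the search itself is reproduced by
`grid_search` over lr ∈ {1e−6 … 3e−4} and weight decay ∈ {1e−4, 3e−4,
1e−3}, ties broken toward the smaller rate). The desk-scale models used in the bundled experiments are ~10⁴×
smaller, and their tuned toy rates are correspondingly larger: peak 5e−3
to 1e−2 for training from random initialization, 3e−3 for full
fine-tuning (a gentler rate protects pretrained features from the
catastrophic forgetting that small fine-tune sets otherwise induce), and
1e−2 for head-only (frozen) training, which is a generalized linear model
and tolerates aggressive steps.

## Homology-aware splitting

PSL interval mappings (21-column, as emitted by pslMap/BLAT) carry
query→target alignments. A window's overlap with a reference interval set
is the number of its bases whose mapped target position falls in the set,
each base counted once (interval-union arithmetic, equal to a per-base
brute-force scan in the tests; minus-strand blocks map reversed). The
assignment rule: more overlap with the reference training set than the
validation set → train, and vice versa; equal nonzero overlaps go to
validation (conservative against leakage into train); windows with no
mapping at all are assigned by a seeded ratio (default 0.8/0.1/0.1 for
standalone use; 0.6/0.2/0.2 in the synthetic world, which needs usable
held-out sets). The homology proportion of a window is its union overlap
with the reference training set divided by its length, and drives the
leakage-binned evaluation; bin edges are configurable because no canonical
edges exist.

## Synthetic benchmark

The generator emulates the *structure* of the real corpora — a large
multi-track pretraining species and a smaller transfer species — not their
read-level detail (no fragment-length or enzyme-bias structure, no real
genome).

* **Motifs**: PWMs with Dirichlet(0.05) rows (~1.6 bits/position, so a
  10-bp motif carries ~16 bits, comparable to real TF motifs). Motif
  instances are planted in i.i.d. background DNA (per-species GC) at
  Poisson-distributed positions; the tiny preset plants 2 occurrences per
  motif per kb so a few hundred windows contain enough instances for a
  small model to discover each motif.
* **Tasks**: each track weights 3 motifs with |N(5, 5/3)| weights over a
  baseline rate of 1 count/bin; the per-bin rate is
  softplus(log baseline + Σ w·exp(−d²/2σ²)) with σ = 96 bp (tiny preset),
  giving peak-to-background contrasts of roughly an order of magnitude, in
  line with accessibility data. Counts are independent Poisson draws; the
  resulting noise ceiling r(λ, y) is ≈ 0.77–0.89 per task on the tiny
  preset.
* **Cross-species structure**: the transfer species shares 75% of the
  motif vocabulary (with fresh task weights) plus species-specific motifs
  and a GC shift (0.46 → 0.50), so transfer is informative but not
  trivial. Exact segments copied from the reference genome into the
  transfer genome are recorded as PSL and exercise the homology splitter
  end-to-end; occurrences inside a pasted segment are carried over so
  labels stay consistent with sequence.
* **Sizes (tiny preset)**: 1024-bp windows, 512-bp crop, 64-bp bins;
  1536 reference windows (12 pretraining tracks) and 192 transfer windows
  (3 tracks) — the transfer corpus is ~25% of the pretraining corpus,
  mirroring the proportions of the real datasets. The desk preset scales
  the same structure to 4096-bp windows, 128-bp bins and 40 pretraining
  tracks.

What passing tests on this benchmark do and do not show: they demonstrate
the *training machinery and experiment logic* — that pretraining transfers,
that freezing preserves and protects features, that fine-tuning improves a
diluted track — under a generative model whose signal really is
sequence-driven. They do not calibrate absolute correlations attainable on
real data, and per-task attainment varies substantially between random
task realizations (as it does between real datasets), so comparisons are
made within paired seeds and summarized by medians.

## Experiment designs and problem sizes

* **Architecture comparison**: the four ablation combinations plus the
  5-block variant, trained with identical seeds and data order (paired
  comparison), per-epoch validation r and parameter counts persisted.
* **Transfer**: one pretrained checkpoint (tiny preset: 16 epochs at peak
  5e−3 over the 12-track reference corpus) feeds full and frozen
  fine-tuning arms across five fine-tuning seeds, against scratch and
  frozen-scratch controls; summary reports per-arm means/medians and the
  percent improvement of fine-tuning over scratch.
* **Tradeoff sweep**: for each additional-track count (tiny default
  1/4/8 of the 12-track catalogue; log-spaced like the published counts)
  and replicate, the additional tracks are redrawn per replicate, the
  model trained multi-track, evaluated on the track of interest and on all
  tracks, then fine-tuned 10 epochs on the single track of interest. The
  inverted-U over track counts is a recorded outcome, not an assertion —
  toy dynamics need not place the peak where large-scale runs do.

The tests run these designs at reduced sizes (e.g. 192-window sweep
corpora, 6-epoch sweep training) chosen so the full suite completes in
minutes on one CPU; the sizes are stated in the tests themselves.

## Known limitations

* NumPy training is single-threaded and desk-scale; full-scale (196-kb
  window) forward passes are out of reach, and full-scale configs are used
  only for geometry and parameter-count verification.
* The Pearson formula is implemented with the standard square-root
  denominator. One published statement of the metric divides by the
  product of variances without the root, which is not bounded by 1; the
  standard definition is used and cross-checked against SciPy.
* Per-task learnability at tiny scale varies with the task realization;
  headline checks therefore fix seeds and compare arms in paired fashion.
* bedGraph values are interpreted as per-base depth; bin labels are sums
  over the bin (mean available behind a flag). No reverse-complement or
  shift augmentation is applied by default.
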