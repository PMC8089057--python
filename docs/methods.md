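# Methods

## Model

Two prediction branches share building blocks and are ensembled by
elementwise averaging of their L×L sigmoid outputs.

**Sequence-attention branch.** 1D path: instance norm over the L×20 profile
→ 1D convolution ('same' padding, kernel 5, ReLU) → bidirectional LSTM
(forward/backward outputs concatenated) → multi-head scaled dot-product
attention. The encoder output is linearly projected to `n_heads · d_att`
channels; each head applies its own (d_att × d_att) query/key/value
matrices to its slice, scores are scaled by 1/√d_att and row-softmaxed, and
head outputs are concatenated. The attention output is tiled to 2D:
`out[i, j] = Z[i] ⊕ Z[j]` (row block first, column block second). 2D path:
instance norm → ReLU → 1×1 convolution to twice the trunk width → Maxout
over channel pairs, halving it. Concatenation feeds the residual trunk; a
1×1 convolution + sigmoid emits the map.

**Regional-attention branch.** The tiled raw profile (L×L×40) is
concatenated with the coupling tensor at the input and passes through the
same 2D preprocessing and trunk; a 3×3 convolution reduces to the
pre-attention width (32 at full scale), then windowed attention: the
region-stretching operation gathers each cell's n×n neighbourhood
(row-major, zero padded; n = 5), the centre cell's channel vector is
projected to the per-head query, window cells to keys/values, logits are
scaled by 1/√d and masked to −∞ at out-of-bounds cells before the softmax,
so padded cells receive exactly zero weight and every centre distributes
exactly one unit. Head outputs are concatenated and projected back to the
pre-attention width; a 1×1 convolution + sigmoid emits the map.

**Residual trunk.** Four blocks with 3, 4, 6, 3 repetitions of (instance
norm → ReLU → 3×3 convolution with 64 kernels), a 1×1-convolution shortcut
added to the block output, then a squeeze-and-excitation gate (global
channel means → bottleneck dense pair → sigmoid → per-channel rescale).
Everything is fully convolutional: any L ≥ 8 passes through unchanged in
spatial shape.

**Baseline variant.** Either branch can be built with its attention layer
removed (the LSTM output is tiled directly; the 32-channel features feed
the output convolution directly). This isolates what the attention layers
add.

## Parameters and defaults

| parameter | full scale | tiny preset | notes |
|---|---|---|---|
| coupling channels C | 441 | 16 | presumed 21×21 couplings; configurable |
| trunk width | 64 | 16 | 3×3 kernels |
| block repeats | 3,4,6,3 | 1,1,1,1 | |
| pre-reduction width | 128 → 64 | 32 → 16 | 1×1 conv then Maxout |
| attention heads | 4 | 4 | best configuration in ablation |
| d_att (1D) | 32 | 4 | per-head width; chosen, configurable |
| window n (2D) | 5 | 5 | odd by construction |
| d (2D heads) | 32 | 8 | per-head width |
| pre-attention width | 32 | 16 | |
| LSTM hidden (per dir.) | 64 | 8 | chosen; configurable |
| 1D conv kernel | 5 | 5 | unspecified upstream; chosen |
| SE bottleneck ratio | 16 | 4 | standard |

The tiny preset exists so the whole pipeline — training included — runs in
seconds-to-minutes on one CPU; the full-scale preset mirrors the quoted
sizes and is exercised structurally (parameter counts, layer counts,
shapes) rather than trained.

Training: batch size 1 (feature maps scale as L²); Adam lr 0.001 for epochs
0–29, SGD lr 0.01 momentum 0.9 for 30–59, stop at 60; shortened runs that
end before the switch simply never leave the Adam phase. Weights use a
truncated-normal initializer (±2σ, He-scaled σ by default). The loss is
mean binary cross-entropy over pairs with |i−j| ≥ 6, computed from logits
(softplus form) for stability; near-diagonal pairs are excluded because
they are trivially in contact and would dominate the objective. Validation
uses symmetrized maps and exactly the evaluation definition of top-L/2
long-range precision, so checkpoint selection optimizes the reported
metric. Ties in the per-epoch validation score resolve to the earliest
epoch.

## Evaluation conventions

Maps are symmetrized ((M + Mᵀ)/2) before ranking; only i < j pairs are
ranked; ties break by ascending (i, j); the selection depth is ⌊L/n⌋ with a
minimum of 1 (the rounding is not specified upstream). Pairs involving
unresolved residues are excluded from numerator and denominator via the
validity mask. Targets whose band holds no scorable pair (e.g. L < 25 for
long range) are reported as missing and excluded from dataset means rather
than scored zero. ROC and PR curves are pooled threshold sweeps with
trapezoidal areas; the PR curve is anchored at recall 0 with the precision
of the top-ranked point.

## Interpretation

Sequence importance is the column sum of the head-averaged attention
matrix (total mass L, conserved by row-stochasticity). For the regional
branch the captured (L, L, heads, n²) tensor has no unique L×L reduction;
we fold each centre's distribution back onto the cells it covers
("received attention"), which conserves total mass at L² and makes border
effects explicit, then combine normalized row and column sums into a
profile summing to 1.

Permutation ablation shuffles the channel vector of every coupling cell in
an m×m window (channel-axis shuffle, so even a 1×1 region is genuinely
perturbed — a 1×1 spatial shuffle would be a no-op). Because predictions
are symmetrized, the mirrored window at (j, i) is permuted together with
(i, j); otherwise half the pair's features survive and the effect is
systematically damped. Centres are the k highest/lowest received-attention
cells within a prediction-outcome group at top-L/5 depth (TP/FP/TN/FN),
with k equal to the target's true-positive count. Single-centre deltas are
quantized in units of 1/⌊L/5⌋, so comparisons aggregate over centres,
targets and permutation seeds.

Φ-value comparison: one-sided Mann–Whitney rank-sum of importance inside
vs outside the highest-Φ peak region (a contiguous window of half-width 3
around the argmax by default; the extent is not defined upstream), exact
when the data are tie-free, plus the Pearson correlation over measured
residues. Φ profiles load from two-column text (1-based index, value).

## Synthetic data

The generator emulates the *shape and signal structure* of real inputs,
not their biology. Chains are compact self-avoiding walks: fixed 3.8 Å
steps whose directions blend persistence (0.45), a centroid pull (0.60)
and Gaussian noise (0.90), with a 3.4 Å clash floor; the blend was
calibrated once by simulation so 60-residue chains show long-range contact
densities of roughly 2–20% (mean ≈ 9%), comparable to globular proteins.
Contacts follow from the standard 8 Å threshold. Coupling tensors place
`signal_channels` symmetric channels equal to contacts + N(0, 1/snr) among
pure-noise channels; profiles are Dirichlet-like with extra hydrophobic
mass at residues having at least one long-range contact, mirroring the
burial signal real profiles carry. Everything derives deterministically
from one seed via spawned seed sequences.

What passing tests on this data do **not** show: performance on real
proteins. The generator has no alignment statistics, no phylogenetic
correlation between channels, no secondary-structure geometry, and its
planted signal is far cleaner than inferred couplings; results quantify
that the architecture, training loop and interpretation machinery work,
not that the model rivals MSA-based predictors.

## Numerical choices

Float64 throughout; autograd softmax subtracts the (detached) row maximum;
the masked softmax's −10⁹ bias underflows to exactly zero weight after
exponentiation, and weights are additionally multiplied by the bounds mask.
Maxout ties route the gradient to the even-indexed channel. Instance-norm
ε = 10⁻⁵. BCE probabilities are clipped at 10⁻⁷ in the functional
(probability-space) loss. Degenerate inputs are errors, not silent
results: fewer than two resolved residues, all-masked losses, single-class
ROC pools, even window sizes.

## Design decisions taken where the architecture was underspecified

- Out-of-bounds window cells are masked from the regional softmax rather
  than letting zero-padded features absorb weight; this gives clean
  conservation invariants but may differ from other implementations at map
  borders.
- The regional query comes from the centre cell only (one query per
  position); full window-to-window self-attention would leave the
  per-position output reduction undefined.
- ReLU follows every instance norm in the trunk (stated upstream only for
  the 2D input preprocessing; extended by convention).
- The pre-attention 32-filter convolution uses a 3×3 kernel (size
  unstated).
- The no-attention baseline is defined as both branches minus their
  attention layers.

## Known limitations

- Desk-scale problem sizes only: the study condition used throughout is 30
  training proteins of length 24–48 at signal-to-noise 5, trained 10
  epochs; the numbers in the README come from these sizes.
- The tiny model's attention maps are only weakly differentiated *within*
  the true-positive group; the ablation contrast that is robust at this
  scale is high-attention true positives vs low-attention locations.
- No distance-bin prediction, no positional encodings, no attention
  dropout, no multi-GPU training; single-sequence (batch-1) processing
  throughout.
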