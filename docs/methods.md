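# Methods

## Data model and coordinates

A guide is stored as a 21-nt DNA string: the 20-nt protospacer plus the
first PAM base. All supported datasets fix the last two PAM bases to GG, so
23-nt inputs are verified to end in GG and truncated; comparisons that need
the full 23-mer restore the GG. The optional 30-nt context is laid out (0-
based, half-open) as [0,4) upstream, [4,24) guide, [24,27) PAM, [27,30)
downstream; the invariant `context30[4:25] == guide21` and
`context30[25:27] == "GG"` is enforced at construction. RNA inputs are
mapped U→T; letter order A,C,G,T and enzyme order WT, Esp, HF are frozen
constants so encodings are reproducible across runs.

Efficiencies are min-max normalized per dataset **before** any filtering
or splitting, and the raw min/max are recorded in a JSON sidecar so
predictions can be mapped back to the original scale. Guides lacking a
measurement under some enzyme keep an absent entry — nothing is imputed;
multi-task training simply flattens each guide into one sample per
*observed* condition, which is the only loss definition consistent with
partially measured guides.

## Leakage control

All similarity is Hamming distance over the 23-nt guide+PAM, with the
strict convention "edge iff distance < T". Three thresholds are in play:
source-vs-target removal uses distance < 4; the pre-training train/test
split links clusters at < 5; fine-tuning splits likewise at < 5.
Candidate pairs come from pigeonhole segmentation — a 23-mer split into
max_dist+1 segments (sizes 5,5,5,4,4 at max_dist 4) guarantees any pair
within max_dist agrees exactly on one segment — followed by exact
verification, then union-find with path compression for connected
components. This replaces the ~1.4×10¹⁰ pairwise comparisons a quadratic
scan would need at the scale of the combined source screens.

Split assignment walks clusters (by size, ties broken by smallest member
id, or in seeded random order) and gives each whole cluster to whichever
side is furthest below its quota; the achieved test fraction is within
max-cluster-size/N of the request. A cluster larger than both quotas goes
to train with a logged warning. When the test set is constrained to
fully-measured guides, the whole connected component containing an
incomplete test record moves to train — moving single records could leave
a near-duplicate pair straddling the split, and component moves provably
cannot.

## Architectures

Both model families are explicit computation graphs over a small
reverse-mode autodiff engine (float64 NumPy). Gradients are exact; the
test suite checks them against central finite differences.

**Recurrent.** One-hot tokens (start symbol + 21 nt, alphabet of 5) ×
embedding matrix → bidirectional gated recurrent encoder (GRU; the spec of
the contract is "bidirectional recurrent encoder", and the GRU provides it
with three gate products per step instead of four) → the full per-position
state sequence, flattened → concatenated with the 11 bio-features (and the
3-way enzyme indicator when multi-task) → dense cascade → sigmoid scalar.
Emitting the whole state sequence rather than only the final states keeps
every position directly visible to the head; with final states only, the
encoder must funnel all positional information through one vector, which
in practice under-represents middle positions in both accuracy and
saliency.

**Convolutional.** 30×4 one-hot context → three parallel 1-D convolution
branches (widths 3/5/7, 100 filters each by default, following the
published convolutional design this family mirrors) → global max pooling →
concat → dense → concat binding-energy scalar → dense → sigmoid scalar.
Pooling is max (config-exposed).

Every trainable parameter carries exactly one group tag
(`input_embedding_or_conv`, `sequence_encoder`, `dense_hidden`,
`last_hidden`, `output`); the "last hidden layer" is the final dense layer
before the output unit. Freezing is implemented by excluding parameters
from the optimizer and its state entirely, so frozen weights are
bit-identical afterwards — asserted exactly in tests. Multi-task
conditioning is a shared head fed the enzyme indicator as an input, not
separate per-enzyme heads.

## Bio-features and the energy feature

The recurrent model's 11 features are: mean predicted unpaired probability
over protospacer windows 1–7, 8–14, 15–20; the fraction of seed positions
(16–20) predicted paired (stem-loop); nearest-neighbor melting temperature
of the full 20-mer and segments 1–5, 6–13, 14–20 (biopython's Tm_NN); and
GC count, GC fraction, and seed GC fraction. The exact formulas are **this
package's defaults, not a published canon** — the contract downstream
training depends on is "11 deterministic finite reals per guide" — and all
window boundaries are exposed in `BioFeatureConfig`. Secondary structure
comes from a pluggable backend: the default is a deterministic
self-complementarity hairpin heuristic (longest complementary stem with a
≥3-nt loop), so the pipeline never requires an external tool; an adapter
for the ViennaRNA partition function is provided where its Python bindings
are importable.

The convolutional model's binding-energy feature (a ΔGB-style
approximation of Cas9–gRNA–DNA binding free energy) is consumed, never
re-implemented: it is ingested from a precomputed column or any injected
callable. A linear-in-GC proxy is provided for synthetic runs and labeled
as such.

## Training and transfer

Defaults follow the published convolutional protocol: Adam, learning rate
1e-4, batch 500, ensemble of 6 (all in `TrainConfig`). Pre-training
early-stops each member on a cluster-aware 10% validation carve-out; the
training log keeps an epoch-0 entry (the untrained starting point), and
early stopping restores the best epoch's weights — including epoch 0 if
training never helps, which makes a useless fine-tune degrade gracefully
to the no-transfer baseline. With patience p, training stops after p
consecutive epochs without a new validation best; patience 0 therefore
trains exactly one epoch.

Fine-tuning schemes map to trainable tag sets: `full` → all;
`last_layer` → {last_hidden, output}; `no_input_layer` → all minus the
embedding/convolution group; `gradual` → last-layer phase at the
configured learning rate, then all weights at learning_rate ×
`gradual_lr_factor` (default 0.1; the reduction factor is this package's
choice). The recurrent path fixes its epoch budget by cluster-aware
k-fold cross-validation: each fold fine-tunes a copy of the first ensemble
member with early stopping and the budget is the rounded (half away from
zero) mean of the per-fold best epochs, minimum 1. Only the first member
is used per fold because k × ensemble_size fine-tunes would dominate
runtime without materially changing a rounded mean. The convolutional path
fine-tunes with early stopping directly (patience 100, max 5000 epochs at
full scale). Whether the gradual scheme's first phase uses early stopping
or the fixed budget is not externally specified; it follows the same
epoch-determination rule as the second phase.

Ensemble reproducibility: member seeds fan out from the global seed via
`numpy` seed sequences; per-member shuffle seeds derive from (seed, member
index), so runs are repeatable yet members diverse.

Random hyper-parameter search samples from named choice lists over
architecture and optimization fields, scores each trial by validation
Spearman on a cluster-aware 10% carve-out, records failed trials at −∞,
and returns the argmax (the sampled point itself when there is only one
trial).

## Evaluation and significance

Spearman correlation with average ranks for ties (scipy); a constant
vector yields NaN with a warning rather than an exception, and NaN repeats
are excluded from means with a recorded count, so degenerate predictors
cannot crash a comparison. The repeated protocol draws five (configurable)
independent cluster-aware 80/20 splits — independent splits, not folds —
with logged seeds. Method comparisons use the two-sided Wilcoxon rank-sum
test: for groups of ≤10 scores the p-value is computed exactly by
enumerating all rank assignments (ties permute their average ranks);
larger groups use the tie-corrected normal approximation. The
cross-context matrix scores every model on every complete dataset; no
common rescaling is applied because Spearman is invariant to it.

## Saliency

Attribution of input feature j is the sample-mean gradient of the output,
I_j = (1/n) Σ_i ∂Y_i/∂X_{i,j}, computed per member and averaged over the
ensemble (by linearity this equals the attribution of the ensemble mean).
For the recurrent model the embedding lookup is computed as one-hot ×
embedding-matrix, so the gradient is taken at the one-hot layer where
nucleotide features live; the start symbol and the fixed PAM GG carry no
information and are dropped from the logo. Bio-feature and energy
attributions are reported in a sidecar, not the logo. Attributions are
signed by default; the renderer can also draw magnitudes. Logo matrices
are exported as plain TSV at full float precision (exact round-trips).

## The simulator

Each guide's true score is `logistic(Σ_j w[j, letter_j] + gc·(GC − 0.5))`;
observations add Gaussian noise and are min-max normalized per dataset
(each dataset gets its own normalization, as real datasets do). The
source and target weight matrices are mixed so their expected correlation
is ρ: `w_t = ρ·w_s + √(1−ρ²)·fresh`, and the scalar GC coefficient is
mixed by the same rule — a shared GC term would leave residual
source-target correlation even at ρ = 0, defeating the dial. The fixed
PAM GG rows carry no effect. Additive position-letter effects with a
logistic squash are the simplest mechanism making both saliency recovery
and transfer benefit well-posed; no biological fidelity is claimed, and
real-data features the simulator does not emulate (read-count noise
structure, library composition, indel spectra, chromatin context) mean
passing tests demonstrate correctness of the machinery, not real-data
performance.

Default study conditions: a 5000-guide source screen with observation
noise SD 0.1, a 300-guide target with noise SD 0.25, effect scale 0.15,
GC effect 0.5, ρ = 0.6. The target is noisier than the source because
that is the regime the method exists for — high-throughput screens are
large and self-consistent while functional and endogenous measurements
are small and noisy (observed-vs-true rank correlation ≈ 0.55 at these
settings, comparable to how well models fit real functional data).

## Desk-scale benchmark

`crisprtl.benchmarks` packages the two headline experiments so tests and
scripts run one protocol. Problem sizes were chosen to give a stable
contrast on one CPU core: a 16-unit recurrent encoder with embedding 8 and
dense (16, 8); pre-training at learning rate 0.01, batch 256, ≤50 epochs,
patience 8, ensemble 3; fine-tuning at 2e-3, batch 64, budget from 5-fold
cluster-aware cross-validation (5 rather than 10 folds so each fold's
validation split keeps a usable size at 240 training guides); the
from-scratch baseline gets a larger budget (≤120 epochs, patience 12)
because cold starts need more optimization than warm starts — comparing a
converged warm start against an under-trained cold start would overstate
transfer. Each arm is scored by three repeated cluster-aware 80/20 splits
per seed, and the per-seed source screen is shared between the ρ = 0.6 and
ρ = 0 arms (the source does not depend on ρ), halving compute.

## Numerical choices and limitations

* float64 everywhere; bit-reproducible on a fixed machine and BLAS.
* Sigmoid output keeps predictions in [0, 1]; divergent hyper-parameter
  trials therefore fail by score, not by overflow.
* Max-pool ties and ReLU kinks make one-hot-input gradients one-sided at
  measure-zero points; finite-difference checks use interior points.
* The exact rank-sum enumeration is O(C(n1+n2, n1)) and capped at groups
  of 10, matching its use on ensemble-size score collections.
* Hamming-only similarity: no alignment or k-mer criteria; guides of
  different lengths cannot be compared.
* The simulator's additive model cannot probe epistasis between positions;
  saliency recovery checks first-order effects only.
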