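# Methods

## Model

The classifier is a composition of four modules over an RGB image H with
multi-hot target y ∈ {0,1}^C (C = 8 by default):

1. **Feature extraction.**  X = f(H; θ) ∈ R^{D×h×w}.  Two interchangeable
   backbones implement the contract:
   - `inception_v3`: the standard Inception-v3 stage layout — stem
     (299→35×35×192), three Inception-A blocks (→35×35×288), grid reduction
     plus four Inception-B blocks (→17×17×768), a second reduction plus two
     Inception-C blocks (→8×8×2048) — with the conventional branch channel
     splits (≈21.8 M conv parameters).  The feature map is taken before
     global pooling; auxiliary classifiers are omitted because nothing in
     the relation pathway consumes them.
   - `tiny`: four 3×3 conv–BN–ReLU stages; the number of stride-2 stages is
     derived from the input/output sizes (64×64 → 8×8 uses three), channel
     widths D/8, D/4, D/2, D.  It exists so the full pipeline trains on one
     CPU in minutes.
   Pixels in [0,1] are rescaled to [−1,1] (Inception convention,
   switchable).
2. **LFA.**  1×1→mid, 3×3→mid (same padding), 1×1→C convolutions, each with
   batch norm (affine) and ReLU; `mid` is 1024 for the Inception
   configuration and D/2 (min 32) for tiny.  Channel-wise spatial softmax
   then yields A with each label channel a distribution over the h×w grid.
3. **ADA.**  SE gate: z_l = mean_{i,j} A_l(i,j); s = σ(W₂ ReLU(W₁ z)) with
   both FC layers C-dimensional (no reduction ratio); Ã_l = A_l s_l.
4. **ARL.**  Channels flattened to h·w vectors; shared linear maps
   W_Q, W_K : R^{h·w}→R^{d_K} (d_K = 64) and W_V : R^{h·w}→R^{h·w}, no
   biases.  Scores wS_ml = ⟨W_K fA_m, W_Q fA_l⟩ / √d_K, weights
   w_ml = softmax over sources m ≠ l (diagonal excluded), correlation
   features fR_l = Σ_{m≠l} w_ml W_V fA_m.  A per-label-parameters mode
   (each query label owns its three maps) is available via
   `ARLParams(per_label_params=True)`.
5. **Head.**  fM = Ã + fR; logit_l = spatial mean of fM_l; confidence =
   sigmoid(logit).

**Loss.**  Multilabel binary cross-entropy, summed over labels and averaged
over the batch, computed in the softplus form
`softplus(ŷ_l) − y_l ŷ_l` for numerical stability.

**A structural property worth knowing.**  Because every aggregated channel
is a spatial softmax, its spatial mean is identically 1/(h·w): the squeeze
vector z is constant, so the SE gate is a *learned per-label constant*
rather than an input-dependent one, and the pooled logit of the gated map
alone is s_l/(h·w), constant across samples.  Consequently (a) in the
without-ARL ablation the test-time confidences do not vary between images
and its ranking metrics sit at the prevalence baseline, and (b) in the full
model all image-dependent signal reaches the logits through the relation
branch (W_V and the attention weights).  The architecture is implemented as
specified; this property is documented rather than "fixed".

## Training protocol

Four stages, each with SGD (momentum 0.9, weight decay 5e-4) and
exponential learning-rate decay per epoch (γ = 0.95 default), batch size 16:

1. backbone, trained through its own pooled C-way sigmoid head (the
   "Linear" stage of the Inception layout, and exactly the all-ablated
   baseline head) — the relation pathway provides no useful gradient to the
   backbone before LFA is trained;
2. LFA + ADA with the backbone frozen;
3. ARL only;
4. joint fine-tuning.

Frozen modules keep parameters *and* batch-norm statistics bit-identical
across a stage (they run in inference mode).  When a validation split is
given, each stage reverts to its best-validation-mAP checkpoint.  All
batching randomness comes from a single seed; runs are deterministic.

Full-scale defaults are 2000/1000/1000/2000 iterations at base LR 1e-3
(the published recipe assumed an ImageNet-pretrained backbone).  The
desk-scale experiment (`farnet.experiments`) uses 240/160/160/640
iterations at base LR 0.2: the tiny backbone trains from random
initialization, and the rate was chosen from loss-curve convergence on a
one-fifth-scale dataset before any full-vs-ablation comparison was run.

**Initialization.**  Conv and FC weights are Kaiming-normal.  W_Q/W_K use
unit-std entries: their inputs are softmax-normalized maps with norm ≪ 1,
and fan-in scaling would put the initial attention scores near 1e-3, a flat
softmax that effectively never differentiates at desk scale.  W_V keeps the
1/√(h·w) fan-in scale so fused features start commensurate with the gated
maps.

## Synthetic data

`farnet.synthdata` emulates the unavailable jujube dataset.  The default
spec reproduces the published census literally: 15 combinations —
n 100; r, mr, sr, c, s, p, bp 80 each; r+p, r+c, mr+p, mr+c, bp+p, s+p 200
each; r+p+mr 20, r+p+c 20, mr+c+p 15, bp+sr+c 15 — totalling 1930 with
660/1200/70 by cardinality, 65.8% multilabel and peeling in 48.4% of
samples.  "Normal" never co-occurs with a defect (the census shows it only
alone).  Each image is a shaded reddish disc on a dark background with one
locally confined, geometrically distinct motif per label (tan speck
clusters for russeting, dark irregular blobs for rot, a thin dark polyline
for cracking, concentric rings for shriveling, a bright patch for peeling,
a rimmed hole for bird pecking), plus mild Gaussian pixel noise.  Motif
positions are uniform inside the disc; rendering is a pure function of
(combo, motif parameters, rng state).

What this emulates: the label vocabulary, the exact co-occurrence census,
and locally confined label-specific evidence that makes one-channel-per-
label aggregation learnable.  What it does not: photographic appearance,
lighting/pose variation, inter-defect occlusion, or ambiguous boundaries
between mild and severe rot.  Tests passing on this generator therefore
demonstrate the mechanics of the architecture and training protocol, not
field performance on real produce.

The 3:1:1 train/val/test split is stratified by label combination with
largest-remainder apportionment (every census count is divisible by 5, so
the split is exact: 1158/386/386) and a seeded permutation.

## Evaluation

Per-label AP is every-point average precision: mean of the running
precision at each positive in the confidence-ranked list (stable descending
sort; ties keep input order).  mAP is the arithmetic mean over labels with
at least one positive.  Thresholded metrics binarize strictly
(positive iff confidence > 0.5 by default); 0/0 precision or recall is
reported as 0 with an explicit undefined flag.  Micro-F1 pools TP/FP/FN
globally; macro-F1 averages per-label F1.  The confidence grid is the N×k
matrix of per-label confidences (default k = 4: r, mr, c, p) with a
pairwise scatter figure.

## Numerical choices

- float64 throughout; softmaxes are max-shifted; the logistic is computed
  via tanh; softplus via `logaddexp`.
- Batch norm: batch statistics in training, running averages (momentum 0.1)
  at inference, ε = 1e-5.
- Attention-weight columns over m ≠ l sum to 1 to 1e-6; the diagonal is
  excluded by masking before the softmax.
- The attention scale divides by √d_K (the scaled dot-product convention);
  `ARLParams(scale="dk")` selects division by d_K instead.
- AP with zero positives raises; the report-level wrapper instead excludes
  such labels from the mAP mean and flags them.

## Desk-scale mechanism experiment

`run_mechanism_experiment(seed, n_seeds=3)` generates the full 1930-image
census at 64×64, trains the full tiny-backbone network and its without-ARL
ablation from scratch for each of three seeds, and reports mean test mAP
for both plus the mean attention weight over label pairs that co-occur in
the census versus pairs that never do (measured on the test split).  The
expected qualitative outcome — the full model outranks the ablation and
co-occurring pairs attract larger attention weights — is the desk-scale
analogue of the module-occlusion comparison; absolute mAP values are *not*
comparable to full-scale results (different backbone, no pretraining,
synthetic data).

## Known limitations

- The SE gate is input-independent (see the structural property above);
  "activation/deactivation" therefore acts as a learned static per-label
  scale, and ablating it changes little at desk scale.
- The without-ARL configuration is evaluated exactly as specified
  (pooling the gated aggregated map), which makes it a prevalence-level
  baseline at test time.
- The NumPy engine is single-threaded apart from BLAS matmuls; training the
  Inception backbone end-to-end is possible but not practical — it is
  intended for shape-contract verification and inference experiments.
- Checkpoints store raw arrays keyed by module path (`.npz`); there is no
  cross-version migration.
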