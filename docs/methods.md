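# Methods

This note documents the model, the numerical choices, and what the
synthetic experiments do and do not show.  It is the package's own
account of its design; everything quantitative here is computed by the
test suite or by `scripts/acceptance.py`.

## Feature model

Band-limited EEG within a short window is treated as a stationary
Gaussian process, so its differential entropy has the closed form
½·ln(2πe·σ²) with σ² the window's signal variance.  We use the unbiased
sample variance and natural logarithms (nats).  Windows are 1 s,
non-overlapping, a common convention for this family of datasets; the
length is configurable (`window_s`).  Filters are zero-phase
forward-backward Butterworth band-passes of order 4 — zero-phase so
that trial boundaries stay aligned, Butterworth for a flat pass-band;
family and order are configurable.  A broad 0–75 Hz pre-filter stage is
available behind a flag, but by default the five per-band filters alone
define the analysis bands (their union lies inside any such pre-filter,
which therefore changes next to nothing).  Raw signals at other rates
are polyphase-resampled to 200 Hz.

Per-recording feature normalization is a per-column z-score using that
recording's own statistics.  The scope matters: statistics are never
pooled across recordings, so the unlabeled target's statistics cannot
leak into the sources (and vice versa), keeping the protocol honestly
unsupervised.  Constant columns map to zero.  The switch is exposed as
an ablation (`normalize=False`).

## Network and objective

Architecture (widths fixed by the method's design): common extractor
310 → 256 → 128 → 64 (three affine layers, LeakyReLU slope 0.01 after
each — the two hidden widths are our choice of a smooth geometric
reduction, configurable); per domain, three parallel branches
64 → 64 → 64 → {48, 32, 16} (three affine layers each, LeakyReLU after
each); per domain, one affine classifier 96 → M with softmax.  The
"single representation" ablation (`mdsfe=False`) replaces each bank
with one 64 → 64 → 64 → 96 branch so the classifier width is unchanged
and the comparison isolates the multi-representation effect.  Weights
are initialised with a seeded uniform fan-in scheme, U(±1/√fan_in).

The alignment loss is the squared maximum mean discrepancy with a
mixture of five Gaussian kernels whose squared bandwidths are spaced by
factors of 2 around half the median pairwise squared distance of the
joint batch — the usual convention in deep domain adaptation; the
method itself does not prescribe a kernel.  The biased V-statistic is the default:
it is non-negative and stable on minibatches; the unbiased U-statistic
is available by flag.  Bandwidths are treated as constants of the
current batch — no gradient flows through the median heuristic.
Because the whole stack is plain numpy, the MMD gradient is analytic:
for the Gaussian kernel ∂k(a,b)/∂a = −k(a,b)(a−b)/σ², accumulated over
the estimator's pair weights; it is verified against finite differences
in the test suite.

Per optimisation step, one batch is drawn per source domain plus one
unlabeled target batch; all domains are updated jointly in a single
Adam step (lr 0.01, β₁ 0.9, β₂ 0.999, no weight decay — only the
learning rate is prescribed; the rest are standard defaults).  One
epoch is one pass over the pooled source windows
(⌈Σᵢ nᵢ / batch⌉ steps).  Domains smaller than the batch are sampled
with replacement (logged).  The trade-off coefficient follows
α(i) = 2/(1+e^(−10·i/epochs)) − 1 with i the 0-based epoch index, so
α(0) = 0: classification is learned first, alignment dominates later.
A per-step variant of the schedule is available by flag.

Source and target batch indices come from independent seeded RNG
streams, so disabling the alignment term (`compute_mmd=False`)
reproduces the pure multi-head classifier trajectory bit-for-bit at
α = 0 — a useful equivalence that the tests assert.  Two runs with the
same configuration and seed are bitwise identical.

At inference the N heads' softmax outputs are averaged uniformly and
ties break toward the lowest class index.  Uniform averaging is the
simplest symmetric fusion rule; the method itself does not prescribe
one, and per-domain weighted fusion is deliberately out of scope.
Evaluation is window-level accuracy by default; a trial-level majority
vote is available (`trial_vote=True`).

## Degenerate inputs and numerical guards

Zero-variance windows raise rather than return −∞ (differential
entropy diverges).  Cross-entropy clamps the predicted probability at
the true class to 1e−12 and logs the event.  MMD batches need at least
two points per side (the singleton relaxation exists only for
closed-form checks).  An odd number of source recordings is a hard
error by default; `allow_singleton` admits a final one-member domain.

## The synthetic study

Real cross-subject EEG corpora in this family are license-gated, so
the package's empirical claims are made on synthetic data whose
structure mirrors theirs: a subject × session grid of recordings, each
a windows × 310 class-conditional Gaussian feature tensor.  DE
features are strongly collinear across channels in practice, so the
generator embeds a low-rank latent mixture (default rank 10) into the
310 observed columns through a random orthonormal basis, plus small
sensor noise (σ/10).  Classes are separated by `delta_class` = 3σ along
orthogonal latent directions.  Each recording applies its own
distortion, scaled by `delta_domain` = 1.5:

* an additive per-column mean offset ~ N(0, (1.5σ)²) — electrode
  baseline differences;
* a log-normal per-column gain — impedance/amplification differences;
* a per-class latent mean displacement (std 0.7·1.5σ per latent
  dimension), drawn **orthogonal** to the shared class-separation
  subspace — recording-specific emotion-correlated activity that does
  not generalise across recordings.

The first two are removed exactly by per-recording standardization;
the displacement survives it and is what makes the transfer problem
non-trivial.  Within any one recording the displaced directions are
genuinely class-informative, so a source-only model learns them; on
the target they point elsewhere and the model's accuracy drops.  They
are also exactly where source and target marginals disagree, so the
alignment loss suppresses them, forcing the representation onto the
shared class subspace — which is how adaptation recovers the lost
accuracy.  The orthogonality matters for a second reason: a
displacement component *along* the class-separation directions moves
clusters toward each other's positions, and once it approaches the
class separation, marginal alignment can map target clusters onto the
wrong source clusters and fail catastrophically (accuracy far below
chance on individual partitions — a genuine failure mode of the
method, observed in pilots with isotropic displacement, not an
implementation artefact).  Orthogonal displacement leaves cluster
correspondence unambiguous at any realistic scale, the regime in which
unlabeled alignment is well-posed.

The default transfer suite is a 5-subject × 2-session grid, giving ten
cross-subject leave-one-out partitions with N = 2 paired source
domains each, 200 windows per recording — sized so the full ablation
grid (4 variants × 10 partitions, 50 epochs each) trains in minutes on
one CPU.  On this suite the full model's mean target accuracy exceeds
0.8 and beats the α = 0 (no-adaptation) ablation by more than five
accuracy points.  Removing per-recording normalization costs by far
the most (the raw offsets and gains are large); the
single-representation variant sits within a point or two of the full
model, so that ordering is directional only — consistent with the
sub-point gap the method reports between these variants on real data.

What passing this suite shows: the pipeline is internally consistent
end-to-end — features, pairing, the joint objective, the analytic
gradients and the schedule interact as designed, and kernel alignment
on unlabeled data recovers accuracy lost to a realistic *family* of
between-recording distortions.  What it does not show: performance on
real EEG, whose shifts are neither Gaussian nor low-rank-linear, and
whose class structure is far less clean than `delta_class` = 3σ.

## Known limitations

* Marginal alignment cannot distinguish correct from permuted cluster
  correspondence when between-recording class displacement approaches
  the class separation; no safeguard beyond the schedule exists.
* The MMD is estimated on minibatches; per-step estimates are noisy
  and the objective value at α ≈ 1 fluctuates accordingly.
* The MAT-container reader implements the documented extracted-feature
  layout (per-trial channels × bands × windows arrays) and is
  validated only against synthetic fixtures shaped that way.
* Training is single-threaded numpy; it is sized for desk-scale
  studies, not for large grids.
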