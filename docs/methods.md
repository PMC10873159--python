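# Methods

## Setting and model of the data

The package simulates federated partially-supervised segmentation (FPSS):
`N` clients share one anatomy concept (the same `Nc = 4` organ classes) but
each in-federation client annotates only a subset `Ci ⊂ {1..Nc}`, with the
three in-FL annotated sets pairwise disjoint and jointly covering all
classes; a fourth, fully annotated client is held out of training and used
only to measure generalization.

The phantom generator realises this with ellipsoidal "organs" placed by
rejection sampling (disjointness is guaranteed by construction; a
configurable attempt cap turns impossible geometries into a diagnostic
error naming the class).  Class identity is carried by per-class intensity
plateaus (background 0.15, kidney 0.45, spleen 0.55, liver 0.65, pancreas
0.80 in arbitrary units), and client identity by a `DomainProfile` applied
in the order blur → contrast → bias → additive Gaussian noise.  The in-FL
profiles differ moderately (bias −0.05..+0.05, contrast 0.9..1.1, noise
0.02..0.04, blur 0..0.5); the held-out client's profile lies outside their
convex hull (bias 0.12, contrast 0.8, noise 0.06, blur 0.8) so that the
out-FL score is a genuine domain-shift measurement.  Default data: 64×64
images, 16 per client (12 train / 4 test, disjoint split).  Sixteen samples
per client are enough for the pseudolabel baseline to plateau before the
late-phase modules activate, matching the reference schedule in which the
global teacher takes over only after convergence.

What the phantoms deliberately do **not** model: CT physics (beam
hardening, reconstruction artifacts), anatomical shape priors and organ
adjacency, resampling/patching pipelines, 3-D context (a 3-D phantom mode
exists, but the network is 2-D).  Consequently, passing end-to-end tests
shows that the *algorithmic* pipeline behaves as designed under controlled
class heterogeneity and client drift — not that it would reach any
particular accuracy on clinical CT.

## Network and optimizer

The segmentation function is a two-resolution U-shaped CNN (3×3 conv →
2×2 average pool → 3×3 conv → nearest ×2 upsampling → skip concatenation →
3×3 conv → 1×1 head, LeakyReLU slope 0.05, width 6 → ~1.7k parameters)
implemented on numpy with analytic backward passes; gradients are verified
against central finite differences (relative error ≤ 1e-3) in the test
suite.  LeakyReLU rather than ReLU is load-bearing at this width: dead-unit
initialisations otherwise occasionally silence an entire class channel,
which at federation scale leaves the global model near chance exactly when
the late-phase modules assume convergence.

The parameter partition (encoder = the two downsampling convs, decoder =
the post-skip conv, head = the 1×1 classifier) is exposed through a flat
`ParamVector`; "decoder" for uncertainty-aware aggregation means decoder +
head, the part of the network closest to the prediction.

The inner optimizer is Adam (lr 0.02).  Per-position second moments are
needed because the gradient scale of rare-organ head channels differs from
the trunk by orders of magnitude; plain SGD stalls in background-only
optima on these losses.  Client Adam moments persist across rounds (the
incoming global weights replace the parameters but not the optimizer
state).  The sparse sharpness-aware step keeps a pluggable `step_fn` so its
degeneracy contract (full mask ≡ adaptive SAM; zero radius ≡ one plain
gradient step) is asserted against plain SGD, exactly.

Teachers train for 60 epochs on their client's partial labels only; if the
held-out Dice sanity bound (0.5) fails — the dead-init symptom — the
teacher retrains from a fresh init, up to three attempts, and the failure
is logged.

## Pipeline conventions and defaults

Parameters the method needs but whose values are implementation choices
(units in parentheses; all exposed in config):

| parameter | default | meaning / why |
| --- | --- | --- |
| `v` | 0.5 | foreground-overlap fraction gating teacher∩global fusion; evaluated per training image (the unit fed to the network) |
| `T` | 80 (percentile) | bank percentile separating head from tail samples |
| `τ_μ, τ_σ` | 0.1 | softmax temperatures on bank mean/variance |
| ramp scale | 20 | reverse-CE coefficient `exp(−20(1−r/R))` |
| `TL` | 0.6 | local top-k mask fraction (≈ the fraction of steep gradients) |
| `TG` | 0.1 | extra-mask fraction of total positions |
| `α_mo` | 0.9 | momentum of the momentum-gradient accumulator |
| `r_fre` | 5 (rounds) | mask refresh period; the activation round always refreshes so no mask can be stale |
| `ρ` | 0.01 | ascent radius. At ~1.7k parameters a radius of 0.05 produces perturbations larger than typical Adam steps and a reproducible dip at optimizer activation; 0.01 is stable and preserves the generalization benefit |
| `η` | 0.01 | adaptive-scaling offset `T = diag(|w|+η)` |

Numerical conventions, fixed once and used end-to-end:

* **Entropy** is averaged over all `Nc+1` channels (natural log), and the
  per-sample uncertainty averages over all channels as well (a switch
  restricts it to foreground).  The per-class denominator carries add-one
  smoothing so absent classes contribute 0, not ∞.
* **Tail-shift normalisation** `(U_j − μ)/(U_max − U_min)` is taken
  literally (it can be negative); a degenerate bank (max = min) normalises
  to 0.  Banks accumulate through warm-up, then roll to the latest round's
  scores so summaries track the current model.
* **Reverse CE** uses the conventional `log 0 := −4` clamp (p clamped to
  `e^{−4}`) and is normalised over voxels × channels so it shares the base
  loss's scale.  A tighter clamp (1e-4) with voxel-only normalisation makes
  the term ~10× the base loss near the end of training and reliably
  collapses the model toward the pseudolabels' background — inconsistent
  with this loss being a mild late-training refinement.
* **Soft Dice** uses ε = 1e-5 in numerator and denominator; BCE clamps
  probabilities at 1e-7.  The tail-shift weight multiplies the whole
  per-sample loss (base + reverse-CE).
* **Fusion ties**: the merge priority is descending expected organ volume
  (liver, spleen, kidney, pancreas); top-k mask ties break toward the lower
  index; the ascent perturbation is computed from the *full* gradient and
  then masked (a flag switches to mask-before-normalise).
* **Empty-foreground fusion** returns the global prediction unchanged
  (vacuous overlap condition).
* **Metrics**: Dice with empty∩empty := 1; Hausdorff on inner-boundary
  voxels in voxel units, 95th-percentile variant by default in reports,
  image-diagonal sentinel for empty masks.  Post-processing fills holes
  (4-connectivity) and removes components below `min_size` (8-connectivity),
  and is idempotent.

## Schedule

The desk-scale default compresses the reference 500-round schedule
proportionally: 30 rounds, 3 warm-up rounds (linear LR ramp 10%→100%),
global-main-teacher fusion and the sparse optimizer both activating at
round 15, mask refresh every 5 rounds; `FederationConfig.paper_profile()`
restores 500/10/300/300.  One local epoch per communication round; full
client participation.  Aggregation weights are recomputed from the shipped
bank summaries each round; with uncertainty-aware aggregation disabled the
server reduces to sample-proportional federated averaging everywhere.

Baseline modes: `FedAvg*` (pseudolabels + Dice/BCE, all other modules off)
and `SOLO` (isolated local training on partial labels only, no
pseudolabels — its models are exactly what the class-specific teachers
are).  The 11-row module-toggle grid from SOLO through the full method is
exposed as `ABLATION_GRID`.

## What the end-to-end comparison shows

Across three seeds at the defaults, the full method and the pseudolabel
baseline fit the in-federation clients about equally well, while the full
method generalizes substantially better to the held-out domain-shifted
client, and both dominate isolated training; the margins are computed
afresh by `scripts/acceptance.py` and asserted by the test suite rather
than quoted here.  The gain concentrates in the sparse sharpness-aware
optimizer and the global-teacher fusion; at this scale the uncertainty
reweightings are small corrections, consistent with their role as
refinements.

## Known limitations

* The phantom task is intensity-separable, so teachers approach Dice 1.0 on
  their own domain; the pseudolabel noise that the denoising modules target
  comes only from the cross-client domain shift and is milder than in
  clinical data.
* With near-perfect teachers the global-main-teacher fusion cannot improve
  on them in-domain; its observable benefit is on the held-out domain.
* Training runs are deterministic given a seed on a fixed platform, but
  bit-level reproducibility across BLAS builds is not guaranteed; the
  end-to-end assertions are therefore formulated on seed-averaged margins,
  not trajectories.
* Single-channel 2-D images and one batch element per step; the optimizer
  contracts do not depend on this, but wall-clock scaling to 3-D volumes
  was not a goal.
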