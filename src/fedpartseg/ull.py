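"""Unified label learning: pseudolabel fusion, uncertainty, and losses.

In federated partially-supervised segmentation each client annotates only a
subset Ci of the organ classes; everything else is collapsed into the
background.  Unified label learning completes the missing classes by
distillation from class-specific teacher models so every client trains on
the full label space, and then treats the result as a noisy-label problem:

* :func:`teacher_pseudolabel` merges per-teacher predictions (background =
  intersection of all teachers' backgrounds, foreground merged in a fixed
  priority sequence) and overwrites the annotated classes with ground truth;
* :func:`gmt_fuse` refines late-round pseudolabels by intersecting the
  global model's prediction (the "global main teacher") with the local
  teachers whenever the overlap volume is large enough;
* :func:`sample_uncertainty` scores each sample by pseudolabel-weighted mean
  prediction entropy; scores accumulate in a per-client
  :class:`UncertaintyBank` whose mean/variance feed both aggregation
  re-weighting (:func:`ua_weights`) and the tail-shift loss scheduler
  (:func:`ts_weight`);
* :func:`base_loss` (soft Dice + BCE) and :func:`arce_loss` (reverse
  cross-entropy ramped up over training) supply the training signal, with
  analytic gradients with respect to the softmax probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import softmax  # noqa: F401  (re-exported convenience)

__all__ = [
    "ULLConfig",
    "TeacherEnsemble",
    "UncertaintyBank",
    "merge_teacher_predictions",
    "apply_ground_truth",
    "teacher_pseudolabel",
    "gmt_fuse",
    "voxel_entropy",
    "sample_uncertainty",
    "ua_weights",
    "ts_weight",
    "arce_coefficient",
    "arce_loss",
    "one_hot",
    "dice_loss",
    "bce_loss",
    "base_loss",
    "softmax_grad_to_logits",
]


@dataclass(frozen=True)
class ULLConfig:
    """Knobs of the unified-label-learning pipeline.

    v           volume-overlap fraction in (0, 1] gating global/teacher fusion
    T           bank percentile (0, 100) separating head from tail samples
    tau_mu      softmax temperature for bank means (> 0)
    tau_sigma   softmax temperature for bank variances (> 0)
    rce_scale   exponential ramp constant of the adaptive RCE coefficient
    gmt_start_round  round at which the global model becomes the main teacher
    """

    v: float = 0.5
    T: float = 80.0
    tau_mu: float = 0.1
    tau_sigma: float = 0.1
    rce_scale: float = 20.0
    gmt_start_round: int = 300
    entropy_include_background: bool = True

    def __post_init__(self):
        if not 0 < self.v <= 1:
            raise ValueError("v must be in (0, 1]")
        if not 0 < self.T < 100:
            raise ValueError("T must be in (0, 100)")
        if self.tau_mu <= 0 or self.tau_sigma <= 0:
            raise ValueError("temperatures must be positive")


# ---------------------------------------------------------------------------
# pseudolabel fusion


@dataclass
class TeacherEnsemble:
    """Frozen class-specific teachers plus the global merge priority.

    Each entry pairs a model with the class set it was pretrained on; only
    those channels of its prediction are trusted.  ``priority`` is a
    permutation of all classes; earlier classes claim contested voxels
    first.
    """

    teachers: list = field(default_factory=list)  # [(model, frozenset), ...]
    priority: tuple = ()

    def class_cover(self):
        return frozenset().union(*[cs for _, cs in self.teachers] or [frozenset()])

    def predict_maps(self, image):
        """Per-teacher label maps, each restricted to its trusted classes."""
        out = []
        for model, class_set in self.teachers:
            pred = model.predict_labels(image)
            pred = np.squeeze(pred)
            pred = np.where(np.isin(pred, list(class_set)), pred, 0)
            out.append((pred.astype(np.int16), class_set))
        return out


def merge_teacher_predictions(preds, priority):
    """Merge per-teacher label maps into one full-class map.

    A voxel stays background iff every teacher calls it background.
    Foreground classes are painted in ``priority`` order: a class earlier in
    the sequence claims a voxel first; later classes fill only voxels still
    unassigned.
    """
    if not preds:
        raise ValueError("need at least one teacher prediction")
    out = np.zeros_like(preds[0][0])
    for c in priority:
        owners = [p for p, cs in preds if c in cs]
        for pred in owners:
            out = np.where((out == 0) & (pred == c), c, out)
    return out


def apply_ground_truth(pseudolabel, gt, annotated_set):
    """Replace the annotated classes of a pseudolabel with ground truth."""
    if not annotated_set:
        return pseudolabel.copy()
    ci = list(annotated_set)
    out = np.where(np.isin(pseudolabel, ci), 0, pseudolabel)
    out = np.where(np.isin(gt, ci), gt, out)
    return out.astype(pseudolabel.dtype)


def teacher_pseudolabel(image, ensemble: TeacherEnsemble, gt, annotated_set,
                        n_classes=None):
    """Full-class pseudolabel for one sample from the teacher ensemble.

    Every class must be either covered by some teacher or locally annotated,
    otherwise the label space is not unified and an error is raised.
    """
    if n_classes is not None:
        needed = set(range(1, n_classes + 1)) - set(annotated_set)
        uncovered = needed - set(ensemble.class_cover())
        if uncovered:
            raise ValueError(
                f"classes {sorted(uncovered)} neither teacher-covered nor annotated"
            )
    preds = ensemble.predict_maps(image)
    merged = merge_teacher_predictions(preds, ensemble.priority)
    return apply_ground_truth(merged, gt, annotated_set)


def gmt_fuse(global_pred, teacher_pred, v):
    """Fuse the global main teacher's prediction with the local teachers.

    When the foreground supports of the two predictions overlap by at least
    ``v`` times the global foreground volume, the voxel-wise intersection
    (same nonzero class in both) is returned; otherwise — including the
    degenerate empty-global-foreground case — the global prediction is
    trusted as-is.
    """
    if not 0 < v <= 1:
        raise ValueError("v must be in (0, 1]")
    global_pred = np.asarray(global_pred)
    teacher_pred = np.asarray(teacher_pred)
    if global_pred.shape != teacher_pred.shape:
        raise ValueError("predictions must share one grid")
    fg_g = global_pred != 0
    n_g = int(fg_g.sum())
    if n_g == 0:
        return global_pred.copy()
    overlap = int((fg_g & (teacher_pred != 0)).sum())
    if overlap < v * n_g:
        return global_pred.copy()
    agree = fg_g & (teacher_pred == global_pred)
    return np.where(agree, global_pred, 0).astype(global_pred.dtype)


# ---------------------------------------------------------------------------
# uncertainty


def voxel_entropy(prob):
    """Channel-averaged Shannon entropy per voxel, natural log.

    ``prob`` has channels on axis 0; the map is
    ``-(1/C) * sum_c p_c log p_c`` with the 0·log0 = 0 convention.
    """
    prob = np.asarray(prob, dtype=np.float64)
    if prob.min() < -1e-9 or prob.max() > 1 + 1e-9:
        raise ValueError("probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(prob > 0, prob * np.log(prob), 0.0)
    return -plogp.sum(axis=0) / prob.shape[0]


def sample_uncertainty(entropy_map, q_onehot, include_background=True):
    """Data-wise uncertainty: pseudolabel-masked mean entropy per class.

    ``q_onehot`` holds binary per-class indicator maps on axis 0 (channel 0
    = background).  Each class contributes its entropy mass inside the
    pseudolabel region, normalised by the region volume plus one (add-one
    smoothing keeps absent classes finite); the class contributions are then
    averaged.
    """
    q = np.asarray(q_onehot, dtype=np.float64)
    e = np.asarray(entropy_map, dtype=np.float64)
    if q.shape[1:] != e.shape:
        raise ValueError("entropy map and indicator maps must be aligned")
    channels = range(q.shape[0]) if include_background else range(1, q.shape[0])
    channels = list(channels)
    total = 0.0
    for c in channels:
        total += float((e * q[c]).sum()) / (float(q[c].sum()) + 1.0)
    return total / len(channels)


class UncertaintyBank:
    """Per-client append-only store of sample uncertainty scores.

    Accumulated during warm-up, then (by the orchestrator) trimmed to a
    rolling window of the most recent round so the summaries track the
    current model.
    """

    def __init__(self):
        self._values = []

    def add(self, u):
        u = float(u)
        if u < 0:
            raise ValueError("uncertainty scores must be nonnegative")
        self._values.append(u)

    @property
    def values(self):
        return np.asarray(self._values, dtype=np.float64)

    def __len__(self):
        return len(self._values)

    @property
    def is_empty(self):
        return not self._values

    def _require(self):
        if self.is_empty:
            raise ValueError("uncertainty bank is empty")

    @property
    def mean(self):
        self._require()
        return float(np.mean(self._values))

    @property
    def var(self):
        self._require()
        return float(np.var(self._values))

    @property
    def max(self):
        self._require()
        return float(np.max(self._values))

    @property
    def min(self):
        self._require()
        return float(np.min(self._values))

    def percentile(self, T):
        """Uncertainty value below which the lowest ``T`` percent lie."""
        self._require()
        return float(np.percentile(self._values, T))

    def trim_to_last(self, n):
        """Keep only the ``n`` most recent scores (rolling window)."""
        if n < 1:
            raise ValueError("window must keep at least one score")
        self._values = self._values[-n:]


def ua_weights(mu, sigma, aw, tau_mu=0.1, tau_sigma=0.1):
    """Uncertainty-aware aggregation weights.

    Mean of three simplex vectors: softmax of the negative bank means
    (temperature ``tau_mu``), softmax of the negative bank variances
    (``tau_sigma``), and the sample-proportional weights ``aw``.  Clients
    with lower pseudolabel uncertainty receive weakly larger weight; the
    output is again on the simplex.
    """
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    aw = np.asarray(aw, dtype=np.float64)
    if not (mu.shape == sigma.shape == aw.shape) or mu.ndim != 1:
        raise ValueError("mu, sigma, aw must be 1-D vectors of equal length")
    if tau_mu <= 0 or tau_sigma <= 0:
        raise ValueError("temperatures must be positive")
    if (aw < -1e-12).any() or abs(aw.sum() - 1.0) > 1e-9:
        raise ValueError("aw must lie on the probability simplex")

    def _softmax(x):
        z = x - x.max()
        e = np.exp(z)
        return e / e.sum()

    return (_softmax(-mu / tau_mu) + _softmax(-sigma / tau_sigma) + aw) / 3.0


# ---------------------------------------------------------------------------
# schedulers


def ts_weight(u_j, bank: UncertaintyBank, T, r, R):
    """Tail-shift loss weight for one sample.

    norm(U) = (U - bank mean) / (bank max - bank min); samples above the
    bank's T-th percentile (the uncertain tail) get the round-ramped branch
    ``2 - exp(norm - r/R)`` so hard samples gain emphasis as training
    progresses, others get ``2 - exp(norm)``.  A degenerate bank (max ==
    min) normalises to 0.
    """
    bank._require()
    if not 0 <= r <= R:
        raise ValueError("need 0 <= r <= R")
    spread = bank.max - bank.min
    norm = 0.0 if spread == 0 else (float(u_j) - bank.mean) / spread
    if float(u_j) > bank.percentile(T):
        return 2.0 - float(np.exp(norm - r / R))
    return 2.0 - float(np.exp(norm))


def arce_coefficient(r, R, scale=20.0):
    """Ramp ``exp(-scale * (1 - r/R))``: ~0 at round 0, exactly 1 at r = R."""
    if r > R:
        raise ValueError("current round r cannot exceed total rounds R")
    return float(np.exp(-scale * (1.0 - r / R)))


def arce_loss(pred_prob, target_onehot, r, R, rce_scale=20.0, clip=None,
              return_grad=False):
    """Adaptive reverse cross-entropy.

    Reverse CE swaps the roles of prediction q and (hard, clamped) target p:
    ``-mean sum_c q_c log p_c`` with the conventional log 0 := -4, i.e. p
    clamped to [e^-4, 1], and the mean taken over voxels and channels like
    the base BCE term so the two losses share a scale.  The ramp coefficient
    lets the student's own predictions take over supervision only once they
    have become reliable late in training.
    """
    coeff = arce_coefficient(r, R, rce_scale)
    q = np.asarray(pred_prob, dtype=np.float64)
    if clip is None:
        clip = float(np.exp(-4.0))
    p = np.clip(np.asarray(target_onehot, dtype=np.float64), clip, 1.0)
    logp = np.log(p)
    loss = -coeff * float((q * logp).sum()) / q.size
    if not return_grad:
        return loss
    dq = -coeff * logp / q.size
    return loss, dq


# ---------------------------------------------------------------------------
# base segmentation losses (channel axis 0, one sample)


def one_hot(labels, n_channels):
    """Integer label map -> (n_channels, *spatial) float indicator stack."""
    labels = np.asarray(labels)
    out = np.zeros((n_channels,) + labels.shape, dtype=np.float64)
    for c in range(n_channels):
        out[c] = labels == c
    return out


def dice_loss(prob, target_onehot, eps=1e-5, return_grad=False):
    """Soft Dice loss averaged over channels, with add-eps smoothing."""
    p = np.asarray(prob, dtype=np.float64)
    t = np.asarray(target_onehot, dtype=np.float64)
    C = p.shape[0]
    axes = tuple(range(1, p.ndim))
    inter = (p * t).sum(axis=axes)
    sums = p.sum(axis=axes) + t.sum(axis=axes)
    dice = (2 * inter + eps) / (sums + eps)
    loss = float((1 - dice).mean())
    if not return_grad:
        return loss
    shape = (C,) + (1,) * (p.ndim - 1)
    num = (2 * inter + eps).reshape(shape)
    den = (sums + eps).reshape(shape)
    ddice_dp = (2 * t * den - num) / den**2
    return loss, -ddice_dp / C


def bce_loss(prob, target_onehot, clip=1e-7, return_grad=False):
    """Per-channel binary cross-entropy, mean over channels and voxels."""
    p = np.clip(np.asarray(prob, dtype=np.float64), clip, 1 - clip)
    t = np.asarray(target_onehot, dtype=np.float64)
    n = p.size
    loss = -float((t * np.log(p) + (1 - t) * np.log(1 - p)).sum()) / n
    if not return_grad:
        return loss
    return loss, (p - t) / (p * (1 - p)) / n


def base_loss(prob, target_onehot, sample_weight=1.0, eps=1e-5,
              return_grad=False):
    """Dice + BCE composite, scaled by the per-sample scheduler weight."""
    if not return_grad:
        return sample_weight * (
            dice_loss(prob, target_onehot, eps) + bce_loss(prob, target_onehot)
        )
    ld, gd = dice_loss(prob, target_onehot, eps, return_grad=True)
    lb, gb = bce_loss(prob, target_onehot, return_grad=True)
    return sample_weight * (ld + lb), sample_weight * (gd + gb)


def softmax_grad_to_logits(prob, dprob):
    """Chain d(loss)/d(prob) through per-voxel softmax to the logits."""
    inner = (dprob * prob).sum(axis=0, keepdims=True)
    return prob * (dprob - inner)
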