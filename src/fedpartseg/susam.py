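"""Sparse unified sharpness-aware minimization (sUSAM).

Sharpness-aware minimization takes a two-step view of each update: an
*ascent* step to the locally sharpest nearby point, then a *descent* step
from the original weights using the gradient measured at the perturbed
point.  The unified variant decouples the data of the two steps — the
ascent gradient is computed on strongly augmented images (standing in for
the unseen global data distribution), while the descent gradient is
computed on the client's original images so local fitting ability is kept.
The sparse variant perturbs only a masked subset of parameter positions:

* ``ML``    — local top-k mask of the current ascent gradient magnitudes,
* ``ML,mo`` — top-k mask of the client's momentum gradients, shipped to the
  server after local training,
* ``MG``    — global mask marking positions where the clients' momentum
  masks *disagree* (neither everybody nor nobody selected them),
* ``ME``    — a small random sample of ``MG``-only positions, re-injecting
  directions other clients consider important.

Mask refresh happens every ``r_fre`` rounds; in between, frozen history
masks are reused and momentum gradients are not accumulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SUSAMConfig",
    "asam_ascent",
    "update_momentum",
    "topk_mask",
    "merge_global_mask",
    "extra_mask",
    "susam_step",
    "relative_diff_ratio",
    "strong_augment",
    "identity_augment",
    "pack_mask",
    "unpack_mask",
]


@dataclass(frozen=True)
class SUSAMConfig:
    """Hyperparameters of the sparse unified SAM optimizer.

    rho        ascent radius (> 0)
    eta        adaptive-scaling offset of the |w|+eta preconditioner (>= 0)
    TL         local top-k fraction of positions kept in the ascent (0, 1]
    TG         extra-mask fraction of total positions (>= 0)
    alpha_mo   momentum of the momentum-gradient accumulator
    r_fre      mask refresh period in rounds (>= 1)
    start_round  round at which sUSAM activates (late training)
    mask_before_normalize  alternative ascent flavor: mask the gradient
               before the ASAM normalisation rather than the perturbation
               after it
    """

    rho: float = 0.01
    eta: float = 0.01
    TL: float = 0.6
    TG: float = 0.1
    alpha_mo: float = 0.9
    r_fre: int = 5
    start_round: int = 300
    mask_before_normalize: bool = False

    def __post_init__(self):
        if self.rho < 0:
            raise ValueError("rho must be nonnegative")
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")
        if not 0 < self.TL <= 1:
            raise ValueError("TL must be in (0, 1]")
        if self.TG < 0:
            raise ValueError("TG must be nonnegative")
        if self.r_fre < 1:
            raise ValueError("r_fre must be >= 1")


# ---------------------------------------------------------------------------
# strong augmentation (ascent-side data)


def identity_augment(images, rng=None):
    return np.asarray(images).copy()


def strong_augment(images, rng, n_knots=4, bias_amp=0.15, noise_sd=0.03):
    """Randomized intensity-domain augmentation, labels untouched.

    A synthetic stand-in for generative domain-randomisation pipelines:
    each image receives a smooth monotone nonlinear intensity remapping
    (random increasing piecewise-linear transfer curve), a low-frequency
    multiplicative bias field, and additive Gaussian noise.  Geometry is
    unchanged, so label maps remain valid.
    """
    x = np.asarray(images, dtype=np.float64).copy()
    single = x.ndim == 2
    if single:
        x = x[None]
    lo, hi = x.min(), x.max()
    span = hi - lo if hi > lo else 1.0
    for i in range(x.shape[0]):
        img = (x[i] - lo) / span
        # monotone transfer curve through random increasing knots
        knots_x = np.linspace(0, 1, n_knots + 2)
        steps = rng.uniform(0.25, 1.75, size=n_knots + 1)
        knots_y = np.concatenate([[0.0], np.cumsum(steps)])
        knots_y /= knots_y[-1]
        img = np.interp(img, knots_x, knots_y)
        # low-frequency bias field from a coarse random grid
        coarse = rng.uniform(-1, 1, size=(4,) * img.ndim)
        zoom = [s / 4 for s in img.shape]
        from scipy.ndimage import zoom as ndzoom

        bias = ndzoom(coarse, zoom, order=1)
        img = img * (1.0 + bias_amp * bias[tuple(slice(0, s) for s in img.shape)])
        img = img + rng.normal(0, noise_sd, img.shape)
        x[i] = img * span + lo
    return x[0] if single else x


# ---------------------------------------------------------------------------
# ascent, momentum, masks


def asam_ascent(params, grads, rho, eta=0.0, mask=None,
                mask_before_normalize=False):
    """Adaptive-SAM ascent perturbation.

    With the elementwise preconditioner T = |w| + eta, the perturbation is
    ``rho * T^2 g / ||T g||``, which maximises the first-order loss increase
    subject to ||T^-1 eps|| <= rho.  A zero gradient yields a zero
    perturbation.  If ``mask_before_normalize`` is set and a mask is given,
    the gradient is masked before normalisation (otherwise callers mask the
    returned perturbation).
    """
    w = np.asarray(params, dtype=np.float64)
    g = np.asarray(grads, dtype=np.float64)
    if w.shape != g.shape:
        raise ValueError("params and grads must be aligned")
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    if mask_before_normalize and mask is not None:
        g = g * mask
    t = np.abs(w) + eta
    tg = t * g
    norm = float(np.linalg.norm(tg))
    if norm == 0.0 or rho == 0.0:
        return np.zeros_like(w)
    return rho * (t * tg) / norm


def update_momentum(g_mo, grads, alpha_mo=0.9):
    """Exponential moving average ``alpha*Gmo + (1-alpha)*grad``."""
    g_mo = np.asarray(g_mo, dtype=np.float64)
    grads = np.asarray(grads, dtype=np.float64)
    if g_mo.shape != grads.shape:
        raise ValueError("momentum and gradient vectors must be aligned")
    return alpha_mo * g_mo + (1.0 - alpha_mo) * grads


def topk_mask(vec, TL):
    """Boolean mask of the ceil(TL*P) largest-|value| positions.

    Ties are broken toward the lower index so the mask is deterministic.
    """
    if not 0 < TL <= 1:
        raise ValueError("TL must be in (0, 1]")
    vec = np.asarray(vec, dtype=np.float64)
    P = vec.size
    k = int(np.ceil(TL * P))
    mask = np.zeros(P, dtype=bool)
    if k >= P:
        mask[:] = True
        return mask
    # sort by (-|v|, index): stable argsort on -|v| gives lower-index-first ties
    order = np.argsort(-np.abs(vec), kind="stable")
    mask[order[:k]] = True
    return mask


def merge_global_mask(momentum_masks):
    """Server-side merge: 1 where the clients' momentum masks disagree.

    A position is in the global mask iff some but not all clients selected
    it (0 < sum < N); unanimous positions carry no cross-client information.
    """
    if len(momentum_masks) == 0:
        raise ValueError("need at least one mask")
    masks = [np.asarray(m, dtype=bool) for m in momentum_masks]
    P = masks[0].size
    if any(m.size != P for m in masks):
        raise ValueError("all masks must have equal length")
    s = np.sum(masks, axis=0)
    return (s > 0) & (s < len(masks))


def extra_mask(ml, mg, TG, rng):
    """Random re-injection mask from the global-only candidate positions.

    Candidates GN are positions in the global mask but not the local top-k
    mask; the extra mask is a uniform random subset of GN of size
    ``min(floor(TG*P), |GN|)``, hence always disjoint from ML.
    """
    ml = np.asarray(ml, dtype=bool)
    mg = np.asarray(mg, dtype=bool)
    if ml.size != mg.size:
        raise ValueError("masks must be aligned")
    if TG < 0:
        raise ValueError("TG must be nonnegative")
    candidates = np.flatnonzero(mg & ~ml)
    k = min(int(np.floor(TG * ml.size)), candidates.size)
    me = np.zeros(ml.size, dtype=bool)
    if k > 0:
        chosen = rng.choice(candidates, size=k, replace=False)
        me[chosen] = True
    return me


# ---------------------------------------------------------------------------
# the optimizer step


def susam_step(model, batch_images, batch_targets, loss_grad_fn, lr,
               cfg: SUSAMConfig, ml=None, me=None, g_mo=None, rng=None,
               update_masks=False, augment=None, step_fn=None):
    """One sparse-unified-SAM iteration on one batch.

    ``loss_grad_fn(model, images, targets) -> (loss, flat_grad)`` evaluates
    the training loss and its flat gradient at the model's current weights.

    Sequence: (1) gradient on the strongly augmented batch; (2) ASAM ascent
    perturbation from that gradient; (3) perturb only positions in ML∪ME;
    (4) gradient of the ORIGINAL batch at the perturbed weights; (5) restore
    weights and apply the optimizer update with that gradient (``step_fn``,
    default a plain SGD step of size ``lr``); (6) in mask-update rounds,
    refresh ML from the ascent gradient and accumulate the momentum
    gradients.

    Returns ``(loss, ml, g_mo)`` — the descent loss and the possibly
    refreshed local mask and momentum-gradient state.
    """
    if augment is None:
        augment = identity_augment
    pv = model.flatten()
    w0 = pv.values.copy()
    P = w0.size

    aug_images = augment(batch_images, rng)
    _, g_ascent = loss_grad_fn(model, aug_images, batch_targets)

    if update_masks:
        ml = topk_mask(g_ascent, cfg.TL)
        if g_mo is not None:
            g_mo = update_momentum(g_mo, g_ascent, cfg.alpha_mo)
    if ml is None:
        raise ValueError("local mask is stale: no history mask and not an "
                         "update round")

    combined = ml.copy()
    if me is not None:
        combined = combined | me

    eps = asam_ascent(w0, g_ascent, cfg.rho, cfg.eta,
                      mask=combined, mask_before_normalize=cfg.mask_before_normalize)
    perturb = np.where(combined, eps, 0.0)
    model.set_flat(w0 + perturb)
    loss, g_descent = loss_grad_fn(model, batch_images, batch_targets)
    model.set_flat(w0)
    if step_fn is None:
        model.set_flat(w0 - lr * g_descent)
    else:
        step_fn(model, g_descent)
    return loss, ml, g_mo


def relative_diff_ratio(g_usam, g_base):
    """Per-position log relative gradient difference, a sharpness diagnostic.

    ``r = log|(g_usam - g_base) / g_base|`` wherever the baseline gradient
    is nonzero; positions with zero baseline gradient are excluded and
    counted separately.  Returns ``(ratios, finite_positions, n_excluded)``.
    Identical gradients give -inf (reported in the underflow bin by
    callers).
    """
    gu = np.asarray(g_usam, dtype=np.float64)
    gb = np.asarray(g_base, dtype=np.float64)
    if gu.shape != gb.shape:
        raise ValueError("gradient vectors must be aligned")
    valid = gb != 0
    n_excluded = int((~valid).sum())
    with np.errstate(divide="ignore"):
        ratios = np.log(np.abs((gu[valid] - gb[valid]) / gb[valid]))
    return ratios, np.flatnonzero(valid), n_excluded


# ---------------------------------------------------------------------------
# mask serialization (communication format)


def pack_mask(mask):
    """Bit-pack a boolean mask with an explicit length header."""
    mask = np.asarray(mask, dtype=bool)
    return {"length": mask.size, "bits": np.packbits(mask)}


def unpack_mask(packed):
    bits = np.unpackbits(packed["bits"])[: packed["length"]]
    return bits.astype(bool)
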