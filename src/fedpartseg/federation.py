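"""Federation lifecycle: teacher pretraining, local rounds, aggregation.

Orchestrates the full training pipeline over the synthetic multi-client
datasets: class-specific teacher pretraining, warm-up, per-round local
training with the scheduled losses, client-package exchange
(parameters, momentum masks, uncertainty summaries), uncertainty-aware
aggregation, and the late-round activation of the global-main-teacher
fusion and the sparse sharpness-aware optimizer.  Baseline modes reduce the
pipeline to plain federated averaging with pseudolabels ("FedAvg*") or to
isolated local training ("SOLO"), which together bracket the method.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import evalio, phantoms, susam as susam_mod, ull
from .model import Adam, SegNet, softmax
from .phantoms import DEFAULT_MERGE_SEQUENCE, PhantomConfig, make_federated_dataset
from .susam import SUSAMConfig
from .ull import ULLConfig

logger = logging.getLogger("fedpartseg")

__all__ = [
    "FederationConfig",
    "ClientPackage",
    "ProvenanceAudit",
    "FederationResult",
    "pretrain_teachers",
    "local_round",
    "aggregate",
    "schedule",
    "run_federation",
    "evaluate_model",
    "ABLATION_GRID",
    "load_config",
]

ALL_MODULES = ("arce", "ws", "ua", "gmt", "susam")

# Module-toggle rows of the standard ablation grid: from isolated training
# through pseudolabels-only up to the full method.
ABLATION_GRID = (
    {"mode": "SOLO"},
    {"mode": "FedAvg*"},
    {"mode": "UFPS", "toggles": ("arce",)},
    {"mode": "UFPS", "toggles": ("ws",)},
    {"mode": "UFPS", "toggles": ("ua",)},
    {"mode": "UFPS", "toggles": ("gmt",)},
    {"mode": "UFPS", "toggles": ("susam",)},
    {"mode": "UFPS", "toggles": ("arce", "ws")},
    {"mode": "UFPS", "toggles": ("arce", "ws", "ua")},
    {"mode": "UFPS", "toggles": ("arce", "ws", "ua", "gmt")},
    {"mode": "UFPS", "toggles": ALL_MODULES},
)


@dataclass(frozen=True)
class FederationConfig:
    """Run configuration.

    The default profile is desk-scale: 30 rounds with warm-up, fusion and
    optimizer activation at rounds 3 / 15 / 15, scaling the reference
    500-round schedule (warm-up 10, late-phase start 300) proportionally.
    ``paper_profile`` restores the reference schedule.
    """

    rounds: int = 30
    local_rounds_per_global: int = 1
    warmup_rounds: int = 3
    gmt_start: int = 15
    susam_start: int = 15
    baseline_mode: str = "UFPS"          # UFPS | FedAvg* | SOLO
    toggles: dict = field(default_factory=lambda: {m: True for m in ALL_MODULES})
    lr: float = 0.02                     # Adam step size, local training
    teacher_epochs: int = 60
    teacher_lr: float = 0.02
    teacher_min_dice: float = 0.5
    eval_every: int = 10
    seed: int = 0
    model_width: int = 6
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    ull: ULLConfig = field(default_factory=lambda: ULLConfig(gmt_start_round=15))
    susam: SUSAMConfig = field(default_factory=lambda: SUSAMConfig(start_round=15))

    def __post_init__(self):
        if self.baseline_mode not in ("UFPS", "FedAvg*", "SOLO"):
            raise ValueError(f"unknown baseline_mode {self.baseline_mode!r}")
        if not self.warmup_rounds < self.gmt_start <= self.rounds:
            raise ValueError("need warmup_rounds < gmt_start <= rounds")

    def module_on(self, name):
        if self.baseline_mode != "UFPS":
            return False
        return bool(self.toggles.get(name, False))

    @classmethod
    def paper_profile(cls, **overrides):
        """The reference 500-round schedule (warm-up 10, late phase 300)."""
        base = dict(rounds=500, warmup_rounds=10, gmt_start=300, susam_start=300)
        base.update(overrides)
        cfg = cls(**{k: v for k, v in base.items() if k != "susam"})
        return replace(
            cfg,
            ull=replace(cfg.ull, gmt_start_round=base["gmt_start"]),
            susam=replace(cfg.susam, start_round=base["susam_start"]),
        )


@dataclass
class ClientPackage:
    """What one client ships to the server after a local round."""

    client_id: int
    params: np.ndarray
    mu: float
    sigma: float
    n_samples: int
    momentum_mask: np.ndarray | None = None


class ProvenanceAudit:
    """Records which client ids touched each stage of the pipeline.

    Used to prove that held-out (out-of-federation) clients never influence
    teachers, uncertainty banks, gradient masks, or aggregation.
    """

    STAGES = ("teacher", "bank", "mask", "aggregate", "pseudolabel")

    def __init__(self):
        self.events = {s: set() for s in self.STAGES}

    def record(self, stage, client_id):
        self.events[stage].add(client_id)

    def leaked_clients(self, datasets):
        out_ids = {d.client_id for d in datasets if not d.in_federation}
        return {s: sorted(ids & out_ids) for s, ids in self.events.items()
                if ids & out_ids}


@dataclass
class FederationResult:
    global_model: SegNet | None
    solo_models: dict
    history: list
    datasets: list
    teachers: ull.TeacherEnsemble
    audit: ProvenanceAudit
    config: FederationConfig

    def history_jsonl(self, path):
        with open(path, "w") as fh:
            for rec in self.history:
                fh.write(json.dumps(rec) + "\n")


class _ClientState:
    """Persistent per-client training state across rounds.

    The uncertainty bank, momentum gradients, history local mask and the
    client's Adam moments all survive the round-boundary weight replacement
    by the incoming global model.
    """

    def __init__(self, n_params, lr):
        self.bank = ull.UncertaintyBank()
        self.g_mo = np.zeros(n_params)
        self.ml = None
        self.opt = Adam(n_params, lr=lr)


# ---------------------------------------------------------------------------
# losses


def _make_loss_grad_fn(n_channels, ts_w, arce_on, r, R, rce_scale):
    """Composite per-sample loss (Dice+BCE, optional aRCE, TS-weighted)."""

    def fn(model, image, target_onehot):
        logits, cache = model.forward(image, return_cache=True)
        prob = softmax(logits, axis=1)[0]
        loss, dprob = ull.base_loss(prob, target_onehot, sample_weight=ts_w,
                                    return_grad=True)
        if arce_on:
            la, da = ull.arce_loss(prob, target_onehot, r, R, rce_scale,
                                   return_grad=True)
            loss += ts_w * la
            dprob = dprob + ts_w * da
        dlogits = ull.softmax_grad_to_logits(prob, dprob)[None]
        grads = model.backward(cache, dlogits)
        return loss, model.flatten_grads(grads)

    return fn


def _train_epoch(model, opt, images, label_maps, n_channels, order=None):
    """One epoch of per-sample optimizer steps; returns the mean loss."""
    losses = []
    idx = range(len(images)) if order is None else order
    fn = _make_loss_grad_fn(n_channels, 1.0, False, 0, 1, 20.0)
    for j in idx:
        target = ull.one_hot(label_maps[j], n_channels)
        loss, grad = fn(model, images[j], target)
        opt.step(model, grad)
        losses.append(loss)
    return float(np.mean(losses))


# ---------------------------------------------------------------------------
# teacher pretraining


def pretrain_teachers(datasets, cfg: FederationConfig, audit=None):
    """Pretrain one frozen class-specific teacher per in-federation client.

    Each teacher trains only on its client's partial labels (annotated
    classes vs background); all other channels receive empty targets, so
    the teacher's usable output is exactly {background} ∪ Ci.  A teacher
    whose held-out Dice on its own classes falls below ``teacher_min_dice``
    (a symptom of a dead-unit initialisation at this tiny width) is retrained
    from a fresh init up to ``retries`` times; if it still fails, a warning
    is logged and the best attempt is kept (not fatal).
    """
    nc = cfg.phantom.n_classes
    n_channels = nc + 1
    teachers = []
    for ds in datasets:
        if not ds.in_federation:
            continue
        if audit is not None:
            audit.record("teacher", ds.client_id)
        imgs = ds.train_images()
        labs = ds.train_partial_labels()
        held_refs = phantoms.restrict_labels(ds.test_full_labels(),
                                             ds.annotated_set)
        best_model, best_score, retries = None, -1.0, 3
        for attempt in range(retries):
            model = SegNet(
                nc, cfg.model_width,
                seed=(cfg.seed * 977 + ds.client_id + 65537 * attempt)
                % (2**31 - 1))
            opt = Adam(model.n_params, lr=cfg.teacher_lr)
            for _ in range(cfg.teacher_epochs):
                _train_epoch(model, opt, imgs, labs, n_channels)
            if not len(ds.test_idx):
                best_model, best_score = model, np.inf
                break
            score = float(np.mean(
                [evalio.dice(np.squeeze(model.predict_labels(im)), lab, c)
                 for im, lab in zip(ds.test_images(), held_refs)
                 for c in sorted(ds.annotated_set)]))
            if score > best_score:
                best_model, best_score = model, score
            if score >= cfg.teacher_min_dice:
                break
        if best_score < cfg.teacher_min_dice:
            logger.warning("teacher for client %d below sanity Dice bound: %.3f",
                           ds.client_id, best_score)
        teachers.append((best_model, ds.annotated_set))
    priority = tuple(c for c in DEFAULT_MERGE_SEQUENCE
                     if c in set().union(*[cs for _, cs in teachers]))
    # any configured class missing from the default sequence goes last
    priority += tuple(sorted(set(range(1, nc + 1)) - set(priority)))
    return ull.TeacherEnsemble(teachers=teachers, priority=priority)


def _cache_teacher_pseudolabels(datasets, teachers, nc, audit=None):
    cache = {}
    for ds in datasets:
        if not ds.in_federation:
            continue
        if audit is not None:
            audit.record("pseudolabel", ds.client_id)
        pls = [ull.teacher_pseudolabel(img, teachers, gt, ds.annotated_set,
                                       n_classes=nc)
               for img, gt in zip(ds.train_images(), ds.train_partial_labels())]
        cache[ds.client_id] = pls
    return cache


# ---------------------------------------------------------------------------
# schedule


def schedule(r, cfg: FederationConfig):
    """Phase flags and learning-rate ramp for round ``r``."""
    if not 0 <= r < cfg.rounds:
        raise ValueError("round index out of range")
    warmup = r < cfg.warmup_rounds
    ramp = (0.1 + 0.9 * (r + 1) / cfg.warmup_rounds) if warmup else 1.0
    use_susam = cfg.module_on("susam") and r >= cfg.susam_start
    # the activation round always refreshes masks so none can be stale
    update = use_susam and (r % cfg.susam.r_fre == 0 or r == cfg.susam_start)
    return {
        "warmup": warmup,
        "use_gmt": cfg.module_on("gmt") and r >= cfg.gmt_start,
        "use_susam": use_susam,
        "update_masks": update,
        "lr_scale": min(ramp, 1.0),
    }


# ---------------------------------------------------------------------------
# local round


def local_round(state: _ClientState, ds, global_values, teachers, teacher_pls,
                global_mask, r, cfg: FederationConfig, rng, audit=None):
    """Train one client for one round from the received global weights.

    Builds per-sample pseudolabels (teacher-only before the fusion phase,
    global-main-teacher intersection afterwards), deposits each sample's
    uncertainty in the client bank, applies the tail-shift weight and
    optional reverse-CE term, and steps with either plain SGD or the sparse
    sharpness-aware optimizer depending on the phase.  Emits the client's
    package for aggregation.
    """
    nc = cfg.phantom.n_classes
    n_channels = nc + 1
    flags = schedule(r, cfg)
    lr = cfg.lr * flags["lr_scale"]

    model = SegNet(nc, cfg.model_width, seed=0).set_flat(global_values)
    global_model = SegNet(nc, cfg.model_width, seed=0).set_flat(global_values) \
        if flags["use_gmt"] else None

    imgs = ds.train_images()
    order = rng.permutation(len(imgs))
    losses = []
    n_visited = 0
    for j in order:
        img = imgs[j]
        pl = teacher_pls[j]
        if flags["use_gmt"]:
            gpred = np.squeeze(global_model.predict_labels(img))
            fused = ull.gmt_fuse(gpred, pl, cfg.ull.v)
            pl = ull.apply_ground_truth(fused, ds.train_partial_labels()[j],
                                        ds.annotated_set)
        target = ull.one_hot(pl, n_channels)

        prob = model.predict_proba(img)[0]
        ent = ull.voxel_entropy(prob)
        u_j = ull.sample_uncertainty(
            ent, target, include_background=cfg.ull.entropy_include_background)
        state.bank.add(u_j)
        if audit is not None:
            audit.record("bank", ds.client_id)

        ts_w = 1.0
        if cfg.module_on("ws") and not flags["warmup"] and len(state.bank) > 1:
            ts_w = ull.ts_weight(u_j, state.bank, cfg.ull.T, r, cfg.rounds)

        fn = _make_loss_grad_fn(n_channels, ts_w, cfg.module_on("arce"),
                                r, cfg.rounds, cfg.ull.rce_scale)

        if flags["use_susam"]:
            me = None
            if state.ml is not None and global_mask is not None:
                me = susam_mod.extra_mask(state.ml, global_mask,
                                          cfg.susam.TG, rng)
            if state.ml is None and not flags["update_masks"]:
                raise RuntimeError("stale masks: sUSAM active without history "
                                   "mask outside an update round")
            loss, state.ml, g_mo = susam_mod.susam_step(
                model, img, target, fn, lr, cfg.susam,
                ml=state.ml, me=me,
                g_mo=state.g_mo if flags["update_masks"] else None,
                rng=rng, update_masks=flags["update_masks"],
                augment=susam_mod.strong_augment,
                step_fn=lambda m, g: state.opt.step(m, g, flags["lr_scale"]))
            if g_mo is not None:
                state.g_mo = g_mo
        else:
            loss, grad = fn(model, img, target)
            state.opt.step(model, grad, flags["lr_scale"])
        losses.append(loss)
        n_visited += 1

    mom_mask = None
    if flags["use_susam"] and flags["update_masks"]:
        mom_mask = susam_mod.topk_mask(state.g_mo, cfg.susam.TL)
        if audit is not None:
            audit.record("mask", ds.client_id)

    mu, sigma = state.bank.mean, state.bank.var
    if not flags["warmup"]:
        state.bank.trim_to_last(n_visited)

    return ClientPackage(
        client_id=ds.client_id,
        params=model.flatten().values,
        mu=mu, sigma=sigma,
        n_samples=n_visited,
        momentum_mask=mom_mask,
    ), float(np.mean(losses))


# ---------------------------------------------------------------------------
# aggregation


def aggregate(packages, cfg: FederationConfig, partition=None, audit=None):
    """Server-side model fusion.

    Encoder (and everything outside the decoder partition) is averaged with
    the sample-proportional weights; when uncertainty-aware aggregation is
    enabled, the decoder + head positions are averaged with the
    uncertainty-corrected weights instead.
    """
    if not packages:
        raise ValueError("need at least one client package")
    P = packages[0].params.size
    if any(p.params.size != P for p in packages):
        raise ValueError("inconsistent parameter counts across packages")
    if audit is not None:
        for p in packages:
            audit.record("aggregate", p.client_id)
    n = np.array([p.n_samples for p in packages], dtype=np.float64)
    aw = n / n.sum()
    stacked = np.stack([p.params for p in packages])
    out = aw @ stacked
    if cfg.module_on("ua"):
        if partition is None:
            raise ValueError("UA aggregation needs the parameter partition")
        mu = np.array([p.mu for p in packages])
        sigma = np.array([p.sigma for p in packages])
        ua_w = ull.ua_weights(mu, sigma, aw, cfg.ull.tau_mu, cfg.ull.tau_sigma)
        idx = partition.decoder_head_idx
        out[idx] = ua_w @ stacked[:, idx]
    return out


# ---------------------------------------------------------------------------
# evaluation helpers


def evaluate_model(model, ds, classes):
    """Mean all-class Dice of a model on one client's held-out split."""
    scores = []
    for img, ref in zip(ds.test_images(), ds.test_full_labels()):
        pred = np.squeeze(model.predict_labels(img))
        scores.extend(evalio.dice(pred, ref, c) for c in classes)
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# the full lifecycle


def run_federation(cfg: FederationConfig, datasets=None, teachers=None):
    """Execute the configured federation and return models + history.

    Deterministic given ``cfg.seed`` (up to floating-point summation order,
    which is itself fixed here).  ``datasets``/``teachers`` may be supplied
    to reuse phantoms and pretrained teachers across baseline modes.
    """
    audit = ProvenanceAudit()
    phantom_cfg = replace(cfg.phantom, seed=cfg.seed)
    if datasets is None:
        datasets = make_federated_dataset(phantom_cfg)
    nc = phantom_cfg.n_classes
    classes = list(range(1, nc + 1))
    in_fl = [d for d in datasets if d.in_federation]

    rng = np.random.default_rng(cfg.seed * 7919 % (2**31 - 1))
    template = SegNet(nc, cfg.model_width, seed=cfg.seed % (2**31 - 1))
    partition = template.flatten()
    history = []

    if cfg.baseline_mode == "SOLO":
        # isolated local training on the partial labels only — no
        # pseudolabels, no communication: the lower bound of the benchmark
        solo = {}
        for ds in in_fl:
            model = SegNet(nc, cfg.model_width, seed=0).set_flat(
                partition.values)
            opt = Adam(model.n_params, lr=cfg.lr)
            imgs = ds.train_images()
            labs = ds.train_partial_labels()
            for r in range(cfg.rounds):
                loss = _train_epoch(model, opt, imgs, labs, nc + 1,
                                    order=rng.permutation(len(imgs)))
                if (r + 1) % cfg.eval_every == 0 or r == cfg.rounds - 1:
                    history.append({"round": r, "client": ds.client_id,
                                    "loss": loss,
                                    "dice": evaluate_model(model, ds, classes)})
            solo[ds.client_id] = model
        leaked = audit.leaked_clients(datasets)
        if leaked:
            raise RuntimeError(f"out-of-federation data leaked into: {leaked}")
        return FederationResult(None, solo, history, datasets,
                                teachers or ull.TeacherEnsemble(), audit, cfg)

    if teachers is None:
        teachers = pretrain_teachers(datasets, cfg, audit)
    teacher_pls = _cache_teacher_pseudolabels(datasets, teachers, nc, audit)

    states = {ds.client_id: _ClientState(partition.size, cfg.lr)
              for ds in in_fl}
    global_values = partition.values.copy()
    global_mask = None

    for r in range(cfg.rounds):
        flags = schedule(r, cfg)
        packages, losses = [], {}
        for ds in in_fl:
            pkg, loss = local_round(states[ds.client_id], ds, global_values,
                                    teachers, teacher_pls[ds.client_id],
                                    global_mask, r, cfg, rng, audit)
            packages.append(pkg)
            losses[ds.client_id] = loss
        if flags["use_susam"] and flags["update_masks"] and \
                all(p.momentum_mask is not None for p in packages):
            global_mask = susam_mod.merge_global_mask(
                [p.momentum_mask for p in packages])
        global_values = aggregate(packages, cfg, partition, audit)

        rec = {"round": r, "losses": losses,
               "mask_sparsity": (float(global_mask.mean())
                                 if global_mask is not None else None)}
        if (r + 1) % cfg.eval_every == 0 or r == cfg.rounds - 1:
            gm = SegNet(nc, cfg.model_width, seed=0).set_flat(global_values)
            rec["dice"] = {ds.client_id: evaluate_model(gm, ds, classes)
                           for ds in datasets}
        history.append(rec)

    leaked = audit.leaked_clients(datasets)
    if leaked:
        raise RuntimeError(f"out-of-federation data leaked into: {leaked}")
    global_model = SegNet(nc, cfg.model_width, seed=0).set_flat(global_values)
    return FederationResult(global_model, {}, history, datasets, teachers,
                            audit, cfg)


# ---------------------------------------------------------------------------
# config file loading


def load_config(path, overrides=None):
    """Build a :class:`FederationConfig` from a YAML file with sections
    ``{data, model, ull, susam, federation}`` plus ``k=v`` overrides."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if overrides:
        for kv in overrides:
            key, val = kv.split("=", 1)
            section, _, name = key.partition(".")
            raw.setdefault(section, {})[name] = yaml.safe_load(val)
    kwargs = dict(raw.get("federation", {}))
    if "model" in raw:
        kwargs["model_width"] = raw["model"].get("width", 4)
    if "data" in raw:
        data = dict(raw["data"])
        if "image_size" in data:
            data["image_size"] = tuple(data["image_size"])
        kwargs["phantom"] = PhantomConfig(**data)
    if "ull" in raw:
        kwargs["ull"] = ULLConfig(**raw["ull"])
    if "susam" in raw:
        kwargs["susam"] = SUSAMConfig(**raw["susam"])
    if "toggles" in kwargs:
        kwargs["toggles"] = {m: bool(kwargs["toggles"].get(m, False))
                             for m in ALL_MODULES}
    return FederationConfig(**kwargs)
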