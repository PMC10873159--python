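"""Synthetic multi-client segmentation phantoms.

Generates reproducible 2-D (optionally 3-D) grayscale "CT-like" images with
multi-class organ label maps, emulating a federation in which every client
shares the same anatomy concept but

* sees a client-specific imaging domain (intensity bias, contrast, noise,
  blur) — the non-IID ingredient, and
* annotates only a subset of the organ classes — the partial-label
  ingredient.

Organs are smooth ellipsoidal regions placed by rejection sampling so that
foreground regions are pairwise disjoint by construction.  The default
four-client topology mirrors a federation where client 1 annotates the
kidney, client 2 spleen + pancreas, client 3 the liver, and client 4 is a
fully annotated hold-out that never participates in training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PhantomConfig",
    "DomainProfile",
    "ClientDataset",
    "make_phantom",
    "make_federated_dataset",
    "default_client_specs",
    "save_client_npz",
    "load_client_npz",
    "export_nifti",
]

# Class indices are global and shared by every client; 0 is background.
DEFAULT_CLASS_NAMES = ("kidney", "liver", "spleen", "pancreas")
KIDNEY, LIVER, SPLEEN, PANCREAS = 1, 2, 3, 4

# Merge priority for pseudolabel fusion: descending expected organ volume.
DEFAULT_MERGE_SEQUENCE = (LIVER, SPLEEN, KIDNEY, PANCREAS)

# Per-class radius ranges (fraction of image size) chosen so that the four
# organs fit disjointly in a 64x64 frame with high probability: the liver is
# the largest structure, the pancreas the smallest and most elongated.
_DEFAULT_GEOMETRY = {
    KIDNEY: {"radius": (0.09, 0.13), "ecc": (0.6, 0.9)},
    LIVER: {"radius": (0.18, 0.24), "ecc": (0.7, 1.0)},
    SPLEEN: {"radius": (0.11, 0.16), "ecc": (0.6, 0.9)},
    PANCREAS: {"radius": (0.07, 0.10), "ecc": (0.35, 0.6)},
}

# Noise-free tissue plateaus (arbitrary CT-like units in [0, 1]).
_DEFAULT_INTENSITY = {0: 0.15, KIDNEY: 0.45, LIVER: 0.65, SPLEEN: 0.55, PANCREAS: 0.80}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and sampling configuration for phantom generation."""

    image_size: tuple = (64, 64)
    n_classes: int = 4
    n_samples_per_client: int = 16
    class_names: tuple = DEFAULT_CLASS_NAMES
    organ_geometry: dict = field(default_factory=lambda: dict(_DEFAULT_GEOMETRY))
    class_intensity: dict = field(default_factory=lambda: dict(_DEFAULT_INTENSITY))
    max_place_attempts: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.image_size) not in (2, 3):
            raise ValueError("image_size must be 2-D or 3-D")

    @property
    def classes(self):
        return tuple(range(1, self.n_classes + 1))


@dataclass(frozen=True)
class DomainProfile:
    """Client-specific appearance transform applied to the shared anatomy."""

    intensity_bias: float = 0.0
    contrast_scale: float = 1.0
    noise_sd: float = 0.0
    blur_sigma: float = 0.0
    class_intensity: dict | None = None  # overrides PhantomConfig plateaus

    def __post_init__(self):
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sd and blur_sigma must be nonnegative")


IDENTITY_PROFILE = DomainProfile()


@dataclass
class ClientDataset:
    """One client's images plus full (evaluation-only) and partial labels."""

    client_id: int
    images: np.ndarray          # (n, *image_size) float
    full_labels: np.ndarray     # (n, *image_size) int, held out for eval
    partial_labels: np.ndarray  # full_labels restricted to annotated_set
    annotated_set: frozenset    # Ci ⊆ {1..Nc}
    in_federation: bool
    profile: DomainProfile
    train_idx: np.ndarray
    test_idx: np.ndarray

    @property
    def n_samples(self):
        return self.images.shape[0]

    @property
    def n_train(self):
        return len(self.train_idx)

    def train_images(self):
        return self.images[self.train_idx]

    def train_partial_labels(self):
        return self.partial_labels[self.train_idx]

    def train_full_labels(self):
        return self.full_labels[self.train_idx]

    def test_images(self):
        return self.images[self.test_idx]

    def test_full_labels(self):
        return self.full_labels[self.test_idx]


class PhantomGeometryError(RuntimeError):
    """Raised when an organ cannot be placed disjointly from earlier ones."""


def _ellipsoid_mask(shape, center, radii, theta, rng):
    """Boolean mask of a (rotated, 2-D) ellipse or axis-aligned 3-D ellipsoid."""
    coords = np.indices(shape).astype(float)
    offs = [coords[d] - center[d] for d in range(len(shape))]
    if len(shape) == 2:
        c, s = np.cos(theta), np.sin(theta)
        u = c * offs[0] + s * offs[1]
        v = -s * offs[0] + c * offs[1]
        return (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0
    return sum((offs[d] / radii[d]) ** 2 for d in range(3)) <= 1.0


def make_phantom(rng_seed, cfg: PhantomConfig, profile: DomainProfile = IDENTITY_PROFILE):
    """Generate one (image, label map) pair.

    The label map contains every configured class as a disjoint ellipsoidal
    region; the image is the per-class intensity plateau picture pushed
    through the client's :class:`DomainProfile` (blur, contrast, bias,
    additive Gaussian noise, in that order).  Deterministic given
    ``rng_seed``.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(rng_seed)
    shape = tuple(cfg.image_size)
    ndim = len(shape)
    size = min(shape)
    labels = np.zeros(shape, dtype=np.int16)

    for c in cfg.classes:
        geom = cfg.organ_geometry.get(c, {"radius": (0.08, 0.14), "ecc": (0.5, 0.9)})
        placed = False
        for _ in range(cfg.max_place_attempts):
            r_major = rng.uniform(*geom["radius"]) * size
            ecc = rng.uniform(*geom["ecc"])
            radii = [r_major] + [max(1.5, r_major * ecc)] * (ndim - 1)
            margin = r_major + 1
            if any(shape[d] - 2 * margin <= 0 for d in range(ndim)):
                continue
            center = [rng.uniform(margin, shape[d] - margin) for d in range(ndim)]
            theta = rng.uniform(0, np.pi)
            mask = _ellipsoid_mask(shape, center, radii, theta, rng)
            if mask.sum() >= 4 and not (mask & (labels > 0)).any():
                labels[mask] = c
                placed = True
                break
        if not placed:
            name = cfg.class_names[c - 1] if c - 1 < len(cfg.class_names) else str(c)
            raise PhantomGeometryError(
                f"could not place class {c} ({name}) disjointly within "
                f"{cfg.max_place_attempts} attempts for image size {shape}"
            )

    intensity = dict(cfg.class_intensity)
    if profile.class_intensity:
        intensity.update(profile.class_intensity)
    image = np.full(shape, intensity.get(0, 0.0), dtype=np.float64)
    for c in cfg.classes:
        image[labels == c] = intensity.get(c, 0.5)

    if profile.blur_sigma > 0:
        image = gaussian_filter(image, profile.blur_sigma)
    image = image * profile.contrast_scale + profile.intensity_bias
    if profile.noise_sd > 0:
        image = image + rng.normal(0.0, profile.noise_sd, size=shape)
    return image, labels


def restrict_labels(full_labels, annotated_set):
    """Zero every voxel whose class is not in the annotated set."""
    keep = np.isin(full_labels, list(annotated_set))
    return np.where(keep, full_labels, 0).astype(full_labels.dtype)


def default_client_specs(cfg: PhantomConfig):
    """The default four-client topology.

    Three in-federation clients with disjoint partial target sets covering
    all classes, plus one fully annotated out-of-federation client whose
    appearance profile lies outside the convex hull of the in-FL profiles
    (stronger bias and noise than any participant), so that generalization
    to it is a genuine domain-shift test.
    """
    n = cfg.n_samples_per_client
    return [
        (frozenset({KIDNEY}), DomainProfile(0.00, 1.00, 0.02, 0.0), n, True),
        (frozenset({SPLEEN, PANCREAS}), DomainProfile(0.05, 0.90, 0.03, 0.5), n, True),
        (frozenset({LIVER}), DomainProfile(-0.05, 1.10, 0.04, 0.3), n, True),
        (frozenset(cfg.classes), DomainProfile(0.12, 0.80, 0.06, 0.8), n, False),
    ]


def make_federated_dataset(cfg: PhantomConfig, client_specs=None, test_fraction=0.25):
    """Build the per-client datasets for a federation.

    ``client_specs`` is a list of ``(Ci, DomainProfile, n_samples,
    in_federation)`` tuples; the in-FL annotated sets must jointly cover
    every class.  Partial labels are derived from the full labels by zeroing
    classes outside Ci.  Each client gets a disjoint train/test split.
    """
    if client_specs is None:
        client_specs = default_client_specs(cfg)

    covered = frozenset().union(
        *[ci for ci, _, _, in_fl in client_specs if in_fl] or [frozenset()]
    )
    if covered != frozenset(cfg.classes):
        missing = sorted(set(cfg.classes) - covered)
        raise ValueError(
            f"in-federation annotated sets must cover all classes; missing {missing}"
        )

    datasets = []
    for cid, (ci, profile, n, in_fl) in enumerate(client_specs, start=1):
        if not 0 < len(ci) <= cfg.n_classes:
            raise ValueError(f"client {cid}: annotated set size must be in (0, Nc]")
        images, fulls = [], []
        for j in range(n):
            # distinct stream per (dataset seed, client, sample)
            seed = (cfg.seed * 1_000_003 + cid * 10_007 + j) % (2**31 - 1)
            img, lab = make_phantom(seed, cfg, profile)
            images.append(img)
            fulls.append(lab)
        images = np.stack(images)
        fulls = np.stack(fulls)
        partial = restrict_labels(fulls, ci)
        n_test = max(1, int(round(test_fraction * n))) if n > 1 else 0
        idx = np.arange(n)
        datasets.append(
            ClientDataset(
                client_id=cid,
                images=images,
                full_labels=fulls,
                partial_labels=partial,
                annotated_set=frozenset(ci),
                in_federation=in_fl,
                profile=profile,
                train_idx=idx[: n - n_test],
                test_idx=idx[n - n_test:],
            )
        )
    return datasets


# ---------------------------------------------------------------------------
# persistence

def save_client_npz(path, ds: ClientDataset):
    np.savez_compressed(
        path,
        client_id=ds.client_id,
        images=ds.images,
        full_labels=ds.full_labels,
        partial_labels=ds.partial_labels,
        annotated_set=np.array(sorted(ds.annotated_set)),
        in_federation=ds.in_federation,
        train_idx=ds.train_idx,
        test_idx=ds.test_idx,
    )


def load_client_npz(path):
    with np.load(path) as z:
        return ClientDataset(
            client_id=int(z["client_id"]),
            images=z["images"],
            full_labels=z["full_labels"],
            partial_labels=z["partial_labels"],
            annotated_set=frozenset(int(c) for c in z["annotated_set"]),
            in_federation=bool(z["in_federation"]),
            profile=DomainProfile(),
            train_idx=z["train_idx"],
            test_idx=z["test_idx"],
        )


def export_nifti(path, volume):
    """Write a volume or label map as NIfTI with identity affine."""
    import nibabel as nib

    arr = np.asarray(volume)
    if arr.ndim == 2:
        arr = arr[..., None]
    nib.save(nib.Nifti1Image(arr.astype(np.float32), np.eye(4)), str(path))
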