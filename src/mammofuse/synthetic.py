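"""Seedable synthetic inputs with the statistical structure each pipeline
stage assumes.

Three generators are provided:

``generate_images``
    Two-class grayscale phantoms (emitted as replicated 3-channel arrays)
    with mammogram-like low-frequency background texture. Malignant images
    carry 1-3 high-contrast anisotropic Gaussian blobs ("masses") whose
    contrast scales with the ``effect`` separability; benign images carry
    only texture plus an optional faint smooth blob. Ground-truth lesion
    masks are returned for localization checks.

``generate_correlated_pair``
    Two feature matrices sharing a single latent factor, scaled so the
    population first canonical correlation equals a requested ``r``.

``generate_selection_benchmark``
    A feature matrix with a known set of class-informative columns
    (class-shifted Gaussians) amid independent standard-Gaussian noise
    columns, for scoring wrapper feature selectors by recall.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureMatrix

BENIGN, MALIGNANT = "benign", "malignant"
CLASSES = (BENIGN, MALIGNANT)


@dataclass
class ImageSet:
    """Labeled image collection with provenance and seed metadata."""

    images: np.ndarray            # (N, H, W, 3) float32 in [0, 1]
    labels: list[str]             # per-image class name
    lesion_masks: np.ndarray | None = None   # (N, H, W) bool
    seed: int | None = None
    params: dict = field(default_factory=dict)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")
        if not self.sample_ids:
            self.sample_ids = [f"img{i:05d}" for i in range(len(self.images))]

    def __len__(self) -> int:
        return len(self.images)

    @property
    def y(self) -> np.ndarray:
        """Integer labels: benign=0, malignant=1."""
        return np.asarray([CLASSES.index(c) for c in self.labels])

    def subset(self, idx) -> "ImageSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        idx = idx.astype(np.intp)
        return ImageSet(
            images=self.images[idx],
            labels=[self.labels[i] for i in idx],
            lesion_masks=None if self.lesion_masks is None else self.lesion_masks[idx],
            seed=self.seed,
            params=dict(self.params),
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def write(self, out_dir) -> None:
        """Write PNGs per class, masks, and a manifest.tsv."""
        from PIL import Image

        out = Path(out_dir)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        rows = []
        for i, (img, label, sid) in enumerate(
            zip(self.images, self.labels, self.sample_ids)
        ):
            (out / label).mkdir(exist_ok=True)
            path = out / label / f"{sid}.png"
            Image.fromarray((img[:, :, 0] * 255).astype(np.uint8)).save(path)
            if self.lesion_masks is not None:
                Image.fromarray(
                    (self.lesion_masks[i] * 255).astype(np.uint8)
                ).save(out / "masks" / f"{sid}.png")
            rows.append(f"{sid}\t{label}\t{path.relative_to(out)}\t{self.seed}")
        (out / "manifest.tsv").write_text(
            "sample_id\tclass\tpath\tseed\n" + "\n".join(rows) + "\n"
        )


@dataclass
class CorrelatedFeaturePair:
    F1: FeatureMatrix
    F2: FeatureMatrix
    latent_corr: float
    seed: int


@dataclass
class SelectionBenchmark:
    X: FeatureMatrix
    y: np.ndarray
    informative_idx: np.ndarray
    seed: int


# ---------------------------------------------------------------------------

def _background(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Low-frequency Gaussian random field plus pixel noise, scaled to ~[0.2, 0.6]."""
    from scipy.ndimage import gaussian_filter

    coarse = gaussian_filter(rng.normal(size=(h, w)), sigma=min(h, w) / 8.0)
    coarse = (coarse - coarse.min()) / (np.ptp(coarse) + 1e-12)
    field = 0.2 + 0.35 * coarse + 0.03 * rng.normal(size=(h, w))
    return np.clip(field, 0.0, 1.0)


def _blob(rng: np.random.Generator, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """One anisotropic Gaussian bump with randomized eccentricity.

    Returns (profile in [0,1], support mask at half maximum).
    """
    cy = rng.uniform(0.25 * h, 0.75 * h)
    cx = rng.uniform(0.25 * w, 0.75 * w)
    r_major = rng.uniform(0.06, 0.14) * min(h, w)
    ecc = rng.uniform(0.5, 1.0)
    angle = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    u = dy * np.cos(angle) + dx * np.sin(angle)
    v = -dy * np.sin(angle) + dx * np.cos(angle)
    d2 = (u / r_major) ** 2 + (v / (ecc * r_major)) ** 2
    profile = np.exp(-0.5 * d2 * 4.0)
    return profile, profile > 0.5


def generate_images(n_per_class: int, size: tuple[int, int] = (227, 227),
                    effect: float = 0.8, seed: int = 0) -> ImageSet:
    """Generate a balanced two-class phantom image set.

    Parameters
    ----------
    n_per_class : number of images per class (benign first, then malignant).
    size : (H, W) with H, W >= 64.
    effect : class separability in [0, 1]; scales the contrast of malignant
        lesions relative to the background texture.
    seed : RNG seed; identical (params, seed) give bit-identical output.
    """
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    h, w = size
    if h < 64 or w < 64:
        raise ValueError("image size must be at least 64x64")
    if not 0.0 <= effect <= 1.0:
        raise ValueError("effect must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    images = np.empty((2 * n_per_class, h, w, 3), dtype=np.float32)
    masks = np.zeros((2 * n_per_class, h, w), dtype=bool)
    labels: list[str] = []
    for i in range(2 * n_per_class):
        label = BENIGN if i < n_per_class else MALIGNANT
        img = _background(rng, h, w)
        if label == MALIGNANT:
            mask = np.zeros((h, w), dtype=bool)
            for _ in range(rng.integers(1, 4)):
                profile, support = _blob(rng, h, w)
                contrast = 0.15 + 0.45 * effect
                img = img + contrast * profile
                mask |= support
            masks[i] = mask
        elif rng.random() < 0.5:
            # optional faint smooth blob, below the malignant contrast range
            profile, _ = _blob(rng, h, w)
            img = img + 0.05 * profile
        img = np.clip(img, 0.0, 1.0)
        images[i] = img[:, :, None]
        labels.append(label)
    return ImageSet(images=images, labels=labels, lesion_masks=masks, seed=seed,
                    params={"n_per_class": n_per_class, "size": list(size),
                            "effect": effect})


def generate_correlated_pair(n: int, p1: int, p2: int, r: float,
                             seed: int = 0, noise: float = 1.0
                             ) -> CorrelatedFeaturePair:
    """Two feature matrices with a planted first canonical correlation.

    Both views load a shared standard-normal latent ``z`` on their first
    direction with independent Gaussian noise; the loading is chosen so the
    population canonical correlation between the views equals ``r``:
    each view's correlation with z is sqrt(r), hence corr(view1, view2) = r.
    """
    if n <= 4:
        raise ValueError("n must exceed 4")
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n, 1))
    a1 = rng.normal(size=(1, p1))
    a2 = rng.normal(size=(1, p2))
    a1 /= np.linalg.norm(a1)
    a2 /= np.linalg.norm(a2)
    if r >= 1.0 or noise <= 0:
        scale = 1e6 if noise <= 0 else np.inf
    else:
        # signal sd s with unit noise: corr(view, z) = s/sqrt(s^2+noise^2)
        scale = noise * np.sqrt(np.sqrt(r) ** 2 / (1 - np.sqrt(r) ** 2)) \
            if r > 0 else 0.0
    if not np.isfinite(scale):
        e1 = np.zeros((n, p1))
        e2 = np.zeros((n, p2))
        scale = 1.0
    else:
        e1 = noise * rng.normal(size=(n, p1))
        e2 = noise * rng.normal(size=(n, p2))
    f1 = scale * z @ a1 + e1
    f2 = scale * z @ a2 + e2
    return CorrelatedFeaturePair(
        F1=FeatureMatrix(f1, feature_ids=[f"v1.f{j}" for j in range(p1)]),
        F2=FeatureMatrix(f2, feature_ids=[f"v2.f{j}" for j in range(p2)]),
        latent_corr=float(r), seed=seed,
    )


def generate_selection_benchmark(n: int, p_inf: int, p_noise: int,
                                 seed: int = 0, shift: float = 1.0
                                 ) -> SelectionBenchmark:
    """Feature matrix with known informative columns.

    Informative columns are Gaussians whose class means differ by ``shift``
    standard deviations; noise columns are standard Gaussians independent of
    the label. Informative column indices are scattered by a seeded
    permutation so selectors cannot exploit ordering.
    """
    if p_inf < 1:
        raise ValueError("p_inf must be >= 1")
    if p_noise < 0:
        raise ValueError("p_noise must be nonnegative")
    rng = np.random.default_rng(seed)
    p = p_inf + p_noise
    y = np.arange(n) % 2
    rng.shuffle(y)
    X = rng.normal(size=(n, p))
    perm = rng.permutation(p)
    informative = np.sort(perm[:p_inf])
    X[:, informative] += shift * y[:, None]
    return SelectionBenchmark(
        X=FeatureMatrix(X, feature_ids=[f"f{j:04d}" for j in range(p)]),
        y=y, informative_idx=informative, seed=seed,
    )
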