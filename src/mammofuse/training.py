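"""Dataset splitting, augmentation, Bayesian hyperparameter search and
SGD-momentum training for the bottleneck-residual networks.

Defaults follow the reference operating point: learning rate 0.000241,
momentum 0.776, 50 epochs, mini-batch 64, stochastic gradient descent with
momentum, and a stratified 50:50 train/test split. Augmentation (horizontal
flip, vertical flip, +90 and 180 degree rotations) is applied after the
split and to the training partition only, so no test-set pixels leak into
training-side computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Network, SGDMomentum
from .synthetic import ImageSet


@dataclass
class HyperParams:
    """SGD-momentum training configuration."""

    learning_rate: float = 0.000241
    momentum: float = 0.776
    epochs: int = 50
    minibatch: int = 64
    optimizer: str = "sgdm"

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.epochs < 0 or self.minibatch < 1:
            raise ValueError("epochs must be >= 0 and minibatch >= 1")
        if self.optimizer != "sgdm":
            raise ValueError("only the 'sgdm' optimizer is supported")


@dataclass
class SplitPlan:
    train_ids: list[int]
    test_ids: list[int]
    fraction: float = 0.5
    stratified: bool = True
    seed: int = 0


class TrainingFailure(RuntimeError):
    """Raised when the loss diverges (NaN/inf); carries diagnostics."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


def split_dataset(images: ImageSet, seed: int = 0,
                  fraction: float = 0.5) -> SplitPlan:
    """Stratified split; per-class train size is within 1 of
    fraction * class size."""
    y = images.y
    train_ids: list[int] = []
    test_ids: list[int] = []
    rng = np.random.default_rng(seed)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 images")
        rng.shuffle(idx)
        k = int(round(fraction * len(idx)))
        k = min(max(k, 1), len(idx) - 1)
        train_ids.extend(idx[:k].tolist())
        test_ids.extend(idx[k:].tolist())
    return SplitPlan(train_ids=sorted(train_ids), test_ids=sorted(test_ids),
                     fraction=fraction, stratified=True, seed=seed)


_AUG_OPS = {
    "hflip": lambda a: a[:, ::-1],
    "vflip": lambda a: a[::-1, :],
    "rot90": lambda a: np.rot90(a, 1),
    "rot180": lambda a: np.rot90(a, 2),
}


def augment(images: ImageSet, seed: int = 0,
            ops: tuple[str, ...] = ("hflip", "vflip", "rot90", "rot180")
            ) -> ImageSet:
    """Append flip/rotation variants of every image (1 original + 4 variants
    with the default ops). Labels and lesion masks follow their source;
    provenance is recorded in the sample IDs."""
    if len(images) == 0:
        raise ValueError("cannot augment an empty image set")
    h, w = images.images.shape[1:3]
    if h != w and any(op.startswith("rot") for op in ops):
        raise ValueError("90-degree rotations require square images")
    out_images = [images.images]
    out_masks = [images.lesion_masks] if images.lesion_masks is not None else None
    labels = list(images.labels)
    sample_ids = list(images.sample_ids)
    for op in ops:
        f = _AUG_OPS[op]
        out_images.append(np.stack([f(img) for img in images.images]))
        if out_masks is not None:
            out_masks.append(np.stack([f(m) for m in images.lesion_masks]))
        labels.extend(images.labels)
        sample_ids.extend(f"{sid}.{op}" for sid in images.sample_ids)
    return ImageSet(
        images=np.concatenate(out_images),
        labels=labels,
        lesion_masks=None if out_masks is None else np.concatenate(out_masks),
        seed=seed,
        params={**images.params, "augment_ops": list(ops)},
        sample_ids=sample_ids,
    )


def train_network(net: Network, train_set: ImageSet, hp: HyperParams,
                  seed: int = 0) -> Network:
    """Mini-batch SGD-momentum training on the cross-entropy loss.

    Per-epoch mean training loss is recorded on ``net.train_history``. A
    non-finite loss raises :class:`TrainingFailure` with the history so far.
    """
    x = train_set.images
    y = train_set.y
    opt = SGDMomentum(net.params(), lr=hp.learning_rate, momentum=hp.momentum)
    rng = np.random.default_rng(seed)
    history: list[float] = []
    n = len(x)
    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, hp.minibatch):
            batch = order[start : start + hp.minibatch]
            net.zero_grad()
            loss = net.loss_and_grad(x[batch], y[batch])
            if not np.isfinite(loss):
                raise TrainingFailure(
                    f"loss diverged at epoch {epoch} (lr={hp.learning_rate}, "
                    f"momentum={hp.momentum})", history)
            opt.step()
            losses.append(loss * len(batch))
        history.append(float(np.sum(losses) / n))
    net.train_history = history
    if hp.epochs > 0:
        recalibrate_batchnorm(net, x, rng)
    return net


def recalibrate_batchnorm(net: Network, x: np.ndarray,
                          rng: np.random.Generator | None = None,
                          max_images: int = 256) -> None:
    """Replace batchnorm running statistics with population moments.

    Mini-batch running averages lag the final weights when training is
    short; one full forward pass in training mode with zeroed momentum
    resets every layer's statistics to the moments of (a sample of) the
    training data under the trained weights.
    """
    from .nn import BatchNorm2D

    if len(x) > max_images:
        rng = rng or np.random.default_rng(0)
        x = x[rng.choice(len(x), size=max_images, replace=False)]
    bns = [l for l in net.layers() if isinstance(l, BatchNorm2D)]
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.momentum = 0.0
    try:
        net.forward(x, training=True)
    finally:
        for bn, m in zip(bns, saved):
            bn.momentum = m


def training_accuracy(net: Network, image_set: ImageSet,
                      batch: int = 16) -> float:
    """Fraction of images whose argmax class matches the label."""
    correct = 0
    for start in range(0, len(image_set), batch):
        probs = net.predict_proba(image_set.images[start : start + batch])
        correct += int((probs.argmax(axis=1)
                        == image_set.y[start : start + batch]).sum())
    return correct / len(image_set)


def bayes_optimize(net_name: str, train_set: ImageSet,
                   val_fraction: float = 0.3, budget: int = 10, seed: int = 0,
                   proxy_epochs: int = 2, proxy_minibatch: int = 16,
                   build_fn=None) -> HyperParams:
    """Gaussian-process Bayesian optimization of (learning rate, momentum).

    The search box is log-uniform lr in [1e-5, 1e-2] and momentum in
    [0.5, 0.99]; the objective is validation accuracy after a short proxy
    training. Expected improvement over a seeded candidate pool picks each
    next point, so the whole search is deterministic given ``seed``. The
    best-so-far objective is therefore monotone nondecreasing in budget.
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern
    from scipy.stats import norm

    if budget < 1:
        raise ValueError("budget must be >= 1")
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    if build_fn is None:
        from .architectures import build_network as build_fn

    rng = np.random.default_rng(seed)
    split = split_dataset(train_set, seed=seed, fraction=1.0 - val_fraction)
    fit_set = train_set.subset(split.train_ids)
    val_set = train_set.subset(split.test_ids)

    def objective(log_lr: float, momentum: float) -> float:
        hp = HyperParams(learning_rate=10.0 ** log_lr, momentum=momentum,
                         epochs=proxy_epochs, minibatch=proxy_minibatch)
        net = build_fn(net_name, seed=seed)
        try:
            train_network(net, fit_set, hp, seed=seed)
        except TrainingFailure:
            return 0.0
        return training_accuracy(net, val_set)

    lo = np.array([-5.0, 0.5])
    hi = np.array([-2.0, 0.99])
    xs: list[np.ndarray] = []
    ys: list[float] = []
    first = lo + rng.random(2) * (hi - lo)
    xs.append(first)
    ys.append(objective(*first))
    gp = GaussianProcessRegressor(kernel=Matern(nu=2.5), alpha=1e-4,
                                  normalize_y=True, random_state=seed)
    for _ in range(budget - 1):
        gp.fit(np.array(xs), np.array(ys))
        pool = lo + rng.random((256, 2)) * (hi - lo)
        mu, sd = gp.predict(pool, return_std=True)
        best = max(ys)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mu - best) / np.where(sd > 0, sd, 1.0)
            ei = np.where(sd > 0, (mu - best) * norm.cdf(z) + sd * norm.pdf(z), 0.0)
        nxt = pool[int(np.argmax(ei))]
        xs.append(nxt)
        ys.append(objective(*nxt))
    best_x = xs[int(np.argmax(ys))]
    hp = HyperParams(learning_rate=float(10.0 ** best_x[0]),
                     momentum=float(best_x[1]))
    hp.search_history = list(zip([tuple(map(float, v)) for v in xs], ys))
    return hp
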