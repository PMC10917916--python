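"""End-to-end orchestration: simulate -> split/augment -> train -> extract
-> fuse -> select -> classify -> t-test -> Grad-CAM.

Stages write their artifacts under the configured output directory and are
resumable: a stage whose outputs already exist is skipped, so deleting one
intermediate file re-executes only the stages downstream of it. A single
global seed fans out deterministically to per-stage seeds, making every
stage independently reproducible.

Networks are trained on the training partition only; augmentation follows
the split and touches the training partition only; feature fusion is
unsupervised and runs over all rows; wrapper selection and classifier
cross-validation run on the test partition (the evaluation convention of
k-fold CV "for the testing results").
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .features import FeatureMatrix

logger = logging.getLogger("mammofuse.pipeline")

_STAGES = ("simulate", "train", "extract", "fuse", "select", "classify",
           "ttest", "gradcam")

_DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "mammofuse_run",
    "log_level": "INFO",
    "simulate": {"n_per_class": 50, "size": [96, 96], "effect": 0.9},
    "train": {"epochs": 2, "minibatch": 16, "learning_rate": 0.000241,
              "momentum": 0.776, "augment": False, "bayes_budget": 0},
    "extract": {"batch": 8},
    "fuse": {"sigma": None, "reg": 1e-3, "bins": 256},
    "select": {"n": 6, "iters": 5, "folds": 3,
               "classifier": {"preset": "narrow", "max_iter": 60}},
    "classify": {"presets": ["medium", "trilayered"], "folds": 5,
                 "max_iter": 200, "partition": "test"},
    "ttest": {"p_level": 0.05},
    "gradcam": {"n_images": 4},
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = {}
    for key, val in override.items():
        if key not in defaults:
            raise ValueError(f"unknown config key {path + key!r}")
    for key, dval in defaults.items():
        if key in override and isinstance(dval, dict):
            out[key] = _merge(dval, override[key] or {}, path + key + ".")
        elif key in override:
            out[key] = override[key]
        else:
            out[key] = json.loads(json.dumps(dval))  # deep copy
    return out


@dataclass
class PipelineConfig:
    """Validated stage configuration; unknown keys are rejected."""

    data: dict

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(_merge(_DEFAULTS, d or {}))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=True)

    def __getitem__(self, key):
        return self.data[key]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31."""
        h = hashlib.sha256(f"{self.data['seed']}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class RunManifest:
    seed: int
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, seed: int, params: dict,
               outputs: list[Path], elapsed: float, resumed: bool) -> None:
        self.stages[stage] = {
            "seed": seed,
            "params": params,
            "elapsed_s": round(elapsed, 3),
            "resumed": resumed,
            "outputs": [{"path": str(p), "sha256": _sha256(p)}
                        for p in outputs],
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "stages": self.stages}, fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class DependencyError(RuntimeError):
    """A stage's upstream artifact is missing."""


def _fresh(outputs: list[Path], inputs: list[Path] = ()) -> bool:
    """True when every output exists and none is older than any input."""
    if not all(p.exists() for p in outputs):
        return False
    if not inputs:
        return True
    newest_in = max((p.stat().st_mtime for p in inputs if p.exists()),
                    default=0.0)
    oldest_out = min(p.stat().st_mtime for p in outputs)
    return oldest_out >= newest_in


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage {stage!r} requires missing artifact {path}; run the "
            "upstream stage first")
    return path


def run_pipeline(config: PipelineConfig,
                 stages: tuple[str, ...] = _STAGES) -> RunManifest:
    """Execute (or resume) the pipeline and return the run manifest."""
    from . import architectures, fusion, selection, training
    from .classify import crossval_evaluate
    from .selection import select_features
    from .stats import PairedAccuracies, paired_ttest
    from .synthetic import generate_images

    logging.basicConfig(level=config["log_level"])
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    manifest = RunManifest(seed=config["seed"])

    image_set = None          # lazily rebuilt from the simulate stage seed
    split = None

    def _images():
        nonlocal image_set
        if image_set is None:
            p = config["simulate"]
            image_set = generate_images(
                p["n_per_class"], tuple(p["size"]), p["effect"],
                seed=config.stage_seed("simulate"))
        return image_set

    def _split():
        nonlocal split
        if split is None:
            split = training.split_dataset(_images(),
                                           seed=config.stage_seed("train"))
        return split

    # ---- simulate --------------------------------------------------------
    if "simulate" in stages:
        t0 = time.time()
        sim_dir = out / "images"
        resumed = (sim_dir / "manifest.tsv").exists()
        if not resumed:
            _images().write(sim_dir)
        manifest.record("simulate", config.stage_seed("simulate"),
                        config["simulate"], [sim_dir / "manifest.tsv"],
                        time.time() - t0, resumed)

    # ---- train both networks --------------------------------------------
    nets: dict[str, object] = {}
    if "train" in stages or "extract" in stages or "gradcam" in stages:
        t0 = time.time()
        p = config["train"]
        seed = config.stage_seed("train")
        names = ("three_block", "four_block")
        ckpt = {n: out / f"weights_{n}.npz" for n in names}
        loss_paths = [out / f"loss_{n}.tsv" for n in names]
        resumed = all(c.exists() for c in ckpt.values()) and \
            all(l.exists() for l in loss_paths)
        if resumed:
            for name in names:
                net = architectures.build_network(name, seed=seed)
                net.load_weights(ckpt[name])
                nets[name] = net
        else:
            sp = _split()
            train_set = _images().subset(sp.train_ids)
            if p["augment"]:
                train_set = training.augment(train_set, seed=seed)
            for name, loss_path in zip(names, loss_paths):
                if p["bayes_budget"] > 0:
                    hp = training.bayes_optimize(name, train_set,
                                                 budget=p["bayes_budget"],
                                                 seed=seed)
                    hp.epochs, hp.minibatch = p["epochs"], p["minibatch"]
                else:
                    hp = training.HyperParams(
                        learning_rate=p["learning_rate"],
                        momentum=p["momentum"],
                        epochs=p["epochs"], minibatch=p["minibatch"])
                net = architectures.build_network(name, seed=seed)
                logger.info("training %s (%d params, %d images, %d epochs)",
                            name, net.count_parameters(), len(train_set),
                            hp.epochs)
                training.train_network(net, train_set, hp, seed=seed)
                nets[name] = net
                net.save_weights(ckpt[name])
                with open(loss_path, "w") as fh:
                    fh.write("epoch\tloss\n")
                    for e, l in enumerate(net.train_history):
                        fh.write(f"{e}\t{l:.6f}\n")
        if "train" in stages:
            manifest.record("train", seed, p, loss_paths, time.time() - t0,
                            resumed)

    # ---- extract ---------------------------------------------------------
    feat_paths = {n: out / f"features_{n}.tsv"
                  for n in ("three_block", "four_block")}
    if "extract" in stages:
        t0 = time.time()
        wpaths = [out / f"weights_{n}.npz" for n in feat_paths]
        resumed = _fresh(list(feat_paths.values()), wpaths)
        if not resumed:
            for name, net in nets.items():
                fm = architectures.extract_features(
                    net, _images(), batch=config["extract"]["batch"])
                fm.to_tsv(feat_paths[name])
        manifest.record("extract", config.stage_seed("extract"),
                        config["extract"], list(feat_paths.values()),
                        time.time() - t0, resumed)

    # ---- fuse ------------------------------------------------------------
    fused_path = out / "fused_features.tsv"
    if "fuse" in stages:
        t0 = time.time()
        resumed = _fresh([fused_path, out / "fusion_report.json"],
                         list(feat_paths.values()))
        if not resumed:
            f1 = FeatureMatrix.from_tsv(_require(feat_paths["three_block"],
                                                 "fuse"))
            f2 = FeatureMatrix.from_tsv(_require(feat_paths["four_block"],
                                                 "fuse"))
            p = config["fuse"]
            fused = fusion.fuse(f1, f2, sigma=p["sigma"], reg=p["reg"],
                                bins=p["bins"])
            fused.as_feature_matrix().to_tsv(fused_path)
            with open(out / "fusion_report.json", "w") as fh:
                json.dump({"rho": fused.kcca.rho, "reg": fused.kcca.reg,
                           "sigma": list(fused.sigma),
                           "entropy_weights": {
                               "min": float(fused.weights.min()),
                               "mean": float(fused.weights.mean()),
                               "max": float(fused.weights.max())},
                           "shape": list(fused.values.shape)}, fh, indent=2)
        manifest.record("fuse", config.stage_seed("fuse"), config["fuse"],
                        [fused_path, out / "fusion_report.json"],
                        time.time() - t0, resumed)

    def _partition_rows(fm: FeatureMatrix):
        if config["classify"]["partition"] == "all":
            return fm, _images().y
        ids = _split().test_ids
        return (FeatureMatrix(fm.values[ids],
                              sample_ids=[fm.sample_ids[i] for i in ids],
                              feature_ids=list(fm.feature_ids)),
                _images().y[ids])

    # ---- select ----------------------------------------------------------
    mask_path = out / "selected_mask.tsv"
    if "select" in stages:
        t0 = time.time()
        resumed = _fresh([mask_path, out / "selection_report.json"],
                         [fused_path])
        if not resumed:
            fm = FeatureMatrix.from_tsv(_require(fused_path, "select"))
            sub, y = _partition_rows(fm)
            p = config["select"]
            res = select_features(sub, y, n=p["n"], iters=p["iters"],
                                  seed=config.stage_seed("select"),
                                  classifier_cfg=dict(p["classifier"]),
                                  folds=p["folds"])
            with open(mask_path, "w") as fh:
                fh.write("feature_id\tselected\n")
                for fid, m in zip(fm.feature_ids, res.mask):
                    fh.write(f"{fid}\t{int(m)}\n")
            with open(out / "selection_report.json", "w") as fh:
                json.dump({"cost": res.cost, "cv_accuracy": res.accuracy,
                           "n_selected": res.n_selected,
                           "history": res.history,
                           "fitness_ratio": res.fitness_ratio}, fh, indent=2)
        manifest.record("select", config.stage_seed("select"),
                        config["select"],
                        [mask_path, out / "selection_report.json"],
                        time.time() - t0, resumed)

    # ---- classify --------------------------------------------------------
    metrics_path = out / "metrics.json"
    if "classify" in stages:
        t0 = time.time()
        resumed = _fresh([metrics_path],
                         [fused_path, mask_path] + list(feat_paths.values()))
        if not resumed:
            experiments = {}
            mask = None
            if mask_path.exists():
                import pandas as pd
                mask = pd.read_csv(mask_path, sep="\t")["selected"] \
                    .to_numpy(dtype=bool)
            sources = {
                "three_block": feat_paths["three_block"],
                "four_block": feat_paths["four_block"],
                "fusion": fused_path,
            }
            p = config["classify"]
            results: dict = {}
            for exp, path in sources.items():
                fm = FeatureMatrix.from_tsv(_require(path, "classify"))
                sub, y = _partition_rows(fm)
                results[exp] = {
                    preset: crossval_evaluate(
                        sub, y, preset=preset, folds=p["folds"],
                        seed=config.stage_seed("classify"),
                        max_iter=p["max_iter"]).to_dict()
                    for preset in p["presets"]}
            if mask is not None:
                fm = FeatureMatrix.from_tsv(fused_path).subset_columns(mask)
                sub, y = _partition_rows(fm)
                results["selection"] = {
                    preset: crossval_evaluate(
                        sub, y, preset=preset, folds=p["folds"],
                        seed=config.stage_seed("classify"),
                        max_iter=p["max_iter"]).to_dict()
                    for preset in p["presets"]}
            with open(metrics_path, "w") as fh:
                json.dump(results, fh, indent=2)
        manifest.record("classify", config.stage_seed("classify"),
                        config["classify"], [metrics_path],
                        time.time() - t0, resumed)

    # ---- paired t-test ---------------------------------------------------
    ttest_path = out / "ttest.json"
    if "ttest" in stages:
        t0 = time.time()
        resumed = _fresh([ttest_path], [metrics_path])
        if not resumed:
            with open(_require(metrics_path, "ttest")) as fh:
                results = json.load(fh)
            presets = config["classify"]["presets"]
            if len(presets) < 2:
                raise ValueError("ttest stage needs >= 2 classifier presets")
            exps = [e for e in ("four_block", "three_block", "fusion",
                                "selection") if e in results]
            pa = PairedAccuracies(
                labels=exps,
                a=[results[e][presets[0]]["accuracy"] for e in exps],
                b=[results[e][presets[1]]["accuracy"] for e in exps])
            res = paired_ttest(pa, p_level=config["ttest"]["p_level"])
            with open(ttest_path, "w") as fh:
                json.dump({"classifiers": presets[:2], **res.to_dict()}, fh,
                          indent=2)
        manifest.record("ttest", config.stage_seed("ttest"), config["ttest"],
                        [ttest_path], time.time() - t0, resumed)

    # ---- Grad-CAM --------------------------------------------------------
    if "gradcam" in stages:
        t0 = time.time()
        cam_dir = out / "gradcam"
        cam_dir.mkdir(exist_ok=True)
        report_path = cam_dir / "gradcam_report.json"
        resumed = _fresh([report_path],
                         [out / f"weights_{n}.npz"
                          for n in ("three_block", "four_block")])
        if not resumed:
            from PIL import Image

            imgs = _images()
            test_ids = _split().test_ids
            mal = [i for i in test_ids if imgs.labels[i] == "malignant"]
            mal = mal[: config["gradcam"]["n_images"]]
            stats = []
            net = nets.get("three_block")
            if net is None:
                raise DependencyError("gradcam requires the trained "
                                      "three_block network (run 'train')")
            for i in mal:
                cam = architectures.gradcam(net, imgs.images[i], 1)
                Image.fromarray((cam * 255).astype(np.uint8)).save(
                    cam_dir / f"{imgs.sample_ids[i]}_cam.png")
                m = imgs.lesion_masks[i]
                stats.append({"sample_id": imgs.sample_ids[i],
                              "mean_inside": float(cam[m].mean())
                              if m.any() else None,
                              "mean_outside": float(cam[~m].mean())})
            with open(report_path, "w") as fh:
                json.dump(stats, fh, indent=2)
        manifest.record("gradcam", config.stage_seed("gradcam"),
                        config["gradcam"], [report_path],
                        time.time() - t0, resumed)

    manifest.save(out / "run_manifest.json")
    return manifest
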