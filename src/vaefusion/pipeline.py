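"""End-to-end orchestration: data prep, branch training, fusion, evaluation.

The training protocol is two-stage: the generative branches (one image VAE
and one feature beta-VAE per view) are trained unsupervised on the training
split, then frozen; the softmax head is trained on the concatenated
posterior means. Defaults follow the study protocol: batch size 128 for the
image VAE, 256 for the feature beta-VAE, Adam, 50 epochs per branch, a
classifier learning rate of 0.001 for 200 epochs, and an 80/20 patient-level
split. All randomness is derived from one run seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .branches import (BackboneSpec, FeatureBetaVae, FeatureBetaVaeConfig,
                       ImageVae, ImageVaeConfig, extract_features,
                       images_to_batch, load_checkpoint, save_checkpoint,
                       train_branch)
from .errors import ConfigurationError
from .eval_stats import accuracy, auc, pairwise_delong, roc_points
from .fusion_classifier import (ClassifierConfig, SoftmaxHead, classify, fuse,
                                train_classifier)
from .imageprep import (fit_normalizer, load_and_resize, normalize,
                        save_stats)
from .manifest_io import (DatasetSplit, build_pairs, parse_manifest,
                          split_dataset, write_pairs_table)
from .nn import Tensor

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_run_config", "save_run_config", "run_train",
           "run_evaluate", "run_beta_sweep", "export_latents", "MODES"]

MODES = ("multi_view", "frontal_only", "lateral_only")
_VIEWS_FOR_MODE = {"multi_view": ("frontal", "lateral"),
                   "frontal_only": ("frontal",),
                   "lateral_only": ("lateral",)}


@dataclass(frozen=True)
class RunConfig:
    manifest: str
    image_root: str
    output_dir: str
    target_column: str = "Pneumonia"
    image_size: int = 64
    latent_dim: int = 32
    beta: float = 0.001
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    image_batch_size: int = 128
    feature_batch_size: int = 256
    image_epochs: int = 50
    feature_epochs: int = 50
    classifier_lr: float = 0.001
    classifier_epochs: int = 200
    split_ratio: float = 0.8
    mode: str = "multi_view"
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.beta < 0:
            raise ConfigurationError("beta must be >= 0")

    def image_vae_config(self) -> ImageVaeConfig:
        return ImageVaeConfig(input_size=self.image_size, latent_dim=self.latent_dim)

    def feature_vae_config(self, beta: float | None = None) -> FeatureBetaVaeConfig:
        return FeatureBetaVaeConfig(input_dim=self.backbone.output_dim,
                                    latent_dim=self.latent_dim,
                                    beta=self.beta if beta is None else beta)


def load_run_config(path: str | Path) -> RunConfig:
    payload = yaml.safe_load(Path(path).read_text())
    if "backbone" in payload:
        payload["backbone"] = BackboneSpec(**payload["backbone"])
    return RunConfig(**payload)


def save_run_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config)))


def _sub_seed(seed: int, label: str) -> int:
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def prepare_data(config: RunConfig) -> dict:
    """Manifest -> pairs -> split -> normalized per-view image arrays."""
    records = parse_manifest(config.manifest, config.target_column)
    pairs = build_pairs(records)
    split = split_dataset(pairs, config.split_ratio, _sub_seed(config.seed, "split"))
    root = Path(config.image_root)
    data: dict = {"split": split, "images": {}, "stats": {}, "labels": {}}
    for side, members in (("train", split.train), ("test", split.test)):
        data["labels"][side] = np.array([p.label for p in members], dtype=int)
        data["patients"] = data.get("patients", {})
        data["patients"][side] = [p.patient_id for p in members]
    for view in ("frontal", "lateral"):
        raw = {side: [load_and_resize(root / getattr(p, view).image_path,
                                      config.image_size)
                      for p in members]
               for side, members in (("train", split.train), ("test", split.test))}
        stats = fit_normalizer(raw["train"])
        data["stats"][view] = stats
        data["images"][view] = {
            side: images_to_batch([normalize(im, stats) for im in raw[side]])
            for side in ("train", "test")}
    return data


def _branch_latents(image_vae: ImageVae, feature_vae: FeatureBetaVae,
                    images: np.ndarray, backbone: BackboneSpec
                    ) -> dict[str, np.ndarray]:
    """Posterior means from both branches for one view's image batch."""
    features = extract_features(images, backbone)
    return {"image": image_vae.encode(images).mu,
            "feature": feature_vae.encode(features).mu}


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def run_train(config: RunConfig, modes: list[str] | None = None) -> dict:
    """Train branches and classifier head(s); write checkpoints and metrics.

    `modes` defaults to [config.mode]; passing several modes reuses the same
    trained branches and fits one head per mode (the single- vs multi-view
    ablation). Returns a dict with the metrics payload and artifact paths.
    Writes: checkpoints, per-branch loss-history CSVs, normalization sidecars,
    the canonical pairs table, per-mode test predictions, metrics.json
    (deterministic) and provenance.json (timings, config hash, version).
    """
    modes = list(modes or [config.mode])
    for mode in modes:
        if mode not in MODES:
            raise ConfigurationError(f"unknown mode {mode!r}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    data = prepare_data(config)
    split: DatasetSplit = data["split"]
    write_pairs_table(split, out / "pairs.csv")
    for view in ("frontal", "lateral"):
        save_stats(data["stats"][view], out / f"norm_stats_{view}.json")
    timings["prepare_data"] = time.perf_counter() - t0

    views_needed = sorted({v for m in modes for v in _VIEWS_FOR_MODE[m]})
    branches: dict[str, dict[str, object]] = {"image": {}, "feature": {}}
    for view in views_needed:
        t0 = time.perf_counter()
        train_images = data["images"][view]["train"]
        init_rng = np.random.default_rng(_sub_seed(config.seed, f"init-image-{view}"))
        image_vae = ImageVae(config.image_vae_config(), init_rng)
        hist_img = train_branch(image_vae, train_images, config.image_epochs,
                                config.image_batch_size,
                                seed=_sub_seed(config.seed, f"train-image-{view}"),
                                beta=1.0)
        save_checkpoint(image_vae, out / f"image_vae_{view}.npz", seed=config.seed)
        _write_history(hist_img, out / f"image_vae_{view}_history.csv")

        train_features = extract_features(train_images, config.backbone)
        init_rng = np.random.default_rng(_sub_seed(config.seed, f"init-feature-{view}"))
        feature_vae = FeatureBetaVae(config.feature_vae_config(), init_rng)
        hist_feat = train_branch(feature_vae, train_features, config.feature_epochs,
                                 config.feature_batch_size,
                                 seed=_sub_seed(config.seed, f"train-feature-{view}"),
                                 beta=config.beta)
        save_checkpoint(feature_vae, out / f"feature_betavae_{view}.npz",
                        seed=config.seed)
        _write_history(hist_feat, out / f"feature_betavae_{view}_history.csv")
        branches["image"][view] = image_vae
        branches["feature"][view] = feature_vae
        timings[f"branches_{view}"] = time.perf_counter() - t0

    latents = {side: {} for side in ("train", "test")}
    for view in views_needed:
        for side in ("train", "test"):
            per_branch = _branch_latents(branches["image"][view],
                                         branches["feature"][view],
                                         data["images"][view][side],
                                         config.backbone)
            for branch_name, mu in per_branch.items():
                latents[side][(branch_name, view)] = mu

    metrics = {"config_seed": config.seed, "beta": config.beta, "modes": {}}
    for mode in modes:
        t0 = time.perf_counter()
        fused_train = fuse(latents["train"], mode=mode)
        fused_test = fuse(latents["test"], mode=mode)
        head_config = ClassifierConfig(input_dim=fused_train.dim,
                                       learning_rate=config.classifier_lr,
                                       epochs=config.classifier_epochs)
        head, head_history = train_classifier(
            fused_train.vector, data["labels"]["train"], head_config,
            seed=_sub_seed(config.seed, f"classifier-{mode}"))
        _save_head(head, out / f"head_{mode}.npz")
        probs = classify(fused_test, head)
        scores = probs[:, 1]
        labels_test = data["labels"]["test"]
        roc = auc(scores, labels_test)
        acc = accuracy(labels_test, (scores >= 0.5).astype(int))
        pd.DataFrame({"study_id": data["patients"]["test"],
                      "label": labels_test, "p_positive": scores}
                     ).to_csv(out / f"predictions_{mode}.csv", index=False)
        metrics["modes"][mode] = {"accuracy": acc, "auc": roc.auc,
                                  "n_test": int(len(labels_test)),
                                  "final_head_loss": head_history[-1]["loss"]
                                  if head_history else None}
        timings[f"classifier_{mode}"] = time.perf_counter() - t0

    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    provenance = {"config_hash": hashlib.sha256(
                      yaml.safe_dump(asdict(config)).encode()).hexdigest(),
                  "seed": config.seed, "package_version": _pkg_version,
                  "stage_timings_s": timings}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return {"metrics": metrics, "output_dir": str(out)}


def _write_history(history, path: Path) -> None:
    pd.DataFrame([{"epoch": i, "recon": h.recon, "kl": h.kl, "beta": h.beta,
                   "total": h.total} for i, h in enumerate(history)]
                 ).to_csv(path, index=False)


def _save_head(head: SoftmaxHead, path: Path) -> None:
    meta = {"kind": "SoftmaxHead", "config": asdict(head.config)}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **head.state())


def _load_head(path: Path) -> SoftmaxHead:
    with np.load(path) as payload:
        meta = json.loads(bytes(payload["__meta__"]).decode())
        state = {k: payload[k] for k in payload.files if k != "__meta__"}
    head = SoftmaxHead(ClassifierConfig(**meta["config"]), np.random.default_rng(0))
    head.load_state(state)
    return head


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def run_evaluate(config: RunConfig, run_dir: str | Path | None = None) -> dict:
    """Evaluate every trained head found in the run directory on the test
    split; write a report with accuracy/AUC per mode and the pairwise DeLong
    p-value matrix over the modes' score vectors."""
    run_dir = Path(run_dir or config.output_dir)
    head_paths = {mode: run_dir / f"head_{mode}.npz" for mode in MODES
                  if (run_dir / f"head_{mode}.npz").exists()}
    if not head_paths:
        raise ConfigurationError(f"no trained heads found in {run_dir}")
    data = prepare_data(config)
    labels_test = data["labels"]["test"]
    loaded: dict[str, dict[str, object]] = {"image": {}, "feature": {}}
    views_needed = sorted({v for m in head_paths for v in _VIEWS_FOR_MODE[m]})
    for view in views_needed:
        loaded["image"][view] = load_checkpoint(run_dir / f"image_vae_{view}.npz")
        loaded["feature"][view] = load_checkpoint(run_dir / f"feature_betavae_{view}.npz")
    latents_test = {}
    for view in views_needed:
        per_branch = _branch_latents(loaded["image"][view], loaded["feature"][view],
                                     data["images"][view]["test"], config.backbone)
        for branch_name, mu in per_branch.items():
            latents_test[(branch_name, view)] = mu
    report = {"modes": {}, "delong_p": {}}
    rocs = {}
    for mode, head_path in head_paths.items():
        head = _load_head(head_path)
        scores = classify(fuse(latents_test, mode=mode), head)[:, 1]
        roc = auc(scores, labels_test)
        rocs[mode] = roc
        report["modes"][mode] = {
            "accuracy": accuracy(labels_test, (scores >= 0.5).astype(int)),
            "auc": roc.auc}
        pd.DataFrame({"study_id": data["patients"]["test"], "label": labels_test,
                      "p_positive": scores}
                     ).to_csv(run_dir / f"predictions_{mode}.csv", index=False)
        pd.DataFrame(roc_points(roc), columns=["fpr", "tpr"]
                     ).to_csv(run_dir / f"roc_{mode}.csv", index=False)
    report["delong_p"] = pairwise_delong(rocs)
    (run_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# Beta sweep
# ---------------------------------------------------------------------------

def run_beta_sweep(config: RunConfig, beta_grid: list[float] | None = None
                   ) -> pd.DataFrame:
    """Train the feature beta-VAE branch and a head per beta on a fixed
    split and seed; tabulate (beta, accuracy, auc, final recon, final kl).

    The classifier for each beta uses the concatenated feature-branch latent
    means of the two views (the beta-VAE model alone, no image branch).
    """
    beta_grid = list(beta_grid if beta_grid is not None
                     else (0.001, 0.1, 1, 2, 5, 10, 100))
    if not beta_grid:
        raise ConfigurationError("beta grid must be nonempty")
    data = prepare_data(config)
    features = {view: {side: extract_features(data["images"][view][side],
                                              config.backbone)
                       for side in ("train", "test")}
                for view in ("frontal", "lateral")}
    rows = []
    for beta in beta_grid:
        mus = {"train": [], "test": []}
        recon_final, kl_final = [], []
        for view in ("frontal", "lateral"):
            init_rng = np.random.default_rng(_sub_seed(config.seed, f"init-feature-{view}"))
            branch = FeatureBetaVae(config.feature_vae_config(beta=beta), init_rng)
            history = train_branch(branch, features[view]["train"],
                                   config.feature_epochs, config.feature_batch_size,
                                   seed=_sub_seed(config.seed, f"train-feature-{view}"),
                                   beta=beta)
            recon_final.append(history[-1].recon if history else np.nan)
            kl_final.append(history[-1].kl if history else np.nan)
            for side in ("train", "test"):
                mus[side].append(branch.encode(features[view][side]).mu)
        fused = {side: np.concatenate(mus[side], axis=1) for side in mus}
        head_config = ClassifierConfig(input_dim=fused["train"].shape[1],
                                       learning_rate=config.classifier_lr,
                                       epochs=config.classifier_epochs)
        head, _ = train_classifier(fused["train"], data["labels"]["train"],
                                   head_config,
                                   seed=_sub_seed(config.seed, "classifier-sweep"))
        scores = classify(fused["test"], head)[:, 1]
        labels_test = data["labels"]["test"]
        rows.append({"beta": beta,
                     "accuracy": accuracy(labels_test, (scores >= 0.5).astype(int)),
                     "auc": auc(scores, labels_test).auc,
                     "final_recon": float(np.mean(recon_final)),
                     "final_kl": float(np.mean(kl_final))})
    table = pd.DataFrame(rows)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "beta_sweep.csv", index=False)
    return table


# ---------------------------------------------------------------------------
# Latent export
# ---------------------------------------------------------------------------

def export_latents(config: RunConfig, run_dir: str | Path | None = None,
                   out_path: str | Path | None = None) -> Path:
    """Export posterior-mean latents for every paired study, keyed by
    study id, as a compressed array file."""
    run_dir = Path(run_dir or config.output_dir)
    out_path = Path(out_path or run_dir / "latents.npz")
    data = prepare_data(config)
    arrays: dict[str, np.ndarray] = {}
    for view in ("frontal", "lateral"):
        image_vae = load_checkpoint(run_dir / f"image_vae_{view}.npz")
        feature_vae = load_checkpoint(run_dir / f"feature_betavae_{view}.npz")
        for side in ("train", "test"):
            per_branch = _branch_latents(image_vae, feature_vae,
                                         data["images"][view][side], config.backbone)
            for branch_name, mu in per_branch.items():
                for patient, row in zip(data["patients"][side], mu):
                    arrays[f"{patient}/{branch_name}/{view}"] = row
    np.savez_compressed(out_path, **arrays)
    return out_path
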