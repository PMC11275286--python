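"""Synthetic paired-view pseudo-radiographs with controllable class signal.

Each synthetic patient gets a frontal and a lateral grayscale image built
from an elliptical "thorax" template (torso plus darker lung fields) with
additive Gaussian noise. Positive patients additionally receive one to three
bright elliptical opacity blobs whose placement is view-specific — inside
the lung fields on the frontal view, in a posterior band on the lateral view
— scaled by per-view signal strengths. Optional per-view visibility
probabilities make the signal partial and complementary across views (when
both draws come up invisible, the higher-visibility view is forced so every
positive carries signal somewhere). Configured fractions of patients get
uncertain (-1.0) or blank target labels or only a single view, exercising
the label policy and pair filtering downstream. The manifest is written in
the CheXpert dialect, so the generated tree is a drop-in stand-in for a real
study layout.

All assignments are deterministic given the seed: fractions are realised as
"first floor(f * n) patients after a seeded shuffle", so expected counts are
exact rather than binomial.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .errors import ConfigurationError

__all__ = ["SyntheticConfig", "generate", "generate_latent_toy"]

#: class imbalance of the filtered study population this generator emulates
DEFAULT_POSITIVE_FRACTION = 4948 / (4948 + 1278)


@dataclass(frozen=True)
class SyntheticConfig:
    n_patients: int = 100
    image_size: int = 64
    positive_fraction: float = DEFAULT_POSITIVE_FRACTION
    signal_strength_frontal: float = 0.5
    signal_strength_lateral: float = 0.5
    noise_sd: float = 0.05
    uncertain_fraction: float = 0.0
    missing_fraction: float = 0.0
    single_view_fraction: float = 0.0
    visibility_frontal: float = 1.0
    visibility_lateral: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        for name in ("positive_fraction", "uncertain_fraction", "missing_fraction",
                     "single_view_fraction", "visibility_frontal", "visibility_lateral"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.missing_fraction + self.single_view_fraction > 1.0:
            raise ConfigurationError("missing + single-view fractions exceed 1")
        if min(self.signal_strength_frontal, self.signal_strength_lateral) < 0:
            raise ConfigurationError("signal strengths must be >= 0")


def _ellipse(size: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1)
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _gaussian_blob(size: int, cy: float, cx: float, sigma: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1)
    return np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma ** 2))


def _frontal_template(size: int) -> np.ndarray:
    img = np.full((size, size), 0.05)
    img[_ellipse(size, 0.50, 0.50, 0.46, 0.40)] = 0.50
    img[_ellipse(size, 0.46, 0.32, 0.28, 0.14)] = 0.25
    img[_ellipse(size, 0.46, 0.68, 0.28, 0.14)] = 0.25
    return img


def _lateral_template(size: int) -> np.ndarray:
    img = np.full((size, size), 0.05)
    img[_ellipse(size, 0.50, 0.50, 0.46, 0.30)] = 0.50
    img[_ellipse(size, 0.46, 0.46, 0.30, 0.18)] = 0.25
    return img


def _add_opacities(img: np.ndarray, view: str, strength: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Superimpose 1-3 bright blobs in view-specific regions."""
    size = img.shape[0]
    n_blobs = int(rng.integers(1, 4))
    out = img.copy()
    for _ in range(n_blobs):
        if view == "frontal":
            # within one of the two lung fields
            cx = rng.choice([0.32, 0.68]) + rng.uniform(-0.06, 0.06)
            cy = rng.uniform(0.28, 0.64)
        else:
            # posterior band of the lateral projection
            cx = rng.uniform(0.52, 0.64)
            cy = rng.uniform(0.30, 0.64)
        sigma = rng.uniform(0.05, 0.10)
        amplitude = strength * rng.uniform(0.8, 1.2)
        out += amplitude * _gaussian_blob(size, cy, cx, sigma)
    return out


def _write_png(img: np.ndarray, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.clip(img, 0.0, 1.0).__mul__(255).round().astype(np.uint8),
                    mode="L").save(path, format="PNG")


def generate(config: SyntheticConfig, out_dir: str | Path) -> Path:
    """Write the synthetic image tree plus manifest; return the manifest path.

    Patient roles (missing-label, single-view, uncertain-label) are assigned
    deterministically from seeded shuffles; uncertain labels go to positive
    patients so the uncertain-to-positive policy keeps labels consistent with
    the imagery. Missing-label patients have both rows blank (they drop out
    entirely); single-view patients keep only their frontal image.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ids = [f"patient{i + 1:05d}" for i in range(n)]

    n_pos = int(round(config.positive_fraction * n))
    label_order = rng.permutation(n)
    positive = np.zeros(n, dtype=bool)
    positive[label_order[:n_pos]] = True

    status_order = rng.permutation(n)
    n_missing = int(np.floor(config.missing_fraction * n))
    n_single = int(np.floor(config.single_view_fraction * n))
    missing = np.zeros(n, dtype=bool)
    single_view = np.zeros(n, dtype=bool)
    missing[status_order[:n_missing]] = True
    single_view[status_order[n_missing:n_missing + n_single]] = True

    uncertain = np.zeros(n, dtype=bool)
    pos_not_missing = [i for i in rng.permutation(n)
                       if positive[i] and not missing[i]]
    n_unc = int(np.floor(config.uncertain_fraction * n))
    for i in pos_not_missing[:n_unc]:
        uncertain[i] = True

    rows = []
    for i, patient in enumerate(ids):
        # per-view visibility of the opacity signal (positives only)
        vis_f = vis_l = False
        if positive[i]:
            vis_f = rng.uniform() < config.visibility_frontal
            vis_l = rng.uniform() < config.visibility_lateral
            if not (vis_f or vis_l):
                if config.visibility_frontal >= config.visibility_lateral:
                    vis_f = True
                else:
                    vis_l = True
        for view, template, strength, visible in (
                ("frontal", _frontal_template, config.signal_strength_frontal, vis_f),
                ("lateral", _lateral_template, config.signal_strength_lateral, vis_l)):
            if view == "lateral" and single_view[i]:
                continue
            img = template(config.image_size)
            if positive[i] and visible and strength > 0:
                img = _add_opacities(img, view, strength, rng)
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
            rel = Path(patient) / "study1" / f"view1_{view}.png"
            _write_png(img, out_dir / "images" / rel)
            if missing[i]:
                cell = ""
            elif uncertain[i]:
                cell = "-1.0"
            else:
                cell = "1.0" if positive[i] else "0.0"
            rows.append({
                "Path": str(Path("images") / rel),
                "Sex": "Unknown", "Age": "",
                "Frontal/Lateral": "Frontal" if view == "frontal" else "Lateral",
                "AP/PA/Lateral": ("AP" if i % 2 == 0 else "PA")
                                 if view == "frontal" else "Lateral",
                "Pneumonia": cell,
            })
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    (out_dir / "config.yaml").write_text(yaml.safe_dump(asdict(config)))
    return manifest_path


def generate_latent_toy(n: int, d: int, effect: float, seed: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-covariance Gaussian classes separated by `effect` along a
    random unit direction — a fast fixture for classifier and metric tests.

    The optimal-direction AUC is Phi(effect / sqrt(2)) in closed form.
    """
    if n < 2 or d < 1:
        raise ConfigurationError("need n >= 2 and d >= 1")
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(d)
    direction /= np.linalg.norm(direction)
    labels = (np.arange(n) % 2 == 0).astype(int)
    labels = labels[rng.permutation(n)]
    features = rng.standard_normal((n, d)) + np.outer(labels, effect * direction)
    return features, labels
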