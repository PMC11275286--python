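"""Latent fusion and the softmax classification head.

Latent codes from the feature-space beta-VAE (z1) and the image-space VAE
(z2), one per view, are concatenated in a fixed segment order —
(z1-frontal, z1-lateral, z2-frontal, z2-lateral) — and fed to a single fully
connected layer with a softmax over the two classes (pneumonia present /
absent). In a single-view ablation mode only that view's two segments are
fused. Classification-time latents are the posterior means, so predictions
are deterministic given trained weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, DegenerateInputError
from .nn import Adam, Linear, Module, Tensor, logsumexp
from .vae_core import LatentCode

__all__ = ["FusedRepresentation", "ClassifierConfig", "SEGMENT_ORDER", "fuse",
           "slice_back", "SoftmaxHead", "classify", "train_classifier"]

#: (branch, view) segments in their fixed concatenation order;
#: "feature" is the beta-VAE branch (z1), "image" the conv VAE branch (z2).
SEGMENT_ORDER: tuple[tuple[str, str], ...] = (
    ("feature", "frontal"), ("feature", "lateral"),
    ("image", "frontal"), ("image", "lateral"),
)

_MODE_SEGMENTS = {
    "multi_view": SEGMENT_ORDER,
    "frontal_only": (("feature", "frontal"), ("image", "frontal")),
    "lateral_only": (("feature", "lateral"), ("image", "lateral")),
}


@dataclass(frozen=True)
class FusedRepresentation:
    """Concatenated latent vector(s) plus the segment layout that built it."""

    vector: np.ndarray
    provenance: tuple[tuple[str, str, int], ...]

    @property
    def dim(self) -> int:
        return self.vector.shape[-1]


@dataclass(frozen=True)
class ClassifierConfig:
    input_dim: int
    n_classes: int = 2
    learning_rate: float = 0.001
    epochs: int = 200


def fuse(latents: dict[tuple[str, str], LatentCode | np.ndarray],
         mode: str = "multi_view") -> FusedRepresentation:
    """Concatenate latent codes in the fixed segment order (no transformation).

    `latents` maps (branch, view) to a code; codes may be 1-D (one sample) or
    2-D (batch, dim). A segment required by `mode` but absent raises a
    contract error naming it.
    """
    if mode not in _MODE_SEGMENTS:
        raise ContractError(f"unknown fusion mode {mode!r}")
    parts, provenance = [], []
    for branch, view in _MODE_SEGMENTS[mode]:
        if (branch, view) not in latents:
            raise ContractError(f"missing latent segment ({branch}, {view})")
        code = latents[(branch, view)]
        arr = code.z if isinstance(code, LatentCode) else np.asarray(code, dtype=np.float64)
        parts.append(arr)
        provenance.append((branch, view, arr.shape[-1]))
    return FusedRepresentation(vector=np.concatenate(parts, axis=-1),
                               provenance=tuple(provenance))


def slice_back(fused: FusedRepresentation) -> dict[tuple[str, str], np.ndarray]:
    """Recover each input segment from a fused vector (fusion is lossless)."""
    out, offset = {}, 0
    for branch, view, dim in fused.provenance:
        out[(branch, view)] = fused.vector[..., offset:offset + dim]
        offset += dim
    return out


class SoftmaxHead(Module):
    """A single fully connected layer to class logits."""

    def __init__(self, config: ClassifierConfig, rng: np.random.Generator):
        self.config = config
        self.linear = Linear(config.input_dim, config.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.linear(x)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.linear(Tensor(np.atleast_2d(np.asarray(x, dtype=np.float64)))).data
        shifted = logits - logits.max(axis=1, keepdims=True)
        expd = np.exp(shifted)
        return expd / expd.sum(axis=1, keepdims=True)


def classify(fused: FusedRepresentation | np.ndarray, head: SoftmaxHead) -> np.ndarray:
    """Class probabilities for fused representation(s); rows sum to one."""
    x = fused.vector if isinstance(fused, FusedRepresentation) else np.asarray(fused)
    x = np.atleast_2d(x)
    if x.shape[-1] != head.config.input_dim:
        raise ContractError(
            f"fused dim {x.shape[-1]} != classifier input_dim {head.config.input_dim}")
    return head.predict_proba(x)


def _cross_entropy(head: SoftmaxHead, x: Tensor, onehot: np.ndarray) -> Tensor:
    logits = head(x)
    lse = logsumexp(logits, axis=1)
    picked = (logits * Tensor(onehot)).sum(axis=1, keepdims=True)
    return (lse - picked).mean()


def train_classifier(features: np.ndarray, labels: np.ndarray,
                     config: ClassifierConfig, seed: int = 0
                     ) -> tuple[SoftmaxHead, list[dict]]:
    """Train the softmax head with Adam full-batch cross-entropy descent.

    `features` are fused latent means, (n, input_dim); `labels` are binary.
    Returns the head and a per-epoch history of loss and training accuracy.
    `epochs=0` returns an initialised head with an empty history.
    """
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    labels = np.asarray(labels, dtype=int)
    if features.shape[0] != labels.shape[0]:
        raise ContractError("features and labels length mismatch")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise DegenerateInputError(
            f"training set has {len(classes)} class(es) {classes.tolist()}; "
            "need both classes to train the classifier")
    rng = np.random.default_rng(seed)
    head = SoftmaxHead(config, rng)
    opt = Adam(head.parameters(), lr=config.learning_rate)
    onehot = np.eye(config.n_classes)[labels]
    x = Tensor(features)
    history: list[dict] = []
    for epoch in range(config.epochs):
        loss = _cross_entropy(head, x, onehot)
        opt.zero_grad()
        loss.backward()
        opt.step()
        preds = head.predict_proba(features).argmax(axis=1)
        history.append({"epoch": epoch, "loss": loss.item(),
                        "train_accuracy": float((preds == labels).mean())})
    return head, history
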