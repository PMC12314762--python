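"""Fully convolutional anomaly detectors for unilateral breast MIPs.

Four training objectives on one fully convolutional backbone:

* ``fcdd`` — fully convolutional data description. The backbone's spatial
  feature map phi(X) is reduced per location to a pseudo-Huber score
  ``A_uv = sqrt(||phi_.uv||^2 + 1) - 1``; the breast-level anomaly score is
  the mean of that map, and the map itself is the explanation.
* ``fcdd-sym`` — same, but each location is scored by its pseudo-Huber
  distance to the contralateral breast's feature vector, i.e. the opposite
  side acts as the normal-class center.
* ``hsc`` — hypersphere classification on the globally pooled embedding;
  image-level scores only (Grad-CAM provides post-hoc maps).
* ``bce`` — a conventional binary classifier head (global average pool +
  linear logit) trained with sigmoid cross-entropy.

The semisupervised one-class loss used by fcdd/fcdd-sym/hsc is, per sample
with score s >= 0 and label y in {0, 1}:

    loss = (1 - y) * s - y * log(1 - exp(-s))

so benign samples are pulled toward the center and malignant samples pushed
away. ``exp(-s)`` is clamped to ``1 - 1e-6`` so the y=1 branch is finite at
s = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ._nn import BatchNorm2d, Conv2d, LeakyReLU, Sequential, SGD

OBJECTIVES = ("fcdd", "fcdd-sym", "hsc", "bce")
_EPS = 1e-6


# ---------------------------------------------------------------------------
# configuration


@dataclass
class BackboneConfig:
    """Layer spec of the fully convolutional backbone.

    ``channels[i]`` output channels of conv layer i; 3x3 kernels throughout;
    ``strides[i]`` the layer's stride. Receptive field and cumulative stride
    follow in closed form from the spec.
    """

    channels: tuple[int, ...] = (16, 32, 64, 128)
    strides: tuple[int, ...] = (1, 2, 1, 2)
    kernel: int = 3
    negative_slope: float = 0.1
    batch_norm: bool = True          # scale-only BN after each hidden conv
    standardize_inputs: bool = True  # per-image zero-mean/unit-SD at the stem
    dtype: str = "float32"           # compute precision of the backbone
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.strides):
            raise ValueError("channels and strides must have equal length")
        if self.receptive_field < 3:
            raise ValueError("receptive field must be >= 3")

    @property
    def total_stride(self) -> int:
        return int(np.prod(self.strides))

    @property
    def receptive_field(self) -> int:
        r, j = 1, 1
        for s in self.strides:
            r += (self.kernel - 1) * j
            j *= s
        return r

    @property
    def embedding_dim(self) -> int:
        return self.channels[-1]

    def grid_shape(self, h: int, w: int) -> tuple[int, int]:
        for s in self.strides:
            h = (h + s - 1) // s
            w = (w + s - 1) // s
        return h, w

    def build(self, rng: np.random.Generator | None = None) -> Sequential:
        rng = rng or np.random.default_rng(self.seed)
        dt = np.dtype(self.dtype)
        layers: list = []
        in_ch = 1
        for i, (ch, st) in enumerate(zip(self.channels, self.strides)):
            layers.append(Conv2d(in_ch, ch, kernel=self.kernel, stride=st, rng=rng, dtype=dt))
            if i < len(self.channels) - 1:
                if self.batch_norm:
                    layers.append(BatchNorm2d(ch, dtype=dt))
                layers.append(LeakyReLU(self.negative_slope))
            in_ch = ch
        return Sequential(layers)


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    lr: float = 1e-2
    momentum: float = 0.9
    weight_decay: float = 1e-4
    cosine_decay: bool = True
    seed: int = 0


# ---------------------------------------------------------------------------
# score maps and losses (pure functions on arrays)


def pseudo_huber_map(phi: np.ndarray) -> np.ndarray:
    """Pseudo-Huber anomaly map ``sqrt(||phi_.uv||^2 + 1) - 1``.

    ``phi`` has the channel axis third from the end, i.e. (d, u, v) or
    (N, d, u, v). Zero feature vectors map to exactly zero.
    """
    phi = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("feature map contains non-finite values")
    sq = np.sum(phi * phi, axis=-3)
    return np.sqrt(sq + 1.0) - 1.0


def symmetric_anomaly_map(phi_ipsi: np.ndarray, phi_contra: np.ndarray) -> np.ndarray:
    """Pseudo-Huber distance to the contralateral feature vector per location."""
    phi_ipsi = np.asarray(phi_ipsi, dtype=float)
    phi_contra = np.asarray(phi_contra, dtype=float)
    if phi_ipsi.shape != phi_contra.shape:
        raise ValueError(f"shape mismatch {phi_ipsi.shape} vs {phi_contra.shape}")
    return pseudo_huber_map(phi_ipsi - phi_contra)


def breast_score(anomaly_map: np.ndarray) -> float:
    """Breast-level score: mean of the pixelwise anomaly map."""
    a = np.asarray(anomaly_map, dtype=float)
    if a.size == 0:
        raise ValueError("empty anomaly map")
    if np.any(a < 0):
        raise ValueError("anomaly map must be nonnegative")
    return float(a.mean())


def _one_class_loss_terms(s: np.ndarray, y: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    e = np.minimum(np.exp(-s), 1.0 - _EPS)
    return (1.0 - y) * s - y * np.log1p(-e)


def _one_class_loss_grad(s: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d loss / d s, per sample (before batch averaging)."""
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    e = np.minimum(np.exp(-s), 1.0 - _EPS)
    return (1.0 - y) - y * e / (1.0 - e)


def fcdd_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Semisupervised one-class loss on breast-level scores, batch-averaged."""
    scores = np.asarray(scores, dtype=float)
    if np.any(scores < 0):
        raise ValueError("fcdd scores must be nonnegative")
    return float(_one_class_loss_terms(scores, labels).mean())


def hsc_score(z: np.ndarray) -> np.ndarray:
    """Pseudo-Huber norm of pooled embeddings; z is (N, d)."""
    z = np.asarray(z, dtype=float)
    return np.sqrt(np.sum(z * z, axis=-1) + 1.0) - 1.0


def hsc_loss(z: np.ndarray, labels: np.ndarray) -> float:
    """Hypersphere-classification loss on pooled embeddings, batch-averaged."""
    return float(_one_class_loss_terms(hsc_score(z), labels).mean())


def bce_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Sigmoid cross-entropy in the numerically stable log-sum-exp form."""
    l = np.asarray(logits, dtype=float)
    y = np.asarray(labels, dtype=float)
    per = np.maximum(l, 0.0) - l * y + np.log1p(np.exp(-np.abs(l)))
    return float(per.mean())


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# trained detector


class _LinearHead:
    """Global average pool + linear logit, used by the bce objective."""

    def __init__(self, dim: int, rng: np.random.Generator):
        from ._nn import Parameter

        self.w = Parameter(rng.normal(0.0, 1.0 / np.sqrt(dim), size=dim))
        self.b = Parameter(np.zeros(1))

    def parameters(self):
        return [self.w, self.b]

    def forward(self, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z = phi.mean(axis=(-2, -1))  # (N, d)
        return z @ self.w.value + self.b.value[0], z

    def backward(self, dlogit: np.ndarray, z: np.ndarray, phi_shape) -> np.ndarray:
        self.w.grad += dlogit @ z
        self.b.grad += dlogit.sum(keepdims=True)
        n, d, u, v = phi_shape
        dz = np.outer(dlogit, self.w.value)  # (N, d)
        return np.broadcast_to(dz[:, :, None, None], phi_shape) / (u * v)


def _standardize(x: np.ndarray) -> np.ndarray:
    """Per-image zero-mean, unit-SD scaling (constant images map to zero)."""
    m = x.mean(axis=(-2, -1), keepdims=True)
    s = x.std(axis=(-2, -1), keepdims=True)
    return (x - m) / np.where(s > 0, s, 1.0)


class TrainedDetector:
    """An inference-ready detector: backbone weights + objective + config."""

    def __init__(self, objective: str, backbone: Sequential, config: BackboneConfig,
                 head: _LinearHead | None = None, loss_log: list[float] | None = None,
                 seed: int = 0):
        if objective not in OBJECTIVES:
            raise ValueError(f"unknown objective {objective!r}; expected one of {OBJECTIVES}")
        self.objective = objective
        self.backbone = backbone
        self.config = config
        self.head = head
        self.loss_log = loss_log or []
        self.seed = seed

    # -- inference ---------------------------------------------------------

    def feature_map(self, images: np.ndarray) -> np.ndarray:
        """phi(X) for a batch (N, H, W) -> (N, d, u, v)."""
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if self.config.standardize_inputs:
            x = _standardize(x)
        x = x.astype(np.dtype(self.config.dtype), copy=False)
        self.backbone.set_train_mode(False)
        out, _ = self.backbone.forward(x[:, None, :, :])
        return out

    def forward_with_cache(self, image: np.ndarray):
        """Inference-mode forward of one image returning (phi, layer cache);
        used by saliency methods that need intermediate activations."""
        x = np.asarray(image, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if self.config.standardize_inputs:
            x = _standardize(x)
        x = x.astype(np.dtype(self.config.dtype), copy=False)
        self.backbone.set_train_mode(False)
        return self.backbone.forward(x[:, None, :, :])

    def anomaly_map(self, image: np.ndarray, contralateral: np.ndarray | None = None) -> np.ndarray:
        """Low-resolution (u, v) anomaly map for one image."""
        phi = self.feature_map(image[None] if image.ndim == 2 else image)
        if self.objective == "fcdd-sym":
            if contralateral is None:
                raise ValueError("fcdd-sym needs the contralateral image")
            phi_c = self.feature_map(contralateral[None] if contralateral.ndim == 2 else contralateral)
            return symmetric_anomaly_map(phi, phi_c)[0]
        return pseudo_huber_map(phi)[0]

    def score(self, images: np.ndarray, contralateral: np.ndarray | None = None) -> np.ndarray:
        """Breast-level scores for a batch; higher = more anomalous/malignant."""
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        phi = self.feature_map(x)
        if self.objective == "fcdd":
            return pseudo_huber_map(phi).mean(axis=(-2, -1))
        if self.objective == "fcdd-sym":
            if contralateral is None:
                raise ValueError("fcdd-sym needs contralateral images")
            xc = np.asarray(contralateral, dtype=np.float64)
            if xc.ndim == 2:
                xc = xc[None]
            phi_c = self.feature_map(xc)
            return symmetric_anomaly_map(phi, phi_c).mean(axis=(-2, -1))
        if self.objective == "hsc":
            return hsc_score(phi.mean(axis=(-2, -1)))
        logits, _ = self.head.forward(phi)
        return _sigmoid(logits)

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        state = {f"backbone.{k}": v for k, v in self.backbone.state_dict().items()}
        if self.head is not None:
            state["head.w"] = self.head.w.value
            state["head.b"] = self.head.b.value
        meta = {"objective": self.objective, "seed": self.seed,
                "config": asdict(self.config), "loss_log": self.loss_log}
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path: str) -> "TrainedDetector":
        data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
        meta = json.loads(bytes(data["_meta"]).decode())
        cfg_d = meta["config"]
        cfg_d["channels"] = tuple(cfg_d["channels"])
        cfg_d["strides"] = tuple(cfg_d["strides"])
        cfg = BackboneConfig(**cfg_d)
        backbone = cfg.build()
        backbone.load_state_dict({k[len("backbone."):]: data[k] for k in data.files
                                  if k.startswith("backbone.")})
        head = None
        if "head.w" in data.files:
            head = _LinearHead(cfg.embedding_dim, np.random.default_rng(0))
            head.w.value = np.asarray(data["head.w"], dtype=np.float64)
            head.b.value = np.asarray(data["head.b"], dtype=np.float64)
        return cls(meta["objective"], backbone, cfg, head=head,
                   loss_log=list(meta["loss_log"]), seed=meta["seed"])


# ---------------------------------------------------------------------------
# training


def train(objective: str, images: np.ndarray, labels: np.ndarray,
          backbone_config: BackboneConfig | None = None,
          train_config: TrainConfig | None = None,
          contralateral: np.ndarray | None = None) -> TrainedDetector:
    """Train a detector with the given objective.

    ``images`` is (N, H, W) in [0, 1]; ``labels`` in {0, 1}. For
    ``fcdd-sym``, ``contralateral`` holds the paired opposite-side image of
    each sample in canonical orientation. Benign-only training (all y = 0)
    is valid for the one-class objectives. Deterministic given the configs'
    seeds.
    """
    if objective not in OBJECTIVES:
        raise ValueError(f"unknown objective {objective!r}; expected one of {OBJECTIVES}")
    x = np.asarray(images, dtype=np.float64)
    y = np.asarray(labels, dtype=float)
    if x.ndim != 3 or x.shape[0] != y.shape[0]:
        raise ValueError("images must be (N, H, W) aligned with labels")
    if x.shape[0] == 0:
        raise ValueError("empty training split")
    if np.all(y == 1):
        raise ValueError("training needs at least one benign image")
    if objective == "fcdd-sym":
        if contralateral is None:
            raise ValueError("fcdd-sym needs contralateral images")
        xc = np.asarray(contralateral, dtype=np.float64)
        if xc.shape != x.shape:
            raise ValueError("contralateral batch must match images")

    bc = backbone_config or BackboneConfig()
    tc = train_config or TrainConfig()
    if bc.standardize_inputs:
        x = _standardize(x)
        if objective == "fcdd-sym":
            xc = _standardize(xc)
    x = x.astype(np.dtype(bc.dtype), copy=False)
    if objective == "fcdd-sym":
        xc = xc.astype(np.dtype(bc.dtype), copy=False)
    rng = np.random.default_rng(tc.seed)
    backbone = bc.build(rng)
    backbone.set_train_mode(True)
    head = _LinearHead(bc.embedding_dim, rng) if objective == "bce" else None
    params = backbone.parameters() + (head.parameters() if head else [])
    n = x.shape[0]
    steps_per_epoch = max(1, int(np.ceil(n / tc.batch_size)))
    opt = SGD(params, lr=tc.lr, momentum=tc.momentum, weight_decay=tc.weight_decay,
              total_steps=tc.epochs * steps_per_epoch if tc.cosine_decay else None)

    loss_log: list[float] = []
    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, tc.batch_size):
            idx = order[start:start + tc.batch_size]
            xb, yb = x[idx][:, None], y[idx]
            opt.zero_grad()
            loss = _step(objective, backbone, head, xb, yb,
                         x_contra=xc[idx][:, None] if objective == "fcdd-sym" else None)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {start // tc.batch_size}: {loss}")
            opt.step()
            epoch_loss += loss * len(idx)
        loss_log.append(epoch_loss / n)

    backbone.set_train_mode(False)
    return TrainedDetector(objective, backbone, bc, head=head, loss_log=loss_log, seed=tc.seed)


def _step(objective: str, backbone: Sequential, head, xb: np.ndarray, yb: np.ndarray,
          x_contra: np.ndarray | None = None) -> float:
    """One forward/backward pass; accumulates parameter grads; returns loss."""
    nb = xb.shape[0]
    phi, cache = backbone.forward(xb)
    _, d, u, v = phi.shape

    if objective in ("fcdd", "fcdd-sym"):
        if objective == "fcdd-sym":
            phi_c, cache_c = backbone.forward(x_contra)
            diff = phi - phi_c
        else:
            diff = phi
        root = np.sqrt(np.sum(diff * diff, axis=1) + 1.0)  # (N, u, v)
        a = root - 1.0
        s = a.mean(axis=(-2, -1))
        loss = fcdd_loss(s, yb)
        ds = _one_class_loss_grad(s, yb) / nb            # (N,)
        da = ds[:, None, None] / (u * v)                  # (N, u, v)
        ddiff = ((da / root)[:, None] * diff).astype(phi.dtype)  # (N, d, u, v)
        backbone.backward(ddiff, cache)
        if objective == "fcdd-sym":
            backbone.backward(-ddiff, cache_c)
        return loss

    if objective == "hsc":
        z = phi.mean(axis=(-2, -1))                       # (N, d)
        root = np.sqrt(np.sum(z * z, axis=1) + 1.0)
        h = root - 1.0
        loss = float(_one_class_loss_terms(h, yb).mean())
        dh = _one_class_loss_grad(h, yb) / nb
        dz = (dh / root)[:, None] * z
        dphi = (np.broadcast_to(dz[:, :, None, None], phi.shape) / (u * v)).astype(phi.dtype)
        backbone.backward(dphi, cache)
        return loss

    # bce
    logits, z = head.forward(phi)
    loss = bce_loss(logits, yb)
    dlogit = (_sigmoid(logits) - yb) / nb
    dphi = head.backward(dlogit, z, phi.shape).astype(phi.dtype)
    backbone.backward(dphi, cache)
    return loss
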