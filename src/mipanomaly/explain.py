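"""Full-resolution explanation maps and pixelwise localization scoring.

FCDD-style detectors output a low-resolution anomaly map on the backbone's
output grid; it is lifted to image resolution with a fixed (non-learned)
Gaussian-kernel transposed convolution whose size equals the receptive field
and whose stride equals the cumulative stride, so each grid cell spreads its
score over the image region it actually saw. BCE and HSC detectors are not
spatially explainable by construction, so Grad-CAM saliency is provided for
them. Maps are compared with binary truth masks via rank-based pixelwise
AUC, which is invariant under strictly monotone rescaling of the map.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from sklearn.metrics import roc_auc_score

from .detector import TrainedDetector

SOURCES = ("fcdd", "fcdd-sym", "hsc-gradcam", "bce-gradcam")


@dataclass
class ExplanationMap:
    pixels: np.ndarray
    source: str
    normalization: str = "raw"   # raw | local | global

    def __post_init__(self) -> None:
        if self.normalization == "raw" and np.any(self.pixels < 0):
            raise ValueError("raw explanation maps must be nonnegative")
        if self.normalization in ("local", "global"):
            if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
                raise ValueError("normalized maps must lie in [0, 1]")


def gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    """2D Gaussian kernel of the given size, normalized to sum 1."""
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-0.5 * (ax / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def upsample_heatmap(low_res: np.ndarray, receptive_field: int, stride: int,
                     sigma: float | None = None,
                     out_shape: tuple[int, int] | None = None,
                     source: str = "fcdd") -> ExplanationMap:
    """Transposed convolution of the low-res map with a fixed Gaussian.

    Kernel size = receptive field r, stride = cumulative stride s, default
    sigma = r / 4. The natural output, size (u-1)*s + r, is center-cropped
    (or zero-padded) to ``out_shape``. Because the kernel sums to one, total
    mass is conserved for maps supported away from the borders, and the
    operation is linear in the input map.
    """
    a = np.asarray(low_res, dtype=float)
    if a.ndim != 2:
        raise ValueError("low-res anomaly map must be 2D")
    if np.any(a < 0):
        raise ValueError("anomaly map must be nonnegative")
    r, s = int(receptive_field), int(stride)
    if r < s:
        raise ValueError(f"receptive field {r} smaller than stride {s}")
    sigma = r / 4.0 if sigma is None else float(sigma)
    k = gaussian_kernel(r, sigma)
    u, v = a.shape
    nat_h, nat_w = (u - 1) * s + r, (v - 1) * s + r
    out = np.zeros((nat_h, nat_w))
    for i in range(r):
        for j in range(r):
            out[i:i + s * u:s, j:j + s * v:s] += a * k[i, j]
    if out_shape is not None:
        h, w = out_shape
        out = _center_fit(out, h, w)
    return ExplanationMap(out, source=source, normalization="raw")


def _center_fit(x: np.ndarray, h: int, w: int) -> np.ndarray:
    """Center-crop or zero-pad to (h, w)."""
    def fit(arr, size, axis):
        n = arr.shape[axis]
        if n > size:
            lo = (n - size) // 2
            sl = [slice(None)] * arr.ndim
            sl[axis] = slice(lo, lo + size)
            return arr[tuple(sl)]
        if n < size:
            pad = [(0, 0)] * arr.ndim
            lo = (size - n) // 2
            pad[axis] = (lo, size - n - lo)
            return np.pad(arr, pad)
        return arr

    return fit(fit(x, h, 0), w, 1)


def _bilinear_resize(x: np.ndarray, h: int, w: int) -> np.ndarray:
    if x.shape == (h, w):
        return x
    rr = np.linspace(0.0, x.shape[0] - 1.0, h)
    cc = np.linspace(0.0, x.shape[1] - 1.0, w)
    grid = np.meshgrid(rr, cc, indexing="ij")
    return ndimage.map_coordinates(x, grid, order=1, mode="nearest")


def gradcam(detector: TrainedDetector, image: np.ndarray,
            layer: int | None = None) -> ExplanationMap:
    """Grad-CAM saliency for the bce/hsc comparators.

    The target scalar is the classification logit (bce) or the pooled
    anomaly score (hsc). Channel weights are the spatial means of the
    target's gradient at the chosen conv layer; the map is
    ReLU(sum_k w_k * activation_k) bilinearly upsampled to image size.
    """
    if detector.objective not in ("bce", "hsc"):
        raise ValueError("Grad-CAM is defined here for the bce/hsc comparators")
    x = np.asarray(image, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("image must be 2D")
    phi, cache = detector.forward_with_cache(x)

    # d(target)/d(phi), analytically through the pooling head
    _, d, u, v = phi.shape
    if detector.objective == "bce":
        dphi = np.broadcast_to(
            detector.head.w.value[None, :, None, None], phi.shape) / (u * v)
    else:
        z = phi.mean(axis=(-2, -1))
        root = np.sqrt(np.sum(z * z, axis=1) + 1.0)
        dz = z / root[:, None]
        dphi = np.broadcast_to(dz[:, :, None, None], phi.shape) / (u * v)

    n_layers = len(detector.backbone.layers)
    layer = n_layers - 1 if layer is None else layer
    if not 0 <= layer < n_layers:
        raise ValueError(f"layer index {layer} out of range")
    if layer == n_layers - 1:
        acts, grads = phi, np.asarray(dphi)
    else:
        grads = detector.backbone.backward(np.ascontiguousarray(dphi), cache,
                                           stop_at=layer + 1)
        acts = cache["activations"][layer + 1]
    if acts.ndim != 4:
        raise ValueError("chosen layer has no spatial extent")

    weights = grads.mean(axis=(-2, -1))                        # (1, channels)
    cam = np.maximum((weights[:, :, None, None] * acts).sum(axis=1), 0.0)[0]
    cam = _bilinear_resize(cam, x.shape[0], x.shape[1])
    return ExplanationMap(np.maximum(cam, 0.0), source=f"{detector.objective}-gradcam",
                          normalization="raw")


def normalize_maps(maps: list[ExplanationMap], mode: str) -> list[ExplanationMap]:
    """Min-max normalize per map ("local") or over the whole set ("global").

    Local normalization eases model-to-model comparison on one breast;
    global normalization preserves case-to-case ordering across a test set.
    Constant maps normalize to all zeros.
    """
    if mode not in ("local", "global"):
        raise ValueError("mode must be 'local' or 'global'")
    if not maps:
        raise ValueError("empty map list")

    def scale(px: np.ndarray, lo: float, hi: float) -> np.ndarray:
        return (px - lo) / (hi - lo) if hi > lo else np.zeros_like(px)

    if mode == "global":
        lo = min(float(m.pixels.min()) for m in maps)
        hi = max(float(m.pixels.max()) for m in maps)
        return [replace(m, pixels=scale(m.pixels, lo, hi), normalization="global")
                for m in maps]
    return [replace(m, pixels=scale(m.pixels, float(m.pixels.min()), float(m.pixels.max())),
                    normalization="local") for m in maps]


def pixelwise_auc(expl: ExplanationMap | np.ndarray, truth_mask: np.ndarray) -> float:
    """Rank-based AUC of map values against pixel abnormal/normal labels.

    Pixels inside the annotation are abnormal, all others normal; ties count
    half (Mann-Whitney convention). Returns NaN when the mask is
    single-class (e.g. a benign image), which callers exclude from
    explainability summaries.
    """
    px = expl.pixels if isinstance(expl, ExplanationMap) else np.asarray(expl, dtype=float)
    mask = np.asarray(truth_mask).astype(bool)
    if px.shape != mask.shape:
        raise ValueError(f"map shape {px.shape} does not match mask {mask.shape}")
    y = mask.ravel()
    if y.all() or not y.any():
        return float("nan")
    return float(roc_auc_score(y, px.ravel()))


def save_overlay_gallery(images: list[np.ndarray], maps: list[ExplanationMap],
                         masks: list[np.ndarray | None], path, max_cases: int = 16) -> None:
    """PNG gallery: image, heat-map overlay, truth-mask contour per case."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = min(len(images), max_cases)
    fig, axes = plt.subplots(n, 2, figsize=(6, 3 * n), squeeze=False)
    for i in range(n):
        axes[i][0].imshow(images[i], cmap="gray", vmin=0, vmax=1)
        axes[i][0].set_title("MIP")
        axes[i][1].imshow(images[i], cmap="gray", vmin=0, vmax=1)
        axes[i][1].imshow(maps[i].pixels, cmap="inferno", alpha=0.5)
        axes[i][1].set_title(f"{maps[i].source} ({maps[i].normalization})")
        if masks[i] is not None and np.any(masks[i]):
            axes[i][1].contour(masks[i].astype(float), levels=[0.5], colors="cyan",
                               linewidths=0.8)
        for ax in axes[i]:
            ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
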