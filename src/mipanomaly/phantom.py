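"""Synthetic bilateral breast-MIP phantoms with pixel-level ground truth.

The generator emulates the statistical structure a subtraction-MIP screening
cohort presents to an anomaly detector: half-ellipse breast regions on a dark
background, low-pass Gaussian random-field parenchymal enhancement whose
amplitude follows the four BPE categories (minimal/mild/moderate/marked),
approximately mirror-symmetric left/right pairs, and two lesion phenotypes —
bright compact "mass" bumps and diffuse, irregular, lower-contrast "NME"
patches — each with a binary truth mask. Cohort-level knobs (prevalence,
known-cancer fraction, BPE mix, lesion-type mix) default to values mirroring
a screening population with 20% breast-level malignancy that drops to ~1.85%
once known cancers are excluded.

Right-side images are stored mirrored (anatomy facing the midline, as on a
bilateral MIP); ``canonical_pixels`` puts every breast in one orientation
with the chest wall on the left, which is what the detectors consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

BPE_LEVELS = ("minimal", "mild", "moderate", "marked")
LESION_TYPES = ("mass", "nme")
STAGE_BINS = ("Tis-like", "T1-like", "T2-like", "T3-like")

MANIFEST_COLUMNS = [
    "patient_id", "exam_id", "laterality", "label", "known_cancer",
    "bpe", "lesion_type", "stage_proxy", "image_path", "mask_path",
]


class LesionPlacementError(RuntimeError):
    """Raised when a lesion cannot be placed inside the breast mask."""


@dataclass(frozen=True)
class PhantomConfig:
    image_height: int = 128
    image_width: int = 128
    n_patients: int = 100
    # distribution over number of exams per patient
    exams_per_patient: dict = field(default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2})
    prevalence: float = 0.20            # breast-level malignancy rate
    known_cancer_fraction: float = 0.94  # malignant exams flagged as known cancer
    bpe_mix: tuple = (0.49, 0.30, 0.14, 0.07)
    bpe_amplitudes: tuple = (0.05, 0.10, 0.16, 0.24)  # texture SD per BPE level
    base_level: float = 0.22            # mean enhancement inside the breast
    field_sigma: float = 6.0            # low-pass scale of the background field (px)
    mass_radius_range: tuple = (3.0, 8.0)     # half-max radius, px
    mass_contrast_range: tuple = (0.35, 0.70)
    nme_area_range: tuple = (80.0, 600.0)     # px^2
    nme_contrast_range: tuple = (0.12, 0.30)
    nme_irregularity: float = 4.0       # mid-frequency scale of NME texture (px)
    lesion_type_mix: tuple = (0.65, 0.35)     # (mass, nme)
    symmetry_rho: float = 0.85          # left/right background sharing weight
    noise_sigma: float = 0.02
    # fixed mask-area cut points (px^2) for the stage proxy, at 128x128 scale
    stage_area_cuts: tuple = (85.0, 175.0, 440.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if not 0.0 <= self.prevalence <= 0.5:
            raise ValueError("breast-level prevalence must be in [0, 0.5] "
                             "(at most one malignant breast per exam)")
        if not 0.0 <= self.symmetry_rho <= 1.0:
            raise ValueError("symmetry_rho must be in [0, 1]")
        if not 0.0 <= self.known_cancer_fraction <= 1.0:
            raise ValueError("known_cancer_fraction must be in [0, 1]")
        for probs, name in ((self.bpe_mix, "bpe_mix"),
                            (self.lesion_type_mix, "lesion_type_mix"),
                            (tuple(self.exams_per_patient.values()), "exams_per_patient")):
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        if any(np.diff(self.bpe_amplitudes) <= 0):
            raise ValueError("bpe_amplitudes must be strictly increasing")
        if min(self.mass_contrast_range) <= 0 or min(self.nme_contrast_range) < 0:
            raise ValueError("contrast ranges must be positive")


@dataclass
class ScreeningImage:
    patient_id: str
    exam_id: str
    laterality: str                      # "left" | "right"
    pixels: np.ndarray                   # (H, W) in [0, 1], as-displayed
    label: int                           # 0 benign, 1 malignant
    known_cancer: bool
    bpe: str
    lesion_type: str                     # "none" | "mass" | "nme"
    stage_proxy: str                     # "none" | STAGE_BINS
    truth_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        nonempty = self.truth_mask is not None and bool(np.any(self.truth_mask))
        if bool(self.label) != nonempty:
            raise ValueError("label=1 iff truth_mask nonempty")
        if self.label == 0 and self.lesion_type != "none":
            raise ValueError("benign images must have lesion_type 'none'")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixels must lie in [0, 1]")

    @property
    def image_id(self) -> str:
        return f"{self.exam_id}_{self.laterality}"

    def canonical_pixels(self) -> np.ndarray:
        """Chest wall on the left for both lateralities."""
        return self.pixels if self.laterality == "left" else self.pixels[:, ::-1]

    def canonical_mask(self) -> np.ndarray | None:
        if self.truth_mask is None:
            return None
        return self.truth_mask if self.laterality == "left" else self.truth_mask[:, ::-1]


# ---------------------------------------------------------------------------
# geometry and fields


def breast_mask(h: int, w: int) -> np.ndarray:
    """Half-ellipse breast region, chest wall flush with the left edge."""
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    a = 0.44 * h   # vertical semi-axis
    b = 0.88 * w   # horizontal semi-axis
    return ((rows - h / 2.0) / a) ** 2 + (cols / b) ** 2 <= 1.0


def _smooth_field(rng: np.random.Generator, h: int, w: int, sigma: float) -> np.ndarray:
    """Unit-variance low-pass Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_background_pair(config: PhantomConfig, rng: np.random.Generator,
                             bpe: str = "mild") -> tuple[np.ndarray, np.ndarray]:
    """Bilaterally correlated benign backgrounds (left, mirrored right).

    Both sides share one low-pass field with weight ``symmetry_rho`` and mix
    in an independent field with weight ``sqrt(1 - rho^2)``; the realized
    pixel correlation between sides is therefore rho^2. The right image is
    mirrored so its anatomy faces the midline.
    """
    h, w = config.image_height, config.image_width
    rho = config.symmetry_rho
    amp = config.bpe_amplitudes[BPE_LEVELS.index(bpe)]
    mask = breast_mask(h, w)

    shared = _smooth_field(rng, h, w, config.field_sigma)
    indep_l = _smooth_field(rng, h, w, config.field_sigma)
    indep_r = _smooth_field(rng, h, w, config.field_sigma)
    ortho = np.sqrt(max(0.0, 1.0 - rho * rho))
    field_l = rho * shared + ortho * indep_l
    field_r = rho * shared + ortho * indep_r

    def compose(f: np.ndarray, noise: np.ndarray) -> np.ndarray:
        img = mask * (config.base_level + amp * f) + config.noise_sigma * noise
        return np.clip(img, 0.0, 1.0)

    noise_l = rng.standard_normal((h, w)) if config.noise_sigma > 0 else np.zeros((h, w))
    noise_r = rng.standard_normal((h, w)) if config.noise_sigma > 0 else np.zeros((h, w))
    left = compose(field_l, noise_l)
    right = compose(field_r, noise_r)[:, ::-1]
    return left, right


def render_lesion(kind: str, config: PhantomConfig, rng: np.random.Generator,
                  mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Render one lesion inside ``mask`` (canonical orientation).

    Returns (intensity_field, truth_mask). Masses are anisotropic Gaussian
    bumps with truth = half-max region; NME is thresholded mid-frequency
    noise inside a local disk, giving irregular, possibly multi-lobed masks
    at lower contrast. Raises LesionPlacementError after 100 failed
    placements.
    """
    if kind not in LESION_TYPES:
        raise ValueError(f"unknown lesion kind {kind!r}")
    if not np.any(mask):
        raise LesionPlacementError("empty breast mask")
    h, w = mask.shape
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]

    # candidate centers: interior points, away from the breast edge
    interior = ndimage.binary_erosion(mask, iterations=max(2, int(0.06 * min(h, w))))
    cand = np.argwhere(interior if interior.any() else mask)

    scale = min(h, w) / 128.0  # geometric params are quoted at 128x128

    for _ in range(100):
        cy, cx = cand[rng.integers(len(cand))]
        if kind == "mass":
            r_half = rng.uniform(*config.mass_radius_range) * scale
            contrast = rng.uniform(*config.mass_contrast_range)
            ratio = rng.uniform(0.6, 1.0)
            theta = rng.uniform(0.0, np.pi)
            sig = r_half / np.sqrt(2.0 * np.log(2.0))
            ct, st = np.cos(theta), np.sin(theta)
            u = (rows - cy) * ct + (cols - cx) * st
            v = -(rows - cy) * st + (cols - cx) * ct
            q = (u / sig) ** 2 + (v / (sig * ratio)) ** 2
            bump = contrast * np.exp(-0.5 * q)
            truth = bump >= contrast / 2.0
        else:
            area = rng.uniform(*config.nme_area_range) * scale * scale
            contrast = rng.uniform(*config.nme_contrast_range)
            r_patch = max(3.0, 1.8 * np.sqrt(area / np.pi))
            disk = (rows - cy) ** 2 + (cols - cx) ** 2 <= r_patch ** 2
            tex = _smooth_field(rng, h, w, config.nme_irregularity * max(scale, 0.25))
            vals = tex[disk & mask]
            if vals.size == 0:
                continue
            frac = min(0.9, area / max(1, vals.size))
            thr = np.quantile(vals, 1.0 - frac)
            truth = disk & mask & (tex > thr)
            soft = ndimage.gaussian_filter(truth.astype(float), 1.0)
            peak = soft.max()
            bump = contrast * (soft / peak if peak > 0 else soft)
        if not truth.any():
            continue
        if np.array_equal(truth & mask, truth):  # fully inside the breast
            return bump, truth
    raise LesionPlacementError(f"could not place {kind} lesion in 100 attempts")


def stage_bin(area_px: float, config: PhantomConfig) -> str:
    """Stage proxy from truth-mask area, normalized to 128x128 scale."""
    norm = (128.0 * 128.0) / (config.image_height * config.image_width)
    a = area_px * norm
    for cut, name in zip(config.stage_area_cuts, STAGE_BINS[:3]):
        if a < cut:
            return name
    return STAGE_BINS[3]


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: PhantomConfig) -> tuple[pd.DataFrame, list[ScreeningImage]]:
    """Generate a full phantom cohort: patients -> exams -> bilateral pairs.

    At most one breast per exam is malignant. Deterministic given
    ``config.seed``; the manifest row order is patient, exam, left-then-right.
    """
    rng = np.random.default_rng(config.seed)
    exam_counts = sorted(config.exams_per_patient.items())
    count_vals = np.array([k for k, _ in exam_counts])
    count_probs = np.array([p for _, p in exam_counts])

    images: list[ScreeningImage] = []
    rows: list[dict] = []
    n_malignant = 0
    for p in range(config.n_patients):
        pid = f"P{p:05d}"
        n_exams = int(rng.choice(count_vals, p=count_probs))
        for e in range(n_exams):
            eid = f"{pid}E{e}"
            bpe = BPE_LEVELS[int(rng.choice(4, p=np.asarray(config.bpe_mix)))]
            left_px, right_px = generate_background_pair(config, rng, bpe=bpe)
            malignant_exam = rng.random() < 2.0 * config.prevalence
            mal_side = rng.choice(["left", "right"]) if malignant_exam else None
            known = bool(malignant_exam and rng.random() < config.known_cancer_fraction)
            for lat, px in (("left", left_px), ("right", right_px)):
                canon = px if lat == "left" else px[:, ::-1]
                lesion_type, stage, truth = "none", "none", None
                if lat == mal_side:
                    kind = LESION_TYPES[int(rng.choice(2, p=np.asarray(config.lesion_type_mix)))]
                    bump, truth = render_lesion(kind, config, rng, breast_mask(*canon.shape))
                    canon = np.clip(canon + bump, 0.0, 1.0)
                    lesion_type = kind
                    stage = stage_bin(float(truth.sum()), config)
                    n_malignant += 1
                stored = canon if lat == "left" else canon[:, ::-1]
                stored_mask = None
                if truth is not None:
                    stored_mask = truth if lat == "left" else truth[:, ::-1]
                img = ScreeningImage(
                    patient_id=pid, exam_id=eid, laterality=lat, pixels=stored,
                    label=int(lat == mal_side), known_cancer=known, bpe=bpe,
                    lesion_type=lesion_type, stage_proxy=stage, truth_mask=stored_mask)
                images.append(img)
                rows.append({
                    "patient_id": pid, "exam_id": eid, "laterality": lat,
                    "label": img.label, "known_cancer": known, "bpe": bpe,
                    "lesion_type": lesion_type, "stage_proxy": stage,
                    "image_path": f"images/{img.image_id}.png",
                    "mask_path": f"masks/{img.image_id}.png" if img.label else "",
                })
    if config.prevalence > 0 and n_malignant == 0:
        warnings.warn("prevalence * cohort size too small: no malignant breast realized",
                      stacklevel=2)
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return manifest, images


def write_cohort(manifest: pd.DataFrame, images: list[ScreeningImage], out_dir) -> str:
    """Write images (16-bit PNG), masks (binary PNG) and the manifest CSV."""
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for img in images:
        arr = np.round(img.pixels * 65535.0).astype(np.uint32).astype(np.int32)
        Image.fromarray(arr, mode="I").convert("I;16").save(out / "images" / f"{img.image_id}.png")
        if img.truth_mask is not None:
            Image.fromarray((img.truth_mask * 255).astype(np.uint8), mode="L").save(
                out / "masks" / f"{img.image_id}.png")
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return str(manifest_path)
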