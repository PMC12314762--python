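"""Manifest/image I/O and deterministic seed bookkeeping."""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import MANIFEST_COLUMNS


class ManifestError(ValueError):
    """Schema violation in a cohort manifest."""


def child_seed(global_seed: int, *tags) -> int:
    """Deterministic per-stage seed below 2**31.

    Every source of randomness in a run hangs off one global seed through
    named tags (stage, model, fold, seed index), so paired comparisons stay
    paired across reruns.
    """
    key = "/".join(str(t) for t in tags)
    return int(np.random.SeedSequence(
        [int(global_seed), zlib.crc32(key.encode())]).generate_state(1)[0] % (2 ** 31))


def read_manifest(path) -> pd.DataFrame:
    """Read and strictly validate a cohort manifest CSV.

    Required columns are checked, labels must be 0/1, unknown columns are
    preserved, and an empty manifest is an explicit error.
    """
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing required columns: {missing}")
    if len(df) == 0:
        raise ManifestError("manifest is empty")
    bad = df.index[~df["label"].isin([0, 1])].tolist()
    if bad:
        raise ManifestError(f"label outside {{0,1}} at rows {bad[:10]}")
    bad_lat = df.index[~df["laterality"].isin(["left", "right"])].tolist()
    if bad_lat:
        raise ManifestError(f"laterality must be left/right, bad rows {bad_lat[:10]}")
    df["label"] = df["label"].astype(int)
    df["known_cancer"] = df["known_cancer"].map(
        {True: True, False: False, "True": True, "False": False, 1: True, 0: False})
    if df["known_cancer"].isna().any():
        raise ManifestError("known_cancer must be boolean")
    return df


def read_image(path) -> np.ndarray:
    """Read a grayscale image (PNG via Pillow or NIfTI via nibabel) to [0, 1]."""
    p = Path(path)
    if p.suffix in (".nii", ".gz"):
        import nibabel as nib

        arr = np.asanyarray(nib.load(str(p)).dataobj).astype(float)
    else:
        from PIL import Image

        with Image.open(p) as im:
            arr = np.asarray(im).astype(float)
        if arr.max() > 1.0:
            arr = arr / (65535.0 if arr.max() > 255 else 255.0)
    return arr


def read_mask(path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im) > 0


def load_cohort_arrays(manifest: pd.DataFrame, root) -> dict:
    """Load a written cohort into canonical-orientation arrays keyed by image_id."""
    root = Path(root)
    images, masks = {}, {}
    for _, row in manifest.iterrows():
        iid = f"{row['exam_id']}_{row['laterality']}"
        px = read_image(root / row["image_path"])
        mask = read_mask(root / row["mask_path"]) if row["mask_path"] else None
        if row["laterality"] == "right":
            px = px[:, ::-1]
            mask = mask[:, ::-1] if mask is not None else None
        images[iid] = px
        masks[iid] = mask
    return {"images": images, "masks": masks}


def write_report(report: dict, out_dir) -> None:
    """Persist a report bundle: CSV tables, JSON summary, Markdown table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in report.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.csv", index=False)
        elif isinstance(obj, str):
            (out / f"{name}.md").write_text(obj)
        else:
            (out / f"{name}.json").write_text(json.dumps(obj, indent=2, default=float))
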