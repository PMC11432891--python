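"""Readers/writers for the formats the pipeline touches, and checkpoints.

Conventions: PNG label maps hold raw integer class ids; images are 8- or
16-bit grey rescaled to [0, 1] on read.  NIfTI volumes are sliced along the
last axis into 2-D samples.  Checkpoints are numpy ``.npz`` archives of the
flattened parameter pytree, with mask arrays stored under the ``masks/``
namespace.  Serialized index lists are 0-based and row-major.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def write_image_pair(path_img, path_label, image: np.ndarray, labels: np.ndarray):
    img16 = np.clip(np.round(np.asarray(image) * 65535), 0, 65535).astype(np.uint16)
    Image.fromarray(img16).save(path_img)
    Image.fromarray(np.asarray(labels).astype(np.uint8), mode="L").save(path_label)


def _read_png_grey(path) -> np.ndarray:
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected single-channel image, got {arr.shape}")
    return arr


def read_image_pair(path_img, path_label, n_classes: int | None = None):
    """Read an (image, label) pair; PNG grey or NIfTI.

    Images rescale to [0, 1] by dtype range; labels stay integer.  NIfTI
    volumes return lists of 2-D slices along the last axis.
    """
    path_img, path_label = str(path_img), str(path_label)
    if path_img.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        img = np.asarray(nib.load(path_img).dataobj, np.float64)
        lab = np.asarray(nib.load(path_label).dataobj).astype(np.int64)
        if img.shape != lab.shape:
            raise ValueError(f"image grid {img.shape} != label grid {lab.shape}")
        lo, hi = img.min(), img.max()
        img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
        imgs = [img[..., k] for k in range(img.shape[-1])]
        labs = [lab[..., k] for k in range(lab.shape[-1])]
    else:
        arr = _read_png_grey(path_img)
        scale = {np.uint8: 255.0, np.uint16: 65535.0}.get(arr.dtype.type)
        if scale is None:
            raise ValueError(f"{path_img}: unsupported dtype {arr.dtype}")
        imgs = [arr.astype(np.float64) / scale]
        labs = [_read_png_grey(path_label).astype(np.int64)]
        if imgs[0].shape != labs[0].shape:
            raise ValueError(
                f"image grid {imgs[0].shape} != label grid {labs[0].shape}")
    for lab in labs:
        if n_classes is not None and (lab.min() < 0 or lab.max() >= n_classes):
            raise ValueError(
                f"label values [{lab.min()}, {lab.max()}] outside 0..{n_classes - 1}")
    if len(imgs) == 1:
        return imgs[0], labs[0]
    return imgs, labs


def write_nifti(path, volume: np.ndarray):
    import nibabel as nib
    nib.save(nib.Nifti1Image(np.asarray(volume, np.float32), np.eye(4)), str(path))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: dict, meta: dict | None = None):
    flat = {p: np.asarray(leaf) for p, leaf in nn.tree_leaves(params)}
    if meta:
        flat["__meta__"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **{k.replace(".", "/"): v for k, v in flat.items()})


def load_checkpoint(path):
    with np.load(path) as z:
        meta = None
        params: dict = {}
        for key in z.files:
            if key == "__meta__":
                meta = json.loads(bytes(z[key]).decode())
                continue
            node = params
            parts = key.split("/")
            for k in parts[:-1]:
                node = node.setdefault(k, {})
            node[parts[-1]] = z[key]
    return params, meta


# ---------------------------------------------------------------------------
# dataset <-> arrays
# ---------------------------------------------------------------------------

def samples_to_arrays(samples):
    X = np.stack([s.image for s in samples]).astype(nn.DTYPE)[:, None]
    y = np.stack([s.labels for s in samples]).astype(np.int64)
    return X, y


def save_manifest(path, entries):
    Path(path).write_text(json.dumps(entries, indent=1, sort_keys=True))
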