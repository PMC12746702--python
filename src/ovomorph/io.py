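"""Reading and writing of images, masks and tables.

Multi-channel images are multi-page TIFFs (one page per channel) with the
channel names and pixel size stored as JSON in the image description; label
masks are 16-bit TIFFs; feature matrices are CSV with a sidecar JSON catalog.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .images import LabelMask, MultiChannelImage
from .morphometry import FeatureCatalog, FeatureDescriptor, FeatureMatrix

__all__ = [
    "write_image",
    "read_image",
    "write_label_mask",
    "read_label_mask",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_json",
    "read_json",
]


def write_image(image: MultiChannelImage, path) -> None:
    meta = {"channels": list(image.channels), "pixel_size_um": image.pixel_size}
    pages = np.moveaxis(image.data, -1, 0).astype(np.float32)
    tifffile.imwrite(str(path), pages, description=json.dumps(meta), photometric="minisblack")


def read_image(path) -> MultiChannelImage:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    try:
        meta = json.loads(desc)
        channels = tuple(meta["channels"])
        pixel_size = float(meta["pixel_size_um"])
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"{path}: missing or malformed image metadata ({exc})") from exc
    if data.ndim == 2:
        data = data[None]
    return MultiChannelImage(data=np.moveaxis(data, 0, -1), channels=channels, pixel_size=pixel_size)


def write_label_mask(mask: LabelMask, path) -> None:
    if mask.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot store as 16-bit TIFF")
    meta = {"compartment": mask.compartment, "pixel_size_um": mask.pixel_size}
    tifffile.imwrite(str(path), mask.labels.astype(np.uint16), description=json.dumps(meta))


def read_label_mask(path) -> LabelMask:
    with tifffile.TiffFile(str(path)) as tf:
        labels = tf.asarray()
        desc = tf.pages[0].description
    try:
        meta = json.loads(desc)
        return LabelMask(
            labels=labels.astype(np.int32),
            compartment=meta["compartment"],
            pixel_size=float(meta["pixel_size_um"]),
        )
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"{path}: missing or malformed mask metadata ({exc})") from exc


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    """CSV of metadata + feature columns, with a sidecar ``.catalog.json``."""
    path = Path(path)
    table = pd.concat([fm.metadata.reset_index(drop=True), fm.features.reset_index(drop=True)], axis=1)
    table.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "metadata_columns": list(fm.metadata.columns),
        "n_dropped": fm.n_dropped,
        "catalog_hash": fm.catalog.content_hash(),
        "descriptors": fm.catalog.to_records(),
    }
    path.with_suffix(".catalog.json").write_text(json.dumps(sidecar, indent=1))


def read_feature_matrix(path) -> FeatureMatrix:
    path = Path(path)
    sidecar_path = path.with_suffix(".catalog.json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar catalog {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    table = pd.read_csv(path)
    meta_cols = sidecar["metadata_columns"]
    feat_cols = [c for c in table.columns if c not in meta_cols]
    for c in feat_cols:
        converted = pd.to_numeric(table[c], errors="coerce")
        bad = converted.isna() & table[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric feature value at row {row}, column '{c}': "
                f"{table[c].iloc[row]!r}"
            )
        table[c] = converted
    catalog = FeatureCatalog([FeatureDescriptor(**d) for d in sidecar["descriptors"]])
    return FeatureMatrix(
        features=table[feat_cols],
        metadata=table[meta_cols],
        catalog=catalog,
        n_dropped=int(sidecar.get("n_dropped", 0)),
    )


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default))


def read_json(path):
    return json.loads(Path(path).read_text())
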