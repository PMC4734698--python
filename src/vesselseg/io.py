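"""Raster containers, TIFF input/output and gray-level histogram entropy.

The pipeline operates on single-plane 16-bit grayscale brightfield images
(DAB/Nickel stained tissue: stained structures are *dark* on a light
background). 8-bit TIFFs are promoted to 16-bit by a left shift of 8 bits;
multi-plane and multi-channel files are rejected rather than silently
truncated.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: Full scale of the 16-bit intensity range.
FULL_SCALE = 65535

#: Columns of the structure feature table written by :func:`write_outputs`.
TABLE_COLUMNS = [
    "structure_id",
    "area_px",
    "area_um2",
    "diameter_px",
    "length_px",
    "solidity",
    "aspect_ratio",
    "mean_intensity",
    "predicted_class",
]


@dataclass(frozen=True)
class IHCImage:
    """A single-plane 16-bit grayscale micrograph.

    Parameters
    ----------
    pixels
        2-D ``uint16`` array, row-major, (row, col) indexed.
    pixel_spacing_um
        Physical center-to-center pixel distance in micrometres
        (0.5 um for the acquisition protocol this pipeline targets).
    """

    pixels: np.ndarray
    pixel_spacing_um: float = 0.5

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("IHCImage requires a non-empty 2-D array")
        if px.dtype != np.uint16:
            raise ValueError(f"IHCImage pixels must be uint16, got {px.dtype}")
        if not self.pixel_spacing_um > 0:
            raise ValueError("pixel_spacing_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class BinaryMask:
    """Boolean foreground mask with the same shape as its source image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.dtype != bool:
            raise ValueError("BinaryMask requires a 2-D boolean array")
        object.__setattr__(self, "pixels", px)

    @property
    def n_true(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class LabelMap:
    """Integer raster of 8-connected structures; 0 is background.

    Positive labels are compact: exactly ``{1..n_structures}``.
    """

    labels: np.ndarray
    n_structures: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("LabelMap requires a 2-D integer array")
        if lab.size and lab.min() < 0:
            raise ValueError("labels must be non-negative")
        mx = int(lab.max()) if lab.size else 0
        if mx != self.n_structures:
            raise ValueError(
                f"labels not compact: max label {mx} != n_structures {self.n_structures}"
            )
        object.__setattr__(self, "labels", lab)

    def structure_ids(self) -> range:
        return range(1, self.n_structures + 1)


def read_image(path: str | os.PathLike, pixel_spacing_um: float = 0.5) -> IHCImage:
    """Read a single-plane grayscale TIFF as an :class:`IHCImage`.

    8-bit data is promoted to 16-bit by left-shifting 8 bits; RGB or
    multi-page files raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(
                f"{path}: multi-plane TIFF ({len(tif.pages)} pages); "
                "split stacks into single planes first"
            )
        arr = tif.pages[0].asarray()
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        arr = arr.astype(np.uint16) << 8
    elif arr.dtype != np.uint16:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype} (need uint8/uint16)")
    return IHCImage(arr, pixel_spacing_um=pixel_spacing_um)


def write_image(image: IHCImage, path: str | os.PathLike) -> None:
    """Write a 16-bit grayscale TIFF (bit-exact round trip)."""
    tifffile.imwrite(os.fspath(path), image.pixels)


def image_entropy(image: IHCImage | np.ndarray, n_bins: int = 256) -> float:
    """Shannon entropy (bits) of the gray-level histogram.

    The histogram uses ``n_bins`` equal-width bins spanning the full 16-bit
    range [0, 65535]; empty bins contribute nothing (0*log 0 = 0). Bounded by
    ``log2(n_bins)`` (8 bits at the default), the standard proxy for image
    background complexity used throughout the synthetic benchmark.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    px = image.pixels if isinstance(image, IHCImage) else np.asarray(image)
    if px.size == 0:
        raise ValueError("cannot compute entropy of an empty image")
    counts, _ = np.histogram(px, bins=n_bins, range=(0, FULL_SCALE + 1))
    p = counts[counts > 0] / px.size
    return float(-(p * np.log2(p)).sum())


def structure_table(records, classes=None, pixel_spacing_um: float = 0.5) -> pd.DataFrame:
    """Assemble the per-structure feature table.

    ``records`` are :class:`~vesselseg.structures.StructureRecord` objects;
    ``classes`` is an optional parallel sequence of predicted labels
    ('M' microvessel / 'N' non-vessel).
    """
    rows = []
    for i, r in enumerate(records):
        rows.append(
            {
                "structure_id": r.structure_id,
                "area_px": r.area_px,
                "area_um2": r.area_px * pixel_spacing_um**2,
                "diameter_px": r.diameter_px,
                "length_px": r.length_px,
                "solidity": r.solidity,
                "aspect_ratio": r.aspect_ratio,
                "mean_intensity": r.mean_intensity,
                "predicted_class": classes[i] if classes is not None else "",
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _structure_contours(labelmap: LabelMap, which: set[int]) -> np.ndarray:
    """Boolean boundary mask of the selected structures (inner boundary)."""
    from scipy import ndimage

    sel = np.isin(labelmap.labels, list(which)) if which else np.zeros_like(
        labelmap.labels, dtype=bool
    )
    if not sel.any():
        return sel
    eroded = ndimage.binary_erosion(sel, structure=np.ones((3, 3)), border_value=0)
    return sel & ~eroded


def write_outputs(
    image: IHCImage,
    labelmap: LabelMap,
    records,
    classes,
    out_dir: str | os.PathLike,
    stem: str = "image",
) -> dict[str, Path]:
    """Write the standard per-image result set.

    Produces a binary mask TIFF, a 16-bit labelmap TIFF, an RGB overlay PNG
    with green contours around structures classified as microvessels, and the
    structure feature table as CSV. Returns the paths written, keyed by kind.
    """
    import imageio.v3 as iio

    if labelmap.labels.shape != image.pixels.shape:
        raise ValueError("labelmap shape does not match image")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    paths = {
        "mask": out_dir / f"{stem}_mask.tif",
        "labelmap": out_dir / f"{stem}_labelmap.tif",
        "overlay": out_dir / f"{stem}_overlay.png",
        "table": out_dir / f"{stem}_structures.csv",
    }

    mask = (labelmap.labels > 0).astype(np.uint8) * 255
    tifffile.imwrite(os.fspath(paths["mask"]), mask)
    tifffile.imwrite(os.fspath(paths["labelmap"]), labelmap.labels.astype(np.uint16))

    gray8 = (image.pixels >> 8).astype(np.uint8)
    overlay = np.stack([gray8, gray8, gray8], axis=-1)
    vessel_ids = {r.structure_id for r, c in zip(records, classes) if c == "M"}
    contour = _structure_contours(labelmap, vessel_ids)
    overlay[contour] = (0, 255, 0)
    iio.imwrite(paths["overlay"], overlay)

    table = structure_table(records, classes, image.pixel_spacing_um)
    table.to_csv(paths["table"], index=False)
    return paths
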