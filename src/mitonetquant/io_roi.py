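"""Calibrated grayscale image I/O, cell ROIs, and batch cropping.

A quantification run starts from a large acquisition frame containing many
cells.  Cells are delineated by rectangular or polygonal ROIs collected in a
JSON manifest; :func:`batch_crop` turns the manifest into one small TIFF per
cell, which the downstream pipeline consumes one at a time.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from skimage.draw import polygon as draw_polygon
from skimage.draw import polygon_perimeter

log = logging.getLogger(__name__)

__all__ = [
    "GrayImage",
    "ROI",
    "RoiManifest",
    "FormatError",
    "BoundsError",
    "read_image",
    "write_image",
    "crop_roi",
    "load_manifest",
    "save_manifest",
    "batch_crop",
    "read_imagej_roi",
    "read_imagej_roiset",
]


class FormatError(ValueError):
    """Input file is not a single-channel 2D grayscale image."""


class BoundsError(ValueError):
    """ROI does not lie fully inside its parent image."""


_ALLOWED_DTYPES = {np.dtype(np.uint8): 8, np.dtype(np.uint16): 16}


@dataclass(frozen=True)
class GrayImage:
    """A calibrated single-channel 2D intensity raster.

    Parameters
    ----------
    pixels
        2D ``uint8`` or ``uint16`` array, row-major, origin top-left.
    pixel_size_um
        Physical edge length of one (square) pixel in micrometres.
    source_id
        Provenance string (file stem, or ``<source>__<roi_id>`` for crops).
    valid_mask
        Optional boolean raster marking pixels that belong to the ROI.  Set
        by polygon crops; ``None`` means every pixel is valid.
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.0
    source_id: str = ""
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise FormatError(f"expected 2D raster of at least 2x2, got shape {px.shape}")
        if px.dtype not in _ALLOWED_DTYPES:
            raise FormatError(f"expected uint8 or uint16 pixels, got {px.dtype}")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.valid_mask is not None and self.valid_mask.shape != px.shape:
            raise ValueError("valid_mask shape must match pixels")
        object.__setattr__(self, "pixels", px)

    @property
    def bit_depth(self) -> int:
        return _ALLOWED_DTYPES[self.pixels.dtype]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ROI:
    """A named cell region on a parent image.

    Rectangles are half-open pixel boxes ``[row0, row0+height) x
    [col0, col0+width)``; polygons are ordered ``(row, col)`` vertex lists
    rasterized with the even-odd rule, boundary pixels included.
    """

    roi_id: str
    source_id: str
    kind: str  # "rectangle" | "polygon"
    rect: tuple[int, int, int, int] | None = None  # row0, col0, height, width
    vertices: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.kind == "rectangle":
            if self.rect is None:
                raise ValueError("rectangle ROI requires rect")
            r0, c0, h, w = self.rect
            if h < 8 or w < 8:
                raise ValueError(f"ROI {self.roi_id}: rectangle must be at least 8x8 px, got {h}x{w}")
        elif self.kind == "polygon":
            v = np.asarray(self.vertices, dtype=float)
            if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
                raise ValueError(f"ROI {self.roi_id}: polygon needs at least 3 (row, col) vertices")
            # non-collinearity: some triple spans nonzero area
            a, b = v[1:-1] - v[0], v[2:] - v[0]
            area2 = np.abs(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
            if not np.any(area2 > 1e-9):
                raise ValueError(f"ROI {self.roi_id}: polygon vertices are collinear")
        else:
            raise ValueError(f"ROI {self.roi_id}: unknown kind {self.kind!r}")

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(row0, col0, height, width) of the axis-aligned bounding box."""
        if self.kind == "rectangle":
            return self.rect  # type: ignore[return-value]
        v = np.asarray(self.vertices, dtype=float)
        r0 = int(np.floor(v[:, 0].min()))
        c0 = int(np.floor(v[:, 1].min()))
        r1 = int(np.ceil(v[:, 0].max()))
        c1 = int(np.ceil(v[:, 1].max()))
        return r0, c0, r1 - r0 + 1, c1 - c0 + 1

    def to_dict(self) -> dict:
        if self.kind == "rectangle":
            r0, c0, h, w = self.rect  # type: ignore[misc]
            shape = {"type": "rectangle", "row0": r0, "col0": c0, "height": h, "width": w}
        else:
            shape = {"type": "polygon", "vertices": [list(v) for v in self.vertices]}  # type: ignore[union-attr]
        return {"roi_id": self.roi_id, "source_id": self.source_id, "shape": shape}

    @classmethod
    def from_dict(cls, d: dict) -> "ROI":
        shape = d["shape"]
        if shape["type"] == "rectangle":
            return cls(
                roi_id=d["roi_id"],
                source_id=d["source_id"],
                kind="rectangle",
                rect=(int(shape["row0"]), int(shape["col0"]), int(shape["height"]), int(shape["width"])),
            )
        if shape["type"] == "polygon":
            return cls(
                roi_id=d["roi_id"],
                source_id=d["source_id"],
                kind="polygon",
                vertices=tuple(tuple(map(float, v)) for v in shape["vertices"]),
            )
        raise ValueError(f"unknown ROI shape type {shape['type']!r}")


@dataclass
class RoiManifest:
    """An ordered ROI list plus the source_id -> image path map."""

    entries: list[ROI] = field(default_factory=list)
    image_paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.roi_id for r in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate roi_ids in manifest: {dupes}")
        missing = sorted({r.source_id for r in self.entries} - set(self.image_paths))
        if missing:
            raise ValueError(f"manifest entries reference unknown source_ids: {missing}")


def read_image(path: str | Path, pixel_size_um: float = 1.0) -> GrayImage:
    """Read a single-channel grayscale TIFF as a :class:`GrayImage`.

    Multi-page stacks are reduced to page 0 with a warning (quantification
    operates on single best-focus planes).  RGB or multi-channel files are
    rejected.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # tifffile raises assorted exception types
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        # Distinguish a z/t stack (pages, H, W) from an RGB(A) image (H, W, ch).
        if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:2]):
            raise FormatError(
                f"{path} has {arr.shape[-1]} channels; expected single-channel grayscale"
            )
        log.warning("%s is a %d-page stack; using page 0", path, arr.shape[0])
        arr = arr[0]
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected 2D grayscale data, got shape {arr.shape}")
    if arr.dtype not in _ALLOWED_DTYPES:
        raise FormatError(f"{path}: unsupported dtype {arr.dtype}; expected uint8 or uint16")
    return GrayImage(pixels=arr, pixel_size_um=pixel_size_um, source_id=path.stem)


def write_image(image: GrayImage, path: str | Path) -> None:
    """Write pixels to a grayscale TIFF (bit depth preserved)."""
    tifffile.imwrite(Path(path), image.pixels)


def _polygon_mask(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd rasterization with boundary pixels included."""
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(vertices[:, 0], vertices[:, 1], shape=shape)
    mask[rr, cc] = True
    rr, cc = polygon_perimeter(vertices[:, 0], vertices[:, 1], shape=shape, clip=True)
    mask[rr, cc] = True
    return mask


def crop_roi(image: GrayImage, roi: ROI) -> GrayImage:
    """Crop one ROI out of its parent image.

    Rectangles return the exact sub-raster.  Polygons return the bounding-box
    sub-raster with outside-polygon pixels zeroed and a ``valid_mask``
    recording which pixels belong to the cell.  Calibration is inherited.
    """
    h_img, w_img = image.shape
    r0, c0, h, w = roi.bounding_box()
    if r0 < 0 or c0 < 0 or r0 + h > h_img or c0 + w > w_img:
        raise BoundsError(
            f"ROI {roi.roi_id} (bbox {r0},{c0},{h}x{w}) exceeds image {h_img}x{w_img}"
        )
    sub = image.pixels[r0 : r0 + h, c0 : c0 + w].copy()
    valid = None
    if roi.kind == "polygon":
        v = np.asarray(roi.vertices, dtype=float) - np.array([r0, c0], dtype=float)
        valid = _polygon_mask(v, sub.shape)
        sub[~valid] = 0
    return GrayImage(
        pixels=sub,
        pixel_size_um=image.pixel_size_um,
        source_id=f"{roi.source_id}__{roi.roi_id}",
        valid_mask=valid,
    )


def load_manifest(path: str | Path) -> RoiManifest:
    """Load a JSON ROI manifest.

    Schema: ``{"images": {source_id: path}, "rois": [{roi_id, source_id,
    shape}]}`` where shape is ``{"type": "rectangle", row0, col0, height,
    width}`` or ``{"type": "polygon", "vertices": [[row, col], ...]}``.
    Relative image paths resolve against the manifest's directory.
    """
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    base = path.parent
    images = {
        k: str(p if (p := Path(v)).is_absolute() else base / v)
        for k, v in data["images"].items()
    }
    entries = [ROI.from_dict(d) for d in data["rois"]]
    return RoiManifest(entries=entries, image_paths=images)


def save_manifest(manifest: RoiManifest, path: str | Path) -> None:
    data = {
        "images": dict(manifest.image_paths),
        "rois": [r.to_dict() for r in manifest.entries],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


def batch_crop(
    manifest: RoiManifest, out_dir: str | Path, pixel_size_um: float = 1.0
) -> tuple[list[tuple[str, Path]], int]:
    """Crop every manifest ROI to ``<out_dir>/<source_id>__<roi_id>.tif``.

    Returns ``(listing, n_failed)`` where listing preserves manifest order.
    A failing ROI (out of bounds, unreadable source) is logged and skipped;
    the run continues.  Re-running overwrites deterministically.  Polygon
    crops additionally write ``<name>.mask.tif`` (uint8 0/255 validity mask)
    so downstream batch runs can restore polygon-aware coverage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images: dict[str, GrayImage] = {}
    listing: list[tuple[str, Path]] = []
    n_failed = 0
    for roi in manifest.entries:
        try:
            if roi.source_id not in images:
                images[roi.source_id] = read_image(
                    manifest.image_paths[roi.source_id], pixel_size_um=pixel_size_um
                )
            crop = crop_roi(images[roi.source_id], roi)
            dest = out_dir / f"{roi.source_id}__{roi.roi_id}.tif"
            write_image(crop, dest)
            if crop.valid_mask is not None:
                tifffile.imwrite(
                    dest.with_suffix(".mask.tif"),
                    (crop.valid_mask.astype(np.uint8) * 255),
                )
            listing.append((roi.roi_id, dest))
        except (OSError, ValueError) as exc:
            n_failed += 1
            log.error("skipping ROI %s: %s", roi.roi_id, exc)
    return listing, n_failed


# --- ImageJ .roi compatibility -------------------------------------------
#
# Minimal reader for the binary .roi format so ROI sets saved by the original
# ImageJ workflow can be migrated.  Only rectangle (type 1) and polygon
# (type 0) records are supported.

_IJ_RECT, _IJ_POLYGON = 1, 0


def read_imagej_roi(data: bytes, roi_id: str, source_id: str) -> ROI:
    """Parse one ImageJ ``.roi`` record (rectangle or polygon)."""
    if data[:4] != b"Iout":
        raise FormatError("not an ImageJ .roi file (missing 'Iout' magic)")
    roi_type = data[6]
    top, left, bottom, right = struct.unpack(">4h", data[8:16])
    if roi_type == _IJ_RECT:
        return ROI(
            roi_id=roi_id,
            source_id=source_id,
            kind="rectangle",
            rect=(top, left, bottom - top, right - left),
        )
    if roi_type == _IJ_POLYGON:
        n = struct.unpack(">h", data[16:18])[0]
        xs = struct.unpack(f">{n}h", data[64 : 64 + 2 * n])
        ys = struct.unpack(f">{n}h", data[64 + 2 * n : 64 + 4 * n])
        verts = tuple((float(top + y), float(left + x)) for x, y in zip(xs, ys))
        return ROI(roi_id=roi_id, source_id=source_id, kind="polygon", vertices=verts)
    raise FormatError(f"unsupported ImageJ ROI type {roi_type}")


def read_imagej_roiset(path: str | Path, source_id: str) -> list[ROI]:
    """Read an ImageJ RoiSet.zip into a list of ROIs (names become roi_ids)."""
    rois = []
    with zipfile.ZipFile(path) as zf:
        for name in zf.namelist():
            rois.append(read_imagej_roi(zf.read(name), Path(name).stem, source_id))
    return rois
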