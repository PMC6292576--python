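"""Egg localisation and per-frame embryo segmentation.

The egg capsule is static while the embryo moves inside it, so the capsule
interior is outlined by combining the sequence max-projection (bright
structures) with the temporal variance map (moving structures); an ellipse
is fitted to the dominant high-signal component.  Within that elliptical
ROI, each frame is segmented by a global automatic (Otsu) threshold on
3x3-median-filtered intensities — dark-field imaging gives strongly
bimodal histograms — followed by binary opening and selection of the
largest connected component.  Area follows the polygon (Green's theorem)
convention on the traced 0.5-level boundary, the same convention used when
outlines are drawn by hand, so automated and manual areas are directly
comparable.

Segmentation soft-fails: a frame with no component above the minimum-size
floor yields ``valid=False`` with NaN measures rather than an exception,
keeping time axes aligned across partial sequences.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.morphology import disk

from .errors import EggNotFoundError, ValidationError
from .experiment_io import ImageSequence

logger = logging.getLogger(__name__)

#: minimum embryo size as a fraction of the ROI ellipse area
MIN_SIZE_FRACTION = 1e-3


@dataclass(frozen=True)
class EggROI:
    """Elliptical egg region of interest, pixel coordinates (row, col)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]  # (a, b) along (row, col)
    angle_deg: float = 0.0
    source: str = "auto"  # auto | override

    def __post_init__(self):
        if self.semi_axes[0] <= 0 or self.semi_axes[1] <= 0:
            raise ValidationError("ROI semi-axes must be > 0")

    def validate_bounds(self, frame_shape: tuple[int, int]) -> None:
        """Raise unless the ellipse bounding box lies inside the frame."""
        top, left, h, w = self.bbox()
        if top < 0 or left < 0 or top + h > frame_shape[0] or left + w > frame_shape[1]:
            raise ValidationError(
                f"ROI {self.center}, axes {self.semi_axes} exceeds frame {frame_shape}"
            )

    def bbox(self) -> tuple[int, int, int, int]:
        """(top, left, height, width) of the axis-aligned bounding box."""
        th = np.deg2rad(self.angle_deg)
        a, b = self.semi_axes
        # extent of a rotated ellipse along each axis
        er = np.sqrt((a * np.cos(th)) ** 2 + (b * np.sin(th)) ** 2)
        ec = np.sqrt((a * np.sin(th)) ** 2 + (b * np.cos(th)) ** 2)
        top = int(np.floor(self.center[0] - er))
        left = int(np.floor(self.center[1] - ec))
        bottom = int(np.ceil(self.center[0] + er))
        right = int(np.ceil(self.center[1] + ec))
        return top, left, bottom - top, right - left

    def mask(self, frame_shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels inside the ellipse."""
        rr, cc = np.mgrid[: frame_shape[0], : frame_shape[1]]
        th = np.deg2rad(self.angle_deg)
        dr = rr - self.center[0]
        dc = cc - self.center[1]
        u = dr * np.cos(th) + dc * np.sin(th)
        v = -dr * np.sin(th) + dc * np.cos(th)
        return (u / self.semi_axes[0]) ** 2 + (v / self.semi_axes[1]) ** 2 <= 1.0

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])


@dataclass
class FrameMeasures:
    """Size/shape/position of the embryo in one frame (pixel units)."""

    area: float
    centroid: tuple[float, float]
    perimeter: float
    bbox: tuple[int, int, int, int]  # top, left, height, width
    solidity: float
    valid: bool
    boundary_touch: bool = False
    area_um2: float = float("nan")

    @classmethod
    def invalid(cls) -> "FrameMeasures":
        nan = float("nan")
        return cls(
            area=nan,
            centroid=(nan, nan),
            perimeter=nan,
            bbox=(0, 0, 0, 0),
            solidity=nan,
            valid=False,
        )


def locate_egg(sequence: ImageSequence, expand: float = 1.05) -> EggROI:
    """Find the egg ellipse from a sequence's projection and variance maps.

    The max-projection highlights every bright structure (capsule ring,
    embryo at all the positions it visits); the temporal variance map
    highlights where the embryo moved.  Both are min-max normalised and
    combined by elementwise maximum; the largest connected component above
    an Otsu threshold is fitted with an ellipse from its second moments,
    inflated slightly (``expand``) and clipped to the frame.  Deterministic
    for fixed input.
    """
    if sequence.n_frames < 10:
        raise ValidationError("egg localisation needs >= 10 frames")
    frames = sequence.frames.astype(np.float32)
    maxproj = frames.max(axis=0)
    var = frames.var(axis=0)

    def _norm(img):
        lo, hi = float(img.min()), float(img.max())
        if hi - lo <= 1e-9:
            return None
        return (img - lo) / (hi - lo)

    maps = [m for m in (_norm(maxproj), _norm(var)) if m is not None]
    if not maps:
        raise EggNotFoundError("sequence has no contrast above background")
    combined = np.maximum.reduce(maps)
    # lowest of the 3-class thresholds separates background from every
    # bright structure (capsule ring and embryo differ in brightness, so
    # plain 2-class Otsu would drop the dimmer ring)
    try:
        thr = float(threshold_multiotsu(combined, classes=3)[0])
    except ValueError:
        thr = float(threshold_otsu(combined))
    fg = combined > thr
    if not fg.any():
        raise EggNotFoundError("no region above background threshold")
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg)
    if n == 0:
        raise EggNotFoundError("no candidate region found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    if sizes.max() < 0.002 * fg.size:
        raise EggNotFoundError("candidate regions all below size floor")
    comp = labels == (1 + int(np.argmax(sizes)))

    props = measure.regionprops(comp.astype(np.uint8))[0]
    a = props.axis_major_length / 2.0 * expand
    b = props.axis_minor_length / 2.0 * expand
    # orientation: angle between major axis and the row axis
    angle = float(np.rad2deg(-props.orientation)) % 180.0
    # skimage orientation is relative to rows for axis_major along rows
    center = tuple(float(c) for c in props.centroid)
    H, W = combined.shape
    # clip so the ellipse stays inside the frame
    max_r = min(center[0], H - 1 - center[0])
    max_c = min(center[1], W - 1 - center[1])
    limit = max(2.0, min(max_r, max_c))
    if a > limit:
        b *= limit / a
        a = limit
    if b <= 0:
        raise EggNotFoundError("degenerate candidate region")
    roi = EggROI(center=center, semi_axes=(a, b), angle_deg=angle, source="auto")
    roi.validate_bounds((H, W))
    return roi


def apply_roi_overrides(
    rois: Mapping[str, EggROI],
    overrides_file: str | Path,
    frame_shape: tuple[int, int],
) -> dict[str, EggROI]:
    """Replace automatic ROIs with user-supplied ellipse parameters.

    The overrides CSV has columns ``embryo_id, center_row, center_col,
    semi_a, semi_b, angle_deg``.  Overridden ROIs are validated against
    frame bounds and tagged ``source='override'``; embryos not listed keep
    their automatic ROI.
    """
    updated = dict(rois)
    with open(overrides_file, newline="") as fh:
        for row in csv.DictReader(fh):
            roi = EggROI(
                center=(float(row["center_row"]), float(row["center_col"])),
                semi_axes=(float(row["semi_a"]), float(row["semi_b"])),
                angle_deg=float(row.get("angle_deg", 0.0) or 0.0),
                source="override",
            )
            roi.validate_bounds(frame_shape)
            updated[row["embryo_id"]] = roi
    return updated


def _contour_area_perimeter(mask: np.ndarray) -> tuple[float, float]:
    """Polygon area (shoelace / Green's theorem) and perimeter of the
    largest traced 0.5-level boundary of a binary mask."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return 0.0, 0.0
    contour = max(contours, key=len)
    r, c = contour[:, 0], contour[:, 1]
    area = 0.5 * abs(np.dot(r, np.roll(c, 1)) - np.dot(c, np.roll(r, 1)))
    perimeter = float(np.sum(np.linalg.norm(np.diff(contour, axis=0), axis=1)))
    return float(area), perimeter


def segment_embryo(
    frame: np.ndarray,
    roi: EggROI,
    scale: float | None = None,
    min_size_fraction: float = MIN_SIZE_FRACTION,
) -> FrameMeasures:
    """Segment the embryo in one frame within the egg ROI.

    Never raises for image content: frames with no qualifying foreground
    component return ``valid=False`` with NaN measures.  When several
    components tie for largest size, the one nearest the ROI centre wins.
    ``scale`` (um/px) fills ``area_um2`` when given.
    """
    frame = np.asarray(frame)
    roi.validate_bounds(frame.shape)
    top, left, h, w = roi.bbox()
    crop = frame[top : top + h, left : left + w].astype(np.float32)
    roi_mask_full = roi.mask(frame.shape)
    roi_mask = roi_mask_full[top : top + h, left : left + w]

    if not np.isfinite(crop[roi_mask]).any():
        return FrameMeasures.invalid()
    filtered = ndimage.median_filter(crop, size=3)
    vals = filtered[roi_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0 or float(vals.max() - vals.min()) <= 1e-9:
        return FrameMeasures.invalid()
    thr = threshold_otsu(vals)
    binary = (filtered > thr) & roi_mask
    binary = ndimage.binary_opening(binary, structure=disk(1))
    labels, n = ndimage.label(binary)
    if n == 0:
        return FrameMeasures.invalid()
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    floor = min_size_fraction * roi.area
    if sizes.max() < floor:
        return FrameMeasures.invalid()
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:  # tie-break: nearest ROI centre
        roi_center_local = (roi.center[0] - top, roi.center[1] - left)
        centroids = ndimage.center_of_mass(binary, labels, best)
        d = [np.hypot(c[0] - roi_center_local[0], c[1] - roi_center_local[1])
             for c in centroids]
        label = int(best[int(np.argmin(d))])
    else:
        label = int(best[0])
    comp = labels == label

    area, perimeter = _contour_area_perimeter(comp)
    props = measure.regionprops(comp.astype(np.uint8))[0]
    centroid = (props.centroid[0] + top, props.centroid[1] + left)
    minr, minc, maxr, maxc = props.bbox
    bbox = (minr + top, minc + left, maxr - minr, maxc - minc)

    # boundary-touch: component reaches the rim of the ROI ellipse
    eroded = ndimage.binary_erosion(roi_mask, iterations=2, border_value=0)
    touches = bool(np.any(comp & ~eroded))

    return FrameMeasures(
        area=area,
        centroid=centroid,
        perimeter=perimeter,
        bbox=bbox,
        solidity=float(props.solidity),
        valid=True,
        boundary_touch=touches,
        area_um2=area * scale**2 if scale else float("nan"),
    )


def segment_sequence(
    sequence: ImageSequence, roi: EggROI, scale: float | None = None
) -> list[FrameMeasures]:
    """Segment every frame of a sequence (soft-failing per frame)."""
    return [segment_embryo(f, roi, scale=scale) for f in sequence.frames]


def export_roi_overlays(
    sequences: Mapping[str, ImageSequence],
    rois: Mapping[str, EggROI],
    out_dir: str | Path,
) -> list[Path]:
    """Write one PNG per embryo: first frame, ROI ellipse, embryo contour.

    Non-interactive stand-in for a visual ROI check; embryos whose first
    frame fails segmentation get the ROI only and are logged.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for eid, seq in sequences.items():
        roi = rois[eid]
        fig, ax = plt.subplots(figsize=(4, 4), dpi=100)
        ax.imshow(seq.frames[0], cmap="gray")
        tt = np.linspace(0, 2 * np.pi, 200)
        th = np.deg2rad(roi.angle_deg)
        a, b = roi.semi_axes
        r = roi.center[0] + a * np.cos(tt) * np.cos(th) - b * np.sin(tt) * np.sin(th)
        c = roi.center[1] + a * np.cos(tt) * np.sin(th) + b * np.sin(tt) * np.cos(th)
        ax.plot(c, r, "y-", lw=1)
        fm = segment_embryo(seq.frames[0], roi)
        if fm.valid:
            mask = _embryo_mask(seq.frames[0], roi)
            for contour in measure.find_contours(np.pad(mask.astype(float), 1), 0.5):
                ax.plot(contour[:, 1] - 1, contour[:, 0] - 1, "r-", lw=0.8)
        else:
            logger.warning("embryo %s: no valid contour in first frame", eid)
        ax.set_axis_off()
        path = out_dir / f"{eid}.png"
        fig.savefig(path, bbox_inches="tight", pad_inches=0)
        plt.close(fig)
        written.append(path)
    return written


def _embryo_mask(frame: np.ndarray, roi: EggROI) -> np.ndarray:
    """Full-frame binary mask of the segmented embryo (empty if invalid)."""
    top, left, h, w = roi.bbox()
    crop = frame[top : top + h, left : left + w].astype(np.float32)
    roi_mask = roi.mask(frame.shape)[top : top + h, left : left + w]
    filtered = ndimage.median_filter(crop, size=3)
    vals = filtered[roi_mask]
    out = np.zeros(frame.shape, dtype=bool)
    if vals.size == 0 or float(vals.max() - vals.min()) <= 1e-9:
        return out
    binary = (filtered > threshold_otsu(vals)) & roi_mask
    binary = ndimage.binary_opening(binary, structure=disk(1))
    labels, n = ndimage.label(binary)
    if n == 0:
        return out
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    out[top : top + h, left : left + w] = labels == (1 + int(np.argmax(sizes)))
    return out
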