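"""Fluorescence and area quantitation formulas for heart imaging.

Exact pixel-count arithmetic on hand-drawn ROIs and binary masks: maximum
intensity projection, background-corrected area-normalized fluorescence with
fold increase over controls, fractional area change (a 2-D contractility
index), percent labeled-area coverage, and ventricular area normalized to a
control group.  ROIs may be polygons (a pixel belongs to the ROI iff its
center lies inside, even–odd rule) or binary masks.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

__all__ = [
    "RegionOfInterest",
    "IntensityMeasurement",
    "max_intensity_projection",
    "corrected_mean_intensity",
    "fold_increase",
    "fractional_area_change",
    "area_coverage",
    "normalized_ventricular_area",
]


def _points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd rule point-in-polygon test, vectorized over points."""
    x, y = points[:, 0], points[:, 1]
    vx, vy = vertices[:, 0], vertices[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    n = len(vertices)
    j = n - 1
    for i in range(n):
        x1, y1 = vx[j], vy[j]
        x2, y2 = vx[i], vy[i]
        crosses = (y2 > y) != (y1 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x2 + (y - y2) * (x1 - x2) / (y1 - y2)
        inside ^= crosses & (x < np.where(crosses, x_at, np.inf))
        j = i
    return inside


def _segments_intersect(p, q, r, s) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1, d2 = orient(p, q, r), orient(p, q, s)
    d3, d4 = orient(r, s, p), orient(r, s, q)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


@dataclasses.dataclass
class RegionOfInterest:
    """A simple polygon ROI in pixel coordinates (x = column, y = row)."""

    vertices: np.ndarray  # (N, 2) as (x, y)
    label: str = "roi"

    def __post_init__(self) -> None:
        self.vertices = np.atleast_2d(np.asarray(self.vertices, float))
        if len(self.vertices) < 3:
            raise ValueError("a polygon ROI needs at least 3 vertices")
        n = len(self.vertices)
        edges = [(self.vertices[i], self.vertices[(i + 1) % n]) for i in range(n)]
        for i in range(n):
            for j in range(i + 2, n):
                if i == 0 and j == n - 1:
                    continue  # first and last edges share a vertex
                if _segments_intersect(*edges[i], *edges[j]):
                    raise ValueError("self-intersecting polygon is not a valid ROI")
        if self.polygon_area == 0:
            raise ValueError("degenerate polygon: zero area")

    @property
    def polygon_area(self) -> float:
        """Shoelace area in px² (continuous, not pixel-count)."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize: True where the pixel center falls inside the polygon."""
        h, w = shape
        ys = np.arange(h)
        xs = np.arange(w)
        x0 = max(0, int(np.floor(self.vertices[:, 0].min())))
        x1 = min(w, int(np.ceil(self.vertices[:, 0].max())) + 1)
        y0 = max(0, int(np.floor(self.vertices[:, 1].min())))
        y1 = min(h, int(np.ceil(self.vertices[:, 1].max())) + 1)
        out = np.zeros((h, w), dtype=bool)
        if x0 >= x1 or y0 >= y1:
            return out
        xx, yy = np.meshgrid(xs[x0:x1], ys[y0:y1])
        pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        out[y0:y1, x0:x1] = _points_in_polygon(pts, self.vertices).reshape(yy.shape)
        return out

    def area_px(self, shape: tuple[int, int]) -> int:
        return int(self.mask(shape).sum())

    def to_dict(self) -> dict:
        return {"vertices": self.vertices.tolist(), "label": self.label}

    @classmethod
    def from_dict(cls, d: dict) -> "RegionOfInterest":
        return cls(vertices=np.asarray(d["vertices"], float), label=d.get("label", "roi"))


@dataclasses.dataclass(frozen=True)
class IntensityMeasurement:
    """Background-corrected, area-normalized ROI fluorescence."""

    roi_integrated: float  # total intensity inside the ROI
    roi_area: float  # px²
    background_mean: float  # intensity per pixel
    corrected_per_area: float  # (integrated − bg·area) / area

    @property
    def roi_mean(self) -> float:
        return self.roi_integrated / self.roi_area


def _as_mask(roi, shape) -> np.ndarray:
    if isinstance(roi, RegionOfInterest):
        return roi.mask(shape)
    m = np.asarray(roi, dtype=bool)
    if m.shape != tuple(shape):
        raise ValueError("mask shape does not match the image")
    return m


def max_intensity_projection(stack) -> np.ndarray:
    """Pixelwise maximum across the planes of a z- or time-stack."""
    frames = stack.frames if hasattr(stack, "frames") else np.asarray(stack, float)
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        return frames.copy()
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("expected a non-empty (n_planes, h, w) stack")
    return frames.max(axis=0)


def corrected_mean_intensity(
    image: np.ndarray, roi, background_rois
) -> IntensityMeasurement:
    """Mean ROI fluorescence above background, per unit ROI area.

    The background level is the mean pixel intensity pooled over all
    background ROIs, which must be disjoint from the ROI; the corrected
    value is ``(∑ I_roi − background_mean × area_roi) / area_roi``.
    Negative corrected values are kept (and warned about), not clipped.
    """
    image = np.asarray(image, float)
    roi_mask = _as_mask(roi, image.shape)
    if not roi_mask.any():
        raise ValueError("ROI covers no pixels")
    if not background_rois:
        raise ValueError("at least one background ROI is required")
    bg_mask = np.zeros(image.shape, dtype=bool)
    for bg in background_rois:
        m = _as_mask(bg, image.shape)
        if (m & roi_mask).any():
            raise ValueError("background ROI overlaps the measurement ROI")
        bg_mask |= m
    if not bg_mask.any():
        raise ValueError("background ROIs cover no pixels")
    area = float(roi_mask.sum())
    integrated = float(image[roi_mask].sum())
    bg_mean = float(image[bg_mask].mean())
    corrected = (integrated - bg_mean * area) / area
    if corrected < 0:
        warnings.warn("corrected fluorescence is negative (ROI dimmer than background)",
                      stacklevel=2)
    return IntensityMeasurement(
        roi_integrated=integrated, roi_area=area,
        background_mean=bg_mean, corrected_per_area=corrected,
    )


def fold_increase(measurement: IntensityMeasurement, control_measurements) -> float:
    """Corrected ROI fluorescence divided by the mean of the control pool."""
    if not control_measurements:
        raise ValueError("control pool is empty")
    ctrl = float(np.mean([m.corrected_per_area for m in control_measurements]))
    if ctrl <= 0:
        raise ValueError("mean control corrected fluorescence must be > 0")
    return measurement.corrected_per_area / ctrl


def fractional_area_change(end_diastolic_area: float, end_systolic_area: float) -> float:
    """FAC = (EDA − ESA) / EDA × 100 (%); negative values warn."""
    if not end_diastolic_area > 0:
        raise ValueError("end-diastolic area must be > 0")
    fac = (end_diastolic_area - end_systolic_area) / end_diastolic_area * 100.0
    if fac < 0:
        warnings.warn("negative fractional area change (ESA exceeds EDA)", stacklevel=2)
    return fac


def area_coverage(labeled_mask, region_mask) -> float:
    """Percent of the region's area covered by the labeled mask."""
    region = np.asarray(region_mask, bool)
    labeled = np.asarray(labeled_mask, bool)
    if labeled.shape != region.shape:
        raise ValueError("labeled and region masks must share a shape")
    region_area = int(region.sum())
    if region_area == 0:
        raise ValueError("empty region mask")
    return int((labeled & region).sum()) / region_area * 100.0


def normalized_ventricular_area(ventricle, control_areas) -> float:
    """Ventricular area divided by the mean control (e.g. pre-injury) area.

    ``ventricle`` may be a binary mask (area = pixel count) or a scalar area.
    """
    if np.ndim(ventricle) == 0:
        area = float(ventricle)
    else:
        area = float(np.asarray(ventricle, bool).sum())
    controls = np.asarray(control_areas, float)
    if controls.size == 0:
        raise ValueError("control area list is empty")
    mean_ctrl = float(controls.mean())
    if mean_ctrl <= 0:
        raise ValueError("mean control area must be > 0")
    return area / mean_ctrl
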