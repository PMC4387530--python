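"""Cell segmentation by iterative seeded region extraction with halo stripping.

Three phases: (1) pre-processing — the red and green channels from the start
and end of the recording are summed, min-max normalized, Gaussian-blurred,
globally masked and locally-mean suppressed; (2) ROI extraction — the
brightest remaining pixel seeds a region grown down to a fraction of the
seed's own intensity (an adaptive threshold) within a maximum radius; a
second, lower-threshold region forms a surrounding "halo" that is zeroed to
separate neighbouring cells; (3) review — a programmatic accept/reject step
standing in for interactive checking.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclasses.dataclass
class SegmentationParams:
    blur_sigma_px: float = 2.0
    mask_threshold: float = 0.08          # fraction of the normalized range
    localmean_window_px: int = 31
    localmean_fraction: float = 0.8       # zero pixels below this x local mean
    roi_threshold_fraction: float = 0.5   # region level relative to seed
    halo_threshold_fraction: float = 0.3
    max_radius_px: float = 30.0
    min_size_px: int = 50
    max_size_px: int = 2000
    max_roi_count: int = 500

    def validate(self) -> None:
        if not (0 < self.halo_threshold_fraction
                < self.roi_threshold_fraction <= 1):
            raise ValueError(
                "need 0 < halo_threshold_fraction < roi_threshold_fraction <= 1")
        if self.min_size_px >= self.max_size_px:
            raise ValueError("min_size_px must be < max_size_px")
        if self.max_radius_px <= 0:
            raise ValueError("max_radius_px must be > 0")


@dataclasses.dataclass
class ROI:
    id: int
    seed_px: tuple[int, int]        # (x, y)
    pixel_count: int
    centroid_px: tuple[float, float]


@dataclasses.dataclass
class ROIMap:
    labels: np.ndarray              # int32 (H, W), 0 = background
    rois: list[ROI]

    @property
    def ids(self) -> list[int]:
        return [r.id for r in self.rois]

    def __len__(self) -> int:
        return len(self.rois)

    def mask(self, roi_id: int) -> np.ndarray:
        return self.labels == roi_id


def combine_channels(red_frames: np.ndarray,
                     green_frames: np.ndarray) -> np.ndarray:
    """Sum the selected red and green frames and min-max normalize.

    A constant sum (degenerate normalization) maps to all zeros.
    """
    red_frames = np.asarray(red_frames, dtype=float)
    green_frames = np.asarray(green_frames, dtype=float)
    if red_frames.ndim == 2:
        red_frames = red_frames[None]
    if green_frames.ndim == 2:
        green_frames = green_frames[None]
    if red_frames.size == 0 or green_frames.size == 0:
        raise ValueError("empty frame selection")
    if red_frames.shape[-2:] != green_frames.shape[-2:]:
        raise ValueError("red and green frame shapes differ")
    combined = red_frames.sum(axis=0) + green_frames.sum(axis=0)
    lo, hi = float(combined.min()), float(combined.max())
    if hi == lo:
        return np.zeros_like(combined)
    return (combined - lo) / (hi - lo)


def preprocess(combined: np.ndarray,
               params: SegmentationParams | None = None) -> np.ndarray:
    """Blur, global mask, then local-mean suppression of cell borders."""
    p = params or SegmentationParams()
    p.validate()
    img = np.asarray(combined, dtype=float)
    if (p.localmean_window_px > min(img.shape)):
        raise ValueError("local-mean window larger than image")
    out = ndimage.gaussian_filter(img, p.blur_sigma_px)
    out[out < p.mask_threshold] = 0.0
    local_mean = ndimage.uniform_filter(out, size=p.localmean_window_px)
    out[out < p.localmean_fraction * local_mean] = 0.0
    return out


def _seed_region(sub: np.ndarray, seed_local: tuple[int, int],
                 level: float, dist2_ok: np.ndarray) -> np.ndarray:
    cand = (sub >= level) & dist2_ok
    lab, _ = ndimage.label(cand, structure=_EIGHT)
    return lab == lab[seed_local]


def extract_rois(prepared: np.ndarray,
                 params: SegmentationParams | None = None) -> ROIMap:
    """Iteratively extract ROIs from the brightest remaining pixel.

    Each iteration: grow the 8-connected region above
    ``roi_threshold_fraction`` x the seed intensity within ``max_radius_px``
    (the ROI), grow the lower-threshold region (the halo), zero both, and
    accept the ROI if its size lies inside the configured bounds.  Stops at
    ``max_roi_count`` or when the residual maximum falls below the global
    mask threshold.  Ties for the maximum break to the lowest (row, column).
    """
    p = params or SegmentationParams()
    p.validate()
    working = np.asarray(prepared, dtype=float).copy()
    h, w = working.shape
    labels = np.zeros((h, w), dtype=np.int32)
    rois: list[ROI] = []
    r = int(np.ceil(p.max_radius_px))
    next_id = 1
    while len(rois) < p.max_roi_count:
        flat = int(np.argmax(working))       # first maximum in C order
        sy, sx = divmod(flat, w)
        seed_val = working[sy, sx]
        if seed_val < p.mask_threshold or seed_val <= 0:
            break
        y0, y1 = max(0, sy - r), min(h, sy + r + 1)
        x0, x1 = max(0, sx - r), min(w, sx + r + 1)
        sub = working[y0:y1, x0:x1]
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist2_ok = ((yy - sy) ** 2 + (xx - sx) ** 2) <= p.max_radius_px ** 2
        seed_local = (sy - y0, sx - x0)
        roi = _seed_region(sub, seed_local, p.roi_threshold_fraction * seed_val,
                           dist2_ok)
        halo = _seed_region(sub, seed_local,
                            p.halo_threshold_fraction * seed_val,
                            dist2_ok) & ~roi
        sub[roi | halo] = 0.0
        count = int(roi.sum())
        if p.min_size_px <= count <= p.max_size_px:
            cy, cx = ndimage.center_of_mass(roi)
            labels[y0:y1, x0:x1][roi] = next_id
            rois.append(ROI(next_id, (sx, sy), count,
                            (float(cx + x0), float(cy + y0))))
            next_id += 1
    return ROIMap(labels, rois)


def review_rois(roimap: ROIMap, rejections: list[int]) -> ROIMap:
    """Drop the listed ROI ids, leaving all other labels untouched."""
    known = set(roimap.ids)
    for rid in rejections:
        if rid not in known:
            raise KeyError(f"unknown ROI id {rid}")
    drop = set(rejections)
    labels = roimap.labels.copy()
    labels[np.isin(labels, list(drop))] = 0
    return ROIMap(labels, [r for r in roimap.rois if r.id not in drop])


def score_segmentation(roimap: ROIMap, layout, match_radius_px: float = 5.0
                       ) -> tuple[float, float, float]:
    """(recall, precision, centroid RMSE) by greedy one-to-one matching."""
    true_xy = layout.centroids
    det_xy = np.array([roi.centroid_px for roi in roimap.rois], dtype=float)
    if det_xy.size == 0:
        return 0.0, 0.0, float("nan")
    d = np.sqrt(((det_xy[:, None, :] - true_xy[None, :, :]) ** 2).sum(-1))
    pairs = np.argwhere(d <= match_radius_px)
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]])
    used_det: set[int] = set()
    used_true: set[int] = set()
    sq = []
    for di, ti in pairs[order]:
        if di in used_det or ti in used_true:
            continue
        used_det.add(int(di))
        used_true.add(int(ti))
        sq.append(d[di, ti] ** 2)
    matched = len(sq)
    recall = matched / len(true_xy)
    precision = matched / len(det_xy)
    rmse = float(np.sqrt(np.mean(sq))) if sq else float("nan")
    return recall, precision, rmse
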