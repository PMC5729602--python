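"""Box-counting fractal dimension of a binary edge map.

The dimension is estimated as the negative slope of the ordinary
least-squares line of log N(s) against log s, where N(s) is the number of
grid boxes of side s (pixels) containing at least one edge pixel.  For the
endocardial border of a 2-D slice the estimate lies between 1 (smooth
curve) and 2 (plane-filling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .image_io import SliceImage
from .segment import (
    EdgeMap,
    RoiSpec,
    SegmentationParams,
    detect_edges,
    magnify,
    segment_blood_pool,
)

# largest box may not exceed this fraction of the smaller ROI dimension
MAX_BOX_FRACTION = 0.45
# smallest default box side: at least twice the stroke width, so counts
# scale with boundary length rather than stroke area.  Thin rasterized
# curves are 1 px wide; the Sobel response band on a binary mask is ~2 px.
MIN_BOX_THIN = 2
MIN_BOX_EDGEMAP = 4
MIN_SCALES = 4


@dataclass
class BoxCountCurve:
    """Box sizes s (pixels, strictly increasing) and occupied counts N(s)."""

    sizes: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.sizes.size != self.counts.size:
            raise ValidationError("sizes and counts must have equal length")
        if self.sizes.size < MIN_SCALES:
            raise ValidationError(f"need >= {MIN_SCALES} box sizes")
        if np.any(self.sizes < 2) or np.any(np.diff(self.sizes) <= 0):
            raise ValidationError("sizes must be strictly increasing and >= 2")
        if np.any(self.counts <= 0):
            raise ValidationError("occupied-box counts must be positive")
        if np.any(np.diff(self.counts) > 0):
            raise ValidationError("counts must be non-increasing in box size")


@dataclass
class FDResult:
    """Fitted fractal dimension with diagnostics."""

    fd: float
    r_squared: float
    curve: BoxCountCurve
    n_scales: int
    slice_index: int | None = None


def default_box_sizes(shape: tuple[int, int],
                      min_size: int = MIN_BOX_THIN) -> np.ndarray:
    """Powers of two from min_size up to the largest <= 0.45 x min(h, w)."""
    limit = MAX_BOX_FRACTION * min(shape)
    if limit < min_size:
        raise ValidationError(f"image {shape} too small for box counting")
    n = int(np.floor(np.log2(limit)))
    sizes = 2 ** np.arange(int(np.log2(min_size)), n + 1)
    if sizes.size < MIN_SCALES:
        raise ValidationError(
            f"image {shape} yields only {sizes.size} usable box sizes (< {MIN_SCALES})"
        )
    return sizes


def _count_boxes(edges: np.ndarray, s: int) -> int:
    """Occupied boxes of side s, grid anchored at the array origin.

    Partial boxes at the right/bottom margins count (ceil semantics).
    """
    h, w = edges.shape
    ph = (-h) % s
    pw = (-w) % s
    if ph or pw:
        edges = np.pad(edges, ((0, ph), (0, pw)))
    nh, nw = edges.shape[0] // s, edges.shape[1] // s
    blocks = edges.reshape(nh, s, nw, s).any(axis=(1, 3))
    return int(blocks.sum())


def box_count(edges: EdgeMap | np.ndarray, sizes=None) -> BoxCountCurve:
    """Count occupied grid boxes over a range of box sizes.

    For an EdgeMap coming from segmentation the grid is anchored at the
    top-left corner of the ROI bounding box and the default size range is
    derived from the ROI dimensions; for a bare array the full image is
    used.  A single grid per size is used (no offset averaging) so results
    are exactly reproducible.  The default minimum box size is 4 px for
    segmentation-derived edge maps (the Sobel band is ~2 px wide) and
    2 px for bare thin-curve images.
    """
    min_size = MIN_BOX_THIN
    if isinstance(edges, EdgeMap):
        arr = edges.edges
        min_size = MIN_BOX_EDGEMAP
        if edges.source is not None:
            rr, cc = np.nonzero(edges.source.roi_mask)
            arr = arr[rr.min(): rr.max() + 1, cc.min(): cc.max() + 1]
    else:
        arr = np.asarray(edges, dtype=bool)
    if not arr.any():
        raise ValidationError("edge map is empty")
    if sizes is None:
        sizes = default_box_sizes(arr.shape, min_size=min_size)
    sizes = np.asarray(sizes, dtype=int)
    counts = np.array([_count_boxes(arr, int(s)) for s in sizes])
    return BoxCountCurve(sizes=sizes, counts=counts)


def fit_fd(curve: BoxCountCurve) -> FDResult:
    """FD = negative OLS slope of log N(s) vs log s (natural log)."""
    x = np.log(curve.sizes.astype(float))
    y = np.log(curve.counts.astype(float))
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in log box size")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return FDResult(
        fd=float(-slope),
        r_squared=max(0.0, min(1.0, r2)),
        curve=curve,
        n_scales=int(curve.sizes.size),
    )


def slice_fd(
    slice_: SliceImage,
    roi: RoiSpec | None = None,
    params: SegmentationParams | None = None,
    sizes=None,
) -> FDResult:
    """Full per-slice pipeline: magnify -> segment -> Sobel -> box count -> fit.

    The ROI, when given, is expressed in magnified-pixel coordinates.
    Component errors propagate tagged with the slice index.
    """
    params = params or SegmentationParams()
    try:
        mag = magnify(slice_, params.magnification)
        pool = segment_blood_pool(mag, roi=roi, params=params)
        edges = detect_edges(pool)
        curve = box_count(edges, sizes=sizes)
        result = fit_fd(curve)
    except (ValidationError,) as exc:
        raise ValidationError(f"slice {slice_.slice_index}: {exc}") from exc
    except Exception as exc:
        exc.args = (f"slice {slice_.slice_index}: {exc}",)
        raise
    result.slice_index = slice_.slice_index
    return result
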