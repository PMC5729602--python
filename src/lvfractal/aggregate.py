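"""Stack-level aggregation of per-slice fractal dimensions.

The most apical slice is excluded wholesale from fractal analysis (partial
volume effects).  Global FD is the arithmetic mean of the analyzed slice
FDs.  For regional measures the analyzed stack is split into basal and
apical halves — dropping the middle slice when the count is odd — and the
mean and maximum apical FD are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .fractal import FDResult, slice_fd
from .image_io import StackED
from .segment import RoiSpec, SegmentationParams

MIN_ANALYZED = 3


@dataclass
class SubjectFD:
    """Per-subject fractal summary over the analyzed (base->apex) slices."""

    subject_id: str
    per_slice: list[tuple[int, float]]
    global_fd: float
    mean_apical_fd: float
    max_apical_fd: float
    n_slices_analyzed: int
    excluded_indices: list[int]
    slice_results: list[FDResult] | None = None


def split_halves(per_slice: Sequence) -> tuple[list[int], list[int], int | None]:
    """Split an ordered base->apex list into basal/apical half positions.

    Returns (basal positions, apical positions, excluded middle position or
    None).  Odd-length stacks drop the middle element from both halves.
    """
    n = len(per_slice)
    if n < 2:
        raise ValidationError("regional split needs >= 2 analyzed slices")
    half = n // 2
    if n % 2 == 0:
        return list(range(half)), list(range(half, n)), None
    return list(range(half)), list(range(half + 1, n)), half


def aggregate_fds(
    fds: Sequence[float], indices: Sequence[int] | None = None, subject_id: str = "anonymous",
    excluded_indices: Sequence[int] | None = None,
) -> SubjectFD:
    """Aggregate already-computed per-slice FDs (base->apex order)."""
    fds = [float(f) for f in fds]
    if indices is None:
        indices = list(range(len(fds)))
    if len(fds) < 2:
        raise ValidationError("need >= 2 per-slice FDs to aggregate")
    basal, apical, _mid = split_halves(fds)
    apical_fds = [fds[i] for i in apical]
    return SubjectFD(
        subject_id=subject_id,
        per_slice=list(zip(indices, fds)),
        global_fd=float(np.mean(fds)),
        mean_apical_fd=float(np.mean(apical_fds)),
        max_apical_fd=float(np.max(apical_fds)),
        n_slices_analyzed=len(fds),
        excluded_indices=list(excluded_indices or []),
    )


def analyze_stack(
    stack: StackED,
    roi_set: dict[int, RoiSpec] | None = None,
    params: SegmentationParams | None = None,
) -> SubjectFD:
    """Analyze a stack: drop the most apical slice, FD per remaining slice,
    then aggregate.

    `roi_set` maps slice_index -> RoiSpec (magnified coordinates); slices
    without an entry get the automatic ROI.  Any slice-level failure aborts
    the subject with the offending slice named in the error.
    """
    analyzed = stack.slices[:-1]  # exclude most apical slice
    excluded = [stack.slices[-1].slice_index]
    if len(analyzed) < MIN_ANALYZED:
        raise ValidationError(
            f"need >= {MIN_ANALYZED} analyzed slices, got {len(analyzed)}"
        )
    results: list[FDResult] = []
    for s in analyzed:
        roi = roi_set.get(s.slice_index) if roi_set else None
        results.append(slice_fd(s, roi=roi, params=params))
    fds = [r.fd for r in results]
    out = aggregate_fds(
        fds,
        indices=[s.slice_index for s in analyzed],
        subject_id=stack.subject_id,
        excluded_indices=excluded,
    )
    out.slice_results = results
    return out
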