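"""Turn raw samples into analysis-ready per-segment, per-eye pupil series.

Segmentation uses half-open windows [t_start, t_end) so block boundaries are
never double-counted.  Invalid spans (blinks, tracking dropouts) are linearly
interpolated when short; long gaps flag the segment as degraded and heavily
invalid segments are rejected outright — degraded/rejected segments later
propagate as *missing* indicator values, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import SegmentRejectedError, SeriesTooShortError
from .model import Segment

#: Default maximum interior gap (seconds) that is repaired by interpolation;
#: a typical blink lasts 100-200 ms.
DEFAULT_MAX_GAP_S = 0.2

#: Reject a segment when more than this fraction of its samples is invalid.
DEFAULT_REJECT_INVALID_FRACTION = 0.5

#: Tolerated timestamp jitter, as a fraction of the nominal sample interval.
GRID_JITTER_TOLERANCE = 0.1


@dataclass(frozen=True)
class PupilSeries:
    """A per-eye pupil-diameter series on a regular sample grid.

    ``valid`` marks usable samples; after :func:`repair_gaps` every sample is
    valid (interpolated or original).  ``degraded`` records that a gap longer
    than the repair limit had to be bridged.
    """

    eye: str
    t: np.ndarray
    d: np.ndarray
    valid: np.ndarray
    degraded: bool = False

    @property
    def n(self) -> int:
        return len(self.d)

    @property
    def duration(self) -> float:
        """Span between first and last sample, in seconds."""
        return float(self.t[-1] - self.t[0]) if self.n > 1 else 0.0


def extract_segment_series(samples: pd.DataFrame, segment: Segment,
                           eye: str) -> PupilSeries:
    """Slice one eye's samples for a segment (half-open window).

    ``samples`` may hold several participants; rows are matched on the
    segment's participant id.  Raises :class:`SeriesTooShortError` when the
    span contains no samples.
    """
    if eye not in ("left", "right"):
        raise ValueError(f"eye must be 'left' or 'right', got {eye!r}")
    # frames are participant-sorted, so first/last agreeing with the target
    # participant means the frame is already single-participant
    sub = samples
    pids = samples["participant_id"]
    if len(pids) == 0 or pids.iloc[0] != segment.participant_id \
            or pids.iloc[-1] != segment.participant_id:
        sub = samples[pids == segment.participant_id]
    t = sub["t"].to_numpy()
    i0, i1 = np.searchsorted(t, [segment.t_start, segment.t_end], side="left")
    if i1 <= i0:
        raise SeriesTooShortError(
            f"segment {segment.segment_id}: no samples in "
            f"[{segment.t_start:g}, {segment.t_end:g})",
            segment_id=segment.segment_id)
    return PupilSeries(
        eye=eye,
        t=t[i0:i1].copy(),
        d=sub[f"pupil_{eye}"].to_numpy()[i0:i1].copy(),
        valid=sub[f"valid_{eye}"].to_numpy().astype(bool)[i0:i1].copy())


def _invalid_runs(valid: np.ndarray):
    """(start, stop) index pairs of contiguous invalid runs, stop exclusive."""
    idx = np.nonzero(~valid)[0]
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.r_[idx[0], idx[breaks + 1]]
    stops = np.r_[idx[breaks] + 1, idx[-1] + 1]
    return list(zip(starts.tolist(), stops.tolist()))


def repair_gaps(series: PupilSeries,
                max_gap_s: float = DEFAULT_MAX_GAP_S,
                reject_invalid_fraction: float = DEFAULT_REJECT_INVALID_FRACTION
                ) -> PupilSeries:
    """Trim edge gaps and linearly interpolate interior invalid runs.

    Interior runs not longer than ``max_gap_s`` are repaired by linear
    interpolation between the flanking valid samples (so interpolated values
    never leave their range); longer runs are also bridged but mark the
    series degraded.  A series with more than ``reject_invalid_fraction``
    invalid samples raises :class:`SegmentRejectedError`.  Idempotent on its
    own output.
    """
    valid = series.valid.astype(bool)
    n = len(valid)
    if n == 0:
        raise SegmentRejectedError("empty series", reason="empty")
    frac = 1.0 - valid.mean()
    if frac > reject_invalid_fraction:
        raise SegmentRejectedError(
            f"{frac:.0%} of samples invalid (limit "
            f"{reject_invalid_fraction:.0%})", reason="too_many_invalid")
    if valid.all():
        return series

    idx = np.nonzero(valid)[0]
    lo, hi = idx[0], idx[-1] + 1          # trim leading/trailing invalid
    t = series.t[lo:hi]
    d = series.d[lo:hi].astype(float).copy()
    v = valid[lo:hi]

    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    if len(t) > 2:
        jitter = np.abs(np.diff(t) - dt)
        if np.any(jitter > GRID_JITTER_TOLERANCE * dt):
            raise SegmentRejectedError(
                "irregular sample grid beyond jitter tolerance",
                reason="irregular_grid")

    degraded = series.degraded
    for start, stop in _invalid_runs(v):
        gap_s = (stop - start) * dt
        left, right = d[start - 1], d[stop]   # interior: flanks exist
        w = np.arange(1, stop - start + 1) / (stop - start + 1)
        d[start:stop] = left + w * (right - left)
        if gap_s > max_gap_s:
            degraded = True
    return PupilSeries(eye=series.eye, t=t, d=d,
                       valid=np.ones(len(d), dtype=bool), degraded=degraded)


def prepare_segment(samples: pd.DataFrame, segment: Segment, eye: str,
                    max_gap_s: float = DEFAULT_MAX_GAP_S,
                    reject_invalid_fraction: float = DEFAULT_REJECT_INVALID_FRACTION
                    ) -> PupilSeries:
    """Extract and repair one eye's series for a segment in one step."""
    series = extract_segment_series(samples, segment, eye)
    try:
        return repair_gaps(series, max_gap_s=max_gap_s,
                           reject_invalid_fraction=reject_invalid_fraction)
    except SegmentRejectedError as err:
        raise SegmentRejectedError(
            f"segment {segment.segment_id} ({eye}): {err}",
            segment_id=segment.segment_id, reason=err.reason) from None
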