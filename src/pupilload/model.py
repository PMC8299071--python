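"""Shared domain types: condition labels, segments, and the session design.

A recording session consists of a fixation task, three test blocks of 20
items spanning six difficulty levels (a–f, two neighbouring levels per
block), and a closing fixation task.  Segments tie contiguous sample spans
to these condition labels; the :class:`StudyDesign` describes the session
layout declaratively so the synthetic generator and the analysis side agree
on timing (e.g. which parts of a fixation task show the cross rather than
the announcement square).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

#: All condition labels, in session order.
LABELS = ("fix1", "a", "b", "c", "d", "e", "f", "fix2")

#: Difficulty levels of the performance test, easiest first.
LEVELS = ("a", "b", "c", "d", "e", "f")

#: Labels of the two fixation tasks.
FIXATION_LABELS = ("fix1", "fix2")

ITEM_TYPES = ("possible", "impossible", "none")

#: Canonical column order of a samples table.
SAMPLE_COLUMNS = ("participant_id", "t", "pupil_left", "pupil_right",
                  "gaze_x", "gaze_y", "valid_left", "valid_right")

#: Canonical column order of a segments table.
SEGMENT_COLUMNS = ("participant_id", "segment_id", "label", "item_type",
                   "response_correct", "t_start", "t_end")

#: Maximum item presentation time in seconds (response window).
MAX_ITEM_DURATION_S = 60.0


class PupilSample(NamedTuple):
    """One time-stamped binocular measurement.

    Bulk data flows through pandas frames with :data:`SAMPLE_COLUMNS`;
    this tuple is the per-row view used when constructing small inputs.
    """

    participant_id: str
    t: float
    pupil_left: float
    pupil_right: float
    gaze_x: float
    gaze_y: float
    valid_left: bool
    valid_right: bool


@dataclass(frozen=True)
class Segment:
    """A labelled contiguous sample span; the unit on which the IPA is computed.

    ``item_type`` is ``"none"`` exactly for the fixation tasks;
    ``response_correct`` is 0/1 for answered items and NaN when missing.
    """

    participant_id: str
    segment_id: str
    label: str
    item_type: str
    response_correct: float
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown segment label {self.label!r}")
        if self.item_type not in ITEM_TYPES:
            raise ValueError(f"unknown item_type {self.item_type!r}")
        if not (self.t_start < self.t_end):
            raise ValueError(
                f"segment {self.segment_id}: t_start must be < t_end "
                f"({self.t_start} >= {self.t_end})")
        is_fix = self.label in FIXATION_LABELS
        if is_fix != (self.item_type == "none"):
            raise ValueError(
                f"segment {self.segment_id}: item_type 'none' is required for "
                f"fixation tasks and forbidden for items (label={self.label!r}, "
                f"item_type={self.item_type!r})")
        if not is_fix and self.duration > MAX_ITEM_DURATION_S + 1e-9:
            raise ValueError(
                f"segment {self.segment_id}: item duration {self.duration:.3f}s "
                f"exceeds the {MAX_ITEM_DURATION_S:.0f}s response window")
        if not (math.isfinite(self.t_start) and math.isfinite(self.t_end)):
            raise ValueError(f"segment {self.segment_id}: non-finite span")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class StudyDesign:
    """Declarative session structure shared by the generator and the aggregator.

    Defaults encode the study layout: nine 3 s announcement squares each
    followed by a 3 s fixation cross on a 3x3 grid, three blocks of 20 items
    (five possible and five impossible per level, two levels per block),
    a 1 s pre-item cross, and a 300 Hz recording rate.
    """

    fixation_cross_count: int = 9
    fixation_cross_duration: float = 3.0
    fixation_square_duration: float = 3.0
    blocks: int = 3
    items_per_block: int = 20
    levels: tuple[str, ...] = LEVELS
    pre_item_cross_duration: float = 1.0
    sampling_rate: float = 300.0
    screen_width_px: float = 1920.0
    screen_height_px: float = 1080.0
    fixation_grid_spacing_px: float = 300.0

    def __post_init__(self) -> None:
        for name in ("fixation_cross_count", "blocks", "items_per_block"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError("levels must be distinct")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.items_per_block % (2) != 0:
            raise ValueError("items_per_block must split evenly over two levels")

    # -- layout arithmetic ------------------------------------------------

    @property
    def n_items(self) -> int:
        return self.blocks * self.items_per_block

    @property
    def items_per_level(self) -> int:
        return self.n_items // len(self.levels)

    @property
    def fixation_task_duration(self) -> float:
        """Total span of one fixation task (squares and crosses)."""
        return self.fixation_cross_count * (
            self.fixation_square_duration + self.fixation_cross_duration)

    def block_levels(self, block: int) -> tuple[str, str]:
        """The two neighbouring difficulty levels shown in ``block`` (0-based)."""
        return self.levels[2 * block], self.levels[2 * block + 1]

    # -- fixation-task geometry and timing --------------------------------

    def fixation_targets(self) -> np.ndarray:
        """Cross positions, a 3x3 grid centred on the screen, row-major order.

        Returns an array of shape (fixation_cross_count, 2) in pixels.
        """
        cx = self.screen_width_px / 2.0
        cy = self.screen_height_px / 2.0
        s = self.fixation_grid_spacing_px
        side = int(round(math.sqrt(self.fixation_cross_count)))
        offs = (np.arange(side) - (side - 1) / 2.0) * s
        grid = [(cx + ox, cy + oy) for oy in offs for ox in offs]
        return np.asarray(grid[: self.fixation_cross_count], dtype=float)

    def cross_windows(self, t_start: float = 0.0):
        """Time windows of the cross presentations within one fixation task.

        Each cross is announced by a square at the same position; only the
        cross phase is used for precision scoring.  Yields
        ``(t0, t1, target_xy)`` with a half-open window ``[t0, t1)``.
        """
        targets = self.fixation_targets()
        step = self.fixation_square_duration + self.fixation_cross_duration
        out = []
        for i in range(self.fixation_cross_count):
            t0 = t_start + i * step + self.fixation_square_duration
            out.append((t0, t0 + self.fixation_cross_duration, targets[i]))
        return out
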