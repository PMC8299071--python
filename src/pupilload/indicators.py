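"""Indicator channels, within-participant z-standardization, aggregation,
and the auxiliary accuracy and fixation-precision measures.

Four channels are derived from the per-eye IPA values of each segment:
left, right, their mean, and the absolute between-eye difference.  The diff
channel carries the "reduced autonomic variability under load" hypothesis —
the smaller the between-eye difference, the higher the expected effort.
Z-standardization within participant (across all segments, both fixation
tasks and all items, per channel) removes inter-individual range
differences before condition comparisons.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import numpy as np
import pandas as pd

from .model import LEVELS, Segment, StudyDesign

logger = logging.getLogger(__name__)

CHANNELS = ("left", "right", "mean", "diff")


def channels_from_eyes(ipa_left: float, ipa_right: float) -> dict:
    """The four indicator channels of one segment.

    If either eye is missing (NaN) the whole set is missing: a one-eyed
    mean would silently change the measure's meaning.
    """
    if ipa_left is None or ipa_right is None or \
            not (math.isfinite(ipa_left) and math.isfinite(ipa_right)):
        return {c: float("nan") for c in CHANNELS}
    return {"left": ipa_left, "right": ipa_right,
            "mean": (ipa_left + ipa_right) / 2.0,
            "diff": abs(ipa_left - ipa_right)}


def segment_channels(segment_ipa: pd.DataFrame) -> pd.DataFrame:
    """Long-format raw indicator records from a per-segment IPA table.

    Input columns: participant_id, label, segment_id, ipa_left, ipa_right.
    Output: one row per segment x channel with ``standardized=False``;
    segments with either eye missing yield NaN on all four channels.
    """
    df = segment_ipa
    left = df["ipa_left"].to_numpy(dtype=float)
    right = df["ipa_right"].to_numpy(dtype=float)
    ok = np.isfinite(left) & np.isfinite(right)
    values = {"left": np.where(ok, left, np.nan),
              "right": np.where(ok, right, np.nan),
              "mean": np.where(ok, (left + right) / 2.0, np.nan),
              "diff": np.where(ok, np.abs(left - right), np.nan)}
    frames = []
    for channel in CHANNELS:
        frames.append(pd.DataFrame({
            "participant_id": df["participant_id"],
            "label": df["label"],
            "segment_id": df["segment_id"],
            "channel": channel,
            "standardized": False,
            "value": values[channel]}))
    return pd.concat(frames, ignore_index=True)


def z_standardize(values) -> np.ndarray:
    """(x - mean) / sd with the n-1 denominator, NaNs passed through.

    Returns all-NaN when fewer than two finite values exist or the spread
    is zero ("constant indicator"): a constant channel carries no
    within-participant information and must become missing, not zero.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        return np.full_like(x, np.nan)
    m = x[finite].mean()
    s = x[finite].std(ddof=1)
    if s == 0:
        logger.info("z_standardize: constant indicator, values set missing")
        return np.full_like(x, np.nan)
    out = np.full_like(x, np.nan)
    out[finite] = (x[finite] - m) / s
    return out


def z_standardize_records(records: pd.DataFrame,
                          diff_mode: str = "z_of_diff") -> pd.DataFrame:
    """Standardized copies of raw indicator records, per participant x channel.

    The reference distribution is all of a participant's segments (both
    fixation tasks and all items).  ``diff_mode`` selects the reading of a
    "standardized difference value": ``"z_of_diff"`` standardizes the raw
    |L - R| series (default); ``"diff_of_z"`` takes |z(L) - z(R)| per
    segment instead.
    """
    if diff_mode not in ("z_of_diff", "diff_of_z"):
        raise ValueError("diff_mode must be 'z_of_diff' or 'diff_of_z'")
    raw = records[~records["standardized"]]
    out = raw.copy()
    out["standardized"] = True
    out["value"] = raw.groupby(["participant_id", "channel"], sort=False,
                               group_keys=False)["value"].transform(
                                   lambda s: z_standardize(s.to_numpy()))
    if diff_mode == "diff_of_z":
        z = out[out["channel"].isin(["left", "right"])]
        wide = z.pivot_table(index=["participant_id", "label", "segment_id"],
                             columns="channel", values="value",
                             aggfunc="first", dropna=False)
        dz = np.abs(wide["left"] - wide["right"])
        mask = out["channel"] == "diff"
        key = pd.MultiIndex.from_frame(
            out.loc[mask, ["participant_id", "label", "segment_id"]])
        out.loc[mask, "value"] = dz.reindex(key).to_numpy()
    return out


def aggregate_by_label(records: pd.DataFrame) -> pd.DataFrame:
    """Per participant x label x channel x standardized mean over segments.

    Missing segment values are excluded (never zero-filled); labels with no
    usable segment produce no row.
    """
    df = records.copy()
    grouped = df.groupby(
        ["participant_id", "label", "channel", "standardized"], sort=False)
    agg = grouped["value"].agg(value="mean",
                               n_segments=lambda s: int(s.notna().sum()))
    agg = agg.reset_index()
    agg = agg[agg["n_segments"] >= 1].reset_index(drop=True)
    return agg


def accuracy_score(segments: Iterable[Segment], level: str) -> float:
    """Proportion correct over the *possible* items of one level.

    Impossible items never enter numerator or denominator; an unanswered
    possible item (missing response, i.e. timeout) scores 0.  Returns NaN
    when the level has no possible item.
    """
    hits = 0
    total = 0
    for seg in segments:
        if seg.label != level or seg.item_type != "possible":
            continue
        total += 1
        if seg.response_correct == 1:
            hits += 1
    return hits / total if total else float("nan")


def accuracy_table(segments: pd.DataFrame) -> pd.DataFrame:
    """Per participant x level accuracy over possible items."""
    poss = segments[segments["item_type"] == "possible"]
    rows = []
    for (pid, level), grp in poss.groupby(["participant_id", "label"],
                                          sort=False):
        if level not in LEVELS:
            continue
        correct = (grp["response_correct"] == 1).sum()
        rows.append({"participant_id": pid, "level": level,
                     "accuracy": correct / len(grp), "n_items": len(grp)})
    return pd.DataFrame(rows, columns=["participant_id", "level",
                                       "accuracy", "n_items"])


def fixation_precision(residual_x, residual_y) -> tuple[float, float]:
    """Gaze precision: per-coordinate sd of residuals around the targets.

    Residuals are gaze positions minus the active cross's target position,
    pooled over all cross presentations of one fixation task; n-1
    denominator.  Returns (NaN, NaN) below two samples.
    """
    rx = np.asarray(residual_x, dtype=float)
    ry = np.asarray(residual_y, dtype=float)
    ok = np.isfinite(rx) & np.isfinite(ry)
    if ok.sum() < 2:
        return (float("nan"), float("nan"))
    return (float(rx[ok].std(ddof=1)), float(ry[ok].std(ddof=1)))


def fixation_residuals(samples: pd.DataFrame, segment: Segment,
                       design: StudyDesign) -> tuple[np.ndarray, np.ndarray]:
    """Residual gaze positions during the cross phases of one fixation task.

    Only samples inside a cross window with at least one valid eye are
    used; each sample's residual is taken against the target of the cross
    active at that time (design timing: 3 s announcement square, then 3 s
    cross, nine positions).
    """
    sub = samples
    pids = samples["participant_id"]
    if len(pids) == 0 or pids.iloc[0] != segment.participant_id \
            or pids.iloc[-1] != segment.participant_id:
        sub = samples[pids == segment.participant_id]
    t = sub["t"].to_numpy()
    gx = sub["gaze_x"].to_numpy(dtype=float)
    gy = sub["gaze_y"].to_numpy(dtype=float)
    usable = (sub["valid_left"].to_numpy().astype(bool)
              | sub["valid_right"].to_numpy().astype(bool))
    res_x, res_y = [], []
    for t0, t1, target in design.cross_windows(segment.t_start):
        i0, i1 = np.searchsorted(t, [t0, t1], side="left")
        sel = slice(i0, i1)
        ok = usable[sel] & np.isfinite(gx[sel]) & np.isfinite(gy[sel])
        res_x.append(gx[sel][ok] - target[0])
        res_y.append(gy[sel][ok] - target[1])
    return (np.concatenate(res_x) if res_x else np.array([]),
            np.concatenate(res_y) if res_y else np.array([]))
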