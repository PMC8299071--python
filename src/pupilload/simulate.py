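"""Synthetic binocular pupillometry sessions and cohorts with full ground truth.

The generator emulates the signal structure the analysis assumes: a slowly
drifting baseline (fatigue proxy), low-frequency hippus, workload-dependent
high-frequency transient dilation events (smooth Gaussian bumps so they are
genuine pupil-like transients, not step artifacts), additive measurement
noise, blink gaps, and gaze scatter around the fixation targets.  A coupling
parameter rho splits both the transient events and the noise into a
component shared by the two eyes and eye-specific components — at rho = 1
with zero independent noise both eyes are sample-for-sample identical, so
the between-eye difference channel vanishes.

Sessions follow the study layout (fixation task, three blocks of twenty
items over six difficulty levels, fixation task); item correctness is
Bernoulli with per-level probabilities, and everything is reproducible from
one master seed via spawned per-participant seeds.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as pio
from .model import (FIXATION_LABELS, LABELS, LEVELS, SAMPLE_COLUMNS,
                    SEGMENT_COLUMNS, StudyDesign)

__all__ = ["SignalParams", "CohortDesign", "generate_pupil_segment",
           "generate_session", "generate_cohort", "write_cohort",
           "workload_cohort", "null_cohort", "PRESETS",
           "LEVEL_ACCURACY"]

#: Per-level accuracy probabilities used by the presets (test calibration).
LEVEL_ACCURACY = {"a": 0.95, "b": 0.93, "c": 0.86, "d": 0.80,
                  "e": 0.73, "f": 0.43}

#: Median item response times (s), log-normal, truncated at the 60 s window.
ITEM_DURATION_MEDIANS = {"a": 4.0, "b": 5.0, "c": 6.0, "d": 7.0,
                         "e": 8.0, "f": 10.0}

_WORKLOAD_RATES = {"fix1": 1.0, "a": 1.8, "b": 1.8, "c": 1.8, "d": 1.8,
                   "e": 1.8, "f": 1.8, "fix2": 1.0}
_WORKLOAD_COUPLINGS = {"fix1": 0.3, "a": 0.7, "b": 0.7, "c": 0.9, "d": 0.9,
                       "e": 0.9, "f": 0.9, "fix2": 0.3}


@dataclass(frozen=True)
class SignalParams:
    """Parameters of one synthetic binocular pupil signal.

    Amplitudes are in millimetres, rates in Hz.  ``coupling`` is the
    fraction of transient events and of noise variance shared between the
    eyes.
    """

    baseline_mm: float = 3.5
    drift_mm_per_min: float = -0.02
    hippus_amp_mm: float = 0.05
    hippus_freq_hz: float = 0.2
    event_rate_hz: float = 1.0
    event_amp_mm: float = 0.4
    event_width_s: float = 0.033
    coupling: float = 0.5
    noise_sd_mm: float = 0.008
    blink_rate_hz: float = 0.15
    blink_dur_s: float = 0.15

    def __post_init__(self) -> None:
        for name in ("baseline_mm", "hippus_amp_mm", "hippus_freq_hz",
                     "event_rate_hz", "event_amp_mm", "event_width_s",
                     "noise_sd_mm", "blink_rate_hz", "blink_dur_s"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"SignalParams.{name} must be >= 0, got {v}")
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError(
                f"SignalParams.coupling must lie in [0, 1], got {self.coupling}")


def _add_bumps(d: np.ndarray, times: np.ndarray, fs: float, amp: float,
               sigma_s: float) -> None:
    """Add Gaussian dilation bumps centred at ``times`` (in-place)."""
    if amp == 0 or sigma_s == 0:
        return
    n = len(d)
    half = int(math.ceil(4.0 * sigma_s * fs))
    for t0 in times:
        c = int(round(t0 * fs))
        i0, i1 = max(0, c - half), min(n, c + half + 1)
        if i1 <= i0:
            continue
        idx = np.arange(i0, i1)
        d[i0:i1] += amp * np.exp(-0.5 * ((idx / fs - t0) / sigma_s) ** 2)


def generate_pupil_segment(duration: float, sampling_rate: float,
                           params: SignalParams,
                           rng: np.random.Generator,
                           t_offset: float = 0.0) -> dict:
    """One binocular pupil chunk plus its ground truth.

    signal = baseline + drift*t + hippus + shared events + eye-specific
    events + noise, with the shared/specific split governed by
    ``params.coupling``; event times are a Poisson process at
    ``event_rate_hz``; blinks are inserted as invalid runs in both eyes.
    The baseline drift uses absolute session time (``t_offset`` + within-
    chunk time) so fatigue accumulates over a session.

    Returns a dict with keys t, left, right, valid (both eyes share blink
    validity), and per-eye ground-truth event times.
    """
    n = int(round(duration * sampling_rate))
    if n < 1:
        raise ValueError("duration * sampling_rate must be >= 1")
    trel = np.arange(n) / sampling_rate
    t = t_offset + trel
    rho = params.coupling
    lam = params.event_rate_hz

    # Poisson event times: shared stream plus one independent stream per eye
    k_sh = rng.poisson(rho * lam * duration)
    t_sh = np.sort(rng.uniform(0.0, duration, k_sh))
    k_l = rng.poisson((1.0 - rho) * lam * duration)
    t_l = np.sort(rng.uniform(0.0, duration, k_l))
    k_r = rng.poisson((1.0 - rho) * lam * duration)
    t_r = np.sort(rng.uniform(0.0, duration, k_r))

    base = params.baseline_mm + params.drift_mm_per_min / 60.0 * t
    if params.hippus_amp_mm > 0:
        phase = rng.uniform(0.0, 2.0 * math.pi)
        base = base + params.hippus_amp_mm * np.sin(
            2.0 * math.pi * params.hippus_freq_hz * trel + phase)

    left = base.astype(float).copy()
    right = base.astype(float).copy()
    # event_width_s is the total bump width (~ +/- 3 sigma); the Gaussian
    # sigma must stay a few samples so the transient carries energy in the
    # coarsest detail band the IPA inspects
    sigma_s = params.event_width_s / 6.0
    _add_bumps(left, np.r_[t_sh, t_l], sampling_rate, params.event_amp_mm,
               sigma_s)
    _add_bumps(right, np.r_[t_sh, t_r], sampling_rate, params.event_amp_mm,
               sigma_s)

    if params.noise_sd_mm > 0:
        shared = rng.normal(0.0, 1.0, n)
        nl = rng.normal(0.0, 1.0, n)
        nr = rng.normal(0.0, 1.0, n)
        left += params.noise_sd_mm * (math.sqrt(rho) * shared
                                      + math.sqrt(1.0 - rho) * nl)
        right += params.noise_sd_mm * (math.sqrt(rho) * shared
                                       + math.sqrt(1.0 - rho) * nr)

    valid = np.ones(n, dtype=bool)
    if params.blink_rate_hz > 0 and params.blink_dur_s > 0:
        k_b = rng.poisson(params.blink_rate_hz * duration)
        blink_len = max(1, int(round(params.blink_dur_s * sampling_rate)))
        for s in rng.uniform(0.0, duration, k_b):
            i0 = int(s * sampling_rate)
            i1 = min(n, i0 + blink_len)
            valid[i0:i1] = False
            left[i0:i1] = 0.0      # tracker dropout: non-positive diameter
            right[i0:i1] = 0.0

    return {"t": t, "left": left, "right": right, "valid": valid,
            "events_shared": t_offset + t_sh,
            "events_left": t_offset + np.sort(np.r_[t_sh, t_l]),
            "events_right": t_offset + np.sort(np.r_[t_sh, t_r])}


@dataclass(frozen=True)
class CohortDesign:
    """Declarative description of a synthetic cohort.

    Per-label event rates and couplings set the designed workload profile;
    per-participant heterogeneity comes from a baseline offset, a shared
    rate offset (general responsiveness) and a condition-specific rate
    jitter (participant x condition interaction), all Gaussian.  Accuracy
    probabilities apply to the possible items of each level.
    """

    n_participants: int = 30
    base: SignalParams = field(default_factory=SignalParams)
    event_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_WORKLOAD_RATES))
    couplings: Mapping[str, float] = field(
        default_factory=lambda: dict(_WORKLOAD_COUPLINGS))
    accuracy: Mapping[str, float] = field(
        default_factory=lambda: dict(LEVEL_ACCURACY))
    item_duration_median_s: Mapping[str, float] = field(
        default_factory=lambda: dict(ITEM_DURATION_MEDIANS))
    item_duration_sigma: float = 0.4
    participant_rate_sd: float = 0.3
    condition_rate_sd: float = 0.35
    participant_baseline_sd: float = 0.4
    gaze_fixation_sd_px: float = 15.0
    gaze_item_sd_px: float = 80.0
    study: StudyDesign = field(default_factory=StudyDesign)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for label in LABELS:
            if label not in self.event_rates:
                raise ValueError(f"event_rates missing label {label!r}")
            if label not in self.couplings:
                raise ValueError(f"couplings missing label {label!r}")
        for level in self.study.levels:
            p = self.accuracy.get(level)
            if p is None or not (0.0 <= p <= 1.0):
                raise ValueError(
                    f"accuracy[{level!r}] must lie in [0, 1], got {p}")
            if level not in self.item_duration_median_s:
                raise ValueError(f"item_duration_median_s missing {level!r}")

    def label_params(self, label: str, baseline: float, rate: float
                     ) -> SignalParams:
        return dataclasses.replace(self.base, baseline_mm=baseline,
                                   event_rate_hz=rate,
                                   coupling=float(self.couplings[label]))


def workload_cohort(n_participants: int = 30, master_seed: int = 0,
                    **overrides) -> CohortDesign:
    """Preset with a graded demand profile.

    Transient rates step up from the fixation tasks to the test levels
    (identical across levels, and identical in both fixation tasks — no
    fatigue change in the event rate), while between-eye coupling rises
    from the fixation tasks through the one-transformation levels (a, b) to
    the two-transformation levels (c-f), so the difference channel falls
    with demand.  Accuracy probabilities follow the published per-level
    means.
    """
    return CohortDesign(n_participants=n_participants,
                        master_seed=master_seed, **overrides)


def null_cohort(n_participants: int = 30, master_seed: int = 0,
                **overrides) -> CohortDesign:
    """Preset with no condition effects: equal rates and couplings everywhere.

    Item durations are equalised across levels as well — the per-segment
    sampling noise of the difference channel scales with segment length, so
    level-dependent response times would otherwise leak a systematic
    between-condition effect into a nominally null design.
    """
    rates = {label: 1.0 for label in LABELS}
    coup = {label: 0.5 for label in LABELS}
    durations = overrides.pop("item_duration_median_s",
                              {level: 8.0 for level in LEVELS})
    return CohortDesign(n_participants=n_participants,
                        master_seed=master_seed, event_rates=rates,
                        couplings=coup, item_duration_median_s=durations,
                        **overrides)


PRESETS = {"workload": workload_cohort, "null": null_cohort}


def _fixation_gaze(design: StudyDesign, n: int, fs: float, sd: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Per-sample gaze during one fixation task: active target + scatter."""
    targets = design.fixation_targets()
    step = design.fixation_square_duration + design.fixation_cross_duration
    idx = np.minimum((np.arange(n) / fs / step).astype(int),
                     len(targets) - 1)
    return targets[idx] + rng.normal(0.0, sd, (n, 2))


def generate_session(participant_id: str, design: CohortDesign,
                     rng: np.random.Generator) -> tuple[dict, list[dict], dict]:
    """One participant's full session.

    Returns ``(samples, segments, truth)`` where ``samples`` is a dict of
    column arrays, ``segments`` a list of row dicts, and ``truth`` the
    ground-truth record (per-condition rates, per-segment event counts,
    correctness).  Draw order is fixed: participant-level parameters first,
    then chunks in session order.
    """
    study = design.study
    fs = study.sampling_rate
    baseline = float(np.clip(
        design.base.baseline_mm + rng.normal(0.0, design.participant_baseline_sd),
        2.0, 6.0))
    u_p = rng.normal(0.0, design.participant_rate_sd)
    rates = {label: max(float(design.event_rates[label]) + u_p
                        + rng.normal(0.0, design.condition_rate_sd), 0.05)
             for label in LABELS}
    params = {label: design.label_params(label, baseline, rates[label])
              for label in LABELS}

    chunks = []          # (samples dict, gaze array)
    segments: list[dict] = []
    truth_segments: dict[str, dict] = {}
    cursor = 0           # sample index from session start

    def emit(label_for_signal: str, duration: float, gaze_kind: str):
        nonlocal cursor
        t0 = cursor / fs
        chunk = generate_pupil_segment(duration, fs,
                                       params[label_for_signal], rng,
                                       t_offset=t0)
        n = len(chunk["t"])
        if gaze_kind == "fixation":
            gaze = _fixation_gaze(study, n, fs, design.gaze_fixation_sd_px,
                                  rng)
        else:
            centre = np.array([study.screen_width_px / 2.0,
                               study.screen_height_px / 2.0])
            gaze = centre + rng.normal(0.0, design.gaze_item_sd_px, (n, 2))
        chunks.append((chunk, gaze))
        cursor += n
        return chunk, t0, cursor / fs

    # -- opening fixation task -------------------------------------------
    chunk, t0, t1 = emit("fix1", study.fixation_task_duration, "fixation")
    segments.append({"participant_id": participant_id,
                     "segment_id": f"{participant_id}_fix1", "label": "fix1",
                     "item_type": "none", "response_correct": np.nan,
                     "t_start": t0, "t_end": t1})
    truth_segments[f"{participant_id}_fix1"] = {
        "label": "fix1", "n_events_left": len(chunk["events_left"]),
        "n_events_right": len(chunk["events_right"]),
        "n_events_shared": len(chunk["events_shared"]),
        "duration": t1 - t0}

    # -- test blocks -------------------------------------------------------
    per_level = study.items_per_block // 2
    for block in range(study.blocks):
        lv1, lv2 = study.block_levels(block)
        items = [(lv, kind) for lv in (lv1, lv2)
                 for kind in ("possible",) * (per_level // 2)
                 + ("impossible",) * (per_level - per_level // 2)]
        order = rng.permutation(len(items))
        for j, pick in enumerate(order):
            level, kind = items[pick]
            # 1 s pre-item cross: low-demand signal, not part of any segment
            emit("fix1", study.pre_item_cross_duration, "item")
            dur = min(60.0, float(
                design.item_duration_median_s[level]
                * math.exp(design.item_duration_sigma * rng.normal())))
            dur = max(dur, 1.5)
            chunk, t0, t1 = emit(level, dur, "item")
            correct = int(rng.random() < float(design.accuracy[level]))
            sid = f"{participant_id}_b{block + 1}_i{j + 1:02d}"
            segments.append({"participant_id": participant_id,
                             "segment_id": sid, "label": level,
                             "item_type": kind,
                             "response_correct": float(correct),
                             "t_start": t0, "t_end": t1})
            truth_segments[sid] = {
                "label": level, "item_type": kind, "correct": correct,
                "n_events_left": len(chunk["events_left"]),
                "n_events_right": len(chunk["events_right"]),
                "n_events_shared": len(chunk["events_shared"]),
                "duration": t1 - t0}

    # -- closing fixation task --------------------------------------------
    chunk, t0, t1 = emit("fix2", study.fixation_task_duration, "fixation")
    segments.append({"participant_id": participant_id,
                     "segment_id": f"{participant_id}_fix2", "label": "fix2",
                     "item_type": "none", "response_correct": np.nan,
                     "t_start": t0, "t_end": t1})
    truth_segments[f"{participant_id}_fix2"] = {
        "label": "fix2", "n_events_left": len(chunk["events_left"]),
        "n_events_right": len(chunk["events_right"]),
        "n_events_shared": len(chunk["events_shared"]),
        "duration": t1 - t0}

    samples = {
        "t": np.concatenate([c["t"] for c, _ in chunks]),
        "pupil_left": np.concatenate([c["left"] for c, _ in chunks]),
        "pupil_right": np.concatenate([c["right"] for c, _ in chunks]),
        "gaze_x": np.concatenate([g[:, 0] for _, g in chunks]),
        "gaze_y": np.concatenate([g[:, 1] for _, g in chunks]),
        "valid": np.concatenate([c["valid"] for c, _ in chunks]),
    }
    truth = {"participant_id": participant_id, "baseline_mm": baseline,
             "rate_offset": float(u_p), "event_rates_hz": rates,
             "couplings": {label: float(design.couplings[label])
                           for label in LABELS},
             "segments": truth_segments}
    return samples, segments, truth


def generate_cohort(design: CohortDesign, signals: bool = True
                    ) -> tuple[pd.DataFrame | None, pd.DataFrame, dict]:
    """A full cohort: samples frame, segments frame, ground-truth manifest.

    ``signals=False`` skips the pupil/gaze signal synthesis and produces
    only the segment table (with correctness ground truth), which is enough
    for design-level checks and much faster.  Deterministic from
    ``design.master_seed`` via spawned per-participant seed sequences.
    """
    ss = np.random.SeedSequence(design.master_seed)
    children = ss.spawn(design.n_participants)
    sample_frames = []
    segment_rows: list[dict] = []
    manifest = {"master_seed": design.master_seed,
                "n_participants": design.n_participants,
                "sampling_rate": design.study.sampling_rate,
                "event_rates_hz": dict(design.event_rates),
                "couplings": dict(design.couplings),
                "accuracy": dict(design.accuracy),
                "participants": []}
    for i, child in enumerate(children):
        pid = f"p{i + 1:03d}"
        rng = np.random.default_rng(child)
        if signals:
            samples, segments, truth = generate_session(pid, design, rng)
            n = len(samples["t"])
            frame = pd.DataFrame({
                "participant_id": pd.Categorical([pid] * n),
                "t": samples["t"],
                "pupil_left": samples["pupil_left"],
                "pupil_right": samples["pupil_right"],
                "gaze_x": samples["gaze_x"],
                "gaze_y": samples["gaze_y"],
                "valid_left": samples["valid"],
                "valid_right": samples["valid"],
            })
            sample_frames.append(frame)
        else:
            segments, truth = _segments_only_session(pid, design, rng)
        segment_rows.extend(segments)
        manifest["participants"].append(truth)
    segments_df = pd.DataFrame(segment_rows, columns=list(SEGMENT_COLUMNS))
    samples_df = (pd.concat(sample_frames, ignore_index=True)
                  if signals else None)
    return samples_df, segments_df, manifest


def _segments_only_session(participant_id: str, design: CohortDesign,
                           rng: np.random.Generator):
    """Segment table and correctness truth without signal synthesis.

    Mirrors :func:`generate_session`'s layout and correctness draws (the
    signal-level draws are skipped, so per-segment event counts are not
    part of the truth record).
    """
    study = design.study
    fs = study.sampling_rate
    rng.normal(0.0, design.participant_baseline_sd)   # keep draw order close
    rng.normal(0.0, design.participant_rate_sd)
    for _ in LABELS:
        rng.normal(0.0, design.condition_rate_sd)
    segments: list[dict] = []
    truth_segments: dict[str, dict] = {}
    cursor = int(round(study.fixation_task_duration * fs))
    segments.append({"participant_id": participant_id,
                     "segment_id": f"{participant_id}_fix1", "label": "fix1",
                     "item_type": "none", "response_correct": np.nan,
                     "t_start": 0.0, "t_end": cursor / fs})
    per_level = study.items_per_block // 2
    for block in range(study.blocks):
        lv1, lv2 = study.block_levels(block)
        items = [(lv, kind) for lv in (lv1, lv2)
                 for kind in ("possible",) * (per_level // 2)
                 + ("impossible",) * (per_level - per_level // 2)]
        order = rng.permutation(len(items))
        for j, pick in enumerate(order):
            level, kind = items[pick]
            cursor += int(round(study.pre_item_cross_duration * fs))
            dur = min(60.0, float(
                design.item_duration_median_s[level]
                * math.exp(design.item_duration_sigma * rng.normal())))
            dur = max(dur, 1.5)
            n = int(round(dur * fs))
            t0, t1 = cursor / fs, (cursor + n) / fs
            cursor += n
            correct = int(rng.random() < float(design.accuracy[level]))
            sid = f"{participant_id}_b{block + 1}_i{j + 1:02d}"
            segments.append({"participant_id": participant_id,
                             "segment_id": sid, "label": level,
                             "item_type": kind,
                             "response_correct": float(correct),
                             "t_start": t0, "t_end": t1})
            truth_segments[sid] = {"label": level, "item_type": kind,
                                   "correct": correct}
    t0 = cursor / fs
    cursor += int(round(study.fixation_task_duration * fs))
    segments.append({"participant_id": participant_id,
                     "segment_id": f"{participant_id}_fix2", "label": "fix2",
                     "item_type": "none", "response_correct": np.nan,
                     "t_start": t0, "t_end": cursor / fs})
    truth = {"participant_id": participant_id, "segments": truth_segments}
    return segments, truth


def write_cohort(design: CohortDesign, out_dir, signals: bool = True) -> dict:
    """Generate a cohort and write samples/segments/manifest files.

    Returns a dict of the written paths.  Output is byte-identical across
    runs with the same design (fixed formatting, seeded generation).
    """
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples, segments, manifest = generate_cohort(design, signals=signals)
    paths = {"segments": out / "segments.csv",
             "manifest": out / "manifest.json"}
    pio.write_segments(segments, paths["segments"])
    if samples is not None:
        paths["samples"] = out / "samples.csv"
        pio.write_samples(samples, paths["samples"])
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return paths
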