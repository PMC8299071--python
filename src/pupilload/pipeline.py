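"""End-to-end orchestration: ingest -> preprocess -> IPA -> indicators ->
Bayesian comparisons -> report.

`run_analysis` is deterministic given its inputs and configuration; every
dropped segment or participant is logged with a reason code, and degraded
or rejected segments become missing indicator values.  `make_report` only
renders previously written artifacts — it recomputes nothing.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import bayes, indicators, io as pio, preprocess
from .errors import (DegenerateDataError, PupilloadError, SegmentRejectedError,
                     SeriesTooShortError)
from .ipa import IPAParams, compute_ipa
from .model import FIXATION_LABELS, LABELS, Segment, StudyDesign

logger = logging.getLogger(__name__)

_LABEL_DISPLAY = {"fix1": "Fix. task 1", "fix2": "Fix. task 2",
                  "a": "Level a", "b": "Level b", "c": "Level c",
                  "d": "Level d", "e": "Level e", "f": "Level f"}


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one analysis run.

    Serialised into the output directory as flat dotted keys (e.g.
    ``ipa.threshold_factor: 0.8``) so a run is reproducible from its
    artifacts alone.
    """

    ipa: IPAParams = field(default_factory=IPAParams)
    max_gap_s: float = preprocess.DEFAULT_MAX_GAP_S
    reject_invalid_fraction: float = preprocess.DEFAULT_REJECT_INVALID_FRACTION
    pupil_min_mm: float = pio.PUPIL_MIN_MM
    pupil_max_mm: float = pio.PUPIL_MAX_MM
    prior_scale: float = 1.0
    channels: tuple[str, ...] = ("mean", "diff")
    standardized: tuple[bool, ...] = (False, True)
    diff_mode: str = "z_of_diff"
    plan: tuple = bayes.DEFAULT_PLAN
    design: StudyDesign = field(default_factory=StudyDesign)
    time_unit: str = "s"
    seed: int = 0

    def to_flat(self) -> dict:
        flat = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if dataclasses.is_dataclass(v):
                for sub in dataclasses.fields(v):
                    flat[f"{f.name}.{sub.name}"] = _plain(getattr(v, sub.name))
            else:
                flat[f.name] = _plain(v)
        return flat

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_flat(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            flat = yaml.safe_load(fh) or {}
        return cls.from_flat(flat)

    @classmethod
    def from_flat(cls, flat: dict) -> "RunConfig":
        nested: dict = {}
        for key, value in flat.items():
            if "." in key:
                head, tail = key.split(".", 1)
                nested.setdefault(head, {})[tail] = value
            else:
                nested[key] = value
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in nested:
                continue
            v = nested[f.name]
            if f.name == "ipa":
                kwargs["ipa"] = IPAParams(**v)
            elif f.name == "design":
                v = dict(v)
                if "levels" in v:
                    v["levels"] = tuple(v["levels"])
                kwargs["design"] = StudyDesign(**v)
            elif f.name == "plan":
                kwargs["plan"] = tuple(tuple(entry) for entry in v)
            elif f.name in ("channels",):
                kwargs[f.name] = tuple(v)
            elif f.name == "standardized":
                kwargs[f.name] = tuple(bool(x) for x in v)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)


def _plain(v):
    if isinstance(v, tuple):
        return [_plain(x) for x in v]
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def compute_segment_ipa(samples: pd.DataFrame, segments: pd.DataFrame,
                        config: RunConfig,
                        log: list[str] | None = None) -> pd.DataFrame:
    """Per-segment, per-eye IPA values.

    Returns one row per segment with ``ipa_left``/``ipa_right``; a rejected,
    too-short, or degraded eye yields NaN for that eye (reason logged).
    """
    if log is None:
        log = []
    rows = []
    # one numpy view bundle per participant; per-segment slicing is then
    # a pair of searchsorted calls instead of frame filtering
    groups = {}
    for pid, sub in samples.groupby("participant_id", sort=False,
                                    observed=True):
        groups[pid] = {
            "t": sub["t"].to_numpy(),
            "left": sub["pupil_left"].to_numpy(),
            "right": sub["pupil_right"].to_numpy(),
            "valid_left": sub["valid_left"].to_numpy().astype(bool),
            "valid_right": sub["valid_right"].to_numpy().astype(bool)}
    for seg in pio.iter_segments(segments):
        arrs = groups.get(seg.participant_id)
        row = {"participant_id": seg.participant_id,
               "segment_id": seg.segment_id, "label": seg.label,
               "ipa_left": np.nan, "ipa_right": np.nan}
        if arrs is None:
            log.append(f"missing_samples participant={seg.participant_id} "
                       f"segment={seg.segment_id}")
            rows.append(row)
            continue
        i0, i1 = np.searchsorted(arrs["t"], [seg.t_start, seg.t_end],
                                 side="left")
        for eye in ("left", "right"):
            try:
                if i1 <= i0:
                    raise SeriesTooShortError(
                        f"segment {seg.segment_id}: empty span",
                        segment_id=seg.segment_id)
                series = preprocess.PupilSeries(
                    eye=eye, t=arrs["t"][i0:i1], d=arrs[eye][i0:i1],
                    valid=arrs[f"valid_{eye}"][i0:i1])
                series = preprocess.repair_gaps(
                    series, max_gap_s=config.max_gap_s,
                    reject_invalid_fraction=config.reject_invalid_fraction)
                result = compute_ipa(series, config.ipa)
            except SegmentRejectedError as err:
                log.append(f"segment_rejected segment={seg.segment_id} "
                           f"eye={eye} reason={err.reason}")
                continue
            except SeriesTooShortError as err:
                log.append(f"segment_too_short segment={seg.segment_id} "
                           f"eye={eye} required={err.required}")
                continue
            if result.degraded:
                log.append(f"segment_degraded segment={seg.segment_id} "
                           f"eye={eye} reason=long_gap")
                continue
            row[f"ipa_{eye}"] = result.ipa
        rows.append(row)
    return pd.DataFrame(rows, columns=["participant_id", "segment_id",
                                       "label", "ipa_left", "ipa_right"])


def _precision_tables(samples: pd.DataFrame, segments: pd.DataFrame,
                      config: RunConfig,
                      log: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant fixation precision plus the equality test between tasks."""
    rows = []
    groups = dict(iter(samples.groupby("participant_id", sort=False,
                                       observed=True)))
    for seg in pio.iter_segments(segments):
        if seg.label not in FIXATION_LABELS:
            continue
        sub = groups.get(seg.participant_id)
        if sub is None:
            log.append(f"precision_missing segment={seg.segment_id}")
            continue
        rx, ry = indicators.fixation_residuals(sub, seg, config.design)
        sd_x, sd_y = indicators.fixation_precision(rx, ry)
        if not np.isfinite(sd_x):
            log.append(f"precision_missing segment={seg.segment_id}")
        rows.append({"participant_id": seg.participant_id, "task": seg.label,
                     "sd_x": sd_x, "sd_y": sd_y, "n_samples": len(rx)})
    prec = pd.DataFrame(rows, columns=["participant_id", "task", "sd_x",
                                       "sd_y", "n_samples"])
    tests = []
    if len(prec):
        wide = prec.pivot_table(index="participant_id", columns="task",
                                aggfunc="first", dropna=False)
        for coord in ("sd_x", "sd_y"):
            try:
                diffs = (wide[(coord, "fix2")]
                         - wide[(coord, "fix1")]).dropna().to_numpy()
                t, n = bayes.paired_t(diffs)
                bf = bayes.jzs_bf(t, n, r=config.prior_scale,
                                  direction="two_sided")
                tests.append({"coordinate": coord.split("_")[1], "n": n,
                              "t_stat": t, "bf10": bf,
                              "evidence": bayes.classify_evidence(bf)})
            except (KeyError, DegenerateDataError) as err:
                log.append(f"precision_test_skipped coord={coord} "
                           f"reason={err}")
    tests_df = pd.DataFrame(tests, columns=["coordinate", "n", "t_stat",
                                            "bf10", "evidence"])
    return prec, tests_df


def run_analysis(samples, segments, config: RunConfig | None = None,
                 out_dir=None) -> dict:
    """Run the full analysis and return (optionally write) its artifacts.

    ``samples``/``segments`` may be file paths or canonical frames.
    Returns a dict with keys ``segment_ipa``, ``indicators``, ``aggregates``,
    ``comparisons``, ``accuracy``, ``precision``, ``precision_tests`` and
    ``log``.  With ``out_dir`` each table is written as CSV together with
    the resolved config and the run log.
    """
    config = config or RunConfig()
    log: list[str] = []
    dialect = pio.Dialect(time_unit=config.time_unit)
    if not isinstance(samples, pd.DataFrame):
        samples = pio.read_samples(samples, dialect,
                                   pupil_min_mm=config.pupil_min_mm,
                                   pupil_max_mm=config.pupil_max_mm)
    if not isinstance(segments, pd.DataFrame):
        segments = pio.read_segments(segments, dialect)

    segment_ipa = compute_segment_ipa(samples, segments, config, log)
    raw = indicators.segment_channels(segment_ipa)
    std = indicators.z_standardize_records(raw, diff_mode=config.diff_mode)
    records = pd.concat([raw, std], ignore_index=True)
    aggregates = indicators.aggregate_by_label(records)
    comparisons = bayes.run_pairwise_comparisons(
        aggregates, plan=config.plan, channels=config.channels,
        standardized=config.standardized, r=config.prior_scale)
    accuracy = indicators.accuracy_table(segments)
    precision, precision_tests = _precision_tables(samples, segments, config,
                                                   log)
    outputs = {"segment_ipa": segment_ipa, "indicators": records,
               "aggregates": aggregates, "comparisons": comparisons,
               "accuracy": accuracy, "precision": precision,
               "precision_tests": precision_tests, "log": log}
    if out_dir is not None:
        _write_outputs(outputs, config, out_dir)
    return outputs


def _write_outputs(outputs: dict, config: RunConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pio.write_indicators(outputs["indicators"], out / "indicators.csv")
    pio.write_aggregates(outputs["aggregates"], out / "aggregates.csv")
    pio.write_comparisons(outputs["comparisons"], out / "comparisons.csv")
    outputs["accuracy"].to_csv(out / "accuracy.csv", index=False,
                               float_format="%.6f")
    outputs["precision"].to_csv(out / "precision.csv", index=False,
                                float_format="%.4f")
    outputs["precision_tests"].to_csv(out / "precision_tests.csv",
                                      index=False, float_format="%.6g")
    config.to_yaml(out / "config.yaml")
    with open(out / "run.log", "w", encoding="utf-8") as fh:
        for line in outputs["log"]:
            fh.write(line + "\n")


# -- report ---------------------------------------------------------------

def _fmt_pair(a: str, b: str) -> str:
    return f"{_LABEL_DISPLAY.get(a, a)} - {_LABEL_DISPLAY.get(b, b)}"


def make_report(out_dir) -> str:
    """Human-readable summary of a completed run (reads artifacts only)."""
    out = Path(out_dir)
    for name in ("comparisons.csv", "aggregates.csv"):
        if not (out / name).exists():
            raise FileNotFoundError(f"missing artifact: {out / name}")
    comparisons = pio.read_comparisons(out / "comparisons.csv")
    aggregates = pio.read_aggregates(out / "aggregates.csv")

    lines = ["Pupillary workload analysis", "=" * 27, ""]

    if len(aggregates):
        lines.append("Condition profile (participant means of per-label "
                     "aggregates)")
        prof = aggregates.groupby(["channel", "standardized", "label"],
                                  sort=False)["value"].mean().reset_index()
        prof["label"] = pd.Categorical(prof["label"], categories=LABELS,
                                       ordered=True)
        prof = prof.sort_values("label", kind="mergesort")
        for (chan, std), grp in prof.groupby(["channel", "standardized"],
                                             sort=False):
            kind = "z-standardized" if std else "conventional"
            vals = " ".join(f"{_LABEL_DISPLAY.get(r.label, r.label)}="
                            f"{r.value:.3f}"
                            for r in grp.itertuples())
            lines.append(f"  {chan} ({kind}): {vals}")
        lines.append("")

    lines.append("Pairwise comparisons (ES = posterior mean [95% CI], "
                 "JZS BF10)")
    if len(comparisons) == 0:
        lines.append("  no computable pairs")
    else:
        for (chan, std), grp in comparisons.groupby(
                ["channel", "standardized"], sort=False):
            kind = "z-standardized" if std else "conventional"
            lines.append(f"  channel {chan}, {kind}:")
            for r in grp.itertuples():
                if not np.isfinite(r.bf10):
                    lines.append(f"    {_fmt_pair(r.pair_a, r.pair_b):28s} "
                                 f"{r.evidence}")
                    continue
                mark = bayes.evidence_marker(r.evidence)
                lines.append(
                    f"    {_fmt_pair(r.pair_a, r.pair_b):28s} "
                    f"ES {r.es_mean: .2f} [{r.es_lo: .2f}; {r.es_hi: .2f}]  "
                    f"BF10 {r.bf10:.2f}{mark}")
        lines.append("")
        lines.append("  evidence markers: moderate (*/'), strong (**/''), "
                     "very strong (***/'''), extreme (****/'''') for "
                     "H1 (*) / H0 (')")

    acc_path = out / "accuracy.csv"
    if acc_path.exists():
        acc = pd.read_csv(acc_path)
        if len(acc):
            lines.append("")
            lines.append("Accuracy (possible items only)")
            summary = acc.groupby("level", sort=True)["accuracy"] \
                .agg(["mean", "std"])
            for level, row in summary.iterrows():
                lines.append(f"  Level {level}: {row['mean']:.2f} "
                             f"({row['std']:.2f})")

    prec_path = out / "precision_tests.csv"
    if prec_path.exists():
        tests = pd.read_csv(prec_path)
        if len(tests):
            lines.append("")
            lines.append("Fixation precision, task-2 vs task-1 equality "
                         "(undirected)")
            for r in tests.itertuples():
                mark = bayes.evidence_marker(r.evidence)
                lines.append(f"  {r.coordinate}-coordinate: "
                             f"BF10 {r.bf10:.2f}{mark} (n={r.n})")
    return "\n".join(lines) + "\n"
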