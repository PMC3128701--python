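"""Scoring of raw trial streams into the scalar behavioural measures.

A trial stream is the timestamped event log of one task session.  The
ongoing (OG) task is a two-alternative forced choice (left/right mouse key,
self-paced with a 3 s cap).  During the prospective-memory (PM) phase the
participant additionally presses the spacebar either when a cue trial
appears (event-based: a pre-specified category of stimulus) or every 30 s
(time-based, with an openable stopwatch box).  Two time-estimation tasks
(TE1/TE2) ask for silent continuation of an externally paced count.

Event kinds: ``stimulus_on``, ``left``, ``right``, ``spacebar``,
``clock_open``, ``clock_close``.  Timestamps are milliseconds from session
start and must be nondecreasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats

EVENT_KINDS = ("stimulus_on", "left", "right", "spacebar",
               "clock_open", "clock_close")

TASKS = ("OGonly", "PM_phase_time", "PM_phase_event", "SRT", "PREP",
         "DETECT", "INHIB", "INSTRUCT", "SWITCH", "TE1", "TE2")

#: Number of OG trials between successive event-based PM targets (fixed,
#: identical for all participants), plus two terminal OG trials.
EVENT_PM_SCHEDULE = (30, 24, 22, 16, 14, 8, 6, 2, 4, 10, 12, 18, 20, 26, 28)
EVENT_PM_TERMINAL_OG = 2
#: self-pace response cap on ongoing trials, ms
OG_RESPONSE_CAP_MS = 3000.0
#: TE trial design: (numeral period s, count reached per trial).
TE_DESIGNS = {
    "TE1": (1.0, (20, 30, 40, 50)),
    "TE2": (2.0, (15, 20, 25, 30)),
}
TE_PACED_COUNT = 10  # externally paced numerals establishing the rhythm
TE_IDEAL_TOTAL_S = 100.0


def validate_event_schedule(schedule=EVENT_PM_SCHEDULE,
                            terminal=EVENT_PM_TERMINAL_OG) -> dict:
    """Arithmetic of the fixed event-PM target schedule.

    Returns the OG-trial count, target count, and the target frequency in
    percent with the terminal OG trials excluded from the denominator.
    """
    n_og = sum(schedule) + terminal
    n_targets = len(schedule)
    freq_pct = 100.0 * n_targets / (sum(schedule) + n_targets)
    return {"n_og_trials": n_og, "n_targets": n_targets,
            "target_frequency_pct": freq_pct}


@dataclass
class TrialStream:
    """Timestamped event log of one task session."""

    session_id: str
    task: str
    events: pd.DataFrame  # columns: t_ms, kind, is_pm_target, correct_side

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        ev = self.events
        needed = {"t_ms", "kind"}
        if not needed <= set(ev.columns):
            raise ValueError(f"events need columns {needed}")
        if "is_pm_target" not in ev.columns:
            ev = ev.assign(is_pm_target=False)
        if "correct_side" not in ev.columns:
            ev = ev.assign(correct_side=None)
        if np.any(np.diff(ev["t_ms"].to_numpy(float)) < 0):
            raise ValueError("event timestamps must be nondecreasing")
        bad = set(ev["kind"].unique()) - set(EVENT_KINDS)
        if bad:
            raise ValueError(f"unknown event kinds {sorted(bad)}")
        self.events = ev.reset_index(drop=True)

    @property
    def duration_ms(self) -> float:
        """Session length, taken as the last event timestamp (t=0 = start)."""
        return float(self.events["t_ms"].iloc[-1]) if len(self.events) else 0.0


@dataclass
class TaskScore:
    accuracy_pct: float
    mean_rt_ms: float  # NaN when no correct analysed trial carries an RT
    n_trials: int


@dataclass
class TimeBasedScore:
    mean_interpress_s: float  # NaN when fewer than 2 presses
    press_count: int
    press_ratio_pct: float
    clock_checks: int


@dataclass
class TimeEstimationScore:
    trial_durations_s: tuple  # one entry per trial, NaN where press missing
    total_s: float
    partial: bool  # True when a trial's press was missing


def stream_to_frame(stream: TrialStream) -> pd.DataFrame:
    df = stream.events.copy()
    df.insert(0, "task", stream.task)
    df.insert(0, "session_id", stream.session_id)
    return df


def write_trial_stream(stream: TrialStream, path: str | Path) -> None:
    stream_to_frame(stream).to_csv(path, index=False)


def read_trial_stream(path: str | Path) -> TrialStream:
    df = pd.read_csv(path)
    if df["session_id"].nunique() != 1 or df["task"].nunique() != 1:
        raise ValueError(f"{path}: expected a single session per file")
    session_id = str(df["session_id"].iloc[0])
    task = str(df["task"].iloc[0])
    ev = df.drop(columns=["session_id", "task"])
    if "is_pm_target" in ev.columns:
        ev["is_pm_target"] = ev["is_pm_target"].fillna(False).astype(bool)
    if "correct_side" in ev.columns:
        ev["correct_side"] = ev["correct_side"].where(
            ev["correct_side"].notna(), None)
    return TrialStream(session_id=session_id, task=task, events=ev)


def _trials(stream: TrialStream) -> pd.DataFrame:
    """One row per stimulus: onset, target flag, correct side, response.

    The response of a trial is the first left/right/spacebar event between
    its onset and the next stimulus onset.
    """
    ev = stream.events
    onsets = ev.index[ev["kind"] == "stimulus_on"].to_numpy()
    rows = []
    for i, idx in enumerate(onsets):
        end = onsets[i + 1] if i + 1 < len(onsets) else len(ev)
        window = ev.iloc[idx + 1:end]
        resp = window[window["kind"].isin(("left", "right", "spacebar"))]
        rows.append({
            "onset_ms": float(ev["t_ms"].iloc[idx]),
            "is_pm_target": bool(ev["is_pm_target"].iloc[idx]),
            "correct_side": ev["correct_side"].iloc[idx],
            "response": resp["kind"].iloc[0] if len(resp) else None,
            "rt_ms": float(resp["t_ms"].iloc[0]) - float(ev["t_ms"].iloc[idx])
            if len(resp) else math.nan,
        })
    return pd.DataFrame(rows)


def _og_score(trials: pd.DataFrame) -> TaskScore:
    n = len(trials)
    if n == 0:
        raise ValueError("no trials to score")
    correct = trials["response"] == trials["correct_side"]
    rts = trials.loc[correct, "rt_ms"].dropna()
    return TaskScore(
        accuracy_pct=100.0 * correct.sum() / n,
        mean_rt_ms=float(rts.mean()) if len(rts) else math.nan,
        n_trials=n,
    )


def score_ongoing(stream: TrialStream, discard_first: int = 10) -> TaskScore:
    """Accuracy and mean correct RT of an ongoing block.

    The first ``discard_first`` trials are warm-up and discarded (a 30-trial
    ongoing block yields 20 analysed trials).  Accuracy is the percentage of
    analysed trials answered on the correct side; a trial without a response
    (the 3 s cap elapsed) counts as incorrect.
    """
    trials = _trials(stream)
    if len(trials) <= discard_first:
        raise ValueError(
            f"only {len(trials)} trials; cannot discard first {discard_first}"
        )
    return _og_score(trials.iloc[discard_first:])


def score_event_pm(stream: TrialStream) -> tuple[TaskScore, TaskScore]:
    """Score the event-based PM phase: (ongoing trials, PM targets).

    A target is credited if a spacebar press occurs anywhere from its onset
    until the end of the following trial — participants are explicitly told
    to register the cue even when late, so the crediting window extends one
    trial beyond the cue itself.  PM accuracy is the percentage of targets
    credited; PM RT is press time minus target onset over credited targets.
    Ongoing accuracy/RT are computed over the non-target trials.
    """
    trials = _trials(stream)
    targets = trials.index[trials["is_pm_target"]].to_numpy()
    if len(targets) == 0:
        raise ValueError("stream contains no PM targets")
    ev = stream.events
    onsets = trials["onset_ms"].to_numpy()
    presses = ev.loc[ev["kind"] == "spacebar", "t_ms"].to_numpy(float)
    credited_rts = []
    n_credited = 0
    for i in targets:
        start = onsets[i]
        # window closes at the onset of the trial after the following one
        end = onsets[i + 2] if i + 2 < len(onsets) else math.inf
        hits = presses[(presses >= start) & (presses < end)]
        if len(hits):
            n_credited += 1
            credited_rts.append(hits[0] - start)
    pm = TaskScore(
        accuracy_pct=100.0 * n_credited / len(targets),
        mean_rt_ms=float(np.mean(credited_rts)) if credited_rts else math.nan,
        n_trials=len(targets),
    )
    og = _og_score(trials[~trials["is_pm_target"]])
    return og, pm


def score_time_pm(stream: TrialStream, target_interval_s: float = 30.0,
                  session_duration_s: float | None = None) -> TimeBasedScore:
    """Score the time-based PM phase.

    ``mean_interpress_s`` is the mean of successive spacebar-press
    differences (NaN — reported missing, never zero — with fewer than two
    presses).  ``press_ratio_pct`` is 100 x press count / floor(session
    duration / target interval), the real press count as a percentage of
    the ideal one.  Clock checks count the stopwatch-box openings.
    """
    ev = stream.events
    presses = ev.loc[ev["kind"] == "spacebar", "t_ms"].to_numpy(float) / 1000.0
    if session_duration_s is None:
        session_duration_s = stream.duration_ms / 1000.0
    mean_ip = float(np.diff(presses).mean()) if len(presses) >= 2 else math.nan
    ideal = math.floor(session_duration_s / target_interval_s)
    ratio = 100.0 * len(presses) / ideal if ideal > 0 else math.nan
    return TimeBasedScore(
        mean_interpress_s=mean_ip,
        press_count=len(presses),
        press_ratio_pct=ratio,
        clock_checks=int((ev["kind"] == "clock_open").sum()),
    )


def score_time_estimation(stream: TrialStream,
                          variant: str | None = None) -> TimeEstimationScore:
    """Score a time-estimation session (four trials).

    Each trial shows a paced count of numerals, then the participant
    continues counting silently and presses the spacebar on reaching the
    trial's end number.  The produced duration is the press time minus the
    onset of the last paced numeral; the global score sums the four trials
    (ideal: 10 + 20 + 30 + 40 = 100 s for both variants).  A trial without a
    press scores NaN and marks the total as partial.
    """
    variant = variant or stream.task
    if variant not in TE_DESIGNS:
        raise ValueError(f"variant must be one of {sorted(TE_DESIGNS)}")
    ev = stream.events
    # each trial shows exactly TE_PACED_COUNT numerals then awaits a press;
    # a full numeral run without a press is a trial with a missing response
    durations: list[float] = []
    last_numeral = math.nan
    n_numerals = 0
    for _, row in ev.iterrows():
        if row["kind"] == "stimulus_on":
            if n_numerals == TE_PACED_COUNT:
                durations.append(math.nan)
                n_numerals = 0
            n_numerals += 1
            last_numeral = float(row["t_ms"])
        elif row["kind"] == "spacebar":
            durations.append((float(row["t_ms"]) - last_numeral) / 1000.0)
            n_numerals = 0
    if n_numerals:
        durations.append(math.nan)
    if len(durations) != 4:
        raise ValueError(f"expected 4 trials, found {len(durations)}")
    partial = any(math.isnan(d) for d in durations)
    total = float(np.nansum(durations)) if not all(
        math.isnan(d) for d in durations) else math.nan
    return TimeEstimationScore(trial_durations_s=tuple(durations),
                               total_s=total, partial=partial)


def spearman(x, y) -> stats.TestResult:
    """Spearman rank correlation (delegates to the stats kernel)."""
    return stats.spearman(x, y)
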