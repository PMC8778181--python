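"""Session-log analysis: how robot actions relate to child state dynamics.

Works on attempt-level frame logs sampled at 3 Hz.  Each frame records the
robot's action value in four modalities — Animation (None / Disappointed /
Default / Stand), Sound, LEDs and Speaking (no / yes) — and, when the
child's face was detected, the 68 facial landmarks.  A frame is *complete*
iff it carries both; an attempt is *eligible* iff it has at least one
complete frame.  The *outset* of a robot action (a modality switching from
inactive to active) is an *event*.

Four tools are provided:

1. ``modality_histogram`` — normalized distribution of a modality's active
   complete frames over the nine states.
2. ``detect_events`` / ``transitions`` — event-triggered state transitions:
   an event at (1-based) index k in the complete-frame series counts as a
   transition iff s_{k-1} != s_{k+lag}, lag in {1, 2, 3}, labeled by the
   two-digit string "ab" (a = s_{k-1}, b = s_{k+lag}).
3. ``state_timeseries`` — plot-ready per-frame states with gap markers for
   frames where no face was detected.
4. ``mine_patterns`` — run-collapsed state substrings: every window of
   three consecutive maximal runs with three distinct states and run
   lengths at most three is an occurrence; variants such as "806", "8066"
   and "8806" collapse to the same equivalence class "806".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, StateError

MODALITIES = ("Animation", "Sound", "LEDs", "Speaking")
ANIMATION_VALUES = ("None", "Disappointed", "Default", "Stand")
BINARY_VALUES = ("no", "yes")
N_STATES = 9
SAMPLING_HZ = 3.0


@dataclass
class Frame:
    """One 3 Hz sample of robot actions plus optional face landmarks."""

    timestamp: object
    animation: str = "None"
    sound: str = "no"
    leds: str = "no"
    speaking: str = "no"
    landmarks: np.ndarray | None = None
    state: int | None = None

    @property
    def complete(self) -> bool:
        return self.landmarks is not None

    def modality_value(self, modality: str) -> str:
        try:
            return getattr(self, modality.lower())
        except AttributeError:
            raise InputError(f"unknown modality: {modality!r}") from None


@dataclass
class Attempt:
    """An ordered run of frames from one execution of an activity."""

    attempt_id: str
    frames: list[Frame] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def eligible(self) -> bool:
        return any(f.complete for f in self.frames)


@dataclass(frozen=True)
class EventRecord:
    """The outset of a robot action at 1-based complete-frame index k."""

    k: int
    modality: str
    value: str


@dataclass
class StateSeries:
    """Per-complete-frame states s_1..s_N of one attempt."""

    states: np.ndarray
    attempt_id: str | None = None

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=int)
        if self.states.size and not np.all((self.states >= 0) & (self.states < N_STATES)):
            raise InputError("states must lie in 0..8")

    def __len__(self) -> int:
        return self.states.size

    def as_string(self) -> str:
        return "".join(str(s) for s in self.states)


def is_active(frame: Frame, modality: str) -> bool:
    """Whether a modality is producing a stimulus in this frame.

    Animation is active for any value other than "None"; the binary
    modalities are active when "yes".
    """
    v = frame.modality_value(modality)
    return v != "None" if modality == "Animation" else v == "yes"


def filter_complete(attempt: Attempt) -> list[Frame]:
    """Ordered complete frames of an attempt (frames with no detected face
    are discarded); an empty result marks the attempt ineligible."""
    return [f for f in attempt.frames if f.complete]


# ---------------------------------------------------------------------------
# tool 1: modality-conditional state histograms
# ---------------------------------------------------------------------------


@dataclass
class ModalityHistogram:
    """Normalized distribution of a modality's active frames over states."""

    modality: str
    counts: np.ndarray
    n_active: int

    @property
    def probabilities(self) -> np.ndarray:
        if self.n_active == 0:
            return np.zeros(N_STATES)
        return self.counts / self.n_active

    @property
    def empty(self) -> bool:
        return self.n_active == 0


def modality_histogram(frames, modality: str, active_values=None) -> ModalityHistogram:
    """Distribution over the nine states of the complete frames in which
    ``modality`` is active.

    ``active_values`` optionally overrides which action values count as
    active (by default: anything but "None" for Animation, "yes" otherwise).
    """
    if modality not in MODALITIES:
        raise InputError(f"unknown modality: {modality!r}")
    counts = np.zeros(N_STATES, dtype=int)
    n_active = 0
    for f in frames:
        if active_values is None:
            active = is_active(f, modality)
        else:
            active = f.modality_value(modality) in active_values
        if not active:
            continue
        if f.state is None:
            raise StateError("histogram frames must carry assigned states")
        counts[f.state] += 1
        n_active += 1
    return ModalityHistogram(modality=modality, counts=counts, n_active=n_active)


# ---------------------------------------------------------------------------
# tool 2: events and state transitions
# ---------------------------------------------------------------------------


def detect_events(frames) -> list[EventRecord]:
    """Action outsets in an ordered complete-frame list.

    One record per modality per inactive-to-active transition, indexed by
    the 1-based position k of the frame where the action starts;
    simultaneous outsets in several modalities yield one record each.
    """
    frames = list(frames)
    events = []
    for i in range(1, len(frames)):
        for m in MODALITIES:
            if not is_active(frames[i - 1], m) and is_active(frames[i], m):
                events.append(EventRecord(k=i + 1, modality=m, value=frames[i].modality_value(m)))
    return events


@dataclass
class TransitionTally:
    """Per-modality event-triggered transition counts at one lag."""

    modality: str
    lag: int
    transitions: Counter = field(default_factory=Counter)  # "ab" -> count
    yes: int = 0
    no: int = 0


def transitions(series: StateSeries, events, lag: int = 1) -> dict[str, TransitionTally]:
    """Count event-triggered state transitions at the given lag.

    For an event at 1-based index k, a transition occurs iff
    s_{k-1} != s_{k+lag}; events with k-1 < 1 or k+lag > N are skipped.
    """
    if lag not in (1, 2, 3):
        raise InputError("lag must be 1, 2 or 3")
    s = series.states
    n = len(s)
    tallies = {m: TransitionTally(modality=m, lag=lag) for m in MODALITIES}
    for ev in events:
        k = ev.k
        if k - 1 < 1 or k + lag > n:
            continue
        a, b = int(s[k - 2]), int(s[k + lag - 1])
        t = tallies[ev.modality]
        if a != b:
            t.yes += 1
            t.transitions[f"{a}{b}"] += 1
        else:
            t.no += 1
    return tallies


def merge_tallies(per_attempt: list[dict[str, TransitionTally]]) -> dict[str, TransitionTally]:
    """Pool per-attempt tallies (same lag) across attempts."""
    if not per_attempt:
        return {}
    lag = next(iter(per_attempt[0].values())).lag
    out = {m: TransitionTally(modality=m, lag=lag) for m in MODALITIES}
    for tallies in per_attempt:
        for m, t in tallies.items():
            if t.lag != lag:
                raise InputError("cannot pool tallies computed at different lags")
            out[m].yes += t.yes
            out[m].no += t.no
            out[m].transitions.update(t.transitions)
    return out


def total_transitions(tallies: dict[str, TransitionTally]) -> int:
    """Grand total of transition ("yes") counts across modalities."""
    return sum(t.yes for t in tallies.values())


def transition_table(tallies_by_lag: dict[int, dict[str, TransitionTally]]) -> pd.DataFrame:
    """Modality x lag yes/no table, with a TOTAL row."""
    rows = []
    for m in MODALITIES:
        row = {"modality": m}
        for lag, tallies in sorted(tallies_by_lag.items()):
            row[f"lag{lag}_yes"] = tallies[m].yes
            row[f"lag{lag}_no"] = tallies[m].no
        rows.append(row)
    total = {"modality": "TOTAL"}
    for lag, tallies in sorted(tallies_by_lag.items()):
        total[f"lag{lag}_yes"] = total_transitions(tallies)
        total[f"lag{lag}_no"] = sum(t.no for t in tallies.values())
    rows.append(total)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tool 3: state time series
# ---------------------------------------------------------------------------


def state_timeseries(attempt: Attempt) -> pd.DataFrame:
    """Per-frame (timestamp, state) records; state is NA at gap frames
    (no face detected)."""
    recs = {
        "timestamp": [f.timestamp for f in attempt.frames],
        "state": pd.array(
            [f.state if f.complete else None for f in attempt.frames], dtype="Int64"
        ),
    }
    return pd.DataFrame(recs)


def plot_state_timeseries(ts: pd.DataFrame, path) -> None:
    """Render a state time series (gaps marked along the bottom) to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    x = np.arange(len(ts))
    state = ts["state"].to_numpy(dtype=float, na_value=np.nan)
    ax.plot(x, state, ".-", ms=3, lw=0.5, label="state")
    gaps = np.isnan(state)
    if gaps.any():
        ax.plot(x[gaps], np.full(gaps.sum(), -0.6), "|", color="red", label="no face detected")
    ax.set_yticks(range(N_STATES))
    ax.set_ylim(-1, N_STATES - 0.5)
    ax.set_xlabel("frame (3 Hz)")
    ax.set_ylabel("state")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# tool 4: equivalence-class pattern mining
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatternOccurrence:
    """A literal pattern variant and the run-collapsed class it belongs to.

    ``start``/``end`` are 0-based inclusive indices into the attempt's
    complete-frame series.
    """

    variant: str
    pattern_class: str
    start: int
    end: int
    attempt_id: str | None = None

    @property
    def spanned_frames(self) -> int:
        return self.end - self.start + 1


def _runs(states: np.ndarray):
    """Maximal runs of a state string as (symbol, start, length) triples."""
    runs = []
    i = 0
    n = len(states)
    while i < n:
        j = i
        while j + 1 < n and states[j + 1] == states[i]:
            j += 1
        runs.append((int(states[i]), i, j - i + 1))
        i = j + 1
    return runs


@dataclass
class PatternClassReport:
    """All occurrences of one equivalence class, with variant frequencies."""

    pattern_class: str
    variant_counts: Counter = field(default_factory=Counter)
    occurrences: list[PatternOccurrence] = field(default_factory=list)

    @property
    def total(self) -> int:
        return len(self.occurrences)


def mine_patterns(
    series_list, min_distinct: int = 3, max_run: int = 3
) -> dict[str, PatternClassReport]:
    """Mine run-collapsed state patterns from per-attempt state series.

    Each series is tokenized into maximal runs; every window of
    ``min_distinct`` consecutive runs whose symbols are all distinct and
    whose run lengths are all at most ``max_run`` is one occurrence.  The
    occurrence's *variant* is the literal substring and its *equivalence
    class* is the run-symbol sequence (e.g. "8066" -> class "806").
    Windows never cross attempt boundaries.
    """
    if min_distinct < 2:
        raise InputError("min_distinct must be >= 2")
    if max_run < 1:
        raise InputError("max_run must be >= 1")
    reports: dict[str, PatternClassReport] = {}
    for series in series_list:
        if isinstance(series, StateSeries):
            states, att = series.states, series.attempt_id
        else:
            states, att = np.asarray(list(series), dtype=int), None
            if states.size and not np.all((states >= 0) & (states < N_STATES)):
                raise InputError("states must lie in 0..8")
        runs = _runs(states)
        w = min_distinct
        for i in range(len(runs) - w + 1):
            window = runs[i : i + w]
            if any(length > max_run for _, _, length in window):
                continue
            symbols = [sym for sym, _, _ in window]
            if len(set(symbols)) != w:
                continue
            start = window[0][1]
            end = window[-1][1] + window[-1][2] - 1
            cls = "".join(str(s) for s in symbols)
            variant = "".join(str(s) for s in states[start : end + 1])
            occ = PatternOccurrence(
                variant=variant, pattern_class=cls, start=start, end=end, attempt_id=att
            )
            rep = reports.setdefault(cls, PatternClassReport(pattern_class=cls))
            rep.variant_counts[variant] += 1
            rep.occurrences.append(occ)
    return reports


def pattern_modality_profile(occurrences, frames_by_attempt) -> dict[str, Counter]:
    """Distribution of each modality's action values over the frames
    spanned by a class's occurrences.

    ``frames_by_attempt`` maps attempt id to that attempt's ordered
    complete-frame list (a plain frame list is accepted when every
    occurrence has ``attempt_id is None``).  Frames spanned by several
    overlapping occurrences are counted once, so every modality's counts
    sum to the same spanned-frame total.
    """
    if not isinstance(frames_by_attempt, dict):
        frames_by_attempt = {None: list(frames_by_attempt)}
    spanned: dict[object, set[int]] = {}
    for occ in occurrences:
        spanned.setdefault(occ.attempt_id, set()).update(range(occ.start, occ.end + 1))
    profile: dict[str, Counter] = {m: Counter() for m in MODALITIES}
    for att, idxs in spanned.items():
        if att not in frames_by_attempt:
            raise InputError(f"no frames supplied for attempt {att!r}")
        frames = frames_by_attempt[att]
        for i in sorted(idxs):
            if i >= len(frames):
                raise InputError(f"occurrence index {i} outside attempt {att!r}")
            for m in MODALITIES:
                profile[m][frames[i].modality_value(m)] += 1
    return profile
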