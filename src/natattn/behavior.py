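"""Behavioral annotation I/O and sustained-attention event extraction.

Naturalistic infant sessions are video-coded into *look bouts*: intervals in
which the infant's gaze and head are clearly oriented to one target (a toy,
the caregiver, cables, ...).  Coding conventions end a bout when the infant
looks away for more than ~100 ms, so this module provides an explicit merge
step for gaps at or below that tolerance, then extracts sustained-attention
events: merged bouts strictly longer than 8 s, duration capped at 15 s, toy
targets only by default.  Participants contributing fewer than 5 events are
flagged for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "LookBout",
    "EventCriteria",
    "AttentionEvent",
    "read_annotations",
    "write_annotations",
    "merge_bouts",
    "extract_events",
    "participant_gate",
]

#: column order of the tab-delimited annotation dialect
ANNOTATION_COLUMNS = ("participant", "target", "start_s", "end_s")


@dataclass(frozen=True)
class LookBout:
    """One coded attention bout: the infant looking at a single target."""

    participant_id: str
    target: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"look bout must have end > start, got "
                f"[{self.start_s}, {self.end_s}] for {self.participant_id!r}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class EventCriteria:
    """Rules mapping merged look bouts to sustained-attention events.

    Looks must exceed ``min_look_s`` (strictly: a bout of exactly 8 s is not
    an event), block duration is capped at ``max_block_s``, look-aways of at
    most ``gap_merge_ms`` do not terminate a bout, and participants need at
    least ``min_events_per_participant`` events to enter group analysis.
    """

    min_look_s: float = 8.0
    max_block_s: float = 15.0
    gap_merge_ms: float = 100.0
    min_events_per_participant: int = 5
    allowed_targets: frozenset[str] = field(default_factory=lambda: frozenset({"toy"}))

    def __post_init__(self) -> None:
        if not self.min_look_s < self.max_block_s:
            raise ValueError("min_look_s must be below max_block_s")
        if self.gap_merge_ms < 0:
            raise ValueError("gap_merge_ms must be non-negative")
        object.__setattr__(self, "allowed_targets", frozenset(self.allowed_targets))


@dataclass(frozen=True)
class AttentionEvent:
    """A sustained-attention event anchored at its behavioral look onset.

    ``shift_s`` is the onset offset applied downstream when aligning to the
    hemodynamic series (0 until :func:`natattn.epoching.apply_shift` runs).
    """

    participant_id: str
    target: str
    look_onset_s: float
    duration_s: float
    shift_s: float = 0.0

    @property
    def shifted_onset_s(self) -> float:
        return self.look_onset_s + self.shift_s


def read_annotations(path) -> list[LookBout]:
    """Read a tab-delimited annotation export into validated look bouts.

    The dialect has a header line ``participant\\ttarget\\tstart_s\\tend_s``
    and one bout per row, times in session-relative seconds.  Rows are
    validated (numeric times, end > start) and the result is sorted by
    participant then start time.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    bouts = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start, end = float(row.start_s), float(row.end_s)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
        if pd.isna(row.participant) or pd.isna(row.target):
            raise ValueError(f"{path}: malformed row at line {i}: empty label")
        try:
            bouts.append(LookBout(str(row.participant), str(row.target), start, end))
        except ValueError as exc:
            raise ValueError(f"{path}: invalid bout at line {i}: {exc}") from exc
    bouts.sort(key=lambda b: (b.participant_id, b.start_s))
    _check_no_overlap(bouts)
    return bouts


def write_annotations(bouts: list[LookBout], path) -> None:
    """Write bouts in the tab-delimited dialect read by :func:`read_annotations`."""
    df = pd.DataFrame(
        [(b.participant_id, b.target, b.start_s, b.end_s) for b in bouts],
        columns=list(ANNOTATION_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def _check_no_overlap(bouts: list[LookBout]) -> None:
    for prev, cur in zip(bouts, bouts[1:]):
        if cur.participant_id == prev.participant_id and cur.start_s < prev.end_s:
            raise ValueError(
                f"overlapping bouts for {cur.participant_id!r} at {cur.start_s} s"
            )


def merge_bouts(bouts: list[LookBout], gap_merge_ms: float = 100.0) -> list[LookBout]:
    """Fuse consecutive same-target bouts separated by at most ``gap_merge_ms``.

    Look-aways of 100 ms or less are below the saccadic-planning timescale
    and do not terminate an attention bout; the merged bout spans the first
    start to the last end.  Idempotent.
    """
    gap_s = gap_merge_ms / 1000.0
    merged: list[LookBout] = []
    for bout in sorted(bouts, key=lambda b: (b.participant_id, b.start_s)):
        if (
            merged
            and bout.participant_id == merged[-1].participant_id
            and bout.target == merged[-1].target
            and bout.start_s - merged[-1].end_s <= gap_s
        ):
            merged[-1] = replace(merged[-1], end_s=max(merged[-1].end_s, bout.end_s))
        else:
            merged.append(bout)
    return merged


def extract_events(
    bouts: list[LookBout], criteria: EventCriteria = EventCriteria()
) -> list[AttentionEvent]:
    """Select sustained-attention events from merged bouts.

    A merged bout becomes an event when its target is allowed and its
    duration strictly exceeds ``criteria.min_look_s``; the event duration is
    capped at ``criteria.max_block_s``.
    """
    events = []
    for b in bouts:
        if b.target in criteria.allowed_targets and b.duration_s > criteria.min_look_s:
            events.append(
                AttentionEvent(
                    participant_id=b.participant_id,
                    target=b.target,
                    look_onset_s=b.start_s,
                    duration_s=min(b.duration_s, criteria.max_block_s),
                )
            )
    return events


def participant_gate(
    events: list[AttentionEvent], criteria: EventCriteria = EventCriteria()
) -> tuple[set[str], pd.DataFrame]:
    """Apply the minimum-events-per-participant inclusion rule.

    Returns the set of participants with at least
    ``criteria.min_events_per_participant`` events and a per-participant
    report with columns ``participant``, ``n_events``, ``included``.
    """
    counts: dict[str, int] = {}
    for ev in events:
        counts[ev.participant_id] = counts.get(ev.participant_id, 0) + 1
    report = pd.DataFrame(
        [
            (pid, n, n >= criteria.min_events_per_participant)
            for pid, n in sorted(counts.items())
        ],
        columns=["participant", "n_events", "included"],
    )
    kept = set(report.loc[report["included"], "participant"]) if len(report) else set()
    return kept, report
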