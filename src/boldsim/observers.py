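"""Event extraction: per-individual first-passage times and run summaries.

The simulator records two first-passage events per individual while it
steps: the *leave* (departure) time, the first period at the end of whose
decision its position is at least the threshold distance (10 units by
default) from the refuge, and the *arrival* time, the first period at which
it is at least ``d_food`` units out.  Later backward social moves never
rescind either event.  The group's *end time* is the period at which the
last individual arrives.

From a finished :class:`EventLog` the study's two harvesting protocols are
supported: a uniformly chosen focal individual with its six statistics
(:func:`summarize_focal`), or the full per-identity table used by the
variance-partitioning analyses (:func:`full_group_times`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class EventLog:
    """Per-individual event times for one completed simulation."""

    identities: np.ndarray
    speeds: np.ndarray
    leave_time: np.ndarray
    arrival_time: np.ndarray
    end_time: int
    config: object = None
    trajectory: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.identities)

    @property
    def travel_time(self) -> np.ndarray:
        return self.arrival_time - self.leave_time

    def validate(self) -> None:
        """Assert the event-time invariants (leave <= arrival <= end)."""
        if not np.all(self.leave_time >= 0):
            raise AssertionError("unrecorded leave time in a finished log")
        if not np.all(self.leave_time <= self.arrival_time):
            raise AssertionError("leave_time must not exceed arrival_time")
        if int(self.arrival_time.max()) != self.end_time:
            raise AssertionError("end_time must equal the last arrival")


@dataclass(frozen=True)
class FocalSummary:
    """The six per-run statistics harvested from one focal individual."""

    focal_identity: int
    leave_time: int
    leave_latency: int
    arrival_time: int
    arrival_latency: int
    travel_time: int
    end_time: int


def first_passage(trajectory: np.ndarray, boundary: float) -> int:
    """Smallest period index t with position >= boundary.

    ``trajectory`` is one individual's position indexed by period, starting
    at period 0.  A start position already past the boundary gives t = 0;
    later re-crossings are irrelevant (first passage).
    """
    hits = np.nonzero(np.asarray(trajectory) >= boundary)[0]
    if len(hits) == 0:
        raise AssertionError(
            f"trajectory never reaches boundary {boundary!r}; a finished "
            "simulation reaches every boundary <= d_food")
    return int(hits[0])


def summarize_focal(log: EventLog, rng: np.random.Generator) -> FocalSummary:
    """Pick a focal individual uniformly and report its six statistics.

    Latencies are measured from the group's first passage, so the
    group-first individual has latency zero.
    """
    f = int(rng.integers(0, log.n))
    leave = int(log.leave_time[f])
    arrival = int(log.arrival_time[f])
    return FocalSummary(
        focal_identity=int(log.identities[f]),
        leave_time=leave,
        leave_latency=leave - int(log.leave_time.min()),
        arrival_time=arrival,
        arrival_latency=arrival - int(log.arrival_time.min()),
        travel_time=arrival - leave,
        end_time=int(log.end_time),
    )


def full_group_times(log: EventLog) -> pd.DataFrame:
    """Per-identity table of (speed, leave, arrival, travel) for one run."""
    return pd.DataFrame({
        "identity": log.identities,
        "speed": log.speeds,
        "leave_time": log.leave_time,
        "arrival_time": log.arrival_time,
        "travel_time": log.travel_time,
        "end_time": log.end_time,
    })
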