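"""Event-stream preprocessing.

Raw behavioural data come as per-individual sequences of time-stamped events
(proximity contacts, messages, ratings, ...).  The quantity modelled downstream
is the inter-event time (IET): the difference between the starting times of two
consecutive retained events of one individual.  Three cleaning rules are
applied before differencing:

* simultaneous events (same timestamp, e.g. contacts with different partners)
  are aggregated into one event;
* runs of events in consecutive time windows of width equal to the recording
  resolution are treated as a single long event and collapsed to their first
  timestamp, so the minimum IET equals the resolution;
* gaps spanning a day boundary can be excluded, removing overnight IETs that
  are dominated by the circadian rhythm rather than by the process under study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EventSequence",
    "InterEventTimes",
    "events_to_iets",
    "filter_individuals",
    "read_events",
    "read_iets",
    "write_iets",
]

SECONDS_PER_DAY = 86_400.0


@dataclass
class EventSequence:
    """Sorted event start times for one individual.

    Parameters
    ----------
    individual_id:
        Opaque identifier.
    timestamps:
        Event start times, in time units (seconds for most recordings).
        Sorted on construction.
    resolution:
        Smallest possible spacing between distinct events (e.g. 20 s for
        proximity-sensor data); must be positive.
    day_length:
        Duration of one day in the same unit, default 86 400 s.
    day_origin:
        Offset of the first day boundary; day membership of an event at time
        ``t`` is ``floor((t - day_origin) / day_length)``.
    """

    individual_id: str
    timestamps: np.ndarray
    resolution: float = 1.0
    day_length: float = SECONDS_PER_DAY
    day_origin: float = 0.0

    def __post_init__(self) -> None:
        self.timestamps = np.sort(np.asarray(self.timestamps, dtype=float))
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.day_length <= 0:
            raise ValueError("day_length must be positive")

    def __len__(self) -> int:
        return len(self.timestamps)

    def day_index(self, t: np.ndarray | float) -> np.ndarray:
        """Integer day to which time ``t`` belongs."""
        return np.floor((np.asarray(t, dtype=float) - self.day_origin) / self.day_length).astype(
            np.int64
        )


@dataclass
class InterEventTimes:
    """Ordered multiset of strictly positive inter-event times."""

    values: np.ndarray
    unit: str = "seconds"
    individual_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if len(self.values) and np.any(self.values <= 0):
            raise ValueError("inter-event times must be strictly positive")

    @property
    def n(self) -> int:
        return len(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


def events_to_iets(
    events: EventSequence,
    *,
    merge_consecutive: bool = True,
    merge_simultaneous: bool = True,
    exclude_cross_day: bool = False,
) -> InterEventTimes:
    """Convert an event sequence into inter-event times.

    Parameters
    ----------
    events:
        Sorted event start times with resolution / day metadata.
    merge_consecutive:
        Collapse any run of events at spacing exactly equal to the resolution
        (events in consecutive time windows, i.e. one continued activity) to
        its first event.  Guarantees ``min(IET) >= resolution``.
    merge_simultaneous:
        Aggregate events with identical timestamps into one event.
    exclude_cross_day:
        Drop gaps whose two endpoint events fall in different days.

    Returns
    -------
    InterEventTimes
        Differences between starting times of consecutive retained events.
        Empty when fewer than two events are retained.

    Raises
    ------
    ValueError
        If a zero inter-event time survives preprocessing (indicates mis-set
        merge flags: downstream initialisation takes ``log10(tau_min)``).
    """
    t = np.asarray(events.timestamps, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be sorted non-decreasingly")
    if len(t) < 2:
        return InterEventTimes(np.empty(0), individual_id=events.individual_id)

    if merge_simultaneous:
        t = np.unique(t)

    if merge_consecutive:
        # drop an event when it follows its predecessor (in the current list)
        # at spacing exactly one resolution step: it continues the same run
        dt = np.diff(t)
        tol = 1e-9 * events.resolution
        keep = np.concatenate(([True], np.abs(dt - events.resolution) > tol))
        t = t[keep]

    if len(t) < 2:
        return InterEventTimes(np.empty(0), individual_id=events.individual_id)

    gaps = np.diff(t)
    if exclude_cross_day:
        days = events.day_index(t)
        gaps = gaps[days[1:] == days[:-1]]

    if np.any(gaps == 0):
        raise ValueError(
            "zero inter-event time after preprocessing; "
            "enable merge_simultaneous or check the resolution"
        )
    return InterEventTimes(gaps, individual_id=events.individual_id)


def filter_individuals(
    collection: Iterable[InterEventTimes], min_n: int
) -> list[InterEventTimes]:
    """Keep individuals with at least ``min_n`` inter-event times, order preserved."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    return [iets for iets in collection if iets.n >= min_n]


# ---------------------------------------------------------------------------
# plain-text I/O


def read_events(
    path: str | Path,
    *,
    directed: bool = False,
    resolution: float = 1.0,
    day_length: float = SECONDS_PER_DAY,
    day_origin: float = 0.0,
) -> list[EventSequence]:
    """Read `individual_id timestamp [partner_id]` lines into event sequences.

    Whitespace- or comma-delimited; lines starting with ``#`` are ignored.  For
    undirected contacts an event is attributed to both endpoints, so pass the
    file twice with the roles swapped upstream, or list each contact once per
    endpoint; with ``directed=True`` only the first column (the sender) gets
    the event.
    """
    events: dict[str, list[float]] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected `id timestamp [partner]`")
            try:
                ts = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad timestamp {parts[1]!r}") from exc
            events.setdefault(parts[0], []).append(ts)
            if not directed and len(parts) >= 3:
                events.setdefault(parts[2], []).append(ts)
    return [
        EventSequence(
            individual_id=ind,
            timestamps=np.array(ts),
            resolution=resolution,
            day_length=day_length,
            day_origin=day_origin,
        )
        for ind, ts in events.items()
    ]


def read_iets(path: str | Path, unit: str = "seconds") -> InterEventTimes:
    """Read one inter-event time per line (``#`` comments allowed)."""
    values = []
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad value {line!r}") from exc
    return InterEventTimes(np.array(values), unit=unit, individual_id=path.stem)


def write_iets(iets: InterEventTimes, path: str | Path) -> None:
    """Write one inter-event time per line."""
    Path(path).write_text("".join(f"{v:.12g}\n" for v in iets.values))
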