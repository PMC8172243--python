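"""Behavioral scoring: place aversion, closed-loop stimulation, zero-maze metrics.

All scores reduce to dwell-time arithmetic on an occupancy record — the
tracker's output of which zone the animal occupies at each moment:

- CPA score: time in the pruritogen-paired compartment, post-test minus
  pre-test (negative = aversion).
- RTPT: time in the stimulation-paired chamber, plus the closed-loop
  stimulation intervals implied by entries/exits.
- EZM: time in and entries into the open sections.
- Scratching time course: histogram of bout onsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .perievent import BoutTrain

__all__ = [
    "OccupancyRecord",
    "time_in_zone",
    "cpa_score",
    "stimulation_intervals",
    "open_section_metrics",
    "bout_timecourse",
]


@dataclass
class OccupancyRecord:
    """Piecewise-constant zone occupancy covering a whole session.

    Stored as maximal intervals (start, end, zone); consecutive intervals are
    contiguous and alternate zones.  Build from tracker exports with
    :meth:`from_samples` (one zone label per timestamp) or
    :meth:`from_intervals`.
    """

    starts_s: np.ndarray
    ends_s: np.ndarray
    zones: np.ndarray
    zone_set: frozenset = field(default=frozenset())
    session_id: str = ""
    phase: str = "test"

    def __post_init__(self):
        self.starts_s = np.asarray(self.starts_s, dtype=float)
        self.ends_s = np.asarray(self.ends_s, dtype=float)
        self.zones = np.asarray(self.zones, dtype=object)
        if not (len(self.starts_s) == len(self.ends_s) == len(self.zones)):
            raise ConfigurationError("interval arrays must have equal length")
        if len(self.starts_s) == 0:
            raise ConfigurationError("occupancy record is empty")
        if np.any(self.ends_s < self.starts_s):
            raise ConfigurationError("interval end precedes start")
        if not np.allclose(self.starts_s[1:], self.ends_s[:-1]):
            raise ConfigurationError("occupancy intervals must be contiguous")
        if not self.zone_set:
            self.zone_set = frozenset(self.zones.tolist())
        unknown = set(self.zones.tolist()) - set(self.zone_set)
        if unknown:
            raise ConfigurationError(f"zones {sorted(unknown)} not in declared zone set")
        self._merge_consecutive()

    def _merge_consecutive(self):
        keep = np.concatenate([[True], self.zones[1:] != self.zones[:-1]])
        if keep.all():
            return
        idx = np.flatnonzero(keep)
        ends = np.append(self.starts_s[idx[1:]], self.ends_s[-1])
        self.starts_s = self.starts_s[idx]
        self.zones = self.zones[idx]
        self.ends_s = ends

    @classmethod
    def from_intervals(cls, starts, ends, zones, zone_set=None, **kw):
        return cls(
            starts_s=np.asarray(starts, float),
            ends_s=np.asarray(ends, float),
            zones=np.asarray(zones, object),
            zone_set=frozenset(zone_set) if zone_set else frozenset(),
            **kw,
        )

    @classmethod
    def from_samples(cls, times_s, zones, session_end_s=None, zone_set=None, **kw):
        """Per-sample dialect: each label holds from its timestamp to the next.

        The final sample holds until ``session_end_s`` (defaults to the last
        timestamp, i.e. the final sample is instantaneous).
        """
        times = np.asarray(times_s, dtype=float)
        if len(times) == 0:
            raise ConfigurationError("occupancy record is empty")
        if np.any(np.diff(times) < 0):
            raise ConfigurationError("occupancy timestamps must be increasing")
        end = float(session_end_s) if session_end_s is not None else float(times[-1])
        if end < times[-1]:
            raise ConfigurationError("session end precedes last sample")
        return cls.from_intervals(
            times, np.append(times[1:], end), zones, zone_set=zone_set, **kw
        )

    @property
    def duration_s(self) -> float:
        return float(self.ends_s[-1] - self.starts_s[0])

    def durations(self) -> np.ndarray:
        return self.ends_s - self.starts_s

    def debounced(self, min_dwell_s: float) -> "OccupancyRecord":
        """Suppress visits shorter than ``min_dwell_s`` (tracker jitter at
        zone boundaries) by absorbing them into the preceding interval."""
        if min_dwell_s <= 0:
            return self
        starts = list(self.starts_s)
        ends = list(self.ends_s)
        zones = list(self.zones)
        i = 1
        while i < len(starts):
            if ends[i] - starts[i] < min_dwell_s:
                ends[i - 1] = ends[i]
                del starts[i], ends[i], zones[i]
            else:
                i += 1
        return OccupancyRecord.from_intervals(
            starts, ends, zones, zone_set=self.zone_set,
            session_id=self.session_id, phase=self.phase,
        )


def time_in_zone(rec: OccupancyRecord, zone) -> float:
    """Total dwell time (s) in ``zone``; summing over all zones gives the
    session duration exactly."""
    if zone not in rec.zone_set:
        raise ConfigurationError(f"zone {zone!r} not in declared set {sorted(rec.zone_set)}")
    return float(rec.durations()[rec.zones == zone].sum())


def cpa_score(pre: OccupancyRecord, post: OccupancyRecord, paired_zone) -> float:
    """Conditioned-place-aversion score: time in the paired compartment,
    post-test minus pre-test (seconds; negative indicates aversion)."""
    if paired_zone not in pre.zone_set or paired_zone not in post.zone_set:
        raise ConfigurationError(
            f"paired zone {paired_zone!r} must be declared in both phases"
        )
    return time_in_zone(post, paired_zone) - time_in_zone(pre, paired_zone)


def stimulation_intervals(rec: OccupancyRecord, stim_zone) -> list[tuple[float, float]]:
    """Closed-loop photostimulation intervals: stimulation starts on entry
    into ``stim_zone`` and stops on exit, so the intervals are exactly the
    maximal occupancy intervals of that zone."""
    if stim_zone not in rec.zone_set:
        raise ConfigurationError(f"zone {stim_zone!r} not in declared set")
    sel = rec.zones == stim_zone
    return list(zip(rec.starts_s[sel].tolist(), rec.ends_s[sel].tolist()))


def open_section_metrics(
    rec: OccupancyRecord, open_zones
) -> tuple[float, float, int]:
    """Elevated-zero-maze scores: (open time s, open fraction, entry count).

    An entry is a transition from a closed zone into an open zone; starting
    the session in an open zone does not count as an entry.
    """
    open_zones = set(open_zones)
    if not open_zones <= set(rec.zone_set):
        raise ConfigurationError("open zones must be a subset of the declared zone set")
    is_open = np.array([z in open_zones for z in rec.zones])
    open_time = float(rec.durations()[is_open].sum())
    entries = int(np.sum(is_open[1:] & ~is_open[:-1]))
    return open_time, open_time / rec.duration_s, entries


def bout_timecourse(
    bouts: BoutTrain, bin_s: float, duration_s: float | None = None
) -> np.ndarray:
    """Histogram of bout onsets in bins of ``bin_s`` seconds; counts sum to
    the number of bouts."""
    if bin_s <= 0:
        raise ConfigurationError("bin width must be positive")
    if duration_s is None:
        duration_s = bouts.session_duration_s
    n_bins = max(1, int(np.ceil(duration_s / bin_s)))
    counts, _ = np.histogram(
        bouts.bout_onsets_s, bins=n_bins, range=(0.0, n_bins * bin_s)
    )
    return counts
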