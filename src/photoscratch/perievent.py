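"""Bout segmentation and peri-event analysis of the dF/F trace.

Scratching is scored as discrete event timestamps; events falling within a
30-s window of each other are combined into a single bout, and the calcium
trace is aligned to bout onsets (time zero) to build a trials × time matrix,
its z-scored version, the averaged trace ± SEM, and the pre- vs post-onset
comparison summarized with a pooled-variance two-sample t test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy import stats as spstats

from .errors import ConfigurationError, EmptyResultError, ZeroVarianceError

logger = logging.getLogger(__name__)


@dataclass
class EventTrain:
    """Scored behavioral event onsets (seconds from recording start)."""

    onsets_s: np.ndarray
    session_duration_s: float
    durations_s: np.ndarray | None = None

    def __post_init__(self):
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if self.durations_s is not None:
            self.durations_s = np.asarray(self.durations_s, dtype=float)
            if len(self.durations_s) != len(self.onsets_s):
                raise ConfigurationError("durations length must match onsets")
            if np.any(self.durations_s < 0):
                raise ConfigurationError("durations must be nonnegative")
        if self.session_duration_s <= 0:
            raise ConfigurationError("session_duration_s must be positive")
        if len(self.onsets_s):
            if np.any(np.diff(self.onsets_s) <= 0):
                raise ConfigurationError("event onsets must be strictly increasing")
            if self.onsets_s[0] < 0 or self.onsets_s[-1] > self.session_duration_s:
                raise ConfigurationError("event onsets must lie within the session")

    def __len__(self) -> int:
        return len(self.onsets_s)


@dataclass
class BoutTrain:
    """Merged scratching bouts: onset, offset and member-event count per bout."""

    bout_onsets_s: np.ndarray
    bout_offsets_s: np.ndarray
    events_per_bout: np.ndarray
    merge_window_s: float
    session_duration_s: float

    def __post_init__(self):
        self.bout_onsets_s = np.asarray(self.bout_onsets_s, dtype=float)
        self.bout_offsets_s = np.asarray(self.bout_offsets_s, dtype=float)
        self.events_per_bout = np.asarray(self.events_per_bout, dtype=int)
        if np.any(self.bout_offsets_s < self.bout_onsets_s):
            raise ConfigurationError("bout offset precedes onset")

    def __len__(self) -> int:
        return len(self.bout_onsets_s)

    @property
    def n_events(self) -> int:
        return int(self.events_per_bout.sum())


def merge_bouts(
    events: EventTrain, window_s: float = 30.0, gap_mode: str = "onset-to-onset"
) -> BoutTrain:
    """Combine events closer than ``window_s`` into single bouts.

    Successive events whose gap is ≤ ``window_s`` belong to the same bout.
    The gap is measured onset-to-onset by default; ``gap_mode="offset-to-onset"``
    measures from the previous event's offset (onset + duration) instead.
    Bout onset is the first member's onset; bout offset is the last member's
    onset plus its duration when durations are given.
    """
    if window_s < 0:
        raise ConfigurationError("merge window must be nonnegative")
    if gap_mode not in ("onset-to-onset", "offset-to-onset"):
        raise ConfigurationError(f"unknown gap_mode {gap_mode!r}")
    onsets = events.onsets_s
    durs = events.durations_s
    if durs is None:
        durs = np.zeros(len(onsets))
    if gap_mode == "offset-to-onset":
        anchors = onsets + durs
    else:
        anchors = onsets

    bout_on, bout_off, counts = [], [], []
    for i, t in enumerate(onsets):
        if i == 0 or t - anchors[i - 1] > window_s:
            bout_on.append(t)
            bout_off.append(t + durs[i])
            counts.append(1)
        else:
            bout_off[-1] = t + durs[i]
            counts[-1] += 1
    return BoutTrain(
        bout_onsets_s=np.array(bout_on),
        bout_offsets_s=np.array(bout_off),
        events_per_bout=np.array(counts, dtype=int),
        merge_window_s=window_s,
        session_duration_s=events.session_duration_s,
    )


@dataclass
class PeriEventMatrix:
    """Trials × time-bins array aligned to bout onsets (time zero at onset)."""

    values: np.ndarray
    pre_s: float
    post_s: float
    bin_s: float
    units: str = "dff"
    onsets_s: np.ndarray | None = None
    excluded_trials: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.onsets_s is not None:
            self.onsets_s = np.asarray(self.onsets_s, dtype=float)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def bin_times(self) -> np.ndarray:
        """Bin-center times relative to bout onset."""
        return -self.pre_s + (np.arange(self.n_bins) + 0.5) * self.bin_s

    def window_columns(self, start_s: float, end_s: float) -> np.ndarray:
        """Column indices whose bin centers fall in [start_s, end_s)."""
        t = self.bin_times()
        cols = np.flatnonzero((t >= start_s) & (t < end_s))
        if len(cols) == 0:
            raise ConfigurationError(
                f"window [{start_s}, {end_s}) s contains no bins of the matrix span "
                f"[{-self.pre_s}, {self.post_s}) s"
            )
        return cols


def _trace_arrays(trace):
    """Values, mask and time base from either a ChannelTrace or a CorrectedTrace."""
    values = trace.dff if hasattr(trace, "dff") else trace.values
    rate = getattr(trace, "source_rate_hz", None) or trace.sample_rate_hz
    mask = trace.settling_mask
    t0 = getattr(trace, "t0_s", 0.0)
    return np.asarray(values, float), np.asarray(mask, bool), float(rate), float(t0)


def build_perievent_matrix(
    trace,
    bouts: BoutTrain,
    pre_s: float,
    post_s: float,
    bin_s: float | None = None,
) -> PeriEventMatrix:
    """Extract one row per bout onset whose full window fits in the unmasked trace.

    Rows are resampled (linear interpolation) onto a common bin-center grid
    spanning ``[-pre_s, +post_s)``.  Onsets whose window would cross a masked
    or out-of-range region are excluded and listed with a reason; if nothing
    is retained an EmptyResultError is raised.
    """
    if pre_s <= 0 or post_s <= 0:
        raise ConfigurationError("pre_s and post_s must be positive")
    values, mask, rate, t0 = _trace_arrays(trace)
    if bin_s is None:
        bin_s = 1.0 / rate
    n_bins = int(round((pre_s + post_s) / bin_s))
    rel_centers = -pre_s + (np.arange(n_bins) + 0.5) * bin_s

    times = t0 + np.arange(len(values)) / rate
    ok = ~mask
    if not ok.any():
        raise EmptyResultError("trace is entirely masked")
    valid_start = times[ok][0]
    valid_end = times[ok][-1]

    rows, kept_onsets, excluded = [], [], []
    for i, onset in enumerate(bouts.bout_onsets_s):
        lo, hi = onset - pre_s, onset + post_s
        if lo < valid_start or hi > valid_end:
            excluded.append((i, "window exceeds recording"))
            continue
        seg = np.flatnonzero((times >= lo) & (times <= hi))
        if mask[seg].any():
            excluded.append((i, "window overlaps masked samples"))
            continue
        rows.append(np.interp(onset + rel_centers, times, values))
        kept_onsets.append(onset)
    if not rows:
        raise EmptyResultError(
            f"no retainable trials: all {len(bouts)} bout windows fall outside the "
            f"unmasked trace"
        )
    return PeriEventMatrix(
        values=np.vstack(rows),
        pre_s=pre_s,
        post_s=post_s,
        bin_s=bin_s,
        units="dff",
        onsets_s=np.array(kept_onsets),
        excluded_trials=excluded,
    )


def zscore_matrix(
    m: PeriEventMatrix,
    reference: str = "trial",
    session_trace=None,
    baseline_window_s: tuple[float, float] | None = None,
) -> PeriEventMatrix:
    """Standardize the matrix: z = (x − μ_ref) / σ_ref, sample (n−1) convention.

    ``reference`` selects where μ and σ come from:

    - ``"trial"`` — each trial's own full peri-event window (default);
    - ``"trial_baseline"`` — each trial's pre-onset baseline window
      (``baseline_window_s``, default the whole pre period);
    - ``"session"`` — the unmasked samples of ``session_trace``.
    """
    if reference == "session":
        if session_trace is None:
            raise ConfigurationError("session reference requires session_trace")
        values, mask, _, _ = _trace_arrays(session_trace)
        ref = values[~mask]
        mu = np.full(m.n_trials, np.mean(ref))
        sd = np.full(m.n_trials, np.std(ref, ddof=1))
    elif reference in ("trial", "trial_baseline"):
        if reference == "trial_baseline":
            win = baseline_window_s or (-m.pre_s, 0.0)
            cols = m.window_columns(*win)
            ref = m.values[:, cols]
        else:
            ref = m.values
        mu = ref.mean(axis=1)
        sd = ref.std(axis=1, ddof=1)
    else:
        raise ConfigurationError(f"unknown z-score reference {reference!r}")

    bad = np.flatnonzero(sd == 0)
    if len(bad):
        raise ZeroVarianceError(f"zero-variance z-score reference for trial(s) {bad.tolist()}")
    z = (m.values - mu[:, None]) / sd[:, None]
    return replace(m, values=z, units="zscore")


def perievent_average(m: PeriEventMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise mean and standard error of the mean across trials."""
    if m.n_trials == 0:
        raise EmptyResultError("cannot average an empty peri-event matrix")
    mean = m.values.mean(axis=0)
    if m.n_trials == 1:
        logger.info("single retained trial: SEM reported as 0 by convention")
        return mean, np.zeros_like(mean)
    sem = m.values.std(axis=0, ddof=1) / np.sqrt(m.n_trials)
    return mean, sem


def pre_post_change(
    m: PeriEventMatrix,
    pre_window_s: tuple[float, float] = (-5.0, 0.0),
    post_window_s: tuple[float, float] = (0.0, 5.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial mean signal in the pre- and post-onset windows.

    Returned as two groups (pre means, post means) for an unpaired
    comparison of group means.
    """
    pre_cols = m.window_columns(*pre_window_s)
    post_cols = m.window_columns(*post_window_s)
    return m.values[:, pre_cols].mean(axis=1), m.values[:, post_cols].mean(axis=1)


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


def ttest_two_sample(x, y, equal_var: bool = True) -> TTestResult:
    """Two-sample t test; pooled variance (df = n1 + n2 − 2) by default.

    With ``equal_var=False`` the Welch statistic and Welch–Satterthwaite
    degrees of freedom are used.  Two-sided p value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ConfigurationError("each group needs at least 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ConfigurationError("t test inputs must be finite")
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if equal_var:
        df = n1 + n2 - 2
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    else:
        se2 = v1 / n1 + v2 / n2
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        se = np.sqrt(se2)
    if se == 0:
        t_stat = 0.0
    else:
        t_stat = (x.mean() - y.mean()) / se
    p = 2.0 * spstats.t.sf(abs(t_stat), df)
    return TTestResult(t=float(t_stat), df=float(df), p=float(p))
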