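"""Ground-truthed synthetic photometry sessions, event trains, occupancy and cell tables.

No raw recordings are distributed with studies of this kind, so every
downstream stage is exercised against a forward model of the rig instead:

- scratching events arrive as a Poisson cluster (Neyman–Scott) process —
  cluster centers are homogeneous Poisson, each spawning a burst of events
  with exponential intra-burst gaps, emulating scratching trains;
- each channel's fluorescence envelope is an exponentially bleaching
  baseline; the calcium channel additionally carries difference-of-
  exponentials transients (GCaMP6s-like kinetics) time-locked, with jitter,
  to bout onsets; both channels share a low-frequency motion artifact with
  per-channel gain;
- the photoreceiver voltage is the sum of the envelopes modulated on their
  LED carriers (raised sinusoid drive) plus white sensor noise.

Every generator is a pure function of its configuration and seed, and the
latent components are returned as :class:`GroundTruth` for parameter-recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

from .behavior import OccupancyRecord
from .coloc import CellTable
from .correct import CorrectedTrace
from .demod import ChannelTrace, ModulatedRecording
from .errors import ConfigurationError
from .perievent import EventTrain, merge_bouts

#: internal sample rate (Hz) at which the motion Gaussian process is generated
_MOTION_RATE_HZ = 50.0


@dataclass(frozen=True)
class SimConfig:
    """Forward-model parameters for one synthetic photometry session.

    Defaults describe a 10-min head-fixed-style session on the reference
    rig: 10 kHz acquisition, 405 nm excitation modulated at 211 Hz and
    470 nm at 537 Hz, slow photobleaching, calcium transients of fractional
    amplitude 0.2 over baseline with GCaMP6s-like kinetics, a shared <2 Hz
    motion artifact whose per-channel gain scales with the channel baseline
    (a multiplicative optical-path artifact), and additive sensor noise.
    """

    seed: int = 0
    duration_s: float = 600.0
    sample_rate_hz: float = 10_000.0
    carrier_map: Mapping[int, float] = field(
        default_factory=lambda: {405: 211.0, 470: 537.0}
    )
    bleach_tau_s: Mapping[int, float] = field(
        default_factory=lambda: {405: 2400.0, 470: 2400.0}
    )
    baseline_level: Mapping[int, float] = field(
        default_factory=lambda: {405: 1.0, 470: 2.0}
    )
    transient_amplitude: float = 0.2
    transient_rise_s: float = 0.2
    transient_decay_s: float = 1.5
    transient_jitter_s: float = 0.05
    event_rate_hz: float = 0.01  # cluster centers per second
    events_per_cluster: float = 4.0
    intra_cluster_gap_s: float = 2.0
    motion_gain: Mapping[int, float] = field(
        default_factory=lambda: {405: 0.06, 470: 0.12}
    )
    motion_cutoff_hz: float = 2.0
    noise_sd: float = 0.005
    waveform: str = "sine"  # or "square"

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample_rate_hz must be positive")
        for name in ("event_rate_hz", "events_per_cluster", "intra_cluster_gap_s",
                     "transient_rise_s", "transient_decay_s"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.noise_sd < 0 or self.transient_jitter_s < 0:
            raise ConfigurationError("noise_sd and jitter must be nonnegative")
        if self.waveform not in ("sine", "square"):
            raise ConfigurationError(f"unknown waveform {self.waveform!r}")
        nyq = self.sample_rate_hz / 2.0
        carriers = list(self.carrier_map.values())
        if len(set(carriers)) != len(carriers):
            raise ConfigurationError("carrier frequencies must be distinct")
        for wl, f in self.carrier_map.items():
            if not 0 < f < nyq:
                raise ConfigurationError(
                    f"carrier {f} Hz ({wl} nm) must lie strictly below Nyquist {nyq} Hz"
                )
            if wl not in self.baseline_level or wl not in self.bleach_tau_s:
                raise ConfigurationError(f"missing baseline/bleach parameters for {wl} nm")


@dataclass
class GroundTruth:
    """Latent components of a simulated session, for parameter-recovery tests."""

    event_times: np.ndarray
    transient_times: np.ndarray
    transient_amplitudes: np.ndarray
    motion_trace: np.ndarray  # unit variance, at sample_rate_hz
    bleach_params: dict[int, tuple[float, float]]  # wavelength → (level, tau)
    envelopes: dict[int, np.ndarray]  # wavelength → noiseless envelope at sample_rate_hz
    sample_rate_hz: float

    def channel_traces(self, out_rate_hz: float = 100.0) -> dict[int, ChannelTrace]:
        """Noiseless envelopes decimated to ``out_rate_hz`` as ChannelTraces.

        These are what a perfect demodulator would return; useful for testing
        the correction stage in isolation.
        """
        step = max(1, int(round(self.sample_rate_hz / out_rate_hz)))
        out = {}
        for wl, env in self.envelopes.items():
            vals = env[::step]
            out[wl] = ChannelTrace(
                values=vals,
                sample_rate_hz=self.sample_rate_hz / step,
                wavelength_nm=wl,
                source_mean=float(vals.mean()),
            )
        return out

    def motion_at(self, out_rate_hz: float = 100.0) -> np.ndarray:
        step = max(1, int(round(self.sample_rate_hz / out_rate_hz)))
        return self.motion_trace[::step]


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_event_clusters(config: SimConfig) -> tuple[np.ndarray, EventTrain]:
    """Like :func:`simulate_events` but also returns the latent cluster centers."""
    rng_centers, rng_counts, rng_gaps = _streams(config.seed, 3)
    n_centers = rng_centers.poisson(config.event_rate_hz * config.duration_s)
    centers = np.sort(rng_centers.uniform(0.0, config.duration_s, size=n_centers))
    onsets = []
    for c in centers:
        n_ev = 1 + rng_counts.poisson(max(config.events_per_cluster - 1.0, 0.0))
        gaps = rng_gaps.exponential(config.intra_cluster_gap_s, size=n_ev - 1)
        times = c + np.concatenate([[0.0], np.cumsum(gaps)])
        onsets.extend(times[times <= config.duration_s])
    onsets = np.unique(np.asarray(onsets, dtype=float))
    return centers, EventTrain(onsets_s=onsets, session_duration_s=config.duration_s)


def simulate_events(config: SimConfig) -> EventTrain:
    """Draw a clustered scratching-event train (Neyman–Scott process).

    Cluster centers are a homogeneous Poisson process of rate
    ``event_rate_hz``; each center spawns ``1 + Poisson(events_per_cluster − 1)``
    events separated by exponential gaps of mean ``intra_cluster_gap_s``.
    """
    return simulate_event_clusters(config)[1]


def transient_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Difference-of-exponentials calcium kernel, peak-normalized to 1, zero for t < 0."""
    if decay_s <= rise_s:
        raise ConfigurationError("decay must exceed rise time")
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay_s) - np.exp(-np.maximum(t, 0) / rise_s), 0.0)
    t_peak = np.log(decay_s / rise_s) * rise_s * decay_s / (decay_s - rise_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    return k / peak


def _motion_process(rng: np.random.Generator, duration_s: float, cutoff_hz: float,
                    t_out: np.ndarray) -> np.ndarray:
    """Unit-variance low-frequency (< cutoff) Gaussian-process motion trace."""
    n = int(np.ceil(duration_s * _MOTION_RATE_HZ)) + 1
    white = rng.standard_normal(n)
    sos = sps.butter(2, cutoff_hz / (_MOTION_RATE_HZ / 2.0), btype="low", output="sos")
    slow = sps.sosfiltfilt(sos, white)
    slow = (slow - slow.mean()) / slow.std()
    t_src = np.arange(n) / _MOTION_RATE_HZ
    return np.interp(t_out, t_src, slow)


def simulate_session(
    config: SimConfig, events: EventTrain | None = None
) -> tuple[ModulatedRecording, GroundTruth]:
    """Forward-model one session: raw photoreceiver voltage plus ground truth.

    ``raw(t) = Σ_c envelope_c(t)·(1 + sin(2π f_c t))/2 + noise``, with one
    calcium transient triggered (with jitter) at each scratching-bout onset.
    """
    if events is None:
        events = simulate_events(config)
    rng_motion, rng_noise, rng_jitter = _streams(config.seed + 1, 3)

    n = int(round(config.duration_s * config.sample_rate_hz))
    t = np.arange(n) / config.sample_rate_hz

    motion = _motion_process(rng_motion, config.duration_s, config.motion_cutoff_hz, t)

    # one transient per scratching bout (30-s merge of the event train)
    bouts = merge_bouts(events, window_s=30.0)
    transient_times = bouts.bout_onsets_s + rng_jitter.normal(
        0.0, config.transient_jitter_s, size=len(bouts)
    )
    transient_times = np.sort(np.clip(transient_times, 0.0, config.duration_s))
    amplitudes = np.full(len(transient_times), config.transient_amplitude)

    transient_sum = np.zeros(n)
    if config.transient_amplitude > 0 and len(transient_times):
        span = int((config.transient_rise_s + 10 * config.transient_decay_s)
                   * config.sample_rate_hz)
        for t_i, a_i in zip(transient_times, amplitudes):
            i0 = int(np.ceil(t_i * config.sample_rate_hz))
            i1 = min(i0 + span, n)
            if i0 >= n:
                continue
            transient_sum[i0:i1] += a_i * transient_kernel(
                t[i0:i1] - t_i, config.transient_rise_s, config.transient_decay_s
            )

    envelopes: dict[int, np.ndarray] = {}
    bleach_params: dict[int, tuple[float, float]] = {}
    for wl in config.carrier_map:
        level = config.baseline_level[wl]
        tau = config.bleach_tau_s[wl]
        bleach = level * np.exp(-t / tau)
        env = bleach.copy()
        if wl == 470:
            env *= 1.0 + transient_sum
        env += config.motion_gain.get(wl, 0.0) * motion
        if np.min(env) <= 0:
            raise ConfigurationError(
                f"envelope for {wl} nm is not strictly positive; reduce motion_gain"
            )
        envelopes[wl] = env
        bleach_params[wl] = (level, tau)

    raw = np.zeros(n)
    for wl, f_c in config.carrier_map.items():
        phase = 2.0 * np.pi * f_c * t
        carrier = np.sin(phase) if config.waveform == "sine" else np.sign(np.sin(phase))
        raw += envelopes[wl] * (1.0 + carrier) / 2.0
    if config.noise_sd > 0:
        raw += rng_noise.normal(0.0, config.noise_sd, size=n)

    rec = ModulatedRecording(
        samples=raw, sample_rate_hz=config.sample_rate_hz,
        carrier_map=dict(config.carrier_map),
    )
    truth = GroundTruth(
        event_times=events.onsets_s.copy(),
        transient_times=transient_times,
        transient_amplitudes=amplitudes,
        motion_trace=motion,
        bleach_params=bleach_params,
        envelopes=envelopes,
        sample_rate_hz=config.sample_rate_hz,
    )
    return rec, truth


def simulate_occupancy(
    seed: int,
    duration_s: float,
    zones: list,
    transition_rate_hz: float = 0.05,
    bias: Mapping | None = None,
) -> OccupancyRecord:
    """Markov zone-occupancy record whose long-run fractions follow ``bias``.

    At exponential waiting times (rate ``transition_rate_hz``) the subject
    redraws its zone from the normalized bias weights, so the stationary
    occupancy fraction of each zone equals its normalized weight.
    """
    if not zones:
        raise ConfigurationError("need at least one zone")
    if duration_s <= 0:
        raise ConfigurationError("duration_s must be positive")
    weights = np.array([1.0 if bias is None else bias.get(z, 0.0) for z in zones], float)
    if np.any(weights < 0) or weights.sum() == 0:
        raise ConfigurationError("zone weights must be nonnegative and not all zero")
    p = weights / weights.sum()
    rng = np.random.default_rng(seed)

    starts, labels = [0.0], [zones[rng.choice(len(zones), p=p)]]
    t_now = 0.0
    while True:
        if transition_rate_hz <= 0:
            break
        t_now += rng.exponential(1.0 / transition_rate_hz)
        if t_now >= duration_s:
            break
        starts.append(t_now)
        labels.append(zones[rng.choice(len(zones), p=p)])
    ends = starts[1:] + [duration_s]
    return OccupancyRecord.from_intervals(starts, ends, labels, zone_set=zones)


def simulate_cell_table(
    seed: int,
    n_cells: int,
    pos_fraction: float,
    puncta_mean_pos: float = 20.0,
    puncta_mean_neg: float = 0.5,
    channels: tuple[str, ...] = ("Fos",),
    section_id: str = "s1",
) -> tuple[CellTable, pd.DataFrame]:
    """Two-component Poisson-mixture puncta counts with latent positivity truth.

    Each cell is latently positive for each channel with probability
    ``pos_fraction``; counts are Poisson with mean ``puncta_mean_pos`` or
    ``puncta_mean_neg``.  Returns the table and a same-shape truth frame of
    latent labels.
    """
    if not 0.0 <= pos_fraction <= 1.0:
        raise ConfigurationError("pos_fraction must lie in [0, 1]")
    if puncta_mean_pos < 0 or puncta_mean_neg < 0:
        raise ConfigurationError("puncta means must be nonnegative")
    rng = np.random.default_rng(seed)
    data = {"cell_id": [f"c{i:05d}" for i in range(n_cells)],
            "section_id": [section_id] * n_cells}
    truth = {}
    for ch in channels:
        latent = rng.random(n_cells) < pos_fraction
        means = np.where(latent, puncta_mean_pos, puncta_mean_neg)
        data[f"{ch}_puncta"] = rng.poisson(means) if n_cells else np.array([], dtype=int)
        truth[ch] = latent
    return CellTable(data=pd.DataFrame(data)), pd.DataFrame(truth)


def simulate_dff_trace(
    seed: int,
    duration_s: float,
    sample_rate_hz: float = 100.0,
    onsets_s=(),
    amplitude: float = 0.0,
    rise_s: float = 0.2,
    decay_s: float = 1.5,
    noise_sd: float = 0.02,
    noise_bandwidth_hz: float = 4.0,
    baseline: float = 1.0,
) -> CorrectedTrace:
    """Desk-scale generator of a pipeline-output-like dF/F trace.

    Emulates the statistical structure of the corrected trace directly —
    baseline plus transients plus Gaussian noise band-limited to the
    pipeline's 4 Hz output bandwidth with standard deviation ``noise_sd``
    (dF/F units) — without simulating the 10 kHz front end.  Used for
    statistical-calibration studies where thousands of replicates are needed.
    """
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    rng = np.random.default_rng(seed)
    values = np.full(n, float(baseline))
    for onset in onsets_s:
        i0 = int(np.ceil(onset * sample_rate_hz))
        if i0 >= n:
            continue
        values[i0:] += amplitude * transient_kernel(t[i0:] - onset, rise_s, decay_s)
    if noise_sd > 0:
        white = rng.standard_normal(n)
        sos = sps.butter(2, noise_bandwidth_hz / (sample_rate_hz / 2.0),
                         btype="low", output="sos")
        colored = sps.sosfiltfilt(sos, white)
        values = values + noise_sd * (colored - colored.mean()) / colored.std()
    return CorrectedTrace(
        dff=values, mean_corrected=float(baseline), fit=None,
        source_rate_hz=sample_rate_hz, mode="synthetic",
    )
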