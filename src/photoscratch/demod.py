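"""Lock-in demodulation of frequency-multiplexed photometry recordings.

A single photoreceiver voltage carries two LED excitation channels, each
modulated at its own carrier frequency (405 nm and 470 nm excitation,
carriers well below Nyquist of the 10 kHz acquisition).  Quadrature lock-in
demodulation — multiply by sine and cosine references at the carrier, low-pass
both products, take the magnitude — recovers each channel's slowly varying
fluorescence envelope regardless of carrier phase.

The drive waveform is modeled as a raised sinusoid, ``E(t) * (1 + sin(2πf t)) / 2``,
so the demodulated magnitude is multiplied by 4 to return ``E(t)`` directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

#: number of filter time constants (1/cutoff) masked at each trace edge
SETTLING_TIME_CONSTANTS = 3.0


@dataclass
class ModulatedRecording:
    """Raw photoreceiver samples with carrier metadata.

    Parameters
    ----------
    samples : ndarray
        Photoreceiver voltage, uniformly sampled.
    sample_rate_hz : float
        Acquisition rate (10 kHz in the reference rig).
    carrier_map : dict
        Excitation wavelength (nm) → carrier frequency (Hz).
    t0_s : float
        Time of the first sample.
    """

    samples: np.ndarray
    sample_rate_hz: float
    carrier_map: dict[int, float] = field(default_factory=lambda: {405: 211.0, 470: 537.0})
    t0_s: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ConfigurationError("recording samples must be one-dimensional")
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample_rate_hz must be positive")
        nyq = self.sample_rate_hz / 2.0
        carriers = list(self.carrier_map.values())
        if len(set(carriers)) != len(carriers):
            raise ConfigurationError("carrier frequencies must be distinct")
        for wl, f in self.carrier_map.items():
            if not 0 < f < nyq:
                raise ConfigurationError(
                    f"carrier {f} Hz for {wl} nm must lie in (0, Nyquist={nyq} Hz)"
                )

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.samples)) / self.sample_rate_hz


@dataclass
class ChannelTrace:
    """Per-wavelength demodulated fluorescence envelope on a uniform time base."""

    values: np.ndarray
    sample_rate_hz: float
    wavelength_nm: int | None = None
    lowpass_hz: float | None = None
    settling_mask: np.ndarray | None = None
    t0_s: float = 0.0
    #: session mean of the raw (uncorrected) signal; carried through
    #: motion correction so the dF/F guard has a reference scale.
    source_mean: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.settling_mask is None:
            self.settling_mask = np.zeros(len(self.values), dtype=bool)
        else:
            self.settling_mask = np.asarray(self.settling_mask, dtype=bool)
        if len(self.settling_mask) != len(self.values):
            raise ConfigurationError("settling_mask length must match values")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("trace values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.values)) / self.sample_rate_hz

    @property
    def unmasked(self) -> np.ndarray:
        return self.values[~self.settling_mask]


def _lowpass_sos(cutoff_hz: float, sample_rate_hz: float, order: int):
    nyq = sample_rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ConfigurationError(f"low-pass cutoff {cutoff_hz} Hz ≥ Nyquist {nyq} Hz")
    return sps.butter(order, cutoff_hz / nyq, btype="low", output="sos")


def _settling_mask(n: int, cutoff_hz: float, sample_rate_hz: float,
                   order: int = 4) -> np.ndarray:
    # effective time constant of the zero-phase filter grows with order
    tau_s = (order / 2.0) / cutoff_hz
    n_settle = int(np.ceil(SETTLING_TIME_CONSTANTS * tau_s * sample_rate_hz))
    mask = np.zeros(n, dtype=bool)
    if n_settle > 0:
        mask[:n_settle] = True
        mask[n - n_settle:] = True
    return mask


def lockin_demodulate(
    rec: ModulatedRecording,
    carrier_hz: float,
    lowpass_hz: float = 4.0,
    out_rate_hz: float = 100.0,
    order: int = 4,
    wavelength_nm: int | None = None,
) -> ChannelTrace:
    """Recover one channel's envelope by quadrature lock-in demodulation.

    The raw signal is mixed with sine and cosine references at ``carrier_hz``,
    both products are zero-phase low-pass filtered at ``lowpass_hz``, and the
    magnitude is scaled by 4 so a raised-sinusoid drive ``E(t)·(1+sin)/2``
    returns ``E(t)``.  The filtered envelope is then decimated to
    ``out_rate_hz``; because the content is already band-limited to
    ``lowpass_hz`` the decimation is alias-free.
    """
    nyq = rec.sample_rate_hz / 2.0
    if carrier_hz >= nyq:
        raise ConfigurationError(f"carrier {carrier_hz} Hz ≥ Nyquist {nyq} Hz")
    others = [f for f in rec.carrier_map.values() if f != carrier_hz]
    if others:
        min_sep = min(abs(f - carrier_hz) for f in others)
        if lowpass_hz > min_sep / 4:
            logger.warning(
                "low-pass cutoff %.3g Hz is close to the carrier separation %.3g Hz; "
                "cross-channel leakage may be elevated", lowpass_hz, min_sep,
            )
    if wavelength_nm is None:
        for wl, f in rec.carrier_map.items():
            if f == carrier_hz:
                wavelength_nm = wl
                break

    t = rec.times()
    phase = 2.0 * np.pi * carrier_hz * t
    sos = _lowpass_sos(lowpass_hz, rec.sample_rate_hz, order)
    i_comp = sps.sosfiltfilt(sos, rec.samples * np.sin(phase))
    q_comp = sps.sosfiltfilt(sos, rec.samples * np.cos(phase))
    envelope = 4.0 * np.hypot(i_comp, q_comp)

    step = max(1, int(round(rec.sample_rate_hz / out_rate_hz)))
    actual_rate = rec.sample_rate_hz / step
    envelope = envelope[::step]
    mask = _settling_mask(len(envelope), lowpass_hz, actual_rate, order)
    return ChannelTrace(
        values=envelope,
        sample_rate_hz=actual_rate,
        wavelength_nm=wavelength_nm,
        lowpass_hz=lowpass_hz,
        settling_mask=mask,
        t0_s=rec.t0_s,
        source_mean=float(np.mean(envelope[~mask])) if (~mask).any() else None,
    )


def demodulate_recording(
    rec: ModulatedRecording,
    lowpass_hz: float = 4.0,
    out_rate_hz: float = 100.0,
    order: int = 4,
) -> dict[int, ChannelTrace]:
    """Demodulate every channel declared in the recording's carrier map."""
    return {
        wl: lockin_demodulate(
            rec, f, lowpass_hz=lowpass_hz, out_rate_hz=out_rate_hz,
            order=order, wavelength_nm=wl,
        )
        for wl, f in rec.carrier_map.items()
    }


def lowpass(trace: ChannelTrace, cutoff_hz: float = 4.0, order: int = 4) -> ChannelTrace:
    """Zero-phase low-pass filter a trace (unit DC gain, no phase delay)."""
    sos = _lowpass_sos(cutoff_hz, trace.sample_rate_hz, order)
    filtered = sps.sosfiltfilt(sos, trace.values)
    mask = trace.settling_mask | _settling_mask(
        len(filtered), cutoff_hz, trace.sample_rate_hz, order)
    return replace(trace, values=filtered, lowpass_hz=cutoff_hz, settling_mask=mask)
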