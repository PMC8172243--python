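"""Isosbestic motion correction and dF/F normalization.

The 405 nm excitation channel is calcium-insensitive (isosbestic for GCaMP),
so fluctuations it shares with the 470 nm channel reflect motion, fiber
bending and hemodynamic artifacts rather than neural activity.  The control
channel is scaled to fit the signal channel over the whole session
(ordinary least squares), the scaled control is subtracted, and the result
is normalized to dF/F.

Two dF/F conventions are provided:

``session-mean``
    dF/F = corrected / mean(corrected), i.e. the subtracted signal divided by
    its own session mean.  Only well-posed when the corrected trace retains a
    positive baseline.  An affine OLS fit has exactly zero-mean
    residuals, so under the default affine scaling this divisor degenerates;
    a guard raises :class:`~photoscratch.errors.DegenerateBaselineError`
    naming the remedy.

``fitted-control``
    dF/F = (signal − fitted_control) / fitted_control, the widespread
    convention for isosbestic-corrected photometry.  Well-posed whenever the
    fitted control is positive, hence the pipeline default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .demod import ChannelTrace
from .errors import DegenerateBaselineError, DegenerateFitError

__all__ = [
    "ScalingFit",
    "CorrectedTrace",
    "fit_isosbestic",
    "motion_correct",
    "compute_dff",
    "compute_dff_fitted_control",
    "correct_session",
]


@dataclass(frozen=True)
class ScalingFit:
    """Least-squares fit of the signal channel on the control channel.

    ``signal ≈ gain_a * control + offset_b`` over the unmasked samples.
    """

    gain_a: float
    offset_b: float
    residual_rms: float
    n_samples: int


@dataclass
class CorrectedTrace:
    """Motion-corrected, normalized dF/F trace plus the fit that produced it."""

    dff: np.ndarray
    mean_corrected: float
    fit: ScalingFit | None
    source_rate_hz: float
    settling_mask: np.ndarray | None = None
    mode: str = "session-mean"
    t0_s: float = 0.0

    def __post_init__(self):
        self.dff = np.asarray(self.dff, dtype=float)
        if self.settling_mask is None:
            self.settling_mask = np.zeros(len(self.dff), dtype=bool)
        else:
            self.settling_mask = np.asarray(self.settling_mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.dff)

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.dff)) / self.source_rate_hz

    @property
    def unmasked(self) -> np.ndarray:
        return self.dff[~self.settling_mask]


def _shared_mask(a: ChannelTrace, b: ChannelTrace) -> np.ndarray:
    if len(a) != len(b):
        raise DegenerateFitError(
            f"traces have different lengths ({len(a)} vs {len(b)})"
        )
    if not np.isclose(a.sample_rate_hz, b.sample_rate_hz):
        raise DegenerateFitError("traces have different sample rates")
    return a.settling_mask | b.settling_mask


def fit_isosbestic(
    control: ChannelTrace, signal: ChannelTrace, gain_only: bool = False
) -> ScalingFit:
    """Scale the control (405 nm) channel to fit the signal (470 nm) channel.

    Ordinary least squares of ``signal`` on ``control`` over the samples
    unmasked in both traces.  With ``gain_only`` the offset is pinned to
    zero (pure proportional scaling).
    """
    mask = _shared_mask(control, signal)
    c = control.values[~mask]
    s = signal.values[~mask]
    if len(c) < 2:
        raise DegenerateFitError("need at least 2 unmasked samples to fit")
    if np.ptp(c) == 0:
        raise DegenerateFitError("control channel is constant; scaling is not identifiable")
    if gain_only:
        a = float(np.dot(c, s) / np.dot(c, c))
        b = 0.0
    else:
        a, b = np.polyfit(c, s, 1)
        a, b = float(a), float(b)
    resid = s - (a * c + b)
    return ScalingFit(
        gain_a=a,
        offset_b=b,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_samples=len(c),
    )


def fitted_control_trace(control: ChannelTrace, fit: ScalingFit) -> np.ndarray:
    """The scaled control, ``gain_a * control + offset_b``, as a plain array."""
    return fit.gain_a * control.values + fit.offset_b


def motion_correct(
    signal: ChannelTrace, control: ChannelTrace, fit: ScalingFit
) -> ChannelTrace:
    """Subtract the scaled control channel from the signal channel."""
    mask = _shared_mask(control, signal)
    corrected = signal.values - fitted_control_trace(control, fit)
    src_mean = signal.source_mean
    if src_mean is None and (~mask).any():
        src_mean = float(np.mean(signal.values[~mask]))
    return replace(signal, values=corrected, settling_mask=mask, source_mean=src_mean)


def compute_dff(
    corrected: ChannelTrace,
    min_mean_fraction: float = 0.05,
    fit: ScalingFit | None = None,
) -> CorrectedTrace:
    """Normalize the corrected trace by its own session mean (session-mean convention).

    The divisor is the mean of the unmasked corrected samples; the returned
    dF/F therefore has unmasked mean exactly 1.  When the subtraction has
    removed (nearly) all baseline the divisor approaches zero and the result
    is meaningless: if the divisor falls below ``min_mean_fraction`` times
    the mean of the uncorrected signal (carried on
    ``corrected.source_mean``), a DegenerateBaselineError is raised naming
    the fitted-control convention as the remedy.
    """
    mask = corrected.settling_mask
    vals = corrected.values[~mask]
    if len(vals) == 0:
        raise DegenerateBaselineError("no unmasked samples")
    divisor = float(np.mean(vals))
    reference = corrected.source_mean
    floor = min_mean_fraction * abs(reference) if reference is not None else 0.0
    if divisor <= floor:
        raise DegenerateBaselineError(
            f"corrected-trace mean {divisor:.4g} is below {min_mean_fraction:g} of the "
            f"uncorrected signal mean; the divide-by-own-mean convention is degenerate "
            f"here — use dff_mode='fitted-control' instead"
        )
    return CorrectedTrace(
        dff=corrected.values / divisor,
        mean_corrected=divisor,
        fit=fit,
        source_rate_hz=corrected.sample_rate_hz,
        settling_mask=mask.copy(),
        mode="session-mean",
        t0_s=corrected.t0_s,
    )


def compute_dff_fitted_control(
    signal: ChannelTrace, control: ChannelTrace, fit: ScalingFit
) -> CorrectedTrace:
    """dF/F = (signal − fitted control) / fitted control.

    Baseline sits at 0 rather than 1; a calcium transient of fractional
    amplitude ``a`` over baseline appears as a dF/F excursion of ``a``.
    """
    mask = _shared_mask(control, signal)
    fitted = fitted_control_trace(control, fit)
    if np.min(fitted[~mask]) <= 0:
        raise DegenerateBaselineError(
            "fitted control is non-positive somewhere; cannot divide by it"
        )
    dff = (signal.values - fitted) / fitted
    return CorrectedTrace(
        dff=dff,
        mean_corrected=float(np.mean(fitted[~mask])),
        fit=fit,
        source_rate_hz=signal.sample_rate_hz,
        settling_mask=mask,
        mode="fitted-control",
        t0_s=signal.t0_s,
    )


def correct_session(
    signal: ChannelTrace,
    control: ChannelTrace,
    dff_mode: str = "session-mean",
    gain_only: bool = False,
    min_mean_fraction: float = 0.05,
) -> CorrectedTrace:
    """Fit, subtract and normalize in one call (the pipeline's correction stage)."""
    fit = fit_isosbestic(control, signal, gain_only=gain_only)
    if dff_mode == "session-mean":
        corrected = motion_correct(signal, control, fit)
        return compute_dff(corrected, min_mean_fraction=min_mean_fraction, fit=fit)
    if dff_mode == "fitted-control":
        return compute_dff_fitted_control(signal, control, fit)
    raise ValueError(f"unknown dff_mode {dff_mode!r} (expected 'session-mean' or 'fitted-control')")
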