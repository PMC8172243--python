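"""End-to-end session pipeline: demodulate → correct → dF/F → bouts → peri-event stats.

:class:`PipelineConfig` collects every stage parameter and round-trips
losslessly through YAML; :func:`run_pipeline` executes the stages in order,
writes every intermediate artifact under the output directory and returns a
structured run report.  Identical config (and inputs) produce byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as psio
from .correct import correct_session
from .demod import demodulate_recording
from .errors import ConfigurationError, PhotoscratchError
from .perievent import (
    build_perievent_matrix,
    merge_bouts,
    perievent_average,
    pre_post_change,
    ttest_two_sample,
    zscore_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters for one photometry session analysis."""

    recording: str = ""
    events: str = ""
    out_dir: str = "photoscratch_out"
    seed: int = 0
    log_level: str = "INFO"

    # demodulation
    carrier_map: dict = field(default_factory=lambda: {405: 211.0, 470: 537.0})
    signal_nm: int = 470
    control_nm: int = 405
    lowpass_hz: float = 4.0
    out_rate_hz: float = 100.0
    filter_order: int = 4

    # correction; the divide-by-own-mean ("session-mean") convention degenerates
    # after affine subtraction, so the pipeline defaults to fitted-control
    dff_mode: str = "fitted-control"
    gain_only: bool = False
    min_mean_fraction: float = 0.05

    # peri-event
    merge_window_s: float = 30.0
    pre_s: float = 5.0
    post_s: float = 10.0
    bin_s: float | None = None
    zscore_reference: str = "trial"
    change_pre_window_s: tuple = (-5.0, 0.0)
    change_post_window_s: tuple = (0.0, 5.0)

    # colocalization
    min_puncta: int = 5

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration key(s): {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.carrier_map:
            cfg.carrier_map = {int(k): float(v) for k, v in cfg.carrier_map.items()}
        for key in ("change_pre_window_s", "change_post_window_s"):
            setattr(cfg, key, tuple(float(x) for x in getattr(cfg, key)))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["change_pre_window_s"] = list(self.change_pre_window_s)
        d["change_post_window_s"] = list(self.change_post_window_s)
        return d

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


class PipelineStageError(PhotoscratchError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage {stage!r} failed: {original}")


@dataclass
class RunReport:
    """Everything a reader needs to audit one pipeline run."""

    version: str
    config: dict
    fit_gain_a: float
    fit_offset_b: float
    fit_residual_rms: float
    n_events: int
    n_bouts: int
    n_trials_retained: int
    n_trials_excluded: int
    excluded_reasons: list
    recovered_amplitude: float
    pre_mean: float
    post_mean: float
    t: float
    df: float
    p: float

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> RunReport:
    """Run every stage in order on the configured recording and event file.

    Writes the demodulated traces, the dF/F trace, the peri-event matrices
    (dF/F and z-scored) and a YAML run report under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    rec = _stage("read-recording")(psio.read_recording)(config.recording)
    if config.carrier_map:
        rec.carrier_map = dict(config.carrier_map)
    events = _stage("read-events")(psio.read_events)(
        config.events, session_duration_s=rec.duration_s
    )

    traces = _stage("demodulate")(demodulate_recording)(
        rec, lowpass_hz=config.lowpass_hz, out_rate_hz=config.out_rate_hz,
        order=config.filter_order,
    )
    try:
        signal = traces[config.signal_nm]
        control = traces[config.control_nm]
    except KeyError as exc:
        raise PipelineStageError("demodulate", ConfigurationError(
            f"wavelength {exc} not present in carrier map {rec.carrier_map}"))

    dff = _stage("correct")(correct_session)(
        signal, control, dff_mode=config.dff_mode, gain_only=config.gain_only,
        min_mean_fraction=config.min_mean_fraction,
    )

    bouts = _stage("merge-bouts")(merge_bouts)(events, window_s=config.merge_window_s)
    matrix = _stage("perievent")(build_perievent_matrix)(
        dff, bouts, pre_s=config.pre_s, post_s=config.post_s, bin_s=config.bin_s
    )
    zmatrix = _stage("zscore")(zscore_matrix)(
        matrix, reference=config.zscore_reference, session_trace=dff
    )
    mean_trace, _sem = perievent_average(matrix)

    pre_vals, post_vals = _stage("pre-post")(pre_post_change)(
        matrix, pre_window_s=config.change_pre_window_s,
        post_window_s=config.change_post_window_s,
    )
    test = ttest_two_sample(post_vals, pre_vals)

    # amplitude recovery: peri-event-average peak in the post window over
    # the pre-window baseline (dF/F units)
    m_for_amp = build_perievent_matrix(
        dff, bouts, pre_s=config.pre_s, post_s=config.post_s, bin_s=config.bin_s
    )
    avg, _ = perievent_average(m_for_amp)
    post_cols = m_for_amp.window_columns(*config.change_post_window_s)
    pre_cols = m_for_amp.window_columns(*config.change_pre_window_s)
    recovered = float(avg[post_cols].max() - avg[pre_cols].mean())

    report = RunReport(
        version=__version__,
        config=config.to_dict(),
        fit_gain_a=float(dff.fit.gain_a),
        fit_offset_b=float(dff.fit.offset_b),
        fit_residual_rms=float(dff.fit.residual_rms),
        n_events=len(events),
        n_bouts=len(bouts),
        n_trials_retained=matrix.n_trials,
        n_trials_excluded=len(matrix.excluded_trials),
        excluded_reasons=[[int(i), r] for i, r in matrix.excluded_trials],
        recovered_amplitude=recovered,
        pre_mean=float(np.mean(pre_vals)),
        post_mean=float(np.mean(post_vals)),
        t=test.t, df=test.df, p=test.p,
    )

    if write_outputs:
        for wl, tr in traces.items():
            psio.write_trace(out / f"trace_{wl}nm.csv", tr)
        psio.write_trace(out / "dff.csv", dff)
        psio.write_matrix(out / "perievent_dff.csv", matrix)
        psio.write_matrix(out / "perievent_zscore.csv", zmatrix)
        np.savetxt(out / "perievent_average.csv",
                   np.column_stack([matrix.bin_times(), mean_trace, _sem]),
                   header="time_s,mean,sem", delimiter=",", comments="# ")
        report.to_yaml(out / "report.yaml")
    return report
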