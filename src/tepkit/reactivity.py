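"""Global and local EEG reactivity measures of the response to a TMS pulse.

Global response: the global mean field amplitude (GMFA) of the sensor-space
evoked potential — the instantaneous dispersion of voltage across channels.
Local response: the source-space series of the stimulated region of interest,
rectified per vertex, averaged, and z-scored against the pre-stimulus
baseline (-500 to -3 ms).  Scalar predictors for the regression stage are
trapezoidal areas under these curves from 15 to 400 ms post-stimulus, plus
the rectified baseline activity itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ROIDefinition, ReactivityScore, TEPTimeSeries, window_indices

BASELINE_WINDOW_MS = (-500.0, -3.0)
RESPONSE_WINDOW_MS = (15.0, 400.0)


class DegenerateBaselineError(ValueError):
    """Baseline standard deviation is zero; z-scoring is undefined."""


@dataclass
class ResponseSeries:
    """A per-timepoint scalar response derived from a TEP.

    kind "global_gmfa" (microvolt) or "local_z" (z units); ``baseline_mu`` /
    ``baseline_sigma`` record the z-scoring parameters for the local kind.
    """

    kind: str
    values: np.ndarray
    t0_ms: float
    fs_hz: float
    baseline_mu: float | None = None
    baseline_sigma: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("global_gmfa", "local_z"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "local_z" and not (self.baseline_sigma and self.baseline_sigma > 0):
            raise ValueError("local_z series must record a positive baseline_sigma")

    @property
    def times(self) -> np.ndarray:
        return self.t0_ms + np.arange(len(self.values)) / self.fs_hz * 1000.0


def gmfa(tep: TEPTimeSeries, ddof: int = 0) -> ResponseSeries:
    """Global mean field amplitude: per-timepoint standard deviation of the
    channel voltages around their instantaneous mean.

    The population form (ddof=0) is the classical global field power; pass
    ddof=1 for the sample-variance variant.
    """
    if tep.n_series < 2:
        raise ValueError("GMFA undefined for fewer than 2 channels")
    values = tep.data.std(axis=1, ddof=ddof)
    return ResponseSeries(kind="global_gmfa", values=values,
                          t0_ms=tep.t0_ms, fs_hz=tep.fs_hz)


def _roi_rectified_mean(tep: TEPTimeSeries, roi: ROIDefinition) -> np.ndarray:
    """s(t): per-vertex rectification then average over the ROI."""
    roi.check_against(tep)
    cols = [tep.series_index(v) for v in roi.vertex_ids]
    return np.abs(tep.data[:, cols]).mean(axis=1)


def local_response(tep: TEPTimeSeries, roi: ROIDefinition,
                   baseline_window: tuple[float, float] = BASELINE_WINDOW_MS
                   ) -> ResponseSeries:
    """Rectified ROI-average series, z-scored against the pre-stimulus baseline.

    z(t) = (s(t) - mu) / sigma where mu and sigma are the mean and population
    standard deviation of s over the closed baseline window.
    """
    s = _roi_rectified_mean(tep, roi)
    idx = window_indices(tep.times, *baseline_window)
    mu = float(s[idx].mean())
    sigma = float(s[idx].std(ddof=0))
    if sigma == 0:
        raise DegenerateBaselineError(
            f"constant baseline for subject {tep.subject_id}, target {tep.target}"
        )
    return ResponseSeries(kind="local_z", values=(s - mu) / sigma,
                          t0_ms=tep.t0_ms, fs_hz=tep.fs_hz,
                          baseline_mu=mu, baseline_sigma=sigma)


def auc(series: ResponseSeries,
        window: tuple[float, float] = RESPONSE_WINDOW_MS) -> float:
    """Trapezoidal area under the series over the closed window, time in ms."""
    times = series.times
    idx = window_indices(times, *window)
    return float(np.trapezoid(series.values[idx], times[idx]))


def baseline_activity(tep: TEPTimeSeries, roi: ROIDefinition,
                      window: tuple[float, float] = BASELINE_WINDOW_MS) -> float:
    """Trapezoidal integral of the rectified ROI average (pre-z-scoring)
    over the pre-stimulus window: the local baseline pre-TMS activity."""
    s = _roi_rectified_mean(tep, roi)
    times = tep.times
    idx = window_indices(times, *window)
    return float(np.trapezoid(s[idx], times[idx]))


class MissingDataError(ValueError):
    """A required TEP space is missing for a subject x target."""


def score_subject(tep_sensor: TEPTimeSeries | None,
                  tep_source: TEPTimeSeries | None,
                  roi: ROIDefinition) -> ReactivityScore:
    """Bundle the three scalar predictors for one subject x target.

    global AUC from sensor-space GMFA, local AUC from the z-scored source
    ROI response, baseline activity from the rectified ROI average.
    """
    if tep_sensor is None or tep_source is None:
        missing = "sensor" if tep_sensor is None else "source_roi"
        raise MissingDataError(f"missing {missing} TEP for scoring")
    if tep_sensor.subject_id != tep_source.subject_id or tep_sensor.target != tep_source.target:
        raise ValueError("sensor/source TEPs refer to different subject x target")
    g = gmfa(tep_sensor)
    z = local_response(tep_source, roi)
    return ReactivityScore(
        subject_id=tep_source.subject_id,
        target=tep_source.target,
        local_auc=auc(z),
        global_auc=auc(g),
        baseline_activity=baseline_activity(tep_source, roi),
    )
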