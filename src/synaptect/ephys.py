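"""Field-potential (fEPSP) measurement suite.

Implements the classic extracellular CA1 measurements: fEPSP initial slope,
fiber-volley amplitude, input–output curves, paired-pulse facilitation,
baseline-stability screening, time-course normalization and windowed
plasticity magnitudes (LTP / LTD / PTP).

Conventions
-----------
* fEPSPs are negative-going (stratum radiatum field); slopes and amplitudes
  are reported as unsigned magnitudes.
* The initial slope is a linear fit over the 20–80% span of the falling
  phase; the stimulus artifact and fiber volley are excluded by a latency
  gate relative to the stimulus time.
* A quantity that cannot be measured (no deflection above noise) is returned
  as ``nan`` — flagged, never silently zero.  Downstream ratios reject ``nan``
  inputs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

PROTOCOLS = ("IO", "PPF", "LTP", "LTD", "PTP")

#: Post-stimulus latency gates (ms): the fiber volley is read between artifact
#: end and fEPSP onset; the fEPSP after volley end.
VOLLEY_GATE_MS = (0.5, 2.1)
FEPSP_GATE_MS = (2.2, 25.0)

#: Quantification windows in minutes post-induction.  The juvenile LTP window
#: is the last 10 min of a 60 min follow-up; LTD uses 30–40 min; PTP (NMDA
#: receptors blocked) the first 5 min after the tetanus.  The adult LTP
#: convention (response around 35 min) is the 30–40 min mean.
DEFAULT_WINDOWS_MIN = {
    "LTP": (50.0, 60.0),
    "LTD": (30.0, 40.0),
    "PTP": (0.0, 5.0),
}
ADULT_LTP_WINDOW_MIN = (30.0, 40.0)

_AMPLITUDE_FLOOR_MV = 1e-6  # below this a deflection is unmeasurable


@dataclasses.dataclass
class SweepSeries:
    """A series of voltage sweeps sharing one sampling rate and protocol.

    ``sweeps`` is ``(n_sweeps, n_samples)`` in mV, ``timestamps_s`` the start
    time of each sweep in the recording, ``stimulus_times_ms`` the
    within-sweep stimulus onset(s) per sweep.
    """

    sampling_khz: float
    sweeps: np.ndarray
    timestamps_s: np.ndarray
    stimulus_times_ms: list[list[float]]
    protocol: str
    induction_time_s: float | None = None

    def __post_init__(self) -> None:
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.sampling_khz < 10:
            raise ValueError("sampling_khz must be >= 10 (10 kHz digitization)")
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}")
        if len(self.timestamps_s) != self.sweeps.shape[0]:
            raise ValueError("one timestamp per sweep required")
        if len(self.stimulus_times_ms) != self.sweeps.shape[0]:
            raise ValueError("one stimulus-time list per sweep required")
        span = self.sweeps.shape[1] / self.sampling_khz
        for stims in self.stimulus_times_ms:
            for t in stims:
                if not 0 <= t < span:
                    raise ValueError(f"stimulus time {t} ms outside sweep span {span} ms")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def sweep_span_ms(self) -> float:
        return self.sweeps.shape[1] / self.sampling_khz

    def time_ms(self) -> np.ndarray:
        """Within-sweep sample times (ms)."""
        return np.arange(self.sweeps.shape[1]) / self.sampling_khz


# ---------------------------------------------------------------------------
# CSV I/O (t_ms, v_mV, sweep_id)
# ---------------------------------------------------------------------------

def write_sweeps_csv(series: SweepSeries, path: str | Path) -> Path:
    path = Path(path)
    t = series.time_ms()
    frames = [
        pd.DataFrame({"t_ms": t, "v_mV": series.sweeps[i], "sweep_id": i})
        for i in range(series.n_sweeps)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_sweeps_csv(
    path: str | Path,
    protocol: str,
    stimulus_times_ms: list[list[float]] | list[float],
    sweep_interval_s: float = 20.0,
    induction_time_s: float | None = None,
) -> SweepSeries:
    """Load sweeps from the ``(t_ms, v_mV, sweep_id)`` schema.

    Stimulus times are metadata the acquisition knows but the bare schema does
    not carry, so they are supplied by the caller: either one list shared by
    all sweeps or one list per sweep.
    """
    df = pd.read_csv(path)
    required = {"t_ms", "v_mV", "sweep_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"sweep CSV must have columns {sorted(required)}")
    sweep_ids = sorted(df["sweep_id"].unique())
    sweeps = []
    for sid in sweep_ids:
        sub = df[df["sweep_id"] == sid].sort_values("t_ms")
        sweeps.append(sub["v_mV"].to_numpy())
    t = np.sort(df[df["sweep_id"] == sweep_ids[0]]["t_ms"].to_numpy())
    dt = np.diff(t)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-4):
        raise ValueError("non-uniform sample spacing in sweep CSV")
    if stimulus_times_ms and not isinstance(stimulus_times_ms[0], (list, tuple)):
        stims = [list(stimulus_times_ms)] * len(sweep_ids)  # type: ignore[arg-type]
    else:
        stims = [list(s) for s in stimulus_times_ms]  # type: ignore[union-attr]
    return SweepSeries(
        sampling_khz=1.0 / float(dt[0]),
        sweeps=np.vstack(sweeps),
        timestamps_s=np.arange(len(sweep_ids)) * sweep_interval_s,
        stimulus_times_ms=stims,
        protocol=protocol,
        induction_time_s=induction_time_s,
    )


# ---------------------------------------------------------------------------
# Per-sweep measurements
# ---------------------------------------------------------------------------

def _local_baseline(v: np.ndarray, khz: float, stim_ms: float, span_ms: float = 2.0) -> float:
    i1 = int(round(stim_ms * khz))
    i0 = max(0, i1 - int(round(span_ms * khz)))
    if i1 <= i0:
        return 0.0
    return float(np.mean(v[i0:i1]))


def fepsp_slope_trace(
    v_mv: np.ndarray,
    sampling_khz: float,
    stimulus_time_ms: float,
    gate_ms: tuple[float, float] = FEPSP_GATE_MS,
    fit_span: tuple[float, float] = (0.2, 0.8),
) -> float:
    """Initial fEPSP slope (mV/ms, magnitude) on one trace.

    The fEPSP is located as the negative extremum inside the latency gate;
    the slope is a least-squares line over the samples lying between the
    ``fit_span`` fractional amplitudes (default 20–80%) of the falling phase,
    falling back to the interpolated 20/80% chord when fewer than three
    samples fall in the band.  Returns ``nan`` when no deflection rises above
    the noise (unmeasurable — deliberately not zero).
    """
    v = np.asarray(v_mv, dtype=float)
    khz = float(sampling_khz)
    base = _local_baseline(v, khz, stimulus_time_ms)
    i0 = int(round((stimulus_time_ms + gate_ms[0]) * khz))
    i1 = min(len(v), int(round((stimulus_time_ms + gate_ms[1]) * khz)))
    if i1 - i0 < 4:
        return float("nan")
    seg = v[i0:i1]
    ipk = int(np.argmin(seg))
    amp = base - seg[ipk]
    # noise floor from the local pre-stimulus baseline spread
    j1 = int(round(stimulus_time_ms * khz))
    j0 = max(0, j1 - int(round(2.0 * khz)))
    noise = float(np.std(v[j0:j1])) if j1 > j0 else 0.0
    if amp < max(4.0 * noise, _AMPLITUDE_FLOOR_MV):
        return float("nan")
    lo, hi = fit_span
    v_lo = base - lo * amp  # shallow threshold (crossed first)
    v_hi = base - hi * amp  # deep threshold
    # falling phase: walk back from the peak to the last sample above v_lo
    fall = seg[: ipk + 1]
    above = np.nonzero(fall > v_lo)[0]
    if len(above) == 0:
        return float("nan")
    k0 = above[-1]
    below = np.nonzero(fall[k0:] <= v_hi)[0]
    if len(below) == 0:
        return float("nan")
    k1 = k0 + below[0]
    t = np.arange(len(seg)) / khz
    band = np.nonzero((fall <= v_lo) & (fall >= v_hi))[0]
    band = band[(band >= k0) & (band <= k1)]
    if len(band) >= 3:
        slope = np.polyfit(t[band], fall[band], 1)[0]
    else:
        # interpolated chord between the exact 20% and 80% crossing times
        t20 = np.interp(v_lo, [fall[k0 + 1], fall[k0]], [t[k0 + 1], t[k0]])
        t80 = np.interp(v_hi, [fall[k1], fall[k1 - 1]], [t[k1], t[k1 - 1]])
        if t80 <= t20:
            return float("nan")
        slope = (v_hi - v_lo) / (t80 - t20)
    return float(abs(slope))


def fiber_volley_amplitude_trace(
    v_mv: np.ndarray,
    sampling_khz: float,
    stimulus_time_ms: float,
    gate_ms: tuple[float, float] = VOLLEY_GATE_MS,
) -> float:
    """Fiber-volley amplitude (mV, peak-to-baseline) on one trace.

    Gated to the short latency window between artifact end and fEPSP onset.
    Returns ``nan`` when no deflection rises above the noise.
    """
    v = np.asarray(v_mv, dtype=float)
    khz = float(sampling_khz)
    base = _local_baseline(v, khz, stimulus_time_ms)
    i0 = int(round((stimulus_time_ms + gate_ms[0]) * khz))
    i1 = min(len(v), int(round((stimulus_time_ms + gate_ms[1]) * khz)))
    if i1 - i0 < 2:
        return float("nan")
    amp = base - float(np.min(v[i0:i1]))
    j1 = int(round(stimulus_time_ms * khz))
    j0 = max(0, j1 - int(round(2.0 * khz)))
    noise = float(np.std(v[j0:j1])) if j1 > j0 else 0.0
    if amp < max(4.0 * noise, _AMPLITUDE_FLOOR_MV):
        return float("nan")
    return float(amp)


def fepsp_slope(series: SweepSeries, sweep: int = 0, stimulus_index: int = 0, **kw) -> float:
    """fEPSP slope of one stimulus epoch of one sweep (see :func:`fepsp_slope_trace`)."""
    stim = series.stimulus_times_ms[sweep][stimulus_index]
    return fepsp_slope_trace(series.sweeps[sweep], series.sampling_khz, stim, **kw)


def fiber_volley_amplitude(series: SweepSeries, sweep: int = 0, stimulus_index: int = 0, **kw) -> float:
    stim = series.stimulus_times_ms[sweep][stimulus_index]
    return fiber_volley_amplitude_trace(series.sweeps[sweep], series.sampling_khz, stim, **kw)


# ---------------------------------------------------------------------------
# Input–output relation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class IOCurve:
    """Input–output relation: fEPSP slope as a function of fiber-volley amplitude."""

    points: np.ndarray  # (n, 2): volley mV, slope mV/ms — sorted by volley

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if np.any(self.points[:, 0] < 0):
            raise ValueError("fiber volley amplitudes must be >= 0")
        order = np.argsort(self.points[:, 0], kind="stable")
        self.points = self.points[order]


def build_io_curve(series: SweepSeries) -> IOCurve:
    """Measure (fiber volley, fEPSP slope) on every sweep of an I/O series.

    Sweeps on which either quantity is unmeasurable are dropped.
    """
    pts = []
    for i in range(series.n_sweeps):
        volley = fiber_volley_amplitude(series, sweep=i)
        slope = fepsp_slope(series, sweep=i)
        if np.isfinite(volley) and np.isfinite(slope):
            pts.append((volley, slope))
    return IOCurve(points=np.array(pts).reshape(-1, 2))


def query_io(curve: IOCurve, volley_mv: float) -> float:
    """Slope at a query volley amplitude by linear interpolation (no extrapolation)."""
    x = curve.points[:, 0]
    if len(x) == 0:
        raise ValueError("empty I/O curve")
    if not (x[0] <= volley_mv <= x[-1]):
        raise ValueError(
            f"query {volley_mv} mV outside measured range [{x[0]}, {x[-1]}] mV; "
            "extrapolation is not supported"
        )
    return float(np.interp(volley_mv, x, curve.points[:, 1]))


def percent_reduction(reference: float, value: float) -> float:
    """Percent reduction of ``value`` relative to ``reference`` (e.g. KO vs WT I/O slope)."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (reference - value) / reference


# ---------------------------------------------------------------------------
# Paired-pulse facilitation
# ---------------------------------------------------------------------------

def ppf_ratio(series: SweepSeries, sweep: int = 0, interpulse_ms: float = 40.0,
              use_slope: bool = False) -> float:
    """Paired-pulse ratio: second response / first response.

    The paper's convention is the peak-amplitude ratio, each peak measured
    against its own local pre-stimulus baseline; a slope-ratio mode is
    available but non-default.
    """
    stims = series.stimulus_times_ms[sweep]
    if len(stims) != 2:
        raise ValueError(f"paired-pulse sweep needs exactly 2 stimulus epochs, got {len(stims)}")
    if abs((stims[1] - stims[0]) - interpulse_ms) > 1.0 / series.sampling_khz + 1e-9:
        raise ValueError(
            f"interpulse interval {stims[1] - stims[0]:.3f} ms != expected {interpulse_ms} ms"
        )
    if use_slope:
        a1 = fepsp_slope(series, sweep=sweep, stimulus_index=0)
        a2 = fepsp_slope(series, sweep=sweep, stimulus_index=1)
    else:
        a1 = _fepsp_peak_amplitude(series, sweep, stims[0])
        a2 = _fepsp_peak_amplitude(series, sweep, stims[1])
    if not np.isfinite(a1) or a1 <= 0:
        raise ValueError("first response unmeasurable; PPF ratio undefined")
    if not np.isfinite(a2):
        raise ValueError("second response unmeasurable; PPF ratio undefined")
    return float(a2 / a1)


def _fepsp_peak_amplitude(series: SweepSeries, sweep: int, stim_ms: float) -> float:
    v = series.sweeps[sweep]
    khz = series.sampling_khz
    base = _local_baseline(v, khz, stim_ms)
    i0 = int(round((stim_ms + FEPSP_GATE_MS[0]) * khz))
    i1 = min(len(v), int(round((stim_ms + FEPSP_GATE_MS[1]) * khz)))
    if i1 - i0 < 2:
        return float("nan")
    amp = base - float(np.min(v[i0:i1]))
    return amp if amp >= _AMPLITUDE_FLOOR_MV else float("nan")


# ---------------------------------------------------------------------------
# Baseline stability
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StabilityResult:
    passed: bool
    drift_pct: float          # fitted total drift over the span, % of mean
    slopes: np.ndarray        # per-sweep fEPSP slopes used for the fit


def baseline_stability(series: SweepSeries, span_min: float = 10.0,
                       max_drift_pct: float = 10.0) -> StabilityResult:
    """Screen a baseline recording for drift.

    Linear regression of per-sweep fEPSP slope against time over the first
    ``span_min`` minutes; the series passes when the fitted total change is at
    most ``max_drift_pct`` of the mean response.
    """
    mask = series.timestamps_s <= span_min * 60.0 + 1e-9
    if mask.sum() < 3:
        raise ValueError("need at least 3 sweeps inside the stability span")
    t = series.timestamps_s[mask]
    y = np.array([fepsp_slope(series, sweep=i) for i in np.nonzero(mask)[0]])
    ok = np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("too few measurable sweeps for a stability estimate")
    t, y = t[ok], y[ok]
    b, a = np.polyfit(t, y, 1)
    mean = float(np.mean(y))
    if mean == 0:
        raise ValueError("zero mean response")
    drift = 100.0 * b * (t[-1] - t[0]) / mean
    return StabilityResult(passed=bool(abs(drift) <= max_drift_pct), drift_pct=float(drift), slopes=y)


# ---------------------------------------------------------------------------
# Plasticity time courses
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PlasticityResult:
    """Normalized fEPSP-slope time course around an induction event.

    ``minutes`` holds the left edge of each 1 min bin relative to induction
    (negative = baseline); ``normalized_pct`` the per-minute mean slope as a
    percentage of the pre-induction baseline mean (baseline mean is exactly
    100 by construction).
    """

    minutes: np.ndarray
    normalized_pct: np.ndarray
    protocol: str
    window_min: tuple[float, float]


def normalize_timecourse(series: SweepSeries, induction_time_s: float | None = None,
                         window_min: tuple[float, float] | None = None) -> PlasticityResult:
    """Per-minute fEPSP slopes normalized to the pre-induction baseline mean."""
    if induction_time_s is None:
        induction_time_s = series.induction_time_s
    if induction_time_s is None:
        raise ValueError("induction time required (none recorded in the series)")
    slopes = np.array([fepsp_slope(series, sweep=i) for i in range(series.n_sweeps)])
    rel_min = (series.timestamps_s - induction_time_s) / 60.0
    ok = np.isfinite(slopes)
    if not np.any(ok & (rel_min < 0)):
        raise ValueError("no measurable baseline sweeps before induction")
    bins = np.floor(rel_min[ok]).astype(int)
    vals = slopes[ok]
    uniq = np.unique(bins)
    per_min = np.array([vals[bins == b].mean() for b in uniq])
    baseline_mean = per_min[uniq < 0].mean()
    if baseline_mean == 0:
        raise ValueError("zero baseline mean")
    norm = per_min / baseline_mean * 100.0
    window = window_min or DEFAULT_WINDOWS_MIN.get(series.protocol, (0.0, 10.0))
    return PlasticityResult(minutes=uniq.astype(float), normalized_pct=norm,
                            protocol=series.protocol, window_min=tuple(window))


def plasticity_magnitude(result: PlasticityResult,
                         window_min: tuple[float, float] | None = None) -> float:
    """Mean normalized slope (% of baseline) over the quantification window."""
    w0, w1 = window_min or result.window_min
    m = (result.minutes >= w0) & (result.minutes < w1)
    if not np.any(m):
        raise ValueError(f"window [{w0}, {w1}) min contains no time-course bins")
    return float(result.normalized_pct[m].mean())
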