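"""ECG processing: filtering, R-peak detection and cardiac anxiety markers.

The processing chain mirrors a standard short-recording HRV workflow:

1. zero-phase low-pass filter (default 30 Hz cutoff);
2. R-peak detection by local maxima over an adaptive amplitude threshold
   (blockwise median + k * scaled MAD) with a 250 ms refractory period;
3. physiological rejection of RR intervals outside 25-200 bpm;
4. instantaneous heart rate interpolated onto a uniform 4 Hz grid;
5. three markers: mean HR (bpm), CVRR (SD(RR)/mean(RR) in percent) and
   slope HR (OLS slope of the 4 Hz HR series on time, in bpm/min).

Recordings here are short task phases, so only these time-domain markers
are computed; spectral and nonlinear HRV are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

HR_MIN_BPM = 25.0
HR_MAX_BPM = 200.0
DEFAULT_CUTOFF_HZ = 30.0
DEFAULT_FS_OUT_HZ = 4.0
REFRACTORY_S = 0.250
THRESHOLD_WINDOW_S = 2.0
THRESHOLD_K = 3.0
_MAD_TO_SD = 1.4826  # consistency factor for Gaussian noise


@dataclass(frozen=True)
class EcgRecording:
    samples: np.ndarray  # mV
    fs: float  # Hz
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs


@dataclass(frozen=True)
class RrSeries:
    """R-peak times with the RR intervals and their closing-beat times.

    ``rr_times[i]`` is the time of the beat ending interval ``rr[i]``;
    after physiological rejection the two arrays stay aligned while
    ``peak_times`` keeps every detected peak.
    """

    peak_times: np.ndarray  # s
    rr: np.ndarray  # s
    rr_times: np.ndarray | None = None
    too_few_peaks: bool = False

    def __post_init__(self) -> None:
        if self.rr_times is None:
            object.__setattr__(self, "rr_times", np.asarray(self.peak_times)[1:])
        if len(self.rr_times) != len(self.rr):
            raise ValueError("rr and rr_times must have equal length")


@dataclass(frozen=True)
class CardiacMetrics:
    mean_hr: float  # bpm
    cvrr: float  # percent
    slope_hr: float  # bpm/min


def read_ecg_csv(path: str | Path) -> EcgRecording:
    """Read an ECG trace from a two-column CSV (`t_s, mv`)."""
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy(float)
    fs = 1.0 / float(np.median(np.diff(t)))
    return EcgRecording(samples=df["mv"].to_numpy(float), fs=round(fs, 6), t0=float(t[0]))


def write_ecg_csv(rec: EcgRecording, path: str | Path) -> None:
    pd.DataFrame({"t_s": rec.times, "mv": rec.samples}).to_csv(
        path, index=False, float_format="%.6f"
    )


def lowpass_filter(rec: EcgRecording, cutoff: float = DEFAULT_CUTOFF_HZ, order: int = 4) -> EcgRecording:
    """Zero-phase Butterworth low-pass; length preserved."""
    if cutoff >= rec.fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({rec.fs / 2} Hz)")
    sos = signal.butter(order, cutoff, btype="low", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return EcgRecording(samples=filtered, fs=rec.fs, t0=rec.t0)


def detect_r_peaks(
    rec: EcgRecording,
    k: float = THRESHOLD_K,
    window_s: float = THRESHOLD_WINDOW_S,
    refractory_s: float = REFRACTORY_S,
) -> RrSeries:
    """Detect R peaks with an adaptive amplitude threshold.

    The threshold is computed per non-overlapping window as
    ``median + k * 1.4826 * MAD`` and interpolated across window centers,
    adapting to baseline drift and noise level.  Candidates must further
    reach half the rolling median candidate amplitude (signal-peak vs
    noise-peak discrimination, as in classic QRS detectors); local maxima
    closer than the refractory period are pruned keeping the larger one.
    """
    x = rec.samples
    n = len(x)
    w = max(int(round(window_s * rec.fs)), 2)
    starts = np.arange(0, n, w)
    centers, thresholds = [], []
    for s in starts:
        block = x[s : s + w]
        med = np.median(block)
        mad = np.median(np.abs(block - med))
        centers.append(s + len(block) / 2)
        thresholds.append(med + k * _MAD_TO_SD * mad)
    thr = np.interp(np.arange(n), centers, thresholds)

    distance = max(int(round(refractory_s * rec.fs)), 1)
    idx, _ = signal.find_peaks(x, distance=distance)
    idx = idx[x[idx] > thr[idx]]
    if len(idx) > 2:
        # amplitude consistency: QRS amplitudes vary slowly, noise peaks
        # sit far below the local median candidate amplitude
        amps = x[idx] - thr[idx]
        half = 10
        med_amp = np.array([
            np.median(amps[max(i - half, 0) : i + half + 1]) for i in range(len(amps))
        ])
        keep = amps > 0.5 * med_amp
        idx = idx[keep]
    if len(idx) < 2:
        if len(idx) > 0:
            warnings.warn("fewer than 2 R peaks detected", stacklevel=2)
        return RrSeries(rec.t0 + idx / rec.fs, np.empty(0), np.empty(0), too_few_peaks=True)

    # sub-sample refinement: parabola through the peak and its neighbors
    offsets = np.zeros(len(idx))
    inner = (idx > 0) & (idx < n - 1)
    ii = idx[inner]
    denom = x[ii - 1] - 2 * x[ii] + x[ii + 1]
    ok = denom < 0
    offsets[inner] = np.where(ok, 0.5 * (x[ii - 1] - x[ii + 1]) / np.where(ok, denom, 1.0), 0.0)
    peak_times = rec.t0 + (idx + np.clip(offsets, -0.5, 0.5)) / rec.fs
    return RrSeries(peak_times=peak_times, rr=np.diff(peak_times))


def rr_filter(series: RrSeries) -> RrSeries:
    """Reject RR intervals implying HR below 25 or above 200 bpm.

    The associated beat times are kept (an RR interval is attributed to the
    beat closing it); the operation is idempotent and order-preserving.
    """
    if len(series.rr) == 0:
        return series
    hr = 60.0 / series.rr
    keep = (hr >= HR_MIN_BPM) & (hr <= HR_MAX_BPM)
    return RrSeries(
        peak_times=series.peak_times,
        rr=series.rr[keep],
        rr_times=series.rr_times[keep],
        too_few_peaks=series.too_few_peaks,
    )


def instantaneous_hr(
    series: RrSeries,
    fs_out: float = DEFAULT_FS_OUT_HZ,
    method: Literal["spline", "linear"] = "spline",
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate beat-wise instantaneous HR onto a uniform grid.

    Instantaneous HR (60/RR) is located at the beat closing each interval
    and resampled at ``fs_out`` (default 4 Hz, grid spacing 0.25 s) from
    the first to the last retained beat.  Returns ``(t, hr)``.
    """
    if len(series.rr) < 1 or len(series.peak_times) < 2:
        raise ValueError("need at least 2 valid peaks for HR interpolation")
    beat_t = series.rr_times
    hr = 60.0 / series.rr
    t = np.arange(beat_t[0], beat_t[-1] + 1e-12, 1.0 / fs_out)
    if len(beat_t) < 4 or method == "linear":
        out = np.interp(t, beat_t, hr)
    else:
        out = CubicSpline(beat_t, hr)(t)
    return t, out


def cardiac_metrics(
    hr_t: np.ndarray, hr: np.ndarray, series: RrSeries
) -> CardiacMetrics:
    """Compute mean HR, CVRR and slope HR.

    mean HR averages the uniformly resampled series; CVRR is the sample
    coefficient of variation of retained RR intervals, in percent; slope HR
    is the OLS slope of the resampled HR on time, expressed per minute.
    Both are invariant to the recording's time origin.
    """
    mean_hr = float(np.mean(hr))
    rr = series.rr
    cvrr = float(np.std(rr, ddof=1) / np.mean(rr) * 100.0) if len(rr) >= 2 else 0.0
    if len(hr) >= 2 and np.ptp(hr_t) > 0:
        slope_per_s = float(np.polyfit(hr_t - hr_t[0], hr, 1)[0])
    else:
        slope_per_s = 0.0
    return CardiacMetrics(mean_hr=mean_hr, cvrr=cvrr, slope_hr=slope_per_s * 60.0)


def process_recording(
    rec: EcgRecording,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    fs_out: float = DEFAULT_FS_OUT_HZ,
    method: Literal["spline", "linear"] = "spline",
) -> CardiacMetrics:
    """Full chain: filter -> detect -> reject -> interpolate -> metrics."""
    filtered = lowpass_filter(rec, cutoff)
    series = rr_filter(detect_r_peaks(filtered))
    if series.too_few_peaks or len(series.rr) < 2:
        return CardiacMetrics(np.nan, np.nan, np.nan)
    t, hr = instantaneous_hr(series, fs_out, method)
    return cardiac_metrics(t, hr, series)


def process_study(study_dir: str | Path, cutoff: float = DEFAULT_CUTOFF_HZ,
                  fs_out: float = DEFAULT_FS_OUT_HZ) -> pd.DataFrame:
    """Process every participant's ECG CSV under a study tree."""
    study_dir = Path(study_dir)
    rows = []
    for pdir in sorted(d for d in study_dir.iterdir() if d.is_dir()):
        f = pdir / "ecg.csv"
        if not f.exists():
            continue
        m = process_recording(read_ecg_csv(f), cutoff=cutoff, fs_out=fs_out)
        rows.append(dict(id=pdir.name, phase="overall", mean_hr_bpm=m.mean_hr,
                         cvrr_pct=m.cvrr, slope_hr_bpm_per_min=m.slope_hr))
    return pd.DataFrame(rows)
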