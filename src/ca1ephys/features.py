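"""Electrophysiological feature extraction from current-clamp sweeps.

Implements the feature catalogue used throughout the analysis: resting
membrane potential, input resistance (holding-current and step methods),
membrane time constant fitted from stimulus onset to the sag minimum, sag
amplitude, spike detection at a fixed voltage threshold, first-AP shape
(width at half height between onset voltage and peak, amplitude, peak,
max dV/dt), phase-plane samples, instantaneous frequencies from the first
ten inter-spike intervals, and the per-cell feature table assembling all of
these.  Extraction is pure: the same traces and config always produce the
same table.  Missing values are explicit (NaN), never silent zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .biophys import Trace

__all__ = [
    "SpikeDetectConfig",
    "RMP_EXCLUSION_MV",
    "RMPResult",
    "TauFit",
    "SagResult",
    "SpikeTrain",
    "APFeatures",
    "CellSweeps",
    "resting_membrane_potential",
    "input_resistance_hold",
    "input_resistance_step",
    "fit_membrane_tau",
    "measure_sag",
    "detect_spikes",
    "first_ap_features",
    "phase_plane",
    "instantaneous_frequency",
    "mean_frequency",
    "isi_adaptation_index",
    "extract_feature_table",
    "feature_columns",
]

RMP_EXCLUSION_MV = -50.0  # cells with RMP above this are flagged for exclusion

TAU_CURRENTS = (-200, -150, -100, -50)
SAG_CURRENTS = (-200, -150, -100, -50)
SPIKE_CURRENTS = (50, 100, 150, 200, 250, 300, 350, 400)
FREQ_CURRENT = 300
N_ISI = 10


@dataclass(frozen=True)
class SpikeDetectConfig:
    """Spike detection / AP-shape configuration.

    threshold : voltage crossing that defines a spike (mV)
    onset_dvdt : dV/dt criterion locating AP onset (mV/ms)
    smooth_samples : moving-average half-width (samples) applied to the
        derivative for onset localisation only (raw derivative is used for
        max dV/dt); 0 disables smoothing
    """

    threshold: float = -10.0
    onset_dvdt: float = 20.0
    smooth_samples: int = 2

    def __post_init__(self) -> None:
        if self.onset_dvdt <= 0:
            raise ValueError("onset_dvdt must be positive")


@dataclass(frozen=True)
class RMPResult:
    value: float
    excluded: bool


@dataclass(frozen=True)
class TauFit:
    tau: float
    converged: bool
    reason: str = ""
    v_onset: float = float("nan")
    v_ss: float = float("nan")


@dataclass(frozen=True)
class SagResult:
    sag: float
    flagged: bool = False


@dataclass(frozen=True)
class SpikeTrain:
    times_ms: np.ndarray
    truncated_last: bool = False

    @property
    def count(self) -> int:
        return int(self.times_ms.size)


@dataclass(frozen=True)
class APFeatures:
    width: float
    amplitude: float
    peak: float
    onset_voltage: float
    max_dvdt: float
    latency: float


@dataclass
class CellSweeps:
    """All sweeps of one cell, plus the unbiased sweep used for RMP."""

    cell_id: str
    group_label: str
    traces: list[Trace]
    rmp_trace: Trace | None = None

    def by_amplitude(self) -> dict[float, Trace]:
        return {t.stimulus.amplitude: t for t in self.traces}


# ---------------------------------------------------------------------------
# scalar features
# ---------------------------------------------------------------------------

def _step_window(trace: Trace) -> tuple[int, int]:
    s = trace.stimulus
    return trace.sample_index(s.onset), trace.sample_index(s.onset + s.duration)


def _trough_index(seg: np.ndarray, dt: float, smooth_ms: float = 1.0) -> int:
    """Sample index of the voltage trough, located on a lightly smoothed copy.

    Locating the minimum on the raw trace is extreme-value biased under
    recording noise (the deepest noise excursion wins); a ~1 ms moving
    average removes that bias while leaving the slow sag trough intact.
    """
    w = int(round(smooth_ms / dt))
    if w < 2:
        return int(np.argmin(seg))
    kernel = np.full(w, 1.0 / w)
    sm = np.convolve(seg, kernel, mode="same")
    # guard the convolution edges, where the window is truncated
    half = w // 2 + 1
    return int(np.argmin(sm[half:len(sm) - half])) + half


def resting_membrane_potential(trace: Trace, baseline_ms: float = 100.0) -> RMPResult:
    """Mean of the unstimulated baseline; flagged if above the exclusion cut.

    Requires at least 100 ms of baseline before the stimulus onset.
    """
    n = trace.sample_index(min(trace.stimulus.onset, baseline_ms))
    n = min(n, trace.sample_index(trace.stimulus.onset))
    if n * trace.dt < 100.0:
        return RMPResult(float("nan"), False)
    v = float(np.mean(trace.voltage[:n]))
    return RMPResult(v, v > RMP_EXCLUSION_MV)


def input_resistance_hold(rmp_mV: float, i_hold_pA: float,
                          holding_target: float = -65.0) -> float:
    """Ohm's-law input resistance from the holding current, in MOhm."""
    if i_hold_pA == 0 or not np.isfinite(i_hold_pA) or not np.isfinite(rmp_mV):
        return float("nan")
    return (holding_target - rmp_mV) / i_hold_pA * 1e3  # mV/pA = GOhm -> MOhm


def input_resistance_step(traces: Iterable[Trace],
                          amplitudes: Sequence[float] = (-100.0, -50.0),
                          steady_frac: float = 0.1) -> float:
    """Input resistance (MOhm) from steady-state responses to small steps.

    Least-squares slope of end-of-step voltage against injected current over
    the requested amplitudes; needs at least two usable sweeps.
    """
    pts = []
    for tr in traces:
        a = tr.stimulus.amplitude
        if a not in amplitudes:
            continue
        i0, i1 = _step_window(tr)
        seg = tr.voltage[i0:i1 + 1]
        nss = max(1, int(len(seg) * steady_frac))
        pts.append((a, float(np.mean(seg[-nss:]))))
    if len(pts) < 2:
        return float("nan")
    i = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    slope = np.polyfit(i, v, 1)[0]  # mV/pA
    return float(slope * 1e3)


def fit_membrane_tau(trace: Trace, tau_range: tuple[float, float] = (0.5, 200.0)) -> TauFit:
    """Membrane time constant from onset to the sag minimum.

    Least-squares fit of V(t) = V_ss + (V_on - V_ss) exp(-(t - t_on)/tau)
    over [stimulus onset, time of the voltage minimum] of a hyperpolarizing
    sweep.  Returns a missing value with a diagnostic when the fit fails or
    tau falls outside ``tau_range``.
    """
    if trace.stimulus.amplitude >= 0:
        return TauFit(float("nan"), False, "not a hyperpolarizing sweep")
    i0, i1 = _step_window(trace)
    seg = trace.voltage[i0:i1 + 1]
    imin = _trough_index(seg, trace.dt)
    if imin < 4:
        return TauFit(float("nan"), False, "no relaxation before minimum")
    t = np.arange(imin + 1) * trace.dt
    v = seg[:imin + 1]

    def f(t, v_ss, v_on, tau):
        return v_ss + (v_on - v_ss) * np.exp(-t / tau)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(f, t, v, p0=[v[-1], v[0], 20.0], maxfev=10000)
    except Exception as err:
        return TauFit(float("nan"), False, f"fit failed: {err}")
    tau = float(popt[2])
    if not (tau_range[0] < tau <= tau_range[1]):
        return TauFit(float("nan"), False,
                      f"tau {tau:.3g} ms outside {tau_range}")
    return TauFit(tau, True, "", v_onset=float(popt[1]), v_ss=float(popt[0]))


def measure_sag(trace: Trace, steady_frac: float = 0.1,
                trough_smooth_ms: float = 1.0) -> SagResult:
    """Sag amplitude: steady-state (last 10% of step) minus the trough, mV.

    The trough is located and read on a ~1 ms smoothed copy of the step
    segment so recording noise does not bias the minimum downward.  Clipped
    at zero; flagged when the trough sits at the step edge (no relaxation)
    or when the raw value was negative.
    """
    if trace.stimulus.amplitude >= 0:
        return SagResult(float("nan"), True)
    i0, i1 = _step_window(trace)
    seg = trace.voltage[i0:i1 + 1]
    imin = _trough_index(seg, trace.dt, trough_smooth_ms)
    half = max(1, int(round(trough_smooth_ms / trace.dt)) // 2)
    lo, hi = max(0, imin - half), min(len(seg), imin + half + 1)
    v_min = float(np.mean(seg[lo:hi]))
    nss = max(1, int(len(seg) * steady_frac))
    v_ss = float(np.mean(seg[-nss:]))
    raw = v_ss - v_min
    edge = imin <= 1 or imin >= len(seg) - nss
    return SagResult(max(raw, 0.0), flagged=edge or raw < 0)


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def detect_spikes(trace: Trace, cfg: SpikeDetectConfig = SpikeDetectConfig()) -> SpikeTrain:
    """One event per upward crossing of the voltage threshold.

    Event time = time of the local voltage maximum between the upward and
    the following downward crossing.  A trace ending mid-spike keeps the
    event and flags the train as truncated.
    """
    v = trace.voltage
    above = v >= cfg.threshold
    rises = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times, truncated = [], False
    for r in rises:
        falls = np.flatnonzero(~above[r:])
        if falls.size:
            end = r + falls[0]
        else:
            end = v.size
            truncated = True
        ipk = r + int(np.argmax(v[r:end]))
        times.append(ipk * trace.dt)
    return SpikeTrain(np.asarray(times, dtype=float), truncated)


def _dvdt(v: np.ndarray, dt: float) -> np.ndarray:
    return np.gradient(v, dt)


def _smoothed(v: np.ndarray, half: int) -> np.ndarray:
    if half <= 0:
        return v
    w = 2 * half + 1
    kernel = np.full(w, 1.0 / w)
    return np.convolve(v, kernel, mode="same")


def first_ap_features(trace: Trace,
                      cfg: SpikeDetectConfig = SpikeDetectConfig()) -> APFeatures | None:
    """Shape of the first action potential; None when there is no spike.

    Onset is the first sample of the contiguous dV/dt >= onset_dvdt run
    preceding the peak (a lightly smoothed derivative localises it);
    amplitude = peak - onset voltage; width is the full width at the voltage
    halfway between onset voltage and peak, linearly interpolated between
    samples; max dV/dt comes from raw centered differences around the peak.
    """
    train = detect_spikes(trace, cfg)
    if train.count == 0:
        return None
    dt = trace.dt
    v = trace.voltage
    ipk = int(round(train.times_ms[0] / dt))

    dv_s = _dvdt(_smoothed(v, cfg.smooth_samples), dt)
    i = ipk
    while i > 0 and dv_s[i - 1] >= cfg.onset_dvdt:
        i -= 1
    # i is the first sample of the suprathreshold-dV/dt run before the peak
    if i == ipk:  # derivative never reached criterion: fall back to threshold
        while i > 0 and v[i - 1] > cfg.threshold:
            i -= 1
    onset_v = float(v[i])
    peak_v = float(v[ipk])
    amp = peak_v - onset_v
    half_v = onset_v + 0.5 * amp

    def cross_forward(a: int, b: int, level: float) -> float:
        for k in range(a, b):
            if (v[k] - level) * (v[k + 1] - level) <= 0 and v[k] != v[k + 1]:
                frac = (level - v[k]) / (v[k + 1] - v[k])
                return (k + frac) * dt
        return float("nan")

    t_up = cross_forward(i, ipk, half_v)
    end = min(v.size - 1, ipk + int(round(20.0 / dt)))
    t_dn = cross_forward(ipk, end, half_v)
    width = t_dn - t_up

    win0 = max(0, i - 2)
    win1 = min(v.size, ipk + int(round(10.0 / dt)))
    max_dvdt = float(np.max(_dvdt(v[win0:win1], dt)))
    latency = train.times_ms[0] - trace.stimulus.onset
    return APFeatures(width=width, amplitude=amp, peak=peak_v,
                      onset_voltage=onset_v, max_dvdt=max_dvdt,
                      latency=latency)


def phase_plane(trace: Trace, cfg: SpikeDetectConfig = SpikeDetectConfig(),
                window_ms: tuple[float, float] = (-5.0, 10.0)) -> tuple[np.ndarray, np.ndarray]:
    """(V, dV/dt) pairs in a window around the first action potential."""
    train = detect_spikes(trace, cfg)
    if train.count == 0:
        raise ValueError("no spike in trace; phase plane undefined")
    dt = trace.dt
    ipk = int(round(train.times_ms[0] / dt))
    a = max(0, ipk + int(round(window_ms[0] / dt)))
    b = min(trace.voltage.size, ipk + int(round(window_ms[1] / dt)))
    v = trace.voltage[a:b]
    return v, _dvdt(v, dt)


def instantaneous_frequency(times_ms: np.ndarray, n: int = N_ISI) -> np.ndarray:
    """f_i = 1000/ISI_i (Hz) for the first ``n`` inter-spike intervals.

    Entries beyond the available ISIs are NaN.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    out = np.full(n, np.nan)
    if times_ms.size >= 2:
        isi = np.diff(times_ms)[:n]
        out[:isi.size] = 1000.0 / isi
    return out


def mean_frequency(times_ms: np.ndarray, duration_ms: float) -> float:
    """Spike count divided by the step duration, in Hz."""
    times_ms = np.asarray(times_ms)
    return float(times_ms.size / (duration_ms / 1000.0))


def isi_adaptation_index(times_ms: np.ndarray) -> float:
    """Mean of successive (ISI_{i+1} - ISI_i)/(ISI_{i+1} + ISI_i); NaN if < 3 spikes."""
    times_ms = np.asarray(times_ms, dtype=float)
    if times_ms.size < 3:
        return float("nan")
    isi = np.diff(times_ms)
    return float(np.mean((isi[1:] - isi[:-1]) / (isi[1:] + isi[:-1])))


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

def feature_columns() -> list[str]:
    """Stable, versioned column order of the feature table."""
    cols = ["rmp", "rmp_excluded", "rin_hold", "rin_step"]
    cols += [f"tau_{a}" for a in TAU_CURRENTS]
    cols += [f"sag_{a}" for a in SAG_CURRENTS]
    cols += [f"spike_count_{a}" for a in SPIKE_CURRENTS]
    for a in SPIKE_CURRENTS:
        cols += [f"ap_width_{a}", f"ap_amplitude_{a}", f"ap_peak_{a}",
                 f"ap_onset_v_{a}", f"ap_max_dvdt_{a}", f"latency_{a}"]
    cols += [f"f{i}_{FREQ_CURRENT}" for i in range(1, N_ISI + 1)]
    cols += [f"mean_freq_{FREQ_CURRENT}", f"adapt_index_{FREQ_CURRENT}"]
    return cols


def current_dependent_columns() -> list[str]:
    """The per-current feature subset used by the trace classifier."""
    return [c for c in feature_columns()
            if c not in ("rmp", "rmp_excluded", "rin_hold", "rin_step")]


def extract_cell_features(cell: CellSweeps,
                          cfg: SpikeDetectConfig = SpikeDetectConfig()) -> dict:
    """One feature-table row (dict) for a cell's sweep family."""
    row: dict[str, float] = {c: float("nan") for c in feature_columns()}
    row["rmp_excluded"] = float("nan")
    by_amp = cell.by_amplitude()

    if cell.rmp_trace is not None:
        rmp = resting_membrane_potential(cell.rmp_trace)
        row["rmp"] = rmp.value
        row["rmp_excluded"] = float(rmp.excluded)
        hold = next((t.hold_current_pA for t in cell.traces
                     if t.hold_current_pA is not None), None)
        if hold is not None and np.isfinite(rmp.value):
            row["rin_hold"] = input_resistance_hold(
                rmp.value, hold, cell.traces[0].stimulus.holding_target)

    row["rin_step"] = input_resistance_step(cell.traces)

    for a in TAU_CURRENTS:
        tr = by_amp.get(float(a))
        if tr is not None:
            row[f"tau_{a}"] = fit_membrane_tau(tr).tau
    for a in SAG_CURRENTS:
        tr = by_amp.get(float(a))
        if tr is not None:
            row[f"sag_{a}"] = measure_sag(tr).sag

    for a in SPIKE_CURRENTS:
        tr = by_amp.get(float(a))
        if tr is None:
            continue
        train = detect_spikes(tr, cfg)
        row[f"spike_count_{a}"] = float(train.count)
        if train.count:
            ap = first_ap_features(tr, cfg)
            if ap is not None:
                row[f"ap_width_{a}"] = ap.width
                row[f"ap_amplitude_{a}"] = ap.amplitude
                row[f"ap_peak_{a}"] = ap.peak
                row[f"ap_onset_v_{a}"] = ap.onset_voltage
                row[f"ap_max_dvdt_{a}"] = ap.max_dvdt
                row[f"latency_{a}"] = ap.latency
        if a == FREQ_CURRENT:
            fi = instantaneous_frequency(train.times_ms)
            for i in range(N_ISI):
                row[f"f{i + 1}_{FREQ_CURRENT}"] = fi[i]
            row[f"mean_freq_{FREQ_CURRENT}"] = mean_frequency(
                train.times_ms, tr.stimulus.duration)
            row[f"adapt_index_{FREQ_CURRENT}"] = isi_adaptation_index(
                train.times_ms)
    return row


def extract_feature_table(cells: Iterable[CellSweeps],
                          cfg: SpikeDetectConfig = SpikeDetectConfig()) -> pd.DataFrame:
    """Per-cell feature table: one row per cell, indexed (cell_id, group).

    Malformed sweep sets are skipped with a warning, never silently.
    """
    rows, index = [], []
    for cell in cells:
        if not cell.traces:
            warnings.warn(f"cell {cell.cell_id}: no sweeps, skipped")
            continue
        try:
            rows.append(extract_cell_features(cell, cfg))
        except Exception as err:
            warnings.warn(f"cell {cell.cell_id}: extraction failed ({err}), skipped")
            continue
        index.append((cell.cell_id, cell.group_label))
    df = pd.DataFrame(rows, columns=feature_columns(),
                      index=pd.MultiIndex.from_tuples(index or [],
                                                      names=["cell_id", "group_label"]))
    return df
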