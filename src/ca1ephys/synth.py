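"""Synthetic patch-clamp cohorts with known ground truth.

Generates labelled groups of model cells whose subthreshold behaviour comes
from the packaged per-group parameter sets (with lognormal between-cell
variation) and whose spiking sweeps are built by splicing a parametric AP
template onto a stylized integrate-and-fire trajectory.  Spike times follow
the group's rate model (rate = slope * (I - rheobase), geometric ISI
adaptation), so spike count, instantaneous frequencies and AP width have
exact, controllable ground truth — the point of the generator is to give the
feature extractor something to be checked against.

Subthreshold sweeps are exact model simulations plus additive white noise;
with zero noise they are bit-identical to ``simulate_step`` output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .biophys import (
    CellModel,
    StimulusStep,
    Trace,
    cell_model_for_group,
    compute_holding_current,
    default_protocol,
    load_group_params,
    simulate_step,
    steady_state_voltage,
    with_params,
)
from .features import CellSweeps, measure_sag

__all__ = [
    "APTemplate",
    "SpikingSpec",
    "GroupSpec",
    "CohortSpec",
    "SyntheticCell",
    "Cohort",
    "CalibrationError",
    "default_group_specs",
    "sample_cell",
    "synthesize_sweeps",
    "calibrate_sag",
    "generate_cohort",
]

# cohort sizes of the recorded dataset the generator emulates
DEFAULT_N_CELLS = {"WT-1m": 14, "WT-4m": 12, "WT-10m": 19,
                   "AD-1m": 11, "AD-4m": 15, "AD-10m": 21}


class CalibrationError(RuntimeError):
    """Sag calibration target outside the attainable range."""


@dataclass(frozen=True)
class APTemplate:
    """Triangular action-potential template spliced into spiking sweeps.

    The rise and fall are linear, so the full width at half height between
    onset voltage (= peak - amplitude) and peak is exactly
    (rise + fall)/2 = ``width_ms``, giving exact shape ground truth.
    """

    width_ms: float = 1.2
    amplitude_mV: float = 85.0
    peak_mV: float = 35.0
    rise_fraction: float = 0.3
    ahp_mV: float = 8.0
    approach_dvdt: float = 10.0  # mV/ms, sub-criterion take-off ramp

    def __post_init__(self) -> None:
        if self.width_ms <= 0 or self.amplitude_mV <= 0:
            raise ValueError("template width and amplitude must be positive")
        if not (0.05 < self.rise_fraction < 0.95):
            raise ValueError("rise_fraction must be in (0.05, 0.95)")

    @property
    def onset_mV(self) -> float:
        return self.peak_mV - self.amplitude_mV

    @property
    def rise_ms(self) -> float:
        return 2.0 * self.width_ms * self.rise_fraction

    @property
    def fall_ms(self) -> float:
        return 2.0 * self.width_ms * (1.0 - self.rise_fraction)

    @property
    def fall_total_ms(self) -> float:
        """Duration of the linear fall from peak down to the AHP trough.

        The fall continues past the onset voltage to onset - ahp at the same
        slope, so the half-height crossing stays at fall_ms/2 and the width
        ground truth remains exact.
        """
        return self.fall_ms * (self.amplitude_mV + self.ahp_mV) / self.amplitude_mV


@dataclass(frozen=True)
class SpikingSpec:
    """Firing phenomenology of a synthetic cell.

    rheobase_pA : smallest current that elicits spikes
    fi_slope : mean firing rate per pA above rheobase, Hz/pA
    adaptation_ratio : ISI_10 / ISI_1 of the scheduled train (geometric)
    """

    rheobase_pA: float = 100.0
    fi_slope: float = 0.12
    adaptation_ratio: float = 1.5
    template: APTemplate = field(default_factory=APTemplate)

    def rate_hz(self, amplitude_pA: float) -> float:
        return max(0.0, self.fi_slope * (amplitude_pA - self.rheobase_pA))

    def isi_schedule(self, amplitude_pA: float, n_max: int = 200) -> np.ndarray:
        """Geometric ISI sequence whose first-10 mean matches the rate."""
        rate = self.rate_hz(amplitude_pA)
        if rate <= 0:
            return np.empty(0)
        T = 1000.0 / rate
        g = self.adaptation_ratio ** (1.0 / 9.0)
        if abs(g - 1.0) < 1e-12:
            isi1 = T
        else:
            isi1 = T * 10.0 * (g - 1.0) / (g ** 10 - 1.0)
        return isi1 * g ** np.arange(n_max)


@dataclass
class GroupSpec:
    """Recipe for one cohort group.

    label : group name; when ``params`` is None the packaged parameter row
        for this label is used
    cv : lognormal coefficient of variation applied per parameter
    noise_sd : additive white recording noise, mV
    sag_targets : optional {amplitude_pA: sag_mV} calibration targets
    """

    label: str
    n_cells: int = 10
    params: dict[str, float] | None = None
    cv: float = 0.1
    noise_sd: float = 0.2
    spiking: SpikingSpec = field(default_factory=SpikingSpec)
    sag_targets: dict[float, float] | None = None
    Cm: float = 1.0
    E_h: float = -30.0
    calibration_info: dict | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.cv < 0 or self.noise_sd < 0:
            raise ValueError("cv and noise_sd must be >= 0")
        if self.params is None:
            self.params = dict(load_group_params()[self.label])

    def mean_model(self) -> CellModel:
        base = cell_model_for_group(self.label, Cm=self.Cm, E_h=self.E_h)
        return with_params(base, **self.params)


@dataclass
class CohortSpec:
    groups: list[GroupSpec]
    amplitudes: Sequence[float] | None = None
    dt: float = 0.025
    master_seed: int = 0

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")


@dataclass
class SyntheticCell:
    cell_id: str
    group_label: str
    model: CellModel
    spiking: SpikingSpec
    seed: int


@dataclass
class Cohort:
    """Generated cohort: sweeps per cell plus the ground-truth manifest."""

    cells: list[CellSweeps]
    manifest: dict
    spec: CohortSpec


def default_group_specs(n_cells: dict[str, int] | None = None,
                        cv: float = 0.1, noise_sd: float = 0.2) -> list[GroupSpec]:
    """The six study groups with their emulated firing phenotypes.

    Spiking defaults encode the qualitative findings being emulated: wider
    first AP in the amyloidopathy-free mutant group, narrower (~12-15%) with
    developing amyloidopathy, and lower instantaneous frequency in the
    strong-amyloidopathy mutants.
    """
    n = dict(DEFAULT_N_CELLS)
    if n_cells:
        n.update(n_cells)
    widths = {"WT-1m": 1.20, "AD-1m": 1.35, "WT-4m": 1.20, "AD-4m": 1.05,
              "WT-10m": 1.20, "AD-10m": 1.02}
    slopes = {"WT-1m": 0.120, "AD-1m": 0.100, "WT-4m": 0.120, "AD-4m": 0.120,
              "WT-10m": 0.120, "AD-10m": 0.105}
    out = []
    for label in ("WT-1m", "AD-1m", "WT-4m", "AD-4m", "WT-10m", "AD-10m"):
        spk = SpikingSpec(fi_slope=slopes[label],
                          template=APTemplate(width_ms=widths[label]))
        out.append(GroupSpec(label=label, n_cells=n[label], cv=cv,
                             noise_sd=noise_sd, spiking=spk))
    return out


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

_LOGNORMAL_FIELDS = ("Rm", "gbar", "a0t", "zetat")
_MAGNITUDE_FIELDS = ("e_pas", "Vl_half", "kl", "Vt_half")  # negative-valued


def _ln_mult(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal multiplier with the given coefficient of variation."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return math.exp(rng.normal(0.0, sigma) - 0.5 * sigma * sigma)


def sample_cell(g: GroupSpec, seed: int, cell_id: str | None = None) -> SyntheticCell:
    """Draw one cell: lognormal multiplicative variation around group means."""
    rng = np.random.default_rng(seed)
    p = dict(g.params)
    for k in _LOGNORMAL_FIELDS:
        p[k] = p[k] * _ln_mult(rng, g.cv)
    for k in _MAGNITUDE_FIELDS:
        p[k] = -abs(p[k]) * _ln_mult(rng, g.cv)
    p["e_pas"] = float(np.clip(p["e_pas"], -119.0, -41.0))
    model = with_params(g.mean_model(), **p)

    spk = g.spiking
    spk = replace(
        spk,
        rheobase_pA=spk.rheobase_pA * _ln_mult(rng, g.cv),
        fi_slope=spk.fi_slope * _ln_mult(rng, g.cv),
        template=replace(spk.template,
                         width_ms=spk.template.width_ms * _ln_mult(rng, g.cv / 2),
                         amplitude_mV=spk.template.amplitude_mV * _ln_mult(rng, g.cv / 2)),
    )
    return SyntheticCell(cell_id=cell_id or f"{g.label}-c{seed}",
                         group_label=g.label, model=model, spiking=spk,
                         seed=seed)


# ---------------------------------------------------------------------------
# sweep synthesis
# ---------------------------------------------------------------------------

def _spike_peak_times(spk: SpikingSpec, stim: StimulusStep) -> np.ndarray:
    """Scheduled AP peak times (ms, absolute) inside the step window."""
    isis = spk.isi_schedule(stim.amplitude)
    if isis.size == 0:
        return np.empty(0)
    peaks = stim.onset + isis[0] / 2.0 + np.concatenate([[0.0], np.cumsum(isis[:-1])])
    t_end = stim.onset + stim.duration - spk.template.fall_total_ms
    return peaks[peaks <= t_end]


def _render_spiking_sweep(cell: SyntheticCell, stim: StimulusStep, dt: float,
                          tau_m_ms: float, hold_pA: float) -> tuple[np.ndarray, np.ndarray]:
    """Stylized suprathreshold sweep: IF-style charge-up segments between
    scheduled spikes, each spike rendered from the triangular template.

    Returns (voltage, spike peak times).
    """
    tpl = cell.spiking.template
    n = int(round(stim.total_ms / dt)) + 1
    t = np.arange(n) * dt
    v = np.full(n, stim.holding_target)
    peaks = _spike_peak_times(cell.spiking, stim)

    on, off = stim.onset, stim.onset + stim.duration
    i_on, i_off = int(round(on / dt)), int(round(off / dt))
    v_ceil = tpl.onset_mV          # IF trajectories relax toward AP take-off
    v_reset = tpl.onset_mV - tpl.ahp_mV

    def charge(i0: int, i1: int, v0: float) -> None:
        tt = (np.arange(i0, i1) - i0) * dt
        v[i0:i1] = v_ceil + (v0 - v_ceil) * np.exp(-tt / tau_m_ms)

    cursor, v_prev = i_on, stim.holding_target
    for pk in peaks:
        i_rise0 = int(round((pk - tpl.rise_ms) / dt))
        # sub-criterion approach ramp bridges the IF trajectory to take-off
        v_at_ramp_start = v_ceil + (v_prev - v_ceil) * math.exp(
            -max(i_rise0 - cursor, 0) * dt / tau_m_ms)
        gap = tpl.onset_mV - v_at_ramp_start
        ramp_samples = max(0, int(round(abs(gap) / tpl.approach_dvdt / dt)))
        i_ramp0 = max(cursor, i_rise0 - ramp_samples)
        charge(cursor, i_ramp0, v_prev)
        if i_rise0 > i_ramp0:
            v[i_ramp0:i_rise0] = np.linspace(v[i_ramp0 - 1] if i_ramp0 > cursor
                                             else v_prev, tpl.onset_mV,
                                             i_rise0 - i_ramp0, endpoint=False)
        ipk = int(round(pk / dt))
        i_fall1 = int(round((pk + tpl.fall_total_ms) / dt))
        rise_n = max(ipk - i_rise0, 1)
        v[i_rise0:ipk + 1] = tpl.onset_mV + (tpl.peak_mV - tpl.onset_mV) * \
            np.arange(rise_n + 1) / rise_n
        fall_n = max(i_fall1 - ipk, 1)
        v[ipk:i_fall1 + 1] = tpl.peak_mV - (tpl.peak_mV - v_reset) * \
            np.arange(fall_n + 1) / fall_n
        cursor, v_prev = i_fall1 + 1, v_reset
    charge(cursor, i_off, v_prev)
    v_at_off = v[i_off - 1] if i_off > cursor else v_prev
    tt = (np.arange(i_off, n) - i_off) * dt
    v[i_off:] = stim.holding_target + (v_at_off - stim.holding_target) * \
        np.exp(-tt / tau_m_ms)
    return v, peaks


def synthesize_sweeps(cell: SyntheticCell, protocol: Sequence[StimulusStep] | None,
                      dt: float, noise_sd: float,
                      rng: np.random.Generator) -> tuple[list[Trace], dict]:
    """Full sweep family for one cell plus its ground-truth record."""
    if protocol is None:
        protocol = default_protocol()
    model = cell.model
    hold = compute_holding_current(model, protocol[0].holding_target)
    rest = steady_state_voltage(model, 0.0)
    tau_m = model.passive.tau_ms

    truth: dict = {"params": {**{k: getattr(model.passive, k) for k in ("Rm", "Cm", "e_pas")},
                              **{k: getattr(model.ih, k) for k in
                                 ("gbar", "E_h", "Vl_half", "kl", "Vt_half",
                                  "a0t", "zetat", "gmt")}},
                   "hold_current_pA": hold, "rmp_mV": rest,
                   "template_width_ms": cell.spiking.template.width_ms,
                   "template_peak_mV": cell.spiking.template.peak_mV,
                   "template_amplitude_mV": cell.spiking.template.amplitude_mV,
                   "rheobase_pA": cell.spiking.rheobase_pA,
                   "fi_slope": cell.spiking.fi_slope,
                   "seed": cell.seed,
                   "sweeps": {}}

    traces: list[Trace] = []
    for k, stim in enumerate(protocol):
        rate = cell.spiking.rate_hz(stim.amplitude)
        sweep_truth: dict = {"amplitude_pA": stim.amplitude}
        if stim.amplitude > 0 and rate > 0:
            v, peaks = _render_spiking_sweep(cell, stim, dt, tau_m, hold)
            sweep_truth["spike_times_ms"] = [float(x) for x in peaks]
            sweep_truth["spike_count"] = int(peaks.size)
            if peaks.size >= 2:
                isi = np.diff(peaks)[:10]
                sweep_truth["instantaneous_freq_hz"] = [float(1000.0 / x) for x in isi]
        else:
            clean = simulate_step(model, stim, dt, hold_current_pA=hold)
            v = clean.voltage
            sweep_truth["spike_times_ms"] = []
            sweep_truth["spike_count"] = 0
            if stim.amplitude < 0:
                sweep_truth["sag_mV"] = measure_sag(clean).sag
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, v.size)
        traces.append(Trace(dt=dt, voltage=v, stimulus=stim,
                            cell_id=cell.cell_id, group_label=cell.group_label,
                            sweep_id=f"sweep{k:02d}", hold_current_pA=hold))
        truth["sweeps"][f"{stim.amplitude:+.0f}"] = sweep_truth

    # unbiased sweep at the open-circuit resting potential, for RMP
    rmp_stim = StimulusStep(amplitude=0.0, onset=100.0, duration=400.0,
                            holding_target=rest, pre=100.0, post=100.0)
    clean = simulate_step(model, rmp_stim, dt, hold_current_pA=0.0)
    v = clean.voltage
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, v.size)
    rmp_trace = Trace(dt=dt, voltage=v, stimulus=rmp_stim,
                      cell_id=cell.cell_id, group_label=cell.group_label,
                      sweep_id="rmp", hold_current_pA=0.0)
    return traces, {"rmp_trace": rmp_trace, "truth": truth}


# ---------------------------------------------------------------------------
# sag calibration
# ---------------------------------------------------------------------------

def _group_mean_sag(g: GroupSpec, amplitudes: Sequence[float],
                    dt: float = 0.05) -> np.ndarray:
    model = g.mean_model()
    out = []
    for a in amplitudes:
        tr = simulate_step(model, StimulusStep(amplitude=float(a)), dt)
        out.append(measure_sag(tr).sag)
    return np.asarray(out)


def calibrate_sag(g: GroupSpec, targets: dict[float, float],
                  tol: float = 0.02, scale_kl: bool = True,
                  on_unachievable: str = "raise") -> GroupSpec:
    """Scale gbar (and, when needed, kl) so the noiseless group-mean sag
    matches the target at each amplitude within ``tol`` (relative).

    The least-squares knobs are a gbar factor (up to x20) and a kl factor
    (x0.4 to x2.5).  When the joint targets cannot be reached,
    ``on_unachievable`` decides: "raise" (default) raises CalibrationError
    reporting the attainable values; "best" returns the least-squares
    compromise with the residuals recorded in ``calibration_info``.
    """
    if on_unachievable not in ("raise", "best"):
        raise ValueError("on_unachievable must be 'raise' or 'best'")
    amps = sorted(targets)
    want = np.array([float(targets[a]) for a in amps])
    if np.any(want < 0):
        raise ValueError("sag targets must be >= 0")

    def make(x: np.ndarray) -> GroupSpec:
        s_g = math.exp(x[0])
        s_k = math.exp(x[1]) if scale_kl else 1.0
        p = dict(g.params)
        p["gbar"] = g.params["gbar"] * s_g
        p["kl"] = g.params["kl"] * s_k
        return replace(g, params=p, sag_targets=dict(targets))

    if np.allclose(want, 0.0):
        p = dict(g.params)
        p["gbar"] = 0.0
        return replace(g, params=p, sag_targets=dict(targets))

    def resid(x: np.ndarray) -> np.ndarray:
        got = _group_mean_sag(make(x), amps)
        return (got - want) / np.maximum(want, 1e-6)

    x0 = np.zeros(2)
    lo = np.array([math.log(1e-3), math.log(0.4)])
    hi = np.array([math.log(20.0), math.log(2.5)])
    if not scale_kl:
        lo[1], hi[1] = -1e-9, 1e-9
    sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-10, ftol=1e-12,
                        diff_step=1e-4)
    final = resid(sol.x)
    got = _group_mean_sag(make(sol.x), amps)
    info = {"targets": {a: float(t) for a, t in zip(amps, want)},
            "achieved": {a: float(v) for a, v in zip(amps, got)},
            "relative_error": {a: float(r) for a, r in zip(amps, final)},
            "gbar_scale": math.exp(sol.x[0]),
            "kl_scale": math.exp(sol.x[1]) if scale_kl else 1.0,
            "within_tol": bool(np.all(np.abs(final) <= tol))}
    if not info["within_tol"] and on_unachievable == "raise":
        raise CalibrationError(
            f"targets {info['targets']} unattainable; closest "
            f"{ {a: round(v, 3) for a, v in info['achieved'].items()} } "
            f"(gbar x{info['gbar_scale']:.2f}, kl x{info['kl_scale']:.2f})")
    out = make(sol.x)
    out.calibration_info = info
    return out


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate every group of ``spec``; fully reproducible from master seed."""
    protocol = default_protocol(spec.amplitudes)
    ss = np.random.SeedSequence(spec.master_seed)
    group_seeds = ss.spawn(len(spec.groups))
    cells: list[CellSweeps] = []
    manifest: dict = {"master_seed": spec.master_seed, "dt": spec.dt,
                      "amplitudes": [s.amplitude for s in protocol],
                      "groups": {}, "cells": {}}
    for g, gseed in zip(spec.groups, group_seeds):
        child = gseed.spawn(g.n_cells)
        manifest["groups"][g.label] = {
            "n_cells": g.n_cells, "cv": g.cv, "noise_sd": g.noise_sd,
            "params": dict(g.params),
            "rheobase_pA": g.spiking.rheobase_pA,
            "fi_slope": g.spiking.fi_slope,
            "adaptation_ratio": g.spiking.adaptation_ratio,
            "template_width_ms": g.spiking.template.width_ms,
        }
        for i, cseed in enumerate(child):
            cell_seed = int(cseed.generate_state(1)[0] % (2 ** 31))
            cell_id = f"{g.label}-c{i:02d}"
            cell = sample_cell(g, cell_seed, cell_id=cell_id)
            rng = np.random.default_rng(cseed)
            traces, extra = synthesize_sweeps(cell, protocol, spec.dt,
                                              g.noise_sd, rng)
            cells.append(CellSweeps(cell_id=cell_id, group_label=g.label,
                                    traces=traces,
                                    rmp_trace=extra["rmp_trace"]))
            manifest["cells"][cell_id] = extra["truth"]
    return Cohort(cells=cells, manifest=manifest, spec=spec)
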