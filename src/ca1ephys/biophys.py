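"""Reduced CA1 pyramidal-neuron model: leak conductance plus the
hyperpolarization-activated cation current I_h.

The membrane is a single isopotential compartment (an optional ball-and-stick
mode adds a passive dendrite with a sigmoidal I_h density gradient).  I_h uses
the Borg-Graham thermodynamic formulation: a single gating variable ``l`` with

    l_inf(V)  = 1 / (1 + exp(-(V - Vl_half)/kl))          (kl < 0, so l_inf
                                                           falls with V)
    alpha(V)  = exp(c * zetat * (V - Vt_half))
    beta(V)   = exp(c * zetat * gmt * (V - Vt_half))
    tau_l(V)  = beta / (q_t * a0t * (1 + alpha))           q_t = q10^((T-T_ref)/10)

and the membrane balance (mV, ms, Ohm*cm^2, uF/cm^2, S/cm^2, pA, cm^2)

    Cm dV/dt = -(V - e_pas)/Rm - gbar*l*(V - E_h) + (I_inj + I_hold)/area.

Simulations run at 34 degC by default.  Voltages are in mV, times in ms,
currents in pA throughout the public API.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PassiveParams",
    "IhParams",
    "Geometry",
    "CellModel",
    "StimulusStep",
    "Trace",
    "IntegrationError",
    "NonClampableError",
    "GROUP_LABELS",
    "load_group_params",
    "cell_model_for_group",
    "ih_steady_state",
    "ih_time_constant",
    "compute_holding_current",
    "steady_state_voltage",
    "simulate_step",
    "run_protocol",
    "default_protocol",
]

# thermodynamic slope constant F/(R*T) at ~34 degC, in 1/mV
C_THERMO = 0.0378
EXP_CLAMP = 50.0  # |exponent| clamp in alpha/beta to avoid overflow

GROUP_LABELS = ("WT-1m", "AD-1m", "WT-4m", "AD-4m", "WT-10m", "AD-10m")


class IntegrationError(RuntimeError):
    """Numerical blow-up (|V| > 200 mV) during integration."""


class NonClampableError(RuntimeError):
    """No bias current brings the model's steady state to the target voltage."""


@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane properties.

    Rm : specific membrane resistance, Ohm*cm^2
    Cm : specific capacitance, uF/cm^2
    e_pas : leak reversal potential, mV
    """

    Rm: float
    Cm: float = 1.0
    e_pas: float = -88.0

    def __post_init__(self) -> None:
        if not (self.Rm > 0 and self.Cm > 0):
            raise ValueError("Rm and Cm must be positive")
        if not (-120.0 <= self.e_pas <= -40.0):
            raise ValueError("e_pas outside physiological range [-120, -40] mV")

    @property
    def tau_ms(self) -> float:
        """Passive membrane time constant Rm*Cm in ms."""
        return self.Rm * self.Cm * 1e-3


@dataclass(frozen=True)
class IhParams:
    """Kinetic parameters of the hyperpolarization-activated current.

    gbar : peak conductance, S/cm^2
    E_h : reversal potential, mV
    Vl_half, kl : half-activation voltage (mV) and shape factor (mV, < 0)
    Vt_half, a0t, zetat, gmt : time-constant voltage dependence
    q10, T_ref : temperature scaling of the rate
    """

    gbar: float
    E_h: float = -30.0
    Vl_half: float = -90.0
    kl: float = -12.0
    Vt_half: float = -83.0
    a0t: float = 3.0e-3
    zetat: float = 5.0
    gmt: float = 0.45
    q10: float = 4.5
    T_ref: float = 33.0

    def __post_init__(self) -> None:
        if self.gbar < 0:
            raise ValueError("gbar must be >= 0")
        if self.kl >= 0:
            raise ValueError("kl must be negative (activation on hyperpolarization)")
        if self.a0t <= 0:
            raise ValueError("a0t must be positive")
        if not (0.0 < self.gmt < 1.0):
            raise ValueError("gmt must lie in (0, 1)")
        if self.q10 <= 0:
            raise ValueError("q10 must be positive")


@dataclass(frozen=True)
class Geometry:
    """Compartmental layout.

    mode 'single' uses one compartment of membrane area ``area_cm2``.
    mode 'ball-and-stick' adds ``n_seg`` passive dendritic segments of the
    given length/diameter with I_h density rising sigmoidally with distance:
    g(x) = gbar * (1 + A_f / (1 + exp((d_half - x)/z))).
    """

    mode: str = "single"
    area_cm2: float = 2.0e-4
    dend_length_um: float = 400.0
    dend_diam_um: float = 2.0
    n_seg: int = 5
    A_f: float = 8.0
    d_half_um: float = 280.0
    z_um: float = 50.0

    def __post_init__(self) -> None:
        if self.mode not in ("single", "ball-and-stick"):
            raise ValueError(f"unknown geometry mode {self.mode!r}")
        if self.area_cm2 <= 0:
            raise ValueError("area must be positive")
        if self.A_f < 0 or self.z_um <= 0:
            raise ValueError("sigmoid parameters invalid (A_f >= 0, z > 0)")


@dataclass(frozen=True)
class CellModel:
    """Complete model cell: passive + I_h + geometry at a given temperature."""

    passive: PassiveParams
    ih: IhParams
    geom: Geometry = field(default_factory=Geometry)
    temperature: float = 34.0


@dataclass(frozen=True)
class StimulusStep:
    """Square current step riding on a holding bias.

    amplitude in pA; onset/duration and the pre/post padding in ms;
    holding_target is the voltage (mV) the bias current clamps before onset.
    """

    amplitude: float
    onset: float = 100.0
    duration: float = 400.0
    holding_target: float = -65.0
    pre: float = 100.0
    post: float = 100.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.onset < self.pre:
            object.__setattr__(self, "onset", self.pre)

    @property
    def total_ms(self) -> float:
        return self.onset + self.duration + self.post


@dataclass(frozen=True)
class Trace:
    """One current-clamp sweep on a uniform time grid.

    ``hold_current_pA`` records the bias current applied throughout the sweep
    (known in both real recordings and simulations); it is used by the
    holding-based input-resistance estimate and by the fitter.
    """

    dt: float
    voltage: np.ndarray
    stimulus: StimulusStep
    cell_id: str = ""
    group_label: str = ""
    sweep_id: str = ""
    hold_current_pA: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage, dtype=float)
        object.__setattr__(self, "voltage", v)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(v)):
            raise ValueError("voltage contains non-finite samples")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.voltage.size) * self.dt

    def sample_index(self, t_ms: float) -> int:
        return int(round(t_ms / self.dt))


# ---------------------------------------------------------------------------
# channel kinetics
# ---------------------------------------------------------------------------

def ih_steady_state(V, p: IhParams):
    """Steady-state activation l_inf(V) of I_h; in (0, 1), decreasing in V."""
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("V must be finite")
    x = np.clip(-(V - p.Vl_half) / p.kl, -EXP_CLAMP, EXP_CLAMP)
    out = 1.0 / (1.0 + np.exp(x))
    return float(out) if out.ndim == 0 else out


def _qt(p: IhParams, temperature: float) -> float:
    return p.q10 ** ((temperature - p.T_ref) / 10.0)


def ih_time_constant(V, p: IhParams, temperature: float = 34.0):
    """Activation time constant tau_l(V) in ms (always positive)."""
    V = np.asarray(V, dtype=float)
    za = np.clip(C_THERMO * p.zetat * (V - p.Vt_half), -EXP_CLAMP, EXP_CLAMP)
    zb = np.clip(C_THERMO * p.zetat * p.gmt * (V - p.Vt_half), -EXP_CLAMP, EXP_CLAMP)
    alpha = np.exp(za)
    beta = np.exp(zb)
    tau = beta / (_qt(p, temperature) * p.a0t * (1.0 + alpha))
    return float(tau) if tau.ndim == 0 else tau


# ---------------------------------------------------------------------------
# steady states and holding current
# ---------------------------------------------------------------------------

def _membrane_current_density(V: float, m: CellModel) -> float:
    """Total intrinsic current density at voltage V with l = l_inf(V), mA/cm^2."""
    l = ih_steady_state(V, m.ih)
    return -(V - m.passive.e_pas) / m.passive.Rm - m.ih.gbar * l * (V - m.ih.E_h)


def compute_holding_current(model: CellModel, target: float = -65.0) -> float:
    """Bias current (pA) that holds the membrane at ``target`` mV.

    At steady state l = l_inf(target) and the algebraic balance is explicit:
    I_hold = -area * I_intrinsic(target).  In ball-and-stick mode the
    dendritic steady state is solved jointly.  Raises NonClampableError if
    the result is non-finite.
    """
    if model.geom.mode == "ball-and-stick":
        _, i_pA = _cable_steady_state(model, target)
        if not math.isfinite(i_pA):
            raise NonClampableError(f"cannot clamp model at {target} mV")
        return float(i_pA)
    i_density = _membrane_current_density(target, model)  # mA/cm^2 (mV/Ohm/cm^2)
    i_pA = -i_density * model.geom.area_cm2 * 1e9
    if not math.isfinite(i_pA):
        raise NonClampableError(f"cannot clamp model at {target} mV")
    return i_pA


def steady_state_voltage(model: CellModel, i_inj_pA: float,
                         bracket: tuple[float, float] = (-150.0, 20.0)) -> float:
    """Voltage (mV) solving the coupled steady state at total injected current.

    Root of  I_intrinsic(V) + I_inj/area = 0  with l = l_inf(V), found by
    bisection (brentq).  Used both by the simulator contract and as an
    independent check on end-of-step voltages.
    """
    extra = i_inj_pA * 1e-9 / model.geom.area_cm2  # mA/cm^2

    def f(V: float) -> float:
        return _membrane_current_density(V, model) + extra

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise NonClampableError("no steady state in bracket "
                                f"[{lo}, {hi}] mV for I = {i_inj_pA} pA")
    return brentq(f, lo, hi, xtol=1e-10)


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

def _integrate_py(v0, l0, dt, rm, cm, e_pas, gbar, e_h,
                  vl_half, kl, vt_half, a0t, zetat, gmt, qt,
                  i_dens, v_out, l_out):
    """Advance the coupled (V, l) system over the samples of ``i_dens``.

    ``i_dens`` holds the total injected current density (mA/cm^2) at every
    sample.  The gating variable relaxes exactly toward l_inf(V) over each dt
    and the voltage takes a backward-Euler step of the (linear in V given l)
    membrane equation; the scheme is unconditionally stable.  Returns the
    index of numerical blow-up, or -1.
    """
    n = i_dens.shape[0]
    v, l = v0, l0
    v_out[0] = v
    l_out[0] = l
    for k in range(1, n):
        x = -(v - vl_half) / kl
        if x > EXP_CLAMP:
            x = EXP_CLAMP
        elif x < -EXP_CLAMP:
            x = -EXP_CLAMP
        linf = 1.0 / (1.0 + math.exp(x))
        za = C_THERMO * zetat * (v - vt_half)
        if za > EXP_CLAMP:
            za = EXP_CLAMP
        elif za < -EXP_CLAMP:
            za = -EXP_CLAMP
        zb = C_THERMO * zetat * gmt * (v - vt_half)
        if zb > EXP_CLAMP:
            zb = EXP_CLAMP
        elif zb < -EXP_CLAMP:
            zb = -EXP_CLAMP
        tau = math.exp(zb) / (qt * a0t * (1.0 + math.exp(za)))
        l = linf + (l - linf) * math.exp(-dt / tau)
        # factor 1000 converts mA/cm^2 to uA/cm^2 against Cm in uF/cm^2
        g = 1000.0 * (1.0 / rm + gbar * l)
        b = 1000.0 * (e_pas / rm + gbar * l * e_h) + 1000.0 * i_dens[k]
        v = (v + dt / cm * b) / (1.0 + dt / cm * g)
        if abs(v) > 200.0:
            return k
        v_out[k] = v
        l_out[k] = l
    return -1


try:  # pragma: no cover - exercised indirectly everywhere
    from numba import njit

    _integrate_nb = njit(cache=True, fastmath=False)(_integrate_py)
except Exception:  # pragma: no cover
    _integrate_nb = None


def _integrate(*args):
    if _integrate_nb is not None:
        return _integrate_nb(*args)
    return _integrate_py(*args)  # pragma: no cover


def integrate_segment(model: CellModel, v0: float, l0: float,
                      i_total_pA, dt: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Low-level entry: integrate from state (v0, l0) under a per-sample
    total injected current (pA, scalar or array).  Returns (V, l, blow_index).
    """
    i_total_pA = np.asarray(i_total_pA, dtype=float)
    i_dens = i_total_pA * 1e-9 / model.geom.area_cm2
    v_out = np.empty(i_dens.shape[0])
    l_out = np.empty(i_dens.shape[0])
    p, q = model.passive, model.ih
    blew = _integrate(
        float(v0), float(l0), float(dt), float(p.Rm), float(p.Cm),
        float(p.e_pas), float(q.gbar), float(q.E_h), float(q.Vl_half),
        float(q.kl), float(q.Vt_half), float(q.a0t), float(q.zetat),
        float(q.gmt), float(_qt(q, model.temperature)), i_dens, v_out, l_out)
    return v_out, l_out, blew


def stimulus_current_array(stim: StimulusStep, dt: float,
                           hold_current_pA: float) -> np.ndarray:
    """Total injected current (pA) at every sample of the sweep."""
    n = int(round(stim.total_ms / dt)) + 1
    i = np.full(n, hold_current_pA)
    on = int(round(stim.onset / dt))
    off = int(round((stim.onset + stim.duration) / dt))
    i[on:off] += stim.amplitude
    return i


def simulate_step(model: CellModel, stim: StimulusStep, dt: float = 0.025,
                  hold_current_pA: float | None = None) -> Trace:
    """Simulate one current step and return the voltage Trace.

    The accuracy contract is the grid-refinement invariant: halving dt moves
    no voltage sample by more than 0.05 mV at the default dt = 0.025 ms.
    When ``hold_current_pA`` is not given it is computed so the pre-stimulus
    baseline sits at the stimulus' holding target.
    """
    if dt > 0.1:
        raise ValueError("dt must be <= 0.1 ms")
    if model.geom.mode == "ball-and-stick":
        return _simulate_step_cable(model, stim, dt, hold_current_pA)
    if hold_current_pA is None:
        hold_current_pA = compute_holding_current(model, stim.holding_target)
    i_pA = stimulus_current_array(stim, dt, hold_current_pA)
    v0 = stim.holding_target
    l0 = ih_steady_state(v0, model.ih)
    out, _, blew = integrate_segment(model, v0, l0, i_pA, dt)
    if blew >= 0:
        raise IntegrationError(
            f"|V| exceeded 200 mV at t = {blew * dt:.3f} ms "
            f"(amplitude {stim.amplitude} pA)")
    return Trace(dt=dt, voltage=out, stimulus=stim,
                 hold_current_pA=hold_current_pA)


# ---------------------------------------------------------------------------
# optional ball-and-stick mode: soma + passive dendrite carrying a sigmoidal
# I_h density gradient g_h(x) = gbar * (1 + A_f / (1 + exp((d_half - x)/z)))
# ---------------------------------------------------------------------------

RA_OHM_CM = 150.0  # axial resistivity


def _cable_layout(model: CellModel):
    g = model.geom
    nseg = g.n_seg
    seg_len_cm = (g.dend_length_um / nseg) * 1e-4
    seg_area = math.pi * (g.dend_diam_um * 1e-4) * seg_len_cm
    xsec = math.pi * (g.dend_diam_um * 1e-4 / 2.0) ** 2
    g_axial = xsec / (RA_OHM_CM * seg_len_cm)  # S, between segment centres
    areas = np.array([g.area_cm2] + [seg_area] * nseg)
    x_mid = np.array([0.0] + [(i + 0.5) * g.dend_length_um / nseg
                              for i in range(nseg)])
    gh = model.ih.gbar * (1.0 + g.A_f / (1.0 + np.exp((g.d_half_um - x_mid)
                                                      / g.z_um)))
    gh[0] = model.ih.gbar
    return areas, gh, g_axial


def _cable_steady_state(model: CellModel, v_soma: float):
    """Dendritic steady-state voltages and the somatic bias (pA) that holds
    the soma at ``v_soma`` with every gate at its steady state."""
    from scipy.optimize import fsolve

    areas, gh, g_ax = _cable_layout(model)
    p, q = model.passive, model.ih
    nseg = model.geom.n_seg

    def dend_balance(vd):
        v = np.concatenate([[v_soma], vd])
        l = ih_steady_state(v, q)
        imem = (-(v - p.e_pas) / p.Rm - gh * l * (v - q.E_h)) * areas  # mA
        res = np.empty(nseg)
        for i in range(1, nseg + 1):
            ax = g_ax * (v[i - 1] - v[i])  # S * mV = mA
            if i < nseg:
                ax += g_ax * (v[i + 1] - v[i])
            res[i - 1] = imem[i] + ax
        return res

    vd = fsolve(dend_balance, np.full(nseg, v_soma), full_output=False)
    v = np.concatenate([[v_soma], vd])
    l0 = ih_steady_state(v_soma, q)
    i_soma_mem = (-(v_soma - p.e_pas) / p.Rm
                  - gh[0] * l0 * (v_soma - q.E_h)) * areas[0]
    i_ax = g_ax * (v[1] - v[0])
    hold_pA = -(i_soma_mem + i_ax) * 1e9
    return v, hold_pA


def _simulate_step_cable(model: CellModel, stim: StimulusStep, dt: float,
                         hold_current_pA: float | None) -> Trace:
    """Backward-Euler / exact-gate splitting on the compartment chain.

    Internal units: mV, ms, uS, nF, nA (uS*mV = nA; nF*mV/ms = nA).
    """
    areas, gh, g_ax = _cable_layout(model)
    p, q = model.passive, model.ih
    ncomp = areas.size
    v, hold = _cable_steady_state(model, stim.holding_target)
    if hold_current_pA is None:
        hold_current_pA = hold
    l = ih_steady_state(v, q)

    g_ax_uS = g_ax * 1e6
    g_leak_uS = areas / p.Rm * 1e6
    c_nF = p.Cm * areas * 1e3

    n = int(round(stim.total_ms / dt)) + 1
    on = int(round(stim.onset / dt))
    off = int(round((stim.onset + stim.duration) / dt))
    out = np.empty(n)
    out[0] = v[0]

    lap = np.zeros((ncomp, ncomp))  # axial coupling matrix
    for i in range(ncomp - 1):
        lap[i, i] += g_ax_uS
        lap[i + 1, i + 1] += g_ax_uS
        lap[i, i + 1] -= g_ax_uS
        lap[i + 1, i] -= g_ax_uS

    for k in range(1, n):
        linf = ih_steady_state(v, q)
        taul = ih_time_constant(v, q, model.temperature)
        l = linf + (l - linf) * np.exp(-dt / taul)
        gh_uS = gh * l * areas * 1e6
        i_inj = np.zeros(ncomp)
        i_inj[0] = hold_current_pA * 1e-3
        if on <= k < off:
            i_inj[0] += stim.amplitude * 1e-3
        A = lap + np.diag(c_nF / dt + g_leak_uS + gh_uS)
        b = c_nF / dt * v + g_leak_uS * p.e_pas + gh_uS * q.E_h + i_inj
        v = np.linalg.solve(A, b)
        if abs(v[0]) > 200.0:
            raise IntegrationError(
                f"|V| exceeded 200 mV at t = {k * dt:.3f} ms "
                f"(amplitude {stim.amplitude} pA)")
        out[k] = v[0]
    return Trace(dt=dt, voltage=out, stimulus=stim,
                 hold_current_pA=hold_current_pA)


def default_protocol(amplitudes: Sequence[float] | None = None,
                     onset: float = 100.0, duration: float = 400.0,
                     holding_target: float = -65.0,
                     post: float = 100.0) -> list[StimulusStep]:
    """The recording protocol: -200 to +400 pA inclusive in 50 pA steps."""
    if amplitudes is None:
        amplitudes = list(range(-200, 401, 50))
    return [StimulusStep(amplitude=float(a), onset=onset, duration=duration,
                         holding_target=holding_target, pre=onset, post=post)
            for a in amplitudes]


def run_protocol(model: CellModel, protocol: Sequence[StimulusStep],
                 dt: float = 0.025) -> list[Trace]:
    """Simulate every step of a protocol (holding current computed once)."""
    traces: list[Trace] = []
    hold = None
    for i, stim in enumerate(protocol):
        if hold is None or stim.holding_target != protocol[0].holding_target:
            hold = compute_holding_current(model, stim.holding_target)
        try:
            traces.append(simulate_step(model, stim, dt, hold_current_pA=hold))
        except IntegrationError as err:
            raise IntegrationError(f"sweep {i} ({stim.amplitude} pA): {err}") from err
    return traces


# ---------------------------------------------------------------------------
# packaged parameter sets
# ---------------------------------------------------------------------------

def load_group_params(path: str | None = None) -> dict[str, dict[str, float]]:
    """Load the per-group optimized parameter table (packaged by default)."""
    if path is None:
        text = resources.files("ca1ephys.data").joinpath(
            "group_params.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return json.loads(text)


def cell_model_for_group(label: str, *, Cm: float = 1.0, E_h: float = -30.0,
                         geom: Geometry | None = None,
                         temperature: float = 34.0,
                         params: dict[str, dict[str, float]] | None = None) -> CellModel:
    """Build a CellModel from one row of the group parameter table."""
    table = params if params is not None else load_group_params()
    if label not in table:
        raise KeyError(f"unknown group {label!r}; have {sorted(table)}")
    row = table[label]
    passive = PassiveParams(Rm=row["Rm"], Cm=Cm, e_pas=row["e_pas"])
    ih = IhParams(gbar=row["gbar"], E_h=E_h, Vl_half=row["Vl_half"],
                  kl=row["kl"], Vt_half=row["Vt_half"], a0t=row["a0t"],
                  zetat=row["zetat"], gmt=row["gmt"])
    return CellModel(passive=passive, ih=ih,
                     geom=geom if geom is not None else Geometry(),
                     temperature=temperature)


def with_params(model: CellModel, **updates: float) -> CellModel:
    """Return a copy of ``model`` with named passive/Ih parameters replaced."""
    passive_fields = {"Rm", "Cm", "e_pas"}
    ih_fields = {"gbar", "E_h", "Vl_half", "kl", "Vt_half", "a0t",
                 "zetat", "gmt", "q10", "T_ref"}
    pas_up = {k: v for k, v in updates.items() if k in passive_fields}
    ih_up = {k: v for k, v in updates.items() if k in ih_fields}
    unknown = set(updates) - passive_fields - ih_fields
    if unknown:
        raise KeyError(f"unknown parameters {sorted(unknown)}")
    return replace(model,
                   passive=replace(model.passive, **pas_up) if pas_up else model.passive,
                   ih=replace(model.ih, **ih_up) if ih_up else model.ih)
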