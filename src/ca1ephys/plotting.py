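"""Quick-look plots: sweep families, phase planes and fit overlays."""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .biophys import Trace
from .features import SpikeDetectConfig, phase_plane
from .fitting import IhFitResults

__all__ = ["plot_traces", "plot_phase_plane", "plot_fit"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt
    _, ax = plt.subplots()
    return ax


def plot_traces(traces: Iterable[Trace], ax=None, **kwargs):
    """Overlay a sweep family (label = step amplitude in pA)."""
    ax = _axes(ax)
    for tr in traces:
        ax.plot(tr.time, tr.voltage,
                label=f"{tr.stimulus.amplitude:+.0f} pA", **kwargs)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("V (mV)")
    ax.legend(fontsize="small")
    return ax


def plot_phase_plane(trace: Trace, cfg: SpikeDetectConfig = SpikeDetectConfig(),
                     ax=None, **kwargs):
    """dV/dt against V around the first action potential."""
    ax = _axes(ax)
    v, dvdt = phase_plane(trace, cfg)
    ax.plot(v, dvdt, **kwargs)
    ax.set_xlabel("V (mV)")
    ax.set_ylabel("dV/dt (mV/ms)")
    return ax


def plot_fit(result: IhFitResults, ax=None):
    """Reference sweeps (grey) with the best-fit model overlaid (colored)."""
    ax = _axes(ax)
    for tr in result.model.traces:
        ax.plot(tr.time, tr.voltage, color="0.6", lw=0.8)
        sim = result.model.simulate(result.params, tr)
        ax.plot(tr.time, sim, lw=1.2,
                label=f"{tr.stimulus.amplitude:+.0f} pA "
                      f"(rms {np.sqrt(np.mean((sim - tr.voltage) ** 2)):.3f} mV)")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("V (mV)")
    ax.legend(fontsize="small")
    return ax
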