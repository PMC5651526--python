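"""Synthetic periodic inlet flow waveforms.

The pipeline needs a physiological volumetric-flow pulse for the ascending
aorta and a scaled copy for the descending segment that hosts the heat
exchanger.  No tabulated waveform is shipped; instead a closed-form pulse is
generated: a raised-cosine systolic lobe, an optional early-diastolic reverse
lobe, and a few small seeded zero-mean harmonics for cycle-to-cycle realism.
The generator normalises so that the discrete time-average equals ``mean_q``
exactly and the discrete maximum equals ``peak_ratio * mean_q`` exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["FlowWaveform", "make_inlet_waveform", "descending_fraction"]


@dataclass(frozen=True)
class FlowWaveform:
    """One period of a volumetric flow waveform.

    ``times`` are sample instants in [0, period) (uniform, wrap-periodic),
    ``q`` the flow in m^3/s at each instant, ``mean_q`` the discrete mean.
    """

    period: float
    times: np.ndarray
    q: np.ndarray
    mean_q: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing 1-D")
        if t[0] < 0 or t[-1] >= self.period:
            raise ValueError("times must lie in [0, period)")
        if len(self.q) != t.size:
            raise ValueError("q and times must have equal length")

    def __call__(self, t):
        """Periodic linear interpolation of q at arbitrary times."""
        tp = np.mod(t, self.period)
        tt = np.concatenate([self.times, [self.period]])
        qq = np.concatenate([self.q, [self.q[0]]])
        return np.interp(tp, tt, qq)

    def to_csv(self, path: str | Path) -> None:
        """Write (time_s, q_m3s) CSV plus a JSON sidecar with the period."""
        path = Path(path)
        header = "time_s,q_m3s"
        data = np.column_stack([self.times, self.q])
        np.savetxt(path, data, delimiter=",", header=header, comments="")
        sidecar = {"period_s": self.period, "mean_q_m3s": self.mean_q,
                   "provenance": "hemotherm synthetic waveform"}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FlowWaveform":
        path = Path(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        meta = json.loads(path.with_suffix(".json").read_text())
        q = data[:, 1]
        return cls(period=float(meta["period_s"]), times=data[:, 0], q=q,
                   mean_q=float(np.mean(q)))


def make_inlet_waveform(
    period: float = 1.0,
    mean_q: float = 5.0 / 0.7 / 60000.0,
    peak_ratio: float = 4.0,
    reverse_fraction: float = 0.05,
    n_samples: int = 200,
    seed: int = 0,
) -> FlowWaveform:
    """Generate a periodic cardiac-like inlet flow pulse.

    Parameters
    ----------
    period : cardiac period, s.
    mean_q : time-mean volumetric flow, m^3/s (default corresponds to a
        5 L/min descending-aorta mean after a 0.7 flow split).
    peak_ratio : systolic peak flow divided by the mean (> 1; exactly 1
        degenerates to constant flow).
    reverse_fraction : relative depth of the early-diastolic reverse lobe
        (0 disables it; must stay below 0.2).
    n_samples : number of uniform samples over one period (>= 16).
    seed : RNG seed for the small residual harmonics; the generator is a
        pure function of its arguments.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if mean_q <= 0:
        raise ValueError("mean_q must be positive")
    if peak_ratio < 1:
        raise ValueError("peak_ratio must be >= 1")
    if not (0 <= reverse_fraction < 0.2):
        raise ValueError("reverse_fraction must lie in [0, 0.2)")
    if n_samples < 16:
        raise ValueError("need at least 16 samples per period")

    t = np.arange(n_samples) * (period / n_samples)
    ph = t / period

    # Systolic lobe: raised cosine centred at 15% of the cycle, 30% wide.
    def lobe(center, width):
        d = (ph - center + 0.5) % 1.0 - 0.5
        out = np.zeros_like(ph)
        inside = np.abs(d) < width / 2
        out[inside] = np.cos(np.pi * d[inside] / width) ** 2
        return out

    shape = lobe(0.15, 0.30)
    if reverse_fraction > 0:
        shape = shape - reverse_fraction * lobe(0.36, 0.12)

    rng = np.random.default_rng(seed)
    amps = 0.02 * rng.standard_normal(3)
    phases = rng.uniform(0, 2 * np.pi, 3)
    for k, (A, phi) in enumerate(zip(amps, phases), start=3):
        shape = shape + A * np.sin(2 * np.pi * k * ph + phi)

    shape = shape - shape.mean()
    peak = shape.max()
    if peak_ratio == 1.0 or peak <= 0:
        q = np.full(n_samples, mean_q)
    else:
        q = mean_q * (1.0 + (peak_ratio - 1.0) * shape / peak)
    return FlowWaveform(period=period, times=t, q=q, mean_q=float(np.mean(q)))


def descending_fraction(waveform: FlowWaveform, fraction: float) -> FlowWaveform:
    """Scale a waveform by the descending-aorta flow fraction.

    Represents the branch outflow split (brachiocephalic/carotid/subclavian)
    as a single scalar on the inlet pulse.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    q = waveform.q * fraction
    return FlowWaveform(period=waveform.period, times=waveform.times.copy(),
                        q=q, mean_q=float(np.mean(q)))
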