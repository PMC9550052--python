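"""Phenomenological two-variable cardiac cell model.

The tissue solver is written against a pluggable cell-model interface; the
default is the Mitchell-Schaeffer two-variable model, whose normalized
state ``u`` (0 at rest, ~1 at the plateau) is mapped to physical voltage by

    V = V_rest + amplitude * u        (defaults: -85 mV + 120 mV * u)

so that threshold-based quantities (activation at -20 mV, repolarization
below -70 mV) are meaningful.  The border zone uses a separate parameter
set: a longer closing time constant (action-potential-duration
prolongation) and a larger inward time constant (reduced excitability),
which is the minimal electrophysiological remodeling needed for
repolarization-gradient studies around scar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass(frozen=True)
class MitchellSchaefferParams:
    """Mitchell-Schaeffer time constants (ms) and gate threshold."""

    tau_in: float = 0.3
    tau_out: float = 6.0
    tau_open: float = 120.0
    tau_close: float = 100.0
    u_gate: float = 0.13


#: Border-zone defaults: action potential modestly prolonged (~210 ms vs
#: ~198 ms at the -70 mV return; tau_close x 1.3 with slightly slower
#: outward kinetics) and excitability reduced (tau_in x 1.5, which also
#: slows conduction).  Declared package defaults, not literature values.
BZ_DEFAULT = MitchellSchaefferParams(tau_in=0.45, tau_out=6.5, tau_close=130.0)


@dataclass
class CellModelParams:
    """Per-tissue-class cell parameters plus the voltage mapping."""

    model: str = "mitchell-schaeffer"
    healthy: MitchellSchaefferParams = field(default_factory=MitchellSchaefferParams)
    bz: MitchellSchaefferParams = field(default_factory=lambda: BZ_DEFAULT)
    v_rest: float = -85.0  # mV
    amplitude: float = 120.0  # mV

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("voltage amplitude must be positive")

    def to_mv(self, u: np.ndarray) -> np.ndarray:
        return self.v_rest + self.amplitude * u

    def u_at(self, v_mv: float) -> float:
        """Normalized state corresponding to a physical voltage."""
        return (v_mv - self.v_rest) / self.amplitude

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "healthy": asdict(self.healthy),
            "bz": asdict(self.bz),
            "v_rest": self.v_rest,
            "amplitude": self.amplitude,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellModelParams":
        return cls(
            model=d.get("model", "mitchell-schaeffer"),
            healthy=MitchellSchaefferParams(**d["healthy"]),
            bz=MitchellSchaefferParams(**d["bz"]),
            v_rest=d.get("v_rest", -85.0),
            amplitude=d.get("amplitude", 120.0),
        )


def reaction_rates(u, h, tau_in, tau_out, tau_open, tau_close, u_gate):
    """Right-hand sides (du/dt, dh/dt) of the Mitchell-Schaeffer model.

    Parameters may be scalars or per-node arrays (heterogeneous tissue).
    """
    du = h * u * u * (1.0 - u) / tau_in - u / tau_out
    dh = np.where(u < u_gate, (1.0 - h) / tau_open, -h / tau_close)
    return du, dh


def simulate_single_cell(params: MitchellSchaefferParams, duration: float,
                         dt: float = 0.01, stim_amplitude: float = 1.0,
                         stim_duration: float = 1.0):
    """0-D (space-clamped) forward-Euler run; returns (times, u).

    Serves as the reference action potential for the tissue model: the
    stimulus is applied from t=0 for ``stim_duration`` ms.
    """
    n = int(round(duration / dt))
    times = np.arange(n + 1) * dt
    u = np.zeros(n + 1)
    h = 1.0
    uu = 0.0
    for i in range(n):
        du, dh = reaction_rates(uu, h, params.tau_in, params.tau_out,
                                params.tau_open, params.tau_close, params.u_gate)
        if times[i] < stim_duration:
            du = du + stim_amplitude
        uu = uu + dt * du
        h = h + dt * dh
        u[i + 1] = uu
    return times, u


def apd_at_threshold(times: np.ndarray, u: np.ndarray, u_up: float, u_down: float) -> float:
    """Duration between the upward crossing of ``u_up`` and the subsequent
    downward crossing of ``u_down``, with linear interpolation."""
    above = u >= u_up
    idx = np.flatnonzero(above[1:] & ~above[:-1])
    if idx.size == 0:
        return float("nan")
    i = idx[0]
    t_up = np.interp(u_up, [u[i], u[i + 1]], [times[i], times[i + 1]])
    below = u < u_down
    j_candidates = np.flatnonzero(below[i + 1:]) + i + 1
    if j_candidates.size == 0:
        return float("nan")
    j = j_candidates[0]
    t_down = np.interp(u_down, [u[j], u[j - 1]], [times[j], times[j - 1]])
    return float(t_down - t_up)
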