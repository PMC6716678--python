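"""Neuronal triplets: coupled excitatory/inhibitory phase oscillators gating a rate neuron.

Every node in the processing network and the burst controller is a *triplet*:
a phase-code pair (E, I) that oscillates by virtue of its mutual coupling,
plus one rate-code neuron x whose excitability is modulated by E.  The phase
pair follows a discrete (forward-Euler) rotation

    dE = -C*I - Damp*J(r > r_min)*E + burst
    dI = +C*E - Damp*J(r > r_min)*I

where r = sqrt(E^2 + I^2), J is an indicator that switches damping on only
above the attractor radius r_min, and ``burst`` is an external kick applied
to the excitatory neuron.  Without bursts the radius therefore hovers at
r_min and the phase advances at a fixed rate set by the coupling C.

The rate neuron is memoryless on the 2 ms grid:

    dx = -x + f(net - bias) * G(E)

with G a steep sigmoid of the excitatory phase (the "gate") and f either a
biased sigmoid (multi-layer networks) or the identity (linear networks).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "OscillatorParams",
    "gamma_params",
    "theta_params",
    "coupling_for_frequency",
    "step_phase",
    "gate",
    "step_rate",
    "random_phase_state",
]

#: simulation time step in seconds (2 ms), fixed for every oscillator
DT = 0.002

#: gate steepness and midpoint of G(E) = 1 / (1 + exp(-5*(E - .6)))
_GATE_SLOPE = 5.0
_GATE_MID = 0.6


@dataclass(frozen=True)
class OscillatorParams:
    """Parameters of one E/I phase pair.

    Attributes
    ----------
    coupling : float
        E-I coupling C in radians per time step; sets the oscillation
        frequency.
    damp : float
        Damping coefficient applied per step while the radius exceeds
        ``r_min``.
    r_min : float
        Attractor radius of the oscillation.
    dt : float
        Time step in seconds (2 ms throughout).
    """

    coupling: float
    damp: float
    r_min: float
    dt: float = DT

    def __post_init__(self) -> None:
        if self.coupling <= 0:
            raise ValueError("coupling must be positive")
        if self.damp < 0:
            raise ValueError("damp must be non-negative")
        if self.r_min <= 0:
            raise ValueError("r_min must be positive")

    def with_frequency(self, freq_hz: float) -> "OscillatorParams":
        """Return a copy recalibrated so the triplet oscillates at ``freq_hz``."""
        c = coupling_for_frequency(freq_hz, self.damp, self.r_min, self.dt)
        return replace(self, coupling=c)


def _trajectory_frequency(coupling: float, damp: float, r_min: float,
                          dt: float, steps: int) -> float:
    """Mean rotation frequency (Hz) of a burst-free triplet started at (r_min, 0)."""
    e, i = r_min, 0.0
    r2min = r_min * r_min
    es = np.empty(steps)
    js = np.empty(steps)
    for k in range(steps):
        j = 1.0 if e * e + i * i > r2min else 0.0
        e, i = e - coupling * i - damp * j * e, i + coupling * e - damp * j * i
        es[k] = e
        js[k] = i
    phase = np.unwrap(np.arctan2(js, es))
    return (phase[-1] - phase[0]) / (2.0 * np.pi) / ((steps - 1) * dt)


@lru_cache(maxsize=None)
def coupling_for_frequency(freq_hz: float, damp: float, r_min: float,
                           dt: float = DT, steps: int = 1000) -> float:
    """Coupling C that makes a burst-free triplet oscillate at ``freq_hz``.

    The small-angle value 2*pi*f*dt is only exact in the continuum limit: the
    forward-Euler map advances phase by arctan(C) per undamped step and by
    arctan(C / (1 - Damp)) per damped step, so for gamma-band couplings the
    emergent frequency overshoots the small-angle target by several percent.
    We therefore calibrate C by root-finding on the phase-slope frequency of
    the actual discrete trajectory.
    """
    c0 = 2.0 * np.pi * freq_hz * dt
    f = lambda c: _trajectory_frequency(c, damp, r_min, dt, steps) - freq_hz
    return brentq(f, 0.5 * c0, 1.5 * c0, xtol=1e-12)


def gamma_params(freq_hz: float = 40.0, damp: float = 0.3,
                 r_min: float = 1.0) -> OscillatorParams:
    """Default processing-unit oscillator (gamma band)."""
    return OscillatorParams(coupling_for_frequency(freq_hz, damp, r_min),
                            damp, r_min)


def theta_params(freq_hz: float = 5.0, damp: float = 0.003,
                 r_min: float = 0.05) -> OscillatorParams:
    """Default controller (pMFC) oscillator: slow theta with weak damping."""
    return OscillatorParams(coupling_for_frequency(freq_hz, damp, r_min),
                            damp, r_min)


def step_phase(e, i, params: OscillatorParams, burst=0.0):
    """One Euler step of the phase pair; ``burst`` kicks the excitatory neuron.

    Accepts scalars or equal-shaped arrays and returns the updated (E, I).
    """
    e = np.asarray(e, dtype=float)
    i = np.asarray(i, dtype=float)
    burst = np.asarray(burst, dtype=float)
    if not (np.all(np.isfinite(e)) and np.all(np.isfinite(i))
            and np.all(np.isfinite(burst))):
        raise ValueError("non-finite phase state or burst")
    j = (e * e + i * i > params.r_min ** 2).astype(float)
    e_new = e + (-params.coupling * i - params.damp * j * e + burst)
    i_new = i + (params.coupling * e - params.damp * j * i)
    if e_new.ndim == 0:
        return float(e_new), float(i_new)
    return e_new, i_new


def gate(e):
    """Gating gain G(E) in (0, 1): a steep sigmoid of the excitatory phase."""
    return 1.0 / (1.0 + np.exp(-_GATE_SLOPE * (np.asarray(e, dtype=float) - _GATE_MID)))


def step_rate(x, net, gain, kind: str = "sigmoid", bias: float = 5.0):
    """One update of the rate neuron; returns the new activation.

    ``kind`` selects the activation family: ``"sigmoid"`` applies the biased
    logistic f(net - bias) used by multi-layer nodes, ``"linear"`` passes net
    through unchanged.  Because dx = -x + f(.)*gain, the new activation is
    simply f(net - bias) * gain; ``x`` enters only through the decay term.
    """
    x = np.asarray(x, dtype=float)
    net = np.asarray(net, dtype=float)
    if kind == "sigmoid":
        drive = 1.0 / (1.0 + np.exp(-(net - bias)))
    elif kind == "linear":
        drive = net
    else:
        raise ValueError(f"unknown activation kind: {kind!r}")
    out = drive * np.asarray(gain, dtype=float)
    if out.ndim == 0:
        return float(out)
    return out


def random_phase_state(n: int, r_min: float, rng: np.random.Generator):
    """(E, I) arrays for ``n`` triplets at radius r_min with uniform random phases."""
    angles = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return r_min * np.cos(angles), r_min * np.sin(angles)
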