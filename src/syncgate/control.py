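"""Control unit: task pointers (LFC) and the theta-paced burst controller (pMFC).

The lateral-frontal part holds one pointer per task module, +1 for the module
that should be bound to the input (and output) layers and -1 for modules that
should be unbound; a fourth, constant pointer (+1) covers the non-modular
layers.  The medial-frontal part is a single theta triplet whose rate neuron
emits Bernoulli bursts phase-locked to the theta peak; a shared standardized
Gaussian draw per time step turns those bursts into correlated kicks for
same-sign pointers and anticorrelated kicks for opposite-sign pointers, which
is what synchronizes and desynchronizes modules.  After an error the
controller itself is re-energized by bursts whose probability is a Gaussian
bump peaking 200 ms into the next inter-trial interval and whose amplitude is
the previous trial's negative prediction error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .oscillator import DT, OscillatorParams, theta_params

__all__ = [
    "LFCState",
    "PMFC",
    "burst_probability",
    "sample_pmfc_output",
    "compose_processing_bursts",
    "feedback_burst_schedule",
    "feedback_probability",
]


@dataclass
class LFCState:
    """Task pointers: exactly one module at +1, the rest at -1."""

    module_pointers: np.ndarray
    layer_pointer: float = 1.0

    @classmethod
    def pointing_at(cls, module: int, n_modules: int = 3) -> "LFCState":
        state = cls(module_pointers=np.full(n_modules, -1.0))
        state.set_pointer(module)
        return state

    @property
    def current(self) -> int:
        return int(np.argmax(self.module_pointers))

    def set_pointer(self, module: int) -> None:
        n = self.module_pointers.size
        if not 0 <= module < n:
            raise ValueError(f"module index {module} out of range 0..{n - 1}")
        self.module_pointers[:] = -1.0
        self.module_pointers[module] = 1.0


def burst_probability(e_pmfc):
    """Probability that the pMFC rate neuron bursts, p = 1/(1+exp(-10*(E-1)))."""
    return expit(10.0 * (np.asarray(e_pmfc, dtype=float) - 1.0))


def sample_pmfc_output(e_pmfc: float, rng: np.random.Generator) -> int:
    """Draw the Bernoulli burst output of the pMFC rate neuron."""
    return int(rng.random() < burst_probability(e_pmfc))


def compose_processing_bursts(pointers: np.ndarray, pmfc_out: int,
                              u: float) -> np.ndarray:
    """Per-node burst amplitudes B_i = pointer_i * pMFC(t) * U(t).

    ``u`` is the single standardized-Gaussian draw for this time step, shared
    across every node: sharing it is what makes same-sign pointers receive
    correlated kicks and opposite-sign pointers anticorrelated ones.
    """
    if pmfc_out == 0:
        return np.zeros_like(pointers)
    return pointers * (pmfc_out * u)


def feedback_probability(step_index, peak_s: float = 0.200, sd_s: float = 0.025,
                         dt: float = DT):
    """Gaussian-bump burst probability at ITI step(s) ``step_index``."""
    t = np.asarray(step_index, dtype=float) * dt
    return np.exp(-((t - peak_s) ** 2) / (2.0 * sd_s ** 2))


def feedback_burst_schedule(delta_minus: float, n_steps: int,
                            rng: np.random.Generator, peak_s: float = 0.200,
                            sd_s: float = 0.025, dt: float = DT) -> np.ndarray:
    """Burst amplitudes delivered to the pMFC during one inter-trial interval.

    Each step fires independently with the Gaussian-bump probability (peak
    200 ms, SD 25 ms after feedback, i.e. after the previous trial's end);
    firing steps carry the previous trial's negative prediction error as
    amplitude.
    """
    if delta_minus < 0:
        raise ValueError("negative prediction error must be non-negative")
    if delta_minus == 0.0:
        return np.zeros(n_steps)
    p = feedback_probability(np.arange(n_steps), peak_s, sd_s, dt)
    return delta_minus * (rng.random(n_steps) < p)


@dataclass
class PMFC:
    """The theta-band controller triplet and its trial-to-trial error memory."""

    params: OscillatorParams = field(default_factory=theta_params)
    e: float = 0.0
    i: float = 0.0
    pending_error: float = 0.0

    def reset_phase(self, rng: np.random.Generator,
                    radius: float | None = None) -> None:
        """Random phase at ``radius`` (default: elevated start amplitude 1).

        The controller begins the task with full control — its amplitude then
        decays slowly toward r_min across error-free trials and is
        re-energized by error feedback.
        """
        r = 1.0 if radius is None else radius
        angle = rng.uniform(0.0, 2.0 * np.pi)
        self.e = r * np.cos(angle)
        self.i = r * np.sin(angle)

    @property
    def radius(self) -> float:
        return float(np.hypot(self.e, self.i))

    #: numerical ceiling on the controller radius.  With fast couplings and
    #: weak damping the forward-Euler map grows even on damped steps, so the
    #: amplitude diverges; the cap keeps arithmetic finite without touching
    #: any regime in which the controller is functional (radius stays below
    #: ~1e2 there, and the burst probability saturates far earlier).
    RADIUS_CAP = 1e6

    def step(self, burst: float = 0.0) -> None:
        p = self.params
        j = 1.0 if self.e * self.e + self.i * self.i > p.r_min * p.r_min else 0.0
        e_new = self.e + (-p.coupling * self.i - p.damp * j * self.e + burst)
        i_new = self.i + (p.coupling * self.e - p.damp * j * self.i)
        r = np.hypot(e_new, i_new)
        if r > self.RADIUS_CAP:
            e_new *= self.RADIUS_CAP / r
            i_new *= self.RADIUS_CAP / r
        self.e, self.i = e_new, i_new
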