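"""Reward-value evaluation (RVPM): module values, prediction errors, switching.

A value neuron V predicts the reward of the currently pointed task module
(V = Q^T (LFC+1)/2).  Two half-wave-rectified prediction-error neurons
compare V with the binary reward; negative errors feed both the burst
controller (fast time scale) and a leaky switch accumulator (slow time
scale) that triggers a softmax re-selection of the module when it reaches
threshold, with a decaying inhibition tag on the just-abandoned module so
the agent does not oscillate between two modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RVPM",
    "prediction_errors",
    "softmax_probabilities",
]


def prediction_errors(reward: float, value: float) -> tuple[float, float]:
    """(delta+, delta-): rectified prediction errors; at most one is nonzero."""
    return max(reward - value, 0.0), max(value - reward, 0.0)


def softmax_probabilities(q: np.ndarray, inh: np.ndarray) -> np.ndarray:
    """Selection probabilities P(i) proportional to exp(Q_i + Inh_i)."""
    z = np.exp(q + inh - np.max(q + inh))
    return z / z.sum()


@dataclass
class RVPM:
    """State and update rules of the reinforcement-learning unit.

    Parameters
    ----------
    alpha : float
        Value learning rate (.1 for the linear model, .01 for multi-layer).
    sigma : float
        Leak of the switch accumulator (.5 linear, .8 multi-layer).
    threshold : float
        Switch threshold on the accumulator (default .5).
    q_init : float
        Initial module value.  The value update is multiplicative in V, so
        zero is absorbing and a positive prior is required.
    """

    n_modules: int = 3
    alpha: float = 0.1
    sigma: float = 0.5
    threshold: float = 0.5
    q_init: float = 0.5
    inhibition: float = 2.0
    inhibition_decay: float = 0.9
    q: np.ndarray = field(init=False)
    inh: np.ndarray = field(init=False)
    s: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.sigma < 1.0:
            raise ValueError("sigma must be in (0, 1)")
        self.q = np.full(self.n_modules, float(self.q_init))
        self.inh = np.zeros(self.n_modules)

    def value(self, module_pointers: np.ndarray) -> float:
        """Expected reward of the pointed module, V = Q^T (LFC+1)/2."""
        return float(self.q @ ((module_pointers + 1.0) / 2.0))

    def update_values(self, module_pointers: np.ndarray, value: float,
                      delta_plus: float, delta_minus: float) -> None:
        """Reinforcement-modulated Hebbian update; only the pointed module moves."""
        self.q += (self.alpha * value * ((module_pointers + 1.0) / 2.0)
                   * (delta_plus - delta_minus))

    def update_switch(self, delta_minus: float) -> bool:
        """Leaky accumulation of negative errors; True (and reset) at threshold."""
        self.s = self.sigma * self.s + (1.0 - self.sigma) * delta_minus
        if self.s >= self.threshold:
            self.s = 0.0
            return True
        return False

    def choose_module(self, current: int, rng: np.random.Generator) -> int:
        """Softmax re-selection after a switch; inhibits the abandoned module."""
        self.inh[current] = -self.inhibition
        p = softmax_probabilities(self.q, self.inh)
        return int(rng.choice(self.n_modules, p=p))

    def decay_inhibition(self) -> None:
        """Inhibition tags decay by 10% at the end of every trial."""
        self.inh *= self.inhibition_decay
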