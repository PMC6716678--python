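"""Electrophysiology-style statistics on simulated signals.

The simulated excitatory traces play the role of MEG/EEG source signals:
zero-lag correlation quantifies binding between node groups, debiased
phase-amplitude coupling (dPAC) quantifies theta-gamma nesting,

    dPAC = | (1/h) * sum_t a_t * (exp(i*phi_t) - mean_t exp(i*phi_t)) |

and Morlet-wavelet convolution gives time-frequency power of the
controller signal, contrasted between inter-trial intervals that follow
errors versus correct responses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .oscillator import DT

__all__ = [
    "zero_crossing_frequency",
    "zero_lag_synchrony",
    "group_synchrony",
    "gamma_amplitude",
    "hilbert_phase",
    "dpac",
    "trial_dpac",
    "morlet_tfr",
    "feedback_power_contrast",
    "iti_power_windows",
]


def zero_crossing_frequency(trace: np.ndarray, dt: float = DT) -> float:
    """Dominant frequency in Hz estimated from sign changes of the trace."""
    trace = np.asarray(trace, dtype=float)
    crossings = int(np.sum(np.diff(np.sign(trace)) != 0))
    return crossings / 2.0 / (trace.size * dt)


def zero_lag_synchrony(sig_a: np.ndarray, sig_b: np.ndarray) -> float:
    """Pearson correlation at phase lag zero; NaN for constant input.

    +1 is complete synchronization, -1 complete desynchronization
    (anti-phase).
    """
    a = np.asarray(sig_a, dtype=float)
    b = np.asarray(sig_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("signals must have equal length")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def group_synchrony(traces: np.ndarray, idx_a, idx_b) -> float:
    """Mean pairwise zero-lag correlation between two node groups.

    ``traces`` is (time, nodes); the result averages corr(a, b) over all
    pairs with a in ``idx_a`` and b in ``idx_b``.
    """
    corr = np.corrcoef(np.asarray(traces, dtype=float).T)
    return float(corr[np.ix_(idx_a, idx_b)].mean())


def gamma_amplitude(proc_e: np.ndarray) -> np.ndarray:
    """a_t = mean absolute excitatory activation over processing nodes."""
    return np.mean(np.abs(np.asarray(proc_e, dtype=float)), axis=-1)


def hilbert_phase(signal: np.ndarray) -> np.ndarray:
    """Instantaneous (analytic) phase of a real signal."""
    return np.angle(hilbert(np.asarray(signal, dtype=float)))


def dpac(amplitude: np.ndarray, phase: np.ndarray) -> float:
    """Debiased phase-amplitude coupling of one trial-length window."""
    a = np.asarray(amplitude, dtype=float)
    phi = np.asarray(phase, dtype=float)
    if a.size == 0 or a.shape != phi.shape:
        raise ValueError("amplitude and phase must be equal-length, non-empty")
    vec = np.exp(1j * phi)
    return float(np.abs(np.mean(a * (vec - vec.mean()))))


def trial_dpac(pmfc_e: np.ndarray, proc_e: np.ndarray,
               trial_steps: int) -> np.ndarray:
    """Per-trial dPAC between controller theta phase and gamma amplitude.

    Phase is the analytic phase of the whole controller trace (so trial
    edges do not distort the Hilbert transform); amplitude is the mean
    absolute processing-unit excitatory activation.  Both are then cut into
    trial-length windows.
    """
    phase = hilbert_phase(pmfc_e)
    amp = gamma_amplitude(proc_e)
    n_trials = amp.size // trial_steps
    out = np.empty(n_trials)
    for n in range(n_trials):
        sl = slice(n * trial_steps, (n + 1) * trial_steps)
        out[n] = dpac(amp[sl], phase[sl])
    return out


def morlet_tfr(signal: np.ndarray, freqs=None, dt: float = DT,
               n_cycles_support: float = 4.0) -> np.ndarray:
    """Time-frequency power by complex Morlet convolution.

    Wavelet exp(i*2*pi*f*t) * exp(-t^2 / (2*sigma^2)) with sigma =
    4/(2*pi*f); power is the squared magnitude of the convolved signal.
    The signal is reflect-padded by the half-support of each wavelet so
    interior samples carry no edge artifact.  Returns (n_freqs, n_samples).
    """
    x = np.asarray(signal, dtype=float)
    freqs = np.linspace(1.0, 10.0, 10) if freqs is None else np.asarray(freqs)
    power = np.empty((freqs.size, x.size))
    for k, f in enumerate(freqs):
        sigma = 4.0 / (2.0 * np.pi * f)
        half = int(np.ceil(n_cycles_support * sigma / dt))
        if x.size <= half:
            raise ValueError(f"signal too short for the {f:g} Hz wavelet")
        t = np.arange(-half, half + 1) * dt
        wavelet = np.exp(2j * np.pi * f * t) * np.exp(-t * t / (2 * sigma ** 2))
        wavelet /= np.abs(wavelet).sum() / 2.0   # unit-gain for a sinusoid
        padded = np.concatenate((x[half:0:-1], x, x[-2:-half - 2:-1]))
        conv = np.convolve(padded, wavelet, mode="same")[half:half + x.size]
        power[k] = np.abs(conv) ** 2
    return power


def iti_power_windows(pmfc_e: np.ndarray, trial_steps: int, iti_steps: int,
                      freqs=None, dt: float = DT) -> np.ndarray:
    """Per-trial time-frequency power of the controller during each ITI.

    Returns (n_trials, n_freqs, iti_steps).  The transform runs over the
    whole concatenated trace, then windows are cut out, so wavelet support
    extends into neighboring trials rather than zero padding.
    """
    power = morlet_tfr(pmfc_e, freqs, dt)
    n_trials = pmfc_e.size // trial_steps
    out = np.empty((n_trials, power.shape[0], iti_steps))
    for n in range(n_trials):
        out[n] = power[:, n * trial_steps:n * trial_steps + iti_steps]
    return out


def feedback_power_contrast(iti_power: np.ndarray,
                            prev_correct: np.ndarray) -> np.ndarray:
    """Error-minus-correct mean ITI power, (n_freqs, iti_steps).

    ``prev_correct`` flags whether the feedback *preceding* each ITI was
    correct; both classes must be non-empty.
    """
    prev_correct = np.asarray(prev_correct, dtype=bool)
    if prev_correct.size != iti_power.shape[0]:
        raise ValueError("one flag per ITI window required")
    if prev_correct.all() or not prev_correct.any():
        raise ValueError("need at least one ITI in each class")
    return (iti_power[~prev_correct].mean(axis=0)
            - iti_power[prev_correct].mean(axis=0))
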