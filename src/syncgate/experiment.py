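"""Trial loop, simulations, replications, sweeps and behavioral scores.

``run_simulation`` wires the processing network, the burst controller and
the reinforcement-learning unit into the per-trial protocol: 250 steps of
inter-trial interval (no stimulus input; the controller receives
error-driven feedback bursts and keeps pacing synchronization bursts),
250 steps of stimulation, then readout, reward, the RL updates (value,
prediction errors, switch accumulator, possible module re-selection) and
one synaptic learning step.

Behavioral summaries follow the 120-bin convention: *plasticity* is the
mean accuracy over the first 5 bins of each rule's first block, and
*stability* is the accuracy on re-entering a rule (first 5 bins of its
second block) minus the accuracy at the end of its first block — zero
means perfect retention, negative means forgetting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from . import tasks
from .control import (LFCState, PMFC, burst_probability,
                      feedback_burst_schedule)
from .oscillator import OscillatorParams, coupling_for_frequency
from .processing import Network, NetworkSpec, static_mlp_forward
from .rl import RVPM, prediction_errors

__all__ = [
    "SimParams",
    "SimulationResult",
    "BinnedMetrics",
    "run_simulation",
    "run_replications",
    "bin_metrics",
    "aggregate_replications",
    "sweep_learning_rate",
    "sweep_oscillator_params",
    "bursting_synchrony_demo",
    "MODEL_KINDS",
]

MODEL_KINDS = ("rw-full", "rw-nosync", "bp-full", "bp-nosync")


@dataclass(frozen=True)
class SimParams:
    """All tunable simulation parameters with their default values."""

    proc_freq: float = 40.0     # Hz, processing-unit (gamma) oscillators
    proc_damp: float = 0.3
    proc_r_min: float = 1.0
    ctrl_freq: float = 5.0      # Hz, controller (theta) oscillator
    ctrl_damp: float = 0.003
    ctrl_r_min: float = 0.05
    ctrl_init_radius: float = 1.0   # start amplitude; decays toward ctrl_r_min
    bias: float = 5.0
    trial_steps: int = 500      # 1 s at 2 ms per step
    iti_steps: int = 250        # first 500 ms: no stimulus input
    input_drive: float = 1.0
    nodes_per_module: int | None = None   # default: 3 (rw) / 4 (bp)
    alpha: float | None = None            # default: .1 (rw) / .01 (bp)
    sigma: float | None = None            # default: .5 (rw) / .8 (bp)
    switch_threshold: float = 0.5
    q_init: float | None = None           # default: .5 (rw) / 1.0 (bp)
    inhibition: float = 2.0
    inhibition_decay: float = 0.9

    def proc_osc(self) -> OscillatorParams:
        return OscillatorParams(
            coupling_for_frequency(self.proc_freq, self.proc_damp,
                                   self.proc_r_min),
            self.proc_damp, self.proc_r_min)

    def ctrl_osc(self) -> OscillatorParams:
        return OscillatorParams(
            coupling_for_frequency(self.ctrl_freq, self.ctrl_damp,
                                   self.ctrl_r_min),
            self.ctrl_damp, self.ctrl_r_min)

    def family_defaults(self, algorithm: str) -> tuple[int, float, float, float]:
        """Per-family defaults for module size and RL parameters.

        The value prior follows the family's learning speed: the linear
        model gets a neutral prior (.5) — it masters a rule within a
        block's first trials, and with its fast accumulator (sigma = .5) an
        optimistic prior would let any single full-magnitude error cross
        the switch threshold.  The slow multi-layer family gets an
        optimistic prior (1.0): while performance is still near chance the
        leaky accumulator can only reach the .5 threshold if negative
        errors carry near-full magnitude, so without optimism the
        stay/switch mechanism could never explore alternative modules.
        """
        npm = self.nodes_per_module or (3 if algorithm == "rw" else 4)
        alpha = self.alpha if self.alpha is not None else \
            (0.1 if algorithm == "rw" else 0.01)
        sigma = self.sigma if self.sigma is not None else \
            (0.5 if algorithm == "rw" else 0.8)
        q_init = self.q_init if self.q_init is not None else \
            (0.5 if algorithm == "rw" else 1.0)
        return npm, alpha, sigma, q_init


@dataclass
class SimulationResult:
    """One simulated run: per-trial records plus optional dense traces."""

    model_kind: str
    beta: float
    seed: int
    n_dims: int
    records: pd.DataFrame
    trial_steps: int
    iti_steps: int
    weight_change: np.ndarray | None = None   # (n_trials, n_modules)
    proc_E: np.ndarray | None = None          # (n_trials*trial_steps, n_nodes)
    pmfc_E: np.ndarray | None = None          # (n_trials*trial_steps,)

    @property
    def accuracy(self) -> float:
        return float(self.records["accuracy"].mean())


def _task_dims(task: pd.DataFrame) -> int:
    return sum(1 for c in task.columns if c.startswith("f") and c[1:].isdigit())


def run_simulation(model_kind: str, task: pd.DataFrame, beta: float = 0.2,
                   seed: int = 0, params: SimParams | None = None,
                   record_traces: bool = False,
                   record_weight_change: bool = False) -> SimulationResult:
    """Simulate one model on one task sequence; deterministic given ``seed``.

    Four independent random streams are derived from the seed (weights,
    task order is carried by the task itself, burst noise, RL choices) so
    components can be replayed in isolation.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    params = params or SimParams()
    algorithm, mode = model_kind.split("-")
    full = mode == "full"
    n_dims = _task_dims(task)
    npm, alpha, sigma, q_init = params.family_defaults(algorithm)

    ss = np.random.SeedSequence(seed)
    rng_w, rng_burst, rng_rl = (np.random.default_rng(s) for s in ss.spawn(3))

    n_inputs = tasks.input_width(n_dims)
    if algorithm == "rw":
        spec = NetworkSpec("rw", full, n_inputs, 3 if full else 1, 3, 0,
                           bias=params.bias)
    else:
        spec = NetworkSpec("bp", full, n_inputs, 3, npm, 3, bias=params.bias)
    net = Network(spec, rng_w, params.proc_osc() if full else None)

    n_trials = len(task)
    steps, iti = params.trial_steps, params.iti_steps
    input_rows = [tasks.trial_input_indices(row, n_dims)
                  for _, row in task.iterrows()]
    stim_vecs = np.zeros((n_trials, n_inputs))
    for k, idx in enumerate(input_rows):
        stim_vecs[k, idx] = params.input_drive

    if full:
        pmfc = PMFC(params.ctrl_osc())
        pmfc.reset_phase(rng_burst, params.ctrl_init_radius)
        lfc = LFCState.pointing_at(int(rng_rl.integers(3)))
        rl = RVPM(3, alpha=alpha, sigma=sigma,
                  threshold=params.switch_threshold, q_init=q_init,
                  inhibition=params.inhibition,
                  inhibition_decay=params.inhibition_decay)
        net.set_module_pointers(lfc.module_pointers, lfc.layer_pointer)
        pending_dm = 0.0

    if record_traces:
        proc_E = np.empty((n_trials * steps, spec.n_nodes), dtype=np.float32)
        pmfc_E = np.empty(n_trials * steps)
    wchange = np.zeros((n_trials, spec.n_modules)) if record_weight_change else None

    rec: dict[str, list] = {k: [] for k in
                            ("response", "reward", "accuracy", "v",
                             "delta_plus", "delta_minus", "s", "module",
                             "switch")}
    correct_col = task["correct"].to_numpy()

    for n in range(n_trials):
        stim = stim_vecs[n]
        net.begin_trial()
        if full:
            fb = feedback_burst_schedule(pending_dm, iti, rng_burst)
            bern = rng_burst.random(steps)
            us = rng_burst.standard_normal(steps)
            base = n * steps
            for t in range(steps):
                pmfc.step(fb[t] if t < iti else 0.0)
                out = 1 if bern[t] < burst_probability(pmfc.e) else 0
                net.step(stim if t >= iti else None, out, us[t])
                if record_traces:
                    proc_E[base + t] = net.E
                    pmfc_E[base + t] = pmfc.e
        else:
            # no-synchrony models have no phase code; the memoryless rate
            # dynamics settle on their steady state within two steps, so the
            # per-trial maxima equal the closed-form feedforward sweep
            net.X_in[:] = stim
            if algorithm == "rw":
                net.X_l2[:] = np.maximum(net.w1 @ stim, 0.0)
            else:
                x_h, x_o = static_mlp_forward(net.w1, net.w2, stim, spec.bias)
                net.X_l2[:] = x_h
                net.X_out[:] = x_o
            if record_traces:
                proc_E[n * steps:(n + 1) * steps] = 0.0
                pmfc_E[n * steps:(n + 1) * steps] = 0.0

        response = net.readout()
        correct = int(correct_col[n])
        reward = 1.0 if response == correct else 0.0

        if full:
            v = rl.value(lfc.module_pointers)
            dp, dm = prediction_errors(reward, v)
            rl.update_values(lfc.module_pointers, v, dp, dm)
            switched = rl.update_switch(dm)
            if switched:
                new_module = rl.choose_module(lfc.current, rng_rl)
                lfc.set_pointer(new_module)
                net.set_module_pointers(lfc.module_pointers,
                                        lfc.layer_pointer)
            rl.decay_inhibition()
            pending_dm = dm
            rec["v"].append(v)
            rec["delta_plus"].append(dp)
            rec["delta_minus"].append(dm)
            rec["s"].append(rl.s)
            rec["module"].append(lfc.current)
            rec["switch"].append(switched)
        else:
            rec["v"].append(np.nan)
            rec["delta_plus"].append(np.nan)
            rec["delta_minus"].append(np.nan)
            rec["s"].append(np.nan)
            rec["module"].append(-1)
            rec["switch"].append(False)

        target = np.zeros(3)
        target[correct] = 1.0
        dw = net.learn(target, beta)
        if record_weight_change:
            wchange[n] = dw

        rec["response"].append(response)
        rec["reward"].append(reward)
        rec["accuracy"].append(1.0 if response == correct else 0.0)

    records = task.reset_index(drop=True).copy()
    for k, v in rec.items():
        records[k] = v
    return SimulationResult(model_kind, beta, seed, n_dims, records,
                            steps, iti,
                            weight_change=wchange,
                            proc_E=proc_E if record_traces else None,
                            pmfc_E=pmfc_E if record_traces else None)


def run_replications(model_kind: str, task_maker, beta: float, n_reps: int,
                     seed: int, params: SimParams | None = None,
                     **run_kwargs) -> list[SimulationResult]:
    """Independent replications: fresh task order and model seed per rep."""
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_reps):
        task_seed, model_seed = child.generate_state(2) >> np.uint32(1)
        out.append(run_simulation(model_kind, task_maker(int(task_seed)),
                                  beta, int(model_seed), params,
                                  **run_kwargs))
    return out


# ---- binned behavioral metrics ---------------------------------------

@dataclass
class BinnedMetrics:
    accuracy: np.ndarray          # per-bin mean accuracy
    bin_size: int
    bins_per_block: int
    n_blocks: int
    plasticity: float = field(init=False)
    stability: float = field(init=False)

    def __post_init__(self) -> None:
        bpb, nb = self.bins_per_block, self.n_blocks
        half = nb // 2
        first5 = lambda b: self.accuracy[b * bpb:b * bpb + 5]
        last5 = lambda b: self.accuracy[(b + 1) * bpb - 5:(b + 1) * bpb]
        self.plasticity = float(np.mean([first5(b) for b in range(half)]))
        self.stability = float(np.mean([first5(b) for b in range(half, nb)])
                               - np.mean([last5(b) for b in range(half)]))


def default_bin_count(n_trials: int, n_blocks: int = 6,
                      target: int = 120) -> int:
    """Largest bin count <= ``target`` that divides the trials evenly into
    block-aligned bins (the standard analyses use 120)."""
    if n_trials % n_blocks:
        raise ValueError("trials must divide into equal blocks")
    per_block = n_trials // n_blocks
    for k in range(min(per_block, target // n_blocks), 0, -1):
        if per_block % k == 0:
            return n_blocks * k
    return n_blocks


def bin_metrics(records: pd.DataFrame, n_bins: int = 120) -> BinnedMetrics:
    """Per-bin accuracy plus the plasticity and stability scores."""
    n = len(records)
    if n % n_bins:
        raise ValueError(f"{n} trials not divisible into {n_bins} bins")
    n_blocks = int(records["block"].nunique())
    if n_bins % n_blocks:
        raise ValueError("bins must align with blocks")
    acc = (records["accuracy"].to_numpy()
           .reshape(n_bins, n // n_bins).mean(axis=1))
    return BinnedMetrics(acc, n // n_bins, n_bins // n_blocks, n_blocks)


def aggregate_replications(metrics: list[BinnedMetrics]) -> dict:
    """Mean curves/scores over replications with CI half-width 2*SD/sqrt(Nrep)."""
    nrep = len(metrics)
    acc = np.stack([m.accuracy for m in metrics])
    ci = lambda x: 2.0 * np.std(x, axis=0, ddof=1) / np.sqrt(nrep) \
        if nrep > 1 else np.zeros_like(np.mean(x, axis=0))
    plas = np.array([m.plasticity for m in metrics])
    stab = np.array([m.stability for m in metrics])
    return {
        "n_reps": nrep,
        "accuracy_mean": acc.mean(axis=0),
        "accuracy_ci": ci(acc),
        "plasticity_mean": float(plas.mean()),
        "plasticity_ci": float(ci(plas)),
        "stability_mean": float(stab.mean()),
        "stability_ci": float(ci(stab)),
    }


# ---- sweeps -----------------------------------------------------------

def sweep_learning_rate(model_kind: str, task_maker, betas=None,
                        n_reps: int = 10, seed: int = 0,
                        params: SimParams | None = None,
                        n_bins: int | None = None) -> pd.DataFrame:
    """Learning-rate grid (default 0..1 in 11 steps) with replications.

    ``task_maker(seed)`` must return a fresh task DataFrame.
    """
    betas = np.round(np.linspace(0.0, 1.0, 11), 10) if betas is None else betas
    ss = np.random.SeedSequence(seed)
    rows = []
    children = iter(ss.spawn(len(betas) * n_reps))
    for beta in betas:
        for rep in range(n_reps):
            child = next(children)
            t_seed, m_seed = child.generate_state(2) >> np.uint32(1)
            res = run_simulation(model_kind, task_maker(int(t_seed)),
                                 float(beta), int(m_seed), params)
            m = bin_metrics(res.records,
                            n_bins or default_bin_count(len(res.records)))
            rows.append((float(beta), rep, int(m_seed), res.accuracy,
                         m.plasticity, m.stability))
    return pd.DataFrame(rows, columns=["beta", "rep", "seed", "accuracy",
                                       "plasticity", "stability"])


def sweep_oscillator_params(ctrl_freqs, proc_freqs, ctrl_damps, ctrl_r_mins,
                            task_maker, n_reps: int = 5, beta: float = 0.2,
                            seed: int = 0,
                            base_params: SimParams | None = None) -> pd.DataFrame:
    """Full crossing of controller/processing frequencies and the controller's
    damping and attractor radius, on the linear full model; mean whole-task
    accuracy per cell."""
    base = base_params or SimParams()
    grid = list(product(ctrl_freqs, proc_freqs, ctrl_damps, ctrl_r_mins))
    ss = np.random.SeedSequence(seed)
    rows = []
    children = iter(ss.spawn(len(grid) * n_reps))
    for cf, pf, cd, cr in grid:
        p = SimParams(proc_freq=pf, proc_damp=base.proc_damp,
                      proc_r_min=base.proc_r_min, ctrl_freq=cf,
                      ctrl_damp=cd, ctrl_r_min=cr, bias=base.bias,
                      trial_steps=base.trial_steps, iti_steps=base.iti_steps)
        for rep in range(n_reps):
            child = next(children)
            t_seed, m_seed = child.generate_state(2) >> np.uint32(1)
            res = run_simulation("rw-full", task_maker(int(t_seed)), beta,
                                 int(m_seed), p)
            rows.append((cf, pf, cd, cr, rep, res.accuracy))
    return pd.DataFrame(rows, columns=["ctrl_freq", "proc_freq", "ctrl_damp",
                                       "ctrl_r_min", "rep", "accuracy"])


# ---- synchronization mechanics demo -----------------------------------

def bursting_synchrony_demo(seed: int = 0, pointed: int = 0,
                            burst_steps: int = 500,
                            measure_steps: int = 250,
                            pmfc_radius: float = 1.5,
                            params: SimParams | None = None
                            ) -> tuple[float, float]:
    """Drive a full linear network from random phases with theta bursts.

    Returns the mean zero-lag correlation of excitatory traces between the
    input layer and (pointed module, anti-pointed modules), measured over a
    burst-free coda after ``burst_steps`` of bursting.  The controller
    starts at ``pmfc_radius`` — the amplitude it reaches after error
    feedback — so bursts actually fire.
    """
    params = params or SimParams()
    rng = np.random.default_rng(seed)
    spec = NetworkSpec.rw_full()
    net = Network(spec, rng, params.proc_osc())
    lfc = LFCState.pointing_at(pointed)
    net.set_module_pointers(lfc.module_pointers, lfc.layer_pointer)
    pmfc = PMFC(params.ctrl_osc())
    pmfc.e, pmfc.i = pmfc_radius, 0.0

    for _ in range(burst_steps):
        pmfc.step(0.0)
        out = 1 if rng.random() < burst_probability(pmfc.e) else 0
        net.step(None, out, rng.standard_normal())

    traces = np.empty((measure_steps, spec.n_nodes))
    for t in range(measure_steps):
        net.step(None, 0, 0.0)
        traces[t] = net.E

    corr = np.corrcoef(traces.T)
    n_in = spec.n_inputs
    mod = net.module_of
    l2 = slice(n_in, n_in + spec.n_layer2)
    c_in_l2 = corr[:n_in, l2]           # (inputs, layer2 nodes)
    pointed_mask = mod == pointed
    c_pointed = float(c_in_l2[:, pointed_mask].mean())
    c_anti = float(c_in_l2[:, ~pointed_mask].mean())
    return c_pointed, c_anti
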