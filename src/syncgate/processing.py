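"""The task-learning network: layered rate/phase architecture with task modules.

Layer 1 codes stimulus features.  Layer 2 is split into task modules — one
per task rule the agent may have to hold — whose nodes are response options
in the linear (Rescorla-Wagner) family and hidden units in the multi-layer
(backpropagation) family; the latter adds a shared layer-3 of three response
nodes.  In the full models every node is an oscillatory triplet and the
communication between layers is gated by the phase of each node's excitatory
neuron, so a module that oscillates in anti-phase with the input layer is
effectively silent and its weights are protected from change.  No-synchrony
variants drop the phase code entirely (all gates fixed at 1).

Weight learning happens once per trial on the per-node maxima X_i of the
rate activations:

    modified RW  (full model):   dW_io = beta * (T_o - X_o) * X_i * X_o
    classic  RW  (no-synchrony): dW_io = beta * (T_o - X_o) * X_i
    BP: squared-error backpropagation with logistic derivatives on X

The extra X_o factor of the modified rule restricts eligibility to
co-activated pairs, which is what lets gating protect dormant modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .oscillator import OscillatorParams, gamma_params, random_phase_state

__all__ = [
    "NetworkSpec",
    "Network",
    "rw_modified_delta",
    "rw_classic_delta",
    "bp_weight_deltas",
    "static_mlp_forward",
]

_GATE_SLOPE = 5.0
_GATE_MID = 0.6


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the processing network."""

    algorithm: str                  # "rw" | "bp"
    synchrony: bool
    n_inputs: int
    n_modules: int
    nodes_per_module: int
    n_outputs: int                  # 0 for the two-layer RW family
    bias: float = 5.0

    def __post_init__(self) -> None:
        if self.algorithm not in ("rw", "bp"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.algorithm == "rw" and self.n_outputs != 0:
            raise ValueError("RW networks have two layers: layer-2 module "
                             "nodes are the response options")
        if self.algorithm == "bp" and self.n_outputs <= 0:
            raise ValueError("BP networks need a shared output layer")

    @property
    def n_layer2(self) -> int:
        return self.n_modules * self.nodes_per_module

    @property
    def n_nodes(self) -> int:
        return self.n_inputs + self.n_layer2 + self.n_outputs

    # ---- the four model families -------------------------------------
    @classmethod
    def rw_full(cls, n_inputs: int = 3, n_modules: int = 3) -> "NetworkSpec":
        return cls("rw", True, n_inputs, n_modules, 3, 0)

    @classmethod
    def rw_nosync(cls, n_inputs: int = 3) -> "NetworkSpec":
        # with all gates at 1 the three modules are redundant replicas, so
        # the no-synchrony linear model is a single input->response map
        return cls("rw", False, n_inputs, 1, 3, 0)

    @classmethod
    def bp_full(cls, n_inputs: int, n_modules: int = 3,
                nodes_per_module: int = 4) -> "NetworkSpec":
        return cls("bp", True, n_inputs, n_modules, nodes_per_module, 3)

    @classmethod
    def bp_nosync(cls, n_inputs: int, n_modules: int = 3,
                  nodes_per_module: int = 4) -> "NetworkSpec":
        return cls("bp", False, n_inputs, n_modules, nodes_per_module, 3)

    @classmethod
    def for_kind(cls, kind: str, n_inputs: int) -> "NetworkSpec":
        table = {
            "rw-full": cls.rw_full,
            "rw-nosync": cls.rw_nosync,
            "bp-full": cls.bp_full,
            "bp-nosync": cls.bp_nosync,
        }
        if kind not in table:
            raise ValueError(f"unknown model kind {kind!r}; "
                             f"choose from {sorted(table)}")
        return table[kind](n_inputs)


# ---- trial-level learning rules (pure, on the per-trial maxima) -------

def rw_modified_delta(x_in: np.ndarray, x_out: np.ndarray,
                      target: np.ndarray, beta: float) -> np.ndarray:
    """dW_io = beta * (T_o - X_o) * X_i * X_o (co-activation-gated delta rule)."""
    return beta * ((target - x_out) * x_out)[:, None] * x_in[None, :]

def rw_classic_delta(x_in: np.ndarray, x_out: np.ndarray,
                     target: np.ndarray, beta: float) -> np.ndarray:
    """Classic delta rule dW_io = beta * (T_o - X_o) * X_i."""
    return beta * (target - x_out)[:, None] * x_in[None, :]

def bp_weight_deltas(x_in: np.ndarray, x_hidden: np.ndarray,
                     x_out: np.ndarray, w2: np.ndarray, target: np.ndarray,
                     beta: float) -> tuple[np.ndarray, np.ndarray]:
    """One backpropagation step on squared error with logistic derivatives.

    Returns (dW1, dW2) for the input->hidden and hidden->output weights.
    """
    delta_out = (target - x_out) * x_out * (1.0 - x_out)
    delta_hid = (w2.T @ delta_out) * x_hidden * (1.0 - x_hidden)
    dw2 = beta * delta_out[:, None] * x_hidden[None, :]
    dw1 = beta * delta_hid[:, None] * x_in[None, :]
    return dw1, dw2

def static_mlp_forward(w1: np.ndarray, w2: np.ndarray, x_in: np.ndarray,
                       bias: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state activations of the ungated network (gains fixed at 1).

    With sustained input and open gates the memoryless rate dynamics settle
    on exactly this biased-logistic composition, so it serves as the
    reference for gradient checking the trial-level BP step.
    """
    x_h = 1.0 / (1.0 + np.exp(-(w1 @ x_in - bias)))
    x_o = 1.0 / (1.0 + np.exp(-(w2 @ x_h - bias)))
    return x_h, x_o


def learn_rbm_step(*args, **kwargs):
    """Extension hook for the restricted-Boltzmann learning family.

    The trial structure of that family (an ITI followed by 5 iterations of
    bidirectional information flow, 250 steps per direction, with
    stochastic binarization of the per-step maxima between iterations) is
    architecturally compatible with :class:`Network`, but the learning rule
    itself is not implemented here.
    """
    raise NotImplementedError(
        "the Boltzmann learning family is a documented extension hook only")


class Network:
    """Mutable state of the processing network across a simulation.

    Holds the weights, one oscillator triplet per node (full models), the
    instantaneous rate activations and the per-trial maxima ``X`` that feed
    the learning rules.
    """

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator,
                 osc_params: OscillatorParams | None = None):
        self.spec = spec
        scale = spec.bias / 2.0 if spec.algorithm == "bp" else 1.0
        self.w1 = rng.uniform(0.0, 1.0, size=(spec.n_layer2, spec.n_inputs)) * scale
        self.w2 = (rng.uniform(0.0, 1.0, size=(spec.n_outputs, spec.n_layer2)) * scale
                   if spec.algorithm == "bp" else None)

        self.module_of = np.repeat(np.arange(spec.n_modules), spec.nodes_per_module)
        if spec.algorithm == "rw":
            self.response_of = np.tile(np.arange(3), spec.n_modules)

        self.x_in = np.zeros(spec.n_inputs)
        self.x_l2 = np.zeros(spec.n_layer2)
        self.x_out = np.zeros(spec.n_outputs)
        self.X_in = np.zeros(spec.n_inputs)
        self.X_l2 = np.zeros(spec.n_layer2)
        self.X_out = np.zeros(spec.n_outputs)

        if spec.synchrony:
            self.osc = osc_params if osc_params is not None else gamma_params()
            self.E, self.I = random_phase_state(spec.n_nodes, self.osc.r_min, rng)
            # per-node pointer signs, refreshed whenever the LFC switches
            self.pointers = np.ones(spec.n_nodes)
        else:
            self.osc = None
            self.E = self.I = self.pointers = None

    # ---- pointer plumbing --------------------------------------------
    def set_module_pointers(self, module_pointers: np.ndarray,
                            layer_pointer: float = 1.0) -> None:
        """Map LFC pointers onto nodes: module sign for layer 2, layer sign else."""
        s = self.spec
        self.pointers[:s.n_inputs] = layer_pointer
        self.pointers[s.n_inputs:s.n_inputs + s.n_layer2] = \
            module_pointers[self.module_of]
        if s.n_outputs:
            self.pointers[s.n_inputs + s.n_layer2:] = layer_pointer

    # ---- dynamics -----------------------------------------------------
    def begin_trial(self) -> None:
        self.X_in[:] = 0.0
        self.X_l2[:] = 0.0
        self.X_out[:] = 0.0

    def step(self, input_vec: np.ndarray | None,
             pmfc_out: int = 0, u: float = 0.0) -> None:
        """Advance one 2 ms step: phases, gates, then a feedforward rate sweep."""
        s = self.spec
        if s.synchrony:
            osc = self.osc
            E, I = self.E, self.I
            j = (E * E + I * I > osc.r_min * osc.r_min).astype(float)
            burst = self.pointers * (u if pmfc_out else 0.0)
            E_new = E + (-osc.coupling * I - osc.damp * j * E + burst)
            I_new = I + (osc.coupling * E - osc.damp * j * I)
            self.E, self.I = E_new, I_new
            gains = 1.0 / (1.0 + np.exp(-_GATE_SLOPE * (E_new - _GATE_MID)))
            g_in = gains[:s.n_inputs]
            g_l2 = gains[s.n_inputs:s.n_inputs + s.n_layer2]
            g_out = gains[s.n_inputs + s.n_layer2:]
        else:
            g_in = g_l2 = g_out = 1.0

        # layer 1: linear pass-through of the external drive
        if input_vec is None:
            self.x_in = np.zeros(s.n_inputs) if np.isscalar(g_in) else 0.0 * g_in
        else:
            self.x_in = input_vec * g_in

        net2 = self.w1 @ self.x_in
        if s.algorithm == "rw":
            self.x_l2 = net2 * g_l2
        else:
            self.x_l2 = g_l2 / (1.0 + np.exp(-(net2 - s.bias)))
            net3 = self.w2 @ self.x_l2
            self.x_out = g_out / (1.0 + np.exp(-(net3 - s.bias)))
            np.maximum(self.X_out, self.x_out, out=self.X_out)

        np.maximum(self.X_in, self.x_in, out=self.X_in)
        np.maximum(self.X_l2, self.x_l2, out=self.X_l2)

    # ---- readout and learning ----------------------------------------
    def readout(self) -> int:
        """Response with the largest per-trial maximum; ties break low.

        RW pools same-response nodes across modules by max so a gated-out
        module cannot vote; BP reads the shared output layer.
        """
        if self.spec.algorithm == "rw":
            pooled = self.X_l2.reshape(self.spec.n_modules, 3).max(axis=0)
            return int(np.argmax(pooled))
        return int(np.argmax(self.X_out))

    def learn(self, target: np.ndarray, beta: float) -> np.ndarray:
        """Apply the family's trial-end learning rule.

        ``target`` is the one-hot correct-response vector.  Returns the
        summed absolute weight change into each module's nodes (layer-1 ->
        layer-2 weights plus, for BP, that module's outgoing weights), used
        to quantify how well gating protects dormant modules.
        """
        s = self.spec
        if s.algorithm == "rw":
            t_l2 = target[self.response_of]
            if s.synchrony:
                dw1 = rw_modified_delta(self.X_in, self.X_l2, t_l2, beta)
            else:
                dw1 = rw_classic_delta(self.X_in, self.X_l2, t_l2, beta)
            self.w1 += dw1
            per_node = np.abs(dw1).sum(axis=1)
            dw2_share = 0.0
        else:
            dw1, dw2 = bp_weight_deltas(self.X_in, self.X_l2, self.X_out,
                                        self.w2, target, beta)
            self.w1 += dw1
            self.w2 += dw2
            per_node = np.abs(dw1).sum(axis=1)
            dw2_share = np.abs(dw2).sum(axis=0)
        totals = np.zeros(s.n_modules)
        np.add.at(totals, self.module_of, per_node + dw2_share)
        return totals
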