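"""Reversal-learning task generators.

Two deterministic stimulus-response paradigms over six equal blocks with
rule order A B C A B C:

* a one-dimensional task (360 trials): one of three features is shown and
  each rule is a cyclic permutation feature -> response (A identity, B shift
  by one, C shift by two);
* an N-dimensional cued task (3600 trials, N in {2, 3}): every stimulus
  dimension shows one of three features and an extra cue dimension (with N
  features) marks which stimulus dimension is relevant; the rule's
  permutation is applied to the relevant dimension's feature.

Stimuli are balanced within each block by constructing shuffled tilings of
the full combination list rather than i.i.d. sampling, so per-block counts
differ by at most one (and are exactly equal whenever the block length is a
multiple of the number of combinations).
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "RULES",
    "RULE_ORDER",
    "correct_response",
    "make_one_dim_task",
    "make_multi_dim_task",
    "trial_input_indices",
    "input_width",
]

#: rule -> permutation: RULES[rule][feature] is the rewarded response
RULES: dict[str, tuple[int, int, int]] = {
    "A": (0, 1, 2),
    "B": (1, 2, 0),
    "C": (2, 0, 1),
}

RULE_ORDER: tuple[str, ...] = ("A", "B", "C", "A", "B", "C")


def correct_response(feature: int, rule: str) -> int:
    """Rewarded response for ``feature`` under ``rule`` (pure permutation lookup)."""
    return RULES[rule][feature]


def _balanced_block(combos: list, n: int, rng: np.random.Generator) -> list:
    """``n`` draws covering ``combos`` as evenly as possible (counts differ <= 1)."""
    out: list = []
    while len(out) < n:
        batch = list(combos)
        rng.shuffle(batch)
        out.extend(batch)
    return out[:n]


def make_one_dim_task(seed: int | np.random.Generator,
                      n_trials: int = 360, n_blocks: int = 6) -> pd.DataFrame:
    """The three-feature task: columns trial, block, rule, f0, correct."""
    rng = np.random.default_rng(seed)
    if n_trials % n_blocks:
        raise ValueError("n_trials must divide into equal blocks")
    block_len = n_trials // n_blocks
    rows = []
    for b in range(n_blocks):
        rule = RULE_ORDER[b % len(RULE_ORDER)]
        for f in _balanced_block(list(range(3)), block_len, rng):
            rows.append((b, rule, f, correct_response(f, rule)))
    df = pd.DataFrame(rows, columns=["block", "rule", "f0", "correct"])
    df.insert(0, "trial", np.arange(n_trials))
    return df


def make_multi_dim_task(n_dims: int, seed: int | np.random.Generator,
                        n_trials: int = 3600,
                        n_blocks: int = 6) -> pd.DataFrame:
    """The cued task: a cue feature picks the relevant stimulus dimension.

    Columns: trial, block, rule, cue, f0..f{N-1}, correct.
    """
    if n_dims not in (2, 3):
        raise ValueError("n_dims must be 2 or 3")
    rng = np.random.default_rng(seed)
    if n_trials % n_blocks:
        raise ValueError("n_trials must divide into equal blocks")
    block_len = n_trials // n_blocks
    combos = list(product(range(n_dims), *([range(3)] * n_dims)))
    rows = []
    for b in range(n_blocks):
        rule = RULE_ORDER[b % len(RULE_ORDER)]
        for combo in _balanced_block(combos, block_len, rng):
            cue, feats = combo[0], combo[1:]
            rows.append((b, rule, cue, *feats,
                         correct_response(feats[cue], rule)))
    cols = ["block", "rule", "cue"] + [f"f{d}" for d in range(n_dims)] + ["correct"]
    df = pd.DataFrame(rows, columns=cols)
    df.insert(0, "trial", np.arange(n_trials))
    return df


def input_width(n_dims: int) -> int:
    """Number of layer-1 nodes: 3 for the plain task, N + 3N for the cued task."""
    return 3 if n_dims == 1 else n_dims + 3 * n_dims


def trial_input_indices(row: pd.Series, n_dims: int) -> list[int]:
    """Active layer-1 node indices for one trial.

    Layout for the cued task: cue features occupy indices 0..N-1, then
    dimension d's features occupy N + 3d .. N + 3d + 2.
    """
    if n_dims == 1:
        return [int(row["f0"])]
    idx = [int(row["cue"])]
    for d in range(n_dims):
        idx.append(n_dims + 3 * d + int(row[f"f{d}"]))
    return idx
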