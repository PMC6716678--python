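"""HDF5 archives for dense simulation traces.

Per-trial excitatory traces are large (trials x 500 steps x nodes), so they
go to HDF5 rather than CSV.  Each archive carries the run's identifying
metadata so downstream analyses can refuse mismatched inputs.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .experiment import SimulationResult

__all__ = ["save_traces", "load_traces"]


def save_traces(result: SimulationResult, path: str | Path,
                config_hash: str = "") -> None:
    """Write the dense traces of one simulation to an HDF5 archive."""
    if result.proc_E is None or result.pmfc_E is None:
        raise ValueError("simulation was run without record_traces=True")
    with h5py.File(path, "w") as f:
        f.create_dataset("proc_E", data=result.proc_E, compression="gzip")
        f.create_dataset("pmfc_E", data=result.pmfc_E, compression="gzip")
        f.create_dataset("accuracy",
                         data=result.records["accuracy"].to_numpy())
        f.attrs["model_kind"] = result.model_kind
        f.attrs["beta"] = result.beta
        f.attrs["seed"] = result.seed
        f.attrs["trial_steps"] = result.trial_steps
        f.attrs["iti_steps"] = result.iti_steps
        f.attrs["config_hash"] = config_hash


def load_traces(path: str | Path, expect_hash: str | None = None) -> dict:
    """Read a trace archive back; refuses a mismatched config hash."""
    with h5py.File(path, "r") as f:
        stored = f.attrs.get("config_hash", "")
        if expect_hash is not None and stored != expect_hash:
            raise ValueError(f"config hash mismatch: archive has "
                             f"{stored!r}, expected {expect_hash!r}")
        return {
            "proc_E": np.asarray(f["proc_E"]),
            "pmfc_E": np.asarray(f["pmfc_E"]),
            "accuracy": np.asarray(f["accuracy"]),
            "model_kind": f.attrs["model_kind"],
            "beta": float(f.attrs["beta"]),
            "seed": int(f.attrs["seed"]),
            "trial_steps": int(f.attrs["trial_steps"]),
            "iti_steps": int(f.attrs["iti_steps"]),
            "config_hash": stored,
        }
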