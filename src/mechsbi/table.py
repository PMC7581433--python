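"""Columnar storage for (parameter, feature) simulation records."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["SimulationTable", "save_table", "load_table"]

_SCHEMA_VERSION = 1


@dataclass
class SimulationTable:
    """Rows of (parameters theta, features x, round index, validity, seed).

    Rows whose simulation failed feature extraction are kept but flagged
    invalid; their feature entries are NaN.  Optionally carries the log
    proposal density each parameter row was drawn from (used for
    importance weighting across rounds).
    """

    theta: np.ndarray
    x: np.ndarray
    round_index: np.ndarray
    valid: np.ndarray
    seeds: np.ndarray
    log_proposal: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        n = self.theta.shape[0]
        self.round_index = np.asarray(self.round_index, dtype=int).reshape(n)
        self.valid = np.asarray(self.valid, dtype=bool).reshape(n)
        self.seeds = np.asarray(self.seeds, dtype=np.uint32).reshape(n)
        if self.log_proposal is None:
            self.log_proposal = np.zeros(n)
        self.log_proposal = np.asarray(self.log_proposal, dtype=float).reshape(n)

    def __len__(self):
        return self.theta.shape[0]

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def concat(self, other: "SimulationTable") -> "SimulationTable":
        return SimulationTable(
            np.vstack([self.theta, other.theta]),
            np.vstack([self.x, other.x]),
            np.concatenate([self.round_index, other.round_index]),
            np.concatenate([self.valid, other.valid]),
            np.concatenate([self.seeds, other.seeds]),
            np.concatenate([self.log_proposal, other.log_proposal]),
            dict(self.meta),
        )

    @classmethod
    def empty(cls, n_params: int, n_features: int) -> "SimulationTable":
        return cls(np.empty((0, n_params)), np.empty((0, n_features)),
                   np.empty(0, dtype=int), np.empty(0, dtype=bool),
                   np.empty(0, dtype=np.uint32))


def save_table(table: SimulationTable, path: str) -> None:
    """One dataset per column in an HDF5 container, plus a plain-text
    sidecar naming the simulator, prior and extractor."""
    path = str(path)
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = _SCHEMA_VERSION
        fh.create_dataset("theta", data=table.theta)
        fh.create_dataset("x", data=table.x)
        fh.create_dataset("round_index", data=table.round_index)
        fh.create_dataset("valid", data=table.valid)
        fh.create_dataset("seeds", data=table.seeds)
        fh.create_dataset("log_proposal", data=table.log_proposal)
    with open(path + ".meta.json", "w") as fh:
        json.dump({"schema_version": _SCHEMA_VERSION, **table.meta}, fh, indent=1)


def load_table(path: str) -> SimulationTable:
    path = str(path)
    with h5py.File(path, "r") as fh:
        if int(fh.attrs.get("schema_version", -1)) != _SCHEMA_VERSION:
            raise ValueError("unsupported simulation-table schema version")
        table = SimulationTable(
            fh["theta"][...], fh["x"][...], fh["round_index"][...],
            fh["valid"][...], fh["seeds"][...], fh["log_proposal"][...])
    try:
        with open(path + ".meta.json") as fh:
            table.meta = {k: v for k, v in json.load(fh).items()
                          if k != "schema_version"}
    except FileNotFoundError:
        pass
    return table
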