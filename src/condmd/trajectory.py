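"""In-memory trajectory container shared by builders, analysis and IO."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trajectory:
    """Time-ordered frames of unwrapped bead positions plus chain topology.

    Positions are stored unwrapped (continuous across the periodic
    boundaries) so mean-square displacements are exact; analysis that needs
    wrapped coordinates re-wraps with :meth:`wrapped`.
    """

    times: np.ndarray  # (F,)
    positions: np.ndarray  # (F, n, 3) unwrapped
    box: np.ndarray  # (3,)
    roles: np.ndarray  # (n,) int8
    chain_len: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[0] != len(self.times):
            raise ValueError("positions must be (n_frames, n_beads, 3) matching times")
        if self.positions.shape[1] % self.chain_len:
            raise ValueError("bead count must be a multiple of chain_len")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    @property
    def n_chains(self) -> int:
        return self.n_beads // self.chain_len

    @property
    def central_bead_indices(self) -> np.ndarray:
        return np.arange(self.n_chains) * self.chain_len + self.chain_len // 2

    def wrapped(self, frame: int) -> np.ndarray:
        return np.mod(self.positions[frame], self.box[None, :])

    def slice_frames(self, start: int = 0, stop: int | None = None, stride: int = 1) -> "Trajectory":
        sl = slice(start, stop, stride)
        return Trajectory(self.times[sl], self.positions[sl], self.box,
                          self.roles, self.chain_len, dict(self.meta))


class TrajectoryRecorder:
    """Collects frames from a running simulation into a Trajectory."""

    def __init__(self, state) -> None:
        self._topology = state.topology
        self._box = state.box.copy()
        self._times: list = []
        self._frames: list = []

    def capture(self, state) -> None:
        self._times.append(state.time)
        self._frames.append(state.unwrapped)

    def trajectory(self, **meta) -> Trajectory:
        return Trajectory(np.array(self._times), np.array(self._frames),
                          self._box, self._topology.roles,
                          self._topology.chain_len, meta)
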