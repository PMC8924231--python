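"""Langevin dynamics engine for many bead-spring chains in a periodic box.

The integrator is the symmetric BAOAB splitting (half-kick, half-drift,
Ornstein-Uhlenbeck velocity update, half-drift, half-kick); with friction
set to zero it reduces to velocity Verlet and conserves energy, which is
the validation mode used in the tests.  Trajectories are bit-reproducible
for a given (seed, inputs, step count) because the thermostat noise is
counter-based rather than sequential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import _kernels
from .model import BeadRole, CGModel, InteractionTable, ModelValidationError, ProteinSequence

__all__ = [
    "Topology",
    "SimulationState",
    "EngineParams",
    "IntegrationError",
    "CheckpointError",
    "step",
    "compute_forces",
    "kinetic_energy",
    "switch_interactions",
    "write_checkpoint",
    "read_checkpoint",
]

CHECKPOINT_VERSION = 1


class IntegrationError(RuntimeError):
    pass


class CheckpointError(RuntimeError):
    pass


@dataclass(frozen=True)
class Topology:
    """Chain structure: ``n_chains`` identical chains of ``chain_len`` beads.

    Bead ``i`` belongs to chain ``i // chain_len``; consecutive beads of a
    chain are bonded and excluded from nonbonded interactions.
    """

    n_chains: int
    chain_len: int
    roles: np.ndarray  # (n_chains * chain_len,) int8 BeadRole values

    def __post_init__(self) -> None:
        if len(self.roles) != self.n_chains * self.chain_len:
            raise ModelValidationError("roles length must equal n_chains * chain_len")

    @property
    def n_beads(self) -> int:
        return self.n_chains * self.chain_len

    @property
    def central_bead_indices(self) -> np.ndarray:
        mid = self.chain_len // 2
        return np.arange(self.n_chains) * self.chain_len + mid

    @classmethod
    def from_sequence(cls, sequence: ProteinSequence, n_chains: int) -> "Topology":
        return cls(n_chains, sequence.n_beads, np.tile(sequence.roles_array(), n_chains))


@dataclass
class SimulationState:
    """Positions (wrapped) + image counts + velocities + clock.

    ``step_count`` doubles as the RNG counter: together with the engine seed
    it fully determines all future thermostat noise, so it is the
    reproducibility token stored in checkpoints.
    """

    positions: np.ndarray  # (n, 3), wrapped into [0, box)
    images: np.ndarray  # (n, 3) int64 periodic image counts
    velocities: np.ndarray
    box: np.ndarray  # (3,)
    topology: Topology
    time: float = 0.0
    step_count: int = 0
    switch_log: list = field(default_factory=list)

    @property
    def unwrapped(self) -> np.ndarray:
        return self.positions + self.images * self.box[None, :]

    def copy(self) -> "SimulationState":
        return SimulationState(
            self.positions.copy(), self.images.copy(), self.velocities.copy(),
            self.box.copy(), self.topology, self.time, self.step_count,
            list(self.switch_log),
        )


@dataclass(frozen=True)
class EngineParams:
    dt: float = 0.005
    friction_gamma: float = 0.1
    temperature_kT: float = 1.0
    neighbor_skin: float = 0.4
    seed: int = 0
    mass: float = 1.0
    force_cap: float = 0.0  # 0 disables; used only during initial relaxation

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ModelValidationError("dt must be positive")
        if self.friction_gamma < 0:
            raise ModelValidationError("friction must be non-negative")


def _kernel_args(model: CGModel):
    pot = model.potential
    sigma = model.units.sigma
    form_id = 0 if pot.form == "lennard_jones" else 1
    cutoff = pot.cutoff * sigma
    if form_id == 0 and pot.shift_at_cutoff:
        sr6 = (sigma / cutoff) ** 6
        c_shift = 4.0 * (sr6 * sr6 - sr6)
    else:
        c_shift = 0.0
    if form_id == 1:
        from .model import _wf_alpha

        wf_alpha = _wf_alpha(cutoff, sigma, pot.wf_nu, pot.wf_mu)
    else:
        wf_alpha = 0.0
    return (model.interactions.as_matrix(), form_id, sigma, cutoff, c_shift,
            wf_alpha, pot.wf_mu, pot.wf_nu, model.bonds.k_bond, model.bonds.r0)


def _check_box(state: SimulationState, model: CGModel, params: EngineParams) -> None:
    rlist = model.potential.cutoff * model.units.sigma + params.neighbor_skin
    if rlist > 0.5 * float(np.min(state.box)):
        raise ModelValidationError(
            f"cutoff+skin ({rlist:.2f}) exceeds half the smallest box edge "
            f"({0.5 * float(np.min(state.box)):.2f})"
        )


def step(state: SimulationState, params: EngineParams, model: CGModel, n_steps: int) -> SimulationState:
    """Advance the state in place by ``n_steps`` Langevin steps."""
    _check_box(state, model, params)
    (eps_mat, form_id, sigma, cutoff, c_shift, wf_alpha, wf_mu, wf_nu,
     k_bond, r0) = _kernel_args(model)
    pe, n_rebuilds, n_ov, ok = _kernels.run_langevin(
        state.positions, state.images, state.velocities, state.box,
        state.topology.roles, state.topology.chain_len, eps_mat, form_id,
        sigma, cutoff, c_shift, wf_alpha, wf_mu, wf_nu, k_bond, r0,
        params.dt, params.friction_gamma, params.temperature_kT, params.mass,
        n_steps, params.seed, state.step_count, params.neighbor_skin,
        params.force_cap,
    )
    state.step_count += n_steps
    state.time += n_steps * params.dt
    if not ok:
        raise IntegrationError(
            f"non-finite coordinates after step {state.step_count} "
            f"(t={state.time:.3f}); reduce dt or enable the force cap"
        )
    if n_ov and params.force_cap == 0.0:
        logging.getLogger("condmd.engine").warning(
            "%d bead overlap(s) closer than 0.5 sigma during an uncapped "
            "run ending at t=%.2f; deep overlaps are evaluated at "
            "r = 0.3 sigma", n_ov, state.time,
        )
    return state


def compute_forces(state: SimulationState, model: CGModel, skin: float = 0.4,
                   force_cap: float = 0.0):
    """Forces and potential energy at the current positions (fresh neighbor list)."""
    (eps_mat, form_id, sigma, cutoff, c_shift, wf_alpha, wf_mu, wf_nu,
     k_bond, r0) = _kernel_args(model)
    idx2d, shift2d, counts = _kernels.build_neighbor_list(
        state.positions, state.box, cutoff + skin, state.topology.chain_len)
    f = np.empty_like(state.positions)
    pe, n_overlap = _kernels._forces(
        state.positions, state.box, 1.0 / state.box, state.topology.roles,
        state.topology.chain_len, eps_mat, form_id, sigma, cutoff, c_shift,
        wf_alpha, wf_mu, wf_nu, k_bond, r0, force_cap, idx2d, shift2d, counts, f,
    )
    return f, pe


def kinetic_energy(state: SimulationState, mass: float = 1.0) -> float:
    return 0.5 * mass * float(np.sum(state.velocities ** 2))


def switch_interactions(state: SimulationState, model: CGModel,
                        new_table: InteractionTable) -> CGModel:
    """Swap well depths mid-run (the hysteresis 'heating'/'cooling' move).

    Positions and velocities are untouched; the switch is appended to the
    state's schedule log with its time stamp.
    """
    present = set(int(r) for r in np.unique(state.topology.roles))
    if not present <= {int(r) for r in BeadRole}:
        raise ModelValidationError("topology contains unknown bead roles")
    state.switch_log.append(
        {"time": state.time, "eps_D": new_table.eps_D, "eps_S": new_table.eps_S}
    )
    return model.with_interactions(new_table)


def write_checkpoint(state: SimulationState, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["version"] = CHECKPOINT_VERSION
        h5.attrs["time"] = state.time
        h5.attrs["step_count"] = state.step_count
        h5.attrs["n_chains"] = state.topology.n_chains
        h5.attrs["chain_len"] = state.topology.chain_len
        h5.create_dataset("positions", data=state.positions)
        h5.create_dataset("images", data=state.images)
        h5.create_dataset("velocities", data=state.velocities)
        h5.create_dataset("box", data=state.box)
        h5.create_dataset("roles", data=state.topology.roles)
        if state.switch_log:
            log = np.array([[e["time"], e["eps_D"], e["eps_S"]] for e in state.switch_log])
            h5.create_dataset("switch_log", data=log)


def read_checkpoint(path) -> SimulationState:
    try:
        with h5py.File(path, "r") as h5:
            version = int(h5.attrs.get("version", -1))
            if version != CHECKPOINT_VERSION:
                raise CheckpointError(
                    f"checkpoint version {version} != supported {CHECKPOINT_VERSION}"
                )
            topo = Topology(int(h5.attrs["n_chains"]), int(h5.attrs["chain_len"]),
                            h5["roles"][...])
            switch_log = []
            if "switch_log" in h5:
                for t, ed, es in h5["switch_log"][...]:
                    switch_log.append({"time": float(t), "eps_D": float(ed), "eps_S": float(es)})
            return SimulationState(
                h5["positions"][...], h5["images"][...], h5["velocities"][...],
                h5["box"][...], topo, float(h5.attrs["time"]),
                int(h5.attrs["step_count"]), switch_log,
            )
    except OSError as exc:
        raise CheckpointError(f"unreadable checkpoint {path}: {exc}") from exc
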