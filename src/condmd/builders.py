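"""Initial-condition builders: dilute gases, bulk condensed boxes, preformed
droplets, tangent droplet pairs, and analytic fixture trajectories.

All builders are deterministic given their seed.  Dense phases are prepared
by placing self-avoiding random-walk chains at low density (or inside a
sphere) and relaxing under damped, force-capped dynamics; bulk boxes are
then compressed stepwise to the target density -- a robust route that
random insertion alone cannot reach.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from . import analysis
from .engine import EngineParams, SimulationState, Topology, compute_forces, step
from .model import BeadRole, CGModel, InteractionTable, ProteinSequence, make_sequence
from .trajectory import Trajectory

__all__ = [
    "SystemSpec",
    "PackingError",
    "FragmentationError",
    "NonPhaseSeparatingError",
    "build_dilute",
    "build_bulk",
    "build_droplet",
    "build_tangent_pair",
    "estimate_coexistence_density",
    "make_synthetic_fixtures",
]


class PackingError(RuntimeError):
    pass


class FragmentationError(RuntimeError):
    pass


class NonPhaseSeparatingError(RuntimeError):
    pass


@dataclass(frozen=True)
class SystemSpec:
    """Geometry request for one experiment."""

    n_chains: int
    sequence: ProteinSequence
    box: tuple
    geometry_tag: str = "dilute_gas"  # dilute_gas | bulk_condensed | droplet | tangent_droplets
    droplet_sizes: tuple = ()

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.geometry_tag == "tangent_droplets" and len(self.droplet_sizes) != 2:
            raise ValueError("tangent_droplets needs exactly two droplet sizes")


def _random_in_sphere(rng: np.random.Generator, radius: float) -> np.ndarray:
    while True:
        p = rng.uniform(-radius, radius, 3)
        if np.dot(p, p) <= radius * radius:
            return p


def _place_saw_chains(n_chains: int, chain_len: int, box: np.ndarray,
                      rng: np.random.Generator, min_dist: float = 0.9,
                      bond_len: float = 1.0, max_retries: int = 400,
                      center: np.ndarray | None = None,
                      radius: float | None = None) -> np.ndarray:
    """Random-walk chains with a minimum inter-bead distance, optionally
    confined to a sphere (droplet packing)."""
    placed: list = []
    for _ in range(n_chains):
        tree = cKDTree(np.mod(np.vstack(placed), box), boxsize=box) if placed else None
        for _attempt in range(max_retries):
            if radius is not None:
                p0 = center + _random_in_sphere(rng, radius)
            else:
                p0 = rng.uniform(0.0, 1.0, 3) * box
            if tree is not None and tree.query(np.mod(p0, box))[0] < min_dist:
                continue
            chain = [p0]
            dead = False
            for _ in range(chain_len - 1):
                prev = np.array(chain[:-1]) if len(chain) > 1 else None
                for _try in range(60):
                    d = rng.normal(size=3)
                    d *= bond_len / np.linalg.norm(d)
                    nxt = chain[-1] + d
                    if radius is not None and np.linalg.norm(nxt - center) > radius:
                        continue
                    if prev is not None and \
                            np.linalg.norm(prev - nxt, axis=1).min() < min_dist:
                        continue
                    if tree is not None and \
                            tree.query(np.mod(nxt, box))[0] < min_dist:
                        continue
                    break
                else:
                    dead = True
                    break
                chain.append(nxt)
            if dead:
                continue
            chain = np.array(chain)
            placed.append(chain)
            break
        else:
            raise PackingError(
                f"could not place chain {len(placed) + 1}/{n_chains}; "
                "use a larger box or lower density"
            )
    return np.vstack(placed)


def make_chains_whole(state: SimulationState) -> None:
    """Rewrite images so every chain is contiguous in unwrapped coordinates.

    Required before any operation that changes the box (minimum images of
    split chains are not preserved under resizing).
    """
    L = state.topology.chain_len
    box = state.box
    u = state.unwrapped.reshape(state.topology.n_chains, L, 3)
    bonds = np.diff(u, axis=1)
    bonds -= box * np.rint(bonds / box)
    whole = np.concatenate(
        [u[:, :1, :], u[:, :1, :] + np.cumsum(bonds, axis=1)], axis=1)
    posu = whole.reshape(-1, 3)
    img = np.floor(posu / box[None, :]).astype(np.int64)
    state.positions = posu - img * box[None, :]
    state.images = img


def resize_box(state: SimulationState, new_box) -> None:
    """Change the periodic box, keeping whole chains intact.

    Unwrapped coordinates are fixed under the old box first; only then are
    they re-wrapped into the new one.
    """
    make_chains_whole(state)
    posu = state.unwrapped  # under the old box
    state.box = np.asarray(new_box, dtype=float)
    img = np.floor(posu / state.box[None, :]).astype(np.int64)
    state.positions = posu - img * state.box[None, :]
    state.images = img


def _make_state(positions: np.ndarray, box: np.ndarray, sequence: ProteinSequence,
                n_chains: int) -> SimulationState:
    topo = Topology.from_sequence(sequence, n_chains)
    pos = np.mod(positions, box[None, :])
    return SimulationState(pos, np.zeros_like(pos, dtype=np.int64),
                           np.zeros_like(pos), np.asarray(box, dtype=float), topo)


def _relax(state: SimulationState, model: CGModel, seed: int,
           capped_steps: int = 1500, settle_steps: int = 1000) -> None:
    """Heal residual overlaps and thermalize without disturbing structure."""
    if capped_steps:
        step(state, EngineParams(dt=0.001, friction_gamma=5.0, seed=seed,
                                 force_cap=50.0), model, capped_steps)
    if settle_steps:
        step(state, EngineParams(dt=0.005, friction_gamma=1.0, seed=seed + 1),
             model, settle_steps)


def build_dilute(spec: SystemSpec, seed: int = 0) -> SimulationState:
    """Homogeneous dilute gas of chains (the nucleation starting point)."""
    box = np.asarray(spec.box, dtype=float)
    n_beads = spec.n_chains * spec.sequence.n_beads
    phi = n_beads * np.pi / 6.0 / box.prod()
    if phi > 0.08:
        raise PackingError(f"requested packing fraction {phi:.3f} is not dilute")
    rng = np.random.default_rng(seed)
    pos = _place_saw_chains(spec.n_chains, spec.sequence.n_beads, box, rng)
    return _make_state(pos, box, spec.sequence, spec.n_chains)


def build_bulk(n_chains: int, sequence: ProteinSequence, model: CGModel,
               density: float, seed: int = 0, start_density: float = 0.10,
               compress_steps: int = 1200, equil_steps: int = 6000) -> SimulationState:
    """Periodic bulk box at a target bead density (condensed-phase NVT).

    Chains are placed at ``start_density`` and the box is compressed by up
    to 5 % per stage under damped dynamics until the target is reached,
    then equilibrated.
    """
    n_beads = n_chains * sequence.n_beads
    bl = (n_beads / start_density) ** (1.0 / 3.0)
    box = np.array([bl] * 3)
    rng = np.random.default_rng(seed)
    pos = _place_saw_chains(n_chains, sequence.n_beads, box, rng)
    state = _make_state(pos, box, sequence, n_chains)
    _relax(state, model, seed + 10, capped_steps=1500, settle_steps=500)
    rho = n_beads / state.box.prod()
    k = 0
    while rho < density - 1e-9:
        s = max(0.95, (rho / density) ** (1.0 / 3.0))
        state.positions *= s
        state.box *= s
        state.images[:] = 0
        rho = n_beads / state.box.prod()
        step(state, EngineParams(dt=0.002, friction_gamma=5.0, seed=seed + 20 + k,
                                 force_cap=200.0), model, compress_steps)
        k += 1
    step(state, EngineParams(dt=0.005, friction_gamma=1.0, seed=seed + 90),
         model, equil_steps)
    return state


def build_droplet(n_chains: int, sequence: ProteinSequence, model: CGModel,
                  seed: int = 0, pack_density: float = 0.35,
                  box_factor: float = 6.0, relax_rounds: int = 8,
                  round_steps: int = 2500, kappa2_tol: float | None = None,
                  cluster_cutoff: float = 1.5) -> SimulationState:
    """Preformed, roughly spherical condensate centered in a large box.

    Chains are packed into a sphere at ``pack_density`` beads/sigma^3 and
    equilibrated with the supplied (weak, liquid-regime) model until the
    cluster is near-spherical (kappa^2 < ``kappa2_tol``) and the potential
    energy has plateaued.  The default tolerance allows for the larger
    surface shape fluctuations of small droplets: max(0.05, 1.5/n_chains).
    Raises FragmentationError if the cluster falls apart, the signature of
    a non-phase-separating model.
    """
    if kappa2_tol is None:
        kappa2_tol = max(0.05, 1.5 / n_chains)
    n_beads = n_chains * sequence.n_beads
    R = (3.0 * n_beads / (4.0 * np.pi * pack_density)) ** (1.0 / 3.0)
    edge = max(box_factor * R, 4.0 * R + 10.0)
    box = np.array([edge] * 3)
    center = box / 2.0
    rng = np.random.default_rng(seed)
    pos = _place_saw_chains(n_chains, sequence.n_beads, box, rng,
                            center=center, radius=R + 0.5)
    state = _make_state(pos, box, sequence, n_chains)
    if n_chains == 1:
        return state
    _relax(state, model, seed + 10)
    prev_pe = None
    for r_i in range(relax_rounds):
        step(state, EngineParams(dt=0.005, friction_gamma=1.0, seed=seed + 100 + r_i),
             model, round_steps)
        w = np.mod(state.positions, state.box[None, :])
        labels, sizes = analysis.chain_clusters(w, state.box, sequence.n_beads,
                                                cluster_cutoff)
        if sizes[0] < 0.9 * n_chains:
            raise FragmentationError(
                f"droplet fragmented during relaxation: largest cluster holds "
                f"{sizes[0] / n_chains:.2f} of chains"
            )
        idx = analysis.largest_cluster_beads(w, state.box, sequence.n_beads,
                                             cluster_cutoff)
        pts = analysis.unwrap_cluster(w, state.box, idx, cluster_cutoff)
        k2 = analysis.shape_metrics(pts).kappa2
        _, pe = compute_forces(state, model)
        converged = k2 < kappa2_tol and prev_pe is not None and \
            abs(pe - prev_pe) < 0.02 * abs(prev_pe)
        prev_pe = pe
        if converged:
            break
    else:
        if k2 >= 2.0 * kappa2_tol:
            raise PackingError(f"droplet failed to sphere up (kappa^2 = {k2:.3f})")
    # recenter the droplet on the box center
    com = np.mod(pts.mean(axis=0), state.box)
    shift = center - com
    state.positions = np.mod(state.positions + shift[None, :], state.box[None, :])
    state.images[:] = 0
    return state


def build_tangent_pair(n1: int, n2: int, sequence: ProteinSequence, model: CGModel,
                       seed: int = 0, gap: float = 1.0, min_dist: float = 0.9,
                       max_rotations: int = 20, **droplet_kw) -> SimulationState:
    """Two pre-equilibrated droplets placed with surfaces in tangent contact.

    Each droplet is built independently, randomly rotated, and the pair is
    placed along x with a surface gap of ``gap`` sigma (closest approach at
    least ``min_dist``).  The box is about three merged-droplet diameters
    per axis.
    """
    d1 = build_droplet(n1, sequence, model, seed=seed, **droplet_kw)
    d2 = build_droplet(n2, sequence, model, seed=seed + 7919, **droplet_kw)
    rng = np.random.default_rng(seed + 15809)

    c1 = d1.unwrapped - d1.unwrapped.mean(axis=0)
    c2 = d2.unwrapped - d2.unwrapped.mean(axis=0)
    nb1 = n1 * sequence.n_beads
    Rm = ((nb1 + n2 * sequence.n_beads) * 3.0 / (4.0 * np.pi * 0.45)) ** (1.0 / 3.0)
    for _rot in range(max_rotations):
        q1 = Rotation.random(random_state=rng).as_matrix()
        q2 = Rotation.random(random_state=rng).as_matrix()
        a = c1 @ q1.T
        b = c2 @ q2.T
        s = a[:, 0].max() - b[:, 0].min() + gap
        for _push in range(60):
            bb = b + np.array([s, 0.0, 0.0])
            dmin = cKDTree(a).query(bb, k=1)[0].min()
            if dmin >= min_dist:
                break
            s += 0.2
        else:
            continue
        # pull back so the surfaces actually touch (closest approach within
        # [min_dist, min_dist + 0.3]) -- a pair parked beyond the contact
        # range would have to re-find itself by diffusion
        for _pull in range(60):
            trial = b + np.array([s - 0.05, 0.0, 0.0])
            d2 = cKDTree(a).query(trial, k=1)[0].min()
            if d2 < min_dist:
                break
            s -= 0.05
            bb, dmin = trial, d2
        if not (min_dist <= dmin <= min_dist + 0.3):
            continue
        extent = (a[:, 0].max() - a[:, 0].min()) + (bb[:, 0].max() - bb[:, 0].min())
        edge = max(6.0 * Rm, extent + 4.0 * Rm)
        box = np.array([edge] * 3)
        pos = np.vstack([a, bb])
        pos = pos - pos.mean(axis=0) + box / 2.0
        state = _make_state(pos, box, sequence, n1 + n2)
        # sanity: the two droplets separate at any cutoff below the gap
        w = np.mod(state.positions, state.box[None, :])
        _, sizes = analysis.chain_clusters(w, state.box, sequence.n_beads, 1.5)
        if len(sizes) <= 2:
            return state
    raise PackingError("could not place tangent droplets without overlap")


def estimate_coexistence_density(model: CGModel, sequence: ProteinSequence,
                                 seed: int = 0, n_chains: int = 50,
                                 sample_steps: int = 10000, n_samples: int = 4,
                                 **droplet_kw):
    """Condensed-phase density from the radial plateau of a droplet run.

    Builds a droplet with the model itself, runs production dynamics and
    averages the core density over ``n_samples`` snapshots.  Returns
    (beads/sigma^3, chains/sigma^3).  Raises NonPhaseSeparatingError when no
    stable droplet exists at this state point.
    """
    try:
        state = build_droplet(n_chains, sequence, model, seed=seed, **droplet_kw)
    except (FragmentationError, PackingError) as exc:
        raise NonPhaseSeparatingError(
            f"no stable droplet at eps_D={model.interactions.eps_D}: {exc}"
        ) from exc
    params = EngineParams(dt=0.005, friction_gamma=0.1, seed=seed + 31)
    densities = []
    for _ in range(n_samples):
        step(state, params, model, sample_steps // n_samples)
        w = np.mod(state.positions, state.box[None, :])
        _, sizes = analysis.chain_clusters(w, state.box, sequence.n_beads, 1.5)
        if sizes[0] < 0.5 * n_chains:
            raise NonPhaseSeparatingError(
                f"droplet evaporated at eps_D={model.interactions.eps_D} "
                f"(largest cluster fraction {sizes[0] / n_chains:.2f})"
            )
        rho, _, _, flags = analysis.condensate_density(w, state.box, sequence.n_beads)
        densities.append(rho)
    rho_beads = float(np.mean(densities))
    return rho_beads, rho_beads / sequence.n_beads


def make_synthetic_fixtures(kind: str, params: dict | None = None,
                            seed: int = 0) -> Trajectory:
    """Analytic fixture trajectories with known ground truth.

    Kinds: ``brownian_walkers`` (free diffusion at D_true),
    ``rigid_sphere_cloud`` (static uniform ball of known density),
    ``rigid_rod`` (collinear points, kappa^2 = 1),
    ``two_spheres_merging`` (scheduled fusion completing at merge_frame),
    ``contact_toy`` (two chains with one A-B contact at a set distance).
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "brownian_walkers":
        n = int(params.get("n_walkers", 200))
        D = float(params.get("D_true", 0.5))
        F = int(params.get("n_frames", 201))
        dtf = float(params.get("dt_frame", 1.0))
        box = np.array([1e6] * 3)
        steps = rng.normal(0.0, np.sqrt(2.0 * D * dtf), size=(F - 1, n, 3))
        pos = np.concatenate([np.zeros((1, n, 3)), np.cumsum(steps, axis=0)], axis=0)
        pos += box / 2.0
        return Trajectory(np.arange(F) * dtf, pos, box,
                          np.full(n, int(BeadRole.SPACER), np.int8), 1,
                          {"D_true": D})
    if kind == "rigid_sphere_cloud":
        n = int(params.get("n_points", 3000))
        R = float(params.get("radius", 8.0))
        F = int(params.get("n_frames", 3))
        box = np.array([max(10.0 * R, 100.0)] * 3)
        pts = np.array([_random_in_sphere(rng, R) for _ in range(n)]) + box / 2.0
        pos = np.repeat(pts[None, :, :], F, axis=0)
        rho = n / (4.0 / 3.0 * np.pi * R ** 3)
        return Trajectory(np.arange(F, dtype=float), pos, box,
                          np.full(n, int(BeadRole.SPACER), np.int8), 1,
                          {"density": rho, "radius": R})
    if kind == "rigid_rod":
        n = int(params.get("n_points", 50))
        box = np.array([1e4] * 3)
        pts = np.zeros((n, 3))
        pts[:, 0] = np.arange(n, dtype=float)
        pts += box / 2.0
        pos = np.repeat(pts[None, :, :], 2, axis=0)
        return Trajectory(np.arange(2, dtype=float), pos, box,
                          np.full(n, int(BeadRole.SPACER), np.int8), 1, {})
    if kind == "two_spheres_merging":
        R = float(params.get("radius", 5.0))
        k = int(params.get("merge_frame", 80))
        F = int(params.get("n_frames", 120))
        box = np.array([20.0 * R] * 3)
        # unit-lattice-filled balls stay cutoff-connected, unlike sparse
        # random samples
        g = np.arange(-int(R), int(R) + 1, dtype=float)
        gx, gy, gz = np.meshgrid(g, g, g, indexing="ij")
        lattice = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        lattice = lattice[np.linalg.norm(lattice, axis=1) <= R]
        jitter = 0.05
        a = lattice + rng.normal(0.0, jitter, lattice.shape)
        b = lattice + rng.normal(0.0, jitter, lattice.shape)
        n_per = len(lattice)
        d0 = 2.0 * R + 2.0  # initial surface gap above the cluster cutoff
        frames = []
        for f in range(F):
            # separation collapses sharply as f -> merge_frame, then zero
            x = max(0.0, 1.0 - f / k)
            d = d0 * x ** 0.25
            ca = box / 2.0 - np.array([d / 2.0, 0.0, 0.0])
            cb = box / 2.0 + np.array([d / 2.0, 0.0, 0.0])
            frames.append(np.vstack([a + ca, b + cb]))
        return Trajectory(np.arange(F, dtype=float), np.array(frames), box,
                          np.full(2 * n_per, int(BeadRole.SPACER), np.int8), 1,
                          {"merge_frame": k})
    if kind == "contact_toy":
        r_ab = float(params.get("r_contact", 1.1))
        seq = make_sequence("uniform")
        L = seq.n_beads
        box = np.array([200.0] * 3)
        from .model import DEFAULT_A_POSITIONS, DEFAULT_B_POSITIONS

        a0 = DEFAULT_A_POSITIONS[0]  # chain 2's first A sticker
        b0 = DEFAULT_B_POSITIONS[0]  # chain 1's first B sticker
        c1 = np.zeros((L, 3))
        c1[:, 0] = 50.0 + np.arange(L, dtype=float)
        c1[:, 1] = 100.0
        c1[:, 2] = 100.0
        # chain 2 is L-shaped with the corner at its first A sticker, which
        # sits r_ab away from chain 1's first B sticker; every other bead
        # points away from chain 1
        c2 = np.zeros((L, 3))
        j = np.arange(L, dtype=float)
        c2[:, 0] = c1[b0, 0]
        c2[:, 1] = 100.0 + r_ab + np.maximum(j - a0, 0.0)
        c2[:, 2] = 100.0 + np.maximum(a0 - j, 0.0)
        pos = np.vstack([c1, c2])
        roles = np.concatenate([seq.roles_array(), seq.roles_array()])
        return Trajectory(np.array([0.0]), pos[None, :, :], box, roles, L,
                          {"r_contact": r_ab, "expected_contacts": 1})
    raise ValueError(f"unknown fixture kind {kind!r}")
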