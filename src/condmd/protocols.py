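"""Turnkey experiment drivers: bulk diffusion scans, nucleation and growth,
thermal hysteresis, in-droplet maturation, coalescence matrices and LLPS
threshold scans.

Every driver returns :class:`ExperimentRecord` objects that carry their
full configuration and seed, so any record can be re-run bit-identically.
Sizes and durations default to desk-scale systems; the phenomenology
(regime ordering in eps_S, coalescence-time ordering in droplet size,
path-dependent arrest) is ordinal and survives the scale-down.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field

import numpy as np

from . import analysis, builders
from .analysis import DiffusionSeries, classify_regime, msd_windowed
from .engine import EngineParams, SimulationState, step, switch_interactions
from .model import CGModel, InteractionTable, PotentialSpec, ProteinSequence, make_sequence
from .trajectory import TrajectoryRecorder

__all__ = [
    "ExperimentRecord",
    "DEFAULT_KINETIC_THRESHOLD",
    "run_bulk_diffusion_scan",
    "run_nucleation_growth",
    "run_hysteresis",
    "run_maturation_in_droplet",
    "run_coalescence_matrix",
    "scan_llps_threshold",
    "rerun_record",
]

# Kinetic threshold separating liquid from ageing on our simulation
# timescale: one tenth of the weak-binding liquid plateau.  The definition
# is scale-free; the constant reflects this package's own measured
# homopolymer eps_D = 0.66 plateau of ~1e-2 sigma^2/tau* in the condensed
# phase.
DEFAULT_KINETIC_THRESHOLD = 1e-3

# Weak liquid-regime interactions used to pre-equilibrate droplets before a
# protocol switches the strong interactions on.
PREEQUIL_TABLE = InteractionTable(0.5, 5.0, coupled=True)

# Global bead packing fraction of dilute starting boxes.
DILUTE_PACKING_FRACTION = 0.02


@dataclass
class ExperimentRecord:
    """Protocol output: config + seed + observable series + final labels."""

    protocol: str
    config: dict
    seed: int
    schedule: list = field(default_factory=list)
    series: dict = field(default_factory=dict)
    labels: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        import dataclasses

        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, np.bool_):
                return bool(x)
            if dataclasses.is_dataclass(x) and not isinstance(x, type):
                return {f.name: conv(getattr(x, f.name))
                        for f in dataclasses.fields(x)}
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            return x

        return {"protocol": self.protocol, "config": conv(self.config),
                "seed": self.seed, "schedule": conv(self.schedule),
                "series": conv(self.series), "labels": conv(self.labels),
                "provenance": conv(self.provenance)}


def _dilute_box(n_beads: int, phi: float = DILUTE_PACKING_FRACTION) -> np.ndarray:
    edge = (n_beads * np.pi / 6.0 / phi) ** (1.0 / 3.0)
    return np.array([edge] * 3)


def _run_sampled(state: SimulationState, params: EngineParams, model: CGModel,
                 duration: float, frame_dt: float) -> TrajectoryRecorder:
    rec = TrajectoryRecorder(state)
    rec.capture(state)
    n_frames = max(1, int(round(duration / frame_dt)))
    steps_per_frame = max(1, int(round(frame_dt / params.dt)))
    for _ in range(n_frames):
        step(state, params, model, steps_per_frame)
        rec.capture(state)
    return rec


def _cluster_stats(state: SimulationState):
    w = np.mod(state.positions, state.box[None, :])
    L = state.topology.chain_len
    _, sizes = analysis.chain_clusters(w, state.box, L)
    idx = analysis.largest_cluster_beads(w, state.box, L)
    pts = analysis.unwrap_cluster(w, state.box, idx)
    k2 = analysis.shape_metrics(pts).kappa2
    return sizes[0] / state.topology.n_chains, k2


def _provenance(t0: float) -> dict:
    from . import __version__

    return {"code_version": __version__, "wall_time_s": round(_time.time() - t0, 2)}


def run_bulk_diffusion_scan(eps_S_grid, n_chains: int = 60, duration: float = 400.0,
                            seed: int = 0, sequence: ProteinSequence | None = None,
                            potential: PotentialSpec | None = None,
                            threshold: float = DEFAULT_KINETIC_THRESHOLD,
                            displacement_factor: float = 3.0,
                            frame_dt: float = 2.0,
                            density_chains: int = 30,
                            homopolymer_eps_D=None) -> list:
    """D(t) in the condensed bulk phase for a grid of eps_S (eps_D = eps_S/10).

    Each state point is simulated in a periodic NVT box at its own
    self-measured coexistence density.  Optionally appends homopolymer
    control points at uniform well depth ``homopolymer_eps_D`` (scalar or
    list).  State points that do not phase separate are recorded with the
    label ``non_llps`` instead of raising.
    """
    records = []
    jobs = [("sticker_spacer", float(e)) for e in eps_S_grid]
    if homopolymer_eps_D is not None:
        eps_list = np.atleast_1d(homopolymer_eps_D)
        jobs += [("homopolymer", float(e)) for e in eps_list]
    for k, (kind, eps) in enumerate(jobs):
        t0 = _time.time()
        if kind == "homopolymer":
            seq = make_sequence("homopolymer")
            table = InteractionTable(eps, eps)
        else:
            seq = sequence or make_sequence("uniform")
            table = InteractionTable.from_eps_S(eps)
        model = CGModel(table, potential or PotentialSpec())
        cfg = {"kind": kind, "eps": eps, "eps_D": table.eps_D, "eps_S": table.eps_S,
               "n_chains": n_chains, "duration": duration,
               "displacement_factor": displacement_factor, "threshold": threshold,
               "frame_dt": frame_dt, "density_chains": density_chains,
               "patterning": seq.patterning_tag}
        rec = ExperimentRecord("bulk_diffusion_scan", cfg, seed + 1000 * k)
        try:
            rho, _ = builders.estimate_coexistence_density(
                model, seq, seed=rec.seed, n_chains=density_chains)
        except builders.NonPhaseSeparatingError as exc:
            rec.labels = {"regime": "non_llps", "detail": str(exc)}
            rec.provenance = _provenance(t0)
            records.append(rec)
            continue
        state = builders.build_bulk(n_chains, seq, model, rho, seed=rec.seed + 1)
        params = EngineParams(dt=0.005, friction_gamma=0.1, seed=rec.seed + 2)
        traj = _run_sampled(state, params, model, duration, frame_dt).trajectory()
        series = msd_windowed(traj, displacement_factor, allow_partial=True)
        label = classify_regime(series, threshold)
        rec.series = {"diffusion": series, "coexistence_density": rho}
        rec.labels = {"regime": label.label, "onset_time": label.onset_time,
                      "low_confidence": label.low_confidence,
                      "terminal_D": float(series.D_values[-1])}
        rec.provenance = _provenance(t0)
        records.append(rec)
    return records


def run_nucleation_growth(eps_S: float, n_chains: int = 60, duration: float = 400.0,
                          seed: int = 0, homopolymer_eps_D: float | None = None,
                          potential: PotentialSpec | None = None,
                          threshold: float = DEFAULT_KINETIC_THRESHOLD,
                          frame_dt: float = 2.0) -> ExperimentRecord:
    """Nucleation and growth from a homogeneous dilute start.

    Reports the terminal largest-cluster shape: liquid settings give a
    near-spherical condensate, ageing settings an aspherical arrested
    aggregate.  With ``homopolymer_eps_D`` set, runs the uniform-weak
    control at that well depth instead of the sticker-spacer model.
    """
    t0 = _time.time()
    if homopolymer_eps_D is not None:
        seq = make_sequence("homopolymer")
        table = InteractionTable(homopolymer_eps_D, homopolymer_eps_D)
    else:
        seq = make_sequence("uniform")
        table = InteractionTable.from_eps_S(eps_S)
    model = CGModel(table, potential or PotentialSpec())
    cfg = {"eps_D": table.eps_D, "eps_S": table.eps_S, "n_chains": n_chains,
           "duration": duration, "threshold": threshold, "frame_dt": frame_dt,
           "patterning": seq.patterning_tag, "eps_S_arg": eps_S,
           "homopolymer_eps_D": homopolymer_eps_D}
    rec = ExperimentRecord("nucleation_growth", cfg, seed)
    box = _dilute_box(n_chains * seq.n_beads)
    spec = builders.SystemSpec(n_chains, seq, tuple(box))
    state = builders.build_dilute(spec, seed=seed)
    params = EngineParams(dt=0.005, friction_gamma=0.1, seed=seed + 2)
    traj = _run_sampled(state, params, model, duration, frame_dt).trajectory()
    frac, k2 = _cluster_stats(state)
    try:
        series = msd_windowed(traj, 3.0, allow_partial=True)
        label = classify_regime(series, threshold)
        rec.series["diffusion"] = series
        regime = label.label
        terminal_D = float(series.D_values[-1])
    except analysis.TrajectoryTooShortError:
        regime = "ageing"
        terminal_D = None
    rec.labels = {"nucleated": bool(frac >= 0.5), "largest_fraction": frac,
                  "terminal_kappa2": k2, "regime": regime,
                  "terminal_D": terminal_D}
    rec.provenance = _provenance(t0)
    return rec


def run_hysteresis(schedule, n_chains: int = 60, seed: int = 0,
                   potential: PotentialSpec | None = None,
                   threshold: float = DEFAULT_KINETIC_THRESHOLD,
                   frame_dt: float = 2.0) -> ExperimentRecord:
    """Multi-leg interaction-strength schedule from a homogeneous start.

    ``schedule`` is a list of (eps_S, duration) legs; interactions are
    switched between legs (the model's proxy for cooling/heating, since
    T* = kBT / eps).  Per leg the record stores the terminal largest-cluster
    fraction, shape anisotropy and diffusion estimate.  Hysteresis shows up
    as an arrested, aspherical leg at an eps_S whose direct run is liquid;
    a final leg at eps_S = 3.5 dissolves the condensate entirely.
    """
    t0 = _time.time()
    schedule = [(float(e), float(d)) for e, d in schedule]
    if not schedule:
        raise ValueError("schedule must contain at least one leg")
    seq = make_sequence("uniform")
    cfg = {"schedule": schedule, "n_chains": n_chains, "threshold": threshold,
           "frame_dt": frame_dt}
    rec = ExperimentRecord("hysteresis", cfg, seed)
    for _, dur in schedule:
        if dur < 3 * frame_dt:
            raise ValueError("each leg must span at least three analysis frames")
    model = CGModel(InteractionTable.from_eps_S(schedule[0][0]),
                    potential or PotentialSpec())
    box = _dilute_box(n_chains * seq.n_beads)
    state = builders.build_dilute(builders.SystemSpec(n_chains, seq, tuple(box)),
                                  seed=seed)
    legs = []
    for li, (eps_S, dur) in enumerate(schedule):
        if li > 0:
            model = switch_interactions(state, model, InteractionTable.from_eps_S(eps_S))
        params = EngineParams(dt=0.005, friction_gamma=0.1, seed=seed + 10 * li + 3)
        traj = _run_sampled(state, params, model, dur, frame_dt).trajectory()
        frac, k2 = _cluster_stats(state)
        leg = {"eps_S": eps_S, "duration": dur, "largest_fraction": frac,
               "kappa2": k2}
        try:
            series = msd_windowed(traj, 3.0, allow_partial=True)
            lab = classify_regime(series, threshold)
            leg["regime"] = lab.label
            leg["terminal_D"] = float(series.D_values[-1])
        except analysis.TrajectoryTooShortError:
            leg["regime"] = "ageing"
            leg["terminal_D"] = None
        leg["dissolved"] = bool(frac < 0.1)
        legs.append(leg)
    rec.schedule = list(state.switch_log)
    rec.series["legs"] = legs
    rec.labels = {"final_dissolved": legs[-1]["dissolved"],
                  "final_kappa2": legs[-1]["kappa2"]}
    rec.provenance = _provenance(t0)
    return rec


def run_maturation_in_droplet(n_chains: int = 60, eps_S: float = 6.6,
                              duration: float = 300.0, seed: int = 0,
                              potential: PotentialSpec | None = None,
                              threshold_contact_density: float = 0.01,
                              frame_dt: float = 5.0,
                              contact_cutoff: float = 1.5) -> ExperimentRecord:
    """Strong-interaction maturation inside a preformed spherical droplet.

    The droplet is equilibrated under weak (liquid) interactions, then the
    strong well depth is switched to ``eps_S``.  The record tracks the
    number of inter-chain A-B contacts (normalised by condensate volume and
    by ``threshold_contact_density``, the contact density taken to arrest
    the liquid) together with the shape anisotropy -- which stays near
    spherical even as contacts accumulate past the threshold.
    """
    t0 = _time.time()
    seq = make_sequence("uniform")
    cfg = {"n_chains": n_chains, "eps_S": eps_S, "duration": duration,
           "threshold_contact_density": threshold_contact_density,
           "frame_dt": frame_dt, "contact_cutoff": contact_cutoff}
    rec = ExperimentRecord("maturation_in_droplet", cfg, seed)
    model = CGModel(PREEQUIL_TABLE, potential or PotentialSpec())
    state = builders.build_droplet(n_chains, seq, model, seed=seed)
    frac0, k2_0 = _cluster_stats(state)
    model = switch_interactions(state, model, InteractionTable.from_eps_S(eps_S))
    params = EngineParams(dt=0.005, friction_gamma=0.1, seed=seed + 5)
    L = seq.n_beads
    times, counts, vols, k2s, fracs = [], [], [], [], []

    def sample():
        w = np.mod(state.positions, state.box[None, :])
        n_strong, _, _ = analysis.strong_contacts(w, state.box,
                                                  state.topology.roles, L,
                                                  contact_cutoff)
        idx = analysis.largest_cluster_beads(w, state.box, L)
        pts = analysis.unwrap_cluster(w, state.box, idx)
        k2 = analysis.shape_metrics(pts).kappa2
        r = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        r_eq = np.quantile(r, 0.95)  # near-equimolar radius of the droplet
        vol = 4.0 / 3.0 * np.pi * r_eq ** 3
        times.append(state.time)
        counts.append(n_strong)
        vols.append(vol)
        k2s.append(k2)
        fracs.append(len(idx) / (L * n_chains))

    sample()
    n_frames = max(0, int(round(duration / frame_dt)))
    steps_per_frame = max(1, int(round(frame_dt / params.dt)))
    for _ in range(n_frames):
        step(state, params, model, steps_per_frame)
        sample()
    times_a = np.array(times)
    counts_a = np.array(counts, dtype=float)
    vols_a = np.array(vols)
    normalized = counts_a / vols_a / threshold_contact_density
    rec.schedule = list(state.switch_log)
    rec.series["contacts"] = analysis.ContactSeries(
        times_a, counts_a, vols_a, normalized, threshold_contact_density)
    rec.series["kappa2"] = np.array(k2s)
    rec.series["largest_fraction"] = np.array(fracs)
    evaporated = fracs[-1] < 0.5
    rec.labels = {
        "initial_kappa2": k2_0,
        "final_kappa2": k2s[-1],
        "max_kappa2": float(np.max(k2s)),
        "crossed_threshold": bool(normalized[-1] >= 1.0),
        "crossing_time": (float(times_a[normalized >= 1.0][0])
                          if np.any(normalized >= 1.0) else None),
        "shape_preserved": bool(np.max(k2s) <= max(2.0 * k2_0, 0.1)),
        "evaporated": bool(evaporated),
    }
    rec.provenance = _provenance(t0)
    return rec


def run_coalescence_matrix(sizes=(20, 50, 100), eps_S_grid=(5.0, 5.25, 5.75),
                           censor_time: float | None = None, seed: int = 0,
                           potential: PotentialSpec | None = None,
                           frame_dt: float = 5.0,
                           sphericity_tol: float | None = None,
                           dwell_fraction: float = 0.1) -> dict:
    """Coalescence time tau_c of equal-size tangent droplet pairs.

    For each droplet size and eps_S, two pre-equilibrated droplets are
    placed in tangent contact, the interactions are switched to eps_S, and
    the run is censored at ``censor_time`` (default: 20x the measured tau_c
    of the weakest-binding pair of the same size).  The sphericity
    tolerance defaults to max(0.02, 2.5 / total chains): small merged
    droplets never fall below the full-scale 0.02 because their equilibrium
    surface shape fluctuations alone exceed it.  Returns a dict with the
    records and a tidy table of (size, eps_S, tau_c, censored).
    """
    import pandas as pd

    seq = make_sequence("uniform")
    records, rows = [], []
    for si, n in enumerate(sizes):
        cell_censor = censor_time
        # matches the measured equilibrium kappa^2 of desk-scale droplets
        cell_tol = sphericity_tol if sphericity_tol is not None \
            else max(0.02, 2.5 / (2 * n))
        for ei, eps_S in enumerate(sorted(eps_S_grid)):
            t0 = _time.time()
            cfg = {"size": int(n), "eps_S": float(eps_S), "frame_dt": frame_dt,
                   "sphericity_tol": cell_tol,
                   "dwell_fraction": dwell_fraction}
            rec = ExperimentRecord("coalescence", cfg, seed + 97 * si + 11 * ei)
            model = CGModel(PREEQUIL_TABLE, potential or PotentialSpec())
            try:
                state = builders.build_tangent_pair(n, n, seq, model, seed=rec.seed)
            except (builders.PackingError, builders.FragmentationError) as exc:
                rec.labels = {"status": "build_failed", "detail": str(exc)}
                records.append(rec)
                rows.append({"size": n, "eps_S": eps_S, "tau_c": np.nan,
                             "censored": True, "status": "build_failed"})
                continue
            model = switch_interactions(state, model,
                                        InteractionTable.from_eps_S(eps_S))
            horizon = cell_censor if cell_censor is not None else 600.0
            params = EngineParams(dt=0.005, friction_gamma=0.1, seed=rec.seed + 3)
            traj = _run_sampled(state, params, model, horizon, frame_dt).trajectory()
            res = analysis.coalescence_time(traj, cell_tol, dwell_fraction,
                                            censor_time=horizon)
            if cell_censor is None and not res.censored:
                # peg this size's censor horizon to its weakest-binding tau_c
                cell_censor = 20.0 * res.tau_c
            rec.series["coalescence"] = res
            rec.schedule = list(state.switch_log)
            rec.labels = {"tau_c": res.tau_c, "censored": res.censored,
                          "status": res.status, "censor_time": res.censor_time}
            rec.provenance = _provenance(t0)
            records.append(rec)
            rows.append({"size": n, "eps_S": eps_S, "tau_c": res.tau_c,
                         "censored": res.censored, "status": res.status})
    return {"records": records, "table": pd.DataFrame(rows)}


def scan_llps_threshold(patterning: str = "homopolymer",
                        eps_grid=(0.25, 0.30, 0.35, 0.40, 0.45, 0.50),
                        n_chains: int = 60, duration: float = 600.0,
                        seed: int = 0, potential: PotentialSpec | None = None,
                        frame_dt: float = 5.0, block: float = 100.0,
                        persistent_fraction: float = 0.5) -> ExperimentRecord:
    """Smallest interaction strength at which a persistent condensate forms.

    For each grid value, a dilute homogeneous system is evolved in blocks of
    ``block`` tau* until the block-averaged largest-cluster fraction stops
    drifting (or ``duration`` is exhausted, whichever first) -- near the
    threshold, coarsening is slow and premature truncation would misclassify
    the state point.  It is phase separated when the converged fraction
    reaches ``persistent_fraction``.  For the homopolymer the grid is in
    eps_D; for sticker-spacer patternings it is in eps_S with
    eps_D = eps_S / 10.  The threshold carries one grid step of uncertainty.
    """
    t0 = _time.time()
    eps_grid = sorted(float(e) for e in eps_grid)
    seq = make_sequence(patterning)
    cfg = {"patterning": patterning, "eps_grid": eps_grid, "n_chains": n_chains,
           "duration": duration, "persistent_fraction": persistent_fraction,
           "frame_dt": frame_dt, "block": block}
    rec = ExperimentRecord("llps_threshold_scan", cfg, seed)
    outcomes = []
    for gi, eps in enumerate(eps_grid):
        if patterning == "homopolymer":
            table = InteractionTable(eps, eps)
        else:
            table = InteractionTable.from_eps_S(eps)
        model = CGModel(table, potential or PotentialSpec())
        box = _dilute_box(n_chains * seq.n_beads)
        state = builders.build_dilute(builders.SystemSpec(n_chains, seq, tuple(box)),
                                      seed=seed + 31 * gi)
        params = EngineParams(dt=0.005, friction_gamma=0.1, seed=seed + 31 * gi + 1)
        L = seq.n_beads
        frames_per_block = max(2, int(round(block / frame_dt)))
        steps_per_frame = max(1, int(round(frame_dt / params.dt)))
        n_blocks = max(2, int(round(duration / block)))
        block_means = []
        t_used = 0.0
        for _bi in range(n_blocks):
            fracs = []
            for _ in range(frames_per_block):
                step(state, params, model, steps_per_frame)
                w = np.mod(state.positions, state.box[None, :])
                _, sizes = analysis.chain_clusters(w, state.box, L)
                fracs.append(sizes[0] / n_chains)
            block_means.append(float(np.mean(fracs)))
            t_used = state.time
            if len(block_means) >= 2 and \
                    abs(block_means[-1] - block_means[-2]) < 0.05:
                break
        tail = block_means[-1]
        separated = bool(tail >= persistent_fraction)
        outcomes.append({"eps": eps, "separated": separated,
                         "tail_fraction": tail, "t_used": t_used,
                         "block_means": block_means})
    seps = [o["separated"] for o in outcomes]
    threshold = None
    boundary_flag = None
    if any(seps):
        threshold = eps_grid[seps.index(True)]
        if seps[0]:
            boundary_flag = "low"  # threshold at or below the grid start
    else:
        boundary_flag = "high"
    spacing = min(np.diff(eps_grid)) if len(eps_grid) > 1 else None
    rec.series["outcomes"] = outcomes
    rec.labels = {"threshold": threshold, "uncertainty": spacing,
                  "boundary_flag": boundary_flag}
    rec.provenance = _provenance(t0)
    return rec


_PROTOCOLS = {
    "nucleation_growth": run_nucleation_growth,
    "hysteresis": run_hysteresis,
    "maturation_in_droplet": run_maturation_in_droplet,
    "llps_threshold_scan": scan_llps_threshold,
}


def rerun_record(record: ExperimentRecord) -> ExperimentRecord:
    """Re-execute a record from its own stored config and seed."""
    fn = _PROTOCOLS.get(record.protocol)
    if fn is None:
        raise ValueError(f"protocol {record.protocol!r} cannot be re-run directly")
    cfg = dict(record.config)
    if record.protocol == "nucleation_growth":
        return fn(cfg["eps_S_arg"], n_chains=cfg["n_chains"],
                  duration=cfg["duration"], seed=record.seed,
                  homopolymer_eps_D=cfg["homopolymer_eps_D"],
                  threshold=cfg["threshold"], frame_dt=cfg["frame_dt"])
    if record.protocol == "hysteresis":
        sched = [(e, d) for e, d in cfg["schedule"]]
        return fn(sched, n_chains=cfg["n_chains"], seed=record.seed,
                  threshold=cfg["threshold"], frame_dt=cfg["frame_dt"])
    if record.protocol == "maturation_in_droplet":
        return fn(n_chains=cfg["n_chains"], eps_S=cfg["eps_S"],
                  duration=cfg["duration"], seed=record.seed,
                  threshold_contact_density=cfg["threshold_contact_density"],
                  frame_dt=cfg["frame_dt"], contact_cutoff=cfg["contact_cutoff"])
    if record.protocol == "llps_threshold_scan":
        return fn(cfg["patterning"], cfg["eps_grid"], n_chains=cfg["n_chains"],
                  duration=cfg["duration"], seed=record.seed,
                  frame_dt=cfg["frame_dt"],
                  persistent_fraction=cfg["persistent_fraction"])
    raise ValueError(record.protocol)
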