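"""Configuration files, trajectory formats and result export.

Canonical interchange format is extended XYZ (species column carries the
bead role, the comment line carries box, time and chain length; coordinates
are stored wrapped with integer image flags so unwrapped positions are
exact).  LAMMPS-dump text is supported for interoperability; its reader
tolerates arbitrary column order by parsing the ATOMS header.
All quantities are reduced units: sigma, kBT, tau*.
"""

from __future__ import annotations

import hashlib
import json
import os
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .model import (BeadRole, BondSpec, CGModel, InteractionTable, PotentialSpec,
                    ProteinSequence, make_sequence)
from .trajectory import Trajectory

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "config_hash",
    "write_trajectory",
    "read_trajectory",
    "export_results",
]

_ROLE_TO_SPECIES = {int(BeadRole.STICKER_A): "A", int(BeadRole.STICKER_B): "B",
                    int(BeadRole.SPACER): "S"}
_SPECIES_TO_ROLE = {v: k for k, v in _ROLE_TO_SPECIES.items()}


class ConfigError(ValueError):
    pass


_SCHEMA = {
    "model": {"patterning", "n_beads", "sticker_positions_A", "sticker_positions_B",
              "eps_D", "eps_S", "coupled", "potential", "bonds"},
    "model.potential": {"form", "cutoff", "shift_at_cutoff", "wf_nu", "wf_mu"},
    "model.bonds": {"k_bond", "r0"},
    "engine": {"dt", "friction_gamma", "temperature_kT", "neighbor_skin", "seed",
               "mass", "force_cap"},
    "geometry": {"geometry_tag", "n_chains", "box", "droplet_sizes"},
    "protocol": None,  # free-form driver arguments, validated by the driver
    "output": {"outdir", "formats", "stride"},
}

_DEFAULTS = {
    "model": {"patterning": "uniform", "n_beads": 39, "coupled": True,
              "potential": {"form": "lennard_jones", "cutoff": 3.0,
                            "shift_at_cutoff": True, "wf_nu": 1, "wf_mu": 1},
              "bonds": {"k_bond": 1000.0, "r0": 1.0}},
    "engine": {"dt": 0.005, "friction_gamma": 0.1, "temperature_kT": 1.0,
               "neighbor_skin": 0.4, "seed": 0, "mass": 1.0, "force_cap": 0.0},
    "geometry": {"geometry_tag": "dilute_gas", "n_chains": 60},
    "protocol": {},
    "output": {"outdir": "out", "formats": ["extxyz"], "stride": 1},
}


@dataclass(frozen=True)
class RunConfig:
    """Fully validated configuration with defaults resolved."""

    model: dict
    engine: dict
    geometry: dict
    protocol: dict
    output: dict
    provenance_hash: str = ""

    def sequence(self) -> ProteinSequence:
        m = self.model
        return make_sequence(m["patterning"], m["n_beads"],
                             m.get("sticker_positions_A"),
                             m.get("sticker_positions_B"))

    def interaction_table(self) -> InteractionTable:
        m = self.model
        if m["coupled"]:
            if "eps_S" in m and "eps_D" in m:
                if abs(m["eps_S"] - 10.0 * m["eps_D"]) > 1e-9:
                    raise ConfigError(
                        "model.eps_S and model.eps_D violate the coupling rule "
                        "eps_S = 10 eps_D; set coupled = false to decouple them"
                    )
            eps_S = m.get("eps_S", 10.0 * m.get("eps_D", 0.5))
            return InteractionTable.from_eps_S(eps_S)
        return InteractionTable(m["eps_D"], m["eps_S"])

    def cg_model(self) -> CGModel:
        p = self.model["potential"]
        b = self.model["bonds"]
        return CGModel(self.interaction_table(),
                       PotentialSpec(p["form"], p["cutoff"], p["shift_at_cutoff"],
                                     p["wf_nu"], p["wf_mu"]),
                       BondSpec(b["k_bond"], b["r0"]))

    def to_dict(self) -> dict:
        return {"model": self.model, "engine": self.engine,
                "geometry": self.geometry, "protocol": self.protocol,
                "output": self.output}


def _merge(defaults: dict, user: dict, path: str) -> dict:
    allowed = _SCHEMA.get(path)
    if allowed is not None:
        unknown = set(user) - allowed
        if unknown:
            raise ConfigError(f"unknown key(s) {sorted(unknown)} in [{path}]")
    out = {}
    for k, v in defaults.items():
        if isinstance(v, dict):
            out[k] = _merge(v, user.get(k, {}), f"{path}.{k}")
        else:
            out[k] = user.get(k, v)
    for k, v in user.items():
        if k not in out:
            out[k] = v
    return out


def config_hash(data: dict) -> str:
    return hashlib.sha256(
        json.dumps(data, sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a TOML or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".toml", ".tml"):
        raw = tomllib.loads(text)
    elif path.suffix in (".yaml", ".yml"):
        raw = yaml.safe_load(text) or {}
    else:
        raise ConfigError(f"unsupported config format {path.suffix!r}")
    unknown = {k for k in raw if k not in _DEFAULTS}
    if unknown:
        raise ConfigError(f"unknown top-level section(s) {sorted(unknown)}")
    sections = {}
    for sec, dflt in _DEFAULTS.items():
        sections[sec] = _merge(dflt, raw.get(sec, {}), sec)
    cfg = RunConfig(**sections, provenance_hash=config_hash(sections))
    cfg.sequence()
    cfg.interaction_table()
    cfg.cg_model()
    return cfg


# ---------------------------------------------------------------------------
# trajectory formats


def write_trajectory(traj: Trajectory, path, fmt: str = "extxyz",
                     precision: int = 8) -> None:
    path = Path(path)
    box = traj.box
    species = [_ROLE_TO_SPECIES[int(r)] for r in traj.roles]
    p = precision
    with open(path, "w") as fh:
        for fidx in range(traj.n_frames):
            upos = traj.positions[fidx]
            img = np.floor(upos / box[None, :]).astype(int)
            wpos = upos - img * box[None, :]
            if fmt == "extxyz":
                fh.write(f"{traj.n_beads}\n")
                fh.write(
                    f'Lattice="{box[0]:.{p}g} 0 0 0 {box[1]:.{p}g} 0 0 0 '
                    f'{box[2]:.{p}g}" Properties=species:S:1:pos:R:3:image:I:3 '
                    f"Time={traj.times[fidx]:.{p}g} ChainLen={traj.chain_len}\n"
                )
                for i in range(traj.n_beads):
                    x, y, z = wpos[i]
                    ix, iy, iz = img[i]
                    fh.write(f"{species[i]} {x:.{p}f} {y:.{p}f} {z:.{p}f} "
                             f"{ix} {iy} {iz}\n")
            elif fmt == "lammpsdump":
                # plain LAMMPS layout (no TIME block: standard readers are
                # strict about the section order); physical time is
                # timestep * time_per_step on read
                fh.write("ITEM: TIMESTEP\n")
                fh.write(f"{fidx}\n")
                fh.write("ITEM: NUMBER OF ATOMS\n")
                fh.write(f"{traj.n_beads}\n")
                fh.write("ITEM: BOX BOUNDS pp pp pp\n")
                for d in range(3):
                    fh.write(f"0.0 {box[d]:.{p}g}\n")
                fh.write("ITEM: ATOMS id type x y z ix iy iz\n")
                for i in range(traj.n_beads):
                    x, y, z = wpos[i]
                    ix, iy, iz = img[i]
                    fh.write(f"{i + 1} {int(traj.roles[i]) + 1} "
                             f"{x:.{p}f} {y:.{p}f} {z:.{p}f} {ix} {iy} {iz}\n")
            else:
                raise ValueError(f"unknown trajectory format {fmt!r}")


class TrajectoryFormatError(ValueError):
    pass


def read_trajectory(path, fmt: str | None = None, chain_len: int | None = None,
                    time_per_step: float = 1.0) -> Trajectory:
    """Read extended XYZ or LAMMPS dump text into a Trajectory.

    The format is inferred from the first line unless given.  ``chain_len``
    is required for LAMMPS dumps (the format has no slot for it) and
    defaults to the value recorded in the extended-XYZ comment line.
    LAMMPS dumps carry integer timesteps only; their physical time is
    ``timestep * time_per_step`` (an ITEM: TIME section, when present,
    takes precedence).
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        return Trajectory(np.empty(0), np.empty((0, 0, 3)), np.ones(3),
                          np.empty(0, dtype=np.int8), chain_len or 1)
    if fmt is None:
        fmt = "lammpsdump" if lines[0].startswith("ITEM:") else "extxyz"
    if fmt == "extxyz":
        return _read_extxyz(lines, chain_len)
    if fmt == "lammpsdump":
        if chain_len is None:
            chain_len = 1
        return _read_lammpsdump(lines, chain_len, time_per_step)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def _read_extxyz(lines, chain_len):
    times, frames = [], []
    roles = None
    box = None
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            nat = int(lines[ln].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(f"line {ln + 1}: expected atom count") from exc
        comment = lines[ln + 1]
        fields = dict(_parse_extxyz_comment(comment))
        lat = [float(v) for v in fields["Lattice"].split()]
        box = np.array([lat[0], lat[4], lat[8]])
        times.append(float(fields.get("Time", len(times))))
        if chain_len is None and "ChainLen" in fields:
            chain_len = int(fields["ChainLen"])
        pos = np.empty((nat, 3))
        img = np.zeros((nat, 3), dtype=int)
        rls = np.empty(nat, dtype=np.int8)
        for i in range(nat):
            parts = lines[ln + 2 + i].split()
            if len(parts) < 4:
                raise TrajectoryFormatError(f"line {ln + 3 + i}: truncated atom record")
            rls[i] = _SPECIES_TO_ROLE.get(parts[0], int(BeadRole.SPACER))
            pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            if len(parts) >= 7:
                img[i] = [int(parts[4]), int(parts[5]), int(parts[6])]
        frames.append(pos + img * box[None, :])
        roles = rls
        ln += 2 + nat
    return Trajectory(np.array(times), np.array(frames), box, roles,
                      chain_len or 1)


def _parse_extxyz_comment(comment):
    out = []
    i = 0
    while i < len(comment):
        eq = comment.find("=", i)
        if eq < 0:
            break
        key = comment[i:eq].strip().split()[-1]
        if eq + 1 < len(comment) and comment[eq + 1] == '"':
            end = comment.find('"', eq + 2)
            val = comment[eq + 2:end]
            i = end + 1
        else:
            end = comment.find(" ", eq + 1)
            if end < 0:
                end = len(comment)
            val = comment[eq + 1:end]
            i = end + 1
        out.append((key, val))
    return out


def _read_lammpsdump(lines, chain_len, time_per_step=1.0):
    times, frames = [], []
    roles = None
    box = None
    ln = 0
    t_step = None
    t_real = None
    while ln < len(lines):
        line = lines[ln]
        if line.startswith("ITEM: TIMESTEP"):
            t_step = float(lines[ln + 1])
            ln += 2
        elif line.startswith("ITEM: TIME"):
            t_real = float(lines[ln + 1])
            ln += 2
        elif line.startswith("ITEM: NUMBER OF ATOMS"):
            nat = int(lines[ln + 1])
            ln += 2
        elif line.startswith("ITEM: BOX BOUNDS"):
            b = []
            for d in range(3):
                lo, hi = (float(v) for v in lines[ln + 1 + d].split()[:2])
                b.append(hi - lo)
            box = np.array(b)
            ln += 4
        elif line.startswith("ITEM: ATOMS"):
            cols = line.split()[2:]
            try:
                c_id = cols.index("id")
                c_x, c_y, c_z = cols.index("x"), cols.index("y"), cols.index("z")
            except ValueError as exc:
                raise TrajectoryFormatError(
                    f"line {ln + 1}: dump must provide id and x y z columns") from exc
            c_type = cols.index("type") if "type" in cols else None
            c_ix = cols.index("ix") if "ix" in cols else None
            c_iy = cols.index("iy") if "iy" in cols else None
            c_iz = cols.index("iz") if "iz" in cols else None
            pos = np.empty((nat, 3))
            img = np.zeros((nat, 3), dtype=int)
            rls = np.full(nat, int(BeadRole.SPACER), dtype=np.int8)
            for k in range(nat):
                parts = lines[ln + 1 + k].split()
                i = int(parts[c_id]) - 1
                pos[i] = [float(parts[c_x]), float(parts[c_y]), float(parts[c_z])]
                if c_type is not None:
                    rls[i] = int(parts[c_type]) - 1
                if c_ix is not None and c_iy is not None and c_iz is not None:
                    img[i] = [int(parts[c_ix]), int(parts[c_iy]),
                              int(parts[c_iz])]
            frames.append(pos + img * box[None, :])
            if t_real is not None:
                times.append(t_real)
            elif t_step is not None:
                times.append(t_step * time_per_step)
            else:
                times.append(float(len(times)))
            t_real = t_step = None
            roles = rls
            ln += 1 + nat
        else:
            ln += 1
    if not frames:
        return Trajectory(np.empty(0), np.empty((0, 0, 3)), np.ones(3),
                          np.empty(0, dtype=np.int8), chain_len)
    return Trajectory(np.array(times), np.array(frames), box, roles, chain_len)


# ---------------------------------------------------------------------------
# results export


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def export_results(records, outdir) -> dict:
    """Write one JSON per record plus merged tidy CSVs and a manifest.

    Returns the manifest dict.  Writes are atomic (write + rename) so a
    crash never leaves truncated files behind.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"records": [], "hash": None}
    diff_rows, coal_rows, leg_rows = [], [], []
    for k, rec in enumerate(records):
        d = rec.to_dict()
        name = f"{rec.protocol}_{k:03d}"
        _atomic_write(outdir / f"{name}.json", json.dumps(d, indent=1))
        manifest["records"].append({"name": name, "protocol": rec.protocol,
                                    "seed": rec.seed,
                                    "config_hash": config_hash(d["config"])})
        ser = rec.series
        if "diffusion" in ser:
            s = ser["diffusion"]
            for c, D, sp in zip(s.window_centers, s.D_values, s.window_spans):
                diff_rows.append({"record": name, "window_center": c, "D": D,
                                  "window_span": sp,
                                  "eps_S": rec.config.get("eps_S"),
                                  "eps_D": rec.config.get("eps_D")})
        if "coalescence" in ser:
            r = ser["coalescence"]
            coal_rows.append({"record": name, "size": rec.config.get("size"),
                              "eps_S": rec.config.get("eps_S"),
                              "tau_c": r.tau_c, "censored": r.censored,
                              "censor_time": r.censor_time, "status": r.status})
        if "legs" in ser:
            for li, leg in enumerate(ser["legs"]):
                leg_rows.append({"record": name, "leg": li, **leg})
    if diff_rows:
        _atomic_write(outdir / "diffusion_windows.csv",
                      pd.DataFrame(diff_rows).to_csv(index=False))
    if coal_rows:
        _atomic_write(outdir / "coalescence.csv",
                      pd.DataFrame(coal_rows).to_csv(index=False))
    if leg_rows:
        _atomic_write(outdir / "hysteresis_legs.csv",
                      pd.DataFrame(leg_rows).to_csv(index=False))
    manifest["hash"] = config_hash({"records": manifest["records"]})
    _atomic_write(outdir / "manifest.json", json.dumps(manifest, indent=1))
    return manifest
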