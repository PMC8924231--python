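"""Coarse-grained sticker-spacer protein model.

A protein is a fully flexible bead-spring heteropolymer.  Each bead stands
for a short stretch (~6-8 residues) of an intrinsically disordered region
and carries one of three roles:

* ``STICKER_A`` / ``STICKER_B`` -- complementary "sticker" regions that bind
  each other strongly (well depth ``eps_S``),
* ``SPACER`` -- everything else; spacer-spacer, spacer-sticker and homotypic
  sticker-sticker pairs all bind weakly (well depth ``eps_D``).

The model couples the two scales through ``eps_S = 10 * eps_D`` by default,
so a single knob controls both the background cohesion that drives
liquid-liquid phase separation and the strong heterotypic contacts that
drive condensate ageing.

All quantities are in reduced units: lengths in the bead diameter sigma,
energies in kBT at the reference temperature, masses in the bead mass, and
times in ``tau* = sigma * sqrt(m / eps_ref)``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BeadRole",
    "ReducedUnits",
    "ProteinSequence",
    "InteractionTable",
    "PotentialSpec",
    "BondSpec",
    "CGModel",
    "make_sequence",
    "build_interaction_table",
    "pair_energy",
    "pair_force",
    "bond_energy",
    "bond_force",
    "DEFAULT_N_BEADS",
    "DEFAULT_A_POSITIONS",
    "DEFAULT_B_POSITIONS",
    "HALF_CHAIN_A_POSITIONS",
    "HALF_CHAIN_B_POSITIONS",
]


class BeadRole(enum.IntEnum):
    """Role of one bead; the integer values index interaction matrices."""

    STICKER_A = 0
    STICKER_B = 1
    SPACER = 2


class ModelValidationError(ValueError):
    """Raised when a model component violates its invariants."""


@dataclass(frozen=True)
class ReducedUnits:
    """Reduced unit system: sigma, eps_ref and bead mass all equal one.

    ``tau_star`` is derived, never set independently, so the unit system is
    internally consistent by construction.
    """

    sigma: float = 1.0
    epsilon_ref: float = 1.0
    mass: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.epsilon_ref <= 0 or self.mass <= 0:
            raise ModelValidationError("reduced units must all be positive")

    @property
    def tau_star(self) -> float:
        return self.sigma * math.sqrt(self.mass / self.epsilon_ref)

    def reduced_temperature(self, kT: float, eps: float) -> float:
        """T* = kBT / eps for a given interaction scale."""
        return kT / eps


DEFAULT_N_BEADS = 39
# 3 A stickers + 2 B stickers spread over the full chain (0-based indices).
DEFAULT_A_POSITIONS = (4, 18, 32)
DEFAULT_B_POSITIONS = (11, 25)
# Variant with all five stickers packed into the first half of the chain.
HALF_CHAIN_A_POSITIONS = (2, 10, 18)
HALF_CHAIN_B_POSITIONS = (6, 14)


@dataclass(frozen=True)
class ProteinSequence:
    """Ordered bead roles for one chain."""

    roles: tuple
    patterning_tag: str = "uniform"

    def __post_init__(self) -> None:
        if not self.roles:
            raise ModelValidationError("sequence must contain at least one bead")
        counts = self.role_counts()
        if self.patterning_tag == "homopolymer":
            if counts[BeadRole.STICKER_A] or counts[BeadRole.STICKER_B]:
                raise ModelValidationError("homopolymer sequences contain only spacers")
        elif self.patterning_tag in ("uniform", "half_chain"):
            if counts[BeadRole.STICKER_A] != 3 or counts[BeadRole.STICKER_B] != 2:
                raise ModelValidationError(
                    "sticker-spacer patterning requires exactly 3 A and 2 B stickers, "
                    f"got {counts[BeadRole.STICKER_A]} A / {counts[BeadRole.STICKER_B]} B"
                )
        else:
            raise ModelValidationError(f"unknown patterning tag {self.patterning_tag!r}")

    @property
    def n_beads(self) -> int:
        return len(self.roles)

    def role_counts(self) -> dict:
        return {r: sum(1 for x in self.roles if x == r) for r in BeadRole}

    def roles_array(self) -> np.ndarray:
        return np.array([int(r) for r in self.roles], dtype=np.int8)


def make_sequence(
    patterning_tag: str = "uniform",
    n_beads: int = DEFAULT_N_BEADS,
    sticker_positions_A=None,
    sticker_positions_B=None,
) -> ProteinSequence:
    """Build a chain sequence for one of the three patterning variants.

    ``uniform`` spreads the five stickers along the full chain, ``half_chain``
    packs them all into indices below ``n_beads // 2``, and ``homopolymer``
    has no stickers at all (the uniformly weak control).
    """
    if n_beads < 1:
        raise ModelValidationError("n_beads must be >= 1")
    if patterning_tag == "homopolymer":
        if sticker_positions_A or sticker_positions_B:
            raise ModelValidationError("homopolymer chains take no sticker positions")
        return ProteinSequence(tuple([BeadRole.SPACER] * n_beads), "homopolymer")

    if patterning_tag == "uniform":
        pos_a = tuple(sticker_positions_A) if sticker_positions_A is not None else DEFAULT_A_POSITIONS
        pos_b = tuple(sticker_positions_B) if sticker_positions_B is not None else DEFAULT_B_POSITIONS
    elif patterning_tag == "half_chain":
        pos_a = tuple(sticker_positions_A) if sticker_positions_A is not None else HALF_CHAIN_A_POSITIONS
        pos_b = tuple(sticker_positions_B) if sticker_positions_B is not None else HALF_CHAIN_B_POSITIONS
    else:
        raise ModelValidationError(f"unknown patterning tag {patterning_tag!r}")

    all_pos = pos_a + pos_b
    if len(set(all_pos)) != len(all_pos):
        raise ModelValidationError("sticker positions overlap")
    if any(p < 0 or p >= n_beads for p in all_pos):
        raise ModelValidationError("sticker position out of range")
    if patterning_tag == "half_chain" and any(p >= n_beads // 2 for p in all_pos):
        raise ModelValidationError("half_chain stickers must sit in the first half")

    roles = [BeadRole.SPACER] * n_beads
    for p in pos_a:
        roles[p] = BeadRole.STICKER_A
    for p in pos_b:
        roles[p] = BeadRole.STICKER_B
    return ProteinSequence(tuple(roles), patterning_tag)


@dataclass(frozen=True)
class InteractionTable:
    """Symmetric well-depth lookup over role pairs.

    Every pair binds with the weak depth ``eps_D`` except the complementary
    heterotypic sticker pair A-B, which binds with ``eps_S``.  With the
    coupling rule enabled the two depths are locked to ``eps_S = 10 eps_D``.
    """

    eps_D: float
    eps_S: float
    coupled: bool = False

    def __post_init__(self) -> None:
        if self.eps_D <= 0 or self.eps_S <= 0:
            raise ModelValidationError("interaction strengths must be positive")
        if self.eps_S < self.eps_D:
            raise ModelValidationError("eps_S must be >= eps_D")
        if self.coupled and not math.isclose(self.eps_S, 10.0 * self.eps_D, rel_tol=1e-12):
            raise ModelValidationError(
                f"coupling rule violated: eps_S={self.eps_S} != 10*eps_D={10 * self.eps_D}"
            )

    def well_depth(self, role_i: BeadRole, role_j: BeadRole) -> float:
        if {BeadRole(role_i), BeadRole(role_j)} == {BeadRole.STICKER_A, BeadRole.STICKER_B}:
            return self.eps_S
        return self.eps_D

    def as_matrix(self) -> np.ndarray:
        """3x3 well-depth matrix indexed by BeadRole integer values."""
        m = np.full((3, 3), self.eps_D, dtype=np.float64)
        a, b = int(BeadRole.STICKER_A), int(BeadRole.STICKER_B)
        m[a, b] = m[b, a] = self.eps_S
        return m

    @classmethod
    def from_eps_S(cls, eps_S: float) -> "InteractionTable":
        """Coupled table with eps_D = eps_S / 10."""
        return cls(eps_D=eps_S / 10.0, eps_S=eps_S, coupled=True)


def build_interaction_table(eps_D: float, eps_S: float, coupled: bool = False) -> InteractionTable:
    return InteractionTable(eps_D=eps_D, eps_S=eps_S, coupled=coupled)


@dataclass(frozen=True)
class PotentialSpec:
    """Nonbonded pair potential: 12-6 Lennard-Jones or Wang-Frenkel.

    The Wang-Frenkel form goes to zero with zero slope at its cutoff and,
    with the default cutoff of 1.5 sigma, is markedly shorter ranged than
    the shifted LJ default (cutoff 3 sigma) -- the property used to probe
    how interaction range shifts the ageing threshold.
    """

    form: str = "lennard_jones"
    cutoff: float = 3.0
    shift_at_cutoff: bool = True
    wf_nu: int = 1
    wf_mu: int = 1

    def __post_init__(self) -> None:
        if self.form not in ("lennard_jones", "wang_frenkel"):
            raise ModelValidationError(f"unknown potential form {self.form!r}")
        if self.cutoff <= 2.0 ** (1.0 / 6.0):
            raise ModelValidationError("cutoff must exceed the LJ minimum 2^(1/6) sigma")
        if self.wf_nu < 1 or self.wf_mu < 1:
            raise ModelValidationError("Wang-Frenkel exponents must be >= 1")

    @classmethod
    def wang_frenkel(cls, cutoff: float = 1.5, nu: int = 1, mu: int = 1) -> "PotentialSpec":
        # WF is already zero-valued and zero-sloped at its cutoff; no shift needed.
        return cls(form="wang_frenkel", cutoff=cutoff, shift_at_cutoff=False, wf_nu=nu, wf_mu=mu)


def _wf_alpha(cutoff: float, sigma: float, nu: int, mu: int) -> float:
    rcs = (cutoff / sigma) ** (2 * mu)
    return 2.0 * nu * rcs * ((1.0 + 2.0 * nu) / (2.0 * nu * (rcs - 1.0))) ** (2 * nu + 1)


def wf_r_min(cutoff: float, sigma: float, nu: int, mu: int) -> float:
    """Location of the Wang-Frenkel minimum (depth is exactly -eps there)."""
    rcs = (cutoff / sigma) ** (2 * mu)
    return cutoff * ((1.0 + 2.0 * nu) / (1.0 + 2.0 * nu * rcs)) ** (1.0 / (2.0 * mu))


def _lj_unshifted(r, eps, sigma):
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def _wf_unshifted(r, eps, sigma, cutoff, nu, mu):
    alpha = _wf_alpha(cutoff, sigma, nu, mu)
    sr = (sigma / r) ** (2 * mu)
    cr = (cutoff / r) ** (2 * mu)
    return eps * alpha * (sr - 1.0) * (cr - 1.0) ** (2 * nu)


def pair_energy(spec: PotentialSpec, r: float, eps: float, sigma: float = 1.0) -> float:
    """Nonbonded pair energy at separation ``r``; zero beyond the cutoff."""
    if r <= 0:
        raise ModelValidationError("pair separation must be positive")
    if r >= spec.cutoff * sigma:
        return 0.0
    if spec.form == "lennard_jones":
        u = _lj_unshifted(r, eps, sigma)
        if spec.shift_at_cutoff:
            u -= _lj_unshifted(spec.cutoff * sigma, eps, sigma)
        return u
    return _wf_unshifted(r, eps, sigma, spec.cutoff * sigma, spec.wf_nu, spec.wf_mu)


def pair_force(spec: PotentialSpec, r_vector, eps: float, sigma: float = 1.0) -> np.ndarray:
    """Force on particle i at ``r_vector = x_i - x_j``; equals -grad pair_energy."""
    r_vector = np.asarray(r_vector, dtype=np.float64)
    r = float(np.linalg.norm(r_vector))
    if r <= 0:
        raise ModelValidationError("zero separation in pair_force")
    if r >= spec.cutoff * sigma:
        return np.zeros_like(r_vector)
    if spec.form == "lennard_jones":
        sr6 = (sigma / r) ** 6
        # dU/dr; the cutoff shift is a constant and does not alter the force
        dudr = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
    else:
        cutoff = spec.cutoff * sigma
        nu, mu = spec.wf_nu, spec.wf_mu
        alpha = _wf_alpha(cutoff, sigma, nu, mu)
        sr = (sigma / r) ** (2 * mu)
        cr = (cutoff / r) ** (2 * mu)
        dsr = -2.0 * mu * sr / r
        dcr = -2.0 * mu * cr / r
        dudr = eps * alpha * (
            dsr * (cr - 1.0) ** (2 * nu)
            + (sr - 1.0) * 2 * nu * (cr - 1.0) ** (2 * nu - 1) * dcr
        )
    return (-dudr / r) * r_vector


@dataclass(frozen=True)
class BondSpec:
    """Harmonic bond U(r) = 0.5 k (r - r0)^2 between consecutive beads."""

    k_bond: float = 1000.0
    r0: float = 1.0

    def __post_init__(self) -> None:
        if self.k_bond <= 0 or self.r0 <= 0:
            raise ModelValidationError("bond parameters must be positive")


def bond_energy(spec: BondSpec, r: float) -> float:
    if r < 0:
        raise ModelValidationError("bond length must be non-negative")
    return 0.5 * spec.k_bond * (r - spec.r0) ** 2


def bond_force(spec: BondSpec, r_vector) -> np.ndarray:
    """Force on particle i at ``r_vector = x_i - x_j`` for a bonded pair."""
    r_vector = np.asarray(r_vector, dtype=np.float64)
    r = float(np.linalg.norm(r_vector))
    if r <= 0:
        raise ModelValidationError("zero separation in bond_force")
    return (-spec.k_bond * (r - spec.r0) / r) * r_vector


@dataclass(frozen=True)
class CGModel:
    """Bundle of everything the force loop needs: table + potential + bonds."""

    interactions: InteractionTable
    potential: PotentialSpec = field(default_factory=PotentialSpec)
    bonds: BondSpec = field(default_factory=BondSpec)
    units: ReducedUnits = field(default_factory=ReducedUnits)

    def with_interactions(self, table: InteractionTable) -> "CGModel":
        return replace(self, interactions=table)
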