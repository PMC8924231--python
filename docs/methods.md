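# Methods

## The model

Proteins are fully flexible bead–spring heteropolymers of 39 beads. Each
bead stands for a short stretch (~6–8 residues) of an intrinsically
disordered region and carries one of three roles: sticker A (3 per chain),
sticker B (2 per chain), or spacer (34 per chain). All pairs interact
through a Lennard-Jones potential; the well depth is `eps_D` for every
pair except complementary inter-chain sticker A–sticker B pairs, which
bind with `eps_S`. The coupling rule `eps_S = 10 eps_D` ties the two
scales together so a single parameter moves the system along the
weak-to-strong binding axis. A homopolymer variant (all spacers, uniform
`eps_D`) serves as the control without strong heterotypic contacts, and a
`half_chain` patterning (all five stickers in the first half of the
sequence) probes patterning effects. The default sticker placement spreads
the five stickers along the chain (A at 0-based indices 4, 18, 32; B at
11, 25); positions are configurable because only the counts and the
qualitative placement are fixed by the model definition.

Everything is expressed in reduced units: lengths in the bead diameter
sigma, energies in kBT (the simulation temperature is fixed at kT = 1, so
"changing temperature" is implemented by rescaling the well depths — the
reduced temperature is T* = kBT/eps), masses in the bead mass, and times
in tau* = sigma sqrt(m/kBT).

Default potential parameters:

| parameter | default | notes |
|---|---|---|
| LJ cutoff | 3.0 sigma, energy-shifted | continuous energy at the cutoff |
| Wang–Frenkel variant | cutoff 1.5 sigma, nu = mu = 1 | markedly shorter-ranged; zero value *and* slope at the cutoff by construction |
| bond | harmonic, k = 1000 kBT/sigma^2, r0 = 1.0 sigma | near-rigid at dt = 0.005 without constraint algorithms |
| exclusions | bonded 1–2 pairs | standard bead–spring convention |

No electrostatics, solvent, angles or dihedrals: the model isolates the
competition between transient weak contacts and long-lived strong
contacts, which is the mechanism under study.

With these defaults the homopolymer phase-separates for eps_D above
~0.35 kBT (measured by the package's own threshold scan) and a
direct-coexistence slab at eps_D = 0.66 holds a dense liquid of
~0.7 beads/sigma^3 against an essentially empty vapor — the liquid-like
control regime.

## Engine

Langevin dynamics with the symmetric BAOAB splitting (half-kick,
half-drift, Ornstein–Uhlenbeck velocity refresh, half-drift, half-kick).
With friction gamma = 0 the scheme reduces to velocity Verlet and
conserves energy, which is the engine's validation mode. Defaults:
dt = 0.005 tau*, gamma = 0.1 /tau* (underdamped — accelerates diffusive
exploration; in the condensed phase inter-bead collisions dominate the
effective friction anyway, so condensed-phase D is insensitive to the
thermostat constant), kT = 1.

Integration runs on unwrapped coordinates. The Verlet neighbor list
(cutoff + 0.4 sigma skin, rebuilt when any bead has moved half the skin)
stores, for each pair, the periodic offset of the minimum image frozen at
build time; because unwrapped coordinates are continuous and the skin
criterion bounds the motion between rebuilds, a frozen offset can only go
stale for pairs already outside the interaction range. This matters: an
earlier formulation against wrapped coordinates lost pairs whenever a bead
crossed the boundary between rebuilds, which injects energy. The engine is
cross-validated against an all-pairs reference on static configurations
(to 1e-10) and against free-particle and NVE closed forms on dynamics.

Thermostat noise comes from a counter-based RNG (splitmix64 finalizer over
(seed, step index, bead index, stream)), so a run is bit-reproducible from
its seed and call sequence, and checkpoint/restore continues identically.
Forces may be capped (norm clamp, plus deep overlaps evaluated at
r = 0.3 sigma) during initial relaxation only; production runs never cap.

## Builders

Dilute gases place chains as self-avoiding random walks (minimum inter-bead
distance 0.9 sigma) at a global bead packing fraction of 0.02 by default.
Dense bulk boxes start from a dilute walk placement and are compressed ~5 %
per stage under strongly damped, force-capped dynamics until the target
density is reached — random insertion cannot reach condensed densities.
Droplets pack chains into a sphere at 0.35 beads/sigma^3 and equilibrate
under weak liquid-regime interactions until the cluster is near-spherical
and the energy plateaus; the sphericity tolerance is size-aware
(kappa^2 < max(0.05, 1.5/n_chains)) because small droplets have large
surface shape fluctuations. Tangent pairs are two independently built
droplets, randomly rotated, placed with a ~1 sigma surface gap along x in
a box of about three merged-droplet diameters per axis (large enough to
stay below the slab/cylinder crossover of periodic geometries).

Changing a periodic box invalidates minimum images of chains that straddle
a boundary, so every box change goes through `make_chains_whole` /
`resize_box`.

The condensed-phase density is estimated from the radial-profile plateau of
a droplet run (volume-weighted core density, equimolar-style dividing
radius). Small droplets bias this estimate low by a few percent relative
to a flat-interface slab (interface smearing); the bias is accepted and
noted where it matters.

## Analysis

**Windowed diffusion.** D(t) of the chains' central beads is estimated on
consecutive windows grown until the rms central-bead displacement reaches
3–5 bead diameters (default factor 3 in the drivers, 4 in the API), so
slower dynamics automatically demand longer windows. Within a window the
MSD is time-origin averaged and D is the slope of a weighted linear fit
over the final two thirds of the window (weights follow the per-lag origin
counts); the first third is discarded as sub-diffusive, and a
non-positive tail slope (a caged system whose MSD has plateaued) falls
back to the endpoint upper bound. Two corrections matter only at desk
scale and are negligible at hundreds of chains: displacements are taken
relative to the system center of mass (a Langevin thermostat does not
conserve momentum, so a small system's free COM diffusion kT/(m gamma N)
otherwise contaminates the signal), and, for free-standing droplets, an
optional Kabsch alignment removes the rigid-body tumbling that would
otherwise read as internal mobility. On Brownian-walker fixtures the
pooled estimate recovers the ground truth to within ~2 % (bias), with
per-window scatter set by walker count. Arrested systems where no window
can close are reported through a flagged partial window whose D is an
upper bound that tightens with observation time.

**Regime classification.** A series is liquid when its terminal D sits
above the kinetic threshold and has plateaued (relative change < 15 % over
the last 3 windows); it is ageing when it has crossed below the threshold
(onset = log-interpolated crossing) or is still decaying steeply (overall
decay > 3x) without a plateau, in which case the onset is extrapolated in
log D–log t and flagged. The kinetic threshold is defined scale-free as
one tenth of the weak-binding liquid plateau measured in the same
campaign; this package's measured eps_D = 0.66 condensed-phase plateau is
~1e-2 sigma^2/tau*, so the default threshold is 1e-3 sigma^2/tau*.

**Contacts and clusters.** Strong contacts are inter-chain A–B pairs
within 1.5 sigma (the LJ well region; configurable). Chain clusters are
connected components of the bead proximity graph at the same cutoff.
Cluster geometry (gyration tensor, kappa^2, radial profiles) is computed
after a minimum-image BFS unwrap, so condensates straddling the periodic
boundary are handled exactly.

**Coalescence.** Tangent droplets in contact percolate into a single
graph cluster immediately, so fusion is carried by the shape signal:
tau_c is the first time a single cluster holds >= 95 % of the chains while
the largest cluster's kappa^2 stays below the sphericity tolerance for a
dwell period (10 % of the censor horizon; within the dwell the mean must
stay below tolerance and every frame below twice it, so single
fluctuation spikes do not reset the clock).  The tolerance is 0.02 at
full scale but max(0.02, 2.5/N_chains) for small merged droplets, which
matches their measured equilibrium shape fluctuations — a merged
24-chain droplet never reaches kappa^2 < 0.02 at equilibrium.  Runs that
never meet the criterion are censored at the (stated) maximum simulated
time, and runs whose largest cluster decays below half the chains are
labelled evaporated.

**Real units.** The diffusion-time helper maps D (um^2/s) and a distance
L (um) to the 3-D first-passage estimate L^2/(6D): for D = 1 um^2/s and
L = 5 um this gives 25/6 ~ 4.2 s, and a 2–3 order-of-magnitude slow-down
maps it to ~7 minutes–1.2 hours.

## Protocols and problem sizes

The drivers default to desk-scale systems (tens of chains, hundreds of
tau*) rather than the hundreds of chains and much longer horizons a
full-scale campaign would use. The phenomenology being tested is ordinal —
regime labels ordered in eps_S, coalescence times ordered in droplet size,
arrest retained or not along a thermodynamic path — and survives this
scale-down; absolute time axes do not, and are not claimed. The LLPS scan
runs each state point in adaptive blocks of 100 tau* until the
largest-cluster fraction stops drifting (capped at the configured
duration), because near-threshold coarsening is slow and fixed short runs
misclassify marginal state points. The in-droplet maturation driver
normalises strong-contact counts by condensate volume and by a
configurable arrest-threshold contact density (default 0.01 /sigma^3; the
qualitative statements — crossing the threshold while the shape stays
spherical — do not depend on the constant).

The acceptance script (`scripts/acceptance.py`) uses 24-chain scans, a
30-chain droplet for the density estimate and a 24-chain bulk box run up
to 1600 tau*; these sizes keep the full campaign at desk scale while
staying inside the regimes listed above.  Immediate-arrest classification
prepares a dense liquid droplet under the weak control interactions and
switches the uniform well depth in place (interaction strengthening
inside an already-formed condensate): a condensate assembled loosely at a
strong well depth never densifies and its floppy network modes would be
mistaken for mobility.

## Known limitations

* Absolute dynamical scales are parameter-bound. The condensed-phase
  diffusion coefficient of the eps_D = 0.66 homopolymer control comes out
  at ~2e-2 sigma^2/tau* at the self-measured coexistence density — an
  order of magnitude above the ~2e-3 reported for the reference
  parameterisation of this model family. The value is robust here against
  the thermostat constant (collisional friction dominates) and against the
  droplet-vs-slab density estimate (0.67 vs 0.75 beads/sigma^3); it is
  therefore attributed to integration/friction/bond constants of the
  original parameterisation that are not recoverable from the main text.
  Relative statements (deceleration with eps_S, liquid/ageing ordering)
  are unaffected.
* The dynamical eps-thresholds shift with the dynamics: in this
  parameterisation the bulk liquid/ageing boundary sits above
  eps_S = 5.25, immediate homopolymer arrest sets in near eps_D ~ 2
  rather than just above 1, the sticker–spacer system still phase
  separates at eps_S = 3.5 (its non-LLPS bound is ~2.5–3.0), and small
  tangent pairs still fuse at eps_S = 5.75.  The orderings (stronger
  binding -> slower, earlier arrest, later fusion; larger droplets ->
  slower fusion; path dependence of the matured state) are reproduced.
* Small systems fluctuate: regime labels near the liquid/ageing boundary
  carry seed-to-seed variability at 16–60 chains, and terminal cluster
  shapes of ~10-chain aggregates are noisy.
* The synthetic fixtures (Brownian walkers, rigid shapes, scheduled
  mergers) emulate the *observables'* ground truth, not condensate
  microphysics; passing fixture tests validates the estimators, not the
  model.
* No viscosity, FRAP emulation, or interfacial tension; no slab-based
  phase-diagram study beyond the core-density estimate; no atomistic
  component.
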