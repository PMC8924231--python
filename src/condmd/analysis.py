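"""Observables: windowed diffusion, regime classification, strong contacts,
condensate density, shape metrics, coalescence detection and the
liquid/ageing border curve.

The central dynamical observable is the time-dependent diffusion
coefficient of the central bead of each chain, estimated on consecutive
time windows that are grown until the chains have diffused a prescribed
multiple (3-5) of their bead diameter -- slower dynamics therefore demand
longer windows, exactly as condensate ageing requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .model import BeadRole
from .trajectory import Trajectory

__all__ = [
    "DiffusionSeries",
    "RegimeLabel",
    "ContactSeries",
    "ShapeMetrics",
    "CoalescenceResult",
    "TrajectoryTooShortError",
    "msd_windowed",
    "classify_regime",
    "strong_contacts",
    "chain_clusters",
    "largest_cluster_beads",
    "condensate_density",
    "shape_metrics",
    "coalescence_time",
    "border_curve",
    "diffusion_time_real_units",
    "deceleration_time_bracket",
]


class TrajectoryTooShortError(RuntimeError):
    """Raised when no MSD window can satisfy the displacement rule."""


# ---------------------------------------------------------------------------
# windowed diffusion


@dataclass
class DiffusionSeries:
    """Windowed diffusion coefficients of the chains' central beads."""

    window_centers: np.ndarray  # tau* times
    D_values: np.ndarray  # sigma^2 / tau*
    window_spans: np.ndarray  # tau*
    displacement_check: np.ndarray  # rms central-bead displacement per window, sigma
    displacement_factor: float = 4.0
    partial_last: bool = False  # last window did not reach the displacement rule

    def __len__(self) -> int:
        return len(self.D_values)


def msd_windowed(traj: Trajectory, displacement_factor: float = 4.0,
                 sigma: float = 1.0, fit: str = "slope",
                 allow_partial: bool = False,
                 remove_com: bool = True,
                 align_rigid: bool = False) -> DiffusionSeries:
    """Estimate D(t) of the central beads on displacement-controlled windows.

    Each window starts where the previous one ended and is extended until
    the rms central-bead displacement reaches ``displacement_factor * sigma``
    (the 3-5 diameter sampling rule).  Within a window, D is the slope of a
    linear fit to MSD(lag) over the tail of the window (``fit = 'slope'``)
    or the endpoint ratio MSD/(6 t) (``fit = 'endpoint'``).

    ``remove_com`` (default) measures displacements relative to the
    system's center of mass: a Langevin thermostat does not conserve
    momentum, so in small systems the free COM diffusion (kT / (m gamma N))
    otherwise contaminates the in-condensate mobility.  ``align_rigid``
    additionally removes the best-fit rigid-body rotation of each frame
    (Kabsch alignment onto the first frame, over all beads) -- needed when
    measuring internal mobility of a small free-standing condensate, whose
    rigid tumbling otherwise reads as diffusion.

    With ``allow_partial`` the trailing, unconverged window is reported too
    (flagged), which is how arrested systems -- where the displacement rule
    may be unattainable -- are still assigned an upper bound on D.
    """
    if traj.n_frames < 3:
        raise TrajectoryTooShortError("need at least 3 frames")
    if align_rigid:
        from scipy.spatial.transform import Rotation

        ref = traj.positions[0] - traj.positions[0].mean(axis=0)
        aligned = np.empty_like(traj.positions)
        for f in range(traj.n_frames):
            p = traj.positions[f] - traj.positions[f].mean(axis=0)
            rot, _ = Rotation.align_vectors(ref, p)
            aligned[f] = rot.apply(p)
        r = aligned[:, traj.central_bead_indices, :]
    else:
        r = traj.positions[:, traj.central_bead_indices, :]  # (F, C, 3)
        if remove_com:
            r = r - traj.positions.mean(axis=1, keepdims=True)
    times = traj.times
    target2 = (displacement_factor * sigma) ** 2

    centers, Ds, spans, checks = [], [], [], []
    partial = False
    a = 0
    F = traj.n_frames
    while a < F - 2:
        msd_a = np.mean(np.sum((r[a + 1:] - r[a]) ** 2, axis=2), axis=1)  # (F-a-1,)
        reached = np.nonzero(msd_a >= target2)[0]
        if reached.size == 0:
            if allow_partial and F - 1 - a >= 2 and not centers:
                b = F - 1
                partial = True
            elif allow_partial and F - 1 - a >= 2:
                b = F - 1
                partial = True
            else:
                if centers:
                    break  # trailing incomplete window dropped
                t_need = times[-1] + (target2 / max(msd_a[-1], 1e-12)) * (times[-1] - times[a])
                raise TrajectoryTooShortError(
                    f"displacement rule ({displacement_factor} sigma) unmet; "
                    f"trajectory of ~{t_need:.0f} tau* likely required"
                )
        else:
            b = a + 1 + reached[0]
        # time-origin-averaged MSD within the window for variance reduction
        nlag = b - a
        lags = times[a + 1: b + 1] - times[a]
        msd_w = np.empty(nlag)
        for ell in range(1, nlag + 1):
            d = r[a + ell: b + 1] - r[a: b + 1 - ell]
            msd_w[ell - 1] = np.mean(np.sum(d * d, axis=2))
        if fit == "slope" and nlag >= 4:
            # tail fit past the sub-diffusive regime, weighted by the number
            # of origins contributing to each lag
            lo = nlag // 3
            w = np.sqrt(nlag - np.arange(lo, nlag, dtype=float))
            slope = np.polyfit(lags[lo:], msd_w[lo:], 1, w=w)[0]
            D = slope / 6.0
            if D <= 0.0:
                # caged dynamics: the MSD has plateaued and the tail slope is
                # pure noise; fall back to the endpoint upper bound
                D = msd_w[-1] / (6.0 * lags[-1])
        else:
            D = msd_w[-1] / (6.0 * lags[-1])
        centers.append(0.5 * (times[a] + times[b]))
        Ds.append(D)
        spans.append(times[b] - times[a])
        checks.append(np.sqrt(msd_w[-1]))
        if partial:
            break
        a = b
    if not centers:
        raise TrajectoryTooShortError("no diffusion window could be constructed")
    return DiffusionSeries(np.array(centers), np.array(Ds), np.array(spans),
                           np.array(checks), displacement_factor, partial)


@dataclass
class RegimeLabel:
    """Liquid vs ageing classification of a D(t) series."""

    label: str  # "liquid" | "ageing"
    onset_time: float | None = None  # first crossing below threshold (ageing)
    threshold_used: float = 0.0
    low_confidence: bool = False
    extrapolated: bool = False


def classify_regime(series: DiffusionSeries, threshold: float,
                    plateau_tol: float = 0.15, plateau_windows: int = 3,
                    decay_factor: float = 3.0) -> RegimeLabel:
    """Label a D(t) series as ergodic liquid or ageing.

    Liquid requires the terminal D to sit above the kinetic threshold and to
    have plateaued (relative change < ``plateau_tol`` across the last
    ``plateau_windows`` windows).  A terminal D below threshold is ageing,
    with the onset at the interpolated crossing.  A series still decaying
    steeply (overall decay > ``decay_factor``) without crossing within the
    observed horizon is also ageing -- maturation that fails to reach a
    plateau on the accessible timescale -- with an extrapolated onset,
    flagged as such.
    """
    D = np.asarray(series.D_values, dtype=float)
    t = np.asarray(series.window_centers, dtype=float)
    if len(D) < 1:
        raise ValueError("empty diffusion series")
    terminal = D[-1]

    def first_crossing() -> float:
        below = np.nonzero(D < threshold)[0]
        i = below[0]
        if i == 0:
            return float(t[0])
        # log-linear interpolation between the bracketing windows
        d0, d1 = D[i - 1], D[i]
        if d0 <= 0 or d1 <= 0:
            return float(t[i])
        w = (np.log(d0) - np.log(threshold)) / (np.log(d0) - np.log(d1))
        return float(t[i - 1] + w * (t[i] - t[i - 1]))

    if terminal < threshold:
        return RegimeLabel("ageing", first_crossing(), threshold,
                           low_confidence=series.partial_last)
    k = min(plateau_windows, len(D))
    tail = D[-k:]
    plateaued = (tail.max() - tail.min()) <= plateau_tol * tail.max() if k >= 2 else False
    if plateaued:
        return RegimeLabel("liquid", None, threshold)
    if len(D) >= 3 and D.max() / max(terminal, 1e-300) > decay_factor and D[-1] < D[0]:
        # still decaying: extrapolate the tail in log D - log t space
        kk = min(3, len(D))
        coef = np.polyfit(np.log(t[-kk:]), np.log(D[-kk:]), 1)
        slope, icpt = coef[0], coef[1]
        if slope < 0:
            t_cross = float(np.exp((np.log(threshold) - icpt) / slope))
        else:
            t_cross = float(t[-1] * 10.0)
        return RegimeLabel("ageing", t_cross, threshold,
                           low_confidence=True, extrapolated=True)
    return RegimeLabel("liquid", None, threshold, low_confidence=True)


# ---------------------------------------------------------------------------
# contacts and clusters


@dataclass
class ContactSeries:
    """Strong (sticker A - sticker B) contact counts over time."""

    times: np.ndarray
    n_strong: np.ndarray
    condensate_volume: np.ndarray  # sigma^3, largest cluster only
    normalized: np.ndarray  # contacts per volume / arrest-threshold contact density
    threshold_density: float = float("nan")


def _pairs_within(pos_wrapped: np.ndarray, box: np.ndarray, cutoff: float) -> np.ndarray:
    """All bead pairs within ``cutoff`` under periodic boundaries, as (m, 2)."""
    # cKDTree with boxsize requires coordinates strictly inside [0, box)
    p = np.mod(pos_wrapped, box[None, :])
    np.minimum(p, np.nextafter(box, 0.0)[None, :], out=p)
    tree = cKDTree(p, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs


def strong_contacts(positions: np.ndarray, box: np.ndarray, roles: np.ndarray,
                    chain_len: int, contact_cutoff: float = 1.5):
    """Count inter-chain sticker A - sticker B contacts in one frame.

    Returns ``(count, chain_cluster_labels, pairs)`` where the cluster labels
    are connected components of the chain-level strong-contact graph (chains
    without strong contacts each form their own singleton).
    """
    n = len(roles)
    n_chains = n // chain_len
    pairs = _pairs_within(positions, box, contact_cutoff)
    if pairs.size:
        ri = roles[pairs[:, 0]]
        rj = roles[pairs[:, 1]]
        ab = ((ri == int(BeadRole.STICKER_A)) & (rj == int(BeadRole.STICKER_B))) | (
            (ri == int(BeadRole.STICKER_B)) & (rj == int(BeadRole.STICKER_A)))
        ci = pairs[:, 0] // chain_len
        cj = pairs[:, 1] // chain_len
        keep = ab & (ci != cj)
        strong = pairs[keep]
        ci, cj = ci[keep], cj[keep]
    else:
        strong = pairs.reshape(0, 2)
        ci = cj = np.empty(0, dtype=int)
    graph = sparse.coo_matrix((np.ones(len(ci)), (ci, cj)), shape=(n_chains, n_chains))
    _, labels = connected_components(graph, directed=False)
    return len(strong), labels, strong


def chain_clusters(positions: np.ndarray, box: np.ndarray, chain_len: int,
                   cutoff: float = 1.5):
    """Chain-level clusters from the bead proximity graph (any role).

    Returns (labels per chain, sizes sorted descending).
    """
    n = positions.shape[0]
    n_chains = n // chain_len
    pairs = _pairs_within(positions, box, cutoff)
    if pairs.size:
        ci = pairs[:, 0] // chain_len
        cj = pairs[:, 1] // chain_len
        keep = ci != cj
        ci, cj = ci[keep], cj[keep]
    else:
        ci = cj = np.empty(0, dtype=int)
    graph = sparse.coo_matrix((np.ones(len(ci)), (ci, cj)), shape=(n_chains, n_chains))
    _, labels = connected_components(graph, directed=False)
    sizes = np.sort(np.bincount(labels))[::-1]
    return labels, sizes


def largest_cluster_beads(positions: np.ndarray, box: np.ndarray, chain_len: int,
                          cutoff: float = 1.5) -> np.ndarray:
    """Bead indices of the largest chain cluster."""
    labels, _ = chain_clusters(positions, box, chain_len, cutoff)
    big = np.argmax(np.bincount(labels))
    chains = np.nonzero(labels == big)[0]
    return (chains[:, None] * chain_len + np.arange(chain_len)[None, :]).ravel()


def unwrap_cluster(positions: np.ndarray, box: np.ndarray, idx: np.ndarray,
                   cutoff: float = 1.5) -> np.ndarray:
    """Minimum-image unwrap of one spatial cluster (BFS over its contact graph).

    Needed because a condensate may straddle the periodic boundary; returns
    continuous coordinates for the selected beads.
    """
    p = np.mod(positions[idx], box[None, :])
    tree = cKDTree(np.minimum(p, np.nextafter(box, 0.0)[None, :]), boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    m = len(idx)
    adj: list = [[] for _ in range(m)]
    for a, b in pairs:
        adj[a].append(b)
        adj[b].append(a)
    out = p.copy()
    seen = np.zeros(m, dtype=bool)
    # BFS from the first bead of each connected piece
    for s in range(m):
        if seen[s]:
            continue
        seen[s] = True
        stack = [s]
        while stack:
            a = stack.pop()
            for b in adj[a]:
                if seen[b]:
                    continue
                d = p[b] - out[a]
                out[b] = out[a] + d - box * np.rint(d / box)
                seen[b] = True
                stack.append(b)
    return out


# ---------------------------------------------------------------------------
# density and shape


def condensate_density(positions: np.ndarray, box: np.ndarray, chain_len: int,
                       cluster_cutoff: float = 1.5, shell_width: float = 0.5):
    """Density of the largest cluster: radial-profile plateau in beads/sigma^3.

    Returns ``(density, profile_r, profile_rho, flags)``.  For clusters
    below 100 beads no radial plateau exists and the density falls back to
    the convex-hull volume estimate (flagged ``small_cluster``).
    """
    idx = largest_cluster_beads(positions, box, chain_len, cluster_cutoff)
    pts = unwrap_cluster(positions, box, idx, cluster_cutoff)
    com = pts.mean(axis=0)
    r = np.linalg.norm(pts - com, axis=1)
    flags: list = []
    if len(idx) < 100:
        from scipy.spatial import ConvexHull

        flags.append("small_cluster")
        if len(idx) >= 4:
            vol = ConvexHull(pts).volume
            density = len(idx) / vol if vol > 0 else float("nan")
        else:
            density = float("nan")
        return density, np.array([]), np.array([]), flags
    edges = np.arange(0.0, r.max() + shell_width, shell_width)
    counts, _ = np.histogram(r, bins=edges)
    vols = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho = counts / vols
    mid = 0.5 * (edges[1:] + edges[:-1])
    n_sh = len(rho)
    # core estimate: volume-weighted over the inner quarter, skipping the
    # innermost shell whose tiny volume makes it Poisson-dominated
    q = max(2, n_sh // 4)
    core = float(counts[1: q + 1].sum() / vols[1: q + 1].sum())
    # equimolar-style dividing radius: first drop to half the core density,
    # searched outward from the core region only
    below = np.nonzero(rho[q:] < 0.5 * core)[0]
    r_e = mid[q + below[0]] if below.size else mid[-1]
    plateau_mask = (mid < max(r_e - 2.0, shell_width)) & (mid > 0.5 * shell_width)
    if plateau_mask.sum() < 1:
        flags.append("thin_core")
        density = core
    else:
        # volume-weighted: total beads over total volume of the core region
        density = float(counts[plateau_mask].sum() / vols[plateau_mask].sum())
    return density, mid, rho, flags


@dataclass
class ShapeMetrics:
    gyration_eigenvalues: np.ndarray  # ascending, sigma^2
    asphericity: float
    relative_shape_anisotropy: float  # kappa^2 in [0, 1]
    reduced_rank: bool = False

    @property
    def kappa2(self) -> float:
        return self.relative_shape_anisotropy


def shape_metrics(points: np.ndarray) -> ShapeMetrics:
    """Gyration-tensor shape descriptors of a point cloud.

    kappa^2 = 1 - 3 (l1 l2 + l2 l3 + l3 l1) / (l1+l2+l3)^2 is 0 for
    spherically symmetric clouds and 1 for collinear ones.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (m, 3)")
    m = pts.shape[0]
    reduced = m < 4
    d = pts - pts.mean(axis=0)
    gyr = d.T @ d / m
    lam = np.linalg.eigvalsh(gyr)
    lam = np.clip(lam, 0.0, None)
    tr = lam.sum()
    if tr <= 0:
        return ShapeMetrics(lam, 0.0, 0.0, True)
    aspher = lam[2] - 0.5 * (lam[0] + lam[1])
    kappa2 = 1.0 - 3.0 * (lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]) / tr ** 2
    rank = np.linalg.matrix_rank(gyr, tol=1e-10 * max(tr, 1.0))
    return ShapeMetrics(lam, float(aspher), float(np.clip(kappa2, 0.0, 1.0)),
                        reduced or rank < 3)


# ---------------------------------------------------------------------------
# coalescence


@dataclass
class CoalescenceResult:
    tau_c: float | None  # None when censored
    censored: bool
    censor_time: float
    times: np.ndarray
    kappa2_series: np.ndarray
    cluster_count_series: np.ndarray
    largest_fraction_series: np.ndarray
    status: str = "ok"  # "ok" | "censored" | "evaporated"


def coalescence_time(traj: Trajectory, sphericity_tol: float = 0.02,
                     dwell_fraction: float = 0.1, censor_time: float | None = None,
                     cluster_cutoff: float = 1.5,
                     merged_fraction: float = 0.95) -> CoalescenceResult:
    """Detect the fusion of two tangent droplets into one spherical condensate.

    The coalescence time is the first time at which a single cluster holds
    at least ``merged_fraction`` of the chains AND the largest cluster's
    relative shape anisotropy stays below ``sphericity_tol`` for a dwell
    period (``dwell_fraction`` of the censor horizon; within the dwell the
    mean kappa^2 must stay below the tolerance and every frame below twice
    it, so single fluctuation spikes of small droplets do not reset the
    clock).  Tangent droplets in contact form a single percolating cluster
    from the first frame, so the fusion signal is carried by the shape: the
    initial frame must either show two clusters or an aspherical (dumbbell)
    largest cluster.  Runs that never meet the criterion are censored at
    ``censor_time``; a run whose largest cluster decays below half the
    chains is labelled ``evaporated``.
    """
    if censor_time is None:
        censor_time = float(traj.times[-1])
    dwell = dwell_fraction * censor_time
    n_chains = traj.n_chains
    times, k2s, ncl, frac = [], [], [], []
    for fidx in range(traj.n_frames):
        if traj.times[fidx] > censor_time:
            break
        w = traj.wrapped(fidx)
        labels, sizes = chain_clusters(w, traj.box, traj.chain_len, cluster_cutoff)
        idx = largest_cluster_beads(w, traj.box, traj.chain_len, cluster_cutoff)
        pts = unwrap_cluster(w, traj.box, idx, cluster_cutoff)
        k2s.append(shape_metrics(pts).kappa2)
        ncl.append(len(sizes))
        frac.append(sizes[0] / n_chains)
        times.append(traj.times[fidx])
    times = np.array(times)
    k2s = np.array(k2s)
    ncl = np.array(ncl)
    frac = np.array(frac)

    if ncl[0] < 2 and k2s[0] < sphericity_tol:
        raise ValueError(
            "not a tangent-pair start: initial frame is a single "
            f"near-spherical cluster (kappa^2 = {k2s[0]:.3f})"
        )
    if frac[-1] < 0.5:
        return CoalescenceResult(None, True, censor_time, times, k2s, ncl, frac,
                                 status="evaporated")
    ok = (frac >= merged_fraction) & (k2s < sphericity_tol)
    for i in np.nonzero(ok)[0]:
        t0 = times[i]
        in_dwell = (times >= t0) & (times <= t0 + dwell)
        k2_dwell = k2s[in_dwell]
        frac_ok = np.all(frac[in_dwell] >= merged_fraction)
        shape_ok = (k2_dwell.mean() < sphericity_tol and
                    np.all(k2_dwell < 2.0 * sphericity_tol))
        if frac_ok and shape_ok and (times[-1] >= t0 + dwell or i == len(times) - 1):
            return CoalescenceResult(float(t0), False, censor_time, times, k2s,
                                     ncl, frac)
    return CoalescenceResult(None, True, censor_time, times, k2s, ncl, frac,
                             status="censored")


def border_curve(series_by_eps: dict, threshold: float, **classify_kw):
    """(eps_S, ageing onset time) pairs for every ageing state point.

    Liquid state points have no crossing and are excluded.  On a scan the
    onset times decrease with eps_S: stronger binding arrests sooner.
    """
    pts = []
    for eps in sorted(series_by_eps):
        lab = classify_regime(series_by_eps[eps], threshold, **classify_kw)
        if lab.label == "ageing" and lab.onset_time is not None:
            pts.append((float(eps), float(lab.onset_time)))
    return pts


# ---------------------------------------------------------------------------
# real units


def diffusion_time_real_units(D_real: float, L: float) -> float:
    """Mean time (s) to diffuse a distance L (um) at D (um^2/s): L^2 / (6 D)."""
    if D_real <= 0:
        raise ValueError("D must be positive")
    return L * L / (6.0 * D_real)


def deceleration_time_bracket(t_liquid: float, orders_low: float = 2.0,
                              orders_high: float = 3.0):
    """Map a 10^k-fold diffusion slow-down to the implied diffusion times."""
    return t_liquid * 10.0 ** orders_low, t_liquid * 10.0 ** orders_high
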