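"""Differential-growth curvature mechanics and the roadblock-caging model.

A bent tube of half-width r whose centerline has curvature κ = 1/R_c has
outer-edge radius R_c + r and inner-edge radius R_c − r.  Maintaining the
bend while elongating requires the outer edge to elongate faster than the
inner edge by the ratio (R_c + r)/(R_c − r) = 1 + f, giving the closed
forms

    κ = f / (r · (2 + f))        and        f = 2·κ·r / (1 − κ·r).

The stochastic roadblock simulator formalizes the caging hypothesis:
growth-complex agents random-walk around the discretized cell
circumference; a dense obstacle sector (the protein ribbon at the outer
curve) lets agents in but only lets them out with probability
``p_escape`` per boundary encounter, and raises their per-tick reversal
probability.  Each tick deposits wall growth at the agent's current
angular bin, so trap occupancy converts directly into growth asymmetry
and, via the closed form above, into emergent curvature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .geometry import CellGeometry, arc_centerline, make_cell, straight_centerline


# ---------------------------------------------------------------------------
# Closed-form geometry
# ---------------------------------------------------------------------------

def asymmetry_to_curvature(f: float, r: float) -> float:
    """Centerline curvature κ (µm⁻¹) sustained by fractional outer-edge
    growth excess ``f`` on a tube of half-width ``r``."""
    if f < 0:
        raise ValueError("growth asymmetry must be >= 0")
    if r <= 0:
        raise ValueError("half-width must be positive")
    return f / (r * (2.0 + f))


def curvature_to_asymmetry(kappa: float, r: float) -> float:
    """Fractional outer-edge growth excess required to sustain curvature
    ``kappa`` on a tube of half-width ``r`` (edge-versus-edge measure)."""
    if r <= 0:
        raise ValueError("half-width must be positive")
    kr = kappa * r
    if kr >= 1:
        raise ValueError("kappa * r must be < 1 (inner edge radius > 0)")
    if kr < 0:
        raise ValueError("kappa must be >= 0")
    return 2.0 * kr / (1.0 - kr)


def curvature_to_asymmetry_centerline(kappa: float, r: float) -> float:
    """Alternative edge-versus-centerline measure, reported alongside the
    edge-versus-edge default: (R_c + r)/R_c − 1 = κ·r."""
    if r <= 0:
        raise ValueError("half-width must be positive")
    return kappa * r


# ---------------------------------------------------------------------------
# Roadblock simulator
# ---------------------------------------------------------------------------

@dataclass
class RoadblockParams:
    """Agent-based caging simulation parameters.

    The circumference is split into ``n_bins`` angular bins; the trap
    sector occupies the fraction ``trap_width`` of them starting at bin 0.
    Agents move ``step`` bins per tick in their current direction, may
    reverse with a location-dependent probability, and exit the trap
    sector only with probability ``p_escape`` per attempted boundary
    crossing (failed exits bounce the agent back).  Each tick deposits
    ``growth_per_tick`` length units at the agent's bin.
    """

    n_bins: int = 24
    trap_width: float = 0.25
    step: int = 1
    p_escape: float = 0.1
    p_reverse_in_trap: float = 0.3
    p_reverse_free: float = 0.05
    n_agents: int = 200
    n_ticks: int = 2000
    growth_per_tick: float = 1.0
    burn_in: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 8:
            raise ValueError("need at least 8 angular bins")
        if not 0.0 <= self.trap_width < 1.0:
            raise ValueError("trap_width must be in [0, 1)")
        for p in (self.p_escape, self.p_reverse_in_trap, self.p_reverse_free):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.step < 1 or self.n_agents < 1 or self.n_ticks < 1:
            raise ValueError("step, n_agents and n_ticks must be positive")

    @property
    def trap_bins(self) -> np.ndarray:
        m = int(round(self.trap_width * self.n_bins))
        return np.arange(m)

    def trap_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_bins, dtype=bool)
        mask[self.trap_bins] = True
        return mask


@dataclass
class GrowthState:
    """Outcome of a roadblock simulation."""

    deposited: np.ndarray       # per-bin deposited length
    occupancy: np.ndarray       # per-bin visit counts (post burn-in)
    params: RoadblockParams

    @property
    def total_deposited(self) -> float:
        return float(self.deposited.sum())


def simulate_roadblock(params: RoadblockParams) -> GrowthState:
    """Run the lattice random walk with a caging sector (vectorized over
    agents).  Deposited growth is an exact integer ledger:
    Σ bins = n_agents · n_ticks · growth_per_tick."""
    rng = np.random.default_rng(params.seed)
    m = params.n_bins
    trap = params.trap_mask()

    bins = rng.integers(0, m, size=params.n_agents)
    dirs = rng.choice([-1, 1], size=params.n_agents)

    deposited = np.zeros(m)
    occupancy = np.zeros(m)
    total_ticks = params.burn_in + params.n_ticks
    for tick in range(total_ticks):
        in_trap = trap[bins]
        p_rev = np.where(in_trap, params.p_reverse_in_trap,
                         params.p_reverse_free)
        flip = rng.random(params.n_agents) < p_rev
        dirs = np.where(flip, -dirs, dirs)

        proposed = (bins + dirs * params.step) % m
        exiting = in_trap & ~trap[proposed]
        escape_ok = rng.random(params.n_agents) < params.p_escape
        blocked = exiting & ~escape_ok
        bins = np.where(blocked, bins, proposed)
        dirs = np.where(blocked, -dirs, dirs)

        if tick >= params.burn_in:
            np.add.at(deposited, bins, params.growth_per_tick)
            np.add.at(occupancy, bins, 1)
    return GrowthState(deposited=deposited, occupancy=occupancy,
                       params=params)


def roadblock_transition_matrix(params: RoadblockParams) -> np.ndarray:
    """Exact one-tick transition matrix of the (bin, direction) Markov
    chain implemented by :func:`simulate_roadblock`.  State index is
    2·bin + (0 for direction −1, 1 for +1)."""
    m = params.n_bins
    trap = params.trap_mask()
    n_states = 2 * m
    P = np.zeros((n_states, n_states))

    def sidx(b, d):
        return 2 * b + (1 if d > 0 else 0)

    for b in range(m):
        p_rev = params.p_reverse_in_trap if trap[b] else params.p_reverse_free
        for d in (-1, 1):
            src = sidx(b, d)
            for d_after, w in ((d, 1 - p_rev), (-d, p_rev)):
                if w == 0:
                    continue
                prop = (b + d_after * params.step) % m
                if trap[b] and not trap[prop]:
                    # exit attempt: succeed with p_escape, else bounce
                    P[src, sidx(prop, d_after)] += w * params.p_escape
                    P[src, sidx(b, -d_after)] += w * (1 - params.p_escape)
                else:
                    P[src, sidx(prop, d_after)] += w
    return P


def stationary_occupancy(params: RoadblockParams) -> np.ndarray:
    """Exact stationary per-bin occupancy of the roadblock Markov chain
    (eigen-decomposition oracle for the agent simulation)."""
    P = roadblock_transition_matrix(params)
    w, v = np.linalg.eig(P.T)
    i = np.argmin(np.abs(w - 1.0))
    pi = np.real(v[:, i])
    pi = np.abs(pi) / np.abs(pi).sum()
    return pi.reshape(params.n_bins, 2).sum(axis=1)


def growth_asymmetry(state: GrowthState,
                     trap_mask: np.ndarray | None = None) -> float:
    """Fractional excess of per-bin growth inside the trap sector over
    outside: f = (in/bin − out/bin) / (out/bin)."""
    mask = state.params.trap_mask() if trap_mask is None else trap_mask
    dep = state.deposited
    if mask.sum() == 0:
        return 0.0
    outside = dep[~mask]
    if outside.sum() == 0:
        raise ValueError("all growth deposited inside the trap sector; "
                         "asymmetry diverges")
    per_in = dep[mask].mean()
    per_out = outside.mean()
    return float(per_in / per_out - 1.0)


# ---------------------------------------------------------------------------
# Steady-state curvature
# ---------------------------------------------------------------------------

def delivered_asymmetry(f0: float, kappa: float, r: float) -> float:
    """Asymmetry actually delivered at curvature κ: the baseline f₀ is
    diluted by the growing outer-edge track length, modeled as
    f₀·(1 − κ·r)/(1 + κ·r)."""
    kr = kappa * r
    if kr >= 1:
        raise ValueError("kappa * r must be < 1")
    return f0 * (1.0 - kr) / (1.0 + kr)


def steady_state_curvature(f0: float, r: float, gain: float = 0.5,
                           tol: float = 1e-6, max_iter: int = 10000):
    """Relaxed fixed-point iteration for the steady-state curvature.

    Iterates κ ← κ + gain·(κ_target(f_delivered(κ)) − κ) until |Δκ| < tol
    (µm⁻¹).  Returns (κ*, trajectory array).  The fixed point satisfies
    f_delivered(κ*) = f_required(κ*) = 2κ*r/(1−κ*r).
    """
    if not 0 < gain <= 1:
        raise ValueError("gain must be in (0, 1]")
    kappa = 0.0
    traj = [kappa]
    for _ in range(max_iter):
        f_del = delivered_asymmetry(f0, kappa, r)
        target = asymmetry_to_curvature(f_del, r)
        new = kappa + gain * (target - kappa)
        traj.append(new)
        if abs(new - kappa) < tol:
            return new, np.asarray(traj)
        kappa = new
    raise RuntimeError(
        f"no convergence in {max_iter} iterations; trajectory tail "
        f"{traj[-3:]}")


def steady_state_curvature_root(f0: float, r: float) -> float:
    """Independent root-bracketing solution of
    f_delivered(κ) − f_required(κ) = 0 (oracle for the iteration)."""
    if f0 == 0:
        return 0.0

    def g(kappa):
        return delivered_asymmetry(f0, kappa, r) \
            - curvature_to_asymmetry(kappa, r)

    hi = 0.999 / r
    return brentq(g, 0.0, hi, xtol=1e-12)


# ---------------------------------------------------------------------------
# Synthetic growth trajectories
# ---------------------------------------------------------------------------

def grow_synthetic_cell(kappa_traj: np.ndarray, r: float, length0: float,
                        growth_per_tick: float) -> list[CellGeometry]:
    """Emit the cell geometry sequence for a growing tube whose curvature
    follows ``kappa_traj`` while its length increases by
    ``growth_per_tick`` per tick.  Raises if κ·r ≥ 1 or if the bent tube
    would self-intersect (arc angle too close to a full turn)."""
    geoms = []
    length = length0
    for kappa in np.asarray(kappa_traj, dtype=float):
        if kappa * r >= 1:
            raise ValueError("kappa * r must stay below 1")
        if kappa > 0:
            theta = kappa * length
            if theta >= 2 * np.pi - 2 * np.arcsin(
                    min(kappa * r, 1.0)):
                raise ValueError("tube self-intersects at this curvature "
                                 "and length")
            centerline = arc_centerline(1.0 / kappa, length, n=256)
        else:
            centerline = straight_centerline(length, n=64)
        geoms.append(make_cell(centerline, r))
        length += growth_per_tick
    return geoms
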