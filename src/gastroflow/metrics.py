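"""Output statistics: emptying rate and its decomposition, pressure probes,
mixing efficiency, Lagrangian tracers and regional emptying probability.

Sign conventions: transpyloric flux q(t) is positive from the antrum to the
duodenum (anterograde); the cycle-averaged rate decomposes as
``Q = Q_plus + Q_minus`` with ``Q_plus = <max(q, 0)>`` and
``Q_minus = <min(q, 0)>`` (retrograde, <= 0).  The dimensionless emptying
rate is ``q* = Q / (D^2 V)`` with D the antral diameter and V the wave
speed; with the Strouhal number St = D/(VT) and Reynolds number
Re = rho V D / mu these fix the flow regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from gastroflow.geometry import GutGeometry, RegionLabels

ML = 1000.0


# -- emptying rate -----------------------------------------------------------


def transpyloric_flux(sim) -> float:
    """Instantaneous transpyloric flux of a running gastric simulation
    (ml/min, positive antrum -> duodenum); the plane is the lattice plane
    through the pyloric midpoint, normal along the centerline."""
    return sim.transpyloric_flux()


@dataclass
class EmptyingSeries:
    """Cycle-averaged emptying statistics from an instantaneous flux series."""

    t: np.ndarray  # s
    q: np.ndarray  # ml/min, + toward duodenum
    Q: float  # ml/min
    Q_plus: float
    Q_minus: float
    q_star: float  # Q / (D^2 V)
    n_cycles: int


def decompose_emptying(
    t: np.ndarray,
    q: np.ndarray,
    T: float,
    n_cycles: int | None = None,
    D: float = 50.0,
    V: float = 2.5,
) -> EmptyingSeries:
    """Average the flux over an integer number of trailing cycles.

    ``q`` in ml/min on (possibly uneven) sample times ``t``; the window is
    the last ``n_cycles`` full periods (default: as many as fit, at least
    one, excluding nothing else -- transient removal is the caller's
    choice).  Raises ValueError when less than one full cycle is available.
    """
    t = np.asarray(t, float)
    q = np.asarray(q, float)
    span = t[-1] - t[0]
    max_cycles = int(np.floor(span / T + 1e-9))
    if max_cycles < 1:
        raise ValueError(f"need at least one full cycle ({T} s), got {span:.3g} s")
    if n_cycles is None:
        n_cycles = max_cycles
    if n_cycles > max_cycles:
        raise ValueError(f"window of {n_cycles} cycles exceeds the {span:.3g} s record")
    t0 = t[-1] - n_cycles * T
    m = t >= t0 - 1e-12
    tt, qq = t[m], q[m]
    width = tt[-1] - tt[0]
    Q = float(np.trapezoid(qq, tt) / width)
    Qp = float(np.trapezoid(np.maximum(qq, 0.0), tt) / width)
    Qm = float(np.trapezoid(np.minimum(qq, 0.0), tt) / width)
    # enforce the identity exactly against quadrature round-off
    Qm = Q - Qp
    q_mm3_s = Q * ML / 60.0
    return EmptyingSeries(t=tt, q=qq, Q=Q, Q_plus=Qp, Q_minus=Qm,
                          q_star=q_mm3_s / (D**2 * V), n_cycles=n_cycles)


def dimensionless_numbers(mu: float, rho: float = 1000.0, D: float = 50.0,
                          V: float = 2.5, T: float = 20.0) -> tuple[float, float]:
    """(St, Re) = (D/(V T), rho V D / mu); D, V, T in mm, mm/s, s; SI fluid."""
    St = D / (V * T)
    Re = rho * (V * 1e-3) * (D * 1e-3) / mu
    return St, Re


# -- pressure ----------------------------------------------------------------


@dataclass
class PressureProbeSeries:
    """Pressure at centerline points +/-5 mm of the pyloric midpoint."""

    t: np.ndarray
    p_antral: np.ndarray  # Pa, NaN where the probe was dry
    p_duodenal: np.ndarray

    @property
    def dp(self) -> np.ndarray:
        """p_antral - p_duodenal; positive drives anterograde flow."""
        return self.p_antral - self.p_duodenal


def pressure_series(records: list[dict]) -> PressureProbeSeries:
    return PressureProbeSeries(
        t=np.array([r["t"] for r in records]),
        p_antral=np.array([r["p_antral"] for r in records]),
        p_duodenal=np.array([r["p_duodenal"] for r in records]),
    )


# -- mixing efficiency -------------------------------------------------------


def strain_rate_invariant(u: np.ndarray, wet: np.ndarray, dx: float,
                          convention: str = "shear_norm") -> float:
    """Spatial mean of the strain-rate invariant over interior liquid nodes.

    ``u`` is (nx, ny, nz, 3) in mm/s.  ``shear_norm`` is the magnitude
    sqrt(2 S:S) (units 1/s); ``second_invariant`` is the algebraic
    II_S = -1/2 [ (tr S)^2 - tr(S^2) ] (for incompressible flow tr S ~ 0,
    so II_S ~ S:S / ... sign conventions differ; reported as-is).
    Gradients are one-sided at non-liquid neighbours by masking: only nodes
    whose full 3x3x3 neighbourhood is wet contribute.
    """
    grads = []
    for comp in range(3):
        g = np.gradient(u[..., comp], dx, edge_order=1)
        if u.shape[1] == 1:  # quasi-2-D: no y variation
            g[1] = np.zeros_like(u[..., comp])
        grads.append(g)  # grads[comp][axis]
    S2 = np.zeros(u.shape[:3])
    trS = np.zeros(u.shape[:3])
    for a in range(3):
        trS += grads[a][a]
        for b in range(3):
            Sab = 0.5 * (grads[a][b] + grads[b][a])
            S2 += Sab * Sab
    interior = wet.copy()
    for ax in range(3):
        if wet.shape[ax] == 1:
            continue
        for sh in (-1, 1):
            interior &= np.roll(wet, sh, axis=ax)
    if not interior.any():
        return float("nan")
    if convention == "shear_norm":
        val = np.sqrt(2.0 * S2)
    elif convention == "second_invariant":
        val = -0.5 * (trS**2 - S2)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return float(val[interior].mean())


@dataclass
class MixingEfficiencyRecord:
    M: float  # 1/s (shear_norm convention)
    n_snapshots: int
    convention: str = "shear_norm"

    def nondimensional(self, D: float = 50.0, V: float = 2.5) -> float:
        return self.M * D / V


def mixing_efficiency(snapshots: list[tuple[np.ndarray, np.ndarray]], dx: float,
                      convention: str = "shear_norm", min_snapshots: int = 20,
                      ) -> MixingEfficiencyRecord:
    """Time-mean over one cycle of the spatial-mean strain-rate invariant.

    ``snapshots`` is a list of (velocity mm/s, wet mask) sampled uniformly
    over one full contraction cycle (at least ``min_snapshots`` of them).
    """
    if len(snapshots) < min_snapshots:
        raise ValueError(f"need >= {min_snapshots} snapshots per cycle, got {len(snapshots)}")
    vals = [strain_rate_invariant(u, wet, dx, convention) for u, wet in snapshots]
    return MixingEfficiencyRecord(M=float(np.nanmean(vals)), n_snapshots=len(snapshots),
                                  convention=convention)


# -- tracers -----------------------------------------------------------------


@dataclass
class TracerSet:
    """Lagrangian tracer particles with emptying bookkeeping.

    A particle counts as emptied when it is on the duodenal side of the
    pyloric midplane (arclength s < 0); returning to the stomach clears the
    flag (retrograde return).  Particles that leave through the duodenal
    outlet are frozen and stay emptied.
    """

    pos: np.ndarray  # (N, 3) mm
    initial_region: np.ndarray  # int, 1-based
    emptied: np.ndarray  # bool
    emptying_time: np.ndarray  # s, NaN until first emptied
    gone: np.ndarray  # left the domain through the outlet
    repairs: int = 0  # wall-penetration projections applied (logged)

    @classmethod
    def random_in_stomach(
        cls,
        geom: GutGeometry,
        regions: RegionLabels | None,
        n: int,
        seed: int,
        fill_height: float | None = None,
        region_boundaries: np.ndarray | None = None,
    ) -> "TracerSet":
        """Uniform random positions in the liquid-filled stomach lumen."""
        rng = np.random.default_rng(seed)
        lo, hi = geom.bounding_box()
        if fill_height is not None:
            hi = hi.copy()
            hi[2] = min(hi[2], fill_height)
        pts = np.empty((0, 3))
        while len(pts) < n:
            cand = rng.uniform(lo, hi, size=(max(4 * n, 1000), 3))
            s, d, _ = geom.nearest(cand)
            keep = (d < geom.r0(s)) & (s > 0)
            if fill_height is not None:
                keep &= cand[:, 2] <= fill_height
            pts = np.vstack([pts, cand[keep]])
        pts = pts[:n]
        if region_boundaries is None:
            region_boundaries = np.linspace(0.0, geom.s_max, (regions.n_regions if regions else 13) + 1)
        s, _, _ = geom.nearest(pts)
        reg = np.minimum(np.searchsorted(region_boundaries, s, side="right"),
                         len(region_boundaries) - 1)
        return cls(
            pos=pts,
            initial_region=reg.astype(np.int32),
            emptied=np.zeros(n, bool),
            emptying_time=np.full(n, np.nan),
            gone=np.zeros(n, bool),
        )

    def update_emptied(self, geom: GutGeometry, t: float) -> None:
        s, _, _ = geom.nearest(self.pos)
        out_now = (s < 0.0) | self.gone
        newly = out_now & ~self.emptied
        self.emptying_time[newly] = t
        back = ~out_now & self.emptied
        self.emptying_time[back] = np.nan
        self.emptied = out_now


def make_velocity_interpolant(u: np.ndarray, origin: np.ndarray, dx: float):
    """Trilinear interpolant of a (nx, ny, nz, 3) velocity field; 0 outside."""
    axes = [origin[k] + dx * np.arange(u.shape[k]) for k in range(3)]
    interps = [
        RegularGridInterpolator(axes, u[..., c], bounds_error=False, fill_value=0.0)
        for c in range(3)
    ]

    def vel(x: np.ndarray) -> np.ndarray:
        return np.column_stack([f(x) for f in interps])

    return vel


def advect_tracers(tracers: TracerSet, vel, dt: float) -> TracerSet:
    """One RK4 step of all live particles through the (frozen) velocity field."""
    live = ~tracers.gone
    x = tracers.pos[live]
    k1 = vel(x)
    k2 = vel(x + 0.5 * dt * k1)
    k3 = vel(x + 0.5 * dt * k2)
    k4 = vel(x + dt * k3)
    tracers.pos[live] = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return tracers


def repair_wall_penetration(tracers: TracerSet, geom: GutGeometry,
                            radius_at, margin: float = 0.5) -> int:
    """Project particles outside the instantaneous lumen back inside.

    ``radius_at(s)`` returns the current lumen radius; particles with
    radial distance beyond ``radius - margin`` are pulled radially inward.
    Returns the number of repairs (accumulated on the tracer set).
    """
    live = ~tracers.gone
    pts = tracers.pos[live]
    s, d, e_r = geom.nearest(pts)
    r_now = np.maximum(np.asarray(radius_at(s), float), 2 * margin)
    bad = d > r_now - margin
    nbad = int(bad.sum())
    if nbad:
        scale = (r_now[bad] - margin) / np.maximum(d[bad], 1e-9)
        c = pts[bad] - e_r[bad] * d[bad][:, None]
        pts[bad] = c + e_r[bad] * (d[bad] * scale)[:, None]
        tracers.pos[live] = pts
        tracers.repairs += nbad
    return nbad


# -- emptying probability ----------------------------------------------------


@dataclass
class EmptyingProbability:
    """Fraction of tracers from each region emptied by each horizon."""

    regions: np.ndarray  # 1..n
    horizons: np.ndarray  # s
    fraction: np.ndarray  # (n_regions, n_horizons), NaN for empty regions
    counts: np.ndarray  # tracers initialized per region


def emptying_probability(tracers: TracerSet, n_regions: int,
                         horizons: np.ndarray) -> EmptyingProbability:
    """Per-region fraction emptied by each horizon (uses emptying times of
    currently-emptied particles, so retrograde returns are not counted)."""
    horizons = np.asarray(horizons, float)
    regions = np.arange(1, n_regions + 1)
    frac = np.full((n_regions, len(horizons)), np.nan)
    counts = np.zeros(n_regions, int)
    te = np.where(tracers.emptied, tracers.emptying_time, np.nan)
    for ridx, r in enumerate(regions):
        m = tracers.initial_region == r
        counts[ridx] = m.sum()
        if counts[ridx] == 0:
            continue
        for hidx, h in enumerate(horizons):
            frac[ridx, hidx] = np.mean(te[m] <= h)
    return EmptyingProbability(regions=regions, horizons=horizons,
                               fraction=frac, counts=counts)
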