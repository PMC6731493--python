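"""Canonical solver benchmarks with analytic references.

Each fixture builds a small lattice by hand and returns measured vs
analytic quantities, so the solver's viscosity, wall treatment, outlet and
free-surface closures can be checked independently of the gastric problem.
Channels are quasi-2-D (single periodic y slab on the D3Q19 stencil).
"""

from __future__ import annotations

import numpy as np

from gastroflow import _kernels as K
from gastroflow import lattice as L
from gastroflow.lbm import FreeSurfaceModel, LatticeConfig, LBMCore


def _channel_core(n_across: int, config: LatticeConfig, dt: float, *, nx: int = 4,
                  body_force=(0.0, 0.0, 0.0), lid_speed: float = 0.0,
                  wall_offset: float = 0.5) -> LBMCore:
    """Plane channel along x, walls normal to z at ``wall_offset`` cells
    outside the first/last fluid node (0.5 = half-way walls)."""
    nz = n_across + 2
    flags = np.full((nx, 1, nz), K.LIQUID, np.uint8)
    flags[:, :, 0] = K.SOLID
    flags[:, :, -1] = K.SOLID
    kz = np.arange(nz, dtype=np.float32)
    lo = 1.0 - wall_offset  # wall plane position (lattice units)
    hi = nz - 2.0 + wall_offset
    psi = np.maximum(lo - kz, kz - hi).astype(np.float32)[None, None, :]
    psi = np.broadcast_to(psi, flags.shape).copy()
    core = LBMCore(flags, config, dt, psi=psi, body_force=body_force)
    if lid_speed:
        core.uwx[:, :, -1] = lid_speed * dt / config.dx
    return core


def poiseuille_channel(
    n_across: int = 24,
    mu: float = 0.1,
    accel: float = 14.0,  # mm/s^2 along x
    dx: float = 1.0,
    n_steps: int | None = None,
    wall_offset: float = 0.5,
) -> dict:
    """Body-force Poiseuille flow; compare the velocity profile and flux."""
    nu = mu / 1000.0 * 1e6
    H = (n_across - 1 + 2 * wall_offset) * dx
    u_max = accel * H**2 / (8 * nu)
    config = LatticeConfig(dx=dx, mu=mu, u_ref=4 * u_max)
    dt = config.resolve_dt()
    core = _channel_core(n_across, config, dt, body_force=(accel, 0, 0), wall_offset=wall_offset)
    if n_steps is None:
        n_steps = int(2.0 * H**2 / nu / dt)  # a couple of diffusion times
    core.run(n_steps)
    z = (np.arange(1, n_across + 1) - (1 - wall_offset)) * dx  # distance from lower wall
    u_num = core.ux[0, 0, 1:-1] * dx / dt
    u_ref = accel / (2 * nu) * z * (H - z)
    return {
        "u_numeric": u_num,
        "u_analytic": u_ref,
        "max_rel_err": float(np.max(np.abs(u_num - u_ref)) / u_ref.max()),
        "centerline_rel_err": float(abs(u_num.max() - u_max) / u_max),
    }


def couette_channel(
    n_across: int = 24,
    mu: float = 0.1,
    lid_speed: float = 5.0,  # mm/s
    dx: float = 1.0,
) -> dict:
    """Impulsively started lid; steady profile should be linear."""
    config = LatticeConfig(dx=dx, mu=mu, u_ref=4 * lid_speed)
    dt = config.resolve_dt()
    core = _channel_core(n_across, config, dt, lid_speed=lid_speed)
    nu = config.nu
    H = (n_across) * dx  # wall planes at half-links: gap = n_across * dx
    n_steps = int(2.0 * H**2 / nu / dt)
    core.run(n_steps)
    z = (np.arange(1, n_across + 1) - 0.5) * dx  # node heights above the lower wall
    u_num = core.ux[0, 0, 1:-1] * dx / dt
    u_ref = lid_speed * z / H
    return {
        "u_numeric": u_num,
        "u_analytic": u_ref,
        "max_rel_err": float(np.max(np.abs(u_num - u_ref)) / lid_speed),
    }


def shear_wave_decay(
    n: int = 32,
    mu: float = 4.2e-3,
    u0: float = 2.0,  # mm/s
    dx: float = 1.0,
    n_steps: int = 400,
) -> dict:
    """Periodic shear wave u_x(z) = u0 sin(2 pi z / L); amplitude decays as
    exp(-nu k^2 t).  Returns measured vs configured kinematic viscosity.
    The timestep keeps nu_lat <= 0.1 so discrete-dispersion corrections to
    the decay rate stay well below 1%.
    """
    nu = mu / 1000.0 * 1e6
    dt = min(0.05 * dx / (8 * u0), 0.1 * dx**2 / nu)
    config = LatticeConfig(dx=dx, mu=mu, dt=dt)
    flags = np.full((2, 1, n), K.LIQUID, np.uint8)
    core = LBMCore(flags, config, dt)
    kz = 2 * np.pi / n
    u = np.zeros((2, 1, n, 3))
    u[..., 0] = u0 * (dt / dx) * np.sin(kz * np.arange(n))[None, None, :]
    core.f[:] = L.feq(np.ones((2, 1, n)), u)
    amp0 = None
    t0 = None
    for s in range(n_steps):
        core.step()
        if s == n_steps // 4:
            amp0 = float(np.abs(core.ux[0, 0, :]).max())
            t0 = core.step_count
    amp1 = float(np.abs(core.ux[0, 0, :]).max())
    nu_lat = -np.log(amp1 / amp0) / (kz**2 * (core.step_count - t0))
    nu_meas = nu_lat * dx**2 / dt
    return {
        "nu_measured": nu_meas,
        "nu_configured": config.nu,
        "rel_err": float(abs(nu_meas - config.nu) / config.nu),
    }


def tube_poiseuille(
    radius_cells: float = 7.5,
    mu: float = 0.1,
    accel: float = 10.0,  # mm/s^2 along the axis
    dx: float = 1.0,
    with_outlet: bool = False,
    nx: int = 24,
    axis: str = "x",
) -> dict:
    """Hagen--Poiseuille flow in a circular tube (curved-wall bounce-back).

    Periodic along the axis by default; with ``with_outlet`` both ends are
    held at the reference pressure through the non-reflecting boundary and
    the outflow bookkeeping accumulates.  ``axis`` rotates the whole
    problem onto a different lattice axis (axis-independence check).  The
    timestep targets tau ~ 1 where interpolated bounce-back is accurate.
    """
    R = radius_cells * dx
    nu = mu / 1000.0 * 1e6
    u_max = accel * R**2 / (4 * nu)
    dt = min(0.05 * dx / (4 * u_max), 0.5 * dx**2 / (3.0 * nu))
    config = LatticeConfig(dx=dx, mu=mu, dt=dt)
    half = int(np.ceil(radius_cells)) + 2
    n = 2 * half + 1
    if not with_outlet:
        nx = 4
    yy, zz = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    r = np.sqrt((yy - half) ** 2 + (zz - half) ** 2) * dx
    psi2d = ((r - R) / dx).astype(np.float32)
    flags = np.where(psi2d < 0, K.LIQUID, K.SOLID).astype(np.uint8)[None, :, :]
    flags = np.broadcast_to(flags, (nx, n, n)).copy()
    psi = np.broadcast_to(psi2d[None, :, :], (nx, n, n)).copy()
    outlet = None
    extra = None
    if with_outlet:
        # solid cap at i = 0 so the two open layers do not wrap into each
        # other; pressure inlet at i = 1, accounted outlet at i = nx - 1
        flags[0, :, :] = K.SOLID
        psi[0, :, :] = 0.5
        jk = np.argwhere(psi2d < 0)
        mk = lambda i: (np.full(len(jk), i), np.ascontiguousarray(jk[:, 0]), np.ascontiguousarray(jk[:, 1]))  # noqa: E731
        outlet = mk(nx - 1)
        extra = [(mk(1), (1, 0, 0))]
    force = (accel, 0.0, 0.0)
    if axis == "z":
        flags = np.ascontiguousarray(np.transpose(flags, (1, 2, 0)))
        psi = np.ascontiguousarray(np.transpose(psi, (1, 2, 0)))
        force = (0.0, 0.0, accel)
        if with_outlet:
            raise ValueError("outlet variant only supports axis='x'")
    core = LBMCore(flags, config, dt, psi=psi, body_force=force,
                   outlet_cells=outlet, outlet_inward=(-1, 0, 0), extra_open=extra)
    n_steps = int(2.0 * (2 * R) ** 2 / nu / dt)
    core.run(n_steps)
    if axis == "z":
        mid = flags.shape[2] // 2
        wet = core.flags[:, :, mid] == K.LIQUID
        u_axis = core.uz[:, :, mid][wet]
    else:
        mid = nx // 2
        wet = core.flags[mid] == K.LIQUID
        u_axis = core.ux[mid][wet]
    q_num = float(u_axis.sum()) * (dx / dt) * dx**2  # mm^3/s
    q_ref = np.pi * accel * R**4 / (8 * nu)
    return {
        "q_numeric": q_num,
        "q_analytic": q_ref,
        "rel_err": float(abs(q_num - q_ref) / q_ref),
        "emptied_volume_ml": core.emptied_volume,
        "u_max": float(u_axis.max()) * dx / dt,
        "u_max_analytic": u_max,
        "tau": config.tau(dt),
    }


def closed_box_conservation(n: int = 10, n_steps: int = 2000, mu: float = 0.1) -> dict:
    """Static closed box of liquid, no forcing: mass constant to round-off."""
    config = LatticeConfig(dx=1.0, mu=mu, u_ref=10.0)
    dt = config.resolve_dt()
    flags = np.full((n, n, n), K.SOLID, np.uint8)
    flags[1:-1, 1:-1, 1:-1] = K.LIQUID
    core = LBMCore(flags, config, dt)
    # irregular initial density perturbation to make the test non-trivial
    rng = np.random.default_rng(0)
    rho = 1.0 + 0.01 * rng.standard_normal((n, n, n))
    core.f[:] = L.feq(rho, np.zeros((n, n, n, 3)))
    core.f[flags == K.SOLID] = 0.0
    m0 = float(core.f.sum())
    core.run(n_steps)
    m1 = float(core.f.sum())
    umax = float(np.abs([core.ux, core.uy, core.uz]).max())
    return {"mass_drift": abs(m1 - m0) / m0, "u_max_lat": umax}


def quiescent_free_surface(n: int = 12, n_steps: int = 500) -> dict:
    """Half-filled closed box with a flat interface at h_bar: the restoring
    force is zero and the state stays quiescent (velocity at round-off)."""
    config = LatticeConfig(dx=1.0, mu=0.1, u_ref=10.0)
    dt = config.resolve_dt()
    flags = np.full((n, n, n), K.SOLID, np.uint8)
    flags[1:-1, 1:-1, 1:-1] = K.LIQUID
    half = n // 2
    flags[1:-1, 1:-1, half + 1:-1] = K.GAS
    flags[1:-1, 1:-1, half] = K.INTERFACE
    core = LBMCore(flags, config, dt, free_surface=FreeSurfaceModel())
    v0 = core.total_liquid_volume()
    core.run(n_steps)
    umax = float(np.abs([core.ux[core.flags == K.LIQUID],
                         core.uy[core.flags == K.LIQUID],
                         core.uz[core.flags == K.LIQUID]]).max()) if (core.flags == K.LIQUID).any() else 0.0
    return {
        "u_max_lat": umax,
        "volume_drift": abs(core.total_liquid_volume() - v0) / v0,
        "href_drift": abs(core.href - (core.z_mm[0, 0, half] + 0.0)) if core.href else 0.0,
    }


def sloshing_decay(n: int = 24, tilt: float = 0.1, n_steps: int = 4000,
                   k_flat: float = 300.0) -> dict:
    """Tilted interface in a closed box relaxes toward flat under the
    interface-flattening force; the tilt amplitude must decay."""
    config = LatticeConfig(dx=1.0, mu=0.05, u_ref=30.0)
    dt = config.resolve_dt()
    nz = n
    flags = np.full((n, 4, nz), K.SOLID, np.uint8)
    flags[1:-1, :, 1:-1] = K.LIQUID
    x = np.arange(n)
    # tilted fill height across x
    h = nz // 2 + tilt * nz * (x - n / 2) / n
    for i in range(1, n - 1):
        ktop = int(round(h[i]))
        flags[i, :, ktop + 1:-1] = K.GAS
        flags[i, :, ktop] = K.INTERFACE
    core = LBMCore(flags, config, dt, free_surface=FreeSurfaceModel(k_flat=k_flat))

    def tilt_amp() -> float:
        zs = []
        for i in range(1, n - 1):
            kk = np.where(core.flags[i, 2, :] == K.INTERFACE)[0]
            zs.append(kk.mean() if len(kk) else np.nan)
        zs = np.asarray(zs)
        return float(np.nanmax(zs) - np.nanmin(zs))

    a0 = tilt_amp()
    amps = [a0]
    for _ in range(8):
        core.run(n_steps // 8)
        amps.append(tilt_amp())
    return {"amplitude_series": np.array(amps), "initial": a0, "final": amps[-1],
            "time_elapsed": core.t}
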