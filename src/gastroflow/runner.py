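"""Run orchestration: single simulations, coordination sweeps, reports.

``run_simulation`` executes one configured gastric run and returns a
self-describing bundle (config, per-step records, summary metrics, tracer
state); ``run_sweep`` enumerates a :class:`SweepSpec` Cartesian grid and
tabulates per-cell emptying/mixing statistics with the antro-pyloric
coordination predicates; ``make_report`` renders the standard figures from
bundles/tables.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from gastroflow import io as gio
from gastroflow import metrics as gm
from gastroflow import motility as gmot
from gastroflow.config import RunConfig, SweepSpec
from gastroflow.geometry import build_gut_geometry, label_regions
from gastroflow.lbm import GastricSimulation

log = logging.getLogger("gastroflow")


def _phase_mask(shape, flags):
    from gastroflow import _kernels as K

    return (flags == K.LIQUID) | (flags == K.INTERFACE)


def run_simulation(config: RunConfig, outdir: str | Path | None = None,
                   geom=None, n_regions: int = 13) -> dict:
    """Execute one configured run; returns (and optionally writes) a bundle.

    The run is deterministic for a fixed config: the solver has no random
    element and tracer initialization is fixed by ``config.seed``.
    """
    t_start = time.time()
    geom = geom or build_gut_geometry(config.geometry)
    sim = GastricSimulation(
        geom,
        config.wave,
        config.schedule,
        config.lattice,
        fill_fraction=config.fill_fraction,
        free_surface=config.free_surface,
    )
    T = config.schedule.T
    log.info("run: dx=%.3g mm dt=%.4g s mu=%.3g Pa s", config.lattice.dx, sim.dt, config.lattice.mu)

    # transient
    sim.run_cycles(config.transient_cycles, record_every=config.record_every)

    # tracers initialized after the transient, in the liquid-filled stomach
    tracers = None
    t_tracer0 = sim.core.t
    if config.tracer_count > 0:
        boundaries = np.linspace(0.0, geom.s_max, n_regions + 1)
        tracers = gm.TracerSet.random_in_stomach(
            geom, None, config.tracer_count, config.seed,
            fill_height=sim.core.href, region_boundaries=boundaries,
        )

    measured = config.n_cycles - config.transient_cycles
    n_steps = int(round(measured * T / sim.dt))
    snap_start = int(round((measured - 1.0) * T / sim.dt))
    snap_stride = max(int(round(T / sim.dt / config.mixing_snapshots)), 1)
    snapshots: list[tuple[np.ndarray, np.ndarray]] = []

    dt_trac = config.tracer_every * sim.dt
    for n in range(n_steps):
        sim.core.step()
        if n % config.record_every == 0:
            sim.records.append(sim.sample())
        if tracers is not None and (n + 1) % config.tracer_every == 0:
            u = sim.velocity_mm_s()
            vel = gm.make_velocity_interpolant(u, sim.grid.origin, config.lattice.dx)
            gm.advect_tracers(tracers, vel, dt_trac)
            x_out = sim.grid.origin[0] + (sim.grid.shape[0] - 2) * config.lattice.dx
            tracers.gone |= tracers.pos[:, 0] > x_out
            gm.repair_wall_penetration(tracers, geom, sim.lumen_radius_at_s,
                                       margin=0.3 * config.lattice.dx)
            tracers.update_emptied(geom, sim.core.t - t_tracer0)
        if n >= snap_start and (n - snap_start) % snap_stride == 0:
            u = sim.velocity_mm_s()
            snapshots.append((u, _phase_mask(u.shape, sim.core.flags.copy())))

    rec = pd.DataFrame(sim.records)
    D = config.geometry.antral_diameter_D
    V = config.wave.V_prox
    es = gm.decompose_emptying(
        rec["t"].to_numpy(), rec["q_pyloric"].to_numpy(), T,
        n_cycles=None, D=D, V=V,  # as many full trailing cycles as recorded
    )
    mix = gm.mixing_efficiency(snapshots, config.lattice.dx,
                               min_snapshots=min(20, config.mixing_snapshots))
    St, Re = gm.dimensionless_numbers(config.lattice.mu, config.lattice.rho0, D, V, T)

    metrics = {
        "Q_ml_min": es.Q,
        "Q_plus_ml_min": es.Q_plus,
        "Q_minus_ml_min": es.Q_minus,
        "q_star": es.q_star,
        "mixing_efficiency_per_s": mix.M,
        "St": St,
        "Re": Re,
        "open_during_tac": gmot.open_during_tac(config.schedule, config.wave),
        "open_during_relaxation": gmot.open_during_relaxation(config.schedule, config.wave),
        "mass_balance_error": sim.mass_balance_error(),
        "emptied_volume_ml": sim.core.emptied_volume,
        "wall_seconds": time.time() - t_start,
        "dt": sim.dt,
        "n_steps": sim.core.step_count,
    }
    bundle = {"config": config, "records": rec, "metrics": metrics,
              "tracers": tracers, "sim": sim, "t_tracer0": t_tracer0}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        rec.to_csv(outdir / "records.csv", index=False)
        gio.dump_json(outdir / "metrics.json", metrics)
        if tracers is not None:
            gio.write_vtk_points(
                outdir / "tracers.vtk", tracers.pos,
                {"region": tracers.initial_region.astype(float),
                 "emptied": tracers.emptied.astype(float)},
            )
    return bundle


def emptying_probability_from_bundle(bundle: dict, horizons=None,
                                     n_regions: int = 13) -> gm.EmptyingProbability:
    """Regional emptying probability at cycle-multiple horizons."""
    tracers = bundle["tracers"]
    if tracers is None:
        raise ValueError("run had no tracers")
    T = bundle["config"].schedule.T
    sim = bundle["sim"]
    if horizons is None:
        t_max = sim.core.t - bundle["t_tracer0"]
        horizons = np.arange(T, t_max + 1e-9, T)
    return gm.emptying_probability(tracers, n_regions, horizons)


def run_sweep(spec: SweepSpec, base: RunConfig, outdir: str | Path | None = None) -> pd.DataFrame:
    """Run every sweep cell; failures are recorded and the sweep continues."""
    import dataclasses

    geom = build_gut_geometry(base.geometry)
    rows = []
    for mu, tc, td in spec.cells():
        T = base.schedule.T
        cfg = dataclasses.replace(
            base,
            lattice=dataclasses.replace(base.lattice, mu=mu),
            schedule=gmot.PyloricSchedule(
                T_C=tc * T, T_D=td * T, T=T,
                tac_onset_frac=base.schedule.tac_onset_frac,
                ramp_frac=base.schedule.ramp_frac,
            ),
        )
        row = {"mu": mu, "tc_frac": tc, "td_frac": td}
        try:
            b = run_simulation(cfg, geom=geom)
            m = b["metrics"]
            row.update(
                Q=m["Q_ml_min"], Q_plus=m["Q_plus_ml_min"], Q_minus=m["Q_minus_ml_min"],
                q_star=m["q_star"], M=m["mixing_efficiency_per_s"],
                open_during_tac=m["open_during_tac"],
                open_during_relaxation=m["open_during_relaxation"],
                error="",
            )
        except Exception as exc:  # noqa: BLE001 -- sweep must continue
            log.error("cell (%.3g, %.3g, %.3g) failed: %s", mu, tc, td, exc)
            row.update(error=f"{type(exc).__name__}: {exc}")
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(["mu", "tc_frac", "td_frac"]).reset_index(drop=True)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "sweep.csv", index=False)
    return df


# -- report ------------------------------------------------------------------


def make_report(bundles: list[dict] | None = None, sweep: pd.DataFrame | None = None,
                outdir: str | Path = "report") -> list[Path]:
    """Standard figures: flux time history with phase chart, emptying rate
    vs viscosity / closure duration / closure delay, coordination heat
    maps, regional emptying-probability bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not bundles and (sweep is None or sweep.empty):
        raise ValueError("nothing to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for ib, b in enumerate(bundles or []):
        rec = b["records"]
        T = b["config"].schedule.T
        fig, (ax, axp) = plt.subplots(
            2, 1, figsize=(7, 4), sharex=True, height_ratios=[3, 1]
        )
        tt = rec["t"] / T
        ax.plot(tt, rec["q_pyloric"], lw=0.8)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_ylabel("q(t) [ml/min]")
        axp.fill_between(tt, 0, rec["phi"], step="mid", alpha=0.6)
        axp.set_ylabel("pylorus\nopen frac")
        axp.set_xlabel("t / T")
        fig.tight_layout()
        p = outdir / f"flux_timeseries_{ib}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

        if b.get("tracers") is not None:
            ep = emptying_probability_from_bundle(b)
            fig, ax = plt.subplots(figsize=(6, 3))
            ax.bar(ep.regions, 100 * ep.fraction[:, -1])
            ax.set_xlabel("region (1 = terminal antrum)")
            ax.set_ylabel(f"emptied by {ep.horizons[-1]:.0f} s [%]")
            fig.tight_layout()
            p = outdir / f"emptying_probability_{ib}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)

    if sweep is not None and not sweep.empty:
        ok = sweep[sweep["error"] == ""] if "error" in sweep else sweep
        if ok["mu"].nunique() > 1:
            fig, ax = plt.subplots(figsize=(5, 3.5))
            for (tc, td), gdf in ok.groupby(["tc_frac", "td_frac"]):
                ax.semilogx(gdf["mu"], gdf["Q"], "o-",
                            label=f"T_C/T={tc:.2g}, T_D/T={td:.2g}")
            ax.set_xlabel("viscosity [Pa s]")
            ax.set_ylabel("Q [ml/min]")
            ax.legend(fontsize=6)
            fig.tight_layout()
            p = outdir / "Q_vs_viscosity.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
        for xvar, fname in (("tc_frac", "Q_vs_TC.png"), ("td_frac", "Q_vs_TD.png")):
            if ok[xvar].nunique() > 1:
                fig, ax = plt.subplots(figsize=(5, 3.5))
                for mu, gdf in ok.groupby("mu"):
                    gg = gdf.groupby(xvar)["Q"].mean()
                    ax.plot(gg.index, gg.values, "o-", label=f"mu={mu:g}")
                ax.axhline(0, color="k", lw=0.5)
                ax.set_xlabel(xvar.replace("_frac", "/T"))
                ax.set_ylabel("Q [ml/min]")
                ax.legend(fontsize=7)
                fig.tight_layout()
                p = outdir / fname
                fig.savefig(p, dpi=120)
                plt.close(fig)
                written.append(p)
        if ok["tc_frac"].nunique() > 1 and ok["td_frac"].nunique() > 1:
            for mu, gdf in ok.groupby("mu"):
                fig, axes = plt.subplots(1, 4, figsize=(13, 3))
                for ax, col in zip(axes, ("Q_minus", "Q_plus", "Q", "M")):
                    pv = gdf.pivot_table(index="td_frac", columns="tc_frac", values=col)
                    im = ax.pcolormesh(pv.columns, pv.index, pv.values, shading="nearest")
                    fig.colorbar(im, ax=ax, label=col)
                    ax.set_xlabel("T_C/T")
                    ax.set_ylabel("T_D/T")
                fig.tight_layout()
                p = outdir / f"coordination_maps_mu{mu:g}.png"
                fig.savefig(p, dpi=120)
                plt.close(fig)
                written.append(p)
    return written
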