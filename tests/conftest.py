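import warnings

import numpy as np
import pytest

from gastroflow import build_gut_geometry, voxelize

warnings.filterwarnings("ignore", message=".*reduced-resolution.*")


@pytest.fixture(scope="session")
def geom():
    """Default volume-calibrated gastroduodenal geometry (shared, read-only)."""
    return build_gut_geometry()


@pytest.fixture(scope="session")
def grid3(geom):
    """Default geometry voxelized at the reduced 3 mm spacing."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return voxelize(geom, 3.0, strict=False)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def study(geom, tmp_path_factory):
    """Coordination-study runs on the reduced lattice, computed once.

    Control (3 cycles, for the periodic-steady-state check), pylorus
    unable to close, delayed closure (1/8 and 3/8), permanent closure,
    and a plateau-viscosity point.
    """
    from gastroflow import protocol as P
    from gastroflow.runner import run_simulation

    outdir = tmp_path_factory.mktemp("ctrl_bundle")
    cases = {}
    cases["control"] = run_simulation(
        P.study_config(n_cycles=3.0, transient_cycles=1.0, tracer_count=500),
        outdir=outdir, geom=geom,
    )
    cases["control"]["outdir"] = outdir
    for name, tc, td, ncyc in [
        ("open", 0.0, 0.0, 2.0),
        ("delay_eighth", 2 / 3, 1 / 8, 2.0),
        ("delay_three_eighths", 2 / 3, 3 / 8, 2.0),
        ("closed", 1.0, 0.0, 2.0),
    ]:
        cases[name] = run_simulation(
            P.study_config(tc_frac=tc, td_frac=td, n_cycles=ncyc,
                           transient_cycles=1.0),
            geom=geom,
        )
    cases["plateau"] = run_simulation(
        P.study_config(mu=P.MU_PLATEAU, n_cycles=2.0, transient_cycles=1.0),
        geom=geom,
    )
    return cases


@pytest.fixture(scope="session")
def tracer_study(geom):
    """Re ~ 0.1 control with tracers from t = 0 (3-minute horizon)."""
    from gastroflow import protocol as P

    bundle, ep = P.run_tracer_study(seed=0, geom=geom)
    return bundle, ep


@pytest.fixture(scope="session")
def benchmarks():
    """Analytic solver benchmarks, shared between suites."""
    from gastroflow import validate as gv

    return {
        "poiseuille": gv.poiseuille_channel(n_across=24),
        "couette": gv.couette_channel(n_across=24),
        "tube": gv.tube_poiseuille(radius_cells=7.5),
        "shear_low": gv.shear_wave_decay(mu=4.2e-3),
        "shear_high": gv.shear_wave_decay(mu=4.2),
        "box": gv.closed_box_conservation(n=10, n_steps=2000),
        "quiescent": gv.quiescent_free_surface(),
        "slosh": gv.sloshing_decay(n_steps=4000),
    }
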