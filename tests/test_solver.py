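"""Solver benchmarks against analytic references, and free-surface behaviour.

Channel flows, shear-wave viscosity recovery and conservation run at small
sizes; they exercise the same kernels as the gastric problem.
"""

import numpy as np
import pytest

from gastroflow import validate as gv
from gastroflow.lbm import LatticeConfig, StabilityError


class TestChannelBenchmarks:
    def test_poiseuille_profile_within_1pct(self, benchmarks):
        assert benchmarks["poiseuille"]["max_rel_err"] < 0.01

    def test_couette_profile_within_1pct(self, benchmarks):
        assert benchmarks["couette"]["max_rel_err"] < 0.01

    def test_tube_flux_within_2pct(self, benchmarks):
        assert benchmarks["tube"]["rel_err"] < 0.02

    def test_outlet_flux_and_bookkeeping(self):
        r = gv.tube_poiseuille(radius_cells=7.5, with_outlet=True)
        assert r["rel_err"] < 0.02
        assert r["emptied_volume_ml"] > 0.0

    def test_lattice_axis_independence(self):
        rx = gv.tube_poiseuille(radius_cells=5.3, axis="x")
        rz = gv.tube_poiseuille(radius_cells=5.3, axis="z")
        assert abs(rx["q_numeric"] - rz["q_numeric"]) / rx["q_numeric"] < 0.005


class TestViscosityRecovery:
    @pytest.mark.parametrize("key", ["shear_low", "shear_high"])
    def test_shear_wave_decay_within_1pct(self, benchmarks, key):
        assert benchmarks[key]["rel_err"] < 0.01


class TestConservation:
    def test_closed_box_mass_constant_to_round_off(self, benchmarks):
        assert benchmarks["box"]["mass_drift"] < 1e-12


class TestFreeSurface:
    def test_quiescent_flat_interface_is_stationary(self, benchmarks):
        r = benchmarks["quiescent"]
        assert r["u_max_lat"] < 1e-12
        assert r["volume_drift"] < 1e-12

    def test_sloshing_tilt_decays_to_flat(self, benchmarks):
        amps = benchmarks["slosh"]["amplitude_series"]
        assert amps[-1] <= 0.25 * amps[0]
        # no sustained regrowth after flattening
        assert amps[-1] <= amps[len(amps) // 2] + 1e-9


class TestStabilityEnvelope:
    @pytest.mark.parametrize("mu", [4.2e-3, 4.2e-2, 0.42, 1.3, 4.2])
    def test_admissible_dt_exists_across_sweep(self, mu):
        # for every viscosity in the study sweep an admissible (dx, dt)
        # pair exists with tau in range and the wall Mach below cap
        config = LatticeConfig(dx=3.0, mu=mu)
        dt = config.resolve_dt(u_wall_peak=10.0)
        assert config.tau_min <= config.tau(dt) <= config.tau_max + 1e-12

    def test_inadmissible_dt_refused(self):
        config = LatticeConfig(dx=1.0, mu=4.2, dt=0.1)
        with pytest.raises(StabilityError):
            config.resolve_dt()
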