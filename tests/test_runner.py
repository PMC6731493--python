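"""Run orchestration: bundles, determinism, sweep bookkeeping, report."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from gastroflow.config import RunConfig, SweepSpec
from gastroflow.lbm import LatticeConfig
from gastroflow.runner import (
    emptying_probability_from_bundle,
    make_report,
    run_simulation,
    run_sweep,
)


def tiny_config(**kw):
    """Smallest meaningful gastric run: one measured cycle at 3 mm."""
    defaults = dict(
        lattice=LatticeConfig(dx=3.0, mu=4.2e-3, u_ref=20.0),
        n_cycles=1.2,
        transient_cycles=0.2,
        tracer_count=400,
        tracer_every=20,
        seed=11,
        record_every=8,
    )
    defaults.update(kw)
    return RunConfig(**defaults)


@pytest.fixture(scope="module")
def tiny_bundle(study):
    return study["control"]


class TestRunSimulation:
    def test_bundle_is_self_describing(self, tiny_bundle, tmp_path):
        m = tiny_bundle["metrics"]
        assert m["St"] == pytest.approx(1.0)
        assert np.isfinite(m["Q_ml_min"])
        assert m["Q_ml_min"] == pytest.approx(
            m["Q_plus_ml_min"] + m["Q_minus_ml_min"], abs=1e-9
        )
        assert m["mixing_efficiency_per_s"] > 0
        cfg2 = RunConfig.from_dict(tiny_bundle["config"].to_dict())
        assert cfg2 == tiny_bundle["config"]

    def test_emptying_probability_available(self, tiny_bundle):
        ep = emptying_probability_from_bundle(tiny_bundle)
        assert ep.fraction.shape[0] == 13
        ok = np.isfinite(ep.fraction)
        assert (ep.fraction[ok] >= 0).all() and (ep.fraction[ok] <= 1).all()
        assert (np.diff(ep.fraction, axis=1)[np.isfinite(np.diff(ep.fraction, axis=1))] >= -1e-12).all()

    def test_outputs_written(self, tiny_bundle):
        outdir = tiny_bundle["outdir"]
        assert (outdir / "config.yaml").exists()
        assert (outdir / "metrics.json").exists()
        rec = pd.read_csv(outdir / "records.csv")
        assert {"t", "q_pyloric", "phi", "dp"} <= set(rec.columns)

    def test_identical_config_reproduces_identically(self, geom):
        from gastroflow.lbm import GastricSimulation
        from gastroflow.motility import PyloricSchedule, WaveParams

        sims = []
        for _ in range(2):
            sim = GastricSimulation(
                geom, WaveParams(), PyloricSchedule.control(),
                tiny_config().lattice, free_surface=tiny_config().free_surface,
            )
            sim.run(1.5, record_every=10)
            sims.append(sim.records)
        a = pd.DataFrame(sims[0])
        b = pd.DataFrame(sims[1])
        pd.testing.assert_frame_equal(a, b)  # bit-identical


class TestSweep:
    def test_failed_cells_recorded_and_order_deterministic(self):
        # an inadmissible fixed timestep fails fast in every cell
        base = RunConfig(lattice=LatticeConfig(dx=3.0, mu=4.2, dt=0.1))
        spec = SweepSpec(mu=(4.2, 2.1), tc_frac=(0.0, 2 / 3), td_frac=(0.0,))
        df = run_sweep(spec, base)
        assert len(df) == 4
        assert (df["error"] != "").all()
        assert list(df["mu"]) == sorted(df["mu"])


class TestReport:
    def test_report_from_bundle_and_sweep(self, tiny_bundle, tmp_path):
        sweep = pd.DataFrame(
            [
                dict(mu=m, tc_frac=tc, td_frac=td, Q=1.0 + tc - td, Q_plus=2.0,
                     Q_minus=-1.0, q_star=0.01, M=0.5, open_during_tac=False,
                     open_during_relaxation=False, error="")
                for m in (4.2e-3, 1.3)
                for tc in (0.0, 1 / 3, 2 / 3)
                for td in (0.0, 1 / 4)
            ]
        )
        written = make_report([tiny_bundle], sweep, outdir=tmp_path / "rep")
        names = {p.name for p in written}
        assert "flux_timeseries_0.png" in names
        assert "Q_vs_TC.png" in names and "Q_vs_TD.png" in names
        assert any(n.startswith("coordination_maps") for n in names)

    def test_empty_report_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            make_report([], None, outdir=tmp_path)
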