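# gastroflow

Free-surface lattice Boltzmann simulation of gastric emptying, built to
quantify how the coordination between **pyloric closure** and the **antral
contraction wave** controls emptying of liquid gastric contents — including
rapid (dumping-like) emptying and retrograde (bile-reflux-like) flow from
the duodenum into the antrum.

## Who this is for

Computational physiologists and biofluid-mechanics researchers who want a
desk-scale, fully scriptable model of antro-pyloro-duodenal flow: the
gastric wall motion is *prescribed* (peristaltic wave, terminal antral
contraction, antral relaxation, and an independent pyloric open/close
schedule), and the solver measures what that motility does to the liquid.

## Model in brief

* **Geometry** — a parametric J-shaped stomach–pylorus–duodenum tube of
  revolution calibrated to physiological bulk dimensions: stomach volume
  650 ml, mean antral diameter D = 50 mm, pyloric diameter 9 mm open.
* **Motility** — contraction waves of period T = 20 s travel from the
  mid-corpus at V = 2.5 mm/s, deepening (contraction ratio ε up to 0.9)
  and widening (18 → 54 mm) and accelerating inside the terminal 30 mm
  (terminal antral contraction, TAC), then relax.  The pylorus closes for
  a duration `T_C` starting `T_D` after TAC onset; the healthy control is
  `T_C/T = 2/3`, `T_D = 0`.  Varying `(T_C, T_D)` models impaired
  antro-pyloric coordination.
* **Fluid** — D3Q19 multiple-relaxation-time lattice Boltzmann with
  moving-boundary (interpolated bounce-back) walls, a single-phase
  free-surface model for the gastric air pocket (interface mass tracking
  with a flattening force), hydrostatic-equilibrium gravity handling (no
  net gravity-driven transpyloric gradient), and a constant-pressure
  duodenal outlet.  Liquid density ρ = 1000 kg/m³; viscosity sweeps
  4.2 mPa·s (water-like, Re = ρVD/μ ≈ 30) to 4.2 Pa·s (honey-like).
* **Outputs** — instantaneous transpyloric flux q(t) and its
  cycle-averaged decomposition `Q = Q⁺ + Q⁻` (anterograde/retrograde,
  ml/min; dimensionless form Q/D²V), transpyloric pressure difference from
  probes ±5 mm of the pylorus, mixing efficiency (liquid-mean strain-rate
  magnitude √(2S:S)), Lagrangian tracers with per-region emptying
  probability (stomach split into 13 regions by distance from the
  pylorus), and the dimensionless numbers St = D/VT (= 1) and Re.

See `docs/methods.md` for the numerical details and modelling choices.

## Worked example

```python
from gastroflow.config import RunConfig
from gastroflow.lbm import FreeSurfaceModel, LatticeConfig
from gastroflow.motility import PyloricSchedule
from gastroflow.runner import run_simulation

cfg = RunConfig(
    lattice=LatticeConfig(dx=3.0, mu=4.2e-3, u_ref=20.0),  # reduced 3 mm lattice
    schedule=PyloricSchedule.control(),                    # T_C/T = 2/3, T_D = 0
    free_surface=FreeSurfaceModel(k_flat=50.0, accel_cap=0.002),
    n_cycles=3, transient_cycles=1,
)
bundle = run_simulation(cfg)
m = bundle["metrics"]
print(f"Q  = {m['Q_ml_min']:.2f} ml/min  (Q+ = {m['Q_plus_ml_min']:.2f}, "
      f"Q- = {m['Q_minus_ml_min']:.2f})")
print(f"q* = {m['q_star']:.4f}   St = {m['St']:.1f}   Re = {m['Re']:.0f}")
```

prints (reduced 3 mm lattice; absolute rates converge from below with
resolution, see the methods note):

```
Q  = 2.46 ml/min  (Q+ = 2.46, Q- = -0.00)
q* = 0.0066   St = 1.0   Re = 30
```

i.e. the healthy control empties a few ml/min, almost entirely
anterograde.  Setting `PyloricSchedule(T_C=0.0)` (a pylorus unable to
close) raises Q to ~8.8 ml/min with strong retrograde flow during antral
relaxation; a closure delay of `T_D/T = 1/8` (pylorus open during the
TAC) raises emptying to ~4.0 ml/min through a terminal-antral expulsion
jet, and `T_D/T = 3/8` (pylorus open only around antral relaxation)
drives net *reverse* emptying (~-1.9 ml/min, the bile-reflux surrogate).

The same runs are available from the shell:

```bash
gastroflow run --mode reduced3d --out run_out      # one simulation bundle
gastroflow sweep --out sweep_out                   # (mu, T_C/T, T_D/T) grid
gastroflow tracers --count 20000 --out tracer_out  # emptying probability
gastroflow report --sweep-csv sweep_out/sweep.csv  # figures
gastroflow validate                                # analytic benchmarks
```

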