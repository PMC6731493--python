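"""Prescribed gastroduodenal wall motion.

Each antral contraction cycle (period ``T``) has three phases:

* **peristaltic contraction** — an occlusive wave initiated at the
  mid-corpus travels toward the pylorus at speed ``V(d)`` (``d`` = centerline
  distance from the pylorus), with occlusion depth ``eps(d)`` and width
  ``w(d)`` growing as it approaches the terminal antrum;
* **terminal antral contraction (TAC)** — inside the terminal zone
  (``d < tac_zone``) the wave accelerates and widens (18 -> 54 mm),
  contracting the terminal antrum near-simultaneously;
* **antral relaxation** — after the front reaches the pylorus the deposited
  occlusion decays smoothly back to the rest shape over
  ``relax_fraction * T``.

The pylorus opens and closes on an independent trapezoidal schedule with
closure duration ``T_C`` and delay ``T_D`` measured from TAC onset; varying
(``T_C``, ``T_D``) models impaired antro-pyloric coordination.

The lumen radius is ``r(s, t) = r0(s) * (1 - eps_eff(s, t)) * pf(s, t)``
where ``pf`` is the pyloric closure factor (1 away from the sphincter).
Radial wall velocity is the analytic time derivative of this product.
Lengths mm, times s, speeds mm/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gastroflow.geometry import GutGeometry


@dataclass(frozen=True)
class WaveParams:
    """Antral contraction-wave parameters.

    ``epsilon_profile`` and ``velocity_profile`` are (distance-from-pylorus,
    value) knots, linearly interpolated, constant beyond the end knots.  The
    defaults encode a wave whose occlusion deepens from 0.3 at the
    mid-corpus origin to 0.9 at the pylorus and whose speed ramps from
    ``V_prox`` outside the TAC zone to ``tac_peak_multiplier * V_prox`` at
    the pylorus, giving a ~0.2 T TAC transit.
    """

    V_prox: float = 2.5  # mm/s, proximal propagation speed
    T: float = 20.0  # s, contraction period
    w_prox: float = 18.0  # mm, contraction width outside the TAC zone
    w_max: float = 54.0  # mm, contraction width at the pylorus
    tac_zone: float = 30.0  # mm from the pylorus
    tac_peak_multiplier: float = 7.0  # speed multiplier at the pylorus
    origin_d: float = 110.0  # mm, wave initiation distance (mid-corpus)
    sphincter_margin: float = 6.0  # mm; occlusion fades out over this span
    # above the pyloric sphincter, whose radius is governed only by the
    # open/close schedule (a wave crushing the canal would defeat T_C = 0)
    relax_fraction: float = 0.2  # antral relaxation duration / T
    onset_fraction: float = 0.2  # fraction of T over which a new wave grows in
    tac_onset_frac: float = 0.6  # cycle phase at which the front enters the TAC zone
    eps_max: float = 0.95  # occlusion cap: the antrum never fully closes
    epsilon_profile: tuple[tuple[float, float], ...] = (
        (0.0, 0.9),
        (110.0, 0.3),
    )
    velocity_profile: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if min(self.V_prox, self.T, self.w_prox, self.w_max, self.tac_zone) <= 0:
            raise ValueError("wave speeds, period and widths must be > 0")
        if self.w_max < self.w_prox:
            raise ValueError("w_max must be >= w_prox")
        eps = np.array([e for _, e in self.epsilon_profile])
        if np.any((eps < 0) | (eps > 1)):
            raise ValueError("contraction ratio knots must lie in [0, 1]")
        if self.velocity_profile is None:
            object.__setattr__(
                self,
                "velocity_profile",
                ((0.0, self.tac_peak_multiplier), (self.tac_zone, 1.0)),
            )

    # -- profiles over distance-from-pylorus -------------------------------

    def epsilon(self, d) -> np.ndarray:
        """Contraction ratio (degree of occlusion) carried by a front at d."""
        xs = np.array([k[0] for k in self.epsilon_profile])
        ys = np.array([k[1] for k in self.epsilon_profile])
        return np.interp(np.asarray(d, float), xs, ys)

    def width(self, d) -> np.ndarray:
        """Contraction width w(d): w_prox outside the TAC zone, linear to w_max."""
        d = np.asarray(d, float)
        frac = np.clip(1.0 - d / self.tac_zone, 0.0, 1.0)
        return self.w_prox + (self.w_max - self.w_prox) * frac

    def speed(self, d) -> np.ndarray:
        """Propagation speed V(d) = V_prox * multiplier(d)."""
        xs = np.array([k[0] for k in self.velocity_profile])
        ys = np.array([k[1] for k in self.velocity_profile])
        mult = np.interp(np.asarray(d, float), xs, ys)
        return self.V_prox * mult


@dataclass(frozen=True)
class PyloricSchedule:
    """Pyloric open/close timing.

    The closure interval per cycle is ``[tac_onset_frac*T + T_D,
    ... + T_C)`` wrapped modulo ``T``: the pylorus *begins* to close at the
    interval start and *begins* to open at its end, each transition a
    linear ramp of width ``ramp_frac*T`` following the endpoint.  The
    time-averaged open fraction is exactly ``1 - T_C/T``.  ``T_C = 0``
    keeps the pylorus permanently open (impaired closure); ``T_C = T``
    permanently closed.
    """

    T_C: float  # s, closure duration
    T_D: float = 0.0  # s, closure delay from TAC onset
    T: float = 20.0  # s, cycle period
    tac_onset_frac: float = 0.6
    ramp_frac: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.T_C <= self.T):
            raise ValueError("need 0 <= T_C <= T")
        if not (0.0 <= self.T_D <= self.T):
            raise ValueError("need 0 <= T_D <= T")

    @classmethod
    def control(cls, T: float = 20.0) -> "PyloricSchedule":
        """Healthy coordination: T_C/T = 2/3, no delay."""
        return cls(T_C=2.0 * T / 3.0, T_D=0.0, T=T)

    def closedness(self, t) -> np.ndarray:
        """Trapezoidal closure indicator c(t) in [0, 1]; open fraction = 1 - c."""
        t = np.asarray(t, float)
        if self.T_C <= 0:
            return np.zeros_like(t)
        if self.T_C >= self.T:
            return np.ones_like(t)
        rho = max(min(self.ramp_frac * self.T, self.T_C, self.T - self.T_C), 1e-12)
        a = self.tac_onset_frac * self.T + self.T_D
        u = np.mod(t - a, self.T)
        c = np.zeros_like(u)
        for shift in (0.0, self.T):
            v = u - shift
            # rises 0->1 on [0, rho], 1 on [rho, T_C], falls on [T_C, T_C+rho]
            c = np.maximum(
                c,
                np.clip(np.minimum(v / rho, (self.T_C + rho - v) / rho), 0.0, 1.0),
            )
        return c

    def closedness_rate(self, t) -> np.ndarray:
        """dc/dt of the trapezoid (piecewise constant, +/- 1/ramp)."""
        t = np.asarray(t, float)
        if self.T_C <= 0 or self.T_C >= self.T:
            return np.zeros_like(t)
        rho = max(min(self.ramp_frac * self.T, self.T_C, self.T - self.T_C), 1e-12)
        a = self.tac_onset_frac * self.T + self.T_D
        u = np.mod(t - a, self.T)
        out = np.zeros_like(u)
        out[(u > 0.0) & (u < rho)] = 1.0 / rho
        out[(u > self.T_C) & (u < self.T_C + rho)] = -1.0 / rho
        return out


def pylorus_open_fraction(t, sched: PyloricSchedule) -> np.ndarray:
    """Open fraction phi(t) in [0, 1]: 1 fully open, 0 fully closed."""
    return 1.0 - sched.closedness(t)


# -- wave-front kinematics --------------------------------------------------


class _FrontKinematics:
    """Transit-time table for a single contraction front.

    Solves ds/dt = -V(s) from the origin by quadrature of dt = dd / V(d)
    on a fine grid, giving front distance as a function of wave age and
    vice versa.
    """

    def __init__(self, wave: WaveParams) -> None:
        self.wave = wave
        d = np.linspace(0.0, wave.origin_d, 4001)[::-1]  # origin -> pylorus
        v = wave.speed(d)
        # transit time from origin down to each d
        dt = -np.diff(d) / (0.5 * (v[:-1] + v[1:]))
        self.tau = np.r_[0.0, np.cumsum(dt)]  # increasing with decreasing d
        self.d_grid = d
        self.total_transit = float(self.tau[-1])
        self.tac_entry = float(np.interp(wave.tac_zone, d[::-1], self.tau[::-1]))
        self.tac_transit = self.total_transit - self.tac_entry
        self.relax_time = wave.relax_fraction * wave.T
        # waves initiate so that a front enters the TAC zone at cycle phase
        # tac_onset_frac (TAC begins at cycle phase 0.6)
        self.t_init = wave.tac_onset_frac * wave.T - self.tac_entry

    def front_distance(self, age) -> np.ndarray:
        """Front distance-from-pylorus at wave age (held at 0 after arrival)."""
        age = np.asarray(age, float)
        return np.interp(age, self.tau, self.d_grid)

    def envelope(self, age) -> np.ndarray:
        """Amplitude envelope A(age): smooth growth over onset_fraction*T,
        1 while travelling, cos^2 decay over the relaxation time after
        arrival at the pylorus."""
        age = np.asarray(age, float)
        t_on = max(self.wave.onset_fraction * self.wave.T, 1e-9)
        y = np.clip(age / t_on, 0.0, 1.0)
        grow = np.sin(0.5 * np.pi * y) ** 2
        x = np.clip((age - self.total_transit) / self.relax_time, 0.0, 1.0)
        decay = np.cos(0.5 * np.pi * x) ** 2
        return grow * decay

    def envelope_rate(self, age) -> np.ndarray:
        age = np.asarray(age, float)
        t_on = max(self.wave.onset_fraction * self.wave.T, 1e-9)
        y = age / t_on
        x = (age - self.total_transit) / self.relax_time
        out = np.zeros_like(age)
        m = (y > 0.0) & (y < 1.0)
        out[m] = 0.5 * np.pi / t_on * np.sin(np.pi * y[m])
        m = (x > 0.0) & (x < 1.0)
        out[m] = -0.5 * np.pi / self.relax_time * np.sin(np.pi * x[m])
        return out

    def active_ages(self, t: float) -> np.ndarray:
        """Ages of all waves alive at absolute time t (travel + relaxation)."""
        T = self.wave.T
        life = self.total_transit + self.relax_time
        k_lo = int(np.floor((t - self.t_init - life) / T))
        k_hi = int(np.floor((t - self.t_init) / T))
        ages = np.array([t - (self.t_init + k * T) for k in range(k_lo, k_hi + 1)])
        return ages[(ages >= 0.0) & (ages < life)]


def wave_front_position(t: float, wave: WaveParams, geom: GutGeometry | None = None) -> np.ndarray:
    """Distances-from-pylorus of all active contraction fronts at time t.

    Fronts that have completed their TAC transit are reported at 0 while
    their relaxation envelope decays.  One new wave initiates every T.
    """
    kin = _FrontKinematics(wave)
    ages = kin.active_ages(float(t))
    return np.sort(kin.front_distance(ages))


def front_distance(age: float, wave: WaveParams) -> float:
    """Distance-from-pylorus of a single front of the given age."""
    return float(_FrontKinematics(wave).front_distance(age))


def contraction_width(s, wave: WaveParams) -> np.ndarray:
    """Contraction width at arclength s (= distance from pylorus in the stomach)."""
    return wave.width(np.abs(np.asarray(s, float)))


def _bump(xi: np.ndarray) -> np.ndarray:
    """C1 unit bump g(xi) = cos^2(pi xi / 2) on |xi| <= 1."""
    out = np.zeros_like(xi)
    m = np.abs(xi) < 1.0
    out[m] = np.cos(0.5 * np.pi * xi[m]) ** 2
    return out


def _bump_prime(xi: np.ndarray) -> np.ndarray:
    out = np.zeros_like(xi)
    m = np.abs(xi) < 1.0
    out[m] = -0.5 * np.pi * np.sin(np.pi * xi[m])
    return out


class MotilityEvaluator:
    """Occlusion field and wall kinematics on a fixed set of arclength samples.

    Precomputes the static per-sample profiles (rest radius, occlusion
    depth, width) so that per-timestep evaluation only involves the few
    active fronts.  This is the object the solver queries every step.
    """

    def __init__(
        self,
        geom: GutGeometry,
        wave: WaveParams | None,
        sched: PyloricSchedule,
        s: np.ndarray,
    ) -> None:
        self.geom = geom
        self.wave = wave
        self.sched = sched
        self.s = np.asarray(s, float)
        self.r0 = np.asarray(geom.r0(self.s), float)
        d = np.where(self.s > 0, self.s, np.inf)  # occlusion acts on the stomach side
        self._d = d
        self.kin = _FrontKinematics(wave) if wave is not None else None
        # pyloric closure factor support
        half = geom.params.pylorus_length / 2.0
        self._pyl_bump = np.where(
            np.abs(self.s) <= half,
            np.cos(np.pi * self.s / (2.0 * half)) ** 2,
            0.0,
        )
        # sphincter mask: occlusion does not act on the pyloric canal
        if wave is not None:
            x = np.clip((self.s - half) / max(wave.sphincter_margin, 1e-9), 0.0, 1.0)
            self._sph_mask = np.sin(0.5 * np.pi * x) ** 2
        else:
            self._sph_mask = np.ones_like(self.s)

    def eps_eff_static(self, t: float) -> np.ndarray:
        """Effective occlusion over the samples at time t.

        The bump carries the *front's* depth and width -- the contraction
        ratio and width grow as the wave itself approaches the pylorus --
        so the terminal antral squeeze is concentrated in the TAC window
        rather than pre-compressing the terminal antrum while the front is
        still proximal.
        """
        n = len(self.s)
        if self.kin is None:
            return np.zeros(n)
        eps = np.zeros(n)
        for age in self.kin.active_ages(float(t)):
            d_f = float(self.kin.front_distance(age))
            A = float(self.kin.envelope(age))
            eps_f = float(self.wave.epsilon(d_f))
            w_f = float(self.wave.width(d_f))
            with np.errstate(invalid="ignore"):
                xi = (self._d - d_f) / w_f
            xi = np.where(np.isfinite(xi), xi, 2.0)
            contrib = eps_f * _bump(xi) * A
            np.maximum(eps, contrib, out=eps)  # concurrent fronts: elementwise max
        return np.minimum(eps, self.wave.eps_max) * self._sph_mask

    def eps_eff(self, t: float, delta: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
        """(eps_eff, d(eps_eff)/dt) at time t; rate by central difference."""
        eps = self.eps_eff_static(t)
        if self.kin is None:
            return eps, np.zeros_like(eps)
        deps = (self.eps_eff_static(t + delta) - self.eps_eff_static(t - delta)) / (2 * delta)
        return eps, deps

    def radius(self, t: float) -> tuple[np.ndarray, np.ndarray, float]:
        """(r(s,t), dr/dt(s,t), phi(t)) over the samples."""
        eps, deps = self.eps_eff(t)
        phi = float(pylorus_open_fraction(t, self.sched))
        phidot = -float(self.sched.closedness_rate(t))
        pf = 1.0 - (1.0 - phi) * self._pyl_bump
        r = self.r0 * (1.0 - eps) * pf
        drdt = self.r0 * (-deps * pf + (1.0 - eps) * phidot * self._pyl_bump)
        return r, drdt, phi


def occlusion_field(s, t: float, wave: WaveParams) -> np.ndarray:
    """Effective contraction ratio eps_eff(s, t) from all active fronts.

    Each front contributes ``eps(d_f) g((d - d_f)/w(d_f)) A(age)``: the
    occlusion depth and width are those of the wave at its current
    position (they grow as the wave approaches the pylorus), the bump g is
    a C1 cos^2 unit bump, and A is the onset/relaxation envelope.
    """
    s = np.atleast_1d(np.asarray(s, float))
    kin = _FrontKinematics(wave)
    d = np.abs(s)
    eps = np.zeros_like(d)
    for age in kin.active_ages(float(t)):
        d_f = float(kin.front_distance(age))
        xi = (d - d_f) / float(wave.width(d_f))
        contrib = float(wave.epsilon(d_f)) * _bump(xi) * float(kin.envelope(age))
        eps = np.maximum(eps, contrib)
    half = 6.0  # default pyloric half-length; canal is schedule-governed
    mask = np.sin(0.5 * np.pi * np.clip((d - half) / max(wave.sphincter_margin, 1e-9), 0, 1)) ** 2
    return np.minimum(eps, wave.eps_max) * mask


@dataclass
class WallState:
    """Instantaneous wall kinematics sampled on arclength quadrature points."""

    t: float
    s: np.ndarray  # arclength samples (mm)
    r: np.ndarray  # instantaneous lumen radius (mm)
    drdt: np.ndarray  # radial wall velocity (mm/s, positive outward)
    pylorus_open_fraction: float


def wall_state(
    t: float,
    geom: GutGeometry,
    wave: WaveParams | None,
    sched: PyloricSchedule,
    s: np.ndarray | None = None,
) -> WallState:
    """Evaluate r(s, t) and dr/dt on quadrature points (default: 1 mm grid)."""
    if s is None:
        s = np.arange(geom.s_min, geom.s_max, 1.0)
    ev = MotilityEvaluator(geom, wave, sched, s)
    r, drdt, phi = ev.radius(float(t))
    return WallState(t=float(t), s=ev.s, r=r, drdt=drdt, pylorus_open_fraction=phi)


# -- coordination predicates (T_C, T_D bookkeeping) --------------------------


def tac_window(wave: WaveParams) -> tuple[float, float]:
    """(start, end) cycle times of the terminal antral contraction."""
    kin = _FrontKinematics(wave)
    start = wave.tac_onset_frac * wave.T
    return start, start + kin.tac_transit


def relaxation_window(wave: WaveParams) -> tuple[float, float]:
    """(start, end) cycle times of antral relaxation (follows TAC)."""
    _, tac_end = tac_window(wave)
    return tac_end, tac_end + wave.relax_fraction * wave.T


def _open_time_in_window(sched: PyloricSchedule, a: float, b: float) -> float:
    """Time within [a, b] during which the pylorus is open (interval
    arithmetic on the ideal rectangular schedule, ramps ignored)."""
    T = sched.T
    c0 = sched.tac_onset_frac * T + sched.T_D
    open_t = 0.0
    n = 2000
    for t in np.linspace(a, b, n, endpoint=False):
        u = np.mod(t - c0, T)
        if u >= sched.T_C:
            open_t += (b - a) / n
    return open_t


def open_during_tac(sched: PyloricSchedule, wave: WaveParams, min_frac: float = 0.05) -> bool:
    """True when the pylorus is open during a meaningful part of the TAC.

    Computable from (T_C, T_D) alone; ``min_frac`` of the TAC window
    ignores the sliver of a closing ramp that begins exactly at TAC onset
    (the control case counts as closed-during-TAC).
    """
    a, b = tac_window(wave)
    return _open_time_in_window(sched, a, b) > min_frac * (b - a)


def open_during_relaxation(sched: PyloricSchedule, wave: WaveParams) -> bool:
    """True when the pylorus is open for more than half the relaxation phase."""
    a, b = relaxation_window(wave)
    return _open_time_in_window(sched, a, b) > 0.5 * (b - a)
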