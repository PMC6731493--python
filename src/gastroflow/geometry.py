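"""Parametric gastroduodenal geometry.

The stomach--pylorus--duodenum lumen is modelled as a tube of revolution
around a smooth centerline: a J-shaped gastric centerline (antrum low,
corpus/fundus rising, gravity along -z) joined at the pyloric midpoint to a
straight duodenal segment along +x.  The centerline is parametrized by
signed arclength ``s`` (mm): ``s = 0`` at the pyloric midpoint, ``s > 0``
proximally into the stomach, ``s < 0`` into the duodenum.

The rest lumen radius ``r0(s)`` interpolates monotone-cubically (C1)
between knots.  Bulk dimensions are calibrated to physiological values:
stomach volume ~650 ml, mean antral diameter D = 50 mm, pyloric diameter
9 mm when open.  Because no two anatomies agree on corpus length or
duodenal calibre, those defaults are documented assumptions
(see ``docs/methods.md``), exposed in :class:`GeometryParams`.

All lengths in mm, volumes in ml (1 ml = 1000 mm^3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.optimize import brentq
from scipy.spatial import cKDTree


class GeometryError(ValueError):
    """Invalid geometry parameters or unresolvable geometry."""


class VolumeCalibrationError(GeometryError):
    """Radius-profile rescaling could not reach the target stomach volume."""


class ResolutionError(GeometryError):
    """Grid spacing too coarse to resolve the lumen."""


# Default gastric centerline control points (x, y, z) in mm, pylorus at the
# origin, antrum nearly horizontal, corpus/fundus rising in +z.  The duodenum
# is generated separately as a straight +x tube.
_DEFAULT_CENTERLINE: tuple[tuple[float, float, float], ...] = (
    (0.0, 0.0, 0.0),
    (-30.0, 0.0, 4.0),
    (-65.0, 0.0, 14.0),
    (-95.0, 0.0, 32.0),
    (-118.0, 0.0, 62.0),
    (-128.0, 0.0, 100.0),
    (-122.0, 0.0, 140.0),
    (-102.0, 0.0, 172.0),
    (-75.0, 0.0, 192.0),
)

# (arclength from pylorus, rest radius) knots for the gastric lumen.  Radii at
# s >= corpus_scale_min_s are rescaled during volume calibration.
_DEFAULT_RADIUS_KNOTS: tuple[tuple[float, float], ...] = (
    (0.0, 4.5),
    (6.0, 4.5),
    (20.0, 13.0),
    (40.0, 22.0),
    (60.0, 25.0),
    (95.0, 25.0),
    (125.0, 29.0),
    (160.0, 35.0),
    (200.0, 37.0),
    (235.0, 34.0),
    (262.0, 24.0),
    (280.0, 12.0),
)

ML = 1000.0  # mm^3 per ml


@dataclass(frozen=True)
class GeometryParams:
    """Bulk dimensions and profile knots of the gastroduodenal model."""

    stomach_volume_target: float = 650.0  # ml
    antral_diameter_D: float = 50.0  # mm
    pylorus_diameter_open: float = 9.0  # mm
    pylorus_length: float = 12.0  # mm, axial extent of the sphincter
    duodenum_diameter: float = 25.0  # mm
    duodenum_length: float = 120.0  # mm
    centerline_control_points: tuple[tuple[float, float, float], ...] = _DEFAULT_CENTERLINE
    radius_knots: tuple[tuple[float, float], ...] = _DEFAULT_RADIUS_KNOTS
    corpus_scale_min_s: float = 110.0  # knots above this arclength are calibrated
    fundus_cap_radius: float = 4.0  # mm, lumen radius at the fundus apex

    def __post_init__(self) -> None:
        for name in (
            "stomach_volume_target",
            "antral_diameter_D",
            "pylorus_diameter_open",
            "pylorus_length",
            "duodenum_diameter",
            "duodenum_length",
        ):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be > 0")
        if len(self.centerline_control_points) < 2:
            raise GeometryError("centerline needs at least two control points")
        ss = [k[0] for k in self.radius_knots]
        if any(b <= a for a, b in zip(ss, ss[1:])):
            raise GeometryError("radius knot arclengths must be strictly increasing")
        if any(k[1] <= 0 for k in self.radius_knots):
            raise GeometryError("radius knots must be positive")


@dataclass(frozen=True)
class RegionLabels:
    """Partition of the stomach lumen by centerline distance from the pylorus.

    Region 1 is nearest the pylorus (terminal antrum); region ``n_regions``
    is the fundus apex.  Label 0 marks non-stomach voxels.
    """

    n_regions: int
    boundaries: np.ndarray  # arclength cut points, length n_regions + 1
    labels: np.ndarray  # int array on the voxel grid, 0 outside the stomach

    def counts(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.n_regions + 1)[1:]


@dataclass
class VoxelGrid:
    """Node-centred Cartesian lattice classification of a :class:`GutGeometry`.

    A node is lumen when its rest signed distance is negative (half-open
    convention: nodes exactly on the surface are wall).  ``s`` and ``d``
    give each node's nearest-centerline arclength and distance, which is
    all the moving-wall solver needs to re-evaluate the wall each step,
    since the wall only ever moves radially inward from rest.
    """

    spacing: float
    origin: np.ndarray  # (3,)
    shape: tuple[int, int, int]
    lumen: np.ndarray  # bool, rest-state lumen
    wall: np.ndarray  # bool, non-lumen nodes within one cell of lumen
    outside: np.ndarray  # bool, the rest
    s: np.ndarray  # float32, nearest-centerline arclength (signed, mm)
    d: np.ndarray  # float32, distance to centerline (mm)
    sd_rest: np.ndarray  # float32, rest signed distance d - r0(s)
    e_r: np.ndarray  # float32 (nx,ny,nz,3), outward radial unit vector
    stomach: np.ndarray  # bool, lumen voxels with s > 0
    duodenum: np.ndarray  # bool, lumen voxels with s < 0

    def node_coords(self, mask: np.ndarray) -> np.ndarray:
        idx = np.argwhere(mask)
        return self.origin[None, :] + idx * self.spacing

    @property
    def lumen_volume(self) -> float:
        """Voxel estimate of the rest lumen volume (ml)."""
        return float(self.lumen.sum()) * self.spacing**3 / ML

    @property
    def stomach_volume(self) -> float:
        return float(self.stomach.sum()) * self.spacing**3 / ML


class GutGeometry:
    """Tube-of-revolution lumen with signed-distance and region queries.

    Built by :func:`build_gut_geometry` or :func:`make_tube_fixture`; not
    constructed directly in normal use.
    """

    def __init__(
        self,
        params: GeometryParams,
        centerline_pts: np.ndarray,
        centerline_s: np.ndarray,
        r0_interp,
        s_min: float,
        s_max: float,
        planar: bool = False,
    ) -> None:
        self.params = params
        self._pts = centerline_pts  # dense samples, (N, 3)
        self._s = centerline_s  # arclength at samples, (N,)
        self._r0 = r0_interp  # callable s -> radius
        self.s_min = float(s_min)  # duodenal end (negative)
        self.s_max = float(s_max)  # fundus apex
        self.planar = planar  # 2-D channel mode: distance measured in z only
        self._tree = cKDTree(centerline_pts)
        self._tangents = np.gradient(centerline_pts, centerline_s, axis=0)
        norms = np.linalg.norm(self._tangents, axis=1, keepdims=True)
        self._tangents /= np.maximum(norms, 1e-12)

    # -- centerline queries -------------------------------------------------

    def r0(self, s) -> np.ndarray:
        """Rest lumen radius at arclength ``s`` (mm)."""
        return np.asarray(self._r0(np.clip(s, self.s_min, self.s_max)))

    def point(self, s) -> np.ndarray:
        s = np.clip(np.atleast_1d(s), self.s_min, self.s_max)
        out = np.empty((len(s), 3))
        for k in range(3):
            out[:, k] = np.interp(s, self._s, self._pts[:, k])
        return out

    def tangent(self, s) -> np.ndarray:
        s = np.clip(np.atleast_1d(s), self.s_min, self.s_max)
        out = np.empty((len(s), 3))
        for k in range(3):
            out[:, k] = np.interp(s, self._s, self._tangents[:, k])
        out /= np.maximum(np.linalg.norm(out, axis=1, keepdims=True), 1e-12)
        return out

    def nearest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Nearest-centerline (s, d, e_r) for each query point.

        ``e_r`` is the outward radial unit vector (from centerline to point).
        In planar mode the distance is measured along z only (parallel-plate
        channel) and ``e_r`` is +/-z.
        """
        points = np.atleast_2d(points)
        if self.planar:
            z0 = self._pts[0, 2]
            dz = points[:, 2] - z0
            d = np.abs(dz)
            s = points[:, 0] - self._pts[0, 0] + self._s[0]
            e_r = np.zeros_like(points)
            e_r[:, 2] = np.sign(dz)
            return np.clip(s, self.s_min, self.s_max), d, e_r
        d, idx = self._tree.query(points, workers=-1)
        diff = points - self._pts[idx]
        # refine: remove the axial component along the local tangent so d is
        # the true radial distance, with rounded caps beyond the ends
        t_hat = self._tangents[idx]
        axial = np.einsum("ij,ij->i", diff, t_hat)
        s_new = self._s[idx] + axial
        s = np.clip(s_new, self.s_min, self.s_max)
        over = s_new - s
        radial = diff - axial[:, None] * t_hat
        d_perp = np.linalg.norm(radial, axis=1)
        # flat end caps: beyond the ends, report a distance that keeps the
        # point outside (sd = d - r0 >= |overshoot|)
        r_end = np.asarray(self._r0(s))
        d = np.where(np.abs(over) > 0, r_end + np.maximum(d_perp - r_end, np.abs(over)), d_perp)
        e_r = radial / np.maximum(d_perp[:, None], 1e-12)
        return s, d, e_r

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Rest signed distance to the lumen wall; negative inside."""
        s, d, _ = self.nearest(points)
        return d - self.r0(s)

    # -- bulk measures ------------------------------------------------------

    def stomach_volume_analytic(self) -> float:
        """Enclosed stomach volume (ml) from the Pappus integral of pi r0^2 ds."""
        s = np.linspace(0.0, self.s_max, 4000)
        return float(np.trapezoid(np.pi * self.r0(s) ** 2, s)) / ML

    def duodenum_volume_analytic(self) -> float:
        s = np.linspace(self.s_min, 0.0, 1000)
        return float(np.trapezoid(np.pi * self.r0(s) ** 2, s)) / ML

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        r = self.r0(self._s)
        if self.planar:
            lo = self._pts.min(axis=0) - np.array([0.0, 0.0, r.max()])
            hi = self._pts.max(axis=0) + np.array([0.0, 0.0, r.max()])
        else:
            lo = (self._pts - r[:, None]).min(axis=0)
            hi = (self._pts + r[:, None]).max(axis=0)
        return lo, hi

    def region_of(self, points: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
        """Region id (1-based; 0 = not stomach) for query points."""
        s, _, _ = self.nearest(points)
        reg = np.searchsorted(boundaries, s, side="right")
        reg[(s <= boundaries[0]) | (s > boundaries[-1])] = 0
        return reg

    # -- lattice ------------------------------------------------------------

    def voxelize(self, spacing: float, strict: bool = True, margin: float | None = None) -> VoxelGrid:
        return voxelize(self, spacing, strict=strict, margin=margin)


def _resample_arclength(control_points: np.ndarray, step: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic spline through control points, resampled by arclength."""
    cp = np.asarray(control_points, float)
    if len(cp) == 2:
        length = np.linalg.norm(cp[1] - cp[0])
        n = max(int(length / step), 2)
        t = np.linspace(0, 1, n)
        pts = cp[0] + t[:, None] * (cp[1] - cp[0])
        return pts, t * length
    chord = np.r_[0, np.cumsum(np.linalg.norm(np.diff(cp, axis=0), axis=1))]
    spl = CubicSpline(chord, cp, axis=0)
    tt = np.linspace(0, chord[-1], 40 * len(cp))
    fine = spl(tt)
    seg = np.linalg.norm(np.diff(fine, axis=0), axis=1)
    arc = np.r_[0, np.cumsum(seg)]
    n = max(int(arc[-1] / step), 2)
    s_new = np.linspace(0, arc[-1], n)
    t_new = np.interp(s_new, arc, tt)
    return spl(t_new), s_new


def build_gut_geometry(params: GeometryParams | None = None) -> GutGeometry:
    """Build the parametric gastroduodenal geometry, volume-calibrated.

    The gastric radius-profile knots at arclength >= ``corpus_scale_min_s``
    are rescaled by a single factor so that the Pappus volume integral of
    the stomach hits ``stomach_volume_target`` exactly; a target out of
    reach within [0.4x, 2.5x] rescaling raises
    :class:`VolumeCalibrationError` naming the achieved volume.  The
    returned geometry keeps the antral diameter and pyloric calibre fixed.
    """
    params = params or GeometryParams()
    stomach_pts, stomach_s = _resample_arclength(np.array(params.centerline_control_points))
    s_max = stomach_s[-1]

    # duodenum: straight tube along +x from the pylorus
    p0 = np.array(params.centerline_control_points[0], float)
    n_d = max(int(params.duodenum_length / 0.5), 2)
    duo_s = np.linspace(0, params.duodenum_length, n_d)[1:]
    duo_pts = p0[None, :] + duo_s[:, None] * np.array([1.0, 0.0, 0.0])

    pts = np.vstack([duo_pts[::-1], stomach_pts])
    s_signed = np.r_[-duo_s[::-1], stomach_s]
    s_min = s_signed[0]

    r_pyl = params.pylorus_diameter_open / 2.0
    r_duo = params.duodenum_diameter / 2.0
    half_p = params.pylorus_length / 2.0
    taper = 3.0 * half_p

    def make_r0(scale: float):
        knots = [(s, r) for s, r in params.radius_knots if s < s_max - 1.0]
        knots.append((s_max, params.fundus_cap_radius))
        ks = np.array([k[0] for k in knots])
        kr = np.array(
            [r * (scale if s >= params.corpus_scale_min_s else 1.0) for s, r in knots]
        )
        stomach_interp = PchipInterpolator(ks, kr)
        # duodenal side: pyloric calibre across the sphincter, then taper to
        # the duodenal calibre
        duo_knots_s = np.array([s_min, -half_p - taper, -half_p, 0.0])
        duo_knots_r = np.array([r_duo, r_duo, r_pyl, r_pyl])
        duo_interp = PchipInterpolator(duo_knots_s, duo_knots_r)

        def r0(s):
            s = np.atleast_1d(np.asarray(s, float))
            out = np.where(s >= 0, stomach_interp(np.clip(s, 0, s_max)), duo_interp(np.clip(s, s_min, 0)))
            return out

        return r0

    def volume_ml(scale: float) -> float:
        r0 = make_r0(scale)
        s = np.linspace(0.0, s_max, 4000)
        return float(np.trapezoid(np.pi * r0(s) ** 2, s)) / ML

    target = params.stomach_volume_target
    lo, hi = 0.4, 2.5
    f_lo, f_hi = volume_ml(lo) - target, volume_ml(hi) - target
    if f_lo * f_hi > 0:
        achieved = volume_ml(1.0)
        raise VolumeCalibrationError(
            f"cannot reach stomach volume {target} ml by radius rescaling; "
            f"achieved {achieved:.1f} ml at unit scale"
        )
    scale = brentq(lambda x: volume_ml(x) - target, lo, hi, xtol=1e-6)
    return GutGeometry(params, pts, s_signed, make_r0(scale), s_min, s_max)


def make_tube_fixture(radius: float, length: float, dimensionality: int = 3) -> GutGeometry:
    """Straight validation fixture: a tube (3-D) or parallel-plate channel (2-D).

    The axis runs along +x at the origin; ``s`` spans [0, length].  In 2-D
    mode the geometry is a slab of half-width ``radius`` in z, invariant in
    y (solved quasi-2-D with a thin periodic y direction).
    """
    if radius <= 0 or length <= 0:
        raise GeometryError("radius and length must be > 0")
    if dimensionality not in (2, 3):
        raise GeometryError("dimensionality must be 2 or 3")
    params = GeometryParams(
        stomach_volume_target=np.pi * radius**2 * length / ML,
        antral_diameter_D=2 * radius,
        pylorus_diameter_open=2 * radius,
        pylorus_length=min(length / 10, 12.0),
        duodenum_diameter=2 * radius,
        duodenum_length=length,
        centerline_control_points=((0.0, 0.0, 0.0), (length, 0.0, 0.0)),
        radius_knots=((0.0, radius), (length, radius)),
    )
    n = max(int(length / 0.5), 2)
    s = np.linspace(0, length, n)
    pts = np.zeros((n, 3))
    pts[:, 0] = s

    def r0(ss):
        return np.full_like(np.atleast_1d(np.asarray(ss, float)), radius)

    return GutGeometry(params, pts, s, r0, 0.0, length, planar=(dimensionality == 2))


def voxelize(geom: GutGeometry, spacing: float, strict: bool = True, margin: float | None = None) -> VoxelGrid:
    """Classify a node-centred Cartesian lattice against the rest geometry.

    Nodes with rest signed distance < 0 are lumen; non-lumen nodes within
    one lattice link of lumen are wall; the rest are outside.  Raises
    :class:`ResolutionError` when the spacing cannot resolve the lumen, and
    (in strict mode) when fewer than 3 nodes span the open pylorus.
    """
    if spacing <= 0:
        raise GeometryError("spacing must be > 0")
    min_diam = 2.0 * float(np.min(geom.r0(np.linspace(geom.s_min, geom.s_max, 2000))))
    if min_diam < 2.0 * spacing:
        raise ResolutionError(
            f"spacing {spacing} mm cannot resolve minimum lumen diameter {min_diam:.1f} mm"
        )
    n_pyl = geom.params.pylorus_diameter_open / spacing
    if n_pyl < 3.0:
        msg = (
            f"open pylorus ({geom.params.pylorus_diameter_open} mm) spans only "
            f"{n_pyl:.1f} nodes at {spacing} mm spacing"
        )
        if strict:
            raise ResolutionError(msg)
        warnings.warn(msg + "; running in reduced-resolution mode", stacklevel=2)

    if margin is None:
        margin = 2.0 * spacing
    lo, hi = geom.bounding_box()
    lo = lo - margin
    hi = hi + margin
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    if geom.planar:
        shape = (shape[0], 1, shape[2])
    axes = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    s, d, e_r = geom.nearest(pts)
    sd = (d - geom.r0(s)).astype(np.float32)
    s = s.astype(np.float32).reshape(shape)
    d = d.astype(np.float32).reshape(shape)
    sd = sd.reshape(shape)
    e_r = e_r.astype(np.float32).reshape(shape + (3,))

    lumen = sd < 0.0
    near = np.zeros(shape, bool)
    for ax in range(3):
        if shape[ax] == 1:
            continue
        for shift in (-1, 1):
            near |= np.roll(lumen, shift, axis=ax)
    wall = near & ~lumen
    outside = ~lumen & ~wall
    return VoxelGrid(
        spacing=spacing,
        origin=np.asarray(lo, float),
        shape=shape,
        lumen=lumen,
        wall=wall,
        outside=outside,
        s=s,
        d=d,
        sd_rest=sd,
        e_r=e_r,
        stomach=lumen & (s > 0),
        duodenum=lumen & (s < 0),
    )


def label_regions(geom: GutGeometry, grid: VoxelGrid, n_regions: int = 13) -> RegionLabels:
    """Partition stomach lumen voxels into ``n_regions`` arclength bins.

    Bins are contiguous, equal-width in centerline arclength measured from
    the pylorus; every stomach voxel joins the bin of its nearest
    centerline point.  Region 1 abuts the pylorus.
    """
    if n_regions < 1:
        raise GeometryError("n_regions must be >= 1")
    if n_regions > max(int(geom.s_max / grid.spacing), 1):
        raise ResolutionError(
            f"{n_regions} regions cannot be resolved over {geom.s_max:.0f} mm at "
            f"{grid.spacing} mm spacing"
        )
    boundaries = np.linspace(0.0, geom.s_max, n_regions + 1)
    labels = np.zeros(grid.shape, np.int32)
    sv = grid.s[grid.stomach]
    lab = np.minimum(np.searchsorted(boundaries, sv, side="right"), n_regions)
    labels[grid.stomach] = lab
    return RegionLabels(n_regions=n_regions, boundaries=boundaries, labels=labels)
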