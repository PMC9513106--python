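"""Analytic ground-truth flow fields and gridded-field I/O.

Provides an eccentric cosine-stenosis tube phantom with a parametric
post-stenotic turbulence model, plus readers/writers for externally
gridded velocity / Reynolds-stress fields (HDF5).

Conventions
-----------
* Grid spacing and origin in mm, voxel-center sampling, 0-based indices.
* Flow axis is z (last array axis); arrays are indexed ``[frame, comp, x, y, z]``.
* Velocity in m/s, Reynolds stress in Pa, density in kg/m^3.
* Symmetric tensors are stored with 6 components in order
  ``xx, yy, zz, xy, xz, yz``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "Grid3D",
    "GroundTruthField",
    "StenosisSpec",
    "InletSpec",
    "TurbulenceSpec",
    "RST_COMPONENTS",
    "rst6_to_tensor",
    "tensor_to_rst6",
    "make_stenosis_mask",
    "local_radius",
    "local_center_offset",
    "default_waveform",
    "waveform_value",
    "hagen_poiseuille_profile",
    "make_phantom_flow",
    "ensemble_covariance",
    "temporal_window_average",
    "write_gridded_fields",
    "load_gridded_fields",
]

log = logging.getLogger(__name__)

RST_COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")

#: index pairs of the 6-component storage in the full 3x3 tensor
_RST_IDX = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


def rst6_to_tensor(r6: np.ndarray) -> np.ndarray:
    """Expand 6-component symmetric storage (leading axis 6) to 3x3."""
    r6 = np.asarray(r6)
    out = np.empty((3, 3) + r6.shape[1:], dtype=r6.dtype)
    for c, (i, j) in enumerate(_RST_IDX):
        out[i, j] = r6[c]
        out[j, i] = r6[c]
    return out


def tensor_to_rst6(t: np.ndarray) -> np.ndarray:
    """Contract a symmetric 3x3 tensor field (leading axes 3,3) to 6 components."""
    t = np.asarray(t)
    return np.stack([t[i, j] for (i, j) in _RST_IDX])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Grid3D:
    """Regular Cartesian grid with voxel-center sampling.

    Parameters
    ----------
    shape
        Number of voxels per axis ``(n_x, n_y, n_z)``; each >= 4.
    spacing
        Voxel size per axis in mm (isotropic 0.65 mm by default).
    origin
        Offset of the grid corner in mm; voxel centers sit at
        ``origin + (i + 0.5) * spacing``.
    time_axis
        Frame times in ms, strictly increasing; singleton for steady flow.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (0.65, 0.65, 0.65)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    time_axis: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 4 for n in self.shape):
            raise ValueError(f"grid shape must have 3 axes each >= 4, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        t = np.asarray(self.time_axis, dtype=float)
        if t.ndim != 1 or t.size < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("time_axis must be non-empty and strictly increasing")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))
        object.__setattr__(self, "time_axis", tuple(float(x) for x in t))

    @property
    def n_frames(self) -> int:
        return len(self.time_axis)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along ``axis`` in mm."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij")


@dataclass
class GroundTruthField:
    """Mean velocity + Reynolds-stress ground truth on a regular grid."""

    grid: Grid3D
    u_mean: np.ndarray  # (n_frames, 3, nx, ny, nz) m/s
    rst: np.ndarray  # (n_frames, 6, nx, ny, nz) Pa
    mask: np.ndarray  # (nx, ny, nz) bool
    rho: float = 1060.0  # kg/m^3
    mu: float = 3.5e-3  # Pa s
    #: ground-truth fields are validated (masking + PSD); measurement-resolution
    #: fields produced by the forward model legitimately violate both
    strict: bool = True

    def __post_init__(self) -> None:
        self.u_mean = np.asarray(self.u_mean, dtype=float)
        self.rst = np.asarray(self.rst, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        nt = self.grid.n_frames
        expect_u = (nt, 3) + self.grid.shape
        expect_r = (nt, 6) + self.grid.shape
        if self.u_mean.shape != expect_u:
            raise ValueError(f"u_mean shape {self.u_mean.shape} != {expect_u}")
        if self.rst.shape != expect_r:
            raise ValueError(f"rst shape {self.rst.shape} != {expect_r}")
        if self.mask.shape != self.grid.shape:
            raise ValueError(f"mask shape {self.mask.shape} != {self.grid.shape}")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.strict:
            self.validate()

    @property
    def nu(self) -> float:
        """Kinematic viscosity in m^2/s."""
        return self.mu / self.rho

    def validate(self, psd_tol: float = 1e-9) -> None:
        """Check masking and positive semidefiniteness of the RST."""
        out = ~self.mask
        if np.any(self.u_mean[:, :, out] != 0) or np.any(self.rst[:, :, out] != 0):
            raise ValueError("u_mean and rst must vanish outside the lumen mask")
        if not np.any(self.mask):
            return
        r = self.rst[:, :, self.mask]  # (nt, 6, nvox)
        tens = np.moveaxis(rst6_to_tensor(np.moveaxis(r, 1, 0)), (0, 1), (-2, -1))
        ev = np.linalg.eigvalsh(tens)
        trace = r[:, :3].sum(axis=1)
        floor = -psd_tol * np.maximum(trace, np.finfo(float).tiny)
        if np.any(ev.min(axis=-1) < floor):
            nbad = int(np.sum(ev.min(axis=-1) < floor))
            raise ValueError(f"rst not positive semidefinite at {nbad} masked voxels")

    def frame(self, index: int) -> "GroundTruthField":
        """Single-frame view (copy) of this field."""
        t = self.grid.time_axis[index]
        g = replace(self.grid, time_axis=(t,))
        return GroundTruthField(
            grid=g,
            u_mean=self.u_mean[index : index + 1].copy(),
            rst=self.rst[index : index + 1].copy(),
            mask=self.mask.copy(),
            rho=self.rho,
            mu=self.mu,
            strict=self.strict,
        )

    def tke(self) -> np.ndarray:
        """Turbulent kinetic energy density, J/m^3, per frame."""
        return 0.5 * self.rst[:, :3].sum(axis=1)


@dataclass(frozen=True)
class StenosisSpec:
    """Eccentric cosine stenosis in a straight tube.

    ``severity`` is the fractional area reduction at the throat;
    ``eccentricity`` offsets the constriction center laterally (along x)
    by that fraction of the diameter.  Axial positions are in diameters.
    """

    severity: float = 0.75
    eccentricity: float = 0.05
    diameter: float = 10.0  # mm
    throat_position: float = 3.0  # diameters from inlet
    downstream_length: float = 20.0  # diameters beyond the throat
    stenosis_length: float = 2.0  # axial extent of the constriction, diameters

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity < 1.0:
            raise ValueError("severity must be in [0, 1)")
        if not 0.0 <= self.eccentricity < 0.5:
            raise ValueError("eccentricity must be in [0, 0.5)")
        if self.diameter <= 0 or self.stenosis_length <= 0:
            raise ValueError("diameter and stenosis_length must be positive")

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    @property
    def throat_radius(self) -> float:
        return self.radius * np.sqrt(1.0 - self.severity)

    @property
    def throat_z(self) -> float:
        """Axial position of the throat in mm (inlet at z = 0)."""
        return self.throat_position * self.diameter

    @property
    def length(self) -> float:
        """Required tube length in mm."""
        return (self.throat_position + self.downstream_length) * self.diameter


@dataclass(frozen=True)
class InletSpec:
    """Inlet flow specification (Hagen-Poiseuille profile, pulsatile scaling).

    ``waveform`` is an optional ``(n, 2)`` table of (cycle fraction in
    [0, 1), flow-rate scale); it is normalized so its cycle mean is one.
    When omitted, a raised-cosine systolic pulse with peak/mean ratio
    ``peak_Re / mean_Re`` is used.
    """

    mean_Re: float = 1000.0
    peak_Re: float = 4000.0
    waveform: tuple[tuple[float, float], ...] | None = None
    inlet_area_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_Re <= 0 or self.peak_Re < self.mean_Re:
            raise ValueError("require 0 < mean_Re <= peak_Re")
        if not 0.0 < self.inlet_area_fraction <= 1.0:
            raise ValueError("inlet_area_fraction must be in (0, 1]")
        if self.waveform is not None:
            w = np.asarray(self.waveform, dtype=float)
            if w.ndim != 2 or w.shape[1] != 2 or w.shape[0] < 2:
                raise ValueError("waveform must be an (n>=2, 2) table")
            object.__setattr__(
                self, "waveform", tuple(tuple(map(float, row)) for row in w)
            )


@dataclass(frozen=True)
class TurbulenceSpec:
    """Parametric post-stenotic turbulence for the analytic phantom.

    The Reynolds stress is axisymmetric about the flow axis (axial
    variance ``anisotropy`` times the radial one, plus an optional xz
    shear bounded by ``shear_frac`` of the geometric mean), modulated by
    a smooth axial envelope that is zero upstream of the throat, peaks
    ``peak_offset`` diameters downstream and decays beyond.  Positive
    semidefiniteness holds by construction for ``|shear_frac| < 1``.
    """

    tke_peak: float = 100.0  # J/m^3, spatiotemporal peak of TKE
    anisotropy: float = 2.0  # axial / radial variance ratio
    shear_frac: float = 0.3  # xz covariance over sqrt(Rxx * Rzz)
    peak_offset: float = 4.0  # diameters downstream of the throat
    lag_ms: float = 0.0  # turbulence onset delay behind the flow waveform

    def __post_init__(self) -> None:
        if self.tke_peak < 0:
            raise ValueError("tke_peak must be >= 0")
        if self.anisotropy <= 0:
            raise ValueError("anisotropy must be positive")
        if not abs(self.shear_frac) < 1.0:
            raise ValueError(
                "shear_frac must satisfy |shear_frac| < 1 (PSD would fail)"
            )
        if self.peak_offset <= 0:
            raise ValueError("peak_offset must be positive")


# ---------------------------------------------------------------------------
# stenosis geometry
# ---------------------------------------------------------------------------


def local_radius(spec: StenosisSpec, z_mm: np.ndarray) -> np.ndarray:
    """Lumen radius (mm) along the tube for a cosine constriction."""
    z = np.asarray(z_mm, dtype=float)
    half = 0.5 * spec.stenosis_length * spec.diameter
    s = np.clip((z - spec.throat_z) / half, -1.0, 1.0)
    depth = spec.radius - spec.throat_radius
    bump = 0.5 * (1.0 + np.cos(np.pi * s))  # 1 at throat, 0 at the ends
    bump = np.where(np.abs(z - spec.throat_z) <= half, bump, 0.0)
    return spec.radius - depth * bump


def local_center_offset(spec: StenosisSpec, z_mm: np.ndarray) -> np.ndarray:
    """Lateral (x) offset of the lumen center line in mm."""
    z = np.asarray(z_mm, dtype=float)
    half = 0.5 * spec.stenosis_length * spec.diameter
    s = np.clip((z - spec.throat_z) / half, -1.0, 1.0)
    bump = 0.5 * (1.0 + np.cos(np.pi * s))
    bump = np.where(np.abs(z - spec.throat_z) <= half, bump, 0.0)
    return spec.eccentricity * spec.diameter * bump


def make_stenosis_mask(spec: StenosisSpec, grid: Grid3D) -> np.ndarray:
    """Boolean lumen mask of the eccentric cosine-stenosis tube.

    The tube axis runs along z through the transverse center of the grid;
    the inlet plane is the first z slice.  Raises ``ValueError`` if the
    grid is axially shorter than ``throat_position + downstream_length``
    diameters.
    """
    extent = grid.shape[2] * grid.spacing[2]
    if extent + 1e-9 < spec.length:
        raise ValueError(
            f"grid spans {extent:.1f} mm axially but the stenosis spec "
            f"requires {spec.length:.1f} mm"
        )
    x, y, z = grid.meshgrid()
    z_local = z - grid.origin[2] - 0.5 * grid.spacing[2]  # inlet slice at z=0
    cx = grid.origin[0] + 0.5 * grid.shape[0] * grid.spacing[0]
    cy = grid.origin[1] + 0.5 * grid.shape[1] * grid.spacing[1]
    r = local_radius(spec, z_local)
    off = local_center_offset(spec, z_local)
    d2 = (x - cx - off) ** 2 + (y - cy) ** 2
    return d2 <= r**2


def _lumen_coords(
    spec: StenosisSpec, grid: Grid3D
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized radial coordinate, local radius and axial coordinate (mm)."""
    x, y, z = grid.meshgrid()
    z_local = z - grid.origin[2] - 0.5 * grid.spacing[2]
    cx = grid.origin[0] + 0.5 * grid.shape[0] * grid.spacing[0]
    cy = grid.origin[1] + 0.5 * grid.shape[1] * grid.spacing[1]
    r = local_radius(spec, z_local)
    off = local_center_offset(spec, z_local)
    rho_n = np.sqrt((x - cx - off) ** 2 + (y - cy) ** 2) / r
    return rho_n, r, z_local


# ---------------------------------------------------------------------------
# inlet waveform and profile
# ---------------------------------------------------------------------------


def default_waveform(
    peak_to_mean: float, n: int = 256, systole_fraction: float = 0.3
) -> np.ndarray:
    """Raised-cosine systolic waveform table with unit mean and given peak.

    Returns an ``(n, 2)`` array of (cycle fraction, scale).  The bump
    occupies ``systole_fraction`` of the cycle and peaks at half of it.
    """
    if peak_to_mean < 1:
        raise ValueError("peak_to_mean must be >= 1")
    frac = np.arange(n) / n
    bump = np.where(
        frac < systole_fraction,
        0.5 * (1.0 - np.cos(2.0 * np.pi * frac / systole_fraction)),
        0.0,
    )
    m = bump.mean()
    if peak_to_mean == 1.0:
        scale = np.ones(n)
    else:
        c = (peak_to_mean - 1.0) / (1.0 - m)
        scale = (1.0 - c * m) + c * bump
    return np.column_stack([frac, scale])


def waveform_value(
    inlet: InletSpec, t_ms: float | np.ndarray, period_ms: float
) -> np.ndarray:
    """Flow-rate scale factor at cycle time ``t_ms`` (periodic, unit mean)."""
    if inlet.waveform is None:
        table = default_waveform(inlet.peak_Re / inlet.mean_Re)
    else:
        table = np.asarray(inlet.waveform, dtype=float)
        table = table[np.argsort(table[:, 0])]
        table = np.column_stack([table[:, 0], table[:, 1]])
    frac = np.mod(np.asarray(t_ms, dtype=float) / period_ms, 1.0)
    xs = np.concatenate([table[:, 0], [table[0, 0] + 1.0]])
    ys = np.concatenate([table[:, 1], [table[0, 1]]])
    vals = np.interp(frac, xs, ys)
    # enforce unit cycle mean on the interpolated table
    dense = np.interp(np.arange(4096) / 4096.0, xs, ys)
    return vals / dense.mean()


def hagen_poiseuille_profile(
    inlet: InletSpec,
    mask_slice: np.ndarray,
    spacing_mm: tuple[float, float],
    frame_time_ms: float = 0.0,
    period_ms: float = 1000.0,
    nu_m2s: float = 3.5e-3 / 1060.0,
    diameter_mm: float | None = None,
) -> np.ndarray:
    """Parabolic axial inflow on a circular inlet slice.

    The profile is scaled so the slice-mean velocity U satisfies
    ``U * D / nu = waveform(t) * mean_Re``.  Returns a ``(3, nx, ny)``
    velocity field in m/s with only the axial (z) component nonzero and
    exact zeros at wall (unmasked) voxels.
    """
    mask_slice = np.asarray(mask_slice, dtype=bool)
    if not np.any(mask_slice):
        raise ValueError("inlet slice is empty")
    area_mm2 = mask_slice.sum() * spacing_mm[0] * spacing_mm[1]
    if diameter_mm is None:
        diameter_mm = 2.0 * np.sqrt(area_mm2 / np.pi)
    re = float(waveform_value(inlet, frame_time_ms, period_ms)) * inlet.mean_Re
    u_slice_mean = re * nu_m2s / (diameter_mm * 1e-3)  # m/s

    ix, iy = np.nonzero(mask_slice)
    x = (ix + 0.5) * spacing_mm[0]
    y = (iy + 0.5) * spacing_mm[1]
    cx, cy = x.mean(), y.mean()
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    shape = np.clip(1.0 - r2 / (0.5 * diameter_mm) ** 2, 0.0, None)
    if shape.mean() == 0:
        shape = np.ones_like(shape)
    profile = np.zeros((3,) + mask_slice.shape)
    profile[2][ix, iy] = u_slice_mean * shape / shape.mean()
    return profile


# ---------------------------------------------------------------------------
# analytic phantom flow
# ---------------------------------------------------------------------------


def make_phantom_flow(
    spec: StenosisSpec,
    inlet: InletSpec,
    grid: Grid3D,
    turb: TurbulenceSpec | None = None,
    rho: float = 1060.0,
    mu: float = 3.5e-3,
) -> GroundTruthField:
    """Analytic stand-in for a post-stenotic turbulent jet.

    The axial velocity is a slice-normalized jet: parabolic upstream,
    contracting through the stenosis and relaxing back to parabolic over
    ~8 diameters downstream.  Every z slice is rescaled so the discrete
    slice flux matches the prescribed flow rate, which makes the field
    mass consistent by construction.  The Reynolds stress follows
    :class:`TurbulenceSpec`; for pulsatile runs its amplitude tracks the
    inlet waveform delayed by ``lag_ms``.
    """
    turb = turb or TurbulenceSpec(tke_peak=0.0)
    mask = make_stenosis_mask(spec, grid)
    rho_n, r_loc, z_local = _lumen_coords(spec, grid)
    nu = mu / rho

    period = _cycle_period_ms(grid)
    d = spec.diameter
    u_mean_inlet = inlet.mean_Re * nu / (d * 1e-3)  # m/s, cycle-mean
    area_m2 = np.pi * (0.5 * d * 1e-3) ** 2
    q_mean = u_mean_inlet * area_m2  # m^3/s

    # jet shape: parabolic profile sharpened by a Gaussian factor whose
    # strength decays downstream of the throat (jet spreading)
    zt = spec.throat_z
    recovery = 8.0 * d
    lam = np.where(z_local >= zt, np.exp(-(z_local - zt) / recovery), 0.0)
    b0 = max(spec.throat_radius / spec.radius, 0.05)
    kappa = 3.0 * (1.0 / b0 - 1.0)
    shape = np.clip(1.0 - rho_n**2, 0.0, None) * np.exp(
        -kappa * lam * rho_n**2
    )
    shape = np.where(mask, shape, 0.0)

    # per-slice normalization so the discrete flux equals Q exactly
    dx, dy = grid.spacing[0], grid.spacing[1]
    slice_int = shape.sum(axis=(0, 1)) * dx * dy * 1e-6  # m^2 weighted
    norm = np.zeros_like(slice_int)
    ok = slice_int > 0
    norm[ok] = 1.0 / slice_int[ok]

    # turbulence envelope
    s = np.where(z_local > zt, (z_local - zt) / (turb.peak_offset * d), 0.0)
    ax_env = np.where(s > 0, (s * np.exp(1.0 - s)) ** 2, 0.0)
    rad_env = np.clip(1.0 - rho_n**2, 0.0, None)
    env = np.where(mask, ax_env * rad_env, 0.0)
    env_max = env.max()
    if env_max > 0:
        env = env / env_max

    times = np.asarray(grid.time_axis)
    nt = times.size
    u = np.zeros((nt, 3) + grid.shape)
    rst = np.zeros((nt, 6) + grid.shape)

    beta = turb.anisotropy
    for it, t in enumerate(times):
        if nt == 1:
            w = 1.0
            w_turb = 1.0
        else:
            w = float(waveform_value(inlet, t, period))
            w_turb = _turbulence_modulation(inlet, t, turb.lag_ms, period)
        q_t = q_mean * w
        u[it, 2] = shape * (norm[None, None, :] * q_t)

        tke_vox = turb.tke_peak * env * w_turb  # J/m^3
        # axisymmetric split: Rzz/Rxx = beta, TKE = (Rzz + 2 Rxx) / 2
        rxx = 2.0 * tke_vox / (beta + 2.0)
        rzz = beta * rxx
        rst[it, 0] = rxx
        rst[it, 1] = rxx
        rst[it, 2] = rzz
        rst[it, 4] = turb.shear_frac * np.sqrt(rxx * rzz)

    return GroundTruthField(grid=grid, u_mean=u, rst=rst, mask=mask, rho=rho, mu=mu)


def _cycle_period_ms(grid: Grid3D) -> float:
    t = np.asarray(grid.time_axis)
    if t.size < 2:
        return 1000.0
    dt = np.diff(t)
    return float(t[-1] - t[0] + np.median(dt))


def _turbulence_modulation(
    inlet: InletSpec, t_ms: float, lag_ms: float, period_ms: float
) -> float:
    """Turbulence amplitude in [0, 1], peaking ``lag_ms`` after peak flow."""
    dense_t = np.arange(4096) / 4096.0 * period_ms
    w = waveform_value(inlet, dense_t, period_ms)
    wmax = w.max()
    val = float(waveform_value(inlet, t_ms - lag_ms, period_ms))
    return val / wmax


# ---------------------------------------------------------------------------
# ensemble and temporal-window statistics
# ---------------------------------------------------------------------------


def ensemble_covariance(
    snapshots: list[np.ndarray] | np.ndarray, rho: float = 1060.0
) -> tuple[np.ndarray, np.ndarray]:
    """Mean velocity and Reynolds stress from an ensemble of snapshots.

    ``snapshots`` is a sequence of ``(3, ...)`` velocity fields.  Returns
    ``(u_mean, rst6)`` where ``rst6 = rho * (1/N) sum u' u'^T`` in
    6-component storage.
    """
    snaps = np.asarray(snapshots, dtype=float)
    if snaps.ndim < 2 or snaps.shape[0] < 2 or snaps.shape[1] != 3:
        raise ValueError("need N >= 2 snapshots of shape (3, ...)")
    u_mean = snaps.mean(axis=0)
    fluct = snaps - u_mean
    r6 = np.empty((6,) + snaps.shape[2:])
    for c, (i, j) in enumerate(_RST_IDX):
        r6[c] = rho * np.mean(fluct[:, i] * fluct[:, j], axis=0)
    return u_mean, r6


def temporal_window_average(
    series: GroundTruthField, t0: float, delta_t: float
) -> GroundTruthField:
    """Average a pulsatile field over a temporal window (periodic in the cycle).

    Frames whose times fall inside the closed window ``[t0 - dt/2, t0 + dt/2]``
    (with periodic wrap over the cardiac cycle) form the measurement
    ensemble: the returned mean velocity is the window mean, and the
    returned Reynolds stress is the window mean of the per-frame stresses
    plus ``rho`` times the covariance of the per-frame mean velocities —
    so temporal mean-flow variation shows up as apparent turbulence.
    ``delta_t = 0`` returns the frame nearest ``t0`` unchanged.
    """
    if delta_t < 0:
        raise ValueError("delta_t must be >= 0")
    times = np.asarray(series.grid.time_axis)
    period = _cycle_period_ms(series.grid)
    dist = np.abs((times - t0 + 0.5 * period) % period - 0.5 * period)
    if delta_t == 0 or times.size == 1:
        sel = np.array([int(np.argmin(dist))])
    else:
        sel = np.nonzero(dist <= 0.5 * delta_t + 1e-9)[0]
        if sel.size == 0:
            sel = np.array([int(np.argmin(dist))])

    u_sel = series.u_mean[sel]  # (N, 3, ...)
    r_sel = series.rst[sel]
    u_out = u_sel.mean(axis=0)
    r_out = r_sel.mean(axis=0)
    if sel.size > 1:
        fluct = u_sel - u_out
        for c, (i, j) in enumerate(_RST_IDX):
            r_out[c] += series.rho * np.mean(fluct[:, i] * fluct[:, j], axis=0)

    grid = replace(series.grid, time_axis=(float(t0),))
    return GroundTruthField(
        grid=grid,
        u_mean=u_out[None],
        rst=r_out[None],
        mask=series.mask,
        rho=series.rho,
        mu=series.mu,
        strict=series.strict,
    )


# ---------------------------------------------------------------------------
# gridded-field I/O (HDF5)
# ---------------------------------------------------------------------------


def write_gridded_fields(field: GroundTruthField, path) -> None:
    """Write a :class:`GroundTruthField` to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("u_mean", data=field.u_mean)
        f.create_dataset("rst", data=field.rst)
        f.create_dataset("mask", data=field.mask.astype(np.uint8))
        f.attrs["spacing_mm"] = field.grid.spacing
        f.attrs["origin_mm"] = field.grid.origin
        f.attrs["time_ms"] = field.grid.time_axis
        f.attrs["rho"] = field.rho
        f.attrs["mu"] = field.mu
        f.attrs["rst_order"] = ",".join(RST_COMPONENTS)


def load_gridded_fields(
    path, psd_clip_tol: float = 1e-6, strict: bool = True
) -> GroundTruthField:
    """Load a gridded velocity/RST container written by this package
    (or an equivalent CFD export).

    The RST may be stored either with 6 components (order xx,yy,zz,xy,xz,yz)
    or as a full ``(nt, 3, 3, ...)`` tensor; full tensors are checked for
    symmetry and symmetrized.  Small negative eigenvalues (above
    ``-psd_clip_tol * trace``) are clipped to zero and logged; larger
    violations raise.  ``strict=False`` loads measurement-resolution
    fields (e.g. downsampled containers) without masking/PSD validation.
    """
    with h5py.File(path, "r") as f:
        for name in ("u_mean", "rst", "mask"):
            if name not in f:
                raise ValueError(f"missing dataset /{name} in {path}")
        u = np.asarray(f["u_mean"], dtype=float)
        r = np.asarray(f["rst"], dtype=float)
        mask = np.asarray(f["mask"]).astype(bool)
        attrs = dict(f.attrs)

    for key in ("spacing_mm", "time_ms"):
        if key not in attrs:
            raise ValueError(f"missing attribute {key} in {path}")

    if r.ndim == u.ndim and r.shape[1] == 6:
        r6 = r
    elif r.ndim == u.ndim + 1 and r.shape[1:3] == (3, 3):
        full = np.moveaxis(r, (1, 2), (0, 1))  # (3, 3, nt, ...)
        asym = np.abs(full - np.swapaxes(full, 0, 1))
        scale = np.abs(full).max() or 1.0
        if asym.max() > 1e-6 * scale:
            raise ValueError(
                f"rst tensor asymmetric: max |R_ij - R_ji| = {asym.max():.3e}"
            )
        r6 = np.moveaxis(tensor_to_rst6(0.5 * (full + np.swapaxes(full, 0, 1))), 0, 1)
    elif r.ndim == u.ndim and r.shape[1] == 3:
        raise ValueError(
            "rst has only 3 components (variances); covariances xy, xz, yz "
            "are missing"
        )
    else:
        raise ValueError(f"unrecognized rst shape {r.shape}")

    grid = Grid3D(
        shape=tuple(mask.shape),
        spacing=tuple(np.atleast_1d(attrs["spacing_mm"]).astype(float)),
        origin=tuple(np.atleast_1d(attrs.get("origin_mm", (0.0, 0.0, 0.0))).astype(float)),
        time_axis=tuple(np.atleast_1d(attrs["time_ms"]).astype(float)),
    )

    if strict:
        # clip slightly negative eigenvalues introduced by interpolation
        r6 = _psd_clip(r6, mask, tol=psd_clip_tol)

    return GroundTruthField(
        grid=grid,
        u_mean=u,
        rst=r6,
        mask=mask,
        rho=float(attrs.get("rho", 1060.0)),
        mu=float(attrs.get("mu", 3.5e-3)),
        strict=strict,
    )


def _psd_clip(r6: np.ndarray, mask: np.ndarray, tol: float) -> np.ndarray:
    """Project masked tensors with small negative eigenvalues back to PSD."""
    r6 = r6.copy()
    vox = r6[:, :, mask]  # (nt, 6, nvox)
    tens = np.moveaxis(rst6_to_tensor(np.moveaxis(vox, 1, 0)), (0, 1), (-2, -1))
    ev, vec = np.linalg.eigh(tens)
    trace = np.maximum(vox[:, :3].sum(axis=1), np.finfo(float).tiny)
    rel = ev.min(axis=-1) / trace
    bad = ev.min(axis=-1) < 0
    if not np.any(bad):
        return r6
    if rel.min() < -tol:
        raise ValueError(
            f"rst strongly non-PSD: min eigenvalue {rel.min():.3e} of trace"
        )
    n = int(bad.sum())
    log.warning("clipped negative RST eigenvalues at %d voxel-frames", n)
    ev = np.clip(ev, 0.0, None)
    fixed = np.einsum("...ij,...j,...kj->...ik", vec, ev, vec)
    vox = np.moveaxis(tensor_to_rst6(np.moveaxis(fixed, (-2, -1), (0, 1))), 0, 1)
    r6[:, :, mask] = vox
    return r6
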