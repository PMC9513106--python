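"""Band-limiting of gridded fields to a prescribed MR resolution.

Fields on the fine source grid (spacing ``L``) are apodized in k-space
with a separable truncated Gaussian modulation transfer function of
standard deviation ``sigma_G = sqrt(8 ln 2) * L / Delta_L`` on the
normalized per-axis frequency ``xi = k / k_Nyquist`` and then sampled at
the centers of the coarser target voxels (spacing ``Delta_L``).  Each 1D
Gaussian is cut by a box window where its amplitude falls to 0.5.

The velocity field is filtered componentwise.  The Reynolds stress
picks up the partial-volume term: the filtered second moment of the
mean velocity minus the outer product of the filtered mean, scaled by
the fluid density — unresolved shear masquerades as turbulence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .phantom import Grid3D, GroundTruthField, _RST_IDX

__all__ = [
    "MTFSpec",
    "gaussian_mtf",
    "point_spread_function",
    "apply_mtf",
    "target_grid",
    "decimate",
    "downsample_velocity",
    "downsample_rst",
    "downsample_mask",
    "downsample_field",
]

_FWHM = np.sqrt(8.0 * np.log(2.0))


@dataclass(frozen=True)
class MTFSpec:
    """Gaussian MTF from source spacing ``L`` to target spacing ``Delta_L``."""

    source_spacing: float  # L, mm
    target_spacing: float  # Delta_L, mm

    def __post_init__(self) -> None:
        if self.source_spacing <= 0:
            raise ValueError("source_spacing must be positive")
        if self.target_spacing < self.source_spacing:
            raise ValueError(
                f"target spacing {self.target_spacing} mm must be >= source "
                f"spacing {self.source_spacing} mm"
            )

    @property
    def sigma_g(self) -> float:
        """Nominal Gaussian std ``sqrt(8 ln 2) L / Delta_L`` (always recomputed)."""
        return _FWHM * self.source_spacing / self.target_spacing

    @property
    def sigma_effective(self) -> float:
        """Std of the *net* resolution transfer from L to Delta_L.

        The source grid already carries the L-resolution MTF, so only the
        quotient Gaussian is applied: ``1/sigma_eff^2 = 1/sigma_g^2 -
        1/sigma_g(L->L)^2``.  This makes ``Delta_L = L`` an exact identity
        and converges to ``sigma_g`` for coarse targets.  Returns ``inf``
        at identity.
        """
        inv = 1.0 / self.sigma_g**2 - 1.0 / _FWHM**2
        if inv <= 0:
            return np.inf
        return 1.0 / np.sqrt(inv)

    @property
    def cutoff(self) -> float:
        """Half-width of the truncation box: amplitude-0.5 point per axis."""
        return self.sigma_effective * np.sqrt(2.0 * np.log(2.0))


def _axis_weight(spec: MTFSpec, n: int) -> np.ndarray:
    # xi = k / k_nyq in [-1, 1): twice the cycles-per-sample DFT frequency
    xi = 2.0 * np.fft.fftfreq(n)
    sig = spec.sigma_effective
    if not np.isfinite(sig):
        return np.ones(n)
    w = np.exp(-(xi**2) / (2.0 * sig**2))
    w[np.abs(xi) > spec.cutoff] = 0.0
    return w


def gaussian_mtf(spec: MTFSpec, shape: tuple[int, int, int]) -> np.ndarray:
    """Separable 3D k-space weight on an FFT-ordered grid; weight(0) = 1."""
    wx, wy, wz = (_axis_weight(spec, n) for n in shape)
    return wx[:, None, None] * wy[None, :, None] * wz[None, None, :]


def point_spread_function(spec: MTFSpec, shape: tuple[int, int, int]) -> np.ndarray:
    """Real-space periodic PSF of the MTF, centered (fftshifted), sum = 1."""
    return np.fft.fftshift(np.real(np.fft.ifftn(gaussian_mtf(spec, shape))))


def apply_mtf(field: np.ndarray, spec: MTFSpec) -> np.ndarray:
    """Filter the last three axes of ``field`` with the Gaussian MTF.

    The result is real; the imaginary residue of the inverse FFT (below
    1e-10 of the field scale for real input) is discarded.
    """
    field = np.asarray(field, dtype=float)
    w = gaussian_mtf(spec, field.shape[-3:])
    spectrum = np.fft.fftn(field, axes=(-3, -2, -1)) * w
    return np.real(np.fft.ifftn(spectrum, axes=(-3, -2, -1)))


def target_grid(grid: Grid3D, spec: MTFSpec) -> Grid3D:
    """Coarse grid covering (approximately) the same field of view."""
    ratio = spec.source_spacing / spec.target_spacing
    shape = tuple(max(4, int(round(n * ratio))) for n in grid.shape)
    spacing = tuple(
        s * spec.target_spacing / spec.source_spacing for s in grid.spacing
    )
    return replace(grid, shape=shape, spacing=spacing)


def decimate(
    field: np.ndarray, src_grid: Grid3D, tgt_grid: Grid3D, order: int = 3
) -> np.ndarray:
    """Sample a source-grid field at target voxel centers (spline, periodic).

    Exact (identity) when the grids coincide.  Leading axes of ``field``
    are treated as components.
    """
    field = np.asarray(field)
    coords = np.meshgrid(
        *(
            (tgt_grid.axis_coords(a) - src_grid.origin[a]) / src_grid.spacing[a]
            - 0.5
            for a in range(3)
        ),
        indexing="ij",
    )
    lead = field.shape[:-3]
    flat = field.reshape((-1,) + field.shape[-3:])
    out = np.stack(
        [
            ndimage.map_coordinates(c, coords, order=order, mode="grid-wrap")
            for c in flat
        ]
    )
    return out.reshape(lead + out.shape[-3:])


def downsample_velocity(
    u: np.ndarray, grid: Grid3D, spec: MTFSpec
) -> tuple[np.ndarray, Grid3D]:
    """Band-limit and decimate a velocity field (leading axes preserved)."""
    tgt = target_grid(grid, spec)
    return decimate(apply_mtf(u, spec), grid, tgt), tgt


def downsample_rst(
    rst6: np.ndarray,
    u: np.ndarray,
    grid: Grid3D,
    spec: MTFSpec,
    rho: float,
    return_source: bool = False,
):
    """Band-limit and decimate a Reynolds-stress field with its partial-volume term.

    ``rst6`` has shape ``(..., 6, nx, ny, nz)`` and ``u`` the matching
    ``(..., 3, nx, ny, nz)``.  On the source grid,

        R_filt = MTF(R) + rho * [MTF(u u^T) - u_filt u_filt^T]

    component by component, after which the field is sampled at target
    voxel centers.  Returns ``(rst6_target, grid_target)``; with
    ``return_source=True`` the un-decimated source-grid field is
    returned instead of the target one (no grid change).
    """
    rst6 = np.asarray(rst6, dtype=float)
    u = np.asarray(u, dtype=float)
    if u.shape[-4] != 3 or rst6.shape[-4] != 6:
        raise ValueError("expected u with 3 components and rst with 6")
    u_filt = apply_mtf(u, spec)
    r_filt = apply_mtf(rst6, spec)
    ii = [p[0] for p in _RST_IDX]
    jj = [p[1] for p in _RST_IDX]
    uu = np.stack(
        [u[..., i, :, :, :] * u[..., j, :, :, :] for i, j in zip(ii, jj)], axis=-4
    )
    uu_filt = apply_mtf(uu, spec)
    uu_coarse = np.stack(
        [u_filt[..., i, :, :, :] * u_filt[..., j, :, :, :] for i, j in zip(ii, jj)],
        axis=-4,
    )
    r_src = r_filt + rho * (uu_filt - uu_coarse)
    if return_source:
        return r_src, grid
    tgt = target_grid(grid, spec)
    return decimate(r_src, grid, tgt), tgt


def downsample_mask(
    mask: np.ndarray, grid: Grid3D, spec: MTFSpec, threshold: float = 0.5
) -> tuple[np.ndarray, Grid3D]:
    """Decimate a boolean mask: filtered occupancy >= threshold."""
    tgt = target_grid(grid, spec)
    occ = decimate(apply_mtf(mask.astype(float), spec), grid, tgt, order=1)
    return occ >= threshold, tgt


def downsample_field(
    field: GroundTruthField, spec: MTFSpec
) -> GroundTruthField:
    """Downsample a full ground-truth container to the target resolution.

    Note the result is a *measurement-resolution* field: the
    partial-volume term can push tensors slightly off PSD near sharp
    shear, which is a genuine feature of the forward model, so PSD
    validation is not re-applied here.
    """
    u_t, tgt = downsample_velocity(field.u_mean, field.grid, spec)
    r_t, _ = downsample_rst(field.rst, field.u_mean, field.grid, spec, field.rho)
    mask_t, _ = downsample_mask(field.mask, field.grid, spec)
    return GroundTruthField(
        grid=tgt,
        u_mean=u_t,
        rst=r_t,
        mask=mask_t,
        rho=field.rho,
        mu=field.mu,
        strict=False,
    )
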