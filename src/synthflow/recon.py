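"""Velocity / Reynolds-stress reconstruction from multipoint PC-MRI signals.

Per voxel and encoding direction, the acquisitions at the different
encoding strengths are combined into a directional velocity ``nu`` and
an intra-voxel standard deviation (IVSD) variance ``sigma^2`` by
maximum-a-posteriori estimation under the Gaussian-IVSD signal model
with known complex-Gaussian noise (grid search with iterative zooming,
followed by an analytic polish).  The six directional estimates are then
projected to the Cartesian velocity vector and the symmetric Reynolds
stress tensor with pseudoinverse least squares, from which TKE and KE
maps follow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

from .mrsignal import EncodingScheme, SignalSet
from .phantom import Grid3D, rst6_to_tensor

__all__ = [
    "DirectionalEstimates",
    "ReconResult",
    "ivsd_single_point",
    "multipoint_combine",
    "rst_from_ivsd",
    "velocity_from_phases",
    "tke_map",
    "ke_map",
    "reconstruct",
    "write_recon",
]

log = logging.getLogger(__name__)


@dataclass
class DirectionalEstimates:
    """Per-direction velocity and IVSD-variance estimates on the grid."""

    nu: np.ndarray  # (n_directions, nx, ny, nz) m/s
    sigma2: np.ndarray  # (n_directions, nx, ny, nz) m^2/s^2, >= 0
    flagged: np.ndarray  # (nx, ny, nz) bool, voxels excluded from maps
    n_clamped: int = 0  # negative-IVSD clamps applied

    def __post_init__(self) -> None:
        if np.any(self.sigma2 < 0):
            raise ValueError("sigma2 must be clamped to >= 0")


@dataclass
class ReconResult:
    """Reconstructed velocity, Reynolds stress, TKE and KE maps."""

    u_star: np.ndarray  # (3, nx, ny, nz) m/s
    rst_star: np.ndarray  # (6, nx, ny, nz) Pa
    tke: np.ndarray  # J/m^3
    ke: np.ndarray  # J/m^3
    mask: np.ndarray
    scheme: EncodingScheme
    grid: Grid3D
    rho: float
    frame_time: float = 0.0
    n_clamped: int = 0
    flagged: np.ndarray | None = None


# ---------------------------------------------------------------------------
# single-point IVSD (validation fallback)
# ---------------------------------------------------------------------------


def ivsd_single_point(
    s_ref: np.ndarray, s_enc: np.ndarray, kv: np.ndarray
) -> tuple[np.ndarray, int]:
    """IVSD variance from one encoded/reference magnitude ratio.

    ``sigma^2 = (2 / |k_v|^2) ln(|S_ref| / |S_enc|)``; negative values
    (noise pushing ``|S_enc|`` above ``|S_ref|``) are clamped to zero.
    Returns ``(sigma2, n_clamped)``; voxels with zero reference signal
    yield NaN and must be flagged by the caller.
    """
    mag_ref = np.abs(np.asarray(s_ref))
    mag_enc = np.abs(np.asarray(s_enc))
    k2 = float(np.dot(np.atleast_1d(kv).ravel(), np.atleast_1d(kv).ravel()))
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = (2.0 / k2) * np.log(mag_ref / mag_enc)
    sigma2 = np.where(mag_ref > 0, sigma2, np.nan)
    neg = sigma2 < 0
    n_clamped = int(np.count_nonzero(neg))
    sigma2 = np.where(neg, 0.0, sigma2)
    return sigma2, n_clamped


# ---------------------------------------------------------------------------
# multipoint MAP combination
# ---------------------------------------------------------------------------


def _map_cost_grid(
    y: np.ndarray,  # (L, nvox) reference-phase-corrected signals
    amp: np.ndarray,  # (nvox,)
    k: np.ndarray,  # (L,)
    nu_grid: np.ndarray,  # (nvox, n_nu) candidate velocities
    sig_grid: np.ndarray,  # (nvox, n_sig) candidate IVSDs (std, >= 0)
    inv_two_var: float,
    prior_sig_bounds: tuple[float, float] | None,
) -> np.ndarray:
    """Negative log-posterior on per-voxel (nu, sigma) grids -> (nvox, n_nu, n_sig)."""
    # model m_l = amp * exp(-sigma^2 k_l^2 / 2) * exp(-i k_l nu)
    # |y - m|^2 summed over l expands to
    #   const + amp^2 sum g^2 - 2 amp sum g Re(y_l e^{+i k_l nu})
    g = np.exp(
        -0.5 * (sig_grid[None, :, :] ** 2) * (k[:, None, None] ** 2)
    )  # (L, nvox, n_sig)
    phase = np.exp(1j * k[:, None, None] * nu_grid[None, :, :])  # (L, nvox, n_nu)
    c = np.real(y[:, :, None] * phase)  # (L, nvox, n_nu)
    quad = np.einsum("lvs,lvs->vs", g, g) * amp[:, None] ** 2  # (nvox, n_sig)
    cross = np.einsum("lvs,lvn->vns", g, c)  # (nvox, n_nu, n_sig)
    cost = (quad[:, None, :] - 2.0 * amp[:, None, None] * cross) * inv_two_var
    if prior_sig_bounds is not None:
        lo, _ = prior_sig_bounds
        cost = cost + np.log(np.maximum(sig_grid, lo))[:, None, :]
    return cost


def _combine_direction(
    y: np.ndarray,
    amp: np.ndarray,
    k: np.ndarray,
    nu_max: float,
    sigma_eta: float | None,
    sigma_range: tuple[float, float],
    n_zoom: int,
    chunk: int = 4096,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """MAP (nu, sigma^2) for one direction, chunked over voxels."""
    nvox = y.shape[1]
    if nvox > chunk:
        parts = [
            _combine_direction(
                y[:, i : i + chunk],
                amp[i : i + chunk],
                k,
                nu_max,
                sigma_eta,
                sigma_range,
                n_zoom,
                chunk,
            )
            for i in range(0, nvox, chunk)
        ]
        return (
            np.concatenate([p[0] for p in parts]),
            np.concatenate([p[1] for p in parts]),
            np.concatenate([p[2] for p in parts]),
            sum(p[3] for p in parts),
        )
    nvox = y.shape[1]
    inv_two_var = 1.0 if sigma_eta is None else 1.0 / (2.0 * sigma_eta**2)
    prior = None if sigma_eta is None else sigma_range

    # coarse grids: nu must resolve the basin of the strongest encoding
    venc_min = np.pi / k.max()
    d_nu = venc_min / 8.0
    n_nu = max(int(np.ceil(2 * nu_max / d_nu)) + 1, 9)
    nu0 = np.linspace(-nu_max, nu_max, n_nu)
    sig_hi = sigma_range[1]
    sig0 = np.linspace(0.0, sig_hi, 25)

    nu_grid = np.broadcast_to(nu0, (nvox, n_nu))
    sig_grid = np.broadcast_to(sig0, (nvox, sig0.size))
    cost = _map_cost_grid(y, amp, k, nu_grid, sig_grid, inv_two_var, prior)
    flat = cost.reshape(nvox, -1).argmin(axis=1)
    i_nu, i_sig = np.unravel_index(flat, (n_nu, sig0.size))
    nu_hat = nu0[i_nu]
    sig_hat = sig0[i_sig]
    d_sig = sig0[1] - sig0[0]
    on_boundary = (i_nu == 0) | (i_nu == n_nu - 1)

    # zoom refinement around the coarse optimum
    offs = np.linspace(-1.5, 1.5, 13)
    for _ in range(n_zoom):
        nu_grid = nu_hat[:, None] + offs[None, :] * d_nu
        sig_grid = np.clip(sig_hat[:, None] + offs[None, :] * d_sig, 0.0, None)
        cost = _map_cost_grid(y, amp, k, nu_grid, sig_grid, inv_two_var, prior)
        flat = cost.reshape(nvox, -1).argmin(axis=1)
        i_nu, i_sig = np.unravel_index(flat, (offs.size, offs.size))
        nu_hat = np.take_along_axis(nu_grid, i_nu[:, None], axis=1)[:, 0]
        sig_hat = np.take_along_axis(sig_grid, i_sig[:, None], axis=1)[:, 0]
        d_nu *= 3.0 / (offs.size - 1)
        d_sig *= 3.0 / (offs.size - 1)

    # analytic polish (exact for noise-free data):
    # phase-unwrap update of nu using all levels, weighted by |y| k
    w = (np.abs(y) * k[:, None]) ** 2  # (L, nvox)
    resid = np.angle(y * np.exp(1j * k[:, None] * nu_hat[None, :]))
    wsum = w.sum(axis=0)
    good = wsum > 0
    delta = np.zeros(nvox)
    delta[good] = -np.einsum("lv,lv->v", w, resid / k[:, None])[good] / wsum[good]
    nu_hat = nu_hat + delta

    # weighted log-magnitude regression for sigma^2
    with np.errstate(divide="ignore", invalid="ignore"):
        lmag = np.log(np.abs(y) / amp[None, :])
    wm = np.abs(y) ** 2
    valid = np.isfinite(lmag)
    wm = np.where(valid, wm, 0.0)
    lmag = np.where(valid, lmag, 0.0)
    num = -2.0 * np.einsum("lv,l,lv->v", wm, k**2, lmag)
    den = np.einsum("lv,l->v", wm, k**4)
    sig2_hat = np.where(den > 0, num / np.maximum(den, 1e-300), sig_hat**2)

    n_clamped = int(np.count_nonzero(sig2_hat < 0))
    sig2_hat = np.clip(sig2_hat, 0.0, None)
    return nu_hat, sig2_hat, on_boundary | (np.abs(nu_hat) > nu_max), n_clamped


def multipoint_combine(
    sigset: SignalSet,
    sigma_range: tuple[float, float] = (1e-4, 2.0),
    n_zoom: int = 6,
) -> DirectionalEstimates:
    """Combine the per-direction multi-VENC acquisitions into (nu, sigma^2).

    Grid-then-zoom MAP under the Gaussian-IVSD likelihood with flat
    prior on ``nu`` over +/- max(VENC) and log-uniform prior on sigma
    over ``sigma_range`` (the prior only matters in the noisy case).
    The reference phase is subtracted per voxel before fitting; voxels
    with zero reference signal are flagged and excluded.  With a single
    encoding strength the estimate degenerates to the phase of that
    point plus the magnitude-ratio IVSD.
    """
    scheme = sigset.scheme
    mask = sigset.mask & (np.abs(sigset.reference) > 0)
    flagged = sigset.mask & ~mask
    nvox = int(np.count_nonzero(mask))
    shape = sigset.grid.shape
    n_dir = scheme.n_directions
    nu = np.zeros((n_dir,) + shape)
    sigma2 = np.zeros((n_dir,) + shape)
    boundary = np.zeros(shape, dtype=bool)
    n_clamped = 0
    if nvox == 0:
        return DirectionalEstimates(nu, sigma2, flagged, 0)

    ref = sigset.reference[mask]
    amp = np.abs(ref)
    phase_corr = np.conj(ref) / amp
    nu_max = max(scheme.venc_levels)
    k_levels = np.pi / np.asarray(scheme.venc_levels)  # (L,)

    for d in range(n_dir):
        y = sigset.signals[:, d][:, mask] * phase_corr[None, :]  # (L, nvox)
        if scheme.n_levels == 1:
            k = float(k_levels[0])
            nu_d = -np.angle(y[0]) / k
            s2_d, nc = ivsd_single_point(amp, np.abs(y[0]), scheme.kv(0)[d])
            bnd = np.zeros(nvox, dtype=bool)
        else:
            nu_d, s2_d, bnd, nc = _combine_direction(
                y,
                amp,
                k_levels,
                nu_max,
                sigset.sigma_eta,
                sigma_range,
                n_zoom,
            )
        nu[d][mask] = nu_d
        sigma2[d][mask] = s2_d
        boundary[mask] |= bnd
        n_clamped += nc

    if n_clamped:
        log.info("multipoint_combine clamped %d negative IVSD estimates", n_clamped)
    return DirectionalEstimates(nu, sigma2, flagged | boundary, n_clamped)


# ---------------------------------------------------------------------------
# projection to Cartesian maps
# ---------------------------------------------------------------------------


def rst_from_ivsd(
    estimates: DirectionalEstimates,
    scheme: EncodingScheme,
    rho: float,
    psd_project: bool = False,
) -> np.ndarray:
    """Symmetric Reynolds stress (6 components, Pa) from directional IVSDs.

    Solves the per-voxel linear system ``sigma2 = H r`` with the
    pseudoinverse ``r* = (H^T H)^{-1} H^T sigma2``.  No PSD projection
    by default — negative eigenvalues are a genuine artifact signal —
    but an eigenvalue-clipping projection is available.
    """
    h = scheme.h_matrix(rho)
    if np.linalg.matrix_rank(h) < 6:
        raise ValueError("encoding scheme gives a rank-deficient H matrix")
    pinv = np.linalg.solve(h.T @ h, h.T)  # (6, n_directions)
    s2 = estimates.sigma2.reshape(scheme.n_directions, -1)
    r6 = (pinv @ s2).reshape((6,) + estimates.sigma2.shape[1:])
    if psd_project:
        tens = np.moveaxis(rst6_to_tensor(r6), (0, 1), (-2, -1))
        ev, vec = np.linalg.eigh(tens)
        ev = np.clip(ev, 0.0, None)
        fixed = np.einsum("...ij,...j,...kj->...ik", vec, ev, vec)
        from .phantom import tensor_to_rst6

        r6 = tensor_to_rst6(np.moveaxis(fixed, (-2, -1), (0, 1)))
    return r6


def velocity_from_phases(
    estimates: DirectionalEstimates, scheme: EncodingScheme
) -> np.ndarray:
    """Cartesian velocity (3 components) from directional velocities.

    Least-squares solution ``u* = (K^T K)^{-1} K^T nu`` of the
    overdetermined projection system, with K the matrix of unit
    encoding directions.
    """
    k = scheme.k_matrix()
    if np.linalg.matrix_rank(k) < 3:
        raise ValueError("encoding directions do not span 3D space")
    pinv = np.linalg.solve(k.T @ k, k.T)
    nu = estimates.nu.reshape(scheme.n_directions, -1)
    return (pinv @ nu).reshape((3,) + estimates.nu.shape[1:])


def tke_map(rst_star: np.ndarray) -> np.ndarray:
    """Turbulent kinetic energy density, J/m^3: half the tensor trace."""
    return 0.5 * rst_star[..., :3, :, :, :].sum(axis=-4)


def ke_map(u_star: np.ndarray, rho: float) -> np.ndarray:
    """Kinetic energy density of the mean flow, J/m^3."""
    return 0.5 * rho * np.sum(u_star**2, axis=-4)


def reconstruct(
    sigset: SignalSet,
    psd_project: bool = False,
    sigma_range: tuple[float, float] = (1e-4, 2.0),
    n_zoom: int = 6,
) -> ReconResult:
    """Full reconstruction: signals -> u*, R*, TKE and KE maps."""
    est = multipoint_combine(sigset, sigma_range=sigma_range, n_zoom=n_zoom)
    r6 = rst_from_ivsd(est, sigset.scheme, sigset.rho, psd_project=psd_project)
    u = velocity_from_phases(est, sigset.scheme)
    keep = sigset.mask & ~est.flagged
    u = u * keep[None]
    r6 = r6 * keep[None]
    return ReconResult(
        u_star=u,
        rst_star=r6,
        tke=tke_map(r6),
        ke=ke_map(u, sigset.rho),
        mask=keep,
        scheme=sigset.scheme,
        grid=sigset.grid,
        rho=sigset.rho,
        frame_time=sigset.frame_time,
        n_clamped=est.n_clamped,
        flagged=est.flagged,
    )


def write_recon(result: ReconResult, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("u_star", data=result.u_star)
        f.create_dataset("rst_star", data=result.rst_star)
        f.create_dataset("tke", data=result.tke)
        f.create_dataset("ke", data=result.ke)
        f.create_dataset("mask", data=result.mask.astype(np.uint8))
        f.attrs["spacing_mm"] = result.grid.spacing
        f.attrs["origin_mm"] = result.grid.origin
        f.attrs["time_ms"] = result.grid.time_axis
        f.attrs["rho"] = result.rho
        f.attrs["frame_time"] = result.frame_time
        f.attrs["n_clamped"] = result.n_clamped
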