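"""Complex multipoint phase-contrast MR signal synthesis.

For each velocity-encoding point ``k_v = (pi / VENC) * d`` the noise-free
voxel signal is

    S = S0 * exp(-k_v R k_v^T / (2 rho)) * exp(-1j * k_v . u)

with ``S0`` a velocity-magnitude-dependent reference magnitude in
[1/2, 1].  Complex Gaussian noise is scaled by a hypothetical fixed
scan-time budget: ``SNR = alpha * V * sqrt(dt)`` with voxel volume V in
mm^3 and temporal averaging dt in ms, and per-channel standard deviation
``sigma_eta = mean(|S_ref| over the fluid ROI) / SNR``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .phantom import Grid3D, rst6_to_tensor

__all__ = [
    "ORTHOGONAL_DIRECTIONS",
    "EncodingScheme",
    "NoiseSpec",
    "SignalSet",
    "reference_magnitude",
    "encode_signal",
    "add_noise",
    "write_signals",
    "load_signals",
]

_SQ2 = 1.0 / np.sqrt(2.0)

#: six-direction orthogonal velocity-encoding scheme
ORTHOGONAL_DIRECTIONS = np.array(
    [
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
        [_SQ2, _SQ2, 0.0],
        [_SQ2, 0.0, _SQ2],
        [0.0, _SQ2, _SQ2],
    ]
)


@dataclass(frozen=True)
class EncodingScheme:
    """Multi-VENC, multi-direction velocity encoding.

    ``venc_levels`` (m/s) apply to every direction; level 0 is the
    largest VENC (weakest encoding).  The three-level default is a
    geometric ladder, not a published protocol, and is config-exposed.
    """

    directions: np.ndarray = field(
        default_factory=lambda: ORTHOGONAL_DIRECTIONS.copy()
    )
    venc_levels: tuple[float, ...] = (1.5, 0.75, 0.375)

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3 or d.shape[0] < 3:
            raise ValueError("directions must be an (n>=3, 3) matrix")
        norms = np.linalg.norm(d, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero encoding direction")
        d = d / norms[:, None]
        cross = np.abs(d @ d.T) - np.eye(d.shape[0])
        if np.any(cross > 1.0 - 1e-9):
            raise ValueError("encoding directions must be pairwise non-collinear")
        if any(v <= 0 for v in self.venc_levels):
            raise ValueError("VENC values must be positive")
        object.__setattr__(self, "directions", d)
        object.__setattr__(
            self, "venc_levels", tuple(float(v) for v in self.venc_levels)
        )
        h = self.h_matrix(rho=1.0)
        if np.linalg.cond(h) >= 1e3:
            raise ValueError(
                f"ill-conditioned encoding: cond(H) = {np.linalg.cond(h):.1e}"
            )

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]

    @property
    def n_levels(self) -> int:
        return len(self.venc_levels)

    def kv(self, level: int) -> np.ndarray:
        """Encoding vectors (n_directions, 3) in s/m for one VENC level."""
        return (np.pi / self.venc_levels[level]) * self.directions

    def kv_matrix(self) -> np.ndarray:
        """All encoding vectors, shape (n_levels, n_directions, 3)."""
        return np.stack([self.kv(lv) for lv in range(self.n_levels)])

    def h_matrix(self, rho: float) -> np.ndarray:
        """Direction-to-tensor transformation (n_directions, 6).

        Row i maps the symmetric stress vector (xx, yy, zz, xy, xz, yz)
        to the directional variance along direction i; the encoding
        magnitude cancels, so unit directions are used.
        """
        d = self.directions
        return (
            np.column_stack(
                [
                    d[:, 0] ** 2,
                    d[:, 1] ** 2,
                    d[:, 2] ** 2,
                    2 * d[:, 0] * d[:, 1],
                    2 * d[:, 0] * d[:, 2],
                    2 * d[:, 1] * d[:, 2],
                ]
            )
            / rho
        )

    def k_matrix(self) -> np.ndarray:
        """Normalized velocity-projection matrix (n_directions, 3)."""
        return self.directions.copy()


@dataclass(frozen=True)
class NoiseSpec:
    """Scan-time-budget noise model: ``SNR = alpha * V * sqrt(dt)``."""

    alpha: float = 1.68  # mm^-3 ms^-1/2 scaling
    voxel_volume: float = 8.0  # V, mm^3
    delta_t: float = 5.0  # temporal averaging, ms; 0 = noise-free instantaneous
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.voxel_volume <= 0:
            raise ValueError("alpha and voxel_volume must be positive")
        if self.delta_t < 0:
            raise ValueError("delta_t must be >= 0")

    @property
    def snr(self) -> float:
        """Always recomputed from (alpha, V, delta_t)."""
        return self.alpha * self.voxel_volume * np.sqrt(self.delta_t)


@dataclass
class SignalSet:
    """Complex multipoint PC-MRI signals on the measurement grid."""

    signals: np.ndarray  # (n_levels, n_directions, nx, ny, nz) complex
    reference: np.ndarray  # (nx, ny, nz) complex, the k_v = 0 point
    mask: np.ndarray  # fluid ROI on the measurement grid
    scheme: EncodingScheme
    grid: Grid3D
    rho: float
    noise: NoiseSpec | None = None
    frame_time: float = 0.0
    #: per-channel noise std actually applied; None for noise-free sets
    sigma_eta: float | None = None

    def __post_init__(self) -> None:
        expect = (self.scheme.n_levels, self.scheme.n_directions) + self.grid.shape
        if self.signals.shape != expect:
            raise ValueError(f"signals shape {self.signals.shape} != {expect}")
        if not np.all(np.isfinite(self.signals)) or not np.all(
            np.isfinite(self.reference)
        ):
            raise ValueError("non-finite signal values")


def reference_magnitude(u: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Reference (non-velocity-encoded) signal magnitude in [1/2, 1].

    ``S0 = ((|u| / max|u|)^(1/3) + 1) / 2`` with the maximum taken over the
    fluid mask; an all-zero field yields ``S0 = 1/2`` everywhere.
    """
    u = np.asarray(u, dtype=float)
    speed = np.linalg.norm(u, axis=0)
    vmax = speed[mask].max() if mask is not None and np.any(mask) else speed.max()
    if vmax == 0:
        ratio = np.zeros_like(speed)
    else:
        ratio = speed / vmax
    return 0.5 * (np.cbrt(ratio) + 1.0)


def encode_signal(
    u: np.ndarray,
    rst6: np.ndarray,
    mask: np.ndarray,
    scheme: EncodingScheme,
    grid: Grid3D,
    rho: float,
    frame_time: float = 0.0,
) -> SignalSet:
    """Noise-free multipoint signals from measurement-resolution fields.

    ``u`` is (3, nx, ny, nz) in m/s and ``rst6`` (6, nx, ny, nz) in Pa.
    Signals outside the fluid mask are zero (signal void).
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    u = np.asarray(u, dtype=float)
    rst6 = np.asarray(rst6, dtype=float)
    s0 = reference_magnitude(u, mask)
    tens = rst6_to_tensor(rst6)  # (3, 3, nx, ny, nz)
    kvs = scheme.kv_matrix()  # (L, D, 3)
    # attenuation exponent k R k^T / (2 rho) for every encoding point
    att = np.einsum("ldi,ij...,ldj->ld...", kvs, tens, kvs) / (2.0 * rho)
    phase = np.einsum("ldi,i...->ld...", kvs, u)
    if not np.all(np.isfinite(att)):
        bad = np.argwhere(~np.isfinite(att))
        raise ValueError(f"non-finite attenuation exponent, first at {bad[0]}")
    signals = s0[None, None] * np.exp(-att) * np.exp(-1j * phase)
    signals *= mask[None, None]
    reference = (s0 * mask).astype(complex)
    return SignalSet(
        signals=signals,
        reference=reference,
        mask=np.asarray(mask, dtype=bool),
        scheme=scheme,
        grid=grid,
        rho=rho,
        noise=None,
        frame_time=frame_time,
    )


def add_noise(
    sigset: SignalSet, noise: NoiseSpec, rng: np.random.Generator | None = None
) -> SignalSet:
    """Add i.i.d. complex Gaussian noise to every encoding point.

    Per-channel convention: real and imaginary parts each receive
    N(0, sigma_eta) with ``sigma_eta = mean(|S_ref| over ROI) / SNR``;
    the reference point is noisy too.  Raises for SNR <= 0 (use the
    noise-free set directly for instantaneous encoding).
    """
    snr = noise.snr
    if snr <= 0:
        raise ValueError("SNR must be positive to add noise (got delta_t = 0?)")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    sigma = float(np.abs(sigset.reference[sigset.mask]).mean()) / snr
    shape = sigset.signals.shape

    def _cnoise(shp):
        return rng.normal(0.0, sigma, shp) + 1j * rng.normal(0.0, sigma, shp)

    out = SignalSet(
        signals=sigset.signals + _cnoise(shape),
        reference=sigset.reference + _cnoise(sigset.reference.shape),
        mask=sigset.mask,
        scheme=sigset.scheme,
        grid=sigset.grid,
        rho=sigset.rho,
        noise=noise,
        frame_time=sigset.frame_time,
        sigma_eta=sigma,
    )
    return out


# ---------------------------------------------------------------------------
# HDF5 serialization
# ---------------------------------------------------------------------------


def write_signals(sigset: SignalSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=sigset.signals)
        f.create_dataset("reference", data=sigset.reference)
        f.create_dataset("mask", data=sigset.mask.astype(np.uint8))
        f.create_dataset("kv_matrix", data=sigset.scheme.kv_matrix())
        f.create_dataset("directions", data=sigset.scheme.directions)
        f.create_dataset("venc_table", data=np.asarray(sigset.scheme.venc_levels))
        f.attrs["spacing_mm"] = sigset.grid.spacing
        f.attrs["origin_mm"] = sigset.grid.origin
        f.attrs["time_ms"] = sigset.grid.time_axis
        f.attrs["rho"] = sigset.rho
        f.attrs["frame_time"] = sigset.frame_time
        if sigset.noise is not None:
            f.attrs["noise_alpha"] = sigset.noise.alpha
            f.attrs["noise_voxel_volume"] = sigset.noise.voxel_volume
            f.attrs["noise_delta_t"] = sigset.noise.delta_t
            f.attrs["noise_seed"] = sigset.noise.seed
        if sigset.sigma_eta is not None:
            f.attrs["sigma_eta"] = sigset.sigma_eta


def load_signals(path) -> SignalSet:
    with h5py.File(path, "r") as f:
        signals = np.asarray(f["signals"])
        reference = np.asarray(f["reference"])
        mask = np.asarray(f["mask"]).astype(bool)
        scheme = EncodingScheme(
            directions=np.asarray(f["directions"]),
            venc_levels=tuple(np.asarray(f["venc_table"]).tolist()),
        )
        attrs = dict(f.attrs)
    grid = Grid3D(
        shape=tuple(mask.shape),
        spacing=tuple(np.atleast_1d(attrs["spacing_mm"]).astype(float)),
        origin=tuple(np.atleast_1d(attrs.get("origin_mm", (0, 0, 0))).astype(float)),
        time_axis=tuple(np.atleast_1d(attrs["time_ms"]).astype(float)),
    )
    noise = None
    if "noise_alpha" in attrs:
        noise = NoiseSpec(
            alpha=float(attrs["noise_alpha"]),
            voxel_volume=float(attrs["noise_voxel_volume"]),
            delta_t=float(attrs["noise_delta_t"]),
            seed=int(attrs["noise_seed"]),
        )
    return SignalSet(
        signals=signals,
        reference=reference,
        mask=mask,
        scheme=scheme,
        grid=grid,
        rho=float(attrs["rho"]),
        noise=noise,
        frame_time=float(attrs.get("frame_time", 0.0)),
        sigma_eta=float(attrs["sigma_eta"]) if "sigma_eta" in attrs else None,
    )
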