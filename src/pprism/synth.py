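"""Synthetic phantoms, coil maps, shot phases and the forward model.

The forward acquisition model generates multi-shot multi-channel pPRISM
k-space from a 3D phantom: phantom slices are weighted by their refocused
slice profiles and steady-state amplitudes, mixed across intra-slab slices
by the shot-domain partition encoding (including the intra-slab phase
schedule and, optionally, the Bloch-simulated crosstalk), multiplied by the
per-shot motion phase, collapsed per pseudo slab, CAIPI-phase-modulated and
summed over simultaneous slabs, coil-weighted, 2D Fourier transformed
(unitary), and subsampled in-plane.

No diffusion physics is simulated: "diffusion-weighted" phantoms are just
alternative intensity/phase settings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .prism_encoding import PrismPattern, SlicePlan, caipi_blip_kz
from .psf_model import ResolutionMatrix
from .pseudo_slab_rf import PseudoSlabSpec, partition_kz, slice_centers

__all__ = [
    "Phantom",
    "CoilSet",
    "ShotPhaseSet",
    "KSpaceData",
    "make_phantom",
    "make_coils",
    "make_shot_phases",
    "shot_mixing_matrix",
    "ForwardModel",
    "phantom_slices",
    "simulate_acquisition",
]


@dataclass
class Phantom:
    """Complex 3D object sampled on the slice grid; axes (y, x, z)."""

    image: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    z_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=complex)
        if self.image.ndim != 3:
            raise ValueError("phantom image must be 3D (y, x, z)")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("phantom contains non-finite values")
        if self.z_positions is None:
            nz = self.image.shape[2]
            self.z_positions = (
                (np.arange(nz) - (nz - 1) / 2.0) * self.voxel_size[2]
            )
        self.z_positions = np.asarray(self.z_positions, dtype=float)


@dataclass
class CoilSet:
    """Complex sensitivity maps, axes (channel, y, x, z); RSS ~ 1."""

    maps: np.ndarray

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=complex)
        if self.maps.ndim != 4:
            raise ValueError("coil maps must be 4D (ch, y, x, z)")

    @property
    def n_ch(self) -> int:
        return self.maps.shape[0]


@dataclass
class ShotPhaseSet:
    """Smooth in-plane motion phase per shot and slab (radians)."""

    phases: np.ndarray  # [n_shot, n_slab, ny, nx]

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 4:
            raise ValueError("phases must be 4D (shot, slab, y, x)")


@dataclass
class KSpaceData:
    """Sampled multi-shot multi-channel k-space.

    Only acquired ky lines are stored (``ky_indices`` maps them back to the
    full grid); unsampled locations are absent rather than zero-filled.
    """

    y: np.ndarray  # [n_shot, n_ch, n_ky_sampled, nx]
    ky_indices: np.ndarray
    nky_full: int
    pattern: PrismPattern
    plan: SlicePlan
    r_inplane: int = 1
    partial_fourier: float = 1.0
    noise_sigma: float = 0.0

    @property
    def n_shot(self) -> int:
        return self.y.shape[0]

    @property
    def n_ch(self) -> int:
        return self.y.shape[1]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

# Kak & Slaney ellipsoid table for the 3D Shepp-Logan head phantom:
# (intensity, half-axes a, b, c; centre x0, y0, z0; rotation phi deg)
_SHEPP3D = [
    (1.0, 0.69, 0.92, 0.81, 0.0, 0.0, 0.0, 0.0),
    (-0.8, 0.6624, 0.874, 0.78, 0.0, -0.0184, 0.0, 0.0),
    (-0.2, 0.11, 0.31, 0.22, 0.22, 0.0, 0.0, -18.0),
    (-0.2, 0.16, 0.41, 0.28, -0.22, 0.0, 0.0, 18.0),
    (0.1, 0.21, 0.25, 0.41, 0.0, 0.35, -0.15, 0.0),
    (0.1, 0.046, 0.046, 0.05, 0.0, 0.1, 0.25, 0.0),
    (0.1, 0.046, 0.046, 0.05, 0.0, -0.1, 0.25, 0.0),
    (0.1, 0.046, 0.023, 0.05, -0.08, -0.605, 0.0, 0.0),
    (0.1, 0.023, 0.023, 0.02, 0.0, -0.606, 0.0, 0.0),
    (0.1, 0.023, 0.046, 0.02, 0.06, -0.605, 0.0, 0.0),
]


def make_phantom(
    shape: tuple[int, int, int],
    kind: str = "ellipsoids",
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    path: str | None = None,
) -> Phantom:
    """Deterministic piecewise-smooth 3D phantom.

    ``ellipsoids`` draws a handful of random ellipsoids with distinct
    intensities inside a support ellipsoid; ``shepp3d`` is the classic
    head phantom (nonnegative, max 1); ``from_file`` loads a NIfTI volume.
    """
    if any(s <= 0 for s in shape):
        raise ValueError("phantom shape components must be positive")
    ny, nx, nz = shape
    yy, xx, zz = np.meshgrid(
        np.linspace(-1, 1, ny), np.linspace(-1, 1, nx),
        np.linspace(-1, 1, nz), indexing="ij",
    )
    if kind == "shepp3d":
        img = np.zeros(shape)
        for inten, a, b, c, x0, y0, z0, phi in _SHEPP3D:
            p = math.radians(phi)
            xr = (xx - x0) * math.cos(p) + (yy - y0) * math.sin(p)
            yr = -(xx - x0) * math.sin(p) + (yy - y0) * math.cos(p)
            img += inten * (
                (xr / a) ** 2 + (yr / b) ** 2 + ((zz - z0) / c) ** 2 <= 1.0
            )
        img = np.clip(img, 0.0, None)
        if img.max() > 0:
            img = img / img.max()
        return Phantom(img.astype(complex), voxel_size)
    if kind == "ellipsoids":
        rng = np.random.default_rng(seed)
        img = np.where(xx**2 + yy**2 + zz**2 * 0.6 <= 0.8, 0.6, 0.0)
        for _ in range(6):
            ctr = rng.uniform(-0.5, 0.5, size=3)
            ax = rng.uniform(0.1, 0.4, size=3)
            val = rng.uniform(0.2, 1.0)
            mask = (
                ((xx - ctr[0]) / ax[0]) ** 2
                + ((yy - ctr[1]) / ax[1]) ** 2
                + ((zz - ctr[2]) / ax[2]) ** 2
            ) <= 1.0
            img = np.where(mask, val, img)
        return Phantom(img.astype(complex), voxel_size)
    if kind == "from_file":
        import nibabel as nib

        try:
            vol = np.asanyarray(nib.load(path).dataobj)
        except Exception as exc:
            raise IOError(f"cannot read phantom volume {path!r}: {exc}")
        if vol.ndim != 3:
            raise ValueError("phantom file must contain a 3D volume")
        return Phantom(vol.astype(complex), voxel_size)
    raise ValueError(f"unknown phantom kind {kind!r}")


def make_coils(
    n_ch: int,
    shape: tuple[int, int, int],
    smoothness: float = 1.2,
    seed: int = 0,
) -> CoilSet:
    """Smooth complex coil maps, root-sum-of-squares normalized to 1.

    Channels are Gaussian lobes centred on a ring around the object with a
    smooth low-order complex phase; ``n_ch = 1`` returns a constant unit
    map.  ``smoothness`` scales the Gaussian width (larger = flatter).
    """
    if n_ch < 1:
        raise ValueError("n_ch must be >= 1")
    ny, nx, nz = shape
    if n_ch == 1:
        return CoilSet(np.ones((1, ny, nx, nz), complex))
    rng = np.random.default_rng(seed)
    yy, xx, zz = np.meshgrid(
        np.linspace(-1, 1, ny), np.linspace(-1, 1, nx),
        np.linspace(-1, 1, nz), indexing="ij",
    )
    maps = np.empty((n_ch, ny, nx, nz), complex)
    for c in range(n_ch):
        ang = 2 * math.pi * c / n_ch
        cy, cx = 1.3 * math.sin(ang), 1.3 * math.cos(ang)
        cz = 0.8 * math.sin(2 * ang + 0.5)
        sig = smoothness * (1.0 + 0.1 * rng.standard_normal())
        mag = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2
                        + 0.5 * (zz - cz) ** 2) / (2 * sig**2)))
        ph = (0.5 * rng.standard_normal() * yy
              + 0.5 * rng.standard_normal() * xx
              + 0.3 * rng.standard_normal() * zz
              + 0.3 * rng.standard_normal() * yy * xx
              + rng.uniform(0, 2 * math.pi))
        maps[c] = mag * np.exp(1j * ph)
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    return CoilSet(maps / rss[None])


def make_shot_phases(
    n_shot: int,
    n_slab: int,
    shape: tuple[int, int],
    amplitude: float = math.pi / 2,
    seed: int = 0,
    bandwidth_fraction: float = 0.25,
    fix_first_shot: bool = True,
) -> ShotPhaseSet:
    """Slowly varying random phase maps, one per shot and slab.

    Motion-induced phase is dominated by rigid-body terms, so each map is
    a random polynomial up to second order (80 % of the amplitude budget)
    plus a small apodized random field confined to the central
    ``bandwidth_fraction`` k-space window (20 %), scaled so the peak
    magnitude equals ``amplitude`` (radians).  Shot 1 is the zero-phase
    reference by default.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    ny, nx = shape
    rng = np.random.default_rng(seed)
    phases = np.zeros((n_shot, n_slab, ny, nx))
    yy, xx = np.meshgrid(np.linspace(-1, 1, ny), np.linspace(-1, 1, nx),
                         indexing="ij")
    basis = [yy, xx, yy * xx, yy**2, xx**2]
    wy = max(1, int(round(ny * bandwidth_fraction / 2)))
    wx = max(1, int(round(nx * bandwidth_fraction / 2)))
    taper = np.outer(np.hanning(2 * wy + 1) ** 2,
                     np.hanning(2 * wx + 1) ** 2)
    for i in range(n_shot):
        for m in range(n_slab):
            if amplitude == 0 or (fix_first_shot and i == 0):
                continue
            poly = sum(c * b for c, b in
                       zip(rng.standard_normal(len(basis)), basis))
            poly += rng.uniform(-0.5, 0.5)
            k = np.zeros((ny, nx), complex)
            block = (rng.standard_normal((2 * wy + 1, 2 * wx + 1))
                     + 1j * rng.standard_normal((2 * wy + 1, 2 * wx + 1)))
            k[ny // 2 - wy: ny // 2 + wy + 1,
              nx // 2 - wx: nx // 2 + wx + 1] = block * taper
            field = np.fft.ifft2(np.fft.ifftshift(k)).real
            combo = 0.8 * poly / max(np.abs(poly).max(), 1e-30) \
                + 0.2 * field / max(np.abs(field).max(), 1e-30)
            # project onto the allowed band so the smooth-phase contract
            # holds exactly (the polynomial part leaks slightly otherwise)
            kc = np.fft.fftshift(np.fft.fft2(combo))
            mask = np.zeros((ny, nx))
            mask[ny // 2 - wy: ny // 2 + wy + 1,
                 nx // 2 - wx: nx // 2 + wx + 1] = 1.0
            combo = np.fft.ifft2(np.fft.ifftshift(kc * mask)).real
            phases[i, m] = combo / np.abs(combo).max() * amplitude
    return ShotPhaseSet(phases)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def shot_mixing_matrix(
    spec: PseudoSlabSpec,
    n_shot: int | None = None,
    resolution: ResolutionMatrix | None = None,
    slice_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Shot-domain slice mixing matrix ``T`` (``n_shot x n_p``).

    ``x_i = sum_j T[i, j] s_j``: row ``i`` applies the partition-encoding
    phase of shot ``i`` and the intra-slab phase schedule to slice ``j``.
    With ideal profiles ``T = E_shot diag(e^{i phi_j} w_j)``; a supplied
    :class:`ResolutionMatrix` replaces the diagonal with the Bloch
    crosstalk model via ``T = F R`` (``F`` the slice-position DFT).
    """
    n_p = spec.n_p
    if n_shot is None:
        n_shot = n_p
    kz = partition_kz(spec, n_shot)
    zj = slice_centers(spec)
    E = np.exp(-2j * math.pi * np.outer(kz, zj - spec.center_z))
    sched = np.exp(1j * spec.phases)
    if resolution is not None:
        # R already contains profile weighting and the schedule's effect on
        # the profiles; fold the schedule phases explicitly only when R was
        # built schedule-free
        return E @ resolution.R
    w = np.ones(n_p) if slice_weights is None else np.asarray(slice_weights)
    return E * (sched * w)[None, :]


def inject_off_resonance(
    exc_slab, ref_slab, spec: PseudoSlabSpec, delta_f: float,
    oversample: int = 10,
):
    """Regenerate the slab profiles and shot mixing under a uniform
    off-resonance ``delta_f`` (Hz).

    Returns the resolution matrix at ``delta_f`` and the corresponding
    crosstalk-aware shot mixing matrix; ``delta_f = 0`` reproduces the
    on-resonance pipeline.
    """
    from .psf_model import off_resonance_psf

    rm = off_resonance_psf(exc_slab, ref_slab, spec, delta_f, oversample)
    return {"resolution": rm,
            "mixing": shot_mixing_matrix(spec, resolution=rm)}


def _sampled_ky(nky: int, r_inplane: int, partial_fourier: float
                ) -> np.ndarray:
    if not 0.5 <= partial_fourier <= 1.0:
        raise ValueError("partial_fourier must be in [0.5, 1]")
    kept = int(round(nky * partial_fourier))
    return np.arange(0, kept, r_inplane)


class ForwardModel:
    """Linear pPRISM acquisition operator for fixed shot phases.

    Maps per-slab slice images ``s[m, j, y, x]`` to sampled k-space
    ``y[i, ch, ky, x]``.  The 2D Fourier transform is unitary, so the
    adjoint is exact (dot-product test to machine precision).
    """

    def __init__(
        self,
        coils: CoilSet,
        spec: PseudoSlabSpec,
        pattern: PrismPattern,
        plan: SlicePlan,
        phases: ShotPhaseSet | None = None,
        mixing: np.ndarray | None = None,
        r_inplane: int = 1,
        partial_fourier: float = 1.0,
    ) -> None:
        self.coils = coils
        self.spec = spec
        self.pattern = pattern
        self.plan = plan
        n_ch, ny, nx, nz = coils.maps.shape
        self.shape = (ny, nx)
        self.M = pattern.sms_factor
        self.n_p = spec.n_p
        self.n_shot = spec.n_p
        if nz != self.M * self.n_p:
            raise ValueError(
                "coil maps must hold one z sample per slice "
                f"({self.M * self.n_p}), got {nz}"
            )
        if phases is None:
            phases = ShotPhaseSet(
                np.zeros((self.n_shot, self.M, ny, nx))
            )
        if phases.phases.shape != (self.n_shot, self.M, ny, nx):
            raise ValueError("shot-phase set does not match the geometry")
        self.phase_maps = np.exp(1j * phases.phases)
        self.T = (shot_mixing_matrix(spec) if mixing is None else
                  np.asarray(mixing, complex))
        if self.T.shape != (self.n_shot, self.n_p):
            raise ValueError("mixing matrix must be n_shot x n_p")
        self.ky_indices = _sampled_ky(ny, r_inplane, partial_fourier)
        self.r_inplane = r_inplane
        self.partial_fourier = partial_fourier
        # slab-centre coil maps and CAIPI phase per sampled ky line
        self.slab_coils = np.empty((self.M, n_ch, ny, nx), complex)
        for m in range(self.M):
            sl = slice(m * self.n_p, (m + 1) * self.n_p)
            self.slab_coils[m] = coils.maps[:, :, :, sl].mean(axis=3)
        blips = caipi_blip_kz(self.M, pattern.fov_z, ny)
        zm = plan.slab_centers
        self.caipi = np.exp(
            -2j * math.pi * np.outer(zm, blips[self.ky_indices])
        )  # [M, n_ky_samp]

    # -- collapsed slab images per shot ------------------------------------
    def collapse(self, s: np.ndarray) -> np.ndarray:
        """slice images [M, n_p, y, x] -> slab shot images [shot, M, y, x]."""
        x = np.einsum("ij,mjyx->imyx", self.T, s)
        return x * self.phase_maps.transpose(0, 1, 2, 3)

    def collapse_adjoint(self, x: np.ndarray) -> np.ndarray:
        x = x * np.conj(self.phase_maps)
        return np.einsum("ij,imyx->mjyx", np.conj(self.T), x)

    # -- slab images to sampled k-space ------------------------------------
    def encode_slabs(self, x: np.ndarray) -> np.ndarray:
        """slab shot images [shot, M, y, x] -> k-space [shot, ch, ky, x]."""
        n_shot, M, ny, nx = x.shape
        img = np.einsum("mcyx,imyx->imcyx", self.slab_coils, x)
        k = np.fft.fft2(img, axes=(-2, -1), norm="ortho")
        k = k[:, :, :, self.ky_indices, :]
        k = k * self.caipi[None, :, None, :, None]
        return k.sum(axis=1)

    def encode_slabs_adjoint(self, y: np.ndarray) -> np.ndarray:
        n_shot = y.shape[0]
        ny, nx = self.shape
        k = (y[:, None, :, :, :]
             * np.conj(self.caipi)[None, :, None, :, None])
        kfull = np.zeros((n_shot, self.M, y.shape[1], ny, nx), complex)
        kfull[:, :, :, self.ky_indices, :] = k
        img = np.fft.ifft2(kfull, axes=(-2, -1), norm="ortho")
        return np.einsum("mcyx,imcyx->imyx", np.conj(self.slab_coils), img)

    def apply(self, s: np.ndarray) -> np.ndarray:
        return self.encode_slabs(self.collapse(s))

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        return self.collapse_adjoint(self.encode_slabs_adjoint(y))


def phantom_slices(phantom: Phantom, plan: SlicePlan) -> np.ndarray:
    """Ground-truth slice images [M, n_p, y, x] from the phantom's z grid."""
    M = len(plan.slab_centers)
    n_p = len(plan.slice_offsets)
    if phantom.image.shape[2] != M * n_p:
        raise ValueError("phantom z dimension must equal M * n_p")
    s = phantom.image.transpose(2, 0, 1).reshape(
        M, n_p, *phantom.image.shape[:2]
    )
    return s


def simulate_acquisition(
    phantom: Phantom,
    coils: CoilSet,
    spec: PseudoSlabSpec,
    pattern: PrismPattern,
    plan: SlicePlan,
    phases: ShotPhaseSet | None = None,
    mixing: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    r_inplane: int = 1,
    partial_fourier: float = 1.0,
    seed: int = 0,
) -> KSpaceData:
    """Simulate multi-shot multi-channel pPRISM k-space.

    ``mixing`` defaults to the ideal partition-encoding mixing of the
    schedule in ``spec``; pass ``shot_mixing_matrix(spec, resolution=...)``
    to include Bloch-simulated crosstalk.  Noise is circular Gaussian with
    per-sample complex variance ``noise_sigma**2``.
    """
    fm = ForwardModel(coils, spec, pattern, plan, phases, mixing,
                      r_inplane, partial_fourier)
    s = phantom_slices(phantom, plan)
    y = fm.apply(s)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + noise_sigma / math.sqrt(2.0) * (
            rng.standard_normal(y.shape)
            + 1j * rng.standard_normal(y.shape)
        )
    return KSpaceData(y, fm.ky_indices, fm.shape[0], pattern, plan,
                      r_inplane, partial_fourier, noise_sigma)
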