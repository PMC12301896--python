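"""PRISM k_z encoding patterns, pseudo-FOV aliasing and CAIPI blips.

PRISM (Partition-encoded SImultaneous Multislab) encodes the inter-slab and
intra-slab slice positions of a simultaneous-multislab acquisition jointly,
using gradient encoding only.  The k_z sampling comb is the 1D convolution
of a partition-encoding comb (``n_p`` points spaced ``M q / FOV_z``) with an
SMS comb (``M`` points spaced ``q / FOV_z``): a uniform comb of ``M n_p``
points spaced ``q / FOV_z``.  The resulting Fourier bases are mutually
orthogonal over the slice grid exactly when ``gcd(M, q) = 1``; otherwise
slabs overlap after folding into the pseudo FOV (``FOV_z / q``) and the
encoding is rank deficient.

Coordinates: z in mm, k_z in cycles/mm, FOV interval ``[-FOV_z/2, FOV_z/2)``,
combs centred about k_z = 0 so the zero-encoding shot exists for odd counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PrismPattern",
    "SlicePlan",
    "InvalidPatternError",
    "generate_prism_pattern",
    "build_encoding_matrix",
    "pseudo_fov_alias",
    "fold_overlap_energy",
    "caipi_blip_table",
]


class InvalidPatternError(ValueError):
    """The (M, q) combination violates gcd(M, q) = 1."""


@dataclass(frozen=True)
class PrismPattern:
    """A PRISM k_z shot/blip schedule.

    ``kz_values`` is the full encoding basis (length ``M * n_p``);
    ``shot_kz`` holds the ``n_p`` partition offsets actually stepped across
    shots.  ``slice_spacing`` is the intra-slab slice pitch implied by the
    pattern geometry, ``FOV_z / (M q n_p)``.
    """

    sms_factor: int
    n_p: int
    q: int
    fov_z: float
    kz_values: np.ndarray
    shot_kz: np.ndarray
    caipi_blips: np.ndarray

    @property
    def slice_spacing(self) -> float:
        return self.fov_z / (self.sms_factor * self.q * self.n_p)

    @property
    def slab_span(self) -> float:
        return self.fov_z / (self.sms_factor * self.q)

    @property
    def pseudo_fov(self) -> float:
        return self.fov_z / self.q


@dataclass(frozen=True)
class SlicePlan:
    """Slab centres and per-slab slice positions (mm)."""

    slab_centers: np.ndarray
    slice_offsets: np.ndarray  # per-slab offsets relative to slab centre
    interleave_group: int = 1

    @property
    def positions(self) -> np.ndarray:
        """All slice positions, slab-major then slice order."""
        return (self.slab_centers[:, None]
                + self.slice_offsets[None, :]).ravel()


def generate_prism_pattern(
    M: int, n_p: int, q: int, fov_z: float, n_ky: int = 1
) -> PrismPattern:
    """Build the PRISM k_z comb for (``M``, ``n_p``, ``q``, ``FOV_z``).

    Raises :class:`InvalidPatternError` unless ``gcd(M, q) = 1``.
    """
    if M < 1 or n_p < 1 or q < 1:
        raise ValueError("M, n_p and q must all be >= 1")
    if fov_z <= 0:
        raise ValueError("fov_z must be positive")
    if math.gcd(M, q) != 1:
        raise InvalidPatternError(
            f"gcd(M={M}, q={q}) = {math.gcd(M, q)} != 1: slabs would "
            "overlap after pseudo-FOV folding"
        )
    dk = q / fov_z
    n_total = M * n_p
    kz_values = (np.arange(n_total) - (n_total - 1) / 2.0) * dk
    shot_kz = (np.arange(n_p) - (n_p - 1) / 2.0) * (M * dk)
    blips = caipi_blip_kz(M, fov_z, n_ky)
    return PrismPattern(M, n_p, q, fov_z, kz_values, shot_kz, blips)


def default_slice_plan(pattern: PrismPattern) -> SlicePlan:
    """The slice geometry implied by a pattern: ``M`` slabs spaced
    ``FOV_z / M``, each holding ``n_p`` slices at the pattern pitch."""
    M, n_p = pattern.sms_factor, pattern.n_p
    slabs = (np.arange(M) - (M - 1) / 2.0) * (pattern.fov_z / M)
    offs = (np.arange(n_p) - (n_p - 1) / 2.0) * pattern.slice_spacing
    return SlicePlan(slabs, offs)


def build_encoding_matrix(
    pattern: PrismPattern, plan: SlicePlan | None = None
) -> np.ndarray:
    """Fourier encoding matrix ``E[n, s] = exp(-i 2 pi kz_n z_s)``.

    Rows are encoding bases, columns are slice positions.  With a valid
    pattern and the implied slice plan, ``E^H E = (M n_p) I``.
    """
    if plan is None:
        plan = default_slice_plan(pattern)
    z = plan.positions
    n_need = pattern.sms_factor * pattern.n_p
    if len(z) != n_need:
        raise ValueError(f"plan must contain exactly {n_need} slices")
    if len(np.unique(np.round(z, 9))) != len(z):
        raise ValueError("duplicate slice positions")
    return np.exp(-2j * math.pi * np.outer(pattern.kz_values, z))


def pseudo_fov_alias(
    volume: np.ndarray, q: int, z: np.ndarray, axis: int = -1
) -> tuple[np.ndarray, np.ndarray]:
    """Fold a volume into the pseudo FOV ``FOV_z / q`` along ``axis``.

    The z grid must tile the FOV uniformly and contain a multiple of ``q``
    samples; returns the folded volume and its reduced z grid.
    """
    volume = np.asarray(volume)
    z = np.asarray(z, dtype=float)
    nz = volume.shape[axis]
    if len(z) != nz:
        raise ValueError("z grid does not match the volume's z axis")
    if q < 1:
        raise ValueError("q must be >= 1")
    if nz % q:
        raise ValueError(
            f"non-commensurate grid: {nz} z samples not divisible by q={q}"
        )
    if q == 1:
        return volume.copy(), z.copy()
    vol = np.moveaxis(volume, axis, -1)
    sub = nz // q
    folded = vol.reshape(vol.shape[:-1] + (q, sub)).sum(axis=-2)
    return np.moveaxis(folded, -1, axis), z[:sub]


def fold_overlap_energy(
    volume: np.ndarray, q: int, z: np.ndarray, axis: int = -1
) -> float:
    """Total magnitude mass landing on pseudo-FOV voxels fed by more than
    one fold replicate (zero when slabs concatenate without overlap)."""
    volume = np.asarray(volume)
    nz = volume.shape[axis]
    if nz % q:
        raise ValueError("non-commensurate grid")
    vol = np.abs(np.moveaxis(volume, axis, -1))
    sub = nz // q
    folds = vol.reshape(vol.shape[:-1] + (q, sub))
    total = 0.0
    for a in range(q):
        for b in range(a + 1, q):
            total += float((folds[..., a, :] * folds[..., b, :]).sum())
    return total


def caipi_blip_kz(M: int, fov_z: float, n_ky: int) -> np.ndarray:
    """Per-ky-line k_z blip offsets (cycles/mm) for the standard
    blipped-CAIPI ``FOV_z / M`` inter-slab shift."""
    if n_ky < 1:
        raise ValueError("n_ky must be >= 1")
    if M == 1:
        return np.zeros(n_ky)
    return (np.arange(n_ky) % M) / fov_z


def caipi_blip_table(
    pattern: PrismPattern, n_ky: int, slab_center: float = 0.0
) -> dict:
    """CAIPI blip schedule phase-referenced to ``slab_center``.

    Returns the per-ky k_z offsets and the demodulation phasors
    ``exp(-i 2 pi kz * slab_center)`` that make the referenced slab's CAIPI
    phase zero; shifting the slab centre by ``d`` multiplies the phasors by
    ``exp(-i 2 pi kz d)`` (shift theorem).
    """
    kz = caipi_blip_kz(pattern.sms_factor, pattern.fov_z, n_ky)
    phase = np.exp(-2j * math.pi * kz * slab_center)
    return {"kz": kz, "ref_phase": phase, "slab_center": slab_center}
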