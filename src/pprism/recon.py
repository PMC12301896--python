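"""Two-step pPRISM reconstruction.

Step 1 (slab reconstruction): SENSE unaliasing of the simultaneously
excited pseudo slabs per shot, solving ``argmin_x ||y_i - E C x_i||_2^2``
by conjugate gradient on the normal equations; ``E`` contains the in-plane
Fourier encoding, subsampling and the CAIPI phase per ky line.

Step 2 (slice reconstruction): self-navigated phase estimation on 4x
down-sampled slab images using a structured low-rank (block-Hankel across
shots) nuclear-norm penalty plus Tikhonov, with the regularization weights
tied to the data,

    lambda1 = 0.01 ||x_ds||^2 / ||H(s_ini)||_*      and
    lambda2 = 0.1  ||x_ds||^2 / ||s_ini||^2,

followed by magnitude-weighted phase averaging within the pseudo slab,
k-space zero-pad up-sampling to the unit-magnitude phase estimate, and the
final per-slab slice solve

    argmin_s ||x - P Phi s||_2^2 + lambda ||s||_2^2,   lambda = 0.1/N_shot,

where ``P`` combines partition encoding, the intra-slab phase schedule and
(optionally) the Bloch-simulated PSF.  Analytic SENSE g-factor maps
complete the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

from .prism_encoding import caipi_blip_kz
from .synth import CoilSet, ForwardModel, KSpaceData, ShotPhaseSet

__all__ = [
    "ReconParams",
    "sense_unalias",
    "sense_pinv_oracle",
    "downsample_xy",
    "upsample_xy",
    "estimate_phase_lowrank",
    "reconstruct_slices",
    "gfactor_map",
]


@dataclass
class ReconParams:
    """Solver and regularization settings for the two-step recon."""

    lambda1_scale: float = 0.01
    lambda2_scale: float = 0.1
    lambda_final_scale: float = 0.1  # lambda = scale / n_shot
    downsample: int = 4
    hankel_window: int = 3  # k-space patch side for H(.)
    cg_tol: float = 1e-6
    cg_maxiter: int = 200
    lowrank_iters: int = 60
    lowrank_tol: float = 1e-5
    coupling: float = 1.0  # weight tying s to its low-rank projection


# ---------------------------------------------------------------------------
# step 1: SENSE slab unaliasing
# ---------------------------------------------------------------------------

def _slab_system(kdata: KSpaceData, coils: CoilSet):
    """Per-shot SENSE operator pieces shared by solver and oracle."""
    M = kdata.pattern.sms_factor
    n_p = kdata.pattern.n_p
    n_ch = coils.n_ch
    ny = kdata.nky_full
    nx = kdata.y.shape[-1]
    slab_coils = np.empty((M, n_ch, ny, nx), complex)
    for m in range(M):
        sl = slice(m * n_p, (m + 1) * n_p)
        slab_coils[m] = coils.maps[:, :, :, sl].mean(axis=3)
    blips = caipi_blip_kz(M, kdata.pattern.fov_z, ny)
    zm = kdata.plan.slab_centers
    caipi = np.exp(-2j * math.pi
                   * np.outer(zm, blips[kdata.ky_indices]))
    return slab_coils, caipi, (M, n_ch, ny, nx)


def sense_unalias(
    kdata: KSpaceData,
    coils: CoilSet,
    params: ReconParams | None = None,
) -> np.ndarray:
    """Unalias simultaneous pseudo slabs for every shot.

    Returns collapsed (partition-encoded) slab images
    ``x[shot, slab, y, x]`` solving the per-shot least-squares problem by
    conjugate gradient on the normal equations.
    """
    if params is None:
        params = ReconParams()
    slab_coils, caipi, (M, n_ch, ny, nx) = _slab_system(kdata, coils)
    ky = kdata.ky_indices

    def fwd(x):  # [M, ny, nx] -> [n_ch, n_ky, nx]
        img = slab_coils * x[:, None]
        k = np.fft.fft2(img, axes=(-2, -1), norm="ortho")[:, :, ky, :]
        return (k * caipi[:, None, :, None]).sum(axis=0)

    def adj(y):
        k = y[None, :, :, :] * np.conj(caipi)[:, None, :, None]
        kf = np.zeros((M, n_ch, ny, nx), complex)
        kf[:, :, ky, :] = k
        img = np.fft.ifft2(kf, axes=(-2, -1), norm="ortho")
        return (np.conj(slab_coils) * img).sum(axis=1)

    shape = (M, ny, nx)
    size = M * ny * nx

    def normal(v):
        x = v.reshape(shape)
        return adj(fwd(x)).ravel()

    op = LinearOperator((size, size), matvec=normal, dtype=complex)
    out = np.empty((kdata.n_shot, M, ny, nx), complex)
    for i in range(kdata.n_shot):
        rhs = adj(kdata.y[i]).ravel()
        sol, info = cg(op, rhs, rtol=params.cg_tol,
                       maxiter=params.cg_maxiter)
        if info < 0:
            raise RuntimeError(f"CG breakdown in SENSE solve (shot {i})")
        out[i] = sol.reshape(shape)
    return out


def sense_pinv_oracle(kdata: KSpaceData, coils: CoilSet) -> np.ndarray:
    """Dense pseudo-inverse reference for :func:`sense_unalias`.

    Builds the explicit per-shot encoding matrix column by column (the
    forward map applied to unit images) and solves by least squares;
    intended for small instances only.
    """
    slab_coils, caipi, (M, n_ch, ny, nx) = _slab_system(kdata, coils)
    ky = kdata.ky_indices

    def fwd(x):
        img = slab_coils * x[:, None]
        k = np.fft.fft2(img, axes=(-2, -1), norm="ortho")[:, :, ky, :]
        return (k * caipi[:, None, :, None]).sum(axis=0)

    n_unk = M * ny * nx
    cols = []
    basis = np.zeros(n_unk, complex)
    for n in range(n_unk):
        basis[n] = 1.0
        cols.append(fwd(basis.reshape(M, ny, nx)).ravel())
        basis[n] = 0.0
    A = np.stack(cols, axis=1)
    out = np.empty((kdata.n_shot, M, ny, nx), complex)
    for i in range(kdata.n_shot):
        sol, *_ = np.linalg.lstsq(A, kdata.y[i].ravel(), rcond=None)
        out[i] = sol.reshape(M, ny, nx)
    return out


# ---------------------------------------------------------------------------
# in-plane down/up-sampling (k-space window)
# ---------------------------------------------------------------------------

def downsample_xy(images: np.ndarray, factor: int = 4) -> np.ndarray:
    """Low-pass k-space central-window cropping of the last two axes."""
    if factor == 1:
        return images.copy()
    ny, nx = images.shape[-2:]
    if ny % factor or nx % factor:
        raise ValueError("downsample factor must divide the matrix size")
    k = np.fft.fftshift(
        np.fft.fft2(images, axes=(-2, -1), norm="ortho"), axes=(-2, -1)
    )
    my, mx = ny // factor, nx // factor
    y0, x0 = (ny - my) // 2, (nx - mx) // 2
    kc = k[..., y0:y0 + my, x0:x0 + mx]
    out = np.fft.ifft2(np.fft.ifftshift(kc, axes=(-2, -1)),
                       axes=(-2, -1), norm="ortho")
    return out / factor  # keep image amplitudes comparable


def upsample_xy(images: np.ndarray, factor: int = 4) -> np.ndarray:
    """Zero-padded k-space interpolation, inverse of :func:`downsample_xy`."""
    if factor == 1:
        return images.copy()
    ny, nx = images.shape[-2:]
    k = np.fft.fftshift(
        np.fft.fft2(images, axes=(-2, -1), norm="ortho"), axes=(-2, -1)
    )
    NY, NX = ny * factor, nx * factor
    kf = np.zeros(images.shape[:-2] + (NY, NX), complex)
    y0, x0 = (NY - ny) // 2, (NX - nx) // 2
    kf[..., y0:y0 + ny, x0:x0 + nx] = k
    out = np.fft.ifft2(np.fft.ifftshift(kf, axes=(-2, -1)),
                       axes=(-2, -1), norm="ortho")
    return out * factor


# ---------------------------------------------------------------------------
# step 2a: structured low-rank self-navigation
# ---------------------------------------------------------------------------

def _kspace(s: np.ndarray) -> np.ndarray:
    """Centred 2D k-space of the last two axes (unitary)."""
    return np.fft.fftshift(
        np.fft.fft2(s, axes=(-2, -1), norm="ortho"), axes=(-2, -1)
    )


def _ikspace(k: np.ndarray) -> np.ndarray:
    return np.fft.ifft2(
        np.fft.ifftshift(k, axes=(-2, -1)), axes=(-2, -1), norm="ortho"
    )


def _hankel_forward(k: np.ndarray, w: int) -> np.ndarray:
    """Block-Hankel matrix of per-(shot, slice) centred k-space patches.

    ``k``: [n_shot, n_p, ny, nx].  Rows index (slice, patch position),
    columns stack the ``w x w`` patch pixels of every shot: shots of one
    slice differ only by a slowly varying image phase, so smooth
    annihilating filters exist between the shot columns, the filters are
    shared across the slice row blocks, and the matrix is low rank.
    """
    n_shot, n_p, ny, nx = k.shape
    py, px = ny - w + 1, nx - w + 1
    rows = []
    for j in range(n_p):
        cols = [
            np.lib.stride_tricks.sliding_window_view(
                k[i, j], (w, w)
            ).reshape(py * px, w * w)
            for i in range(n_shot)
        ]
        rows.append(np.concatenate(cols, axis=1))
    return np.concatenate(rows, axis=0)


def _hankel_adjoint(Hmat: np.ndarray, w: int, shape) -> np.ndarray:
    """True adjoint of :func:`_hankel_forward` (patch accumulation)."""
    n_shot, n_p, ny, nx = shape
    py, px = ny - w + 1, nx - w + 1
    out = np.zeros(shape, complex)
    for j in range(n_p):
        rows = Hmat[j * py * px:(j + 1) * py * px]
        for i in range(n_shot):
            b = rows[:, i * w * w:(i + 1) * w * w].reshape(py, px, w, w)
            for dy in range(w):
                for dx in range(w):
                    out[i, j, dy:dy + py, dx:dx + px] += b[:, :, dy, dx]
    return out


def _window_counts(ny: int, nx: int, w: int) -> np.ndarray:
    """Diagonal of H^H H: number of patches covering each k-space sample."""
    c = np.zeros((ny, nx))
    py, px = ny - w + 1, nx - w + 1
    for dy in range(w):
        for dx in range(w):
            c[dy:dy + py, dx:dx + px] += 1
    return c


def _svt(M: np.ndarray, tau: float) -> tuple[np.ndarray, float]:
    """Singular-value soft threshold; returns the result and the nuclear
    norm of the input."""
    U, sv, Vh = np.linalg.svd(M, full_matrices=False)
    nuc = float(sv.sum())
    sv = np.maximum(sv - tau, 0.0)
    return (U * sv) @ Vh, nuc


def _per_pixel_solve(T: np.ndarray, x: np.ndarray, ridge: float,
                     mu: float, prior: np.ndarray) -> np.ndarray:
    """Solve, independently per shot and pixel,
    ``argmin_s |x_i - T_i s_i|^2 + ridge |s_i|^2 + mu |s_i - prior_i|^2``.

    ``T``: [n_shot, n_p]; ``x``: [n_shot, ny, nx];
    ``prior``/result: [n_shot, n_p, ny, nx].  Sherman-Morrison on the
    rank-one row normal matrix gives the closed form.
    """
    n_shot, n_p = T.shape
    out = np.empty_like(prior)
    d = ridge + mu
    for i in range(n_shot):
        t = T[i]
        tt = float(np.vdot(t, t).real)
        if d == 0.0:
            # minimum-norm least-squares solution of the single equation
            out[i] = np.conj(t)[:, None, None] * x[i][None] / tt
            continue
        rhs = (np.conj(t)[:, None, None] * x[i][None]
               + mu * prior[i])  # [n_p, ny, nx]
        # (conj(t) t^T + d I)^{-1} = (I - conj(t) t^T / (d + |t|^2)) / d
        proj = np.tensordot(t, rhs, axes=(0, 0))  # [ny, nx]
        out[i] = (rhs - np.conj(t)[:, None, None] * proj[None]
                  / (d + tt)) / d
    return out


def estimate_phase_lowrank(
    x_ds: np.ndarray,
    T: np.ndarray,
    params: ReconParams | None = None,
    support: np.ndarray | None = None,
) -> dict:
    """Self-navigated shot-phase estimation for one pseudo slab.

    ``x_ds``: down-sampled collapsed slab images [n_shot, ny, nx];
    ``T``: shot mixing matrix (partition encoding + schedule + PSF).
    Returns the per-shot slice images, the slab-averaged phase per shot at
    the down-sampled resolution, the unit-magnitude full-resolution
    estimate (up-sampled by ``params.downsample``) and the lambda values.
    """
    if params is None:
        params = ReconParams()
    n_shot, ny, nx = x_ds.shape
    n_p = T.shape[1]
    w = params.hankel_window
    shape = (n_shot, n_p, ny, nx)

    zeros = np.zeros(shape, complex)
    s_ini = _per_pixel_solve(T, x_ds, 0.0, 0.0, zeros)
    xnorm2 = float(np.vdot(x_ds, x_ds).real)
    _, nuc_ini = _svt(_hankel_forward(_kspace(s_ini), w), 0.0)
    s_norm2 = float(np.vdot(s_ini, s_ini).real)
    lam1 = params.lambda1_scale * xnorm2 / max(nuc_ini, 1e-30)
    lam2 = params.lambda2_scale * xnorm2 / max(s_norm2, 1e-30)

    # ADMM on the split Z = H(F s): SVT for Z, CG for the quadratic
    # s-subproblem (data term is per-pixel rank-one, H^H H is diagonal in
    # k-space, but their sum is not jointly diagonalizable)
    rho = 2.0 * lam1 * params.coupling
    counts = _window_counts(ny, nx, w)
    phx = np.stack([
        np.conj(T[i])[:, None, None] * x_ds[i][None]
        for i in range(n_shot)
    ])

    def php(s):
        out = np.empty_like(s)
        for i in range(n_shot):
            proj = np.tensordot(T[i], s[i], axes=(0, 0))
            out[i] = np.conj(T[i])[:, None, None] * proj[None]
        return out

    def normal_op(v):
        s = v.reshape(shape)
        hterm = _ikspace(_kspace(s) * counts)
        return (php(s) + lam2 * s + (rho / 2.0) * hterm).ravel()

    op = LinearOperator((s_ini.size, s_ini.size), matvec=normal_op,
                        dtype=complex)
    s = s_ini.copy()
    Z = _hankel_forward(_kspace(s), w)
    U = np.zeros_like(Z)
    it = 0
    for it in range(params.lowrank_iters):
        Hs = _hankel_forward(_kspace(s), w)
        Z, _ = _svt(Hs + U, lam1 / rho)
        U = U + Hs - Z
        rhs = phx + (rho / 2.0) * _ikspace(
            _hankel_adjoint(Z - U, w, shape)
        )
        sol, info = cg(op, rhs.ravel(), x0=s.ravel(), rtol=1e-8,
                       maxiter=60)
        if info < 0:
            raise RuntimeError("CG breakdown in low-rank phase solve")
        s_new = sol.reshape(shape)
        delta = np.linalg.norm(s_new - s) / max(np.linalg.norm(s), 1e-30)
        s = s_new
        if delta < params.lowrank_tol:
            break

    # average the slice estimates within the pseudo slab (magnitude-
    # weighted circular mean of the phases = phase of the mean image),
    # up-sample the mean image, then take its phase
    slab_mean = s.sum(axis=1)
    slab_phase = np.angle(slab_mean)
    mean_full = upsample_xy(slab_mean, params.downsample)
    mag = np.abs(mean_full)
    phase_full = np.where(mag > 0, mean_full / np.maximum(mag, 1e-30),
                          1.0 + 0.0j)
    return {
        "slices": s,
        "slab_phase_ds": slab_phase,
        "phase": phase_full,
        "lambda1": lam1,
        "lambda2": lam2,
        "iterations": it + 1,
    }


# ---------------------------------------------------------------------------
# step 2b: final slice reconstruction
# ---------------------------------------------------------------------------

def reconstruct_slices(
    x_full: np.ndarray,
    phase: np.ndarray,
    T: np.ndarray,
    params: ReconParams | None = None,
) -> np.ndarray:
    """Solve ``argmin_s ||x - P Phi s||^2 + lambda ||s||^2`` per pseudo slab.

    ``x_full``: collapsed slab images [n_shot, ny, nx]; ``phase``:
    unit-magnitude shot phases of the same shape; ``T``: shot mixing
    matrix.  Because ``|Phi| = 1``, the per-pixel normal matrix is the
    shot-mixing Gram ``T^H T + lambda I`` everywhere, so the normal
    equations are solved exactly in closed form (the fixed point any
    conjugate-gradient run converges to).
    """
    if params is None:
        params = ReconParams()
    n_shot, ny, nx = x_full.shape
    n_p = T.shape[1]
    if phase.shape != x_full.shape:
        raise ValueError("phase maps must match the slab images")
    if not np.allclose(np.abs(phase), 1.0, atol=1e-6):
        raise ValueError("phase estimate must have unit magnitude")
    lam = params.lambda_final_scale / n_shot
    G = T.conj().T @ T + lam * np.eye(n_p)
    Ginv = np.linalg.inv(G)
    rhs = np.einsum("ij,iyx->jyx", np.conj(T),
                    np.conj(phase) * x_full)
    return np.einsum("jk,kyx->jyx", Ginv, rhs)


# ---------------------------------------------------------------------------
# g-factor
# ---------------------------------------------------------------------------

def gfactor_map(
    coils: CoilSet,
    pattern,
    plan,
    r_inplane: int = 1,
) -> np.ndarray:
    """Analytic SENSE g-factor for the CAIPI-shifted slab unaliasing.

    Returns ``g[m, y, x] >= 1`` per slab; voxels with a singular unaliasing
    system are set to ``inf``.  The blipped-CAIPI kz modulation appears as
    a relative in-plane shift of ``m * ny / M`` between slabs, so each
    output voxel unaliases a set of ``r_inplane * M`` source voxels.
    """
    M = pattern.sms_factor
    n_p = pattern.n_p
    n_ch, ny, nx, nz = coils.maps.shape
    if nz != M * n_p:
        raise ValueError("coil maps must hold one z sample per slice")
    slab_coils = np.empty((M, n_ch, ny, nx), complex)
    for m in range(M):
        sl = slice(m * n_p, (m + 1) * n_p)
        slab_coils[m] = coils.maps[:, :, :, sl].mean(axis=3)
    if ny % r_inplane:
        raise ValueError("r_inplane must divide the matrix size")
    if M > 1 and ny % M:
        raise ValueError("sms_factor must divide the matrix size")

    g = np.ones((M, ny, nx))
    shift = ny // M if M > 1 else 0
    fold = ny // r_inplane
    done = np.zeros((M, ny, nx), bool)
    for y in range(fold):
        for x in range(nx):
            src = [
                (m, (y + t * fold + m * shift) % ny)
                for t in range(r_inplane)
                for m in range(M)
            ]
            C = np.stack(
                [slab_coils[m, :, ys, x] for (m, ys) in src], axis=1
            )  # [n_ch, n_src]
            N = C.conj().T @ C
            dN = np.diag(N).real
            try:
                Ninv = np.linalg.inv(N)
                gv = np.sqrt(np.maximum(np.diag(Ninv).real * dN, 0.0))
            except np.linalg.LinAlgError:
                gv = np.full(len(src), np.inf)
            for (m, ys), val in zip(src, gv):
                if not done[m, ys, x]:
                    g[m, ys, x] = val if np.isfinite(val) else np.inf
                    done[m, ys, x] = True
    return g
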