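"""Single-slice RF pulse design (Shinnar-Le Roux) and Bloch simulation.

The slice-selective pulses used throughout the package are designed with the
Shinnar-Le Roux (SLR) transform: a desired slice profile is expressed as a
polynomial ``B(z)`` (the "beta" filter), the companion minimum-phase "alpha"
polynomial is recovered from ``|A|^2 = 1 - |B|^2``, and the hard-pulse
recursion is inverted to obtain the RF waveform.  Spatial magnetization
profiles are computed with a spinor-domain (Cayley-Klein) hard-pulse Bloch
simulator, which is exact for piecewise-constant B1 and gradient.

Conventions
-----------
* ``z`` is in millimetres, slice centre at z = 0.
* Gradients are in mT/m and constant during the pulse (no VERSE).
* RF ``samples`` are stored as complex nutation angles per sample interval
  (radians); the on-resonance flip at slice centre is ``|sum(samples)|``.
* Excitation profiles are the transverse magnetization ``mxy = 2 conj(a) b``
  from thermal equilibrium; refocusing profiles are the crushed-spin-echo
  response ``b**2`` (the factor multiplying the conjugated excitation
  profile in a spin echo with ideal crushers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import signal as sps

__all__ = [
    "GAMMA_HZ_PER_MT_M_MM",
    "RFPulse",
    "SliceProfile",
    "design_slr",
    "simulate_profile",
    "refocused_signal",
    "profile_metrics",
]

# gyromagnetic ratio of 1H: 42.577478 MHz/T expressed as
# Hz of off-resonance per (mT/m of gradient) per (mm of position)
GAMMA_HZ_PER_MT_M_MM = 42.577478

# default nominal slice thickness (mm); 0.86 mm matches the package's
# default submillimetre protocol
DEFAULT_SLICE_THICKNESS_MM = 0.86


class DesignError(RuntimeError):
    """Raised when an RF pulse design is unattainable."""


@dataclass
class RFPulse:
    """A sampled RF pulse with its constant slice-select gradient.

    Attributes
    ----------
    samples : complex ndarray
        Nutation angle per sample (radians).  ``|sum(samples)|`` is the
        on-resonance flip angle at slice centre.
    dt : float
        Sample interval (s).
    grad : float
        Slice-select gradient amplitude (mT/m), constant during the pulse.
    nominal_flip : float
        Nominal flip angle (degrees).
    time_bandwidth : float
        Dimensionless time-bandwidth product of the base design.
    role : str
        ``"excitation"`` or ``"refocusing"``.
    """

    samples: np.ndarray
    dt: float
    grad: float
    nominal_flip: float
    time_bandwidth: float
    role: Literal["excitation", "refocusing"] = "excitation"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)

    @property
    def duration(self) -> float:
        """Total pulse length (s)."""
        return len(self.samples) * self.dt

    @property
    def bandwidth(self) -> float:
        """RF bandwidth (Hz) implied by the time-bandwidth product."""
        return self.time_bandwidth / self.duration

    @property
    def times(self) -> np.ndarray:
        """Sample times (s), referenced to the pulse centre."""
        n = len(self.samples)
        return (np.arange(n) - (n - 1) / 2.0) * self.dt

    def resampled(self, n: int) -> "RFPulse":
        """Return the pulse interpolated onto ``n`` samples.

        The complex envelope is linearly interpolated and rescaled so the
        integrated nutation angle is preserved; used before composing
        frequency-shifted copies, where a finer raster is needed to
        represent large modulation frequencies.
        """
        if n == len(self.samples):
            return self
        old_t = np.linspace(0.0, 1.0, len(self.samples))
        new_t = np.linspace(0.0, 1.0, n)
        re = np.interp(new_t, old_t, self.samples.real)
        im = np.interp(new_t, old_t, self.samples.imag)
        scale = len(self.samples) / n
        return RFPulse(
            samples=(re + 1j * im) * scale,
            dt=self.duration / n,
            grad=self.grad,
            nominal_flip=self.nominal_flip,
            time_bandwidth=self.time_bandwidth,
            role=self.role,
        )


@dataclass
class SliceProfile:
    """Complex transverse response sampled on a uniform spatial grid."""

    z: np.ndarray
    mxy: np.ndarray
    kind: Literal["excitation", "refocused"] = "excitation"
    off_resonance: float = 0.0

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.mxy = np.asarray(self.mxy, dtype=complex)
        if self.z.shape != self.mxy.shape:
            raise ValueError("z and mxy grids differ in shape")

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0]) if len(self.z) > 1 else 0.0


# ---------------------------------------------------------------------------
# SLR design
# ---------------------------------------------------------------------------

def _dinf(d1: float, d2: float) -> float:
    """Empirical transition-width factor of a Parks-McClellan filter."""
    a = (5.309e-3, 7.114e-2, -4.761e-1, -2.66e-3, -5.941e-1, -4.278e-1)
    l1, l2 = math.log10(d1), math.log10(d2)
    return (a[0] * l1 * l1 + a[1] * l1 + a[2]) * l2 + (
        a[3] * l1 * l1 + a[4] * l1 + a[5]
    )


def _min_phase_from_mag(mag: np.ndarray, n: int) -> np.ndarray:
    """First ``n`` coefficients of the minimum-phase sequence with the
    given magnitude response (cepstral method)."""
    big = len(mag)
    logm = np.log(np.maximum(mag, 1e-12))
    cep = np.fft.ifft(logm)
    fold = np.zeros(big)
    fold[0] = 1.0
    fold[1 : big // 2] = 2.0
    fold[big // 2] = 1.0
    spec = np.exp(np.fft.fft(cep * fold))
    return np.fft.ifft(spec)[:n]


def _ab2rf(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Invert the SLR hard-pulse recursion.

    ``a`` and ``b`` are the coefficient arrays of the Cayley-Klein
    polynomials in powers of z^-1.  Returns the complex nutation angles
    (radians) of the hard-pulse train.
    """
    n = len(a)
    a = a.astype(complex).copy()
    b = b.astype(complex).copy()
    rf = np.zeros(n, dtype=complex)
    for j in range(n, 0, -1):
        ratio = b[0] / a[0]
        phi = 2.0 * math.atan(abs(ratio))
        c = 1.0 / math.sqrt(1.0 + abs(ratio) ** 2)
        s = ratio * c  # the complex S_j = i e^{i theta} sin(phi/2)
        theta = np.angle(s) - math.pi / 2.0
        rf[j - 1] = phi * np.exp(1j * theta)
        a_new = c * a + np.conj(s) * b
        b_new = -s * a + c * b
        a = a_new[: j - 1]
        b = b_new[1:j]
    return rf


def _beta_filter(
    n: int,
    tb: float,
    window: str,
    role: str,
    ripple: tuple[float, float],
) -> np.ndarray:
    """Design the linear-phase beta filter (unit passband gain)."""
    if window == "hamming":
        k = np.arange(n) - (n - 1) / 2.0
        h = np.sinc(tb * k / n) * np.hamming(n)
        return h / h.sum()
    if window != "none":
        raise ValueError(f"unknown window {window!r}")
    d1, d2 = ripple
    # translate magnetization ripples into beta-polynomial ripples
    if role == "excitation":
        d1b, d2b = math.sqrt(d1 / 2.0), d2 / math.sqrt(2.0)
    else:  # refocusing (spin-echo)
        d1b, d2b = d1 / 4.0, math.sqrt(d2)
    w = _dinf(d1b, d2b) / tb  # fractional transition width
    # the dinf estimate is approximate: widen the transition until the
    # achieved passband ripple respects the requested beta ripple
    for _ in range(16):
        f_pass = (1.0 - w) * tb / (2.0 * n)
        f_stop = (1.0 + w) * tb / (2.0 * n)
        if not 0.0 < f_pass < f_stop < 0.5:
            raise DesignError(
                "unattainable ripple/transition combination: "
                f"pass={f_pass:.4g}, stop={f_stop:.4g} cycles/sample"
            )
        try:
            h = sps.remez(n, [0.0, f_pass, f_stop, 0.5], [1.0, 0.0],
                          weight=[1.0 / d1b, 1.0 / d2b], fs=1.0)
        except Exception as exc:  # pragma: no cover - remez failure path
            raise DesignError(
                f"Parks-McClellan design failed: {exc}") from exc
        if not np.all(np.isfinite(h)):
            raise DesignError("Parks-McClellan design did not converge")
        resp = np.abs(np.fft.fft(h, 16 * n))
        freqs = np.fft.fftfreq(16 * n)
        pb = resp[np.abs(freqs) <= f_pass]
        if pb.max() - 1.0 <= 1.05 * d1b and 1.0 - pb.min() <= 1.05 * d1b:
            return h
        w *= 1.15
    raise DesignError("could not meet the requested passband ripple")


def design_slr(
    nominal_flip: float,
    duration: float,
    time_bandwidth: float,
    window: str = "none",
    role: str = "excitation",
    *,
    n: int = 512,
    slice_thickness: float = DEFAULT_SLICE_THICKNESS_MM,
    ripple: tuple[float, float] = (0.01, 0.01),
) -> RFPulse:
    """Design a linear-phase SLR pulse.

    Parameters
    ----------
    nominal_flip : float
        Flip angle in degrees.  Refocusing pulses must be 180.
    duration : float
        Pulse duration (s).
    time_bandwidth : float
        Dimensionless time-bandwidth product; the RF bandwidth is
        ``time_bandwidth / duration`` Hz.
    window : str
        ``"none"`` for an equiripple (Parks-McClellan) beta filter with the
        given ripples, ``"hamming"`` for a Hamming-windowed sinc.
    role : str
        ``"excitation"`` or ``"refocusing"``.
    n : int
        Number of RF samples.
    slice_thickness : float
        Nominal slice thickness (mm); sets the slice-select gradient via
        ``grad = bandwidth / (gamma * thickness)``.
    ripple : (float, float)
        Passband and stopband magnetization ripple for ``window="none"``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if time_bandwidth < 1:
        raise ValueError("time_bandwidth must be >= 1")
    if role not in ("excitation", "refocusing"):
        raise ValueError(f"unknown role {role!r}")
    if role == "refocusing" and nominal_flip not in (0.0, 180.0):
        raise ValueError("refocusing pulses must have nominal_flip = 180")

    bandwidth = time_bandwidth / duration
    grad = bandwidth / (GAMMA_HZ_PER_MT_M_MM * slice_thickness)
    dt = duration / n

    if nominal_flip == 0.0:
        return RFPulse(np.zeros(n, complex), dt, grad, 0.0,
                       time_bandwidth, role)

    b = _beta_filter(n, time_bandwidth, window, role, ripple)

    # calibrate the beta polynomial: centre-of-slice (DC) response equals
    # sin(flip/2) exactly, unless ripple overshoot would push |b| past 1,
    # in which case the peak is pinned just below 1 (refocusing pulses)
    big = 8 * n
    bspec = np.fft.fft(b, big)
    target = math.sin(math.radians(nominal_flip) / 2.0)
    scale = target / np.abs(bspec[0])
    bmax = np.abs(bspec).max()
    if bmax * scale > 1.0 - 1e-6:
        scale = (1.0 - 1e-6) / bmax
    b = b * scale
    bspec = bspec * scale

    amag = np.sqrt(np.maximum(1.0 - np.abs(bspec) ** 2, 0.0))
    a = _min_phase_from_mag(amag, n)
    rf = _ab2rf(a, b.astype(complex))
    # rotate so the pulse lies (nearly) along the +x RF axis
    rf = rf * np.exp(-1j * np.angle(rf[np.argmax(np.abs(rf))]))
    return RFPulse(rf, dt, grad, nominal_flip, time_bandwidth, role)


# ---------------------------------------------------------------------------
# Bloch simulation
# ---------------------------------------------------------------------------

def _spinor_simulate(
    samples: np.ndarray, dt: float, freq: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hard-pulse spinor simulation.

    ``freq`` is the local off-resonance (Hz) per spatial position.  Returns
    the Cayley-Klein parameters ``(a, b)`` per position.
    """
    nz = len(freq)
    a = np.ones(nz, dtype=complex)
    b = np.zeros(nz, dtype=complex)
    psi = 2.0 * math.pi * freq * dt  # z-rotation per sample
    for s in samples:
        bx, by = s.real, s.imag
        phi = np.sqrt(bx * bx + by * by + psi * psi)
        with np.errstate(invalid="ignore", divide="ignore"):
            inv = np.where(phi > 0, 1.0 / np.where(phi > 0, phi, 1.0), 0.0)
        nx, ny, nz_ax = bx * inv, by * inv, psi * inv
        cos = np.cos(phi / 2.0)
        sin = np.sin(phi / 2.0)
        al = cos - 1j * sin * nz_ax
        be = -1j * sin * (nx + 1j * ny)
        a, b = al * a - np.conj(be) * b, be * a + np.conj(al) * b
    return a, b


def simulate_profile(
    pulse: RFPulse,
    z_grid: np.ndarray,
    off_resonance: float = 0.0,
    t1: float = math.inf,
    t2: float = math.inf,
) -> SliceProfile:
    """Bloch-simulate the spatial magnetization profile of a pulse.

    For ``role="excitation"`` the transverse magnetization after the pulse
    (from thermal equilibrium) is returned.  For ``role="refocusing"`` the
    crushed-spin-echo refocusing response ``b(z)**2`` is returned: the
    complex factor that multiplies the conjugated excitation profile to
    give the refocused signal, assuming ideal crushers.

    Relaxation during the pulse is ignored by default (``t1 = t2 = inf``);
    finite relaxation is supported for excitation profiles only.
    """
    z = np.asarray(z_grid, dtype=float)
    if len(z) > 1:
        steps = np.diff(z)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("z_grid must be uniform")
    if pulse.bandwidth > 0 and pulse.dt > 1.0 / (8.0 * pulse.bandwidth):
        raise ValueError(
            "dt too coarse: need >= 8 samples per RF-bandwidth period"
        )
    freq = GAMMA_HZ_PER_MT_M_MM * pulse.grad * z + off_resonance

    finite_relax = math.isfinite(t1) or math.isfinite(t2)
    # the slice-gradient rephasing lobe (area = half the pulse) rewinds the
    # linear gradient phase of the excitation profile; the refocusing b**2
    # response is already echo-referenced in this spinor convention
    # (symmetric crusher timing)
    grad_freq = GAMMA_HZ_PER_MT_M_MM * pulse.grad * z

    if not finite_relax:
        a, b = _spinor_simulate(pulse.samples, pulse.dt, freq)
        if pulse.role == "refocusing":
            mxy = b * b
            kind = "refocused"
        else:
            mxy = (2.0 * np.conj(a) * b
                   * np.exp(-1j * math.pi * grad_freq * pulse.duration))
            kind = "excitation"
        return SliceProfile(z, mxy, kind, off_resonance)

    if pulse.role == "refocusing":
        raise NotImplementedError(
            "finite relaxation is only supported for excitation profiles"
        )
    mxy = _magnetization_simulate(pulse.samples, pulse.dt, freq, t1, t2)
    mxy = mxy * np.exp(-1j * math.pi * grad_freq * pulse.duration)
    return SliceProfile(z, mxy, "excitation", off_resonance)


def _magnetization_simulate(
    samples: np.ndarray,
    dt: float,
    freq: np.ndarray,
    t1: float,
    t2: float,
) -> np.ndarray:
    """Magnetization-domain hard-pulse loop with inter-sample relaxation."""
    nz = len(freq)
    m = np.zeros((3, nz))
    m[2] = 1.0
    e1 = math.exp(-dt / t1) if math.isfinite(t1) else 1.0
    e2 = math.exp(-dt / t2) if math.isfinite(t2) else 1.0
    psi = 2.0 * math.pi * freq * dt
    for s in samples:
        # rotation by |axis| about axis (Rodrigues), axis in radians
        ax = np.array([s.real * np.ones(nz), s.imag * np.ones(nz), psi])
        ang = np.sqrt((ax * ax).sum(axis=0))
        safe = np.where(ang > 0, ang, 1.0)
        u = ax / safe
        cos, sin = np.cos(ang), np.sin(ang)
        dot = (u * m).sum(axis=0)
        cross = np.cross(u.T, m.T).T
        m = m * cos + cross * sin + u * dot * (1.0 - cos)
        m[0] *= e2
        m[1] *= e2
        m[2] = 1.0 + (m[2] - 1.0) * e1
    return m[0] + 1j * m[1]


def refocused_signal(
    excitation: SliceProfile, refocusing: SliceProfile
) -> SliceProfile:
    """Crushed-spin-echo signal: ``conj(mxy_ex) * b_ref**2``."""
    if excitation.z.shape != refocusing.z.shape or not np.allclose(
        excitation.z, refocusing.z
    ):
        raise ValueError("profiles are sampled on different grids")
    mxy = np.conj(excitation.mxy) * refocusing.mxy
    return SliceProfile(excitation.z, mxy, "refocused",
                        excitation.off_resonance)


# ---------------------------------------------------------------------------
# profile quality metrics
# ---------------------------------------------------------------------------

def profile_metrics(
    profile: SliceProfile, ideal_slice: tuple[float, float]
) -> dict:
    """In-slice fluctuation and integration fraction of a profile.

    ``in_slice_fluctuation`` is the peak deviation of the real part of the
    (constant-phase-removed) profile from its in-slice mean, in percent of
    that mean.  ``integration_fraction`` is the magnitude of the integral
    over the ideal slice divided by (slice width x peak attainable signal),
    in percent.
    """
    z_lo, z_hi = ideal_slice
    if z_lo >= z_hi:
        raise ValueError("empty ideal slice")
    if z_lo < profile.z[0] or z_hi > profile.z[-1]:
        raise ValueError("ideal slice outside the profile grid")
    mask = (profile.z >= z_lo) & (profile.z <= z_hi)
    if not mask.any():
        raise ValueError("ideal slice contains no grid points")
    inner = profile.mxy[mask]
    # remove the best-fit constant phase
    phase0 = np.angle(inner.sum())
    flat = inner * np.exp(-1j * phase0)
    mean_re = flat.real.mean()
    if mean_re == 0:
        raise ValueError("zero in-slice signal")
    fluct = 100.0 * np.max(np.abs(flat.real - mean_re)) / abs(mean_re)

    dz = profile.dz
    integral = np.abs(profile.mxy[mask].sum() * dz)
    max_signal = np.abs(profile.mxy).max()
    width = z_hi - z_lo
    frac = 100.0 * integral / (width * max_signal)
    return {"in_slice_fluctuation": float(fluct),
            "integration_fraction": float(frac)}
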