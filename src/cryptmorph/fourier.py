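"""Low-level periodic Fourier-spectral primitives.

All fields live on a uniform periodic grid of ``n`` points over a domain of
physical length ``L`` (computational coordinate xi in [0, 1), physical
coordinate s = xi * L).  ``n`` must be even so the Nyquist mode is
unambiguous.  These helpers are re-exported by :mod:`cryptmorph.spectral_engine`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wavenumbers",
    "spectral_derivative",
    "periodic_antiderivative",
    "exponential_filter",
    "apply_filter",
    "helmholtz_solve",
]


def _check_even(n: int) -> None:
    if n % 2 != 0:
        raise ValueError(f"grid length must be even for FFT differentiation, got {n}")


def wavenumbers(n: int, L: float) -> np.ndarray:
    """Physical wavenumbers k_j = 2*pi*j/L for the rfft layout (j = 0..n/2)."""
    _check_even(n)
    return 2.0 * np.pi * np.arange(n // 2 + 1) / L


def spectral_derivative(f: np.ndarray, order: int, L: float) -> np.ndarray:
    """Spectral derivative of a periodic field.

    Exact for band-limited inputs.  For odd ``order`` the Nyquist mode is
    zeroed (its derivative is not representable on the grid), which keeps the
    result real and the operator skew-symmetric.
    """
    f = np.asarray(f, dtype=float)
    _check_even(f.size)
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite values in field")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    k = wavenumbers(f.size, L)
    fh = np.fft.rfft(f)
    if order == 1:
        fh = 1j * k * fh
        fh[-1] = 0.0
    else:
        fh = -(k**2) * fh
    return np.fft.irfft(fh, n=f.size)


def periodic_antiderivative(f: np.ndarray, L: float) -> np.ndarray:
    """Zero-mean periodic antiderivative of the fluctuating part of ``f``.

    Returns g with dg/ds = f - mean(f) and mean(g) = 0.  The mean of ``f``
    has no periodic antiderivative and must be handled by the caller (for the
    velocity closure it is absorbed into domain growth).
    """
    f = np.asarray(f, dtype=float)
    _check_even(f.size)
    k = wavenumbers(f.size, L)
    fh = np.fft.rfft(f)
    gh = np.zeros_like(fh)
    gh[1:] = fh[1:] / (1j * k[1:])
    gh[-1] = 0.0
    return np.fft.irfft(gh, n=f.size)


def exponential_filter(n: int, cutoff: float = 2.0 / 3.0, alpha: float = 36.0, p: int = 8) -> np.ndarray:
    """High-order exponential low-pass mask over the rfft modes.

    Modes below ``cutoff * k_max`` pass unchanged; above, amplitudes are
    damped by exp(-alpha * ((j - jc)/(jmax - jc))**p).  Controls aliasing of
    the advective term near sharp crypt boundaries.
    """
    _check_even(n)
    j = np.arange(n // 2 + 1, dtype=float)
    jmax = n // 2
    jc = cutoff * jmax
    mask = np.ones_like(j)
    hi = j > jc
    mask[hi] = np.exp(-alpha * ((j[hi] - jc) / (jmax - jc)) ** p)
    return mask


def apply_filter(f: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Apply a spectral mask to a real periodic field."""
    return np.fft.irfft(np.fft.rfft(f) * mask, n=f.size)


def helmholtz_solve(rhs: np.ndarray, diffusivity: float, decay: float, L: float) -> np.ndarray:
    """Solve (decay - diffusivity * d^2/ds^2) u = rhs on the periodic domain.

    Exact in the spectral sense; requires decay > 0 for invertibility of the
    zero mode.
    """
    if decay <= 0:
        raise ValueError("decay rate must be positive for a well-posed periodic solve")
    k = wavenumbers(rhs.size, L)
    uh = np.fft.rfft(rhs) / (decay + diffusivity * k**2)
    return np.fft.irfft(uh, n=rhs.size)
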