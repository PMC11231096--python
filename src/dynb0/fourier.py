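"""Centered Fourier conventions shared across the package.

Image coordinates are in FOV units spanning [-0.5, 0.5) with the origin at
index ``n // 2``; k-space coordinates are in grid units (Delta-k = 1/FOV)
with DC at index ``n // 2``.  Arrays are indexed ``[..., y, x]`` where y is
the phase-encode axis and x the readout axis.
"""

from __future__ import annotations

import numpy as np


def coords(n: int) -> np.ndarray:
    """Image-domain coordinates in FOV units, centered at index n//2."""
    return (np.arange(n) - n // 2) / n


def kcoords(n: int) -> np.ndarray:
    """k-space coordinates in grid units (integer), DC at index n//2."""
    return np.arange(n) - n // 2


def cfft2(img: np.ndarray) -> np.ndarray:
    """Centered 2-D FFT over the last two axes (image -> k-space)."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=(-2, -1)), axes=(-2, -1)),
        axes=(-2, -1),
    )


def cifft2(ksp: np.ndarray) -> np.ndarray:
    """Centered 2-D inverse FFT over the last two axes (k-space -> image)."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(ksp, axes=(-2, -1)), axes=(-2, -1)),
        axes=(-2, -1),
    )


def cfft(arr: np.ndarray, axis: int = -1) -> np.ndarray:
    """Centered 1-D FFT along ``axis``."""
    return np.fft.fftshift(
        np.fft.fft(np.fft.ifftshift(arr, axes=axis), axis=axis), axes=axis
    )


def cifft(arr: np.ndarray, axis: int = -1) -> np.ndarray:
    """Centered 1-D inverse FFT along ``axis``."""
    return np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(arr, axes=axis), axis=axis), axes=axis
    )


def image_grids(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Meshgrids (Y, X) of image coordinates in FOV units, indexed [y, x]."""
    c = coords(n)
    return np.meshgrid(c, c, indexing="ij")


def translation_ramp(n: int, dkx: float, dky: float, phi0: float = 0.0) -> np.ndarray:
    """Image-domain phase ramp realizing a k-space translation.

    Multiplying an image by this ramp shifts its k-space representation by
    (+dkx, +dky) grid units and adds the global phase ``phi0``.
    """
    Y, X = image_grids(n)
    return np.exp(1j * (phi0 + 2.0 * np.pi * (dkx * X + dky * Y)))
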