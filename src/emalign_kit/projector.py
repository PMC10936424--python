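"""Projection images via the Fourier projection-slice theorem, and polar
Fourier transforms of images for common-lines scoring.

The 2D Fourier transform of a projection of a volume equals the central
planar slice of the volume's 3D Fourier transform spanned by the first two
columns of the projection rotation (the third column is the viewing
direction). Slices are evaluated with the package's Kaiser-Bessel gridding
NUFFT; one plan per volume serves any number of projection directions.

FFT convention: forward transform with negative exponent, frequency origin
at the array center (shared by every module).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nufft import NufftPlan
from .maps_io import DensityMap

__all__ = [
    "ProjectionImage",
    "ProjectionRays",
    "FourierSliceProjector",
    "project",
    "polar_ft",
]


@dataclass
class ProjectionImage:
    """Square real projection image; optionally carries the rotation that
    generated it (used by fixtures and tests, never by the aligner)."""

    data: np.ndarray
    rotation: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError(f"projection image must be square, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("projection image contains non-finite values")

    @property
    def n(self) -> int:
        return self.data.shape[0]


@dataclass
class ProjectionRays:
    """Polar Fourier transform of an image: L rays over [0, 360) with n_r
    equispaced radial frequencies in (0, Nyquist]; DC excluded.

    For a real image the ray at theta+180 is the complex conjugate of the
    ray at theta.
    """

    rays: np.ndarray  # complex, shape (L, n_r)
    angular_step: float  # degrees, = 360 / L

    @property
    def L(self) -> int:
        return self.rays.shape[0]

    @property
    def n_r(self) -> int:
        return self.rays.shape[1]


class FourierSliceProjector:
    """Reusable projector for one volume (one NUFFT plan, many rotations)."""

    def __init__(self, map: DensityMap):
        self.n = map.n
        self._plan = NufftPlan(map.data)
        n = self.n
        k = np.arange(n, dtype=np.float64) - n // 2
        ku, kv = np.meshgrid(k, k, indexing="ij")
        self._k2 = np.stack([ku.ravel(), kv.ravel()], axis=1)  # (n^2, 2)

    def project(self, r: np.ndarray) -> ProjectionImage:
        r = np.asarray(r, dtype=np.float64)
        n = self.n
        # corners of the rotated slice fall outside the centered band;
        # the plan evaluates the DFT there by periodicity, matching the
        # periodic extension of the sampled transform
        pts = self._k2 @ np.stack([r[:, 0], r[:, 1]]).astype(np.float64)
        f2 = self._plan.eval(pts).reshape(n, n)
        img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(f2))).real
        return ProjectionImage(img, rotation=r)


def project(map: DensityMap, r: np.ndarray) -> ProjectionImage:
    """Projection of ``map`` along the third column of rotation ``r``.

    Equals the line integral of the rotated volume along z; for repeated
    projections of one volume use :class:`FourierSliceProjector`.
    """
    return FourierSliceProjector(map).project(r)


def _polar_points(n: int, L: int, n_r: int) -> tuple[np.ndarray, np.ndarray]:
    theta = 2.0 * np.pi * np.arange(L) / L
    rho = (np.arange(1, n_r + 1) * (n / 2.0) / n_r)
    kx = np.outer(np.cos(theta), rho)
    ky = np.outer(np.sin(theta), rho)
    return kx, ky


def polar_ft(image: ProjectionImage, L: int = 360, n_r: int | None = None) -> ProjectionRays:
    """Polar Fourier transform of a projection image.

    Direct (exact) non-equally-spaced evaluation on L half-lines through
    the frequency origin with n_r radial samples in (0, n/2]; the two inner
    sums are factored so the cost is O(L * n_r * n^2 / ...) matrix products
    rather than a quadruple loop. Defaults: L=360 (1-degree rays, well
    below the rotation-grid resolution) and n_r = n//2.
    """
    n = image.n
    if n_r is None:
        n_r = n // 2
    if L % 2 != 0:
        raise ValueError("L must be even")
    if n_r > n // 2:
        raise ValueError(f"n_r={n_r} exceeds Nyquist (n//2={n // 2})")
    kx, ky = _polar_points(n, L, n_r)
    x = np.arange(n, dtype=np.float64) - n // 2
    # F(p) = sum_a e^{-2 pi i kx_p a / n} * [ sum_b img[a,b] e^{-2 pi i ky_p b / n} ]
    ey = np.exp(-2j * np.pi * np.outer(x, ky.ravel()) / n)  # (n, P)
    m = image.data @ ey                                      # (n, P)
    ex = np.exp(-2j * np.pi * np.outer(kx.ravel(), x) / n)  # (P, n)
    vals = np.einsum("pa,ap->p", ex, m)
    return ProjectionRays(rays=vals.reshape(L, n_r), angular_step=360.0 / L)
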