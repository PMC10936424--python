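"""Common-line geometry and exhaustive projection alignment.

By the projection-slice theorem, any two projection images of the same
volume agree along one central line of their 2D Fourier transforms (the
common line). Given a query image of unknown orientation and a handful of
reference projections at known rotations, every candidate rotation from a
grid on SO(3) predicts where the common lines should fall; the candidate
whose predicted lines actually correlate best (after a 1D shift search
that absorbs in-plane translation of the query) is the estimated
orientation.

Two code paths compute the same score: a small readable scalar path
(:func:`score_candidate`, built on :func:`commonline_angles` and
:func:`shifted_ray_correlation`) and a vectorized path used by
:func:`align_projection` that scores the whole grid at once. A test pins
them together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps_io import DensityMap
from .projector import FourierSliceProjector, ProjectionImage, ProjectionRays, polar_ft
from .so3 import RotationGrid, random_rotations

__all__ = [
    "CommonLine",
    "ShiftSearch",
    "commonline_angles",
    "shifted_ray_correlation",
    "score_candidate",
    "align_projection",
    "DegeneratePairError",
]

_PARALLEL_TOL = 1e-3  # radians between viewing directions


class DegeneratePairError(ValueError):
    """The two image planes coincide; no unique common line exists."""


@dataclass
class CommonLine:
    """In-plane directions (degrees in [0, 360)) of the common line in
    each of the two images."""

    alpha_i: float
    alpha_j: float


@dataclass
class ShiftSearch:
    """1D shift search range along the common line, in pixels."""

    s_max: float
    step: float = 1.0

    def __post_init__(self):
        if self.s_max < 0:
            raise ValueError("s_max must be >= 0")
        if self.step <= 0:
            raise ValueError("step must be > 0")

    @property
    def candidates(self) -> np.ndarray:
        k = int(np.floor(self.s_max / self.step + 1e-9))
        return np.arange(-k, k + 1) * self.step

    @classmethod
    def for_size(cls, n: int, frac: float = 0.15, step: float = 1.0) -> "ShiftSearch":
        """Default bound: 15% of the image side (covers the 10%-of-size
        translation protocol with margin)."""
        return cls(s_max=float(round(frac * n)), step=step)


def commonline_angles(r_i: np.ndarray, r_j: np.ndarray) -> CommonLine:
    """Directions of the common line induced by two projection rotations.

    The common 3D ray is ``q = unit(r_i[:,2] x r_j[:,2])``; expressed in
    each image's in-plane coordinates it is ``r^T q`` (third component 0),
    and the returned angles are its atan2 directions.
    """
    r_i = np.asarray(r_i, float)
    r_j = np.asarray(r_j, float)
    q = np.cross(r_i[:, 2], r_j[:, 2])
    nq = np.linalg.norm(q)
    if nq < np.sin(_PARALLEL_TOL):
        raise DegeneratePairError("viewing directions are (anti)parallel")
    q /= nq
    pi_ = r_i.T @ q
    pj_ = r_j.T @ q
    ai = float(np.rad2deg(np.arctan2(pi_[1], pi_[0]))) % 360.0
    aj = float(np.rad2deg(np.arctan2(pj_[1], pj_[0]))) % 360.0
    return CommonLine(alpha_i=ai, alpha_j=aj)


def _radial_freqs(n: int, n_r: int) -> np.ndarray:
    # radial frequency (in DFT index units) of each ray sample
    return np.arange(1, n_r + 1) * (n / 2.0) / n_r


def shifted_ray_correlation(
    a: np.ndarray, b: np.ndarray, shifts: ShiftSearch, n: int
) -> tuple[float, float]:
    """Shift-maximized normalized correlation of two Fourier rays.

    For each candidate shift ``s`` the ray ``b`` is modulated by
    ``exp(-2 pi i xi_k s / n)`` (a 1D real-space shift along the line);
    the score is the real part of the normalized complex inner product.
    Ties break toward the smallest |s|, negative first.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("ray length mismatch")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0, 0.0
    xi = _radial_freqs(n, len(a))
    svals = shifts.candidates
    phase = np.exp(-2j * np.pi * np.outer(svals, xi) / n)
    corr = ((a[None, :] * np.conj(b[None, :] * phase)).sum(axis=1)).real / (na * nb)
    # tie-break: smallest |s|, then negative first
    order = np.lexsort((svals > 0, np.abs(svals)))
    best = order[np.argmax(corr[order])]
    return float(corr[best]), float(svals[best])


def _nearest_ray_index(alpha_deg: float | np.ndarray, L: int) -> np.ndarray:
    return (np.round(np.asarray(alpha_deg) * L / 360.0).astype(np.int64)) % L


def score_candidate(
    query: ProjectionRays,
    refs: list[ProjectionRays],
    ref_rotations: list[np.ndarray] | np.ndarray,
    x: np.ndarray,
    shifts: ShiftSearch,
) -> float:
    """Mean shift-maximized common-line correlation of candidate rotation x.

    For each non-degenerate reference the common line of (x, ref) selects
    the nearest sampled ray in each image; degenerate pairs are skipped,
    and if all pairs are degenerate the score is -1.
    """
    if len(refs) == 0:
        raise ValueError("refs must be nonempty")
    n = 2 * query.n_r  # ray sampling was built with n_r = n/2 radial samples
    total = 0.0
    count = 0
    for rays_j, r_j in zip(refs, ref_rotations):
        try:
            cl = commonline_angles(x, r_j)
        except DegeneratePairError:
            continue
        ia = _nearest_ray_index(cl.alpha_i, query.L)
        ja = _nearest_ray_index(cl.alpha_j, rays_j.L)
        c, _ = shifted_ray_correlation(query.rays[ia], rays_j.rays[ja], shifts, n)
        total += c
        count += 1
    if count == 0:
        return -1.0
    return total / count


class _GridGeometry:
    """Precomputed common-line ray indices for (grid x reference set).

    Depends only on the candidate grid and the reference rotations, so one
    instance serves every query image in a run.
    """

    def __init__(self, grid_rots: np.ndarray, ref_rots: np.ndarray, L: int):
        d_g = grid_rots[:, :, 2]  # (M, 3) candidate viewing directions
        d_r = ref_rots[:, :, 2]   # (J, 3)
        q = np.cross(d_g[:, None, :], d_r[None, :, :])  # (M, J, 3)
        nq = np.linalg.norm(q, axis=2)
        self.valid = nq > np.sin(_PARALLEL_TOL)
        qn = np.where(self.valid[..., None], q / np.maximum(nq, 1e-300)[..., None], 0.0)
        # in-plane components of q in candidate frame: (M, J)
        gx = np.einsum("mjk,mk->mj", qn, grid_rots[:, :, 0])
        gy = np.einsum("mjk,mk->mj", qn, grid_rots[:, :, 1])
        rx = np.einsum("mjk,jk->mj", qn, ref_rots[:, :, 0])
        ry = np.einsum("mjk,jk->mj", qn, ref_rots[:, :, 1])
        ag = np.rad2deg(np.arctan2(gy, gx)) % 360.0
        ar = np.rad2deg(np.arctan2(ry, rx)) % 360.0
        self.idx_query = _nearest_ray_index(ag, L)  # (M, J)
        self.idx_ref = _nearest_ray_index(ar, L)


def _score_all(
    query: ProjectionRays,
    refs: list[ProjectionRays],
    geom: _GridGeometry,
    shifts: ShiftSearch,
    n: int,
) -> np.ndarray:
    """Vectorized score of every grid candidate against one query. (M,)"""
    M, J = geom.idx_query.shape
    n_r = query.n_r
    xi = _radial_freqs(n, n_r)
    phase = np.exp(-2j * np.pi * np.outer(xi, shifts.candidates) / n).astype(np.complex64)
    qrays = query.rays.astype(np.complex64)
    qnorm = np.linalg.norm(query.rays, axis=1).astype(np.float64)
    total = np.zeros(M)
    count = geom.valid.sum(axis=1).astype(np.float64)
    for j, rays_j in enumerate(refs):
        rj = rays_j.rays.astype(np.complex64)
        rnorm = np.linalg.norm(rays_j.rays, axis=1)
        a = qrays[geom.idx_query[:, j]]          # (M, n_r)
        b = rj[geom.idx_ref[:, j]]               # (M, n_r)
        cro = a * np.conj(b)                     # (M, n_r)
        corr = (cro @ phase).real                # (M, n_s)
        denom = qnorm[geom.idx_query[:, j]] * rnorm[geom.idx_ref[:, j]]
        denom = np.maximum(denom, 1e-300)
        best = corr.max(axis=1) / denom
        total += np.where(geom.valid[:, j], best, 0.0)
    score = np.where(count > 0, total / np.maximum(count, 1.0), -1.0)
    return score


def _rescore_consistent_shift(
    query: ProjectionRays,
    refs: list[ProjectionRays],
    geom: _GridGeometry,
    shifts: ShiftSearch,
    n: int,
    scores: np.ndarray,
    top_k: int = 50,
) -> tuple[int, float]:
    """Re-rank the best-scoring candidates under a consistent 2D shift.

    The per-pair shift maximization treats each common line's 1D shift as
    free, which saturates scores on smooth images; physically all of them
    are projections s2 . (cos a, sin a) of one in-plane displacement s2 of
    the query. Re-scoring the top candidates with that two-parameter
    model restores the discrimination between nearby rotations. Returns
    (best index, its consistent-shift score).
    """
    if shifts.s_max == 0:
        return int(np.argmax(scores)), float(scores.max())
    k = min(top_k, len(scores))
    cand_idx = np.argpartition(-scores, k - 1)[:k]
    cand_idx = cand_idx[np.argsort(cand_idx)]  # deterministic tie order
    n_r = query.n_r
    xi = _radial_freqs(n, n_r)
    # dense 1D-shift grid covering |s2|*sqrt(2)
    d_step = 0.25
    d_max = float(shifts.s_max) * np.sqrt(2.0) + d_step
    dgrid = np.arange(-d_max, d_max + d_step / 2, d_step)
    phase = np.exp(2j * np.pi * np.outer(xi, dgrid) / n).astype(np.complex64)

    qn = np.linalg.norm(query.rays, axis=1)
    J = len(refs)
    curves = np.empty((k, J, len(dgrid)), dtype=np.float32)
    alphas = np.deg2rad(geom.idx_query[cand_idx] * query.angular_step)  # (k, J)
    valid = geom.valid[cand_idx]
    for j, rays_j in enumerate(refs):
        rn = np.linalg.norm(rays_j.rays, axis=1)
        a = query.rays[geom.idx_query[cand_idx, j]].astype(np.complex64)
        b = rays_j.rays[geom.idx_ref[cand_idx, j]].astype(np.complex64)
        den = np.maximum(qn[geom.idx_query[cand_idx, j]] * rn[geom.idx_ref[cand_idx, j]], 1e-30)
        curves[:, j, :] = ((a * np.conj(b)) @ phase).real / den[:, None].astype(np.float32)

    s2 = shifts.candidates
    sx = np.repeat(s2, len(s2))
    sy = np.tile(s2, len(s2))
    # induced 1D shift per (candidate, ref, 2D-shift), as dense-grid index
    d = (
        np.cos(alphas)[:, :, None] * sx[None, None, :]
        + np.sin(alphas)[:, :, None] * sy[None, None, :]
    )
    di = np.clip(np.round((d + d_max) / d_step).astype(np.int64), 0, len(dgrid) - 1)
    vals = np.take_along_axis(curves, di, axis=2)          # (k, J, n_s2)
    vals = np.where(valid[:, :, None], vals, 0.0)
    count = np.maximum(valid.sum(axis=1), 1)[:, None]
    mean_scores = vals.sum(axis=1) / count                 # (k, n_s2)
    best2 = mean_scores.max(axis=1)
    best2 = np.where(valid.any(axis=1), best2, -1.0)
    j_best = int(np.argmax(best2))
    return int(cand_idx[j_best]), float(best2[j_best])


def align_projection(
    query: ProjectionImage,
    map: DensityMap,
    n_refs: int,
    grid: RotationGrid,
    shifts: ShiftSearch,
    seed: int,
    L: int = 360,
) -> tuple[np.ndarray, float]:
    """Estimate the rotation that generated ``query`` from ``map``.

    Projects the map at ``n_refs`` Haar-random rotations (seeded), scores
    every grid candidate by mean common-line correlation, and returns the
    argmax rotation and its score (ties -> lowest grid index).
    """
    if len(grid) == 0:
        raise ValueError("empty rotation grid")
    if query.n != map.n:
        raise ValueError("query image side must equal map side")
    ref_rots = random_rotations(n_refs, seed)
    projector = FourierSliceProjector(map)
    refs = [polar_ft(projector.project(r), L=L) for r in ref_rots]
    qrays = polar_ft(query, L=L)
    geom = _GridGeometry(np.asarray(grid.rotations), ref_rots, L)
    scores = _score_all(qrays, refs, geom, shifts, map.n)
    best, best_score = _rescore_consistent_shift(qrays, refs, geom, shifts, map.n, scores)
    return grid.rotations[best].copy(), best_score
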