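"""Rotation synchronization and the end-to-end map aligner.

Pipeline: draw random rotations R_1..R_n, project the moving map V2 at
each, estimate each projection's orientation Rhat_i in the reference map
V1's frame by common-lines scoring, and fuse the per-projection gauge
blocks X_i = Rhat_i R_i^T (each an estimate of the unknown transform, up
to a symmetry element of V1) through a rank-3 spectral synchronization
that cancels the symmetry gauge. Handedness is resolved by a second,
essentially free branch: if the maps are mirror images, the same Rhat_i
satisfy X_i = (J Rhat_i J) R_i^T with J = diag(1, 1, -1), so both
hypotheses reuse the identical projection alignments and the better one is
picked by whole-map correlation after translation estimation by phase
correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .commonline_align import (
    ShiftSearch,
    _GridGeometry,
    _rescore_consistent_shift,
    _score_all,
)
from .maps_io import AlignmentParams, DensityMap, apply_transform, correlation
from .projector import FourierSliceProjector, polar_ft
from .so3 import RotationGrid, nearest_orthogonal, random_rotations

__all__ = [
    "GaugeBlock",
    "SyncResult",
    "sync_blocks",
    "estimate_orientation",
    "phase_correlation_shift",
    "align_maps",
    "J_REFLECT",
]

J_REFLECT = np.diag([1.0, 1.0, -1.0])


@dataclass
class GaugeBlock:
    """Product of an estimated projection rotation with the transpose of
    its generating rotation: a gauge-contaminated copy of the sought
    transform."""

    x: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.x.shape != (3, 3):
            raise ValueError("gauge block must be 3x3")
        if not np.allclose(self.x.T @ self.x, np.eye(3), atol=1e-4):
            self.x = nearest_orthogonal(self.x)


@dataclass
class SyncResult:
    """Output of one synchronization branch."""

    estimate: np.ndarray | None
    per_index: list[np.ndarray] = field(default_factory=list)
    spectral_gap: float = np.inf


def sync_blocks(x_list: list[GaugeBlock]) -> SyncResult:
    """Gauge-fix a set of orthogonal blocks by rank-3 synchronization.

    Builds the 3n x 3n block matrix with (i, j) block ``x_i x_j^T`` (rank
    3 by construction: the unknown shared transform cancels), takes the
    three leading eigenvectors scaled by sqrt-eigenvalues, orthogonalizes
    each 3x3 block of the resulting 3n x 3 matrix, and removes the
    arbitrary orthogonal gauge by right-multiplying with the transpose of
    the first block (t_1 = identity). Returns the per-index gauge
    rotations t_i and the 3rd/4th eigenvalue ratio as a quality gap.
    """
    n = len(x_list)
    if n == 0:
        raise ValueError("need at least one gauge block")
    xs = np.stack([b.x for b in x_list])  # (n, 3, 3)
    s = xs.reshape(3 * n, 3)
    big = s @ s.T  # blocks X_i X_j^T
    evals, evecs = np.linalg.eigh(big)
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    if evals[2] <= 1e-10 * max(evals[0], 1.0):
        raise ValueError("degenerate synchronization input: 3rd eigenvalue vanishes")
    gap = float(evals[2] / evals[3]) if n > 1 and evals[3] > 1e-300 else np.inf
    v = evecs[:, :3] * np.sqrt(evals[:3])[None, :]
    blocks = [nearest_orthogonal(v[3 * i : 3 * i + 3]) for i in range(n)]
    t = [b @ blocks[0].T for b in blocks]
    return SyncResult(estimate=None, per_index=t, spectral_gap=gap)


def _project_and_align(
    v1: DensityMap,
    v2: DensityMap,
    n_projs: int,
    grid: RotationGrid,
    shifts: ShiftSearch,
    seed: int,
    L: int = 360,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Draw R_i, project v2, align each projection to v1. Reference
    projections of v1 and the grid geometry are computed once and shared
    across all queries. Returns (R_list, Rhat_list, n_alignments)."""
    r_list = random_rotations(n_projs, seed)
    ref_rots = random_rotations(max(n_projs, 3), _derive_seed(seed, 1))
    proj1 = FourierSliceProjector(v1)
    refs = [polar_ft(proj1.project(r), L=L) for r in ref_rots]
    geom = _GridGeometry(np.asarray(grid.rotations), ref_rots, L)
    proj2 = FourierSliceProjector(v2)
    rhat = np.empty_like(r_list)
    n_align = 0
    for i, r in enumerate(r_list):
        qrays = polar_ft(proj2.project(r), L=L)
        scores = _score_all(qrays, refs, geom, shifts, v1.n)
        best, _ = _rescore_consistent_shift(qrays, refs, geom, shifts, v1.n, scores)
        rhat[i] = grid.rotations[best]
        n_align += 1
    return r_list, rhat, n_align


def _derive_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence(entropy=[seed, salt]).generate_state(1)[0] % (2**31))


def _svd_mean(mats: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Orthogonal matrix nearest (Frobenius, least squares) to the mean."""
    m = np.mean(mats, axis=0)
    u, _, wt = np.linalg.svd(m)
    est = u @ wt
    if np.linalg.det(est) < 0 and np.linalg.det(np.asarray(mats)[0]) > 0:
        u = u.copy()
        u[:, -1] *= -1.0
        est = u @ wt
    return est


_GAUGE_CLUSTER_DEG = 25.0


def _cluster_rotations(mats: np.ndarray, thr_deg: float = _GAUGE_CLUSTER_DEG):
    """Greedy leader clustering by geodesic distance; deterministic."""
    labels = np.full(len(mats), -1, dtype=int)
    leaders: list[np.ndarray] = []
    for i, m in enumerate(mats):
        for c, lead in enumerate(leaders):
            c_ang = (np.trace(lead.T @ m) - 1.0) / 2.0
            if np.rad2deg(np.arccos(np.clip(c_ang, -1.0, 1.0))) < thr_deg:
                labels[i] = c
                break
        else:
            labels[i] = len(leaders)
            leaders.append(m)
    means = [_svd_mean(mats[labels == c]) for c in range(len(leaders))]
    return labels, means


def _sync_branch(r_list: np.ndarray, rhat: np.ndarray, branch: str) -> SyncResult:
    """Synchronize one handedness branch and average the estimates.

    The gauge rotations t_i from the spectral step estimate g_i g_1^T for
    symmetry elements g_i of the reference map. Because the block matrix
    is built from the X_i themselves, those raw gauges absorb each block's
    own estimation noise exactly (O_i = t_i^T X_i collapses to X_1), so
    averaging them would gain nothing. The gauges are therefore snapped to
    the finite set they cluster around: each t_i is replaced by its
    cluster mean taken relative to the largest cluster, which cancels the
    shared anchor-block noise and leaves n independently-noisy estimates
    of (one symmetry copy of) the transform for the final least-squares
    (SVD) average.
    """
    if branch == "proper":
        xs = [GaugeBlock(h @ r.T) for h, r in zip(rhat, r_list)]
    elif branch == "reflected":
        xs = [GaugeBlock(J_REFLECT @ h @ J_REFLECT @ r.T) for h, r in zip(rhat, r_list)]
    else:
        raise ValueError(f"unknown branch {branch!r}")
    try:
        res = sync_blocks(xs)
    except ValueError as e:
        raise ValueError(f"synchronization failed in {branch} branch: {e}") from e
    t_arr = np.asarray(res.per_index)
    labels, means = _cluster_rotations(t_arr)
    sizes = np.bincount(labels)
    anchor = means[int(np.argmax(sizes))]
    snapped = [means[c] @ anchor.T for c in labels]
    o_list = [s.T @ b.x for s, b in zip(snapped, xs)]
    est = _svd_mean(o_list)
    if np.linalg.det(est) < 0:  # heavy-noise safeguard
        u, _, wt = np.linalg.svd(np.mean(o_list, axis=0))
        u = u.copy()
        u[:, -1] *= -1.0
        est = u @ wt
    return SyncResult(estimate=est, per_index=o_list, spectral_gap=res.spectral_gap)


def estimate_orientation(
    v1: DensityMap,
    v2: DensityMap,
    n_projs: int,
    grid: RotationGrid,
    shifts: ShiftSearch,
    branch: str = "proper",
    seed: int = 0,
    precomputed: tuple[np.ndarray, np.ndarray] | None = None,
) -> SyncResult:
    """One handedness branch of the orientation estimate.

    ``precomputed`` may carry ``(R_list, Rhat_list)`` from a previous call
    so the reflected branch reuses the projection alignments verbatim
    (handedness costs no extra common-lines work). The returned estimate
    is a proper rotation; for the reflected hypothesis the full transform
    is ``J_REFLECT @ estimate``.
    """
    if v1.n != v2.n:
        raise ValueError("maps must have equal size")
    if precomputed is not None:
        r_list, rhat = precomputed
    else:
        r_list, rhat, _ = _project_and_align(v1, v2, n_projs, grid, shifts, seed)
    return _sync_branch(np.asarray(r_list), np.asarray(rhat), branch)


def phase_correlation_shift(
    ref: DensityMap, moving: DensityMap, subpixel: bool = True
) -> np.ndarray:
    """Translation ``s`` (voxels) such that ``moving ~= roll(ref, s)``.

    Peak of the inverse FFT of the whitened cross-power spectrum, unwrapped
    to (-n/2, n/2]; optional separable parabolic sub-voxel refinement of
    the peak.
    """
    if ref.data.shape != moving.data.shape:
        raise ValueError("size mismatch")
    n = ref.n
    fa = np.fft.fftn(ref.data)
    fb = np.fft.fftn(moving.data)
    cross = np.conj(fa) * fb
    mag = np.abs(cross)
    # regularized whitening: strong (signal) frequencies are phase-
    # normalized while weak noise-dominated ones keep matched-filter
    # weighting — robust down to heavy noise, exact for clean shifts
    eps = mag.mean() + 1e-30
    surf = np.fft.ifftn(cross / (mag + eps)).real
    peak = np.unravel_index(np.argmax(surf), surf.shape)
    pv = surf[peak]
    if pv <= surf.mean() + 3.0 * surf.std():
        warnings.warn("phase correlation surface is flat; translation unreliable")
    shift = np.array(peak, dtype=np.float64)
    if subpixel:
        for ax in range(3):
            im = [peak[0], peak[1], peak[2]]
            ip = list(im)
            im[ax] = (peak[ax] - 1) % n
            ip[ax] = (peak[ax] + 1) % n
            ym, yp = surf[tuple(im)], surf[tuple(ip)]
            denom = ym - 2.0 * pv + yp
            if denom < -1e-300:
                delta = 0.5 * (ym - yp) / denom
                shift[ax] += np.clip(delta, -0.5, 0.5)
    shift = (shift + n / 2) % n - n / 2
    return shift


def align_maps(
    v1: DensityMap,
    v2: DensityMap,
    n_projs: int = 30,
    grid: RotationGrid | None = None,
    shifts: ShiftSearch | None = None,
    seed: int = 0,
    return_info: bool = False,
):
    """Full rotation + reflection + translation alignment of v2 onto v1.

    Runs the common-lines orientation estimate once, synchronizes both
    handedness branches from the shared projection alignments, estimates
    each branch's translation by phase correlation, applies both candidate
    parameter sets, and returns the branch with the higher whole-map
    correlation as :class:`AlignmentParams`.
    """
    from .so3 import candidate_grid

    if v1.n != v2.n:
        raise ValueError("maps must have equal size")
    if grid is None:
        grid = candidate_grid()
    if shifts is None:
        shifts = ShiftSearch.for_size(v1.n)
    r_list, rhat, n_align = _project_and_align(v1, v2, n_projs, grid, shifts, seed)

    results = {}
    for branch in ("proper", "reflected"):
        sync = _sync_branch(r_list, rhat, branch)
        q = sync.estimate if branch == "proper" else J_REFLECT @ sync.estimate
        rot_only = AlignmentParams(q, reflect=branch == "reflected")
        w = apply_transform(v2, rot_only)
        t = -phase_correlation_shift(v1, w, subpixel=True)
        params = AlignmentParams(q, reflect=branch == "reflected", translation=t)
        aligned = apply_transform(v2, params)
        params.score = correlation(v1, aligned)
        results[branch] = (params, sync)

    best = max(results, key=lambda b: results[b][0].score)
    params = results[best][0]
    rejected = "reflected" if best == "proper" else "proper"
    assert params.score >= results[rejected][0].score
    if return_info:
        info = {
            "n_projection_alignments": n_align,
            "branch_scores": {b: results[b][0].score for b in results},
            "spectral_gap": results[best][1].spectral_gap,
            "rejected_score": results["reflected" if best == "proper" else "proper"][0].score,
        }
        return params, info
    return params
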