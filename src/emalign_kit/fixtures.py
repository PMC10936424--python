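"""Synthetic phantoms and the evaluation harness.

Phantoms are sums of anisotropic 3D Gaussian blobs confined to a centered
ball (so rotations never clip mass), optionally replicated under a point
group so the map is exactly invariant. Because both members of a test pair
are rendered analytically from the same blob list — the moving map's blobs
are the transformed blobs — ground truth carries no interpolation error.

These phantoms emulate the smooth, compactly supported density of a
single-particle reconstruction at moderate resolution; they do not emulate
CTF effects, solvent background, or masking artifacts of real maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .commonline_align import ShiftSearch
from .maps_io import AlignmentParams, DensityMap
from .orientation_sync import J_REFLECT, align_maps
from .refine import refine_params
from .so3 import RotationGrid, SymmetryGroup, random_rotations, rotation_errors, symmetry_elements

__all__ = [
    "PhantomSpec",
    "TrialResult",
    "make_phantom",
    "make_pair",
    "add_noise",
    "run_trial",
]

# blob width range as a fraction of the side length: ~1-3 voxels at the
# working sizes, emulating the atom-scale granularity that gives real
# density maps spectral content out to Nyquist (a handful of fat blobs
# makes projections too smooth to discriminate nearby orientations, which
# no real macromolecule is); wide enough for trilinear resampling fidelity
_SIGMA_FRAC = (0.02, 0.045)
_AMP_RANGE = (0.5, 1.5)


@dataclass
class PhantomSpec:
    """Recipe for a deterministic random phantom."""

    n: int
    n_blobs: int = 100
    symmetry: str = "C1"
    seed: int = 0
    support_radius: float = 0.45

    def __post_init__(self):
        if self.n < 16:
            raise ValueError("n must be >= 16")
        if self.n_blobs < 3:
            raise ValueError("n_blobs must be >= 3")
        if not (0.0 < self.support_radius <= 0.9):
            raise ValueError("support_radius must be in (0, 0.9]")


@dataclass
class TrialResult:
    """Per-trial evaluation record (JSON-serializable)."""

    err_axis: float
    err_angle: float
    err_translation: float
    reflect_correct: bool
    score: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def _blob_params(spec: PhantomSpec, salt: int = 0):
    """Centers (k,3), covariance matrices (k,3,3), amplitudes (k,) of the
    base blobs (before symmetry replication)."""
    rng = np.random.default_rng([spec.seed, 0xB10B, salt])
    r_max = spec.support_radius * spec.n / 2.0
    # rejection-free: sample direction x radius^(1/3) for uniformity in ball
    u = rng.standard_normal((spec.n_blobs, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    radii = r_max * rng.uniform(0, 1, spec.n_blobs) ** (1.0 / 3.0)
    centers = u * radii[:, None]
    sig = rng.uniform(*_SIGMA_FRAC, size=(spec.n_blobs, 3)) * spec.n
    orient = random_rotations(spec.n_blobs, int(rng.integers(2**31)))
    covs = np.einsum("kij,kj,klj->kil", orient, sig**2, orient)
    amps = rng.uniform(*_AMP_RANGE, size=spec.n_blobs)
    return centers, covs, amps


def _replicate(centers, covs, amps, group: SymmetryGroup):
    """Blob list replicated under every group element (exact invariance)."""
    cs, vs, as_ = [], [], []
    for g in group.elements:
        cs.append(centers @ g)       # g.T @ c for each center
        vs.append(np.einsum("ji,kjl,lm->kim", g, covs, g))  # g.T C g
        as_.append(amps)
    return np.concatenate(cs), np.concatenate(vs), np.concatenate(as_)


def _render(n: int, centers, covs, amps) -> np.ndarray:
    c = n // 2
    x = np.arange(n, dtype=np.float64) - c
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)  # (n,n,n,3)
    out = np.zeros((n, n, n))
    for ctr, cov, amp in zip(centers, covs, amps):
        prec = np.linalg.inv(cov)
        d = pts - ctr
        q = np.einsum("...i,ij,...j->...", d, prec, d)
        np.clip(q, None, 60.0, out=q)
        out += amp * np.exp(-0.5 * q)
    return out


def _transform_blobs(centers, covs, q: np.ndarray, t: np.ndarray):
    """Blob parameters of V2(x) = V1(Q x + t): each Gaussian maps to a
    Gaussian at Q^T (c - t) with covariance Q^T C Q."""
    c2 = (centers - t) @ q  # rows: Q^T (c - t)
    v2 = np.einsum("ji,kjl,lm->kim", q, covs, q)
    return c2, v2


def _build_phantom(spec: PhantomSpec):
    """Blob list and rendered map for ``spec``; deterministic per spec.

    For asymmetric (C1) specs the generator verifies the map does not
    accidentally correlate above 0.9 with its own 90-degree z-rotation,
    re-salting the internal draw if it does.
    """
    group = symmetry_elements(spec.symmetry)
    for salt in range(16):
        centers, covs, amps = _blob_params(spec, salt)
        c, v, a = _replicate(centers, covs, amps, group)
        data = _render(spec.n, c, v, a)
        if len(group) > 1:
            return c, v, a, data
        rot90 = _rot_z90_resample(data)
        if np.corrcoef(data.ravel(), rot90.ravel())[0, 1] < 0.9:
            return c, v, a, data
    raise RuntimeError("could not generate an asymmetric phantom")


def make_phantom(spec: PhantomSpec) -> DensityMap:
    """Render the phantom for ``spec``; deterministic per (spec, seed)."""
    return DensityMap(_build_phantom(spec)[3])


def _rot_z90_resample(data: np.ndarray) -> np.ndarray:
    """Exact 90-degree z-rotation about the centered-coordinate origin."""
    from .maps_io import apply_transform

    q = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    return apply_transform(DensityMap(data), AlignmentParams(q, False)).data


def make_pair(
    spec: PhantomSpec,
    reflect: bool = False,
    max_shift_frac: float = 0.10,
    seed: int = 0,
) -> tuple[DensityMap, DensityMap, AlignmentParams]:
    """Reference map, transformed copy, and the generating ground truth.

    The truth transform is a Haar-random rotation (composed with the
    z-reflection J when ``reflect``) plus a random translation of
    magnitude up to ``max_shift_frac * n`` voxels; the copy is rendered
    analytically from the transformed blob list so the pair satisfies
    ``v2(x) = v1(Q x + t)`` to rendering precision.
    """
    if not (0.0 <= max_shift_frac <= 0.2):
        raise ValueError("max_shift_frac must be in [0, 0.2]")
    c, v, a, data = _build_phantom(spec)
    v1 = DensityMap(data)
    rng = np.random.default_rng([seed, 0xA117])
    rot = random_rotations(1, int(rng.integers(2**31)))[0]
    q = J_REFLECT @ rot if reflect else rot
    if max_shift_frac > 0:
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        t = direction * rng.uniform(0, max_shift_frac * spec.n)
    else:
        t = np.zeros(3)
    c2, v2cov = _transform_blobs(c, v, q, t)
    v2 = DensityMap(_render(spec.n, c2, v2cov, a))
    truth = AlignmentParams(q, reflect=reflect, translation=t, score=1.0)
    return v1, v2, truth


def add_noise(map: DensityMap, snr: float, seed: int) -> DensityMap:
    """Additive white Gaussian noise with variance var(map)/snr."""
    if snr <= 0:
        raise ValueError("snr must be > 0")
    var = float(np.var(map.data))
    if var == 0.0:
        raise ValueError("cannot define SNR for a zero-variance map")
    rng = np.random.default_rng([seed, 0x0153])
    noise = rng.standard_normal(map.data.shape) * np.sqrt(var / snr)
    return DensityMap(map.data + noise, voxel_size=map.voxel_size)


def _conjugate_group(group: SymmetryGroup) -> SymmetryGroup:
    """Group conjugated by the z-reflection J (used to evaluate reflected
    trials in terms of proper-rotation factors)."""
    elems = np.array([J_REFLECT @ g @ J_REFLECT for g in group.elements])
    return SymmetryGroup(label=group.label + "^J", elements=elems)


def evaluate_alignment(
    truth: AlignmentParams,
    est: AlignmentParams,
    group: SymmetryGroup,
) -> TrialResult:
    """Compare an estimate against ground truth modulo the symmetry group.

    Rotation errors compare the proper-rotation factors (after removing J
    on the left for reflected transforms, with the group conjugated
    accordingly); the translation error is taken against the
    symmetry-matched copy of the true translation.
    """
    reflect_correct = bool(est.reflect == truth.reflect)
    if truth.reflect:
        true_p = J_REFLECT @ truth.transform
        grp = _conjugate_group(group)
    else:
        true_p = truth.transform
        grp = group
    est_p = J_REFLECT @ est.transform if est.reflect else est.transform
    if reflect_correct:
        err_axis, err_angle = rotation_errors(true_p, est_p, grp)
        dists = [np.linalg.norm(g @ true_p - est_p) for g in grp.elements]
        gstar = group.elements[int(np.argmin(dists))]
        err_t = float(np.linalg.norm(est.translation - gstar @ truth.translation))
    else:
        err_axis = err_angle = 180.0
        err_t = float(np.linalg.norm(est.translation - truth.translation))
    return TrialResult(
        err_axis=err_axis,
        err_angle=err_angle,
        err_translation=err_t,
        reflect_correct=reflect_correct,
        score=est.score,
    )


def run_trial(
    spec: PhantomSpec,
    reflect: bool = False,
    snr: float | None = None,
    *,
    n_projs: int = 30,
    grid: RotationGrid | None = None,
    shifts: ShiftSearch | None = None,
    refine: bool = False,
    max_shift_frac: float = 0.10,
    seed: int = 0,
) -> TrialResult:
    """One end-to-end evaluation trial.

    Builds a phantom pair (noise, when requested, is added to both the
    reference and the moving map), aligns, optionally refines, and scores
    the estimate against ground truth modulo the phantom's symmetry group.
    """
    v1, v2, truth = make_pair(spec, reflect=reflect, seed=seed, max_shift_frac=max_shift_frac)
    if snr is not None:
        v1 = add_noise(v1, snr, seed=seed * 2 + 1)
        v2 = add_noise(v2, snr, seed=seed * 2 + 2)
    est = align_maps(v1, v2, n_projs=n_projs, grid=grid, shifts=shifts, seed=seed)
    if refine:
        est = refine_params(v1, v2, est)
    group = symmetry_elements(spec.symmetry)
    return evaluate_alignment(truth, est, group)
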