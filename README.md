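# emalign-kit

Fully automatic alignment of two 3D cryo-EM density maps over rotation,
handedness (reflection), and translation.

Comparing density maps — for resolution estimation, conformational
analysis, or validation — first requires bringing them into one
coordinate system. Reconstructions of the same molecule can differ by an
arbitrary rotation, a shift, and even a mirror flip, and symmetric
molecules only define the alignment up to a symmetry element.
`emalign-kit` estimates the full transform from the two maps alone: it
needs no symmetry annotation, no masks, and no initial guess.

## Method in brief

With `V2(x) = V1(Qx + t)` for an orthogonal `Q` and shift `t`, the
aligner:

1. projects `V2` along `n_p = 30` random directions (projection-slice
   theorem, evaluated with a Kaiser–Bessel gridding NUFFT);
2. finds each projection's orientation in `V1`'s frame by exhaustive
   **common-lines** scoring over a ~19,000-rotation quasi-uniform grid on
   SO(3): every two projections of one volume agree along a central line
   of their 2D Fourier transforms, so a candidate rotation is scored by
   the mean correlation of its predicted common lines against reference
   projections of `V1` (a 1D shift search absorbs in-plane displacement,
   and the leading candidates are re-ranked under the consistent
   single-displacement shift model);
3. fuses the per-projection estimates `X_i = R̂_i R_iᵀ ≈ g_i Q` by
   rank-3 spectral **synchronization** with group-clustered gauge
   snapping, then averages by the least-squares rotation mean — the
   unknown symmetry elements `g_i` cancel without ever identifying the
   group;
4. decides **handedness** by re-synchronizing the same projection
   alignments under J-conjugation (`J = diag(1,1,−1)`) — the mirror
   branch costs no extra common-lines work — and keeps the branch whose
   aligned map correlates better with `V1`;
5. estimates `t` by regularized **phase correlation** with sub-voxel peak
   interpolation, and
6. optionally polishes all six parameters with **BFGS** on
   `1 − correlation`.

Large maps are searched at a Fourier-cropped working size (default 64³)
and the parameters re-estimated at full scale. See `docs/methods.md` for
the complete account.

## Worked example

```python
import numpy as np
from emalign_kit import align_maps, refine_params, rotation_errors, symmetry_elements
from emalign_kit.fixtures import PhantomSpec, make_pair

# a synthetic pair: 48-voxel phantom, random rotation + up to 10% shift
v1, v2, truth = make_pair(PhantomSpec(n=48, seed=0), seed=0)

params = align_maps(v1, v2, seed=0)
err_axis, err_angle = rotation_errors(
    truth.transform, params.transform, symmetry_elements("C1")
)
print(f"reflect={params.reflect} score={params.score:.4f}")
print(f"axis error {err_axis:.2f} deg, angle error {err_angle:.2f} deg, "
      f"shift error {np.linalg.norm(params.translation - truth.translation):.2f} vox")

refined = refine_params(v1, v2, params)
ra, rg = rotation_errors(truth.transform, refined.transform, symmetry_elements("C1"))
print(f"after refinement: axis {ra:.3f} deg, angle {rg:.3f} deg")
```

Output:

```
reflect=False score=0.9987
axis error 0.60 deg, angle error 0.24 deg, shift error 0.03 vox
after refinement: axis 0.004 deg, angle 0.013 deg
```

The raw common-lines estimate lands within a degree of the generating
transform (grid quantization averaged over 30 projections); BFGS
refinement reduces the residual to millidegrees on clean phantoms.

From the shell, with maps on disk:

```bash
emalign-kit align --ref v1.mrc --query v2.mrc \
    --out aligned.mrc --params params.json --seed 0 --verbose
emalign-kit bench --n 48 --trials 5 --refine   # synthetic harness
```

`params.json` records the rotation matrix, ZYZ Euler angles, translation
in voxels and Å, the reflect flag, and the correlation before/after
refinement.

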