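# Methods

## Problem and model

Two cryo-EM density maps `V1, V2` of the same molecule, sampled on cubic
`n³` voxel grids, are related by an orthogonal transform and a shift:

    V2(x) = V1(Q·x + t),      Q ∈ O(3),  t ∈ R³,

with voxel indices mapped to centered coordinates `x = i − ⌊n/2⌋`. `Q` may
be improper (`det Q = −1`): reconstructions can come out with either
handedness, and the aligner must decide. If `V1` is invariant under a
finite rotation group `G` (cyclic `Cn`, dihedral `Dn`, or the cubic groups
`T`/`O`/`I`), then `(gQ, gt)` is an equally valid solution for every
`g ∈ G`; the aligner never needs to know `G`, but its output is only
defined up to such an element, and the evaluation metrics account for
that.

The estimate `(Q̂, t̂)` is reported so that resampling the moving map as
`V2(Q̂ᵀ(x − t̂))` superimposes it on `V1`.

## Estimation pipeline

1. **Random projections.** Draw `n_p` rotations `R_1..R_n_p` from the Haar
   measure (default `n_p = 30`) and compute the projection image of `V2`
   at each via the projection-slice theorem: the 2D Fourier transform of a
   projection is the central slice of the 3D transform spanned by the
   first two columns of the rotation. Slices are evaluated with an
   in-package Kaiser–Bessel gridding NUFFT (oversampling 2, kernel width
   7, relative error ~1e-6); one oversampled FFT per volume serves all
   projection directions.

2. **Common-lines orientation of each projection.** Any two projections of
   the same volume agree along one central line of their 2D Fourier
   transforms. Given reference projections of `V1` at known rotations, a
   candidate rotation `x` for the query predicts where the common line
   with each reference falls; the score of `x` is the mean over references
   of the correlation between the predicted ray of the query and the
   predicted ray of the reference, each image stored as a polar Fourier
   transform (360 rays of 1°, `n/2` radial samples, DC excluded). A 1D
   shift search along each common line (±15% of the box, 1-pixel steps)
   absorbs the in-plane displacement induced by the 3D translation.
   Maximizing the shift independently per reference pair is permissive —
   each pair gets a free parameter, which saturates scores on smooth
   images — so the 50 best-scoring candidates are re-ranked under the
   physically consistent model in which every 1D shift is the projection
   `s·(cos α, sin α)` of one 2D displacement `s` of the query; the
   two-parameter search restores the discrimination between nearby
   rotations. The candidate set is a fixed quasi-uniform grid on SO(3)
   (below); the re-ranked argmax gives `R̂_i`, the query's orientation in
   `V1`'s frame.

3. **Gauge synchronization and averaging.** Each block `X_i = R̂_i R_iᵀ`
   estimates `g_i Q` for an unknown symmetry element `g_i`. The spectral
   step builds the `3n×3n` matrix with blocks `X_i X_jᵀ` (exactly rank 3),
   takes its three leading eigenvectors scaled by the square-root
   eigenvalues, orthogonalizes the 3×3 blocks, and fixes the gauge by
   right-multiplying with the transpose of the first block, giving
   relative gauges `t_i ≈ g_i g_1ᵀ`. Because the block matrix is the Gram
   matrix of the stacked `X_i`, these raw gauges absorb each block's own
   estimation noise exactly — using them directly would collapse every
   per-index estimate onto block 1 and forfeit the benefit of multiple
   projections. The package therefore snaps the gauges to the finite set
   they cluster around: the `t_i` are clustered by geodesic distance
   (25° threshold — well below the ≥60° separation of distinct symmetry
   elements for the groups of practical interest), each `t_i` is replaced
   by its cluster mean expressed relative to the largest cluster, and the
   per-index estimates `O_i = t̃_iᵀ X_i` are averaged by the
   least-squares rotation mean (SVD projection of the arithmetic mean).
   The snapped gauges cancel the shared anchor noise exactly, so the `n_p`
   independent quantization errors average down roughly as `1/√n_p`. For
   exact inputs the output is exactly a symmetry copy of the true
   transform. A useful side effect: a grossly mis-aligned projection forms
   a singleton cluster, and its snapped estimate degenerates to the anchor
   mean — outliers are absorbed rather than amplified.

4. **Handedness.** If the maps are mirror images, `V2(x) = V1(J·O·x)` with
   `J = diag(1,1,−1)`, the same projections satisfy
   `R̂_i ≈ g J O R_i J`, so the reflected hypothesis reuses the identical
   `R̂_i` with J-conjugated gauge blocks `X_i = (J R̂_i J) R_iᵀ` — the
   second branch costs no additional common-lines work. Both branches are
   completed with a translation estimate and scored by whole-map
   correlation; the better branch wins.

5. **Translation.** After applying the branch rotation, the residual
   shift is the peak of the inverse FFT of the regularized-whitened
   cross-power spectrum `conj(F1)·F2 / (|·| + ε)` with `ε` equal to the
   mean cross-power magnitude, unwrapped to `(−n/2, n/2]`, with separable
   parabolic sub-voxel interpolation of the peak. The `ε` choice
   interpolates between phase correlation (strong frequencies) and
   matched filtering (noise-dominated frequencies): integer shifts of
   clean maps are recovered exactly, and the peak survives heavy noise
   where pure whitening drowns it.

6. **Refinement (optional, default on in the CLI).** BFGS on
   `1 − corr(V1, transformed V2)` over three ZYZ intrinsic Euler angles
   and three translations, initialized at the common-lines estimate, with
   central-difference gradients (0.1° / 0.1 voxel steps) and trilinear
   interpolation inside the objective. Near the ZYZ gimbal configuration
   (β < 5° or > 175°) a fixed 30° offset rotation about y is factored out
   before parameterizing. For a reflected initialization the moving map is
   pre-reflected once and the proper factor is refined. The objective is
   guaranteed not to increase: if the search fails, the initialization is
   returned.

For large maps the whole search runs on Fourier-cropped copies
(default 64³ — cropping the centered 3D DFT and rescaling preserves the
band-limited content exactly), after which the rotation transfers
unchanged and the translation is re-estimated at full scale.

## The candidate rotation grid

The exhaustive scoring step needs a deterministic covering of SO(3) whose
covering radius (the farthest any rotation can be from the grid) is small
enough that the per-projection quantization error stays in the
few-degrees regime. Product-type constructions (viewing directions ×
in-plane angles) behave like simple-cubic lattices and cover noticeably
worse than their size suggests. The package instead builds a
body-centered-cubic lattice in the rotation-vector chart of the Voronoi
fundamental cell of the 60-element icosahedral group — a near-ball of
radius ~37° where the exponential chart is nearly isometric, and where
BCC is close to the optimal covering lattice — and tiles it through the
group. Cell walls keep a margin band of lattice points on both sides,
sized so the nearest infinite-lattice point of any in-cell location
survives even in the worst corner geometry. The default grid (target
19,500; actual 19,020 rotations) has measured covering radius ≤ 7.5°
(5,000,000-probe Monte Carlo; exceedance probability ~1e-6) and mean
nearest-neighbor distance 4.6° — roughly an order of magnitude fewer
rotations than the 186,624-node naive 5° Euler grid at comparable
resolution. Targets below 3,000 fall back to a super-Fibonacci spiral.

## Synthetic phantoms and what they do (not) show

Test data are sums of anisotropic 3D Gaussian blobs confined to a
centered ball (rotations never clip mass), optionally replicated under a
point group for exact symmetry. Defaults: 100 blobs with axis widths
2–4.5% of the box (≈1–3 voxels at the working sizes 48–64), random
orientations, amplitudes 0.5–1.5. The width scale matters: a handful of
wide blobs yields projections whose angular autocorrelation is so broad
that nearby orientations are spectrally indistinguishable — no real
macromolecule looks like that. The chosen granularity emulates the
atom-scale detail that gives real maps spectral content out to Nyquist.
Pairs are rendered analytically: the moving map's blobs are the
transformed blobs (`center → Qᵀ(c − t)`, `covariance → Qᵀ C Q`), so
ground truth carries no interpolation error. Noise is white Gaussian with
variance `var(clean)/SNR` over the full array, added to both maps.

Not emulated: CTF envelopes, solvent background, masking artifacts,
non-uniform local resolution, and the correlated noise of real
reconstructions. Passing the synthetic protocol shows the estimator's
geometry and noise averaging are correct at the stated SNR; it does not
by itself certify accuracy on experimental depositions.

Problem sizes in the test-suite protocol: 48³ maps for clean/reflected/
symmetric trials, 64³ for the noise trials, 30 projections, the default
19k-rotation grid; the harness trends (errors vs projection count,
downsampling) reproduce at these sizes.

## Evaluation metrics

The symmetry element `g* = argmin_g ‖g·Q_true − Q̂‖_F` is found by
enumeration; errors compare `g*·Q_true` with `Q̂`: the axis error is the
angle between rotation axes (absolute dot product — the axis sign is a
gauge), the angle error is the absolute difference of rotation angles in
[0°, 180°], and the translation error is taken against `g*·t_true`. For
reflected transforms the proper factors (`J·Q`) are compared with the
group conjugated by `J`. On clean 48³ pairs the pipeline's mean errors
are ~0.5°/0.5° (axis/angle) before refinement and ~0.005° after; the
acceptance protocol treats 1.9°/1.86° (unrefined) and 0.25°/0.28°
(refined) — accuracy levels this class of aligner achieves on
experimental maps — as upper bounds for the synthetic surrogate.

## Numerical choices

- FFT convention: forward with negative exponent, frequency origin at the
  array center, shared by every module. Even-size Fourier cropping keeps
  the Nyquist row on the negative-frequency side.
- NUFFT: Kaiser–Bessel gridding, oversampling 2, width 7, Beatty-style
  shape parameter; deapodization by quadrature of the kernel transform.
- Nearest-ray lookup on the polar grid (no interpolation between rays):
  ≤0.5° error, negligible against the grid resolution.
- The vectorized scorer works in complex64 (correlation scoring needs ~3
  significant digits); the scalar reference path is complex128 and a test
  pins the two together at 1e-4.
- Ties in the candidate argmax break toward the lowest grid index; shift
  ties toward the smallest magnitude, negative first.
- Degenerate pairs (viewing directions within ~0.06°) are excluded from
  scores; a candidate with no valid pair scores −1.
- `sync_blocks` rejects inputs whose third eigenvalue vanishes; the SVD
  rotation mean flips the last singular vector if heavy noise produces a
  reflection.
- Phase-correlation surfaces whose peak is within 3σ of the mean trigger
  a flatness warning but still return the best peak.

## Known limitations

- Maps must share one cubic grid and voxel size; resample externally
  otherwise.
- Symmetry groups with elements closer than ~25° apart (Cn/Dn with
  n ≥ 8 at the margin, n ≥ 15 clearly) can defeat the gauge-cluster
  separation under heavy noise; the groups of common practice (C2–C7, Dn,
  T, O, I) are comfortably separated.
- The common-lines score carries no frequency weighting; at SNRs far
  below the tested 1/8 regime (desk scale) the argmax degrades before the
  synchronization can rescue it.
- Refinement is local: its basin is a few degrees/voxels wide, which the
  common-lines initialization comfortably provides.
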