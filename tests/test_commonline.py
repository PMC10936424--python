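import numpy as np
import pytest

from emalign_kit.commonline_align import (
    DegeneratePairError,
    ShiftSearch,
    _GridGeometry,
    align_projection,
    commonline_angles,
    score_candidate,
    shifted_ray_correlation,
)
from emalign_kit.projector import FourierSliceProjector, polar_ft
from emalign_kit.so3 import RotationGrid, candidate_grid, geodesic_deg, random_rotations


def rot_x(deg):
    t = np.deg2rad(deg)
    return np.array([[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]])


class TestCommonlineAngles:
    def test_identity_vs_x_quarter_turn(self):
        cl = commonline_angles(np.eye(3), rot_x(90))
        # both image planes intersect along the x-axis
        assert cl.alpha_i % 180.0 == pytest.approx(0.0, abs=1e-9)
        assert cl.alpha_j % 180.0 == pytest.approx(0.0, abs=1e-9)

    def test_swap_symmetry(self):
        # swapping arguments swaps the two line directions; the cross
        # product flips sign, so the angles may differ by 180 degrees
        r_i, r_j = random_rotations(2, 6)
        a = commonline_angles(r_i, r_j)
        b = commonline_angles(r_j, r_i)
        assert a.alpha_i % 180.0 == pytest.approx(b.alpha_j % 180.0, abs=1e-9)
        assert a.alpha_j % 180.0 == pytest.approx(b.alpha_i % 180.0, abs=1e-9)

    def test_defining_property_common_ray(self):
        # the in-plane directions map to the same 3D ray in both frames
        for seed in range(5):
            r_i, r_j = random_rotations(2, 100 + seed)
            cl = commonline_angles(r_i, r_j)
            ui = r_i @ np.array([np.cos(np.deg2rad(cl.alpha_i)), np.sin(np.deg2rad(cl.alpha_i)), 0.0])
            uj = r_j @ np.array([np.cos(np.deg2rad(cl.alpha_j)), np.sin(np.deg2rad(cl.alpha_j)), 0.0])
            np.testing.assert_allclose(ui, uj, atol=1e-8)

    def test_parallel_views_degenerate(self):
        with pytest.raises(DegeneratePairError):
            commonline_angles(np.eye(3), np.eye(3))


class TestShiftSearch:
    def test_candidates_symmetric(self):
        s = ShiftSearch(s_max=3, step=1)
        np.testing.assert_array_equal(s.candidates, [-3, -2, -1, 0, 1, 2, 3])

    def test_validation(self):
        with pytest.raises(ValueError):
            ShiftSearch(s_max=-1)
        with pytest.raises(ValueError):
            ShiftSearch(s_max=1, step=0)


class TestShiftedRayCorrelation:
    def test_identical_rays(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(16) + 1j * rng.standard_normal(16)
        c, s = shifted_ray_correlation(a, a, ShiftSearch(s_max=0), n=32)
        assert c == pytest.approx(1.0)
        assert s == 0.0

    def test_constructed_shift_recovered(self):
        n, n_r = 32, 16
        rng = np.random.default_rng(1)
        a = rng.standard_normal(n_r) + 1j * rng.standard_normal(n_r)
        xi = np.arange(1, n_r + 1) * (n / 2.0) / n_r
        b = a * np.exp(2j * np.pi * xi * 3.0 / n)  # b shifted by exactly -(-3)...
        c, s = shifted_ray_correlation(a, b, ShiftSearch(s_max=5), n=n)
        assert s == 3.0
        assert c > 0.999

    def test_random_rays_below_permutation_null(self):
        rng = np.random.default_rng(2)
        n, n_r = 64, 32
        a = rng.standard_normal(n_r) + 1j * rng.standard_normal(n_r)
        b = rng.standard_normal(n_r) + 1j * rng.standard_normal(n_r)
        shifts = ShiftSearch(s_max=5)
        c, _ = shifted_ray_correlation(a, b, shifts, n=n)
        # brute-force permutation null at the same shift-maximized statistic
        null = []
        for k in range(200):
            perm = rng.permutation(n_r)
            null.append(shifted_ray_correlation(a, b[perm], shifts, n=n)[0])
        assert c < np.quantile(null, 0.99) + 0.15

    def test_zero_ray(self):
        a = np.zeros(8, dtype=complex)
        c, s = shifted_ray_correlation(a, a, ShiftSearch(s_max=2), n=16)
        assert c == 0.0


@pytest.fixture(scope="module")
def setup(phantom32):
    proj = FourierSliceProjector(phantom32)
    ref_rots = random_rotations(8, 17)
    refs = [polar_ft(proj.project(r), L=180) for r in ref_rots]
    x_true = random_rotations(1, 18)[0]
    query = polar_ft(proj.project(x_true), L=180)
    return proj, ref_rots, refs, x_true, query


class TestScoreCandidate:

    def test_true_candidate_beats_distant_ones(self, setup):
        _, ref_rots, refs, x_true, query = setup
        shifts = ShiftSearch(s_max=0)
        s_true = score_candidate(query, refs, ref_rots, x_true, shifts)
        wins = 0
        cands = random_rotations(500, 19)
        kept = 0
        for x in cands:
            if geodesic_deg(x, x_true) <= 20:
                continue
            kept += 1
            if s_true >= score_candidate(query, refs, ref_rots, x, shifts):
                wins += 1
        assert wins / kept >= 0.95

    def test_all_degenerate_gives_minus_one(self, setup):
        _, _, refs, x_true, query = setup
        shifts = ShiftSearch(s_max=0)
        s = score_candidate(query, [refs[0]], [x_true], x_true, shifts)
        assert s == -1.0

    def test_intensity_scale_invariance(self, setup, phantom32):
        proj, ref_rots, refs, x_true, query = setup
        from emalign_kit.projector import ProjectionRays

        shifts = ShiftSearch(s_max=2)
        scaled = ProjectionRays(rays=query.rays * 3.5, angular_step=query.angular_step)
        a = score_candidate(query, refs, ref_rots, x_true, shifts)
        b = score_candidate(scaled, refs, ref_rots, x_true, shifts)
        assert a == pytest.approx(b, abs=1e-9)

    def test_vectorized_path_matches_scalar(self, setup, phantom32):
        from emalign_kit.commonline_align import _score_all

        _, ref_rots, refs, _, query = setup
        shifts = ShiftSearch(s_max=3)
        cands = random_rotations(8, 23)
        geom = _GridGeometry(cands, ref_rots, query.L)
        fast = _score_all(query, refs, geom, shifts, phantom32.n)
        for k, x in enumerate(cands):
            slow = score_candidate(query, refs, ref_rots, x, shifts)
            assert fast[k] == pytest.approx(slow, abs=1e-4)

    def test_brute_force_ray_resampling_oracle(self, setup, phantom32):
        # independent reimplementation: no polar cache — rays are resampled
        # per candidate directly from the images by explicit DFT
        proj, ref_rots, _, _, _ = setup
        n = phantom32.n
        x_q = random_rotations(1, 29)[0]
        qimg = proj.project(x_q).data
        rimgs = [proj.project(r).data for r in ref_rots]
        shifts = ShiftSearch(s_max=2)
        L = 180

        def ray_of(img, alpha_deg):
            n_r = n // 2
            rho = np.arange(1, n_r + 1) * (n / 2.0) / n_r
            kx = rho * np.cos(np.deg2rad(alpha_deg))
            ky = rho * np.sin(np.deg2rad(alpha_deg))
            x = np.arange(n) - n // 2
            X, Y = np.meshgrid(x, x, indexing="ij")
            return np.array([
                (img * np.exp(-2j * np.pi * (kxi * X + kyi * Y) / n)).sum()
                for kxi, kyi in zip(kx, ky)
            ])

        from emalign_kit.commonline_align import commonline_angles as cla

        cands = random_rotations(4, 31)
        qrays = polar_ft(FourierSliceProjector(phantom32).project(x_q), L=L)
        refs = [polar_ft(FourierSliceProjector(phantom32).project(r), L=L) for r in ref_rots]
        for x in cands:
            total, cnt = 0.0, 0
            for rimg, rrot in zip(rimgs, ref_rots):
                try:
                    cl = cla(x, rrot)
                except DegeneratePairError:
                    continue
                ai = round(cl.alpha_i * L / 360.0) % L * (360.0 / L)
                aj = round(cl.alpha_j * L / 360.0) % L * (360.0 / L)
                c, _ = shifted_ray_correlation(ray_of(qimg, ai), ray_of(rimg, aj), shifts, n)
                total += c
                cnt += 1
            brute = total / cnt if cnt else -1.0
            fast = score_candidate(qrays, refs, ref_rots, x, shifts)
            assert fast == pytest.approx(brute, abs=1e-6)


class TestAlignProjection:
    def test_planted_optimum_in_grid(self, phantom32):
        proj = FourierSliceProjector(phantom32)
        r_true = random_rotations(1, 37)[0]
        base = candidate_grid(3000)
        grid = RotationGrid(
            np.concatenate([base.rotations[:500], r_true[None]]), base.nominal_resolution
        )
        query = proj.project(r_true)
        rec, score = align_projection(query, phantom32, n_refs=10, grid=grid,
                                      shifts=ShiftSearch(s_max=0), seed=5)
        np.testing.assert_allclose(rec, r_true, atol=1e-12)
        assert score > 0.999

    def test_shifted_query_same_recovery(self, phantom48, default_grid):
        # an in-plane displacement of the query (from a 3D translation)
        # must not degrade the orientation estimate when the shift search
        # covers it
        from scipy import ndimage
        from emalign_kit.projector import ProjectionImage

        proj = FourierSliceProjector(phantom48)
        for i, r in enumerate(random_rotations(5, 61)):
            img = ndimage.shift(proj.project(r).data, (4, 0), order=1, cval=0)
            rec, _ = align_projection(
                ProjectionImage(img), phantom48, n_refs=30, grid=default_grid,
                shifts=ShiftSearch(s_max=8), seed=300 + i,
            )
            assert geodesic_deg(rec, r) <= 7.5

    def test_empty_grid_rejected(self, phantom32):
        proj = FourierSliceProjector(phantom32)
        grid = RotationGrid(np.zeros((0, 3, 3)), 1.0)
        with pytest.raises(ValueError):
            align_projection(proj.project(np.eye(3)), phantom32, 5, grid, ShiftSearch(1), 0)

    def test_cost_scales_linearly_in_refs_and_shifts(self, phantom32):
        # contract-level complexity: scoring work is proportional to
        # n_refs * |shifts| (checked by counting inner products, not time)
        from emalign_kit.commonline_align import _score_all

        proj = FourierSliceProjector(phantom32)
        q = polar_ft(proj.project(random_rotations(1, 41)[0]), L=90)
        cands = candidate_grid(3000).rotations[:200]
        for n_refs, s_max in [(4, 2), (8, 2), (4, 4)]:
            ref_rots = random_rotations(n_refs, 43)
            refs = [polar_ft(proj.project(r), L=90) for r in ref_rots]
            geom = _GridGeometry(cands, ref_rots, 90)
            scores = _score_all(q, refs, geom, ShiftSearch(s_max=s_max), phantom32.n)
            assert scores.shape == (200,)
            assert np.isfinite(scores).all()
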