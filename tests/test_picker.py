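"""Grid-based local-maximum picker: every stage against a brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gridpick as gp
from gridpick.picker import Candidate, GridSpec


class TestBuildKernel:
    def test_size_one_is_unit(self):
        k = gp.build_kernel(1, sigma=1.0)
        np.testing.assert_array_equal(k.weights, [[1.0]])

    @pytest.mark.parametrize("s,sigma", [(3, 1.0), (8, 2.0), (15, 3.5)])
    def test_normalized_to_one(self, s, sigma):
        assert gp.build_kernel(s, sigma).weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_closed_form_lattice(self):
        k = gp.build_kernel(3, sigma=1.0)
        offsets = [-1, 0, 1]
        raw = np.array([[np.exp(-(x * x + y * y) / 2.0) for x in offsets] for y in offsets])
        np.testing.assert_allclose(k.weights, raw / raw.sum(), atol=1e-14)

    def test_center_weight_maximal_and_symmetric(self):
        w = gp.build_kernel(7, sigma=1.5).weights
        assert w[3, 3] == w.max()
        np.testing.assert_allclose(w, w[::-1, :], atol=0)
        np.testing.assert_allclose(w, w[:, ::-1], atol=0)


def score_oracle(v, weights):
    """Double-loop evaluation of score(m, n) = sum W[x, y] * V[m + x, n + y]."""
    s = weights.shape[0]
    off = np.arange(s) - s // 2
    h, w = v.shape
    out = np.zeros((h, w))
    for m in range(h):
        for n in range(w):
            acc = 0.0
            for yi, dy in enumerate(off):
                for xi, dx in enumerate(off):
                    y, x = m + dy, n + dx
                    if 0 <= y < h and 0 <= x < w:
                        acc += weights[yi, xi] * v[y, x]
            out[m, n] = acc
    return out


class TestScoreMap:
    def test_uniform_map_scores_one_in_interior(self):
        pm = gp.ProbabilityMap(np.ones((11, 11)))
        k = gp.build_kernel(3, 1.0)
        s = gp.score_map(pm, k)
        np.testing.assert_allclose(s[1:-1, 1:-1], 1.0, atol=1e-12)

    def test_zero_map_scores_zero(self):
        s = gp.score_map(gp.ProbabilityMap(np.zeros((8, 8))), gp.build_kernel(5, 1.0))
        assert not s.any()

    def test_single_hot_pixel_matches_loop_oracle(self):
        v = np.zeros((7, 7))
        v[3, 3] = 1.0
        k = gp.build_kernel(3, 1.0)
        np.testing.assert_allclose(
            gp.score_map(gp.ProbabilityMap(v), k), score_oracle(v, k.weights), atol=1e-10
        )

    def test_random_map_matches_loop_oracle(self, rng):
        v = rng.random((12, 12))
        k = gp.build_kernel(5, 1.3)
        np.testing.assert_allclose(
            gp.score_map(gp.ProbabilityMap(v), k), score_oracle(v, k.weights), atol=1e-10
        )

    def test_output_bounded_by_map_range(self, rng):
        s = gp.score_map(gp.ProbabilityMap(rng.random((20, 20))), gp.build_kernel(6, 1.5))
        assert s.min() >= -1e-12 and s.max() <= 1.0 + 1e-12


def grid_argmax_oracle(score, g):
    """Exhaustive per-cell scan with first-in-row-major tie-breaking."""
    h, w = score.shape
    out = []
    for y0 in range(0, h, g):
        for x0 in range(0, w, g):
            best = None
            for y in range(y0, min(y0 + g, h)):
                for x in range(x0, min(x0 + g, w)):
                    if best is None or score[y, x] > best[2]:
                        best = (x, y, score[y, x])
            out.append(best[:2])
    return out


class TestGridInit:
    def test_grid_spec_uses_ceiling_division(self):
        spec = GridSpec.for_map((4096, 4096), 100)
        assert (spec.ny, spec.nx) == (41, 41)
        assert spec.n_cells == 1681

    def test_map_smaller_than_one_grid_gives_global_argmax(self, rng):
        s = rng.random((5, 5))
        cands = gp.init_grid_candidates(s, GridSpec.for_map(s.shape, 10))
        assert len(cands) == 1
        iy, ix = np.unravel_index(np.argmax(s), s.shape)
        assert (cands[0].x, cands[0].y) == (ix, iy)

    def test_matches_per_cell_exhaustive_scan(self, rng):
        s = rng.random((10, 10))
        cands = gp.init_grid_candidates(s, GridSpec.for_map(s.shape, 3))
        assert [(c.x, c.y) for c in cands] == grid_argmax_oracle(s, 3)

    def test_tie_broken_to_lowest_row_major_index(self):
        s = np.zeros((4, 4))
        cands = gp.init_grid_candidates(s, GridSpec.for_map(s.shape, 4))
        assert (cands[0].x, cands[0].y) == (0, 0)

    @given(st.integers(1, 40), st.integers(1, 40), st.integers(1, 50))
    def test_candidate_count_is_ceil_product(self, h, w, g):
        spec = GridSpec.for_map((h, w), g)
        cands = gp.init_grid_candidates(np.zeros((h, w)), spec)
        assert len(cands) == -(-h // g) * -(-w // g) == spec.n_cells


class TestAscent:
    def test_candidate_at_global_maximum_is_fixed_point(self, rng):
        s = rng.random((9, 9))
        iy, ix = np.unravel_index(np.argmax(s), s.shape)
        out = gp.local_max_ascend(s, [Candidate(ix, iy, s[iy, ix])], radius=3)
        assert (out[0].x, out[0].y) == (ix, iy)
        assert out[0].converged and out[0].n_iters == 1

    def test_monotone_ramp_converges_to_top_corner(self):
        yy, xx = np.mgrid[0:12, 0:12]
        s = (yy + xx).astype(float)  # strictly increasing toward (11, 11)
        out = gp.local_max_ascend(s, [Candidate(0, 0, 0.0)], radius=2, max_iters=100)
        assert (out[0].x, out[0].y) == (11, 11)
        assert out[0].converged

    def test_plateau_tie_goes_to_lowest_row_major_index(self):
        s = np.zeros((5, 5))
        s[2:4, 2:4] = 1.0
        out = gp.local_max_ascend(s, [Candidate(3, 3, 1.0)], radius=2)
        assert (out[0].x, out[0].y) == (2, 2)  # first plateau pixel row-major

    def test_score_never_decreases_and_terminates(self, rng):
        s = rng.random((30, 30))
        init = gp.init_grid_candidates(s, GridSpec.for_map(s.shape, 5))
        out = gp.local_max_ascend(s, init, radius=5, max_iters=50)
        for before, after in zip(init, out):
            assert after.score >= before.score
            assert after.n_iters <= 50


def nms_oracle(cands, min_sep):
    """Quadratic reference NMS: independent implementation of the greedy rule."""
    kept = []
    for c in sorted(cands, key=lambda c: (-c.score, c.y, c.x)):
        ok = True
        for k in kept:
            if ((c.x - k.x) ** 2 + (c.y - k.y) ** 2) ** 0.5 < min_sep:
                ok = False
                break
        if ok:
            kept.append(c)
    return kept


class TestDeduplicate:
    def test_identical_positions_keep_one(self):
        out = gp.deduplicate([Candidate(4, 4, 0.8), Candidate(4, 4, 0.8)], 1.0)
        assert len(out) == 1

    def test_greedy_keeps_higher_score(self):
        a, b = Candidate(10, 10, 0.9), Candidate(11, 10, 0.8)
        out = gp.deduplicate([b, a], min_separation=50)
        assert out == [a]

    def test_matches_quadratic_reference(self, rng):
        cands = [
            Candidate(int(x), int(y), float(s))
            for x, y, s in zip(
                rng.integers(0, 50, 20), rng.integers(0, 50, 20), rng.random(20)
            )
        ]
        out = gp.deduplicate(cands, min_separation=10)
        ref = nms_oracle(cands, 10)
        assert [(c.x, c.y) for c in out] == [(c.x, c.y) for c in ref]


class TestFilterPicks:
    CFG = gp.PickerConfig(particle_size=8)

    def test_empty_input_empty_output(self):
        assert len(gp.filter_picks([], self.CFG)) == 0

    def test_default_threshold_drops_below_0p6(self):
        cands = [Candidate(0, 0, 0.9), Candidate(10, 0, 0.7), Candidate(20, 0, 0.5)]
        out = gp.filter_picks(cands, self.CFG)
        assert len(out) == 2
        assert [p.score for p in out] == [0.9, 0.7]

    def test_cap_keeps_top_scoring(self):
        cfg = gp.PickerConfig(particle_size=8, max_picks=5)
        cands = [Candidate(i, 0, 0.6 + i * 1e-3) for i in range(12)]
        out = gp.filter_picks(cands, cfg)
        assert len(out) == 5
        assert min(p.score for p in out) >= 0.6 + 7e-3

    def test_default_cap_is_500(self, rng):
        cands = [
            Candidate(int(i % 1000), int(i // 1000), float(s))
            for i, s in enumerate(0.6 + 0.4 * rng.random(600))
        ]
        out = gp.filter_picks(cands, gp.PickerConfig(particle_size=8))
        assert len(out) == 500
        dropped_max = sorted(c.score for c in cands)[99]  # 100 lowest are dropped
        assert all(p.score >= dropped_max for p in out)

    def test_scoring_hook_refilters(self):
        cands = [Candidate(0, 0, 0.9), Candidate(10, 0, 0.8)]
        out = gp.filter_picks(
            cands, self.CFG, scorer=lambda c, s: 0.95 if c.x == 0 else 0.1
        )
        assert [(p.x, p.score) for p in out] == [(0, 0.95)]


class TestPickParticles:
    def test_zero_map_yields_no_picks(self):
        pm = gp.ProbabilityMap(np.zeros((64, 64)))
        assert len(gp.pick_particles(pm, gp.PickerConfig(particle_size=8))) == 0

    def test_recovers_gaussian_blob_lattice(self):
        # 9 disjoint blobs centered on a 3x3 lattice with spacing 4s
        s = 8
        size = 4 * s * 3 + 2 * s
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        v = np.zeros((size, size))
        centers = [(s + 4 * s * i, s + 4 * s * j) for i in range(3) for j in range(3)]
        for cy, cx in centers:
            v += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * (s / 3) ** 2))
        pm = gp.ProbabilityMap(np.clip(v, 0, 1))
        picks = gp.pick_particles(pm, gp.PickerConfig(particle_size=s))
        assert len(picks) == 9
        for cy, cx in centers:
            d = min(np.hypot(p.x - cx, p.y - cy) for p in picks)
            assert d <= s / 4

    def test_deterministic_across_runs(self, sim_dataset):
        _, _, _, pmap = sim_dataset
        cfg = gp.PickerConfig(particle_size=32)
        a = gp.pick_particles(pmap, cfg)
        b = gp.pick_particles(pmap, cfg)
        assert [(p.x, p.y, p.score) for p in a] == [(p.x, p.y, p.score) for p in b]

    def test_min_separation_enforces_overlap_bound(self, sim_dataset):
        # any two picks >= s/2 apart => pairwise box-overlap area <= s^2/4
        _, _, _, pmap = sim_dataset
        s = 32
        picks = gp.pick_particles(pmap, gp.PickerConfig(particle_size=s))
        xy = picks.coordinates()
        for i in range(len(xy)):
            for j in range(i + 1, len(xy)):
                dx, dy = abs(xy[i, 0] - xy[j, 0]), abs(xy[i, 1] - xy[j, 1])
                assert np.hypot(dx, dy) >= s / 2
                overlap = max(0, s - dx) * max(0, s - dy)
                assert overlap <= s * s / 4 + 1e-9
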