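import numpy as np
import pytest
from scipy import stats

from mkda.brain_space import Mask, VoxelGrid
from mkda.mc_inference import (
    NullDistribution,
    ThresholdSpec,
    exceedance_count_threshold,
    exceedance_threshold,
    extent_threshold,
    height_threshold,
    monte_carlo_null,
    primary_threshold,
    randomize_studyset,
    threshold_map,
)
from mkda.mkda_core import KernelSpec, WeightScheme, density_map, make_provenance
from mkda.mkda_core import DensityMap

from conftest import make_contrast, make_studyset, random_studyset


@pytest.fixture
def small_mask():
    grid = VoxelGrid(affine=np.diag([2.0, 2.0, 2.0, 1.0]), shape=(12, 12, 12))
    inside = np.zeros(grid.shape, bool)
    inside[2:10, 2:10, 2:10] = True
    return Mask(grid=grid, inside=inside)


class TestRandomize:
    def test_structure_preserved_and_inside_mask(self, small_mask):
        ss = make_studyset([make_contrast("c", [(4, 4, 4), (10, 10, 10), (16, 16, 16)], n=13)])
        rng = np.random.default_rng(0)
        out = randomize_studyset(ss, small_mask, rng)
        c = out.contrasts[0]
        assert len(c.foci) == 3 and c.n_participants == 13 and c.design == "random"
        from mkda.brain_space import mm_to_voxel

        for f in c.foci:
            vox = mm_to_voxel(small_mask.grid, f.xyz)
            assert small_mask.inside[tuple(vox)]

    def test_same_seed_same_result(self, small_mask):
        ss = make_studyset([make_contrast("c", [(4, 4, 4), (10, 10, 10)])])
        a = randomize_studyset(ss, small_mask, np.random.default_rng(42))
        b = randomize_studyset(ss, small_mask, np.random.default_rng(42))
        assert a == b

    def test_blob_unit_translates_groups_rigidly(self, small_mask):
        # two foci 4 mm apart (overlapping spheres) stay 4 mm apart;
        # a focus 40 mm away is its own blob and moves independently
        ss = make_studyset(
            [make_contrast("c", [(4.0, 4.0, 4.0), (4.0, 4.0, 8.0), (44.0, 44.0, 44.0)])]
        )
        out = randomize_studyset(ss, small_mask, np.random.default_rng(13), unit="blob")
        f = [np.array(fc.xyz) for fc in out.contrasts[0].foci]
        assert np.linalg.norm(f[0] - f[1]) == pytest.approx(4.0)
        # deterministic given the seed
        again = randomize_studyset(ss, small_mask, np.random.default_rng(13), unit="blob")
        assert out == again

    def test_blob_null_runs_through_monte_carlo(self, small_mask):
        ss = make_studyset([make_contrast("c", [(4, 4, 4), (6, 4, 4)], n=9),
                            make_contrast("d", [(10, 10, 10)], n=16)])
        spec = ThresholdSpec(n_iterations=15, seed=8, primary_alphas=(0.05,))
        null = monte_carlo_null(ss, small_mask.grid, small_mask, spec=spec,
                                randomize_unit="blob")
        assert len(null.max_density) == 15
        assert (null.max_density > 0).all()

    def test_uniform_over_two_voxel_mask(self):
        grid = VoxelGrid(affine=np.eye(4), shape=(2, 1, 1))
        mask = Mask(grid=grid, inside=np.ones((2, 1, 1), bool))
        ss = make_studyset([make_contrast("c", [(0, 0, 0)])])
        rng = np.random.default_rng(7)
        hits = 0
        n = 10_000
        for _ in range(n):
            out = randomize_studyset(ss, mask, rng)
            hits += out.contrasts[0].foci[0].x == 0.0
        lo, hi = stats.binomtest(hits, n, 0.5).proportion_ci(0.999)
        assert lo <= 0.5 <= hi


class TestThresholdConventions:
    def test_height_threshold_picks_top_of_twenty(self):
        null = NullDistribution(
            max_density=np.arange(1, 21) / 100.0, histogram={}, max_cluster_sizes={},
            primary_thresholds={}, n_iterations=20, seed=0, connectivity=18,
        )
        assert height_threshold(null, 0.05) == pytest.approx(0.20)

    def test_height_threshold_all_tied_is_unreachable(self):
        null = NullDistribution(
            max_density=np.full(100, 0.1), histogram={}, max_cluster_sizes={},
            primary_thresholds={}, n_iterations=100, seed=0, connectivity=18,
        )
        t = height_threshold(null, 0.05)
        assert t > 0.1  # nothing passes unless observed density exceeds 0.1

    def test_exceedance_threshold_matches_sort_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.choice([0.0, 0.05, 0.1, 0.1, 0.2, 0.3], size=500)
        for p in (0.01, 0.05, 0.2, 0.5):
            t = exceedance_threshold(vals, p)
            # oracle: scan sorted unique values directly
            cands = [v for v in np.unique(vals) if (vals >= v).mean() <= p]
            expected = min(cands) if cands else np.nextafter(vals.max(), np.inf)
            assert t == expected
            assert (vals >= t).mean() <= p

    def test_extent_threshold_single_outlier(self):
        sizes = np.zeros(100, dtype=int)
        sizes[0] = 50
        null = NullDistribution(
            max_density=np.zeros(100), histogram={},
            max_cluster_sizes={0.05: sizes}, primary_thresholds={},
            n_iterations=100, seed=0, connectivity=18,
        )
        assert extent_threshold(null, 0.05, 0.05) == 1

    def test_extent_threshold_all_tied(self):
        null = NullDistribution(
            max_density=np.zeros(60), histogram={},
            max_cluster_sizes={0.05: np.full(60, 7)}, primary_thresholds={},
            n_iterations=60, seed=0, connectivity=18,
        )
        assert extent_threshold(null, 0.05, 0.05) == 8

    def test_extent_threshold_matches_sort_oracle(self):
        rng = np.random.default_rng(11)
        sizes = rng.integers(0, 30, size=400)
        for p in (0.01, 0.05, 0.25):
            k = exceedance_count_threshold(sizes, p)
            assert (sizes >= k).mean() <= p
            assert k == 0 or (sizes >= k - 1).mean() > p  # smallest such k

    def test_unrecorded_alpha_is_an_error(self):
        null = NullDistribution(
            max_density=np.zeros(10), histogram={},
            max_cluster_sizes={0.05: np.zeros(10, int)}, primary_thresholds={},
            n_iterations=10, seed=0, connectivity=18,
        )
        with pytest.raises(ValueError, match="not recorded"):
            extent_threshold(null, 0.001, 0.05)

    def test_primary_threshold_small_positive_tail(self):
        # 4% of null voxel values are positive; alpha=.05 admits the smallest one
        hist = {0.0: 9600, 0.1: 300, 0.2: 100}
        null = NullDistribution(
            max_density=np.zeros(1), histogram=hist, max_cluster_sizes={},
            primary_thresholds={}, n_iterations=1, seed=0, connectivity=18,
        )
        assert primary_threshold(null, 0.05) == pytest.approx(0.1)
        assert primary_threshold(null, 1.0) == pytest.approx(0.0)

    def test_primary_threshold_matches_cumsum_oracle(self):
        rng = np.random.default_rng(5)
        vals = np.round(rng.random(50), 2)
        counts = rng.integers(1, 100, size=50)
        hist = {}
        for v, c in zip(vals, counts):
            hist[v] = hist.get(v, 0) + int(c)
        null = NullDistribution(
            max_density=np.zeros(1), histogram=hist, max_cluster_sizes={},
            primary_thresholds={}, n_iterations=1, seed=0, connectivity=18,
        )
        total = sum(hist.values())
        for alpha in (0.001, 0.05, 0.3):
            d = primary_threshold(null, alpha)
            tail = sum(c for v, c in hist.items() if v >= d) / total
            assert tail <= alpha
            below = [v for v in hist if v < d]
            if below:
                worse = sum(c for v, c in hist.items() if v >= max(below)) / total
                assert worse > alpha  # d is the smallest qualifying value

    def test_thresholds_monotone_in_p(self):
        rng = np.random.default_rng(9)
        null = NullDistribution(
            max_density=rng.random(300), histogram={},
            max_cluster_sizes={0.05: rng.integers(0, 50, 300)},
            primary_thresholds={}, n_iterations=300, seed=0, connectivity=18,
        )
        hs = [height_threshold(null, p) for p in (0.01, 0.05, 0.2)]
        assert hs[0] >= hs[1] >= hs[2]
        ks = [extent_threshold(null, 0.05, p) for p in (0.01, 0.05, 0.2)]
        assert ks[0] >= ks[1] >= ks[2]


class TestMonteCarloNull:
    def test_single_iteration_lengths(self, small_mask):
        ss = make_studyset([make_contrast("c", [(4, 4, 4)])])
        spec = ThresholdSpec(n_iterations=1, seed=0, primary_alphas=(0.05,))
        null = monte_carlo_null(ss, small_mask.grid, small_mask, spec=spec)
        assert len(null.max_density) == 1
        assert len(null.max_cluster_sizes[0.05]) == 1

    def test_single_contrast_max_density_is_one(self, small_mask):
        ss = make_studyset([make_contrast("c", [(4, 4, 4)])])
        spec = ThresholdSpec(n_iterations=10, seed=1, primary_alphas=(0.05,))
        null = monte_carlo_null(ss, small_mask.grid, small_mask, spec=spec)
        assert np.allclose(null.max_density, 1.0)

    def test_reproducible_bitwise(self, small_mask):
        rng = np.random.default_rng(21)
        ss = random_studyset(rng, small_mask.grid, n_contrasts=4)
        spec = ThresholdSpec(n_iterations=200, seed=99, primary_alphas=(0.01, 0.05))
        a = monte_carlo_null(ss, small_mask.grid, small_mask, spec=spec)
        b = monte_carlo_null(ss, small_mask.grid, small_mask, spec=spec)
        assert np.array_equal(a.max_density, b.max_density)
        assert a.histogram == b.histogram
        for alpha in spec.primary_alphas:
            assert np.array_equal(a.max_cluster_sizes[alpha], b.max_cluster_sizes[alpha])

    def test_json_round_trip(self, small_mask, tmp_path):
        ss = make_studyset([make_contrast("c", [(4, 4, 4), (10, 12, 8)])])
        spec = ThresholdSpec(n_iterations=20, seed=5, primary_alphas=(0.05,))
        null = monte_carlo_null(ss, small_mask.grid, small_mask, spec=spec)
        p = tmp_path / "null.json"
        null.to_json(p)
        back = NullDistribution.from_json(p)
        assert np.array_equal(back.max_density, null.max_density)
        assert back.histogram == pytest.approx(null.histogram)
        assert np.array_equal(back.max_cluster_sizes[0.05], null.max_cluster_sizes[0.05])
        assert back.provenance == null.provenance


class TestThresholdMap:
    def _null(self, mask, ss, **kw):
        spec = ThresholdSpec(n_iterations=kw.pop("n_iterations", 100), seed=2,
                             primary_alphas=(0.05,), **kw)
        return monte_carlo_null(ss, mask.grid, mask, spec=spec), spec

    def test_zero_density_map_is_empty(self, small_mask):
        ss = make_studyset([make_contrast("c", [(4, 4, 4)], n=9),
                            make_contrast("d", [(10, 10, 10)], n=16)])
        null, spec = self._null(small_mask, ss)
        dens = DensityMap(
            grid=small_mask.grid, data=np.zeros(small_mask.grid.shape),
            provenance=dict(null.provenance),
        )
        sig = threshold_map(dens, null, spec)
        assert not sig.combined.any()

    def test_all_ones_single_cluster_passes_both(self, full_mask):
        # enough contrasts on a big enough mask that the null max stays < 1
        ss = make_studyset(
            [make_contrast(f"c{i}", [(24.0, 24.0, 24.0)], n=9 + i) for i in range(10)]
        )
        null, spec = self._null(full_mask, ss)
        dens = DensityMap(
            grid=full_mask.grid,
            data=full_mask.inside.astype(float),
            provenance=dict(null.provenance),
        )
        sig = threshold_map(dens, null, spec)
        assert sig.height[full_mask.inside].all()
        assert sig.extent[0.05][full_mask.inside].all()
        assert sig.combined[full_mask.inside].all()

    def test_extent_only_cluster(self, small_mask):
        ss = make_studyset(
            [make_contrast(f"c{i}", [(4, 4, 4)], n=16) for i in range(10)]
        )
        null, spec = self._null(small_mask, ss, n_iterations=200)
        h = np.sort(null.max_density)
        p05 = null.primary_thresholds[0.05]
        height_thr = exceedance_threshold(null.max_density, 0.05)
        # plant one mask-wide cluster above the primary cutoff, below height
        level = (p05 + height_thr) / 2
        assert p05 < level < height_thr
        dens = DensityMap(
            grid=small_mask.grid,
            data=np.where(small_mask.inside, level, 0.0),
            provenance=dict(null.provenance),
        )
        sig = threshold_map(dens, null, spec)
        assert not sig.height.any()
        assert sig.extent[0.05].sum() == small_mask.n_voxels
        assert sig.combined.any()

    def test_provenance_mismatch_rejected(self, small_mask):
        ss = make_studyset([make_contrast("c", [(4, 4, 4)], n=9),
                            make_contrast("d", [(10, 10, 10)], n=16)])
        null, spec = self._null(small_mask, ss)
        other = density_map(ss, small_mask.grid, small_mask, KernelSpec(radius=8.0))
        with pytest.raises(ValueError, match="provenance mismatch"):
            threshold_map(other, null, spec)
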