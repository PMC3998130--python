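"""Background sampling, corrected density, KDE, tail mass and threshold."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import ndtr

from kdepeaks import (
    BackgroundModel,
    BinGeometry,
    ChromSizes,
    build_background_model,
    corrected_read_density,
    count_read_starts,
    find_threshold,
    kde_density,
    sample_random_sites,
    tail_probability,
)
from conftest import brute_force_corrected, brute_force_count


def seeded_model(seed, n=50, h=1.0):
    rng = np.random.default_rng(seed)
    return BackgroundModel(samples=rng.normal(0, 2, size=n), h=h)


class TestSampleRandomSites:
    def test_single_valid_center_genome(self, geometry):
        sizes = ChromSizes({"chr1": 3000})
        sites = sample_random_sites(sizes, 10, geometry, seed=0)
        assert sites == [("chr1", 1500)]

    def test_seeded_determinism(self, geometry, small_sizes):
        a = sample_random_sites(small_sizes, 200, geometry, seed=7)
        b = sample_random_sites(small_sizes, 200, geometry, seed=7)
        assert a == b

    def test_background_bins_never_overlap(self, geometry, small_sizes):
        sites = sample_random_sites(small_sizes, 500, geometry, seed=3)
        by_chrom = {}
        for chrom, c in sites:
            by_chrom.setdefault(chrom, []).append(c)
        for centers in by_chrom.values():
            centers.sort()
            assert all(b - a >= geometry.background_size
                       for a, b in zip(centers, centers[1:]))

    def test_bins_fit_inside_chromosomes(self, geometry, small_sizes):
        for chrom, c in sample_random_sites(small_sizes, 500, geometry, seed=5):
            lo, hi = geometry.background_window(c)
            assert 0 <= lo and hi <= small_sizes[chrom]

    def test_discard_matches_brute_force_overlap_oracle(self, geometry):
        """The first-come discard pass retains exactly the sites a
        pairwise overlap check over the raw draw sequence would keep."""
        sizes = ChromSizes({"chr1": 300_000})
        retained = sample_random_sites(sizes, 50, geometry, seed=11)
        # regenerate the raw draws with the same generator calls
        rng = np.random.default_rng(11)
        rng.choice(1, size=50, p=np.array([1.0]))
        u = rng.random(50)
        n_valid = 300_000 - 3000 + 1
        raw = (1500 + np.floor(u * n_valid).astype(int)).tolist()
        expect = []
        for c in raw:
            if all(abs(c - kept) >= geometry.background_size
                   for kept in expect):
                expect.append(c)
        assert [c for _, c in retained] == expect

    def test_short_chromosomes_excluded_not_fatal(self, geometry):
        sizes = ChromSizes({"tiny": 100, "chr1": 50_000})
        sites = sample_random_sites(sizes, 100, geometry, seed=2)
        assert sites and all(chrom == "chr1" for chrom, _ in sites)

    def test_no_hostable_chromosome_is_error(self, geometry):
        with pytest.raises(ValueError, match="host"):
            sample_random_sites(ChromSizes({"tiny": 100}), 10, geometry, 0)

    def test_nonpositive_n_sites_is_error(self, geometry, small_sizes):
        with pytest.raises(ValueError):
            sample_random_sites(small_sizes, 0, geometry, 0)


class TestCountReadStarts:
    @pytest.mark.parametrize(
        "positions,start,end,expected",
        [
            ([100, 150, 400], 0, 300, 2),
            ([300], 0, 300, 0),       # half-open: end excluded
            ([0], 0, 300, 1),         # start included
            ([], 0, 300, 0),
        ],
    )
    def test_half_open_window(self, positions, start, end, expected):
        pos = np.asarray(positions, dtype=np.int64)
        assert count_read_starts(pos, start, end) == expected

    def test_matches_linear_scan_oracle_on_random_windows(self):
        rng = np.random.default_rng(9)
        pos = np.sort(rng.integers(0, 10_000, size=1000))
        for _ in range(50):
            a, b = sorted(rng.integers(0, 10_000, size=2).tolist())
            if a == b:
                b += 1
            assert count_read_starts(pos, a, b) == brute_force_count(
                pos.tolist(), a, b)

    def test_empty_window_is_error(self):
        with pytest.raises(ValueError):
            count_read_starts(np.array([1, 2]), 5, 5)


class TestCorrectedReadDensity:
    def test_worked_example(self, geometry):
        """5 central reads, 10 background reads, 300/3000 bp bins -> 4.0."""
        assert corrected_read_density(5, 10, geometry) == 4.0

    @pytest.mark.parametrize("cc,bc,expected", [(0, 0, 0.0), (3, 30, 0.0)])
    def test_boundary_cases(self, geometry, cc, bc, expected):
        assert corrected_read_density(cc, bc, geometry) == expected

    def test_central_exceeding_background_rejected(self, geometry):
        with pytest.raises(ValueError, match="nest"):
            corrected_read_density(11, 10, geometry)

    def test_linear_in_counts_and_scale_invariant_ratio(self):
        g1 = BinGeometry(300, 3000)
        g2 = BinGeometry(600, 6000)  # same ratio
        for cc, bc in [(2, 7), (5, 10), (0, 4)]:
            assert corrected_read_density(cc, bc, g1) == pytest.approx(
                corrected_read_density(cc, bc, g2))
        # linearity
        assert corrected_read_density(4, 20, g1) == pytest.approx(
            2 * corrected_read_density(2, 10, g1))


class TestBuildBackgroundModel:
    def test_read_free_genome_gives_all_zero_samples(self, geometry):
        sites = [("chr1", 5000), ("chr1", 20_000), ("chr2", 8000)]
        model = build_background_model({}, sites, geometry)
        assert model.n == 3
        assert np.all(model.samples == 0.0)

    def test_site_reproducing_worked_example_counts(self, geometry):
        # 5 starts in the central 300 bp, 5 more elsewhere in the 3000 bp
        center = 1500
        central = [1400, 1450, 1500, 1550, 1600]
        outer = [100, 200, 300, 2800, 2900]
        pos = np.sort(np.array(central + outer))
        model = build_background_model({"chr1": pos}, [("chr1", center),
                                                       ("chr1", 90_000)],
                                       geometry)
        assert model.samples[0] == pytest.approx(4.0)

    def test_each_sample_matches_per_site_oracle(self, geometry):
        rng = np.random.default_rng(21)
        pos = np.sort(rng.integers(0, 500_000, size=5000))
        sizes = ChromSizes({"chr1": 500_000})
        sites = sample_random_sites(sizes, 100, geometry, seed=13)
        model = build_background_model({"chr1": pos}, sites, geometry)
        for (chrom, center), sample in zip(sites, model.samples):
            assert sample == pytest.approx(
                brute_force_corrected(pos.tolist(), center, geometry))

    def test_fewer_than_two_sites_is_error(self, geometry):
        with pytest.raises(ValueError):
            build_background_model({}, [("chr1", 5000)], geometry)
        with pytest.raises(ValueError):
            build_background_model({}, [], geometry)


class TestKdeDensity:
    def test_single_sample_mode_height(self):
        model = BackgroundModel(samples=[0.0], h=1.0)
        assert kde_density(model, 0.0) == pytest.approx(
            1.0 / np.sqrt(2 * np.pi))

    def test_symmetry_of_symmetric_samples(self):
        model = BackgroundModel(samples=[-2.0, 2.0], h=1.0)
        for d in np.linspace(0, 5, 11):
            assert kde_density(model, d) == pytest.approx(
                kde_density(model, -d))

    @pytest.mark.parametrize("n", [1, 2, 50])
    def test_integrates_to_one(self, n):
        model = seeded_model(seed=n, n=n)
        lo = model.samples.min() - 10 * model.h
        hi = model.samples.max() + 10 * model.h
        total, _ = quad(lambda x: kde_density(model, x), lo, hi, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_matches_naive_per_sample_summation(self):
        model = seeded_model(seed=4, n=50)
        xs = np.linspace(-6, 6, 21)
        for x in xs:
            naive = sum(
                np.exp(-0.5 * ((x - xi) / model.h) ** 2)
                / np.sqrt(2 * np.pi)
                for xi in model.samples
            ) / (model.n * model.h)
            assert kde_density(model, x) == pytest.approx(naive, rel=1e-12)


class TestTailProbability:
    def test_single_sample_median(self):
        model = BackgroundModel(samples=[0.0], h=1.0)
        assert tail_probability(model, 0.0) == pytest.approx(0.5)

    def test_symmetric_mixture_median(self):
        model = BackgroundModel(samples=[-1.0, 1.0], h=1.0)
        assert tail_probability(model, 0.0) == pytest.approx(0.5)

    def test_limits_and_monotonicity(self):
        model = seeded_model(seed=8)
        xs = np.linspace(-30, 30, 101)
        p = tail_probability(model, xs)
        assert np.all(np.diff(p) <= 1e-12)
        assert p[0] == pytest.approx(1.0, abs=1e-9)
        assert p[-1] == pytest.approx(0.0, abs=1e-9)
        assert np.all((p >= 0) & (p <= 1))

    def test_matches_quadrature_of_kde(self):
        model = seeded_model(seed=15)
        hi = model.samples.max() + 10 * model.h
        for x in np.linspace(-5, 5, 21):
            expected, _ = quad(lambda t: kde_density(model, t), x, hi,
                               limit=200)
            assert tail_probability(model, x) == pytest.approx(
                expected, abs=1e-6)


class TestFindThreshold:
    def test_single_standard_kernel_matches_inverted_survival(self):
        model = BackgroundModel(samples=[0.0], h=1.0)
        thr = find_threshold(model, p_cutoff=0.001)
        # independently invert the Gaussian survival function numerically
        oracle = brentq(lambda z: (1.0 - ndtr(z)) - 0.001, 0.0, 10.0,
                        xtol=1e-10)
        assert thr == pytest.approx(oracle, abs=1e-4)

    @pytest.mark.parametrize("seed", range(20))
    def test_translation_equivariance_and_cutoff_monotonicity(self, seed):
        model = seeded_model(seed=seed, n=40)
        thr = find_threshold(model, 0.001)
        shifted = BackgroundModel(samples=model.samples + 2.5, h=model.h)
        assert find_threshold(shifted, 0.001) == pytest.approx(
            thr + 2.5, abs=1e-4)
        assert thr > find_threshold(model, 0.01)

    def test_threshold_has_cutoff_tail(self):
        model = seeded_model(seed=30)
        thr = find_threshold(model, 0.001)
        assert tail_probability(model, thr) <= 0.001
        assert tail_probability(model, thr - 1e-3) >= 0.001

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_cutoff_rejected(self, p):
        with pytest.raises(ValueError):
            find_threshold(BackgroundModel(samples=[0.0, 1.0]), p)

    def test_doubling_reads_doubles_samples_and_raises_threshold(
            self, geometry):
        rng = np.random.default_rng(17)
        pos = np.sort(rng.integers(0, 200_000, size=4000))
        sizes = ChromSizes({"chr1": 200_000})
        sites = sample_random_sites(sizes, 60, geometry, seed=19)
        m1 = build_background_model({"chr1": pos}, sites, geometry)
        doubled = np.sort(np.concatenate([pos, pos]))
        m2 = build_background_model({"chr1": doubled}, sites, geometry)
        assert np.allclose(m2.samples, 2 * m1.samples)
        assert find_threshold(m2, 0.001) > find_threshold(m1, 0.001)

    def test_model_bit_reproducible_for_fixed_seed(self, geometry):
        rng = np.random.default_rng(23)
        pos = np.sort(rng.integers(0, 200_000, size=3000))
        sizes = ChromSizes({"chr1": 200_000})
        runs = []
        for _ in range(2):
            sites = sample_random_sites(sizes, 80, geometry, seed=29)
            model = build_background_model({"chr1": pos}, sites, geometry)
            runs.append((model.samples.tobytes(),
                         find_threshold(model, 0.001)))
        assert runs[0] == runs[1]
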