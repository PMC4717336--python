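"""Subsampling engine, band/CLT/quartile summaries, Michaelis-Menten fit."""

import numpy as np
import pytest
from scipy import stats

from barcodesim import resampling as rs
from barcodesim._rng import derive_rng
from barcodesim.distances import DistanceMatrix
from barcodesim.errors import ConfigurationError, InvalidArgumentError
from barcodesim.estimators import DiversitySummary, max_pairwise, nucleotide_diversity
from barcodesim.seqsim import Alignment


def random_matrix(n, seed=0, scale=0.03):
    rng = np.random.default_rng(seed)
    tri = np.triu(rng.random((n, n)) * scale, 1)
    return DistanceMatrix(tri + tri.T, [f"s{i}" for i in range(n)])


class TestDrawSubsample:
    def test_full_size_returns_everything(self):
        rng = derive_rng(0)
        idx = rs.draw_subsample(6, 6, rng)
        assert sorted(idx) == list(range(6))

    def test_distinct_and_in_range(self):
        rng = derive_rng(1)
        for _ in range(100):
            idx = rs.draw_subsample(20, 7, rng)
            assert len(np.unique(idx)) == 7
            assert idx.min() >= 0 and idx.max() < 20

    def test_oversized_request_rejected(self):
        with pytest.raises(InvalidArgumentError):
            rs.draw_subsample(5, 6, derive_rng(2))

    def test_inclusion_probability_is_hypergeometric(self):
        """Each index enters a size-2 draw from 5 with probability 2/5."""
        rng = derive_rng(3)
        draws = 50_000
        hits = np.zeros(5)
        for _ in range(draws):
            hits[rs.draw_subsample(5, 2, rng)] += 1
        freq = hits / draws
        se = np.sqrt(0.4 * 0.6 / draws)
        assert np.all(np.abs(freq - 0.4) < 4 * se)


class TestRunSchedule:
    def test_grid_shape_and_determinism(self):
        m = random_matrix(30, seed=4)
        sched = rs.SubsampleSchedule("diversity", (2, 5, 10), 50, seed=5)
        r1 = rs.run_schedule(sched, m=m, dataset_id="d")
        r2 = rs.run_schedule(sched, m=m, dataset_id="d")
        assert r1.values.shape == (3, 50)
        assert np.array_equal(r1.values, r2.values)

    def test_full_size_gives_full_dataset_value(self):
        m = random_matrix(12, seed=6)
        sched = rs.SubsampleSchedule("diversity", (2, 12), 20, seed=7)
        r = rs.run_schedule(sched, m=m)
        assert np.allclose(r.for_size(12), nucleotide_diversity(m))

    def test_haplotypes_require_alignment(self):
        m = random_matrix(10, seed=8)
        sched = rs.SubsampleSchedule("haplotypes", (2, 5), 3, seed=9)
        with pytest.raises(ConfigurationError):
            rs.run_schedule(sched, m=m)

    def test_diversity_requires_matrix(self):
        aln = Alignment.from_strings(["ACGT"] * 5, [f"s{i}" for i in range(5)])
        sched = rs.SubsampleSchedule("diversity", (2, 3), 3, seed=10)
        with pytest.raises(ConfigurationError):
            rs.run_schedule(sched, aln=aln)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """At n = 7 the Monte-Carlo value distribution converges to the
        exhaustive-subset distribution (chi-square on subset frequencies,
        alpha = 0.01)."""
        m = random_matrix(7, seed=11)
        exhaustive = rs.enumerate_exhaustive("diversity", 3, m=m)
        sched = rs.SubsampleSchedule("diversity", (3,), 50_000, seed=12)
        mc = rs.run_schedule(sched, m=m).for_size(3)
        # distances are continuous, so each of the C(7,3)=35 subsets maps to
        # a unique value; compare subset frequencies with uniform expectation
        uniq, counts = np.unique(np.round(mc, 12), return_counts=True)
        assert len(uniq) == len(exhaustive)
        assert np.allclose(np.sort(uniq), np.sort(np.round(exhaustive, 12)))
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 0.01

    def test_tidy_frame_roundtrip(self):
        m = random_matrix(10, seed=13)
        sched = rs.SubsampleSchedule("maxdist", (2, 4), 6, seed=14)
        r = rs.run_schedule(sched, m=m, dataset_id="toy")
        back = rs.ResampleResult.from_frame(r.to_frame())
        assert back.sizes == r.sizes
        assert np.allclose(back.values, r.values)


class TestBandSummary:
    def make_result(self, values_by_size):
        sizes = tuple(values_by_size)
        reps = len(next(iter(values_by_size.values())))
        grid = np.array([values_by_size[s] for s in sizes], dtype=float)
        return rs.ResampleResult("d", "diversity", sizes, reps, grid)

    def test_all_at_beta_is_hundred_percent(self):
        r = self.make_result({5: [0.01] * 4})
        (b,) = rs.band_summary(r, beta=0.01)
        assert b.pct_in_band == 100.0

    def test_half_in_half_out(self):
        r = self.make_result({5: [0.01, 0.012]})
        (b,) = rs.band_summary(r, beta=0.01)
        assert b.pct_in_band == 50.0

    def test_band_is_closed(self):
        r = self.make_result({5: [0.011, 0.0112]})
        (b,) = rs.band_summary(r, beta=0.01, )
        assert b.pct_in_band == 50.0  # |0.011 - 0.01| == 0.001 counts as inside

    def test_requires_diversity_result(self):
        r = rs.ResampleResult("d", "maxdist", (2,), 1, np.array([[0.01]]))
        with pytest.raises(ConfigurationError):
            rs.band_summary(r, beta=0.01)

    def test_replicate_means_track_beta(self, dataset60):
        """Subsample pi is unbiased for the full-dataset beta at every size."""
        norm = dataset60["norm"]
        beta = DiversitySummary.from_matrix(norm).beta
        sched = rs.SubsampleSchedule("diversity", (2, 10, 30), 2000, seed=15)
        r = rs.run_schedule(sched, m=norm)
        for b in rs.band_summary(r, beta):
            vals = r.for_size(b.size)
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(b.mean - beta) < 4 * se


class TestCltDiagnostics:
    def test_constant_values_flagged(self):
        r = rs.ResampleResult("d", "diversity", (5,), 3, np.full((1, 3), 0.01))
        diag = rs.clt_diagnostics(r, beta=0.01)
        assert diag.loc[0, "variance"] == 0.0
        assert diag.loc[0, "skewness"] == 0.0
        assert bool(diag.loc[0, "degenerate"])

    def test_symmetric_values_have_no_skew(self):
        rng = np.random.default_rng(16)
        vals = rng.normal(0.0, 1.0, size=(1, 20_000))
        r = rs.ResampleResult("d", "diversity", (5,), 20_000, vals)
        diag = rs.clt_diagnostics(r, beta=0.0)
        assert abs(diag.loc[0, "skewness"]) < 0.05

    def test_variance_decreases_with_size(self, dataset60):
        norm = dataset60["norm"]
        beta = DiversitySummary.from_matrix(norm).beta
        sched = rs.SubsampleSchedule("diversity", (10, 50), 800, seed=17)
        diag = rs.clt_diagnostics(rs.run_schedule(sched, m=norm), beta)
        assert diag.loc[1, "variance"] < diag.loc[0, "variance"]


class TestQuartileSummary:
    def test_constant_replicates(self):
        r = rs.ResampleResult("d", "haplotypes", (5,), 4, np.full((1, 4), 7))
        row = rs.quartile_summary(r).iloc[0]
        assert row["min"] == row["q1"] == row["median"] == row["q3"] == row["max"] == 7

    def test_even_count_median_is_midpoint(self):
        r = rs.ResampleResult("d", "haplotypes", (5,), 4, np.array([[1, 2, 3, 4]]))
        assert rs.quartile_summary(r).iloc[0]["median"] == 2.5

    def test_matches_percentile_oracle(self):
        rng = np.random.default_rng(18)
        vals = rng.integers(1, 40, size=(1, 101))
        r = rs.ResampleResult("d", "haplotypes", (5,), 101, vals)
        row = rs.quartile_summary(r).iloc[0]
        q1, med, q3 = np.percentile(vals[0], [25, 50, 75])
        assert (row["q1"], row["median"], row["q3"]) == (q1, med, q3)

    def test_haplotype_medians_nondecreasing(self, dataset60):
        aln = dataset60["aln"]
        sched = rs.SubsampleSchedule("haplotypes", (2, 10, 20, 40, 60), 200, seed=19)
        quart = rs.quartile_summary(rs.run_schedule(sched, aln=aln))
        med = quart["median"].to_numpy()
        assert np.all(np.diff(med) >= 0)


class TestMaxCapture:
    def test_probability_of_capturing_full_max_is_monotone(self, dataset60):
        norm = dataset60["norm"]
        full_max = max_pairwise(norm)
        sched = rs.SubsampleSchedule("maxdist", (2, 10, 30, 60), 1000, seed=20)
        r = rs.run_schedule(sched, m=norm)
        probs = [np.mean(r.for_size(s) >= full_max - 1e-12) for s in r.sizes]
        assert np.all(np.diff(probs) >= 0)
        assert probs[-1] == 1.0  # size n always contains the max pair


class TestMichaelisMenten:
    def test_exact_recovery_from_noise_free_data(self):
        a, b = 2.0, 0.05
        x = np.array([2, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 110, 120, 130, 140, 150], dtype=float)
        y = a * x / (1 + b * x)
        fit = rs.fit_michaelis_menten(x, y)
        assert fit.a == pytest.approx(a, abs=1e-6)
        assert fit.b == pytest.approx(b, abs=1e-6)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-12)
        assert fit.n_points == 16

    def test_residual_variance_denominator(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        y = np.array([0.9, 1.7, 2.8, 4.1])
        fit = rs.fit_michaelis_menten(x, y)
        resid = y - fit.predict(x)
        assert fit.residual_variance == pytest.approx(np.sum(resid**2) / 2)

    def test_horizontal_data_dominated_by_asymptote(self):
        x = np.linspace(5, 150, 16)
        y = np.full(16, 12.0)
        fit = rs.fit_michaelis_menten(x, y)
        assert fit.asymptote == pytest.approx(12.0, rel=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidArgumentError):
            rs.fit_michaelis_menten([1, 2], [1, 2])

    def test_slope_examples(self):
        fit = rs.MMFit(a=2.0, b=0.05, residual_variance=0.0, n_points=16)
        assert rs.mm_slope(fit, 0.0) == pytest.approx(2.0)
        assert rs.mm_slope(fit, 20.0) == pytest.approx(0.5)

    def test_slope_matches_finite_difference(self):
        fit = rs.MMFit(a=3.7, b=0.021, residual_variance=0.0, n_points=16)
        for x in (0.5, 7.0, 33.0, 120.0):
            h = 1e-5
            fd = (fit.predict(x + h) - fit.predict(x - h)) / (2 * h)
            assert rs.mm_slope(fit, x) == pytest.approx(fd, abs=1e-8)

    def test_slope_nonnegative_and_decreasing(self):
        fit = rs.MMFit(a=1.5, b=0.08, residual_variance=0.0, n_points=10)
        xs = np.linspace(0, 200, 50)
        slopes = np.array([rs.mm_slope(fit, x) for x in xs])
        assert np.all(slopes >= 0)
        assert np.all(np.diff(slopes) < 0)
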