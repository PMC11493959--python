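"""GC correction, profiles, arm z-scores, PA-score, and the length mixture."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from delfitf.errors import DelfiTFError, PanelError, SampleQCError
from delfitf.features import (
    ArmStats,
    arm_zscores,
    build_healthy_panel,
    fit_base_components,
    gc_correct,
    pa_score,
    profile_correlation,
    sample_length_weights,
    short_long_profile,
)
from delfitf.fragments import LENGTH_GRID


@pytest.fixture(scope="module")
def gc_vec():
    rng = np.random.default_rng(0)
    return np.clip(0.41 + 0.05 * rng.standard_normal(2000), 0.3, 0.6)


class TestGcCorrect:
    def test_linear_gc_trend_is_flattened(self, gc_vec):
        """A count profile that is exactly linear in GC corrects to its level."""
        counts = 100 + 200 * (gc_vec - gc_vec.mean())
        corrected = gc_correct(counts, gc_vec)
        assert np.allclose(corrected, 100, rtol=0.01)

    def test_gc_independent_counts_unchanged(self, gc_vec):
        rng = np.random.default_rng(1)
        counts = rng.poisson(300, gc_vec.size).astype(float)
        corrected = gc_correct(counts, gc_vec)
        # no systematic shift and near-identity up to smoother wiggle
        assert abs(corrected.mean() - counts.mean()) < 2
        assert np.corrcoef(corrected, counts)[0, 1] > 0.99

    def test_constant_counts_are_identity(self, gc_vec):
        counts = np.full(gc_vec.size, 42.0)
        assert np.allclose(gc_correct(counts, gc_vec), 42.0)

    def test_all_zero_counts_returned_unchanged(self, gc_vec):
        assert (gc_correct(np.zeros(gc_vec.size), gc_vec) == 0).all()

    def test_constant_gc_degenerates_to_mean_shift(self):
        counts = np.array([1.0, 5.0, 9.0])
        out = gc_correct(counts, np.full(3, 0.4))
        assert np.allclose(out, counts - counts.mean() + np.median(counts))

    def test_residual_gc_dependence_is_small(self, gc_vec):
        """After correction a loess of corrected-on-GC is flat within 5% of level."""
        rng = np.random.default_rng(2)
        lam = np.maximum(200 + 80 * (gc_vec - gc_vec.mean()) / gc_vec.std(), 1.0)
        counts = rng.poisson(lam)
        corrected = gc_correct(counts.astype(float), gc_vec)
        fit = lowess(corrected, gc_vec, frac=0.75, it=2, return_sorted=False)
        med = np.median(corrected)
        assert np.max(np.abs(fit - med)) < 0.05 * med

    def test_correction_then_profile_is_scale_invariant(self, mini6):
        rng = np.random.default_rng(3)
        short = rng.poisson(40, mini6.n_bins).astype(float)
        long_ = rng.poisson(200, mini6.n_bins).astype(float)
        gc = mini6.gc()
        p1 = short_long_profile(gc_correct(short, gc), gc_correct(long_, gc), mini6)
        p2 = short_long_profile(gc_correct(3 * short, gc), gc_correct(3 * long_, gc), mini6)
        assert np.allclose(p1, p2)


class TestProfile:
    def test_group_ratio_arithmetic(self, mini6):
        short = np.full(mini6.n_bins, 120.0 / 50)
        long_ = np.full(mini6.n_bins, 100.0 / 50)
        ratios = short_long_profile(short, long_, mini6)
        assert np.allclose(ratios, 1.2)

    def test_zero_long_group_flagged_missing(self, mini6):
        short = np.full(mini6.n_bins, 5.0)
        long_ = np.full(mini6.n_bins, 7.0)
        gids = mini6.bins["group5mb"].to_numpy()
        long_[gids == 0] = 0.0
        ratios = short_long_profile(short, long_, mini6)
        assert np.isnan(ratios[0]) and np.isfinite(ratios[1:]).all()

    def test_too_many_missing_groups_rejects_sample(self, mini6):
        short = np.full(mini6.n_bins, 5.0)
        long_ = np.zeros(mini6.n_bins)
        with pytest.raises(SampleQCError):
            short_long_profile(short, long_, mini6)

    def test_self_correlation_is_one(self):
        prof = np.random.default_rng(4).uniform(0.1, 0.4, 504)
        assert profile_correlation(prof, prof) == pytest.approx(1.0)

    def test_reflection_gives_minus_one(self):
        med = np.random.default_rng(5).uniform(0.1, 0.4, 504)
        reflected = -(med - med.mean()) + med.mean()
        assert profile_correlation(reflected, med) == pytest.approx(-1.0)

    def test_correlation_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=(2, 504))
        expected = float(((a - a.mean()) * (b - b.mean())).sum()
                         / np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()))
        assert profile_correlation(a, b) == pytest.approx(expected)
        assert abs(profile_correlation(a, b)) < 0.2  # independent profiles

    def test_zero_variance_profile_warns_nan(self):
        med = np.random.default_rng(7).uniform(0.1, 0.4, 10)
        with pytest.warns(UserWarning, match="zero-variance"):
            assert np.isnan(profile_correlation(np.full(10, 0.3), med))


class TestArmZscores:
    def _panel_like(self, mini6, seed=0):
        """A tiny synthetic panel built directly from Poisson healthy samples."""
        from delfitf.fragments import BinnedCounts, LENGTH_GRID

        rng = np.random.default_rng(seed)
        counts = []
        hist = np.zeros(LENGTH_GRID.size, np.int64)
        hist[117] = 20_000  # all lengths at 167 bp
        for i in range(8):
            counts.append(
                BinnedCounts(f"h{i}", rng.poisson(30, mini6.n_bins),
                             rng.poisson(150, mini6.n_bins), hist, 0)
            )
        return build_healthy_panel(counts, mini6, min_samples=2)

    def test_panel_mean_sample_scores_zero(self, mini6):
        panel = self._panel_like(mini6)
        # construct a sample whose arm fractions equal the panel mean exactly
        arm_of_bin = mini6.bins["arm"].map(
            {a: i for i, a in enumerate(mini6.arms)}
        ).to_numpy()
        bins_per_arm = np.bincount(arm_of_bin)
        per_bin = (panel.arm_mean / bins_per_arm)[arm_of_bin]
        stats = arm_zscores(per_bin * 500, per_bin * 500, mini6, panel)
        # gc_correct is not applied here; fractions are exact by construction
        assert np.allclose(stats.z, 0, atol=1e-9)
        assert stats.top1_abs == pytest.approx(0.0)

    def test_doubled_arm_has_unique_max(self, mini6):
        panel = self._panel_like(mini6)
        arm_of_bin = mini6.bins["arm"].map(
            {a: i for i, a in enumerate(mini6.arms)}
        ).to_numpy()
        bins_per_arm = np.bincount(arm_of_bin)
        per_bin = (panel.arm_mean / bins_per_arm)[arm_of_bin] * 1000
        bumped = per_bin.copy()
        bumped[arm_of_bin == 3] *= 2
        stats = arm_zscores(bumped, bumped, mini6, panel)
        # brute-force recompute of the arm fractions
        f = np.array([2 * bumped[arm_of_bin == i].sum() for i in range(len(mini6.arms))])
        f = f / f.sum()
        expected_z = (f - panel.arm_mean) / panel.arm_sd
        assert np.allclose(stats.z, expected_z)
        assert np.argmax(np.abs(stats.z)) == 3

    def test_top_two_ordering_with_ties_by_label(self):
        stats = ArmStats(arms=["1p", "1q", "2p", "2q"], z=np.array([3.0, -5.0, 0.0, 3.0]))
        assert stats.top1_abs == 5.0
        assert stats.top2_abs == 3.0  # tie between 1p and 2q broken by order

    def test_zero_panel_sd_is_configuration_error(self, mini6):
        panel = self._panel_like(mini6)
        panel.arm_sd = panel.arm_sd.copy()
        with pytest.raises(PanelError):
            panel.arm_sd[0] = 0.0
            panel.__post_init__()


class TestPaScore:
    ARMS_5 = [f"{i}p" for i in range(1, 6)] + [f"{i}q" for i in range(1, 6)]

    def test_all_zero_z_gives_zero(self):
        assert pa_score(ArmStats(self.ARMS_5, np.zeros(10))) == pytest.approx(0.0)

    def test_critical_t_value_reproduces_closed_form(self):
        zc = sps.t.ppf(0.99, 3)  # one-tailed 0.01 critical value, ~4.541
        z = np.zeros(10)
        z[:5] = zc  # one arm on each of the five chromosomes
        assert pa_score(ArmStats(self.ARMS_5, z)) == pytest.approx(-5 * np.log(0.02), abs=1e-9)

    def test_matches_brute_force_on_random_z(self):
        rng = np.random.default_rng(8)
        arms = [f"{c}{a}" for c in range(1, 8) for a in "pq"]
        z = rng.normal(0, 3, len(arms))
        # independent brute-force evaluation of the definition
        per_chrom = {}
        for lab, zv in zip(arms, z):
            c = lab[:-1]
            per_chrom[c] = max(per_chrom.get(c, 0.0), abs(zv))
        top5 = sorted(per_chrom.values(), reverse=True)[:5]
        expected = -sum(np.log(max(2 * sps.t.sf(v, 3), 1e-300)) for v in top5)
        assert pa_score(ArmStats(arms, z)) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=14, max_size=14))
    def test_permutation_invariant_and_monotone(self, zs):
        arms = [f"{c}{a}" for c in range(1, 8) for a in "pq"]
        z = np.array(zs)
        base = pa_score(ArmStats(arms, z))
        perm = np.random.default_rng(0).permutation(len(arms))
        assert pa_score(
            ArmStats([arms[i] for i in perm], z[perm])
        ) == pytest.approx(base, rel=1e-12)
        z2 = z.copy()
        z2[np.argmax(np.abs(z2))] *= 2  # increase a selected |z|
        assert pa_score(ArmStats(arms, z2)) >= base - 1e-12

    def test_fewer_than_five_chromosomes_errors(self):
        with pytest.raises(DelfiTFError, match="chromosomes"):
            pa_score(ArmStats(["1p", "1q", "2p", "2q"], np.ones(4)))


class TestLengthMixture:
    def test_free_parameter_count_is_35(self):
        hist = np.zeros(LENGTH_GRID.size)
        hist[50:230:15] = 2000  # spread mass so 12 components fit
        mix = fit_base_components(hist=hist)
        assert mix.k == 12
        assert mix.n_free_parameters == 35

    def test_recovers_well_separated_components(self):
        rng = np.random.default_rng(42)
        true_means = 60 + 25 * np.arange(12.0)  # 60..335, 25 bp apart
        true_w = np.full(12, 1 / 12)
        comp = rng.choice(12, 100_000, p=true_w)
        lengths = rng.normal(true_means[comp], 5.0)
        mix = fit_base_components(lengths)
        assert np.all(np.abs(mix.means - true_means) < 2.0)
        assert np.all(np.abs(mix.weights - true_w) < 0.02)

    def test_point_mass_dominated_by_one_component(self):
        mix = fit_base_components(np.full(20_000, 167.0))
        j = int(np.argmax(mix.weights))
        assert mix.weights[j] > 0.95
        assert abs(mix.means[j] - 167) < 1.0

    def test_too_few_lengths_rejected(self):
        with pytest.raises(PanelError, match="10,000"):
            fit_base_components(np.full(500, 167.0))

    def test_loglik_competitive_with_sklearn_em(self):
        """Independent EM (sklearn GaussianMixture) reaches no better optimum."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(9)
        lengths = np.concatenate([
            rng.normal(145, 10, 10_000), rng.normal(167, 8, 15_000),
            rng.normal(320, 25, 5_000),
        ])
        mix = fit_base_components(lengths, k=3)
        x = np.rint(lengths)
        x = x[(x >= 50) & (x <= 400)]
        own_ll = np.log(
            (mix.weights[:, None] * sps.norm.pdf(x[None, :], mix.means[:, None],
                                                 mix.sds[:, None])).sum(0)
        ).mean()
        gm = GaussianMixture(3, covariance_type="diag", n_init=3, random_state=0)
        gm.fit(x[:, None])
        assert own_ll > gm.score(x[:, None]) - 0.02

    def test_weight_refit_recovers_single_component(self):
        base_hist = np.zeros(LENGTH_GRID.size)
        base_hist[40:260:18] = 2000
        base = fit_base_components(hist=base_hist)
        rng = np.random.default_rng(10)
        lengths = rng.normal(base.means[2], base.sds[2], 20_000)
        w = sample_length_weights(lengths, base)
        assert w.sum() == pytest.approx(1.0, abs=1e-8)
        assert w[2] > 0.95

    def test_weight_refit_recovers_even_split(self):
        rng = np.random.default_rng(11)
        true_means = 60 + 25 * np.arange(12.0)
        base_lengths = rng.normal(true_means[rng.choice(12, 60_000)], 5.0)
        base = fit_base_components(base_lengths)
        comp = rng.choice([0, 1], 50_000)
        w = sample_length_weights(rng.normal(true_means[comp], 5.0), base)
        assert abs(w[0] - 0.5) < 0.03 and abs(w[1] - 0.5) < 0.03

    def test_empty_and_small_samples(self):
        base_hist = np.zeros(LENGTH_GRID.size)
        base_hist[40:260:18] = 2000
        base = fit_base_components(hist=base_hist)
        with pytest.raises(DelfiTFError, match="zero lengths"):
            sample_length_weights(hist=np.zeros(LENGTH_GRID.size), base=base)
        with pytest.warns(UserWarning, match="unstable"):
            sample_length_weights(np.full(100, 167.0), base)
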