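import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.integrate import quad

from emkmer.kmers import KmerStats, MotifKey, MotifObservations, collect_all_stats
from emkmer.scoring import (
    SD_FLOOR,
    assign_significance,
    compute_llr,
    fit_all_nulls,
    fit_gamma_null,
    score_all,
    scores_from_stats,
)


def oracle_llr(native, wga):
    """Independent term-by-term evaluation of the pooled-spread normal
    log-density ratio, using scipy's logpdf directly."""
    y, z = np.log(native), np.log(wga)
    mu_y, mu_z = y.mean(), z.mean()
    var_y = np.mean((y - mu_y) ** 2)
    var_z = np.mean((z - mu_z) ** 2)
    sd_p = max(
        np.sqrt((len(y) * var_y + len(z) * var_z) / (len(y) + len(z))), SD_FLOOR
    )
    terms = sps.norm.logpdf(y, mu_y, sd_p) - sps.norm.logpdf(y, mu_z, sd_p)
    return terms.sum()


positive_sets = st.lists(
    st.floats(min_value=0.05, max_value=20.0, allow_nan=False), min_size=2, max_size=30
)


class TestComputeLlr:
    def test_identical_sets_zero_and_noise_direction(self):
        x = np.array([1.0, 2.0, 3.0])
        llr, direction = compute_llr(x, x)
        assert llr == 0.0
        assert direction == "wga_higher"

    def test_against_term_by_term_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n, m = rng.integers(2, 25, size=2)
            nat = np.exp(rng.normal(rng.normal(0, 0.5), 0.4, size=n))
            wga = np.exp(rng.normal(0, 0.4, size=m))
            llr, _ = compute_llr(nat, wga)
            assert np.isclose(llr, max(oracle_llr(nat, wga), 0.0), rtol=1e-9, atol=1e-12)

    @settings(max_examples=80, deadline=None)
    @given(positive_sets, positive_sets)
    def test_nonnegative(self, nat, wga):
        llr, _ = compute_llr(np.array(nat), np.array(wga))
        assert llr >= 0.0

    @settings(max_examples=40, deadline=None)
    @given(positive_sets, positive_sets, st.floats(min_value=0.1, max_value=10))
    def test_scale_equivariance(self, nat, wga, c):
        a, _ = compute_llr(np.array(nat), np.array(wga))
        b, _ = compute_llr(c * np.array(nat), c * np.array(wga))
        assert np.isclose(a, b, rtol=1e-7, atol=1e-7)

    def test_direction_tracks_mean_shift(self):
        nat = np.exp([1.0, 1.1, 0.9])
        wga = np.exp([0.0, 0.1, -0.1])
        _, direction = compute_llr(nat, wga)
        assert direction == "native_higher"
        _, direction = compute_llr(wga, nat)
        assert direction == "wga_higher"

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            compute_llr(np.array([1.0]), np.array([1.0, 2.0]))


class TestScoreAll:
    def _obs(self, key, nat, wga):
        return MotifObservations(
            key=key,
            native_medians=np.asarray(nat, float),
            wga_medians=np.asarray(wga, float),
            n_occurrences=max(len(nat), len(wga)),
        )

    def test_empty_input(self):
        assert len(score_all([])) == 0

    def test_unscorable_flagging_and_order_invariance(self):
        rng = np.random.default_rng(1)
        obs = [
            self._obs(MotifKey("GATC", 1), rng.lognormal(1, 0.3, 30), rng.lognormal(0, 0.3, 30)),
            self._obs(MotifKey("ACGT", 0), [1.0, 2.0], [1.0, 2.0]),  # below min_obs
        ]
        a = score_all(obs, min_obs=25)
        assert a.loc[0, "scorable"] and not a.loc[1, "scorable"]
        b = score_all(obs[::-1], min_obs=25).iloc[::-1].reset_index(drop=True)
        assert np.isclose(a.loc[0, "llr"], b.loc[0, "llr"])

    def test_batch_path_matches_single_path(self, small_sim):
        """scores_from_stats (sufficient statistics) must agree with
        compute_llr on explicitly collected observation sets."""
        from emkmer.io import aggregate_medians
        from emkmer.kmers import collect_observations

        nat = aggregate_medians(small_sim.native, role="native")
        wga = aggregate_medians(small_sim.wga, role="wga")
        stats = collect_all_stats(small_sim.ref, nat, wga, kmin=4, kmax=4)
        table = scores_from_stats(stats, min_obs=25)
        sub = table[table.scorable].sample(20, random_state=0)
        for _, row in sub.iterrows():
            obs = collect_observations(
                small_sim.ref, nat, wga, MotifKey(row.seq, int(row.offset))
            )
            llr, direction = compute_llr(obs.native_medians, obs.wga_medians)
            assert np.isclose(row.llr, llr, rtol=1e-9)
            assert row.direction == direction


class TestGammaNull:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        draws = rng.gamma(shape=2.0, scale=1.5, size=10_000)
        # realistic direction mix: the noise maximum then bounds the trim
        directions = np.where(rng.random(10_000) < 0.5, "wga_higher", "native_higher")
        null = fit_gamma_null(draws, directions, k=4)
        assert abs(null.shape - 2.0) / 2.0 < 0.10
        assert abs(null.scale - 1.5) / 1.5 < 0.10

    def test_outliers_above_cutoff_do_not_move_fit(self):
        rng = np.random.default_rng(1)
        clean = rng.gamma(2.0, 1.5, size=5000)
        directions = np.where(rng.random(5000) < 0.5, "wga_higher", "native_higher")
        base = fit_gamma_null(clean, directions, k=4)
        spiked = np.concatenate([clean, np.full(5, 1e4)])
        dir2 = np.concatenate([directions, ["native_higher"] * 5])
        refit = fit_gamma_null(spiked, dir2, k=4)
        assert np.isclose(base.shape, refit.shape, rtol=0.02)
        assert np.isclose(base.scale, refit.scale, rtol=0.02)

    def test_all_noise_boundary(self):
        rng = np.random.default_rng(2)
        draws = rng.gamma(1.0, 1.0, size=2000)
        null = fit_gamma_null(draws, np.full(2000, "wga_higher"), k=5)
        # noise max dominates the cutoff: nearly everything is in the fit
        assert null.n_fit >= 1990
        assert null.fit_cutoff_llr == pytest.approx(draws.max())

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_gamma_null(np.ones(5), np.full(5, "native_higher"), k=4)


class TestSignificance:
    def _scores(self, llrs, directions, k=4):
        import pandas as pd

        n = len(llrs)
        return pd.DataFrame(
            {
                "seq": ["AAAA"] * n,
                "offset": range(n),
                "k": k,
                "n_occ": 30,
                "n_native": 30,
                "n_wga": 30,
                "llr": llrs,
                "direction": directions,
                "scorable": True,
                "p_gamma": np.nan,
                "gamma_corr": np.nan,
            }
        )

    def test_zero_llr_gives_full_correction_factor(self):
        from emkmer.scoring import GammaNull

        scores = self._scores([0.0], ["native_higher"])
        out = assign_significance(scores, {4: GammaNull(4, 2.0, 1.0, 100, 5.0)})
        assert out.loc[0, "p_gamma"] == 1.0
        assert out.loc[0, "gamma_corr"] == 4 * 4**4

    def test_survival_against_quadrature(self):
        from emkmer.scoring import GammaNull

        null = GammaNull(4, 2.0, 1.0, 100, 5.0)
        scores = self._scores([4.0], ["native_higher"])
        out = assign_significance(scores, {4: null})
        expected, _ = quad(lambda x: sps.gamma.pdf(x, 2.0, scale=1.0), 4.0, np.inf)
        assert np.isclose(out.loc[0, "p_gamma"], expected, rtol=1e-8)
        assert np.isclose(out.loc[0, "gamma_corr"], expected * 1024, rtol=1e-8)

    def test_noise_direction_forced_to_one(self):
        from emkmer.scoring import GammaNull

        scores = self._scores([50.0], ["wga_higher"])
        out = assign_significance(scores, {4: GammaNull(4, 2.0, 1.0, 100, 5.0)})
        assert out.loc[0, "p_gamma"] == 1.0

    def test_correction_monotone_in_k(self):
        from emkmer.scoring import GammaNull

        nulls = {k: GammaNull(k, 2.0, 1.0, 100, 5.0) for k in (4, 5)}
        s4 = assign_significance(self._scores([3.0], ["native_higher"], k=4), nulls)
        s5 = assign_significance(self._scores([3.0], ["native_higher"], k=5), nulls)
        assert s5.loc[0, "gamma_corr"] > s4.loc[0, "gamma_corr"]
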