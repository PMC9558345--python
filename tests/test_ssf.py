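import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_fixes
from pulsetrack import ssf
from pulsetrack.rasters import RasterStack


class TestDecomposeSteps:
    def test_straight_line_lengths_and_zero_turn(self):
        fixes = make_fixes([(0, 0), (1000, 0), (2000, 0)])
        steps = ssf.decompose_steps(fixes)
        np.testing.assert_allclose(steps["length"], 1000.0)
        assert steps["turn"].iloc[1] == pytest.approx(0.0)

    def test_left_turn_is_positive_half_pi(self):
        fixes = make_fixes([(0, 0), (1000, 0), (1000, 1000)])
        steps = ssf.decompose_steps(fixes)
        assert steps["turn"].iloc[1] == pytest.approx(np.pi / 2)

    def test_closed_square_loop_turns_sum_to_2pi(self):
        fixes = make_fixes([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0), (1, 0)])
        steps = ssf.decompose_steps(fixes)
        turns = steps["turn"].dropna().to_numpy()
        assert np.all(np.sign(turns) == np.sign(turns[0]))
        assert np.abs(turns[:4]).sum() == pytest.approx(2 * np.pi)

    def test_zero_length_step_invalidates_next_turn(self):
        fixes = make_fixes([(0, 0), (10, 0), (10, 0), (20, 0)])
        steps = ssf.decompose_steps(fixes)
        assert not steps["valid"].iloc[1]  # the zero-length step itself
        assert not steps["valid"].iloc[2]  # turn after it is undefined


class TestFitStepKernels:
    def test_gamma_recovery_at_1e4_steps(self):
        rng = np.random.default_rng(5)
        steps = pd.DataFrame(
            {
                "length": rng.gamma(2.0, 300.0, 10_000),
                "turn": rng.vonmises(0.0, 1.0, 10_000),
                "valid": True,
            }
        )
        k = ssf.fit_step_kernels(steps)
        assert 1.9 <= k.gamma_shape <= 2.1
        assert 285 <= k.gamma_scale <= 315

    def test_symmetric_turns_give_mu_near_zero(self):
        rng = np.random.default_rng(6)
        steps = pd.DataFrame(
            {
                "length": rng.gamma(2.0, 300.0, 5000),
                "turn": rng.vonmises(0.0, 2.0, 5000),
                "valid": True,
            }
        )
        k = ssf.fit_step_kernels(steps)
        assert abs(k.vonmises_mu) < 0.1

    def test_uniform_turns_give_tiny_kappa(self):
        rng = np.random.default_rng(7)
        steps = pd.DataFrame(
            {
                "length": rng.gamma(2.0, 300.0, 10_000),
                "turn": rng.uniform(-np.pi, np.pi, 10_000),
                "valid": True,
            }
        )
        k = ssf.fit_step_kernels(steps)
        assert k.vonmises_kappa < 0.05

    def test_identical_lengths_rejected_with_advice(self):
        steps = pd.DataFrame(
            {"length": np.full(100, 250.0), "turn": np.zeros(100), "valid": True}
        )
        with pytest.raises(ValueError, match="jitter"):
            ssf.fit_step_kernels(steps)


class TestGenerateRandomSteps:
    def base_steps(self):
        fixes = make_fixes([(0, 0), (1000, 0), (2000, 0), (3000, 0), (4000, 0)])
        return ssf.decompose_steps(fixes)

    def test_high_kappa_candidates_nearly_collinear(self):
        steps = self.base_steps()
        kernels = ssf.StepKernels(2.0, 300.0, 0.0, 500.0)
        rand = ssf.generate_random_steps(steps, kernels, K=50, seed=1)
        # previous bearing is due east; with kappa=500 turns are tiny
        assert np.abs(rand["turn"]).max() < 0.2

    def test_fixed_seed_identical(self):
        steps = self.base_steps()
        kernels = ssf.StepKernels(2.0, 300.0, 0.0, 1.0)
        a = ssf.generate_random_steps(steps, kernels, K=20, seed=3)
        b = ssf.generate_random_steps(steps, kernels, K=20, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_distances_pass_ks_against_generating_gamma(self):
        fixes = make_fixes(np.column_stack([np.arange(600) * 500.0, np.zeros(600)]))
        steps = ssf.decompose_steps(fixes)
        kernels = ssf.StepKernels(2.0, 300.0, 0.0, 1.0)
        rand = ssf.generate_random_steps(steps, kernels, K=20, seed=9)
        assert len(rand) >= 10_000
        d = stats.kstest(rand["length"], stats.gamma(a=2.0, scale=300.0).cdf)
        assert d.pvalue > 0.01


def stationary_prey(x=1000.0, y=1000.0, event="2021-05-10"):
    t = pd.date_range("2021-05-01", periods=3000, freq="30min", tz="UTC")
    traj = pd.DataFrame(
        {"animal_id": "p1", "species": "elk", "sex": "F", "t": t, "x": x, "y": y}
    )
    return [(traj, pd.Timestamp(event, tz="UTC"))]


class TestEncounterIndicator:
    def test_prey_150m_away_5_days_postpartum(self):
        pset = stationary_prey()
        t = pd.Timestamp("2021-05-15 12:07", tz="UTC")
        assert ssf.encounter_indicator((1150.0, 1000.0), t, pset) == 1

    def test_prey_150m_away_31_days_postpartum(self):
        pset = stationary_prey()
        t = pd.Timestamp("2021-06-10 12:07", tz="UTC")
        assert ssf.encounter_indicator((1150.0, 1000.0), t, pset) == 0

    def test_exactly_200m_is_inclusive(self):
        pset = stationary_prey()
        t = pd.Timestamp("2021-05-15 12:00", tz="UTC")
        assert ssf.encounter_indicator((1200.0, 1000.0), t, pset) == 1
        assert ssf.encounter_indicator((1200.1, 1000.0), t, pset) == 0

    def test_no_contemporaneous_fix_means_no_encounter(self):
        pset = stationary_prey()
        t = pd.Timestamp("2021-08-01 00:00", tz="UTC")  # after prey data end
        assert ssf.encounter_indicator((1000.0, 1000.0), t, pset) == 0


@pytest.fixture(scope="module")
def flat_stack():
    """Constant layers except canopy, on a 3-km grid."""
    rng = np.random.default_rng(12)
    n = 100
    layers = {
        "canopy": rng.uniform(0, 100, (n, n)),
        "veg_class": rng.integers(0, 4, (n, n)).astype(float),
        "ruggedness": rng.uniform(0, 1, (n, n)),
        "dist_road": rng.uniform(0, 2000, (n, n)),
        "dist_water": rng.uniform(0, 2000, (n, n)),
        "shrub": rng.uniform(0, 50, (n, n)),
        "forb": rng.uniform(0, 50, (n, n)),
        "slope": rng.uniform(0, 45, (n, n)),
        "aspect": rng.uniform(0, 360, (n, n)),
        "elevation": rng.uniform(1000, 2000, (n, n)),
    }
    return RasterStack(layers=layers, cell_size=30.0, categorical={"veg_class"})


class TestBuildStrata:
    def make_predator(self, n=60):
        rng = np.random.default_rng(8)
        xy = np.cumsum(rng.normal(0, 80, (n, 2)), axis=0) + 1500.0
        return make_fixes(xy, species="cougar", sex="M", interval_min=180)

    def test_each_stratum_has_21_rows_with_k20(self, flat_stack):
        fixes = self.make_predator()
        design = ssf.build_strata(fixes, flat_stack, K=20, seed=4)
        sizes = design.table.groupby("stratum_id").size()
        assert (sizes == 21).all()
        ones = design.table.groupby("stratum_id")["observed"].sum()
        assert (ones == 1).all()

    def test_stratum_count_bounded_by_fix_count(self, flat_stack):
        fixes = self.make_predator(n=50)
        design = ssf.build_strata(fixes, flat_stack, K=5, seed=4)
        assert design.n_strata <= len(fixes) - 2

    def test_continuous_covariates_standardized_over_design(self, flat_stack):
        fixes = self.make_predator()
        design = ssf.build_strata(fixes, flat_stack, K=10, seed=4)
        for col in ["canopy", "ln_step_length"]:
            v = design.table[col].to_numpy()
            assert abs(v.mean()) < 1e-9
            assert abs(v.std() - 1) < 1e-9
        # cos(turn) deliberately left unscaled
        assert design.table["cos_turn"].abs().max() <= 1.0 + 1e-12

    def test_constant_layer_flagged_as_zero_variance(self):
        n = 100
        layers = {
            "canopy": np.full((n, n), 40.0),
            "veg_class": np.zeros((n, n)),
            "ruggedness": np.full((n, n), 0.2),
            "dist_road": np.full((n, n), 500.0),
            "dist_water": np.full((n, n), 300.0),
        }
        stack = RasterStack(layers=layers, cell_size=30.0, categorical={"veg_class"})
        design = ssf.build_strata(self.make_predator(), stack, K=5, seed=1)
        assert "canopy" in design.standardization.constant_columns


def grid_search_cl(df, covariates, lo=-10.0, hi=10.0, n=200_001):
    """Independent oracle: dense grid maximization of the conditional
    log-likelihood (1-D) or nested grids (2-D)."""
    sid = df["stratum_id"].to_numpy()
    y = df["observed"].to_numpy()
    X = df[covariates].to_numpy(dtype=float)

    def ll(beta):
        eta = X @ beta
        tot = 0.0
        for s in np.unique(sid):
            m = sid == s
            tot += eta[m][y[m] == 1][0] - np.log(np.exp(eta[m]).sum())
        return tot

    if len(covariates) == 1:
        grid = np.linspace(lo, hi, n)
        vals = [ll(np.array([b])) for b in grid[:: max(1, n // 2001)]]
        coarse = grid[:: max(1, n // 2001)][int(np.argmax(vals))]
        fine = np.linspace(coarse - 0.02, coarse + 0.02, 4001)
        vals = [ll(np.array([b])) for b in fine]
        return np.array([fine[int(np.argmax(vals))]])
    best, best_ll = None, -np.inf
    coarse = np.linspace(lo, hi, 81)
    for b1 in coarse:
        for b2 in coarse:
            v = ll(np.array([b1, b2]))
            if v > best_ll:
                best_ll, best = v, (b1, b2)
    for span, m in [(0.3, 61), (0.012, 49)]:
        fine1 = np.linspace(best[0] - span, best[0] + span, m)
        fine2 = np.linspace(best[1] - span, best[1] + span, m)
        for b1 in fine1:
            for b2 in fine2:
                v = ll(np.array([b1, b2]))
                if v > best_ll:
                    best_ll, best = v, (b1, b2)
    return np.array(best)


def toy_design(rows):
    """rows: list of (stratum, observed, cov...) tuples."""
    cols = ["stratum_id", "observed"] + [f"c{i}" for i in range(len(rows[0]) - 2)]
    return pd.DataFrame(rows, columns=cols)


class TestFitConditionalLogistic:
    def test_all_zero_covariates_give_uniform_loglik(self):
        rows = []
        K = 4
        for s in range(6):
            rows.append((s, 1, 0.0))
            rows.extend((s, 0, 0.0) for _ in range(K))
        fit = ssf.fit_conditional_logistic(toy_design(rows), ["c0"])
        assert fit.names == []
        assert fit.loglik == pytest.approx(-6 * np.log(K + 1))

    def test_three_strata_binary_covariate_matches_grid_search(self):
        rows = [
            (0, 1, 1.0),
            (0, 0, 0.0),
            (1, 1, 1.0),
            (1, 0, 0.0),
            (2, 1, 0.0),
            (2, 0, 1.0),
        ]
        df = toy_design(rows)
        fit = ssf.fit_conditional_logistic(df, ["c0"])
        oracle = grid_search_cl(df, ["c0"])
        assert fit.beta[0] == pytest.approx(oracle[0], abs=1e-4)
        # closed form: maximizer of 2*b - 3*log(1+e^b) ... sanity direction
        assert fit.beta[0] > 0

    def test_two_covariates_five_strata_match_grid_search(self):
        rng = np.random.default_rng(13)
        rows = []
        for s in range(5):
            rows.append((s, 1, *rng.normal(0, 1, 2)))
            rows.extend((s, 0, *rng.normal(0, 1, 2)) for _ in range(3))
        df = toy_design(rows)
        fit = ssf.fit_conditional_logistic(df, ["c0", "c1"])
        oracle = grid_search_cl(df, ["c0", "c1"])
        np.testing.assert_allclose(fit.beta, oracle, atol=1e-3)

    def test_stratum_constant_shift_leaves_estimate_unchanged(self):
        rng = np.random.default_rng(14)
        rows = []
        for s in range(20):
            rows.append((s, 1, *rng.normal(0, 1, 2)))
            rows.extend((s, 0, *rng.normal(0, 1, 2)) for _ in range(5))
        df = toy_design(rows)
        fit1 = ssf.fit_conditional_logistic(df, ["c0", "c1"])
        shifted = df.copy()
        shifted.loc[shifted["stratum_id"] == 3, "c0"] += 57.0
        fit2 = ssf.fit_conditional_logistic(shifted, ["c0", "c1"])
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-6)

    def test_matches_statsmodels_conditional_logit(self):
        """Independent implementation cross-check on a moderate design."""
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(15)
        rows = []
        beta_true = np.array([0.8, -0.5])
        for s in range(150):
            xs = rng.normal(0, 1, (6, 2))
            p = np.exp(xs @ beta_true)
            p /= p.sum()
            chosen = rng.choice(6, p=p)
            for j in range(6):
                rows.append((s, int(j == chosen), *xs[j]))
        df = toy_design(rows)
        fit = ssf.fit_conditional_logistic(df, ["c0", "c1"])
        ref = ConditionalLogit(
            df["observed"], df[["c0", "c1"]], groups=df["stratum_id"]
        ).fit(disp=False)
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-5)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-3)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_separation_flagged_not_silent(self):
        rows = []
        for s in range(10):
            rows.append((s, 1, 1.0, *np.random.default_rng(s).normal(0, 1, 1)))
            rows.extend(
                (s, 0, 0.0, *np.random.default_rng(100 + s + k).normal(0, 1, 1))
                for k in range(4)
            )
        df = toy_design(rows)
        fit = ssf.fit_conditional_logistic(df, ["c0", "c1"])
        assert not fit.converged
        assert fit.message != ""

    def test_recovered_encounter_effect_monotone_in_generative_effect(self):
        """Stronger generative attraction to parturient prey yields a larger
        estimated encounter coefficient (rank check over small replicates)."""
        from pulsetrack import scenarios

        means = []
        for level in (0.0, 0.5, 1.0):
            ests = [
                scenarios.ssf_replicate(
                    level, 500 + r, n_predators=6, n_prey=10, duration_d=45.0
                ).coef("enc")
                for r in range(2)
            ]
            means.append(np.mean(ests))
        assert means[0] < means[1] < means[2]

    def test_wald_p_small_for_strong_effect(self):
        rng = np.random.default_rng(16)
        rows = []
        for s in range(300):
            xs = rng.normal(0, 1, 7)
            p = np.exp(1.0 * xs)
            p /= p.sum()
            chosen = rng.choice(7, p=p)
            rows.extend((s, int(j == chosen), xs[j]) for j in range(7))
        fit = ssf.fit_conditional_logistic(toy_design(rows), ["c0"])
        assert fit.p_of("c0") < 1e-6
        assert 0.8 < fit.coef("c0") < 1.2
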