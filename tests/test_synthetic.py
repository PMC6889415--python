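import numpy as np
import pytest
from scipy import stats as sps

from aktredox.assays import OVERLAY_DOSES_PMOL, hill
from aktredox.simulate import Protocol
from aktredox.synthetic import (
    MCAR,
    ConditionStructured,
    MNARLogistic,
    OmicsDesign,
    generate_hill_curve,
    generate_phospho_matrix,
    generate_redox_matrix,
    generate_timecourses,
    insulin_only_pattern,
)


def null_design(seed=1, n=200, noise_sd=0.1):
    return OmicsDesign(
        n_features=n,
        groups=[("control", "2 h"), ("treated", "2 h")],
        noise_sd=noise_sd,
        seed=seed,
    )


class TestRedoxMatrix:
    def test_null_design_group_means_close(self):
        matrix, truth = generate_redox_matrix(null_design())
        log2 = np.log2(matrix.values.to_numpy())
        a, b = log2[:, :4], log2[:, 4:]
        se = np.sqrt(a.var(axis=1, ddof=1) / 4 + b.var(axis=1, ddof=1) / 4)
        frac = np.mean(np.abs(a.mean(axis=1) - b.mean(axis=1)) < 4 * se)
        assert frac >= 0.95
        assert not truth["differential"].any()

    def test_same_seed_identical(self):
        m1, t1 = generate_redox_matrix(null_design(seed=3))
        m2, t2 = generate_redox_matrix(null_design(seed=3))
        assert m1.values.equals(m2.values)
        assert t1.equals(t2)

    def test_different_seed_differs(self):
        m1, _ = generate_redox_matrix(null_design(seed=3))
        m2, _ = generate_redox_matrix(null_design(seed=4))
        assert not m1.values.equals(m2.values)

    def test_concordant_flags_require_same_sign_at_both_times(self):
        n = 10
        eff_2h = np.array([1, 1, -1, 0, 1, 0, 0, 0, 0, 0], dtype=float)
        eff_24h = np.array([1, -1, -1, 1, 0, 0, 0, 0, 0, 0], dtype=float)
        design = OmicsDesign(
            n_features=n,
            groups=[("c", "2 h"), ("c", "24 h"), ("t", "2 h"), ("t", "24 h")],
            feature_effects={("t", "2 h"): eff_2h, ("t", "24 h"): eff_24h},
            noise_sd=0.1,
            seed=0,
        )
        _, truth = generate_redox_matrix(design)
        assert truth["concordant"].tolist() == [True, False, True] + [False] * 7

    def test_invalid_design_names_field(self):
        with pytest.raises(ValueError, match="n_samples_per_group"):
            OmicsDesign(n_features=5, n_samples_per_group=1, groups=[("a", "1 h")], noise_sd=0.1)
        with pytest.raises(ValueError, match="noise_sd"):
            OmicsDesign(n_features=5, groups=[("a", "1 h")], noise_sd=0.0)
        with pytest.raises(ValueError, match="MCAR rate"):
            OmicsDesign(
                n_features=5, groups=[("a", "1 h")], noise_sd=0.1, missing_model=MCAR(1.5)
            )


class TestPhosphoMatrix:
    def phospho_design(self, fraction, seed=0, n=1000, slope=1.0):
        return OmicsDesign(
            n_features=n,
            groups=[("basal", "1 h"), ("insulin", "1 h")],
            noise_sd=0.3,
            missing_model=ConditionStructured(fraction=fraction, midpoint=16.0, slope=slope),
            seed=seed,
        )

    def test_requires_basal_and_insulin_labels(self):
        design = OmicsDesign(
            n_features=10,
            groups=[("a", "1 h"), ("b", "1 h")],
            noise_sd=0.3,
            missing_model=ConditionStructured(0.1),
        )
        with pytest.raises(ValueError, match="basal"):
            generate_phospho_matrix(design)

    def test_fraction_zero_no_insulin_only_features(self):
        matrix, truth = generate_phospho_matrix(self.phospho_design(0.0))
        assert not insulin_only_pattern(matrix).any()
        assert not truth["insulin_only"].any()

    def test_fraction_count_in_binomial_interval(self):
        matrix, truth = generate_phospho_matrix(self.phospho_design(0.1, seed=5))
        count = int(insulin_only_pattern(matrix).sum())
        lo, hi = sps.binom.ppf([0.005, 0.995], 1000, 0.1)
        assert lo <= count <= hi
        # every flagged-true feature matches the pattern
        assert insulin_only_pattern(matrix)[truth["insulin_only"].to_numpy()].all()

    def test_mnar_slope_zero_missingness_independent_of_intensity(self):
        # with slope 0 the logistic is flat: missingness must not track intensity
        hits = 0
        for seed in range(20):
            design = OmicsDesign(
                n_features=300,
                groups=[("basal", "1 h"), ("insulin", "1 h")],
                noise_sd=0.3,
                missing_model=MNARLogistic(midpoint=20.0, slope=0.0),
                seed=seed,
            )
            matrix, _ = generate_phospho_matrix(design)
            log2 = np.log2(matrix.values.to_numpy())
            some_obs = ~np.isnan(log2).all(axis=1)
            log2 = log2[some_obs]
            base = np.nanmean(log2, axis=1)
            miss = np.isnan(log2).mean(axis=1)
            terciles = np.digitize(base, np.quantile(base, [1 / 3, 2 / 3]))
            table = [
                [np.sum(miss[terciles == t] * 8), np.sum((1 - miss[terciles == t]) * 8)]
                for t in range(3)
            ]
            _, p, *_ = sps.chi2_contingency(np.array(table))
            hits += p > 0.01
        assert hits >= 18

    def test_mnar_positive_slope_targets_low_intensities(self):
        design = self.phospho_design(0.0, slope=1.0, seed=2)
        design = OmicsDesign(
            n_features=500,
            groups=design.groups,
            noise_sd=0.3,
            missing_model=MNARLogistic(midpoint=20.0, slope=1.0),
            seed=2,
        )
        matrix, _ = generate_phospho_matrix(design)
        log2 = np.log2(matrix.values.to_numpy())
        some_obs = ~np.isnan(log2).all(axis=1)
        log2 = log2[some_obs]
        base = np.nanmean(log2, axis=1)
        miss = np.isnan(log2).mean(axis=1)
        low, high = base < np.median(base), base >= np.median(base)
        assert miss[low].mean() > miss[high].mean() + 0.1


class TestTimecourses:
    @pytest.fixture(scope="class")
    @staticmethod
    def protocols():
        return [Protocol.insulin_stimulation(insulin=1.0, horizon=30, n_grid=31)]

    def test_zero_noise_equals_simulation(self, network, ref_params, protocols):
        from aktredox.simulate import simulate

        ds = generate_timecourses(
            ref_params, protocols, network, times=np.linspace(0, 30, 7), noise_cv=0.0, seed=0
        )
        tc = simulate(network, ref_params, protocols[0])
        for obs in ("Akt_PM", "pAkt", "pSub"):
            sub = ds.data[ds.data["observable"] == obs]
            expected = np.interp(sub["time"], tc.time, tc.observable(obs))
            np.testing.assert_allclose(sub["mean"], expected, rtol=1e-12)
            assert (sub["sem"] == 0).all()

    def test_sem_tracks_noise_cv(self, network, ref_params, protocols):
        ds = generate_timecourses(
            ref_params,
            protocols,
            network,
            times=np.linspace(1, 30, 40),
            noise_cv=0.1,
            n_replicates=4,
            seed=11,
        )
        sub = ds.data[ds.data["mean"] > 1e-6]
        ratio = (sub["sem"] / sub["mean"].abs()).mean()
        # expected SEM ~ cv/sqrt(4) = 0.05 of the mean, within +-50%
        assert 0.025 < ratio < 0.075

    def test_two_seeds_same_truth_different_noise(self, network, ref_params, protocols):
        kw = dict(times=np.linspace(0, 30, 7), noise_cv=0.2, n_replicates=4)
        d1 = generate_timecourses(ref_params, protocols, network, seed=1, **kw)
        d2 = generate_timecourses(ref_params, protocols, network, seed=2, **kw)
        assert not np.allclose(d1.data["mean"], d2.data["mean"])
        d0a = generate_timecourses(ref_params, protocols, network, seed=1, **kw)
        assert np.array_equal(d1.data["mean"], d0a.data["mean"])


class TestHillCurve:
    def test_midpoint_identity(self):
        dr = generate_hill_curve(10.0, 2.0, top=3.0, bottom=1.0, doses=[10.0])
        assert dr.responses[0] == pytest.approx(2.0, abs=1e-12)

    def test_steep_limit_approaches_step(self):
        dr = generate_hill_curve(10.0, 80.0, top=1.0, bottom=0.0, doses=[5.0, 20.0])
        assert dr.responses[0] == pytest.approx(0.0, abs=1e-12)
        assert dr.responses[1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_formula_at_overlay_doses(self):
        dr = generate_hill_curve(28.84, 2.407, top=1.0, bottom=0.0)
        expected = hill(np.array(OVERLAY_DOSES_PMOL), 28.84, 2.407, 1.0, 0.0)
        np.testing.assert_allclose(dr.responses, expected, atol=1e-12)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            generate_hill_curve(-1.0, 2.0)
        with pytest.raises(ValueError):
            generate_hill_curve(10.0, 2.0, doses=[0.0, 1.0])
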