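import numpy as np
import pandas as pd
import pytest

from aktredox.fitting import FitDataset, GAConfig, ga_fit, multi_start, objective, predict_averaged
from aktredox.simulate import Protocol, simulate
from aktredox.synthetic import generate_timecourses


@pytest.fixture(scope="module")
def noiseless_ds(network, ref_params):
    protos = [
        Protocol.insulin_stimulation(insulin=1.0, horizon=30, n_grid=61),
        Protocol.insulin_stimulation(insulin=1.0, bcnu_af=True, horizon=30, n_grid=61),
    ]
    return generate_timecourses(
        ref_params, protos, network, times=np.linspace(0, 30, 11), noise_cv=0.0, seed=0
    )


class TestObjective:
    def test_self_fit_is_zero(self, noiseless_ds, network, ref_params):
        assert objective(ref_params, noiseless_ds, network) < 1e-6

    def test_two_sem_shift_adds_about_four(self, noiseless_ds, network, ref_params):
        ds = FitDataset(
            data=noiseless_ds.data.copy(),
            protocols=noiseless_ds.protocols,
            scale_mode=dict(noiseless_ds.scale_mode),
        )
        ds.data["sem"] = 0.02  # constant weights
        base = objective(ref_params, ds, network)
        shifted = ds.data.copy()
        shifted.loc[10, "mean"] += 2 * 0.02
        ds2 = FitDataset(data=shifted, protocols=ds.protocols, scale_mode=dict(ds.scale_mode))
        assert objective(ref_params, ds2, network) - base == pytest.approx(4.0, abs=0.05)

    def test_scale_profiling_invariance(self, noiseless_ds, network, ref_params):
        ds = FitDataset(
            data=noiseless_ds.data.copy(),
            protocols=noiseless_ds.protocols,
            scale_mode={"Akt_PM": "scaled", "pAkt": "scaled", "pSub": "scaled"},
        )
        ds.data["sem"] = 0.05
        base = objective(ref_params, ds, network)
        scaled = ds.data.copy()
        scaled.loc[scaled["observable"] == "pAkt", "mean"] *= 7.0
        ds2 = FitDataset(data=scaled, protocols=ds.protocols, scale_mode=dict(ds.scale_mode))
        assert objective(ref_params, ds2, network) == pytest.approx(base, abs=1e-9)

    def test_empty_dataset_rejected(self, network):
        with pytest.raises(ValueError, match="empty"):
            FitDataset(data=pd.DataFrame(columns=["protocol_id", "observable", "time", "mean", "sem", "n"]),
                       protocols={})


class TestGA:
    def small_cfg(self, **kw):
        defaults = dict(population=12, generations=6, polish=False)
        defaults.update(kw)
        return GAConfig(**defaults)

    def test_same_seed_identical_result(self, noiseless_ds, network, ref_params):
        bounds = {"k_on_ox": (1.0, 100.0)}
        a = ga_fit(noiseless_ds, network, bounds, self.small_cfg(), seed=5, base_params=ref_params)
        b = ga_fit(noiseless_ds, network, bounds, self.small_cfg(), seed=5, base_params=ref_params)
        assert a.objective == b.objective
        assert a.params.rates == b.params.rates
        pd.testing.assert_frame_equal(a.trace, b.trace)

    def test_degenerate_bounds_recover_self_fit(self, noiseless_ds, network, ref_params):
        truth = ref_params["k_on_ox"]
        bounds = {"k_on_ox": (truth, truth)}
        res = ga_fit(noiseless_ds, network, bounds, self.small_cfg(), seed=0, base_params=ref_params)
        assert res.objective < 1e-6
        assert res.params["k_on_ox"] == pytest.approx(truth, rel=1e-12)

    def test_trace_non_increasing_with_elitism(self, noiseless_ds, network, ref_params):
        bounds = {"k_on_ox": (1.0, 100.0), "k_on_red": (0.01, 10.0)}
        res = ga_fit(noiseless_ds, network, bounds, self.small_cfg(generations=8), seed=1,
                     base_params=ref_params)
        best = res.trace["best"].to_numpy()
        assert (np.diff(best) <= 1e-12).all()

    def test_result_round_trips_through_file(self, noiseless_ds, network, ref_params, tmp_path):
        bounds = {"k_on_ox": (1.0, 100.0)}
        res = ga_fit(noiseless_ds, network, bounds, self.small_cfg(), seed=2, base_params=ref_params)
        res.to_file(tmp_path / "fit.yaml")
        from aktredox.fitting import FitResult

        back = FitResult.from_file(tmp_path / "fit.yaml")
        assert back.objective == pytest.approx(res.objective, rel=1e-12)
        assert back.params["k_on_ox"] == pytest.approx(res.params["k_on_ox"], rel=1e-12)


class TestMultiStart:
    def test_sorted_and_warns_on_duplicate_seeds(self, noiseless_ds, network, ref_params):
        bounds = {"k_on_ox": (1.0, 100.0)}
        cfg = GAConfig(population=10, generations=3, polish=False)
        res = multi_start(noiseless_ds, network, bounds, cfg, n_starts=3, seeds=[0, 1, 2],
                          base_params=ref_params)
        objs = [r.objective for r in res]
        assert objs == sorted(objs)
        with pytest.warns(UserWarning, match="duplicate seeds"):
            dup = multi_start(noiseless_ds, network, bounds, cfg, n_starts=2, seeds=[3, 3],
                              base_params=ref_params)
        assert dup[0].objective == dup[1].objective


class TestPredictAveraged:
    def make_fits(self, ref_params, deltas):
        from aktredox.fitting import FitResult

        fits = []
        for i, d in enumerate(deltas):
            fits.append(
                FitResult(
                    params=ref_params.with_rates(k_on_ox=ref_params["k_on_ox"] * d),
                    objective=0.0,
                    trace=pd.DataFrame({"generation": [0], "best": [0.0], "mean": [0.0]}),
                    seed=i,
                    bounds={},
                    fitted_names=["k_on_ox"],
                )
            )
        return fits

    def test_identical_sets_zero_sem(self, network, ref_params):
        fits = self.make_fits(ref_params, [1.0, 1.0])
        proto = Protocol.insulin_stimulation(insulin=1.0, horizon=20, n_grid=21)
        df = predict_averaged(fits, network, protocol=proto)
        assert np.allclose(df["sem"], 0.0, atol=1e-12)

    def test_mean_sem_match_hand_computation(self, network, ref_params):
        fits = self.make_fits(ref_params, [0.8, 1.0, 1.25])
        proto = Protocol.insulin_stimulation(insulin=1.0, horizon=20, n_grid=21)
        df = predict_averaged(fits, network, protocol=proto, observables=("Akt_PM",))
        curves = np.array(
            [simulate(network, f.params, proto).observable("Akt_PM") for f in fits]
        )
        np.testing.assert_allclose(df["mean"], curves.mean(axis=0), rtol=1e-9)
        np.testing.assert_allclose(
            df["sem"], curves.std(axis=0, ddof=1) / np.sqrt(3), rtol=1e-9
        )

    def test_single_fit_rejected(self, network, ref_params):
        fits = self.make_fits(ref_params, [1.0])
        with pytest.raises(ValueError, match=">= 2 fits"):
            predict_averaged(fits, network, protocol=Protocol.insulin_stimulation())
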