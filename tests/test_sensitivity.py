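"""Sensitivity sweeps and the two calibration procedures."""

import numpy as np
import pytest

from cellgrammar.scenarios import FixtureGenerator, generate_fixture
from cellgrammar.sensitivity import (
    SweepSpec,
    biphasic_hill,
    calibrate_layers,
    fit_biphasic_hill,
    run_sweep,
)

TRUTH = dict(b_max=0.8, up_half_max=0.3, up_power=2.0,
             down_half_max=1.2, down_power=4.0)


def linear_runner(slope=2.0, intercept=10.0, noise=0.0):
    """Analytic model: QoI linear in the multiplicative factor of 'p'."""

    def run(factors, seed):
        f = factors.get("p", 1.0)
        eps = np.random.default_rng(seed).normal(0, noise) if noise else 0.0
        return {"q": intercept + slope * f + eps, "orphan_qoi": 5.0}

    return run


class TestRunSweep:
    def test_zero_level_gives_zero_indices(self):
        spec = SweepSpec(parameters=["p"], levels=(0.0,), replicates=2)
        res = run_sweep(linear_runner(), spec)
        assert res.index("p") == 0.0

    def test_orphan_parameter_has_zero_index(self):
        spec = SweepSpec(parameters=["unused"], levels=(0.1,), replicates=2)
        res = run_sweep(linear_runner(), spec)
        assert res.index("unused") == pytest.approx(0.0, abs=1e-12)

    def test_linear_model_matches_closed_form_elasticity(self):
        slope, intercept = 2.0, 10.0
        spec = SweepSpec(parameters=["p"], levels=(0.05, 0.1), replicates=2,
                         qois=("q",))
        res = run_sweep(linear_runner(slope, intercept), spec)
        # |q(1+e) - q(1-e)| / (2 e |q(1)|) = slope / (intercept + slope)
        expected = slope / (intercept + slope)
        assert res.index("p") == pytest.approx(expected, rel=0.05)

    def test_paired_seeds_cancel_replicate_noise(self):
        # with shared seeds the +/- runs see identical noise, so a pure-noise
        # model yields exactly zero index
        def noisy(factors, seed):
            return {"q": 100.0 + np.random.default_rng(seed).normal(0, 5)}

        spec = SweepSpec(parameters=["p"], levels=(0.1,), replicates=4)
        res = run_sweep(noisy, spec)
        assert res.index("p") == pytest.approx(0.0, abs=1e-12)

    def test_tidy_records_and_csv(self):
        spec = SweepSpec(parameters=["p"], levels=(0.05,), replicates=2, qois=("q",))
        res = run_sweep(linear_runner(), spec)
        assert len(res.records) == 2
        csv = res.to_csv()
        assert csv.splitlines()[0].startswith("parameter,level,replicate,qoi")

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            SweepSpec(parameters=["p"], replicates=0)
        with pytest.raises(ValueError):
            SweepSpec(parameters=["p"], levels=(1.5,))


class TestBiphasicHillFit:
    def test_noiseless_recovery_within_two_percent(self):
        gen = FixtureGenerator("motility_dataset", seed=3, params=dict(noise=0.0))
        df = generate_fixture(gen)
        fit = fit_biphasic_hill(df["density"], df["speed"])
        assert fit["max_value"] == pytest.approx(TRUTH["b_max"], rel=0.02)
        assert fit["up_half_max"] == pytest.approx(TRUTH["up_half_max"], rel=0.02)
        assert fit["up_power"] == pytest.approx(TRUTH["up_power"], rel=0.02)
        assert fit["down_half_max"] == pytest.approx(TRUTH["down_half_max"], rel=0.02)
        assert fit["down_power"] == pytest.approx(TRUTH["down_power"], rel=0.02)
        assert fit["rss"] < 1e-10
        assert fit["base_value"] == 0.0

    def test_fit_is_biphasic_down_beyond_up(self):
        df = generate_fixture(FixtureGenerator("motility_dataset", seed=1))
        fit = fit_biphasic_hill(df["density"], df["speed"])
        assert fit["down_half_max"] > fit["up_half_max"]

    def test_noisy_recovery_median_bmax_within_ten_percent(self):
        recovered = []
        for seed in range(20):
            gen = FixtureGenerator("motility_dataset", seed=seed,
                                   params=dict(noise=0.05))
            df = generate_fixture(gen)
            fit = fit_biphasic_hill(df["density"], df["speed"], seed=seed)
            recovered.append(fit["max_value"])
        assert np.median(recovered) == pytest.approx(TRUTH["b_max"], rel=0.10)

    def test_monotone_data_pushes_down_term_inactive(self):
        from cellgrammar.responses import hill

        x = np.geomspace(0.05, 4.0, 30)
        y = 0.5 * hill(x, 0.4, 2.0)
        fit = fit_biphasic_hill(x, y)
        # the down half-max runs to its upper bound (10x the data range)
        assert fit["down_half_max"] > 0.9 * 10 * x.max()
        assert fit["rss"] < 1e-10

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_biphasic_hill([1, 2, 3], [0.1, 0.2, 0.1])


class TestCalibrateLayers:
    @staticmethod
    def toy_runner(params, seed):
        # layered-growth surrogate: thickness proportional to a rate parameter
        rng = np.random.default_rng(seed)
        r = params["rate"]
        return {"deep": 50.0 * r / 0.02 + rng.normal(0, 1),
                "superficial": 30.0 * r / 0.02 + rng.normal(0, 1)}

    def test_recovers_generating_grid_point(self):
        ref = {"deep": 50.0, "superficial": 30.0}  # generated at rate 0.02
        best, rss, table = calibrate_layers(self.toy_runner, ref,
                                            {"rate": [0.01, 0.02, 0.04]},
                                            replicates=3)
        assert best == {"rate": 0.02}

    def test_single_point_grid_returned(self):
        ref = {"deep": 10.0}
        best, rss, table = calibrate_layers(self.toy_runner, ref,
                                            {"rate": [0.03]}, replicates=2)
        assert best == {"rate": 0.03}
        assert len(table) == 1

    def test_argmin_definition(self):
        ref = {"deep": 50.0, "superficial": 30.0}
        best, rss, table = calibrate_layers(self.toy_runner, ref,
                                            {"rate": [0.005, 0.01, 0.02, 0.04]},
                                            replicates=2)
        assert rss == min(row["rss"] for row in table)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            calibrate_layers(self.toy_runner, {"deep": 1.0}, {}, replicates=1)


class TestFixtureGenerators:
    def test_spot_table_schema(self):
        df = generate_fixture(FixtureGenerator("spot_table", seed=0,
                                               params=dict(n_spots=500)))
        assert len(df) == 500
        assert set(df.columns) == {"x", "y", "cell_type", "ecm_density"}
        allowed = {"epithelial tumor", "mesenchymal tumor", "fibroblast", "inert"}
        assert set(df["cell_type"]) <= allowed
        assert df["ecm_density"].between(0, 1).all()

    def test_motility_dataset_noiseless_on_curve(self):
        df = generate_fixture(FixtureGenerator("motility_dataset", seed=0,
                                               params=dict(noise=0.0)))
        expected = biphasic_hill(df["density"].to_numpy(), *TRUTH.values())
        assert np.max(np.abs(df["speed"].to_numpy() - expected)) < 1e-12

    def test_cohort_counts_row_sums_exact(self):
        df = generate_fixture(FixtureGenerator("cohort_counts", seed=5,
                                               params=dict(n_patients=8,
                                                           library_size=400)))
        numeric = df.drop(columns=["patient", "pdl1_hi_fraction"])
        assert (numeric.sum(axis=1) == 400).all()
        assert df["pdl1_hi_fraction"].between(0, 1).all()

    def test_fixtures_deterministic_given_seed(self):
        a = generate_fixture(FixtureGenerator("cohort_counts", seed=9))
        b = generate_fixture(FixtureGenerator("cohort_counts", seed=9))
        assert a.equals(b)

    def test_layer_reference_ordering(self):
        ref = generate_fixture(FixtureGenerator("layer_reference", seed=0))
        assert ref["layer 6 neuron"] > ref["layer 4 neuron"]

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            generate_fixture(FixtureGenerator("nonsense"))
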