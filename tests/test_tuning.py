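"""Tuning engine: robust fits, bootstrap aggregation, deviation report."""

import numpy as np
import pandas as pd
import pytest

from lakealign import (
    GilersonCoefficients,
    LinearCalibration,
    OcxCoefficients,
    TuningSettings,
    bootstrap_tune,
    coefficient_deviation,
    fit_linear_scaling,
    fit_once,
    per_lake_tune,
)
from lakealign.tuning import bootstrap_draw_counts, model_for


def _synthetic_fit_data(rng, algorithm, coeffs, n=400, noise_sd=0.0):
    predict, _ = model_for(algorithm, coeffs)
    if algorithm in ("oc2", "oc3"):
        x = rng.uniform(-0.2, 0.8, n)
    elif algorithm == "gilerson":
        x = rng.uniform(0.6, 3.0, n)
    else:
        x = rng.uniform(0.5, 10.0, n)
    theta = np.asarray(coeffs.values, float)
    y = predict(x, theta)
    if noise_sd:
        y = y + rng.normal(0, noise_sd, n)
    return x, y


class TestFitOnce:
    def test_zero_noise_start_at_optimum(self):
        rng = np.random.default_rng(0)
        coeffs = OcxCoefficients(0.24, -1.9, 1.7, -3.0, -0.1)
        x, y = _synthetic_fit_data(rng, "oc2", coeffs)
        fitted = fit_once(x, y, "oc2", coeffs, TuningSettings())
        np.testing.assert_allclose(fitted.values, coeffs.values, rtol=1e-6)

    def test_perturbed_init_recovers_generator(self):
        rng = np.random.default_rng(1)
        truth = OcxCoefficients(0.24, -1.9, 1.7, -3.0, -0.1)
        x, y = _synthetic_fit_data(rng, "oc2", truth, n=2000)
        init = OcxCoefficients(*(v * 1.1 for v in truth.values))
        fitted = fit_once(x, y, "oc2", init, TuningSettings())
        np.testing.assert_allclose(fitted.values, truth.values, rtol=1e-3)

    def test_gilerson_recovery(self):
        rng = np.random.default_rng(2)
        truth = GilersonCoefficients(35.75, -19.30, 1.124)
        x, y = _synthetic_fit_data(rng, "gilerson", truth, n=2000)
        init = GilersonCoefficients(32.0, -17.0, 1.2)
        fitted = fit_once(x, y, "gilerson", init, TuningSettings())
        np.testing.assert_allclose(fitted.values, truth.values, rtol=1e-3)

    def test_underdetermined_raises(self):
        coeffs = OcxCoefficients(0.2, -1.9, 1.7, -3.0, -0.1)
        with pytest.raises(ValueError):
            fit_once(np.array([0.1, 0.2]), np.array([1.0, 2.0]), "oc2",
                     coeffs, TuningSettings())

    def test_linear_loss_matches_lstsq_oracle(self):
        """With linear loss and no outliers the robust solver agrees with a
        closed-form unweighted least-squares solution."""
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 500)
        y = 0.85 * x + 0.3 + rng.normal(0, 0.05, 500)
        settings = TuningSettings(loss="linear")
        fitted = fit_once(x, y, "turbidity_b665", LinearCalibration(1, 0), settings)
        design = np.column_stack([x, np.ones_like(x)])
        oracle, *_ = np.linalg.lstsq(design, y, rcond=None)
        np.testing.assert_allclose(fitted.values, oracle, rtol=1e-8, atol=1e-10)


def _lake_table(rng, sizes, coeffs, noise_sd=0.0, algorithm="oc2"):
    """Filtered-style table with oc2 predictor bands + reference product."""
    frames = []
    predict, _ = model_for(algorithm, coeffs)
    for i, n in enumerate(sizes):
        x = rng.uniform(-0.2, 0.8, n)
        y = predict(x, np.asarray(coeffs.values))
        if noise_sd:
            y = y + rng.normal(0, noise_sd, n)
        frames.append(pd.DataFrame({
            "lake_id": f"lake{i:02d}",
            "timestamp": [f"2017-01-01T00:{j % 60:02d}:{j // 60 % 60:02d}" for j in range(n)],
            "lat": np.round(rng.uniform(-1, 1, n), 6),
            "lon": np.round(rng.uniform(-1, 1, n), 6),
            "rw_msi_b560": 0.01,
            "rw_msi_b490": 0.01 * 10.0 ** x,
            "chla_olci": y,
        }))
    return pd.concat(frames, ignore_index=True)


class TestBootstrap:
    SETTINGS = TuningSettings(n_per_lake=150, min_unique_per_lake=140,
                              n_replicates=25, seed=99)

    def test_uniqueness_threshold_excludes_small_lakes(self):
        rng = np.random.default_rng(4)
        coeffs = OcxCoefficients(0.24, -1.9, 1.7, -3.0, -0.1)
        table = _lake_table(rng, [139, 140, 500], coeffs, noise_sd=0.01)
        result = bootstrap_tune(table, "oc2", coeffs, self.SETTINGS)
        assert result.lakes_excluded == ["lake00"]
        assert result.lakes_included == ["lake01", "lake02"]

    def test_no_eligible_lake_is_hard_error(self):
        rng = np.random.default_rng(5)
        coeffs = OcxCoefficients(0.24, -1.9, 1.7, -3.0, -0.1)
        table = _lake_table(rng, [50, 60], coeffs)
        with pytest.raises(ValueError):
            bootstrap_tune(table, "oc2", coeffs, self.SETTINGS)

    def test_identity_data_keeps_reference_coefficients(self):
        rng = np.random.default_rng(6)
        coeffs = OcxCoefficients(0.24, -1.9, 1.7, -3.0, -0.1)
        table = _lake_table(rng, [300, 300], coeffs, noise_sd=0.0)
        result = bootstrap_tune(table, "oc2", coeffs, self.SETTINGS)
        np.testing.assert_allclose(result.median, coeffs.values, rtol=1e-6)

    def test_bit_reproducible_from_seed(self):
        rng = np.random.default_rng(7)
        coeffs = OcxCoefficients(0.24, -1.9, 1.7, -3.0, -0.1)
        table = _lake_table(rng, [200, 300], coeffs, noise_sd=0.05)
        r1 = bootstrap_tune(table, "oc2", coeffs, self.SETTINGS)
        shuffled = table.sample(frac=1.0, random_state=0)
        r2 = bootstrap_tune(shuffled, "oc2", coeffs, self.SETTINGS)
        np.testing.assert_array_equal(r1.samples, r2.samples)

    def test_equal_draws_per_lake_and_within_lake_uniformity(self):
        """Every replicate draws exactly n_per_lake from each included lake,
        and row selection within a lake is uniform (chi-square over many
        replicates is unremarkable)."""
        rng = np.random.default_rng(8)
        coeffs = OcxCoefficients(0.24, -1.9, 1.7, -3.0, -0.1)
        table = _lake_table(rng, [150, 1500, 15000], coeffs)
        settings = TuningSettings(n_per_lake=150, min_unique_per_lake=140,
                                  n_replicates=200, seed=5)
        counts = bootstrap_draw_counts(table, settings, n_replicates=200)
        assert (counts == 150).all().all()
        assert list(counts.columns) == ["lake00", "lake01", "lake02"]

        # uniformity within the smallest lake, aggregated over replicates
        from scipy import stats

        pool = np.flatnonzero((table["lake_id"] == "lake00").to_numpy())
        tally = np.zeros(len(pool))
        root = np.random.SeedSequence(5)
        for child in root.spawn(200):
            r = np.random.default_rng(child)
            draw = r.choice(pool, size=150, replace=True)
            tally += np.bincount(np.searchsorted(pool, draw), minlength=len(pool))
        chi2 = ((tally - tally.mean()) ** 2 / tally.mean()).sum()
        p = stats.chi2.sf(chi2, df=len(pool) - 1)
        assert p > 1e-4


class TestPerLake:
    def test_single_lake_summary_degenerate(self):
        rng = np.random.default_rng(9)
        coeffs = OcxCoefficients(0.24, -1.9, 1.7, -3.0, -0.1)
        table = _lake_table(rng, [300], coeffs, noise_sd=0.01)
        per_lake, summary = per_lake_tune(table, "oc2", coeffs, TuningSettings())
        assert len(per_lake) == 1
        np.testing.assert_allclose(summary["mean"], summary["median"])
        np.testing.assert_allclose(summary["min"], summary["max"])

    def test_two_lakes_recover_their_own_generators(self):
        rng = np.random.default_rng(10)
        a = GilersonCoefficients(35.75, -19.30, 1.124)
        b = GilersonCoefficients(20.0, -9.0, 1.3)
        frames = []
        for i, coeffs in enumerate([a, b]):
            x = rng.uniform(0.8, 3.0, 600)
            y = (coeffs.a * x + coeffs.b) ** coeffs.c
            frames.append(pd.DataFrame({
                "lake_id": f"lake{i}",
                "timestamp": "2017-06-01T00:00:00",
                "lat": np.round(rng.uniform(-1, 1, 600), 6),
                "lon": np.round(rng.uniform(-1, 1, 600), 6),
                "rw_msi_b665": 0.01,
                "rw_msi_b708": 0.01 * x,
                "chla_olci": y,
            }))
        table = pd.concat(frames, ignore_index=True)
        init = GilersonCoefficients(30.0, -15.0, 1.2)
        per_lake, summary = per_lake_tune(table, "gilerson", init, TuningSettings())
        np.testing.assert_allclose(per_lake.loc["lake0"], a.values, rtol=1e-3)
        np.testing.assert_allclose(per_lake.loc["lake1"], b.values, rtol=1e-3)
        assert (summary["sd"] > 0).all()

    def test_undersized_lake_skipped_with_warning(self):
        rng = np.random.default_rng(11)
        coeffs = OcxCoefficients(0.24, -1.9, 1.7, -3.0, -0.1)
        table = _lake_table(rng, [3, 300], coeffs, noise_sd=0.01)
        with pytest.warns(UserWarning):
            per_lake, _ = per_lake_tune(table, "oc2", coeffs, TuningSettings())
        assert list(per_lake.index) == ["lake01"]


class TestLinearScaling:
    def test_identity(self):
        x = np.linspace(0, 1, 50)
        cal = fit_linear_scaling(x, x)
        assert cal.gain == pytest.approx(1.0, abs=1e-12)
        assert cal.offset == pytest.approx(0.0, abs=1e-12)

    def test_published_scaling_recovered_exactly(self):
        x = np.linspace(-0.5, 1.5, 100)
        y = 1.442 * x - 0.51
        cal = fit_linear_scaling(x, y)
        assert cal.gain == pytest.approx(1.442, abs=1e-10)
        assert cal.offset == pytest.approx(-0.51, abs=1e-10)

    def test_two_points_closed_form(self):
        cal = fit_linear_scaling([0.0, 1.0], [1.0, 3.0])
        assert (cal.gain, cal.offset) == (pytest.approx(2.0), pytest.approx(1.0))

    def test_constant_predictor_raises(self):
        with pytest.raises(ValueError):
            fit_linear_scaling([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDeviation:
    def test_identity(self):
        c = GilersonCoefficients(35.75, -19.30, 1.124)
        assert all(v == 1.0 for v in coefficient_deviation(c, c).values())

    def test_published_multipliers(self, registry):
        init = registry.get("initial", "msi", "oc2")
        tuned = registry.get("tuned", "msi", "oc2")
        dev = coefficient_deviation(init, tuned)
        assert dev["a0"] == pytest.approx(1.60, abs=0.005)
        gons = coefficient_deviation(
            registry.get("initial", "msi", "gons05"),
            registry.get("tuned", "msi", "gons05"),
        )
        assert gons["a_chl_star"] == pytest.approx(1.2, abs=0.05)

    def test_zero_initial_flagged(self):
        a = OcxCoefficients(0.0, 1, 1, 1, 1)
        b = OcxCoefficients(0.5, 2, 2, 2, 2)
        dev = coefficient_deviation(a, b)
        assert np.isnan(dev["a0"])
        assert dev["a1"] == 2.0
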