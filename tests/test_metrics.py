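import numpy as np
import pytest

from crimpute.data import CompetingRisksDataset, SingleEventDataset, TimeGrid
from crimpute.errors import ConfigurationError, GridMismatchError
from crimpute.imputer import naive_censor
from crimpute.metrics import (
    ConcordanceResult,
    aalen_johansen,
    calibration_curves,
    cindex_ipcw,
    km_complement,
    mean_cindex,
)
from crimpute.simulate import SimConfig, simulate, true_type1_cif

from conftest import brute_force_cindex, make_dataset


class TestAalenJohansen:
    def test_hand_computation(self, toy_aj):
        f1 = aalen_johansen(toy_aj, j=1)
        np.testing.assert_allclose(f1.values, [1 / 4, 1 / 4, 1 / 4, 3 / 4])
        f2 = aalen_johansen(toy_aj, j=2)
        np.testing.assert_allclose(f2.values, [0, 1 / 4, 1 / 4, 1 / 4])

    def test_frozen_cmprsk_oracle(self):
        """40-record dataset validated once against cmprsk::cuminc in R."""
        rng = np.random.default_rng(9)
        time = rng.integers(1, 7, 40)
        status = rng.integers(0, 3, 40)
        d = make_dataset(time, status, k=6)
        np.testing.assert_allclose(
            aalen_johansen(d, 1).values,
            [0.05, 0.05, 0.106471, 0.106471, 0.198259, 0.351239],
            atol=5e-7,
        )

    def test_reduces_to_ecdf_without_censoring_or_competing(self):
        time = np.array([1, 1, 2, 3, 3, 3])
        d = make_dataset(time, np.ones(6), k=3)
        f1 = aalen_johansen(d, 1)
        ecdf = [np.mean(time <= t) for t in (1, 2, 3)]
        np.testing.assert_allclose(f1.values, ecdf)

    def test_mass_conservation_no_censoring(self):
        rng = np.random.default_rng(21)
        d = make_dataset(rng.integers(1, 6, 80), rng.integers(1, 3, 80), k=5)
        f1 = aalen_johansen(d, 1).values
        f2 = aalen_johansen(d, 2).values
        # survival: all-cause KM
        surv = 1 - km_complement(naive_censor(
            make_dataset(d.time, (d.status > 0).astype(int), 5)
        )).values
        np.testing.assert_allclose(f1 + f2 + surv, 1.0, atol=1e-12)

    def test_bounded_and_monotone(self, random_cr_datasets):
        for d in random_cr_datasets:
            for j in range(1, d.J + 1):
                v = aalen_johansen(d, j).values
                assert np.all(np.diff(v) >= -1e-12)
                assert np.all((v >= 0) & (v <= 1 + 1e-12))

    def test_invalid_event_type(self, toy_aj):
        with pytest.raises(ConfigurationError):
            aalen_johansen(toy_aj, j=5)


class TestKMComplement:
    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(31)
        time = rng.integers(1, 8, 120)
        event = rng.integers(0, 2, 120)
        se = SingleEventDataset(
            time=time, event=event, covariates=np.zeros((120, 1)), grid=TimeGrid(7)
        )
        ours = km_complement(se).values
        km = lifelines.KaplanMeierFitter().fit(time, event)
        ref = 1 - km.survival_function_at_times(np.arange(1, 8)).to_numpy()
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_equals_aj_when_single_event_type(self, random_cr_datasets):
        for d in random_cr_datasets[:5]:
            single = make_dataset(d.time, (d.status > 0).astype(int), d.grid.k)
            np.testing.assert_allclose(
                km_complement(naive_censor(single)).values,
                aalen_johansen(single, 1).values,
            )


class TestCalibrationCurves:
    def test_zero_gap_for_matching_model(self, toy_aj):
        ref = aalen_johansen(toy_aj, 1)
        cifs = np.tile(ref.values, (5, 1))
        table, gap = calibration_curves(cifs, ref)
        assert gap == 0.0
        np.testing.assert_allclose(table["model_mean"], table["reference"])

    def test_mean_is_linear(self, toy_aj):
        ref = aalen_johansen(toy_aj, 1)
        rng = np.random.default_rng(1)
        cifs = rng.uniform(size=(6, 4))
        t1, _ = calibration_curves(cifs, ref)
        t2, _ = calibration_curves(0.5 * cifs, ref)
        np.testing.assert_allclose(0.5 * t1["model_mean"], t2["model_mean"])

    def test_grid_mismatch(self, toy_aj):
        ref = aalen_johansen(toy_aj, 1)
        with pytest.raises(GridMismatchError):
            calibration_curves(np.zeros((3, 7)), ref)

    def test_plot_export(self, toy_aj, tmp_path):
        from crimpute.metrics import plot_calibration

        ref = aalen_johansen(toy_aj, 1)
        table, _ = calibration_curves(np.tile(ref.values, (2, 1)), ref)
        out = tmp_path / "calib.png"
        plot_calibration(table, str(out))
        assert out.stat().st_size > 0

    def test_true_cif_tracks_aalen_johansen(self):
        """Known-truth average CIF vs the nonparametric estimate."""
        cfg = SimConfig(n=30_000, q=0.4, seed=17)
        d = simulate(cfg)
        cif = true_type1_cif(d.grid, d.covariates, cfg.q)
        ref = aalen_johansen(d, 1)
        table, _ = calibration_curves(cif, ref)
        gap = np.max(
            np.abs(table["model_mean"].to_numpy() - table["reference"].to_numpy())[:-1]
        )
        assert gap < 0.02


class TestCindex:
    def test_three_individual_example(self):
        d = make_dataset([1, 2, 3], [1, 1, 2], k=4)
        res = cindex_ipcw(d, np.array([0.9, 0.5, 0.1]), t=3)
        assert res.values[2] == 1.0
        # reversed marker order: perfectly discordant
        res_r = cindex_ipcw(d, np.array([0.1, 0.5, 0.9]), t=3)
        assert res_r.values[2] == 0.0

    def test_tied_markers_give_half(self):
        d = make_dataset([1, 2, 3], [1, 1, 2], k=4)
        res = cindex_ipcw(d, np.array([0.4, 0.4, 0.4]), t=3)
        assert res.values[2] == 0.5

    def test_no_comparable_pairs_is_nan(self):
        d = make_dataset([2, 3], [0, 0], k=4)
        res = cindex_ipcw(d, np.array([0.1, 0.2]))
        assert np.all(np.isnan(res.values))

    def test_matches_brute_force_without_censoring(self):
        """Exhaustive-pair oracle equality on uncensored data."""
        rng = np.random.default_rng(77)
        for _ in range(30):
            n = int(rng.integers(5, 50))
            k = int(rng.integers(3, 8))
            d = make_dataset(
                rng.integers(1, k + 1, n), rng.integers(1, 3, n), k
            )
            marker = rng.uniform(size=n)
            res = cindex_ipcw(d, marker)
            for t in range(1, k):
                expected = brute_force_cindex(d.time, d.status, marker, t)
                if np.isnan(expected):
                    assert np.isnan(res.values[t - 1])
                else:
                    assert res.values[t - 1] == pytest.approx(expected, abs=1e-12)

    def test_true_cif_marker_beats_noise(self):
        cfg = SimConfig(n=3000, q=0.4, seed=18)
        d = simulate(cfg)
        truth = true_type1_cif(d.grid, d.covariates, cfg.q)
        rng = np.random.default_rng(0)
        noise = rng.uniform(size=d.n)
        c_true = mean_cindex(cindex_ipcw(d, truth))
        c_noise = mean_cindex(cindex_ipcw(d, noise))
        assert c_true > 0.6
        assert abs(c_noise - 0.5) < 0.03


class TestMeanCindex:
    def test_constant_and_partial(self):
        res = ConcordanceResult(
            values=np.array([0.7, np.nan, 0.5]), n_pairs=np.array([3, 0, 2])
        )
        assert mean_cindex(res) == pytest.approx(0.6)
        all_nan = ConcordanceResult(
            values=np.array([np.nan]), n_pairs=np.array([0])
        )
        assert np.isnan(mean_cindex(all_nan))
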