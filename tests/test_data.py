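import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crimpute.data import (
    CompetingRisksDataset,
    SingleEventDataset,
    TimeGrid,
    discretize,
    read_survival_table,
    stratified_split,
    write_survival_table,
)
from crimpute.errors import (
    ConfigurationError,
    DataError,
    DegenerateGridError,
    FormatError,
)
from crimpute.simulate import SimConfig, simulate

from conftest import make_dataset


class TestTimeGrid:
    def test_rejects_single_interval(self):
        with pytest.raises(ConfigurationError):
            TimeGrid(k=1)

    def test_rejects_unsorted_cut_points(self):
        with pytest.raises(ConfigurationError):
            TimeGrid(k=3, cut_points=np.array([2.0, 1.0]))

    def test_equality_includes_cut_points(self):
        a = TimeGrid(3, np.array([1.0, 2.0]))
        assert a == TimeGrid(3, np.array([1.0, 2.0]))
        assert a != TimeGrid(3, np.array([1.0, 2.5]))
        assert a != TimeGrid(3)


class TestReadWrite:
    def test_parse_statuses_and_J(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("time,status,x1\n1,0,0.5\n2,1,-1.0\n3,2,2.0\n")
        d = read_survival_table(f)
        assert d.n == 3 and d.J == 2 and d.p == 1
        assert d.grid.k == 3

    def test_tab_delimited_accepted(self, tmp_path):
        f = tmp_path / "d.tsv"
        f.write_text("time\tstatus\tx1\n1\t0\t0.5\n2\t1\t1.5\n")
        d = read_survival_table(f)
        assert d.n == 2

    def test_all_censored_gives_J_one(self, tmp_path, caplog):
        f = tmp_path / "d.csv"
        f.write_text("time,status,x1\n1,0,0\n2,0,0\n")
        with caplog.at_level("WARNING"):
            d = read_survival_table(f)
        assert d.J == 1

    def test_time_zero_rejected(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("time,status,x1\n0,1,0\n2,0,0\n")
        with pytest.raises(FormatError):
            read_survival_table(f)

    def test_missing_column_is_configuration_error(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("t,status,x1\n1,0,0\n")
        with pytest.raises(ConfigurationError):
            read_survival_table(f)

    def test_na_cell_names_row(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("time,status,x1\n1,0,0.5\n2,1,\n")
        with pytest.raises(DataError, match="row 1"):
            read_survival_table(f)

    def test_round_trip_on_simulator_output(self, tmp_path):
        d = simulate(SimConfig(n=200, seed=4))
        path = tmp_path / "sim.csv"
        write_survival_table(d, path)
        back = read_survival_table(path, k=d.grid.k)
        assert np.array_equal(back.time, d.time)
        assert np.array_equal(back.status, d.status)
        np.testing.assert_allclose(back.covariates, d.covariates)
        # column order stable across writes
        write_survival_table(back, tmp_path / "sim2.csv")
        assert (tmp_path / "sim.csv").read_text() == (
            tmp_path / "sim2.csv"
        ).read_text()

    def test_single_event_dataset_serializes_binary_event(self, tmp_path):
        se = SingleEventDataset(
            time=[1, 2], event=[0, 1], covariates=np.zeros((2, 1)), grid=TimeGrid(3)
        )
        path = tmp_path / "se.csv"
        write_survival_table(se, path)
        back = read_survival_table(path, k=3)
        assert set(back.status) <= {0, 1}


class TestDiscretize:
    def test_uniform_spacing_balanced_occupancy(self):
        idx, grid = discretize(np.arange(1, 21, dtype=float), k=4)
        assert np.array_equal(np.bincount(idx)[1:], [5, 5, 5, 5])
        assert grid.k == 4

    def test_k2_splits_at_median(self):
        raw = np.array([1.0, 2.0, 3.0, 10.0])
        idx, grid = discretize(raw, k=2)
        assert grid.cut_points[0] == np.quantile(raw, 0.5)
        assert np.array_equal(idx, [1, 1, 2, 2])

    def test_exponential_sample_near_equal_occupancy(self):
        rng = np.random.default_rng(0)
        raw = rng.exponential(size=10_000)
        idx, grid = discretize(raw, k=20)
        occ = np.bincount(idx)[1:]
        # independent quantile computation: each interval holds ~n/k
        assert occ.min() >= 480 and occ.max() <= 520
        np.testing.assert_allclose(
            grid.cut_points, np.quantile(raw, np.arange(1, 20) / 20)
        )

    def test_too_few_distinct_values(self):
        with pytest.raises(DegenerateGridError):
            discretize(np.array([1.0, 1.0, 2.0]), k=3)

    def test_value_on_cut_point_goes_up(self):
        raw = np.arange(9, dtype=float)  # median 4.0 is a data value
        idx, grid = discretize(raw, k=2)
        assert grid.cut_points[0] == 4.0
        assert idx[4] == 2

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1e6, allow_nan=False),
            min_size=8,
            max_size=60,
            unique=True,
        ),
        st.integers(min_value=2, max_value=5),
    )
    def test_monotone_in_raw_time(self, raw, k):
        raw = np.sort(np.asarray(raw))
        try:
            idx, _ = discretize(raw, k)
        except DegenerateGridError:
            return
        assert np.all(np.diff(idx) >= 0)


class TestStratifiedSplit:
    def test_standard_protocol_sizes(self):
        d = simulate(SimConfig(n=30_000, seed=5))
        tr, va, te = stratified_split(d, (0.5, 1 / 6, 1 / 3), seed=0)
        assert abs(tr.n - 15_000) <= 2
        assert abs(va.n - 5_000) <= 2
        assert abs(te.n - 10_000) <= 2

    def test_partition_property(self):
        d = simulate(SimConfig(n=999, seed=6))
        tr, va, te = stratified_split(d, (0.5, 0.25, 0.25), seed=1)
        key = lambda ds: {tuple(r) for r in np.column_stack([ds.time, ds.status, ds.covariates[:, 0]])}
        assert tr.n + va.n + te.n == d.n
        # status composition preserved within 1 per category
        for cat in np.unique(d.status):
            total = np.sum(d.status == cat)
            for part, frac in zip((tr, va, te), (0.5, 0.25, 0.25)):
                assert abs(np.sum(part.status == cat) - frac * total) <= 1

    def test_deterministic_given_seed(self):
        d = simulate(SimConfig(n=500, seed=7))
        a = stratified_split(d, (0.5, 0.25, 0.25), seed=3)
        b = stratified_split(d, (0.5, 0.25, 0.25), seed=3)
        for x, y in zip(a, b):
            assert np.array_equal(x.time, y.time)
            assert np.array_equal(x.status, y.status)

    def test_single_category_plain_split(self):
        d = make_dataset(np.arange(1, 11), np.ones(10), k=10)
        tr, va, te = stratified_split(d, (0.5, 0.2, 0.3), seed=0)
        assert tr.n == 5 and va.n == 2 and te.n == 3

    def test_invalid_fractions(self):
        d = make_dataset([1, 2], [0, 1], k=2)
        with pytest.raises(ConfigurationError):
            stratified_split(d, (0.5, 0.5, 0.5), seed=0)
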