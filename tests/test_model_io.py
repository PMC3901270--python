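import logging

import numpy as np
import pytest

from mccims import io as mio
from mccims.model import (
    FeatureMatrix,
    MeasurementGrid,
    MeasurementMetadata,
    Peak,
    PeakList,
    ValidationError,
)

from conftest import make_grid


class TestMeasurementRoundTrip:
    def test_round_trip_bit_exact(self, rng, tmp_path):
        for _ in range(10):
            n_r, n_t = rng.integers(1, 12, size=2)
            grid = make_grid(
                rng.normal(size=(n_r, n_t)) * rng.uniform(1e-3, 1e3),
                polarity="negative",
            )
            path = tmp_path / "m.ims.csv"
            mio.write_measurement(grid, path)
            back = mio.read_measurement(path)
            np.testing.assert_array_equal(back.S, grid.S)
            np.testing.assert_array_equal(back.T, grid.T)
            np.testing.assert_array_equal(back.R, grid.R)
            assert back.metadata.polarity == "negative"
            assert back.metadata.measurement_id == grid.metadata.measurement_id

    def test_dimension_bookkeeping(self, tmp_path):
        grid = make_grid(np.arange(12.0).reshape(3, 4))
        path = tmp_path / "m.ims.csv"
        mio.write_measurement(grid, path)
        back = mio.read_measurement(path)
        assert back.n_r == 3 and back.n_t == 4

    def test_1x1_grid_single_data_cell(self, tmp_path):
        grid = make_grid([[7.5]])
        path = tmp_path / "m.ims.csv"
        mio.write_measurement(grid, path)
        data_rows = [
            l for l in path.read_text().splitlines() if l and not l.startswith("#")
        ]
        assert len(data_rows) == 2  # T axis row + one spectrum row
        assert data_rows[1].split(",")[1] == "7.5"

    def test_non_monotone_retention_rejected(self, tmp_path):
        grid = make_grid(np.ones((3, 2)))
        path = tmp_path / "m.ims.csv"
        mio.write_measurement(grid, path)
        lines = path.read_text().splitlines()
        # swap the retention times of the last two rows
        a, b = lines[-2].split(","), lines[-1].split(",")
        a[0], b[0] = b[0], a[0]
        lines[-2], lines[-1] = ",".join(a), ",".join(b)
        path.write_text("\n".join(lines))
        with pytest.raises(ValidationError, match="strictly increasing"):
            mio.read_measurement(path)

    def test_nan_grid_rejected_on_write(self, tmp_path):
        grid = make_grid([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValidationError, match="non-finite"):
            mio.write_measurement(grid, tmp_path / "m.ims.csv")

    def test_malformed_header_names_line(self, tmp_path):
        path = tmp_path / "m.ims.csv"
        path.write_text("# this has no equals sign\n0.4,0.5\n5.0,1.0,2.0\n")
        with pytest.raises(mio.FormatError, match="key=value"):
            mio.read_measurement(path)

    def test_ragged_row_rejected(self, tmp_path):
        path = tmp_path / "m.ims.csv"
        path.write_text("0.4,0.5\n5.0,1.0\n")
        with pytest.raises(mio.FormatError, match="fields"):
            mio.read_measurement(path)


class TestPeakListIO:
    def test_empty_table(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("measurement_id,peak_id,t,r,s\n")
        assert len(mio.read_peak_list(path)) == 0

    def test_single_row(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("measurement_id,peak_id,t,r,s\nm1,p1,0.46,12.0,30.5\n")
        pl = mio.read_peak_list(path)
        assert len(pl) == 1
        p = pl[0]
        assert (p.i, p.t, p.r, p.s) == ("m1", 0.46, 12.0, 30.5)

    def test_round_trip(self, rng, tmp_path):
        peaks = [
            Peak(i=f"m{k % 3}", r=float(rng.uniform(5, 500)),
                 t=float(rng.uniform(0.4, 1.2)), s=float(rng.uniform(1, 100)))
            for k in range(20)
        ]
        pl = PeakList(detector="lms", peaks=peaks)
        path = tmp_path / "p.csv"
        mio.write_peak_list(pl, path)
        back = mio.read_peak_list(path)
        assert [(p.i, p.t, p.r, p.s) for p in back] == [
            (p.i, p.t, p.r, p.s) for p in peaks
        ]

    def test_duplicate_peak_id_warns_and_keeps_both(self, tmp_path, caplog):
        path = tmp_path / "p.csv"
        path.write_text(
            "measurement_id,peak_id,t,r,s\nm1,p1,0.46,12.0,30.5\nm1,p1,0.50,14.0,20.0\n"
        )
        with caplog.at_level(logging.WARNING):
            pl = mio.read_peak_list(path)
        assert len(pl) == 2
        assert any("duplicate" in rec.message for rec in caplog.records)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("measurement_id,t,r\nm1,0.46,12.0\n")
        with pytest.raises(mio.FormatError, match="missing column"):
            mio.read_peak_list(path)


class TestFeatureMatrixIO:
    def make_fm(self):
        return FeatureMatrix(
            measurement_ids=["m1", "m2"],
            cluster_ids=["c1", "c2", "c3"],
            values=[[1.0, 2.0, 0.0], [3.0, 0.0, 4.0]],
            labels={"m1": "K", "m2": "D"},
        )

    def test_shape_and_label_column(self, tmp_path):
        path = tmp_path / "fm.csv"
        mio.write_feature_matrix(self.make_fm(), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 3  # header + 2 measurements
        header = lines[0].split(",")
        assert header == ["measurement_id", "label", "c1", "c2", "c3"]
        assert lines[1].split(",")[1] == "K"
        assert lines[2].split(",")[1] == "D"

    def test_round_trip(self, tmp_path):
        fm = self.make_fm()
        path = tmp_path / "fm.csv"
        mio.write_feature_matrix(fm, path)
        back = mio.read_feature_matrix(path)
        np.testing.assert_array_equal(back.values, fm.values)
        assert back.labels == fm.labels

    def test_absent_peak_encoded_as_zero(self, tmp_path):
        path = tmp_path / "fm.csv"
        mio.write_feature_matrix(self.make_fm(), path)
        back = mio.read_feature_matrix(path)
        assert back.values[0, 2] == 0.0 and back.values[1, 1] == 0.0

    def test_bad_label_rejected(self):
        fm = self.make_fm()
        fm.labels["m1"] = "X"
        with pytest.raises(ValidationError, match="'K' or 'D'"):
            fm.validate()


class TestGridInvariants:
    def test_shape_mismatch_rejected(self):
        grid = MeasurementGrid(
            T=np.array([0.4, 0.5]),
            R=np.array([5.0, 7.0, 9.0]),
            S=np.ones((2, 2)),
            metadata=MeasurementMetadata("m1"),
        )
        with pytest.raises(ValidationError, match="shape"):
            grid.validate()

    def test_negative_flow_rejected(self):
        meta = MeasurementMetadata("m1", drift_gas_flow=-1.0)
        with pytest.raises(ValidationError, match="non-negative"):
            meta.validate()

    def test_empty_id_rejected(self):
        with pytest.raises(ValidationError, match="non-empty"):
            MeasurementMetadata("").validate()

    def test_peak_invariants(self):
        with pytest.raises(ValidationError):
            Peak(i="m1", r=-1.0, t=0.5, s=1.0).validate()
        with pytest.raises(ValidationError):
            Peak(i="m1", r=1.0, t=0.0, s=1.0).validate()
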