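import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytoagi.fcs_io import (ChannelInfo, EventMatrix, SpilloverMatrix,
                            TransformSpec, PanelMismatchError, FCSParseError,
                            ConfigError, default_panel, read_events,
                            write_events, read_labels, compensate,
                            apply_transform, raw_from_transformed)


def _raw_matrix(n=100, seed=0):
    rng = np.random.default_rng(seed)
    panel = default_panel()
    vals = np.abs(rng.normal(1000, 300, (n, len(panel))))
    vals[:, -1] = np.sort(rng.uniform(0, 300, n))   # time monotone
    return EventMatrix(vals, panel, "raw", "t")


class TestRoundTrip:
    @pytest.mark.parametrize("ext", ["fcs", "csv"])
    def test_write_read_lossless_at_float32(self, tmp_path, ext):
        em = _raw_matrix(1000)
        path = str(tmp_path / f"x.{ext}")
        write_events(em, path)
        back = read_events(path)
        assert back.stage == "raw"
        assert back.n_events == 1000
        assert back.markers == em.markers
        np.testing.assert_array_equal(back.values.astype(np.float32),
                                      em.values.astype(np.float32))

    def test_csv_and_fcs_twins_agree(self, tmp_path):
        em = _raw_matrix(50)
        write_events(em, str(tmp_path / "x.fcs"))
        write_events(em, str(tmp_path / "x.csv"))
        a = read_events(str(tmp_path / "x.fcs"))
        b = read_events(str(tmp_path / "x.csv"))
        np.testing.assert_array_equal(a.values, b.values)

    def test_label_channel_round_trip(self, tmp_path):
        em = _raw_matrix(60)
        labels = ["B cell" if i % 2 else "T cell" for i in range(60)]
        for ext in ("fcs", "csv"):
            path = str(tmp_path / f"lab.{ext}")
            write_events(em, path, labels=labels)
            assert read_labels(path) == labels
            # data unaffected by the extra label channel
            back = read_events(path)
            np.testing.assert_array_equal(back.values.astype(np.float32),
                                          em.values.astype(np.float32))

    def test_empty_matrix_round_trips(self, tmp_path):
        em = EventMatrix(np.empty((0, 22)), default_panel(), "raw", "e")
        path = str(tmp_path / "empty.fcs")
        write_events(em, path)
        assert read_events(path).n_events == 0

    def test_unknown_marker_rejected(self, tmp_path):
        panel = default_panel()
        bad = [ChannelInfo("CD99", "CD99", "fluorescence")] + panel[1:]
        em = EventMatrix(np.ones((5, 22)), bad, "raw")
        path = str(tmp_path / "bad.fcs")
        write_events(em, path)
        with pytest.raises(PanelMismatchError, match="CD99"):
            read_events(path, panel)

    def test_truncated_file_rejected(self, tmp_path):
        em = _raw_matrix(100)
        path = str(tmp_path / "trunc.fcs")
        write_events(em, path)
        data = open(path, "rb").read()
        open(path, "wb").write(data[:len(data) // 2])
        with pytest.raises(FCSParseError):
            read_events(path)


class TestCompensation:
    def test_identity_spillover_is_noop(self):
        em = _raw_matrix(200)
        spill = SpilloverMatrix.identity(
            [c.detector_name for c in em.channels if c.kind == "fluorescence"])
        out = compensate(em, spill)
        assert out.stage == "compensated"
        np.testing.assert_allclose(out.values, em.values)

    def test_two_channel_hand_oracle(self):
        # observed = true @ S with S = [[1, .1], [0, 1]]; event (100, 10)
        # observed in ch2 contains 0.1*100 spill -> true = (100, 0)
        panel = [ChannelInfo("A", "A", "fluorescence"),
                 ChannelInfo("B", "B", "fluorescence")]
        em = EventMatrix(np.array([[100.0, 10.0]]), panel, "raw")
        spill = SpilloverMatrix(np.array([[1.0, 0.1], [0.0, 1.0]]), ["A", "B"])
        out = compensate(em, spill)
        np.testing.assert_allclose(out.values, [[100.0, 0.0]], atol=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_compensation_round_trip_property(self, seed):
        rng = np.random.default_rng(seed)
        k = 4
        s = np.eye(k) + rng.uniform(0, 0.2, (k, k)) * (1 - np.eye(k))
        dets = [f"D{i}" for i in range(k)]
        panel = [ChannelInfo(d, d, "fluorescence") for d in dets]
        em = EventMatrix(np.abs(rng.normal(500, 100, (50, k))), panel, "raw")
        comp = compensate(em, SpilloverMatrix(s, dets))
        back = comp.values @ s
        np.testing.assert_allclose(back, em.values, rtol=1e-6)

    def test_singular_spillover_rejected(self):
        with pytest.raises(ConfigError):
            SpilloverMatrix(np.array([[1.0, 1.0], [1.0, 1.0]]), ["A", "B"])


class TestTransform:
    def test_asinh_closed_form(self):
        em = _raw_matrix(1)
        em.values[0, em.marker_index("CD19")] = 150.0
        comp = em.with_values(em.values, "compensated")
        out = apply_transform(comp, TransformSpec.default(em.channels, 150.0))
        assert out.stage == "transformed"
        assert out.column("CD19")[0] == pytest.approx(np.arcsinh(1.0))
        assert np.arcsinh(1.0) == pytest.approx(0.8814, abs=1e-4)

    def test_zero_maps_to_zero_any_cofactor(self):
        em = _raw_matrix(3)
        em.values[:, 3:21] = 0.0
        comp = em.with_values(em.values, "compensated")
        for cf in (10.0, 150.0, 5000.0):
            out = apply_transform(comp, TransformSpec.default(em.channels, cf))
            assert np.all(out.values[:, 3:21] == 0.0)

    def test_identity_spec_is_noop(self):
        em = _raw_matrix(20).with_values(_raw_matrix(20).values, "compensated")
        out = apply_transform(em, TransformSpec(identity=True))
        np.testing.assert_array_equal(out.values, em.values)

    def test_rank_order_preserved_per_channel(self):
        em = _raw_matrix(500, seed=5)
        comp = em.with_values(em.values, "compensated")
        out = apply_transform(comp, TransformSpec.default(em.channels))
        for j, ch in enumerate(em.channels):
            ranks_in = np.argsort(em.values[:, j], kind="stable")
            ranks_out = np.argsort(out.values[:, j], kind="stable")
            np.testing.assert_array_equal(ranks_in, ranks_out)

    def test_inverse_recovers_raw(self):
        em = _raw_matrix(100, seed=9)
        spec = TransformSpec.default(em.channels)
        tr = apply_transform(em.with_values(em.values, "compensated"), spec)
        back = raw_from_transformed(tr, spec)
        np.testing.assert_allclose(back.values, em.values, rtol=1e-9)

    def test_non_positive_cofactor_rejected(self):
        with pytest.raises(ConfigError):
            TransformSpec({"CD19": -1.0})

    def test_stage_order_enforced(self):
        em = _raw_matrix(10)
        with pytest.raises(ValueError):
            apply_transform(em, TransformSpec.default(em.channels))
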