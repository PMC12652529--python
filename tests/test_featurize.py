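import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nanobrdu as nb
from nanobrdu.featurize import FEATURE_DIM, N_CLASSES


class TestNormalizeReadSignal:
    def test_output_median_is_zero(self):
        rng = np.random.default_rng(0)
        out = nb.normalize_read_signal(rng.normal(80, 12, size=500))
        assert np.median(out) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_input_symmetric_output(self):
        out = nb.normalize_read_signal([1, 2, 3, 4, 5])
        assert np.allclose(out, -out[::-1])

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero spread"):
            nb.normalize_read_signal([2.0, 2.0, 2.0, 2.0])

    def test_zero_mad_falls_back_to_sd(self):
        # majority identical values -> MAD 0, but sd > 0
        out = nb.normalize_read_signal([1.0, 1.0, 1.0, 1.0, 9.0])
        assert np.isfinite(out).all() and out[-1] > 0


class TestEncodeEvent:
    def test_layout_and_onehot_order(self):
        e = nb.EventRecord("r", 0, "C", "C", 0.5, 0.1, 7)
        assert nb.encode_event(e).tolist() == [0.5, 0.1, 7, 0, 1, 0, 0]
        e = nb.EventRecord("r", 0, "T", "T", -1.2, 0.0, 1)
        assert nb.encode_event(e).tolist() == [-1.2, 0.0, 1, 0, 0, 0, 1]

    def test_vector_length_is_seven(self):
        e = nb.EventRecord("r", 0, "G", "G", 0.0, 0.0, 1)
        assert nb.encode_event(e).shape == (FEATURE_DIM,) == (7,)

    def test_basecalled_b_rejected(self):
        e = nb.EventRecord("r", 0, "B", "B", 0.0, 0.0, 1)
        with pytest.raises(ValueError):
            nb.encode_event(e)


class TestExtractWindows:
    def test_window_count_is_length_minus_four(self, pore_model):
        ev = nb.simulate_reads(pore_model, nb.SimConfig(n_reads=1, read_length=300, seed=0))
        assert len(nb.extract_windows(ev, mode="all")) == 296

    def test_short_read_yields_nothing(self, pore_model):
        ev = nb.simulate_reads(pore_model, nb.SimConfig(n_reads=1, read_length=5, seed=0))
        with pytest.warns(UserWarning, match="events"):
            ws = nb.extract_windows(ev.head(4), mode="all")
        assert len(ws) == 0

    def test_t_mode_counts_match_direct_scan(self, small_events):
        ws_all = nb.extract_windows(small_events, mode="all")
        ws_t = nb.extract_windows(small_events, mode="t")
        expected = 0
        for _, read in small_events.groupby("read_id"):
            called = read.sort_values("pos")["base_called"].to_numpy()
            expected += int((called[2:-2] == "T").sum())
        assert len(ws_t) == expected
        assert len(ws_t) <= len(ws_all)

    def test_t_mode_is_subset_of_all_mode(self, small_events):
        ws_all = nb.extract_windows(small_events, mode="all")
        ws_t = nb.extract_windows(small_events, mode="t")
        key_all = {(r, c) for r, c in zip(ws_all.read_ids, ws_all.center_pos)}
        key_t = {(r, c) for r, c in zip(ws_t.read_ids, ws_t.center_pos)}
        assert key_t <= key_all
        # and every t-window's center row is one-hot T
        assert (ws_t.X[:, 2, 3:].argmax(axis=1) == 3).all()

    def test_windows_match_bruteforce_slices(self, small_events):
        """Window extraction equals a per-read scan slicing every 5 events."""
        ws = nb.extract_windows(small_events, mode="all")
        read_id = small_events["read_id"].iloc[0]
        read = small_events[small_events["read_id"] == read_id].sort_values("pos")
        rows = [nb.encode_event(r) for r in nb.iter_records(read)]
        mask = ws.read_ids == read_id
        got = ws.X[mask]
        for i in range(len(read) - 4):
            assert np.allclose(got[i], np.stack(rows[i : i + 5]))
        assert list(ws.truth[mask]) == list(read["true_base"].to_numpy()[2:-2])

    def test_non_contiguous_positions_rejected(self, small_events):
        broken = small_events[small_events["pos"] != 10]
        with pytest.raises(ValueError, match="contiguous"):
            nb.extract_windows(broken)

    def test_log_dwell_switch(self, small_events):
        raw = nb.extract_windows(small_events, mode="all")
        logged = nb.extract_windows(small_events, mode="all", log_dwell=True)
        assert np.allclose(np.log1p(raw.X[:, :, 2]), logged.X[:, :, 2])
        assert np.allclose(raw.X[:, :, :2], logged.X[:, :, :2])


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1), st.integers(5, 40))
def test_onehot_validity_property(seed, read_length):
    """Every emitted feature row and label is a valid one-hot."""
    pm = nb.build_pore_model(seed=0, shift_magnitude=1.0)
    ev = nb.simulate_reads(pm, nb.SimConfig(n_reads=2, read_length=read_length,
                                            substitution_rate=0.5, seed=seed))
    ws = nb.extract_windows(ev, mode="all")
    base_block = ws.X[:, :, 3:]
    assert ((base_block == 0) | (base_block == 1)).all()
    assert (base_block.sum(axis=2) == 1).all()
    y = ws.y
    assert (y.sum(axis=1) == 1).all()
    assert ((y == 0) | (y == 1)).all()
    assert (ws.X[:, :, 2] >= 1).all() and (ws.X[:, :, 1] >= 0).all()


class TestFilterAlignments:
    def test_mapq_threshold_inclusive(self):
        recs = [nb.AlignmentRecord("a", 10, 300), nb.AlignmentRecord("b", 20, 300),
                nb.AlignmentRecord("c", 60, 300)]
        out = nb.filter_alignments(recs, min_mapq=20, min_len=0)
        assert [r.read_id for r in out] == ["b", "c"]

    def test_length_threshold_inclusive(self):
        recs = [nb.AlignmentRecord("a", 60, 269), nb.AlignmentRecord("b", 60, 270),
                nb.AlignmentRecord("c", 60, 500)]
        out = nb.filter_alignments(recs, min_mapq=0, min_len=270)
        assert [r.read_id for r in out] == ["b", "c"]

    def test_flag_zero_requirement(self):
        recs = [nb.AlignmentRecord("a", 60, 600, sam_flag=0),
                nb.AlignmentRecord("b", 60, 600, sam_flag=16),
                nb.AlignmentRecord("c", 60, 600, sam_flag=0)]
        out = nb.filter_alignments(recs, min_mapq=0, min_len=0, require_flag_zero=True)
        assert [r.read_id for r in out] == ["a", "c"]

    def test_dataframe_input_and_presets(self):
        df = pd.DataFrame({"read_id": list("abc"), "mapq": [60, 60, 19],
                           "aligned_len": [500, 499, 600], "sam_flag": [0, 0, 0]})
        mq, ln = nb.FILTER_PRESETS["genomic"]
        assert list(nb.filter_alignments(df, mq, ln)["read_id"]) == ["a"]
        assert nb.FILTER_PRESETS["standards"] == (20, 270)

    def test_invalid_mapq_rejected(self):
        with pytest.raises(ValueError):
            nb.AlignmentRecord("a", 61, 100)


class TestSplitDataset:
    def test_exact_800_100_100(self, pore_model):
        ev = nb.simulate_reads(pore_model, nb.SimConfig(n_reads=4, read_length=255, seed=1))
        ws = nb.extract_windows(ev, mode="all")
        ws = ws.subset(slice(0, 1000))
        tr, va, te = nb.split_dataset(ws, nb.SplitSpec(shuffle_seed=3))
        assert (len(tr), len(va), len(te)) == (800, 100, 100)

    def test_floor_arithmetic_n13(self, small_windows):
        tr, va, te = nb.split_dataset(small_windows.subset(slice(0, 13)))
        assert (len(tr), len(va), len(te)) == (10, 1, 2)

    def test_partition_is_exact(self, small_windows):
        tr, va, te = nb.split_dataset(small_windows, nb.SplitSpec(shuffle_seed=5))
        keys = [(r, c) for part in (tr, va, te)
                for r, c in zip(part.read_ids, part.center_pos)]
        assert len(keys) == len(small_windows)
        all_keys = set(zip(small_windows.read_ids, small_windows.center_pos))
        assert set(keys) == all_keys and len(set(keys)) == len(keys)

    def test_class_counts_conserved_across_splits(self, small_windows):
        parts = nb.split_dataset(small_windows, nb.SplitSpec(shuffle_seed=2))
        total = {}
        for part in parts:
            sym, cnt = np.unique(part.truth, return_counts=True)
            for s, c in zip(sym, cnt):
                total[s] = total.get(s, 0) + int(c)
        sym, cnt = np.unique(small_windows.truth, return_counts=True)
        assert total == {s: int(c) for s, c in zip(sym, cnt)}

    def test_same_seed_same_partition(self, small_windows):
        a = nb.split_dataset(small_windows, nb.SplitSpec(shuffle_seed=9))
        b = nb.split_dataset(small_windows, nb.SplitSpec(shuffle_seed=9))
        for x, y in zip(a, b):
            assert np.array_equal(x.center_pos, y.center_pos)
            assert np.array_equal(x.read_ids, y.read_ids)

    def test_too_few_windows_rejected(self, small_windows):
        with pytest.raises(ValueError):
            nb.split_dataset(small_windows.subset(slice(0, 9)))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            nb.SplitSpec(fractions=(0.5, 0.3, 0.1))


def test_window_tsv_round_trip(small_windows, tmp_path):
    p = tmp_path / "windows.tsv"
    sub = small_windows.subset(slice(0, 50))
    nb.write_windows(sub, p)
    back = nb.read_windows(p)
    assert np.allclose(back.X, sub.X)
    assert list(back.truth) == list(sub.truth)
    assert list(back.read_ids) == list(sub.read_ids)
    assert np.array_equal(back.center_pos, sub.center_pos)


def test_window_tsv_blank_labels_round_trip(small_windows, tmp_path):
    sub = small_windows.subset(slice(0, 10))
    sub.truth[:] = "."
    p = tmp_path / "unlabeled.tsv"
    nb.write_windows(sub, p)
    back = nb.read_windows(p)
    assert (back.truth == ".").all()
    assert np.isnan(back.y).all()
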