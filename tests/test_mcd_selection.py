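import numpy as np
import pytest

from ewmcd.distortion import mse
from ewmcd.mcd_selection import (
    MCDItemset,
    extract_positives,
    select_mcd_a,
    select_mcd_b,
)
from ewmcd.stream_core import AdaptedWindow, Instance

from conftest import chunk_from_arrays


def window_of(index, feats_labels_tms):
    """AdaptedWindow from (features, label, time_moment, is_synthetic) rows."""
    return AdaptedWindow(
        index=index,
        instances=tuple(
            Instance(features=f, label=lb, time_moment=tm, is_synthetic=sy)
            for f, lb, tm, sy in feats_labels_tms
        ),
    )


class TestExtractPositives:
    def test_order_and_selection(self, make_chunk):
        chunk = make_chunk(0, np.arange(8).reshape(4, 2), [0, 1, 0, 1])
        pos = extract_positives(chunk)
        assert len(pos) == 2
        np.testing.assert_allclose(pos[0].features, [2, 3])
        np.testing.assert_allclose(pos[1].features, [6, 7])

    def test_all_negative_gives_empty(self, make_chunk):
        chunk = make_chunk(0, np.zeros((3, 2)), [0, 0, 0])
        assert extract_positives(chunk) == ()

    def test_all_positive_gives_all(self, make_chunk):
        chunk = make_chunk(0, np.zeros((5, 2)), [1] * 5)
        assert len(extract_positives(chunk)) == 5


class TestItemsetInvariants:
    def test_rejects_negative_items(self):
        neg = Instance(features=[0.0], label=0, time_moment=0)
        with pytest.raises(ValueError):
            MCDItemset(items=(neg,), bypass_count=0, filtered_count=1)

    def test_counts_must_sum(self):
        pos = Instance(features=[0.0], label=1, time_moment=0)
        with pytest.raises(ValueError):
            MCDItemset(items=(pos,), bypass_count=1, filtered_count=1)


class TestSelectA:
    def test_empty_previous_positives_skips(self, make_chunk):
        prev = AdaptedWindow.from_chunk(make_chunk(0, np.zeros((3, 2)), [0, 0, 0]))
        cur = make_chunk(1, np.ones((3, 2)), [1, 0, 0])
        itemset, centroid, cluster = select_mcd_a(cur, prev)
        assert len(itemset) == 0 and centroid is None and cluster is None

    def test_empty_current_positives_skips(self, make_chunk):
        prev = AdaptedWindow.from_chunk(make_chunk(0, np.ones((3, 2)), [1, 0, 0]))
        cur = make_chunk(1, np.zeros((3, 2)), [0, 0, 0])
        itemset, centroid, cluster = select_mcd_a(cur, prev)
        assert len(itemset) == 0 and centroid is None

    def test_worked_example(self, make_chunk):
        # current positives {(0,0),(2,2)}: centroid (1,1), MSE 2
        # previous positives {(1,1)} (d^2=0, accepted), {(4,4)} (d^2=18, rejected)
        cur = make_chunk(1, np.array([[0.0, 0], [2, 2], [9, 9]]), [1, 1, 0])
        prev = AdaptedWindow.from_chunk(
            chunk_from_arrays(0, np.array([[1.0, 1], [4, 4]]), [1, 1])
        )
        itemset, centroid, cluster = select_mcd_a(cur, prev)
        assert len(itemset) == 1
        np.testing.assert_allclose(itemset.items[0].features, [1, 1])
        np.testing.assert_allclose(centroid, [1, 1])
        assert cluster.mse == pytest.approx(2.0)
        assert itemset.bypass_count == 0 and itemset.filtered_count == 1

    def test_duplicates_of_centroid_all_accepted(self, make_chunk):
        cur = make_chunk(1, np.array([[0.0, 0], [2, 2]]), [1, 1])
        prev = AdaptedWindow.from_chunk(
            chunk_from_arrays(0, np.tile([1.0, 1.0], (4, 1)), [1, 1, 1, 1])
        )
        itemset, _, _ = select_mcd_a(cur, prev)
        assert len(itemset) == 4  # no dedup: each evaluated independently

    def test_synthetic_previous_positives_are_candidates(self, make_chunk):
        cur = make_chunk(1, np.array([[0.0, 0], [2, 2]]), [1, 1])
        prev = window_of(0, [(np.array([1.0, 1.0]), 1, 0, True)])
        itemset, _, _ = select_mcd_a(cur, prev)
        assert len(itemset) == 1 and itemset.items[0].is_synthetic

    def test_index_mismatch_rejected(self, make_chunk):
        prev = AdaptedWindow.from_chunk(make_chunk(0, np.ones((2, 2)), [1, 0]))
        cur = make_chunk(2, np.ones((2, 2)), [1, 0])
        with pytest.raises(ValueError, match="index"):
            select_mcd_a(cur, prev)

    def test_pure_function_of_inputs(self, make_chunk, rng):
        cur = make_chunk(1, rng.standard_normal((20, 3)), rng.integers(0, 2, 20))
        prev = AdaptedWindow.from_chunk(
            chunk_from_arrays(0, rng.standard_normal((20, 3)), rng.integers(0, 2, 20))
        )
        r1 = select_mcd_a(cur, prev)
        r2 = select_mcd_a(cur, prev)
        assert [i.features.tolist() for i in r1[0].items] == [
            i.features.tolist() for i in r2[0].items
        ]


class TestSelectB:
    def test_worked_example_with_bypass_and_filter(self, make_chunk):
        # current positives {(0,0),(2,2)}, last-chunk item {(1,1)} bypasses
        # and joins VC: centroid (1,1), SSE 4, MSE 4/3.  Older item (5,5)
        # has d^2 = 32 > 4/3 -> rejected.
        prev = window_of(
            1,
            [
                (np.array([1.0, 1.0]), 1, 1, False),
                (np.array([5.0, 5.0]), 1, 0, True),
            ],
        )
        cur = make_chunk(2, np.array([[0.0, 0], [2, 2]]), [1, 1])
        itemset, centroid, cluster = select_mcd_b(cur, prev)
        np.testing.assert_allclose(centroid, [1, 1])
        assert cluster.sse == pytest.approx(4.0)
        assert cluster.mse == pytest.approx(4.0 / 3.0)
        assert len(itemset) == 1
        assert itemset.bypass_count == 1 and itemset.filtered_count == 0
        np.testing.assert_allclose(itemset.items[0].features, [1, 1])

    def test_all_last_chunk_items_bypass(self, make_chunk, rng):
        prev_chunk = chunk_from_arrays(
            0, rng.standard_normal((10, 3)) + 50, [1] * 10
        )
        prev = AdaptedWindow.from_chunk(prev_chunk)
        cur = make_chunk(1, rng.standard_normal((10, 3)), [1] * 5 + [0] * 5)
        itemset, _, _ = select_mcd_b(cur, prev)
        assert len(itemset) == 10
        assert itemset.bypass_count == 10 and itemset.filtered_count == 0

    def test_bypass_items_seed_cluster_when_current_has_no_positives(
        self, make_chunk
    ):
        prev = AdaptedWindow.from_chunk(
            chunk_from_arrays(0, np.array([[1.0, 1], [3, 3]]), [1, 1])
        )
        cur = make_chunk(1, np.zeros((3, 2)), [0, 0, 0])
        itemset, centroid, _ = select_mcd_b(cur, prev)
        assert len(itemset) == 2
        np.testing.assert_allclose(centroid, [2, 2])

    def test_no_positives_anywhere_skips(self, make_chunk):
        prev = AdaptedWindow.from_chunk(make_chunk(0, np.zeros((3, 2)), [0] * 3))
        cur = make_chunk(1, np.zeros((3, 2)), [0] * 3)
        itemset, centroid, _ = select_mcd_b(cur, prev)
        assert len(itemset) == 0 and centroid is None

    def test_partition_invariant(self, make_chunk, rng):
        # bypass items all have time_moment == previous.index; filtered
        # items are strictly older
        rows = []
        for k in range(12):
            tm = int(rng.integers(0, 4))
            rows.append(
                (rng.standard_normal(3), 1, tm, tm < 3)
            )
        prev = window_of(3, rows)
        cur = make_chunk(4, rng.standard_normal((30, 3)), [1] * 6 + [0] * 24)
        itemset, _, _ = select_mcd_b(cur, prev)
        for item in itemset.items[: itemset.bypass_count + itemset.filtered_count]:
            assert item.time_moment <= 3
        bypass = [i for i in itemset.items if i.time_moment == 3]
        filtered = [i for i in itemset.items if i.time_moment < 3]
        assert len(bypass) == itemset.bypass_count
        assert len(filtered) == itemset.filtered_count

    def test_relaxation_superset_of_model_a(self, rng):
        # when all previous positives are last-chunk items, B admits all
        # while A filters, so B's itemset contains A's
        for trial in range(20):
            rng_t = np.random.default_rng(trial)
            prev_chunk = chunk_from_arrays(
                0,
                rng_t.standard_normal((8, 4)) * 2,
                [1] * 8,
            )
            prev = AdaptedWindow.from_chunk(prev_chunk)
            cur = chunk_from_arrays(
                1, rng_t.standard_normal((8, 4)), [1] * 4 + [0] * 4
            )
            a_items, _, _ = select_mcd_a(cur, prev)
            b_items, _, _ = select_mcd_b(cur, prev)
            a_set = {id(i) for i in a_items.items}
            b_set = {id(i) for i in b_items.items}
            assert a_set <= b_set
            assert len(b_items) == 8
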