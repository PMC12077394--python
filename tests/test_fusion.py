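"""Overlap weights, weighted statistics, fusion, and the analysis filters."""

import numpy as np
import pandas as pd
import pytest

from sectionfuse.core import BinaryMask, DimensionError
from sectionfuse.fusion import (
    assign_tissue_type,
    export_fused,
    filter_by_coverage,
    fuse,
    overlap_weights,
    read_fused,
    sham_rotate,
    spot_coverage,
    tissue_type_match,
    weighted_stats,
)
from sectionfuse.omics import MeasurementTable, ReferenceMatrix
from sectionfuse.transforms import AffineTransform, TransformChain


def _ref(labels, ids):
    return ReferenceMatrix(np.asarray(labels, dtype=np.int32), ids)


def brute_force_weights(target, source):
    """Independent per-cell accumulation oracle for overlap_weights."""
    counts = {}
    t, s = target.labels, source.labels
    for y in range(t.shape[0]):
        for x in range(t.shape[1]):
            if t[y, x] > 0 and s[y, x] > 0:
                tid = target.id_of(t[y, x])
                sid = source.id_of(s[y, x])
                counts.setdefault(tid, {}).setdefault(sid, 0)
                counts[tid][sid] += 1
    out = {}
    for tid, per in counts.items():
        total = sum(per.values())
        out[tid] = {sid: c / total for sid, c in per.items()}
    return out


class TestOverlapWeights:
    def test_single_source_covers_spot(self):
        t = _ref([[1, 1], [1, 0]], ["s"])
        s = _ref([[1, 1], [1, 1]], ["p"])
        om = overlap_weights(t, s)
        assert om["s"] == [("p", 1.0)]

    def test_300_100_split(self):
        t = np.zeros((20, 20), dtype=np.int32)
        t[:, :] = 1
        s = np.zeros((20, 20), dtype=np.int32)
        s[:15, :] = 1  # 300 cells
        s[15:, :] = 2  # 100 cells
        om = overlap_weights(_ref(t, ["spot"]), _ref(s, ["a", "b"]))
        w = dict(om["spot"])
        assert w["a"] == pytest.approx(300 / 400)
        assert w["b"] == pytest.approx(100 / 400)

    def test_matches_brute_force_on_random_rasters(self, rng):
        t = rng.integers(0, 21, (60, 60)).astype(np.int32)
        s = rng.integers(0, 201, (60, 60)).astype(np.int32)
        tref = _ref(t, [f"T{i}" for i in range(1, 21)])
        sref = _ref(s, [f"S{i}" for i in range(1, 201)])
        om = overlap_weights(tref, sref)
        oracle = brute_force_weights(tref, sref)
        assert set(om.weights) == set(oracle)
        for tid in oracle:
            got = dict(om[tid])
            assert set(got) == set(oracle[tid])
            for sid in oracle[tid]:
                assert got[sid] == pytest.approx(oracle[tid][sid], abs=1e-12)

    def test_weights_sum_to_one(self, rng):
        t = rng.integers(0, 10, (40, 40)).astype(np.int32)
        s = rng.integers(0, 50, (40, 40)).astype(np.int32)
        om = overlap_weights(_ref(t, list("ABCDEFGHI")),
                             _ref(s, [f"S{i}" for i in range(49)]))
        for tid, pairs in om.weights.items():
            assert sum(w for _, w in pairs) == pytest.approx(1.0, abs=1e-9)

    def test_shape_mismatch_is_space_error(self):
        with pytest.raises(DimensionError, match="register"):
            overlap_weights(_ref(np.zeros((4, 4)), []), _ref(np.zeros((5, 5)), []))


def oracle_weighted_stats(values, weights):
    """Two-pass brute-force reference for the weighted summary."""
    mean = sum(w * v for v, w in zip(values, weights))
    var = sum(w * (v - mean) ** 2 for v, w in zip(values, weights))
    order = np.argsort(values, kind="stable")
    cum = 0.0
    median = None
    for i in order:
        cum += weights[i]
        if cum >= 0.5:
            median = values[i]
            break
    return {"min": min(values), "max": max(values), "mean": mean,
            "std": np.sqrt(var), "median": median}


class TestWeightedStats:
    def test_two_value_example(self):
        s = weighted_stats([10.0, 20.0], [0.75, 0.25])
        assert s["mean"] == pytest.approx(12.5)
        assert s["min"] == 10.0
        assert s["max"] == 20.0

    def test_uniform_weights_match_population_stats(self, rng):
        v = rng.normal(0, 3, 41)
        s = weighted_stats(v, np.full(41, 1 / 41))
        assert s["mean"] == pytest.approx(v.mean())
        assert s["std"] == pytest.approx(v.std())
        assert s["median"] == pytest.approx(np.sort(v)[20])

    def test_thousand_random_sets_match_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 12))
            v = rng.normal(0, 5, n)
            w = rng.uniform(0.01, 1, n)
            w /= w.sum()
            got = weighted_stats(v, w)
            want = oracle_weighted_stats(list(v), list(w))
            for key in ("min", "max", "mean", "std", "median"):
                assert got[key] == pytest.approx(want[key], abs=1e-10), key

    def test_empty_flagged_missing(self):
        s = weighted_stats(np.array([]), np.array([]))
        assert all(np.isnan(x) for x in s.values())


class TestFuse:
    def _setup(self):
        t = np.zeros((10, 10), dtype=np.int32)
        t[:5, :] = 1
        t[5:, :] = 2
        s = np.zeros((10, 10), dtype=np.int32)
        s[:, :5] = 1
        s[:, 5:] = 2
        table = MeasurementTable(pd.DataFrame({"m": [3.0, 7.0]}, index=["p1", "p2"]))
        om = overlap_weights(_ref(t, ["s1", "s2"]), _ref(s, ["p1", "p2"]))
        return table, om

    def test_constant_source_gives_constant_means(self):
        table = MeasurementTable(pd.DataFrame({"m": [5.0, 5.0]}, index=["p1", "p2"]))
        _, om = self._setup()
        fused = fuse(table, om)
        assert np.allclose(fused.frame["m_mean"], 5.0)
        assert np.allclose(fused.frame["m_std"], 0.0)

    def test_half_half_mean(self):
        table, om = self._setup()
        fused = fuse(table, om)
        assert fused.frame.loc["s1", "m_mean"] == pytest.approx(5.0)

    def test_no_overlap_flagged_not_dropped(self):
        table, om = self._setup()
        fused = fuse(table, om, all_target_ids=["s1", "s2", "s3"])
        assert bool(fused.frame.loc["s3", "no_overlap"])
        assert np.isnan(fused.frame.loc["s3", "m_mean"])

    def test_linearity(self, rng):
        t = rng.integers(0, 5, (30, 30)).astype(np.int32)
        s = rng.integers(0, 20, (30, 30)).astype(np.int32)
        vals = rng.normal(0, 2, 19)
        ids = [f"p{i}" for i in range(19)]
        om = overlap_weights(_ref(t, list("abcd")), _ref(s, ids))
        f1 = fuse(MeasurementTable(pd.DataFrame({"m": vals}, index=ids)), om)
        f2 = fuse(MeasurementTable(pd.DataFrame({"m": 3 * vals + 2}, index=ids)), om)
        assert np.allclose(f2.frame["m_mean"], 3 * f1.frame["m_mean"] + 2)

    def test_order_invariance(self, rng):
        t = rng.integers(0, 5, (30, 30)).astype(np.int32)
        s = rng.integers(0, 20, (30, 30)).astype(np.int32)
        ids = [f"p{i}" for i in range(19)]
        vals = rng.normal(0, 2, 19)
        om = overlap_weights(_ref(t, list("abcd")), _ref(s, ids))
        perm = rng.permutation(19)
        f1 = fuse(MeasurementTable(pd.DataFrame({"m": vals}, index=ids)), om)
        f2 = fuse(
            MeasurementTable(
                pd.DataFrame({"m": vals[perm]}, index=[ids[i] for i in perm])
            ),
            om,
        )
        assert np.allclose(f1.frame["m_mean"], f2.frame["m_mean"])


class TestFilters:
    def test_coverage_boundary_semantics(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[0, :10] = 1  # 10 cells
        ref = _ref(labels, ["s"])
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, :8] = True
        cov = spot_coverage(ref, BinaryMask(mask))
        assert cov["s"] == pytest.approx(0.8)
        assert filter_by_coverage(cov, 0.8) == ["s"]
        mask[0, 7] = False  # 0.7 coverage now
        cov = spot_coverage(ref, BinaryMask(mask))
        assert filter_by_coverage(cov, 0.8) == []

    def test_coverage_matches_enumeration(self, rng):
        labels = rng.integers(0, 6, (40, 40)).astype(np.int32)
        mask = rng.uniform(size=(40, 40)) < 0.6
        ref = _ref(labels, list("abcde"))
        cov = spot_coverage(ref, BinaryMask(mask))
        for k, sid in enumerate(ref.ids, start=1):
            cells = labels == k
            if cells.any():
                assert cov[sid] == pytest.approx(mask[cells].mean())

    def test_tissue_type_matching(self):
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[0, :] = 1
        labels[1, :] = 2
        labels[2, :] = 3
        ref = _ref(labels, ["a", "b", "c"])
        ann_t = np.zeros((4, 4), dtype=np.int32)
        ann_t[0, :] = 2   # a: gland
        ann_t[1, :] = 2   # b: gland
        ann_t[2, :] = 1   # c: stroma
        ann_s = np.zeros((4, 4), dtype=np.int32)
        ann_s[0, :] = 2   # a: gland (match)
        ann_s[1, :] = 1   # b: stroma (mismatch)
        ann_s[2, :] = 0   # c: unannotated
        names = {1: "stroma", 2: "gland"}
        t = assign_tissue_type(ref, ann_t, names)
        s = assign_tissue_type(ref, ann_s, names)
        assert t.labels == {"a": "gland", "b": "gland", "c": "stroma"}
        assert s.labels["c"] is None
        assert tissue_type_match(t, s) == ["a"]

    def test_majority_fraction_threshold(self):
        labels = np.zeros((2, 4), dtype=np.int32)
        labels[:, :] = 1
        ref = _ref(labels, ["a"])
        ann = np.zeros((2, 4), dtype=np.int32)
        ann[0, :2] = 1
        ann[0, 2:] = 2
        ann[1, :2] = 1
        # 4/8 stroma, 2/8 gland, 2/8 unannotated -> stroma at exactly 0.5
        sa = assign_tissue_type(ref, ann, {1: "stroma", 2: "gland"})
        assert sa.labels["a"] == "stroma"


class TestShamRotate:
    def _identity_chain(self, w=10, h=8):
        return TransformChain([AffineTransform.identity()],
                              fixed_shape=(h, w), moving_shape=(h, w))

    def test_180_maps_corners(self):
        chain = sham_rotate(self._identity_chain(), 180.0)
        out = chain.forward_points([[0.0, 0.0]])
        assert np.allclose(out, [[9.0, 7.0]])  # (W-1-x, H-1-y)

    def test_double_sham_is_original(self, rng):
        chain = self._identity_chain()
        double = sham_rotate(sham_rotate(chain), 180.0)
        pts = rng.uniform(0, 8, (50, 2))
        assert np.allclose(double.forward_points(pts), pts, atol=0.5)


class TestExport:
    def test_wide_table_roundtrip(self, tmp_path, rng):
        t = rng.integers(0, 4, (20, 20)).astype(np.int32)
        s = rng.integers(0, 10, (20, 20)).astype(np.int32)
        ids = [f"p{i}" for i in range(9)]
        om = overlap_weights(_ref(t, list("abc")), _ref(s, ids))
        table = MeasurementTable(
            pd.DataFrame({"m1": rng.normal(size=9), "m2": rng.normal(size=9)},
                         index=ids)
        )
        fused = fuse(table, om)
        path = tmp_path / "fused.csv"
        export_fused(fused, path, "wide_table")
        back = read_fused(path)
        # id + 2 measures x 5 stats + area + count + flag
        stat_cols = [c for c in back.columns if c.startswith(("m1_", "m2_"))]
        assert len(stat_cols) == 10
        for col in stat_cols:
            assert np.allclose(back[col], fused.frame[col], atol=1e-9)

    def test_image_stack_paints_means(self, tmp_path):
        import tifffile

        labels = np.zeros((6, 6), dtype=np.int32)
        labels[:3, :] = 1
        ref = _ref(labels, ["a"])
        s = np.ones((6, 6), dtype=np.int32)
        om = overlap_weights(ref, _ref(s, ["p"]))
        table = MeasurementTable(pd.DataFrame({"m": [4.5]}, index=["p"]))
        fused = fuse(table, om)
        path = tmp_path / "stack.tiff"
        export_fused(fused, path, "image_stack", target_ref=ref)
        stack = tifffile.imread(path)
        stack = stack.reshape(-1, 6, 6)
        assert stack.shape[0] == 1  # single measure -> single page
        assert np.allclose(stack[0][labels == 1], 4.5)
        assert np.allclose(stack[0][labels == 0], 0.0)
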