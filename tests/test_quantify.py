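"""Masking, ratio maps and ROI statistics."""

import numpy as np
import pandas as pd
import pytest

from nanosip.errors import (
    DimensionError,
    InsufficientDataError,
    MissingInputError,
)
from nanosip.organelles import OrganelleClass
from nanosip.phantom import AcquisitionSpec, simulate_session
from nanosip.quantify import (
    ROIStat,
    accumulate,
    build_mask,
    qc_count_dependence,
    quantify_rois,
    ratio_map,
    roi_stats_frame,
    summarize,
)
from nanosip.stack_io import IonCountStack, MeasurementSession, ROILabelMap, Species

from conftest import uniform_truth


def make_session(cn15, cn14, condition="dysoxic"):
    """One-plane session from 2-D count images."""
    cn15 = np.asarray(cn15)[None, :, :]
    cn14 = np.asarray(cn14)[None, :, :]
    return MeasurementSession(
        stacks={
            Species.CN15: IonCountStack(Species.CN15, cn15, 40.0),
            Species.CN14: IonCountStack(Species.CN14, cn14, 40.0),
        },
        pixel_size_nm=40.0,
        condition=condition,
    )


def label_map_like(shape, classes):
    """Labels 1..k as equal horizontal bands with the given classes."""
    labels = np.zeros(shape, dtype=np.int32)
    rows = np.array_split(np.arange(shape[0]), len(classes))
    table = []
    for i, (rr, cls) in enumerate(zip(rows, classes), start=1):
        labels[rr, :] = i
        table.append({"label": i, "roi_id": i, "class": cls,
                      "condition": "dysoxic", "chamber": ""})
    return ROILabelMap(labels, pd.DataFrame(table))


class TestAccumulate:
    def test_single_plane_identity(self):
        stack = IonCountStack(Species.CN14, np.arange(12).reshape(1, 3, 4), 40.0)
        np.testing.assert_array_equal(accumulate(stack), np.arange(12).reshape(3, 4))

    def test_fifty_planes_of_ones(self):
        stack = IonCountStack(Species.CN14, np.ones((50, 4, 4), dtype=int), 40.0)
        assert (accumulate(stack) == 50).all()

    def test_total_conserved(self, small_session):
        for stack in small_session.stacks.values():
            assert accumulate(stack).sum() == stack.counts.sum()


class TestBuildMask:
    def test_boundary_semantics(self):
        # "below 1000 removed" keeps the boundary value
        img = np.array([[999, 1000, 1001]])
        mask = build_mask(cn_total=img, element="N")
        np.testing.assert_array_equal(mask.valid, [[False, True, True]])

    def test_sulfur_thresholds_s32_only(self):
        s32 = np.array([[59, 60]])
        mask = build_mask(s32_total=s32, element="S")
        np.testing.assert_array_equal(mask.valid, [[False, True]])

    def test_all_zero_is_empty_mask_not_error(self):
        mask = build_mask(cn_total=np.zeros((4, 4)), element="N")
        assert mask.n_valid == 0

    def test_missing_input(self):
        with pytest.raises(MissingInputError):
            build_mask(s32_total=np.ones((2, 2)), element="N")


class TestRatioMap:
    def test_uniform_fraction(self):
        minor = np.full((4, 4), 1)
        major = np.full((4, 4), 999)
        mask = build_mask(cn_total=minor + major, cn_min=0, element="N")
        rm = ratio_map(minor, major, mask)
        np.testing.assert_allclose(rm.fraction, 0.001)

    def test_all_masked(self):
        mask = build_mask(cn_total=np.zeros((3, 3)), cn_min=1, element="N")
        rm = ratio_map(np.ones((3, 3)), np.ones((3, 3)), mask)
        assert np.isnan(rm.fraction).all()

    def test_zero_total_pixel_demoted(self):
        minor = np.array([[0, 1]])
        major = np.array([[0, 9]])
        mask = build_mask(cn_total=np.array([[5, 10]]), cn_min=0, element="N")
        rm = ratio_map(minor, major, mask)
        assert rm.n_demoted == 1
        assert np.isnan(rm.fraction[0, 0])


class TestQuantifyROIs:
    def test_forced_arithmetic_pixelwise_equals_pooled(self):
        cn15 = np.array([[1, 2, 3]])
        cn14 = np.array([[99, 98, 97]])
        session = make_session(cn15, cn14)
        lm = label_map_like((1, 3), ["mitochondrion"])
        pw = quantify_rois(session, lm, element="N", method="pixelwise", cn_min=0)[0]
        pl = quantify_rois(session, lm, element="N", method="pooled", cn_min=0)[0]
        assert pw.f_mean == pytest.approx(0.02)
        assert pl.f_mean == pytest.approx(6 / 300)

    def test_uniform_roi_pixelwise_equals_pooled_exactly(self):
        cn15 = np.full((4, 4), 5)
        cn14 = np.full((4, 4), 495)
        session = make_session(cn15, cn14)
        lm = label_map_like((4, 4), ["cytosome"])
        pw = quantify_rois(session, lm, element="N", method="pixelwise", cn_min=0)[0]
        pl = quantify_rois(session, lm, element="N", method="pooled", cn_min=0)[0]
        assert pw.f_mean == pl.f_mean

    def test_fully_masked_roi_flagged_not_dropped(self):
        session = make_session(np.array([[1, 50]]), np.array([[1, 2000]]))
        lm = label_map_like((1, 2), ["resin"])
        lm.labels[0, 0] = 1
        lm.labels[0, 1] = 0  # only the low-count pixel belongs to the ROI
        (stat,) = quantify_rois(session, lm, element="N", cn_min=1000)
        assert stat.n_valid == 0 and not stat.has_estimate
        assert np.isnan(stat.f_mean)

    def test_dim_mismatch(self, small_session):
        lm = label_map_like((7, 5), ["resin"])
        with pytest.raises(DimensionError):
            quantify_rois(small_session, lm, element="N")

    def test_masking_monotonicity(self, small_session, small_truth):
        lo = quantify_rois(small_session, small_truth.label_map, element="N", cn_min=500)
        hi = quantify_rois(small_session, small_truth.label_map, element="N", cn_min=1500)
        lo_by = {s.roi_id: s.n_valid for s in lo}
        for s in hi:
            assert s.n_valid <= lo_by[s.roi_id]

    def test_plane_order_and_label_renumbering_invariance(self, small_truth):
        acq = AcquisitionSpec(planes=8, raster=96)
        session = simulate_session(small_truth, acq, seed=3)
        shuffled = MeasurementSession(
            stacks={
                sp: IonCountStack(sp, st.counts[::-1].copy(), st.pixel_size_nm)
                for sp, st in session.stacks.items()
            },
            pixel_size_nm=session.pixel_size_nm,
            condition=session.condition,
            specimen_id=session.specimen_id,
        )
        a = quantify_rois(session, small_truth.label_map, element="N", cn_min=100)
        b = quantify_rois(shuffled, small_truth.label_map, element="N", cn_min=100)
        for sa, sb in zip(a, b):
            assert sa.f_mean == sb.f_mean or (np.isnan(sa.f_mean) and np.isnan(sb.f_mean))

        lm = small_truth.label_map
        relabeled = ROILabelMap(
            lm.labels * 10,
            lm.table.assign(label=lm.table["label"] * 10),
        )
        c = quantify_rois(session, relabeled, element="N", cn_min=100)
        for sa, sc in zip(a, c):
            assert sc.roi_id == sa.roi_id * 10
            assert sa.n_valid == sc.n_valid

    def test_pixelwise_and_pooled_converge_at_high_counts(self):
        truth = uniform_truth(rows=24, cols=24, f15=0.012, lambda_cn=40.0)
        sess = simulate_session(truth, AcquisitionSpec(planes=25, raster=24,
                                                       species=("CN",)), seed=5)
        pw = quantify_rois(sess, truth.label_map, element="N", method="pixelwise")[0]
        pl = quantify_rois(sess, truth.label_map, element="N", method="pooled")[0]
        assert abs(pw.f_mean - pl.f_mean) < pl.f_se  # < 1 counting SE at 1000 cts/px


class TestSummarize:
    def _stat(self, cls, cond, f_mean, roi_id=1):
        return ROIStat(
            specimen="s", condition=cond, organelle=OrganelleClass(cls), roi_id=roi_id,
            n_valid=10, f_mean=f_mean, f_sd=0.0, f_se=0.0, total_minor=1,
            total_major=99, method="pixelwise", element="N", has_estimate=True,
        )

    def test_single_roi_sd_empty(self):
        out = summarize([self._stat("resin", "anoxic", 0.004)])
        assert out.loc[0, "n"] == 1
        assert np.isnan(out.loc[0, "sd_atom_pct"])

    def test_mean_and_sample_sd(self):
        stats = [self._stat("resin", "anoxic", f, roi_id=i)
                 for i, f in enumerate([0.01, 0.02, 0.03])]
        out = summarize(stats)
        assert out.loc[0, "mean_atom_pct"] == pytest.approx(2.0)
        assert out.loc[0, "sd_atom_pct"] == pytest.approx(1.0)

    def test_empty_input_empty_table(self):
        out = summarize([])
        assert out.empty

    def test_roi_table_column_order(self):
        frame = roi_stats_frame([self._stat("resin", "anoxic", 0.004)])
        assert list(frame.columns[:10]) == [
            "specimen", "condition", "class", "roi_id", "n_valid",
            "f_mean", "f_sd", "f_se", "total_minor", "total_major",
        ]


class TestQCCountDependence:
    def _stat(self, total, f_mean, roi_id):
        return ROIStat(
            specimen="s", condition="anoxic", organelle=OrganelleClass.RESIN,
            roi_id=roi_id, n_valid=10, f_mean=f_mean, f_sd=0.0, f_se=0.0,
            total_minor=0, total_major=total, method="pixelwise", element="N",
            has_estimate=True,
        )

    def test_monotone_input_rho_one(self):
        stats = [self._stat(100 * i, 0.001 * i, i) for i in range(1, 6)]
        rho, _ = qc_count_dependence(stats)
        assert rho == pytest.approx(1.0)

    def test_insufficient_data(self):
        stats = [self._stat(100, 0.1, 1), self._stat(200, 0.2, 2)]
        with pytest.raises(InsufficientDataError):
            qc_count_dependence(stats)

    def test_null_simulation_over_seeds(self):
        # 50 same-class ROIs of varying size with ROI-jittered fractions:
        # totals (driven by area) and fractions are independent by
        # construction, so |rho| < 0.4 in >= 95% of seeds.
        import pandas as pd

        from nanosip.phantom import ClassTruth, PhantomConfig, PhantomTruth
        from nanosip.stack_io import ROILabelMap

        n_roi = 50
        rng0 = np.random.default_rng(123)
        widths = rng0.integers(1, 5, size=n_roi)
        rows_total = int(widths.sum())
        cols = rows_total  # square field so the raster matches the map
        labels = np.repeat(np.arange(1, n_roi + 1), widths)[:, None] * np.ones(
            (1, cols), dtype=int
        )
        table = pd.DataFrame(
            [{"label": i, "roi_id": i, "class": "mitochondrion",
              "condition": "dysoxic", "chamber": ""} for i in range(1, n_roi + 1)]
        )
        cfg = PhantomConfig(rows=rows_total, cols=cols,
                            pixel_size_nm=10000.0 / cols, organelle_counts={})
        ok = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            f15 = np.clip(rng.normal(0.0124, 0.0020, size=n_roi), 1e-4, 0.5)
            truth_tbl = pd.DataFrame(
                {"label": np.arange(1, n_roi + 1), "class": "mitochondrion",
                 "f15_true": f15, "f34_true": 0.05, "lambda_cn": 40.0,
                 "lambda_s": 3.0}
            )
            truth = PhantomTruth(
                label_map=ROILabelMap(labels.astype(np.int32), table),
                truths=[ClassTruth(OrganelleClass.MITOCHONDRION, 0.0124, 0.05,
                                   40.0, 3.0)],
                roi_truth=truth_tbl, seed=seed, config=cfg,
            )
            sess = simulate_session(
                truth, AcquisitionSpec(planes=5, raster=rows_total, species=("CN",)),
                seed=seed + 1000,
            )
            stats = quantify_rois(sess, truth.label_map, element="N", cn_min=0)
            rho, _ = qc_count_dependence(stats)
            if abs(rho) < 0.4:
                ok += 1
        assert ok / n_seeds >= 0.95
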