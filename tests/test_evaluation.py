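"""Agreement statistics against independent brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from pasture import (
    PairedSeries,
    agreement,
    compare_methods,
    compute_ndvi,
    fit_exponential,
    lin_ccc,
    transect_compare,
    zonal_mean,
)
from pasture.calibration import RULER_BOTH
from pasture.scene import sample_transect


def oracle_ccc(x, y):
    """Lin's CCC computed term by term with population moments."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    vx = sum((xi - mx) ** 2 for xi in x) / n
    vy = sum((yi - my) ** 2 for yi in y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / n
    return 2 * cov / (vx + vy + (mx - my) ** 2)


def oracle_report(ref, est):
    n = len(ref)
    dev = [e - r for e, r in zip(est, ref)]
    bias = sum(dev) / n
    rmse = (sum(d * d for d in dev) / n) ** 0.5
    re = rmse / (sum(ref) / n) * 100
    return bias, rmse, re


class TestAgreement:
    def test_identity_is_perfect(self, rng):
        x = rng.normal(2000, 300, 30)
        rep = agreement(PairedSeries(x, x.copy()))
        assert rep.bias == 0 and rep.rmse == 0
        assert rep.ccc == pytest.approx(1.0)
        assert rep.cb == pytest.approx(1.0)
        assert rep.slope == pytest.approx(1.0) and rep.intercept == pytest.approx(0.0, abs=1e-9)

    def test_constant_shift(self, rng):
        x = rng.normal(2000, 300, 40)
        rep = agreement(PairedSeries(x, x + 100.0))
        assert rep.bias == pytest.approx(100.0)
        assert rep.rmse == pytest.approx(100.0)
        assert rep.r == pytest.approx(1.0)
        assert rep.ccc < 1.0 and rep.cb < 1.0
        assert rep.ccc == pytest.approx(rep.r * rep.cb)

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(5, 30)
            ref = rng.normal(rng.uniform(500, 3000), rng.uniform(50, 500), n)
            est = ref + rng.normal(0, rng.uniform(10, 400), n)
            rep = agreement(PairedSeries(ref, est))
            bias, rmse, re = oracle_report(ref.tolist(), est.tolist())
            assert rep.bias == pytest.approx(bias, abs=1e-10)
            assert rep.rmse == pytest.approx(rmse, abs=1e-10)
            assert rep.re_percent == pytest.approx(re, abs=1e-10)
            assert rep.ccc == pytest.approx(oracle_ccc(ref.tolist(), est.tolist()), abs=1e-10)

    def test_rmse_decomposition(self, rng):
        ref = rng.normal(2000, 400, 60)
        est = ref + rng.normal(50, 150, 60)
        rep = agreement(PairedSeries(ref, est))
        dev = est - ref
        assert rep.rmse**2 == pytest.approx(rep.bias**2 + dev.var(), rel=1e-12)

    def test_ccc_bounded_by_r(self, rng):
        ref = rng.normal(2000, 400, 50)
        est = 0.8 * ref + 300 + rng.normal(0, 100, 50)
        rep = agreement(PairedSeries(ref, est))
        assert abs(rep.ccc) <= abs(rep.r) <= 1.0
        assert 0 < rep.cb <= 1.0

    def test_zero_variance_gives_nan_sentinels(self, rng):
        ref = rng.normal(2000, 300, 10)
        rep = agreement(PairedSeries(ref, np.full(10, 1500.0)))
        assert np.isnan(rep.ccc) and np.isnan(rep.r)
        assert rep.rmse > 0  # deviation stats still defined

    def test_missing_pairs_dropped_with_count(self, rng):
        ref = rng.normal(2000, 300, 12)
        est = ref.copy()
        est[3] = np.nan
        series = PairedSeries(ref, est)
        assert series.n == 11 and series.n_dropped == 1


class TestCompareMethods:
    def test_identical_methods(self, rng):
        x = rng.normal(2000, 400, 20)
        rep = compare_methods(x, x, x)
        assert rep["rmse"] == 0.0
        assert rep["within_band_fraction"] == 1.0

    def test_constant_offset_from_control_mean(self, rng):
        cdax = rng.normal(2000, 400, 30)
        ruler = rng.normal(2000, 400, 30)
        uav = (cdax + ruler) / 2 + 300.0
        rep = compare_methods(uav, cdax, ruler)
        assert rep["rmse"] == pytest.approx(300.0)
        assert rep["bias"] == pytest.approx(300.0)
        assert rep["within_band_fraction"] == 1.0

    def test_rmse_matches_analytic_expectation(self):
        """Controls = truth + noise(sd 400): RMSE -> sqrt(400^2/2) over 500 paddock-dates."""
        rng = np.random.default_rng(7)
        n = 500
        truth = rng.uniform(1500, 2500, n)
        cdax = truth + rng.normal(0, 400, n)
        ruler = truth + rng.normal(0, 400, n)
        rep = compare_methods(truth, cdax, ruler)
        expected = 400.0 / np.sqrt(2.0)
        assert rep["rmse"] == pytest.approx(expected, rel=0.10)

    def test_paired_ttest_type_i_error(self):
        """Null (no method difference): rejection rate 5% +/- 2 points, 500 reps."""
        rng = np.random.default_rng(101)
        reps, rejections = 500, 0
        for _ in range(reps):
            truth = rng.uniform(1500, 2500, 52)
            uav = truth + rng.normal(0, 300, 52)
            cdax = truth + rng.normal(0, 300, 52)
            rejections += compare_methods(uav, cdax, cdax)["t_vs_cdax"]["p"] < 0.05
        assert abs(rejections / reps - 0.05) <= 0.02

    def test_misaligned_ids_rejected(self, rng):
        x = rng.normal(2000, 300, 4)
        with pytest.raises(ValueError, match="misaligned"):
            compare_methods(x, x, x, ids=["a", "b", "b", "c"])

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="aligned"):
            compare_methods(np.ones(5), np.ones(4), np.ones(5))


class TestTransectCompare:
    def test_closed_loop_agreement(self, small_scene):
        """Noiseless scene, heights from the inverse height rule at sampling
        points: UAV-derived and transect paddock means agree to < 1 kg DM/ha."""
        spec, scene, pmap, truth = small_scene
        import pandas as pd

        ndvi = compute_ndvi(scene)
        # exact calibration from noiseless pixels
        rng = np.random.default_rng(3)
        idx = rng.choice(truth.data[0].size, 72, replace=False)
        cal = fit_exponential(ndvi.data[0].ravel()[idx], truth.data[0].ravel()[idx])
        # sampling points on pixel centers along each paddock's midline, so a
        # sub-pixel buffer sees exactly the pixel the height was derived from
        t = truth.transform
        frames = []
        for p in pmap:
            minx, miny, maxx, maxy = p.geometry.bounds
            row = int((t.y0 - (miny + maxy) / 2.0) / t.dy)
            cols = np.arange(int(minx / t.dx) + 2, int(maxx / t.dx) - 2, 2)
            x, y = t.pixel_center(np.full_like(cols, row), cols)
            biomass = truth.data[0][row, cols]
            frames.append(
                pd.DataFrame(
                    {
                        "paddock_id": p.paddock_id,
                        "x": x,
                        "y": y,
                        "height": (biomass + 515.0) / 123.0,  # invert the ruler rule
                    }
                )
            )
        transects = pd.concat(frames, ignore_index=True)
        paired = transect_compare(
            ndvi, cal, transects, {"any": RULER_BOTH}, pmap, height_unit="cm",
            buffer_diameter=1.0,
        )
        assert len(paired) == len(pmap)
        diff = (paired["uav_biomass"] - paired["transect_biomass"]).abs()
        assert (diff < 1.0).all()

    def test_buffer_vs_zonal_on_smooth_field(self, small_scene):
        """1-m-buffer transect mean differs from the paddock zonal mean by
        less than the within-paddock SD on a smooth field."""
        spec, scene, pmap, truth = small_scene
        from pasture.ndvi import _center_containment, buffer_extract

        p = pmap.paddocks[0]
        pts = sample_transect(truth, p, spacing=2.7, seed=9)
        extracted = buffer_extract(truth, pts, diameter=4.0)
        transect_mean = extracted["buffer_mean"].mean()
        zonal = zonal_mean(truth, pmap).set_index("paddock_id").loc[p.paddock_id, "mean"]
        inside = _center_containment(truth, p.geometry)
        within_sd = truth.data[0][inside].std()
        assert abs(transect_mean - zonal) < within_sd

    def test_fully_masked_paddock_skipped(self, small_scene):
        spec, scene, pmap, truth = small_scene
        import pandas as pd

        ndvi = compute_ndvi(scene)
        rng = np.random.default_rng(3)
        idx = rng.choice(truth.data[0].size, 72, replace=False)
        cal = fit_exponential(ndvi.data[0].ravel()[idx], truth.data[0].ravel()[idx])
        good = sample_transect(truth, pmap.paddocks[0], spacing=5.0, seed=1)
        good["height"] = 15.0
        bad = pd.DataFrame(
            {"paddock_id": pmap.paddocks[1].paddock_id, "x": [-900.0], "y": [-900.0], "height": [15.0]}
        )
        transects = pd.concat([good, bad], ignore_index=True)
        with pytest.warns(UserWarning):
            paired = transect_compare(ndvi, cal, transects, {"any": RULER_BOTH}, pmap, "cm")
        assert list(paired["paddock_id"]) == [pmap.paddocks[0].paddock_id]
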