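import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wingpol import internalization as im
from wingpol import stats as wstats
from wingpol import synthwing as sw
from wingpol.errors import ProtocolError, SpecError


def flood_fill_components(binary):
    """Independent 8-connected component counter (explicit BFS)."""
    binary = np.asarray(binary, bool)
    seen = np.zeros_like(binary)
    count = 0
    h, w = binary.shape
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                count += 1
                queue = [(r, c)]
                seen[r, c] = True
                while queue:
                    i, j = queue.pop()
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = i + di, j + dj
                            if (0 <= ni < h and 0 <= nj < w and binary[ni, nj]
                                    and not seen[ni, nj]):
                                seen[ni, nj] = True
                                queue.append((ni, nj))
    return count


class TestThreshold:
    def test_discrete_worked_example(self):
        plane = np.zeros((100, 100))
        plane.ravel()[:100] = 100.0
        thr, achieved = im.find_puncta_threshold(plane, np.ones_like(plane, bool))
        assert thr == 0.0
        assert achieved == pytest.approx(0.0100, abs=1e-12)

    def test_target_one_includes_everything(self):
        rng = np.random.default_rng(0)
        plane = rng.random((20, 20))
        thr, achieved = im.find_puncta_threshold(plane, np.ones_like(plane, bool),
                                                 target_fraction=1.0)
        assert thr < plane.min()
        assert achieved == 1.0

    def test_continuous_plane_achieved_fraction_band(self):
        rng = np.random.default_rng(42)
        plane = rng.random((300, 400))
        n = plane.size
        _, achieved = im.find_puncta_threshold(plane, np.ones_like(plane, bool))
        assert 0.01 - 1.0 / n < achieved <= 0.01

    def test_constant_region_warns_zero_puncta(self):
        plane = np.full((10, 10), 4.2)
        with pytest.warns(UserWarning):
            thr, achieved = im.find_puncta_threshold(plane, np.ones_like(plane, bool))
        assert thr == 4.2
        assert achieved == 0.0

    @given(st.lists(st.floats(min_value=0.001, max_value=0.9), min_size=2,
                    max_size=5, unique=True))
    def test_threshold_monotone_in_target(self, targets):
        rng = np.random.default_rng(7)
        plane = rng.normal(10, 3, (50, 50))
        mask = np.ones_like(plane, bool)
        thrs = [im.find_puncta_threshold(plane, mask, t)[0] for t in sorted(targets)]
        assert all(a >= b for a, b in zip(thrs, thrs[1:]))

    def test_bad_target_rejected(self):
        with pytest.raises(SpecError):
            im.find_puncta_threshold(np.ones((4, 4)), np.ones((4, 4), bool), 0.0)


class TestExtractPuncta:
    def test_single_block(self):
        plane = np.zeros((10, 10))
        plane[2:5, 3:6] = 5.0
        pset = im.extract_puncta(plane, np.ones_like(plane, bool), 1.0)
        assert pset.count == 1
        assert pset.puncta["area_px"].iloc[0] == 9
        assert pset.puncta["integrated_intensity"].iloc[0] == pytest.approx(45.0)

    def test_diagonal_pixels_are_one_punctum(self):
        plane = np.zeros((5, 5))
        plane[1, 1] = plane[2, 2] = 3.0
        pset = im.extract_puncta(plane, np.ones_like(plane, bool), 1.0)
        assert pset.count == 1

    def test_min_area_filter(self):
        plane = np.zeros((8, 8))
        plane[1, 1] = 3.0
        plane[5:7, 5:7] = 3.0
        pset = im.extract_puncta(plane, np.ones_like(plane, bool), 1.0, min_area=2)
        assert pset.count == 1
        assert pset.puncta["area_px"].iloc[0] == 4

    def test_component_count_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            plane = (rng.random((40, 40)) > 0.7).astype(float)
            pset = im.extract_puncta(plane, np.ones_like(plane, bool), 0.5)
            assert pset.count == flood_fill_components(plane > 0.5)

    def test_generated_count_recovered_when_well_separated(self):
        spec = sw.WingSpec(seed=5)
        label, clone = sw.make_lattice(spec)
        pspec = sw.PunctaSpec(density_wt_per_kpx=0.5, density_mut_per_kpx=0.5,
                              noise_sd=0.0, background=0.0, seed=12)
        stack, truth = sw.render_puncta_plane(label, clone, pspec)
        plane = stack.voxels[0]
        pset = im.extract_puncta(plane, np.ones_like(plane, bool), 1.0, min_area=2)
        # Poisson placement can merge nearby blobs; allow a small deficit only
        assert pset.count <= len(truth)
        assert pset.count >= 0.8 * len(truth)


class TestTimecourse:
    def _records(self, values_by_time, genotype="WILDTYPE"):
        recs = []
        for t, vals in values_by_time.items():
            for i, v in enumerate(vals):
                recs.append(im.TimecourseRecord(f"w{i}-{t}", genotype, t, v))
        return recs

    def test_flat_series_normalizes_to_one(self):
        recs = self._records({0: [5.0, 5.0], 10: [5.0], 30: [5.0]})
        out = im.normalize_timecourse(recs, 0.0)
        assert all(r.normalized_intensity == pytest.approx(1.0) for r in out)

    def test_generator_retention_recovered_exactly(self):
        retention = {"WILDTYPE": {0: 1.0, 10: 0.6, 30: 0.3},
                     "MUTANT": {0: 1.0, 10: 0.6, 30: 0.3}}
        recs, bg = sw.simulate_internalization(
            n_wings=3, retention=retention, noise_sd=0.0, wing_effect_sd=0.0, seed=1)
        out = im.normalize_timecourse(recs, bg)
        for r in out:
            assert r.normalized_intensity == pytest.approx(
                retention[r.genotype_region][r.time_min], rel=1e-12)

    def test_background_equal_to_signal_warns_and_zeroes(self):
        recs = self._records({0: [5.0, 5.0], 10: [3.0]})
        with pytest.warns(UserWarning):
            out = im.normalize_timecourse(recs, 5.0)
        assert all(r.normalized_intensity == 0.0 for r in out)

    def test_missing_zero_minute_is_protocol_error(self):
        recs = self._records({10: [1.0, 2.0]})
        with pytest.raises(ProtocolError):
            im.normalize_timecourse(recs, 0.0)

    def test_anova_dunnett_adjustment_monotone(self):
        recs, bg = sw.simulate_internalization(n_wings=6, seed=3)
        out = im.normalize_timecourse(recs, bg)
        tests = im.timecourse_anova(out)
        for gt, (anova, dunnett) in tests.items():
            for dres in dunnett:
                # unadjusted p of the same contrast (same statistic, same
                # pooled-variance df) can only be smaller
                from scipy import stats as sps
                unadj = 2 * sps.t.sf(abs(dres.statistic), dres.df)
                # tolerance covers the Monte-Carlo error of the multivariate-t
                # integration at very small p
                assert dres.p >= unadj - max(1e-6, 0.2 * unadj)

    def test_dunnett_single_comparison_matches_t(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        _, dunnett = wstats.anova_dunnett([a, b], control_index=0)
        t = wstats.unpaired_t(b, a)
        assert dunnett[0].p == pytest.approx(t.p, abs=1e-4)


class TestPunctaRatios:
    def _pset(self, plane, thr=1.0, region="WILDTYPE"):
        return im.extract_puncta(plane, np.ones_like(plane, bool), thr, region=region)

    def test_identical_regions_ratio_one(self):
        rng = np.random.default_rng(2)
        plane = (rng.random((30, 30)) > 0.9) * 5.0
        frame, _ = im.puncta_ratio_tests([(self._pset(plane), self._pset(plane))])
        assert frame["count_ratio"].iloc[0] == pytest.approx(1.0)
        assert frame["area_ratio"].iloc[0] == pytest.approx(1.0)

    def test_zero_wildtype_puncta_excludes_wing(self):
        empty = np.zeros((10, 10))
        some = np.zeros((10, 10))
        some[4, 4] = 5.0
        with pytest.warns(UserWarning):
            frame, _ = im.puncta_ratio_tests([(self._pset(empty), self._pset(some))])
        assert len(frame) == 0

    def test_density_ratio_recovered_over_wings(self):
        # mutant density 2x wild-type: mean count ratio within 3 SE of 2
        ratios = []
        for seed in range(30):
            spec = sw.WingSpec(seed=seed)
            label, clone = sw.make_lattice(spec)
            pspec = sw.PunctaSpec(density_wt_per_kpx=1.5, density_mut_per_kpx=3.0,
                                  noise_sd=0.0, background=0.0, seed=seed)
            stack, _ = sw.render_puncta_plane(label, clone, pspec)
            plane = stack.voxels[0]
            thr, _ = im.find_puncta_threshold(plane, clone.mask(im.Region.WILDTYPE),
                                              0.02)
            wt = im.extract_puncta(plane, clone.mask(im.Region.WILDTYPE), thr,
                                   min_area=2)
            mut = im.extract_puncta(plane, clone.mask(im.Region.MUTANT), thr,
                                    min_area=2)
            if wt.count:
                ratios.append(mut.density_per_kpx / wt.density_per_kpx)
        ratios = np.array(ratios)
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 2.0) <= 3 * se
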