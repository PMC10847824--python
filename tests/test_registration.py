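import numpy as np
import pytest

from octvbm import (
    OCTVolume,
    ScanGeometry,
    TargetGrid,
    ThicknessMap,
    apply_translation,
    build_mean_template,
    compute_global_translation,
    detect_fovea,
    extract_retina,
    fit_aline_affine,
    fit_aline_affine_grid,
    make_template,
    normalize_intensity,
    register_scan,
    sample_subject,
    template_target,
)
from octvbm.errors import DegenerateInputError, FoveaError, LateralityError
from octvbm.io import BoundarySet


def _retina_map(values, geometry):
    return ThicknessMap(values=values, layer="Retina",
                        laterality="left-normalized", geometry=geometry)


class TestNormalizeIntensity:
    def test_affine_standardization(self, small_geometry, rng):
        base = rng.normal(0, 1, (25, 8, 64))
        base = (base - base.mean()) / base.std()
        v = OCTVolume(intensity=base * 10 + 50, geometry=small_geometry,
                      laterality="OS")
        out = normalize_intensity(v, 100.0, 20.0)
        assert out.intensity.mean() == pytest.approx(100.0)
        assert out.intensity.std() == pytest.approx(20.0)
        np.testing.assert_allclose(out.intensity, v.intensity * 2, rtol=1e-9)

    def test_already_at_reference_unchanged(self, small_geometry, rng):
        base = rng.normal(0, 1, (25, 8, 64))
        base = (base - base.mean()) / base.std() * 20 + 100
        v = OCTVolume(intensity=base, geometry=small_geometry,
                      laterality="OS")
        out = normalize_intensity(v, 100.0, 20.0)
        np.testing.assert_allclose(out.intensity, v.intensity, atol=1e-9)

    def test_rank_order_preserved(self, small_geometry, rng):
        v = OCTVolume(intensity=rng.random((25, 8, 64)),
                      geometry=small_geometry, laterality="OS")
        out = normalize_intensity(v, 7.0, 3.0)
        np.testing.assert_array_equal(np.argsort(v.intensity, axis=None),
                                      np.argsort(out.intensity, axis=None))

    def test_zero_variance_rejected(self, small_geometry):
        v = OCTVolume(intensity=np.full((25, 8, 64), 5.0),
                      geometry=small_geometry, laterality="OS")
        with pytest.raises(DegenerateInputError):
            normalize_intensity(v, 0.0, 1.0)


class TestExtractRetina:
    def _volume_and_bounds(self, geometry, ilm, bm, n_depth=100):
        v = OCTVolume(intensity=np.ones((geometry.n_bscans, n_depth,
                                         geometry.n_ascans)),
                      geometry=geometry, laterality="OS")
        shape = geometry.shape
        surfaces = {"ILM": np.full(shape, ilm),
                    "RNFL/GCL": np.full(shape, ilm),
                    "IPL/INL": np.full(shape, ilm),
                    "INL/OPL": np.full(shape, ilm),
                    "BM": np.full(shape, bm)}
        b = BoundarySet(surfaces=surfaces, geometry=geometry,
                        laterality="OS")
        return v, b

    def test_masked_count_matches_counting_oracle(self, small_geometry):
        v, b = self._volume_and_bounds(small_geometry, ilm=100.0, bm=250.0)
        out = extract_retina(v, b)
        depth = v.depth_axis_um()
        inside_per_aline = int(((depth >= 100.0) & (depth <= 250.0)).sum())
        n_alines = small_geometry.n_bscans * small_geometry.n_ascans
        expected_masked = n_alines * (v.n_depth - inside_per_aline)
        assert int(np.isnan(out.intensity).sum()) == expected_masked

    def test_degenerate_aline_fully_masked(self, small_geometry):
        v, b = self._volume_and_bounds(small_geometry, ilm=100.0, bm=250.0)
        b.surfaces["ILM"][3, 5] = 120.0
        b.surfaces["BM"][3, 5] = 120.0
        out = extract_retina(v, b)
        depth = v.depth_axis_um()
        on_boundary = int((depth == 120.0).sum())
        assert np.isnan(out.intensity[3, :, 5]).sum() == v.n_depth - on_boundary


class TestDetectFovea:
    def test_template_pit_found_at_center(self, small_spec):
        maps, _ = make_template(small_spec)
        assert detect_fovea(maps["Retina"]) == small_spec.resolved_fovea()
        # brute-force argmin over raw voxels agrees
        raw = np.unravel_index(np.nanargmin(maps["Retina"].values),
                               maps["Retina"].values.shape)
        assert tuple(raw) == small_spec.resolved_fovea()

    def test_single_perturbed_minimum(self, small_geometry):
        values = np.full(small_geometry.shape, 300.0)
        values[3, 7] = 200.0
        assert detect_fovea(_retina_map(values, small_geometry),
                            smooth_sigma_um=0) == (3, 7)

    def test_plateau_tie_breaks_to_centroid(self, small_geometry):
        values = np.full(small_geometry.shape, 300.0)
        values[10:13, 50] = 200.0
        assert detect_fovea(_retina_map(values, small_geometry),
                            smooth_sigma_um=0) == (11, 50)

    def test_all_invalid_map_raises(self, small_geometry):
        values = np.full(small_geometry.shape, np.nan)
        with pytest.raises(FoveaError):
            detect_fovea(_retina_map(values, small_geometry))


class TestGlobalTranslation:
    def test_subtraction_examples(self):
        target = TargetGrid(n_rows=25, n_cols=1024, fovea_position=(12, 512))
        assert compute_global_translation((10, 500), target) == (2, 12)
        assert compute_global_translation((12, 512), target) == (0, 0)

    def test_composition_moves_fovea_onto_target(self, small_geometry):
        values = np.full(small_geometry.shape, 300.0)
        values[8, 20] = 200.0
        target = TargetGrid(n_rows=25, n_cols=64, fovea_position=(12, 30))
        delta = compute_global_translation((8, 20), target)
        moved = apply_translation(values, delta)
        assert detect_fovea(_retina_map(moved, small_geometry),
                            smooth_sigma_um=0) == (12, 30)


class TestAlineAffine:
    @pytest.mark.parametrize("subject,target,expected", [
        ((100.0, 400.0), (110.0, 410.0), (1.0, 10.0)),
        ((100.0, 400.0), (100.0, 250.0), (0.5, 50.0)),
    ])
    def test_two_point_line(self, subject, target, expected):
        a, b = fit_aline_affine(subject[0], subject[1], target[0], target[1])
        assert (a, b) == pytest.approx(expected)

    def test_anchors_mapped_exactly_on_random_input(self, rng):
        for _ in range(200):
            s_ilm = rng.uniform(50, 200)
            s_bm = s_ilm + rng.uniform(100, 400)
            t_ilm = rng.uniform(50, 200)
            t_bm = t_ilm + rng.uniform(100, 400)
            a, b = fit_aline_affine(s_ilm, s_bm, t_ilm, t_bm)
            assert abs(a * s_ilm + b - t_ilm) < 1e-9
            assert abs(a * s_bm + b - t_bm) < 1e-9

    def test_zero_span_raises(self):
        with pytest.raises(DegenerateInputError):
            fit_aline_affine(100.0, 100.0, 100.0, 200.0)

    def test_grid_version_flags_degenerate_alines(self):
        s_ilm = np.array([[100.0, 100.0]])
        s_bm = np.array([[400.0, 100.0]])
        a, b = fit_aline_affine_grid(s_ilm, s_bm, s_ilm + 10, s_bm + 10)
        assert a[0, 0] == pytest.approx(1.0)
        assert np.isnan(a[0, 1])


class TestRegisterScan:
    def test_identity_registration_keeps_values(self, small_spec):
        maps, bounds = make_template(small_spec)
        target = template_target(small_spec)
        registered, tr = register_scan(maps, bounds, target)
        assert tr.translation == (0, 0)
        for layer in maps:
            np.testing.assert_array_equal(registered[layer].values,
                                          maps[layer].values)
            assert registered[layer].registered

    @pytest.mark.parametrize("jitter", [(0, 0), (2, 4), (-3, 5), (5, -5),
                                        (-5, -5), (1, 0)])
    def test_known_shift_recovered_exactly_noise_free(self, small_spec,
                                                      jitter):
        target = template_target(small_spec)
        scan = sample_subject(small_spec, jitter=jitter, noise_sd_um=0.0)
        registered, tr = register_scan(scan.maps, scan.boundaries, target)
        assert tr.translation == (-jitter[0], -jitter[1])
        # values at mutually valid voxels equal the template exactly
        template_maps, _ = make_template(small_spec)
        got = registered["GCIPL"].values
        want = template_maps["GCIPL"].values
        both = np.isfinite(got) & np.isfinite(want)
        np.testing.assert_allclose(got[both], want[both], atol=1e-9)

    def test_shared_translation_across_layers(self, small_spec):
        target = template_target(small_spec)
        scan = sample_subject(small_spec, jitter=(1, 3), seed=5)
        registered, tr = register_scan(scan.maps, scan.boundaries, target)
        assert len({m.values.shape for m in registered.values()}) == 1
        assert tr.translation == (-1, -3)

    def test_requires_left_normalized_maps(self, small_spec):
        maps, bounds = make_template(small_spec)
        target = template_target(small_spec)
        bad = {k: m.copy_with(laterality="OD") for k, m in maps.items()}
        with pytest.raises(LateralityError):
            register_scan(bad, bounds, target)

    def test_affine_anchors_exact_on_registered_scan(self, small_spec):
        target = template_target(small_spec)
        scan = sample_subject(small_spec, jitter=(2, -3), seed=3)
        _, tr = register_scan(scan.maps, scan.boundaries, target)
        ilm_t = apply_translation(scan.boundaries.surfaces["ILM"],
                                  tr.translation)
        bm_t = apply_translation(scan.boundaries.surfaces["BM"],
                                 tr.translation)
        res_ilm = np.nanmax(np.abs(tr.scale * ilm_t + tr.offset
                                   - target.ilm_depth))
        res_bm = np.nanmax(np.abs(tr.scale * bm_t + tr.offset
                                  - target.bm_depth))
        assert res_ilm < 1e-9
        assert res_bm < 1e-9

    def test_cohort_of_identical_maps_order_invariant(self, small_spec):
        target = template_target(small_spec)
        scans = [sample_subject(small_spec, jitter=(0, 0), noise_sd_um=0.0)
                 for _ in range(4)]
        means = []
        for order in ([0, 1, 2, 3], [3, 1, 0, 2]):
            regs = [register_scan(scans[i].maps, scans[i].boundaries,
                                  target)[0]["Retina"].values
                    for i in order]
            means.append(np.nanmean(regs, axis=0))
        np.testing.assert_array_equal(means[0], means[1])

    def test_rescale_thickness_mode_scales_by_affine(self, small_spec):
        target = template_target(small_spec)
        scan = sample_subject(small_spec, jitter=(0, 0), noise_sd_um=0.0)
        reg_off, tr = register_scan(scan.maps, scan.boundaries, target,
                                    rescale_thickness=False)
        reg_on, _ = register_scan(scan.maps, scan.boundaries, target,
                                  rescale_thickness=True)
        both = np.isfinite(reg_off["Retina"].values) & np.isfinite(tr.scale)
        np.testing.assert_allclose(
            reg_on["Retina"].values[both],
            (reg_off["Retina"].values * tr.scale)[both], rtol=1e-9)


class TestMeanTemplate:
    def test_mean_template_recenters_on_average(self, small_spec, rng):
        scans = []
        for i in range(5):
            s = sample_subject(small_spec,
                               jitter=(int(rng.integers(-2, 3)),
                                       int(rng.integers(-4, 5))),
                               rng=rng)
            scans.append((s.maps, s.boundaries))
        target = build_mean_template(scans)
        assert target.source == "cohort-mean-template"
        assert target.ilm_depth is not None
        # a fresh subject registers onto it with a small translation
        s = sample_subject(small_spec, jitter=(0, 0), rng=rng)
        _, tr = register_scan(s.maps, s.boundaries, target)
        assert abs(tr.translation[0]) <= 2
        assert abs(tr.translation[1]) <= 4
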