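import numpy as np
import pytest
from shapely.geometry import Point

from endomosaic.geometry import FieldRect
from endomosaic.synthesis import (
    FoldSpec,
    GeneratorConfig,
    Illumination,
    SessionSeries,
    generate_centers,
    generate_mosaic,
    ground_truth_flags,
    hex_spacing,
    plan_fields,
    render_hoechst,
    render_specular,
    simulate_series,
    snap_field,
)

SMALL_FIELD = snap_field(320, 256)  # ~234 x 187 µm, keeps rendering cheap


class TestGeneratorConfig:
    def test_spacing_formula(self):
        # density of a triangular lattice with spacing s is 2/(sqrt(3) s^2)
        s = hex_spacing(2500.0)
        assert 2.0 / (np.sqrt(3) * s**2) * 1e6 == pytest.approx(2500.0)
        assert s == pytest.approx(21.49, abs=0.01)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"target_ecd": 0},
            {"jitter_sigma": -1},
            {"indistinct_fraction": 1.5},
            {"noise_sigma": -2},
            {"nucleus_radius": 0},
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            GeneratorConfig(**kwargs)

    def test_vignette_bounds(self):
        with pytest.raises(ValueError):
            Illumination(vignette_strength=1.5)


class TestGenerateMosaic:
    def test_realized_count_near_target(self):
        cfg = GeneratorConfig(target_ecd=2500, jitter_sigma=2, seed=0)
        centers = generate_centers(cfg)
        expected = 2500 * 0.69938  # ≈ 1749
        assert abs(len(centers) - expected) / expected < 0.05

    @pytest.mark.parametrize("target", [1800, 2300, 3000])
    def test_density_control_across_seeds(self, target):
        field = FieldRect()
        for seed in range(5):
            cfg = GeneratorConfig(target_ecd=target, jitter_sigma=2, seed=seed)
            realized = len(generate_centers(cfg)) / field.area_mm2
            assert abs(realized - target) / target < 0.05

    def test_zero_jitter_interior_cells_have_six_neighbors(self):
        cfg = GeneratorConfig(target_ecd=2500, jitter_sigma=0.0, seed=3, field=SMALL_FIELD)
        mosaic, _ = generate_mosaic(cfg)
        interior = mosaic.interior_mask()
        assert interior.sum() > 20
        for i in np.nonzero(interior)[0]:
            assert len(mosaic.adjacency[i]) == 6

    def test_determinism(self):
        cfg = GeneratorConfig(target_ecd=2500, jitter_sigma=3, seed=42, field=SMALL_FIELD)
        m1, g1 = generate_mosaic(cfg)
        m2, g2 = generate_mosaic(cfg)
        np.testing.assert_array_equal(m1.centers, m2.centers)
        np.testing.assert_array_equal(g1.nuclei_px, g2.nuclei_px)

    def test_too_low_density_errors(self):
        with pytest.raises(ValueError, match="too low"):
            generate_centers(GeneratorConfig(target_ecd=1.0, field=FieldRect(100, 80)))

    def test_true_ecd_recorded(self):
        cfg = GeneratorConfig(target_ecd=2200, seed=1, field=SMALL_FIELD)
        mosaic, _ = generate_mosaic(cfg)
        assert mosaic.true_ecd == pytest.approx(mosaic.n_cells / SMALL_FIELD.area_mm2)

    def test_nuclei_inside_their_polygons(self):
        cfg = GeneratorConfig(target_ecd=2500, jitter_sigma=2, seed=6, field=SMALL_FIELD)
        mosaic, gt = generate_mosaic(cfg)
        nuclei = gt.nuclei_um()
        for i, poly in enumerate(mosaic.shapely_polygons()):
            assert poly.contains(Point(*nuclei[i]))


class TestPlanFields:
    def test_default_layout_disjoint_and_inside_disc(self):
        placements = plan_fields()
        assert len(placements) == 5
        assert placements[0].label == "center"
        polys = [p.polygon() for p in placements]
        for i in range(5):
            for j in range(i + 1, 5):
                assert polys[i].intersection(polys[j]).area == 0.0
        for p in placements:
            x0, y0, x1, y1 = p.bounds
            for cx, cy in ((x0, y0), (x1, y0), (x0, y1), (x1, y1)):
                assert np.hypot(cx, cy) <= 4000.0

    def test_small_disc_errors(self):
        with pytest.raises(ValueError, match="too large"):
            plan_fields(disc_diameter_mm=2.0)

    def test_tiny_field_fits_with_positive_separation(self):
        placements = plan_fields(field=FieldRect(1.0, 1.0))
        centers = np.array([(p.cx, p.cy) for p in placements])
        for i in range(5):
            for j in range(i + 1, 5):
                assert np.hypot(*(centers[i] - centers[j])) > 0


class TestRenderSpecular:
    def test_borders_darker_than_interiors(self):
        cfg = GeneratorConfig(
            target_ecd=2500,
            jitter_sigma=2,
            seed=5,
            field=SMALL_FIELD,
            noise_sigma=0.0,
            illumination=Illumination(vignette_strength=0.0),
        )
        mosaic, gt = generate_mosaic(cfg)
        img, _ = render_specular(mosaic, gt, cfg)
        # recompute the label/border maps independently of the renderer
        from scipy.spatial import cKDTree

        u = gt.um_per_px
        nrows, ncols = img.shape
        xs = (np.arange(ncols) + 0.5) * u
        ys = (np.arange(nrows) + 0.5) * u
        X, Y = np.meshgrid(xs, ys)
        label = (
            cKDTree(mosaic.centers)
            .query(np.column_stack([X.ravel(), Y.ravel()]))[1]
            .reshape(nrows, ncols)
        )
        border = np.zeros_like(label, dtype=bool)
        border[1:, :] |= label[1:, :] != label[:-1, :]
        border[:, 1:] |= label[:, 1:] != label[:, :-1]
        assert img[border].mean() < img[~border].mean() - 20

    def test_determinism_byte_identical(self):
        cfg = GeneratorConfig(
            target_ecd=2500, jitter_sigma=2, seed=9, field=SMALL_FIELD,
            folds=FoldSpec(n_bands=1, band_width=15.0), indistinct_fraction=0.1,
        )
        mosaic, gt = generate_mosaic(cfg)
        img1, gt1 = render_specular(mosaic, gt, cfg)
        img2, gt2 = render_specular(mosaic, gt, cfg)
        assert np.array_equal(img1, img2)
        np.testing.assert_array_equal(gt1.visible, gt2.visible)

    def test_fold_coverage_matches_invisible_fraction(self):
        field = FieldRect()
        fractions = []
        for seed in range(20):
            cfg = GeneratorConfig(
                target_ecd=2500,
                jitter_sigma=2,
                seed=seed,
                field=field,
                folds=FoldSpec(n_bands=3, band_width=0.1 * field.height / 1.0),
            )
            centers = generate_centers(cfg)
            from endomosaic.geometry import Mosaic

            mosaic = Mosaic(field=field, centers=centers, polygons=[], adjacency=[])
            visible, _, _ = ground_truth_flags(
                Mosaic(field=field, centers=centers, polygons=[], adjacency=[]), cfg
            )
            fractions.append(1.0 - visible.mean())
        assert np.mean(fractions) == pytest.approx(0.30, abs=0.05)

    def test_visibility_flag_matches_band_membership_exactly(self):
        cfg = GeneratorConfig(
            target_ecd=2500, jitter_sigma=2, seed=13, field=SMALL_FIELD,
            folds=FoldSpec(n_bands=2, band_width=20.0),
        )
        mosaic, gt = generate_mosaic(cfg)
        img, gt2 = render_specular(mosaic, gt, cfg)
        visible, _, bands = ground_truth_flags(mosaic, cfg)
        np.testing.assert_array_equal(gt2.visible, visible)
        # horizontal bands: u coordinate is y
        under = np.zeros(mosaic.n_cells, dtype=bool)
        for lo, hi in bands:
            under |= (mosaic.centers[:, 1] >= lo) & (mosaic.centers[:, 1] <= hi)
        np.testing.assert_array_equal(gt2.visible, ~under)

    def test_indistinct_cells_flagged(self):
        cfg = GeneratorConfig(
            target_ecd=2500, jitter_sigma=2, seed=14, field=SMALL_FIELD,
            indistinct_fraction=0.2,
        )
        mosaic, gt = generate_mosaic(cfg)
        _, distinct, _ = ground_truth_flags(mosaic, cfg)
        frac = 1.0 - distinct.mean()
        assert frac == pytest.approx(0.2, abs=0.02)

    def test_anisotropic_field_rejected(self):
        cfg = GeneratorConfig(target_ecd=2500, seed=1, field=FieldRect(233.0, 187.0))
        mosaic, gt = generate_mosaic(cfg)
        with pytest.raises(ValueError, match="pixel pitch"):
            render_specular(mosaic, gt, cfg)


class TestRenderHoechst:
    def test_one_blob_per_cell_and_determinism(self):
        cfg = GeneratorConfig(target_ecd=2200, jitter_sigma=2, seed=21, field=SMALL_FIELD)
        mosaic, gt = generate_mosaic(cfg)
        img1, nuclei1 = render_hoechst(mosaic, cfg, gt.nuclei_um())
        img2, nuclei2 = render_hoechst(mosaic, cfg, gt.nuclei_um())
        assert np.array_equal(img1, img2)
        np.testing.assert_array_equal(nuclei1, nuclei2)
        assert len(nuclei1) == mosaic.n_cells

    def test_peak_to_background_contrast(self):
        cfg = GeneratorConfig(target_ecd=2200, jitter_sigma=2, seed=22, field=SMALL_FIELD)
        mosaic, gt = generate_mosaic(cfg)
        img, _ = render_hoechst(mosaic, cfg, gt.nuclei_um())
        background = np.median(img)
        assert img.max() - background >= 5 * cfg.noise_sigma


class TestSimulateSeries:
    def _mosaic(self, seed=30, field=SMALL_FIELD):
        cfg = GeneratorConfig(target_ecd=2500, jitter_sigma=2, seed=seed, field=field)
        return generate_mosaic(cfg)

    def test_zero_loss_keeps_centers(self):
        mosaic, gt = self._mosaic()
        series = SessionSeries(days=(2, 26, 28), loss_fractions=(0.0, 0.0, 0.0))
        out = simulate_series(mosaic, series, seed=1, ground_truth0=gt)
        for m, _ in out:
            np.testing.assert_array_equal(m.centers, mosaic.centers)

    def test_binomial_expectation(self):
        cfg = GeneratorConfig(target_ecd=2500, jitter_sigma=2, seed=31)
        mosaic, gt = generate_mosaic(cfg)  # ~1740 cells
        n0 = mosaic.n_cells
        series = SessionSeries(days=(2, 26), loss_fractions=(0.1, 0.1))
        out = simulate_series(mosaic, series, seed=2, ground_truth0=gt)
        expected = n0 * 0.9 * 0.9
        sd = np.sqrt(n0 * 0.81 * (1 - 0.81))
        assert abs(out[-1][0].n_cells - expected) <= 3 * sd

    def test_retessellated_tiling(self):
        mosaic, gt = self._mosaic(seed=32)
        series = SessionSeries(days=(2, 26), loss_fractions=(0.2, 0.2))
        out = simulate_series(mosaic, series, seed=3, ground_truth0=gt)
        for m, _ in out:
            rel = abs(m.polygon_areas().sum() - m.field.area_um2) / m.field.area_um2
            assert rel < 1e-6

    def test_nuclei_stay_inside_enlarged_cells(self):
        mosaic, gt = self._mosaic(seed=33)
        series = SessionSeries(days=(2, 26), loss_fractions=(0.3, 0.0))
        out = simulate_series(mosaic, series, seed=4, ground_truth0=gt)
        m, g = out[-1]
        nuclei = g.nuclei_um()
        for i, poly in enumerate(m.shapely_polygons()):
            assert poly.contains(Point(*nuclei[i]))

    def test_excessive_loss_errors(self):
        mosaic, gt = self._mosaic(seed=34)
        series = SessionSeries(days=(2,), loss_fractions=(0.999,))
        with pytest.raises(ValueError, match="at least 3"):
            simulate_series(mosaic, series, seed=5, ground_truth0=gt)

    def test_series_validation(self):
        with pytest.raises(ValueError):
            SessionSeries(days=(5, 2), loss_fractions=(0.0, 0.0))
        with pytest.raises(ValueError):
            SessionSeries(days=(2, 5), loss_fractions=(0.0,))
        with pytest.raises(ValueError):
            SessionSeries(days=(2, 5), loss_fractions=(0.0, 1.0))
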