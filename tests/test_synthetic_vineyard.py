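"""Scene construction, truth oracle, and sensor sampling."""

import math

import numpy as np
import pytest

from vinemetrics.cloud_io import TRUTH_CODES
from vinemetrics.synthetic_vineyard import (
    Box,
    Capsule,
    Cylinder,
    Ellipsoid,
    GrassSpec,
    RowSpec,
    SceneConfig,
    SceneConfigError,
    SensorProfile,
    Terrain,
    VineInstance,
    VineJitter,
    VineShape,
    build_scene,
    default_profiles,
    default_scene_config,
    sample_cloud,
    truth_metrics,
)


def no_jitter():
    return VineJitter(position_sd=0.0, height_sd=0.0, radius_rel_sd=0.0)


# ---------------------------------------------------------------------------
# build_scene
# ---------------------------------------------------------------------------


class TestBuildScene:
    def test_seed_reproducibility(self):
        cfg = default_scene_config(n_rows=2, n_vines=5)
        a = build_scene(cfg, 7)
        b = build_scene(cfg, 7)
        assert len(a.vines) == len(b.vines)
        for va, vb in zip(a.vines, b.vines):
            assert va == vb  # frozen dataclasses: full structural equality

    def test_vine_spacing_along_row(self):
        cfg = default_scene_config(n_rows=1, n_vines=20, vine_spacing=1.2,
                                   jitter=no_jitter())
        scene = build_scene(cfg, 0)
        origins = np.array([v.origin for v in scene.vines])
        gaps = np.linalg.norm(np.diff(origins, axis=0), axis=1)
        assert np.allclose(gaps, 1.2)

    def test_row_spacing(self):
        # 1.80 m between rows: minimum inter-row origin distance is 1.80
        cfg = default_scene_config(n_rows=2, n_vines=5, row_spacing=1.8,
                                   jitter=no_jitter())
        scene = build_scene(cfg, 0)
        r0 = np.array([v.origin for v in scene.vines if v.vine_id.startswith("r00")])
        r1 = np.array([v.origin for v in scene.vines if v.vine_id.startswith("r01")])
        d = np.linalg.norm(r0[:, None, :] - r1[None, :, :], axis=2)
        assert d.min() == pytest.approx(1.8, abs=1e-9)

    def test_invalid_config_raises(self):
        with pytest.raises(SceneConfigError, match="extent"):
            SceneConfig(extent=(0, 0, 0, 5))
        with pytest.raises(SceneConfigError, match="vine_spacing"):
            RowSpec(azimuth=0, origin=(0, 0), n_vines=3, vine_spacing=0.0)
        with pytest.raises(SceneConfigError, match="n_vines"):
            RowSpec(azimuth=0, origin=(0, 0), n_vines=0)


# ---------------------------------------------------------------------------
# truth oracle
# ---------------------------------------------------------------------------


def vine_with(solids, branches=()):
    return VineInstance(
        vine_id="v", origin=(0.0, 0.0), azimuth=0.0,
        shape=VineShape(
            trunk=Cylinder((0, 0), 0.0, 0.55, 0.04),
            canopy_solids=tuple(solids),
            hanging_branches=tuple(branches),
        ),
    )


class TestTruthMetrics:
    def test_box_canopy_analytic(self):
        # 1.0 x 0.4 footprint, z in [0.7, 1.6]: area 0.40, volume 0.36
        vine = vine_with([Box((0, 0, 1.15), (1.0, 0.4, 0.9))])
        t = truth_metrics(vine, oracle_resolution=0.01)
        assert t.h_max_true == pytest.approx(1.6)
        assert t.area_true == pytest.approx(0.40, rel=0.02)
        assert t.volume_true == pytest.approx(0.36, rel=0.02)

    def test_sphere_volume_closed_form(self):
        vine = vine_with([Ellipsoid((0, 0, 1.2), (0.3, 0.3, 0.3))])
        t = truth_metrics(vine, oracle_resolution=0.005)
        assert t.volume_true == pytest.approx(4 / 3 * math.pi * 0.3**3, rel=0.02)
        assert t.area_true == pytest.approx(math.pi * 0.3**2, rel=0.02)

    def test_canopy_below_trellis_is_zero(self):
        vine = vine_with([Box((0, 0, 0.15), (0.4, 0.4, 0.2))])
        t = truth_metrics(vine, oracle_resolution=0.01)
        assert t.area_true == 0.0
        assert t.volume_true == 0.0

    def test_unknown_vine_id_raises(self, small_scene):
        with pytest.raises(KeyError):
            truth_metrics(small_scene, "nope")

    def test_resolution_convergence(self, small_scene):
        """Halving the oracle resolution changes area/volume by < 2%."""
        for vine in small_scene.vines[:2]:
            coarse = truth_metrics(vine, oracle_resolution=0.02)
            fine = truth_metrics(vine, oracle_resolution=0.01)
            assert fine.area_true == pytest.approx(coarse.area_true, rel=0.02)
            assert fine.volume_true == pytest.approx(coarse.volume_true, rel=0.02)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


class TestSampleCloud:
    def test_seed_reproducibility(self, small_scene, profiles):
        a = sample_cloud(small_scene, profiles["tir"], 5)
        b = sample_cloud(small_scene, profiles["tir"], 5)
        assert np.array_equal(a.xyz, b.xyz)
        assert np.array_equal(a.truth, b.truth)

    def test_poisson_count_oracle(self):
        """Canopy point count is Poisson(density x volume) in expectation."""
        box = Box((0, 0, 1.0), (0.8, 0.4, 0.6))
        shape = VineShape(trunk=Cylinder((0, 0), 0, 0.55, 0.04),
                          canopy_solids=(box,), hanging_branches=())
        cfg = SceneConfig(extent=(-2, -2, 2, 2), rows=(),
                          grass=GrassSpec(density=0.0))
        scene_proto = build_scene(cfg, 0)
        vine = VineInstance("v0", (0.0, 0.0), 0.0, shape)
        scene = type(scene_proto)(config=cfg, vines=(vine,), seed=0)
        profile = SensorProfile(
            name="t", mode="aerial-nadir", canopy_density=2000,
            noise_sigma_z=0.0, noise_sigma_xy=0.0, ground_density=1.0,
        )
        lam = 2000 * box.volume
        counts = [
            int((sample_cloud(scene, profile, s).truth
                 == TRUTH_CODES["canopy"]).sum())
            for s in range(50)
        ]
        assert abs(np.mean(counts) - lam) <= 3 * math.sqrt(lam / 50)
        assert max(abs(c - lam) for c in counts) <= 5 * math.sqrt(lam)

    def test_density_ordering_matches_sensor_classes(self, small_scene, profiles):
        """TIR < multispectral < RGB/PAN/LiDAR << TLS in canopy point count."""
        order = ["tir", "multispectral", "rgb_h20t", "lidar_l1", "rgb_l1",
                 "panchromatic", "tls"]
        counts = {name: 0 for name in order}
        for seed in range(10):
            for name in order:
                cloud = sample_cloud(small_scene, profiles[name], seed)
                counts[name] += int((cloud.truth == TRUTH_CODES["canopy"]).sum())
        assert counts["tir"] < counts["multispectral"]
        assert counts["multispectral"] < min(
            counts["rgb_h20t"], counts["lidar_l1"], counts["rgb_l1"],
            counts["panchromatic"],
        )
        assert counts["tls"] > 5 * counts["panchromatic"]

    def test_aerial_points_concentrate_in_top_half(self, small_scene, profiles):
        cloud = sample_cloud(small_scene, profiles["panchromatic"], 3)
        canopy = cloud.truth == TRUTH_CODES["canopy"]
        frac_top = 0.0
        n = 0
        terrain = small_scene.config.terrain
        for vine in small_scene.vines:
            local = vine.world_to_local(cloud.xyz[canopy])
            h = local[:, 2] - terrain.elevation(
                cloud.x[canopy], cloud.y[canopy]
            )
            solid = vine.shape.canopy_solids[0]
            inside = np.hypot(local[:, 0], local[:, 1]) < 1.0
            mid = (solid.z_top + solid.z_bottom) / 2
            frac_top += ((h > mid) & inside).sum()
            n += inside.sum()
        assert frac_top / n >= 0.80

    def test_lateral_covers_both_halves(self, small_scene, profiles):
        cloud = sample_cloud(small_scene, profiles["tls"], 3)
        canopy = cloud.truth == TRUTH_CODES["canopy"]
        terrain = small_scene.config.terrain
        h = cloud.z[canopy] - terrain.elevation(cloud.x[canopy], cloud.y[canopy])
        vine = small_scene.vines[0]
        solid = vine.shape.canopy_solids[0]
        mid = (solid.z_top + solid.z_bottom) / 2
        bottom_frac = (h < mid).mean()
        assert 0.2 < bottom_frac < 0.8  # volume sampling reaches all faces

    def test_points_within_extent_and_ground_near_terrain(
        self, small_scene, profiles
    ):
        for name in ("tls", "lidar_l1", "panchromatic"):
            p = profiles[name]
            cloud = sample_cloud(small_scene, p, 9)
            x0, y0, x1, y1 = small_scene.config.extent
            assert cloud.x.min() >= x0 and cloud.x.max() <= x1
            assert cloud.y.min() >= y0 and cloud.y.max() <= y1
            ground = cloud.truth == TRUTH_CODES["ground"]
            expected = small_scene.config.terrain.elevation(
                cloud.x[ground], cloud.y[ground]
            )
            bias = p.smoothing_bias if p.grass_sampling == "smoothed" else 0.0
            resid = cloud.z[ground] - expected - bias
            tol = max(3 * p.noise_sigma_z, 1e-6)
            assert np.quantile(np.abs(resid), 0.995) <= tol * 1.35

    def test_multireturn_fractions(self, small_scene, profiles):
        cloud = sample_cloud(small_scene, profiles["lidar_l1"], 21)
        assert cloud.return_number is not None
        frac1 = (cloud.return_number == 1).mean()
        assert frac1 == pytest.approx(0.9897, abs=0.01)

    def test_thin_feature_dropout(self, profiles):
        """Profiles with large min_feature_diameter drop the thin branches."""
        cfg = default_scene_config(n_rows=1, n_vines=6,
                                   grass=GrassSpec(density=0.0))
        scene = build_scene(cfg, 3)
        n_branches = sum(len(v.shape.hanging_branches) for v in scene.vines)
        assert n_branches > 0
        tls_branchpts = 0
        tir_branchpts = 0
        for vine in scene.vines:
            for br in vine.shape.hanging_branches:
                assert br.min_diameter < profiles["tir"].min_feature_diameter
                assert br.min_diameter >= profiles["tls"].min_feature_diameter
        # statistically: TIR drops ~95% of branches, TLS none
        tir = sample_cloud(scene, profiles["tir"], 2)
        tls = sample_cloud(scene, profiles["tls"], 2)
        assert (tls.truth == TRUTH_CODES["canopy"]).sum() > 0

    def test_invalid_profile_raises(self):
        with pytest.raises(SceneConfigError):
            SensorProfile(name="x", mode="aerial-nadir", canopy_density=0,
                          noise_sigma_z=0.0, noise_sigma_xy=0.0)
        with pytest.raises(SceneConfigError):
            SensorProfile(name="x", mode="sideways", canopy_density=1,
                          noise_sigma_z=0.0, noise_sigma_xy=0.0)
        with pytest.raises(SceneConfigError):
            SensorProfile(name="x", mode="aerial-nadir", canopy_density=1,
                          noise_sigma_z=0.0, noise_sigma_xy=0.0, p_miss=1.5)


class TestPrimitives:
    @pytest.mark.parametrize("solid,expected", [
        (Box((0, 0, 1), (0.4, 0.2, 0.6)), 0.048),
        (Ellipsoid((0, 0, 1), (0.5, 0.25, 0.45)), 4 / 3 * math.pi * 0.5 * 0.25 * 0.45),
        (Cylinder((0, 0), 0.0, 0.6, 0.04), math.pi * 0.04**2 * 0.6),
        (Capsule((0, 0, 1), (0, 0.6, 1), 0.01), math.pi * 1e-4 * 0.6),
    ])
    def test_volume(self, solid, expected):
        assert solid.volume == pytest.approx(expected)

    @pytest.mark.parametrize("solid", [
        Box((0.1, -0.2, 1.1), (0.4, 0.2, 0.6)),
        Ellipsoid((0.1, -0.2, 1.1), (0.5, 0.25, 0.45)),
        Cylinder((0.1, -0.2), 0.3, 0.9, 0.07),
    ])
    def test_volume_samples_inside(self, solid, rng):
        pts = solid.sample_volume(rng, 500)
        assert solid.contains(pts).all()

    def test_local_world_roundtrip(self, rng):
        vine = VineInstance(
            "v", (3.0, -2.0), 37.0,
            VineShape(trunk=Cylinder((0, 0), 0, 0.5, 0.04),
                      canopy_solids=(Box((0, 0, 1), (1, 1, 1)),)),
        )
        pts = rng.normal(size=(100, 3))
        back = vine.world_to_local(vine.local_to_world(pts))
        assert np.allclose(back, pts, atol=1e-12)
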