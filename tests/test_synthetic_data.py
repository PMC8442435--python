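import numpy as np
import pytest

from mhcfish import allele_analysis as aa
from mhcfish import synthetic_data as sd
from mhcfish.io_model import CHANNELS, Spot, physical_to_voxel


class TestConfigValidation:
    def test_oversized_zone_rejected_by_name(self):
        # the template is re-centered on its centroid, so the reported
        # offender is whichever sphere then reaches farthest
        with pytest.raises(sd.ConfigError, match="survival zone '[rgb]'"):
            sd.SimulationConfig(
                sz_centers={"r": (0, 0, 0), "g": (3.5, 0, 0), "b": (0.5, 0.6, 0)},
                seed=0,
            )

    def test_bad_fraction(self):
        with pytest.raises(sd.ConfigError):
            sd.SimulationConfig(frac_decompacted=1.5, seed=0)

    def test_bad_voxel(self):
        with pytest.raises(sd.ConfigError):
            sd.SimulationConfig(voxel_size=(0.079, -1, 0.244), seed=0)


class TestSimulatePopulation:
    def test_population_shape(self, resting_population, base_config):
        records, truth = resting_population
        assert len(records) == base_config.n_nuclei
        assert sum(len(r.spots) for r in records) == 6 * base_config.n_nuclei
        for rec in records:
            by_ch = rec.spots_by_channel()
            assert all(len(by_ch[ch]) == 2 for ch in CHANNELS)
        assert len(truth.nuclei) == base_config.n_nuclei
        assert all(len(n["alleles"]) == 2 for n in truth.nuclei)

    def test_deterministic_under_fixed_seed(self, base_config, resting_population):
        records, _ = resting_population
        again, _ = sd.simulate_population(base_config, "resting")
        for a, b in zip(records, again):
            for s, t in zip(a.spots, b.spots):
                assert np.array_equal(s.position, t.position)

    def test_spots_inside_nucleus(self, resting_population, activated_population):
        for records, _ in (resting_population, activated_population):
            for rec in records:
                for s in rec.spots:
                    d = np.linalg.norm(s.position - rec.geometry.center)
                    assert d <= rec.geometry.radius + 1e-9

    def test_prefix_stable_when_population_grows(self, base_config):
        """Per-nucleus seed streams: adding nuclei never perturbs earlier ones."""
        small, _ = sd.simulate_population(base_config, "resting")
        import dataclasses
        bigger_cfg = dataclasses.replace(base_config, n_nuclei=base_config.n_nuclei + 10)
        big, _ = sd.simulate_population(bigger_cfg, "resting")
        for a, b in zip(small, big):
            for s, t in zip(a.spots, b.spots):
                assert np.array_equal(s.position, t.position)

    def test_all_compacted_when_fraction_zero_and_noiseless(self):
        cfg = sd.SimulationConfig(frac_decompacted=0.0, measurement_noise_sd=0.0,
                                  n_nuclei=25, seed=5)
        records, _ = sd.simulate_population(cfg, "resting")
        for rec in records:
            a1, a2 = aa.pair_spots(rec)
            assert aa.classify_allele(a1) == aa.COMPACTED
            assert aa.classify_allele(a2) == aa.COMPACTED

    def test_decompacted_fraction_converges(self):
        """Empirical decompacted fraction within the binomial 99% CI at n=2000."""
        cfg = sd.SimulationConfig(frac_decompacted=0.3, n_nuclei=1000, seed=7)
        _, truth = sd.simulate_population(cfg, "resting")
        drawn = [al["decompacted_drawn"] for n in truth.nuclei for al in n["alleles"]]
        n = len(drawn)  # 2000 alleles
        frac = np.mean(drawn)
        half = 2.576 * np.sqrt(0.3 * 0.7 / n)
        assert abs(frac - 0.3) < half

    def test_activation_lengthens_only_target_pair(self, base_config):
        rest, tr = sd.simulate_population(base_config, "resting")
        act, ta = sd.simulate_population(base_config, "activated")

        def mean_dist(truth, c1, c2):
            vals = []
            for nuc in truth.nuclei:
                for al in nuc["alleles"]:
                    p = {ch: np.array(v) for ch, v in al["positions"].items()}
                    vals.append(np.linalg.norm(p[c1] - p[c2]))
            return np.mean(vals)

        c1, c2 = base_config.activation_pair
        (c3,) = [ch for ch in CHANNELS if ch not in (c1, c2)]
        assert mean_dist(ta, c1, c2) > mean_dist(tr, c1, c2) + 0.5 * base_config.activation_shift
        # untouched pairs move by far less than the imposed shift
        assert abs(mean_dist(ta, c1, c3) - mean_dist(tr, c1, c3)) < 0.1 * base_config.activation_shift
        assert abs(mean_dist(ta, c2, c3) - mean_dist(tr, c2, c3)) < 0.1 * base_config.activation_shift

    def test_bad_condition(self, base_config):
        with pytest.raises(ValueError):
            sd.simulate_population(base_config, "stimulated")


@pytest.fixture(scope="module")
def tiny_config():
    return sd.SimulationConfig(n_nuclei=2, nucleus_radius_mean=2.5,
                               nucleus_radius_sd=0.05, spot_radius=0.25,
                               sz_centers={"r": (0, 0, 0), "g": (0.5, 0, 0),
                                           "b": (0.25, 0.35, 0)},
                               sz_radii={"r": 0.15, "g": 0.15, "b": 0.15},
                               activation_shift=0.2, measurement_noise_sd=0.02,
                               seed=3)


class TestRenderDetect:

    def test_single_spot_argmax_at_truth(self, tiny_config):
        rec, _ = sd.simulate_population(tiny_config, "resting")
        rec = rec[0]
        one = type(rec)(nucleus_id="n", species="pig", condition="resting",
                        geometry=rec.geometry, spots=[rec.spots[0]])
        stack, origin = sd.render_image(one, tiny_config)
        ci = CHANNELS.index(rec.spots[0].channel)
        z, y, x = np.unravel_index(np.argmax(stack[ci]), stack[ci].shape)
        vs = tiny_config.voxel_size
        expected = physical_to_voxel(rec.spots[0].position - origin, vs)
        assert abs(x - expected[0]) <= 1
        assert abs(y - expected[1]) <= 1
        assert abs(z - expected[2]) <= 1

    def test_empty_record_renders_zero(self, tiny_config):
        from mhcfish.io_model import CellRecord, NucleusGeometry
        rec = CellRecord(nucleus_id="e", species="pig", condition="resting",
                         geometry=NucleusGeometry(center=np.zeros(3), radius=2.0),
                         spots=[])
        stack, _ = sd.render_image(rec, tiny_config)
        assert np.all(stack == 0)

    def test_too_small_volume_errors(self, tiny_config):
        rec, _ = sd.simulate_population(tiny_config, "resting")
        with pytest.raises(ValueError, match="too\\s+small"):
            sd.render_image(rec[0], tiny_config, shape=(4, 4, 4))

    def test_roundtrip_centroids_within_one_voxel(self, tiny_config):
        records, _ = sd.simulate_population(tiny_config, "resting")
        rec = records[0]
        stack, origin = sd.render_image(rec, tiny_config)
        spots = sd.detect_spots(stack, tiny_config.voxel_size, threshold=0.2)
        vs = np.asarray(tiny_config.voxel_size)
        for true_spot in rec.spots:
            same = [s for s in spots if s.channel == true_spot.channel]
            err = min(
                np.max(np.abs((s.position + origin - true_spot.position) / vs))
                for s in same
            )
            assert err <= 1.0

    def test_all_zero_stack_detects_nothing(self):
        stack = np.zeros((3, 8, 8, 8), dtype=np.float32)
        assert sd.detect_spots(stack, (0.1, 0.1, 0.1), threshold=0.5) == []

    def test_two_separated_blobs_in_one_channel(self, tiny_config):
        from mhcfish.io_model import CellRecord, NucleusGeometry
        geom = NucleusGeometry(center=np.zeros(3), radius=2.0)
        rec = CellRecord(
            nucleus_id="two", species="pig", condition="resting", geometry=geom,
            spots=[
                Spot(channel="classI", position=np.array([-1.0, 0, 0]), radius=0.25),
                Spot(channel="classI", position=np.array([1.0, 0, 0]), radius=0.25),
            ])
        stack, _ = sd.render_image(rec, tiny_config)
        spots = sd.detect_spots(stack, tiny_config.voxel_size, threshold=0.3)
        assert len(spots) == 2 and all(s.channel == "classI" for s in spots)

    def test_detected_radius_tracks_blob_halfwidth(self, tiny_config):
        from mhcfish.io_model import CellRecord, NucleusGeometry
        geom = NucleusGeometry(center=np.zeros(3), radius=2.0)
        rec = CellRecord(
            nucleus_id="r", species="pig", condition="resting", geometry=geom,
            spots=[Spot(channel="classI", position=np.zeros(3), radius=0.25)])
        threshold = 0.5
        stack, _ = sd.render_image(rec, tiny_config)
        spots = sd.detect_spots(stack, tiny_config.voxel_size, threshold=threshold)
        # at threshold t the Gaussian blob's super-threshold region is a
        # ball of radius sigma * sqrt(2 ln(1/t))
        expected = tiny_config.spot_radius * np.sqrt(2 * np.log(1 / threshold))
        assert len(spots) == 1
        assert spots[0].radius == pytest.approx(expected, rel=0.25)

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            sd.detect_spots(np.zeros((3, 4, 4, 4)), (0.1, 0.1, 0.1), threshold=0.0)


class TestTiffExport:
    def test_stack_roundtrip(self, tmp_path, base_config, resting_population):
        import tifffile
        records, _ = resting_population
        stack, _ = sd.render_image(records[0], base_config)
        path = tmp_path / "stack.tiff"
        sd.write_stack_tiff(stack, path, base_config.voxel_size)
        back = tifffile.imread(path)
        assert back.shape == stack.shape
        np.testing.assert_array_equal(back, stack)
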