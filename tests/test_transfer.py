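import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbisim import colorspace as cs
from nbisim import fixtures as fx
from nbisim import transfer as tr
from oracles import two_pass_channel_stats


def lab_image(values):
    return np.asarray(values, dtype=np.float64)


class TestComputeStats:
    def test_constant_image(self):
        img = np.tile([0.3, -0.1, 0.7], (4, 5, 1))
        stats = tr.compute_stats(img)
        np.testing.assert_allclose(stats.mean, [0.3, -0.1, 0.7], atol=1e-12)
        np.testing.assert_allclose(stats.std, 0.0, atol=1e-12)
        assert stats.n_pixels == 20

    def test_two_pixel_population_std(self):
        img = lab_image([[[0, 0, 0], [2, 2, 2]]])
        stats = tr.compute_stats(img)
        np.testing.assert_allclose(stats.mean, 1.0)
        np.testing.assert_allclose(stats.std, 1.0)  # population, not sample

    def test_matches_two_pass_oracle(self, rng):
        img = rng.normal(size=(16, 16, 3))
        stats = tr.compute_stats(img)
        mean, std = two_pass_channel_stats(img)
        np.testing.assert_allclose(stats.mean, mean, atol=1e-12)
        np.testing.assert_allclose(stats.std, std, atol=1e-12)

    def test_mask_restricts_pixels(self, rng):
        img = rng.normal(size=(6, 6, 3))
        mask = np.zeros((6, 6), dtype=bool)
        mask[:2, :3] = True
        stats = tr.compute_stats(img, mask)
        mean, std = two_pass_channel_stats(img[mask])
        np.testing.assert_allclose(stats.mean, mean, atol=1e-12)
        np.testing.assert_allclose(stats.std, std, atol=1e-12)
        assert stats.n_pixels == 6

    def test_degenerate_mask_rejected(self, rng):
        img = rng.normal(size=(4, 4, 3))
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True
        with pytest.raises(ValueError):
            tr.compute_stats(img, mask)
        with pytest.raises(ValueError):
            tr.compute_stats(img, np.ones((3, 3), dtype=bool))


class TestTransferStatistics:
    def test_identity_when_target_equals_source(self, rng):
        img = rng.normal(size=(8, 8, 3))
        stats = tr.compute_stats(img)
        out = tr.transfer_statistics(img, stats, stats)
        np.testing.assert_allclose(out, img, atol=1e-12)

    def test_affine_map_closed_form(self):
        img = lab_image([[[-1, -1, -1], [1, 1, 1]]])
        src = tr.compute_stats(img)  # mean 0, std 1 on each axis
        tgt = tr.ChannelStats(mean=[5, 5, 5], std=[2, 2, 2], n_pixels=2)
        out = tr.transfer_statistics(img, src, tgt)
        np.testing.assert_allclose(out[0, 0], [3, 3, 3], atol=1e-12)
        np.testing.assert_allclose(out[0, 1], [7, 7, 7], atol=1e-12)

    def test_constant_axis_maps_to_target_mean(self, rng):
        img = rng.normal(size=(5, 5, 3))
        img[..., 1] = 0.42  # degenerate axis
        src = tr.compute_stats(img)
        tgt = tr.ChannelStats(mean=[0.0, 9.0, 0.0], std=[1, 1, 1], n_pixels=1)
        out = tr.transfer_statistics(img, src, tgt)
        np.testing.assert_allclose(out[..., 1], 9.0, atol=1e-12)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_imposition_idempotence_and_order(self, seed):
        """Transferred stats hit the target; the map is idempotent and
        order-preserving per axis."""
        r = np.random.default_rng(seed)
        img = r.normal(loc=r.normal(scale=2, size=3), scale=r.uniform(0.2, 3, size=3),
                       size=(12, 12, 3))
        tgt = tr.ChannelStats(
            mean=r.normal(scale=2, size=3), std=r.uniform(0.1, 3, size=3), n_pixels=1
        )
        src = tr.compute_stats(img)
        out = tr.transfer_statistics(img, src, tgt)
        got = tr.compute_stats(out)
        np.testing.assert_allclose(got.mean, tgt.mean, atol=1e-9)
        np.testing.assert_allclose(got.std, tgt.std, atol=1e-9)
        twice = tr.transfer_statistics(out, got, tgt)
        np.testing.assert_allclose(twice, out, atol=1e-9)
        for axis in range(3):
            order_in = np.argsort(img[..., axis].ravel(), kind="stable")
            order_out = np.argsort(out[..., axis].ravel(), kind="stable")
            assert np.array_equal(order_in, order_out)


class TestChannelStatsSerialization:
    def test_json_round_trip(self):
        stats = tr.ChannelStats(mean=[0.1, -0.2, 0.3], std=[1, 2, 3], n_pixels=99)
        again = tr.ChannelStats.from_json(stats.to_json())
        np.testing.assert_allclose(again.mean, stats.mean)
        np.testing.assert_allclose(again.std, stats.std)
        assert again.n_pixels == 99

    def test_schema_fields(self):
        payload = json.loads(
            tr.ChannelStats(mean=[0, 0, 0], std=[1, 1, 1], n_pixels=4).to_json()
        )
        assert payload["space"] == "lab_ruderman_log10"
        assert set(payload) == {"space", "mean", "std", "n_pixels"}

    def test_wrong_space_rejected(self):
        with pytest.raises(ValueError):
            tr.ChannelStats.from_dict(
                {"space": "cielab", "mean": [0] * 3, "std": [1] * 3, "n_pixels": 1}
            )

    def test_negative_std_rejected(self):
        with pytest.raises(ValueError):
            tr.ChannelStats(mean=[0, 0, 0], std=[1, -1, 1], n_pixels=4)


class TestPooledStats:
    def test_pooling_equals_concatenation(self, rng):
        a = rng.normal(size=(5, 4, 3))
        b = rng.normal(loc=2.0, size=(7, 3, 3))
        pooled = tr.pooled_stats([a, b])
        stacked = np.concatenate([a.reshape(-1, 3), b.reshape(-1, 3)])
        np.testing.assert_allclose(pooled.mean, stacked.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(pooled.std, stacked.std(axis=0), atol=1e-12)
        assert pooled.n_pixels == 20 + 21


class TestSimulateNbi:
    def test_self_reference_is_identity(self, random_rgb):
        sim = tr.simulate_nbi(random_rgb, random_rgb)
        np.testing.assert_allclose(sim.simulated, random_rgb, atol=1e-5)
        assert sim.clipped_fraction == 0.0

    def test_zero_std_reference_gives_constant_color(self, random_rgb):
        color = np.array([0.6, 0.3, 0.4])
        lab = cs.rgb_to_lab(color.reshape(1, 1, 3))[0, 0]
        tgt = tr.ChannelStats(mean=lab, std=[0, 0, 0], n_pixels=1)
        sim = tr.simulate_nbi(random_rgb, tgt)
        np.testing.assert_allclose(
            sim.simulated, np.broadcast_to(color, random_rgb.shape), atol=1e-6
        )

    def test_output_stats_match_reference(self):
        wli, nbi_ref = fx.generate_pair(fx.SyntheticSpec(width=160, height=120, seed=4))
        ref_stats = tr.compute_stats(cs.rgb_to_lab(nbi_ref))
        sim = tr.simulate_nbi(wli, ref_stats)
        assert sim.clipped_fraction == 0.0
        got = tr.compute_stats(cs.rgb_to_lab(sim.simulated))
        np.testing.assert_allclose(got.mean, ref_stats.mean, atol=1e-6)
        np.testing.assert_allclose(got.std, ref_stats.std, atol=1e-6)

    def test_reference_image_and_its_stats_agree(self, rng, random_rgb):
        ref = rng.uniform(0.1, 0.9, size=(10, 10, 3))
        by_image = tr.simulate_nbi(random_rgb, ref)
        by_stats = tr.simulate_nbi(random_rgb, tr.compute_stats(cs.rgb_to_lab(ref)))
        np.testing.assert_allclose(by_image.simulated, by_stats.simulated, atol=1e-12)

    def test_mask_shape_mismatch_rejected(self, random_rgb):
        with pytest.raises(ValueError):
            tr.simulate_nbi(random_rgb, random_rgb, mask=np.ones((3, 3), dtype=bool))


class TestAutoBorderMask:
    def test_black_border_excluded(self):
        img = np.full((8, 8, 3), 0.5)
        img[:2] = 0.0  # black border strip
        mask = tr.auto_border_mask(img)
        assert not mask[:2].any()
        assert mask[2:].all()
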