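"""Generator contracts: determinism, ground-truth consistency, noise behavior."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

import lc3quant as lq
from oracles import flood_fill_components


class TestNucleiChannel:
    def test_empty_spec_yields_blank_background(self):
        spec = lq.SyntheticSpec(n_nuclei=0, n_border_nuclei=0,
                                noise_model=lq.NoiseModel(kind="none"))
        raster, truth = lq.generate_nuclei_channel(spec)
        assert truth.nuclei == [] and truth.puncta == []
        assert np.all(raster == spec.background_level)

    def test_component_count_matches_flood_fill_oracle(self, clean_spec):
        spec = dataclasses.replace(clean_spec, n_nuclei=5, n_border_nuclei=0)
        raster, truth = lq.generate_nuclei_channel(spec)
        mask = raster > (spec.background_level + spec.nucleus_amplitude) / 2.0
        labels = flood_fill_components(mask)
        assert labels.max() == 5
        assert len(truth.nuclei) == 5

    def test_same_spec_same_seed_is_bit_identical(self, small_spec):
        r1, t1 = lq.generate_nuclei_channel(small_spec)
        r2, t2 = lq.generate_nuclei_channel(small_spec)
        assert np.array_equal(r1, r2)
        assert t1.nuclei == t2.nuclei

    def test_border_nuclei_are_clipped_and_flagged(self, clean_spec):
        raster, truth = lq.generate_nuclei_channel(clean_spec)
        border = [n for n in truth.nuclei if n.is_border]
        assert len(border) == clean_spec.n_border_nuclei
        h, w = clean_spec.image_shape
        for n in border:
            r, c = n.center
            assert min(r, h - 1 - r, c, w - 1 - c) < n.radius  # disc leaves the frame

    def test_impossible_placement_raises(self):
        spec = lq.SyntheticSpec(image_shape=(64, 64), n_nuclei=30, n_border_nuclei=0,
                                nucleus_radius_mean=14.0)
        with pytest.raises(lq.PlacementError, match="crowded|small"):
            lq.generate_nuclei_channel(spec)


class TestPunctaChannels:
    @pytest.mark.parametrize("fraction, check", [
        (0.0, "all_both"),
        (1.0, "green_blank"),
    ])
    def test_degenerate_fractions(self, clean_spec, fraction, check):
        spec = dataclasses.replace(clean_spec, autolysosome_fraction=fraction)
        blue, truth = lq.generate_nuclei_channel(spec)
        green, red, truth = lq.generate_puncta_channels(spec, truth)
        assert len(truth.puncta) > 0
        if check == "all_both":
            assert all(p.klass == lq.AUTOPHAGOSOME for p in truth.puncta)
            for p in truth.puncta:  # rendered in both channels
                r, c = int(round(p.center[0])), int(round(p.center[1]))
                assert green[r, c] > spec.background_level + 100
                assert red[r, c] > spec.background_level + 100
        else:
            assert all(p.klass == lq.AUTOLYSOSOME for p in truth.puncta)
            assert np.all(green == spec.background_level)

    def test_red_only_fraction_within_binomial_interval(self):
        spec = lq.SyntheticSpec(
            image_shape=(1024, 1024), n_nuclei=12, n_border_nuclei=0,
            puncta_per_cell_mean=42.0, autolysosome_fraction=0.3,
            cytoplasm_reach=110.0, seed=5,
            noise_model=lq.NoiseModel(kind="none"),
        )
        _, truth = lq.generate_image(spec)
        n = len(truth.puncta)
        assert n >= 400
        k = truth.n_autolysosome
        lo, hi = sps.binom.interval(0.99, n, 0.3)
        assert lo <= k <= hi

    def test_puncta_lie_inside_image_and_outside_nuclei(self, small_spec):
        img, truth = lq.generate_image(small_spec)
        h, w = small_spec.image_shape
        for p in truth.puncta:
            assert 0 <= p.center[0] <= h - 1 and 0 <= p.center[1] <= w - 1
            for n in truth.nuclei:
                d = np.hypot(p.center[0] - n.center[0], p.center[1] - n.center[1])
                assert d >= n.radius

    def test_class_counts_sum_to_puncta_count(self, small_spec):
        _, truth = lq.generate_image(small_spec)
        assert truth.n_autophagosome + truth.n_autolysosome == len(truth.puncta)


class TestNoise:
    @pytest.mark.parametrize("kind,levels", [
        ("gaussian", [0.0, 10.0, 40.0]),
        ("speckle", [0.0, 0.005, 0.02]),
    ])
    def test_noise_monotonicity(self, clean_spec, kind, levels):
        """More noise never decreases the raster's pixel variance."""
        variances = []
        for level in levels:
            nm = (lq.NoiseModel(kind=kind, gaussian_sd=level) if kind == "gaussian"
                  else lq.NoiseModel(kind=kind, speckle_density=level))
            spec = dataclasses.replace(clean_spec, noise_model=nm)
            raster, _ = lq.generate_nuclei_channel(spec)
            variances.append(float(raster.var()))
        assert variances == sorted(variances)

    def test_speckle_adds_isolated_max_pixels(self, clean_spec):
        spec = dataclasses.replace(
            clean_spec, noise_model=lq.NoiseModel(kind="speckle", speckle_density=0.003)
        )
        clean, _ = lq.generate_nuclei_channel(clean_spec)
        noisy, _ = lq.generate_nuclei_channel(spec)
        impulses = noisy > clean.max() + 1
        assert 0 < impulses.sum() < 0.01 * noisy.size


class TestColocalizationPair:
    @pytest.mark.parametrize("rho", [1.0, -1.0])
    def test_perfect_correlation_is_affine(self, rho):
        a, b = lq.generate_colocalization_pair((128, 128), rho, seed=3)
        r = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert r == pytest.approx(rho, abs=1e-10)

    def test_intermediate_rho_recovered(self):
        a, b = lq.generate_colocalization_pair((512, 512), 0.5, seed=9)
        r = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert r == pytest.approx(0.5, abs=0.02)


class TestDataset:
    def test_file_and_row_counts(self, tmp_path, clean_spec):
        conditions = {
            "ctrl": clean_spec,
            "treat": dataclasses.replace(clean_spec, puncta_per_cell_mean=8.0, seed=21),
        }
        truth_df, manifest_df = lq.generate_dataset(conditions, n_images=3, out_dir=tmp_path)
        assert len(manifest_df) == 6
        assert len(list(tmp_path.glob("*_b.tif"))) == 6
        assert len(list(tmp_path.glob("*.tif"))) == 18
        assert set(truth_df["image"].unique()) == set(manifest_df["name"])

    def test_doubled_puncta_rate_in_truth(self, tmp_path, clean_spec):
        base = dataclasses.replace(clean_spec, n_border_nuclei=0, puncta_per_cell_mean=5.0)
        conditions = {
            "a": base,
            "b": dataclasses.replace(base, puncta_per_cell_mean=10.0),
        }
        truth_df, _ = lq.generate_dataset(conditions, n_images=6, out_dir=tmp_path)
        puncta = truth_df[truth_df["kind"] == "punctum"]
        n_a = (puncta["condition"] == "a").sum()
        n_b = (puncta["condition"] == "b").sum()
        # Poisson 99% interval for the count ratio around 2
        lo_b, hi_b = sps.poisson.interval(0.99, 2 * n_a)
        assert lo_b <= n_b <= hi_b

    def test_rerun_is_byte_identical(self, tmp_path, clean_spec):
        conditions = {"only": clean_spec}
        lq.generate_dataset(conditions, n_images=2, out_dir=tmp_path / "run1")
        lq.generate_dataset(conditions, n_images=2, out_dir=tmp_path / "run2")
        t1 = (tmp_path / "run1" / "ground_truth.csv").read_bytes()
        t2 = (tmp_path / "run2" / "ground_truth.csv").read_bytes()
        assert t1 == t2
        b1 = (tmp_path / "run1" / "only_000_g.tif").read_bytes()
        b2 = (tmp_path / "run2" / "only_000_g.tif").read_bytes()
        assert b1 == b2
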