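"""Bouton/axon/cell detection and per-animal metric normalization."""
import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

import mesoframe as mf
from mesoframe.morphology import background_mask, skeleton_length


def puncta_image(coords, amplitude, sigma_px=1.6, shape=(64, 64),
                 bg_level=20.0, bg_sd=5.0, seed=0):
    """Gaussian puncta of a given peak amplitude on a noisy background."""
    rng = np.random.default_rng(seed)
    delta = np.zeros(shape)
    for r, c in coords:
        delta[r, c] = amplitude * 2 * np.pi * sigma_px ** 2
    green = ndimage.gaussian_filter(delta, sigma_px)
    green += bg_level + rng.normal(0, bg_sd, shape)
    return mf.SectionImage(red=np.zeros(shape), green=green, pixel_size=0.5)


def oracle_component_count(img, sigma_um=0.8, k=5.0):
    """Exhaustive threshold-and-label count on the LoG response."""
    sig_px = sigma_um / img.pixel_size
    resp = -ndimage.gaussian_laplace(img.green, sigma=sig_px)
    bg = background_mask(img.green, img.roi_mask)
    thr = resp[bg].mean() + k * resp[bg].std()
    int_thr = img.green[bg].mean() + k * img.green[bg].std()
    labels, n = ndimage.label(resp > thr)
    count = 0
    for lab in range(1, n + 1):
        if img.green[labels == lab].max() > int_thr:
            count += 1
    return count


class TestDetectBoutons:
    def test_blank_noisy_image_has_no_detections(self):
        rng = np.random.default_rng(1)
        img = mf.SectionImage(red=np.zeros((1000, 1000)),
                              green=20 + rng.normal(0, 5, (1000, 1000)),
                              pixel_size=0.5)
        _, n = mf.detect_boutons(img)
        assert n == 0

    def test_ten_bright_puncta_all_found(self):
        coords = [(r, c) for r in (10, 30, 50) for c in (10, 30, 50)]
        coords.append((50, 20))
        img = puncta_image(coords, amplitude=50.0)  # 10 x background SD
        found, n = mf.detect_boutons(img)
        assert n == 10

    def test_dim_puncta_rejected(self):
        """Puncta at only 2 x background SD fail the 5-SD rule."""
        coords = [(r, c) for r in (10, 30, 50) for c in (10, 30, 50)]
        img = puncta_image(coords, amplitude=10.0)
        _, n = mf.detect_boutons(img)
        assert n == 0

    def test_count_invariant_to_constant_offset(self):
        coords = [(16, 16), (16, 48), (48, 16), (48, 48)]
        img = puncta_image(coords, amplitude=60.0)
        shifted = mf.SectionImage(red=img.red, green=img.green + 37.0,
                                  pixel_size=img.pixel_size)
        assert mf.detect_boutons(img)[1] == mf.detect_boutons(shifted)[1] == 4

    def test_empty_roi_rejected(self):
        img = puncta_image([(16, 16)], amplitude=60.0)
        img.roi_mask = np.zeros_like(img.roi_mask)
        with pytest.raises(ValueError):
            mf.detect_boutons(img)

    def test_matches_threshold_and_label_oracle_on_small_images(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pts = rng.integers(8, 56, (5, 2))
            # enforce separation so each component holds one punctum
            keep = []
            for p in pts:
                if all(np.hypot(*(p - q)) > 12 for q in keep):
                    keep.append(p)
            img = puncta_image([tuple(p) for p in keep], amplitude=60.0,
                               seed=seed)
            assert mf.detect_boutons(img)[1] == oracle_component_count(img) \
                == len(keep)


class TestDetectAxons:
    def test_blank_image_zero_length(self):
        rng = np.random.default_rng(0)
        img = mf.SectionImage(red=20 + rng.normal(0, 5, (256, 256)),
                              pixel_size=0.5)
        _, length = mf.detect_axons(img)
        assert length == 0.0

    def test_straight_line_length(self):
        """A 200-px drawn line at 0.5 um/px measures 100 +/- 2 um."""
        rng = np.random.default_rng(2)
        mask = np.zeros((256, 256))
        mask[128, 28:228] = 1.0
        red = ndimage.gaussian_filter(mask, 1.0)
        red = red / red.max() * 40.0
        red += 20 + rng.normal(0, 5, (256, 256))
        img = mf.SectionImage(red=red, pixel_size=0.5)
        _, length = mf.detect_axons(img)
        assert length == pytest.approx(100.0, abs=2.0)

    def test_simulated_recovery_within_ten_percent(self):
        for seed in range(5):
            img, truth = mf.simulate_morphology_image(
                mf.ImageSimConfig(seed=seed))
            true_len = sum(truth.axon_polyline_lengths)
            _, length = mf.detect_axons(img)
            assert abs(length - true_len) / true_len <= 0.10

    def test_skeleton_length_step_conventions(self):
        sk = np.zeros((10, 10), bool)
        sk[5, 2:8] = True  # 5 orthogonal steps
        assert skeleton_length(sk, 1.0) == pytest.approx(5.0)
        sk2 = np.eye(6, dtype=bool)  # 5 diagonal steps
        assert skeleton_length(sk2, 1.0) == pytest.approx(5 * np.sqrt(2))


class TestCountCells:
    def _cells_image(self, n=25, seed=4):
        img, truth = mf.simulate_morphology_image(
            mf.ImageSimConfig(n_axons=0, boutons_per_100um=0.0, n_cells=n,
                              seed=seed))
        return img, truth

    def test_soma_count_recovered(self):
        img, truth = self._cells_image()
        _, n = mf.count_cells(img)
        assert abs(n - len(truth.cell_coordinates)) <= 1

    def test_blank_image_zero_cells(self):
        rng = np.random.default_rng(3)
        img = mf.SectionImage(red=20 + rng.normal(0, 5, (256, 256)),
                              pixel_size=0.5)
        assert mf.count_cells(img)[1] == 0

    def test_close_somata_merge_to_one(self):
        sig_px = 5.0 / 0.5
        delta = np.zeros((128, 128))
        mass = 60.0 * 2 * np.pi * sig_px ** 2
        delta[60, 60] = mass
        delta[60, 68] = mass  # closer than one soma radius
        red = ndimage.gaussian_filter(delta, sig_px)
        red += 20 + np.random.default_rng(0).normal(0, 5, (128, 128))
        img = mf.SectionImage(red=red, pixel_size=0.5)
        assert mf.count_cells(img)[1] == 1


class TestNormalizeMetrics:
    def _sections(self):
        rows = []
        for animal, group, boutons, axon, cells in [
            ("w1", "WT", 80, 1000.0, 10),
            ("w2", "WT", 100, 1000.0, 10),
            ("w3", "WT", 120, 1000.0, 10),
            ("m1", "MUT", 90, 1000.0, 10),
        ]:
            rows.append(dict(animal=animal, group=group, region="cortex",
                             bouton_count=boutons, axon_length_um=axon,
                             cell_count=0))
            rows.append(dict(animal=animal, group=group, region="midbrain",
                             bouton_count=0, axon_length_um=0.0,
                             cell_count=cells))
        return pd.DataFrame(rows)

    def test_density_and_percent_of_control(self):
        per_animal, summary = mf.normalize_metrics(self._sections(), "WT")
        wt = per_animal[per_animal.group == "WT"].sort_values("animal")
        assert np.allclose(wt.bouton_density, [0.08, 0.10, 0.12])
        assert np.allclose(wt.bouton_density_pct_ctrl, [80.0, 100.0, 120.0])
        assert summary.loc[summary.group == "WT",
                           "bouton_density_pct_mean"].item() \
            == pytest.approx(100.0)
        mut = per_animal[per_animal.group == "MUT"]
        assert mut.bouton_density_pct_ctrl.item() == pytest.approx(90.0)
        assert mut.axon_per_cell.item() == pytest.approx(100.0)

    def test_ratio_of_sums_across_sections(self):
        df = pd.DataFrame([
            dict(animal="a", group="G", region="cortex", bouton_count=10,
                 axon_length_um=50.0, cell_count=0),
            dict(animal="a", group="G", region="cortex", bouton_count=90,
                 axon_length_um=950.0, cell_count=0),
            dict(animal="a", group="G", region="midbrain", bouton_count=0,
                 axon_length_um=0.0, cell_count=20),
        ])
        per_animal, _ = mf.normalize_metrics(df, "G")
        assert per_animal.bouton_density.item() == pytest.approx(0.1)

    def test_zero_denominator_animal_excluded(self):
        df = self._sections()
        df.loc[(df.animal == "m1") & (df.region == "midbrain"),
               "cell_count"] = 0
        per_animal, summary = mf.normalize_metrics(df, "WT")
        assert per_animal[per_animal.animal == "m1"].excluded.item()
        assert "MUT" not in summary.group.values

    def test_doubling_boutons_and_axons_preserves_density(self):
        df = self._sections()
        doubled = df.copy()
        doubled[["bouton_count", "axon_length_um"]] *= 2
        a, _ = mf.normalize_metrics(df, "WT")
        b, _ = mf.normalize_metrics(doubled, "WT")
        assert np.allclose(a.bouton_density, b.bouton_density)
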