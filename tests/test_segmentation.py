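"""Nuclei detection, seeded propagation, cytoplasm extraction, aggregation."""

import logging

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from skimage.measure import regionprops

import flimchip as fc

from conftest import make_scene


def render_nadph_intensity(scene, irf, acq, seed=50):
    stack, _ = fc.render_flim_stack(scene, "NADPH", irf, acq, seed=seed)
    return stack.sum(axis=0).astype(float)


def synthetic_cell_image(centers, cell_r=5.0, nuc_r=2.5, shape=(40, 60),
                         cyto=150.0, nuc=50.0, bg=2.0):
    """Noise-free disc cells with dim nuclei on a dark background."""
    img = np.full(shape, bg)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cx, cy in centers:
        d = np.hypot(xx - cx, yy - cy)
        img[d <= cell_r] = cyto
    for cx, cy in centers:
        d = np.hypot(xx - cx, yy - cy)
        img[d <= nuc_r] = nuc
    return img


class TestDetectNuclei:
    def test_recovers_programmed_cell_count(self, irf, acq):
        """A 120-cell scene yields 120 ± 5 detected nuclei."""
        scene = make_scene("low", "CTL", seed=1)
        nuclei = fc.detect_nuclei(render_nadph_intensity(scene, irf, acq))
        assert abs(int(nuclei.max()) - 120) <= 5

    def test_blank_image_yields_zero_labels(self):
        assert fc.detect_nuclei(np.zeros((32, 32))).max() == 0

    def test_count_invariant_under_intensity_scaling(self, irf, acq):
        scene = make_scene("low", "CTL", seed=2, n_cells=40)
        img = render_nadph_intensity(scene, irf, acq)
        a = fc.detect_nuclei(img)
        b = fc.detect_nuclei(img * 7.3)
        assert a.max() == b.max()

    def test_detected_centroids_match_true_centers(self, irf, acq):
        scene = make_scene("low", "CTL", seed=3)
        nuclei = fc.detect_nuclei(render_nadph_intensity(scene, irf, acq))
        cents = np.array([p.centroid[::-1] for p in regionprops(nuclei)])
        true = np.array([c.center_xy for c in scene.cells])
        d = cdist(true, cents).min(axis=1)
        matched = (d <= scene.cells[0].cell_radius_px).mean()
        assert matched >= 0.9


class TestPropagateCells:
    def test_two_nuclei_partition_shared_disc(self):
        img = synthetic_cell_image([(25, 20), (32, 20)], cell_r=8.0, nuc_r=2.5)
        nuclei = fc.detect_nuclei(img)
        assert nuclei.max() == 2
        cells = fc.propagate_cells(nuclei, img)
        assert cells.max() == 2
        a, b = (cells == 1), (cells == 2)
        assert a.any() and b.any()
        assert not (a & b).any()
        # the two regions share a boundary
        from scipy.ndimage import binary_dilation

        assert (binary_dilation(a) & b).any()

    def test_each_cell_contains_its_seed_nucleus(self, irf, acq):
        scene = make_scene("low", "CTL", seed=4, n_cells=30)
        img = render_nadph_intensity(scene, irf, acq)
        nuclei = fc.detect_nuclei(img)
        cells = fc.propagate_cells(nuclei, img)
        for label in range(1, nuclei.max() + 1):
            sel = nuclei == label
            assert np.all(cells[sel] == label)

    def test_isolated_disc_recovered_with_high_jaccard(self):
        img = synthetic_cell_image([(30, 20)], cell_r=7.0, nuc_r=3.0)
        nuclei = fc.detect_nuclei(img)
        cells = fc.propagate_cells(nuclei, img)
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        truth = np.hypot(xx - 30, yy - 20) <= 7.0
        pred = cells == 1
        jaccard = (truth & pred).sum() / (truth | pred).sum()
        assert jaccard >= 0.8

    def test_propagation_confined_to_foreground(self):
        from skimage.filters import gaussian, threshold_otsu
        from scipy.ndimage import binary_fill_holes

        img = synthetic_cell_image([(20, 20), (45, 20)], cell_r=6.0, nuc_r=2.5)
        nuclei = fc.detect_nuclei(img)
        cells = fc.propagate_cells(nuclei, img)
        opts = fc.SegmentationOptions()
        sm = gaussian(img, opts.smooth_sigma, preserve_range=True)
        mask = binary_fill_holes(sm > threshold_otsu(sm))
        assert not ((cells > 0) & ~mask & (nuclei == 0)).any()


class TestExtractCytoplasm:
    def test_disjoint_and_conserving(self, irf, acq):
        scene = make_scene("low", "CTL", seed=5, n_cells=25)
        img = render_nadph_intensity(scene, irf, acq)
        maps = fc.segment(img)
        assert not ((maps.cytoplasm > 0) & (maps.nuclei > 0)).any()
        for label in range(1, maps.cells.max() + 1):
            n_cell = (maps.cells == label).sum()
            n_nuc = ((maps.nuclei == label) & (maps.cells == label)).sum()
            n_cyto = (maps.cytoplasm == label).sum()
            assert n_cell == n_nuc + n_cyto

    def test_fully_nuclear_cell_yields_empty_cytoplasm(self, caplog):
        labels = np.zeros((10, 10), dtype=int)
        labels[2:5, 2:5] = 1
        with caplog.at_level(logging.WARNING, logger="flimchip.segmentation"):
            cyto = fc.extract_cytoplasm(labels, labels)
        assert (cyto == 0).all()
        assert "entirely nuclear" in caplog.text

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fc.extract_cytoplasm(np.zeros((4, 4), int), np.zeros((5, 5), int))


class TestAggregatePerCell:
    def _label_grid(self, n_cells=120, shape=(80, 192)):
        """n_cells square cytoplasm patches laid out on a grid."""
        labels = np.zeros(shape, dtype=int)
        cols = 20
        for i in range(n_cells):
            r, c = divmod(i, cols)
            labels[2 + r * 6 : 6 + r * 6, 2 + c * 9 : 7 + c * 9] = i + 1
        return labels

    def test_constant_map_gives_constant_means(self):
        labels = self._label_grid(30)
        geom = fc.ChamberGeometry()
        table = fc.aggregate_per_cell({"metric": np.full(labels.shape, 3.5)},
                                      labels, geom, "CTL")
        assert len(table) == 30
        assert np.allclose(table["metric"], 3.5)

    def test_qc_flag_reflects_hundred_cell_minimum(self):
        geom = fc.ChamberGeometry()
        big = fc.aggregate_per_cell(
            {"m": np.ones((80, 192))}, self._label_grid(120), geom, "CTL"
        )
        small = fc.aggregate_per_cell(
            {"m": np.ones((80, 192))}, self._label_grid(40), geom, "CTL"
        )
        assert big.attrs["qc_min_cells"]
        assert not small.attrs["qc_min_cells"]

    def test_nan_pixels_excluded_from_means(self):
        labels = np.zeros((6, 6), dtype=int)
        labels[1:4, 1:4] = 1
        m = np.full((6, 6), 2.0)
        m[1, 1] = np.nan
        table = fc.aggregate_per_cell({"m": m}, labels, fc.ChamberGeometry(), "CTL")
        assert table.loc[0, "m"] == pytest.approx(2.0)

    def test_per_cell_taum_recovered_within_five_percent(self, small_geometry, irf):
        """End of the chain: programmed per-cell NAD(P)H tau_m recovered by
        fit -> segment -> aggregate within ±5% per matched cell (median)."""
        acq = fc.AcquisitionConfig(photons_per_bright_pixel=1200.0)
        scene = make_scene("low", "CTL", seed=6, geometry=small_geometry, n_cells=8)
        stack, _ = fc.render_flim_stack(scene, "NADPH", irf, acq, seed=7)
        maps = fc.fit_image(stack, irf, fc.FitOptions())
        labels = fc.segment(maps["intensity"])
        table = fc.aggregate_per_cell(
            {"nadph_taum_ps": maps["tau_m_ps"]}, labels.cytoplasm,
            small_geometry, "CTL",
        )
        true = np.array([c.center_xy for c in scene.cells])
        true_tm = np.array([c.channel_params["NADPH"].tau_m_ps for c in scene.cells])
        cents = table[["centroid_x_px", "centroid_y_px"]].to_numpy()
        d = cdist(cents, true)
        errors = []
        for i in range(len(table)):
            j = d[i].argmin()
            if d[i, j] <= scene.cells[j].cell_radius_px:
                errors.append(
                    abs(table["nadph_taum_ps"].iloc[i] - true_tm[j]) / true_tm[j]
                )
        assert len(errors) >= 6
        assert np.median(errors) < 0.05
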