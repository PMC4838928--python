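"""Segmentation, propagation, feature measurement, QC and normalization."""

import numpy as np
import pandas as pd
import pytest

import hdmascreen as h
from hdmascreen import cytometry as cyt
from tests.conftest import match_detections


def disk_mask(shape, y, x, r):
    yy, xx = np.indices(shape)
    return (yy - y) ** 2 + (xx - x) ** 2 <= r**2


# -- montage ------------------------------------------------------------


def test_montage_roundtrip():
    layout = h.ArrayLayout(n_columns=4, n_rows=3, tile_px=16)
    rng = np.random.default_rng(0)
    tiles = {
        (c, r): rng.integers(0, 1000, (3, 16, 16)).astype(np.uint16)
        for c in range(4)
        for r in range(1, 4)
    }
    montage = cyt.assemble_montage(tiles, layout)
    out = cyt.slice_montage(montage, layout)
    assert len(out) == 12
    for col, row, tile in out:
        assert (tile == tiles[(col, row)]).all()


def test_montage_single_tile_unchanged():
    layout = h.ArrayLayout(n_columns=1, n_rows=1, tile_px=8)
    m = np.arange(3 * 8 * 8, dtype=np.uint16).reshape(3, 8, 8)
    [(c, r, tile)] = cyt.slice_montage(m, layout)
    assert (c, r) == (0, 1)
    assert (tile == m).all()


def test_montage_layout_error():
    layout = h.ArrayLayout(n_columns=10, n_rows=10, tile_px=16)
    with pytest.raises(cyt.LayoutError):
        cyt.slice_montage(np.zeros((3, 32, 32), np.uint16), layout)


def test_count_conservation_over_slicing():
    """Total segmented nuclei on a montage equal the sum over its tiles."""
    params = h.RenderParams(tile_px=96, chamber_diameter_um=150.0)
    layout = h.ArrayLayout(n_columns=3, n_rows=2, tile_px=96)
    rng = np.random.default_rng(5)
    tiles = {}
    total = 0
    for c in range(3):
        for r in range(1, 3):
            n = int(rng.integers(5, 15))
            cells = h.place_cells(n, 0, 0, 0, params, rng)
            tile = np.full((1, 96, 96), 100.0)
            for rec in cells.itertuples(index=False):
                tile[0][disk_mask((96, 96), rec.y, rec.x, 2.0)] = 4000.0
            tiles[(c, r)] = tile.astype(np.uint16)
            total += n
    montage = cyt.assemble_montage(tiles, layout)
    whole = cyt.segment_nuclei(montage[0])
    per_tile = sum(
        cyt.segment_nuclei(t[0]).max() for _, _, t in cyt.slice_montage(montage, layout)
    )
    assert whole.max() == per_tile == total


# -- nuclei segmentation ------------------------------------------------


def test_blank_tile_zero_objects():
    rng = np.random.default_rng(1)
    blank = rng.normal(100, 10, (128, 128)).clip(0).astype(np.uint16)
    assert cyt.segment_nuclei(blank).max() == 0
    assert cyt.segment_nuclei(np.zeros((64, 64), np.uint16)).max() == 0


def test_separated_disks_counted_with_subpixel_centroids():
    img = np.full((160, 160), 100.0)
    centers = [(30, 30), (30, 120), (90, 70), (130, 130)]
    for y, x in centers:
        img[disk_mask(img.shape, y, x, 4)] = 4000.0
    lbl = cyt.segment_nuclei(img.astype(np.uint16))
    assert lbl.max() == 4
    from scipy import ndimage

    found = ndimage.center_of_mass(np.ones_like(lbl), lbl, range(1, 5))
    found = sorted(tuple(np.round(c, 1)) for c in found)
    for (fy, fx), (ty, tx) in zip(found, sorted(centers)):
        assert abs(fy - ty) < 1 and abs(fx - tx) < 1


def test_touching_disks_declumped():
    img = np.full((80, 80), 100.0)
    # two r=4 disks whose centres are 6.5 px apart: ~20% overlap
    for y, x in [(40, 36), (40, 43)]:
        img[disk_mask(img.shape, y, x, 4)] = 4000.0
    lbl = cyt.segment_nuclei(img.astype(np.uint16), cyt.NucleiParams(max_area=40))
    assert lbl.max() == 2


def test_segmentation_fidelity_on_default_tiles(screen_map):
    pop = h.PopulationModel()
    resp = h.default_response(screen_map.spec.factor_names)
    truth = h.simulate_screen(screen_map, pop, resp, seed=21)
    params = h.RenderParams()
    tp = fp = fn = 0
    for i in range(10):
        row = truth.iloc[i * 777]
        cells, tile = h.simulate_chamber(row, params, seed=21)
        rec, _ = cyt.process_chamber(tile, um_per_px=params.um_per_px)
        a, b, c, _ = match_detections(rec, cells)
        tp, fp, fn = tp + a, fp + b, fn + c
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    assert precision >= 0.95 and recall >= 0.95


# -- cytoplasm propagation ---------------------------------------------


def test_propagation_fills_bright_ring():
    nuclei = np.zeros((80, 80), np.int32)
    nuclei[disk_mask(nuclei.shape, 40, 40, 3)] = 1
    cyto = np.zeros((80, 80))
    ring = disk_mask(cyto.shape, 40, 40, 10)
    cyto[ring] = 500.0
    cells = cyt.propagate_cytoplasm(nuclei, cyto)
    area = (cells == 1).sum()
    assert area == pytest.approx(ring.sum(), rel=0.1)


def test_propagation_fallback_annulus():
    nuclei = np.zeros((60, 60), np.int32)
    nuclei[disk_mask(nuclei.shape, 30, 30, 3)] = 1
    cells = cyt.propagate_cytoplasm(nuclei, np.zeros((60, 60)))
    from skimage.segmentation import expand_labels

    expected = expand_labels(nuclei, distance=2)
    assert (cells == expected).all()


def test_propagation_competing_fronts_disjoint():
    nuclei = np.zeros((60, 100), np.int32)
    nuclei[disk_mask(nuclei.shape, 30, 35, 3)] = 1
    nuclei[disk_mask(nuclei.shape, 30, 65, 3)] = 2
    cyto = np.zeros((60, 100))
    blob = disk_mask(cyto.shape, 30, 35, 12) | disk_mask(cyto.shape, 30, 65, 12)
    cyto[blob] = 300.0
    cells = cyt.propagate_cytoplasm(nuclei, cyto)
    assert set(np.unique(cells)) == {0, 1, 2}
    covered = (cells > 0)
    assert (covered | ~blob).all()  # joint cytoplasm fully assigned
    assert (cells[nuclei == 1] == 1).all() and (cells[nuclei == 2] == 2).all()


def test_propagation_shape_mismatch():
    with pytest.raises(ValueError):
        cyt.propagate_cytoplasm(np.zeros((10, 10), np.int32), np.zeros((12, 12)))


# -- feature measurement ------------------------------------------------


def test_integrated_intensity_uniform_disk():
    nuclei = np.zeros((50, 50), np.int32)
    mask = disk_mask(nuclei.shape, 25, 25, 5)
    nuclei[mask] = 1
    img = np.where(mask, 7.0, 0.0)
    rec = cyt.measure_features(nuclei, nuclei, {"dna": img}, um_per_px=1.0)
    assert len(rec) == 1
    assert rec["nuclear_intensity_dna"].iloc[0] == pytest.approx(7.0 * mask.sum())
    assert rec["nuclear_area_px"].iloc[0] == mask.sum()
    assert rec["eccentricity"].iloc[0] < 0.2
    # rasterized disks have a slightly concave hull boundary
    assert rec["solidity"].iloc[0] > 0.85


def test_intensity_scaling_exact():
    nuclei = np.zeros((40, 40), np.int32)
    nuclei[disk_mask(nuclei.shape, 20, 20, 4)] = 1
    rng = np.random.default_rng(2)
    img = rng.uniform(0, 100, (40, 40))
    r1 = cyt.measure_features(nuclei, nuclei, {"c": img}, background=0.0)
    r3 = cyt.measure_features(nuclei, nuclei, {"c": 3.0 * img}, background=0.0)
    assert r3["nuclear_intensity_c"].iloc[0] == pytest.approx(
        3.0 * r1["nuclear_intensity_c"].iloc[0], rel=1e-12
    )


def test_cell_area_at_least_nuclear(screen_map):
    pop = h.PopulationModel()
    truth = h.simulate_screen(
        screen_map, pop, h.default_response(screen_map.spec.factor_names), seed=8
    )
    cells, tile = h.simulate_chamber(truth.iloc[0], h.RenderParams(), seed=8)
    rec, qc = cyt.process_chamber(tile)
    assert qc.flag == "ok"
    assert (rec["cell_area_px"] >= rec["nuclear_area_px"]).all()
    assert (rec.filter(like="intensity") >= 0).all().all()


def test_features_match_truth_on_rendered_tile():
    params = h.RenderParams(intensity_cv=0.0)
    rng = np.random.default_rng(9)
    cells = h.place_cells(30, 30, 0, 0, params, rng)
    tile = h.render_chamber(cells, params, rng)
    rec, _ = cyt.process_chamber(tile, um_per_px=params.um_per_px)
    tp, fp, fn, idx = match_detections(rec, cells)
    assert fp == 0 and fn == 0
    areas = rec["nuclear_area_px"].to_numpy()
    radii = cells["radius_px"].to_numpy()[idx]
    # soft edge + PSF blur inflate the thresholded disk by ~half a pixel
    nominal = np.pi * (radii + 0.5) ** 2
    assert 0.8 < np.median(areas / nominal) < 1.3
    assert np.corrcoef(areas, radii**2)[0, 1] > 0.8


# -- QC -----------------------------------------------------------------


def test_flag_chamber_rules():
    tile = np.full((3, 32, 32), 100, np.uint16)
    empty = pd.DataFrame(columns=["cell"])
    assert cyt.flag_chamber(empty, tile).flag == "empty"
    sat = np.full((3, 32, 32), 65535, np.uint16)
    assert cyt.flag_chamber(empty, sat).flag == "failed"
    ok = pd.DataFrame({"cell": range(20)})
    assert cyt.flag_chamber(ok, tile).flag == "ok"
    assert cyt.flag_chamber(ok, tile, error="boom").flag == "failed"


def test_flag_requires_reason():
    with pytest.raises(ValueError):
        cyt.ChamberQC(0, "failed", "")
    with pytest.raises(ValueError):
        cyt.ChamberQC(0, "bogus", "x")


# -- dye-loading normalization -----------------------------------------


def test_normalize_column_fluorescence_linear():
    raw = np.array([10.0, 30.0, 50.0])
    out = cyt.normalize_column_fluorescence(raw, blank=10.0)
    assert np.allclose(out, [0.0, 0.5, 1.0])


def test_normalize_averages_replicates_first():
    raw = np.array([[10.0, 10.0], [20.0, 40.0], [50.0, 50.0]])
    out = cyt.normalize_column_fluorescence(raw, blank=10.0)
    assert np.allclose(out, [0.0, 0.5, 1.0])


def test_normalize_degenerate_channel():
    with pytest.raises(ValueError):
        cyt.normalize_column_fluorescence(np.array([5.0, 5.0]), blank=5.0)
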