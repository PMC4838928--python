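"""Synthetic screen generator: law conformance, determinism, rendering."""

import numpy as np
import pandas as pd
import pytest

import hdmascreen as h


@pytest.fixture(scope="module")
def pop():
    return h.PopulationModel()


@pytest.fixture(scope="module")
def null_resp(screen_spec):
    return h.ResponseModel.null(screen_spec.factor_names, screen_spec.c)


def test_response_probability_rules(screen_map):
    resp = h.default_response(screen_map.spec.factor_names)
    control = screen_map.column_pairs[0]
    assert h.response_probability(resp, control, 1, 0.15) == pytest.approx(0.15)
    chir_max = next(
        c for c in screen_map.column_pairs
        if c.level_indices == (2, 0, 0, 0)
    )
    assert h.response_probability(resp, chir_max, 1, 0.15) == pytest.approx(0.30)
    with pytest.warns(UserWarning, match="clamped"):
        assert h.response_probability(resp, chir_max, 1, 0.6) == 1.0


def test_response_model_validation():
    with pytest.raises(ValueError, match="level 0"):
        h.ResponseModel({"A": (2.0, 1.0)})
    with pytest.raises(ValueError, match="margins"):
        h.ResponseModel(
            {"A": (1.0, 2.0), "B": (1.0, 1.0)},
            interaction_multipliers={("A", "B"): np.array([[1.0, 2.0], [1.0, 1.0]])},
        )


def test_row_attenuation_applies_per_row(screen_map):
    spec = screen_map.spec
    atten = tuple(np.linspace(1.0, 0.5, spec.b))
    resp = h.ResponseModel(
        {f: (1.0,) * spec.c for f in spec.factor_names}, row_attenuation=atten
    )
    comp = screen_map.column_pairs[0]
    assert h.response_probability(resp, comp, spec.b, 0.2) == pytest.approx(0.1)


def test_screen_determinism_and_consistency(screen_map, pop, null_resp):
    t1 = h.simulate_screen(screen_map, pop, null_resp, seed=42)
    t2 = h.simulate_screen(screen_map, pop, null_resp, seed=42)
    pd.testing.assert_frame_equal(t1, t2)
    t3 = h.simulate_screen(screen_map, pop, null_resp, seed=43)
    assert not t1["n_cells"].equals(t3["n_cells"])
    assert (t1["n_ki67_myocytes"] <= t1["n_myocytes"]).all()
    assert (t1["n_myocytes"] <= t1["n_cells"]).all()
    assert (t1["n_ki67_nonmyocytes"] <= t1["n_cells"] - t1["n_myocytes"]).all()
    assert len(t1) == screen_map.spec.n_chambers


@pytest.mark.parametrize("law", ["lognormal", "negbinom"])
def test_seeding_cv_recovered(screen_map, null_resp, law):
    pop = h.PopulationModel(count_law=law)
    truth = h.simulate_screen(screen_map, pop, null_resp, seed=7)
    cv = truth["n_cells"].std() / truth["n_cells"].mean()
    assert cv == pytest.approx(0.148, abs=0.01)
    assert truth["n_cells"].mean() == pytest.approx(200.0, rel=0.02)


def test_null_screen_fraction_matches_baseline(screen_map, pop, null_resp):
    truth = h.simulate_screen(screen_map, pop, null_resp, seed=1)
    frac = truth["n_ki67_myocytes"].sum() / truth["n_myocytes"].sum()
    assert frac == pytest.approx(pop.baseline_ki67_myocyte, abs=0.005)
    myo = truth["n_myocytes"].sum() / truth["n_cells"].sum()
    assert myo == pytest.approx(pop.myocyte_fraction, abs=0.005)


def test_dose_response_doubles_treated_chambers(screen_map, pop):
    resp = h.default_response(screen_map.spec.factor_names)
    truth = h.simulate_screen(screen_map, pop, resp, seed=2)
    control = truth[truth["level_CHIR"] == 0]
    treated = truth[truth["level_CHIR"] == 2]
    f0 = control["n_ki67_myocytes"].sum() / control["n_myocytes"].sum()
    f2 = treated["n_ki67_myocytes"].sum() / treated["n_myocytes"].sum()
    assert f2 / f0 == pytest.approx(2.0, abs=0.1)


def test_place_cells_geometry():
    params = h.RenderParams()
    rng = np.random.default_rng(0)
    cells = h.place_cells(150, 120, 20, 3, params, rng)
    assert len(cells) == 150
    assert cells["myocyte"].sum() == 120
    assert (cells["myocyte"] & cells["ki67"]).sum() == 20
    assert (~cells["myocyte"] & cells["ki67"]).sum() == 3
    centre = params.tile_px / 2
    r = np.hypot(cells["y"] - centre, cells["x"] - centre)
    assert (r <= params.chamber_radius_px).all()
    from scipy.spatial import cKDTree

    d, _ = cKDTree(cells[["y", "x"]].to_numpy()).query(
        cells[["y", "x"]].to_numpy(), k=2
    )
    assert d[:, 1].min() >= params.min_distance_um / params.um_per_px - 1e-9


def test_place_cells_rejects_inconsistent_counts():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        h.place_cells(10, 12, 0, 0, h.RenderParams(), rng)
    with pytest.raises(ValueError):
        h.place_cells(10, 5, 6, 0, h.RenderParams(), rng)


def test_render_empty_chamber_is_background():
    params = h.RenderParams()
    rng = np.random.default_rng(0)
    tile = h.render_chamber(h.place_cells(0, 0, 0, 0, params, rng), params, rng)
    assert tile.shape == (3, params.tile_px, params.tile_px)
    assert tile.dtype == np.uint16
    # all channels fluctuate around the background offset only
    assert abs(tile.astype(float).mean() - params.background) < 10


def test_render_single_cell_channel_structure():
    from scipy import ndimage

    params = h.RenderParams()
    rng = np.random.default_rng(1)
    cells = pd.DataFrame(
        {"y": [136.0], "x": [136.0], "radius_px": [2.0], "myocyte": [True], "ki67": [True]}
    )
    tile = h.render_chamber(cells, params, rng)
    for c in range(3):
        mask = tile[c].astype(float) > params.background + 8 * params.read_noise_sd
        _, n = ndimage.label(mask)
        assert n == 1


def test_render_channel_class_restriction():
    """cTnT signal only at myocytes, Ki67 signal only at Ki67+ cells."""
    params = h.RenderParams(read_noise_sd=0.0, background=0.0, psf_sigma_um=0.5)
    rng = np.random.default_rng(2)
    cells = pd.DataFrame(
        {
            "y": [60.0, 136.0, 210.0],
            "x": [60.0, 136.0, 210.0],
            "radius_px": [2.0, 2.0, 2.0],
            "myocyte": [True, False, False],
            "ki67": [False, True, False],
        }
    )
    tile = h.render_chamber(cells, params, rng)

    def local_sum(ch, y, x, w=12):
        return tile[ch, y - w : y + w, x - w : x + w].astype(float).sum()

    assert local_sum(1, 60, 60) > 100
    assert local_sum(1, 136, 136) == 0
    assert local_sum(2, 136, 136) > 100
    assert local_sum(2, 60, 60) == 0
    assert local_sum(2, 210, 210) == 0


def test_render_foreground_area_matches_truth():
    params = h.RenderParams(read_noise_sd=0.0, psf_sigma_um=0.5, intensity_cv=0.0)
    rng = np.random.default_rng(3)
    cells = h.place_cells(80, 0, 0, 0, params, rng)
    tile = h.render_chamber(cells, params, rng)
    # area at half maximum: the soft edge crosses 50% amplitude at the radius
    fg = (tile[0].astype(float) > params.background + params.dna_gain / 2).sum()
    nominal = (np.pi * cells["radius_px"] ** 2).sum()
    assert fg == pytest.approx(nominal, rel=0.15)


def test_overlap_warning():
    params = h.RenderParams()
    rng = np.random.default_rng(4)
    n = 40
    cells = pd.DataFrame(
        {
            "y": np.full(n, 136.0) + rng.normal(0, 0.5, n),
            "x": np.full(n, 136.0) + rng.normal(0, 0.5, n),
            "radius_px": np.full(n, 3.0),
            "myocyte": np.zeros(n, bool),
            "ki67": np.zeros(n, bool),
        }
    )
    with pytest.warns(UserWarning, match="overlap"):
        h.render_chamber(cells, params, rng)


def test_chamber_render_determinism(screen_map, pop, null_resp):
    truth = h.simulate_screen(screen_map, pop, null_resp, seed=5)
    c1, t1 = h.simulate_chamber(truth.iloc[10], h.RenderParams(), seed=5)
    c2, t2 = h.simulate_chamber(truth.iloc[10], h.RenderParams(), seed=5)
    pd.testing.assert_frame_equal(c1, c2)
    assert (t1 == t2).all()


def test_static_controls_structure(screen_map):
    spec = screen_map.spec
    conds = [screen_map.column_pairs[0], screen_map.column_pairs[1]]
    pop = h.PopulationModel(baseline_ki67_myocyte=0.24)
    null = h.ResponseModel.null(spec.factor_names, spec.c)
    df = h.simulate_static_controls(
        conds, pop, null, n_experiments=20, seed=9, cells_per_well=20000, well_cv=0.0
    )
    means = df.groupby("condition")["ki67_pct"].mean()
    # null response: all conditions share one expectation
    assert abs(means.iloc[0] - means.iloc[1]) < 2.0
    # induction effect is shared within an experiment (paired structure)
    wide = df.pivot(index="experiment", columns="condition", values="ki67_pct")
    between = wide.mean(axis=1).std()
    within = (wide.iloc[:, 0] - wide.iloc[:, 1]).std()
    assert between > 2 * within
    with pytest.raises(ValueError):
        h.simulate_static_controls(conds, pop, null, n_experiments=1, seed=0)


def test_static_controls_doubling(screen_map):
    spec = screen_map.spec
    resp = h.default_response(spec.factor_names)
    chir5 = next(c for c in screen_map.column_pairs if c.level_indices == (2, 0, 0, 0))
    pop = h.PopulationModel(baseline_ki67_myocyte=0.24)
    df = h.simulate_static_controls(
        [screen_map.column_pairs[0], chir5], pop, resp,
        n_experiments=40, seed=3, induction_cv=0.05, well_cv=0.0,
    )
    means = df.groupby("condition")["ki67_pct"].mean()
    assert means["CHIR=5"] / means["none"] == pytest.approx(2.0, abs=0.15)


@pytest.mark.parametrize(
    "frac,lo,hi",
    [(0.0, -1e-9, 0.002), (0.01, 0.008, 0.012), (1.0, 0.995, 1.001)],
)
def test_pulse_event_recovery(frac, lo, hi):
    ev = h.simulate_nuclei_pulse_events(100_000, frac, seed=6)
    from hdmascreen.gating import binucleation_fraction

    rec = binucleation_fraction(ev)
    assert lo <= rec <= hi
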