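"""End-to-end orchestration: design -> simulate -> cytometry -> gate -> analyze.

A run is described by a single YAML/dict config with one top-level seed; each
stochastic stage derives an independent substream from it, so re-running an
identical config reproduces byte-identical CSV outputs, and changing e.g.
the gate method does not perturb the simulation.  Every output file is
recorded in a JSON manifest with its SHA-256 hash.

Two simulation depths are supported: ``render: true`` renders every chamber
tile and runs full image cytometry (the default for demo-scale arrays);
``render: false`` computes chamber statistics directly from the simulated
ground-truth counts, the fast path for full-scale statistical studies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cytometry as cyt
from . import design as dsg
from . import factorial as fct
from . import gating as gat
from . import simulate as sim

__all__ = [
    "RunConfig",
    "load_config",
    "validate_config",
    "run_pipeline",
    "truth_chamber_stats",
    "DEFAULT_CONFIG",
]

log = logging.getLogger("hdmascreen")

DEFAULT_CONFIG: dict = {
    "seed": 17,
    "out_dir": "runs/demo",
    "design": {
        "parallel_replicates": 2,
        "serial_chambers": 5,
        "n_levels": 3,
        "factors": [
            {"name": "CHIR", "unit": "uM", "levels": [0.0, 2.5, 5.0]},
            {"name": "Pm", "unit": "uM", "levels": [0.0, 1.0, 2.0]},
        ],
        "chamber_diameter_mm": 0.513,
        "feature_height_um": 100.0,
    },
    "simulation": {
        "population": {},
        "response": {"factor_multipliers": {"CHIR": [1.0, 1.8, 2.0]}},
        "render": True,
        "render_params": {},
        "persist_tiles": False,
    },
    "cytometry": {"nuclei": {}, "cytoplasm": {}, "qc": {}},
    "gates": {"method": "otsu-on-log", "myocyte_min_area_um2": 50.0},
    "analysis": {"order": 2, "zero_replace_flagged": False, "plots": False},
}


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration (see DEFAULT_CONFIG for the schema)."""

    raw: dict

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def out_dir(self) -> Path:
        return Path(self.raw["out_dir"])

    def section(self, name: str) -> dict:
        merged = dict(DEFAULT_CONFIG.get(name, {}))
        merged.update(self.raw.get(name, {}) or {})
        return merged

    def design_spec(self) -> dsg.DesignSpec:
        d = self.section("design")
        return dsg.DesignSpec(
            parallel_replicates=int(d["parallel_replicates"]),
            serial_chambers=int(d["serial_chambers"]),
            n_levels=int(d["n_levels"]),
            factors=tuple(
                dsg.FactorDef(f["name"], f.get("unit", ""), tuple(f["levels"]))
                for f in d["factors"]
            ),
            chamber_diameter_mm=float(d.get("chamber_diameter_mm", 0.513)),
            feature_height_um=float(d.get("feature_height_um", 100.0)),
            stock_stream_count=d.get("stock_stream_count"),
        )


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    merged = {**DEFAULT_CONFIG, **raw}
    return RunConfig(merged)


def validate_config(config: RunConfig) -> list[str]:
    """Schema and invariant checks; an empty list means the config is runnable."""
    issues: list[str] = []
    try:
        spec = config.design_spec()
    except (KeyError, TypeError) as exc:
        return [f"design section malformed: {exc}"]
    except dsg.DesignError as exc:
        return [f"design: {exc}"]
    simc = config.section("simulation")
    try:
        sim.PopulationModel(**simc.get("population", {}))
    except (TypeError, ValueError) as exc:
        issues.append(f"simulation.population: {exc}")
    try:
        _response_model(simc, spec)
    except (KeyError, ValueError) as exc:
        issues.append(f"simulation.response: {exc}")
    gatec = config.section("gates")
    method = gatec.get("method", "otsu-on-log")
    if method not in ("fixed", "otsu-on-log", "quantile-from-controls"):
        issues.append(
            f"gates.method must be one of fixed/otsu-on-log/quantile-from-controls, got {method!r}"
        )
    order = config.section("analysis").get("order", 2)
    if order not in (1, 2):
        issues.append(f"analysis.order must be 1 or 2, got {order!r}")
    if not isinstance(config.raw.get("seed", 0), int):
        issues.append("seed must be an integer")
    return issues


def _response_model(simc: dict, spec: dsg.DesignSpec) -> sim.ResponseModel:
    rc = simc.get("response") or {}
    mults = {f: (1.0,) * spec.c for f in spec.factor_names}
    for name, values in (rc.get("factor_multipliers") or {}).items():
        if name not in mults:
            raise ValueError(f"response names unknown factor {name!r}")
        if len(values) != spec.c:
            raise ValueError(f"factor {name!r}: need {spec.c} multipliers")
        mults[name] = tuple(float(v) for v in values)
    atten = rc.get("row_attenuation")
    return sim.ResponseModel(
        mults, row_attenuation=tuple(atten) if atten else None
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def truth_chamber_stats(truth: pd.DataFrame) -> pd.DataFrame:
    """Chamber statistics taken directly from ground-truth counts."""
    out = truth[
        ["chamber", "column", "row", "n_cells", "n_myocytes", "n_ki67_myocytes",
         "n_ki67_nonmyocytes"]
    ].copy()
    n_non = out["n_cells"] - out["n_myocytes"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["pct_ki67_myocytes"] = 100.0 * out["n_ki67_myocytes"] / out["n_myocytes"]
        out["pct_ki67_nonmyocytes"] = 100.0 * out["n_ki67_nonmyocytes"] / n_non
    out = out.replace([np.inf, -np.inf], np.nan)
    out["flag"] = "ok"
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest (also written to
    ``manifest.json`` in the output directory)."""
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    warnings_log: list[str] = []
    outputs: list[Path] = []

    # -- design ---------------------------------------------------------
    spec = config.design_spec()
    cmap = dsg.build_design(spec)
    (out / "design.json").write_text(dsg.design_to_json(cmap))
    dsg.design_to_csv(cmap, out / "design.csv")
    outputs += [out / "design.json", out / "design.csv"]
    log.info("design: %d chambers, %d compositions", spec.n_chambers, spec.n_compositions)

    # -- simulate -------------------------------------------------------
    simc = config.section("simulation")
    pop = sim.PopulationModel(**simc.get("population", {}))
    resp = _response_model(simc, spec)
    truth = sim.simulate_screen(cmap, pop, resp, seed=config.seed)
    truth.to_csv(out / "truth.csv", index=False)
    outputs.append(out / "truth.csv")

    # -- cytometry + gating --------------------------------------------
    if simc.get("render", True):
        params = sim.RenderParams(**simc.get("render_params", {}))
        cytc = config.section("cytometry")
        nuc = cyt.NucleiParams(**cytc.get("nuclei", {}))
        cpp = cyt.CytoplasmParams(**cytc.get("cytoplasm", {}))
        qcp = cyt.QCParams(**cytc.get("qc", {}))
        persist = simc.get("persist_tiles", False)
        if persist:
            (out / "tiles").mkdir(exist_ok=True)
        rec_frames, qc_rows = [], []
        for rowrec in truth.itertuples(index=False):
            cells, tile = sim.simulate_chamber(
                truth.iloc[rowrec.chamber], params, seed=config.seed
            )
            if persist:
                import tifffile

                tifffile.imwrite(
                    out / "tiles" / f"c{rowrec.column:03d}_r{rowrec.row:02d}.tif",
                    tile,
                    photometric="minisblack",
                )
            records, qc = cyt.process_chamber(
                tile, chamber=rowrec.chamber, nuclei_params=nuc,
                cyto_params=cpp, qc_params=qcp, um_per_px=params.um_per_px,
            )
            rec_frames.append(records)
            qc_rows.append({"chamber": qc.chamber, "flag": qc.flag, "reason": qc.reason})
            if qc.flag != "ok":
                warnings_log.append(f"chamber {qc.chamber}: {qc.flag} ({qc.reason})")
        cells_df = pd.concat(rec_frames, ignore_index=True)
        qc_df = pd.DataFrame(qc_rows)
        cells_df.to_csv(out / "cells.csv", index=False)
        qc_df.to_csv(out / "qc.csv", index=False)
        outputs += [out / "cells.csv", out / "qc.csv"]

        gatec = config.section("gates")
        gspec = gat.GateSpec(
            method=gatec.get("method", "otsu-on-log"),
            myocyte_min_area_um2=float(gatec.get("myocyte_min_area_um2", 50.0)),
            myocyte_min_ctnt=gatec.get("myocyte_min_ctnt"),
            ki67_threshold=gatec.get("ki67_threshold"),
        )
        gates = gat.fit_gates(cells_df, gspec)
        labeled = gat.classify_cells(cells_df, gates)
        stats_df = gat.chamber_stats(
            labeled,
            qc_df,
            chambers=truth["chamber"],
            zero_replace_flagged=config.section("analysis").get("zero_replace_flagged", False),
        )
        stats_df = stats_df.merge(truth[["chamber", "column", "row"]], on="chamber")
        (out / "gates.json").write_text(json.dumps(dataclasses.asdict(gates), indent=1))
        outputs.append(out / "gates.json")
    else:
        stats_df = truth_chamber_stats(truth)
    stats_df.to_csv(out / "chamber_stats.csv", index=False)
    outputs.append(out / "chamber_stats.csv")

    series = gat.aggregate_column_pair(stats_df, cmap)
    pair_rows = [
        {
            "pair": s.pair,
            **{f"conc_{n}": c for n, c in zip(spec.factor_names, s.composition.concentrations)},
            "mean": s.mean,
            "sd": s.sd,
            "n_rows": int(np.isfinite(s.values).sum()),
        }
        for s in series
    ]
    pd.DataFrame(pair_rows).to_csv(out / "columnpair_stats.csv", index=False)
    col_means = gat.column_means(stats_df)
    col_means.rename("pct_ki67_myocytes").to_csv(out / "column_stats.csv")
    outputs += [out / "columnpair_stats.csv", out / "column_stats.csv"]
    heat = stats_df.pivot_table(
        index="row", columns="column", values="pct_ki67_myocytes", dropna=False
    )
    heat.to_csv(out / "heatmap.csv")
    outputs.append(out / "heatmap.csv")

    # -- factorial analysis --------------------------------------------
    anac = config.section("analysis")
    design_mat = dsg.column_level_matrix(cmap)
    y = col_means.reindex(range(spec.n_columns)).to_numpy()
    levels = {f.name: np.asarray(f.levels) for f in spec.factors}
    if np.isnan(y).any():
        warnings_log.append("missing column means: using least-squares factorial path")
        result = fct.fit_factorial_ols(
            y, design_mat, spec.factor_names, levels, order=anac.get("order", 2)
        )
    else:
        result = fct.fit_factorial(
            y, design_mat, spec.factor_names, levels, order=anac.get("order", 2)
        )
    result.anova.to_csv(out / "anova.csv", index=False)
    fct.effect_plot_data(result).to_csv(out / "effects.csv", index=False)
    fct.interaction_plot_data(result).to_csv(out / "interactions.csv", index=False)
    fct.f_value_ranking(result).to_csv(out / "f_ranking.csv", index=False)
    outputs += [out / "anova.csv", out / "effects.csv", out / "interactions.csv",
                out / "f_ranking.csv"]
    if anac.get("plots", False):
        _write_plots(out, heat, result)
        outputs += [out / "heatmap.png", out / "effects.png", out / "f_ranking.png"]

    import numpy
    from . import __version__

    manifest = {
        "seed": config.seed,
        "started_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime(t0)),
        "elapsed_s": round(time.time() - t0, 2),
        "versions": {"hdmascreen": __version__, "numpy": numpy.__version__},
        "n_chambers": int(spec.n_chambers),
        "outputs": {p.name: _sha256(p) for p in outputs},
        "warnings": warnings_log,
        "grand_mean_pct_ki67_myocytes": result.grand_mean,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _write_plots(out: Path, heat: pd.DataFrame, result) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    im = ax.imshow(heat.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    fig.colorbar(im, label="% Ki67+ myocytes")
    fig.savefig(out / "heatmap.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    eff = fct.effect_plot_data(result)
    fig, axes = plt.subplots(1, len(result.factor_names), figsize=(3 * len(result.factor_names), 3), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, f in zip(axes, result.factor_names):
        sub = eff[eff["factor"] == f]
        ax.plot(sub["level"], sub["mean_response"], "o-")
        ax.axhline(result.grand_mean, ls="--", c="gray")
        ax.set_title(f)
    fig.savefig(out / "effects.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    rank = fct.f_value_ranking(result)
    fig, ax = plt.subplots(figsize=(6, 3))
    colors = ["green" if s else "red" for s in rank["significant"]]
    ax.bar(rank["term"], rank["F"], color=colors)
    ax.set_ylabel("F value")
    ax.tick_params(axis="x", rotation=60)
    fig.savefig(out / "f_ranking.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
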