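"""Gating of per-cell records and reduction to chamber / column statistics.

Mirrors the image-cytometry analysis of the proliferation screen: cells are
first gated as cardiomyocytes on cellular projected area and cellular
integrated cTnT intensity, then cycling cells are gated on nuclear
integrated Ki67 intensity.  Per-chamber fractions are aggregated to
column-pair series (the two replicate columns averaged row-wise, then mean
+/- SD over the serial rows), with the zero-replacement rule for QC-flagged
chambers available as a compatibility mode.  Also hosts the pulse-width
binucleation gate for flow-style nuclear-stain events.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu

from .design import ConditionMap, FactorComposition

__all__ = [
    "GateSpec",
    "ColumnPairSeries",
    "GatingError",
    "fit_gates",
    "classify_cells",
    "chamber_stats",
    "aggregate_column_pair",
    "column_means",
    "column_pair_ttest",
    "binucleation_fraction",
]


class GatingError(ValueError):
    pass


@dataclass(frozen=True)
class GateSpec:
    """Gating scheme and (once fitted) resolved thresholds.

    The myocyte gate is a rectangular region in the (cellular projected
    area, cellular integrated cTnT intensity) plane: both minima must be
    exceeded.  The Ki67 gate is a threshold on nuclear integrated Ki67
    intensity.  ``method`` controls how intensity thresholds are resolved:
    ``fixed`` echoes the given values, ``otsu-on-log`` places them at the
    Otsu split of log-transformed intensities, ``quantile-from-controls``
    places the Ki67 threshold at a stated quantile of a negative-control
    population.
    """

    method: str = "otsu-on-log"
    myocyte_min_area_um2: float = 50.0
    myocyte_min_ctnt: float | None = None
    ki67_threshold: float | None = None
    control_quantile: float = 0.99

    def __post_init__(self) -> None:
        if self.method not in ("fixed", "otsu-on-log", "quantile-from-controls"):
            raise GatingError(f"unknown gating method {self.method!r}")
        if not 0.0 < self.control_quantile < 1.0:
            raise GatingError("control_quantile must be in (0, 1)")

    @property
    def resolved(self) -> bool:
        return self.myocyte_min_ctnt is not None and self.ki67_threshold is not None


def _otsu_on_log(values: np.ndarray) -> float:
    v = np.log1p(np.asarray(values, dtype=float))
    if np.ptp(v) == 0:
        return float(np.expm1(v[0]))
    return float(np.expm1(threshold_otsu(v)))


def fit_gates(
    records: pd.DataFrame,
    spec: GateSpec = GateSpec(),
    reference: pd.DataFrame | None = None,
) -> GateSpec:
    """Resolve gate thresholds on a cell table.

    ``otsu-on-log`` thresholds each intensity at the Otsu split of its
    log1p distribution — scale-free and invariant under duplication of
    records.  ``quantile-from-controls`` takes the Ki67 threshold from the
    ``control_quantile`` of the ``reference`` (negative-control) population
    and the cTnT threshold from the Otsu split as above.
    """
    if spec.method == "fixed":
        if not spec.resolved:
            raise GatingError("fixed method requires explicit thresholds")
        return spec
    if records is None or len(records) == 0:
        raise GatingError("cannot fit gates on an empty cell table")
    ctnt = spec.myocyte_min_ctnt
    if ctnt is None:
        ctnt = _otsu_on_log(records["cell_intensity_ctnt"].to_numpy())
    if spec.method == "quantile-from-controls":
        if reference is None or len(reference) == 0:
            raise GatingError("quantile-from-controls requires a reference population")
        ki67 = float(
            np.quantile(
                reference["nuclear_intensity_ki67"].to_numpy(), spec.control_quantile
            )
        )
    else:
        ki67 = spec.ki67_threshold
        if ki67 is None:
            ki67 = _otsu_on_log(records["nuclear_intensity_ki67"].to_numpy())
    return replace(spec, method="fixed", myocyte_min_ctnt=ctnt, ki67_threshold=ki67)


def classify_cells(records: pd.DataFrame, gates: GateSpec) -> pd.DataFrame:
    """Add boolean ``myocyte`` and ``ki67`` labels, a pure function of the
    feature columns and resolved thresholds."""
    if not gates.resolved:
        raise GatingError("gates are not resolved; call fit_gates first")
    needed = ["cell_area_um2", "cell_intensity_ctnt", "nuclear_intensity_ki67"]
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise KeyError(f"cell table lacks feature columns: {missing}")
    out = records.copy()
    out["myocyte"] = (out["cell_area_um2"] > gates.myocyte_min_area_um2) & (
        out["cell_intensity_ctnt"] > gates.myocyte_min_ctnt
    )
    out["ki67"] = out["nuclear_intensity_ki67"] > gates.ki67_threshold
    return out


def chamber_stats(
    labeled: pd.DataFrame,
    qc: pd.DataFrame | None = None,
    chambers=None,
    zero_replace_flagged: bool = False,
) -> pd.DataFrame:
    """Reduce labelled cells to one summary row per chamber.

    Fractions are percentages in [0, 100].  A chamber with zero myocytes has
    an undefined myocyte fraction, recorded as NaN.  In ``zero_replace_flagged``
    mode every QC-flagged chamber is replaced with all-zero measurements
    (the array-heatmap convention); by default flagged chambers keep their
    values and are excluded later via the ``flag`` column.
    """
    counts = pd.DataFrame(
        columns=["n_cells", "n_myocytes", "n_ki67_myocytes", "n_ki67_nonmyocytes"]
    )
    if len(labeled):
        tmp = labeled.assign(
            myo_ki67=labeled["myocyte"] & labeled["ki67"],
            non_ki67=~labeled["myocyte"] & labeled["ki67"],
        )
        counts = tmp.groupby("chamber").agg(
            n_cells=("cell", "size"),
            n_myocytes=("myocyte", "sum"),
            n_ki67_myocytes=("myo_ki67", "sum"),
            n_ki67_nonmyocytes=("non_ki67", "sum"),
        )
    if chambers is None:
        chambers = counts.index
    out = counts.reindex(chambers, fill_value=0).astype(int)
    out.index.name = "chamber"
    n_non = out["n_cells"] - out["n_myocytes"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["pct_ki67_myocytes"] = 100.0 * out["n_ki67_myocytes"] / out["n_myocytes"]
        out["pct_ki67_nonmyocytes"] = 100.0 * out["n_ki67_nonmyocytes"] / n_non
    out = out.replace([np.inf, -np.inf], np.nan)
    flags = pd.Series("ok", index=out.index, name="flag")
    if qc is not None and len(qc):
        qcs = qc.set_index("chamber")["flag"]
        flags.loc[qcs.index.intersection(flags.index)] = qcs
    out["flag"] = flags
    if zero_replace_flagged:
        bad = out["flag"] != "ok"
        num_cols = [c for c in out.columns if c != "flag"]
        out.loc[bad, num_cols] = 0
    return out.reset_index()


@dataclass
class ColumnPairSeries:
    """Per-row response of one column-pair: the a replicate columns averaged
    row-wise, giving b values plus their mean and SD."""

    pair: int
    composition: FactorComposition | None
    values: np.ndarray  # length b, NaN where undefined

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values)) if np.isfinite(self.values).any() else np.nan

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.values, ddof=1)) if np.isfinite(self.values).sum() > 1 else np.nan


def aggregate_column_pair(
    stats_df: pd.DataFrame,
    cmap: ConditionMap,
    value: str = "pct_ki67_myocytes",
    exclude_flagged: bool = True,
) -> list[ColumnPairSeries]:
    """Column-pair series for every composition of the design.

    ``stats_df`` must carry ``column``, ``row`` and the value column (join
    chamber stats with the design CSV or pass the simulator's table).
    Flagged chambers (``flag != ok``) are dropped before averaging unless
    ``exclude_flagged`` is off.  A composition whose chambers are all
    flagged yields an all-NaN series with a warning.
    """
    import warnings

    df = stats_df
    if exclude_flagged and "flag" in df.columns:
        df = df[df["flag"] == "ok"]
    b = cmap.spec.b
    out = []
    col_to_pair = dict(enumerate(cmap.columns))
    work = df.assign(pair=df["column"].map(col_to_pair))
    grouped = work.groupby(["pair", "row"])[value].mean()
    for pair in range(len(cmap.column_pairs)):
        vals = np.full(b, np.nan)
        if pair in grouped.index.get_level_values(0):
            sub = grouped.loc[pair]
            vals[sub.index.to_numpy() - 1] = sub.to_numpy()
        if not np.isfinite(vals).any():
            warnings.warn(f"column-pair {pair}: no usable chambers", stacklevel=2)
        out.append(
            ColumnPairSeries(pair=pair, composition=cmap.column_pairs[pair], values=vals)
        )
    return out


def column_means(
    stats_df: pd.DataFrame, value: str = "pct_ki67_myocytes"
) -> pd.Series:
    """Per-physical-column mean of a chamber statistic (heatmap marginals and
    the experimental units of the factorial fit)."""
    return stats_df.groupby("column")[value].mean()


def column_pair_ttest(
    treated: ColumnPairSeries, control: ColumnPairSeries
) -> tuple[float, float]:
    """Unpaired two-tailed t-test between the row values of two series."""
    a = treated.values[np.isfinite(treated.values)]
    b = control.values[np.isfinite(control.values)]
    if len(a) < 2 or len(b) < 2:
        raise GatingError("both series need at least 2 finite rows")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise GatingError("degenerate t-test: zero variance in both series")
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def binucleation_fraction(
    events: pd.DataFrame,
    width_gate: float = 1.25,
    max_singlet_area: float = 1.5,
) -> float:
    """Fraction of binucleated cardiomyocytes in a pulse-event table.

    Gates on cTnT+ singlets (``singlet`` column if present, else pulse area
    below ``max_singlet_area``), then counts events whose nuclear-stain pulse
    width exceeds the gate — two nuclei traversing in one event.
    """
    sel = events["ctnt"].to_numpy(dtype=bool)
    if "singlet" in events.columns:
        sel &= events["singlet"].to_numpy(dtype=bool)
    else:
        sel &= events["pulse_area"].to_numpy() < max_singlet_area
    widths = events.loc[sel, "pulse_width"].to_numpy()
    if widths.size == 0:
        return float("nan")
    return float(np.mean(widths > width_gate))
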