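"""Combinatorial condition layout of a high-density microbioreactor array (HDMA).

An HDMA multiplexes ``d`` soluble factors, each at ``c`` concentration levels,
into ``c**d`` distinct compositions.  Each composition feeds ``a`` parallel
replicate columns, and each column carries ``b`` serially connected culture
chambers, for ``n = a * b * c**d`` chambers in total.  This module builds and
validates that layout (which composition flows to which column and chamber),
plus the derived chamber geometry quantities (floor area, nominal volume) and
the stock-concentration multiplier implied by the on-chip dilution network.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

__all__ = [
    "FactorDef",
    "DesignSpec",
    "FactorComposition",
    "ConditionMap",
    "ChamberGeometry",
    "DesignError",
    "build_design",
    "composition_for_chamber",
    "normalized_design_matrix",
    "chamber_geometry",
    "stock_multiplier",
    "fluidic_input_count",
    "reference_design",
    "design_to_json",
    "design_from_json",
    "design_to_csv",
    "column_level_matrix",
]


class DesignError(ValueError):
    """Raised for an invalid array design specification."""


@dataclass(frozen=True)
class FactorDef:
    """One screened factor: its name, unit, and the c concentration levels.

    Levels must be strictly increasing and start at 0 (the no-factor control
    level), so every factor contributes an untreated margin to the design.
    """

    name: str
    unit: str
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(float(v) for v in self.levels))
        if not self.name:
            raise DesignError("factor name must be non-empty")
        if len(self.levels) < 1:
            raise DesignError(f"factor {self.name!r} has no levels")
        if self.levels[0] != 0.0:
            raise DesignError(f"factor {self.name!r}: lowest level must be 0")
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise DesignError(f"factor {self.name!r}: levels must be strictly increasing")

    @property
    def max_level(self) -> float:
        return self.levels[-1]


@dataclass(frozen=True)
class DesignSpec:
    """The a x b x c^d architecture of one array.

    Parameters
    ----------
    parallel_replicates : int
        ``a`` — replicate columns receiving the same composition.
    serial_chambers : int
        ``b`` — chambers along one column sharing one medium stream.
    n_levels : int
        ``c`` — concentration levels per factor.
    factors : sequence of FactorDef
        The ``d`` factors, each with exactly ``c`` levels.
    chamber_diameter_mm, feature_height_um : float
        Circular chamber floor diameter and channel feature height.
    stock_stream_count : int, optional
        Number of equal-flowrate factor/buffer stream pairs merged on chip;
        defaults to ``d``.
    """

    parallel_replicates: int
    serial_chambers: int
    n_levels: int
    factors: tuple[FactorDef, ...]
    chamber_diameter_mm: float = 0.513
    feature_height_um: float = 100.0
    stock_stream_count: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        for attr in ("parallel_replicates", "serial_chambers", "n_levels"):
            v = getattr(self, attr)
            if not isinstance(v, int) or v < 1:
                raise DesignError(f"{attr} must be a positive integer, got {v!r}")
        if len(self.factors) < 1:
            raise DesignError("at least one factor is required")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise DesignError(f"duplicate factor names: {names}")
        for f in self.factors:
            if len(f.levels) != self.n_levels:
                raise DesignError(
                    f"factor {f.name!r} has {len(f.levels)} levels, expected c={self.n_levels}"
                )
        if self.chamber_diameter_mm <= 0 or self.feature_height_um <= 0:
            raise DesignError("chamber dimensions must be positive")
        if self.stock_stream_count is not None and self.stock_stream_count < 1:
            raise DesignError("stock_stream_count must be >= 1")

    # -- derived counts -------------------------------------------------
    @property
    def a(self) -> int:
        return self.parallel_replicates

    @property
    def b(self) -> int:
        return self.serial_chambers

    @property
    def c(self) -> int:
        return self.n_levels

    @property
    def d(self) -> int:
        return len(self.factors)

    @property
    def n_compositions(self) -> int:
        return self.c**self.d

    @property
    def n_columns(self) -> int:
        return self.a * self.n_compositions

    @property
    def n_chambers(self) -> int:
        return self.a * self.b * self.n_compositions

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)


@dataclass(frozen=True)
class FactorComposition:
    """One point of the combinatorial panel: concentration of every factor.

    ``level_indices`` are the per-factor indices into the level lists (the
    mixed-radix digits of the composition); ``normalized`` divides each
    concentration by that factor's maximum level, the 0..1 scale on which
    design matrices are usually drawn.
    """

    concentrations: tuple[float, ...]
    level_indices: tuple[int, ...]
    normalized: tuple[float, ...]
    factor_names: tuple[str, ...]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.factor_names, self.concentrations))

    @property
    def is_control(self) -> bool:
        return all(i == 0 for i in self.level_indices)


@dataclass(frozen=True)
class ConditionMap:
    """Resolved column/chamber -> composition assignment for one design.

    ``column_pairs`` lists the ``c**d`` distinct compositions in deterministic
    order; ``columns[j]`` gives the composition index fed to physical column
    ``j`` (0-based, left to right, the ``a`` replicates of a composition
    adjacent).  All ``b`` serial chambers of a column share its composition.
    """

    spec: DesignSpec
    column_pairs: tuple[FactorComposition, ...]
    columns: tuple[int, ...] = field(repr=False)

    @property
    def n_chambers(self) -> int:
        return self.spec.n_chambers

    def chambers(self):
        """Iterate (column, row, composition) over all chambers, row 1..b."""
        for col, pair_idx in enumerate(self.columns):
            comp = self.column_pairs[pair_idx]
            for row in range(1, self.spec.b + 1):
                yield col, row, comp

    def pair_index_for_column(self, column: int) -> int:
        if not 0 <= column < len(self.columns):
            raise IndexError(f"column {column} out of range 0..{len(self.columns) - 1}")
        return self.columns[column]


def build_design(
    spec: DesignSpec, ordering: Sequence[int] | None = None
) -> ConditionMap:
    """Enumerate the full factorial panel and assign compositions to columns.

    Compositions are ordered mixed-radix with the *last-listed* factor varying
    fastest and levels ascending, so the all-zero control composition comes
    first.  ``ordering`` optionally permutes the column-pair sequence to match
    a physical device layout.
    """
    level_tuples = list(product(*(range(spec.c) for _ in spec.factors)))
    comps = []
    for idx_tuple in level_tuples:
        concs = tuple(f.levels[i] for f, i in zip(spec.factors, idx_tuple))
        norm = tuple(
            (conc / f.max_level) if f.max_level > 0 else 0.0
            for f, conc in zip(spec.factors, concs)
        )
        comps.append(
            FactorComposition(
                concentrations=concs,
                level_indices=idx_tuple,
                normalized=norm,
                factor_names=spec.factor_names,
            )
        )
    if ordering is not None:
        if sorted(ordering) != list(range(len(comps))):
            raise DesignError("ordering must be a permutation of the composition indices")
        comps = [comps[i] for i in ordering]
    columns = tuple(
        pair for pair in range(len(comps)) for _ in range(spec.parallel_replicates)
    )
    return ConditionMap(spec=spec, column_pairs=tuple(comps), columns=columns)


def composition_for_chamber(cmap: ConditionMap, column: int, row: int) -> FactorComposition:
    """Composition seen by chamber (column, row); rows are 1-based 1..b.

    All serial chambers of a column share one medium stream, so the result is
    independent of the row.
    """
    if not 1 <= row <= cmap.spec.b:
        raise IndexError(f"row {row} out of range 1..{cmap.spec.b}")
    return cmap.column_pairs[cmap.pair_index_for_column(column)]


def normalized_design_matrix(cmap: ConditionMap):
    """d x c^d matrix of normalized levels, one row per factor, one column per
    column-pair — the standard graphical rendering of the condition panel."""
    import numpy as np

    return np.array([comp.normalized for comp in cmap.column_pairs]).T


@dataclass(frozen=True)
class ChamberGeometry:
    """Derived geometry of one circular culture chamber."""

    diameter_mm: float
    height_um: float

    @property
    def floor_area_mm2(self) -> float:
        return math.pi * (self.diameter_mm / 2.0) ** 2

    @property
    def volume_nl(self) -> float:
        # mm^2 * um = 1e-3 mm^3 = 1 nL exactly
        return self.floor_area_mm2 * self.height_um * 1.0

    def cells_at_density(self, density_per_cm2: float) -> float:
        """Expected cell count at a given surface seeding density (cells/cm2)."""
        return density_per_cm2 * self.floor_area_mm2 * 1e-2


def chamber_geometry(spec: DesignSpec) -> ChamberGeometry:
    return ChamberGeometry(
        diameter_mm=spec.chamber_diameter_mm, height_um=spec.feature_height_um
    )


def stock_multiplier(spec: DesignSpec) -> int:
    """Concentration multiple at which each factor stock must be supplied.

    Modelled as an idealized merge of ``stock_stream_count`` equal-flowrate
    factor/buffer stream pairs: each factor stream is diluted by the number of
    streams merged, so the stock must be that many times the highest screened
    concentration.
    """
    n = spec.stock_stream_count if spec.stock_stream_count is not None else spec.d
    if n < 1:
        raise DesignError("at least one stream is required")
    return n


def fluidic_input_count(spec: DesignSpec) -> int:
    """Number of fluidic inlets: one factor plus one buffer stream per factor."""
    return 2 * spec.d


def reference_design(
    parallel_replicates: int = 2, serial_chambers: int = 50
) -> DesignSpec:
    """The four-factor cardiomyocyte proliferation screen layout.

    CHIR99021 (Wnt agonist) at 0/2.5/5 uM, Purmorphamine (Hedgehog agonist) at
    0/1/2 uM, IGF-1 and FGF-2 at 0/50/100 ng/mL; three levels each on a linear
    0/half/max scale.  With a=2 and b=50 this is the 8100-chamber device.
    """
    return DesignSpec(
        parallel_replicates=parallel_replicates,
        serial_chambers=serial_chambers,
        n_levels=3,
        factors=(
            FactorDef("CHIR", "uM", (0.0, 2.5, 5.0)),
            FactorDef("Pm", "uM", (0.0, 1.0, 2.0)),
            FactorDef("IGF-1", "ng/mL", (0.0, 50.0, 100.0)),
            FactorDef("FGF-2", "ng/mL", (0.0, 50.0, 100.0)),
        ),
    )


def column_level_matrix(cmap: ConditionMap):
    """(n_columns, d) integer level indices per physical column — the unit
    design matrix for a factorial fit on per-column responses."""
    import numpy as np

    return np.array(
        [cmap.column_pairs[p].level_indices for p in cmap.columns], dtype=int
    )


# -- serialization ------------------------------------------------------


def design_to_json(cmap: ConditionMap) -> str:
    spec = cmap.spec
    payload = {
        "spec": {
            "parallel_replicates": spec.parallel_replicates,
            "serial_chambers": spec.serial_chambers,
            "n_levels": spec.n_levels,
            "chamber_diameter_mm": spec.chamber_diameter_mm,
            "feature_height_um": spec.feature_height_um,
            "stock_stream_count": spec.stock_stream_count,
            "factors": [
                {"name": f.name, "unit": f.unit, "levels": list(f.levels)}
                for f in spec.factors
            ],
        },
        "column_pairs": [list(c.level_indices) for c in cmap.column_pairs],
        "columns": list(cmap.columns),
    }
    return json.dumps(payload, indent=1)


def design_from_json(text: str) -> ConditionMap:
    payload = json.loads(text)
    s = payload["spec"]
    spec = DesignSpec(
        parallel_replicates=s["parallel_replicates"],
        serial_chambers=s["serial_chambers"],
        n_levels=s["n_levels"],
        factors=tuple(
            FactorDef(f["name"], f["unit"], tuple(f["levels"])) for f in s["factors"]
        ),
        chamber_diameter_mm=s["chamber_diameter_mm"],
        feature_height_um=s["feature_height_um"],
        stock_stream_count=s["stock_stream_count"],
    )
    cmap = build_design(spec)
    stored = [tuple(t) for t in payload["column_pairs"]]
    current = [c.level_indices for c in cmap.column_pairs]
    if stored != current:
        order = [current.index(t) for t in stored]
        cmap = build_design(spec, ordering=order)
    if list(cmap.columns) != list(payload["columns"]):
        raise DesignError("stored column assignment does not match a replicate-adjacent layout")
    return cmap


def design_to_csv(cmap: ConditionMap, path) -> None:
    """Flat chamber table (column, row, one concentration column per factor)
    for joining with per-chamber results."""
    names = cmap.spec.factor_names
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["column", "row", "column_pair", *names])
        for col, row, comp in cmap.chambers():
            w.writerow([col, row, cmap.columns[col], *comp.concentrations])
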