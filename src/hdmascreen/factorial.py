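"""Full-factorial design-of-experiments analysis of per-column responses.

Decomposes a response measured over a balanced full factorial (every
combination of factor levels observed equally often) into a grand mean,
per-factor main effects, and two-factor interaction effects, with the
classical balanced-design ANOVA table (term, df, SS, MS, F, p).  Terms above
second order are pooled into the residual, mirroring common screening
practice.  An effect-coded least-squares path handles unbalanced inputs
(e.g. columns dropped by QC) and doubles as an independent cross-check of the
classical estimator.

Also provides the confirmation statistics used to compare the miniaturized
platform against standard static cultures: Pearson correlation of condition
means, one-way ANOVA with Tukey HSD versus control, and paired t-tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FactorialResult",
    "ConfirmationStats",
    "UnbalancedDesignError",
    "fit_factorial",
    "fit_factorial_ols",
    "effect_plot_data",
    "interaction_plot_data",
    "f_value_ranking",
    "confirmation_stats",
]


class UnbalancedDesignError(ValueError):
    """Raised when the classical estimator is applied to an unbalanced design."""


@dataclass
class FactorialResult:
    """Fitted factorial decomposition.

    Attributes
    ----------
    grand_mean : float
    factor_names : tuple of str
    levels : dict factor -> array of level values (concentrations)
    main_effects : dict factor -> array (c,) of deviations from the grand mean
    interaction_effects : dict (f1, f2) -> array (c, c) of cell deviations
        after main effects are removed; both margins sum to zero.
    anova : DataFrame with columns term, df, ss, ms, F, p, significant
    """

    grand_mean: float
    factor_names: tuple[str, ...]
    levels: dict[str, np.ndarray]
    main_effects: dict[str, np.ndarray]
    interaction_effects: dict[tuple[str, str], np.ndarray]
    anova: pd.DataFrame
    n_units: int
    alpha: float = 0.05
    cell_means: pd.DataFrame | None = field(default=None, repr=False)


def _check_balanced(design: np.ndarray, c: int) -> bool:
    keys = [tuple(row) for row in design]
    counts = pd.Series(keys).value_counts()
    full = c ** design.shape[1]
    return len(counts) == full and counts.nunique() == 1


def fit_factorial(
    responses,
    design,
    factor_names=None,
    levels=None,
    order: int = 2,
    alpha: float = 0.05,
) -> FactorialResult:
    """Classical balanced-design factorial fit.

    Parameters
    ----------
    responses : array (N,)
        One response value per experimental unit (e.g. per-column mean
        percentage of proliferating myocytes).
    design : array (N, d) of integer level indices
        The factor level of each unit, indices 0..c-1 per factor.
    factor_names : optional names, default F1..Fd.
    levels : optional dict factor -> level values for plot axes.
    order : 1 or 2 — include main effects only, or also all two-factor
        interactions; higher-order terms are pooled into the residual.

    Level effects are marginal mean minus grand mean; interaction effects are
    two-way cell means with the grand mean and both main effects removed, so
    every effect vector sums to zero over each margin.  F ratios use the
    pooled residual mean square; with zero residual variance (a constant
    response) F is reported as 0 with p = 1.
    """
    y = np.asarray(responses, dtype=float)
    X = np.asarray(design, dtype=int)
    if y.ndim != 1 or X.ndim != 2 or len(y) != len(X):
        raise ValueError("responses must be (N,), design (N, d)")
    if np.isnan(y).any():
        raise ValueError("responses contain NaN; drop those units and use fit_factorial_ols")
    n, d = len(y), X.shape[1]
    if factor_names is None:
        factor_names = tuple(f"F{i + 1}" for i in range(d))
    factor_names = tuple(factor_names)
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    c = int(X.max()) + 1
    if not _check_balanced(X, c):
        raise UnbalancedDesignError(
            "design is not a balanced full factorial; use fit_factorial_ols"
        )
    reps = n // c**d
    if levels is None:
        levels = {f: np.arange(c, dtype=float) for f in factor_names}
    else:
        levels = {f: np.asarray(v, dtype=float) for f, v in levels.items()}

    gm = float(y.mean())
    main = {}
    ss_rows = []
    for j, f in enumerate(factor_names):
        marg = np.array([y[X[:, j] == l].mean() for l in range(c)])
        eff = marg - gm
        main[f] = eff
        n_per = n // c
        ss_rows.append((f, c - 1, n_per * float(np.sum(eff**2))))

    inter: dict[tuple[str, str], np.ndarray] = {}
    if order >= 2 and d >= 2:
        for i, j in itertools.combinations(range(d), 2):
            fi, fj = factor_names[i], factor_names[j]
            cell = np.empty((c, c))
            for li in range(c):
                for lj in range(c):
                    cell[li, lj] = y[(X[:, i] == li) & (X[:, j] == lj)].mean()
            eff = cell - gm - main[fi][:, None] - main[fj][None, :]
            inter[(fi, fj)] = eff
            n_per = n // c**2
            ss_rows.append((f"{fi}*{fj}", (c - 1) ** 2, n_per * float(np.sum(eff**2))))

    ss_total = float(np.sum((y - gm) ** 2))
    df_model = sum(r[1] for r in ss_rows)
    ss_model = sum(r[2] for r in ss_rows)
    df_resid = n - 1 - df_model
    ss_resid = ss_total - ss_model
    if df_resid <= 0:
        raise UnbalancedDesignError(
            "zero residual degrees of freedom; need >= 2 units per composition "
            "or order reduction"
        )
    ms_resid = ss_resid / df_resid

    rows = []
    for term, df_t, ss_t in ss_rows:
        ms_t = ss_t / df_t
        if ms_resid > 0:
            F = ms_t / ms_resid
            p = float(stats.f.sf(F, df_t, df_resid))
        else:
            # constant response: no variance to apportion
            F, p = 0.0, 1.0
        rows.append((term, df_t, ss_t, ms_t, F, p))
    rows.append(("Residual", df_resid, ss_resid, ms_resid, np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, np.nan, np.nan, np.nan))
    anova = pd.DataFrame(rows, columns=["term", "df", "ss", "ms", "F", "p"])
    anova["significant"] = anova["p"] < alpha

    return FactorialResult(
        grand_mean=gm,
        factor_names=factor_names,
        levels=levels,
        main_effects=main,
        interaction_effects=inter,
        anova=anova,
        n_units=n,
        alpha=alpha,
    )


def fit_factorial_ols(
    responses,
    design,
    factor_names=None,
    levels=None,
    order: int = 2,
    alpha: float = 0.05,
) -> FactorialResult:
    """Effect-coded (sum-to-zero) least-squares factorial fit with Type-II SS.

    Handles unbalanced designs (dropped or missing units).  On a balanced
    design it reproduces the classical estimator exactly, which makes it the
    natural cross-check for :func:`fit_factorial`.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    y = np.asarray(responses, dtype=float)
    X = np.asarray(design, dtype=int)
    n, d = len(y), X.shape[1]
    if factor_names is None:
        factor_names = tuple(f"F{i + 1}" for i in range(d))
    factor_names = tuple(factor_names)
    c = int(X.max()) + 1
    if levels is None:
        levels = {f: np.arange(c, dtype=float) for f in factor_names}
    else:
        levels = {f: np.asarray(v, dtype=float) for f, v in levels.items()}

    keep = ~np.isnan(y)
    y, X = y[keep], X[keep]
    safe = {f: f"f{i}" for i, f in enumerate(factor_names)}
    df = pd.DataFrame({safe[f]: X[:, i] for i, f in enumerate(factor_names)})
    df["y"] = y
    terms = [f"C({safe[f]}, Sum)" for f in factor_names]
    if order >= 2:
        terms += [
            f"C({safe[a]}, Sum):C({safe[b]}, Sum)"
            for a, b in itertools.combinations(factor_names, 2)
        ]
    model = smf.ols("y ~ " + " + ".join(terms), data=df).fit()

    gm = float(model.params["Intercept"])
    main = {}
    for f in factor_names:
        eff = np.empty(c)
        for l in range(c - 1):
            eff[l] = model.params[f"C({safe[f]}, Sum)[S.{l}]"]
        eff[c - 1] = -eff[: c - 1].sum()
        main[f] = eff
    inter: dict[tuple[str, str], np.ndarray] = {}
    if order >= 2:
        for fa, fb in itertools.combinations(factor_names, 2):
            grid = np.zeros((c, c))
            for la in range(c - 1):
                for lb in range(c - 1):
                    key = f"C({safe[fa]}, Sum)[S.{la}]:C({safe[fb]}, Sum)[S.{lb}]"
                    grid[la, lb] = model.params[key]
            grid[: c - 1, c - 1] = -grid[: c - 1, : c - 1].sum(axis=1)
            grid[c - 1, :] = -grid[: c - 1, :].sum(axis=0)
            inter[(fa, fb)] = grid

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # anova_lm warns on perfect fits
        tbl = anova_lm(model, typ=2)
    rows = []
    rename = {f"C({safe[f]}, Sum)": f for f in factor_names}
    rename.update(
        {
            f"C({safe[a]}, Sum):C({safe[b]}, Sum)": f"{a}*{b}"
            for a, b in itertools.combinations(factor_names, 2)
        }
    )
    for name, r in tbl.iterrows():
        term = rename.get(name, name)
        rows.append(
            (term, int(r["df"]), float(r["sum_sq"]), float(r["sum_sq"]) / max(r["df"], 1),
             float(r["F"]) if np.isfinite(r["F"]) else np.nan,
             float(r["PR(>F)"]) if np.isfinite(r["PR(>F)"]) else np.nan)
        )
    anova = pd.DataFrame(rows, columns=["term", "df", "ss", "ms", "F", "p"])
    anova["significant"] = anova["p"] < alpha

    return FactorialResult(
        grand_mean=gm,
        factor_names=factor_names,
        levels=levels,
        main_effects=main,
        interaction_effects=inter,
        anova=anova,
        n_units=int(keep.sum()),
        alpha=alpha,
    )


def effect_plot_data(result: FactorialResult) -> pd.DataFrame:
    """Per-factor main-effect lines: fitted mean response at each level.

    The line for factor f at level l is grand_mean + effect(f, l); a flat
    line at the global mean indicates no effect.  The global mean is included
    as the reference.
    """
    rows = []
    for f in result.factor_names:
        for l, eff in enumerate(result.main_effects[f]):
            rows.append(
                {
                    "factor": f,
                    "level_index": l,
                    "level": float(result.levels[f][l]),
                    "mean_response": result.grand_mean + float(eff),
                    "effect": float(eff),
                    "grand_mean": result.grand_mean,
                }
            )
    return pd.DataFrame(rows)


def interaction_plot_data(result: FactorialResult) -> pd.DataFrame:
    """Two-factor interaction grids: fitted cell means under the order-2 model.

    cell mean = grand mean + effect_i + effect_j + interaction_ij; parallel
    lines across levels of the second factor indicate a zero interaction.
    """
    rows = []
    for (fi, fj), grid in result.interaction_effects.items():
        ei, ej = result.main_effects[fi], result.main_effects[fj]
        c = len(ei)
        for li in range(c):
            for lj in range(c):
                rows.append(
                    {
                        "factor_i": fi,
                        "factor_j": fj,
                        "level_i": float(result.levels[fi][li]),
                        "level_j": float(result.levels[fj][lj]),
                        "cell_mean": result.grand_mean + ei[li] + ej[lj] + grid[li, lj],
                        "interaction": float(grid[li, lj]),
                    }
                )
    return pd.DataFrame(rows)


def f_value_ranking(result: FactorialResult) -> pd.DataFrame:
    """Model terms ordered by F value (descending), ties broken by term name.

    ``significant`` flags p below the fit's alpha — the green/red split of the
    usual F-value bar chart.
    """
    tbl = result.anova[~result.anova["term"].isin(["Residual", "Total"])].copy()
    tbl = tbl.sort_values(["F", "term"], ascending=[False, True], kind="mergesort")
    return tbl.reset_index(drop=True)


@dataclass
class ConfirmationStats:
    """Platform-versus-static-culture concordance statistics."""

    pearson_r: float
    pearson_p: float
    anova_F: float
    anova_p: float
    tukey: pd.DataFrame
    paired_tests: pd.DataFrame
    fold_change: pd.Series | None = None


def confirmation_stats(
    platform_means: pd.Series,
    static_data: pd.DataFrame,
    control: str,
    value_col: str = "value",
    myocyte_col: str | None = None,
) -> ConfirmationStats:
    """Compare per-condition platform means against static-culture replicates.

    Parameters
    ----------
    platform_means : Series indexed by condition label
    static_data : long DataFrame with columns ``condition``, ``experiment``
        and ``value_col``; replicates are independent experiments
        (inductions) shared across conditions, giving the pairing for the
        paired t-tests.
    control : condition label of the untreated arm.

    Returns Pearson r between platform and static condition means, one-way
    ANOVA across static conditions, Tukey HSD contrasts against the control,
    per-condition paired two-tailed t-tests versus control, and (when
    ``myocyte_col`` is given) the fold change of total myocytes normalized to
    control within each experiment.
    """
    conditions = list(platform_means.index)
    static_means = static_data.groupby("condition")[value_col].mean()
    missing = set(conditions) - set(static_means.index)
    if missing:
        raise ValueError(f"static data missing conditions: {sorted(missing)}")
    static_means = static_means.loc[conditions]
    r, rp = stats.pearsonr(platform_means.to_numpy(), static_means.to_numpy())

    groups = [g[value_col].to_numpy() for _, g in static_data.groupby("condition")]
    F, ap = stats.f_oneway(*groups)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tk = pairwise_tukeyhsd(
        static_data[value_col].to_numpy(), static_data["condition"].to_numpy()
    )
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    tukey = tukey[(tukey["group1"] == control) | (tukey["group2"] == control)]
    tukey = tukey.reset_index(drop=True)

    wide = static_data.pivot_table(
        index="experiment", columns="condition", values=value_col
    )
    rows = []
    for cond in conditions:
        if cond == control:
            continue
        paired = wide[[control, cond]].dropna()
        if len(paired) < 2:
            rows.append({"condition": cond, "t": np.nan, "p": np.nan, "n_pairs": len(paired)})
            continue
        if len(paired) < 3:
            warnings.warn(f"paired t-test for {cond!r} uses only {len(paired)} pairs")
        t, p = stats.ttest_rel(paired[cond], paired[control])
        rows.append({"condition": cond, "t": float(t), "p": float(p), "n_pairs": len(paired)})
    paired_tests = pd.DataFrame(rows)

    fold = None
    if myocyte_col is not None:
        w = static_data.pivot_table(
            index="experiment", columns="condition", values=myocyte_col
        )
        fold = (w.div(w[control], axis=0)).mean(axis=0)
    return ConfirmationStats(
        pearson_r=float(r),
        pearson_p=float(rp),
        anova_F=float(F),
        anova_p=float(ap),
        tukey=tukey,
        paired_tests=paired_tests,
        fold_change=fold,
    )
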