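"""Lobe-wise statistical analysis of the ischemia study.

Covers the study's statistics stage: per-cell summaries and the
baseline-minus-ischemia deltas, two-way ANOVA (lobe x timepoint, with
interaction) followed by Sidak-adjusted pairwise timepoint comparisons
within each lobe, the Pearson correlation matrix between optical and
biological variables, and demarcation-line detection on StO2 maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .oxygenation import OxygenationMaps

#: Ischemia cutoff: absolute StO2 below which tissue is called ischemic.
DEFAULT_DEMARCATION_THRESHOLD = 25.0


class AnalysisError(ValueError):
    """Malformed study table or analysis request."""


# ---------------------------------------------------------------------------
# Cell summaries and printed deltas
# ---------------------------------------------------------------------------

def cell_summaries(
    table: pd.DataFrame,
    variables: Sequence[str] = ("sto2", "lactate", "ref_sto2"),
    baseline: str = "T0",
    ischemia: str = "T1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell means/SDs and baseline-vs-ischemia deltas per (group, lobe).

    Saturation deltas are reported as the drop ``mean(T0) - mean(T1)`` in
    percentage points; the lactate delta is the rise ``mean(T1) - mean(T0)``
    in mmol/L.  Cells absent from the table yield explicit NaN records.

    Returns
    -------
    (cells, deltas) : cells has one row per (group, lobe, timepoint,
    variable); deltas one row per (group, lobe, variable).
    """
    required = {"group", "lobe", "timepoint", *variables}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise AnalysisError(f"study table lacks columns: {sorted(missing_cols)}")

    long = table.melt(
        id_vars=["group", "lobe", "timepoint"],
        value_vars=list(variables),
        var_name="variable",
    )
    cells = (
        long.groupby(["group", "lobe", "timepoint", "variable"], sort=False)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )

    piv = cells.pivot_table(
        index=["group", "lobe", "variable"], columns="timepoint", values="mean"
    )
    rows = []
    for (g, lobe, var), r in piv.iterrows():
        m0 = r.get(baseline, np.nan)
        m1 = r.get(ischemia, np.nan)
        delta = (m1 - m0) if var == "lactate" else (m0 - m1)
        rows.append(
            {
                "group": g,
                "lobe": lobe,
                "variable": var,
                "delta": delta,
                "missing": bool(np.isnan(delta)),
            }
        )
    return cells, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Two-way ANOVA with multiple comparisons
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Two-way ANOVA table plus Sidak-adjusted pairwise comparisons."""

    anova_table: pd.DataFrame
    cell_means: pd.DataFrame
    comparisons: pd.DataFrame
    response: str
    factors: tuple[str, str]
    adjustment: str = "sidak"


def two_way_anova(
    table: pd.DataFrame,
    response: str = "sto2",
    factors: tuple[str, str] = ("lobe", "timepoint"),
    group: str | None = None,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Classical two-factor ANOVA with interaction, then pairwise
    within-``factors[0]`` comparisons across ``factors[1]`` levels.

    Pairwise tests use the pooled residual mean square of the full model
    (the usual post-ANOVA multiple-comparison construction) with Sidak
    adjustment over the whole comparison family.  Deterministic; invariant
    to row order and animal relabelling.
    """
    df = table if group is None else table[table["group"] == group]
    df = df.copy()
    fa, fb = factors
    for f in factors:
        if df[f].nunique() < 2:
            raise AnalysisError(f"factor '{f}' needs >= 2 levels")
    counts = df.groupby([fa, fb], sort=False)[response].count()
    bad = counts[counts < 2]
    if len(bad):
        raise AnalysisError(f"cells with < 2 replicates: {list(bad.index)}")

    if df[response].nunique() == 1:
        # degenerate: no variation at all -> F = 0, p = 1 by convention
        levels = [f"C({fa})", f"C({fb})", f"C({fa}):C({fb})"]
        anova = pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": 0.0, "PR(>F)": 1.0}, index=levels
        )
        mse, dof = 0.0, int(len(df) - df[fa].nunique() * df[fb].nunique())
    else:
        model = smf.ols(f"{response} ~ C({fa}) * C({fb})", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        mse = float(model.mse_resid)
        dof = int(model.df_resid)
    cell_means = (
        df.groupby([fa, fb], sort=False)[response]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )

    # canonical (sorted) level order keeps results invariant to row order
    levels_b = sorted(df[fb].unique())
    comps = []
    for a_level in sorted(df[fa].unique()):
        sub = cell_means[cell_means[fa] == a_level].set_index(fb)
        for b1, b2 in combinations(levels_b, 2):
            m1, n1 = sub.loc[b1, ["mean", "n"]]
            m2, n2 = sub.loc[b2, ["mean", "n"]]
            se = np.sqrt(mse * (1.0 / n1 + 1.0 / n2))
            if se == 0:
                t, p = 0.0, 1.0
            else:
                t = (m1 - m2) / se
                p = 2.0 * stats.t.sf(abs(t), dof)
            comps.append(
                {fa: a_level, "level_a": b1, "level_b": b2,
                 "diff": m1 - m2, "t": t, "p_raw": p}
            )
    comparisons = pd.DataFrame(comps)
    m = len(comparisons)
    comparisons["p_adj"] = 1.0 - (1.0 - comparisons["p_raw"]) ** m
    comparisons["p_adj"] = comparisons["p_adj"].clip(upper=1.0)
    comparisons["significant"] = comparisons["p_adj"] < alpha
    return ComparisonResult(
        anova_table=anova,
        cell_means=cell_means,
        comparisons=comparisons,
        response=response,
        factors=factors,
    )


# ---------------------------------------------------------------------------
# Correlation matrix
# ---------------------------------------------------------------------------

def correlation_matrix(
    table: pd.DataFrame,
    variables: Sequence[str] = ("sto2", "lactate", "ref_sto2"),
    group: str | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson correlations over pooled observations.

    Pools all (animal, lobe, timepoint) rows — across both groups by
    default, within one group if ``group`` is given.  Missing values are
    handled pairwise-complete.  Returns long-format rows (var_x, var_y, r,
    p, n, note); zero-variance pairs are reported as missing with a reason
    rather than raising.
    """
    df = table if group is None else table[table["group"] == group]
    rows = []
    for vx in variables:
        for vy in variables:
            pair = df[[vx, vy]].dropna()
            n = len(pair)
            if vx == vy:
                rows.append({"var_x": vx, "var_y": vy, "r": 1.0, "p": 0.0, "n": n, "note": ""})
                continue
            if n < 3:
                rows.append({"var_x": vx, "var_y": vy, "r": np.nan, "p": np.nan,
                             "n": n, "note": "fewer than 3 complete rows"})
                continue
            if pair[vx].std(ddof=0) == 0 or pair[vy].std(ddof=0) == 0:
                rows.append({"var_x": vx, "var_y": vy, "r": np.nan, "p": np.nan,
                             "n": n, "note": "zero variance"})
                continue
            r, p = stats.pearsonr(pair[vx], pair[vy])
            rows.append({"var_x": vx, "var_y": vy, "r": float(r), "p": float(p),
                         "n": n, "note": ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Demarcation-line detection
# ---------------------------------------------------------------------------

@dataclass
class DemarcationResult:
    """Ischemic-territory segmentation of one StO2 map."""

    mask: np.ndarray  # largest connected ischemic component
    boundary: np.ndarray  # (N, 2) row/col polyline, empty if no territory
    sharpness: float  # median |grad StO2| along the boundary, %/mm; NaN if empty
    threshold: float


def detect_demarcation(
    sto2_map: np.ndarray | OxygenationMaps,
    threshold: float = DEFAULT_DEMARCATION_THRESHOLD,
    pixel_pitch: float = 1.0,
    valid: np.ndarray | None = None,
) -> DemarcationResult:
    """Threshold an StO2 map at an absolute ischemia cutoff and extract the
    demarcation boundary of the largest ischemic territory.

    The sharpness score — the median StO2 gradient magnitude along the
    boundary (%/mm) — quantifies how "pronounced" the demarcation line is;
    a broad transition zone scores low.
    """
    if isinstance(sto2_map, OxygenationMaps):
        valid = sto2_map.valid if valid is None else valid
        sto2_map = sto2_map.sto2
    sto2 = np.asarray(sto2_map, dtype=float)
    ok = np.isfinite(sto2)
    if valid is not None:
        ok &= np.asarray(valid, dtype=bool)

    ischemic = ok & (sto2 < threshold)
    if not ischemic.any():
        return DemarcationResult(
            mask=np.zeros(sto2.shape, dtype=bool),
            boundary=np.empty((0, 2)),
            sharpness=np.nan,
            threshold=threshold,
        )
    labels = measure.label(ischemic, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest

    contours = measure.find_contours(mask.astype(float), 0.5)
    boundary = max(contours, key=len) if contours else np.empty((0, 2))

    gy, gx = np.gradient(np.where(ok, sto2, np.nan), pixel_pitch)
    grad_mag = np.hypot(gx, gy)
    if len(boundary):
        rr = np.clip(np.round(boundary[:, 0]).astype(int), 0, sto2.shape[0] - 1)
        cc = np.clip(np.round(boundary[:, 1]).astype(int), 0, sto2.shape[1] - 1)
        samples = grad_mag[rr, cc]
        samples = samples[np.isfinite(samples)]
        sharpness = float(np.median(samples)) if len(samples) else np.nan
    else:
        sharpness = np.nan
    return DemarcationResult(
        mask=mask, boundary=np.asarray(boundary), sharpness=sharpness,
        threshold=threshold,
    )
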