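"""Cohort-level statistics for pulsation and vasodilation metrics.

Covers the standard battery for this kind of study: ocular perfusion
pressure (OPP = 2/3*(MAP - IOP)), percent-difference variabilities,
one-way ANOVA across disease groups for systemic/ocular metrics, paired
t-tests comparing pulsation metrics between the RV and ONH_T regions,
and Pearson correlations (PF~HR, PA~IOP, PA~D_A_R, PA~D_V_R), each run
on all subjects and with non-diabetic subjects excluded.  Significance
at p <= 0.05; no multiple-testing correction is applied.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_opp",
    "percent_difference",
    "pearson_r",
    "paired_t",
    "anova_oneway",
    "build_report",
    "write_report",
]

REQUIRED_COLUMNS = (
    "subject_id", "group", "age", "HR", "MAP", "IOP", "HbA1c",
    "PA_RV", "PF_RV", "r2_RV", "PA_ONHT", "PF_ONHT", "r2_ONHT",
    "D_A_R", "D_V_R",
)
SYSTEMIC_METRICS = ("age", "HR", "MAP", "IOP", "OPP", "HbA1c")
GROUPS = ("ND", "NDR", "NPDR")


def compute_opp(MAP, IOP):
    """Ocular perfusion pressure in mmHg: (2/3) * (MAP - IOP)."""
    MAP = np.asarray(MAP, dtype=float)
    IOP = np.asarray(IOP, dtype=float)
    if np.any(IOP < 0) or np.any(MAP <= IOP):
        raise ValueError("require MAP > IOP >= 0 (nonphysiological otherwise)")
    out = (2.0 / 3.0) * (MAP - IOP)
    return float(out) if out.ndim == 0 else out


def percent_difference(x1: float, x2: float, denominator: str = "mean") -> float:
    """Unsigned percent difference between two repeated measurements.

    Default denominator is the pair mean: 100*|x1 - x2| / ((x1 + x2)/2);
    ``denominator='first'`` divides by x1 instead.
    """
    if denominator == "mean":
        denom = (x1 + x2) / 2.0
    elif denominator == "first":
        denom = x1
    else:
        raise ValueError("denominator must be mean | first")
    if denom == 0:
        raise ValueError("percent difference undefined for zero denominator")
    return 100.0 * abs(x1 - x2) / abs(denom)


def pearson_r(x, y) -> tuple[float, float, int]:
    """Sample Pearson correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(x)


def paired_t(x, y) -> tuple[float, float, int]:
    """Two-sided paired t-test.

    Degenerate cases follow fixed conventions: identical vectors give
    t = 0, p = 1; a constant nonzero difference (zero difference sd) gives
    an infinite t with p -> 0 and a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    d = x - y
    if np.allclose(d, 0.0):
        return 0.0, 1.0, len(x)
    if d.std(ddof=1) == 0:
        warnings.warn("zero-variance nonzero differences: t is infinite",
                      stacklevel=2)
        return float(np.sign(d.mean()) * np.inf), 0.0, len(x)
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p), len(x)


def anova_oneway(*groups) -> tuple[float, float]:
    """Standard one-way fixed-effects ANOVA across >= 2 groups."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrs):
        raise ValueError("every group needs n >= 2")
    f, p = stats.f_oneway(*arrs)
    return float(f), float(p)


def _mean_sd(v: pd.Series) -> str:
    return f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"


def _corr_cell(df: pd.DataFrame, xcol: str, ycol: str) -> dict:
    sub = df[[xcol, ycol]].dropna()
    try:
        r, p, n = pearson_r(sub[xcol], sub[ycol])
        return {"r": r, "p": p, "n": n}
    except ValueError as e:
        return {"r": None, "p": None, "n": len(sub), "note": str(e)}


def build_report(
    cohort: pd.DataFrame | str | Path,
    qc_mode: str = "fixed",
    qc_value: float = 0.23,
) -> dict:
    """Run the full statistical battery over a cohort results table.

    The table needs one row per subject with systemic metrics, per-ROI
    pulsation metrics (PA/PF/R² for RV and ONH_T) and dilation ratios.
    Subjects failing the R² criterion in either ROI are excluded from the
    pulsation statistics.  Returns a JSON-serializable report: group
    means ± sd with ANOVA p per systemic metric, paired-t comparisons of
    PA and PF between ROIs, and the correlation grid (PF~HR, PA~IOP,
    PA~D_A_R, PA~D_V_R per ROI, with and without ND subjects).
    """
    from .pulsation import qc_exclude

    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.read_csv(cohort)
    for col in REQUIRED_COLUMNS:
        if col not in cohort.columns:
            raise KeyError(f"cohort table is missing required column {col!r}")
    df = cohort.copy()
    if "OPP" not in df.columns:
        df["OPP"] = compute_opp(df["MAP"].to_numpy(), df["IOP"].to_numpy())

    excl = qc_exclude(df[["r2_RV", "r2_ONHT"]].to_numpy(),
                      mode=qc_mode, value=qc_value)
    df["excluded"] = excl
    kept = df[~df["excluded"]]

    # group table (Table-1 style): mean +- sd per group + ANOVA p
    group_table: dict = {}
    present = [g for g in GROUPS if (df["group"] == g).sum() > 0]
    for metric in SYSTEMIC_METRICS:
        row = {"All": _mean_sd(df[metric])}
        for g in present:
            row[g] = _mean_sd(df.loc[df["group"] == g, metric])
        samples = [df.loc[df["group"] == g, metric].to_numpy()
                   for g in present]
        if len(samples) >= 2 and all(len(s) >= 2 for s in samples):
            _, p = anova_oneway(*samples)
            row["anova_p"] = p
        else:
            row["anova_p"] = None  # not applicable with a single group
        group_table[metric] = row

    # paired comparisons of pulsation metrics between ROIs (Table-2 style)
    paired: dict = {}
    for metric in ("PA", "PF", "r2"):
        a = kept[f"{metric}_RV"].to_numpy()
        b = kept[f"{metric}_ONHT"].to_numpy()
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() >= 2:
            t, p, n = paired_t(a[ok], b[ok])
            paired[metric] = {
                "RV": _mean_sd(pd.Series(a[ok])),
                "ONHT": _mean_sd(pd.Series(b[ok])),
                "t": t, "p": p, "n": n,
            }
        else:
            paired[metric] = {"note": "insufficient paired data"}

    # correlation grid, each with and without ND subjects
    correlations: dict = {}
    no_nd = kept[kept["group"] != "ND"]
    for roi in ("RV", "ONHT"):
        grid = {}
        pairs = [
            (f"PF_{roi}", "HR"),
            (f"PA_{roi}", "IOP"),
            (f"PA_{roi}", "D_A_R"),
            (f"PA_{roi}", "D_V_R"),
        ]
        for ycol, xcol in pairs:
            key = f"{ycol}~{xcol}"
            grid[key] = {
                "all": _corr_cell(kept, xcol, ycol),
                "without_ND": _corr_cell(no_nd, xcol, ycol),
            }
        correlations[roi] = grid

    return {
        "n_subjects": int(len(df)),
        "n_excluded": int(excl.sum()),
        "qc": {"mode": qc_mode, "value": qc_value},
        "group_table": group_table,
        "paired_roi_comparisons": paired,
        "correlations": correlations,
        "excluded_subjects": df.loc[df["excluded"], "subject_id"].tolist(),
    }


def write_report(report: dict, outdir: str | Path) -> None:
    """Write report.json and a human-readable report.md."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    lines = [
        "# Cohort report",
        "",
        f"Subjects: {report['n_subjects']} "
        f"(excluded by R² QC: {report['n_excluded']})",
        "",
        "## Systemic and ocular metrics by group",
        "",
    ]
    gt = report["group_table"]
    groups = [k for k in ("All", "ND", "NDR", "NPDR")
              if any(k in row for row in gt.values())]
    lines.append("| metric | " + " | ".join(groups) + " | ANOVA p |")
    lines.append("|" + "---|" * (len(groups) + 2))
    for metric, row in gt.items():
        p = row.get("anova_p")
        cells = [row.get(g, "-") for g in groups]
        lines.append(
            f"| {metric} | " + " | ".join(cells) + " | "
            + (f"{p:.3g}" if p is not None else "n/a") + " |"
        )
    lines += ["", "## Pulsation metrics: RV vs ONH_T (paired t)", ""]
    lines.append("| metric | RV | ONH_T | t | p | n |")
    lines.append("|---|---|---|---|---|---|")
    for metric, row in report["paired_roi_comparisons"].items():
        if "t" in row:
            lines.append(
                f"| {metric} | {row['RV']} | {row['ONHT']} "
                f"| {row['t']:.3g} | {row['p']:.3g} | {row['n']} |"
            )
        else:
            lines.append(f"| {metric} | {row.get('note', 'n/a')} | | | | |")
    lines += ["", "## Correlations (Pearson)", ""]
    lines.append("| ROI | pair | r (all) | p (all) | r (no ND) | p (no ND) |")
    lines.append("|---|---|---|---|---|---|")
    def _num(v, spec: str) -> str:
        return "-" if v is None else format(v, spec)

    for roi, grid in report["correlations"].items():
        for pair, cell in grid.items():
            a, w = cell["all"], cell["without_ND"]
            lines.append(
                f"| {roi} | {pair} | {_num(a['r'], '.3f')} "
                f"| {_num(a['p'], '.3g')} | {_num(w['r'], '.3f')} "
                f"| {_num(w['p'], '.3g')} |"
            )
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
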