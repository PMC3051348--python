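"""Accuracy and precision statistics for CT volume measurements.

Primitives
----------
* :func:`cov` — coefficient of variation of replicate volumes (sample
  standard deviation over mean, as a percent).
* :func:`ci95` — t-based 95% confidence interval for small replicate
  counts.
* :func:`accuracy_slope` — slope of measured versus true volume with
  the fit forced through the origin; a perfect volumeter has slope 1.
* :func:`anova_oneway_bonferroni` — classical one-way ANOVA with
  Bonferroni-adjusted pairwise comparisons.
* :func:`error_summary` — detected-only percent-error summaries per
  condition and diameter.
* :func:`lookup_min_diameter` — smallest sphere diameter measurable
  within a given error tolerance, by linear interpolation over the
  tested diameters.

Model interface
---------------
:class:`VolumetryAccuracyModel` wraps a tidy measurement table (one row
per sphere and imaging condition) and its :meth:`fit` returns a
:class:`VolumetryAccuracyResults` carrying per-condition accuracy
slopes, precision tables, factor ANOVAs, tolerance lookup tables and a
text ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AccuracySlope", "LookupEntry", "AnovaResult",
    "cov", "ci95", "accuracy_slope", "anova_oneway_bonferroni",
    "error_summary", "lookup_min_diameter",
    "VolumetryAccuracyModel", "VolumetryAccuracyResults",
]

CONDITION_COLS = ["fov_cm", "kernel", "slice_thickness_mm"]


# ---------------------------------------------------------------------
# primitives

def cov(values) -> float:
    """Coefficient of variation: sample SD (n-1) over mean, in percent."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("cov needs >= 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("cov undefined for zero mean")
    return float(v.std(ddof=1) / m * 100.0)


def ci95(values) -> tuple[float, float]:
    """95% confidence interval for the mean: mean +/- t_{.975,n-1} SE."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("ci95 needs >= 2 values")
    m = v.mean()
    half = sps.t.ppf(0.975, v.size - 1) * v.std(ddof=1) / math.sqrt(v.size)
    return (float(m - half), float(m + half))


@dataclass(frozen=True)
class AccuracySlope:
    """Origin-forced regression of measured on true volume."""

    slope: float
    r_squared: float
    n: int
    condition: tuple | None = None


def accuracy_slope(pairs) -> AccuracySlope:
    """Least-squares slope of V_CT on V_true through the origin.

    ``slope = sum(V_true * V_CT) / sum(V_true^2)``; the coefficient of
    determination uses the uncentered total sum of squares, as is
    conventional for regression through the origin.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0 or not np.any(arr[:, 0] > 0):
        raise ValueError("need >= 1 pair with V_true > 0")
    x, y = arr[:, 0], arr[:, 1]
    sxx = float(np.sum(x * x))
    slope = float(np.sum(x * y)) / sxx
    syy = float(np.sum(y * y))
    ss_res = float(np.sum((y - slope * x) ** 2))
    r2 = 1.0 - ss_res / syy if syy > 0 else 1.0
    return AccuracySlope(slope=slope, r_squared=r2, n=len(x))


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    pairwise_adjusted: dict[tuple[int, int], float]
    n_comparisons: int


def anova_oneway_bonferroni(groups, n_comparisons: int | None = None
                            ) -> AnovaResult:
    """One-way ANOVA plus Bonferroni-adjusted pairwise t-tests.

    Pairwise two-sample t-test p values are multiplied by
    ``n_comparisons`` (default: the number of pairs) and capped at 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    f, p = sps.f_oneway(*groups)
    pairs = [(i, j) for i in range(len(groups))
             for j in range(i + 1, len(groups))]
    if n_comparisons is None:
        n_comparisons = len(pairs)
    pairwise = {}
    for i, j in pairs:
        _, praw = sps.ttest_ind(groups[i], groups[j], equal_var=True)
        pairwise[(i, j)] = min(1.0, float(praw) * n_comparisons)
    return AnovaResult(f_statistic=float(f), p_value=float(p),
                       pairwise_adjusted=pairwise,
                       n_comparisons=n_comparisons)


def error_summary(data: pd.DataFrame,
                  by: list[str] | None = None) -> pd.DataFrame:
    """Detected-only percent-error summaries with standard errors.

    Groups by ``by`` (default: condition columns plus diameter) and
    reports n, mean, median, min, max and the standard error of the
    mean.  Non-detections are excluded; empty cells are simply absent.
    """
    if data.empty:
        raise ValueError("empty measurement table")
    if by is None:
        by = [c for c in CONDITION_COLS if c in data.columns] + ["diameter_mm"]
    det = data[data["detected"]]
    g = det.groupby(by)["percent_error"]
    out = g.agg(n="count", mean="mean", median="median",
                min="min", max="max", sd=lambda v: v.std(ddof=1))
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out.reset_index()


@dataclass(frozen=True)
class LookupEntry:
    """Minimum measurable diameter at an error tolerance, or a sentinel."""

    tolerance: float
    min_diameter: float | None
    sentinel: str | None = None     # "> max tested" / "< min tested"
    condition: tuple | None = None

    def __str__(self) -> str:
        if self.sentinel == "> max tested":
            return f">{self._edge:g}"
        if self.sentinel == "< min tested":
            return f"<{self._edge:g}"
        return f"{self.min_diameter:.1f}"

    @property
    def _edge(self) -> float:
        return self.min_diameter if self.min_diameter is not None else float("nan")


def lookup_min_diameter(curve, tolerance: float) -> LookupEntry:
    """Smallest diameter whose expected |error| stays within tolerance.

    ``curve`` is a sequence of (diameter mm, expected |error| %) sorted
    by increasing diameter.  Returns the smallest d such that the
    linearly interpolated |error| is <= tolerance for every tested
    diameter >= d.  If even the largest tested diameter exceeds the
    tolerance the sentinel ``"> max tested"`` is returned; if the
    smallest tested diameter already passes, ``"< min tested"``.
    """
    arr = np.asarray(list(curve), dtype=float)
    if arr.ndim != 2 or len(arr) < 2:
        raise ValueError("curve needs >= 2 (diameter, error) points")
    d, e = arr[:, 0], arr[:, 1]
    if np.any(np.diff(d) <= 0):
        raise ValueError("diameters must be strictly increasing")
    fails = e > tolerance
    if fails[-1]:
        return LookupEntry(tolerance=tolerance, min_diameter=float(d[-1]),
                           sentinel="> max tested")
    if not fails.any():
        return LookupEntry(tolerance=tolerance, min_diameter=float(d[0]),
                           sentinel="< min tested")
    i = int(np.max(np.nonzero(fails)))  # last failing; all above pass
    # Linear interpolation of the tolerance crossing in (d[i], d[i+1]].
    frac = (e[i] - tolerance) / (e[i] - e[i + 1])
    return LookupEntry(tolerance=tolerance,
                       min_diameter=float(d[i] + frac * (d[i + 1] - d[i])))


# ---------------------------------------------------------------------
# model / results

class VolumetryAccuracyModel:
    """Accuracy/precision analysis of a sphere-measurement table.

    Parameters
    ----------
    data : DataFrame
        Tidy table with one row per sphere x condition; required
        columns: ``diameter_mm``, ``v_true_mm3``, ``v_ct_mm3``,
        ``percent_error``, ``detected``, plus the condition columns
        ``fov_cm``, ``kernel``, ``slice_thickness_mm``.
    exclude_diameters : sequence of float
        Size classes generated but excluded from analysis (default:
        none; the pipeline excludes the smallest, problematic class).
    n_replicates : int
        Replicates per size class, used for precision tables.
    """

    def __init__(self, data: pd.DataFrame,
                 exclude_diameters=(), n_replicates: int = 5):
        required = {"diameter_mm", "v_true_mm3", "v_ct_mm3",
                    "percent_error", "detected", *CONDITION_COLS}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"measurement table missing columns: {missing}")
        keep = ~data["diameter_mm"].apply(
            lambda d: any(np.isclose(d, x) for x in exclude_diameters))
        self.data = data[keep].reset_index(drop=True)
        if self.data.empty:
            raise ValueError("no measurements left after exclusions")
        self.exclude_diameters = tuple(exclude_diameters)
        self.n_replicates = n_replicates

    @classmethod
    def from_measurements(cls, measurements, **kwargs) -> "VolumetryAccuracyModel":
        from .measurement import measurements_to_frame
        return cls(measurements_to_frame(measurements), **kwargs)

    def fit(self, tolerances=(10.0, 20.0)) -> "VolumetryAccuracyResults":
        """Compute slopes, precision, summaries, ANOVAs and lookups."""
        df = self.data
        det = df[df["detected"]]

        # Per-condition origin-forced accuracy slopes.
        slope_rows = []
        for cond, grp in det.groupby(CONDITION_COLS):
            res = accuracy_slope(grp[["v_true_mm3", "v_ct_mm3"]].to_numpy())
            slope_rows.append(dict(zip(CONDITION_COLS, cond))
                              | {"slope": res.slope, "r_squared": res.r_squared,
                                 "n": res.n})
        slopes = (pd.DataFrame(slope_rows).sort_values(
            CONDITION_COLS).reset_index(drop=True) if slope_rows
            else pd.DataFrame(columns=CONDITION_COLS
                              + ["slope", "r_squared", "n"]))

        # Precision per condition x diameter: COV and 95% CI of V_CT.
        prec_rows = []
        for key, grp in det.groupby(CONDITION_COLS + ["diameter_mm"]):
            v = grp["v_ct_mm3"].to_numpy()
            row = dict(zip(CONDITION_COLS + ["diameter_mm"], key))
            row["n_detected"] = len(v)
            row["mean_v_ct_mm3"] = v.mean()
            if len(v) >= 2:
                row["sd_mm3"] = v.std(ddof=1)
                row["cov_pct"] = cov(v)
                row["ci95_low_mm3"], row["ci95_high_mm3"] = ci95(v)
            else:
                row["sd_mm3"] = row["cov_pct"] = np.nan
                row["ci95_low_mm3"] = row["ci95_high_mm3"] = np.nan
            prec_rows.append(row)
        precision = (pd.DataFrame(prec_rows).sort_values(
            CONDITION_COLS + ["diameter_mm"]).reset_index(drop=True)
            if prec_rows else pd.DataFrame(
                columns=CONDITION_COLS + ["diameter_mm", "n_detected"]))

        summary = error_summary(df)

        # One-way ANOVA per factor on detected percent error.
        anovas = {}
        factors = {"diameter_mm": "sphere size",
                   "slice_thickness_mm": "slice thickness",
                   "fov_cm": "field of view", "kernel": "kernel"}
        for col in factors:
            groups = [g["percent_error"].to_numpy()
                      for _, g in det.groupby(col) if len(g) >= 2]
            if len(groups) >= 2:
                anovas[col] = anova_oneway_bonferroni(groups)

        # Tolerance lookup per condition from mean |error| vs diameter.
        lookup_rows = []
        for cond, grp in det.groupby(CONDITION_COLS):
            curve = (grp.assign(abs_err=grp["percent_error"].abs())
                     .groupby("diameter_mm")["abs_err"].mean())
            if len(curve) < 2:
                continue
            pts = list(zip(curve.index.to_numpy(), curve.to_numpy()))
            row = dict(zip(CONDITION_COLS, cond))
            for tol in tolerances:
                entry = lookup_min_diameter(pts, tol)
                row[f"min_diameter_{tol:g}pct"] = str(entry)
            lookup_rows.append(row)
        lookup = (pd.DataFrame(lookup_rows).sort_values(
            CONDITION_COLS).reset_index(drop=True) if lookup_rows
            else pd.DataFrame(columns=CONDITION_COLS))

        return VolumetryAccuracyResults(
            model=self, slopes=slopes, precision=precision,
            error_summaries=summary, anovas=anovas, lookup=lookup,
            tolerances=tuple(tolerances))


class VolumetryAccuracyResults:
    """Fitted accuracy/precision tables with a text summary and plots."""

    def __init__(self, model, slopes, precision, error_summaries, anovas,
                 lookup, tolerances):
        self.model = model
        self.slopes = slopes
        self.precision = precision
        self.error_summaries = error_summaries
        self.anovas = anovas
        self.lookup = lookup
        self.tolerances = tolerances

    # -- derived views ------------------------------------------------

    def mean_error_by_thickness(self) -> pd.Series:
        """Mean signed percent error across conditions, per thickness."""
        det = self.model.data[self.model.data["detected"]]
        return det.groupby("slice_thickness_mm")["percent_error"].mean()

    def detection_rates(self) -> pd.Series:
        """Detection fraction per diameter across all conditions."""
        return self.model.data.groupby("diameter_mm")["detected"].mean()

    def summary(self) -> str:
        df = self.model.data
        det = df[df["detected"]]
        lines = [
            "CT volumetry accuracy study",
            "=" * 60,
            f"measurement slots: {len(df)}  detected: {len(det)}"
            f"  ({len(det) / len(df) * 100:.1f}%)",
            f"conditions: {df.groupby(CONDITION_COLS).ngroups}"
            f"  diameters analyzed: {df['diameter_mm'].nunique()}",
            "",
            "origin-forced slope (measured vs true volume)",
            f"  range: {self.slopes['slope'].min():.3f} .. "
            f"{self.slopes['slope'].max():.3f}",
            "",
            "mean signed percent error by slice thickness:",
        ]
        for t, e in self.mean_error_by_thickness().items():
            lines.append(f"  {t:>6.3g} mm : {e:7.1f} %")
        lines.append("")
        lines.append("one-way ANOVA on percent error (detected only):")
        for col, res in self.anovas.items():
            p = "<0.0001" if res.p_value < 1e-4 else f"{res.p_value:.3g}"
            lines.append(f"  {col:<20s} F = {res.f_statistic:9.2f}   p = {p}")
        return "\n".join(lines)

    # -- plots --------------------------------------------------------

    def plot_percent_error(self, fov_cm=None, kernel=None, ax=None):
        """Percent error vs diameter, one curve per slice thickness."""
        import matplotlib.pyplot as plt

        det = self.model.data[self.model.data["detected"]]
        if fov_cm is not None:
            det = det[det["fov_cm"] == fov_cm]
        if kernel is not None:
            det = det[det["kernel"] == kernel]
        if ax is None:
            _, ax = plt.subplots()
        for t, grp in det.groupby("slice_thickness_mm"):
            s = grp.groupby("diameter_mm")["percent_error"]
            ax.errorbar(s.mean().index, s.mean().to_numpy(),
                        yerr=(s.std(ddof=1) / np.sqrt(s.count())).to_numpy(),
                        marker="o", capsize=3, label=f"{t:g} mm")
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("sphere diameter (mm)")
        ax.set_ylabel("percent error in volume")
        ax.legend(title="slice thickness")
        return ax

    def plot_slopes(self, ax=None):
        """Accuracy slope vs slice thickness, grouped by kernel and FOV."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for (kern, fov), grp in self.slopes.groupby(["kernel", "fov_cm"]):
            grp = grp.sort_values("slice_thickness_mm")
            ax.plot(grp["slice_thickness_mm"], grp["slope"], marker="o",
                    label=f"{kern}, {fov:g} cm")
        ax.axhline(1.0, color="k", lw=0.5)
        ax.set_xlabel("slice thickness (mm)")
        ax.set_ylabel("slope, measured vs true volume")
        ax.legend(fontsize="small")
        return ax
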