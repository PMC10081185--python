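"""Scaling-law statistics for vascular trees.

* Branching ratio: segment counts N per Strahler order O decay as
  ``N = N0 * γ^(-O)``; γ is recovered as ``exp(-slope)`` of the ordinary
  least-squares fit of ln N on O.
* Murray's law: at a bifurcation the cube of the parent radius equals the
  sum of the cubed child radii.  Each junction contributes a point
  ``x = (Σ r_i³)^(1/3), y = r_parent``; the law is the identity line, and
  the network's deviation is measured by the fitted slope/intercept/R².
* Robust FDR outlier removal (a documented approximation of the
  ROUT procedure: least-absolute-deviation line, residual scale from the
  68.27th percentile of |residuals|, Benjamini–Hochberg step at rate Q).
* Extra-sum-of-squares F tests for nested model comparisons, including the
  shared-vs-separate log-radius scaling comparison across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .graph import SpatialGraph
from .ordering import OrderingResult, root_segment_tree

__all__ = [
    "BranchingRatioFit",
    "BifurcationRecord",
    "MurrayFit",
    "FTestResult",
    "OutlierConfig",
    "ScalingComparison",
    "fit_branching_ratio",
    "extract_bifurcations",
    "murray_regression",
    "remove_outliers",
    "extra_ss_ftest",
    "compare_scaling",
    "extrapolate_orders",
]


@dataclass
class BranchingRatioFit:
    gamma: float
    n0: float
    slope: float
    intercept: float
    r2: float
    orders_used: list[int]


@dataclass
class BifurcationRecord:
    node_id: int
    parent_segment: int
    parent_radius: float
    child_radii: list[float]
    parent_order: int | None = None


@dataclass
class MurrayFit:
    slope: float
    intercept: float
    r2: float
    n_points: int
    n_outliers_removed: int


@dataclass
class FTestResult:
    f: float
    df_num: int
    df_den: int
    p: float


@dataclass
class OutlierConfig:
    """FDR-controlled robust outlier removal; ``method="none"`` disables it."""

    method: str = "fdr_robust"
    q: float = 0.0005  # maximum false discovery rate (0.05%)

    def validate(self) -> None:
        if self.method not in ("fdr_robust", "none"):
            raise ValueError(f"unknown outlier method {self.method!r}")
        if not (0.0 <= self.q <= 1.0):
            raise ValueError("Q must be in [0, 1]")


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def fit_branching_ratio(counts: dict[int, int] | pd.Series) -> BranchingRatioFit:
    """γ and N0 from the log-linear fit of segment counts vs Strahler order."""
    series = pd.Series(counts, dtype=float).sort_index()
    series = series[series >= 1]
    if len(series) < 2:
        raise ValueError("branching-ratio fit needs >= 2 orders with N >= 1")
    o = series.index.to_numpy(dtype=float)
    ln_n = np.log(series.to_numpy())
    slope, intercept, r2 = _ols(o, ln_n)
    return BranchingRatioFit(gamma=float(np.exp(-slope)), n0=float(np.exp(intercept)),
                             slope=slope, intercept=intercept, r2=r2,
                             orders_used=[int(v) for v in series.index])


def extract_bifurcations(g: SpatialGraph, metrics: pd.DataFrame,
                         ordering: OrderingResult) -> list[BifurcationRecord]:
    """One record per junction with >= 2 children away from the root."""
    tree = root_segment_tree(g, ordering.root)
    records = []
    for parent_sid, kids in sorted(tree.children.items()):
        if len(kids) < 2:
            continue
        records.append(
            BifurcationRecord(
                node_id=tree.distal[parent_sid],
                parent_segment=parent_sid,
                parent_radius=float(metrics.loc[parent_sid, "radius"]),
                child_radii=[float(metrics.loc[k, "radius"]) for k in kids],
                parent_order=ordering.strahler.get(parent_sid),
            )
        )
    return records


def remove_outliers(x: np.ndarray, y: np.ndarray,
                    cfg: OutlierConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Robust-regression FDR outlier split; returns (kept, removed) indices.

    A least-absolute-deviations line is fitted; the residual scale is the
    68.27th percentile of |residuals| (the robust standard deviation).
    Each point's t-like statistic residual/scale is converted to a two-sided
    p-value on n - 2 degrees of freedom and a Benjamini–Hochberg step at
    rate Q marks the discoveries as outliers.  Q = 0 removes nothing.
    """
    cfg = cfg or OutlierConfig()
    cfg.validate()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("outlier removal needs >= 4 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values equal")
    all_idx = np.arange(n)
    if cfg.method == "none" or cfg.q == 0.0:
        return all_idx, np.array([], dtype=int)
    slope, intercept = _lad_fit(x, y)
    resid = y - (slope * x + intercept)
    scale = float(np.percentile(np.abs(resid), 68.27))
    noise_floor = 1e-10 * max(1.0, float(np.abs(y).max()))
    if scale <= noise_floor:  # (near-)exact fit: only gross deviations count
        removed = all_idx[np.abs(resid) > noise_floor]
        return np.setdiff1d(all_idx, removed), removed
    t = np.abs(resid) / scale
    p = 2.0 * stats.t.sf(t, df=max(n - 2, 1))
    order = np.argsort(p)
    thresh = cfg.q * (np.arange(1, n + 1)) / n
    passed = p[order] <= thresh
    k = int(np.max(np.nonzero(passed)[0]) + 1) if passed.any() else 0
    removed = np.sort(order[:k])
    return np.setdiff1d(all_idx, removed), removed


def _lad_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-absolute-deviations line via iteratively reweighted least squares."""
    slope, intercept = np.polyfit(x, y, 1)
    for _ in range(50):
        resid = np.abs(y - (slope * x + intercept))
        w = 1.0 / np.maximum(resid, 1e-12 * max(np.abs(y).max(), 1.0))
        wx = w * x
        a = np.array([[np.sum(w * x * x), np.sum(wx)], [np.sum(wx), np.sum(w)]])
        b = np.array([np.sum(wx * y), np.sum(w * y)])
        try:
            new_slope, new_intercept = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            break
        if abs(new_slope - slope) < 1e-12 and abs(new_intercept - intercept) < 1e-12:
            slope, intercept = new_slope, new_intercept
            break
        slope, intercept = new_slope, new_intercept
    return float(slope), float(intercept)


def murray_regression(records: list[BifurcationRecord], unit_scale: float = 1.0,
                      outliers: OutlierConfig | None = None,
                      cube_space: bool = False) -> MurrayFit:
    """Fit parent radius against the cube-summed child radius.

    Per record: ``x = (Σ r_i³)^(1/3)``, ``y = r_parent`` (both multiplied by
    ``unit_scale``; use 1e-6 for radii recorded in μm but fitted in metres).
    ``cube_space`` regresses the cubes themselves instead.  The theoretical
    Murray line is the identity either way.
    """
    if len(records) < 3:
        raise ValueError("Murray regression needs >= 3 bifurcation records")
    x = np.array([sum(r**3 for r in rec.child_radii) ** (1.0 / 3.0) for rec in records])
    y = np.array([rec.parent_radius for rec in records])
    x = x * unit_scale
    y = y * unit_scale
    if cube_space:
        x, y = x**3, y**3
    cfg = outliers or OutlierConfig(method="none")
    if cfg.method != "none" and len(x) >= 4:
        kept, removed = remove_outliers(x, y, cfg)
        x, y = x[kept], y[kept]
        n_removed = len(removed)
    else:
        n_removed = 0
    if len(x) < 3:
        raise ValueError("fewer than 3 records remain after outlier removal")
    slope, intercept, r2 = _ols(x, y)
    return MurrayFit(slope=slope, intercept=intercept, r2=r2, n_points=len(x),
                     n_outliers_removed=n_removed)


def extra_ss_ftest(ss_null: float, df_null: int, ss_alt: float, df_alt: int) -> FTestResult:
    """Extra-sum-of-squares F test of nested models (null within alternative)."""
    if not (ss_null >= ss_alt >= 0):
        raise ValueError("need ss_null >= ss_alt >= 0")
    if not (df_null > df_alt >= 1):
        raise ValueError("need df_null > df_alt >= 1")
    df_num = df_null - df_alt
    f = ((ss_null - ss_alt) / df_num) / (ss_alt / df_alt) if ss_alt > 0 else (
        0.0 if ss_null == ss_alt else np.inf)
    p = float(stats.f.sf(f, df_num, df_alt))
    return FTestResult(f=float(f), df_num=df_num, df_den=df_alt, p=p)


@dataclass
class ScalingComparison:
    fits: dict[str, tuple[float, float, float]]  # name -> (slope, intercept, r2)
    global_fit: tuple[float, float, float]
    ftest: FTestResult
    ref_order: int


def compare_scaling(dataset_a: dict[int, float] | pd.Series,
                    dataset_b: dict[int, float] | pd.Series,
                    ref_order: int = 9,
                    names: tuple[str, str] = ("a", "b")) -> ScalingComparison:
    """Shared-vs-separate log-radius scaling across two datasets.

    Each dataset maps Strahler order to mean radius.  Radii are normalised to
    the dataset's value at ``ref_order``; ln(normalised radius) is regressed
    on order per dataset and pooled, and the single-line null hypothesis is
    tested with an extra-sum-of-squares F test (2 constrained parameters).
    """
    series = []
    for name, d in zip(names, (dataset_a, dataset_b)):
        s = pd.Series(d, dtype=float).sort_index()
        if ref_order not in s.index:
            raise ValueError(f"dataset {name!r} does not cover reference order {ref_order}")
        series.append(np.log(s / s.loc[ref_order]))
    fits = {}
    ss_alt = 0.0
    n_total = 0
    xs, ys = [], []
    for name, s in zip(names, series):
        x = s.index.to_numpy(dtype=float)
        y = s.to_numpy()
        slope, intercept, r2 = _ols(x, y)
        fits[name] = (slope, intercept, r2)
        ss_alt += float(((y - (slope * x + intercept)) ** 2).sum())
        n_total += len(x)
        xs.append(x)
        ys.append(y)
    x_all = np.concatenate(xs)
    y_all = np.concatenate(ys)
    g_slope, g_intercept, g_r2 = _ols(x_all, y_all)
    ss_null = float(((y_all - (g_slope * x_all + g_intercept)) ** 2).sum())
    ss_null = max(ss_null, ss_alt)  # guard against roundoff on identical datasets
    ftest = extra_ss_ftest(ss_null, n_total - 2, ss_alt, n_total - 4)
    return ScalingComparison(fits=fits, global_fit=(g_slope, g_intercept, g_r2),
                             ftest=ftest, ref_order=ref_order)


def extrapolate_orders(n_terminal: float, n_target: float, gamma: float) -> int:
    """Additional Strahler orders implied by scaling terminal counts by γ per order."""
    if n_terminal < 1 or n_target < 1:
        raise ValueError("counts must be >= 1")
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    extra = round(np.log(n_target / n_terminal) / np.log(gamma))
    return max(int(extra), 0)
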