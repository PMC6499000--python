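"""Per-spheroid readouts, growth-curve fitting and the group-statistics layer.

Readouts follow the study design: fluorescence (propidium iodide for necrosis,
calcein for viability) is averaged over the segmented spheroid area after
subtracting a background level estimated as the median intensity outside the
total mask; spheroid areas are normalized to the mean area of the untreated
controls of the same model and day; growth curves are fit with a three-
parameter logistic.  Group comparisons run a d'Agostino-Pearson normality
check, then Student's t-test (two groups) or one-way ANOVA with
Bonferroni-adjusted pairwise post-hoc tests (more than two groups).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "mean_intensity_in_mask",
    "background_level",
    "normalize_areas",
    "LogisticFit",
    "fit_logistic_growth",
    "compare_groups",
]


def background_level(channel: np.ndarray, total_mask: np.ndarray) -> float:
    """Median intensity outside the total spheroid mask (0 if mask fills frame)."""
    channel = np.asarray(channel, dtype=float)
    outside = channel[~np.asarray(total_mask, dtype=bool)]
    return float(np.median(outside)) if outside.size else 0.0


def mean_intensity_in_mask(
    channel: np.ndarray,
    mask: np.ndarray,
    background: float = 0.0,
) -> float:
    """Arithmetic mean of a channel over mask pixels, background-subtracted.

    The background is subtracted per pixel and clamped at zero before
    averaging.  An empty mask is an explicit no-region outcome returned as
    ``nan`` rather than an exception.
    """
    channel = np.asarray(channel, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if channel.shape != mask.shape:
        raise ValueError(f"shape mismatch: channel {channel.shape} vs mask {mask.shape}")
    if not mask.any():
        return float("nan")
    vals = np.clip(channel[mask] - background, 0.0, None)
    return float(vals.mean())


def normalize_areas(
    records: pd.DataFrame,
    area_col: str = "total_area_um2",
    by: tuple[str, ...] = ("model", "day"),
    control_query: str = "pdt_fluence_J_cm2 == 0 and rt_dose_Gy == 0",
    out_col: str = "norm_area",
) -> pd.DataFrame:
    """Divide each area by the mean control area of its (model, day) group.

    By construction the untreated group has mean normalized area 1.  Groups
    without any control record are rejected, listing the orphaned keys.
    """
    records = records.copy()
    controls = records.query(control_query)
    ctrl_mean = controls.groupby(list(by))[area_col].mean()
    keys = records.set_index(list(by)).index
    orphans = sorted(set(keys) - set(ctrl_mean.index))
    if orphans:
        raise ValueError(f"no untreated control records for groups: {orphans}")
    records[out_col] = records[area_col].to_numpy() / ctrl_mean.loc[keys].to_numpy()
    return records


@dataclass
class LogisticFit:
    """Three-parameter logistic growth fit A(t) = K / (1 + exp(-r (t - t0)))."""

    K: float | None
    r: float | None
    t0: float | None
    residual_norm: float | None
    converged: bool
    degenerate: bool = False
    message: str = ""


def _logistic(t: np.ndarray, K: float, r: float, t0: float) -> np.ndarray:
    return K / (1.0 + np.exp(-r * (t - t0)))


def fit_logistic_growth(days: np.ndarray, areas_um2: np.ndarray) -> LogisticFit:
    """Least-squares logistic fit of a spheroid growth curve.

    Constant (plateaued) curves are reported with K at the plateau and the
    rate flagged as degenerate; non-convergence is flagged, parameters absent.
    """
    t = np.asarray(days, dtype=float)
    a = np.asarray(areas_um2, dtype=float)
    if t.ndim != 1 or t.shape != a.shape:
        raise ValueError("days and areas must be matched 1-D arrays")
    if t.size < 4:
        raise ValueError("need at least 4 time points for a logistic fit")
    if np.any(np.diff(t) <= 0):
        raise ValueError("days must be strictly increasing")
    if np.any(a < 0):
        raise ValueError("areas must be >= 0")

    if np.ptp(a) <= 1e-9 * max(1.0, abs(a.mean())):
        return LogisticFit(
            K=float(a.mean()), r=None, t0=None, residual_norm=0.0,
            converged=True, degenerate=True, message="constant areas: rate unconstrained",
        )

    p0 = (1.05 * a.max(), 4.0 / max(np.ptp(t), 1.0), float(t[np.argmin(np.abs(a - a.max() / 2.0))]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _logistic, t, a, p0=p0,
                bounds=([0.0, 0.0, t.min() - np.ptp(t)], [np.inf, np.inf, t.max() + np.ptp(t)]),
                maxfev=10000,
            )
    except (RuntimeError, ValueError) as exc:
        return LogisticFit(None, None, None, None, converged=False, message=str(exc))
    resid = float(np.linalg.norm(a - _logistic(t, *popt)))
    return LogisticFit(K=float(popt[0]), r=float(popt[1]), t0=float(popt[2]),
                       residual_norm=resid, converged=True)


@dataclass
class GroupComparison:
    """Report of one family of group comparisons."""

    test: str  # "t-test" | "anova" | "none"
    statistic: float | None
    p_value: float | None
    normality_p: dict[str, float | None]
    pairwise: list[dict] = field(default_factory=list)  # raw + Bonferroni-adjusted
    excluded: list[str] = field(default_factory=list)
    n_comparisons: int = 0


def compare_groups(groups: dict[str, np.ndarray], alpha: float = 0.05) -> GroupComparison:
    """Normality check, then t-test or one-way ANOVA + Bonferroni post hoc.

    Groups with fewer than 2 values are excluded with a warning.  The
    Bonferroni family is all pairwise comparisons among the included groups:
    p_adj = min(1, m * p_raw) with m = k(k-1)/2.
    """
    usable: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            excluded.append(name)
            warnings.warn(f"group {name!r} has <2 values; excluded", stacklevel=2)
        else:
            usable[name] = vals
    if len(usable) < 2:
        return GroupComparison("none", None, None, {}, excluded=excluded)

    normality: dict[str, float | None] = {}
    for name, vals in usable.items():
        if vals.size >= 8:  # d'Agostino-Pearson needs n >= 8
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                normality[name] = float(stats.normaltest(vals).pvalue)
        else:
            normality[name] = None

    names = list(usable)
    if len(names) == 2:
        res = stats.ttest_ind(usable[names[0]], usable[names[1]])
        return GroupComparison("t-test", float(res.statistic), float(res.pvalue),
                               normality, excluded=excluded, n_comparisons=1)

    res = stats.f_oneway(*usable.values())
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    pairwise = []
    for a, b in pairs:
        tt = stats.ttest_ind(usable[a], usable[b])
        p_raw = float(tt.pvalue)
        pairwise.append(
            {"groups": (a, b), "statistic": float(tt.statistic),
             "p_raw": p_raw, "p_adj": min(1.0, m * p_raw),
             "significant": min(1.0, m * p_raw) < alpha}
        )
    return GroupComparison("anova", float(res.statistic), float(res.pvalue),
                           normality, pairwise=pairwise, excluded=excluded, n_comparisons=m)
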