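"""Optical redox ratio (ORR) maps from NADH and FAD autofluorescence.

The ORR is defined per pixel as FAD / (FAD + NADH), a dimensionless proxy for
the cellular redox/metabolic state (higher values indicate a more oxidized
flavoprotein pool).  Pixels whose summed signal does not exceed a noise floor
are marked undefined — raw division at dark background pixels is numerically
meaningless — and the per-spheroid ORR is the mean of defined pixels inside
the spheroid mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["OrrMap", "compute_orr", "correlate_orr_necrosis"]


@dataclass
class OrrMap:
    """Per-pixel ORR with a validity mask and the spheroid-mean summary."""

    orr: np.ndarray  # float map, nan where undefined
    valid_mask: np.ndarray
    spheroid_mean_orr: float  # nan when no defined pixel lies in the mask
    noise_floor: float
    no_signal: bool = False


def compute_orr(
    nadh: np.ndarray,
    fad: np.ndarray,
    mask: np.ndarray | None = None,
    noise_floor: float | None = None,
) -> OrrMap:
    """Per-pixel FAD / (FAD + NADH) above a noise floor, averaged in the mask.

    When ``noise_floor`` is not given it defaults to 3x the standard deviation
    of the summed signal outside the mask (0 if no mask or no outside pixels).
    Defined values are clipped to [0, 1] (noise can push single channels
    slightly negative).  If no defined pixel falls inside the mask the result
    is an explicit no-signal outcome.
    """
    nadh = np.asarray(nadh, dtype=float)
    fad = np.asarray(fad, dtype=float)
    if nadh.shape != fad.shape:
        raise ValueError(f"shape mismatch: NADH {nadh.shape} vs FAD {fad.shape}")
    total = fad + nadh
    if noise_floor is None:
        if mask is not None:
            outside = total[~np.asarray(mask, dtype=bool)]
            noise_floor = 3.0 * float(outside.std()) if outside.size else 0.0
        else:
            noise_floor = 0.0
    if noise_floor < 0:
        raise ValueError("noise_floor must be >= 0")

    valid = np.isfinite(total) & (total > noise_floor)
    orr = np.full(nadh.shape, np.nan)
    np.divide(fad, total, out=orr, where=valid)
    orr[valid] = np.clip(orr[valid], 0.0, 1.0)

    region = valid if mask is None else (valid & np.asarray(mask, dtype=bool))
    if region.any():
        mean = float(orr[region].mean())
        no_signal = False
    else:
        mean, no_signal = float("nan"), True
    return OrrMap(orr=orr, valid_mask=valid, spheroid_mean_orr=mean,
                  noise_floor=float(noise_floor), no_signal=no_signal)


@dataclass
class CorrelationReport:
    model: str
    n: int
    pearson_r: float | None = None
    pearson_p: float | None = None
    pearson_ci: tuple[float, float] | None = None
    spearman_rho: float | None = None
    spearman_p: float | None = None
    flagged: bool = False
    message: str = ""


def correlate_orr_necrosis(
    records: pd.DataFrame,
    orr_col: str = "orr",
    pi_col: str = "mean_pi",
    by: str = "model",
    ci_level: float = 0.95,
) -> dict[str, CorrelationReport]:
    """Pearson and Spearman correlation of spheroid ORR vs necrosis per model.

    Groups with fewer than 3 complete records, or with zero variance on either
    axis, are flagged and carry no coefficient.
    """
    out: dict[str, CorrelationReport] = {}
    for model, grp in records.groupby(by):
        sub = grp[[orr_col, pi_col]].dropna()
        n = len(sub)
        if n < 3:
            out[model] = CorrelationReport(model, n, flagged=True,
                                           message="fewer than 3 complete records")
            continue
        x = sub[orr_col].to_numpy()
        y = sub[pi_col].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[model] = CorrelationReport(model, n, flagged=True,
                                           message="zero variance: correlation undefined")
            continue
        pr = stats.pearsonr(x, y)
        ci = pr.confidence_interval(confidence_level=ci_level)
        sr = stats.spearmanr(x, y)
        out[model] = CorrelationReport(
            model, n,
            pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
            pearson_ci=(float(ci.low), float(ci.high)),
            spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue),
        )
    return out
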