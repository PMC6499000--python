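"""Geometric-sum additivity analysis in (normalized area, necrosis) space.

Each treatment group is summarized by its mean position in the plane spanned
by normalized spheroid area (x) and mean PI necrosis signal (y).  A treatment
effect is the vector from the untreated-control mean to the treated mean; the
additive prediction for a combination is the control point plus the vector sum
of the single-agent effects.  The observed combination is then classified per
axis as sub-additive, additive, or super-additive by comparing it to the
prediction within a confidence band obtained by root-sum-square propagation of
the group SEMs (normal approximation).  The paper-style arrow diagram carries
no formal synergy statistic; the confidence-band rule here is this module's
explicit construction and is labelled as such in its output.  A seeded
bootstrap over spheroids is available for small, non-normal groups.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "EffectVector",
    "AdditivityCall",
    "summarize_group",
    "effect_vector",
    "predict_additive",
    "classify_additivity",
    "classify_additivity_bootstrap",
]

# Direction in which each axis reports treatment benefit: necrosis increases
# (+1), area shrinks (-1).  Super-additive means the observed point exceeds
# the additive prediction in the benefit direction.
_AXIS_SIGN = {"area": -1.0, "necrosis": +1.0}


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SEM of one treatment group in (norm area, mean PI) space."""

    model: str
    day: int
    pdt_fluence_J_cm2: float
    rt_dose_Gy: float
    mean_norm_area: float
    sem_norm_area: float
    mean_pi: float
    sem_pi: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group must contain at least one spheroid")
        if self.sem_norm_area < 0 or self.sem_pi < 0:
            raise ValueError("SEMs must be >= 0")


def summarize_group(
    model: str, day: int, pdt: float, rt: float,
    norm_areas: np.ndarray, mean_pis: np.ndarray,
) -> GroupSummary:
    """Build a GroupSummary from per-spheroid values (SEM = sd / sqrt(n))."""
    a = np.asarray(norm_areas, dtype=float)
    p = np.asarray(mean_pis, dtype=float)
    if a.size != p.size or a.size == 0:
        raise ValueError("norm_areas and mean_pis must be non-empty and matched")
    n = a.size
    sem = lambda v: float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return GroupSummary(model, day, pdt, rt, float(a.mean()), sem(a), float(p.mean()), sem(p), n)


@dataclass(frozen=True)
class EffectVector:
    """Treated-minus-control displacement, componentwise."""

    d_area: float
    d_pi: float
    origin: GroupSummary


def _check_same_panel(*groups: GroupSummary) -> None:
    ref = (groups[0].model, groups[0].day)
    for g in groups[1:]:
        if (g.model, g.day) != ref:
            raise ValueError(
                f"groups must share model and day: {ref} vs {(g.model, g.day)}"
            )


def effect_vector(treated: GroupSummary, control: GroupSummary) -> EffectVector:
    """Displacement of the treated group mean from the control group mean."""
    _check_same_panel(treated, control)
    return EffectVector(
        d_area=treated.mean_norm_area - control.mean_norm_area,
        d_pi=treated.mean_pi - control.mean_pi,
        origin=control,
    )


@dataclass(frozen=True)
class AdditivePrediction:
    """Additive combination point with RSS-propagated uncertainty per axis."""

    area: float
    pi: float
    sigma_area: float
    sigma_pi: float


def predict_additive(
    control: GroupSummary, pdt_only: GroupSummary, rt_only: GroupSummary
) -> AdditivePrediction:
    """Control point plus the vector sum of the two single-agent effects.

    predicted = control + (pdt - control) + (rt - control), componentwise;
    uncertainty is the root-sum-square of the three group SEMs (the control
    mean enters the expression twice with opposite signs but its two
    occurrences are the same estimate, so its SEM is counted once).
    """
    _check_same_panel(control, pdt_only, rt_only)
    ep = effect_vector(pdt_only, control)
    er = effect_vector(rt_only, control)
    return AdditivePrediction(
        area=control.mean_norm_area + ep.d_area + er.d_area,
        pi=control.mean_pi + ep.d_pi + er.d_pi,
        sigma_area=float(np.sqrt(
            control.sem_norm_area**2 + pdt_only.sem_norm_area**2 + rt_only.sem_norm_area**2
        )),
        sigma_pi=float(np.sqrt(control.sem_pi**2 + pdt_only.sem_pi**2 + rt_only.sem_pi**2)),
    )


@dataclass(frozen=True)
class AdditivityCall:
    """Per-axis verdict comparing the observed combination to the prediction."""

    axis: str  # "area" | "necrosis"
    verdict: str  # "sub_additive" | "additive" | "super_additive"
    observed: float
    predicted: float
    uncertainty: float  # CI half-width at the chosen alpha
    method: str = "rss-sem normal approximation (module construction, not a paper procedure)"

    def to_dict(self) -> dict:
        return asdict(self)


def _call(axis: str, observed: float, predicted: float, half_width: float) -> AdditivityCall:
    diff = (observed - predicted) * _AXIS_SIGN[axis]
    if diff > half_width:
        verdict = "super_additive"
    elif diff < -half_width:
        verdict = "sub_additive"
    else:
        verdict = "additive"
    return AdditivityCall(axis, verdict, observed, predicted, half_width)


def classify_additivity(
    observed: GroupSummary,
    predicted: AdditivePrediction,
    alpha: float = 0.05,
) -> dict[str, AdditivityCall]:
    """Classify the observed combination per axis at confidence level 1-alpha.

    The half-width is z_{1-alpha/2} times the RSS of the prediction sigma and
    the observed-group SEM.  On the necrosis axis, observed above the band is
    super-additive; on the area axis, observed below the band (stronger
    shrinkage than predicted) is super-additive, and symmetrically.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))
    return {
        "area": _call(
            "area", observed.mean_norm_area, predicted.area,
            z * float(np.hypot(predicted.sigma_area, observed.sem_norm_area)),
        ),
        "necrosis": _call(
            "necrosis", observed.mean_pi, predicted.pi,
            z * float(np.hypot(predicted.sigma_pi, observed.sem_pi)),
        ),
    }


def classify_additivity_bootstrap(
    control: tuple[np.ndarray, np.ndarray],
    pdt_only: tuple[np.ndarray, np.ndarray],
    rt_only: tuple[np.ndarray, np.ndarray],
    combo: tuple[np.ndarray, np.ndarray],
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict[str, AdditivityCall]:
    """Bootstrap alternative for small or non-normal groups.

    Each argument is ``(norm_areas, mean_pis)`` of per-spheroid values.  The
    observed-minus-predicted difference is resampled over spheroids within
    each group (``n_boot`` seeded draws); the verdict uses the percentile CI
    of that difference.
    """
    rng = np.random.default_rng(seed)
    arrs = {name: (np.asarray(a, float), np.asarray(p, float))
            for name, (a, p) in (("control", control), ("pdt", pdt_only),
                                 ("rt", rt_only), ("combo", combo))}
    for name, (a, p) in arrs.items():
        if a.size == 0 or a.size != p.size:
            raise ValueError(f"group {name!r}: per-spheroid arrays empty or mismatched")

    def diff(sample: dict[str, tuple[np.ndarray, np.ndarray]], axis: int) -> float:
        m = {k: (v[axis].mean()) for k, v in sample.items()}
        # observed - (control + (pdt-control) + (rt-control))
        return m["combo"] - (m["pdt"] + m["rt"] - m["control"])

    obs = {"area": diff(arrs, 0), "necrosis": diff(arrs, 1)}
    boots = {"area": np.empty(n_boot), "necrosis": np.empty(n_boot)}
    for i in range(n_boot):
        sample = {
            k: tuple(v[j][rng.integers(0, v[j].size, v[j].size)] for j in (0, 1))
            for k, v in arrs.items()
        }
        boots["area"][i] = diff(sample, 0)
        boots["necrosis"][i] = diff(sample, 1)

    calls = {}
    for axis in ("area", "necrosis"):
        lo, hi = np.quantile(boots[axis], [alpha / 2.0, 1.0 - alpha / 2.0])
        half = float(max(obs[axis] - lo, hi - obs[axis]))
        signed = obs[axis] * _AXIS_SIGN[axis]
        if lo > 0 and hi > 0:
            verdict = "super_additive" if _AXIS_SIGN[axis] > 0 else "sub_additive"
        elif lo < 0 and hi < 0:
            verdict = "sub_additive" if _AXIS_SIGN[axis] > 0 else "super_additive"
        else:
            verdict = "additive"
        observed_mean = arrs["combo"][0 if axis == "area" else 1].mean()
        predicted = observed_mean - obs[axis]
        calls[axis] = AdditivityCall(
            axis, verdict, float(observed_mean), float(predicted), half,
            method=f"percentile bootstrap over spheroids ({n_boot} draws, seeded)",
        )
    return calls
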