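"""BRET titration analysis: signal computation, curve fits, classification.

A BRET titration fixes the luciferase-fused donor and increases the
fluorophore-fused acceptor. Each point is (x, y) with

    x = total fluorescence / total luminescence   (acceptor:donor proxy)
    y = (sample 530/480 ratio - donor-only 530/480 ratio) * 1000   [mBRET]

A specific interaction saturates as a one-site binding hyperbola
y = BRETmax * x / (BRET50 + x): BRETmax is the plateau, BRET50 the x at
half-plateau (an apparent-Kd proxy). Random collisions (bystander
signal) instead grow linearly in x. Titrations are classified as
``specific``, ``nonspecific_linear`` (no plateau / linear fits at least
as well), or ``below_threshold`` (plateau under the 50-mBRET noise
floor), and ligand-induced modulation is read off the change in the two
fitted parameters between conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: Signals whose plateau stays under this are background (mBRET units).
MBRET_THRESHOLD = 50.0
#: Advisory goodness-of-fit bound for a specific saturation curve.
R_SQUARED_ADVISORY = 0.98
#: A fitted BRET50 beyond this multiple of the largest observed x means the
#: curve never approached its plateau inside the observed range.
SATURATION_FACTOR = 2.0
#: Relative change in a fitted parameter below which conditions are equal.
MODULATION_TOLERANCE = 0.15

CONDITIONS = ("control", "MDP")
ROLES = ("sample", "donor_only")


class FitError(ValueError):
    """Too few/degenerate points, or the optimizer failed to converge."""


class BackgroundError(ValueError):
    """No donor-only wells available to define the background ratio."""


@dataclass(frozen=True)
class TitrationPoint:
    x: float  # fluorescence / luminescence, dimensionless
    y: float  # mBRET

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ValueError("acceptor:donor ratio x must be non-negative")


@dataclass
class BretFit:
    bret_max: float
    bret_50: float
    r_squared: float
    model: str = "hyperbolic"  # or "linear"
    classification: str = ""
    quality_warning: bool = False
    converged: bool = True


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float


@dataclass
class ModulationResult:
    delta_bret_max: float  # relative, signed
    delta_bret_50: float
    verdict: str  # no_change | affinity_increase | bretmax_decrease | other


def bret_ratio(sample_ratio_530_480: float, donor_only_ratio: float) -> float:
    """mBRET signal: (sample 530/480 - donor-only 530/480) * 1000."""
    for r in (sample_ratio_530_480, donor_only_ratio):
        if not np.isfinite(r):
            raise ValueError("emission ratios must be finite")
    return (sample_ratio_530_480 - donor_only_ratio) * 1000.0


def build_titration(wells: pd.DataFrame) -> dict[str, list[TitrationPoint]]:
    """Collapse triplicate wells into titration points, per condition.

    ``wells`` is long-format with columns plate, well, role, condition,
    group, lum480, em530, fluo (group identifies a triplicate, e.g. the
    acceptor dose). Background is per plate and per condition, from the
    mean 530/480 ratio of that plate/condition's donor-only wells.
    Incomplete triplicates are averaged over the available wells with a
    logged warning.
    """
    required = {"plate", "role", "condition", "group", "lum480", "em530", "fluo"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"wells table missing columns {sorted(missing)}")
    if (wells["lum480"] <= 0).any():
        raise ValueError("non-positive 480 nm luminescence reading")

    points: dict[str, list[TitrationPoint]] = {}
    for (plate, condition), block in wells.groupby(["plate", "condition"], sort=True):
        donor = block[block["role"] == "donor_only"]
        if donor.empty:
            # fall back to donor-only wells of the plate regardless of condition
            donor = wells[(wells["plate"] == plate) & (wells["role"] == "donor_only")]
        if donor.empty:
            raise BackgroundError(f"plate {plate!r}: no donor-only wells")
        background = float((donor["em530"] / donor["lum480"]).mean())
        for group, trip in block[block["role"] == "sample"].groupby("group", sort=True):
            if len(trip) < 3:
                logger.warning(
                    "plate %s condition %s group %s: %d/3 wells, averaging available",
                    plate, condition, group, len(trip),
                )
            x = float(trip["fluo"].mean() / trip["lum480"].mean())
            y = float(
                np.mean([bret_ratio(r, background) for r in trip["em530"] / trip["lum480"]])
            )
            points.setdefault(str(condition), []).append(TitrationPoint(x, y))
    for cond in points:
        points[cond].sort(key=lambda p: p.x)
    return points


def _xy(points: Sequence[TitrationPoint]) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([p.x for p in points], dtype=float)
    y = np.array([p.y for p in points], dtype=float)
    return x, y


def _one_site(x: np.ndarray, bret_max: float, bret_50: float) -> np.ndarray:
    return bret_max * x / (bret_50 + x)


def fit_hyperbolic(points: Sequence[TitrationPoint]) -> BretFit:
    """Least-squares one-site binding fit y = BRETmax * x / (BRET50 + x).

    Deterministic initialization: BRETmax0 = max(y), BRET500 = median of
    the positive x values. Requires >= 3 distinct x. Non-convergence is
    reported as a failed fit (``converged=False``), never silently
    replaced by another model.
    """
    x, y = _xy(points)
    if len(np.unique(x)) < 3:
        raise FitError("hyperbolic fit needs at least 3 distinct x values")
    x_pos = x[x > 0]
    p0 = (float(y.max()), float(np.median(x_pos)) if x_pos.size else 1.0)
    try:
        popt, _ = optimize.curve_fit(
            _one_site, x, y, p0=p0, bounds=([0.0, 1e-12], [np.inf, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError:
        logger.warning("one-site fit did not converge")
        return BretFit(float("nan"), float("nan"), float("nan"), converged=False)
    residuals = y - _one_site(x, *popt)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return BretFit(float(popt[0]), float(popt[1]), r2)


def fit_linear(points: Sequence[TitrationPoint]) -> LinearFit:
    """Ordinary least-squares line through the titration points."""
    x, y = _xy(points)
    if len(x) < 2 or len(np.unique(x)) < 2:
        raise FitError("linear fit needs at least 2 distinct x values")
    res = stats.linregress(x, y)
    return LinearFit(float(res.slope), float(res.intercept), float(res.rvalue**2))


def classify_titration(
    hyp: BretFit,
    lin: LinearFit,
    x_max: float,
    points: Sequence[TitrationPoint] | None = None,
    mbret_threshold: float = MBRET_THRESHOLD,
    saturation_factor: float = SATURATION_FACTOR,
    r2_advisory: float = R_SQUARED_ADVISORY,
) -> BretFit:
    """Attach a specificity classification to the hyperbolic fit.

    below_threshold: the plateau estimate (fitted BRETmax, or the largest
    observed y when the fit failed) stays under the mBRET noise floor.
    nonspecific_linear: the fitted BRET50 lies beyond saturation_factor x
    the largest observed x (no plateau reached inside the titration), or
    the straight line fits at least as well as the hyperbola.
    Otherwise specific, with a quality warning when r2 < the advisory
    bound.
    """
    if not hyp.converged or not np.isfinite(hyp.bret_max):
        plateau = max((p.y for p in points), default=0.0) if points else 0.0
        classification = (
            "below_threshold" if plateau < mbret_threshold else "nonspecific_linear"
        )
        return BretFit(
            hyp.bret_max, hyp.bret_50, hyp.r_squared,
            model="hyperbolic", classification=classification, converged=False,
        )
    if hyp.bret_max < mbret_threshold:
        classification = "below_threshold"
    elif hyp.bret_50 > saturation_factor * x_max or lin.r_squared >= hyp.r_squared:
        classification = "nonspecific_linear"
    else:
        classification = "specific"
    warning = classification == "specific" and hyp.r_squared < r2_advisory
    if warning:
        logger.warning(
            "specific saturation curve with r2=%.4f below the %.2f advisory",
            hyp.r_squared, r2_advisory,
        )
    return BretFit(
        hyp.bret_max, hyp.bret_50, hyp.r_squared,
        model="hyperbolic", classification=classification, quality_warning=warning,
    )


def analyze_titration(points: Sequence[TitrationPoint], **thresholds) -> BretFit:
    """Fit both models and classify one condition's titration."""
    hyp = fit_hyperbolic(points)
    lin = fit_linear(points)
    x_max = max(p.x for p in points)
    return classify_titration(hyp, lin, x_max, points, **thresholds)


def compare_conditions(
    fit_control: BretFit,
    fit_mdp: BretFit,
    tolerance: float = MODULATION_TOLERANCE,
) -> ModulationResult:
    """Ligand-modulation verdict from two specific saturation fits.

    affinity_increase: BRET50 drops beyond tolerance with a stable
    BRETmax (higher apparent affinity, lower apparent Kd).
    bretmax_decrease: BRETmax drops beyond tolerance with a stable
    BRET50 (fewer donors engaged, conformational change or partial
    dissociation). Within tolerance on both: no_change; anything else:
    other.
    """
    for f in (fit_control, fit_mdp):
        if f.classification != "specific":
            raise ValueError("modulation requires both fits classified specific")
    d_max = (fit_mdp.bret_max - fit_control.bret_max) / fit_control.bret_max
    d_50 = (fit_mdp.bret_50 - fit_control.bret_50) / fit_control.bret_50
    max_stable = abs(d_max) <= tolerance
    k50_stable = abs(d_50) <= tolerance
    if max_stable and k50_stable:
        verdict = "no_change"
    elif d_50 < -tolerance and max_stable:
        verdict = "affinity_increase"
    elif d_max < -tolerance and k50_stable:
        verdict = "bretmax_decrease"
    else:
        verdict = "other"
    return ModulationResult(float(d_max), float(d_50), verdict)


def analyze_wells(wells: pd.DataFrame, **thresholds) -> pd.DataFrame:
    """Per-condition fits and, when both conditions are specific, modulation.

    Returns one row per condition with the fitted parameters plus the
    modulation verdict on the control row when an MDP condition exists.
    """
    points = build_titration(wells)
    rows = []
    fits: dict[str, BretFit] = {}
    for condition, pts in points.items():
        fit = analyze_titration(pts, **thresholds)
        fits[condition] = fit
        rows.append(
            {
                "condition": condition,
                "n_points": len(pts),
                "bret_max": fit.bret_max,
                "bret_50": fit.bret_50,
                "r_squared": fit.r_squared,
                "classification": fit.classification,
                "quality_warning": fit.quality_warning,
                "verdict": "",
            }
        )
    if {"control", "MDP"} <= fits.keys() and all(
        fits[c].classification == "specific" for c in ("control", "MDP")
    ):
        mod = compare_conditions(fits["control"], fits["MDP"])
        for row in rows:
            if row["condition"] == "control":
                row["verdict"] = mod.verdict
    return pd.DataFrame(rows)
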