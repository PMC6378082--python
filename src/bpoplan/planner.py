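"""Feasible opening-angle planning under sagittal alignment criteria.

The alignment goals are closed inequalities on the predicted parameters:

    sva_min ≤ SVA ≤ sva_max,  TPA ≤ tpa_max,  PT ≤ pt_max,  PI − LL ≤ pill_max

SVA, PI (hence PI − LL) and TPA fall with the opening angle while PT rises,
so each goal contributes at most one threshold crossing: the falling
parameters define the minimum OA that corrects them, PT (and SVA dropping
past its lower bound) define the maximum tolerable OA.  The feasible interval
is the intersection; an empty intersection is a result, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import bisect

from .closed_form import DerivedGeometry, LinearModel, closed_form_predict, evaluate_linear
from .geometry import LandmarkSet, apply_osteotomy, measure_parameters

__all__ = [
    "Criteria",
    "PlanResult",
    "threshold_crossing",
    "feasible_oa_range",
    "build_report",
    "oracle_predictors",
    "closed_form_predictors",
    "linear_predictors",
]

Predictor = Callable[[float], float]


@dataclass(frozen=True)
class Criteria:
    """Alignment thresholds and the opening-angle cap (degrees / mm).

    Defaults are the standard correction goals: |SVA| < 5 cm, TPA < 14°,
    PT < 20°, PI − LL < 9°.  Set a threshold to ``None`` to disable it.
    """

    sva_min_mm: float | None = -50.0
    sva_max_mm: float | None = 50.0
    tpa_max_deg: float | None = 14.0
    pt_max_deg: float | None = 20.0
    pi_minus_ll_max_deg: float | None = 9.0
    oa_cap_deg: float = 40.0

    def __post_init__(self) -> None:
        for name in ("sva_min_mm", "sva_max_mm", "tpa_max_deg", "pt_max_deg",
                     "pi_minus_ll_max_deg", "oa_cap_deg"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"{name} must be finite or None")
        if self.sva_min_mm is not None and self.sva_max_mm is not None:
            if not self.sva_min_mm < self.sva_max_mm:
                raise ValueError("sva_min_mm must be below sva_max_mm")
        if not self.oa_cap_deg > 0:
            raise ValueError("oa_cap_deg must be positive")


@dataclass(frozen=True)
class PlanResult:
    """Outcome of the feasibility search over the opening angle."""

    feasible: bool
    oa_min_deg: float | None
    oa_max_deg: float | None
    crossings: Mapping[str, float] = field(default_factory=dict)
    binding_lower: str | None = None
    binding_upper: str | None = None


def threshold_crossing(
    predictor: Predictor,
    threshold: float,
    direction: str,
    oa_cap_deg: float = 40.0,
    parameter_name: str = "parameter",
    tol_deg: float = 1e-6,
) -> float | None:
    """First opening angle at which a monotone parameter meets a threshold.

    ``direction`` is ``"falls_below"`` for decreasing parameters (SVA, TPA,
    PI − LL reaching their ceilings) or ``"rises_above"`` for increasing ones
    (PT hitting its cap).  Returns 0 if the condition already holds at OA = 0,
    ``None`` if it is never met within the cap.  Monotonicity (in the weak
    sense) is verified on a 0.5° grid; bisection then brackets the crossing to
    ``tol_deg``.
    """
    if direction not in ("falls_below", "rises_above"):
        raise ValueError(f"unknown direction {direction!r}")
    grid = np.arange(0.0, oa_cap_deg + 0.25, 0.5)
    grid[-1] = min(grid[-1], oa_cap_deg)
    values = np.array([predictor(oa) for oa in grid])
    diffs = np.diff(values)
    if direction == "falls_below":
        if np.any(diffs > 1e-9):
            raise ValueError(f"{parameter_name} is not monotone decreasing on [0, {oa_cap_deg}]")
        g = lambda oa: predictor(oa) - threshold
    else:
        if np.any(diffs < -1e-9):
            raise ValueError(f"{parameter_name} is not monotone increasing on [0, {oa_cap_deg}]")
        g = lambda oa: threshold - predictor(oa)
    # g decreases through 0 at the crossing in both cases
    if g(0.0) <= 0.0:
        return 0.0
    if g(oa_cap_deg) > 0.0:
        return None
    return float(bisect(g, 0.0, oa_cap_deg, xtol=tol_deg))


def oracle_predictors(
    landmarks: LandmarkSet, ll_deg: float, plumbline: str = "c7"
) -> dict[str, Predictor]:
    """Parameter-vs-OA callables backed by the rigid-rotation oracle."""
    def make(attr: str) -> Predictor:
        def f(oa: float) -> float:
            p = measure_parameters(apply_osteotomy(landmarks, oa), ll_deg, plumbline)
            return getattr(p, attr)
        return f
    return {
        "sva_mm": make("sva_mm"),
        "tpa_deg": make("tpa_deg"),
        "pt_deg": make("pt_deg"),
        "pi_minus_ll_deg": make("pi_minus_ll_deg"),
    }


def closed_form_predictors(geom: DerivedGeometry, ll_deg: float) -> dict[str, Predictor]:
    """Parameter-vs-OA callables backed by the closed-form equations."""
    def make(attr: str) -> Predictor:
        return lambda oa: getattr(closed_form_predict(geom, ll_deg, oa), attr)
    return {
        "sva_mm": make("sva_mm"),
        "tpa_deg": make("tpa_deg"),
        "pt_deg": make("pt_deg"),
        "pi_minus_ll_deg": make("pi_minus_ll_deg"),
    }


def linear_predictors(
    models: Mapping[str, LinearModel], ll_deg: float | None = None
) -> dict[str, Predictor]:
    """Parameter-vs-OA callables from fitted (or transcribed) linear models.

    ``pi_minus_ll_deg`` is derived from the ``pi_deg`` model when an LL value
    is supplied and no explicit model exists for it.
    """
    preds: dict[str, Predictor] = {
        name: (lambda oa, m=m: evaluate_linear(m, oa)) for name, m in models.items()
    }
    if "pi_minus_ll_deg" not in preds and "pi_deg" in models and ll_deg is not None:
        pi_model = models["pi_deg"]
        preds["pi_minus_ll_deg"] = lambda oa: evaluate_linear(pi_model, oa) - ll_deg
    return preds


def feasible_oa_range(
    predictors: Mapping[str, Predictor],
    criteria: Criteria,
    verify_step_deg: float = 0.1,
) -> PlanResult:
    """Intersect all criteria into a feasible opening-angle interval.

    ``predictors`` maps parameter names (``sva_mm``, ``tpa_deg``, ``pt_deg``,
    ``pi_minus_ll_deg``) to monotone OA → value callables; criteria whose
    parameter is missing or whose threshold is ``None`` are skipped.  When an
    interval exists it is verified on a ``verify_step_deg`` grid.
    """
    cap = criteria.oa_cap_deg
    crossings: dict[str, float] = {}
    lower_candidates: list[tuple[str, float]] = [("oa_zero", 0.0)]
    upper_candidates: list[tuple[str, float]] = [("oa_cap", cap)]
    infeasible_constraints: list[str] = []

    def falling(name: str, pred_key: str, threshold: float | None) -> None:
        if threshold is None or pred_key not in predictors:
            return
        oa = threshold_crossing(predictors[pred_key], threshold, "falls_below",
                                cap, parameter_name=pred_key)
        if oa is None:
            infeasible_constraints.append(name)
        else:
            crossings[name] = oa
            lower_candidates.append((name, oa))

    falling("sva_max", "sva_mm", criteria.sva_max_mm)
    falling("tpa_max", "tpa_deg", criteria.tpa_max_deg)
    falling("pi_minus_ll_max", "pi_minus_ll_deg", criteria.pi_minus_ll_max_deg)

    # PT rises: its cap is an upper bound; violated already at OA=0 -> infeasible.
    if criteria.pt_max_deg is not None and "pt_deg" in predictors:
        pred = predictors["pt_deg"]
        if pred(0.0) > criteria.pt_max_deg:
            infeasible_constraints.append("pt_max")
        else:
            oa = threshold_crossing(pred, criteria.pt_max_deg, "rises_above",
                                    cap, parameter_name="pt_deg")
            if oa is not None:
                crossings["pt_max"] = oa
                upper_candidates.append(("pt_max", oa))

    # SVA keeps falling: dropping below sva_min caps the correction from above.
    if criteria.sva_min_mm is not None and "sva_mm" in predictors:
        pred = predictors["sva_mm"]
        if pred(0.0) < criteria.sva_min_mm:
            infeasible_constraints.append("sva_min")
        else:
            oa = threshold_crossing(pred, criteria.sva_min_mm, "falls_below",
                                    cap, parameter_name="sva_mm")
            if oa is not None:
                crossings["sva_min"] = oa
                upper_candidates.append(("sva_min", oa))

    if infeasible_constraints:
        return PlanResult(False, None, None, crossings, infeasible_constraints[0], None)

    binding_lower, oa_min = max(lower_candidates, key=lambda t: t[1])
    binding_upper, oa_max = min(upper_candidates, key=lambda t: t[1])
    if oa_min > oa_max:
        return PlanResult(False, None, None, crossings, binding_lower, binding_upper)

    _verify_interval(predictors, criteria, oa_min, oa_max, verify_step_deg)
    return PlanResult(True, oa_min, oa_max, crossings, binding_lower, binding_upper)


def _verify_interval(predictors, criteria: Criteria, oa_min: float, oa_max: float,
                     step: float, slack: float = 1e-3) -> None:
    """Re-check every criterion on a fine grid across the returned interval."""
    grid = np.arange(oa_min, oa_max + step / 2, step)
    grid = np.clip(grid, oa_min, oa_max)
    checks = [
        ("sva_mm", criteria.sva_max_mm, +1), ("sva_mm", criteria.sva_min_mm, -1),
        ("tpa_deg", criteria.tpa_max_deg, +1), ("pt_deg", criteria.pt_max_deg, +1),
        ("pi_minus_ll_deg", criteria.pi_minus_ll_max_deg, +1),
    ]
    for key, threshold, sign in checks:
        if threshold is None or key not in predictors:
            continue
        vals = np.array([predictors[key](oa) for oa in grid])
        ok = vals <= threshold + slack if sign > 0 else vals >= threshold - slack
        if not np.all(ok):
            raise AssertionError(
                f"internal: {key} violates its threshold inside the reported interval"
            )


def build_report(
    plan: PlanResult,
    table: pd.DataFrame,
    criteria: Criteria,
) -> dict:
    """Summarise baseline parameters, crossings and the feasible interval.

    ``table`` is a prediction table whose first row is the baseline (OA = 0).
    Returns a plain dict with deterministic key ordering, ready for JSON/text
    rendering by the CLI.
    """
    if len(table) == 0:
        raise ValueError("prediction table is empty")
    baseline = table.iloc[0].to_dict()
    report = {
        "baseline": {k: float(v) for k, v in sorted(baseline.items())},
        "criteria": {
            "sva_min_mm": criteria.sva_min_mm,
            "sva_max_mm": criteria.sva_max_mm,
            "tpa_max_deg": criteria.tpa_max_deg,
            "pt_max_deg": criteria.pt_max_deg,
            "pi_minus_ll_max_deg": criteria.pi_minus_ll_max_deg,
            "oa_cap_deg": criteria.oa_cap_deg,
        },
        "crossings_deg": {k: float(v) for k, v in sorted(plan.crossings.items())},
        "feasible": plan.feasible,
        "oa_min_deg": plan.oa_min_deg,
        "oa_max_deg": plan.oa_max_deg,
        "binding_lower": plan.binding_lower,
        "binding_upper": plan.binding_upper,
    }
    return report


def render_report(report: dict) -> str:
    """Plain-text rendering of :func:`build_report` output."""
    lines = ["Baseline parameters:"]
    for k, v in report["baseline"].items():
        lines.append(f"  {k:<18s} {v:12.6g}")
    lines.append("Constraint crossings (deg):")
    for k, v in report["crossings_deg"].items():
        lines.append(f"  {k:<18s} {v:12.6g}")
    if report["feasible"]:
        lines.append(
            f"Feasible opening angle: {report['oa_min_deg']:.6g} deg "
            f"({report['binding_lower']}) to {report['oa_max_deg']:.6g} deg "
            f"({report['binding_upper']})"
        )
    else:
        lines.append(
            "Infeasible: no opening angle satisfies all criteria "
            f"(most restrictive: {report['binding_lower']} vs {report['binding_upper']})"
        )
    return "\n".join(lines) + "\n"
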