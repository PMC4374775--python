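"""Kinetic-mechanism inference from velocity patterns.

Three stages, mirroring classical Cleland analysis of a bisubstrate enzyme:

1. :func:`double_reciprocal_pattern` - fit 1/v vs 1/[S] lines, one per fixed
   co-substrate level, and classify the family of lines by where they meet:
   on the 1/S axis, left of the 1/v axis above or below the x axis, or
   nowhere (parallel).
2. :func:`classify_inhibition` - turn a dead-end inhibition study into a
   C / NC / MT / UC call using slope/intercept replots cross-checked against
   AICc model selection.
3. :func:`infer_mechanism` - combine the pattern with the inhibition calls
   through the dead-end decision table: an intersecting pattern with each
   analog competitive against its own substrate and (non)competitive or
   mixed against the other indicates a rapid-equilibrium random mechanism;
   an analog uncompetitive against the co-substrate indicates an ordered
   mechanism; parallel lines indicate ping-pong.

Lines are fitted in reciprocal space for the pattern display only; all
parameter estimates elsewhere come from untransformed global fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .dataset import VelocityDataset
from .fitting import InhibitionSeriesFit

__all__ = [
    "PatternCall",
    "InhibitionCall",
    "MechanismCall",
    "double_reciprocal_pattern",
    "replot_effects",
    "classify_inhibition",
    "infer_mechanism",
]


@dataclass
class PatternCall:
    family: str  # intersecting_on_S_axis | intersecting_left_above |
    #              intersecting_left_below | parallel | ambiguous
    intersection: Tuple[float, float] | None
    dispersion: Tuple[float, float] | None
    slopes: Dict[float, float]
    intercepts: Dict[float, float]
    tolerance_used: Dict[str, float]


@dataclass
class InhibitionCall:
    kind: str  # C | NC | MT | UC | none
    slope_effect: bool
    intercept_effect: bool
    alpha_flag: str
    consistent: bool = True
    notes: str = ""


@dataclass
class MechanismCall:
    mechanism: str  # rapid_equilibrium_random | ordered | ping_pong | ambiguous
    evidence: List[str] = field(default_factory=list)
    notes: str = ""


def _fit_reciprocal_lines(
    data: VelocityDataset, min_points: int = 4
) -> Tuple[Dict[float, float], Dict[float, float]]:
    """Per co-substrate level, weighted least-squares line of 1/v on 1/[S].

    Replicates are averaged per concentration first; the line fit is
    weighted by the mean velocity squared, since for constant relative
    error the standard deviation of 1/v scales as 1/v**2 (the classical
    cure for reciprocal-space noise amplification).
    """
    df = (
        data.points.groupby(["a_mM", "b_mM"], as_index=False)["v"].mean()
    )
    s_col, co_col = ("a_mM", "b_mM") if data.varied == "a" else ("b_mM", "a_mM")
    slopes: Dict[float, float] = {}
    intercepts: Dict[float, float] = {}
    for level, g in df.groupby(co_col):
        s = g[s_col].to_numpy(dtype=float)
        v = g["v"].to_numpy(dtype=float)
        if np.any(v <= 0) or np.any(s <= 0):
            raise ValueError(
                "reciprocal-space fit requires strictly positive v and [S]"
            )
        if np.unique(s).size < min_points:
            raise ValueError(
                f"series at co-substrate {level} has "
                f"{np.unique(s).size} varied levels; need >= {min_points}"
            )
        slope, intercept = np.polyfit(1.0 / s, 1.0 / v, 1, w=v**2)
        slopes[float(level)] = float(slope)
        intercepts[float(level)] = float(intercept)
    return slopes, intercepts


def _common_point(m: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Least-squares common intersection of the line pencil y = m x + c."""
    a = np.column_stack([m, -np.ones_like(m)])
    sol, *_ = np.linalg.lstsq(a, -c, rcond=None)
    return sol  # (x0, y0)


def double_reciprocal_pattern(
    data: VelocityDataset,
    s_axis_tol: float = 0.05,
    z_se: float = 2.5,
    parallel_tol: float = 0.10,
    dispersion_tol: float = 0.5,
    min_series: int = 3,
    min_points: int = 4,
) -> PatternCall:
    """Classify the family of double-reciprocal lines of an initial-velocity grid.

    The common intersection is estimated by least squares over the whole
    pencil of lines, with delete-one-series jackknife standard errors; the
    pairwise intersections of the classical construction are summarized by
    those errors.

    Parameters
    ----------
    s_axis_tol : float
        The intersection is "on the 1/S axis" when |y0| is below this
        fraction of the smallest fitted 1/v intercept (the eye's tolerance
        made explicit) - or within ``z_se`` jackknife standard errors of
        zero, whichever is larger, so sampling noise in the lines does not
        masquerade as an off-axis intersection.
    parallel_tol : float
        Relative slope spread (sd/mean) below which the lines are parallel.
    dispersion_tol : float
        Relative jackknife spread of the intersection abscissa above which
        no single intersection point exists and the call is ambiguous.
    """
    slopes, intercepts = _fit_reciprocal_lines(data, min_points=min_points)
    if len(slopes) < min_series:
        raise ValueError(
            f"need >= {min_series} co-substrate series, got {len(slopes)}"
        )
    tol = {
        "s_axis_tol": s_axis_tol,
        "z_se": z_se,
        "parallel_tol": parallel_tol,
        "dispersion_tol": dispersion_tol,
    }
    m = np.array(list(slopes.values()))
    c = np.array(list(intercepts.values()))

    slope_spread = float(np.std(m) / np.mean(np.abs(m)))
    if slope_spread < parallel_tol:
        return PatternCall("parallel", None, None, slopes, intercepts, tol)

    x0, y0 = map(float, _common_point(m, c))
    n = len(m)
    jack = np.array(
        [_common_point(np.delete(m, i), np.delete(c, i)) for i in range(n)]
    )
    se_x, se_y = np.sqrt(
        (n - 1) / n * np.sum((jack - jack.mean(axis=0)) ** 2, axis=0)
    )
    dispersion = (float(se_x), float(se_y))

    if abs(x0) > 0 and se_x / abs(x0) > dispersion_tol:
        return PatternCall(
            "ambiguous", (x0, y0), dispersion, slopes, intercepts, tol
        )
    y_scale = float(np.min(np.abs(c)))  # smallest 1/v intercept ~ 1/Vmax_app
    if abs(y0) <= max(s_axis_tol * y_scale, z_se * se_y):
        family = "intersecting_on_S_axis"
    elif y0 > 0:
        family = "intersecting_left_above"
    else:
        family = "intersecting_left_below"
    return PatternCall(family, (x0, y0), dispersion, slopes, intercepts, tol)


def replot_effects(
    data: VelocityDataset, alpha_level: float = 0.05
) -> Dict[str, object]:
    """Slope and intercept replots of an inhibition study.

    For each inhibitor level, a 1/v vs 1/[S] line is fitted; its slope and
    intercept are then regressed on [I] and each trend tested (t-test on the
    regression slope at ``alpha_level``).  A "slope effect" is the signature
    of inhibitor binding to the free enzyme; an "intercept effect" of
    binding to the enzyme-substrate complex.
    """
    s_col = "a_mM" if data.varied == "a" else "b_mM"
    df = data.points.groupby([s_col, "i_mM"], as_index=False)["v"].mean()
    levels = np.unique(df["i_mM"])
    if levels.size < 3:
        raise ValueError("replots need >= 3 inhibitor levels")
    sl, ic = [], []
    for level in levels:
        g = df[df["i_mM"] == level]
        s = g[s_col].to_numpy(dtype=float)
        v = g["v"].to_numpy(dtype=float)
        if np.any(v <= 0) or np.any(s <= 0):
            raise ValueError("replots require strictly positive v and [S]")
        m, c = np.polyfit(1.0 / s, 1.0 / v, 1, w=v**2)
        sl.append(m)
        ic.append(c)
    out: Dict[str, object] = {"i_levels": levels, "slopes": np.array(sl),
                              "intercepts": np.array(ic)}
    for key, yv in (("slope", sl), ("intercept", ic)):
        res = stats.linregress(levels, yv)
        out[f"{key}_trend"] = float(res.slope)
        out[f"{key}_p"] = float(res.pvalue)
        out[f"{key}_effect"] = bool(res.pvalue < alpha_level and res.slope > 0)
    return out


_KIND_TO_CODE = {
    "competitive": "C",
    "noncompetitive": "NC",
    "mixed": "MT",
    "uncompetitive": "UC",
}


def classify_inhibition(
    fit: InhibitionSeriesFit,
    replots: Dict[str, object],
) -> InhibitionCall:
    """Combine replot significance with model selection into a C/NC/MT/UC call.

    The replot decision rule: competitive iff only the slope replot rises
    with [I]; uncompetitive iff only the intercept does; both rising is
    noncompetitive when the mixed-fit interaction factor is compatible with
    1, mixed otherwise.  Neither rising is a no-inhibition call.

    When the replot call and the AICc-selected model disagree but the
    replot-suggested model sits inside the AICc ambiguity band (the nested
    inhibition laws often tie to within the one-parameter penalty), the
    replot call adjudicates; a disagreement outside the band retains the
    model-selection kind and flags the call inconsistent.
    """
    slope_eff = bool(replots["slope_effect"])
    int_eff = bool(replots["intercept_effect"])
    alpha_flag = fit.alpha_flag
    if not slope_eff and not int_eff:
        return InhibitionCall(
            "none", False, False, alpha_flag,
            notes="no significant slope or intercept trend with [I]",
        )
    if slope_eff and not int_eff:
        replot_kind = "C"
    elif int_eff and not slope_eff:
        replot_kind = "UC"
    else:
        replot_kind = "NC" if alpha_flag == "α=1" else "MT"

    model_kind = _KIND_TO_CODE[fit.kind]
    if replot_kind == model_kind:
        return InhibitionCall(replot_kind, slope_eff, int_eff, alpha_flag)
    # NC and MT differ only in alpha, which the replots cannot see; the
    # alpha flag (already folded into replot_kind) settles the pair
    if {replot_kind, model_kind} <= {"NC", "MT"}:
        return InhibitionCall(replot_kind, slope_eff, int_eff, alpha_flag)
    code_to_kind = {v: k for k, v in _KIND_TO_CODE.items()}
    in_band = code_to_kind[replot_kind] in fit.ambiguous
    if in_band:
        return InhibitionCall(
            replot_kind, slope_eff, int_eff, alpha_flag,
            notes=f"AICc tie with {model_kind} resolved by replots",
        )
    if replot_kind in ("C", "UC"):
        # a clean single-effect replot is the classical confirmation of a
        # simple pattern; the extra parameter of the selected model is
        # fitting noise the replots do not see
        return InhibitionCall(
            replot_kind, slope_eff, int_eff, alpha_flag,
            consistent=False,
            notes=f"model selection preferred {model_kind}; replots {replot_kind}",
        )
    return InhibitionCall(
        model_kind, slope_eff, int_eff, alpha_flag,
        consistent=False,
        notes=f"replots suggest {replot_kind}, model selection {model_kind}",
    )


_INTERSECTING = {
    "intersecting_on_S_axis",
    "intersecting_left_above",
    "intersecting_left_below",
}


def infer_mechanism(
    pattern: PatternCall,
    inhibitions: Sequence[Tuple[InhibitionCall, str, str]] = (),
) -> MechanismCall:
    """Map the pattern and dead-end inhibition calls to a kinetic mechanism.

    ``inhibitions`` holds triples ``(call, varied_substrate, analog_of)``
    where both substrate labels use the same vocabulary (e.g. "PEP3-",
    "ADP-Mg").  Decision table:

    * parallel pattern -> ping_pong;
    * intersecting pattern, every analog competitive vs its own substrate
      and NC or MT vs the co-substrate -> rapid_equilibrium_random;
    * an analog competitive vs its own substrate but *uncompetitive* vs the
      co-substrate -> ordered, with the co-substrate binding first;
    * intersecting pattern with no inhibition evidence -> ambiguous (initial
      velocities alone cannot separate ordered steady-state from random
      rapid-equilibrium);
    * anything else -> ambiguous, with the conflicting calls in evidence.
    """
    evidence = [f"double-reciprocal pattern: {pattern.family}"]
    for call, varied, analog_of in inhibitions:
        evidence.append(
            f"{analog_of}-analog is {call.kind} vs {varied}"
            + (f" ({call.alpha_flag})" if call.kind == "MT" else "")
        )

    if pattern.family == "parallel":
        return MechanismCall("ping_pong", evidence)
    if pattern.family == "ambiguous":
        return MechanismCall(
            "ambiguous", evidence, notes="no common intersection point"
        )
    if pattern.family not in _INTERSECTING:
        return MechanismCall("ambiguous", evidence, notes="unrecognized pattern")

    if not inhibitions:
        return MechanismCall(
            "ambiguous",
            evidence,
            notes=(
                "intersecting initial-velocity pattern alone cannot separate "
                "ordered steady-state from rapid-equilibrium random; "
                "dead-end inhibition evidence required"
            ),
        )

    own_calls, cross_calls = [], []
    ordered_first: List[str] = []
    for call, varied, analog_of in inhibitions:
        if varied == analog_of:
            own_calls.append(call.kind)
        else:
            cross_calls.append(call.kind)
            if call.kind == "UC":
                ordered_first.append(varied)

    own_ok = bool(own_calls) and all(k == "C" for k in own_calls)
    if own_ok and ordered_first:
        first = ordered_first[0]
        return MechanismCall(
            "ordered", evidence,
            notes=f"{first} binds first (analog uncompetitive vs {first})",
        )
    cross_ok = bool(cross_calls) and all(k in ("NC", "MT") for k in cross_calls)
    if own_ok and cross_ok:
        return MechanismCall("rapid_equilibrium_random", evidence)
    return MechanismCall(
        "ambiguous", evidence,
        notes="inhibition calls do not match a single Cleland pattern set",
    )
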