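"""Global nonlinear least-squares fitting of rate laws to velocity data.

A single entry point, :func:`fit_global`, fits any registered rate law to a
:class:`~pkmech.dataset.VelocityDataset` over *all* series simultaneously
(the classical "global fit" of enzyme kinetics), with seeded multi-start to
guard against local minima and AICc for model comparison.
:func:`fit_inhibition_series` fits the family of linear dead-end inhibition
laws to one inhibition study and selects among them.

Loss is unweighted least squares on v by default (relative-error weighting
by flag).  Standard errors come from the Jacobian at the optimum
(Gauss-Newton approximation); a seeded residual bootstrap is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, Mapping, Sequence

import lmfit
import numpy as np

from .dataset import VelocityDataset
from .rate_laws import (
    HillParams,
    InhibitionParams,
    OrderedParams,
    PingPongParams,
    RandomREParams,
    rate_hill,
    rate_inhibited,
    rate_ordered,
    rate_ping_pong,
    rate_random_re,
)

__all__ = [
    "FitResult",
    "InhibitionSeriesFit",
    "IdentifiabilityError",
    "fit_global",
    "fit_inhibition_series",
    "MODELS",
]

DEFAULT_SEED = 20150326


class IdentifiabilityError(ValueError):
    """The experimental design cannot identify the requested model."""


@dataclass
class FitResult:
    model: str
    estimates: Dict[str, float]
    stderr: Dict[str, float]
    rss: float
    n_obs: int
    converged: bool
    aicc: float
    n_params: int

    def predict(self, data: VelocityDataset) -> np.ndarray:
        return _model_eval(self.model, data, self.estimates)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "estimates": self.estimates,
            "stderr": self.stderr,
            "rss": self.rss,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "aicc": self.aicc,
        }


# ---------------------------------------------------------------------------
# model registry: name -> (parameter names, evaluator, init heuristic)

def _eval_random_re(data, p):
    return rate_random_re(data.a, data.b, RandomREParams(p["vmax"], p["ka"], p["kb"]))


def _eval_hill(data, p):
    return rate_hill(data.s, HillParams(p["vmax"], p["k05"], p["n"]))


def _eval_michaelis(data, p):
    return rate_hill(data.s, HillParams(p["vmax"], p["km"], 1.0))


def _inhib_eval(kind):
    def ev(data, p):
        params = InhibitionParams(
            v=p["v"], km=p["km"], ki=p["ki"], alpha=p.get("alpha", 1.0), kind=kind
        )
        return rate_inhibited(data.s, data.i, params)

    return ev


def _eval_ordered(data, p):
    return rate_ordered(
        data.a, data.b, OrderedParams(p["vmax"], p["ka"], p["kb"], p["kia"])
    )


def _eval_ping_pong(data, p):
    return rate_ping_pong(data.a, data.b, PingPongParams(p["vmax"], p["ka"], p["kb"]))


def _init_common(data: VelocityDataset) -> Dict[str, float]:
    vmax0 = float(np.max(data.v)) * 1.2 if np.max(data.v) > 0 else 1.0
    s = data.s
    km0 = float(np.median(s[s > 0])) if np.any(s > 0) else 1.0
    return {"vmax": vmax0, "v": vmax0, "km": km0, "k05": km0, "n": 1.0}


def _init_inhibition(data: VelocityDataset) -> float:
    i = data.i
    nz = i[i > 0]
    return float(np.median(nz)) if nz.size else 1.0


MODELS: Dict[str, dict] = {
    "random_re": {
        "params": ("vmax", "ka", "kb"),
        "eval": _eval_random_re,
    },
    "hill": {"params": ("vmax", "k05", "n"), "eval": _eval_hill},
    "michaelis_menten": {"params": ("vmax", "km"), "eval": _eval_michaelis},
    "competitive": {"params": ("v", "km", "ki"), "eval": _inhib_eval("competitive")},
    "noncompetitive": {
        "params": ("v", "km", "ki"),
        "eval": _inhib_eval("noncompetitive"),
    },
    "mixed": {"params": ("v", "km", "ki", "alpha"), "eval": _inhib_eval("mixed")},
    "uncompetitive": {
        "params": ("v", "km", "ki"),
        "eval": _inhib_eval("uncompetitive"),
    },
    "ordered": {"params": ("vmax", "ka", "kb", "kia"), "eval": _eval_ordered},
    "ping_pong": {"params": ("vmax", "ka", "kb"), "eval": _eval_ping_pong},
}

_INHIBITION_MODELS = ("competitive", "noncompetitive", "mixed", "uncompetitive")


def _model_eval(model: str, data: VelocityDataset, p: Mapping[str, float]):
    return MODELS[model]["eval"](data, p)


def _default_bounds(name: str, data: VelocityDataset) -> tuple[float, float]:
    vmax_hi = 100.0 * max(float(np.max(data.v)), 1e-12)
    table = {
        "vmax": (1e-8, vmax_hi),
        "v": (1e-8, vmax_hi),
        "ka": (1e-6, 1e4),
        "kb": (1e-6, 1e4),
        "kia": (1e-6, 1e4),
        "km": (1e-6, 1e4),
        "k05": (1e-6, 1e4),
        "ki": (1e-6, 1e6),
        "alpha": (1e-3, 1e3),
        "n": (0.1, 10.0),
    }
    return table[name]


def _default_init(name: str, data: VelocityDataset) -> float:
    common = _init_common(data)
    if name in common:
        return common[name]
    if name == "ki":
        return _init_inhibition(data)
    if name == "alpha":
        return 1.0
    if name in ("ka", "kia"):
        a = data.a
        return float(np.median(a[a > 0])) if np.any(a > 0) else 1.0
    if name == "kb":
        b = data.b
        return float(np.median(b[b > 0])) if np.any(b > 0) else 1.0
    raise KeyError(name)


def _check_design(model: str, data: VelocityDataset) -> None:
    if model in ("random_re", "ordered", "ping_pong"):
        if data.n_levels("a") < 2 or data.n_levels("b") < 2:
            raise IdentifiabilityError(
                f"model {model!r} needs >= 2 distinct levels of both substrates; "
                f"got {data.n_levels('a')} A-levels and {data.n_levels('b')} B-levels"
            )
    if model in _INHIBITION_MODELS:
        if data.n_levels("i") < 2:
            raise IdentifiabilityError(
                f"model {model!r} needs inhibitor variation; the dataset has "
                f"{data.n_levels('i')} inhibitor level(s)"
            )
    n_par = len(MODELS[model]["params"])
    if len(data) <= n_par:
        raise IdentifiabilityError(
            f"{len(data)} observations cannot identify {n_par} parameters"
        )


def _aicc(rss: float, n: int, k: int) -> float:
    # least-squares AICc; +1 for the implicit error variance
    k_eff = k + 1
    if n - k_eff - 1 <= 0:
        return math.inf
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k_eff + 2 * k_eff * (k_eff + 1) / (n - k_eff - 1)


def fit_global(
    data: VelocityDataset,
    model: str,
    init: Mapping[str, float] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    weights: str = "none",
    n_starts: int = 8,
    seed: int = DEFAULT_SEED,
) -> FitResult:
    """Fit ``model`` to the whole dataset by (weighted) least squares.

    Parameters
    ----------
    data : VelocityDataset
    model : str
        A key of :data:`MODELS`.
    init, bounds : mapping, optional
        Override the data-driven initial values and the default bounds.
    weights : {"none", "relative"}
        "relative" divides residuals by the observed v (floored at its
        smallest positive value), approximating constant relative error.
    n_starts : int
        Number of seeded starts; the first is the data-driven (or supplied)
        init, the rest are log-uniform draws within bounds.  Use 1 for bulk
        simulation studies where the init heuristic is known to be adequate.
    seed : int
        Seed for the multi-start draws.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    _check_design(model, data)
    names = MODELS[model]["params"]
    evaluate = MODELS[model]["eval"]

    v_obs = data.v
    if weights == "relative":
        floor = np.min(v_obs[v_obs > 0]) if np.any(v_obs > 0) else 1.0
        w = 1.0 / np.maximum(v_obs, floor)
    elif weights == "none":
        w = np.ones_like(v_obs)
    else:
        raise ValueError("weights must be 'none' or 'relative'")

    lo_hi = {
        name: (bounds or {}).get(name, _default_bounds(name, data)) for name in names
    }
    x0 = {name: (init or {}).get(name, _default_init(name, data)) for name in names}
    for name in names:
        lo, hi = lo_hi[name]
        x0[name] = min(max(x0[name], lo), hi)

    def residual(params):
        p = {name: params[name].value for name in names}
        return (evaluate(data, p) - v_obs) * w

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        params = lmfit.Parameters()
        for name in names:
            lo, hi = lo_hi[name]
            if start == 0:
                value = x0[name]
            else:
                value = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            params.add(name, value=value, min=lo, max=hi)
        try:
            out = lmfit.minimize(residual, params, method="leastsq")
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr - 1e-12 * (1 + best.chisqr):
            best = out
    if best is None:
        raise RuntimeError(f"all {n_starts} starts failed for model {model!r}")

    estimates = {name: float(best.params[name].value) for name in names}
    stderr = {
        name: float(best.params[name].stderr)
        if best.params[name].stderr is not None
        else float("nan")
        for name in names
    }
    resid = evaluate(data, estimates) - v_obs
    rss = float(np.sum(resid**2))
    n = len(data)
    return FitResult(
        model=model,
        estimates=estimates,
        stderr=stderr,
        rss=rss,
        n_obs=n,
        converged=bool(best.success),
        aicc=_aicc(float(best.chisqr), n, len(names)),
        n_params=len(names),
    )


@dataclass
class InhibitionSeriesFit:
    """Model-selection result over the linear inhibition family."""

    best: FitResult
    kind: str
    alpha_flag: str  # "α<1", "α=1", "α>1", or "n/a"
    fits: Dict[str, FitResult]
    delta_aicc: Dict[str, float]
    ambiguous: tuple[str, ...] = ()


_KIND_CODE = {
    "competitive": "C",
    "noncompetitive": "NC",
    "mixed": "MT",
    "uncompetitive": "UC",
}


def alpha_flag_from_mixed(fit: FitResult, z: float = 2.0) -> str:
    """Classify the mixed-model interaction factor against 1 using its S.E."""
    if "alpha" not in fit.estimates:
        return "n/a"
    a = fit.estimates["alpha"]
    se = fit.stderr.get("alpha", float("nan"))
    if not math.isfinite(se) or se <= 0:
        return "α<1" if a < 1 else ("α>1" if a > 1 else "α=1")
    if a + z * se < 1.0:
        return "α<1"
    if a - z * se > 1.0:
        return "α>1"
    return "α=1"


def fit_inhibition_series(
    data: VelocityDataset,
    candidates: Sequence[str] = ("competitive", "noncompetitive", "mixed", "uncompetitive"),
    ambiguity_band: float = 2.0,
    weights: str = "none",
    n_starts: int = 8,
    seed: int = DEFAULT_SEED,
) -> InhibitionSeriesFit:
    """Fit every candidate inhibition law and select by AICc.

    Requires at least three inhibitor levels including zero.  Candidates
    within ``ambiguity_band`` AICc units of the best are reported in
    ``ambiguous`` rather than silently dropped.  The alpha flag always comes
    from the mixed fit (refit if "mixed" was not among the candidates).
    """
    unknown = [c for c in candidates if c not in _INHIBITION_MODELS]
    if unknown:
        raise ValueError(f"unknown inhibition kinds: {unknown}")
    i_levels = np.unique(data.i)
    if i_levels.size < 3:
        raise IdentifiabilityError(
            f"need >= 3 inhibitor levels, got {i_levels.size}"
        )
    if 0.0 not in i_levels:
        raise IdentifiabilityError("inhibition series must include [I] = 0")

    fits: Dict[str, FitResult] = {}
    for kind in candidates:
        fits[kind] = fit_global(
            data, kind, weights=weights, n_starts=n_starts, seed=seed
        )
    best_kind = min(fits, key=lambda k: fits[k].aicc)
    best = fits[best_kind]
    delta = {k: fits[k].aicc - best.aicc for k in fits}
    ambiguous = tuple(
        k for k in fits if k != best_kind and delta[k] < ambiguity_band
    )

    mixed_fit = fits.get("mixed")
    if mixed_fit is None:
        mixed_fit = fit_global(
            data, "mixed", weights=weights, n_starts=n_starts, seed=seed
        )
    return InhibitionSeriesFit(
        best=best,
        kind=best_kind,
        alpha_flag=alpha_flag_from_mixed(mixed_fit),
        fits=fits,
        delta_aicc=delta,
        ambiguous=ambiguous,
    )
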