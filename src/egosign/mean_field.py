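"""Mean-field analytics for the ego-triad balance/status dynamics.

Under the mean-field assumption that every directed link is an independent
Bernoulli(rho) sign, the net drift of the positive-link density is the
rate of negative-to-positive flips minus the rate of positive-to-negative
flips.  Summing the per-class contributions (class probability times the
expected signed flip) gives a cubic in ``rho`` that factors as ``(1 -
rho) * Q(rho)`` where ::

    Q(rho) = [2(1-q)(2 p_sbt - 1)] rho^2
             - [2(1-q) + (1 - 2 p_st) q] rho + (1-q)

so ``rho = 1`` (paradise) is always a fixed point and the quasistationary
densities are the roots of the quadratic ``Q``.  Depending on the
parameters the phase portrait is *disordered* (an interior stable root),
*paradise* (only ``rho = 1`` attracts), or *bistable* (interior stable
root, an unstable separatrix, and a stable paradise).  Sweeping a control
parameter produces either a continuous transition (the interior stable
root reaches 1) or a discontinuous one (a fold: the stable and unstable
interior roots merge at an interior density and vanish).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .abm_dynamics import ModelParams

__all__ = [
    "PhasePortrait",
    "TransitionResult",
    "drift",
    "eq_coefficients",
    "quasistationary_roots",
    "classify_transition",
    "critical_psbt_at_q0",
    "continuity_boundary_pst",
]

_COEF_TOL = 1e-12
_STAB_EPS = 1e-6


def drift(rho: float, params: ModelParams) -> float:
    """Net mean-field rate of change of the positive-link density.

    Computed directly from the six unstable-triad channels (not from the
    factored quadratic):

    * balance branch, weight ``1-q``: a UH0 triad (prob ``rho^2 (1-rho)``)
      always flips a positive focal link; UN1 and UH1 (each ``rho^2
      (1-rho)``) flip the negative focal link with probability ``p_sbt``;
      UH2 (``(1-rho)^3``) always flips a negative link;
    * status branch, weight ``q``: the nonhierarchical UN1 (``rho^2
      (1-rho)``) and BN1 (``rho (1-rho)^2``) flip their negative focal
      link with probability ``p_st``.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    q, psbt, pst = params.q, params.p_sbt, params.p_st
    r = 1.0 - rho
    bal = (1.0 - q) * (
        - rho * rho * r                      # UH0: positive focal link flips
        + rho * rho * r * (2.0 * psbt - 1.0)  # UN1
        + rho * rho * r * (2.0 * psbt - 1.0)  # UH1
        + r * r * r                          # UH2: negative link flips
    )
    stat = q * (2.0 * pst - 1.0) * (
        rho * rho * r                        # UN1 (status-unstable)
        + rho * r * r                        # BN1
    )
    return bal + stat


def eq_coefficients(params: ModelParams) -> tuple[float, float, float]:
    """Coefficients (a, b, c) of the quasistationary quadratic Q."""
    q, psbt, pst = params.q, params.p_sbt, params.p_st
    a = 2.0 * (1.0 - q) * (2.0 * psbt - 1.0)
    b = -(2.0 * (1.0 - q) + (1.0 - 2.0 * pst) * q)
    c = 1.0 - q
    return a, b, c


@dataclasses.dataclass(frozen=True)
class PhasePortrait:
    params: ModelParams
    roots: tuple[float, ...]           # ascending, always includes 1.0
    stability: tuple[str, ...]         # "stable" | "unstable" | "marginal"
    separatrix: Optional[float]
    regime: str                        # "disordered" | "paradise" | "bistable"

    @property
    def interior_stable(self) -> Optional[float]:
        for r, s in zip(self.roots, self.stability):
            if s == "stable" and r < 1.0 - 1e-9:
                return r
        return None


def _classify_root(rho: float, params: ModelParams) -> str:
    lo = max(rho - _STAB_EPS, 0.0)
    hi = min(rho + _STAB_EPS, 1.0)
    d_lo = drift(lo, params) if lo < rho else None
    d_hi = drift(hi, params) if hi > rho else None
    if d_lo is None:                       # boundary root at 0
        return "stable" if d_hi < 0 else ("unstable" if d_hi > 0 else "marginal")
    if d_hi is None:                       # boundary root at 1
        return "stable" if d_lo > 0 else ("unstable" if d_lo < 0 else "marginal")
    if d_lo > 0 and d_hi < 0:
        return "stable"
    if d_lo < 0 and d_hi > 0:
        return "unstable"
    return "marginal"


def quasistationary_roots(params: ModelParams) -> PhasePortrait:
    """Solve Q(rho) = 0 in [0, 1], append rho = 1, classify stability.

    Degenerate cases are defined outcomes: a vanishing leading coefficient
    reduces to the linear equation; at ``q = 1, p_st = 0.5`` the drift is
    identically zero and every density is marginal (reported as a
    disordered portrait with only the marginal rho = 1).
    """
    a, b, c = eq_coefficients(params)
    interior: list[float] = []
    if abs(a) < _COEF_TOL:
        if abs(b) >= _COEF_TOL:
            interior.append(-c / b)
        # else drift identically zero (q=1, p_st=0.5): no interior roots
    else:
        disc = b * b - 4.0 * a * c
        if abs(disc) <= _COEF_TOL:
            interior.append(-b / (2.0 * a))
        elif disc > 0:
            sq = disc ** 0.5
            interior.extend(((-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)))
    interior = sorted(x for x in interior if 0.0 <= x < 1.0 - 1e-9)

    roots = tuple(interior) + (1.0,)
    stability = tuple(_classify_root(r, params) for r in roots)

    interior_stable = any(s == "stable" for r, s in zip(roots, stability)
                          if r < 1.0 - 1e-9)
    interior_unstable = [r for r, s in zip(roots, stability)
                         if s == "unstable" and r < 1.0 - 1e-9]
    paradise_stable = stability[-1] == "stable"

    if interior_stable and interior_unstable and paradise_stable:
        regime = "bistable"
        separatrix = interior_unstable[-1]
    elif interior_stable:
        regime = "disordered"
        separatrix = None
    elif abs(a) < _COEF_TOL and abs(b) < _COEF_TOL and abs(c) < _COEF_TOL:
        # q=1, p_st=0.5: drift vanishes identically, every density frozen
        regime = "disordered"
        separatrix = None
    else:
        regime = "paradise"
        separatrix = None
    return PhasePortrait(params=params, roots=roots, stability=stability,
                         separatrix=separatrix, regime=regime)


@dataclasses.dataclass(frozen=True)
class TransitionResult:
    control: str
    critical_value: Optional[float]
    type: str        # "continuous" | "discontinuous" | "none-disordered" | "none-paradise"
    grid: tuple[float, ...]
    regimes: tuple[str, ...]


def _params_at(fixed: dict, control: str, x: float) -> ModelParams:
    kw = dict(fixed)
    kw[control] = x
    return ModelParams(**kw)


def classify_transition(fixed: dict, control: str,
                        grid: np.ndarray | None = None) -> TransitionResult:
    """Sweep a control parameter and classify the paradise transition.

    ``fixed`` holds the two non-swept parameters (e.g. ``{"q": 0.5,
    "p_st": 0.2}`` with ``control="p_sbt"``).  Along the sweep the
    transition is *continuous* when the interior stable root reaches 1
    (``Q(1) = 0``) with no coexisting interior unstable root, and
    *discontinuous* when the stable/unstable interior pair merges at an
    interior density (discriminant zero — a fold) and vanishes.  If the
    regime never changes the type is ``none-disordered`` or
    ``none-paradise``.
    """
    if control not in ("q", "p_sbt", "p_st"):
        raise ValueError(f"unknown control parameter {control!r}")
    if set(fixed) != {"q", "p_sbt", "p_st"} - {control}:
        raise ValueError("fixed must supply exactly the two non-swept parameters")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 401)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be increasing with at least two points")

    portraits = [quasistationary_roots(_params_at(fixed, control, x))
                 for x in grid]
    regimes = tuple(p.regime for p in portraits)

    if all(r == "disordered" for r in regimes):
        return TransitionResult(control, None, "none-disordered", tuple(grid), regimes)
    if all(r == "paradise" for r in regimes):
        return TransitionResult(control, None, "none-paradise", tuple(grid), regimes)

    def q1(x: float) -> float:
        a, b, c = eq_coefficients(_params_at(fixed, control, x))
        return a + b + c

    def disc(x: float) -> float:
        a, b, c = eq_coefficients(_params_at(fixed, control, x))
        return b * b - 4.0 * a * c

    def fold_rho(x: float) -> float:
        a, b, _ = eq_coefficients(_params_at(fixed, control, x))
        if abs(a) < _COEF_TOL:
            return np.inf
        return -b / (2.0 * a)

    # fold: discriminant zero with the merging double root strictly interior
    fold_x = None
    for i in range(grid.size - 1):
        d0, d1 = disc(grid[i]), disc(grid[i + 1])
        if d0 == 0.0 or d0 * d1 < 0:
            x = grid[i] if d0 == 0.0 else brentq(disc, grid[i], grid[i + 1],
                                                 xtol=1e-14)
            if 1e-9 < fold_rho(x) < 1.0 - 1e-9:
                fold_x = float(x)
                break

    # Q(1) = 0 crossings: rho=1 becomes a root of Q.  If the companion
    # root (product of roots = c/a) is interior this is the onset of a
    # bistable window (the separatrix enters [0,1]); otherwise the
    # interior stable root itself reaches 1 — a continuous transition.
    q1_x = None
    onset_x = None
    for i in range(grid.size - 1):
        v0, v1 = q1(grid[i]), q1(grid[i + 1])
        if v0 == 0.0 or v0 * v1 < 0:
            x = float(grid[i] if v0 == 0.0
                      else brentq(q1, grid[i], grid[i + 1], xtol=1e-14))
            a, _, c = eq_coefficients(_params_at(fixed, control, x))
            companion = c / a if abs(a) > _COEF_TOL else np.inf
            if 1e-9 < companion < 1.0 - 1e-9:
                onset_x = x
            elif q1_x is None:
                q1_x = x

    if fold_x is not None:
        return TransitionResult(control, fold_x, "discontinuous", tuple(grid), regimes)
    if onset_x is not None or "bistable" in regimes:
        # bistable window opens but the fold lies beyond the sweep range;
        # report the bistability onset as the critical value
        return TransitionResult(control, onset_x, "discontinuous", tuple(grid),
                                regimes)
    if q1_x is not None:
        return TransitionResult(control, q1_x, "continuous", tuple(grid), regimes)
    # regime changed but no analytic event located (should not happen for
    # non-degenerate sweeps); report the grid boundary of the change
    change = next(i for i in range(len(regimes) - 1)
                  if regimes[i] != regimes[i + 1])
    return TransitionResult(control, float(grid[change]),
                            "continuous", tuple(grid), regimes)


def critical_psbt_at_q0() -> float:
    """The p_sbt at which, for q = 0, the interior root reaches rho = 1.

    Solved numerically from the condition ``Q(1) = 0`` along p_sbt.
    """
    def q1(p: float) -> float:
        a, b, c = eq_coefficients(ModelParams(q=0.0, p_sbt=p, p_st=0.5))
        return a + b + c

    return float(brentq(q1, 0.0, 1.0, xtol=1e-14))


def continuity_boundary_pst(q: float = 0.5, lo: float = 0.05, hi: float = 0.95,
                            tol: float = 1e-6,
                            sweep_grid: np.ndarray | None = None) -> float:
    """The p_st separating continuous from discontinuous p_sbt-sweeps.

    For fixed ``q``, sweeping p_sbt yields a discontinuous transition for
    small p_st and a continuous one for large p_st; this bisects on the
    classifier to locate the boundary.
    """
    if sweep_grid is None:
        sweep_grid = np.linspace(0.0, 1.0, 201)

    def is_continuous(pst: float) -> bool:
        res = classify_transition({"q": q, "p_st": pst}, "p_sbt", sweep_grid)
        if res.type not in ("continuous", "discontinuous"):
            raise ValueError(
                f"no paradise transition when sweeping p_sbt at p_st={pst}")
        return res.type == "continuous"

    f_lo, f_hi = is_continuous(lo), is_continuous(hi)
    if f_lo == f_hi:
        raise ValueError("bracket does not straddle the regime boundary")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if is_continuous(mid) == f_hi:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
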