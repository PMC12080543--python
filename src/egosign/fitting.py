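"""Grid-search calibration of (q, p_sbt, p_st) to an observed network.

The observable is the triad-deviation profile: the six relative-density
deviations (from the uniform 1/3) of the one-negative and two-negative
ego-triad groups, plus the positive-link density as a diagnostic.  For
every parameter triple on a grid, the dynamics is simulated on the
*observed topology* (signs re-initialised i.i.d.), the quasistationary
deviations are averaged over repetitions, and the parameter set is scored
by the mean squared error against the observed deviations.  All parameter
sets whose error is below ``selection_factor`` times the best error enter
the estimate; the reported uncertainty per parameter combines their
standard deviation with the grid step in quadrature.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional

import numpy as np

from .signed_graph import SignedDigraph
from .abm_dynamics import (ModelParams, Schedule, _is_complete,
                           prune_nontriadic_links, run)
from .triad_logic import census

__all__ = ["FitConfig", "FitResult", "ObservedTargets", "observed_targets",
           "score_deviations", "fit"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ObservedTargets:
    """Deviation profile of an observed network."""

    rho: float
    deviations: np.ndarray      # UH0, UN1, UH1, BH1, BN1, BH2; NaN if undefined


def observed_targets(g: SignedDigraph, prune: bool = True) -> ObservedTargets:
    """Positive-link density and the six group deviations of a network."""
    if prune:
        g = prune_nontriadic_links(g)
    if g.num_edges == 0:
        raise ValueError("graph has no ego-based triads")
    stats = census(g)
    if stats.total == 0:
        raise ValueError("graph has no ego-based triads")
    return ObservedTargets(rho=stats.rho, deviations=stats.deviation_vector())


def score_deviations(simulated: np.ndarray, observed: np.ndarray) -> float:
    """Mean squared error over the deviations defined on both sides."""
    simulated = np.asarray(simulated, dtype=float)
    observed = np.asarray(observed, dtype=float)
    mask = ~(np.isnan(simulated) | np.isnan(observed))
    if not mask.any():
        raise ValueError("no commonly defined deviations to score")
    diff = simulated[mask] - observed[mask]
    return float(np.mean(diff * diff))


@dataclasses.dataclass(frozen=True)
class FitConfig:
    """Grid-search configuration.

    Defaults mirror the coarse protocol used for large online networks
    (steps 0.025 in q and 0.1 in both flip preferences); the finer 0.05
    step suits smaller school-size networks.  ``rho0`` is the sign
    re-initialisation density; ``None`` means use the observed density.
    ``rho_weight`` optionally adds ``rho_weight * (rho_sim - rho_obs)^2``
    to the error (off by default: the error function is defined on the
    deviations alone).
    """

    q_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0001, 0.025), 6))
    psbt_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0001, 0.1), 6))
    pst_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0001, 0.1), 6))
    reps: int = 5
    rho0: Optional[float] = None
    selection_factor: float = 1.10
    schedule: Schedule = Schedule(burnin_sweeps=50, window_sweeps=50,
                                  census_every=10)
    rho_weight: float = 0.0

    def __post_init__(self):
        for name in ("q_grid", "psbt_grid", "pst_grid"):
            grid = getattr(self, name)
            if len(grid) == 0:
                raise ValueError(f"{name} is empty")
            if any(not 0.0 <= x <= 1.0 for x in grid):
                raise ValueError(f"{name} values must lie in [0, 1]")
        if self.selection_factor < 1.0:
            raise ValueError("selection_factor must be >= 1")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.schedule.census_every is None:
            raise ValueError("schedule must take census snapshots "
                             "(set census_every)")

    def grid_step(self, name: str) -> float:
        grid = {"q": self.q_grid, "p_sbt": self.psbt_grid,
                "p_st": self.pst_grid}[name]
        if len(grid) < 2:
            return 0.0
        return float(np.min(np.diff(sorted(grid))))


@dataclasses.dataclass
class FitResult:
    grid: list[ModelParams]
    errors: np.ndarray                  # NaN where a point was excluded
    best: ModelParams
    best_error: float
    best_deviations: np.ndarray
    best_rho: float
    selected: list[ModelParams]
    means: dict[str, float]
    sds: dict[str, float]
    uncertainties: dict[str, float]
    observed: ObservedTargets

    def to_dict(self) -> dict:
        return {
            "best": dataclasses.asdict(self.best),
            "best_error": self.best_error,
            "best_deviations": self.best_deviations.tolist(),
            "best_rho": self.best_rho,
            "means": self.means,
            "sds": self.sds,
            "uncertainties": self.uncertainties,
            "observed_rho": self.observed.rho,
            "observed_deviations": self.observed.deviations.tolist(),
            "n_selected": len(self.selected),
            "selected": [dataclasses.asdict(p) for p in self.selected],
            "grid": [dataclasses.asdict(p) for p in self.grid],
            "errors": [None if math.isnan(e) else e for e in self.errors],
        }


def simulate_deviations(g: SignedDigraph, params: ModelParams,
                        schedule: Schedule, reps: int, rho0: float,
                        rng: np.random.Generator,
                        mode: str) -> tuple[np.ndarray, float, int]:
    """Mean quasistationary deviations over repetitions on g's topology.

    Signs are re-initialised Bernoulli(rho0) per repetition.  Returns the
    rep-averaged deviation vector (NaN-aware), the mean density, and the
    number of stationary repetitions.
    """
    dev_acc: list[np.ndarray] = []
    rho_acc: list[float] = []
    ok = 0
    for _ in range(reps):
        h = g.copy()
        h.sign[:] = np.where(rng.random(h.num_edges) < rho0, 1, -1)
        res = run(h, params, schedule=schedule, rng=rng, mode=mode)
        if res.absorbed == "paradise":
            # all-positive: group deviations undefined, density 1
            dev_acc.append(np.full(6, np.nan))
            rho_acc.append(1.0)
            ok += 1
            continue
        if not res.stationary:
            continue
        ok += 1
        devs = np.array([s.deviation_vector() for s in res.census_snapshots])
        dev_acc.append(_nanmean_cols(devs))
        rho_acc.append(res.quasistationary_rho)
    if ok == 0:
        return np.full(6, np.nan), math.nan, 0
    return _nanmean_cols(np.array(dev_acc)), float(np.mean(rho_acc)), ok


def _nanmean_cols(rows: np.ndarray) -> np.ndarray:
    """Column-wise NaN-aware mean; all-NaN columns stay NaN, silently."""
    defined = ~np.isnan(rows)
    counts = defined.sum(axis=0)
    sums = np.where(defined, rows, 0.0).sum(axis=0)
    return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def fit(g: SignedDigraph, config: FitConfig = FitConfig(),
        rng=None) -> FitResult:
    """Calibrate the model parameters to an observed signed network."""
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    g = prune_nontriadic_links(g)
    obs = observed_targets(g, prune=False)
    rho0 = obs.rho if config.rho0 is None else config.rho0
    mode = "complete" if _is_complete(g) else "general"

    grid: list[ModelParams] = [
        ModelParams(q=q, p_sbt=pb, p_st=ps)
        for q in config.q_grid for pb in config.psbt_grid
        for ps in config.pst_grid
    ]
    errors = np.full(len(grid), np.nan)
    devs_at = np.full((len(grid), 6), np.nan)
    rho_at = np.full(len(grid), np.nan)
    for i, params in enumerate(grid):
        dev, rho_sim, ok = simulate_deviations(
            g, params, config.schedule, config.reps, rho0, rng, mode)
        if ok == 0:
            logger.warning("grid point %s excluded: no stationary repetition",
                           params)
            continue
        devs_at[i] = dev
        rho_at[i] = rho_sim
        try:
            err = score_deviations(dev, obs.deviations)
        except ValueError:
            logger.warning("grid point %s excluded: deviations undefined",
                           params)
            continue
        if config.rho_weight > 0.0:
            err += config.rho_weight * (rho_sim - obs.rho) ** 2
        errors[i] = err

    if np.all(np.isnan(errors)):
        raise RuntimeError("every grid point was excluded; cannot fit")
    best_i = int(np.nanargmin(errors))
    best_error = float(errors[best_i])
    threshold = config.selection_factor * best_error
    sel_idx = [i for i, e in enumerate(errors)
               if not math.isnan(e) and e <= threshold]
    selected = [grid[i] for i in sel_idx]

    means, sds, uncertainties = {}, {}, {}
    for name in ("q", "p_sbt", "p_st"):
        vals = np.array([getattr(p, name) for p in selected])
        means[name] = float(vals.mean())
        sds[name] = float(vals.std(ddof=0))
        step = config.grid_step(name)
        uncertainties[name] = math.sqrt(sds[name] ** 2 + (step / 2.0) ** 2)

    return FitResult(
        grid=grid, errors=errors, best=grid[best_i], best_error=best_error,
        best_deviations=devs_at[best_i], best_rho=float(rho_at[best_i]),
        selected=selected, means=means, sds=sds,
        uncertainties=uncertainties, observed=obs,
    )
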