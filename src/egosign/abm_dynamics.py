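"""Ego-perspective Monte-Carlo dynamics on signed directed networks.

One elementary update: sample an ego-based triad; with probability ``q``
evaluate its stability by status theory (unstable iff nonhierarchical),
otherwise by structural balance (unstable iff unbalanced).  A stable triad
is left untouched; an unstable one has exactly one of the focal agent's
two out-links flipped.  When the two focal links share a sign the flipped
one is chosen uniformly; when they differ, the negative link is flipped
with probability ``p_st`` (status branch) or ``p_sbt`` (balance branch)
and the positive one otherwise.  The inner link is never touched by the
focal agent.

Time is measured in elementary updates; a *sweep* is ``L`` updates where
``L`` is the number of directed edges.  The all-positive *paradise* state
is absorbing under both theories.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .signed_graph import SignedDigraph, GeneratorSpec, generate
from .triad_logic import EgoTriad, CensusStats, census, classify

__all__ = [
    "ModelParams",
    "Schedule",
    "SimulationResult",
    "StepRecord",
    "sample_ego_triad",
    "prune_nontriadic_links",
    "step",
    "run",
    "estimate_paradise_probability",
    "has_unstable_triad",
]


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """The three model parameters.

    q
        Probability of evaluating a sampled triad by status theory
        (vs. structural balance).
    p_sbt
        When balance-repairing a mixed-sign unstable triad, probability of
        flipping the negative focal link (preference for forming positive
        relations).
    p_st
        Same choice under the status branch (preference for respecting
        others).
    """

    q: float
    p_sbt: float
    p_st: float

    def __post_init__(self):
        for name in ("q", "p_sbt", "p_st"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclasses.dataclass(frozen=True)
class Schedule:
    """Simulation schedule, in sweeps (1 sweep = #edges elementary updates)."""

    burnin_sweeps: int = 50
    window_sweeps: int = 50
    sample_every: int = 1
    max_doublings: int = 3
    stationarity_sigma: float = 3.0
    census_every: Optional[int] = None


@dataclasses.dataclass
class SimulationResult:
    rho_trajectory: np.ndarray        # rho sampled once per `sample_every` sweeps
    absorbed: str                     # "paradise" or "none"
    quasistationary_rho: float
    quasistationary_se: float
    stationary: bool
    steps_run: int
    final_graph: SignedDigraph
    census_snapshots: list[CensusStats] = dataclasses.field(default_factory=list)


@dataclasses.dataclass(frozen=True)
class StepRecord:
    triad: EgoTriad
    theory: str                       # "status" or "balance"
    unstable: bool
    flipped: Optional[tuple[int, int]]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _is_complete(g: SignedDigraph) -> bool:
    return g.num_edges == g.num_nodes * (g.num_nodes - 1)


# ---------------------------------------------------------------------------
# Triad sampling
# ---------------------------------------------------------------------------

class _GeneralSampler:
    """Precomputed eligibility structure for triad sampling on sparse graphs.

    The focal agent A is uniform over agents with at least one eligible
    out-neighbour; B is uniform over A's out-neighbours sharing at least
    one eligible third agent; C is uniform over agents with an A->C link
    and at least one directed link between B and C; the inner link is
    uniform over the existing direction(s).
    """

    __slots__ = ("focal", "bentries")

    def __init__(self, g: SignedDigraph):
        eidx = g.edge_index()
        out: dict[int, list[int]] = {}
        for (u, v) in eidx:
            out.setdefault(u, []).append(v)
        self.focal: list[int] = []
        # bentries[i] parallels focal[i]: list of per-B lists of C-entries
        # (k_ab, k_ac, options); an option is (k_inner, first_is_b).
        self.bentries: list[list[list[tuple]]] = []
        for a in sorted(out):
            blists = []
            for b in sorted(out[a]):
                centries = []
                for c in sorted(out[a]):
                    if c == b:
                        continue
                    options = []
                    if (b, c) in eidx:
                        options.append((eidx[(b, c)], True))
                    if (c, b) in eidx:
                        options.append((eidx[(c, b)], False))
                    if options:
                        centries.append((eidx[(a, b)], eidx[(a, c)], options))
                if centries:
                    blists.append(centries)
            if blists:
                self.focal.append(a)
                self.bentries.append(blists)
        if not self.focal:
            raise ValueError("graph contains no ego-based triads")

    def draw(self, u: tuple[float, float, float, float]) -> tuple[int, int, list]:
        """Map four uniforms to (k_left, k_right, signs-layout) indices."""
        blists = self.bentries[int(u[0] * len(self.focal))]
        centries = blists[int(u[1] * len(blists))]
        k_ab, k_ac, options = centries[int(u[2] * len(centries))]
        k_inner, first_is_b = options[int(u[3] * len(options))]
        if first_is_b:
            return k_ab, k_ac, k_inner
        return k_ac, k_ab, k_inner


def sample_ego_triad(g: SignedDigraph, rng, mode: str = "auto") -> EgoTriad:
    """Sample one ego-based triad.

    In ``complete`` mode an ordered node triple (A, B, C) is uniform over
    all ``N(N-1)(N-2)`` possibilities and the inner link is B->C.  In
    ``general`` mode the eligibility-filtered hierarchical sampling of
    :class:`_GeneralSampler` is used (the graph should be pruned of
    non-triadic links first, see :func:`prune_nontriadic_links`).
    """
    rng = _as_rng(rng)
    if mode == "auto":
        mode = "complete" if _is_complete(g) else "general"
    if mode == "complete":
        if not _is_complete(g):
            raise ValueError("complete mode requires a complete topology")
        n = g.num_nodes
        a, b, c = rng.choice(n, size=3, replace=False)
        a, b, c = int(a), int(b), int(c)
        return EgoTriad(a, b, c,
                        (g.sign_of(a, b), g.sign_of(a, c), g.sign_of(b, c)))
    sampler = _GeneralSampler(g)
    kl, kr, ki = sampler.draw(tuple(rng.random(4)))
    a = int(g.src[kl])
    left, right = int(g.dst[kl]), int(g.dst[kr])
    return EgoTriad(a, left, right,
                    (int(g.sign[kl]), int(g.sign[kr]), int(g.sign[ki])))


def prune_nontriadic_links(g: SignedDigraph) -> SignedDigraph:
    """Remove every edge that participates in no ego-based triad.

    An edge participates either as one of the two focal out-links or as
    the inner link.  Membership only depends on which other edges exist,
    so a single pass suffices.
    """
    n = g.num_nodes
    exist = sp.csr_matrix((np.ones(g.num_edges), (g.src, g.dst)), shape=(n, n))
    sym = ((exist + exist.T) > 0).astype(float)
    # focal role: #{w : (u,w) edge and v,w linked either way}
    focal_cnt = (exist @ sym).toarray()
    # inner role: #{a : (a,u) and (a,v) edges}
    inner_cnt = (exist.T @ exist).toarray()
    keep = np.array([
        focal_cnt[u, v] > 0 or inner_cnt[u, v] > 0
        for u, v in zip(g.src.tolist(), g.dst.tolist())
    ], dtype=bool)
    return SignedDigraph(n, g.src[keep], g.dst[keep], g.sign[keep], g.labels)


# ---------------------------------------------------------------------------
# Single evaluation step (reference implementation)
# ---------------------------------------------------------------------------

def _choose_flip(signs_lr: tuple[int, int], p_neg: float, u: float) -> int:
    """Return 0 to flip the left focal link, 1 for the right one."""
    s1, s2 = signs_lr
    if s1 == s2:
        return 0 if u < 0.5 else 1
    if u < p_neg:      # flip the negative link
        return 0 if s1 < 0 else 1
    return 0 if s1 > 0 else 1


def step(g: SignedDigraph, params: ModelParams, rng,
         mode: str = "auto") -> StepRecord:
    """Perform one elementary update in place and report what happened."""
    rng = _as_rng(rng)
    triad = sample_ego_triad(g, rng, mode=mode)
    cls = triad.triad_class
    if rng.random() < params.q:
        theory, unstable, p_neg = "status", not cls.hierarchical, params.p_st
    else:
        theory, unstable, p_neg = "balance", not cls.balanced, params.p_sbt
    if not unstable:
        return StepRecord(triad, theory, False, None)
    which = _choose_flip(triad.signs[:2], p_neg, rng.random())
    v = triad.left if which == 0 else triad.right
    g.set_sign(triad.focal, v, -triad.signs[which])
    return StepRecord(triad, theory, True, (triad.focal, v))


# ---------------------------------------------------------------------------
# Fast inner loops (chunked pre-drawn uniforms, plain Python lists)
# ---------------------------------------------------------------------------

def _sweep_complete(S: list, n: int, pos: int, L: int, q: float, psbt: float,
                    pst: float, nsteps: int, rng: np.random.Generator):
    """Run `nsteps` updates on a complete graph; returns (pos, absorbed_at)."""
    u = rng.random(5 * nsteps).tolist()
    i = 0
    for t in range(nsteps):
        a = int(u[i] * n)
        b = int(u[i + 1] * (n - 1))
        if b >= a:
            b += 1
        c = int(u[i + 2] * (n - 2))
        lo, hi = (a, b) if a < b else (b, a)
        if c >= lo:
            c += 1
        if c >= hi:
            c += 1
        ut = u[i + 3]
        ul = u[i + 4]
        i += 5
        kb = a * n + b
        kc = a * n + c
        s1 = S[kb]
        s2 = S[kc]
        s3 = S[b * n + c]
        if ut < q:
            if s1 != s2 and s3 == s1:       # nonhierarchical -> unstable
                if ul < pst:
                    k = kb if s1 < 0 else kc
                else:
                    k = kb if s1 > 0 else kc
            else:
                continue
        elif s1 * s2 * s3 < 0:              # unbalanced
            if s1 == s2:
                k = kb if ul < 0.5 else kc
            elif ul < psbt:
                k = kb if s1 < 0 else kc
            else:
                k = kb if s1 > 0 else kc
        else:
            continue
        s = S[k]
        S[k] = -s
        pos += 1 if s < 0 else -1
        if pos == L:
            return pos, t + 1
    return pos, -1


def _sweep_general(S: list, sampler: _GeneralSampler, pos: int, L: int,
                   q: float, psbt: float, pst: float, nsteps: int,
                   rng: np.random.Generator):
    u = rng.random(6 * nsteps).tolist()
    focal = sampler.focal
    bentries = sampler.bentries
    nf = len(focal)
    i = 0
    for t in range(nsteps):
        blists = bentries[int(u[i] * nf)]
        centries = blists[int(u[i + 1] * len(blists))]
        k_ab, k_ac, options = centries[int(u[i + 2] * len(centries))]
        k_inner, first_is_b = options[int(u[i + 3] * len(options))]
        ut = u[i + 4]
        ul = u[i + 5]
        i += 6
        if first_is_b:
            kl, kr = k_ab, k_ac
        else:
            kl, kr = k_ac, k_ab
        s1 = S[kl]
        s2 = S[kr]
        s3 = S[k_inner]
        if ut < q:
            if s1 != s2 and s3 == s1:
                if ul < pst:
                    k = kl if s1 < 0 else kr
                else:
                    k = kl if s1 > 0 else kr
            else:
                continue
        elif s1 * s2 * s3 < 0:
            if s1 == s2:
                k = kl if ul < 0.5 else kr
            elif ul < psbt:
                k = kl if s1 < 0 else kr
            else:
                k = kl if s1 > 0 else kr
        else:
            continue
        s = S[k]
        S[k] = -s
        pos += 1 if s < 0 else -1
        if pos == L:
            return pos, t + 1
    return pos, -1


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------

class _Engine:
    """Bridges a SignedDigraph and the flat-list inner loops."""

    def __init__(self, g: SignedDigraph, mode: str):
        self.g = g
        self.mode = mode
        self.L = g.num_edges
        if mode == "complete":
            self.n = g.num_nodes
            self.S = g.sign_matrix().astype(int).ravel().tolist()
            self.sampler = None
        else:
            self.S = g.sign.astype(int).tolist()
            self.sampler = _GeneralSampler(g)
        self.pos = int(np.count_nonzero(g.sign == 1))

    def advance(self, nsteps: int, params: ModelParams,
                rng: np.random.Generator) -> int:
        if self.mode == "complete":
            self.pos, at = _sweep_complete(
                self.S, self.n, self.pos, self.L, params.q, params.p_sbt,
                params.p_st, nsteps, rng)
        else:
            self.pos, at = _sweep_general(
                self.S, self.sampler, self.pos, self.L, params.q,
                params.p_sbt, params.p_st, nsteps, rng)
        return at

    def rho(self) -> float:
        return self.pos / self.L

    def snapshot(self) -> SignedDigraph:
        g = self.g
        if self.mode == "complete":
            flat = np.asarray(self.S, dtype=np.int8).reshape(self.n, self.n)
            sign = flat[g.src, g.dst]
        else:
            sign = np.asarray(self.S, dtype=np.int8)
        return SignedDigraph(g.num_nodes, g.src.copy(), g.dst.copy(), sign,
                             g.labels)


def run(g: SignedDigraph, params: ModelParams, schedule: Schedule = Schedule(),
        rng=None, mode: str = "auto",
        engine: "_Engine | None" = None) -> SimulationResult:
    """Simulate the dynamics and estimate the quasistationary density.

    The input graph is not modified.  After ``burnin_sweeps`` sweeps the
    positive-link density is sampled every ``sample_every`` sweeps over a
    measurement window; if the first- and second-half means of the window
    disagree by more than ``stationarity_sigma`` pooled standard errors
    the window is doubled, up to ``max_doublings`` times, after which the
    result is flagged non-stationary.  Absorption into paradise (rho = 1)
    stops the run immediately.
    """
    rng = _as_rng(rng)
    if mode == "auto":
        mode = "complete" if _is_complete(g) else "general"
    if engine is None:
        engine = _Engine(g.copy(), mode)
    L = engine.L
    steps_run = 0
    traj: list[float] = [engine.rho()]

    def absorbed_result(stationary=True):
        traj_arr = np.asarray(traj)
        return SimulationResult(
            rho_trajectory=traj_arr, absorbed="paradise",
            quasistationary_rho=1.0, quasistationary_se=0.0,
            stationary=stationary, steps_run=steps_run,
            final_graph=engine.snapshot())

    if engine.pos == L:
        return absorbed_result()

    # burn-in
    for _ in range(schedule.burnin_sweeps):
        at = engine.advance(L, params, rng)
        steps_run += L if at < 0 else at
        traj.append(engine.rho())
        if at >= 0:
            return absorbed_result()

    # measurement window, extendable
    window: list[float] = []
    snapshots: list[CensusStats] = []
    stationary = False
    doublings = 0
    target = schedule.window_sweeps
    sweeps_done = 0
    while True:
        while sweeps_done < target:
            for _ in range(schedule.sample_every):
                at = engine.advance(L, params, rng)
                steps_run += L if at < 0 else at
                if at >= 0:
                    traj.append(engine.rho())
                    return absorbed_result()
            sweeps_done += schedule.sample_every
            traj.append(engine.rho())
            window.append(engine.rho())
            if (schedule.census_every is not None
                    and sweeps_done % schedule.census_every == 0):
                snapshots.append(census(engine.snapshot()))
        half = len(window) // 2
        m1, m2 = np.mean(window[:half]), np.mean(window[half:])
        se = math.sqrt(
            (np.var(window[:half]) + np.var(window[half:])) / max(half, 1))
        if se == 0.0:
            stationary = bool(m1 == m2)
        else:
            stationary = bool(abs(m1 - m2) <= schedule.stationarity_sigma * se)
        if stationary or doublings >= schedule.max_doublings:
            break
        doublings += 1
        target *= 2

    window_arr = np.asarray(window)
    return SimulationResult(
        rho_trajectory=np.asarray(traj),
        absorbed="none",
        quasistationary_rho=float(window_arr.mean()),
        quasistationary_se=float(window_arr.std(ddof=1)
                                 / math.sqrt(len(window_arr))),
        stationary=stationary,
        steps_run=steps_run,
        final_graph=engine.snapshot(),
        census_snapshots=snapshots,
    )


def estimate_paradise_probability(spec: GeneratorSpec, params: ModelParams,
                                  reps: int, rng=None,
                                  schedule: Schedule = Schedule(),
                                  alpha: float = 0.05):
    """Fraction of independent runs absorbing into paradise, with CI.

    Each repetition draws a fresh graph from ``spec`` (fresh seed from the
    supplied stream) and simulates under ``schedule``; runs that have not
    absorbed when the schedule ends count as not-paradise.  Returns
    ``(fraction, (ci_low, ci_high))`` with a Wilson score interval.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = _as_rng(rng)
    hits = 0
    for _ in range(reps):
        g = generate(dataclasses.replace(spec, seed=int(rng.integers(2**31))))
        res = run(g, params, schedule=schedule, rng=rng)
        hits += res.absorbed == "paradise"
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(hits, reps, alpha=alpha, method="wilson")
    return hits / reps, (float(lo), float(hi))


def has_unstable_triad(g: SignedDigraph, params: ModelParams) -> bool:
    """Whether any ego-triad is unstable under a theory used with p > 0.

    On sparse graphs frozen unbalanced motifs can exist; this exhaustive
    check detects full stability (dynamics can never flip a sign again).
    """
    use_status = params.q > 0
    use_balance = params.q < 1
    eidx = g.edge_index()
    out: dict[int, list[int]] = {}
    for (u, v) in eidx:
        out.setdefault(u, []).append(v)
    for a, nbrs in out.items():
        for b in nbrs:
            for c in nbrs:
                if c == b:
                    continue
                for (x, y) in ((b, c), (c, b)):
                    if (x, y) in eidx:
                        cls = classify((g.sign_of(a, x), g.sign_of(a, y),
                                        g.sign_of(x, y)))
                        if use_status and not cls.hierarchical:
                            return True
                        if use_balance and not cls.balanced:
                            return True
    return False
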