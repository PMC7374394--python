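"""Harmony Search engine over the discrete architecture space.

Harmony Search (HS) is a music-inspired stochastic metaheuristic.  A fixed
pool of candidate solutions — the harmony memory (HM) — is refined
iteratively: each iteration proposes a new candidate either by recalling a
member of the memory (probability ``HMCR``), optionally perturbing every
coordinate by a small random step (probability ``PAR``, step magnitude at
most ``MPAP``), or by drawing a fresh uniform candidate.  If the proposal
scores better than the worst memory entry it replaces it, and the memory is
kept sorted by score descending.  The run stops at the iteration budget or
when the best entry has not improved for ``k`` consecutive iterations.

The engine is objective-agnostic: any callable mapping an
:class:`~resphs.space.HPVector` to a recognition rate in percent works, so
the expensive CNN objective and cheap surrogates are interchangeable.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .space import HPVector, HyperparameterSpace, random_hp, validate_hp

__all__ = [
    "HMCR_GRID",
    "PAR_GRID",
    "MPAP_RANGE",
    "ConfigError",
    "HSParams",
    "Harmony",
    "HarmonyMemory",
    "IterationRecord",
    "OptimizationTrace",
    "sample_hs_params",
    "initialize_hm",
    "pitch_adjust",
    "create_new_harmony",
    "update_hm",
    "run_hs",
    "random_search",
    "write_trajectory",
    "write_trace",
]

logger = logging.getLogger(__name__)

#: Legal grid for the memory-considering ratio: 0.50–0.70 in 0.05 steps.
HMCR_GRID = (0.50, 0.55, 0.60, 0.65, 0.70)
#: Legal grid for the pitch-adjusting ratio: 0.60–0.80 in 0.05 steps.
PAR_GRID = (0.60, 0.65, 0.70, 0.75, 0.80)
#: Legal inclusive range for the maximum pitch-adjustment step.
MPAP_RANGE = (10, 18)


class ConfigError(ValueError):
    """An HS parameter override falls outside its legal grid."""


@dataclass(frozen=True)
class HSParams:
    """Parameters of one Harmony Search run.

    ``hms`` is the memory capacity; ``hmcr`` and ``par`` the branch
    probabilities; ``mpap`` the maximum perturbation step; ``k`` the
    stagnation threshold (consecutive iterations without a best-entry
    improvement that trigger early termination).
    """

    hmcr: float
    par: float
    mpap: int
    hms: int = 1000
    max_iterations: int = 10_000
    k: int = 200
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.hmcr <= 1.0:
            raise ValueError(f"hmcr must be in [0, 1], got {self.hmcr}")
        if not 0.0 <= self.par <= 1.0:
            raise ValueError(f"par must be in [0, 1], got {self.par}")
        if self.mpap < 1:
            raise ValueError(f"mpap must be >= 1, got {self.mpap}")
        if self.hms < 2:
            raise ValueError(f"hms must be >= 2, got {self.hms}")
        if self.max_iterations < 1:
            raise ValueError(f"max_iterations must be >= 1, got {self.max_iterations}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")


def sample_hs_params(
    rng: np.random.Generator,
    *,
    hmcr: Optional[float] = None,
    par: Optional[float] = None,
    mpap: Optional[int] = None,
    hms: int = 1000,
    max_iterations: int = 10_000,
    k: int = 200,
    seed: Optional[int] = None,
) -> HSParams:
    """Draw HS parameters from their recommended grids.

    HMCR is uniform on {0.50, 0.55, 0.60, 0.65, 0.70}, PAR uniform on
    {0.60, ..., 0.80} and MPAP uniform on the integers 10–18; the keyword
    overrides pin a value instead, but must lie on the grid.  The grids keep
    memory recall frequent without collapsing into pure random search, and
    steps large enough to escape local maxima on wide integer ranges.
    """
    if hmcr is None:
        hmcr = HMCR_GRID[rng.integers(0, len(HMCR_GRID))]
    elif not any(math.isclose(hmcr, g) for g in HMCR_GRID):
        raise ConfigError(f"hmcr override {hmcr} not on grid {HMCR_GRID}")
    if par is None:
        par = PAR_GRID[rng.integers(0, len(PAR_GRID))]
    elif not any(math.isclose(par, g) for g in PAR_GRID):
        raise ConfigError(f"par override {par} not on grid {PAR_GRID}")
    if mpap is None:
        mpap = int(rng.integers(MPAP_RANGE[0], MPAP_RANGE[1] + 1))
    elif not MPAP_RANGE[0] <= mpap <= MPAP_RANGE[1]:
        raise ConfigError(f"mpap override {mpap} outside range {MPAP_RANGE}")
    return HSParams(
        hmcr=float(hmcr), par=float(par), mpap=int(mpap),
        hms=hms, max_iterations=max_iterations, k=k, seed=seed,
    )


@dataclass(frozen=True)
class Harmony:
    """One memory entry: a candidate architecture and its recognition rate
    in percent."""

    hp: HPVector
    r: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.r) or not 0.0 <= self.r <= 100.0:
            raise ValueError(f"recognition rate must be finite in [0, 100], got {self.r}")


class HarmonyMemory:
    """Capacity-bounded pool of harmonies, sorted by rate descending.

    Ties in rate are broken newest-first so the ordering (and therefore the
    whole run) is deterministic.  Capacity is fixed after initialization;
    duplicates are permitted, which small spaces force anyway.
    """

    def __init__(self, entries: Sequence[Harmony], capacity: int):
        if capacity < 2:
            raise ValueError(f"capacity must be >= 2, got {capacity}")
        self.capacity = capacity
        self.entries: list[Harmony] = sorted(entries, key=lambda h: -h.r)
        if len(self.entries) > capacity:
            raise ValueError("more entries than capacity")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def best(self) -> Harmony:
        return self.entries[0]

    @property
    def worst(self) -> Harmony:
        return self.entries[-1]

    def rates(self) -> np.ndarray:
        return np.array([h.r for h in self.entries])

    def update(self, candidate: Harmony) -> bool:
        """Replace the worst entry iff the candidate is strictly better.

        Equal rates do not replace.  Returns whether the memory changed.
        """
        if len(self.entries) < self.capacity:
            raise RuntimeError("memory not at capacity; initialize first")
        if candidate.r <= self.worst.r:
            return False
        self.entries.pop()
        # bisect on descending rate; insort-left puts the newcomer before
        # equal-rate incumbents (newest first).
        keys = [-h.r for h in self.entries]
        pos = bisect.bisect_left(keys, -candidate.r)
        self.entries.insert(pos, candidate)
        return True


def initialize_hm(
    space: HyperparameterSpace,
    objective: Callable[[HPVector], float],
    params: HSParams,
    rng: np.random.Generator,
) -> HarmonyMemory:
    """Fill the memory with ``hms`` uniform candidates and their scores."""
    entries = []
    for _ in range(params.hms):
        hp = random_hp(space, rng)
        try:
            r = float(objective(hp))
        except Exception:
            logger.exception("objective failed during HM initialization on %s", hp)
            raise
        entries.append(Harmony(hp=hp, r=r))
    return HarmonyMemory(entries, capacity=params.hms)


def _restore_parity(value: int, lo: int, hi: int) -> int:
    """Nudge an even value onto the odd grid, moving toward the interior."""
    if value % 2 == 1:
        return value
    if value + 1 > hi:
        return value - 1
    if value - 1 < lo:
        return value + 1
    # both neighbours admissible: step away from the nearer bound
    return value - 1 if (value - lo) > (hi - value) else value + 1


def pitch_adjust(
    value: int,
    mpap: int,
    bounds: tuple[int, int],
    odd_only: bool,
    rng: np.random.Generator,
    *,
    signed: bool = True,
) -> int:
    """Perturb one coordinate by a random step of magnitude at most ``mpap``.

    The step is drawn uniformly from the signed nonzero integers in
    ``[-mpap, mpap]`` — restricted to even steps on odd-only axes so parity
    is preserved — then the result is clipped to the bounds, with parity
    restored toward the interior after clipping.  ``signed=False`` switches
    to the literal additive variant (always ``+mpap``) for fidelity
    experiments; it drifts coordinates upward and is not the default.
    """
    lo, hi = bounds
    if signed:
        if odd_only:
            steps = [d for d in range(-mpap, mpap + 1) if d != 0 and d % 2 == 0]
        else:
            steps = [d for d in range(-mpap, mpap + 1) if d != 0]
        if not steps:
            raise RuntimeError(f"no admissible pitch step for mpap={mpap}, odd_only={odd_only}")
        delta = steps[rng.integers(0, len(steps))]
    else:
        delta = mpap
    out = int(np.clip(value + delta, lo, hi))
    if odd_only:
        out = _restore_parity(out, lo, hi)
    return out


def create_new_harmony(
    hm: HarmonyMemory,
    space: HyperparameterSpace,
    params: HSParams,
    rng: np.random.Generator,
    *,
    signed_pitch: bool = True,
) -> HPVector:
    """Propose one candidate by memory recall / pitch adjustment / random draw.

    With probability ``hmcr`` a memory member is recalled; with probability
    ``par`` every coordinate of the recalled member is then pitch-adjusted
    (all kernel sizes, all kernel counts and both dense widths), otherwise it
    is returned unchanged.  With probability ``1 - hmcr`` a fresh uniform
    candidate is drawn instead.
    """
    if rng.random() >= params.hmcr:
        return random_hp(space, rng)
    base = hm.entries[rng.integers(0, len(hm))].hp
    if rng.random() >= params.par:
        return base
    ks_b = space.axis_bounds("KS")
    kc_b = space.axis_bounds("KC")
    dl_b = space.axis_bounds("DLNC")
    parity = space.axis_parity("KS")
    ks = tuple(
        pitch_adjust(v, params.mpap, ks_b, parity, rng, signed=signed_pitch)
        for v in base.ks
    )
    kc = tuple(
        pitch_adjust(v, params.mpap, kc_b, False, rng, signed=signed_pitch)
        for v in base.kc
    )
    dlnc = tuple(
        pitch_adjust(v, params.mpap, dl_b, False, rng, signed=signed_pitch)
        for v in base.dlnc
    )
    hp = HPVector(ks=ks, kc=kc, dlnc=dlnc)  # type: ignore[arg-type]
    verdict = validate_hp(space, hp)
    if not verdict:  # pragma: no cover - clipping guarantees validity
        raise RuntimeError(f"pitch adjustment produced invalid candidate: {verdict.problems}")
    return hp


def update_hm(hm: HarmonyMemory, candidate: Harmony) -> bool:
    """Functional wrapper around :meth:`HarmonyMemory.update`."""
    return hm.update(candidate)


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    candidate_r: float
    hm_updated: bool
    best_updated: bool
    delta_i: int


@dataclass
class OptimizationTrace:
    """Bookkeeping of one run: per-iteration records, the trajectory of
    best-entry updates, and why the run stopped."""

    records: list[IterationRecord] = field(default_factory=list)
    best_updates: list[tuple[int, Harmony]] = field(default_factory=list)
    best: Optional[Harmony] = None
    termination: str = "budget"  # "budget" | "stagnation"
    n_evaluations: int = 0  # distinct objective evaluations (cache misses)
    n_proposals: int = 0

    def best_so_far(self) -> np.ndarray:
        """Best rate after each iteration (non-decreasing by construction)."""
        out = np.empty(len(self.records))
        current = self.best_updates[0][1].r if self.best_updates else np.nan
        j = 0
        for i, rec in enumerate(self.records):
            while j < len(self.best_updates) and self.best_updates[j][0] <= rec.iteration:
                current = self.best_updates[j][1].r
                j += 1
            out[i] = current
        return out


def run_hs(
    objective: Callable[[HPVector], float],
    space: HyperparameterSpace,
    params: HSParams,
    rng: np.random.Generator,
    *,
    cache: bool = True,
    signed_pitch: bool = True,
) -> tuple[Harmony, OptimizationTrace]:
    """Run Harmony Search and return the best harmony plus the full trace.

    The loop proposes, evaluates, and conditionally inserts one candidate
    per iteration.  Stagnation accounting follows the best entry: a strict
    improvement of the top rate resets the counter, anything else (including
    a memory update that does not touch the top) increments it; the run
    stops early once ``k`` consecutive non-improving iterations accumulate.
    Objective values are cached per candidate tuple so re-proposed
    architectures are not retrained; disable with ``cache=False``.
    """
    memo: dict[tuple[int, ...], float] = {}
    trace = OptimizationTrace()

    def evaluate(hp: HPVector) -> float:
        key = hp.as_tuple()
        if cache and key in memo:
            return memo[key]
        trace.n_evaluations += 1
        r = float(objective(hp))
        if cache:
            memo[key] = r
        return r

    try:
        hm = initialize_hm(space, evaluate, params, rng)
    except Exception:
        logger.error("aborting run: objective failed during initialization")
        raise
    trace.best_updates.append((-1, hm.best))  # state after initialization

    i_prev = i_curr = 0
    delta_i = 0
    termination = "budget"
    for j in range(params.max_iterations):
        hp = create_new_harmony(hm, space, params, rng, signed_pitch=signed_pitch)
        trace.n_proposals += 1
        try:
            r = evaluate(hp)
        except Exception:
            logger.error("aborting run at iteration %d; trace flushed", j)
            logger.info("trace so far: %d records, best %s", len(trace.records), trace.best_updates[-1])
            raise
        candidate = Harmony(hp=hp, r=r)
        prev_best_r = hm.best.r
        updated = hm.update(candidate)
        best_updated = updated and candidate.r > prev_best_r
        if best_updated:
            i_prev = i_curr = j
            delta_i = 0
            trace.best_updates.append((j, hm.best))
            logger.info("iteration %d: new best r=%.1f%% %s", j, hm.best.r, hm.best.hp.as_tuple())
        else:
            i_curr = j
            delta_i = i_curr - i_prev
        trace.records.append(
            IterationRecord(
                iteration=j, candidate_r=r, hm_updated=updated,
                best_updated=best_updated, delta_i=delta_i,
            )
        )
        if delta_i >= params.k:
            termination = "stagnation"
            break
    trace.termination = termination
    trace.best = hm.best
    return hm.best, trace


def random_search(
    objective: Callable[[HPVector], float],
    space: HyperparameterSpace,
    n_evals: int,
    rng: np.random.Generator,
) -> Harmony:
    """Equal-budget pure random search baseline: draw ``n_evals`` uniform
    candidates and keep the best."""
    best: Optional[Harmony] = None
    for _ in range(n_evals):
        hp = random_hp(space, rng)
        r = float(objective(hp))
        if best is None or r > best.r:
            best = Harmony(hp=hp, r=r)
    assert best is not None
    return best


def _trajectory_frame(trace: OptimizationTrace, cld: int) -> pd.DataFrame:
    rows = []
    for iteration, harmony in trace.best_updates:
        row: dict[str, object] = {"iteration": iteration}
        for d in range(cld):
            row[f"ks{d + 1}"] = harmony.hp.ks[d]
            row[f"kc{d + 1}"] = harmony.hp.kc[d]
        row["dlnc1"], row["dlnc2"] = harmony.hp.dlnc
        row["r"] = round(harmony.r, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def write_trajectory(trace: OptimizationTrace, path, cld: int) -> None:
    """Write the best-entry update trajectory as delimited text: one row per
    improvement with the full hyperparameter vector and its rate."""
    _trajectory_frame(trace, cld).to_csv(path, sep="\t", index=False)


def write_trace(trace: OptimizationTrace, path) -> None:
    """Write the per-iteration trace (candidate rate, update flags, stagnation
    counter) as delimited text."""
    pd.DataFrame([r.__dict__ for r in trace.records]).to_csv(path, sep="\t", index=False)
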