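"""Harmony Search engine: parameter sampling, memory updates, proposals,
stagnation, and optimizer correctness against brute-force oracles."""

import numpy as np
import pytest

from resphs import (
    ConfigError,
    Harmony,
    HarmonyMemory,
    HPVector,
    HSParams,
    HyperparameterSpace,
    create_new_harmony,
    enumerate_space,
    initialize_hm,
    pitch_adjust,
    random_hp,
    run_hs,
    sample_hs_params,
    update_hm,
    validate_hp,
)
from resphs.hs import HMCR_GRID, MPAP_RANGE, PAR_GRID


class _FixedIndexRNG:
    """Stub generator whose integer draws always return a fixed index."""

    def __init__(self, index):
        self.index = index

    def integers(self, low, high=None):
        return self.index


# -- parameter sampling -----------------------------------------------------

def test_sampled_params_lie_on_grids(rng):
    for _ in range(200):
        p = sample_hs_params(rng)
        assert any(np.isclose(p.hmcr, g) for g in HMCR_GRID)
        assert any(np.isclose(p.par, g) for g in PAR_GRID)
        assert MPAP_RANGE[0] <= p.mpap <= MPAP_RANGE[1]
        assert (p.hms, p.max_iterations, p.k) == (1000, 10_000, 200)


def test_override_pins_value(rng):
    p = sample_hs_params(rng, hmcr=0.55, par=0.8, mpap=12)
    assert (p.hmcr, p.par, p.mpap) == (0.55, 0.8, 12)


@pytest.mark.parametrize("kwargs", [{"hmcr": 0.95}, {"par": 0.5}, {"mpap": 25}])
def test_off_grid_override_is_config_error(rng, kwargs):
    with pytest.raises(ConfigError):
        sample_hs_params(rng, **kwargs)


def test_sampling_frequencies_uniform(rng):
    n = 10_000
    counts = {g: 0 for g in HMCR_GRID}
    for _ in range(n):
        counts[sample_hs_params(rng).hmcr] += 1
    p = 1 / len(HMCR_GRID)
    sd = np.sqrt(n * p * (1 - p))
    for g in HMCR_GRID:
        assert abs(counts[g] - n * p) < 5 * sd


def test_params_invariants_enforced():
    for bad in (
        dict(hmcr=1.2, par=0.6, mpap=10),
        dict(hmcr=0.6, par=-0.1, mpap=10),
        dict(hmcr=0.6, par=0.6, mpap=0),
        dict(hmcr=0.6, par=0.6, mpap=10, hms=1),
        dict(hmcr=0.6, par=0.6, mpap=10, k=0),
    ):
        with pytest.raises(ValueError):
            HSParams(**bad)


# -- pitch adjustment -------------------------------------------------------

def test_pitch_adjust_literal_step_arithmetic():
    rng = np.random.default_rng(0)
    assert pitch_adjust(50, 10, (16, 1024), False, rng, signed=False) == 60


def test_pitch_adjust_clips_to_largest_odd():
    # +10 from 79 overshoots the odd-only range [3, 81]: clipped to 81.
    assert pitch_adjust(79, 10, (3, 81), True, _FixedIndexRNG(9), signed=True) == 81


def test_pitch_adjust_clips_at_lower_bound():
    # steps for mpap=18 are [-18..-1, 1..18]; index 0 forces -18.
    assert pitch_adjust(17, 18, (16, 1024), False, _FixedIndexRNG(0)) == 16


def test_pitch_adjust_preserves_parity_and_bounds(rng):
    for _ in range(2000):
        out = pitch_adjust(41, 18, (3, 81), True, rng)
        assert 3 <= out <= 81 and out % 2 == 1
        assert out != 41 or True  # may clip back; bounds/parity are the contract


def test_pitch_adjust_signed_steps_go_both_ways(rng):
    outs = {pitch_adjust(500, 10, (16, 1024), False, rng) for _ in range(500)}
    assert min(outs) < 500 < max(outs)
    assert outs <= set(range(490, 511)) - {500}


# -- harmony memory ---------------------------------------------------------

def _hp(space, rng):
    return random_hp(space, rng)


def test_initialize_constant_objective(tiny_space, rng):
    params = HSParams(hmcr=0.6, par=0.7, mpap=10, hms=5, max_iterations=10, k=5)
    hm = initialize_hm(tiny_space, lambda hp: 50.0, params, rng)
    assert len(hm) == 5
    assert all(h.r == 50.0 for h in hm)


def test_initialize_sorted_descending_injective(tiny_space, rng):
    # Injective objective over the 64-tuple space: entries strictly sorted.
    scores = {hp.as_tuple(): i for i, hp in enumerate(enumerate_space(tiny_space))}
    params = HSParams(hmcr=0.6, par=0.7, mpap=10, hms=10, max_iterations=10, k=5)
    hm = initialize_hm(tiny_space, lambda hp: scores[hp.as_tuple()], params, rng)
    rates = hm.rates()
    assert np.all(np.diff(rates) <= 0)


def test_initialize_duplicates_permitted(rng):
    space = HyperparameterSpace(cld=1, ks_min=3, ks_max=3, kc_min=16, kc_max=16,
                                dlnc_min=256, dlnc_max=256)
    params = HSParams(hmcr=0.6, par=0.7, mpap=10, hms=2, max_iterations=10, k=5)
    hm = initialize_hm(space, lambda hp: 10.0, params, rng)
    assert len(hm) == 2
    assert hm.entries[0].hp == hm.entries[1].hp


def test_update_strictly_better_replaces(tiny_space, rng):
    params = HSParams(hmcr=0.6, par=0.7, mpap=10, hms=4, max_iterations=10, k=5)
    hm = initialize_hm(tiny_space, lambda hp: 84.6, params, rng)
    assert update_hm(hm, Harmony(hp=_hp(tiny_space, rng), r=96.7))
    assert hm.best.r == 96.7
    assert hm.worst.r >= 84.6


def test_update_tie_does_not_replace(tiny_space, rng):
    params = HSParams(hmcr=0.6, par=0.7, mpap=10, hms=4, max_iterations=10, k=5)
    hm = initialize_hm(tiny_space, lambda hp: 50.0, params, rng)
    before = list(hm.entries)
    assert not update_hm(hm, Harmony(hp=_hp(tiny_space, rng), r=50.0))
    assert hm.entries == before


def test_update_matches_keep_best_oracle(tiny_space, rng):
    """A random insertion sequence must leave the same rate multiset as the
    brute-force 'keep the best hms of everything seen' rule."""
    params = HSParams(hmcr=0.6, par=0.7, mpap=10, hms=6, max_iterations=10, k=5)
    for trial in range(10):
        trial_rng = np.random.default_rng(1000 + trial)
        init_rates = list(np.round(trial_rng.uniform(0, 100, 6), 3))
        seen = list(init_rates)
        it = iter(init_rates)
        hm = initialize_hm(tiny_space, lambda hp: next(it), params, trial_rng)
        for r in np.round(trial_rng.uniform(0, 100, 50), 3):
            update_hm(hm, Harmony(hp=_hp(tiny_space, trial_rng), r=float(r)))
            seen.append(float(r))
        expected = sorted(seen, reverse=True)[:6]
        # ties at the cutoff keep incumbents, so compare multisets of rates
        assert sorted(hm.rates(), reverse=True) == pytest.approx(expected)


# -- proposal generation ----------------------------------------------------

def test_recall_without_pitch_returns_member(tiny_space, rng):
    params = HSParams(hmcr=1.0, par=0.0, mpap=10, hms=5, max_iterations=10, k=5)
    hm = initialize_hm(tiny_space, lambda hp: 50.0, params, rng)
    members = {h.hp.as_tuple() for h in hm}
    for _ in range(100):
        assert create_new_harmony(hm, tiny_space, params, rng).as_tuple() in members


def test_hmcr_zero_collapses_to_random_search(tiny_space, rng):
    """With hmcr=0 proposals are uniform draws: each value of a two-value
    coordinate appears with frequency 1/2."""
    params = HSParams(hmcr=0.0, par=0.7, mpap=10, hms=5, max_iterations=10, k=5)
    hm = initialize_hm(tiny_space, lambda hp: 50.0, params, rng)
    n = 4000
    hits = sum(
        create_new_harmony(hm, tiny_space, params, rng).ks[0] == 3 for _ in range(n)
    )
    sd = np.sqrt(n * 0.25)
    assert abs(hits - n / 2) < 5 * sd


def test_memory_recall_frequency_matches_hmcr(full_space, rng):
    params = HSParams(hmcr=0.6, par=0.0, mpap=10, hms=5, max_iterations=10, k=5)
    hm = initialize_hm(full_space, lambda hp: 50.0, params, rng)
    members = {h.hp.as_tuple() for h in hm}
    n = 10_000
    recalls = sum(
        create_new_harmony(hm, full_space, params, rng).as_tuple() in members
        for _ in range(n)
    )
    sd = np.sqrt(n * 0.6 * 0.4)
    assert abs(recalls - n * 0.6) < 5 * sd


def test_pitch_adjust_frequency_matches_par(full_space, rng):
    # Interior member far from every bound with small mpap: an adjusted
    # proposal always differs from the recalled member.
    params = HSParams(hmcr=1.0, par=0.7, mpap=10, hms=2, max_iterations=10, k=5)
    member = HPVector(ks=(41, 41, 41), kc=(500, 500, 500), dlnc=(2000, 2000))
    hm = HarmonyMemory([Harmony(hp=member, r=50.0)] * 2, capacity=2)
    n = 10_000
    adjusted = sum(
        create_new_harmony(hm, full_space, params, rng) != member for _ in range(n)
    )
    sd = np.sqrt(n * 0.7 * 0.3)
    assert abs(adjusted - n * 0.7) < 5 * sd


def test_proposals_always_valid(full_space, rng):
    params = HSParams(hmcr=0.7, par=0.8, mpap=18, hms=8, max_iterations=10, k=5)
    hm = initialize_hm(full_space, lambda hp: 50.0, params, rng)
    for _ in range(500):
        hp = create_new_harmony(hm, full_space, params, rng)
        assert validate_hp(full_space, hp).ok


# -- full runs --------------------------------------------------------------

def _surrogate_for(space, target):
    t = np.array(target.as_tuple(), dtype=float)

    def objective(hp):
        x = np.array(hp.as_tuple(), dtype=float)
        return float(100.0 * np.exp(-np.sum(((x - t) / 100.0) ** 2)))

    return objective


def test_run_hs_finds_brute_force_argmax(tiny_space):
    target = HPVector(ks=(5, 3), kc=(17, 16), dlnc=(257, 256))
    objective = _surrogate_for(tiny_space, target)
    best_bf = max(enumerate_space(tiny_space), key=lambda hp: objective(hp))
    params = HSParams(hmcr=0.6, par=0.7, mpap=10, hms=16, max_iterations=500, k=500)
    best, _ = run_hs(objective, tiny_space, params, np.random.default_rng(7))
    assert best.hp == best_bf == target


def test_constant_objective_stops_at_stagnation_threshold(tiny_space, rng):
    params = HSParams(hmcr=0.6, par=0.7, mpap=10, hms=4, max_iterations=1000, k=10)
    _, trace = run_hs(lambda hp: 50.0, tiny_space, params, rng)
    assert trace.termination == "stagnation"
    assert trace.records[-1].delta_i == 10
    assert trace.records[-1].iteration == 10  # no best update ever: stop at j = k


def test_stagnation_stops_k_after_last_best_update(tiny_space):
    """Termination mirrors 'last improvement + k': the stop iteration equals
    the final best-update iteration plus the threshold."""
    params = HSParams(hmcr=0.6, par=0.7, mpap=10, hms=8, max_iterations=5000, k=50)
    target = HPVector(ks=(5, 3), kc=(17, 16), dlnc=(257, 256))
    best, trace = run_hs(_surrogate_for(tiny_space, target), tiny_space, params,
                         np.random.default_rng(3))
    assert trace.termination == "stagnation"
    last_update = max(j for j, _ in trace.best_updates)
    assert trace.records[-1].iteration == last_update + 50


def test_budget_termination(tiny_space, rng):
    params = HSParams(hmcr=0.6, par=0.7, mpap=10, hms=4, max_iterations=5, k=100)
    _, trace = run_hs(lambda hp: 50.0, tiny_space, params, rng)
    assert trace.termination == "budget"
    assert len(trace.records) == 5


def test_best_so_far_monotone_and_matches_best(tiny_space):
    target = HPVector(ks=(3, 5), kc=(16, 17), dlnc=(256, 257))
    params = HSParams(hmcr=0.6, par=0.7, mpap=10, hms=6, max_iterations=200, k=200)
    best, trace = run_hs(_surrogate_for(tiny_space, target), tiny_space, params,
                         np.random.default_rng(11))
    curve = trace.best_so_far()
    assert np.all(np.diff(curve) >= 0)
    assert curve[-1] == best.r


def test_identical_seed_gives_identical_trace(tiny_space):
    target = HPVector(ks=(5, 5), kc=(16, 17), dlnc=(256, 257))
    objective = _surrogate_for(tiny_space, target)
    params = HSParams(hmcr=0.65, par=0.75, mpap=12, hms=8, max_iterations=100, k=100)
    best1, trace1 = run_hs(objective, tiny_space, params, np.random.default_rng(42))
    best2, trace2 = run_hs(objective, tiny_space, params, np.random.default_rng(42))
    assert best1 == best2
    assert trace1.records == trace2.records
    assert trace1.best_updates == trace2.best_updates


def test_large_memory_finds_optimum_during_initialization():
    """With hms at least the space size and an injective objective, the
    optimum enters the memory during initialization alone."""
    space = HyperparameterSpace(cld=1, ks_min=3, ks_max=9, kc_min=16, kc_max=19,
                                dlnc_min=256, dlnc_max=259)  # 4*4*16 = 256 tuples
    scores = {hp.as_tuple(): float(i) / 10 for i, hp in enumerate(enumerate_space(space))}
    best_hp = max(scores, key=scores.get)
    params = HSParams(hmcr=0.6, par=0.7, mpap=10, hms=2000, max_iterations=1, k=10)
    best, _ = run_hs(lambda hp: scores[hp.as_tuple()], space, params,
                     np.random.default_rng(5))
    assert best.hp.as_tuple() == best_hp


def test_objective_cache_avoids_reevaluation(tiny_space, rng):
    calls = []

    def objective(hp):
        calls.append(hp.as_tuple())
        return 50.0

    params = HSParams(hmcr=0.6, par=0.7, mpap=10, hms=20, max_iterations=100, k=200)
    _, trace = run_hs(objective, tiny_space, params, rng)
    assert len(calls) == trace.n_evaluations == len(set(calls))
    assert trace.n_evaluations <= 64  # never more than the space size
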