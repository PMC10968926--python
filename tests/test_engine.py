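"""Engine semantics: pair games, sweeps, death, replacement, conservation.

Includes an independent scalar oracle: a dict-based reimplementation of
the sequential sweep for deterministic emotions, checked cell-for-cell
against the compiled engine over several steps.
"""

from collections import Counter

import numpy as np
import pytest

from spatial_ultimatum.engine import (
    GameParams,
    iterate_states,
    play_games,
    play_pair,
    replace_dead,
    run_simulation,
    step,
)
from spatial_ultimatum.lattice import PopulationState
from spatial_ultimatum.strategies import EMOTIONS, Emotion, strategy_table

ANGER, FEAR, JOY, SADNESS, SURPRISE = range(5)


def _state(emotion, money=100.0, lives=1):
    emotion = np.asarray(emotion, dtype=np.int8)
    return PopulationState(
        emotion,
        np.full(emotion.shape, float(money)),
        np.full(emotion.shape, int(lives), dtype=np.int64),
    )


# ---------------------------------------------------------------- pair games

def test_fear_offer_at_angers_aspiration_is_refused(rng, strategies):
    out = play_pair(strategies[Emotion.FEAR], strategies[Emotion.ANGER], 12.5, rng)
    assert out.offered_fraction == 0.5
    assert not out.accepted and out.transfer == 0.0


def test_fear_offer_above_sadness_aspiration_transfers(rng, strategies):
    out = play_pair(strategies[Emotion.FEAR], strategies[Emotion.SADNESS], 12.5, rng)
    assert out.accepted
    assert out.transfer == pytest.approx(6.25)  # 0.5 of the 12.5 stake


def test_low_anger_offer_is_rejected_by_anger(rng, strategies):
    out = play_pair(strategies[Emotion.ANGER], strategies[Emotion.ANGER], 5.0, rng)
    assert not out.accepted and out.transfer == 0.0


# ---------------------------------------------------------------- hand oracles

def test_all_fear_lattice_only_circulates_money(rng):
    """Every game succeeds: nobody dies, everyone gains 8 lives per step
    (4 as proposer, 4 as responder), money is only shuffled around."""
    params = GameParams(side=3)
    table = strategy_table()
    state = _state(np.full((3, 3), FEAR))
    for k in range(1, 6):
        state = step(state, params, table, rng)
        assert state.total_money == pytest.approx(900.0)
        assert (state.lives == 1 + 8 * k).all()
        assert (state.emotion == FEAR).all()
        # in-place stakes keep balances near the mean, never far from it
        assert state.money == pytest.approx(np.full((3, 3), 100.0), rel=0.2)


def test_all_anger_lattice_collapses_in_one_sweep(rng):
    """Ties fail, so every anger-anger game is refused.  In the 3x3 sweep
    agents die in proposer-responder pairs until only the last-visited cell
    has no live partner left; cells whose neighbors all died are re-seeded
    at random, the rest copy the surviving anger agent."""
    params = GameParams(side=3)
    table = strategy_table()
    state = _state(np.full((3, 3), ANGER))
    dead = play_games(state, params, table, rng)
    assert state.money == pytest.approx(np.full((3, 3), 100.0))  # nothing moved
    assert not dead[1, 2] and state.lives[1, 2] == 1  # sole survivor
    assert dead.sum() == 8
    state = replace_dead(state, dead, params, rng)
    # the survivor's four neighbors copy it; the other four dead cells had no
    # surviving neighbor and drew a uniform emotion
    for cell in [(0, 2), (2, 2), (1, 0), (1, 1)]:
        assert state.emotion[cell] == ANGER
    assert (state.lives >= 1).all()


# ---------------------------------------------------------------- conservation

def test_money_is_conserved_and_never_negative():
    params = GameParams(side=12, steps=20)
    total0 = params.money_init * 12 * 12
    for s in iterate_states(params, seed=5):
        assert s.total_money == pytest.approx(total0, rel=1e-9)
        assert (s.money >= 0).all()
        assert s.emotion.size == 144  # every cell always occupied
        if s.time > 0:
            assert (s.lives >= 1).all()  # dead were replaced


def test_same_seed_reproduces_the_trajectory_bit_for_bit():
    params = GameParams(side=10, steps=15)
    a = list(iterate_states(params, seed=42))
    b = list(iterate_states(params, seed=42))
    assert (a[-1].emotion == b[-1].emotion).all()
    assert (a[-1].money == b[-1].money).all()
    assert (a[-1].lives == b[-1].lives).all()


def test_initial_money_scale_does_not_affect_decisions():
    """Acceptance depends on percentages only, so scaling D leaves the
    emotion dynamics identical and scales all balances exactly."""
    lo = list(iterate_states(GameParams(side=10, steps=10, money_init=100.0), seed=9))
    hi = list(iterate_states(GameParams(side=10, steps=10, money_init=200.0), seed=9))
    for a, b in zip(lo, hi):
        assert (a.emotion == b.emotion).all()
        assert (a.lives == b.lives).all()
        assert b.money == pytest.approx(2.0 * a.money)


# ---------------------------------------------------------------- monocultures

@pytest.mark.parametrize("emotion", [FEAR, JOY, SADNESS])
def test_deathless_monocultures_are_absorbing(rng, emotion):
    """When every game in a monoculture succeeds, nobody dies and the
    composition is frozen; only money can move."""
    params = GameParams(side=5, steps=0)
    table = strategy_table()
    state = _state(np.full((5, 5), emotion))
    for _ in range(5):
        state = step(state, params, table, rng)
        assert (state.emotion == emotion).all()


# ---------------------------------------------------------------- replacement

def _replacement(emotions, dead_mask, seed=0, rule="copycat_majority"):
    state = _state(np.asarray(emotions, dtype=np.int8))
    dead = np.asarray(dead_mask, dtype=bool)
    state.lives[dead] = 0
    params = GameParams(side=state.side, replacement_rule=rule)
    return replace_dead(state, dead, params, np.random.default_rng(seed))


def test_newborn_copies_the_predominant_surviving_emotion():
    emotions = [[JOY, FEAR, JOY], [FEAR, SADNESS, FEAR], [JOY, SADNESS, JOY]]
    dead = [[0, 0, 0], [0, 1, 0], [0, 0, 0]]
    out = _replacement(emotions, dead)
    assert out.emotion[1, 1] == FEAR  # neighbors N,E,W fear vs S sadness
    assert out.lives[1, 1] == 1
    assert out.money[1, 1] == 100.0  # inherited


def test_dead_neighbors_do_not_vote():
    emotions = [[JOY, FEAR, JOY], [FEAR, SADNESS, FEAR], [JOY, SADNESS, JOY]]
    dead = [[0, 1, 0], [1, 1, 1], [0, 0, 0]]  # three of the four neighbors died
    out = _replacement(emotions, dead)
    assert out.emotion[1, 1] == SADNESS  # only the south neighbor survived


def test_replacement_tie_splits_evenly_across_seeds():
    emotions = [[JOY, FEAR, JOY], [FEAR, SADNESS, JOY], [JOY, JOY, JOY]]
    dead = [[0, 0, 0], [0, 1, 0], [0, 0, 0]]  # neighbors: fear N/W, joy E/S
    picks = Counter(
        int(_replacement(emotions, dead, seed=s).emotion[1, 1]) for s in range(400)
    )
    assert set(picks) == {FEAR, JOY}
    assert 140 <= picks[FEAR] <= 260


def test_richest_neighbor_rule_copies_the_wealthiest_survivor():
    emotions = np.full((3, 3), FEAR, dtype=np.int8)
    emotions[0, 1] = SADNESS
    state = _state(emotions)
    state.money[0, 1] = 500.0  # north neighbor of the dead centre is richest
    dead = np.zeros((3, 3), dtype=bool)
    dead[1, 1] = True
    params = GameParams(side=3, replacement_rule="richest_neighbor")
    out = replace_dead(state, dead, params, np.random.default_rng(1))
    assert out.emotion[1, 1] == SADNESS


# ---------------------------------------------------------------- scalar oracle

_OFFSETS = ((-1, 0), (0, 1), (1, 0), (0, -1))


def _oracle_step(emotion, money, lives, params, x, y):
    """Independent dict-based sweep for deterministic emotions only.

    Raises if a replacement vote is ambiguous (tie or no survivor), so
    the comparison with the engine never depends on random tie-breaks.
    """
    n = max(r for r, _ in emotion) + 1
    dead = set()
    for r in range(n):
        for c in range(n):
            i = (r, c)
            if i in dead or money[i] < params.min_stake or lives[i] < 1:
                continue
            for dr, dc in _OFFSETS:
                if i in dead:
                    break
                j = ((r + dr) % n, (c + dc) % n)
                if j in dead:
                    continue
                offered = x[emotion[i]]
                if offered > y[emotion[j]]:
                    stake = params.fraction * money[i] / 4.0
                    amount = offered * stake
                    money[i] -= amount
                    money[j] += amount
                    lives[i] += 1
                    lives[j] += 1
                else:
                    lives[i] -= 1
                    lives[j] -= 1
                    if lives[i] <= 0:
                        dead.add(i)
                    if lives[j] <= 0:
                        dead.add(j)
    new_emotion = dict(emotion)
    for r, c in dead:
        votes = Counter(
            emotion[((r + dr) % n, (c + dc) % n)]
            for dr, dc in _OFFSETS
            if ((r + dr) % n, (c + dc) % n) not in dead
        )
        ranked = votes.most_common()
        if not ranked or (len(ranked) > 1 and ranked[1][1] == ranked[0][1]):
            raise AssertionError("ambiguous replacement vote in oracle fixture")
        new_emotion[(r, c)] = ranked[0][0]
        lives[(r, c)] = params.lives_init
    return new_emotion, money, lives


@pytest.mark.parametrize(
    "layout",
    [
        # one anger agent embedded in a fear sea
        [[FEAR, FEAR, FEAR], [FEAR, ANGER, FEAR], [FEAR, FEAR, FEAR]],
        # anger centre ringed by sadness with fear corners
        [[FEAR, SADNESS, FEAR], [SADNESS, ANGER, SADNESS], [FEAR, SADNESS, FEAR]],
        # anger pair in a mixed deterministic population
        [[SADNESS, ANGER, FEAR], [FEAR, ANGER, SADNESS], [FEAR, FEAR, SADNESS]],
    ],
)
@pytest.mark.parametrize("lives_init", [1, 2])
def test_engine_matches_independent_scalar_oracle(layout, lives_init):
    params = GameParams(side=3, lives_init=lives_init, steps=5)
    table = strategy_table()
    x = {k: table[e].offer_value for k, e in enumerate(EMOTIONS)}
    y = {k: table[e].accept_threshold for k, e in enumerate(EMOTIONS)}

    state = _state(layout, lives=lives_init)
    emotion = {(r, c): int(state.emotion[r, c]) for r in range(3) for c in range(3)}
    money = {(r, c): float(state.money[r, c]) for r in range(3) for c in range(3)}
    lives = {(r, c): int(state.lives[r, c]) for r in range(3) for c in range(3)}

    rng = np.random.default_rng(0)
    for _ in range(5):
        state = step(state, params, table, rng)
        emotion, money, lives = _oracle_step(emotion, money, lives, params, x, y)
        for r in range(3):
            for c in range(3):
                assert state.emotion[r, c] == emotion[(r, c)]
                assert state.lives[r, c] == lives[(r, c)]
                assert state.money[r, c] == money[(r, c)]  # identical arithmetic


# ---------------------------------------------------------------- trajectories

def test_zero_horizon_run_is_a_single_nearly_uniform_record():
    records = run_simulation(GameParams(side=50, steps=0), seed=3)
    assert len(records) == 1
    assert records[0].Ip == pytest.approx(0.0, abs=0.01)
    assert records[0].Iq == pytest.approx(0.0, abs=0.01)


def test_trajectory_has_t_plus_one_records_and_settles():
    params = GameParams(side=20, steps=40)
    records = run_simulation(params, seed=8)
    assert len(records) == 41
    assert [r.time for r in records] == list(range(41))
    # composition moves away from uniform and the entropy deficit grows
    assert records[-1].Ip > records[0].Ip


def test_parameter_validation():
    with pytest.raises(ValueError):
        GameParams(fraction=1.5)
    with pytest.raises(ValueError):
        GameParams(min_stake=-1)
    with pytest.raises(ValueError):
        GameParams(lives_init=0)
    with pytest.raises(ValueError):
        GameParams(replacement_rule="oldest")
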