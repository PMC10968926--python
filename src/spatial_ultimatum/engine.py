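"""Simulation engine: one sequential round of games per time step.

Agents are visited in a fixed row-major sweep.  At its turn an agent
proposes once to each of its four neighbors (north, east, south, west)
provided it is alive and holds at least the minimum stake ``m``; the
amount wagered on each neighbor is ``f * d_i / 4`` with ``d_i`` the
proposer's money at that moment.  A game succeeds when the proposer's
offered fraction strictly exceeds the responder's aspiration (an offer
exactly at the threshold fails; surprise responders flip a fair coin
instead).  Success transfers ``offer * stake`` from proposer to
responder and both gain a life; failure moves no money and both lose a
life.  Money and lives update in place as games resolve, so later games
in the sweep see the outcomes of earlier ones.

Death is immediate: the moment an agent's lives reach zero its cell is
empty for the remainder of the step — it plays no further games in
either role.  At the step boundary every empty cell is filled,
simultaneously, by a newborn that inherits the dead agent's money,
receives L fresh lives, and adopts the predominant emotion among its
*surviving* neighbors (copycat; ties broken uniformly at random; if all
four neighbors also died the emotion is drawn uniformly from the five).
An alternative replacement rule adopts the emotion of the richest
surviving neighbor instead.

Money is globally conserved — it is only ever redistributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
from numba import njit

from .lattice import GridGeometry, PopulationState, init_population
from .metrics import MetricsRecord, metrics_record
from .strategies import EMOTIONS, Emotion, EmotionStrategy, strategy_table

__all__ = [
    "GameParams",
    "NegotiationOutcome",
    "play_pair",
    "play_games",
    "step",
    "replace_dead",
    "run_simulation",
    "iterate_states",
]

REPLACEMENT_RULES = ("copycat_majority", "richest_neighbor")

# (axis, roll shift) that gathers each neighbor's value onto a cell, in
# N, E, S, W order (used by the vectorized replacement vote).
_ROLLS: tuple[tuple[int, int], ...] = ((0, 1), (1, -1), (0, -1), (1, 1))


@dataclass(frozen=True)
class GameParams:
    """Parameters of one competitive scenario.

    Defaults are the baseline scenario: a 50 x 50 torus, D = 100 dollars
    and L = 1 life per agent, allocated fraction f = 1/2, minimum stake
    m = 1, horizon T = 100 steps, unperturbed strategies.
    """

    side: int = 50  # lattice side n
    money_init: float = 100.0  # D, dollars per agent at t=0
    lives_init: int = 1  # L, lives per agent at t=0 and per newborn
    fraction: float = 0.5  # f, fraction of money allocated per step
    min_stake: float = 1.0  # m, minimum money to act as proposer
    steps: int = 100  # T, horizon
    deltas: Mapping[Emotion, float] = field(default_factory=dict)
    replacement_rule: str = "copycat_majority"

    def __post_init__(self) -> None:
        GridGeometry(self.side)  # validates side >= 3
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"fraction f must be in (0, 1], got {self.fraction}")
        if self.min_stake < 0:
            raise ValueError(f"min_stake m must be >= 0, got {self.min_stake}")
        if self.steps < 0:
            raise ValueError(f"steps T must be >= 0, got {self.steps}")
        if self.money_init <= 0:
            raise ValueError(f"money_init D must be > 0, got {self.money_init}")
        if self.lives_init < 1:
            raise ValueError(f"lives_init L must be >= 1, got {self.lives_init}")
        if self.replacement_rule not in REPLACEMENT_RULES:
            raise ValueError(
                f"replacement_rule must be one of {REPLACEMENT_RULES}, "
                f"got {self.replacement_rule!r}"
            )

    def strategies(self) -> dict[Emotion, EmotionStrategy]:
        return strategy_table(self.deltas)


@dataclass(frozen=True)
class NegotiationOutcome:
    """Resolution of a single proposer-responder game."""

    stake: float
    offered_fraction: float
    accepted: bool
    transfer: float  # offered_fraction * stake if accepted, else 0
    proposer: tuple[int, int] | None = None
    responder: tuple[int, int] | None = None


def play_pair(
    proposer: EmotionStrategy,
    responder: EmotionStrategy,
    stake: float,
    rng: np.random.Generator,
) -> NegotiationOutcome:
    """Resolve one game between a proposer and a responder strategy.

    Scalar reference path with the same acceptance semantics as the
    lattice sweep: threshold responders accept only offers strictly
    above their aspiration; surprise flips a fair coin.
    """
    from .strategies import decide_accept, draw_offer

    if stake < 0:
        raise ValueError("stake must be nonnegative")
    offered = draw_offer(proposer, rng)
    accepted = decide_accept(responder, offered, rng)
    transfer = offered * stake if accepted else 0.0
    return NegotiationOutcome(stake, offered, accepted, transfer)


def _lookup_tables(table: Mapping[Emotion, EmotionStrategy]):
    x = np.array([table[e].offer_value for e in EMOTIONS])
    y = np.array([table[e].accept_threshold for e in EMOTIONS])
    random_offer = np.array([table[e].offer_kind == "uniform_random" for e in EMOTIONS])
    coin_flip = np.array([table[e].accept_kind == "coin_flip" for e in EMOTIONS])
    return x, y, random_offer, coin_flip


@njit(cache=True)
def _sweep(emotion, money, lives, dead, x, y, random_offer, coin_flip,
           fraction, min_stake, seed):  # pragma: no cover - executed via numba
    """One row-major sweep of games, mutating money/lives/dead in place.

    Random draws (offers for joy/surprise proposers, coins for surprise
    responders) are consumed lazily in sweep order, from numba's global
    stream seeded with ``seed``.
    """
    np.random.seed(seed)
    n = emotion.shape[0]
    drs = (-1, 0, 1, 0)
    dcs = (0, 1, 0, -1)
    for r in range(n):
        for c in range(n):
            if dead[r, c] or money[r, c] < min_stake or lives[r, c] < 1:
                continue
            for k in range(4):
                if dead[r, c]:
                    break  # proposer died earlier in its own turn
                rr = (r + drs[k]) % n
                cc = (c + dcs[k]) % n
                if dead[rr, cc]:
                    continue  # empty cell: no game
                e_p = emotion[r, c]
                e_r = emotion[rr, cc]
                stake = fraction * money[r, c] / 4.0
                if random_offer[e_p]:
                    offered = np.random.random()
                else:
                    offered = x[e_p]
                if coin_flip[e_r]:
                    accepted = np.random.random() < 0.5
                else:
                    accepted = offered > y[e_r]  # ties fail
                if accepted:
                    amount = offered * stake
                    money[r, c] -= amount
                    money[rr, cc] += amount
                    lives[r, c] += 1
                    lives[rr, cc] += 1
                else:
                    lives[r, c] -= 1
                    lives[rr, cc] -= 1
                    if lives[r, c] <= 0:
                        dead[r, c] = True
                    if lives[rr, cc] <= 0:
                        dead[rr, cc] = True


def play_games(
    state: PopulationState,
    params: GameParams,
    table: Mapping[Emotion, EmotionStrategy],
    rng: np.random.Generator,
) -> np.ndarray:
    """Run all games of one step in place; return the boolean death mask."""
    x, y, random_offer, coin_flip = _lookup_tables(table)
    dead = np.zeros_like(state.emotion, dtype=np.bool_)
    seed = int(rng.integers(2**31))
    _sweep(
        state.emotion, state.money, state.lives, dead,
        x, y, random_offer, coin_flip,
        params.fraction, params.min_stake, seed,
    )
    return dead


def _gather(a: np.ndarray, k: int) -> np.ndarray:
    axis, shift = _ROLLS[k]
    return np.roll(a, shift, axis=axis)


def replace_dead(
    state: PopulationState,
    dead: np.ndarray,
    params: GameParams,
    rng: np.random.Generator,
) -> PopulationState:
    """Fill every empty cell with a newborn, simultaneously.

    The newborn inherits the deceased agent's money and receives L
    lives.  Its emotion is the mode of the surviving neighbors'
    emotions (copycat; ties uniform at random; uniform over all five
    emotions if no neighbor survived), or the emotion of the richest
    surviving neighbor under the alternative rule.  Mutates ``state``
    in place and returns it.
    """
    if not dead.any():
        return state
    n = state.side
    n_emotions = len(EMOTIONS)
    alive = ~dead

    if params.replacement_rule == "copycat_majority":
        onehot = (
            state.emotion[None, :, :] == np.arange(n_emotions, dtype=np.int8)[:, None, None]
        ) & alive[None, :, :]
        counts = np.zeros((n_emotions, n, n), dtype=np.int64)
        for k in range(4):
            axis, shift = _ROLLS[k]
            counts += np.roll(onehot, shift, axis=axis + 1)
        # integer counts + uniform(0,1) noise: argmax lands uniformly on the
        # tied modes without disturbing a strict majority; cells whose four
        # neighbors all died have all-zero counts, so the noise alone picks
        # an emotion uniformly at random
        scores = counts + rng.random((n_emotions, n, n))
        newborn = np.argmax(scores, axis=0).astype(np.int8)
    else:  # richest_neighbor
        neigh_money = np.stack([_gather(np.where(alive, state.money, -1.0), k) for k in range(4)])
        neigh_emotion = np.stack([_gather(state.emotion, k) for k in range(4)])
        top = neigh_money.max(axis=0, keepdims=True)
        richest = (neigh_money == top) & (neigh_money >= 0)
        scores = np.where(richest, rng.random((4, n, n)), -1.0)
        pick = np.argmax(scores, axis=0)
        newborn = np.take_along_axis(neigh_emotion, pick[None], axis=0)[0]
        orphan = top[0] < 0  # no surviving neighbor at all
        if orphan.any():
            newborn = np.where(
                orphan, rng.integers(0, n_emotions, size=(n, n), dtype=np.int8), newborn
            )

    state.emotion[dead] = newborn[dead]
    state.lives[dead] = params.lives_init
    return state


def step(
    state: PopulationState,
    params: GameParams,
    table: Mapping[Emotion, EmotionStrategy],
    rng: np.random.Generator,
) -> PopulationState:
    """Advance the population one time step (games, deaths, replacement)."""
    new = state.copy()
    dead = play_games(new, params, table, rng)
    new = replace_dead(new, dead, params, rng)
    new.time = state.time + 1
    return new


def iterate_states(
    params: GameParams, seed: int | np.random.SeedSequence
) -> Iterator[PopulationState]:
    """Yield the population state at t = 0, 1, ..., T under a fixed seed."""
    rng = np.random.default_rng(seed)
    table = params.strategies()
    state = init_population(
        GridGeometry(params.side), params.money_init, params.lives_init, rng
    )
    yield state
    for _ in range(params.steps):
        state = step(state, params, table, rng)
        yield state


def run_simulation(
    params: GameParams, seed: int | np.random.SeedSequence
) -> list[MetricsRecord]:
    """Run one replicate and return the metrics trajectory (t = 0 .. T)."""
    return [metrics_record(s, params.money_init) for s in iterate_states(params, seed)]
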