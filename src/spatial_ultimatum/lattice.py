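"""Toroidal square lattice and population state.

Agents live one per cell on an n-by-n grid with periodic boundaries and
interact with their von Neumann neighborhood of unit radius: the four
orthogonally adjacent cells (north, east, south, west).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .strategies import EMOTIONS

__all__ = ["GridGeometry", "PopulationState", "neighbors", "init_population", "snapshot_frame"]

#: Fixed neighbor order: (d_row, d_col) for north, east, south, west.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = ((-1, 0), (0, 1), (1, 0), (0, -1))


@dataclass(frozen=True)
class GridGeometry:
    """An n x n torus; requires n >= 3 so the four neighbors are distinct."""

    side: int

    def __post_init__(self) -> None:
        if self.side < 3:
            raise ValueError(f"lattice side must be >= 3, got {self.side}")

    @property
    def n_cells(self) -> int:
        return self.side * self.side


def neighbors(geometry: GridGeometry, cell: tuple[int, int]) -> list[tuple[int, int]]:
    """The four von Neumann neighbors of ``cell``, in N, E, S, W order.

    Coordinates are 0-based (row, col) and wrap modulo the lattice side.
    """
    n = geometry.side
    r, c = cell
    if not (0 <= r < n and 0 <= c < n):
        raise IndexError(f"cell {cell} outside {n}x{n} lattice")
    return [((r + dr) % n, (c + dc) % n) for dr, dc in NEIGHBOR_OFFSETS]


@dataclass
class PopulationState:
    """Per-cell emotion, money and lives at one time step.

    ``emotion`` holds indices into :data:`~spatial_ultimatum.strategies.EMOTIONS`;
    ``money`` is real-valued (dollars, never rounded); ``lives`` is the
    integer survival buffer.  Total money is conserved by the dynamics.
    """

    emotion: np.ndarray  # (n, n) int8, index into EMOTIONS
    money: np.ndarray  # (n, n) float64
    lives: np.ndarray  # (n, n) int64
    time: int = 0

    def __post_init__(self) -> None:
        if not (self.emotion.shape == self.money.shape == self.lives.shape):
            raise ValueError("emotion, money and lives must share one shape")

    @property
    def side(self) -> int:
        return self.emotion.shape[0]

    @property
    def n_agents(self) -> int:
        return self.emotion.size

    @property
    def total_money(self) -> float:
        return float(self.money.sum())

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.emotion.copy(), self.money.copy(), self.lives.copy(), self.time
        )


def init_population(
    geometry: GridGeometry,
    money_init: float,
    lives_init: int,
    rng: np.random.Generator,
) -> PopulationState:
    """Fresh population at t=0.

    Every agent starts with ``money_init`` dollars (D) and ``lives_init``
    lives (L); emotions are drawn independently and uniformly from the five,
    so each initial fraction fluctuates around 1/5 rather than being an
    exact partition.
    """
    if money_init <= 0:
        raise ValueError("initial money D must be positive")
    if lives_init < 1:
        raise ValueError("initial lives L must be >= 1")
    n = geometry.side
    emotion = rng.integers(0, len(EMOTIONS), size=(n, n), dtype=np.int8)
    money = np.full((n, n), float(money_init))
    lives = np.full((n, n), int(lives_init), dtype=np.int64)
    return PopulationState(emotion, money, lives, time=0)


def snapshot_frame(state: PopulationState) -> pd.DataFrame:
    """One row per cell (row, col, emotion, money, lives), for dumps/debugging."""
    n = state.side
    rows, cols = np.divmod(np.arange(n * n), n)
    return pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "emotion": [EMOTIONS[i].value for i in state.emotion.ravel()],
            "money": state.money.ravel(),
            "lives": state.lives.ravel(),
        }
    )
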