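"""Composition and wealth metrics.

For each emotion e, ``p_e`` is the fraction of agents bearing e and
``q_e`` the fraction of the total money their holders have accumulated.
Population diversity and money dispersion are summarized by normalized
Shannon entropies

    H_p = -sum_e p_e log p_e / log 5,     H_q analogously for q,

and by the inhomogeneities I_p = 1 - H_p and I_q = 1 - H_q: 0 for a
perfectly even five-way split, 1 for a monoculture or monopoly.  The
normalization constant stays log 5 even if some emotions are extinct,
since five emotions are always in play.  Per-capita money per emotion is
phi_e = D q_e / p_e.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _shannon_entropy

from .lattice import PopulationState
from .strategies import EMOTIONS

__all__ = [
    "MetricsRecord",
    "composition",
    "money_per_agent",
    "normalized_entropy",
    "inhomogeneities",
    "metrics_record",
]

_N_EMOTIONS = len(EMOTIONS)
_LOG5 = np.log(_N_EMOTIONS)


@dataclass(frozen=True)
class MetricsRecord:
    """All metrics at one time step; arrays are ordered like EMOTIONS."""

    time: int
    p: np.ndarray  # population fractions, sum 1
    q: np.ndarray  # money fractions, sum 1
    phi: np.ndarray  # dollars per agent per emotion; NaN where extinct
    Hp: float
    Hq: float
    Ip: float
    Iq: float

    def to_row(self) -> dict:
        """Flat mapping for one trajectory-CSV row."""
        row: dict = {"t": self.time}
        for k, e in enumerate(EMOTIONS):
            row[f"p_{e.value}"] = self.p[k]
        for k, e in enumerate(EMOTIONS):
            row[f"q_{e.value}"] = self.q[k]
        for k, e in enumerate(EMOTIONS):
            row[f"phi_{e.value}"] = self.phi[k]
        row.update(Hp=self.Hp, Hq=self.Hq, Ip=self.Ip, Iq=self.Iq)
        return row


def composition(state: PopulationState) -> tuple[np.ndarray, np.ndarray]:
    """Per-emotion population fractions p_e and money fractions q_e.

    p_e = N_e / N and q_e = M_e / (total money); both vectors sum to 1.
    """
    counts = np.bincount(state.emotion.ravel(), minlength=_N_EMOTIONS)
    money_by_emotion = np.bincount(
        state.emotion.ravel(), weights=state.money.ravel(), minlength=_N_EMOTIONS
    )
    p = counts / state.n_agents
    q = money_by_emotion / state.total_money
    return p, q


def money_per_agent(p: np.ndarray, q: np.ndarray, money_init: float) -> np.ndarray:
    """phi_e = D q_e / p_e; NaN (not 0) where an emotion is extinct.

    Raises if an extinct emotion still appears to hold money — that would
    be an internal accounting bug, not a valid state.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    extinct = p == 0.0
    if np.any(extinct & (q > 1e-12)):
        raise RuntimeError("emotion with zero agents holds nonzero money")
    phi = np.full_like(p, np.nan)
    np.divide(money_init * q, p, out=phi, where=~extinct)
    return phi


def normalized_entropy(fractions: np.ndarray) -> float:
    """Shannon entropy of a five-way composition divided by log 5, in [0, 1].

    Zero fractions contribute nothing (0 log 0 := 0); the log base cancels
    in the normalization.  Fractions must be nonnegative and sum to 1.
    """
    f = np.asarray(fractions, dtype=float)
    if f.size != _N_EMOTIONS:
        raise ValueError(f"expected {_N_EMOTIONS} fractions, got {f.size}")
    if np.any(f < 0):
        raise ValueError("fractions must be nonnegative")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {f.sum()}, not 1")
    return float(_shannon_entropy(f) / _LOG5)


def inhomogeneities(Hp: float, Hq: float) -> tuple[float, float]:
    """I_p = 1 - H_p and I_q = 1 - H_q."""
    return 1.0 - Hp, 1.0 - Hq


def metrics_record(state: PopulationState, money_init: float) -> MetricsRecord:
    """Compute the full metrics record for a population state."""
    p, q = composition(state)
    phi = money_per_agent(p, q, money_init)
    Hp = normalized_entropy(p)
    Hq = normalized_entropy(q)
    Ip, Iq = inhomogeneities(Hp, Hq)
    return MetricsRecord(state.time, p, q, phi, Hp, Hq, Ip, Iq)
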