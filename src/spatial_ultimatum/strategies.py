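"""Emotion-driven bargaining strategies.

Each agent carries one of five basic emotions — anger, fear, joy, sadness,
surprise — and the emotion fully determines how the agent plays the
Ultimatum Game: the fraction ``x_e`` of the stake it offers when proposing,
and the minimum fraction ``y_e`` it accepts when responding.

Anger, fear and sadness are deterministic: fixed offer, fixed acceptance
threshold.  Joy and surprise draw a fresh uniform offer for every
interaction; joy accepts anything, surprise accepts or rejects by a fair
coin flip regardless of the offer.  Threshold acceptance is strict: an
offer exactly at the aspiration fails.  This detail carries real
selective weight, because the canonical offers and aspirations collide
exactly (fear's and sadness's 50% offers meet anger's 50% aspiration,
and anger's 20% offers meet sadness's 20% aspiration).

The deterministic emotions admit a signed perturbation ``delta`` used in
sensitivity sweeps: a more intense emotion corresponds to ``delta > 0``
(anger offers less and demands more; fear and sadness offer more).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Emotion",
    "EMOTIONS",
    "EmotionStrategy",
    "make_strategy",
    "strategy_table",
    "draw_offer",
    "decide_accept",
    "serialize_table",
]


class Emotion(str, Enum):
    """The five basic emotions. The set is closed."""

    ANGER = "anger"
    FEAR = "fear"
    JOY = "joy"
    SADNESS = "sadness"
    SURPRISE = "surprise"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical ordering; array-valued code indexes emotions in this order.
EMOTIONS: tuple[Emotion, ...] = (
    Emotion.ANGER,
    Emotion.FEAR,
    Emotion.JOY,
    Emotion.SADNESS,
    Emotion.SURPRISE,
)

#: Deterministic emotions: (base offer x_e, base acceptance threshold y_e).
_BASE_DETERMINISTIC: dict[Emotion, tuple[float, float]] = {
    Emotion.ANGER: (0.20, 0.50),
    Emotion.FEAR: (0.50, 0.00),
    Emotion.SADNESS: (0.50, 0.20),
}


@dataclass(frozen=True)
class EmotionStrategy:
    """Offer and acceptance rule for one emotion.

    Parameters
    ----------
    emotion
        Which basic emotion this strategy encodes.
    offer_kind
        ``"fixed"`` (anger, fear, sadness) or ``"uniform_random"``
        (joy, surprise — a fresh uniform draw per interaction).
    offer_value
        The offered fraction x_e for fixed strategies; ignored otherwise.
    accept_kind
        ``"threshold"`` (accept iff offer > y_e, ties fail) or
        ``"coin_flip"`` (surprise — fair Bernoulli, offer ignored).
    accept_threshold
        The aspiration y_e for threshold strategies; ignored otherwise.
    delta
        The signed perturbation applied to the base values (0 for the
        canonical strategies).
    """

    emotion: Emotion
    offer_kind: str
    offer_value: float
    accept_kind: str
    accept_threshold: float
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.offer_kind not in ("fixed", "uniform_random"):
            raise ValueError(f"unknown offer_kind {self.offer_kind!r}")
        if self.accept_kind not in ("threshold", "coin_flip"):
            raise ValueError(f"unknown accept_kind {self.accept_kind!r}")
        if not 0.0 <= self.offer_value <= 1.0:
            raise ValueError("offer_value outside [0, 1]")
        if not 0.0 <= self.accept_threshold <= 1.0:
            raise ValueError("accept_threshold outside [0, 1]")


def make_strategy(emotion: Emotion, delta: float = 0.0) -> EmotionStrategy:
    """Build the strategy for ``emotion`` with perturbation ``delta``.

    With ``delta = 0`` the canonical strategies are:

    ========  ==============  =================
    emotion   offer x_e       acceptance y_e
    ========  ==============  =================
    anger     0.20            0.50
    fear      0.50            0 (accept all)
    joy       uniform(0, 1)   0 (accept all)
    sadness   0.50            0.20
    surprise  uniform(0, 1)   fair coin flip
    ========  ==============  =================

    A nonzero ``delta`` intensifies (``delta > 0``) or softens
    (``delta < 0``) the deterministic emotions: anger becomes
    ``x = 0.20 - delta``, ``y = 0.50 + delta``; fear ``x = 0.50 + delta``;
    sadness ``x = 0.50 + delta``, ``y = 0.20 + delta``.  Perturbed values
    are clipped into [0, 1] (a fraction outside that range is meaningless);
    clipping is logged.

    Raises
    ------
    ValueError
        If ``delta`` is nonzero for joy or surprise, whose rules have no
        tunable intensity in this model.
    """
    emotion = Emotion(emotion)
    if emotion in (Emotion.JOY, Emotion.SURPRISE):
        if delta != 0.0:
            raise ValueError(
                f"delta is only meaningful for anger, fear and sadness; "
                f"got delta={delta} for {emotion.value}"
            )
        if emotion is Emotion.JOY:
            return EmotionStrategy(emotion, "uniform_random", 0.5, "threshold", 0.0)
        return EmotionStrategy(emotion, "uniform_random", 0.5, "coin_flip", 0.5)

    x0, y0 = _BASE_DETERMINISTIC[emotion]
    if emotion is Emotion.ANGER:
        x, y = x0 - delta, y0 + delta
    elif emotion is Emotion.FEAR:
        x, y = x0 + delta, y0
    else:  # sadness
        x, y = x0 + delta, y0 + delta
    if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
        logger.warning(
            "delta=%s pushes %s outside [0,1] (x=%s, y=%s); clipping",
            delta, emotion.value, x, y,
        )
    x = float(np.clip(x, 0.0, 1.0))
    y = float(np.clip(y, 0.0, 1.0))
    return EmotionStrategy(emotion, "fixed", x, "threshold", y, delta=delta)


def strategy_table(
    deltas: Mapping[Emotion, float] | None = None,
) -> dict[Emotion, EmotionStrategy]:
    """All five strategies, with optional per-emotion perturbations."""
    deltas = dict(deltas or {})
    for key in deltas:
        Emotion(key)  # validate early, before any simulation
    return {
        e: make_strategy(e, float(deltas.get(e, deltas.get(e.value, 0.0))))
        for e in EMOTIONS
    }


def draw_offer(strategy: EmotionStrategy, rng: np.random.Generator) -> float:
    """The fraction of the stake the proposer offers in one interaction.

    Fixed strategies return x_e exactly; random strategies return an
    independent uniform(0, 1) draw (mean 0.5).
    """
    if strategy.offer_kind == "fixed":
        return strategy.offer_value
    return float(rng.random())


def decide_accept(
    strategy: EmotionStrategy, offered_fraction: float, rng: np.random.Generator
) -> bool:
    """Whether the responder accepts ``offered_fraction`` of the stake.

    Threshold strategies accept offers strictly greater than y_e — an
    offer exactly at the aspiration is turned down; the coin-flip
    strategy accepts with probability 1/2 independently of the offer.
    A zero threshold accepts any positive offer (random offers are
    positive almost surely).
    """
    if strategy.accept_kind == "threshold":
        return offered_fraction > strategy.accept_threshold
    return bool(rng.random() < 0.5)


def serialize_table(table: Mapping[Emotion, EmotionStrategy]) -> dict:
    """Audit-friendly mapping of effective per-emotion parameters."""
    return {
        e.value: {
            "offer_kind": s.offer_kind,
            "offer": s.offer_value if s.offer_kind == "fixed" else "uniform(0,1)",
            "accept_kind": s.accept_kind,
            "threshold": s.accept_threshold if s.accept_kind == "threshold" else "coin_flip",
            "delta": s.delta,
        }
        for e, s in table.items()
    }
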