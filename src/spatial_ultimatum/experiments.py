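"""Replicated scenario runs and sweeps.

A scenario is one combination of game parameters simulated several times
with independent seeds; its summary collects replicate means and sample
standard deviations of p_e, q_e, phi_e, I_p and I_q at the measurement
step (default t = 100, by when the trajectories have settled near their
asymptotic values).  The default manifest mirrors the published sweep
design: the initial-money sweep D in {20, 60, 100, 140} at L = 1, the
lives sweep L in {1..6} at D = 100, and one-emotion strategy
perturbations delta in {-0.1, +0.1} for anger, fear and sadness —
fifteen distinct scenarios after removing the shared baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import GameParams, run_simulation
from .metrics import MetricsRecord
from .strategies import EMOTIONS, Emotion

__all__ = [
    "Scenario",
    "ScenarioSummary",
    "spawn_seeds",
    "run_scenario",
    "summarize_records",
    "sweep",
    "emotion_ranking",
    "default_manifest",
    "summary_frame",
]


def spawn_seeds(master_seed: int, count: int) -> tuple[int, ...]:
    """Derive ``count`` per-replicate seeds from one master seed.

    Uses numpy's SeedSequence expansion and keeps each seed below 2^31 so
    seed lists stay small and serializable.
    """
    state = np.random.SeedSequence(master_seed).generate_state(count, dtype=np.uint32)
    return tuple(int(s % (2**31)) for s in state)


@dataclass(frozen=True)
class Scenario:
    """A parameter combination plus its replication plan."""

    params: GameParams
    replicates: int = 10
    measure_at: int = 100
    seeds: tuple[int, ...] | None = None  # filled from the master seed if None
    label: str = ""

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 <= self.measure_at <= self.params.steps:
            raise ValueError("measure_at must lie in [0, steps]")
        if self.seeds is not None and len(self.seeds) != self.replicates:
            raise ValueError("need exactly one seed per replicate")

    def with_seeds(self, master_seed: int) -> "Scenario":
        return replace(self, seeds=spawn_seeds(master_seed, self.replicates))


@dataclass(frozen=True)
class ScenarioSummary:
    """Replicate means and sample SDs of the metrics at the measurement step.

    Per-emotion arrays follow the EMOTIONS order.  SDs use the n-1
    denominator and are NaN for a single replicate.  phi statistics for
    an emotion are taken over the replicates in which it is present.
    """

    label: str
    params: GameParams
    replicates: int
    measure_at: int
    seeds: tuple[int, ...]
    p_mean: np.ndarray
    p_sd: np.ndarray
    q_mean: np.ndarray
    q_sd: np.ndarray
    phi_mean: np.ndarray
    phi_sd: np.ndarray
    Ip_mean: float
    Ip_sd: float
    Iq_mean: float
    Iq_sd: float


def _aggregate(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and sample SD over the replicate axis, NaN-aware.

    NaNs appear only in phi columns of replicates where an emotion went
    extinct; the statistics then cover the replicates where it exists.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        mean = np.nanmean(values, axis=0)
        if values.shape[0] > 1:
            sd = np.nanstd(values, axis=0, ddof=1)
        else:
            sd = np.full(values.shape[1:], np.nan)
    return np.atleast_1d(mean), np.atleast_1d(sd)


def run_scenario(scenario: Scenario, master_seed: int | None = None) -> ScenarioSummary:
    """Run all replicates of a scenario and aggregate the measurement-step metrics."""
    if scenario.seeds is None:
        if master_seed is None:
            raise ValueError("scenario has no seeds; provide a master_seed")
        scenario = scenario.with_seeds(master_seed)
    records: list[MetricsRecord] = []
    for seed in scenario.seeds:
        trajectory = run_simulation(scenario.params, seed)
        records.append(trajectory[scenario.measure_at])
    return summarize_records(scenario, records)


def summarize_records(
    scenario: Scenario, records: list[MetricsRecord]
) -> ScenarioSummary:
    """Aggregate one measurement-step record per replicate into a summary."""
    if scenario.seeds is None or len(records) != scenario.replicates:
        raise ValueError("need seeded scenario and one record per replicate")
    p = np.stack([r.p for r in records])
    q = np.stack([r.q for r in records])
    phi = np.stack([r.phi for r in records])
    Ip = np.array([[r.Ip] for r in records])
    Iq = np.array([[r.Iq] for r in records])

    p_mean, p_sd = _aggregate(p)
    q_mean, q_sd = _aggregate(q)
    phi_mean, phi_sd = _aggregate(phi)
    Ip_mean, Ip_sd = _aggregate(Ip)
    Iq_mean, Iq_sd = _aggregate(Iq)
    return ScenarioSummary(
        label=scenario.label,
        params=scenario.params,
        replicates=scenario.replicates,
        measure_at=scenario.measure_at,
        seeds=scenario.seeds,
        p_mean=p_mean,
        p_sd=p_sd,
        q_mean=q_mean,
        q_sd=q_sd,
        phi_mean=phi_mean,
        phi_sd=phi_sd,
        Ip_mean=float(Ip_mean[0]),
        Ip_sd=float(Ip_sd[0]),
        Iq_mean=float(Iq_mean[0]),
        Iq_sd=float(Iq_sd[0]),
    )


def sweep(scenarios: list[Scenario], master_seed: int | None = None) -> list[ScenarioSummary]:
    """Run each scenario independently; summaries come back in input order.

    Scenarios without explicit seed lists get them spawned from
    ``master_seed`` offset by their position, so every scenario uses an
    independent, reproducible seed set.
    """
    if not scenarios:
        raise ValueError("empty scenario list")
    out = []
    for i, sc in enumerate(scenarios):
        ms = None if sc.seeds is not None or master_seed is None else master_seed + i
        out.append(run_scenario(sc, master_seed=ms))
    return out


def emotion_ranking(summary: ScenarioSummary) -> list[tuple[Emotion, float]]:
    """Emotions sorted by mean per-capita money, richest first.

    Ties break alphabetically by emotion label for a stable order.
    """
    pairs = [(e, float(summary.phi_mean[k])) for k, e in enumerate(EMOTIONS)]
    return sorted(pairs, key=lambda it: (-it[1], it[0].value))


def default_manifest(replicates: int = 10, measure_at: int = 100) -> list[Scenario]:
    """The fifteen-scenario sweep over D, L and the strategy perturbations."""
    scenarios: list[Scenario] = []
    for D in (20.0, 60.0, 100.0, 140.0):
        scenarios.append(
            Scenario(GameParams(money_init=D, lives_init=1), replicates, measure_at,
                     label=f"D={D:g}_L=1")
        )
    for L in (2, 3, 4, 5, 6):
        scenarios.append(
            Scenario(GameParams(money_init=100.0, lives_init=L), replicates, measure_at,
                     label=f"D=100_L={L}")
        )
    for emotion in (Emotion.ANGER, Emotion.FEAR, Emotion.SADNESS):
        for delta in (-0.1, 0.1):
            scenarios.append(
                Scenario(
                    GameParams(deltas={emotion: delta}), replicates, measure_at,
                    label=f"delta_{emotion.value}={delta:+g}",
                )
            )
    return scenarios


def summary_frame(summaries: list[ScenarioSummary]) -> pd.DataFrame:
    """One row per (scenario, emotion): machine-readable analog of the
    published summary tables, with scenario-level Ip/Iq on every row."""
    rows = []
    for s in summaries:
        for k, e in enumerate(EMOTIONS):
            rows.append(
                {
                    "scenario": s.label,
                    "emotion": e.value,
                    "p_mean": s.p_mean[k],
                    "p_sd": s.p_sd[k],
                    "q_mean": s.q_mean[k],
                    "q_sd": s.q_sd[k],
                    "phi_mean": s.phi_mean[k],
                    "phi_sd": s.phi_sd[k],
                    "Ip_mean": s.Ip_mean,
                    "Ip_sd": s.Ip_sd,
                    "Iq_mean": s.Iq_mean,
                    "Iq_sd": s.Iq_sd,
                    "replicates": s.replicates,
                    "measure_at": s.measure_at,
                    "seeds": ";".join(str(x) for x in s.seeds),
                }
            )
    return pd.DataFrame(rows)
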