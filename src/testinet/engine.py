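"""Single-run simulation engine.

One run works on a *paired* population: ``n`` networked agents on a
communication graph, each shadowed by a non-communicating duplicate that is
initialised identically and receives exactly the same evidence stream from
the world.  Comparing the two populations isolates the causal effect of
communication.

Per time step (all updates simultaneous, from start-of-step state):

1. every agent independently receives, with probability ``activity``, one
   report from the world; the report (both the arrival indicator and its
   content) is shared between an agent and its shadow partner;
2. every networked agent whose start-of-step belief exceeds the assertion
   threshold (belief > threshold for "h", belief < 1 - threshold for
   "not-h") asserts, with probability ``p_communicate``, to *all* of its
   neighbours; agents in between remain silent;
3. every agent folds its incoming batch (world report, if any, plus
   neighbour assertions) into its belief using the start-of-step expected
   reliabilities of the sources; expectation-based agents additionally
   revise the trust density of each reporting source, using their
   start-of-step belief in the report's content.  Agents never receive, or
   update from, their own assertions; silence carries no evidential weight.

Ground truth is drawn once per run (hypothesis true with probability
``p_truth``); the world reports the true state with probability
``accuracy``.  Randomness is split into named substreams (truth, network,
world, communication) so the shadow pairing holds bitwise and a run is a
pure function of its configuration and seed.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from .model_core import (
    DEFAULT_GRID_SIZE,
    ReportContent,
    TrustState,
    belief_update_batch,
    trust_update,
)
from .network_gen import NetworkTopology, small_world

__all__ = [
    "WORLD",
    "Strategy",
    "WorldConfig",
    "CommConfig",
    "SimConfig",
    "Population",
    "RunRecord",
    "RngStreams",
    "init_population",
    "world_report",
    "assertion_decision",
    "step",
    "run_simulation",
]

#: source key for the world channel in an agent's trust map
WORLD = "world"


class Strategy(enum.Enum):
    """How agents treat the reliability of their sources."""

    UPDATER = "updater"  # expectation-based trust revision from Beta(2, 1)
    FIXED = "fixed"      # constant trust, never revised


@dataclass(frozen=True)
class WorldConfig:
    """The evidence-dispensing world.

    p_truth   probability the hypothesis is true on a given run (default .6)
    accuracy  probability a world report matches the ground truth (symmetric)
    activity  per-agent, per-step probability of receiving a world report
    """

    p_truth: float = 0.6
    accuracy: float = 0.66
    activity: float = 0.1

    def __post_init__(self) -> None:
        for name in ("p_truth", "accuracy", "activity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.activity > 0.0 and not 0.0 < self.accuracy < 1.0:
            raise ValueError("accuracy must lie strictly in (0, 1) when the world is active")


@dataclass(frozen=True)
class CommConfig:
    """Assertion behaviour.

    threshold      belief level beyond which an agent may assert (strict;
                   mirrored at 1 - threshold for asserting "not-h")
    p_communicate  per-eligible-agent, per-step probability of asserting
    """

    threshold: float = 0.8
    p_communicate: float = 0.25

    def __post_init__(self) -> None:
        if not 0.5 < self.threshold < 1.0:
            raise ValueError(f"threshold must lie in (0.5, 1), got {self.threshold}")
        if not 0.0 <= self.p_communicate <= 1.0:
            raise ValueError(f"p_communicate must lie in [0, 1], got {self.p_communicate}")


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one run."""

    world: WorldConfig = field(default_factory=WorldConfig)
    comm: CommConfig = field(default_factory=CommConfig)
    n: int = 30
    k: int = 2
    p_rewire: float = 0.2
    strategy: Strategy = Strategy.UPDATER
    steps: int = 50
    seed: int = 0
    grid_size: int = DEFAULT_GRID_SIZE
    fixed_trust: float = 0.66
    trust_prior_a: float = 2.0
    trust_prior_b: float = 1.0
    record_trajectories: bool = False
    per_link_delivery: bool = False

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError(f"steps must be >= 1, got {self.steps}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")

    # -- flat key/value serialisation -------------------------------------

    _FLAT_WORLD = ("p_truth", "accuracy", "activity")
    _FLAT_COMM = ("threshold", "p_communicate")

    def to_flat_dict(self) -> dict:
        d = {k: getattr(self.world, k) for k in self._FLAT_WORLD}
        d.update({k: getattr(self.comm, k) for k in self._FLAT_COMM})
        d.update(
            n=self.n,
            k=self.k,
            p_rewire=self.p_rewire,
            strategy=self.strategy.value,
            steps=self.steps,
            seed=self.seed,
            grid_size=self.grid_size,
            fixed_trust=self.fixed_trust,
            trust_prior_a=self.trust_prior_a,
            trust_prior_b=self.trust_prior_b,
            record_trajectories=self.record_trajectories,
            per_link_delivery=self.per_link_delivery,
        )
        return d

    @classmethod
    def from_flat_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        world = WorldConfig(**{k: d.pop(k) for k in cls._FLAT_WORLD if k in d})
        comm = CommConfig(**{k: d.pop(k) for k in cls._FLAT_COMM if k in d})
        if "strategy" in d:
            d["strategy"] = Strategy(d["strategy"])
        return cls(world=world, comm=comm, **d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_flat_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_flat_dict(), fh, sort_keys=True)


@dataclass
class Population:
    """Mutable state of the paired networked/shadow populations.

    Trust maps are per-agent dicts keyed by source: the string ``"world"``
    for the world channel, integer node ids for neighbours.  Shadow agents
    communicate with nobody, so their maps hold only the world channel.
    """

    strategy: Strategy
    beliefs: np.ndarray          # networked, shape (n,)
    shadow_beliefs: np.ndarray   # shadow partners, shape (n,)
    trust: list                  # networked: [{source: TrustState}]
    shadow_trust: list           # shadow:    [{WORLD: TrustState}]

    @property
    def n(self) -> int:
        return self.beliefs.size


@dataclass
class RunRecord:
    """Outcome of one run: final beliefs of both populations plus provenance."""

    truth: bool
    final_beliefs: list
    final_shadow_beliefs: list
    connected: bool
    seed: int
    n: int
    strategy: str
    trajectories: Optional[list] = None         # per-step networked beliefs
    shadow_trajectories: Optional[list] = None  # per-step shadow beliefs

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, line: str) -> "RunRecord":
        return cls(**json.loads(line))


@dataclass
class RngStreams:
    """Named substreams for one run.

    The world stream is consumed in per-step blocks indexed by agent and is
    shared verbatim between an agent and its shadow partner, which is what
    guarantees the two populations see identical world evidence.
    """

    truth: np.random.Generator
    network: np.random.Generator
    world: np.random.Generator
    comm: np.random.Generator

    @staticmethod
    def from_seed(seed: int) -> "RngStreams":
        children = np.random.SeedSequence(seed).spawn(4)
        return RngStreams(*(np.random.default_rng(s) for s in children))


# ---------------------------------------------------------------------------
# population setup and elementary draws


def init_population(config: SimConfig, net: NetworkTopology) -> Population:
    """Fresh paired populations: all beliefs .5; trust per strategy.

    UPDATER agents start every source (world and each neighbour) at the
    discretised Beta trust prior; FIXED agents hold the constant
    ``fixed_trust`` for every source.  Shadow trust maps contain only the
    world channel.
    """
    n = net.n
    if config.strategy is Strategy.UPDATER:
        prior = TrustState.beta(config.trust_prior_a, config.trust_prior_b, config.grid_size)
    elif config.strategy is Strategy.FIXED:
        prior = TrustState.fixed(config.fixed_trust)
    else:
        raise ValueError(f"unknown strategy: {config.strategy!r}")
    neighbors = net.neighbors()
    trust = [
        {WORLD: prior, **{int(j): prior for j in neighbors[i]}} for i in range(n)
    ]
    shadow_trust = [{WORLD: prior} for _ in range(n)]
    return Population(
        strategy=config.strategy,
        beliefs=np.full(n, 0.5),
        shadow_beliefs=np.full(n, 0.5),
        trust=trust,
        shadow_trust=shadow_trust,
    )


def world_report(truth: bool, accuracy: float, rng: np.random.Generator) -> ReportContent:
    """One report from the world: truth-consistent with probability ``accuracy``."""
    if not 0.0 < accuracy < 1.0:
        raise ValueError(f"accuracy must lie strictly in (0, 1), got {accuracy}")
    correct = rng.random() < accuracy
    says_h = correct if truth else not correct
    return ReportContent.ASSERT_H if says_h else ReportContent.ASSERT_NOT_H


def assertion_decision(
    belief: float, comm: CommConfig, rng: np.random.Generator
) -> Optional[ReportContent]:
    """What, if anything, an agent asserts this step.

    Strictly above the threshold the agent asserts "h" with probability
    ``p_communicate``; strictly below the mirrored threshold it asserts
    "not-h" with the same probability; otherwise it is silent.  Exactly one
    uniform draw is consumed regardless of eligibility, so random streams
    stay aligned across steps.
    """
    u = rng.random()
    if belief > comm.threshold:
        return ReportContent.ASSERT_H if u < comm.p_communicate else None
    if belief < 1.0 - comm.threshold:
        return ReportContent.ASSERT_NOT_H if u < comm.p_communicate else None
    return None


# ---------------------------------------------------------------------------
# dynamics


def _belief_in_content(belief: float, content: ReportContent) -> float:
    return belief if content is ReportContent.ASSERT_H else 1.0 - belief


def _apply_batch(
    belief0: float,
    reports: list,
    trust_map: dict,
    updater: bool,
) -> float:
    """Update one agent from its report batch; revise trust in place.

    Reliabilities and the belief-in-content are all taken at their
    start-of-step values (the trust map is only mutated after every rho has
    been read, and only for this agent's own sources).
    """
    rhos = [(trust_map[src].mean, content) for src, content in reports]
    new_belief = belief_update_batch(belief0, rhos)
    if updater:
        for src, content in reports:
            trust_map[src] = trust_update(trust_map[src], _belief_in_content(belief0, content))
    return new_belief


def step(
    population: Population,
    net: NetworkTopology,
    config: SimConfig,
    streams: RngStreams,
    truth: bool,
    neighbors: Optional[list] = None,
) -> Population:
    """Advance both populations by one time step (mutates ``population``)."""
    n = population.n
    updater = population.strategy is Strategy.UPDATER
    if neighbors is None:
        neighbors = net.neighbors()

    b0 = population.beliefs.copy()
    s0 = population.shadow_beliefs.copy()

    # (1) world evidence, one block of draws per step, shared with shadows
    active = streams.world.random(n) < config.world.activity
    correct = streams.world.random(n) < config.world.accuracy
    says_h = correct if truth else ~correct
    world_contents = [
        (ReportContent.ASSERT_H if says_h[i] else ReportContent.ASSERT_NOT_H)
        if active[i]
        else None
        for i in range(n)
    ]

    # (2) assertions from start-of-step beliefs
    theta, p_comm = config.comm.threshold, config.comm.p_communicate
    if config.per_link_delivery:
        # each eligible (speaker, listener) link delivers independently
        u_link = {
            (i, int(j)): streams.comm.random() for i in range(n) for j in neighbors[i]
        }
        u_self = streams.comm.random(n)  # keep per-agent draws aligned

        def delivered(speaker: int, listener: int) -> Optional[ReportContent]:
            b = b0[speaker]
            if b > theta and u_link[(speaker, listener)] < p_comm:
                return ReportContent.ASSERT_H
            if b < 1.0 - theta and u_link[(speaker, listener)] < p_comm:
                return ReportContent.ASSERT_NOT_H
            return None

    else:
        u_comm = streams.comm.random(n)
        asserts: list = []
        for i in range(n):
            b = b0[i]
            content = None
            if b > theta and u_comm[i] < p_comm:
                content = ReportContent.ASSERT_H
            elif b < 1.0 - theta and u_comm[i] < p_comm:
                content = ReportContent.ASSERT_NOT_H
            asserts.append(content)

    # (3) simultaneous batch updates
    for i in range(n):
        reports = []
        if world_contents[i] is not None:
            reports.append((WORLD, world_contents[i]))
        for j in neighbors[i]:
            j = int(j)
            if config.per_link_delivery:
                content = delivered(j, i)
            else:
                content = asserts[j]
            if content is not None:
                reports.append((j, content))
        if reports:
            population.beliefs[i] = _apply_batch(
                b0[i], reports, population.trust[i], updater
            )
        # shadow partner: world report only
        if world_contents[i] is not None:
            population.shadow_beliefs[i] = _apply_batch(
                s0[i],
                [(WORLD, world_contents[i])],
                population.shadow_trust[i],
                updater,
            )
    return population


def run_simulation(config: SimConfig) -> RunRecord:
    """Run one full simulation and return its record.

    Draws the ground truth, builds the network, initialises the paired
    populations and advances ``config.steps`` steps; beliefs are measured
    in the state after the final step.  Bitwise reproducible given
    ``config.seed``.
    """
    streams = RngStreams.from_seed(config.seed)
    truth = bool(streams.truth.random() < config.world.p_truth)
    net = small_world(config.n, config.k, config.p_rewire, streams.network)
    population = init_population(config, net)
    neighbors = net.neighbors()

    trajectories = [] if config.record_trajectories else None
    shadow_trajectories = [] if config.record_trajectories else None
    for _ in range(config.steps):
        step(population, net, config, streams, truth, neighbors=neighbors)
        if config.record_trajectories:
            trajectories.append([float(b) for b in population.beliefs])
            shadow_trajectories.append([float(b) for b in population.shadow_beliefs])

    return RunRecord(
        truth=truth,
        final_beliefs=[float(b) for b in population.beliefs],
        final_shadow_beliefs=[float(b) for b in population.shadow_beliefs],
        connected=net.is_connected(),
        seed=config.seed,
        n=config.n,
        strategy=config.strategy.value,
        trajectories=trajectories,
        shadow_trajectories=shadow_trajectories,
    )
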