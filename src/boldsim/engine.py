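"""Stochastic individual-based model of refuge-to-forage group movement.

A group of ``n`` individuals starts at a safe home site (position 0) on a
one-dimensional axis and must reach a foraging site located ``d_food``
distance units away.  Each individual ``i`` (its *identity*, fixing its place
in a boldness hierarchy) carries

* a constant personal speed ``s_i`` drawn once from U(0.95, 1.0),
* a personal outward-probability increment ``omega_i = (i - 1) * omega_difference``,
* a time-dependent probability of moving outward
  ``p_i(t) = p_baseline + t * omega_i`` (the recursion ``p += omega`` applied
  every period, never clamped).

Within each period every individual makes one decision, in a freshly
randomised order.  An individual already at the foraging site never moves
again; one that has drifted behind the refuge is forced one step outward;
otherwise it moves outward with probability ``p_i(t)`` and on failure
performs the group's social action (move toward the group centroid, toward
the nearest neighbour, toward the local majority, or — non-social — stay
put).  A simulation ends at the first period after which every individual
is at the foraging site.

Two interchangeable implementations are provided: the readable pure-Python
operations in this module, and a numba-compiled kernel
(:mod:`boldsim._kernel`) used by default.  Both consume the *same* random
stream in the same order, so they produce bit-identical results for a given
seed.  The consumption order is: n speed draws at creation; then per period
one Fisher-Yates shuffle of the not-yet-arrived agents (k-1 bounded integer
draws for k such agents) followed, per scheduled agent, by at most one
uniform draw (plus one bounded integer draw on a nearest-neighbour tie).
Arrived agents are frozen — they are skipped by the scheduler and their
probability is never read again, so restricting the shuffle to the active
set is behaviourally identical to shuffling the whole group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .observers import EventLog

RULES = ("central", "nearest_neighbour", "majority", "non_social")
SOCIAL_RULES = ("central", "nearest_neighbour", "majority")

#: How the boldness increment maps onto the hierarchy.  ``zero_based`` is the
#: model as written (omega_i = (i-1)*omega_difference; the shyest individual
#: never ramps).  ``one_based`` gives every individual a ramp
#: (omega_i = i*omega_difference); the published group-level outcomes (end
#: times a few hundred periods in every arm) are only attainable this way,
#: so the results-reproduction protocols use it.  See docs/methods.md.
OMEGA_INDEXINGS = ("zero_based", "one_based")

SPEED_LOW = 0.95
SPEED_HIGH = 1.0
_SPEED_RANGE = 0.05  # literal, so the compiled kernel matches bit-for-bit


class ConfigurationError(ValueError):
    """Raised when a :class:`SimulationConfig` violates a model invariant."""


class SimulationError(RuntimeError):
    """Raised when a simulation fails to terminate within ``max_steps``."""


@dataclass(frozen=True)
class SimulationConfig:
    """Complete parameterisation of one simulation.

    Defaults are the study baselines: ``n=10``, ``p_baseline=0.001``,
    ``omega_difference=0.001``, ``d_food=100``, leave threshold 10 units.
    """

    n: int = 10
    p_baseline: float = 0.001
    omega_difference: float = 0.001
    d_food: float = 100.0
    rule: str = "non_social"
    threshold: float = 10.0
    seed: int = 0
    max_steps: int = 1_000_000
    omega_indexing: str = "zero_based"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.rule not in RULES:
            raise ConfigurationError(
                f"rule: {self.rule!r} is not one of {RULES}")
        if not isinstance(self.n, (int, np.integer)) or self.n < 1:
            raise ConfigurationError(f"n: must be a positive integer, got {self.n!r}")
        if self.rule in SOCIAL_RULES and self.n < 2:
            raise ConfigurationError(
                f"n: social rule {self.rule!r} needs n >= 2 (centroid of "
                f"'others' is undefined for n = {self.n})")
        if not 0.0 < self.p_baseline <= 1.0:
            raise ConfigurationError(
                f"p_baseline: must be in (0, 1], got {self.p_baseline!r}")
        if self.omega_difference < 0.0:
            raise ConfigurationError(
                f"omega_difference: must be >= 0, got {self.omega_difference!r}")
        if self.d_food <= 0.0:
            raise ConfigurationError(f"d_food: must be > 0, got {self.d_food!r}")
        if not 0.0 < self.threshold < self.d_food:
            raise ConfigurationError(
                f"threshold: must satisfy 0 < threshold < d_food, got "
                f"{self.threshold!r} with d_food={self.d_food!r}")
        if self.max_steps < 1:
            raise ConfigurationError(f"max_steps: must be >= 1, got {self.max_steps!r}")
        if self.omega_indexing not in OMEGA_INDEXINGS:
            raise ConfigurationError(
                f"omega_indexing: {self.omega_indexing!r} is not one of "
                f"{OMEGA_INDEXINGS}")

    @property
    def omega_offset(self) -> int:
        """0 for ``zero_based`` indexing, 1 for ``one_based``."""
        return OMEGA_INDEXINGS.index(self.omega_indexing)

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)


@dataclass
class AgentState:
    """One individual: identity (1-based hierarchy position), speed, increment,
    current outward probability and signed position."""

    identity: int
    speed: float
    omega: float
    p: float
    d: float = 0.0


@dataclass
class GroupState:
    """All agents plus the period counter and the simulation's random stream.

    ``active`` lists the 0-based indices of agents that have not yet reached
    the foraging site, in the (evolving) order used by the scheduler.
    """

    agents: list[AgentState]
    rng: np.random.Generator
    t: int = 0
    active: list[int] = field(default_factory=list)
    config: SimulationConfig | None = field(default=None, repr=False)


def init_group(config: SimulationConfig,
               rng: np.random.Generator | None = None) -> GroupState:
    """Create the period-0 group: everyone at the home site with ``p = p_baseline``.

    Speeds consume the first ``n`` draws of the stream, in identity order.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    agents = []
    for i in range(1, config.n + 1):
        speed = SPEED_LOW + _SPEED_RANGE * rng.random()
        agents.append(AgentState(
            identity=i,
            speed=speed,
            omega=(i - 1 + config.omega_offset) * config.omega_difference,
            p=config.p_baseline,
            d=0.0,
        ))
    return GroupState(agents=agents, rng=rng, t=0,
                      active=list(range(config.n)), config=config)


def update_probability(agent: AgentState) -> AgentState:
    """Apply the per-period recursion ``p += omega`` (no clamping at 1)."""
    agent.p += agent.omega
    return agent


def social_action_central(focal: AgentState, group: GroupState) -> AgentState:
    """Move one step toward (possibly past) the mean position of the others.

    No move if the focal position already equals the centroid exactly.
    """
    # sequential sum in identity order: must match the compiled kernel bit-for-bit
    total = 0.0
    for a in group.agents:
        total += a.d
    n = len(group.agents)
    d_prime = (total - focal.d) / (n - 1)
    if d_prime > focal.d:
        focal.d += focal.speed
    elif d_prime < focal.d:
        focal.d -= focal.speed
    return focal


def social_action_nearest(focal: AgentState, group: GroupState) -> AgentState:
    """Move one step toward (possibly past) the nearest neighbour.

    Ties in absolute distance are broken by one uniform integer draw; a
    co-located nearest neighbour means no move.
    """
    d_min = np.inf
    m = 0
    for a in group.agents:
        if a is focal:
            continue
        dist = abs(a.d - focal.d)
        if dist < d_min:
            d_min = dist
            m = 1
        elif dist == d_min:
            m += 1
    if m > 1:
        pick = int(group.rng.integers(0, m))
    else:
        pick = 0
    c = 0
    target = focal.d
    for a in group.agents:
        if a is focal:
            continue
        if abs(a.d - focal.d) == d_min:
            if c == pick:
                target = a.d
                break
            c += 1
    if target > focal.d:
        focal.d += focal.speed
    elif target < focal.d:
        focal.d -= focal.speed
    return focal


def social_action_majority(focal: AgentState, group: GroupState) -> AgentState:
    """Move one step toward the side holding strictly more colleagues.

    Co-located colleagues count for neither side; an exact tie means no move.
    """
    ahead = behind = 0
    for a in group.agents:
        if a is focal:
            continue
        if a.d > focal.d:
            ahead += 1
        elif a.d < focal.d:
            behind += 1
    if ahead > behind:
        focal.d += focal.speed
    elif behind > ahead:
        focal.d -= focal.speed
    return focal


_SOCIAL_ACTIONS = {
    "central": social_action_central,
    "nearest_neighbour": social_action_nearest,
    "majority": social_action_majority,
}


def decide_and_move(agent: AgentState, group: GroupState,
                    config: SimulationConfig) -> AgentState:
    """One movement decision (probability already updated this period).

    Exactly one branch applies: absorbed at the foraging site -> no move;
    behind the refuge -> forced one step outward; otherwise one uniform draw
    is consumed and the agent either steps outward (draw < p) or performs
    the configured social action.
    """
    if agent.d >= config.d_food:
        return agent
    if agent.d < 0.0:
        agent.d += agent.speed
        return agent
    u = group.rng.random()
    if u < agent.p:
        agent.d += agent.speed
    elif config.rule != "non_social":
        _SOCIAL_ACTIONS[config.rule](agent, group)
    return agent


def _shuffle_in_place(seq: list, rng: np.random.Generator) -> None:
    """Fisher-Yates shuffle consuming len(seq)-1 bounded integer draws."""
    for k in range(len(seq) - 1, 0, -1):
        j = int(rng.integers(0, k + 1))
        seq[k], seq[j] = seq[j], seq[k]


def step(group: GroupState, config: SimulationConfig) -> GroupState:
    """Advance one period: shuffle the active agents' acting order, then let
    each update its probability and decide in turn.

    Social computations read *live* positions: agents earlier in the
    permutation have already moved when later agents decide.  Agents that
    reach the foraging site are dropped from the schedule at period end
    (they are frozen regardless, so this changes no behaviour).
    """
    group.t += 1
    _shuffle_in_place(group.active, group.rng)
    for idx in list(group.active):
        agent = group.agents[idx]
        update_probability(agent)
        decide_and_move(agent, group, config)
    group.active = [i for i in group.active
                    if group.agents[i].d < config.d_food]
    return group


def all_arrived(group: GroupState, config: SimulationConfig) -> bool:
    return all(a.d >= config.d_food for a in group.agents)


def _run_python(config: SimulationConfig, rng: np.random.Generator,
                record_trajectory: bool) -> EventLog:
    group = init_group(config, rng)
    n = config.n
    leave = np.full(n, -1, dtype=np.int64)
    arrive = np.full(n, -1, dtype=np.int64)
    trajectory = [[a.d for a in group.agents]] if record_trajectory else None
    while group.active:
        if group.t >= config.max_steps:
            raise SimulationError(
                f"simulation did not terminate within max_steps={config.max_steps}")
        group.t += 1
        _shuffle_in_place(group.active, group.rng)
        for idx in list(group.active):
            agent = group.agents[idx]
            update_probability(agent)
            decide_and_move(agent, group, config)
            if leave[idx] < 0 and agent.d >= config.threshold:
                leave[idx] = group.t
            if arrive[idx] < 0 and agent.d >= config.d_food:
                arrive[idx] = group.t
        group.active = [i for i in group.active
                        if group.agents[i].d < config.d_food]
        if record_trajectory:
            trajectory.append([a.d for a in group.agents])
    return EventLog(
        identities=np.arange(1, n + 1),
        speeds=np.array([a.speed for a in group.agents]),
        leave_time=leave,
        arrival_time=arrive,
        end_time=group.t,
        config=config,
        trajectory=None if trajectory is None else np.asarray(trajectory),
    )


def run_simulation(config: SimulationConfig,
                   rng: np.random.Generator | None = None,
                   record_trajectory: bool = False,
                   use_kernel: bool = True) -> EventLog:
    """Run one simulation to completion and return its event log.

    Parameters
    ----------
    config
        Validated simulation parameters (``config.seed`` seeds the stream
        unless an explicit ``rng`` is supplied).
    rng
        Optional generator to consume; lets callers keep drawing from the
        same stream afterwards (e.g. to pick a focal individual).
    record_trajectory
        Store per-period positions on the log (pure-Python path only; meant
        for tests and debugging).
    use_kernel
        Use the numba-compiled kernel (default).  The kernel and the Python
        path consume the stream identically and return identical logs.

    Raises
    ------
    SimulationError
        If the group has not fully arrived after ``max_steps`` periods.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if record_trajectory or not use_kernel:
        return _run_python(config, rng, record_trajectory)
    from ._kernel import simulate_kernel
    leave, arrive, end_time, speeds = simulate_kernel(
        rng, config.n, config.p_baseline, config.omega_difference,
        config.omega_offset, config.d_food, config.threshold,
        RULES.index(config.rule), config.max_steps)
    if end_time < 0:
        raise SimulationError(
            f"simulation did not terminate within max_steps={config.max_steps}")
    return EventLog(
        identities=np.arange(1, config.n + 1),
        speeds=speeds,
        leave_time=leave,
        arrival_time=arrive,
        end_time=int(end_time),
        config=config,
    )
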