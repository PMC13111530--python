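"""Synthetic spike-raster generators with known statistical structure.

Four scenarios cover the regimes the pipeline is meant to resolve:

* ``poisson`` — independent homogeneous Poisson units (the null: every
  cross-correlogram should be uniform up to the test's false-positive
  rate).
* ``lagged_pair`` — a "leader" Poisson unit and a "follower" echoing each
  leader spike at a fixed lag with Gaussian jitter (a strong
  leader/follower pair with a single correlogram peak at +lag).
* ``periodic_bursts`` — population-wide periodic bursts with partial
  participation over a Poisson baseline (rhythmic synchronization:
  correlogram peaks at multiples of the burst period).
* ``regime_switch`` — one scenario before a switch time, another after
  (models treatment responses such as synchronization onset or per-unit
  death mid-recording).

All randomness flows from one seeded generator per invocation; a fixed
seed gives byte-identical rasters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

from .io import Recording, SpikeTrain

__all__ = [
    "ScenarioSpec",
    "gen_poisson_population",
    "gen_lagged_pair",
    "gen_periodic_bursts",
    "gen_regime_switch",
    "generate",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic scenario.

    Fields irrelevant to a scenario are ignored.  Units: seconds for all
    times/durations, Hz for rates.
    """

    scenario: str = "poisson"
    n_units: int = 20
    duration: float = 600.0
    rate: float = 5.0              # baseline / leader firing rate
    lag: float = 0.010             # follower delay (lagged_pair)
    jitter_sd: float = 0.002       # follower jitter SD (lagged_pair)
    burst_period: float = 0.25     # burst start spacing (periodic_bursts)
    burst_len: float = 0.05        # burst duration
    in_burst_rate: float = 100.0   # within-burst rate
    baseline_rate: float = 0.5     # between-burst rate (periodic_bursts)
    participation: float = 0.8     # P(unit joins a given burst)
    switch_time: float = 300.0     # regime_switch boundary
    base_scenario: str = "poisson"  # pre-switch scenario (regime_switch)
    after: dict = field(default_factory=dict)  # post-switch overrides
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if min(self.rate, self.jitter_sd, self.in_burst_rate, self.baseline_rate) < 0:
            raise ValueError("rates and jitter must be non-negative")
        if not 0 <= self.participation <= 1:
            raise ValueError("participation must be in [0, 1]")

    def ground_truth(self) -> dict:
        """Scenario parameters as a plain dict (JSON sidecar payload)."""
        d = dataclasses.asdict(self)
        return d


def _poisson_train(rng: np.random.Generator, rate: float, t0: float, t1: float) -> np.ndarray:
    span = t1 - t0
    if rate <= 0 or span <= 0:
        return np.empty(0)
    n = rng.poisson(rate * span)
    return np.sort(rng.uniform(t0, t1, size=n))


def gen_poisson_population(spec: ScenarioSpec) -> Recording:
    """Independent homogeneous Poisson units at ``spec.rate`` Hz."""
    rng = np.random.default_rng(spec.seed)
    trains = [
        SpikeTrain(f"u{i:03d}", _poisson_train(rng, spec.rate, 0, spec.duration))
        for i in range(spec.n_units)
    ]
    return Recording(tuple(trains), spec.duration, source=f"synthetic:poisson[{spec.seed}]")


def gen_lagged_pair(spec: ScenarioSpec) -> Recording:
    """A Poisson leader and a jittered fixed-lag follower.

    Follower events are leader times + lag + N(0, jitter_sd), clipped to
    the recording and re-sorted (jitter can reorder events).
    """
    if spec.lag <= 0:
        raise ValueError("lag must be positive")
    rng = np.random.default_rng(spec.seed)
    leader = _poisson_train(rng, spec.rate, 0, spec.duration)
    follower = leader + spec.lag
    if spec.jitter_sd > 0:
        follower = follower + rng.normal(0, spec.jitter_sd, size=follower.size)
    follower = np.sort(np.clip(follower, 0, spec.duration))
    return Recording(
        (SpikeTrain("leader", leader), SpikeTrain("follower", follower)),
        spec.duration,
        source=f"synthetic:lagged_pair[{spec.seed}]",
    )


def gen_periodic_bursts(spec: ScenarioSpec) -> Recording:
    """Population bursts every ``burst_period`` s with partial participation.

    Burst k spans [k*P, k*P + burst_len); each unit joins it with
    probability ``participation`` and fires Poisson(in_burst_rate) inside;
    between bursts every unit fires at ``baseline_rate``.
    """
    if not spec.burst_len < spec.burst_period:
        raise ValueError("burst_len must be shorter than burst_period")
    rng = np.random.default_rng(spec.seed)
    starts = np.arange(0, spec.duration, spec.burst_period)
    trains = []
    for i in range(spec.n_units):
        pieces = [_poisson_train(rng, spec.baseline_rate, 0, spec.duration)]
        join = rng.uniform(size=starts.size) < spec.participation
        for s in starts[join]:
            end = min(s + spec.burst_len, spec.duration)
            pieces.append(_poisson_train(rng, spec.in_burst_rate, s, end))
        trains.append(SpikeTrain(f"u{i:03d}", np.sort(np.concatenate(pieces))))
    return Recording(
        tuple(trains), spec.duration, source=f"synthetic:periodic_bursts[{spec.seed}]"
    )


_GENERATORS = {}


def gen_regime_switch(spec: ScenarioSpec) -> Recording:
    """One scenario before ``switch_time``, another (overridden) after.

    ``spec.after`` holds field overrides applied post-switch — e.g.
    ``{"scenario": "periodic_bursts"}`` for synchronization onset, or
    ``{"rate": 0.0}`` on a unit subset via ``{"dead_fraction": q}`` for
    per-unit death.  Unit count must match across the switch.
    """
    if not 0 < spec.switch_time < spec.duration:
        raise ValueError("switch_time must fall inside the recording")
    rng = np.random.default_rng(spec.seed)
    overrides = dict(spec.after)
    dead_fraction = float(overrides.pop("dead_fraction", 0.0))

    before_spec = replace(
        spec, scenario=spec.base_scenario, duration=spec.switch_time,
        seed=int(rng.integers(2**31)),
    )
    overrides.setdefault("scenario", spec.base_scenario)
    after_spec = replace(
        spec, duration=spec.duration - spec.switch_time,
        seed=int(rng.integers(2**31)), **overrides,
    )
    before = _GENERATORS[before_spec.scenario](before_spec)
    after = _GENERATORS[after_spec.scenario](after_spec)
    if before.n_units != after.n_units:
        raise ValueError("unit count must not change across the switch")

    dead = np.zeros(before.n_units, dtype=bool)
    if dead_fraction > 0:
        n_dead = int(round(dead_fraction * before.n_units))
        dead[rng.choice(before.n_units, size=n_dead, replace=False)] = True

    trains = []
    for i, (bt, at) in enumerate(zip(before.trains, after.trains)):
        post = np.empty(0) if dead[i] else at.times + spec.switch_time
        trains.append(SpikeTrain(bt.unit_id, np.concatenate([bt.times, post])))
    return Recording(
        tuple(trains), spec.duration,
        source=f"synthetic:regime_switch[{spec.seed}]",
    )


_GENERATORS.update(
    {
        "poisson": gen_poisson_population,
        "lagged_pair": gen_lagged_pair,
        "periodic_bursts": gen_periodic_bursts,
        "regime_switch": gen_regime_switch,
    }
)


def generate(spec: ScenarioSpec) -> Recording:
    """Dispatch on ``spec.scenario``."""
    try:
        gen = _GENERATORS[spec.scenario]
    except KeyError:
        raise ValueError(f"unknown scenario {spec.scenario!r}") from None
    return gen(spec)
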