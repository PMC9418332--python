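"""Stochastic simulation of the clockwise hand-over-hand kinetic scheme.

Upon acidification a 16-subunit pre-pore ring shows transient inter-subunit
breakages (Poisson arrivals at ``k_open``, re-closing after an exponential
dwell at ``k_close``).  Occasionally (probability ``q_nucleate`` per
breakage) a breakage nucleates the transition: starting with the subunit
clockwise of the broken bond, a pre-pore-I -> pre-pore-II wave advances
clockwise with i.i.d. Exp(k12) waiting times for a run of n* subunits (n*
drawn from the run-length model conditional on a run occurring), and each
pre-pore-II subunit converts to the pore state after an Exp(k23) dwell
(optionally gated on its counter-clockwise neighbour's pore conversion).
All post-nucleation steps are irreversible.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expfit import LifetimeFit, fit_exponential_right_censored
from .runlength import ArcLengthSample, RunLengthParams, conditional_pmf

RING_SIZE = 16


class SubunitState(enum.IntEnum):
    PRE_I = 0
    PRE_II = 1
    PORE = 2


class EventKind(str, enum.Enum):
    BREAK_OPEN = "BREAK_OPEN"
    BREAK_CLOSE = "BREAK_CLOSE"
    NUCLEATE = "NUCLEATE"
    TO_II = "TO_II"
    TO_PORE = "TO_PORE"


@dataclass(frozen=True)
class Event:
    time: float
    kind: EventKind
    subunit: int | None  # bond index for BREAK_*/NUCLEATE, subunit for TO_*


@dataclass
class RingKineticRates:
    """Rate constants of the kinetic scheme (defaults: the measured values).

    ``k_open`` ring breakage rate (s^-1); ``k_close`` breakage re-closure
    rate (s^-1, only a lower bound >5 s^-1 is observable, default 10);
    ``q_nucleate`` per-breakage nucleation probability, default 0.2/1.8 so
    that k_open*q reproduces the 0.2 s^-1 initiation rate; ``k12``/``k23``
    per-subunit propagation and conversion rates (s^-1);
    ``run_length_params`` governs how far the wave runs;
    ``fixed_run_length`` forces a deterministic run length (e.g. 16);
    ``pore_wave_gated`` selects whether II->pore of subunit i additionally
    waits for subunit i-1's pore conversion.
    """

    k_open: float = 1.8
    k_close: float = 10.0
    q_nucleate: float = 0.2 / 1.8
    k12: float = 13.0
    k23: float = 15.0
    run_length_params: RunLengthParams = field(
        default_factory=lambda: RunLengthParams(N=RING_SIZE, sigma=0.01, s=0.64 / 0.36, n0=11.9)
    )
    fixed_run_length: int | None = None
    pore_wave_gated: bool = False

    def __post_init__(self) -> None:
        for name in ("k_open", "k_close", "k12", "k23"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be a positive finite rate, got {v!r}")
        if not (0.0 <= self.q_nucleate <= 1.0):
            raise ValueError(f"q_nucleate must be in [0, 1], got {self.q_nucleate!r}")
        if self.fixed_run_length is not None and not (
            1 <= self.fixed_run_length <= RING_SIZE
        ):
            raise ValueError("fixed_run_length must be in 1..16")


@dataclass
class RingTrajectory:
    """Time-ordered event list of one ring."""

    events: list[Event]
    ring_id: int
    t_end: float
    breakage_site: int | None = None  # bond b = between subunits b and b+1

    def times(self, kind: EventKind) -> np.ndarray:
        return np.array([e.time for e in self.events if e.kind is kind])

    @property
    def nucleation_time(self) -> float | None:
        t = self.times(EventKind.NUCLEATE)
        return float(t[0]) if t.size else None

    @property
    def run_length(self) -> int:
        return sum(1 for e in self.events if e.kind is EventKind.TO_II)

    def subunit_entry_times(self) -> tuple[dict[int, float], dict[int, float]]:
        """Per-subunit pre-pore-II and pore entry times (s)."""
        t_ii = {e.subunit: e.time for e in self.events if e.kind is EventKind.TO_II}
        t_pore = {e.subunit: e.time for e in self.events if e.kind is EventKind.TO_PORE}
        return t_ii, t_pore

    def state_at(self, t: float) -> np.ndarray:
        """Subunit states at time ``t`` (ignores transient breakages)."""
        states = np.full(RING_SIZE, SubunitState.PRE_I, dtype=np.int8)
        for e in self.events:
            if e.time > t:
                break
            if e.kind is EventKind.TO_II:
                states[e.subunit] = SubunitState.PRE_II
            elif e.kind is EventKind.TO_PORE:
                states[e.subunit] = SubunitState.PORE
        return states

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": [e.time for e in self.events],
                "event": [e.kind.value for e in self.events],
                "subunit": [e.subunit for e in self.events],
                "ring_id": self.ring_id,
            }
        )


def _draw_run_length(rates: RingKineticRates, rng: np.random.Generator) -> int:
    if rates.fixed_run_length is not None:
        return rates.fixed_run_length
    p = rates.run_length_params
    pcond = conditional_pmf(p.N, p.s, p.n0)
    return int(rng.choice(np.arange(1, p.N + 1), p=pcond))


def simulate_ring(
    rates: RingKineticRates, duration: float, seed=None, ring_id: int = 0
) -> RingTrajectory:
    """Exact stochastic simulation of one ring for ``duration`` seconds.

    Breakages arrive as a Poisson process at ``k_open`` on uniformly random
    bonds.  A nucleating breakage is recorded as a single NUCLEATE event at
    the breakage bond; the subsequent wave is simulated to completion even
    if it extends past ``duration`` (``t_end`` marks the observation
    window).  Reproducible for a fixed seed.
    """
    if not (duration > 0):
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events: list[Event] = []
    breakage_site = None
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rates.k_open)
        if t >= duration:
            break
        bond = int(rng.integers(RING_SIZE))
        if rng.random() < rates.q_nucleate:
            breakage_site = bond
            events.append(Event(t, EventKind.NUCLEATE, bond))
            n_star = _draw_run_length(rates, rng)
            gaps = rng.exponential(1.0 / rates.k12, size=n_star)
            dwells = rng.exponential(1.0 / rates.k23, size=n_star)
            t_ii = t + np.cumsum(gaps)
            if rates.pore_wave_gated:
                t_pore = np.empty(n_star)
                prev = -np.inf
                for i in range(n_star):
                    start = max(t_ii[i], prev)
                    t_pore[i] = start + dwells[i]
                    prev = t_pore[i]
            else:
                t_pore = t_ii + dwells
            for i in range(n_star):
                su = (bond + 1 + i) % RING_SIZE
                events.append(Event(float(t_ii[i]), EventKind.TO_II, su))
                events.append(Event(float(t_pore[i]), EventKind.TO_PORE, su))
            break
        else:
            events.append(Event(t, EventKind.BREAK_OPEN, bond))
            events.append(
                Event(t + rng.exponential(1.0 / rates.k_close), EventKind.BREAK_CLOSE, bond)
            )
    events.sort(key=lambda e: e.time)
    return RingTrajectory(events=events, ring_id=ring_id, t_end=duration, breakage_site=breakage_site)


def simulate_ensemble(
    rates: RingKineticRates, n_rings: int, duration: float, seed=None
) -> list[RingTrajectory]:
    """Simulate ``n_rings`` independent rings with per-ring substreams."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [
        simulate_ring(rates, duration, seed=np.random.default_rng(child), ring_id=i)
        for i, child in enumerate(ss.spawn(n_rings))
    ]


def completion_time(traj: RingTrajectory) -> float | None:
    """Time from transition initiation (NUCLEATE) to the last pore event.

    The full-ring mean at the measured rates is ~16/k12 + 1/k23 ~ 1.3 s.
    Returns None when no nucleation occurred.
    """
    t0 = traj.nucleation_time
    if t0 is None:
        return None
    t_pore = traj.times(EventKind.TO_PORE)
    return float(t_pore.max() - t0)


def initiation_survival(trajs: list[RingTrajectory]) -> LifetimeFit:
    """Exponential lifetime of the pre-pore state (time to first nucleation).

    Rings that never nucleate are right-censored at their observation end;
    the fit is the censored exponential MLE.
    """
    times, censored = [], []
    for tr in trajs:
        t0 = tr.nucleation_time
        if t0 is None:
            times.append(tr.t_end)
            censored.append(True)
        else:
            times.append(t0)
            censored.append(False)
    return fit_exponential_right_censored(np.asarray(times), np.asarray(censored))


def arc_length_distribution(trajs: list[RingTrajectory]) -> ArcLengthSample:
    """Histogram of per-ring run lengths (nucleated rings only)."""
    lengths = [tr.run_length for tr in trajs if tr.run_length > 0]
    return ArcLengthSample.from_lengths(lengths, N=RING_SIZE, n_rings_total=len(trajs))


def measured_rates(**overrides) -> RingKineticRates:
    """The measured kinetic preset: k_open=1.8, q=0.2/1.8, k12=13, k23=15,
    run lengths from the fitted model (s=0.64/0.36, n0=11.9)."""
    return replace(RingKineticRates(), **overrides) if overrides else RingKineticRates()
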