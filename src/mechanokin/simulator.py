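"""Kinetic Monte Carlo simulation of the talin-vinculin binding scheme.

The scheme has four states: talin folded, talin unfolded (binding sites
exposed), vinculin bound in its initial weak mode, and vinculin bound in the
mature mode reached by a slow force-independent conformational transition.
Transitions carry Bell-Evans rate laws (or constant rates) and are simulated
exactly with the Gillespie algorithm under piecewise-constant force
protocols: within a segment, waiting times are exponential with the total
exit rate at that segment's force; a segment boundary re-evaluates the rates
and redraws the waiting time, which is statistically exact for memoryless
kinetics.

State trajectories can be rendered into magnetic-tweezers-like extension
traces: each state maps to an extension level (unfolding lengthens the
tether; vinculin binding contracts the unfolded polypeptide by ~3 nm as the
binding site coils back into a helix), sampled uniformly with additive
Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import BellEvansParams, ForceSense, ThermalContext, bell_evans_rate
from . import presets

__all__ = [
    "STATE_TALIN_FOLDED",
    "STATE_TALIN_UNFOLDED",
    "STATE_VINCULIN_WEAK",
    "STATE_VINCULIN_MATURE",
    "BOUND_STATES",
    "Transition",
    "KineticScheme",
    "ForceProtocol",
    "StateTrajectory",
    "LevelMap",
    "ExtensionTrace",
    "default_scheme",
    "simulate_scheme",
    "render_extension",
    "simulate_maturation_experiment",
    "simulate_fpt_traces",
]

STATE_TALIN_FOLDED = "talin_folded"
STATE_TALIN_UNFOLDED = "talin_unfolded"
STATE_VINCULIN_WEAK = "vinculin_weak"
STATE_VINCULIN_MATURE = "vinculin_mature"
BOUND_STATES = (STATE_VINCULIN_WEAK, STATE_VINCULIN_MATURE)


@dataclass(frozen=True)
class Transition:
    """A directed transition with a Bell-Evans law or a constant rate (1/s)."""

    src: str
    dst: str
    rate_law: BellEvansParams | float

    def rate(self, force_pN: float, therm: ThermalContext) -> float:
        if isinstance(self.rate_law, BellEvansParams):
            return bell_evans_rate(self.rate_law, force_pN, therm)
        return float(self.rate_law)


@dataclass(frozen=True)
class KineticScheme:
    states: tuple[str, ...]
    transitions: tuple[Transition, ...]

    def __post_init__(self) -> None:
        declared = set(self.states)
        for tr in self.transitions:
            if tr.src == tr.dst:
                raise ValueError(f"self-transition on state {tr.src!r}")
            if tr.src not in declared or tr.dst not in declared:
                raise ValueError(f"transition references undeclared state: {tr}")
            if isinstance(tr.rate_law, float) and tr.rate_law < 0:
                raise ValueError("constant rates must be non-negative")

    def out_transitions(self, state: str) -> tuple[Transition, ...]:
        return tuple(tr for tr in self.transitions if tr.src == state)

    def exit_rate(self, state: str, force_pN: float, therm: ThermalContext) -> float:
        return sum(tr.rate(force_pN, therm) for tr in self.out_transitions(state))


def default_scheme(
    talin=None,
    binding: BellEvansParams | None = None,
    weak_unbind: BellEvansParams | None = None,
    mature_unbind: BellEvansParams | None = None,
    maturation_rate_per_s: float = presets.MATURATION_RATE_PER_S,
) -> KineticScheme:
    """The four-state binding/maturation scheme with overridable rate laws.

    Unbinding (from either bound mode) returns the system to the talin
    unfolded state: the vinculin-binding site uncoils but talin stays
    unfolded, which is what produces the +3 nm upward step on unbinding.
    Maturation is irreversible and force-independent by default.
    """
    talin = talin or presets.TALIN_R3_PLACEHOLDER
    binding = binding or presets.BINDING_BRANCH_PLACEHOLDER
    weak_unbind = weak_unbind or presets.FLV_UNBINDING
    mature_unbind = mature_unbind or presets.mature_unbinding_at_probe()
    return KineticScheme(
        states=(
            STATE_TALIN_FOLDED,
            STATE_TALIN_UNFOLDED,
            STATE_VINCULIN_WEAK,
            STATE_VINCULIN_MATURE,
        ),
        transitions=(
            Transition(STATE_TALIN_FOLDED, STATE_TALIN_UNFOLDED, talin.unfold),
            Transition(STATE_TALIN_UNFOLDED, STATE_TALIN_FOLDED, talin.fold),
            Transition(STATE_TALIN_UNFOLDED, STATE_VINCULIN_WEAK, binding),
            Transition(STATE_VINCULIN_WEAK, STATE_TALIN_UNFOLDED, weak_unbind),
            Transition(
                STATE_VINCULIN_WEAK, STATE_VINCULIN_MATURE, float(maturation_rate_per_s)
            ),
            Transition(STATE_VINCULIN_MATURE, STATE_TALIN_UNFOLDED, mature_unbind),
        ),
    )


@dataclass(frozen=True)
class ForceProtocol:
    """Ordered (duration_s, force_pN) segments of piecewise-constant force."""

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol must have at least one segment")
        for dur, force in self.segments:
            if not (dur > 0):
                raise ValueError(f"segment duration must be positive, got {dur}")
            if not (force >= 0):
                raise ValueError(f"segment force must be non-negative, got {force}")

    @property
    def duration_s(self) -> float:
        return sum(d for d, _ in self.segments)

    def force_at(self, t: float) -> float:
        acc = 0.0
        for dur, force in self.segments:
            acc += dur
            if t < acc:
                return force
        return self.segments[-1][1]

    @classmethod
    def constant(cls, force_pN: float, duration_s: float) -> "ForceProtocol":
        return cls(segments=((duration_s, force_pN),))


@dataclass
class StateTrajectory:
    """Event-resolved output of the Gillespie simulation."""

    times_s: np.ndarray  # entry time of each epoch, times_s[0] == 0
    states: list[str]
    forces_pN: np.ndarray  # force at entry of each epoch
    duration_s: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.forces_pN = np.asarray(self.forces_pN, dtype=float)
        if len(self.times_s) != len(self.states):
            raise ValueError("times and states must have equal length")
        if np.any(np.diff(self.times_s) < 0):
            raise ValueError("event times must be non-decreasing")

    def state_at(self, t: float) -> str:
        idx = int(np.searchsorted(self.times_s, t, side="right")) - 1
        return self.states[max(idx, 0)]

    def dwell_records(self) -> pd.DataFrame:
        """Per-epoch dwell table (last epoch censored at the horizon)."""
        ends = np.append(self.times_s[1:], self.duration_s)
        return pd.DataFrame(
            {
                "state": self.states,
                "t_start_s": self.times_s,
                "t_end_s": ends,
                "dwell_s": ends - self.times_s,
                "force_pN": self.forces_pN,
                "censored": [False] * (len(self.states) - 1) + [True],
            }
        )


def simulate_scheme(
    scheme: KineticScheme,
    protocol: ForceProtocol,
    seed: int | np.random.Generator,
    initial_state: str | None = None,
    therm: ThermalContext | None = None,
) -> StateTrajectory:
    """Exact stochastic simulation of the scheme under the force protocol.

    Within a constant-force segment waiting times are exponential with the
    total exit rate; crossing a segment boundary redraws the waiting time at
    the new force without forcing a transition (exact by memorylessness).
    Seeded runs are bit-reproducible.
    """
    therm = therm or presets.DEFAULT_THERM
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = initial_state or scheme.states[0]
    if state not in scheme.states:
        raise ValueError(f"unknown initial state {state!r}")

    times = [0.0]
    states = [state]
    forces = [protocol.segments[0][1]]

    t = 0.0
    seg_end = 0.0
    for dur, force in protocol.segments:
        seg_end += dur
        while t < seg_end:
            out = scheme.out_transitions(state)
            rates = np.array([tr.rate(force, therm) for tr in out])
            total = float(rates.sum())
            if total <= 0.0:  # absorbing at this force: sit out the segment
                t = seg_end
                break
            dt = rng.exponential(1.0 / total)
            if t + dt >= seg_end:
                t = seg_end
                break
            t += dt
            idx = rng.choice(len(out), p=rates / total)
            state = out[idx].dst
            times.append(t)
            states.append(state)
            forces.append(force)

    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return StateTrajectory(
        times_s=np.array(times),
        states=states,
        forces_pN=np.array(forces),
        duration_s=protocol.duration_s,
        seed=seed_val,
    )


@dataclass(frozen=True)
class LevelMap:
    """Extension offsets (nm) of each state relative to the folded baseline.

    The unfolded-state extension gain is not a measured constant of this
    package's system description; 20 nm is a typical value for a talin rod
    domain in the relevant force range and is configurable.  Vinculin-bound
    levels sit ``contraction_nm`` below the unfolded level (coil-to-helix
    contraction of the binding site).
    """

    unfolded_gain_nm: float = 20.0
    contraction_nm: float = 3.0

    def level(self, state: str) -> float:
        if state == STATE_TALIN_FOLDED:
            return 0.0
        if state == STATE_TALIN_UNFOLDED:
            return self.unfolded_gain_nm
        if state in BOUND_STATES:
            return self.unfolded_gain_nm - self.contraction_nm
        raise KeyError(f"no level defined for state {state!r}")


@dataclass
class ExtensionTrace:
    """Uniformly sampled extension signal with its force protocol."""

    sampling_hz: float
    extension_nm: np.ndarray
    force_pN: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.extension_nm = np.asarray(self.extension_nm, dtype=float)
        self.force_pN = np.asarray(self.force_pN, dtype=float)
        if self.sampling_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.extension_nm.shape != self.force_pN.shape:
            raise ValueError("extension and force arrays must align")
        if not np.all(np.isfinite(self.extension_nm)):
            raise ValueError("extension contains non-finite values")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.extension_nm.size) / self.sampling_hz

    @property
    def duration_s(self) -> float:
        return self.extension_nm.size / self.sampling_hz


def render_extension(
    traj: StateTrajectory,
    levels: LevelMap | None = None,
    sampling_hz: float = 1000.0,
    noise_sd_nm: float = 0.8,
    seed: int | np.random.Generator = 0,
) -> ExtensionTrace:
    """Render a state trajectory as a noisy piecewise-constant extension trace."""
    if sampling_hz <= 0:
        raise ValueError("sampling rate must be positive")
    if noise_sd_nm < 0:
        raise ValueError("noise sd must be non-negative")
    levels = levels or LevelMap()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = math.ceil(traj.duration_s * sampling_hz)
    t = np.arange(n) / sampling_hz
    epoch = np.searchsorted(traj.times_s, t, side="right") - 1
    epoch = np.clip(epoch, 0, len(traj.states) - 1)
    state_levels = np.array([levels.level(s) for s in traj.states])
    signal = state_levels[epoch]
    force = traj.forces_pN[epoch]
    if noise_sd_nm > 0:
        signal = signal + rng.normal(0.0, noise_sd_nm, size=n)
    prov = {
        "seed": traj.seed,
        "sampling_hz": sampling_hz,
        "noise_sd_nm": noise_sd_nm,
        "unfolded_gain_nm": levels.unfolded_gain_nm,
        "contraction_nm": levels.contraction_nm,
    }
    return ExtensionTrace(sampling_hz, signal, force, provenance=prov)


def simulate_maturation_experiment(
    weak_unbind: BellEvansParams,
    mature_unbind: BellEvansParams,
    maturation_rate_per_s: float,
    hold_force_pN: float,
    probe_force_pN: float,
    lifetimes_s: Sequence[float],
    reps: int,
    seed: int | np.random.Generator,
    therm: ThermalContext | None = None,
    allow_unbind_during_hold: bool = False,
) -> pd.DataFrame:
    """Hold-and-probe experiment: bind, hold, then interrupt at high force.

    For each replicate the complex binds at the hold force and is held for
    the prescribed lifetime, during which maturation may fire (exponential
    with the maturation rate).  The force then jumps to the probe value and
    the unbinding time is drawn from the rate law of whichever bound mode the
    complex is in at probe onset.

    By default replicates are conditioned on the complex surviving the hold
    (lifetimes are measured on complexes still bound when the probe is
    applied), so the matured fraction at lifetime t is exactly
    1 - exp(-t * maturation_rate).  With ``allow_unbind_during_hold`` the
    weak mode may also dissociate during the hold; replicates that unbind are
    redrawn, which tilts the surviving population toward early maturation.

    Returns a dwell table with columns ``lifetime_s``, ``state_at_probe``,
    ``dwell_s`` (probe-force unbinding time), ``force_pN``, ``censored``.
    """
    if reps <= 0:
        raise ValueError("reps must be positive")
    lifetimes = np.asarray(list(lifetimes_s), dtype=float)
    if np.any(lifetimes <= 0):
        raise ValueError("lifetimes must be positive")
    therm = therm or presets.DEFAULT_THERM
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    r_weak_hold = bell_evans_rate(weak_unbind, hold_force_pN, therm)
    r_weak_probe = bell_evans_rate(weak_unbind, probe_force_pN, therm)
    r_mature_probe = bell_evans_rate(mature_unbind, probe_force_pN, therm)

    rows = []
    for lifetime in lifetimes:
        for _ in range(reps):
            while True:
                t_mat = (
                    rng.exponential(1.0 / maturation_rate_per_s)
                    if maturation_rate_per_s > 0
                    else math.inf
                )
                if not allow_unbind_during_hold:
                    break
                t_ub = rng.exponential(1.0 / r_weak_hold) if r_weak_hold > 0 else math.inf
                if t_mat < t_ub or min(t_mat, t_ub) >= lifetime:
                    break  # survived the hold (possibly matured)
            matured = t_mat < lifetime
            rate = r_mature_probe if matured else r_weak_probe
            dwell = rng.exponential(1.0 / rate) if rate > 0 else math.inf
            rows.append(
                {
                    "lifetime_s": lifetime,
                    "state_at_probe": STATE_VINCULIN_MATURE
                    if matured
                    else STATE_VINCULIN_WEAK,
                    "dwell_s": dwell,
                    "force_pN": probe_force_pN,
                    "censored": not math.isfinite(dwell),
                }
            )
    return pd.DataFrame(rows)


def simulate_fpt_traces(
    rate_law: BellEvansParams,
    start_level_nm: float,
    end_level_nm: float,
    force_pN: float,
    sampling_hz: float,
    noise_sd_nm: float,
    horizon_s: float,
    n: int,
    seed: int | np.random.Generator,
    therm: ThermalContext | None = None,
) -> list[ExtensionTrace]:
    """Two-level first-passage traces mimicking constant-force unraveling.

    Each trace sits at ``start_level_nm`` until an exponentially distributed
    transition time (rate evaluated at the given force), then at
    ``end_level_nm``.  Traces whose transition falls beyond the horizon never
    step within the record and come out censored in downstream analysis.
    The true transition time is recorded in the trace provenance.
    """
    if end_level_nm <= start_level_nm:
        raise ValueError("end level must exceed start level")
    if horizon_s <= 0 or n <= 0:
        raise ValueError("horizon and n must be positive")
    therm = therm or presets.DEFAULT_THERM
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = bell_evans_rate(rate_law, force_pN, therm)

    n_samp = math.ceil(horizon_s * sampling_hz)
    t = np.arange(n_samp) / sampling_hz
    traces = []
    for _ in range(n):
        t_trans = rng.exponential(1.0 / rate) if rate > 0 else math.inf
        signal = np.where(t < t_trans, start_level_nm, end_level_nm).astype(float)
        if noise_sd_nm > 0:
            signal = signal + rng.normal(0.0, noise_sd_nm, size=n_samp)
        traces.append(
            ExtensionTrace(
                sampling_hz,
                signal,
                np.full(n_samp, force_pN),
                provenance={
                    "true_transition_s": t_trans,
                    "force_pN": force_pN,
                    "noise_sd_nm": noise_sd_nm,
                },
            )
        )
    return traces
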