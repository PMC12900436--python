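"""Exact Gillespie simulation of a reaction network and event-table I/O.

The simulator produces the *embedded jump chain* consumed by structure
identification: for every reaction event it records the time, the molecular
counts of all species immediately before the jump, the index of the firing
reaction, and the jump vector.  Events from one or more trajectories are
pooled into an :class:`EventDataset` and round-trip losslessly through a
plain CSV (`trajectory_id,time,x_<sp>,...,d_<sp>,...`, with x_* the
pre-jump counts and d_* the jump vector).

The inner SSA loop is compiled with numba; at Togashi-Kaneko rates a single
ensemble can contain millions of events.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .crn_model import ReactionNetwork

__all__ = [
    "JumpEvent",
    "Trajectory",
    "EventDataset",
    "simulate",
    "simulate_ensemble",
    "write_events",
    "read_events",
    "large_outbreak",
    "derive_seed",
]

DEFAULT_MAX_EVENTS = 1_000_000  # per-trajectory cap; bounds runaway simulations


@dataclass(frozen=True)
class JumpEvent:
    time: float
    pre_state: np.ndarray
    reaction_index: int
    jump: np.ndarray


@dataclass
class Trajectory:
    """One SSA realization: ordered jump events from ``initial_state``.

    ``times`` strictly increase; ``pre_states[j]`` is the state immediately
    before the j-th jump, so replaying ``jumps`` from ``initial_state``
    reproduces every recorded pre-state.
    """

    initial_state: np.ndarray
    times: np.ndarray          # (n_events,)
    pre_states: np.ndarray     # (n_events, s) int64
    reaction_indices: np.ndarray  # (n_events,) int64, 0-based
    jumps: np.ndarray          # (n_events, s) int64
    t_end: float
    absorbed: bool
    capped: bool
    seed: int
    trajectory_id: int = 0

    @property
    def n_events(self) -> int:
        return len(self.times)

    def final_state(self) -> np.ndarray:
        if self.n_events == 0:
            return self.initial_state.copy()
        return self.pre_states[-1] + self.jumps[-1]

    def events(self):
        """Iterate events as :class:`JumpEvent` objects (convenience view)."""
        for j in range(self.n_events):
            yield JumpEvent(
                time=float(self.times[j]),
                pre_state=self.pre_states[j],
                reaction_index=int(self.reaction_indices[j]),
                jump=self.jumps[j],
            )


@dataclass
class EventDataset:
    """Pooled jump events from one or more trajectories.

    ``frame`` has columns ``trajectory_id``, ``time``, ``x_<sp>`` (pre-jump
    counts) and ``d_<sp>`` (jump vector) for every species, preserving
    per-trajectory event order.
    """

    species: list[str]
    frame: pd.DataFrame

    @property
    def n_events(self) -> int:
        return len(self.frame)

    @property
    def pre_states(self) -> np.ndarray:
        return self.frame[[f"x_{sp}" for sp in self.species]].to_numpy(np.int64)

    @property
    def jumps(self) -> np.ndarray:
        return self.frame[[f"d_{sp}" for sp in self.species]].to_numpy(np.int64)

    @staticmethod
    def from_trajectories(trajectories: Sequence[Trajectory], species: Sequence[str]) -> "EventDataset":
        frames = []
        for tr in trajectories:
            df = pd.DataFrame({"trajectory_id": np.full(tr.n_events, tr.trajectory_id),
                               "time": tr.times})
            for i, sp in enumerate(species):
                df[f"x_{sp}"] = tr.pre_states[:, i]
            for i, sp in enumerate(species):
                df[f"d_{sp}"] = tr.jumps[:, i]
            frames.append(df)
        frame = pd.concat(frames, ignore_index=True) if frames else _empty_frame(species)
        return EventDataset(species=list(species), frame=frame)


def _empty_frame(species: Sequence[str]) -> pd.DataFrame:
    cols = ["trajectory_id", "time"] + [f"x_{sp}" for sp in species] + [f"d_{sp}" for sp in species]
    return pd.DataFrame({c: [] for c in cols})


# ---------------------------------------------------------------------------
# Core SSA kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ssa_kernel(nu, jump, rates, x0, t_max, max_events, seed):  # pragma: no cover
    np.random.seed(seed)
    m, s = nu.shape
    times = np.empty(max_events, dtype=np.float64)
    pre = np.empty((max_events, s), dtype=np.int64)
    ridx = np.empty(max_events, dtype=np.int64)
    x = x0.copy()
    a = np.empty(m, dtype=np.float64)
    t = 0.0
    n = 0
    absorbed = False
    while n < max_events:
        a0 = 0.0
        for k in range(m):
            ak = rates[k]
            for i in range(s):
                for c in range(nu[k, i]):
                    ak *= x[i] - c
            if ak < 0.0:
                ak = 0.0
            a[k] = ak
            a0 += ak
        if a0 <= 0.0:
            absorbed = True
            break
        t += np.random.exponential(1.0 / a0)
        if t > t_max:
            t = t_max
            break
        u = np.random.random() * a0
        acc = 0.0
        k_sel = m - 1
        for k in range(m):
            acc += a[k]
            if u <= acc:
                k_sel = k
                break
        times[n] = t
        for i in range(s):
            pre[n, i] = x[i]
        ridx[n] = k_sel
        for i in range(s):
            x[i] += jump[k_sel, i]
        n += 1
    return times[:n], pre[:n], ridx[:n], t, absorbed, n == max_events


def simulate(
    net: ReactionNetwork,
    x0: Sequence[int] | np.ndarray | None = None,
    t_max: float = 1.0,
    seed: int = 0,
    max_events: int = DEFAULT_MAX_EVENTS,
    trajectory_id: int = 0,
) -> Trajectory:
    """Exact SSA realization of ``net`` from ``x0`` on [0, t_max].

    Waiting times are Exponential(a0(x)); the next reaction is chosen with
    probability a_k(x)/a0(x).  Terminates at ``t_max``, at absorption
    (a0 = 0), or at the ``max_events`` cap (flagged via ``capped``).
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if x0 is None:
        if net.initial_state is None:
            raise ValueError("no initial state supplied and network has no default")
        x0 = net.initial_state
    x0 = np.asarray(x0, dtype=np.int64)
    times, pre, ridx, t_end, absorbed, capped = _ssa_kernel(
        net.reactant_matrix,
        net.jump_matrix,
        net.rates,
        x0,
        float(t_max),
        int(max_events),
        int(seed) % (2**32),
    )
    return Trajectory(
        initial_state=x0,
        times=times,
        pre_states=pre,
        reaction_indices=ridx,
        jumps=net.jump_matrix[ridx] if len(ridx) else np.empty((0, net.s), np.int64),
        t_end=float(t_end),
        absorbed=bool(absorbed),
        capped=bool(capped),
        seed=int(seed),
        trajectory_id=trajectory_id,
    )


def derive_seed(master_seed: int, counter: int) -> int:
    """Counter-based per-trajectory seed derivation (reproducible ensembles)."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(counter),))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_ensemble(
    net: ReactionNetwork,
    x0: Sequence[int] | np.ndarray | None = None,
    t_max: float = 1.0,
    n_traj: int = 10,
    seed: int = 0,
    max_events: int = DEFAULT_MAX_EVENTS,
    accept: Callable[[Trajectory], bool] | None = None,
    max_retries: int = 1000,
) -> EventDataset:
    """Simulate ``n_traj`` independent trajectories and pool their events.

    Per-trajectory seeds are derived from ``seed`` with a counter, so the
    ensemble replays identically for a fixed master seed.  An optional
    ``accept`` predicate (e.g. :func:`large_outbreak` for epidemic networks)
    is applied by redrawing with fresh counters until ``n_traj`` trajectories
    are accepted; exceeding ``max_retries`` attempts raises ``RuntimeError``.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    kept: list[Trajectory] = []
    counter = 0
    attempts = 0
    while len(kept) < n_traj:
        if attempts >= max_retries + n_traj:
            raise RuntimeError(
                f"acceptance predicate not satisfied after {attempts} attempts"
            )
        tr = simulate(
            net, x0, t_max, seed=derive_seed(seed, counter),
            max_events=max_events, trajectory_id=len(kept),
        )
        counter += 1
        attempts += 1
        if accept is None or accept(tr):
            tr.trajectory_id = len(kept)
            kept.append(tr)
    return EventDataset.from_trajectories(kept, net.species)


def large_outbreak(net: ReactionNetwork, min_infections: int = 50) -> Callable[[Trajectory], bool]:
    """Acceptance predicate keeping trajectories with a sustained outbreak.

    Counts firings of the transmission reaction (jump lowering species 0 and
    raising species 1 by one) and requires more than ``min_infections``
    cumulative infections.
    """
    target = np.zeros(net.s, dtype=np.int64)
    target[0] = -1
    target[1] = 1
    k_inf = [k for k in range(net.m) if np.array_equal(net.jump_matrix[k], target)]
    if not k_inf:
        raise ValueError("network has no transmission-shaped reaction")
    k_inf = k_inf[0]

    def _accept(tr: Trajectory) -> bool:
        return int(np.sum(tr.reaction_indices == k_inf)) > min_infections

    return _accept


# ---------------------------------------------------------------------------
# CSV serialization
# ---------------------------------------------------------------------------

def write_events(ds: EventDataset, path: str | Path) -> None:
    """Write the event table as CSV (see module docstring for the layout).

    Times are written with 17 significant digits so float64 values
    round-trip exactly.
    """
    ds.frame.to_csv(path, index=False, float_format="%.17g")


def read_events(path: str | Path) -> EventDataset:
    """Read an event-table CSV, validating counts and jump feasibility."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if "trajectory_id" not in frame.columns:
        raise ValueError("event CSV missing the trajectory_id column")
    if "time" not in frame.columns:
        raise ValueError("event CSV missing the time column")
    x_cols = [c for c in frame.columns if c.startswith("x_")]
    d_cols = [c for c in frame.columns if c.startswith("d_")]
    species = [c[2:] for c in x_cols]
    if species != [c[2:] for c in d_cols] or not species:
        raise ValueError("event CSV must have matching x_<sp> and d_<sp> columns")
    for col in x_cols + d_cols:
        vals = frame[col]
        if not np.allclose(vals, np.round(vals)):
            raise ValueError(f"non-integer counts in column {col}")
        frame[col] = vals.astype(np.int64)
    x = frame[x_cols].to_numpy(np.int64)
    d = frame[d_cols].to_numpy(np.int64)
    bad = np.where((x < 0).any(axis=1))[0]
    if len(bad):
        raise ValueError(f"negative pre-jump count at row {bad[0]}")
    bad = np.where(((x + d) < 0).any(axis=1))[0]
    if len(bad):
        raise ValueError(f"infeasible jump (negative post-state) at row {bad[0]}")
    frame["trajectory_id"] = frame["trajectory_id"].astype(np.int64)
    return EventDataset(species=species, frame=frame)
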