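"""COVID-like synthetic outbreak generation from the stochastic SIR model.

Generates event-resolved epidemic data by exact SSA simulation of the
SIR-with-demography jump process at a chosen effective population size,
emitting the infection/removal indicator series visible to the inference
machinery together with the hidden (S, I, R) trajectory for validation.

The default truth (beta = 0.36, gamma = 0.28, rho = 1.2e-3, n = 3e4 over a
100-day window) emulates a metropolitan COVID-19 wave at Seoul scale: ~36
initially infectious individuals in an at-risk pool of thirty thousand, a
basic reproduction number near 1.29, and a mean infectious period of ~3.6
days (infection marks infectiousness onset, removal marks case confirmation
with immediate isolation; no incubation delay is modeled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crn_model import ReactionNetwork, build_network
from .epi_infer import Demography, EpiEventSeries, EpiTheta
from .ssa_sim import derive_seed, simulate

__all__ = [
    "OutbreakTruth",
    "generate_outbreak",
    "daily_prevalence",
    "sir_network",
]


@dataclass
class OutbreakTruth:
    """Ground-truth configuration for a synthetic outbreak."""

    theta: EpiTheta = field(default_factory=lambda: EpiTheta(0.36, 0.28, 1.2e-3))
    n: int = 30_000
    demog: Demography = field(default_factory=Demography)
    T: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("horizon T must be positive")
        if self.theta.rho * self.n < 1:
            raise ValueError("expected initial infected rho * n must be >= 1")

    @property
    def I0(self) -> int:
        return int(round(self.theta.rho * self.n))


def sir_network(truth: OutbreakTruth) -> ReactionNetwork:
    """SIR-with-demography jump network at the truth's scale.

    Transmission fires at rate (beta/n) S I, removal at (gamma + nu) I
    (recovery and demographic removal of infecteds share the -1 step in I
    and are merged into a single removal reaction), inflow of susceptibles
    at mu * n, and per-capita outflow of S and R at nu.
    """
    th, n, dg = truth.theta, truth.n, truth.demog
    nu = dg.nu(n)
    spec = {
        "species": ["S", "I", "R"],
        "reactions": [
            {"lhs": "S + I", "rhs": "2 I", "rate": th.beta / n, "name": "transmission"},
            {"lhs": "I", "rhs": "R", "rate": th.gamma + nu, "name": "removal"},
        ],
        "initial_state": [n - truth.I0, truth.I0, 0],
    }
    inflow = dg.inflow_absolute(n)
    if inflow > 0:
        spec["reactions"].append({"lhs": "0", "rhs": "S", "rate": inflow, "name": "inflow"})
    if nu > 0:
        spec["reactions"] += [
            {"lhs": "S", "rhs": "0", "rate": nu, "name": "S outflow"},
            {"lhs": "R", "rhs": "0", "rate": nu, "name": "R outflow"},
        ]
    return build_network(spec)


def generate_outbreak(
    truth: OutbreakTruth,
    require_extant: bool = True,
    max_retries: int = 100,
) -> tuple[EpiEventSeries, pd.DataFrame]:
    """Simulate one outbreak and split it into observed and latent parts.

    Returns the observed :class:`EpiEventSeries` (times and +1/-1 indicators
    of every change in the infected count) and the full latent trajectory as
    a DataFrame with columns ``time, S, I, R`` (post-event states, first row
    the initial state).

    With ``require_extant`` the draw is conditioned on the outbreak not
    going extinct before T/4 (redrawing with fresh sub-seeds up to
    ``max_retries`` times) so the dataset represents a sustained wave.
    """
    net = sir_network(truth)
    i_col = net.species.index("I")
    for attempt in range(max_retries):
        tr = simulate(
            net,
            t_max=truth.T,
            seed=derive_seed(truth.seed, attempt),
            max_events=5_000_000,
        )
        post = tr.pre_states + tr.jumps if tr.n_events else np.empty((0, net.s), np.int64)
        i_path = post[:, i_col]
        extinct_early = bool(np.any((i_path == 0) & (tr.times < truth.T / 4)))
        if not require_extant or not extinct_early:
            break
    else:
        raise RuntimeError(
            f"outbreak extinct before T/4 in all {max_retries} attempts")

    di = tr.jumps[:, i_col] if tr.n_events else np.empty(0, np.int64)
    obs = di != 0
    events = EpiEventSeries(
        times=tr.times[obs],
        y=(di[obs] == 1).astype(np.int64),
        I0=truth.I0,
        T=truth.T,
    )
    latent = pd.DataFrame(
        np.vstack([tr.initial_state, post]) if tr.n_events else tr.initial_state[None, :],
        columns=net.species,
    )
    latent.insert(0, "time", np.concatenate([[0.0], tr.times]) if tr.n_events else [0.0])
    return events, latent


def daily_prevalence(events: EpiEventSeries, day_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Sample the step-function prevalence at day boundaries.

    Returns a table of (day, prevalence) with the infected count at the end
    of each day (``I0`` at day 0).  Round-trips through
    :func:`crnlogit.epi_infer.events_from_prevalence` whenever at most one
    event falls in each day.
    """
    if day_grid is None:
        day_grid = np.arange(0.0, np.floor(events.T) + 1.0)
    day_grid = np.asarray(day_grid, dtype=np.float64)
    if events.n_events == 0:
        vals = np.full(day_grid.shape, events.I0, dtype=np.int64)
    else:
        prev = events.prevalence()
        idx = np.searchsorted(events.times, day_grid, side="right")
        vals = np.where(idx == 0, events.I0, prev[np.maximum(idx - 1, 0)])
    return pd.DataFrame({"day": day_grid, "prevalence": vals.astype(np.int64)})
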