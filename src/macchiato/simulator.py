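"""2-D reaction-diffusion simulation of morphogen-gradient logic devices.

The physical device is an agar plate: droplets of inducer (or sender
colonies) act as sources of a diffusible molecule, receiver colonies read
the local concentration through an engineered dose-response and express a
fluorescent reporter.  The concentration field obeys

    du/dt = D * laplacian(u) + sources

solved with an explicit finite-difference scheme on a regular grid (no-flux
or absorbing boundaries; the explicit stability bound dt <= h^2/(4 D) is
enforced).  The PDE is linear, so fields from individual sources
superpose — this is the physical mechanism that makes input contributions
additive on the signal-concentration axis, and it is exploited throughout:
each source is simulated once and input states are sums of single-source
fields.

Colonies grow logistically, read the local concentration at a fixed
commitment time (the experimentally observed "temporally static" response)
and accumulate fluorescence in proportion to biomass times the committed
dose-response.  Model forms and default parameters are documented
reconstructions, not fitted values: the tunables live in `DoseResponse`,
`ColonySpec` and `SimGrid`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .axis import ActivationFunction, apply_activation
from .logic import TruthTable

__all__ = [
    "SimGrid",
    "SourceSpec",
    "DoseResponse",
    "ColonySpec",
    "SimResult",
    "simulate_field",
    "single_source_snapshots",
    "colony_dynamics",
    "gate_map",
    "predict_gate",
    "DEFAULT_DROPLET_DOSE",
]

#: 1 uL droplet of 7.5 mM inducer = 7.5 nanomole deposited instantaneously.
DEFAULT_DROPLET_DOSE = 7.5


@dataclass(frozen=True)
class SimGrid:
    """Simulation domain and numerics.

    extent (mm), spacing h (mm), time step dt (h), diffusion coefficient D
    (mm^2/h), and the boundary condition.  Default domain is one well of a
    6-well plate (35 x 35 mm); D = 1.4 mm^2/h is a literature-order value
    for a small molecule in agar.
    """

    extent: tuple[float, float] = (35.0, 35.0)
    spacing: float = 0.25
    dt: float = 0.01
    D: float = 1.4
    boundary: str = "no-flux"
    decay_rate: float = 0.0  # 1/h; 0 = conserved molecule

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.boundary not in ("no-flux", "absorbing"):
            raise ValueError(f"unknown boundary {self.boundary!r}")
        limit = self.stability_limit()
        if self.dt > limit:
            raise ValueError(
                f"explicit scheme unstable: dt={self.dt:g} h exceeds "
                f"spacing^2/(4 D) = {limit:g} h; reduce dt"
            )
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")

    def stability_limit(self) -> float:
        return self.spacing**2 / (4.0 * self.D)

    @property
    def shape(self) -> tuple[int, int]:
        """(ny, nx) — rows are y."""
        nx = int(round(self.extent[0] / self.spacing)) + 1
        ny = int(round(self.extent[1] / self.spacing)) + 1
        return ny, nx

    def index_of(self, position: tuple[float, float]) -> tuple[int, int]:
        x, y = position
        if not (0 <= x <= self.extent[0] and 0 <= y <= self.extent[1]):
            raise ValueError(f"position {position} outside domain {self.extent}")
        return int(round(y / self.spacing)), int(round(x / self.spacing))

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.shape
        return np.arange(ny) * self.spacing, np.arange(nx) * self.spacing


@dataclass(frozen=True)
class SourceSpec:
    """A morphogen source: an inducer droplet or a sender colony.

    A droplet deposits ``dose`` (amount units, e.g. nmol) instantaneously at
    t = 0; a sender produces at ``production_rate`` (amount/h) for as long
    as its environmental input is present (``induced``).
    """

    position: tuple[float, float]
    kind: str = "droplet"
    dose: float = DEFAULT_DROPLET_DOSE
    production_rate: float = 0.0
    induced: bool = True

    def __post_init__(self):
        if self.kind not in ("droplet", "sender"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.dose < 0 or self.production_rate < 0:
            raise ValueError("dose and production_rate must be >= 0")


def _laplacian(u: np.ndarray, h: float, boundary: str) -> np.ndarray:
    if boundary == "no-flux":
        up = np.pad(u, 1, mode="edge")
    else:  # absorbing: zero just outside
        up = np.pad(u, 1, mode="constant")
    return (
        up[:-2, 1:-1] + up[2:, 1:-1] + up[1:-1, :-2] + up[1:-1, 2:] - 4.0 * u
    ) / h**2


def _deposit(grid: SimGrid, position: tuple[float, float], amount: float) -> np.ndarray:
    """Gaussian deposit of width one grid cell, normalized to ``amount``.

    Field units are amount per mm^2 (2-D surface concentration).
    """
    ny, nx = grid.shape
    iy, ix = grid.index_of(position)
    y = np.arange(ny)[:, None] - iy
    x = np.arange(nx)[None, :] - ix
    g = np.exp(-(x**2 + y**2) / 2.0)  # sigma = 1 cell
    u = g / (g.sum() * grid.spacing**2) * amount
    return u


def simulate_field(
    grid: SimGrid,
    sources: Sequence[SourceSpec],
    t_end: float,
    snapshot_times: Optional[Sequence[float]] = None,
) -> dict[float, np.ndarray]:
    """Explicit finite-difference solution of the diffusion equation.

    Returns ``{time: field}`` snapshots (always including ``t_end``), field
    units amount/mm^2.  With no-flux boundaries and droplet sources only,
    the integrated amount is conserved to solver tolerance.
    """
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    times = sorted(set([t_end] + list(snapshot_times or [])))
    u = np.zeros(grid.shape)
    for s in sources:
        if s.kind == "droplet":
            u += _deposit(grid, s.position, s.dose)
    senders = [s for s in sources if s.kind == "sender" and s.induced]
    sender_fields = [
        _deposit(grid, s.position, s.production_rate) for s in senders
    ]  # rate density, amount/mm^2/h
    snapshots: dict[float, np.ndarray] = {}
    t = 0.0
    it = iter(times)
    next_t = next(it)
    while True:
        while next_t is not None and t >= next_t - 1e-12:
            snapshots[next_t] = u.copy()
            next_t = next(it, None)
        if next_t is None:
            break
        step = min(grid.dt, next_t - t)
        du = grid.D * _laplacian(u, grid.spacing, grid.boundary)
        if grid.decay_rate:
            du = du - grid.decay_rate * u
        for f in sender_fields:
            du = du + f
        u = u + step * du
        np.maximum(u, 0.0, out=u)  # clip FP round-off; scheme is positive
        t += step
    return snapshots


def total_amount(grid: SimGrid, field_: np.ndarray) -> float:
    """Integrated amount over the domain."""
    return float(field_.sum() * grid.spacing**2)


def single_source_snapshots(
    grid: SimGrid,
    sources: Sequence[SourceSpec],
    times: Sequence[float],
) -> list[dict[float, np.ndarray]]:
    """One simulation per source alone; input states superpose these."""
    return [
        simulate_field(grid, [s], max(times), snapshot_times=times) for s in sources
    ]


# ---------------------------------------------------------------------------
# Colony response
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseResponse:
    """Steady-state expression rate versus inducer concentration.

    highpass: basal + v_max * u^n / (K^n + u^n)          (activating Hill)
    lowpass:  basal + v_max * K^n / (K^n + u^n)          (repressing Hill)
    bandpass: basal + v_max * act(u; K_act) * rep(u; K_rep), K_act < K_rep
              (activation cascade followed by repression at high dose,
              as in a T7-amplifier/repressor circuit)
    bandstop: basal + v_max * (1 - act * rep)

    Units: fluorescence is arbitrary; K's share the field's concentration
    unit (amount/mm^2).
    """

    kind: str = "highpass"
    basal: float = 0.01
    v_max: float = 1.0
    K_act: float = 0.02
    n_act: float = 4.0
    K_rep: Optional[float] = None
    n_rep: float = 4.0

    def __post_init__(self):
        if self.kind not in ("highpass", "lowpass", "bandpass", "bandstop"):
            raise ValueError(f"unknown dose-response kind {self.kind!r}")
        if not (self.v_max > self.basal >= 0):
            raise ValueError("need v_max > basal >= 0")
        if self.n_act <= 0 or self.n_rep <= 0:
            raise ValueError("Hill exponents must be > 0")
        if self.kind in ("bandpass", "bandstop"):
            if self.K_rep is None:
                raise ValueError(f"{self.kind} requires K_rep")
            if not self.K_act < self.K_rep:
                raise ValueError("bandpass/bandstop require K_act < K_rep")

    def rate(self, u) -> np.ndarray:
        """Expression rate at concentration(s) u."""
        u = np.asarray(u, dtype=float)
        act = u**self.n_act / (self.K_act**self.n_act + u**self.n_act)
        if self.kind == "highpass":
            shape = act
        elif self.kind == "lowpass":
            shape = 1.0 - act
        else:
            rep = self.K_rep**self.n_rep / (self.K_rep**self.n_rep + u**self.n_rep)
            band = act * rep
            shape = band if self.kind == "bandpass" else 1.0 - band
        return self.basal + (self.v_max - self.basal) * shape


@dataclass(frozen=True)
class ColonySpec:
    """A receiver colony: strain response + growth + commitment time.

    Growth is logistic (rate 1/h, OD-like capacity, lag h); the colony
    commits to the concentration it sees at ``commit_time`` (h) and holds
    that expression state, matching the observed temporally static rings.
    """

    position: tuple[float, float]
    response: DoseResponse
    growth_rate: float = 0.7
    capacity: float = 1.0
    lag: float = 2.0
    initial_biomass: float = 0.01
    commit_time: float = 6.0
    continuous_integration: bool = False

    def __post_init__(self):
        if min(self.growth_rate, self.capacity, self.lag, self.initial_biomass) <= 0:
            raise ValueError("growth parameters must be positive")
        if self.commit_time < 0:
            raise ValueError("commit_time must be >= 0")

    def biomass(self, t) -> np.ndarray:
        """Logistic growth with lag."""
        t = np.asarray(t, dtype=float)
        te = np.clip(t - self.lag, 0.0, None)
        b0, K, r = self.initial_biomass, self.capacity, self.growth_rate
        return K / (1.0 + (K / b0 - 1.0) * np.exp(-r * te))


def colony_dynamics(
    colony: ColonySpec,
    times: Sequence[float],
    concentrations: Sequence[float],
) -> np.ndarray:
    """Fluorescence trajectory of one colony given its local concentration.

    Fluorescence accumulates as biomass x dose-response of the committed
    concentration (held after ``commit_time``); with
    ``continuous_integration`` the instantaneous concentration is used
    throughout instead.  The trajectory is monotone non-decreasing.
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if times.shape != conc.shape:
        raise ValueError("times and concentrations must align")
    if times[0] > 0:
        raise ValueError("trajectory must start at t = 0")
    if colony.continuous_integration:
        u_eff = conc
    else:
        u_commit = float(np.interp(colony.commit_time, times, conc))
        u_eff = np.where(times < colony.commit_time, conc, u_commit)
    rate = colony.response.rate(u_eff) * colony.biomass(times)
    fl = np.concatenate(
        [[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(times))]
    )
    return fl


def committed_fold_change(colony: ColonySpec, u_commit: float) -> float:
    """Fold change in final fluorescence relative to the no-input condition.

    With identical growth across input states, the fluorescence ratio at
    read-out reduces to the ratio of committed expression rates.
    """
    return float(colony.response.rate(u_commit) / colony.response.rate(0.0))


# ---------------------------------------------------------------------------
# Gate maps and gate prediction
# ---------------------------------------------------------------------------


def _state_field(
    fields: Sequence[np.ndarray], state: int, n: int
) -> np.ndarray:
    """Superposed field for an input state (bit k of the state = input k,
    input A most significant)."""
    total = np.zeros_like(fields[0])
    for k in range(n):
        if (state >> (n - 1 - k)) & 1:
            total += fields[k]
    return total


def gate_map(
    grid: SimGrid,
    input_positions: Sequence[tuple[float, float]],
    act: ActivationFunction,
    t_read: float = 20.0,
    dose: float = DEFAULT_DROPLET_DOSE,
) -> np.ndarray:
    """Per-pixel gate codes for a lawn of receivers with one activation.

    Each input is simulated alone (droplet at t = 0), fields for the 2**n
    input states are superposed, thresholded by the activation function,
    and the per-pixel outputs are assembled into a hex gate code
    (state 0's output in the most significant bit).  Deterministic.
    """
    n = len(input_positions)
    if n < 1:
        raise ValueError("at least one input position required")
    singles = [
        simulate_field(
            grid, [SourceSpec(p, "droplet", dose=dose)], t_read
        )[t_read]
        for p in input_positions
    ]
    m = 2**n
    codes = np.zeros(grid.shape, dtype=np.int64)
    for state in range(m):
        u = _state_field(singles, state, n)
        if act.kind == "highpass":
            on = u > act.theta_lo
        elif act.kind == "lowpass":
            on = u < act.theta_lo
        else:
            band = (u > act.theta_lo) & (u < act.theta_hi)
            on = band if act.kind == "bandpass" else ~band
        codes |= on.astype(np.int64) << (m - 1 - state)
    return codes


def activity_threshold(kind: str, decision_ratio: float) -> float:
    """Fold-change level above which a receiver of this polarity reads ON.

    Activating strains (highpass/bandpass) are dim at zero input and read
    ON above ``decision_ratio``; inverting strains (lowpass/bandstop) are
    bright at zero input, so they read ON while their fold change stays
    above ``1/decision_ratio``.
    """
    if kind in ("highpass", "bandpass"):
        return decision_ratio
    return 1.0 / decision_ratio


@dataclass(frozen=True)
class SimResult:
    """Per-input-state prediction for a multi-receiver gate.

    ``fold_changes[state][r]`` is receiver r's fluorescence fold change
    (relative to the all-absent state, hence state 0 is identically 1).
    ``output[state]`` is the implicit-OR analog output on the *normalized
    activity* scale (fold change over the polarity-aware verdict
    threshold, so > 1 means ON): the max over the receivers designated ON
    there, or over all receivers in OFF states.  ``verdicts[state]`` is
    the digital read-out, and ``score`` is the least ON-state output
    divided by the largest OFF-state output — for a design built from
    activating strains this equals the classic least-fluorescent-ON over
    most-fluorescent-OFF fold-change ratio.
    """

    fold_changes: tuple[tuple[float, ...], ...]
    receiver_verdicts: tuple[tuple[int, ...], ...]
    output: tuple[float, ...]
    verdicts: tuple[int, ...]
    score: float
    truth_table: TruthTable


def predict_gate(
    grid: SimGrid,
    input_sources: Sequence[SourceSpec],
    colonies: Sequence[ColonySpec],
    designed_tables: Optional[Sequence[TruthTable]] = None,
    t_read: float = 20.0,
    decision_ratio: float = 1.5,
    field_cache: Optional[dict] = None,
) -> SimResult:
    """Simulate a gate layout over all input states and score it.

    Each source is simulated alone and committed concentrations are read
    from superposed fields at each colony's commit time.  A receiver is
    digitally ON when its fold change exceeds ``decision_ratio``; the gate
    output is the OR of receiver verdicts and the gate score is
    min(ON outputs) / max(OFF outputs) of the analog output values.

    ``designed_tables`` (the per-receiver induced tables of a design) steer
    the analog output: in a state where some receiver is *designed* ON the
    output is the max fold change among those receivers.  Without designs,
    the max over all receivers is used everywhere.
    """
    n = len(input_sources)
    if n < 1 or not colonies:
        raise ValueError("need at least one source and one colony")
    if designed_tables is not None and len(designed_tables) != len(colonies):
        raise ValueError("designed_tables must match colonies")
    commit_times = sorted({c.commit_time for c in colonies})
    singles = []
    for s in input_sources:
        key = (s.position, s.kind, s.dose, s.production_rate, tuple(commit_times))
        if field_cache is not None and key in field_cache:
            snaps = field_cache[key]
        else:
            snaps = simulate_field(
                grid, [replace(s, induced=True)], max(commit_times), commit_times
            )
            if field_cache is not None:
                field_cache[key] = snaps
        singles.append(snaps)
    m = 2**n
    fold = np.ones((m, len(colonies)))
    for state in range(1, m):
        for r, col in enumerate(colonies):
            iy, ix = grid.index_of(col.position)
            u = 0.0
            for k in range(n):
                if (state >> (n - 1 - k)) & 1:
                    u += float(singles[k][col.commit_time][iy, ix])
            fold[state, r] = committed_fold_change(col, u)
    thr = np.array(
        [activity_threshold(c.response.kind, decision_ratio) for c in colonies]
    )
    activity = fold / thr  # > 1 means digitally ON, any polarity
    rec_verdicts = (activity > 1.0).astype(int)
    outputs = []
    for state in range(m):
        if designed_tables is not None:
            on_idx = [
                r for r, t in enumerate(designed_tables) if t.outputs[state] == 1
            ]
        else:
            on_idx = []
        vals = activity[state, on_idx] if on_idx else activity[state, :]
        outputs.append(float(vals.max()))
    verdicts = tuple(int(rec_verdicts[s].max()) for s in range(m))
    tt = TruthTable(n, verdicts, label="simulated")
    if designed_tables is not None:
        target_on = [s for s in range(m) if any(
            t.outputs[s] == 1 for t in designed_tables)]
    else:
        target_on = [s for s in range(m) if verdicts[s] == 1]
    on_vals = [outputs[s] for s in target_on]
    off_vals = [outputs[s] for s in range(m) if s not in target_on]
    if not off_vals:
        score = float("inf")
    elif not on_vals:
        score = 0.0
    else:
        score = min(on_vals) / max(off_vals)
    return SimResult(
        fold_changes=tuple(tuple(row) for row in fold),
        receiver_verdicts=tuple(tuple(r) for r in rec_verdicts),
        output=tuple(outputs),
        verdicts=verdicts,
        score=score,
        truth_table=tt,
    )
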